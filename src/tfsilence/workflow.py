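"""End-to-end orchestration of the analysis stages.

Stage 1 (compendium): quantile-normalize the array expression matrix and,
per tissue, score bivalent/PRC2-marked TFs for upregulation relative to
the stem-cell ground state with the moderated t.

Stage 2 (per cancer type): log2-regularize the tumour cohort counts,
score cancer-versus-normal differential expression, match a control set
of non-housekeeping genes to the tissue's TFs on normal-adjacent
expression, and test preferential TF silencing with a one-tailed
rank-sum test.

Stage 3 (per cancer type): promoter methylation assignment, Z-score
underexpression calls, alteration calls per channel, per-TF mechanism
frequencies, exclusivity analyses, and the cross-cancer Fisher
meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import integrative, preprocess, tf_pipeline
from .gene_dnam import assign_promoter_dnam
from .stats import combine_fisher, moderated_t_table
from .synthetic_cohort import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "CancerResult", "run_pipeline"]


@dataclass
class CancerResult:
    name: str
    tissue: str
    expr_diff: pd.DataFrame  # tumour vs normal moderated-t table
    dnam_diff: pd.DataFrame  # promoter beta tumour vs normal table
    silenced_tfs: set[str]  # up in tissue and significantly down in cancer
    all_under: set[str]  # all genes significantly down in cancer
    control_genes: set[str]
    p_silencing_vs_control: float
    p_cgi_enrichment: float
    qc_flagged: bool
    calls: integrative.AlterationCalls
    frequencies: pd.DataFrame  # mechanism frequencies of the silenced TFs
    channel_p: dict[str, float]  # p_dnam, p_cnv, p_mut vs underexpressed
    expected_hyper: dict[str, float]
    tertile_p: dict[str, float]
    per_tf_excl: pd.DataFrame


@dataclass
class PipelineResult:
    selections: dict[str, tf_pipeline.TFSelection]
    exclusive: dict[str, set[str]]
    cancers: dict[str, CancerResult]
    meta: pd.Series = field(default_factory=pd.Series)  # combined channel p
    meta_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    tertile_combined: dict[str, float] = field(default_factory=dict)
    concordance: pd.DataFrame = field(default_factory=pd.DataFrame)
    concordance_p: float = float("nan")

    def detected(self) -> dict[str, set[str]]:
        return {n: r.silenced_tfs for n, r in self.cancers.items()}

    def mechanism_classes(self) -> dict[str, pd.Series]:
        return {n: r.frequencies["mechanism_class"]
                for n, r in self.cancers.items()}

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.meta_table.to_csv(out / "meta_table.tsv", sep="\t",
                               index_label="cancer")
        self.meta.to_frame("p_combined").to_csv(out / "meta_combined.tsv",
                                                sep="\t", index_label="channel")
        self.concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)
        for name, r in self.cancers.items():
            cdir = out / name
            cdir.mkdir(exist_ok=True)
            r.expr_diff.to_csv(cdir / "expr_diff.tsv", sep="\t",
                               index_label="gene")
            r.dnam_diff.to_csv(cdir / "dnam_diff.tsv", sep="\t",
                               index_label="gene")
            r.frequencies.to_csv(cdir / "mechanism_frequencies.tsv", sep="\t")
            r.per_tf_excl.to_csv(cdir / "per_tf_exclusivity.tsv", sep="\t")
            pd.Series(sorted(r.silenced_tfs)).to_csv(
                cdir / "silenced_tfs.txt", index=False, header=False)


def run_pipeline(cohort: SyntheticCohort, alpha: float = 0.05,
                 z_threshold: float = integrative.Z_THRESHOLD,
                 cnv_threshold: float = integrative.CNV_LOSS_THRESHOLD,
                 beta_threshold: float = integrative.DELTA_BETA_THRESHOLD,
                 beta_relaxed: float = integrative.DELTA_BETA_RELAXED,
                 n_null_draws: int = 500,
                 seed: int = 0) -> PipelineResult:
    """Run all stages on an in-memory cohort and return every result table.

    ``seed`` drives the random-gene draws of the null comparisons only;
    all other computation is deterministic.
    """
    gl = cohort.gene_lists
    candidates = gl.candidate_tfs

    # --- stage 1: upregulated TFs per tissue ---------------------------
    scm = preprocess.quantile_normalize(cohort.scm_expr)
    hesc_cols = list(cohort.scm_pheno.index[cohort.scm_pheno == "hESC"])
    selections: dict[str, tf_pipeline.TFSelection] = {}
    for tissue in cohort.tissues:
        cols = list(cohort.scm_tissue.index[
            (cohort.scm_tissue == tissue)
            & (cohort.scm_pheno != "hESC")])
        diff = moderated_t_table(scm, cols, hesc_cols)
        selections[tissue] = tf_pipeline.identify_up_tfs(
            diff, candidates, tissue, alpha=alpha)
    exclusive = tf_pipeline.exclusive_sets(list(selections.values()))

    # --- stages 2 and 3 per cancer type --------------------------------
    results: dict[str, CancerResult] = {}
    freq_tables: dict[str, pd.DataFrame] = {}
    for cname, cohort_c in cohort.cancers.items():
        tissue = cohort_c.tissue
        up_tfs = selections[tissue].up_tfs

        expr = preprocess.log2_regularize(cohort_c.counts)
        normal_cols = cohort_c.normal_samples
        tumour_cols = cohort_c.tumour_samples
        qc = preprocess.svd_qc(expr, cohort_c.sample_pheno, alpha=alpha)
        if qc.flagged:
            logger.warning("%s: top component of variation does not track "
                           "normal/tumour status", cname)
        expr_diff = moderated_t_table(expr, tumour_cols, normal_cols)

        sig_down = expr_diff.index[(expr_diff["p_adj"] < alpha)
                                   & (expr_diff["t_mod"] < 0)]
        all_under = set(sig_down)
        silenced = up_tfs & all_under

        # control genes matched on normal-adjacent expression; the TF set
        # for the control comparison additionally requires expression in
        # normal tissue (above the cohort median)
        normal_expr = expr[normal_cols]
        median_expr = float(normal_expr.mean(axis=1).median())
        expressed_tfs = {g for g in up_tfs
                         if g in normal_expr.index
                         and normal_expr.loc[g].mean() > median_expr}
        # exclude every TF (not just this tissue's) and all housekeeping
        # genes from the candidate pool
        control = tf_pipeline.match_control_genes(
            expressed_tfs, normal_expr,
            gl.housekeeping_genes | (gl.tf_genes - expressed_tfs))
        p_sil = tf_pipeline.test_preferential_silencing(
            expr_diff, expressed_tfs, control.genes)
        p_cgi = tf_pipeline.cgi_enrichment(
            silenced or up_tfs, set(expr.index) - up_tfs, gl.cgi_genes)

        # promoter methylation
        gene_meth = assign_promoter_dnam(cohort_c.probe_betas, cohort.manifest)
        beta = gene_meth.values
        dnam_diff = moderated_t_table(beta, tumour_cols, normal_cols)

        # alteration calls
        z = integrative.compute_zscores(expr[tumour_cols], normal_expr)
        segval = integrative.map_segments_to_genes(cohort_c.segments,
                                                   cohort.coords)
        calls = integrative.build_alteration_calls(
            z, segval, beta[tumour_cols], beta[normal_cols],
            cohort_c.mutations, z_threshold, cnv_threshold,
            beta_threshold, beta_relaxed)

        freqs = integrative.mechanism_frequencies(calls,
                                                  genes=sorted(silenced))
        freq_tables[cname] = freqs

        mean_segval = calls.segval.mean(axis=1)
        mut_freq = calls.mutated.mean(axis=1)
        channel_p = integrative.compare_silenced_vs_underexpressed(
            dnam_diff["t_mod"], mean_segval, mut_freq,
            silenced & all_under, all_under)

        expected = integrative.expected_counts_null(
            calls, all_under, silenced, n_draws=n_null_draws, seed=seed)
        try:
            tertile_p = integrative.tertile_exclusivity(freqs)
        except ValueError:
            tertile_p = {"p_hyper_in_low_loss": float("nan"),
                         "p_loss_in_low_hyper": float("nan")}
        under_silenced = calls.underexpressed.loc[
            [g for g in sorted(silenced) if g in calls.underexpressed.index]]
        per_tf = integrative.per_tf_exclusivity(
            integrative.AlterationCalls(
                underexpressed=under_silenced,
                cnv_loss=calls.cnv_loss, hypermeth=calls.hypermeth,
                hypermeth_relaxed=calls.hypermeth_relaxed,
                mutated=calls.mutated, delta_beta=calls.delta_beta,
                segval=calls.segval))

        results[cname] = CancerResult(
            name=cname, tissue=tissue, expr_diff=expr_diff,
            dnam_diff=dnam_diff, silenced_tfs=silenced, all_under=all_under,
            control_genes=control.genes, p_silencing_vs_control=p_sil,
            p_cgi_enrichment=p_cgi, qc_flagged=qc.flagged, calls=calls,
            frequencies=freqs, channel_p=channel_p, expected_hyper=expected,
            tertile_p=tertile_p, per_tf_excl=per_tf)

    # --- meta-analysis over cancer types -------------------------------
    meta_table = pd.DataFrame(
        {n: r.channel_p for n, r in results.items()}).T
    meta = integrative.meta_combine(meta_table)
    tertile_combined = {}
    for key in ("p_hyper_in_low_loss", "p_loss_in_low_hyper"):
        ps = [r.tertile_p[key] for r in results.values()
              if np.isfinite(r.tertile_p[key])]
        tertile_combined[key] = combine_fisher(ps) if len(ps) >= 2 else float("nan")
    concordance, conc_p = integrative.cross_cancer_concordance(freq_tables)

    return PipelineResult(
        selections=selections, exclusive=exclusive, cancers=results,
        meta=meta, meta_table=meta_table, tertile_combined=tertile_combined,
        concordance=concordance, concordance_p=conc_p)
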