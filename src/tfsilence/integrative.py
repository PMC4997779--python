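"""Per-tumour silencing calls and mechanism attribution.

For each TF and tumour, expression is standardised against the matched
normal samples (Z = (X - mu)/sigma) and the TF is called underexpressed
when Z < -2.  Among the underexpressed tumours, three in-cis alteration
channels are scored: copy-number loss (segment value < -0.35), promoter
hypermethylation (tumour beta minus mean normal beta > 0.3; a relaxed 0.1
regime is kept alongside for exclusivity analyses), and inactivating
mutation (any nonsense/missense/deletion record).  Per-TF mechanism
frequencies, mutual-exclusivity statistics and the cross-cancer
meta-analysis are built on top of those calls.

All thresholds use strict inequalities: a value exactly at a threshold
never produces a call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import (
    INACTIVATING_CLASSES,
    GeneCoordinates,
    MutationRecord,
    SegmentRecord,
)
from .stats import combine_fisher, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "MechanismClass",
    "ZScoreMatrix",
    "AlterationCalls",
    "compute_zscores",
    "call_underexpression",
    "map_segments_to_genes",
    "call_cnv_loss",
    "call_hypermethylation",
    "call_inactivating_mutation",
    "build_alteration_calls",
    "mechanism_frequencies",
    "compare_silenced_vs_underexpressed",
    "meta_combine",
    "expected_counts_null",
    "tertile_exclusivity",
    "per_tf_exclusivity",
    "cross_cancer_concordance",
]

Z_THRESHOLD = -2.0
CNV_LOSS_THRESHOLD = -0.35
DELTA_BETA_THRESHOLD = 0.3
DELTA_BETA_RELAXED = 0.1


class MechanismClass(str, Enum):
    DNAmDominant = "DNAmDominant"
    CNVDominant = "CNVDominant"
    Both = "Both"
    Neither = "Neither"


@dataclass
class ZScoreMatrix:
    z: pd.DataFrame  # TF x tumour
    mu: pd.Series  # per-TF normal mean
    sigma: pd.Series  # per-TF normal sd (n-1 denominator)


@dataclass
class AlterationCalls:
    """Boolean call matrices (genes x tumours) plus the underlying data.

    Missing underlying data yields NaN in the float matrices and leaves the
    corresponding call undefined (False with the datum NaN); frequency
    denominators count only non-missing cells.
    """

    underexpressed: pd.DataFrame
    cnv_loss: pd.DataFrame
    hypermeth: pd.DataFrame
    hypermeth_relaxed: pd.DataFrame
    mutated: pd.DataFrame
    delta_beta: pd.DataFrame
    segval: pd.DataFrame


def compute_zscores(tumour_expr: pd.DataFrame,
                    normal_expr: pd.DataFrame) -> ZScoreMatrix:
    """Standardise each gene's tumour expression against its normal
    reference distribution.

    mu and sigma are the mean and (n-1) standard deviation over the normal
    samples.  Genes with sigma = 0 are dropped with a logged count.
    """
    if normal_expr.shape[1] < 3:
        raise ValueError("compute_zscores needs >=3 normal samples")
    common = tumour_expr.index.intersection(normal_expr.index)
    tumour = tumour_expr.loc[common]
    normal = normal_expr.loc[common]
    mu = normal.mean(axis=1)
    sigma = normal.std(axis=1, ddof=1)
    keep = sigma > 0
    if (~keep).any():
        logger.info("compute_zscores: dropped %d genes with sigma = 0",
                    int((~keep).sum()))
    z = tumour.loc[keep].sub(mu[keep], axis=0).div(sigma[keep], axis=0)
    return ZScoreMatrix(z=z, mu=mu[keep], sigma=sigma[keep])


def call_underexpression(z: pd.DataFrame,
                         threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Strict call: underexpressed iff Z < threshold."""
    return z < threshold


def map_segments_to_genes(segments: list[SegmentRecord],
                          coords: list[GeneCoordinates]) -> pd.DataFrame:
    """Assign each gene, per sample, the value of the copy-number segment
    overlapping it the most.

    Ties go to the segment with the smaller start; a gene with no
    overlapping segment in a sample is missing (NaN).
    """
    samples = sorted({s.sample_id for s in segments})
    genes = [c.gene_id for c in coords]
    out = pd.DataFrame(np.nan, index=genes, columns=samples)
    by_sample_chrom: dict[tuple[str, str], list[SegmentRecord]] = {}
    for s in segments:
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append(s)
    for c in coords:
        for sample in samples:
            segs = by_sample_chrom.get((sample, c.chrom))
            if not segs:
                continue
            best = None  # (overlap, -start) maximised
            for s in segs:
                overlap = min(c.end, s.end) - max(c.start, s.start)
                if overlap <= 0:
                    continue
                key = (overlap, -s.start)
                if best is None or key > best[0]:
                    best = (key, s.segval)
            if best is not None:
                out.at[c.gene_id, sample] = best[1]
    return out


def call_cnv_loss(segval: pd.DataFrame | float,
                  threshold: float = CNV_LOSS_THRESHOLD):
    """Strict call: genomic loss iff segment value < threshold.

    Missing segment values never produce a call.
    """
    if isinstance(segval, pd.DataFrame):
        return segval < threshold
    return bool(segval < threshold) if pd.notna(segval) else False


def call_hypermethylation(tumour_beta: pd.DataFrame,
                          normal_betas: pd.DataFrame,
                          threshold: float = DELTA_BETA_THRESHOLD,
                          relaxed: float = DELTA_BETA_RELAXED
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Promoter hypermethylation calls from the tumour-minus-mean-normal
    beta difference.

    Returns (strict call, relaxed call, delta_beta).  Both calls use strict
    '>' comparisons; missing promoter values never produce a call.
    """
    common = tumour_beta.index.intersection(normal_betas.index)
    normal_mean = normal_betas.loc[common].mean(axis=1)
    delta = tumour_beta.loc[common].sub(normal_mean, axis=0)
    return delta > threshold, delta > relaxed, delta


def call_inactivating_mutation(records: list[MutationRecord],
                               genes: list[str],
                               samples: list[str]) -> pd.DataFrame:
    """Boolean gene x sample matrix: any nonsense/missense/deletion record.

    Multiple inactivating mutations in the same gene and sample count once.
    """
    out = pd.DataFrame(False, index=genes, columns=samples)
    gene_set, sample_set = set(genes), set(samples)
    for r in records:
        if (r.variant_class in INACTIVATING_CLASSES
                and r.gene_id in gene_set and r.sample_id in sample_set):
            out.at[r.gene_id, r.sample_id] = True
    return out


def build_alteration_calls(z: ZScoreMatrix,
                           segval: pd.DataFrame,
                           tumour_beta: pd.DataFrame,
                           normal_betas: pd.DataFrame,
                           mutations: list[MutationRecord],
                           z_threshold: float = Z_THRESHOLD,
                           cnv_threshold: float = CNV_LOSS_THRESHOLD,
                           beta_threshold: float = DELTA_BETA_THRESHOLD,
                           beta_relaxed: float = DELTA_BETA_RELAXED
                           ) -> AlterationCalls:
    """Assemble all per-(gene, tumour) call matrices on a common index."""
    tumours = list(z.z.columns)
    genes = list(z.z.index)
    under = call_underexpression(z.z, z_threshold)
    seg = segval.reindex(index=genes, columns=tumours)
    hyper, hyper_rel, delta = call_hypermethylation(
        tumour_beta.reindex(columns=tumours), normal_betas,
        beta_threshold, beta_relaxed)
    delta = delta.reindex(index=genes, columns=tumours)
    mut = call_inactivating_mutation(mutations, genes, tumours)
    return AlterationCalls(
        underexpressed=under,
        cnv_loss=seg < cnv_threshold,
        hypermeth=delta > beta_threshold,
        hypermeth_relaxed=delta > beta_relaxed,
        mutated=mut,
        delta_beta=delta,
        segval=seg,
    )


def mechanism_frequencies(calls: AlterationCalls,
                          genes: list[str] | None = None,
                          dominant_cutoff: float = 0.2,
                          minor_cutoff: float = 0.1) -> pd.DataFrame:
    """Per-TF alteration frequencies over that TF's underexpressed tumours.

    For each gene with at least one underexpressed tumour, f_loss, f_hyper
    and f_mut are the fractions of its underexpressed tumours carrying the
    respective call, each computed over tumours with non-missing data for
    that channel.  The mechanism class is assigned from the frequencies:
    DNAm-dominant when f_hyper >= dominant_cutoff and f_loss < minor_cutoff,
    CNV-dominant symmetrically, Both when both reach the dominant cutoff,
    Neither otherwise.
    """
    if genes is None:
        genes = list(calls.underexpressed.index)
    rows = []
    skipped = 0
    for g in genes:
        if g not in calls.underexpressed.index:
            continue
        under = calls.underexpressed.loc[g]
        n_under = int(under.sum())
        if n_under == 0:
            skipped += 1
            continue
        idx = under[under].index

        def _freq(call_m: pd.DataFrame, data_m: pd.DataFrame) -> tuple[float, int]:
            ok = data_m.loc[g, idx].notna()
            n = int(ok.sum())
            if n == 0:
                return np.nan, 0
            return float(call_m.loc[g, idx][ok].mean()), n

        f_loss, n_loss = _freq(calls.cnv_loss, calls.segval)
        f_hyper, n_hyper = _freq(calls.hypermeth, calls.delta_beta)
        f_hyper_rel, _ = _freq(calls.hypermeth_relaxed, calls.delta_beta)
        # mutation data is complete by construction (absence = no mutation)
        f_mut = float(calls.mutated.loc[g, idx].mean())
        fh = 0.0 if np.isnan(f_hyper) else f_hyper
        fl = 0.0 if np.isnan(f_loss) else f_loss
        if fh >= dominant_cutoff and fl >= dominant_cutoff:
            mech = MechanismClass.Both
        elif fh >= dominant_cutoff and fl < minor_cutoff:
            mech = MechanismClass.DNAmDominant
        elif fl >= dominant_cutoff and fh < minor_cutoff:
            mech = MechanismClass.CNVDominant
        else:
            mech = MechanismClass.Neither
        rows.append((g, n_under, f_loss, f_hyper, f_hyper_rel, f_mut,
                     n_loss, n_hyper, mech.value))
    if skipped:
        logger.info("mechanism_frequencies: %d genes never underexpressed",
                    skipped)
    return pd.DataFrame(
        rows, columns=["gene", "n_under", "f_loss", "f_hyper",
                       "f_hyper_relaxed", "f_mut", "n_loss_data",
                       "n_hyper_data", "mechanism_class"],
    ).set_index("gene")


def compare_silenced_vs_underexpressed(dnam_t: pd.Series,
                                       mean_segval: pd.Series,
                                       mut_freq: pd.Series,
                                       silenced_tfs: set[str],
                                       all_under: set[str]) -> dict[str, float]:
    """Rank-sum p per channel: are the silenced TFs more altered than the
    other underexpressed genes?

    Channel statistics are per gene: differential-methylation moderated t
    (TFs greater), mean copy-number segment value (TFs smaller, i.e. more
    loss), and fraction of tumours with an inactivating mutation (TFs
    greater).  Genes missing a channel's statistic are excluded from that
    channel only.
    """
    if not silenced_tfs <= all_under:
        raise ValueError("silenced TFs must be a subset of underexpressed genes")
    background = all_under - silenced_tfs
    out = {}
    for name, stat, alternative in (
        ("p_dnam", dnam_t, "greater"),
        ("p_cnv", mean_segval, "less"),
        ("p_mut", mut_freq, "greater"),
    ):
        tf_vals = stat.reindex(sorted(silenced_tfs)).dropna().to_numpy()
        bg_vals = stat.reindex(sorted(background)).dropna().to_numpy()
        if tf_vals.size == 0 or bg_vals.size == 0:
            out[name] = np.nan
            continue
        out[name] = rank_sum_test(tf_vals, bg_vals, alternative=alternative)
    return out


def meta_combine(per_cancer: pd.DataFrame) -> pd.Series:
    """Fisher-combine each channel's per-cancer p-values into one row.

    ``per_cancer`` has cancers as rows and channels (p_dnam, p_cnv, p_mut)
    as columns.
    """
    if per_cancer.shape[0] < 2:
        raise ValueError("meta_combine needs >=2 cancer types")
    return per_cancer.apply(lambda col: combine_fisher(col.dropna().tolist()))


def expected_counts_null(calls: AlterationCalls, all_under: set[str],
                         silenced_tfs: set[str], n_draws: int = 1000,
                         seed: int = 0) -> dict[str, float]:
    """Observed hypermethylation-event count of the TF set versus the null
    of drawing equally many genes from all underexpressed genes.

    An event is one (gene, tumour) pair where the gene is underexpressed
    and hypermethylated.  Returns the observed count, the null mean and a
    95% interval over ``n_draws`` seeded draws without replacement.
    """
    rng = np.random.default_rng(seed)
    events = (calls.underexpressed & calls.hypermeth)
    per_gene = events.sum(axis=1)
    pool = sorted(all_under)
    k = len(silenced_tfs & set(pool))
    observed = int(per_gene.reindex(sorted(silenced_tfs)).fillna(0).sum())
    counts = np.empty(n_draws)
    pool_counts = per_gene.reindex(pool).fillna(0).to_numpy()
    for i in range(n_draws):
        idx = rng.choice(len(pool), size=k, replace=False)
        counts[i] = pool_counts[idx].sum()
    lo, hi = np.percentile(counts, [2.5, 97.5])
    result = {
        "observed": float(observed),
        "expected_mean": float(counts.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_draws": n_draws,
    }
    if n_draws < 2:
        result["degenerate"] = True
        logger.warning("expected_counts_null: n_draws=%d gives a degenerate "
                       "interval", n_draws)
    return result


def _tertiles(ranked: pd.DataFrame, by: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split by rank on ``by`` into lowest and top tertiles, keeping ties in
    the same tertile (a tied value never straddles the boundary)."""
    s = ranked.sort_values(by, kind="mergesort")
    n = len(s)
    third = n // 3
    lo_cut = s[by].iloc[third - 1]
    hi_cut = s[by].iloc[n - third]
    low = s[s[by] <= lo_cut]
    top = s[s[by] >= hi_cut]
    return low, top


def tertile_exclusivity(freqs: pd.DataFrame) -> dict[str, float]:
    """Mutual-exclusivity test across TFs at the frequency level.

    Ranks TFs by CNV-loss frequency and asks (one-tailed rank-sum) whether
    hypermethylation frequency is higher in the lowest than the top
    tertile; and the reverse (rank by f_hyper, compare f_loss).
    """
    usable = freqs.dropna(subset=["f_loss", "f_hyper"])
    if len(usable) < 6:
        raise ValueError("tertile_exclusivity needs >=6 TFs")
    out = {}
    for by, compare, key in (("f_loss", "f_hyper", "p_hyper_in_low_loss"),
                             ("f_hyper", "f_loss", "p_loss_in_low_hyper")):
        low, top = _tertiles(usable, by)
        out[key] = rank_sum_test(low[compare].to_numpy(),
                                 top[compare].to_numpy(),
                                 alternative="greater")
    return out


def per_tf_exclusivity(calls: AlterationCalls, min_freq: float = 0.01
                       ) -> pd.DataFrame:
    """Within-TF mutual exclusivity of hypermethylation and CNV loss.

    For each gene with at least ``min_freq`` frequency of both CNV loss and
    relaxed (delta beta > 0.1) hypermethylation among its underexpressed
    tumours, tests (one-tailed rank-sum) whether delta beta is higher in
    the no-loss than in the loss tumours.  Genes with an empty group are
    logged and skipped.
    """
    rows = []
    for g in calls.underexpressed.index:
        under = calls.underexpressed.loc[g]
        idx = under[under].index
        if len(idx) == 0:
            continue
        seg = calls.segval.loc[g, idx]
        delta = calls.delta_beta.loc[g, idx]
        ok = seg.notna() & delta.notna()
        idx = idx[ok]
        if len(idx) == 0:
            continue
        loss = calls.cnv_loss.loc[g, idx]
        hyper_rel = calls.hypermeth_relaxed.loc[g, idx]
        f_loss = float(loss.mean())
        f_hyper_rel = float(hyper_rel.mean())
        if f_loss < min_freq or f_hyper_rel < min_freq:
            continue
        no_loss_idx = idx[~loss]
        loss_idx = idx[loss]
        if len(no_loss_idx) == 0 or len(loss_idx) == 0:
            logger.info("per_tf_exclusivity: %s has an empty group", g)
            continue
        p = rank_sum_test(calls.delta_beta.loc[g, no_loss_idx].to_numpy(),
                          calls.delta_beta.loc[g, loss_idx].to_numpy(),
                          alternative="greater")
        rows.append((g, len(idx), f_loss, f_hyper_rel, p))
    return pd.DataFrame(
        rows, columns=["gene", "n_under", "f_loss", "f_hyper_relaxed", "p"],
    ).set_index("gene")


def cross_cancer_concordance(freq_tables: dict[str, pd.DataFrame],
                             min_shared: int = 3) -> tuple[pd.DataFrame, float]:
    """Between-cancer concordance of per-TF mechanism frequencies.

    For every pair of cancer types, computes the squared Pearson
    correlation of hypermethylation and of CNV-loss frequencies over the
    TFs silenced in both.  The aggregate is a one-tailed paired signed-rank
    p that the hypermethylation R^2 exceeds the CNV R^2 across pairs.
    Pairs with a zero-variance frequency vector are skipped for that
    channel (logged).
    """
    names = sorted(freq_tables)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = freq_tables[a].index.intersection(freq_tables[b].index)
            if len(shared) < min_shared:
                continue
            r2 = {}
            for channel in ("f_hyper", "f_loss"):
                x = freq_tables[a].loc[shared, channel].to_numpy(dtype=float)
                y = freq_tables[b].loc[shared, channel].to_numpy(dtype=float)
                ok = ~(np.isnan(x) | np.isnan(y))
                x, y = x[ok], y[ok]
                if x.size < min_shared or np.std(x) == 0 or np.std(y) == 0:
                    logger.info("cross_cancer_concordance: skipping %s for "
                                "%s-%s (degenerate)", channel, a, b)
                    r2[channel] = np.nan
                    continue
                r2[channel] = float(np.corrcoef(x, y)[0, 1] ** 2)
            rows.append((a, b, len(shared), r2["f_hyper"], r2["f_loss"]))
    table = pd.DataFrame(rows, columns=["cancer_a", "cancer_b", "n_shared",
                                        "r2_dnam", "r2_cnv"])
    paired = table.dropna(subset=["r2_dnam", "r2_cnv"])
    if len(paired) >= 2 and not np.allclose(paired["r2_dnam"],
                                            paired["r2_cnv"]):
        stat = sps.wilcoxon(paired["r2_dnam"], paired["r2_cnv"],
                            alternative="greater")
        p = float(stat.pvalue)
    else:
        p = np.nan
    return table, p
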