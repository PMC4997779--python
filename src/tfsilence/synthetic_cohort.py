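"""Seeded generator of a full multi-omic study with planted ground truth.

The cohort emulates the statistical structure the pipeline assumes: an
array-style expression compendium of embryonic stem cells plus normal
tissues in which developmental TFs are upregulated; matched tumour cohorts
(counts, promoter probe betas, copy-number segments, somatic mutations)
in which a subset of those TFs is silenced, with the silencing planted
through promoter hypermethylation, focal copy-number loss, an exclusive
mixture of the two, an inactivating mutation, or no in-cis event at all.
Background (non-TF) genes are also silenced in each tumour cohort, with
copy-number loss and mutation at least as common as among the TFs and
hypermethylation much rarer — the regime in which the epigenetic channel,
and only that channel, should stand out in the meta-analysis.

Copy-number planting is deliberately less reproducible across cancer types
than methylation planting (per-cancer loss fractions are drawn afresh),
mimicking the cancer-type-specific character of genomic instability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    GeneCoordinates,
    GeneListSet,
    MutationRecord,
    ProbeAnnotation,
    RegionGroup,
    SegmentRecord,
    VariantClass,
    write_bed,
    write_gene_list,
    write_matrix,
    write_mutations,
    write_probe_manifest,
    write_seg,
    read_matrix,
    read_bed,
    read_gene_list,
    read_mutations,
    read_probe_manifest,
    read_seg,
)

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "CancerCohort",
    "SyntheticCohort",
    "generate_cohort",
    "load_cohort",
    "truth_confusion",
]

#: planted silencing mechanisms
MECHANISMS = ("DNAm", "CNV", "Both", "Neither", "Mutation")


@dataclass
class CohortConfig:
    """Knobs of the synthetic study; defaults define the study conditions.

    Effect sizes are on the scales of the corresponding data: log2
    expression units, beta units, normalised segment values.
    """

    seed: int = 1
    n_genes: int = 2000
    n_tfs: int = 200
    n_housekeeping: int = 150
    n_tissues: int = 4
    #: cancer types per tissue (two lung-like, two kidney-like, one each)
    cancers_per_tissue: tuple[int, ...] = (2, 2, 1, 1)
    n_hesc: int = 20
    n_normal_tissue: int = 4  # compendium normals per tissue
    n_normal_adjacent: int = 20  # per cancer cohort
    n_tumour: int = 60  # per cancer cohort

    p_developmental: float = 0.6  # fraction of TFs that are developmental
    p_tissue_membership: float = 0.55  # P(dev TF is up in a given tissue)
    frac_silenced_tfs: float = 0.55  # fraction of developmental TFs silenced
    silenced_tumour_frac: float = 0.6  # fraction of tumours with the drop
    mechanism_mix: dict[str, float] = field(default_factory=lambda: {
        "DNAm": 0.5, "CNV": 0.25, "Both": 0.125, "Neither": 0.125,
        "Mutation": 0.0,
    })
    both_exclusive: bool = True  # Both-TFs: disjoint DNAm/CNV tumour halves

    # background (non-TF) silenced genes per cancer
    bg_silenced_frac: float = 0.15
    bg_mechanism_mix: dict[str, float] = field(default_factory=lambda: {
        "DNAm": 0.05, "CNV": 0.55, "Mutation": 0.10, "Neither": 0.30,
    })

    # effect sizes
    tf_up_log2: float = 2.0
    silencing_log2: float = 1.5
    delta_beta_effect: float = 0.4
    cnv_loss_value: float = -0.7
    mutation_rate: float = 0.002  # background per (gene, tumour)

    # per-(gene, cancer) planting consistency (uniform ranges)
    dnam_plant_frac: tuple[float, float] = (0.7, 1.0)
    cnv_plant_frac: tuple[float, float] = (0.3, 1.0)

    # noise
    expression_mean: float = 7.0
    expression_between_gene_sd: float = 1.5
    expression_sd: float = 0.5
    beta_noise_sd: float = 0.05
    cnv_background_sd: float = 0.05

    # gene geometry
    n_chromosomes: int = 10
    gene_length: int = 1000
    gene_spacing: int = 10000

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "n_housekeeping", "n_tissues",
                     "n_hesc", "n_normal_tissue", "n_normal_adjacent",
                     "n_tumour"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_tfs + self.n_housekeeping >= self.n_genes:
            raise ValueError("n_genes must exceed n_tfs + n_housekeeping")
        if len(self.cancers_per_tissue) != self.n_tissues:
            raise ValueError("cancers_per_tissue must have n_tissues entries")
        for mix_name in ("mechanism_mix", "bg_mechanism_mix"):
            mix = getattr(self, mix_name)
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} proportions must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{mix_name} proportions must be >= 0")
            unknown = set(mix) - set(MECHANISMS)
            if unknown:
                raise ValueError(f"{mix_name} has unknown mechanisms {unknown}")
        for frac in ("p_developmental", "p_tissue_membership",
                     "frac_silenced_tfs", "silenced_tumour_frac",
                     "bg_silenced_frac"):
            if not 0 <= getattr(self, frac) <= 1:
                raise ValueError(f"{frac} must lie in [0, 1]")
        for eff in ("tf_up_log2", "silencing_log2", "delta_beta_effect",
                    "cnv_loss_value"):
            if not np.isfinite(getattr(self, eff)):
                raise ValueError(f"{eff} must be finite")

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("cancers_per_tissue", "dnam_plant_frac", "cnv_plant_frac"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    #: per-TF table: is_developmental, up_in (comma-joined tissues),
    #: silenced (bool), mechanism
    tf_table: pd.DataFrame
    #: cancer -> gene -> set of tumour sample IDs with a planted drop
    planted_tumours: dict[str, dict[str, set[str]]]
    #: cancer -> gene -> tumour IDs with a planted hypermethylation event
    planted_hyper: dict[str, dict[str, set[str]]]
    #: cancer -> gene -> tumour IDs with a planted focal loss
    planted_loss: dict[str, dict[str, set[str]]]
    #: cancer -> tissue name
    cancer_tissue: dict[str, str]

    def silenced_tfs(self, cancer: str) -> set[str]:
        tissue = self.cancer_tissue[cancer]
        t = self.tf_table
        mask = t["silenced"] & t["up_in"].str.split(",").apply(
            lambda ts: tissue in ts)
        return set(t.index[mask])

    def up_tfs(self, tissue: str) -> set[str]:
        t = self.tf_table
        mask = t["is_developmental"] & t["up_in"].str.split(",").apply(
            lambda ts: tissue in ts)
        return set(t.index[mask])


@dataclass
class CancerCohort:
    """One tumour cohort: matched normals plus tumours, all modalities."""

    name: str
    tissue: str
    counts: pd.DataFrame  # genes x samples, RNA-seq-like counts
    sample_pheno: pd.Series  # NormalAdjacent / Tumour
    probe_betas: pd.DataFrame  # probes x samples
    segments: list[SegmentRecord]
    mutations: list[MutationRecord]

    @property
    def tumour_samples(self) -> list[str]:
        return list(self.sample_pheno.index[self.sample_pheno == "Tumour"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_pheno.index[self.sample_pheno == "NormalAdjacent"])


@dataclass
class SyntheticCohort:
    config: CohortConfig
    scm_expr: pd.DataFrame  # genes x (hESC + tissue normal) samples
    scm_pheno: pd.Series
    scm_tissue: pd.Series
    cancers: dict[str, CancerCohort]
    manifest: list[ProbeAnnotation]
    coords: list[GeneCoordinates]
    gene_lists: GeneListSet
    truth: SyntheticTruth

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.config.n_tissues)]

    def write(self, outdir: str | Path) -> None:
        """Dump the cohort in the external formats the readers consume."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        write_matrix(self.scm_expr, out / "scm_expression.tsv", label="gene")
        pd.DataFrame({"phenotype": self.scm_pheno,
                      "tissue": self.scm_tissue}).to_csv(
            out / "scm_samples.tsv", sep="\t", index_label="sample")
        write_probe_manifest(self.manifest, out / "probe_manifest.tsv")
        write_bed(self.coords, out / "genes.bed")
        gl = self.gene_lists
        for name, genes in (("tf_genes", gl.tf_genes),
                            ("bivalent_genes", gl.bivalent_genes),
                            ("prc2_genes", gl.prc2_genes),
                            ("housekeeping_genes", gl.housekeeping_genes),
                            ("cgi_genes", gl.cgi_genes)):
            write_gene_list(genes, out / f"{name}.txt")
        self.truth.tf_table.to_csv(out / "truth_tfs.tsv", sep="\t",
                                   index_label="gene")
        for name, cohort in self.cancers.items():
            cdir = out / name
            cdir.mkdir(exist_ok=True)
            write_matrix(cohort.counts, cdir / "rnaseq_counts.tsv",
                         label="gene", float_format="%.0f")
            cohort.sample_pheno.to_frame("phenotype").to_csv(
                cdir / "samples.tsv", sep="\t", index_label="sample")
            write_matrix(cohort.probe_betas, cdir / "probe_betas.tsv",
                         label="probe")
            write_seg(cohort.segments, cdir / "cnv.seg")
            write_mutations(cohort.mutations, cdir / "mutations.maf")
            with open(cdir / "tissue.txt", "w") as fh:
                fh.write(cohort.tissue + "\n")


def _pick_mechanisms(rng: np.random.Generator, genes: list[str],
                     mix: dict[str, float]) -> dict[str, str]:
    names = [m for m in MECHANISMS if mix.get(m, 0) > 0]
    probs = np.array([mix[m] for m in names])
    probs = probs / probs.sum()
    picks = rng.choice(len(names), size=len(genes), p=probs)
    return {g: names[int(i)] for g, i in zip(genes, picks)}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full study; byte-identical for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    genes = ([f"TF{i:04d}" for i in range(c.n_tfs)]
             + [f"HK{i:04d}" for i in range(c.n_housekeeping)]
             + [f"G{i:05d}" for i in range(c.n_genes - c.n_tfs
                                           - c.n_housekeeping)])
    tf_genes = genes[:c.n_tfs]
    hk_genes = genes[c.n_tfs:c.n_tfs + c.n_housekeeping]
    other_genes = genes[c.n_tfs + c.n_housekeeping:]
    tissues = [f"T{i + 1}" for i in range(c.n_tissues)]
    cancer_tissue: dict[str, str] = {}
    k = 0
    for t, n_c in zip(tissues, c.cancers_per_tissue):
        for _ in range(n_c):
            k += 1
            cancer_tissue[f"C{k}"] = t

    # ----- planted truth ------------------------------------------------
    is_dev = rng.random(c.n_tfs) < c.p_developmental
    up_in: list[list[str]] = []
    for i in range(c.n_tfs):
        if not is_dev[i]:
            up_in.append([])
            continue
        member = rng.random(c.n_tissues) < c.p_tissue_membership
        if not member.any():
            member[rng.integers(c.n_tissues)] = True
        up_in.append([t for t, m in zip(tissues, member) if m])
    dev_tfs = [g for g, d in zip(tf_genes, is_dev) if d]
    silenced_mask = rng.random(len(dev_tfs)) < c.frac_silenced_tfs
    silenced_tfs = [g for g, s in zip(dev_tfs, silenced_mask) if s]
    mechanism = _pick_mechanisms(rng, silenced_tfs, c.mechanism_mix)

    tf_table = pd.DataFrame({
        "is_developmental": is_dev,
        "up_in": [",".join(u) for u in up_in],
        "silenced": [g in set(silenced_tfs) for g in tf_genes],
        "mechanism": [mechanism.get(g, "") for g in tf_genes],
    }, index=pd.Index(tf_genes, name="gene"))

    # ----- gene lists ---------------------------------------------------
    bivalent = {g for g in tf_genes if rng.random() < 0.75} | set(dev_tfs)
    prc2 = {g for g in tf_genes if rng.random() < 0.75}
    cgi = ({g for g in silenced_tfs if rng.random() < 0.85}
           | {g for g in genes if g not in set(silenced_tfs)
              and rng.random() < 0.4})
    gene_lists = GeneListSet(
        tf_genes=set(tf_genes), bivalent_genes=bivalent, prc2_genes=prc2,
        housekeeping_genes=set(hk_genes), cgi_genes=cgi,
    )

    # ----- gene geometry and probes -------------------------------------
    coords: list[GeneCoordinates] = []
    per_chrom = int(np.ceil(c.n_genes / c.n_chromosomes))
    for i, g in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * c.gene_spacing + 1000
        coords.append(GeneCoordinates(g, chrom, start, start + c.gene_length))

    manifest: list[ProbeAnnotation] = []
    probe_counter = 0
    for g in genes:
        n_tss200 = int(rng.choice([0, 1, 2, 3], p=[0.25, 0.3, 0.3, 0.15]))
        n_1stexon = int(rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2]))
        n_tss1500 = int(rng.choice([1, 2], p=[0.6, 0.4]))
        for region, n in ((RegionGroup.TSS200, n_tss200),
                          (RegionGroup.FirstExon, n_1stexon),
                          (RegionGroup.TSS1500, n_tss1500)):
            for _ in range(n):
                manifest.append(ProbeAnnotation(f"cg{probe_counter:08d}",
                                                g, region))
                probe_counter += 1
        if rng.random() < 0.2:  # body probes the recursive model must skip
            manifest.append(ProbeAnnotation(f"cg{probe_counter:08d}", g,
                                            RegionGroup.Other))
            probe_counter += 1
    gene_pos = {g: i for i, g in enumerate(genes)}
    probe_ids = [a.probe_id for a in manifest]
    probe_gene_idx = np.array([gene_pos[a.gene_id] for a in manifest])

    # ----- baseline expression and methylation levels -------------------
    base_expr = rng.normal(c.expression_mean, c.expression_between_gene_sd,
                           c.n_genes)
    base_beta = rng.beta(4, 16, c.n_genes)

    up_shift = np.zeros((c.n_genes, c.n_tissues))
    for i, u in enumerate(up_in):
        for t in u:
            up_shift[i, tissues.index(t)] = c.tf_up_log2

    # ----- compendium (hESC + tissue normals) ---------------------------
    scm_cols, scm_pheno, scm_tissue, scm_blocks = [], [], [], []
    for j in range(c.n_hesc):
        scm_cols.append(f"hESC_{j:03d}")
        scm_pheno.append("hESC")
        scm_tissue.append("hESC")
        scm_blocks.append(base_expr + rng.normal(0, c.expression_sd, c.n_genes))
    for ti, t in enumerate(tissues):
        for j in range(c.n_normal_tissue):
            scm_cols.append(f"{t}_N{j:02d}")
            scm_pheno.append("NormalFetal")
            scm_tissue.append(t)
            scm_blocks.append(base_expr + up_shift[:, ti]
                              + rng.normal(0, c.expression_sd, c.n_genes))
    scm_expr = pd.DataFrame(np.column_stack(scm_blocks), index=genes,
                            columns=scm_cols)
    scm_pheno = pd.Series(scm_pheno, index=scm_cols)
    scm_tissue = pd.Series(scm_tissue, index=scm_cols)

    # ----- tumour cohorts ------------------------------------------------
    gene_index = {g: i for i, g in enumerate(genes)}
    chrom_len = per_chrom * c.gene_spacing + 10000
    coord_by_gene = {cd.gene_id: cd for cd in coords}

    planted_tumours: dict[str, dict[str, set[str]]] = {}
    planted_hyper: dict[str, dict[str, set[str]]] = {}
    planted_loss: dict[str, dict[str, set[str]]] = {}
    cancers: dict[str, CancerCohort] = {}

    for cname, tissue in cancer_tissue.items():
        ti = tissues.index(tissue)
        normal_ids = [f"{cname}_N{j:03d}" for j in range(c.n_normal_adjacent)]
        tumour_ids = [f"{cname}_T{j:03d}" for j in range(c.n_tumour)]
        samples = normal_ids + tumour_ids

        # which genes are silenced in this cancer, and through what
        cancer_silenced = {g for g in silenced_tfs
                           if tissue in up_in[tf_genes.index(g)]}
        n_bg = int(round(c.bg_silenced_frac * len(other_genes)))
        bg_silenced = list(rng.choice(other_genes, size=n_bg, replace=False))
        bg_mech = _pick_mechanisms(rng, bg_silenced, c.bg_mechanism_mix)
        # sorted iteration keeps the random-draw order independent of the
        # process hash seed, so a fixed config is byte-reproducible
        gene_mech = {g: mechanism[g] for g in sorted(cancer_silenced)}
        gene_mech.update(bg_mech)

        drops: dict[str, set[str]] = {}
        hyper: dict[str, set[str]] = {}
        loss: dict[str, set[str]] = {}
        mut_planted: dict[str, set[str]] = {}
        for g, mech in gene_mech.items():
            n_drop = int(round(c.silenced_tumour_frac * c.n_tumour))
            dropped = list(rng.choice(tumour_ids, size=n_drop, replace=False))
            drops[g] = set(dropped)
            q_d = rng.uniform(*c.dnam_plant_frac)
            q_c = rng.uniform(*c.cnv_plant_frac)
            if mech == "DNAm":
                hyper[g] = {s for s in dropped if rng.random() < q_d}
            elif mech == "CNV":
                loss[g] = {s for s in dropped if rng.random() < q_c}
            elif mech == "Both":
                if c.both_exclusive:
                    half = len(dropped) // 2
                    hyper[g] = set(dropped[:half])
                    loss[g] = set(dropped[half:])
                else:
                    hyper[g] = {s for s in dropped if rng.random() < q_d}
                    loss[g] = {s for s in dropped if rng.random() < q_c}
            elif mech == "Mutation":
                mut_planted[g] = set(dropped)
        planted_tumours[cname] = drops
        planted_hyper[cname] = hyper
        planted_loss[cname] = loss

        # expression counts
        log_expr = np.empty((c.n_genes, len(samples)))
        for j, s in enumerate(samples):
            x = base_expr + up_shift[:, ti] + rng.normal(0, c.expression_sd,
                                                         c.n_genes)
            if s in tumour_ids:
                for g, dropped in drops.items():
                    if s in dropped:
                        x[gene_index[g]] -= c.silencing_log2
            log_expr[:, j] = x
        counts = np.maximum(np.round(2.0 ** log_expr - 1.0), 0)
        counts_df = pd.DataFrame(counts, index=genes, columns=samples)

        # probe betas
        betas = np.empty((len(probe_ids), len(samples)))
        for j, s in enumerate(samples):
            gene_level = base_beta.copy()
            if s in tumour_ids:
                for g, hs in hyper.items():
                    if s in hs:
                        gene_level[gene_index[g]] += c.delta_beta_effect
            probe_level = (gene_level[probe_gene_idx]
                           + rng.normal(0, c.beta_noise_sd, len(probe_ids)))
            betas[:, j] = np.clip(probe_level, 0.0, 1.0)
        betas_df = pd.DataFrame(betas, index=probe_ids, columns=samples)

        # CNV segments: per tumour and chromosome, background segments
        # partitioned around any planted focal losses
        loss_by_sample: dict[str, list[GeneCoordinates]] = {}
        for g, ls in loss.items():
            for s in ls:
                loss_by_sample.setdefault(s, []).append(coord_by_gene[g])
        segments: list[SegmentRecord] = []
        for s in tumour_ids:
            focal = loss_by_sample.get(s, [])
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for cd in focal:
                by_chrom.setdefault(cd.chrom, []).append(
                    (max(0, cd.start - 500), cd.end + 500))
            for ci in range(c.n_chromosomes):
                chrom = f"chr{ci + 1}"
                cuts = sorted(by_chrom.get(chrom, []))
                pos = 0
                for f_start, f_end in cuts:
                    if f_start > pos:
                        segments.append(SegmentRecord(
                            s, chrom, pos, f_start,
                            float(rng.normal(0, c.cnv_background_sd))))
                    segments.append(SegmentRecord(
                        s, chrom, f_start, f_end,
                        float(c.cnv_loss_value
                              + rng.normal(0, c.cnv_background_sd))))
                    pos = f_end
                if pos < chrom_len:
                    segments.append(SegmentRecord(
                        s, chrom, pos, chrom_len,
                        float(rng.normal(0, c.cnv_background_sd))))
        segments.sort(key=lambda r: (r.sample_id, r.chrom, r.start))

        # mutations: planted inactivating plus sparse background
        mutations: list[MutationRecord] = []
        for g, ms in mut_planted.items():
            for s in sorted(ms):
                vclass = VariantClass.Nonsense if rng.random() < 0.5 \
                    else VariantClass.Missense
                mutations.append(MutationRecord(s, g, vclass))
        n_bg_mut = rng.binomial(c.n_genes * c.n_tumour, c.mutation_rate)
        bg_gene_idx = rng.integers(0, c.n_genes, n_bg_mut)
        bg_sample_idx = rng.integers(0, c.n_tumour, n_bg_mut)
        bg_class_pool = [VariantClass.Missense, VariantClass.Nonsense,
                         VariantClass.Deletion, VariantClass.Other]
        bg_class_idx = rng.choice(4, size=n_bg_mut, p=[0.45, 0.1, 0.1, 0.35])
        for gi, si, ci in zip(bg_gene_idx, bg_sample_idx, bg_class_idx):
            mutations.append(MutationRecord(tumour_ids[int(si)],
                                            genes[int(gi)],
                                            bg_class_pool[int(ci)]))

        pheno = pd.Series(["NormalAdjacent"] * len(normal_ids)
                          + ["Tumour"] * len(tumour_ids), index=samples)
        cancers[cname] = CancerCohort(
            name=cname, tissue=tissue, counts=counts_df, sample_pheno=pheno,
            probe_betas=betas_df, segments=segments, mutations=mutations,
        )

    truth = SyntheticTruth(
        tf_table=tf_table, planted_tumours=planted_tumours,
        planted_hyper=planted_hyper, planted_loss=planted_loss,
        cancer_tissue=cancer_tissue,
    )
    return SyntheticCohort(
        config=c, scm_expr=scm_expr, scm_pheno=scm_pheno,
        scm_tissue=scm_tissue, cancers=cancers, manifest=manifest,
        coords=coords, gene_lists=gene_lists, truth=truth,
    )


def load_cohort(indir: str | Path) -> SyntheticCohort:
    """Reconstruct an in-memory cohort from a directory written by
    :meth:`SyntheticCohort.write`."""
    d = Path(indir)
    config = CohortConfig.from_yaml(d / "config.yaml")
    scm_expr = read_matrix(d / "scm_expression.tsv")
    scm_samples = pd.read_csv(d / "scm_samples.tsv", sep="\t", index_col=0)
    manifest = read_probe_manifest(d / "probe_manifest.tsv")
    coords = read_bed(d / "genes.bed")
    gene_lists = GeneListSet(
        tf_genes=read_gene_list(d / "tf_genes.txt"),
        bivalent_genes=read_gene_list(d / "bivalent_genes.txt"),
        prc2_genes=read_gene_list(d / "prc2_genes.txt"),
        housekeeping_genes=read_gene_list(d / "housekeeping_genes.txt"),
        cgi_genes=read_gene_list(d / "cgi_genes.txt"),
    )
    tf_table = pd.read_csv(d / "truth_tfs.tsv", sep="\t", index_col=0,
                           keep_default_na=False)
    tf_table["is_developmental"] = tf_table["is_developmental"].astype(bool)
    tf_table["silenced"] = tf_table["silenced"].astype(bool)
    cancers: dict[str, CancerCohort] = {}
    cancer_tissue: dict[str, str] = {}
    for cdir in sorted(p for p in d.iterdir() if p.is_dir()):
        name = cdir.name
        tissue = (cdir / "tissue.txt").read_text().strip()
        cancer_tissue[name] = tissue
        pheno = pd.read_csv(cdir / "samples.tsv", sep="\t",
                            index_col=0)["phenotype"]
        cancers[name] = CancerCohort(
            name=name, tissue=tissue,
            counts=read_matrix(cdir / "rnaseq_counts.tsv"),
            sample_pheno=pheno,
            probe_betas=read_matrix(cdir / "probe_betas.tsv"),
            segments=read_seg(cdir / "cnv.seg"),
            mutations=read_mutations(cdir / "mutations.maf"),
        )
    truth = SyntheticTruth(tf_table=tf_table, planted_tumours={},
                           planted_hyper={}, planted_loss={},
                           cancer_tissue=cancer_tissue)
    return SyntheticCohort(
        config=config, scm_expr=scm_expr,
        scm_pheno=scm_samples["phenotype"], scm_tissue=scm_samples["tissue"],
        cancers=cancers, manifest=manifest, coords=coords,
        gene_lists=gene_lists, truth=truth,
    )


def truth_confusion(truth: SyntheticTruth,
                    detected: dict[str, set[str]],
                    mechanism_class: dict[str, pd.Series] | None = None
                    ) -> dict[str, object]:
    """Score pipeline output against the planted truth.

    ``detected`` maps cancer -> detected silenced TF set;
    ``mechanism_class`` maps cancer -> per-gene predicted class.  Returns
    silencing sensitivity/FDR (pooled over cancers) and, when mechanism
    predictions are given, the truth x predicted confusion matrix with its
    diagonal accuracy (planted Mutation and Neither both map to the
    expected class Neither: neither leaves an in-cis DNAm/CNV footprint).
    """
    known = set(truth.tf_table.index)
    tp = fp = fn = 0
    for cancer, det in detected.items():
        if det - known:
            raise ValueError("truth and pipeline gene universes differ: "
                             f"{sorted(det - known)[:5]} not in the truth table")
        planted = truth.silenced_tfs(cancer)
        tp += len(det & planted)
        fp += len(det - planted)
        fn += len(planted - det)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    fdr = fp / (tp + fp) if tp + fp else 0.0
    out: dict[str, object] = {"sensitivity": sensitivity, "fdr": fdr,
                              "tp": tp, "fp": fp, "fn": fn}
    if mechanism_class is not None:
        expected_map = {"DNAm": "DNAmDominant", "CNV": "CNVDominant",
                        "Both": "Both", "Neither": "Neither",
                        "Mutation": "Neither"}
        classes = ["DNAmDominant", "CNVDominant", "Both", "Neither"]
        conf = pd.DataFrame(0, index=classes, columns=classes)
        for cancer, pred in mechanism_class.items():
            planted = truth.silenced_tfs(cancer)
            for g in pred.index:
                if g not in planted:
                    continue
                true_cls = expected_map[truth.tf_table.loc[g, "mechanism"]]
                conf.loc[true_cls, pred[g]] += 1
        total = conf.to_numpy().sum()
        acc = np.trace(conf.to_numpy()) / total if total else float("nan")
        out["mechanism_confusion"] = conf
        out["mechanism_accuracy"] = float(acc)
    return out
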