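"""Readers and writers for the external file formats the pipeline touches.

All genomic coordinates inside the package are 0-based half-open.  Readers
are the only place where conversion from an external convention happens:
SEG and BED input is assumed 1-based inclusive / 0-based half-open
respectively, per the common dialects of those formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "RegionGroup",
    "VariantClass",
    "ProbeAnnotation",
    "SegmentRecord",
    "MutationRecord",
    "GeneCoordinates",
    "GeneListSet",
    "FormatError",
    "read_matrix",
    "write_matrix",
    "read_seg",
    "write_seg",
    "read_mutations",
    "write_mutations",
    "read_bed",
    "write_bed",
    "read_gene_list",
    "write_gene_list",
    "read_probe_manifest",
    "write_probe_manifest",
    "load_variant_class_map",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class RegionGroup(str, Enum):
    """Promoter region classes of the 450k array manifest."""

    TSS200 = "TSS200"
    FirstExon = "FirstExon"
    TSS1500 = "TSS1500"
    Other = "Other"


#: 450k-manifest vocabulary -> internal region class.
_REGION_VOCAB = {
    "TSS200": RegionGroup.TSS200,
    "1stExon": RegionGroup.FirstExon,
    "FirstExon": RegionGroup.FirstExon,
    "TSS1500": RegionGroup.TSS1500,
}


class VariantClass(str, Enum):
    Nonsense = "Nonsense"
    Missense = "Missense"
    Deletion = "Deletion"
    Other = "Other"


#: classes that count as inactivating a gene
INACTIVATING_CLASSES = frozenset(
    {VariantClass.Nonsense, VariantClass.Missense, VariantClass.Deletion}
)


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    gene_id: str
    region_group: RegionGroup


@dataclass(frozen=True)
class SegmentRecord:
    """A copy-number segment, 0-based half-open, with its normalised value."""

    sample_id: str
    chrom: str
    start: int
    end: int
    segval: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"segment {self.sample_id}:{self.chrom}:{self.start}-{self.end} "
                "has start >= end"
            )
        if not pd.notna(self.segval) or self.segval in (float("inf"), float("-inf")):
            raise FormatError("segment value must be finite")


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_id: str
    variant_class: VariantClass


@dataclass(frozen=True)
class GeneCoordinates:
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"gene {self.gene_id} has start >= end")


@dataclass
class GeneListSet:
    """The externally supplied gene lists the analysis conditions on."""

    tf_genes: set[str] = field(default_factory=set)
    bivalent_genes: set[str] = field(default_factory=set)
    prc2_genes: set[str] = field(default_factory=set)
    housekeeping_genes: set[str] = field(default_factory=set)
    cgi_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("tf_genes", "bivalent_genes", "prc2_genes",
                     "housekeeping_genes", "cgi_genes"):
            if "" in getattr(self, name):
                raise FormatError(f"{name} contains an empty identifier")

    @property
    def candidate_tfs(self) -> set[str]:
        """TFs carrying a poised (bivalent or PRC2) promoter mark."""
        return self.tf_genes & (self.bivalent_genes | self.prc2_genes)


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric TSV matrix (rows x samples).

    The first column holds row labels; the header row holds sample IDs.
    Duplicate row labels or sample IDs are rejected.  Empty cells become NaN.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample IDs {dups}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate row labels {dups}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str),
                       dtype=float)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            ) from None
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 label: str = "id", float_format: str = "%.6g") -> None:
    matrix.to_csv(path, sep="\t", index_label=label, float_format=float_format)


# ---------------------------------------------------------------------------
# SEG


_SEG_COLUMNS = ["sample", "chrom", "start", "end", "seg_mean"]


def read_seg(path: str | Path) -> list[SegmentRecord]:
    """Read a SEG file (1-based inclusive) into 0-based half-open records.

    Columns: sample, chrom, start, end, [num_mark,] seg_mean.  Output is
    sorted by (sample, chrom, start).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] == 6:
        df = df.iloc[:, [0, 1, 2, 3, 5]]
    elif df.shape[1] != 5:
        raise FormatError(f"{path}: expected 5 or 6 SEG columns, got {df.shape[1]}")
    df.columns = _SEG_COLUMNS
    if df["seg_mean"].isna().any():
        raise FormatError(f"{path}: missing seg_mean value")
    records = [
        SegmentRecord(str(r.sample), str(r.chrom), int(r.start) - 1, int(r.end),
                      float(r.seg_mean))
        for r in df.itertuples(index=False)
    ]
    records.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    return records


def write_seg(records: list[SegmentRecord], path: str | Path) -> None:
    """Write records back to the 1-based inclusive SEG dialect."""
    df = pd.DataFrame(
        [(r.sample_id, r.chrom, r.start + 1, r.end, r.segval) for r in records],
        columns=_SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutations (minimal MAF)


_DEFAULT_VARIANT_MAP = {
    "Nonsense_Mutation": "Nonsense",
    "Missense_Mutation": "Missense",
    "Frame_Shift_Del": "Deletion",
    "In_Frame_Del": "Deletion",
}


def load_variant_class_map(path: str | Path | None = None) -> dict[str, VariantClass]:
    """Load the MAF classification -> variant class dictionary.

    Shipped as a YAML config so other MAF dialects can be mapped without
    code changes; unknown strings always fall through to ``Other``.
    """
    if path is None:
        raw = dict(_DEFAULT_VARIANT_MAP)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {k: VariantClass(v) for k, v in raw.items()}


def read_mutations(path: str | Path,
                   class_map: dict[str, VariantClass] | None = None
                   ) -> list[MutationRecord]:
    """Read a minimal MAF-like TSV: sample, gene, variant classification.

    Unmapped classification strings become ``Other`` with a logged warning.
    Duplicate records are preserved (collapsed downstream).
    """
    if class_map is None:
        class_map = load_variant_class_map()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need >=3 columns (sample, gene, class)")
    records = []
    unknown: set[str] = set()
    for r in df.itertuples(index=False):
        sample, gene, vclass = str(r[0]), str(r[1]), str(r[2])
        mapped = class_map.get(vclass)
        if mapped is None:
            unknown.add(vclass)
            mapped = VariantClass.Other
        records.append(MutationRecord(sample, gene, mapped))
    if unknown:
        logger.warning("unmapped variant classes treated as Other: %s",
                       sorted(unknown))
    return records


def write_mutations(records: list[MutationRecord], path: str | Path) -> None:
    inverse = {
        VariantClass.Nonsense: "Nonsense_Mutation",
        VariantClass.Missense: "Missense_Mutation",
        VariantClass.Deletion: "Frame_Shift_Del",
        VariantClass.Other: "Silent",
    }
    df = pd.DataFrame(
        [(r.sample_id, r.gene_id, inverse[r.variant_class]) for r in records],
        columns=["sample", "gene", "variant_classification"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED4 gene coordinates


def read_bed(path: str | Path) -> list[GeneCoordinates]:
    """Read BED4 (chrom, start, end, gene) — already 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"], dtype=str)
    coords = [
        GeneCoordinates(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    seen: set[str] = set()
    for c in coords:
        if c.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene {c.gene_id}")
        seen.add(c.gene_id)
    return coords


def write_bed(coords: list[GeneCoordinates], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in coords:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.gene_id}\n")


# ---------------------------------------------------------------------------
# gene lists and probe manifests


def read_gene_list(path: str | Path) -> set[str]:
    """One gene per line; blank lines ignored."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    return genes


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_probe_manifest(path: str | Path) -> list[ProbeAnnotation]:
    """TSV with columns probe_id, gene_id, region_group (450k vocabulary)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_id", "region_group"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    annos = []
    for r in df.itertuples(index=False):
        group = _REGION_VOCAB.get(str(r.region_group), RegionGroup.Other)
        annos.append(ProbeAnnotation(str(r.probe_id), str(r.gene_id), group))
    seen = set()
    for a in annos:
        key = (a.probe_id, a.gene_id, a.region_group)
        if key in seen:
            raise FormatError(f"{path}: duplicate manifest record {key}")
        seen.add(key)
    return annos


def write_probe_manifest(annos: list[ProbeAnnotation], path: str | Path) -> None:
    vocab = {
        RegionGroup.TSS200: "TSS200",
        RegionGroup.FirstExon: "1stExon",
        RegionGroup.TSS1500: "TSS1500",
        RegionGroup.Other: "Body",
    }
    df = pd.DataFrame(
        [(a.probe_id, a.gene_id, vocab[a.region_group]) for a in annos],
        columns=["probe_id", "gene_id", "region_group"],
    )
    df.to_csv(path, sep="\t", index=False)
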