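"""Identification of developmentally upregulated TFs and the test of their
preferential silencing in cancer.

Stage 1 compares normal-tissue expression against the embryonic stem cell
ground state with the moderated t, keeping bivalent/PRC2-marked TFs that
are significantly upregulated.  Stage 2 asks whether those TFs are more
strongly downregulated in the matched cancer type than a control set of
non-housekeeping genes matched 1:1 on normal-adjacent expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import fisher_exact_one_tailed, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "TFSelection",
    "ControlGeneSet",
    "identify_up_tfs",
    "exclusive_sets",
    "fraction_comparison_vs_random",
    "match_control_genes",
    "test_preferential_silencing",
    "cgi_enrichment",
]


@dataclass
class TFSelection:
    """Up/down TF calls for one tissue relative to the stem-cell state."""

    tissue: str
    up_tfs: set[str]
    down_tfs: set[str]
    fold_changes: pd.Series  # log2, for audit; no fold-change filter applied
    exclusive_up_tfs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.up_tfs & self.down_tfs:
            raise ValueError("a TF cannot be both up- and downregulated")


@dataclass
class ControlGeneSet:
    genes: set[str]
    match_map: dict[str, str]  # TF -> matched control gene


def identify_up_tfs(diff: pd.DataFrame, candidate_tfs: set[str],
                    tissue: str, alpha: float = 0.05) -> TFSelection:
    """Select candidate TFs significantly up (t > 0) or down in the tissue.

    ``diff`` is a moderated-t table (positive t = higher in tissue than in
    hESC); significance is BH-adjusted p < alpha.  Candidates absent from
    the table are logged and skipped.  Fold changes are recorded for all
    scored candidates, without filtering.
    """
    present = candidate_tfs & set(diff.index)
    missing = candidate_tfs - present
    if missing:
        logger.info("identify_up_tfs(%s): %d candidates absent from the "
                    "differential table", tissue, len(missing))
    sub = diff.loc[sorted(present)]
    sig = sub["p_adj"] < alpha
    up = set(sub.index[sig & (sub["t_mod"] > 0)])
    down = set(sub.index[sig & (sub["t_mod"] < 0)])
    return TFSelection(tissue=tissue, up_tfs=up, down_tfs=down,
                       fold_changes=sub["log2_fc"].copy())


def exclusive_sets(selections: list[TFSelection]) -> dict[str, set[str]]:
    """Mark each tissue's up-TFs that are up in no other tissue.

    Mutates the ``exclusive_up_tfs`` field of each selection and returns
    {tissue: exclusive set} plus the common intersection under key
    ``"common"``.
    """
    if len(selections) < 2:
        raise ValueError("exclusive_sets needs >=2 tissues")
    out: dict[str, set[str]] = {}
    common = set.intersection(*(s.up_tfs for s in selections))
    for s in selections:
        others = set().union(*(o.up_tfs for o in selections if o is not s))
        s.exclusive_up_tfs = s.up_tfs - others
        out[s.tissue] = s.exclusive_up_tfs
    out["common"] = common
    return out


def fraction_comparison_vs_random(selection: TFSelection, diff: pd.DataFrame,
                                  n_random: int = 1000,
                                  seed: int = 0,
                                  alpha: float = 0.05) -> float:
    """One-tailed Fisher p that TFs skew towards upregulation more than a
    random draw of genes.

    ``n_random`` genes are drawn without replacement (seeded) from the full
    differential table; the 2x2 table crosses (up, down) with (TF, random).
    """
    rng = np.random.default_rng(seed)
    if n_random > diff.shape[0]:
        raise ValueError("n_random exceeds the number of scored genes")
    picked = diff.index[rng.choice(diff.shape[0], size=n_random, replace=False)]
    sub = diff.loc[picked]
    sig = sub["p_adj"] < alpha
    rnd_up = int((sig & (sub["t_mod"] > 0)).sum())
    rnd_down = int((sig & (sub["t_mod"] < 0)).sum())
    return fisher_exact_one_tailed(len(selection.up_tfs), len(selection.down_tfs),
                                   rnd_up, rnd_down)


def match_control_genes(tf_set: set[str], normal_expression: pd.DataFrame,
                        housekeeping: set[str]) -> ControlGeneSet:
    """Greedy 1:1 nearest-neighbour matching on mean normal-adjacent
    expression, excluding housekeeping genes and the TFs themselves.

    TFs are processed in decreasing order of mean expression; each takes
    the still-unused pool gene with the closest mean (ties broken by
    lexicographic gene ID).  Deterministic by construction.
    """
    mean_expr = normal_expression.mean(axis=1)
    tf_present = sorted(tf_set & set(mean_expr.index))
    pool = mean_expr.drop(index=[g for g in mean_expr.index
                                 if g in tf_set or g in housekeeping])
    if len(pool) < len(tf_present):
        raise ValueError("candidate pool smaller than the TF set")
    # sort the pool by gene ID so equal-distance ties resolve lexicographically
    pool_sorted = pool.loc[sorted(pool.index)]
    pool_ids = np.array(pool_sorted.index)
    pool_vals = pool_sorted.to_numpy()
    used = np.zeros(len(pool_ids), dtype=bool)
    match_map: dict[str, str] = {}
    tf_order = sorted(tf_present, key=lambda g: (-mean_expr[g], g))
    for tf in tf_order:
        dist = np.abs(pool_vals - mean_expr[tf])
        dist[used] = np.inf
        best_j = int(np.argmin(dist))  # argmin returns the first (lowest ID) tie
        used[best_j] = True
        match_map[tf] = str(pool_ids[best_j])
    genes = set(match_map.values())
    assert not genes & housekeeping and not genes & tf_set
    return ControlGeneSet(genes=genes, match_map=match_map)


def test_preferential_silencing(cancer_diff: pd.DataFrame, tf_set: set[str],
                                control_set: set[str]) -> float:
    """One-tailed rank-sum p that TF t-statistics are more negative (more
    silenced in cancer) than the control genes'.

    Negative t means lower expression in cancer than in matched normal.
    """
    if tf_set & control_set:
        raise ValueError("TF and control sets must be disjoint")
    t = cancer_diff["t_mod"]
    tf_t = t.loc[sorted(tf_set & set(t.index))].to_numpy()
    ctl_t = t.loc[sorted(control_set & set(t.index))].to_numpy()
    return rank_sum_test(tf_t, ctl_t, alternative="less")


def cgi_enrichment(silenced_tfs: set[str], background: set[str],
                   cgi_genes: set[str]) -> float:
    """One-tailed Fisher p that silenced TFs preferentially map to CpG
    islands relative to a background gene set."""
    if not silenced_tfs or not background:
        raise ValueError("sets must be non-empty")
    a = len(silenced_tfs & cgi_genes)
    b = len(silenced_tfs - cgi_genes)
    c = len(background & cgi_genes)
    d = len(background - cgi_genes)
    return fisher_exact_one_tailed(a, b, c, d)
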