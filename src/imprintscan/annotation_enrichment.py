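"""Genomic-element annotation, permutation overlap testing, ChIP IP/input
fold change, and the nonparametric comparison statistics.

Statistical conventions: the permutation p-value is (b + 1) / (n_perm + 1)
with b the number of permutations reaching the observed overlap; zero paired
differences are dropped before the signed-rank test; BH adjustment is applied
within the family of comparisons requested in one call.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ChipCountTable, ProbeManifest, RegionSet, ValidationError


@dataclass
class AnnotationClass:
    """A named set of genomic intervals (e.g. 'CpG island', 'LINE')."""

    name: str
    regions: RegionSet


class _IntervalIndex:
    """Per-chromosome sorted starts with running max of ends, for O(log n)
    point-containment and interval-overlap queries."""

    def __init__(self, regions: RegionSet):
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        frame = regions.to_frame()
        for chrom, g in frame.groupby("chrom"):
            g = g.sort_values("start")
            starts = g["start"].to_numpy()
            cummax_end = np.maximum.accumulate(g["end"].to_numpy())
            self._by_chrom[chrom] = (starts, cummax_end)

    def contains_point(self, chrom: str, pos: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, cummax_end = entry
        idx = np.searchsorted(starts, pos, side="right")
        return idx > 0 and cummax_end[idx - 1] > pos

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, cummax_end = entry
        idx = np.searchsorted(starts, end, side="left")
        return idx > 0 and cummax_end[idx - 1] > start


def annotate_units(units: Union[ProbeManifest, RegionSet],
                   classes: Sequence[AnnotationClass]) -> Dict[str, List[str]]:
    """Multi-label annotation: each unit maps to every class whose intervals
    contain it (point units) or overlap it (region units). Units hit by no
    class map to an empty list."""
    indexes = [(cls.name, _IntervalIndex(cls.regions)) for cls in classes]
    names = [n for n, _ in indexes]
    if len(set(names)) != len(names):
        raise ValidationError("annotation class names must be unique")
    out: Dict[str, List[str]] = {}
    if isinstance(units, ProbeManifest):
        for row in units.frame.itertuples(index=False):
            out[row.probe_id] = [n for n, ix in indexes
                                 if ix.contains_point(row.chrom, row.pos)]
    else:
        for r in units:
            out[r.name] = [n for n, ix in indexes
                           if ix.overlaps(r.chrom, r.start, r.end)]
    return out


# ---------------------------------------------------------------------------
# Shuffle overlap test
# ---------------------------------------------------------------------------

@dataclass
class OverlapTestResult:
    observed_overlap: int
    n_perm: int
    p_value: float
    null_mean: float

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


def shuffle_overlap_test(set_a: Iterable, set_b: Iterable, universe: Iterable,
                         n_perm: int, seed: int) -> OverlapTestResult:
    """One-sided permutation test for overlap of two unit sets.

    Each permutation redraws a uniform subset of |A| units from the universe
    (without replacement) and counts its overlap with B; the p-value is
    (b + 1)/(n_perm + 1) with b the number of permutations whose overlap is
    ≥ the observed |A ∩ B|.
    """
    set_a, set_b = set(set_a), set(set_b)
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    if not set_a <= uset or not set_b <= uset:
        raise ValidationError("set_a and set_b must be subsets of the universe")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = len(set_a & set_b)
    b_mask = np.fromiter((u in set_b for u in universe), dtype=bool,
                         count=len(universe))
    rng = np.random.default_rng(seed)
    n_a = len(set_a)
    perm_overlaps = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        idx = rng.choice(len(universe), size=n_a, replace=False)
        perm_overlaps[i] = int(b_mask[idx].sum())
    b = int((perm_overlaps >= observed).sum())
    return OverlapTestResult(
        observed_overlap=observed,
        n_perm=n_perm,
        p_value=(b + 1) / (n_perm + 1),
        null_mean=float(perm_overlaps.mean()),
    )


def shuffle_overlap_test_intervals(set_a: RegionSet, set_b: RegionSet,
                                   chrom_sizes: Mapping[str, int],
                                   n_perm: int, seed: int) -> OverlapTestResult:
    """Alternative mode: shuffle A's intervals uniformly within their own
    chromosomes (lengths preserved) and count how many overlap B."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    for r in set_a:
        if r.chrom not in chrom_sizes or r.length > chrom_sizes[r.chrom]:
            raise ValidationError(f"region {r.name!r} does not fit its chromosome")
    index_b = _IntervalIndex(set_b)
    observed = sum(index_b.overlaps(r.chrom, r.start, r.end) for r in set_a)
    rng = np.random.default_rng(seed)
    perm_overlaps = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        count = 0
        for r in set_a:
            start = int(rng.integers(0, chrom_sizes[r.chrom] - r.length + 1))
            count += index_b.overlaps(r.chrom, start, start + r.length)
        perm_overlaps[i] = count
    b = int((perm_overlaps >= observed).sum())
    return OverlapTestResult(observed_overlap=int(observed), n_perm=n_perm,
                             p_value=(b + 1) / (n_perm + 1),
                             null_mean=float(perm_overlaps.mean()))


# ---------------------------------------------------------------------------
# ChIP fold change and comparison statistics
# ---------------------------------------------------------------------------

def chip_fold_change(counts: ChipCountTable) -> pd.DataFrame:
    """FC = (ip_count/ip_depth) / (input_count/input_depth) per record.

    When input_count = 0, a 0.5 pseudocount is added to both counts of that
    record and the row is flagged.
    """
    df = counts.frame.copy()
    zero = df["input_count"] == 0
    ip = df["ip_count"].astype(float) + 0.5 * zero
    inp = df["input_count"].astype(float) + 0.5 * zero
    df["fc"] = (ip / df["ip_depth"]) / (inp / df["input_depth"])
    df["pseudocount_applied"] = zero
    return df


def rank_biserial(differences: np.ndarray) -> float:
    """Paired rank-biserial r = (W⁺ − W⁻)/(W⁺ + W⁻); zeros dropped."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


def paired_wilcoxon(differences: np.ndarray, alternative: str = "greater"
                    ) -> float:
    """One-sided (by default) signed-rank p for paired differences; exact
    for small tie-free samples, zeros dropped first."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    res = stats.wilcoxon(d, alternative=alternative, method="auto")
    return float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrichment_compare(fc: pd.DataFrame,
                       comparisons: Sequence[Tuple[str, str]],
                       alternative: str = "greater") -> pd.DataFrame:
    """Paired comparison of per-region fold changes between conditions.

    ``fc`` must have columns region, condition, fc (replicates are averaged
    per region × condition). For each (case, reference) pair the paired
    differences case − reference are tested with a one-sided signed-rank
    test; BH adjustment is applied across the requested family; the paired
    rank-biserial correlation is reported as effect size.
    """
    required = {"region", "condition", "fc"}
    if not required <= set(fc.columns):
        raise ValidationError(f"fc table needs columns {sorted(required)}")
    pivot = fc.groupby(["region", "condition"])["fc"].mean().unstack()
    rows = []
    for case, refc in comparisons:
        for cond in (case, refc):
            if cond not in pivot.columns:
                raise ValidationError(f"condition {cond!r} absent from fc table")
        d = (pivot[case] - pivot[refc]).dropna()
        if len(d) < 2:
            raise ValidationError(
                f"comparison {case} vs {refc}: fewer than 2 paired regions")
        rows.append({
            "case": case,
            "reference": refc,
            "n": len(d),
            "median_difference": float(d.median()),
            "p_value": paired_wilcoxon(d.to_numpy(), alternative=alternative),
            "rank_biserial": rank_biserial(d.to_numpy()),
        })
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"])
    return out


def beta_difference_test(delta_a: Sequence[float],
                         delta_b: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum p-value between two Δβ samples.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise; degenerate identical inputs give p = 1.
    """
    a = np.asarray(list(delta_a), dtype=float)
    b = np.asarray(list(delta_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)
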