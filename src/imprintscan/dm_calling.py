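"""Control-panel reference construction and differential-methylation calling.

The core statistic applies to any unit — a single CpG, a 500 bp bin, or a
named region: a unit is called in a test sample when |ΔM| exceeds k times
the control SD of M (strict >) AND |Δβ| exceeds the β threshold (strict >).
ΔM is taken against the control MEAN of M-values; Δβ against the control
MEDIAN of β — the asymmetry is intentional and kept exactly as stated by
the source protocol.

Also provides genome binning at a fixed tile size (anchored at coordinate 0
of each chromosome), unit aggregation with minimum-CpG requirements, and
detection of clusters of contiguous differentially methylated bins.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io_model import (BetaMatrix, MMatrix, ProbeManifest, SampleSheet,
                       ValidationError)

HYPER = "hyper"
HYPO = "hypo"
UNCHANGED = "unchanged"


@dataclass
class ControlReference:
    """Per-unit control-panel summary: mean/SD of M and median of β.

    Defined only for units non-missing in all controls; SD uses the n−1
    denominator.
    """

    table: pd.DataFrame  # index unit_id; columns mean_m, sd_m, median_beta, n_controls

    def __post_init__(self):
        required = {"mean_m", "sd_m", "median_beta", "n_controls"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"reference table missing columns: {sorted(missing)}")
        if (self.table["sd_m"] < 0).any():
            raise ValidationError("negative sd_m in reference")
        if (self.table["n_controls"] < 2).any():
            raise ValidationError("reference requires >= 2 controls per unit")

    @property
    def unit_ids(self) -> list:
        return self.table.index.tolist()


def build_reference(beta: BetaMatrix, m: MMatrix, sheet: SampleSheet) -> ControlReference:
    """Summarise the control panel per unit (mean M, SD M, median β)."""
    controls = sheet.controls()
    if len(controls) < 2:
        raise ValidationError("reference computation needs >= 2 controls")
    for c in controls:
        if c not in beta.data.columns or c not in m.data.columns:
            raise ValidationError(f"control sample {c!r} absent from matrices")
    cb = beta.data[controls]
    cm = m.data[controls]
    complete = cb.notna().all(axis=1) & cm.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} units missing in at least one "
                      "control", stacklevel=2)
    cb, cm = cb.loc[complete], cm.loc[complete]
    table = pd.DataFrame({
        "mean_m": cm.mean(axis=1),
        "sd_m": cm.std(axis=1, ddof=1),
        "median_beta": cb.median(axis=1),
        "n_controls": len(controls),
    })
    return ControlReference(table)


def call_dm(beta: BetaMatrix, m: MMatrix, ref: ControlReference,
            sample_id: str, k: float = 3.0, delta: float = 0.2) -> pd.DataFrame:
    """Call differential methylation for one sample against the reference.

    Returns a frame with columns unit_id, sample_id, delta_beta, delta_m,
    sd_m, status ∈ {hyper, hypo, unchanged}. Units with sd_m = 0 are
    effectively called on the Δβ criterion alone (any nonzero |ΔM| exceeds
    the vacuous threshold); a warning counts them.
    """
    if sample_id not in beta.data.columns:
        raise ValidationError(f"unknown sample: {sample_id!r}")
    units = ref.table.index.intersection(beta.data.index)
    b = beta.data.loc[units, sample_id]
    mv = m.data.loc[units, sample_id]
    present = b.notna() & mv.notna()
    units = units[present.to_numpy()]
    b, mv = b.loc[units], mv.loc[units]
    sub = ref.table.loc[units]

    delta_beta = b - sub["median_beta"]
    delta_m = mv - sub["mean_m"]
    m_crit = delta_m.abs() > k * sub["sd_m"]
    n_degenerate = int((sub["sd_m"] == 0).sum())
    if n_degenerate:
        warnings.warn(f"{n_degenerate} units have sd_m = 0; the {k}·SD "
                      "criterion is vacuous there (Δβ criterion governs)",
                      stacklevel=2)
    status = np.where(m_crit & (delta_beta > delta), HYPER,
                      np.where(m_crit & (delta_beta < -delta), HYPO, UNCHANGED))
    return pd.DataFrame({
        "unit_id": units,
        "sample_id": sample_id,
        "delta_beta": delta_beta.to_numpy(),
        "delta_m": delta_m.to_numpy(),
        "sd_m": sub["sd_m"].to_numpy(),
        "status": status,
    }).reset_index(drop=True)


def call_dm_samples(beta: BetaMatrix, m: MMatrix, ref: ControlReference,
                    sample_ids: Sequence[str], k: float = 3.0,
                    delta: float = 0.2) -> pd.DataFrame:
    """Concatenated :func:`call_dm` over several samples."""
    frames = [call_dm(beta, m, ref, s, k=k, delta=delta) for s in sample_ids]
    if not frames:
        return pd.DataFrame(columns=["unit_id", "sample_id", "delta_beta",
                                     "delta_m", "sd_m", "status"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Binning and aggregation
# ---------------------------------------------------------------------------

_BIN_RE = re.compile(r"^(?P<chrom>.+):(?P<start>\d+)-(?P<end>\d+)$")


def make_bin_id(chrom: str, start: int, bin_size: int = 500) -> str:
    return f"{chrom}:{start}-{start + bin_size}"


def parse_bin_id(bin_id: str) -> Tuple[str, int]:
    mo = _BIN_RE.match(bin_id)
    if mo is None:
        raise ValidationError(f"not a bin id: {bin_id!r}")
    return mo.group("chrom"), int(mo.group("start"))


def assign_bins(manifest: ProbeManifest, bin_size: int = 500) -> pd.DataFrame:
    """Map each probe to its genome tile [⌊pos/size⌋·size, +size)."""
    starts = (manifest.frame["pos"] // bin_size) * bin_size
    out = pd.DataFrame({
        "probe_id": manifest.frame["probe_id"],
        "chrom": manifest.frame["chrom"],
        "bin_start": starts,
    })
    out["bin_id"] = [make_bin_id(c, s, bin_size)
                     for c, s in zip(out["chrom"], out["bin_start"])]
    return out.set_index("probe_id", drop=False)


def bin_membership(manifest: ProbeManifest, bin_size: int = 500) -> Dict[str, str]:
    assigned = assign_bins(manifest, bin_size)
    return dict(zip(assigned["probe_id"], assigned["bin_id"]))


def aggregate_units(beta: BetaMatrix, membership: Mapping[str, str],
                    min_cpgs: int) -> BetaMatrix:
    """Unweighted mean of member-probe β per group and sample.

    Groups with fewer than ``min_cpgs`` member probes present in the matrix
    are dropped entirely; a group value is missing for a sample in which any
    member probe is missing (per-sample completeness).
    """
    if not membership:
        raise ValidationError("empty membership")
    units = [u for u in beta.unit_ids if u in membership]
    if not units:
        raise ValidationError("membership covers no units of the matrix")
    df = beta.data.loc[units]
    groups = pd.Series([membership[u] for u in units], index=df.index)
    grouped = df.groupby(groups, sort=False)
    n_members = grouped.size()
    counts = grouped.count()
    means = grouped.mean()
    means = means.where(counts.eq(n_members, axis=0))
    keep = n_members[n_members >= min_cpgs].index
    order = [g for g in pd.unique(groups) if g in set(keep)]
    return BetaMatrix(means.loc[order])


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Clusters of ≥ min_bins contiguous dm bins plus leftover isolated bins."""

    clusters: List[List[str]]
    isolated: List[str]

    @property
    def n_cluster_bins(self) -> int:
        return sum(len(c) for c in self.clusters)


BinLike = Union[str, Tuple[str, int]]


def find_clusters(dm_bins: Iterable[BinLike], min_bins: int = 2,
                  bin_size: int = 500) -> ClusterSet:
    """Group differentially methylated bins into maximal contiguous runs.

    Contiguity means same chromosome and start difference exactly
    ``bin_size``; runs of length ≥ ``min_bins`` become clusters, the
    remaining bins are isolated. Input bins may be ``"chrom:start-end"``
    ids or ``(chrom, start)`` tuples; duplicates are collapsed.
    """
    parsed = set()
    for b in dm_bins:
        parsed.add(parse_bin_id(b) if isinstance(b, str) else (b[0], int(b[1])))
    ordered = sorted(parsed)

    clusters: List[List[str]] = []
    isolated: List[str] = []
    run: List[Tuple[str, int]] = []

    def flush(run):
        ids = [make_bin_id(c, s, bin_size) for c, s in run]
        if len(run) >= min_bins:
            clusters.append(ids)
        else:
            isolated.extend(ids)

    for item in ordered:
        if run and item[0] == run[-1][0] and item[1] - run[-1][1] == bin_size:
            run.append(item)
        else:
            if run:
                flush(run)
            run = [item]
    if run:
        flush(run)
    return ClusterSet(clusters=clusters, isolated=isolated)
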