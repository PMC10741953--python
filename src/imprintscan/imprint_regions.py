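"""Imprinted-DMR analysis: region filtering, grouping by control methylation,
region-level differential calling, and recovery classification in corrected
clones.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dm_calling import (ControlReference, UNCHANGED, build_reference,
                         call_dm_samples)
from .io_model import (BetaMatrix, ProbeManifest, RegionSet, SampleSheet,
                       ValidationError)
from .preprocess import beta_to_m

GROUP_HIGH = "high"
GROUP_INTERMEDIATE = "intermediate"
GROUP_LOW = "low"


def count_probes_in_regions(regions: RegionSet, manifest: ProbeManifest) -> pd.Series:
    """Number of manifest probes inside each region (half-open containment)."""
    counts = {}
    by_chrom = {c: g["pos"].to_numpy()
                for c, g in manifest.frame.groupby("chrom")}
    for r in regions:
        pos = by_chrom.get(r.chrom)
        if pos is None:
            counts[r.name] = 0
        else:
            counts[r.name] = int(((pos >= r.start) & (pos < r.end)).sum())
    return pd.Series(counts, name="n_probes")


def region_membership(regions: RegionSet, manifest: ProbeManifest) -> Dict[str, str]:
    """Map each probe to the first region containing it (for aggregation)."""
    membership: Dict[str, str] = {}
    for r in regions:
        sel = manifest.frame[(manifest.frame["chrom"] == r.chrom) &
                             (manifest.frame["pos"] >= r.start) &
                             (manifest.frame["pos"] < r.end)]
        for pid in sel["probe_id"]:
            membership.setdefault(pid, r.name)
    return membership


def filter_idmr_regions(regions: RegionSet, manifest: ProbeManifest,
                        min_probes: int = 3,
                        exclude: Sequence[str] = ()) -> RegionSet:
    """Drop regions covered by fewer than ``min_probes`` probes, then drop
    the explicitly excluded names. Idempotent; order preserved."""
    counts = count_probes_in_regions(regions, manifest)
    exclude = set(exclude)
    absent = exclude - set(regions.names)
    if absent:
        warnings.warn(f"excluded names not present: {sorted(absent)}",
                      stacklevel=2)
    kept = [r for r in regions
            if counts[r.name] >= min_probes and r.name not in exclude]
    return RegionSet(kept)


@dataclass
class RegionGroup:
    name: str
    group: str
    control_mean_beta: float


def classify_region_groups(region_beta: BetaMatrix, sheet: SampleSheet,
                           high: float = 0.60, low: float = 0.40) -> pd.DataFrame:
    """Partition regions by mean control β: high ≥ 0.60, intermediate in
    [0.40, 0.60), low < 0.40. The boundaries close the gaps left by the
    printed anchors so every region gets exactly one group."""
    controls = sheet.controls()
    missing = [c for c in controls if c not in region_beta.data.columns]
    if missing:
        raise ValidationError(f"controls absent from region matrix: {missing}")
    mean_beta = region_beta.data[controls].mean(axis=1)
    group = np.where(mean_beta >= high, GROUP_HIGH,
                     np.where(mean_beta >= low, GROUP_INTERMEDIATE, GROUP_LOW))
    return pd.DataFrame({
        "name": region_beta.unit_ids,
        "group": group,
        "control_mean_beta": mean_beta.to_numpy(),
    })


def call_region_dm(region_beta: BetaMatrix, sheet: SampleSheet,
                   k: float = 3.0, delta: float = 0.2,
                   eps: float = 0.001) -> Tuple[pd.DataFrame, ControlReference]:
    """Apply the per-unit dm statistic to region-level β_ave values.

    Builds a region-level control reference (β_ave → M) and calls every
    patient and corrected sample. Returns (calls, reference).
    """
    m = beta_to_m(region_beta, eps=eps)
    ref = build_reference(region_beta, m, sheet)
    samples = sheet.patients() + sheet.corrected()
    calls = call_dm_samples(region_beta, m, ref, samples, k=k, delta=delta)
    return calls, ref


def classify_recovery(patient_calls: pd.DataFrame, corrected_beta: BetaMatrix,
                      ref: ControlReference, sheet: SampleSheet,
                      delta: float = 0.2) -> pd.DataFrame:
    """Classify each unit dm in a patient as recovered/not in its clones.

    recovered ⇔ |β_corrected − control median β| < delta (strict). Rows are
    produced only for units differentially methylated in the parent patient.
    """
    called_samples = set(patient_calls["sample_id"].unique())
    rows = []
    for clone in sheet.corrected():
        parent = sheet.parent_of(clone)
        if parent not in called_samples:
            raise ValidationError(
                f"corrected clone {clone!r}: no calls for parent {parent!r}")
        if clone not in corrected_beta.data.columns:
            raise ValidationError(f"clone {clone!r} absent from beta matrix")
        dm = patient_calls[(patient_calls["sample_id"] == parent) &
                           (patient_calls["status"] != UNCHANGED)]
        if dm.empty:
            continue
        units = dm["unit_id"].to_numpy()
        med = ref.table["median_beta"].reindex(units)
        cdb = corrected_beta.data[clone].reindex(units).to_numpy() - med.to_numpy()
        rows.append(pd.DataFrame({
            "unit_id": units,
            "patient_id": parent,
            "corrected_id": clone,
            "patient_status": dm["status"].to_numpy(),
            "corrected_delta_beta": cdb,
            "recovered": np.abs(cdb) < delta,
        }))
    if not rows:
        return pd.DataFrame(columns=["unit_id", "patient_id", "corrected_id",
                                     "patient_status", "corrected_delta_beta",
                                     "recovered"])
    return pd.concat(rows, ignore_index=True)


@dataclass
class RecoverySummary:
    """Percent of dm units recovered per clone (and per annotation class)."""

    per_clone: pd.DataFrame             # corrected_id, n, n_recovered, percent
    per_class: Optional[pd.DataFrame]   # corrected_id, unit_class, n, n_recovered, percent
    shared_all_clones: Optional[dict]   # n_shared, n_recovered_all, percent


def recovery_summary(recovery: pd.DataFrame,
                     grouping: Optional[Mapping[str, str]] = None
                     ) -> RecoverySummary:
    """Summarise recovery calls: 100·recovered/total per clone, optionally
    per unit class, plus the count of units shared by all patients that
    recovered in every corrected clone."""
    if recovery.empty:
        raise ValidationError("no recovery calls to summarise")

    def _summarise(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        nr = int(g["recovered"].sum())
        return pd.Series({"n": n, "n_recovered": nr, "percent": 100.0 * nr / n})

    per_clone = (recovery.groupby("corrected_id", sort=False)
                 .apply(_summarise, include_groups=False).reset_index())

    per_class = None
    if grouping is not None:
        rec = recovery.copy()
        rec["unit_class"] = rec["unit_id"].map(dict(grouping))
        rec = rec.dropna(subset=["unit_class"])  # classes with 0 calls omitted
        if not rec.empty:
            per_class = (rec.groupby(["corrected_id", "unit_class"], sort=False)
                         .apply(_summarise, include_groups=False).reset_index())

    shared = None
    patients = recovery["patient_id"].unique()
    if len(patients) >= 2:
        unit_sets = [set(recovery.loc[recovery["patient_id"] == p, "unit_id"])
                     for p in patients]
        shared_units = set.intersection(*unit_sets)
        if shared_units:
            sub = recovery[recovery["unit_id"].isin(shared_units)]
            all_rec = sub.groupby("unit_id")["recovered"].all()
            shared = {
                "n_shared": len(shared_units),
                "n_recovered_all": int(all_rec.sum()),
                "percent": 100.0 * float(all_rec.mean()),
            }
    return RecoverySummary(per_clone=per_clone, per_class=per_class,
                           shared_all_clones=shared)
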