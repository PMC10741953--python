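"""Probe-level filtering and β ↔ M conversion.

Filters applied before any calling: detection p-value, SNP overlap, sex
chromosomes, per-sample missingness, and control-panel consistency. A probe
fails detection if p > threshold in ANY sample (strictest common default;
configurable). Removal reasons are attributed first-matching in the fixed
order detection → SNP → sex → missing so the report is deterministic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .io_model import BetaMatrix, MMatrix, ProbeManifest, SampleSheet, ValidationError


@dataclass
class FilterReport:
    """Audit trail: every input probe is attributed to exactly one outcome."""

    n_input: int
    n_removed_detection: int = 0
    n_removed_snp: int = 0
    n_removed_sex: int = 0
    n_removed_control_inconsistent: int = 0
    n_removed_missing: int = 0
    n_retained: int = 0

    def __post_init__(self):
        removed = (self.n_removed_detection + self.n_removed_snp +
                   self.n_removed_sex + self.n_removed_control_inconsistent +
                   self.n_removed_missing)
        if self.n_input != self.n_retained + removed:
            raise ValidationError(
                f"filter report does not balance: {self.n_input} != "
                f"{self.n_retained} + {removed}")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_probes(beta: BetaMatrix, manifest: ProbeManifest,
                  detection_p: Optional[pd.DataFrame] = None,
                  p_threshold: float = 0.01) -> Tuple[BetaMatrix, FilterReport]:
    """Remove probes flagged in the manifest, failing detection, or missing.

    A probe is removed if it overlaps a SNP, lies on a sex chromosome, has
    detection p > ``p_threshold`` in at least one sample, or is missing in
    any sample. Probe order is preserved.
    """
    units = beta.data.index
    absent = units.difference(manifest.frame.index)
    if len(absent) > 0:
        raise ValidationError(
            f"{len(absent)} probes absent from manifest, e.g. "
            f"{absent[:5].tolist()}")
    man = manifest.frame.loc[units]

    if detection_p is not None:
        dp = detection_p.reindex(index=units, columns=beta.data.columns)
        if dp.isna().any().any():
            raise ValidationError(
                "detection p-value matrix does not cover all probes/samples")
        fail_detect = (dp > p_threshold).any(axis=1)
    else:
        fail_detect = pd.Series(False, index=units)

    snp = man["snp_overlap"].to_numpy()
    sex = man["sex_chrom"].to_numpy()
    miss = beta.data.isna().any(axis=1).to_numpy()
    det = fail_detect.to_numpy()

    # first-matching attribution: detection -> SNP -> sex -> missing
    reason_detect = det
    reason_snp = snp & ~reason_detect
    reason_sex = sex & ~reason_detect & ~reason_snp
    reason_miss = miss & ~reason_detect & ~reason_snp & ~reason_sex
    keep = ~(reason_detect | reason_snp | reason_sex | reason_miss)

    report = FilterReport(
        n_input=len(units),
        n_removed_detection=int(reason_detect.sum()),
        n_removed_snp=int(reason_snp.sum()),
        n_removed_sex=int(reason_sex.sum()),
        n_removed_missing=int(reason_miss.sum()),
        n_retained=int(keep.sum()),
    )
    return BetaMatrix(beta.data.loc[keep]), report


def control_consistency_filter(beta: BetaMatrix, sheet: SampleSheet,
                               max_dev: float = 0.2
                               ) -> Tuple[BetaMatrix, FilterReport]:
    """Drop units where any single control deviates from the control mean
    by more than ``max_dev`` in β. Invariant under control-column order."""
    controls = sheet.controls()
    if len(controls) < 2:
        raise ValidationError("control consistency filter needs >= 2 controls")
    missing = [c for c in controls if c not in beta.data.columns]
    if missing:
        raise ValidationError(f"controls absent from beta matrix: {missing}")
    sub = beta.data[controls]
    dev = sub.sub(sub.mean(axis=1), axis=0).abs().max(axis=1)
    remove = (dev > max_dev).fillna(False).to_numpy()
    report = FilterReport(
        n_input=len(beta.data),
        n_removed_control_inconsistent=int(remove.sum()),
        n_retained=int(len(beta.data) - remove.sum()),
    )
    return BetaMatrix(beta.data.loc[~remove]), report


def beta_to_m(beta: BetaMatrix, eps: float = 0.001) -> MMatrix:
    """M = log2(β / (1 − β)) after clipping β into [eps, 1 − eps].

    Missing propagates to missing; the clip keeps M finite at β ∈ {0, 1}.
    """
    if not 0 < eps < 0.5:
        raise ValidationError(f"eps must be in (0, 0.5), got {eps}")
    clipped = beta.data.clip(lower=eps, upper=1 - eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(clipped / (1 - clipped))
    return MMatrix(m)


def m_to_beta(m: MMatrix) -> BetaMatrix:
    """Inverse transform β = 2^M / (1 + 2^M)."""
    b = 1.0 / (1.0 + np.power(2.0, -m.data))
    return BetaMatrix(b)
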