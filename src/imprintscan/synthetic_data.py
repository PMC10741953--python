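"""Truth-annotated synthetic input bundles emulating the study design:
a control iPSC panel, two patients sharing a subset of planted
hypomethylated loci (clustered and isolated bins plus imprinted regions),
corrected clones in which a configurable fraction of planted loci regain
control methylation, fibroblast-like samples at ~50% region methylation,
and ChIP IP/input counts elevated at planted-hypo regions.

Layout conventions: background CpGs tile ``chr1`` two per 500 bp bin;
imprinted regions sit on ``chr2`` at 10 kb spacing. Noise is additive
truncated Gaussian on the β scale; planted effects are applied on the β
scale. Everything is reproducible from the config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_model import (BetaMatrix, ChipCountTable, ProbeManifest, Region,
                       RegionSet, SampleSheet, ValidationError,
                       read_beta_matrix, read_chip_counts, read_manifest,
                       read_regions, read_sample_sheet, write_chip_counts,
                       write_manifest, write_matrix, write_regions,
                       write_sample_sheet)

BIN_SIZE = 500
_IDMR_SPACING = 10_000
_IDMR_LENGTH = 2_000
_GROUP_LEVELS = {"high": 0.85, "intermediate": 0.50, "low": 0.20}


@dataclass
class SimulationConfig:
    n_controls: int = 11
    n_patients: int = 2
    clones_per_patient: int = 2
    n_fibroblasts: int = 2
    n_cpgs: int = 2000              # background CpGs (two per 500 bp bin)
    n_idmrs: int = 50
    idmr_probes_per_region: int = 4
    idmr_group_fractions: Tuple[float, float, float] = (0.5, 0.3, 0.2)  # high/int/low
    planted_hypo_fraction_idmr: float = 0.3   # fraction of iDMRs planted hypo
    planted_hypo_fraction_bins: float = 0.02  # fraction of 500 bp bins planted
    shared_planted_fraction: float = 0.7      # planted loci hit in both patients
    planted_effect: float = 0.4               # Δβ magnitude of planted loci
    resistant_fraction: float = 0.3           # planted loci not recovered in clones
    control_noise_sd: float = 0.02            # β-scale SD of sample noise
    unstable_control_fraction: float = 0.0    # iDMRs destabilised in one control
    fibroblast_idmr_level: float = 0.5
    bimodal_low: float = 0.1
    bimodal_high: float = 0.9
    high_mode_fraction: float = 0.6
    chip_fc_at_hypo: float = 3.0
    chip_base_count: int = 200
    chip_depth: int = 1_000_000
    chip_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 2:
            raise ValidationError("n_controls must be >= 2")
        fracs = [self.planted_hypo_fraction_idmr, self.planted_hypo_fraction_bins,
                 self.shared_planted_fraction, self.resistant_fraction,
                 self.unstable_control_fraction, self.high_mode_fraction]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValidationError("fractions must lie in [0, 1]")
        if not 0 <= self.planted_effect < 1:
            raise ValidationError("planted_effect must lie in [0, 1)")
        if abs(sum(self.idmr_group_fractions) - 1.0) > 1e-9:
            raise ValidationError("idmr_group_fractions must sum to 1")
        if self.n_cpgs < 4:
            raise ValidationError("n_cpgs must be >= 4")


@dataclass
class TruthTable:
    """Planted ground truth at probe, bin, and region granularity."""

    probes: pd.DataFrame   # probe_id, status, patients, resistant, locus_id
    bins: pd.DataFrame     # bin_id, chrom, start, planted, patients, in_cluster, resistant
    regions: pd.DataFrame  # name, group, planted, patients, resistant


@dataclass
class SimBundle:
    beta: BetaMatrix
    manifest: ProbeManifest
    regions: RegionSet
    sheet: SampleSheet
    chip: ChipCountTable
    truth: TruthTable
    config: SimulationConfig
    baseline: Optional[np.ndarray] = None  # per-probe noise-free β (not written)


def _split_loci(loci: List[str], shared_fraction: float, patients: List[str],
                rng: np.random.Generator) -> Dict[str, List[str]]:
    """Assign each planted locus to all patients (shared) or round-robin to
    a single patient."""
    loci = list(loci)
    rng.shuffle(loci)
    n_shared = round(shared_fraction * len(loci))
    assignment: Dict[str, List[str]] = {}
    for locus in loci[:n_shared]:
        assignment[locus] = list(patients)
    for i, locus in enumerate(loci[n_shared:]):
        assignment[locus] = [patients[i % len(patients)]]
    return assignment


def _assign_resistance(assignment: Dict[str, List[str]],
                       locus_sizes: Dict[str, int], fraction: float,
                       patients: List[str],
                       rng: np.random.Generator) -> Dict[str, bool]:
    """Mark loci resistant so that, per disjoint assignment group, roughly
    ``fraction`` of planted probes are resistant (greedy to the target)."""
    groups: Dict[Tuple[str, ...], List[str]] = {}
    for locus, pats in assignment.items():
        groups.setdefault(tuple(sorted(pats)), []).append(locus)
    resistant = {locus: False for locus in assignment}
    for loci in groups.values():
        loci = sorted(loci)
        rng.shuffle(loci)
        total = sum(locus_sizes[l] for l in loci)
        target = fraction * total
        acc = 0
        for locus in loci:
            size = locus_sizes[locus]
            if abs(acc + size - target) <= abs(acc - target):
                resistant[locus] = True
                acc += size
    return resistant


def simulate_bundle(config: SimulationConfig) -> SimBundle:
    """Generate a complete, internally consistent input bundle plus truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = [f"P{i + 1}" for i in range(config.n_patients)]

    # ---- probe layout -----------------------------------------------------
    n_bins = config.n_cpgs // 2
    bg_ids, bg_chrom, bg_pos = [], [], []
    for i in range(n_bins):
        for off in (100, 300):
            bg_ids.append(f"cgBG{len(bg_ids):06d}")
            bg_chrom.append("chr1")
            bg_pos.append(BIN_SIZE * i + off)
    if config.n_cpgs % 2:  # odd leftover: a single-CpG bin (excluded at bin level)
        bg_ids.append(f"cgBG{len(bg_ids):06d}")
        bg_chrom.append("chr1")
        bg_pos.append(BIN_SIZE * n_bins + 100)

    region_rows, idmr_ids, idmr_chrom, idmr_pos, probe_region = [], [], [], [], []
    group_fracs = config.idmr_group_fractions
    n_high = round(group_fracs[0] * config.n_idmrs)
    n_int = round(group_fracs[1] * config.n_idmrs)
    groups = (["high"] * n_high + ["intermediate"] * n_int +
              ["low"] * (config.n_idmrs - n_high - n_int))
    rng.shuffle(groups)
    for i in range(config.n_idmrs):
        name = f"iDMR_{i:02d}"
        start = 100_000 + i * _IDMR_SPACING
        region_rows.append(Region(
            name=name, chrom="chr2", start=start, end=start + _IDMR_LENGTH,
            dmr_class="germline" if i % 3 else "secondary",
            parental_origin="maternal" if i % 2 else "paternal"))
        for j in range(config.idmr_probes_per_region):
            idmr_ids.append(f"cgID{i:02d}_{j}")
            idmr_chrom.append("chr2")
            idmr_pos.append(start + 300 * (j + 1))
            probe_region.append(name)
    regions = RegionSet(region_rows)
    region_group = dict(zip([r.name for r in region_rows], groups))

    manifest = ProbeManifest(pd.DataFrame({
        "probe_id": bg_ids + idmr_ids,
        "chrom": bg_chrom + idmr_chrom,
        "pos": bg_pos + idmr_pos,
        "snp_overlap": False,
        "sex_chrom": False,
    }))
    probe_ids = manifest.probe_ids
    n_probes = len(probe_ids)
    probe_index = {p: i for i, p in enumerate(probe_ids)}

    # ---- baseline β -------------------------------------------------------
    baseline = np.empty(n_probes)
    bg_n = len(bg_ids)
    high_mode = rng.random(bg_n) < config.high_mode_fraction
    baseline[:bg_n] = np.where(high_mode, config.bimodal_high, config.bimodal_low)
    for pid, rname in zip(idmr_ids, probe_region):
        baseline[probe_index[pid]] = _GROUP_LEVELS[region_group[rname]]
    jitter = rng.uniform(-0.02, 0.02, size=n_probes)
    baseline = np.clip(baseline + jitter, 0.02, 0.98)

    # ---- choose planted loci ---------------------------------------------
    # bins: runs of lengths cycling 2/1/3 to give both clusters and isolated
    n_planted_bins = round(config.planted_hypo_fraction_bins * n_bins)
    run_lengths: List[int] = []
    cycle = [2, 1, 3]
    while sum(run_lengths) < n_planted_bins:
        run_lengths.append(min(cycle[len(run_lengths) % 3],
                               n_planted_bins - sum(run_lengths)))
    runs: List[List[int]] = []
    cursor = 4
    for ln in run_lengths:
        if cursor + ln > n_bins:
            raise ValidationError("not enough bins to place planted runs")
        runs.append(list(range(cursor, cursor + ln)))
        cursor += ln + 3  # gap keeps runs non-contiguous
    run_names = [f"run{i}" for i in range(len(runs))]
    run_probes: Dict[str, List[str]] = {}
    for name, bins in zip(run_names, runs):
        plist = []
        for b in bins:
            plist.extend([bg_ids[2 * b], bg_ids[2 * b + 1]])
            # planted bins must start from a high baseline for a −Δβ shift
            for p in plist:
                baseline[probe_index[p]] = max(baseline[probe_index[p]],
                                               config.bimodal_high - 0.02)
        run_probes[name] = plist

    high_regions = [r.name for r in region_rows if region_group[r.name] == "high"]
    n_planted_idmr = min(round(config.planted_hypo_fraction_idmr * config.n_idmrs),
                         len(high_regions))
    planted_regions = list(rng.choice(high_regions, size=n_planted_idmr,
                                      replace=False))
    region_probes = {rn: [p for p, rr in zip(idmr_ids, probe_region) if rr == rn]
                     for rn in planted_regions}

    loci = run_names + planted_regions
    locus_probes = {**run_probes, **region_probes}
    locus_sizes = {l: len(ps) for l, ps in locus_probes.items()}
    assignment = _split_loci(loci, config.shared_planted_fraction, patients, rng)
    resistant = _assign_resistance(assignment, locus_sizes,
                                   config.resistant_fraction, patients, rng)

    # ---- sample matrices --------------------------------------------------
    def noisy(base: np.ndarray) -> np.ndarray:
        return np.clip(base + rng.normal(0, config.control_noise_sd, n_probes),
                       0.0, 1.0)

    columns: Dict[str, np.ndarray] = {}
    sheet_rows = []
    for i in range(config.n_controls):
        sid = f"WT{i + 1:02d}"
        columns[sid] = noisy(baseline)
        sheet_rows.append((sid, "control", None, "iPSC"))

    # optional control instability at some non-planted iDMRs
    unstable_pool = [r for r in high_regions if r not in planted_regions]
    n_unstable = round(config.unstable_control_fraction * config.n_idmrs)
    for rname in unstable_pool[:n_unstable]:
        ctrl = f"WT{int(rng.integers(1, config.n_controls + 1)):02d}"
        idx = [probe_index[p] for p, rr in zip(idmr_ids, probe_region) if rr == rname]
        columns[ctrl][idx] = np.clip(columns[ctrl][idx] - 0.3, 0.0, 1.0)

    patient_base: Dict[str, np.ndarray] = {}
    for pat in patients:
        base = baseline.copy()
        for locus, pats in assignment.items():
            if pat in pats:
                idx = [probe_index[p] for p in locus_probes[locus]]
                base[idx] = np.clip(base[idx] - config.planted_effect, 0.0, 1.0)
        patient_base[pat] = base
        columns[pat] = noisy(base)
        sheet_rows.append((pat, "patient", None, "iPSC"))

    for pat in patients:
        for j in range(config.clones_per_patient):
            sid = f"{pat}c{j + 1}"
            base = patient_base[pat].copy()
            for locus, pats in assignment.items():
                if pat in pats and not resistant[locus]:
                    idx = [probe_index[p] for p in locus_probes[locus]]
                    base[idx] = baseline[idx]  # redrawn from control distribution
            columns[sid] = noisy(base)
            sheet_rows.append((sid, "corrected", pat, "iPSC"))

    for i in range(config.n_fibroblasts):
        sid = f"F{i + 1}"
        base = baseline.copy()
        idx = [probe_index[p] for p in idmr_ids]
        base[idx] = config.fibroblast_idmr_level
        columns[sid] = noisy(base)
        sheet_rows.append((sid, "control", None, "fibroblast"))

    beta = BetaMatrix(pd.DataFrame(columns, index=pd.Index(probe_ids, name="unit_id")))
    sheet = SampleSheet(pd.DataFrame(sheet_rows, columns=[
        "sample_id", "role", "parent_patient", "cell_type"]))

    # ---- ChIP counts ------------------------------------------------------
    chip_rows = []
    clone_parent = {f"{p}c{j + 1}": p for p in patients
                    for j in range(config.clones_per_patient)}
    conditions = ["WT"] + patients + list(clone_parent)
    for cond in conditions:
        for r in region_rows:
            planted_here = False
            if cond in patients:
                planted_here = (r.name in assignment and cond in assignment[r.name])
            elif cond != "WT":
                parent = clone_parent[cond]
                planted_here = (r.name in assignment and parent in
                                assignment[r.name] and resistant[r.name])
            fc = config.chip_fc_at_hypo if planted_here else 1.0
            for rep in range(1, config.chip_replicates + 1):
                ip = int(rng.poisson(config.chip_base_count * fc))
                inp = int(rng.poisson(config.chip_base_count))
                chip_rows.append((r.name, cond, rep, ip, inp,
                                  config.chip_depth, config.chip_depth))
    chip = ChipCountTable(pd.DataFrame(chip_rows, columns=[
        "region", "condition", "replicate", "ip_count", "input_count",
        "ip_depth", "input_depth"]))

    # ---- truth ------------------------------------------------------------
    probe_truth = pd.DataFrame({
        "probe_id": probe_ids,
        "status": "null",
        "patients": "",
        "resistant": False,
        "locus_id": "",
    }).set_index("probe_id", drop=False)
    for locus, pats in assignment.items():
        for p in locus_probes[locus]:
            probe_truth.loc[p, ["status", "patients", "resistant", "locus_id"]] = \
                ["hypo", "+".join(sorted(pats)), resistant[locus], locus]

    bin_rows = []
    planted_bin_info = {}
    for name, bins in zip(run_names, runs):
        for b in bins:
            planted_bin_info[b] = (name, len(bins) >= 2)
    for i in range(n_bins):
        name, in_cluster = planted_bin_info.get(i, ("", False))
        bin_rows.append((f"chr1:{BIN_SIZE * i}-{BIN_SIZE * (i + 1)}", "chr1",
                         BIN_SIZE * i, bool(name),
                         "+".join(sorted(assignment[name])) if name else "",
                         in_cluster, resistant.get(name, False)))
    bin_truth = pd.DataFrame(bin_rows, columns=[
        "bin_id", "chrom", "start", "planted", "patients", "in_cluster",
        "resistant"])

    region_truth = pd.DataFrame({
        "name": [r.name for r in region_rows],
        "group": [region_group[r.name] for r in region_rows],
        "planted": [r.name in assignment for r in region_rows],
        "patients": ["+".join(sorted(assignment.get(r.name, []))) for r in region_rows],
        "resistant": [resistant.get(r.name, False) for r in region_rows],
    })

    truth = TruthTable(probes=probe_truth.reset_index(drop=True),
                       bins=bin_truth, regions=region_truth)
    return SimBundle(beta=beta, manifest=manifest, regions=regions, sheet=sheet,
                     chip=chip, truth=truth, config=config, baseline=baseline)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

FILENAMES = ("beta.tsv", "manifest.tsv", "regions.bed", "samples.tsv",
             "chip.tsv", "truth.tsv")


def write_bundle(bundle: SimBundle, out_dir) -> List[Path]:
    """Write the bundle as six TSV/BED files round-tripping through the
    readers; identical config + seed gives byte-identical output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.beta, out / "beta.tsv")
    write_manifest(bundle.manifest, out / "manifest.tsv")
    write_regions(bundle.regions, out / "regions.bed")
    write_sample_sheet(bundle.sheet, out / "samples.tsv")
    write_chip_counts(bundle.chip, out / "chip.tsv")
    truth = pd.concat([
        bundle.truth.probes.assign(level="probe").rename(columns={"probe_id": "id"}),
        bundle.truth.bins.assign(level="bin").rename(columns={"bin_id": "id"}),
        bundle.truth.regions.assign(level="region").rename(columns={"name": "id"}),
    ], ignore_index=True)
    cols = ["level", "id", "status", "patients", "resistant", "locus_id",
            "chrom", "start", "planted", "in_cluster", "group"]
    truth.reindex(columns=cols).to_csv(out / "truth.tsv", sep="\t", index=False)
    return [out / name for name in FILENAMES]


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[], dtype={"id": str})
    def level(lv):
        return df[df["level"] == lv].copy()
    probes = level("probe").rename(columns={"id": "probe_id"})
    probes = probes[["probe_id", "status", "patients", "resistant", "locus_id"]]
    probes["resistant"] = probes["resistant"].astype(str) == "True"
    bins = level("bin").rename(columns={"id": "bin_id"})
    bins = bins[["bin_id", "chrom", "start", "planted", "patients",
                 "in_cluster", "resistant"]]
    for col in ("planted", "in_cluster", "resistant"):
        bins[col] = bins[col].astype(str) == "True"
    bins["start"] = bins["start"].astype(float).astype(int)
    regions = level("region").rename(columns={"id": "name"})
    regions = regions[["name", "group", "planted", "patients", "resistant"]]
    for col in ("planted", "resistant"):
        regions[col] = regions[col].astype(str) == "True"
    return TruthTable(probes=probes.reset_index(drop=True),
                      bins=bins.reset_index(drop=True),
                      regions=regions.reset_index(drop=True))


def read_bundle(in_dir) -> Tuple[BetaMatrix, ProbeManifest, RegionSet,
                                 SampleSheet, ChipCountTable, TruthTable]:
    """Re-read a written bundle with the io readers."""
    d = Path(in_dir)
    return (read_beta_matrix(d / "beta.tsv"),
            read_manifest(d / "manifest.tsv"),
            read_regions(d / "regions.bed"),
            read_sample_sheet(d / "samples.tsv"),
            read_chip_counts(d / "chip.tsv"),
            read_truth(d / "truth.tsv"))
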