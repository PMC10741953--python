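"""End-to-end orchestration: preprocess → reference → CpG calls → bin calls
→ clusters → iDMR analysis → recovery → annotation → enrichment, with a
reproducible JSON run manifest emitted for every run, success or failure.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .annotation_enrichment import (AnnotationClass, annotate_units,
                                    chip_fold_change, enrichment_compare)
from .dm_calling import (UNCHANGED, aggregate_units, bin_membership,
                         build_reference, call_dm_samples, find_clusters)
from .imprint_regions import (call_region_dm, classify_recovery,
                              classify_region_groups, filter_idmr_regions,
                              recovery_summary, region_membership)
from .io_model import (Region, RegionSet, ValidationError, read_beta_matrix,
                       read_chip_counts, read_detection_matrix, read_manifest,
                       read_regions, read_sample_sheet, write_matrix)
from .preprocess import (beta_to_m, control_consistency_filter, filter_probes)

STAGES = ("preprocess", "reference", "cpg_calls", "bin_calls", "clusters",
          "idmr_analysis", "recovery", "annotation", "enrichment")


@dataclass
class RunConfig:
    """Declarative run configuration; every fixed analysis constant lives
    here with its conventional default."""

    beta: str
    manifest: str
    samples: str
    regions: str
    out_dir: str = "imprintscan_out"
    detection: Optional[str] = None
    chip: Optional[str] = None
    annotations: Optional[str] = None
    k: float = 3.0
    delta: float = 0.2
    p_detect: float = 0.01
    control_max_dev: float = 0.2
    min_cpgs_bin: int = 2
    min_probes_region: int = 3
    min_cluster_bins: int = 2
    recovery_delta: float = 0.2
    bin_size: int = 500
    eps: float = 0.001
    exclude_regions: Tuple[str, ...] = ()
    chip_reference_condition: str = "WT"
    chip_alternative: str = "greater"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "exclude_regions" in raw:
            raw["exclude_regions"] = tuple(raw["exclude_regions"])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list = field(default_factory=list)
    status: str = "running"

    def record(self, name: str, status: str, seconds: float, counts: dict):
        self.stages.append({"name": name, "status": status,
                            "seconds": round(seconds, 3), "counts": counts})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def run_all(config: RunConfig) -> RunManifest:
    """Run every stage in order, writing per-stage TSV outputs and a JSON
    manifest. A stage whose optional inputs are absent is recorded as
    skipped; a failure is recorded and re-raised after the manifest is
    written."""
    for attr in ("beta", "manifest", "samples", "regions"):
        p = getattr(config, attr)
        if not Path(p).exists():
            raise ValidationError(f"input file for {attr!r} does not exist: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_doc = RunManifest(config=asdict(config), version=__version__)

    try:
        _run_stages(config, out, manifest_doc)
        manifest_doc.status = "success"
    except Exception:
        manifest_doc.status = "failed"
        raise
    finally:
        manifest_doc.write(out / "run_manifest.json")
    return manifest_doc


def _run_stages(config: RunConfig, out: Path, doc: RunManifest) -> None:
    t0 = time.perf_counter()

    # -- preprocess ---------------------------------------------------------
    beta = read_beta_matrix(config.beta)
    probe_manifest = read_manifest(config.manifest)
    sheet = read_sample_sheet(config.samples)
    detection = (read_detection_matrix(config.detection)
                 if config.detection else None)
    beta_f, rep1 = filter_probes(beta, probe_manifest, detection,
                                 p_threshold=config.p_detect)
    beta_f, rep2 = control_consistency_filter(beta_f, sheet,
                                              max_dev=config.control_max_dev)
    write_matrix(beta_f, out / "beta_filtered.tsv")
    with open(out / "filter_report.json", "w") as fh:
        json.dump({"probe_filters": rep1.to_dict(),
                   "control_consistency": rep2.to_dict()}, fh, indent=2)
    doc.record("preprocess", "ok", time.perf_counter() - t0,
               {"n_input": rep1.n_input, "n_retained": rep2.n_retained})

    # -- reference ----------------------------------------------------------
    t0 = time.perf_counter()
    m = beta_to_m(beta_f, eps=config.eps)
    ref = build_reference(beta_f, m, sheet)
    ref.table.to_csv(out / "control_reference.tsv", sep="\t",
                     index_label="unit_id")
    doc.record("reference", "ok", time.perf_counter() - t0,
               {"n_units": len(ref.table),
                "n_controls": len(sheet.controls())})

    # -- per-CpG calls ------------------------------------------------------
    t0 = time.perf_counter()
    test_samples = sheet.patients() + sheet.corrected()
    cpg_calls = call_dm_samples(beta_f, m, ref, test_samples,
                                k=config.k, delta=config.delta)
    cpg_calls.to_csv(out / "cpg_calls.tsv", sep="\t", index=False)
    doc.record("cpg_calls", "ok", time.perf_counter() - t0,
               _call_counts(cpg_calls))

    # -- bin calls ----------------------------------------------------------
    t0 = time.perf_counter()
    membership = bin_membership(probe_manifest, bin_size=config.bin_size)
    bin_beta = aggregate_units(beta_f, membership, min_cpgs=config.min_cpgs_bin)
    bin_m = beta_to_m(bin_beta, eps=config.eps)
    bin_ref = build_reference(bin_beta, bin_m, sheet)
    bin_calls = call_dm_samples(bin_beta, bin_m, bin_ref, test_samples,
                                k=config.k, delta=config.delta)
    write_matrix(bin_beta, out / "bin_beta.tsv", index_label="bin_id")
    bin_calls.to_csv(out / "bin_calls.tsv", sep="\t", index=False)
    doc.record("bin_calls", "ok", time.perf_counter() - t0,
               {"n_bins": len(bin_beta.data), **_call_counts(bin_calls)})

    # -- clusters -----------------------------------------------------------
    t0 = time.perf_counter()
    cluster_rows = []
    counts = {}
    for pat in sheet.patients():
        dm_bins = bin_calls.loc[(bin_calls["sample_id"] == pat) &
                                (bin_calls["status"] != UNCHANGED), "unit_id"]
        cs = find_clusters(dm_bins, min_bins=config.min_cluster_bins,
                           bin_size=config.bin_size)
        for ci, cluster in enumerate(cs.clusters):
            for b in cluster:
                cluster_rows.append((pat, f"{pat}_cluster{ci}", b))
        for b in cs.isolated:
            cluster_rows.append((pat, "isolated", b))
        counts[pat] = {"n_clusters": len(cs.clusters),
                       "n_cluster_bins": cs.n_cluster_bins,
                       "n_isolated": len(cs.isolated)}
    pd.DataFrame(cluster_rows, columns=["sample_id", "cluster", "bin_id"]) \
        .to_csv(out / "clusters.tsv", sep="\t", index=False)
    doc.record("clusters", "ok", time.perf_counter() - t0, counts)

    # -- iDMR analysis ------------------------------------------------------
    t0 = time.perf_counter()
    regions = read_regions(config.regions)
    regions_f = filter_idmr_regions(regions, probe_manifest,
                                    min_probes=config.min_probes_region,
                                    exclude=config.exclude_regions)
    r_membership = region_membership(regions_f, probe_manifest)
    region_beta = aggregate_units(beta_f, r_membership,
                                  min_cpgs=config.min_probes_region)
    groups = classify_region_groups(region_beta, sheet)
    region_calls, region_ref = call_region_dm(region_beta, sheet,
                                              k=config.k, delta=config.delta,
                                              eps=config.eps)
    write_matrix(region_beta, out / "region_beta.tsv", index_label="region")
    groups.to_csv(out / "region_groups.tsv", sep="\t", index=False)
    region_calls.to_csv(out / "region_calls.tsv", sep="\t", index=False)
    doc.record("idmr_analysis", "ok", time.perf_counter() - t0,
               {"n_regions_input": len(regions),
                "n_regions_analyzed": len(regions_f),
                **_call_counts(region_calls)})

    # -- recovery -----------------------------------------------------------
    t0 = time.perf_counter()
    patient_cpg = cpg_calls[cpg_calls["sample_id"].isin(sheet.patients())]
    recovery = classify_recovery(patient_cpg, beta_f, ref, sheet,
                                 delta=config.recovery_delta)
    if recovery.empty:
        doc.record("recovery", "ok", time.perf_counter() - t0,
                   {"n_recovery_calls": 0})
    else:
        summary = recovery_summary(recovery)
        recovery.to_csv(out / "recovery_calls.tsv", sep="\t", index=False)
        summary.per_clone.to_csv(out / "recovery_summary.tsv", sep="\t",
                                 index=False)
        doc.record("recovery", "ok", time.perf_counter() - t0,
                   {"n_recovery_calls": len(recovery),
                    "percent_recovered": {
                        row.corrected_id: round(row.percent, 1)
                        for row in summary.per_clone.itertuples()}})

    # -- annotation ---------------------------------------------------------
    t0 = time.perf_counter()
    classes = _load_annotation_classes(config.annotations, regions_f)
    dm_units = cpg_calls.loc[cpg_calls["status"] != UNCHANGED, "unit_id"].unique()
    from .io_model import ProbeManifest  # narrow import to keep header light
    dm_manifest = ProbeManifest(
        probe_manifest.frame.loc[
            probe_manifest.frame["probe_id"].isin(dm_units)].reset_index(drop=True))
    labels = annotate_units(dm_manifest, classes)
    pd.DataFrame([(u, ";".join(ls)) for u, ls in labels.items()],
                 columns=["unit_id", "classes"]) \
        .to_csv(out / "dm_annotation.tsv", sep="\t", index=False)
    doc.record("annotation", "ok", time.perf_counter() - t0,
               {"n_dm_units": len(labels),
                "n_classes": len(classes)})

    # -- enrichment ---------------------------------------------------------
    t0 = time.perf_counter()
    if config.chip is None:
        doc.record("enrichment", "skipped", time.perf_counter() - t0, {})
        return
    chip = read_chip_counts(config.chip)
    fc = chip_fold_change(chip)
    refc = config.chip_reference_condition
    cases = [c for c in fc["condition"].unique() if c != refc]
    stats = enrichment_compare(fc, [(c, refc) for c in cases],
                               alternative=config.chip_alternative)
    fc.to_csv(out / "chip_fc.tsv", sep="\t", index=False)
    stats.to_csv(out / "enrichment_stats.tsv", sep="\t", index=False)
    doc.record("enrichment", "ok", time.perf_counter() - t0,
               {"n_comparisons": len(stats)})


def _call_counts(calls: pd.DataFrame) -> dict:
    by = calls.groupby("sample_id")["status"]
    return {s: {"hypo": int((g == "hypo").sum()),
                "hyper": int((g == "hyper").sum())}
            for s, g in by}


def _load_annotation_classes(path: Optional[str],
                             fallback_regions: RegionSet) -> list:
    """Annotation classes from a TSV (chrom start end name class), or — if
    none is given — a single class built from the analyzed region set."""
    if path is None:
        return [AnnotationClass(name="iDMR", regions=fallback_regions)]
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "class_name"])
    classes = []
    for cname, g in df.groupby("class_name", sort=False):
        regions = RegionSet([
            Region(name=str(r.name), chrom=str(r.chrom), start=int(r.start),
                   end=int(r.end)) for r in g.itertuples(index=False)])
        classes.append(AnnotationClass(name=str(cname), regions=regions))
    return classes
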