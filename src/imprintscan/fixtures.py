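"""Packaged frozen fixtures: the 50-region human iDMR list and the probe
manifest giving each region's array coverage.

The live upstream catalogue is versionless, so the repository ships a frozen
snapshot and treats the online list as an external resource.
"""
from importlib.resources import files

from .io_model import ProbeManifest, RegionSet, read_manifest, read_regions

VTRNA2 = "VTRNA2"  # polymorphic region conventionally excluded from analysis


def load_idmr_regions() -> RegionSet:
    """The frozen 50-region iDMR set (BED-like, 0-based half-open)."""
    with (files("imprintscan.data") / "idmr_regions.bed").open("r") as fh:
        return read_regions(fh)


def load_idmr_manifest() -> ProbeManifest:
    """Array probes covering the frozen iDMR set (per-region coverage counts)."""
    with (files("imprintscan.data") / "idmr_probes.tsv").open("r") as fh:
        return read_manifest(fh)
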