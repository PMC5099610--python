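"""Run configuration for the BAC-pool simulation toolkit.

Every stage of the pipeline is driven by a :class:`RunConfig`, a nested set
of frozen-ish dataclasses with defaults matching the published study design
for the Asian seabass LG2 target region: a ~98 kb HindIII clone library
pooled into 100 plate / 16 row / 24 column superpools, MiSeq-style 2x250 bp
paired reads at 130x per clone with 475 bp fragments, ~24x of long reads,
mapping thresholds of 0.2/0.9 (long-read mining) and 0.95/0.95 (read-back
validation), a 1.36 kb/CB physical-map calibration and a 3.4 cM/Mb genetic
map rate.  Parameters that the study design does not pin down (noise rates,
repeat family geometry, fragment-length spread) carry artifact-chosen
defaults documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "GenomeConfig",
    "LibraryConfig",
    "PoolConfig",
    "ReadConfig",
    "AssemblyConfig",
    "SyntenyConfig",
    "AssocConfig",
    "RunConfig",
    "derive_seed",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from the global seed.

    Uses a CRC32 of the stage name mixed with the global seed so that each
    pipeline stage gets an independent, reproducible stream and any stage can
    be re-run in isolation.  The result is always in ``[0, 2**31)``.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class GenomeConfig:
    """Synthetic target-region genome.

    ``at_fraction`` and ``repeat_fraction`` default to the composition
    observed for the assembled target region (59.39% AT, ~5.6% repeats).
    """

    length_bp: int = 1_000_000
    at_fraction: float = 0.594
    repeat_fraction: float = 0.056
    n_repeat_families: int = 5
    repeat_unit_range: tuple[int, int] = (500, 3000)
    repeat_divergence: tuple[float, float] = (0.01, 0.05)
    n_markers: int = 20
    marker_amplicon_len: int = 300
    n_genes: int = 26
    gene_len_range: tuple[int, int] = (2000, 8000)
    n_snps: int = 13
    snp_alt_freq_range: tuple[float, float] = (0.2, 0.5)
    map_rate_cm_per_mb: float = 3.4


@dataclass
class LibraryConfig:
    """Clone library, fingerprinting and physical-map parameters."""

    cloning_site: str = "AAGCTT"  # HindIII
    partial_digest_prob: float = 0.03
    size_window: tuple[int, int] = (80_000, 120_000)
    coverage_fold: float = 6.0  # clone coverage of the simulated genome
    mean_insert_kb: float = 98.0
    # 5-mer with 3 G/C letters: ~1.36 kb mean spacing at the default AT
    # fraction, so distinct consensus bands calibrate to ~1.36 kb/CB.
    fingerprint_site: str = "GCCAT"
    band_tolerance_bp: int = 3
    min_shared_bands: int = 20
    kb_per_cb: float = 1.36


@dataclass
class PoolConfig:
    """3D pool layout and PCR screen noise."""

    n_plates: int = 100
    n_rows: int = 16
    n_cols: int = 24
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    noisy_confirmation: bool = False


@dataclass
class ReadConfig:
    """Short/long read simulation parameters."""

    read_len: int = 250
    frag_mean: int = 475
    frag_sd: int = 50
    short_coverage: float = 130.0
    short_err_rate: float = 0.002
    long_coverage: float = 24.0
    long_len_range: tuple[int, int] = (500, 31_400)
    long_err_rate: float = 0.01  # residual error of self-corrected long reads


@dataclass
class AssemblyConfig:
    """Preprocessing, assembly, scaffolding and validation thresholds."""

    trim_leading_q: int = 3
    trim_trailing_q: int = 6
    trim_window: int = 4
    trim_window_q: int = 15
    trim_min_len: int = 150
    norm_k: int = 25
    norm_target_cov: int = 100
    min_overlap: int = 40
    min_identity: float = 0.97
    seed_k: int = 15  # k-mer seed for all internal alignment
    map_len_frac: float = 0.2
    map_sim: float = 0.9
    merge_identity: float = 0.99
    merge_min_overlap: int = 20
    val_len_frac: float = 0.95
    val_sim: float = 0.95
    bes_len: int = 854
    bes_end_success: float = 0.972


@dataclass
class SyntenyConfig:
    min_genes: int = 2
    max_query_gap: int = 1
    max_target_gap_genes: int = 5
    max_target_gap_bp: int = 1_000_000
    secondary_homolog_frac: float = 0.25


@dataclass
class AssocConfig:
    n_families: int = 5
    n_offspring: int = 570
    family_weights: tuple[float, ...] = (0.621, 0.273, 0.05, 0.036, 0.02)
    family_sd: float = 0.0
    residual_sd: float = 1.0
    alpha: float = 0.05
    min_family_n: int = 30


@dataclass
class RunConfig:
    """Top-level configuration: one global seed drives every stage."""

    seed: int = 1
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    library: LibraryConfig = field(default_factory=LibraryConfig)
    pools: PoolConfig = field(default_factory=PoolConfig)
    reads: ReadConfig = field(default_factory=ReadConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    stages: tuple[str, ...] = (
        "genome",
        "library",
        "screen",
        "reads",
        "assembly",
        "synteny",
        "association",
    )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            val = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SECTIONS:
                section_cls = _SECTIONS[f.name]
                val = _coerce_section(section_cls, val)
            elif f.name == "stages":
                val = tuple(val)
            kwargs[f.name] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def param_hash(self) -> str:
        """Stable hash of all parameters (used in run manifests)."""
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True).encode()
        return f"{zlib.crc32(blob):08x}"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


_SECTIONS = {
    "genome": GenomeConfig,
    "library": LibraryConfig,
    "pools": PoolConfig,
    "reads": ReadConfig,
    "assembly": AssemblyConfig,
    "synteny": SyntenyConfig,
    "assoc": AssocConfig,
}


def _coerce_section(section_cls, val):
    if isinstance(val, section_cls):
        return val
    out = {}
    for f in dataclasses.fields(section_cls):
        if f.name in val:
            v = val[f.name]
            if isinstance(v, list):
                v = tuple(v)
            out[f.name] = v
    return section_cls(**out)


def _listify(obj):
    """Convert tuples to lists recursively (YAML-friendly)."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
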