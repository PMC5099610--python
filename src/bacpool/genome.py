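"""Ground-truthed synthetic genome for the targeted linkage-group region.

Generates a single chromosome segment with interspersed repeat families,
non-overlapping gene models, SSR marker loci with guaranteed-unique amplicon
templates, and bi-allelic SNPs inside genes with additive trait effects.
Every downstream stage (cloning, pooling, sequencing, assembly, synteny,
association) consumes this truth object, so simulated results can always be
scored against known coordinates.

All coordinates are 0-based half-open.  Genetic map positions are a linear
function of physical position (``cM = bp / 1e6 * rate``), mirroring a
uniform recombination rate along the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import GenomeConfig

__all__ = [
    "MarkerLocus",
    "SnpLocus",
    "GenomeTruth",
    "generate_genome",
    "assign_genetic_positions",
    "revcomp",
    "ConfigurationError",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

TRAITS = ("BW", "TL", "SL")


class ConfigurationError(ValueError):
    """Raised when the requested annotation load cannot be packed."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MarkerLocus:
    """An SSR screening marker: unique amplicon template at a map position."""

    marker_id: str
    position_bp: int
    position_cm: float
    amplicon: str


@dataclass
class SnpLocus:
    """A bi-allelic SNP inside a gene with per-trait additive effects."""

    snp_id: str
    gene_id: str
    position_bp: int
    ref_allele: str
    alt_allele: str
    additive_effect: dict[str, float]
    alt_freq: float

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError("alt_freq must be in [0, 1]")


@dataclass
class GenomeTruth:
    seq: str
    length_bp: int
    repeats: list[tuple[int, int, str]] = field(default_factory=list)
    markers: list[MarkerLocus] = field(default_factory=list)
    genes: list[tuple[str, int, int, str]] = field(default_factory=list)
    snps: list[SnpLocus] = field(default_factory=list)
    seed: int = 0

    # -- composition -------------------------------------------------------

    def at_fraction(self) -> float:
        a = self.seq.count("A") + self.seq.count("T")
        return a / max(1, self.length_bp)

    def repeat_fraction(self) -> float:
        return sum(e - s for s, e, _ in self.repeats) / max(1, self.length_bp)

    # -- export ------------------------------------------------------------

    def to_fasta(self, path, name: str = "target_region") -> None:
        rec = SeqRecord(Seq(self.seq), id=name, description=f"seed={self.seed}")
        SeqIO.write([rec], str(path), "fasta")

    def markers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.marker_id, m.position_bp, round(m.position_cm, 2), m.amplicon)
                for m in self.markers
            ],
            columns=["marker_id", "position_bp", "position_cm", "amplicon"],
        )

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genes, columns=["gene_id", "start", "end", "strand"])

    def repeats_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.repeats, columns=["start", "end", "family_id"])

    def snps_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.snps:
            row = {
                "snp_id": s.snp_id,
                "gene_id": s.gene_id,
                "position_bp": s.position_bp,
                "ref_allele": s.ref_allele,
                "alt_allele": s.alt_allele,
                "alt_freq": s.alt_freq,
            }
            for t in TRAITS:
                row[f"effect_{t}"] = s.additive_effect.get(t, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tables(self, outdir) -> None:
        outdir = Path(outdir)
        self.markers_frame().to_csv(outdir / "markers.tsv", sep="\t", index=False)
        self.genes_frame().to_csv(outdir / "genes.tsv", sep="\t", index=False)
        self.repeats_frame().to_csv(outdir / "repeats.tsv", sep="\t", index=False)
        self.snps_frame().to_csv(outdir / "snps.tsv", sep="\t", index=False)
        # BED export is 0-based half-open by construction
        with open(outdir / "features.bed", "w") as fh:
            for s, e, fam in self.repeats:
                fh.write(f"target_region\t{s}\t{e}\trepeat:{fam}\n")
            for gid, s, e, strand in self.genes:
                fh.write(f"target_region\t{s}\t{e}\tgene:{gid}\t0\t{strand}\n")


# ---------------------------------------------------------------------------


def assign_genetic_positions(markers: list[MarkerLocus], rate_cm_per_mb: float) -> list[MarkerLocus]:
    """Assign ``position_cm = position_bp / 1e6 * rate`` to each marker.

    The map is linear and therefore strictly order-preserving.
    """
    if rate_cm_per_mb <= 0:
        raise ValueError("recombination rate must be positive")
    for m in markers:
        m.position_cm = m.position_bp / 1e6 * rate_cm_per_mb
    return markers


def _random_seq(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute a ``rate`` fraction of positions with a different base."""
    arr = arr.copy()
    pos = np.nonzero(rng.random(arr.size) < rate)[0]
    if pos.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        repl = bases[rng.integers(0, 4, pos.size)]
        clash = repl == arr[pos]
        while clash.any():
            repl[clash] = bases[rng.integers(0, 4, int(clash.sum()))]
            clash = repl == arr[pos]
        arr[pos] = repl
    return arr


def _place_intervals(
    rng: np.random.Generator,
    lengths: list[int],
    genome_len: int,
    occupied: list[tuple[int, int]],
    max_tries: int = 200,
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals of the given lengths by rejection."""
    placed = []
    taken = sorted(occupied)
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    out: list[tuple[int, int] | None] = [None] * len(lengths)
    for idx in order:
        L = lengths[idx]
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(0, max(1, genome_len - L)))
            e = s + L
            if all(e <= ts or s >= te for ts, te in taken):
                out[idx] = (s, e)
                taken.append((s, e))
                taken.sort()
                ok = True
                break
        if not ok:
            raise ConfigurationError(
                f"could not place interval of {L} bp: annotation load too dense"
            )
    placed = [iv for iv in out if iv is not None]
    return placed


def generate_genome(config: GenomeConfig, seed: int) -> GenomeTruth:
    """Generate a ground-truthed genome honoring the configured composition.

    Raises :class:`ConfigurationError` when the requested repeats and genes
    cannot be packed into the genome.  Identical ``(config, seed)`` pairs
    produce byte-identical output.
    """
    if config.length_bp < 1:
        raise ConfigurationError("genome length must be positive")
    if not 0 <= config.repeat_fraction < 1:
        raise ConfigurationError("repeat fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    L = config.length_bp
    arr = _random_seq(rng, L, config.at_fraction)

    # --- repeats: a few families, copies with per-copy divergence ---------
    repeats: list[tuple[int, int, str]] = []
    target_repeat_bp = int(config.repeat_fraction * L)
    if target_repeat_bp > 0 and config.n_repeat_families > 0:
        lo, hi = config.repeat_unit_range
        lo = min(lo, L // 4) or 1
        hi = max(lo + 1, min(hi, L // 2))
        families = {
            f"fam{i}": _random_seq(rng, int(rng.integers(lo, hi)), config.at_fraction)
            for i in range(config.n_repeat_families)
        }
        fam_ids = sorted(families)
        lengths, fams = [], []
        total = 0
        while total < target_repeat_bp:
            fam = fam_ids[int(rng.integers(0, len(fam_ids)))]
            lengths.append(families[fam].size)
            fams.append(fam)
            total += families[fam].size
        spots = _place_intervals(rng, lengths, L, [])
        d_lo, d_hi = config.repeat_divergence
        for (s, e), fam in zip(spots, fams):
            div = rng.uniform(d_lo, d_hi)
            arr[s:e] = _mutate(rng, families[fam], div)
            repeats.append((s, e, fam))
        repeats.sort()

    # --- genes: non-overlapping, outside repeats --------------------------
    genes: list[tuple[str, int, int, str]] = []
    if config.n_genes > 0:
        glo, ghi = config.gene_len_range
        lens = [int(rng.integers(glo, ghi)) for _ in range(config.n_genes)]
        if sum(lens) + sum(e - s for s, e, _ in repeats) > 0.9 * L:
            raise ConfigurationError("repeats + genes exceed genome capacity")
        spots = _place_intervals(rng, lens, L, [(s, e) for s, e, _ in repeats])
        spots.sort()
        for i, (s, e) in enumerate(spots):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((f"gene{i:03d}", s, e, strand))

    seq = arr.tobytes().decode()

    # --- SSR markers: unique amplicon templates by rejection sampling -----
    markers: list[MarkerLocus] = []
    if config.n_markers > 0:
        amp_len = config.marker_amplicon_len
        if amp_len >= L:
            raise ConfigurationError("amplicon longer than genome")
        ssr = "AC" * 8
        stride = L // config.n_markers
        for i in range(config.n_markers):
            lo_i = i * stride
            hi_i = min(L - amp_len, (i + 1) * stride - amp_len)
            placed = False
            for _ in range(60):
                pos = int(rng.integers(lo_i, max(lo_i + 1, hi_i)))
                mid = pos + amp_len // 2
                cand = seq[:mid] + ssr + seq[mid + len(ssr):]
                amp = cand[pos:pos + amp_len]
                if cand.count(amp) == 1 and revcomp(amp) not in cand:
                    seq = cand
                    markers.append(MarkerLocus(f"ssr{i:03d}", pos, 0.0, amp))
                    placed = True
                    break
            if not placed:
                raise ConfigurationError(f"could not place unique marker {i}")
        assign_genetic_positions(markers, config.map_rate_cm_per_mb)

    # --- SNPs inside genes with additive trait effects --------------------
    snps: list[SnpLocus] = []
    if config.n_snps > 0 and genes:
        f_lo, f_hi = config.snp_alt_freq_range
        for i in range(config.n_snps):
            gid, gs, ge, _ = genes[int(rng.integers(0, len(genes)))]
            pos = int(rng.integers(gs, ge))
            ref = seq[pos]
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == ref:
                alt = _BASES[int(rng.integers(0, 4))]
            # roughly a third of simulated SNPs carry a real additive effect
            if i % 3 == 0:
                eff = {t: float(rng.uniform(0.3, 1.0)) for t in TRAITS}
            else:
                eff = {t: 0.0 for t in TRAITS}
            snps.append(
                SnpLocus(
                    f"snp{i:02d}", gid, pos, ref, alt, eff,
                    float(rng.uniform(f_lo, f_hi)),
                )
            )
        snps.sort(key=lambda s: s.position_bp)

    return GenomeTruth(
        seq=seq,
        length_bp=L,
        repeats=repeats,
        markers=markers,
        genes=genes,
        snps=snps,
        seed=seed,
    )
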