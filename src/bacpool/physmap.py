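"""Clone library and physical map: digestion, fingerprints, FPC contigs, MTP.

The clone library is simulated as a partial restriction digest followed by
size selection: each recognition site is retained independently with a small
probability, fragments falling inside the size-selection window become clone
inserts, and clones receive sequential plate/row/column addresses.  HICF
fingerprinting is abstracted to the multiset of complete-digest fragment
sizes of an insert, binned at a small tolerance.  Contig building is
single-linkage clustering on shared-band counts; the number of *distinct*
consensus bands in a contig is its CB-unit length, which calibrates to
kilobases through ``kb_per_cb``.

The minimum tiling path (MTP) is a greedy left-to-right interval cover over
the truth coordinates of the clones in a contig; on gap-free instances the
greedy cover is provably minimum.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeTruth

__all__ = [
    "BacClone",
    "Fingerprint",
    "FpcContig",
    "TilingPath",
    "digest_and_clone",
    "coverage_fold",
    "fingerprint_clone",
    "shared_band_count",
    "build_fpc_contigs",
    "select_mtp",
    "minimum_cover_bruteforce",
    "cb_to_kb",
    "cm_to_mb",
    "SamplingExhaustedError",
    "CoverGapError",
]

import numpy as np


class SamplingExhaustedError(RuntimeError):
    """Too few size-eligible fragments to sample the requested clones."""


class CoverGapError(ValueError):
    """The clone set of a contig does not cover a contiguous interval."""

    def __init__(self, gaps):
        self.gaps = list(gaps)
        super().__init__(f"clone set leaves {len(self.gaps)} coverage gap(s): {self.gaps}")


@dataclass
class BacClone:
    clone_id: str
    address: tuple[int, int, int]  # (plate, row, col)
    start: int
    end: int

    @property
    def insert_len_bp(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class Fingerprint:
    clone_id: str
    bands: tuple[int, ...]  # sorted, binned fragment sizes


@dataclass
class FpcContig:
    contig_id: str
    clone_ids: list[str]
    cb_units: float
    true_span: tuple[int, int]

    @property
    def is_singleton(self) -> bool:
        return len(self.clone_ids) == 1


@dataclass
class TilingPath:
    contig_id: str
    clone_ids: list[str] = field(default_factory=list)
    expected_size_kb: float = 0.0


# ---------------------------------------------------------------------------
# unit conversions


def coverage_fold(n_clones: int, mean_insert_kb: float, genome_mb: float) -> float:
    """Genomic equivalents represented by a clone library, to 1 decimal."""
    if genome_mb <= 0:
        raise ValueError("genome size must be positive")
    if n_clones < 0 or mean_insert_kb < 0:
        raise ValueError("clone count and insert size must be non-negative")
    return round(n_clones * mean_insert_kb / (genome_mb * 1000.0), 1)


def cb_to_kb(cb_units: float, kb_per_cb: float = 1.36) -> float:
    """Physical-map consensus-band units to kb (1-decimal report rounding)."""
    if cb_units < 0:
        raise ValueError("CB units must be non-negative")
    return round(cb_units * kb_per_cb, 1)


def cm_to_mb(cm: float, rate_cm_per_mb: float = 3.4) -> float:
    """Genetic distance to physical distance through a cM/Mb rate."""
    if rate_cm_per_mb <= 0:
        raise ValueError("recombination rate must be positive")
    return cm / rate_cm_per_mb


# ---------------------------------------------------------------------------
# cloning and fingerprinting


def find_sites(seq: str, motif: str) -> list[int]:
    """All occurrence start positions of ``motif`` in ``seq``."""
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def digest_and_clone(
    genome: GenomeTruth,
    site: str = "AAGCTT",
    partial_prob: float = 0.03,
    size_window: tuple[int, int] = (80_000, 120_000),
    n_clones: int = 60,
    seed: int = 0,
    design: tuple[int, int, int] = (100, 16, 24),
    max_rounds: int = 5000,
) -> list[BacClone]:
    """Simulate a partial digest + size selection clone library.

    Each simulated digest retains every cut site with probability
    ``partial_prob``; fragments whose length falls inside ``size_window``
    enter the library.  Digest rounds repeat until ``n_clones`` inserts are
    collected.  Raises :class:`SamplingExhaustedError` if rounds stop
    producing eligible fragments.
    """
    if not 0 < partial_prob <= 1:
        raise ValueError("partial digest probability must be in (0, 1]")
    lo, hi = size_window
    if lo >= hi:
        raise ValueError("size window must satisfy min < max")
    n_plates, n_rows, n_cols = design
    if n_clones > n_plates * n_rows * n_cols:
        raise ValueError("more clones than addressable wells")
    rng = np.random.default_rng(seed)
    sites = np.array(find_sites(genome.seq, site), dtype=np.int64)
    inserts: list[tuple[int, int]] = []
    dry_rounds = 0
    for _ in range(max_rounds):
        if len(inserts) >= n_clones:
            break
        keep = sites[rng.random(sites.size) < partial_prob]
        bounds = np.concatenate(([0], keep, [genome.length_bp]))
        lens = np.diff(bounds)
        ok = np.nonzero((lens >= lo) & (lens <= hi))[0]
        if ok.size == 0:
            dry_rounds += 1
            if dry_rounds >= 50:
                raise SamplingExhaustedError(
                    "no size-eligible fragments after 50 consecutive digests"
                )
            continue
        dry_rounds = 0
        for j in ok:
            inserts.append((int(bounds[j]), int(bounds[j + 1])))
    if len(inserts) < n_clones:
        raise SamplingExhaustedError(
            f"collected {len(inserts)}/{n_clones} eligible inserts"
        )
    rng.shuffle(inserts)  # decouple address order from genome order
    clones = []
    for i, (s, e) in enumerate(inserts[:n_clones]):
        plate = i // (n_rows * n_cols)
        row = (i % (n_rows * n_cols)) // n_cols
        col = i % n_cols
        clones.append(BacClone(f"bac{i:05d}", (plate, row, col), s, e))
    return clones


def fingerprint_clone(
    clone: BacClone,
    genome: GenomeTruth,
    site: str = "GCCAT",
    tolerance_bp: int = 3,
) -> Fingerprint:
    """Complete-digest fragment sizes of the insert, binned at a tolerance."""
    if clone.start < 0 or clone.end > genome.length_bp:
        raise ValueError("clone outside genome")
    insert = genome.seq[clone.start:clone.end]
    cuts = find_sites(insert, site)
    bounds = [0, *cuts, len(insert)]
    bands = sorted(
        _bin(b - a, tolerance_bp) for a, b in zip(bounds, bounds[1:]) if b > a
    )
    return Fingerprint(clone.clone_id, tuple(bands))


def _bin(size: int, tol: int) -> int:
    return int(round(size / tol)) * tol if tol > 1 else int(size)


def shared_band_count(a: Fingerprint, b: Fingerprint) -> int:
    """Multiset intersection size of two binned band sets."""
    return sum((Counter(a.bands) & Counter(b.bands)).values())


# ---------------------------------------------------------------------------
# FPC contigs


def build_fpc_contigs(
    fingerprints: list[Fingerprint],
    min_shared_bands: int = 20,
    clones: list[BacClone] | None = None,
) -> list[FpcContig]:
    """Single-linkage clustering of clones by shared fingerprint bands.

    Clones sharing at least ``min_shared_bands`` binned bands with some other
    clone join the same contig; all others remain singletons (returned as
    single-clone contigs).  In simulation mode (``clones`` given), clones
    within a contig are ordered by truth coordinates and the contig records
    its true span.  CB units are the number of distinct consensus bands.
    """
    if not fingerprints:
        raise ValueError("at least one fingerprint required")
    n = len(fingerprints)
    parent = list(range(n))

    def root(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if shared_band_count(fingerprints[i], fingerprints[j]) >= min_shared_bands:
            ri, rj = root(i), root(j)
            if ri != rj:
                parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(root(i), []).append(i)

    by_id = {c.clone_id: c for c in clones} if clones else {}
    contigs = []
    # deterministic contig numbering: by smallest member index
    for k, members in enumerate(sorted(groups.values(), key=min)):
        fps = [fingerprints[i] for i in members]
        ids = [fp.clone_id for fp in fps]
        span = (0, 0)
        if by_id:
            ids.sort(key=lambda cid: (by_id[cid].start, by_id[cid].end))
            span = (
                min(by_id[c].start for c in ids),
                max(by_id[c].end for c in ids),
            )
        cb = len({b for fp in fps for b in fp.bands})
        prefix = "ctg" if len(members) > 1 else "sgl"
        contigs.append(FpcContig(f"{prefix}{k:04d}", ids, float(cb), span))
    return contigs


# ---------------------------------------------------------------------------
# minimum tiling path


def select_mtp(
    contig: FpcContig,
    clone_intervals: dict[str, tuple[int, int]],
    kb_per_cb: float = 1.36,
) -> TilingPath:
    """Greedy left-to-right interval cover of a contig's clone union.

    Among clones overlapping already-covered territory the one reaching
    furthest right is selected; ties on the right end prefer the leftmost
    start (maximizing overlap redundancy).  Raises :class:`CoverGapError`
    when the clone intervals are disconnected.
    """
    if not contig.clone_ids:
        raise ValueError("empty contig")
    ivals = sorted(
        ((clone_intervals[c][0], clone_intervals[c][1], c) for c in contig.clone_ids),
    )
    gaps = []
    cur_end = ivals[0][1]
    for s, e, _ in ivals[1:]:
        if s > cur_end:
            gaps.append((cur_end, s))
        cur_end = max(cur_end, e)
    if gaps:
        raise CoverGapError(gaps)

    target_end = max(e for _, e, _ in ivals)
    covered = ivals[0][0]
    selected: list[str] = []
    i = 0
    while covered < target_end:
        best = None
        while i < len(ivals) and ivals[i][0] <= covered:
            s, e, c = ivals[i]
            # furthest right wins; ties -> leftmost start (already sorted by s)
            if best is None or e > best[1]:
                best = (s, e, c)
            i += 1
        if best is None:  # cannot happen on gap-free input
            raise CoverGapError([(covered, target_end)])
        selected.append(best[2])
        covered = best[1]
    return TilingPath(
        contig.contig_id,
        selected,
        expected_size_kb=cb_to_kb(contig.cb_units, kb_per_cb),
    )


def minimum_cover_bruteforce(intervals: list[tuple[int, int]]) -> int:
    """Exhaustive minimum interval-cover size (oracle for small instances)."""
    if not intervals:
        return 0
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    n = len(intervals)
    for k in range(1, n + 1):
        for combo in itertools.combinations(range(n), k):
            ivals = sorted(intervals[i] for i in combo)
            cov = lo
            for s, e in ivals:
                if s > cov:
                    break
                cov = max(cov, e)
            if cov >= hi and ivals[0][0] <= lo:
                return k
    return n


# ---------------------------------------------------------------------------
# tabular export


def clones_frame(clones: list[BacClone]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.clone_id, *c.address, c.start, c.end) for c in clones],
        columns=["clone_id", "plate", "row", "col", "start", "end"],
    )


def contigs_frame(contigs: list[FpcContig]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.contig_id, len(c.clone_ids), ";".join(c.clone_ids), c.cb_units,
             c.true_span[0], c.true_span[1])
            for c in contigs
        ],
        columns=["contig_id", "n_clones", "clone_ids", "cb_units", "span_start", "span_end"],
    )


def tiling_frame(paths: list[TilingPath]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.contig_id, len(t.clone_ids), ";".join(t.clone_ids), t.expected_size_kb) for t in paths],
        columns=["contig_id", "n_mtp_clones", "clone_ids", "expected_size_kb"],
    )
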