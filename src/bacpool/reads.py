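"""Read simulation and preprocessing.

Short reads emulate a 2x250 bp paired-end MiSeq run over BAC-pool inserts:
inward-facing pairs drawn from ~475 bp fragments, substitution errors at a
configurable rate, flat high base qualities (the trimmer is exercised with
constructed qualities in tests).  Long reads emulate self-corrected SMRT
reads of 0.5-31.4 kb with ~1% residual substitution error.

Preprocessing mirrors the standard short-read workflow: quality trimming
(leading/trailing clip plus a sliding-window cut) and streaming k-mer
normalization of over-represented reads down to a target coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import revcomp

__all__ = [
    "Read",
    "ReadSet",
    "simulate_short_reads",
    "simulate_long_reads",
    "trim_reads",
    "kmer_normalize",
    "write_fastq",
    "read_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_Q = "H"  # Q39


@dataclass
class Read:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.id}: quality length != sequence length")


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    platform: str = "short"  # "short" | "long"
    frag_mean: float = 0.0
    frag_sd: float = 0.0

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def total_bases(self) -> int:
        return sum(len(r.seq) for r in self.reads)

    def pairs(self) -> dict[str, list[Read]]:
        """Group reads by pair name (``/1``-``/2`` suffix convention)."""
        out: dict[str, list[Read]] = {}
        for r in self.reads:
            base = r.id.rsplit("/", 1)[0]
            out.setdefault(base, []).append(r)
        return out


def _apply_errors(seq: str, err_rate: float, rng: np.random.Generator) -> str:
    if err_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), err_rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    repl = _BASES[rng.integers(0, 4, n_err)]
    clash = repl == arr[pos]
    while clash.any():
        repl[clash] = _BASES[rng.integers(0, 4, int(clash.sum()))]
        clash = repl == arr[pos]
    arr[pos] = repl
    return arr.tobytes().decode()


def simulate_short_reads(
    insert_seqs: dict[str, str],
    coverage_x: float,
    read_len: int = 250,
    frag_mean: int = 475,
    frag_sd: int = 50,
    err_rate: float = 0.002,
    seed: int = 0,
) -> ReadSet:
    """Simulate inward-facing paired 2x``read_len`` reads at a coverage.

    Fragment lengths are normal(``frag_mean``, ``frag_sd``) clipped to
    ``[read_len, template length]``.  Templates shorter than the mean
    fragment are skipped with a warning record (empty output for them).
    """
    if coverage_x <= 0:
        raise ValueError("coverage must be positive")
    if frag_mean < read_len:
        raise ValueError("fragment mean must be >= read length")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for name in sorted(insert_seqs):
        template = insert_seqs[name]
        L = len(template)
        if L < frag_mean:
            import warnings

            warnings.warn(f"template {name} shorter than fragment size; skipped")
            continue
        n_pairs = int(round(coverage_x * L / (2 * read_len)))
        frag_lens = np.clip(
            rng.normal(frag_mean, frag_sd, n_pairs).round().astype(int), read_len, L
        )
        starts = rng.integers(0, L - frag_lens + 1)
        for i in range(n_pairs):
            s, fl = int(starts[i]), int(frag_lens[i])
            frag = template[s:s + fl]
            r1 = _apply_errors(frag[:read_len], err_rate, rng)
            r2 = _apply_errors(revcomp(frag)[:read_len], err_rate, rng)
            q1, q2 = _DEFAULT_Q * len(r1), _DEFAULT_Q * len(r2)
            reads.append(Read(f"{name}_p{i:06d}/1", r1, q1))
            reads.append(Read(f"{name}_p{i:06d}/2", r2, q2))
    return ReadSet(reads, "short", frag_mean, frag_sd)


def simulate_long_reads(
    template_seqs: dict[str, str],
    coverage_x: float,
    len_range: tuple[int, int] = (500, 31_400),
    err_rate: float = 0.01,
    seed: int = 0,
    mean_len: int = 8000,
) -> ReadSet:
    """Simulate long single-molecule reads with residual substitution error.

    Lengths are lognormal around ``mean_len`` clipped to ``len_range`` (and
    to the template), echoing a self-corrected long-read length profile.
    """
    if coverage_x <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = len_range
    reads: list[Read] = []
    for name in sorted(template_seqs):
        template = template_seqs[name]
        L = len(template)
        produced = 0
        target = coverage_x * L
        i = 0
        while produced < target:
            rl = int(np.clip(rng.lognormal(np.log(mean_len), 0.7), lo, hi))
            rl = min(rl, L)
            s = int(rng.integers(0, L - rl + 1))
            seq = template[s:s + rl]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            seq = _apply_errors(seq, err_rate, rng)
            reads.append(Read(f"{name}_L{i:05d}", seq, _DEFAULT_Q * len(seq)))
            produced += rl
            i += 1
    return ReadSet(reads, "long")


# ---------------------------------------------------------------------------
# preprocessing


def _trim_one(
    seq: str,
    qual: str,
    leading_q: int,
    trailing_q: int,
    window: int,
    window_q: int,
) -> tuple[str, str]:
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33
    n = q.size
    start = 0
    while start < n and q[start] < leading_q:
        start += 1
    end = n
    while end > start and q[end - 1] < trailing_q:
        end -= 1
    if end - start >= window:
        w = np.convolve(q[start:end], np.ones(window) / window, mode="valid")
        bad = np.nonzero(w < window_q)[0]
        if bad.size:
            end = start + int(bad[0])
    return seq[start:end], qual[start:end]


def trim_reads(
    reads: ReadSet,
    leading_q: int = 3,
    trailing_q: int = 6,
    window: int = 4,
    window_q: int = 15,
    min_len: int = 150,
) -> ReadSet:
    """Quality-trim reads; drop survivors shorter than ``min_len``.

    Leading/trailing bases below the thresholds are clipped, then the read
    is cut at the start of the first ``window``-base window whose mean
    quality falls below ``window_q``.  If one mate of a pair is dropped the
    survivor is kept as an unpaired read.
    """
    fast_q = chr(33 + max(leading_q, trailing_q, window_q))
    out: list[Read] = []
    for r in reads:
        if r.qual and min(r.qual) >= fast_q:  # all-high-quality fast path
            out.append(r)
            continue
        seq, qual = _trim_one(r.seq, r.qual, leading_q, trailing_q, window, window_q)
        if len(seq) >= min_len:
            out.append(Read(r.id, seq, qual))
    return ReadSet(out, reads.platform, reads.frag_mean, reads.frag_sd)


def kmer_normalize(
    reads: ReadSet,
    k: int = 25,
    target_cov: int = 100,
    stride: int = 4,
) -> ReadSet:
    """Streaming k-mer normalization to a target coverage.

    Reads are visited in order; a read is retained when the median abundance
    of its (strided) k-mers among previously retained reads is below the
    target, after which its k-mers are counted.  Sampling every ``stride``-th
    k-mer position trades a proportionally scaled threshold for speed; with
    ``stride=1`` this is the classical digital normalization.
    """
    if target_cov <= 0:
        raise ValueError("target coverage must be positive")
    counts: dict[int, int] = {}
    eff_target = max(1.0, target_cov / (2 * stride))  # per-strand, strided
    kept: list[Read] = []
    get = counts.get
    for r in reads:
        seq = r.seq
        if len(seq) < k:
            kept.append(r)
            continue
        hashes = _kmer_hashes(seq, k, stride)
        abund = sorted(get(h, 0) for h in hashes)
        med = abund[len(abund) // 2]
        if med < eff_target:
            kept.append(r)
            for h in hashes:
                counts[h] = get(h, 0) + 1
    return ReadSet(kept, reads.platform, reads.frag_mean, reads.frag_sd)


_HASH_COEF = np.random.default_rng(0x5EED).integers(
    1, 2**62, size=512, dtype=np.uint64
) | np.uint64(1)


def _kmer_hashes(seq: str, k: int, stride: int) -> list[int]:
    """Deterministic (process-independent) k-mer hashes at a stride."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)[::stride]
    return (win.astype(np.uint64) * _HASH_COEF[:k]).sum(axis=1).tolist()


# ---------------------------------------------------------------------------
# FASTQ I/O (plain 4-line records)


def write_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path, platform: str = "short") -> ReadSet:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        q = "".join(chr(33 + v) for v in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq), q))
    return ReadSet(reads, platform)
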