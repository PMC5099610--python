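"""Lightweight k-mer-seeded alignment used throughout the toolkit.

All reads produced by the simulator carry substitution errors only, so a
gapless seed-and-verify aligner is exact for the data the pipeline handles
and runs at BAC scale in pure Python/NumPy.  Long queries are mapped in
fixed-size chunks whose per-chunk hits are chained by (reference, strand,
diagonal) into alignment blocks.  Genuinely gapped comparisons (e.g.
assembly-vs-assembly accounting of substitutions and indels) go through
edlib's global Needleman-Wunsch alignment instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .genome import revcomp

__all__ = [
    "KmerIndex",
    "Hit",
    "Block",
    "mismatch_count",
    "map_query",
    "map_chunks",
    "global_diff",
]


def mismatch_count(a: str, b: str) -> int:
    """Hamming distance of two equal-length strings (NumPy-backed)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 0
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((av != bv).sum())


class KmerIndex:
    """Exact k-mer lookup over a set of reference sequences.

    K-mers occurring more than ``max_hits`` times across the references are
    masked (treated as repeats and never used as seeds).
    """

    def __init__(self, refs: dict[str, str], k: int = 15, max_hits: int = 64):
        self.k = k
        self.refs = refs
        index: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in refs.items():
            for i in range(len(seq) - k + 1):
                km = seq[i:i + k]
                if "N" in km:
                    continue
                lst = index.get(km)
                if lst is None:
                    index[km] = [(rid, i)]
                elif len(lst) <= max_hits:
                    lst.append((rid, i))
        self.max_hits = max_hits
        self._index = {
            km: lst for km, lst in index.items() if len(lst) <= max_hits
        }

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


@dataclass
class Hit:
    """A gapless alignment of a (chunk of a) query against a reference."""

    ref_id: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str  # orientation of the query
    mismatches: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def identity(self) -> float:
        n = self.length
        return 1.0 - self.mismatches / n if n else 0.0


def _verify(query: str, ref: str, ref_offset: int) -> Hit | None:
    """Gapless alignment of the whole query at a fixed reference offset.

    The query is clipped at reference ends.  ``ref_offset`` is the reference
    position of query base 0 (may be negative).
    """
    qs = max(0, -ref_offset)
    qe = min(len(query), len(ref) - ref_offset)
    if qe <= qs:
        return None
    rs, re = ref_offset + qs, ref_offset + qe
    mm = mismatch_count(query[qs:qe], ref[rs:re])
    return Hit("", rs, re, qs, qe, "+", mm)


def map_query(
    query: str,
    index: KmerIndex,
    min_len_frac: float = 0.95,
    min_sim: float = 0.95,
    seed_offsets: tuple[int, ...] | None = None,
    both_strands: bool = True,
) -> Hit | None:
    """Best gapless placement of a short query against indexed references.

    Seeds at a few query offsets; each seed proposes a diagonal which is
    verified over the full query.  Returns the hit with the fewest
    mismatches meeting the aligned-length-fraction and similarity
    thresholds, or ``None``.
    """
    k = index.k
    if len(query) < k:
        return None
    if seed_offsets is None:
        n_off = 4 if len(query) >= 4 * k else 2
        step = max(1, (len(query) - k) // n_off)
        seed_offsets = tuple(range(0, len(query) - k + 1, step))[:n_off + 1]
    best: Hit | None = None
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        tried: set[tuple[str, int]] = set()
        for off in seed_offsets:
            for rid, pos in index.lookup(q[off:off + k]):
                diag = pos - off
                key = (rid, diag)
                if key in tried:
                    continue
                tried.add(key)
                hit = _verify(q, index.refs[rid], diag)
                if hit is None:
                    continue
                alen = hit.length
                if alen < min_len_frac * len(query):
                    continue
                if hit.identity < min_sim:
                    continue
                hit.ref_id = rid
                hit.strand = strand
                if strand == "-":
                    hit.query_start, hit.query_end = (
                        len(query) - hit.query_end,
                        len(query) - hit.query_start,
                    )
                if best is None or hit.mismatches < best.mismatches:
                    best = hit
        if best is not None and best.mismatches == 0:
            break
    return best


@dataclass
class Block:
    """Chained chunk hits of a long query on one reference and strand."""

    ref_id: str
    strand: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    matched: int  # aligned query bases over member chunks
    mismatches: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.matched if self.matched else 0.0

    def query_projection(self, query_len: int, ref_len: int) -> tuple[int, int]:
        """Interval the *whole* reference would occupy in query coordinates."""
        if self.strand == "+":
            start = self.query_start - self.ref_start
        else:
            start = self.query_start - (ref_len - self.ref_end)
        return start, start + ref_len


def map_chunks(
    query: str,
    index: KmerIndex,
    chunk: int = 200,
    min_chunk_sim: float = 0.8,
    diag_slack: int = 100,
) -> list[Block]:
    """Map a long query in chunks and chain hits into blocks.

    Each ``chunk``-sized window is placed gaplessly via :func:`map_query`
    relaxed to the window; windows landing on the same reference and strand
    with similar diagonals merge into one block.  Blocks are returned in
    query order.
    """
    n = len(query)
    windows = [(s, min(n, s + chunk)) for s in range(0, max(1, n - chunk // 2), chunk)]
    raw: list[tuple[int, Hit]] = []
    for ws, we in windows:
        sub = query[ws:we]
        if len(sub) < index.k:
            continue
        hit = map_query(sub, index, min_len_frac=0.8, min_sim=min_chunk_sim)
        if hit is not None:
            raw.append((ws, hit))
    blocks: list[Block] = []
    open_blocks: dict[tuple[str, str], Block] = {}
    open_diag: dict[tuple[str, str], int] = {}
    for ws, hit in raw:
        # query coordinates of the chunk hit in forward query orientation
        q0, q1 = ws + hit.query_start, ws + hit.query_end
        if hit.strand == "+":
            diag = hit.ref_start - q0
        else:
            diag = hit.ref_end + q0
        key = (hit.ref_id, hit.strand)
        blk = open_blocks.get(key)
        if blk is not None and abs(open_diag[key] - diag) <= diag_slack and q0 >= blk.query_start:
            blk.query_end = max(blk.query_end, q1)
            blk.ref_start = min(blk.ref_start, hit.ref_start)
            blk.ref_end = max(blk.ref_end, hit.ref_end)
            blk.matched += q1 - q0
            blk.mismatches += hit.mismatches
        else:
            if blk is not None:
                blocks.append(blk)
            blk = Block(
                hit.ref_id, hit.strand, hit.ref_start, hit.ref_end,
                q0, q1, q1 - q0, hit.mismatches,
            )
            open_blocks[key] = blk
            open_diag[key] = diag
    blocks.extend(open_blocks.values())
    blocks.sort(key=lambda b: b.query_start)
    return blocks


@dataclass
class GlobalDiff:
    substitutions: int
    insertions: int
    deletions: int

    @property
    def indels(self) -> int:
        return self.insertions + self.deletions


def global_diff(a: str, b: str) -> GlobalDiff:
    """Global (Needleman-Wunsch) difference accounting between two sequences.

    Substitutions and indels are counted from the optimal path of edlib's
    global alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    subs = ins = dels = 0
    ai = bi = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            ai += n
            bi += n
        elif ch == "X":
            subs += n
            ai += n
            bi += n
        elif ch == "M":
            subs += mismatch_count(a[ai:ai + n], b[bi:bi + n])
            ai += n
            bi += n
        elif ch == "I":  # extra bases in ``a``
            ins += n
            ai += n
        elif ch == "D":  # extra bases in ``b``
            dels += n
            bi += n
    return GlobalDiff(subs, ins, dels)
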