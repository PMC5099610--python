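"""Short-read assembly, long-read hybrid scaffolding and validation.

The assembler is a greedy overlap-merge designed for BAC-pool scale: reads
are indexed by the k-mer at their 5' end (both orientations), a contig is
seeded from an unused read and extended base-accurately by repeatedly
adopting the unused read with the longest acceptable overlap against the
contig end.  Competing extensions that disagree beyond the error level
(each supported by at least two reads) signal an unresolvable branch -- in
practice an interspersed repeat longer than the read span -- and terminate
the contig, so repeat-induced fragmentation arises exactly as it does in a
real short-read assembly.

Hybrid scaffolding mines long reads that align to at least two contigs
(length-fraction / similarity thresholds), turns them into orientation- and
distance-labelled edges of a scaffold graph, and merges contig chains edge
by edge in descending support order -- accepting a junction only after the
implied overlap (or spanning-read gap fill) verifies at the base level, so
diverged repeat copies cannot force a bad join.  Read-back validation
recomputes per-base coverage from stringently mapped reads and splits
scaffolds at zero-coverage runs, removing chimeric joins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Block, KmerIndex, global_diff, map_chunks, map_query, mismatch_count
from .genome import revcomp
from .reads import ReadSet

__all__ = [
    "Contig",
    "Scaffold",
    "ScaffoldEdge",
    "greedy_assemble",
    "hybrid_scaffold",
    "validate_and_split",
    "split_on_coverage",
    "compute_coverage",
    "anchor_sequences",
    "infer_clone_spans",
    "count_mismatches",
    "assembly_report",
]


@dataclass
class Contig:
    id: str
    sequence: str
    source_pool: str = ""
    coverage: np.ndarray | None = None
    anchors: list[tuple] = field(default_factory=list)

    def __len__(self):
        return len(self.sequence)


Scaffold = Contig  # scaffolds share the contig record layout


@dataclass
class ScaffoldEdge:
    a: str
    b: str
    orientation: tuple[str, str]
    gap_estimate: int
    supports: list[dict] = field(default_factory=list)

    @property
    def support_count(self) -> int:
        return len(self.supports)


# ---------------------------------------------------------------------------
# greedy overlap assembly


class _ReadBank:
    """Oriented read sequences with a 5'-end k-mer index."""

    def __init__(self, reads: list[tuple[str, str]], k: int):
        self.k = k
        self.ids = [rid for rid, _ in reads]
        # canonical orientation per read: makes assembly of a
        # reverse-complemented read set byte-identical (strand symmetry)
        self.fwd = [min(seq, revcomp(seq)) for _, seq in reads]
        self.rev = [revcomp(seq) for seq in self.fwd]
        self.used = [False] * len(reads)
        self.max_len = max((len(s) for s in self.fwd), default=0)
        index: dict[str, list[int]] = {}
        for i, seq in enumerate(self.fwd):
            if len(seq) >= k:
                index.setdefault(seq[:k], []).append(i)       # code +i: forward
                index.setdefault(self.rev[i][:k], []).append(~i)  # ~i: reverse
        self.index = index

    def seq(self, code: int) -> str:
        return self.fwd[code] if code >= 0 else self.rev[~code]

    def idx(self, code: int) -> int:
        return code if code >= 0 else ~code

    def candidates(self, kmer: str):
        return self.index.get(kmer, ())


def _extend_right(
    tail: str,
    bank: _ReadBank,
    min_overlap: int,
    min_identity: float,
    branch_window: int = 40,
    branch_scan: int = 120,
    branch_candidates: int = 8,
) -> tuple[list[str], str]:
    """Greedily extend to the right; returns (appended chunks, reason)."""
    k = bank.k
    chunks: list[str] = []
    while True:
        n = len(tail)
        candidates: list[tuple[int, int, str]] = []  # (overlap L, read idx, ext)
        first_L = None
        for L in range(min(bank.max_len, n), min_overlap - 1, -1):
            if L < k:
                break
            if first_L is not None and (
                first_L - L >= branch_scan or len(candidates) >= branch_candidates
            ):
                break
            window = tail[n - L:n - L + k]
            hits = bank.candidates(window)
            if not hits:
                continue
            suffix = tail[n - L:]
            for code in hits:
                i = bank.idx(code)
                if bank.used[i]:
                    continue
                seq = bank.seq(code)
                if len(seq) < L:
                    continue
                allowed = max(1, int((1.0 - min_identity) * L))
                if mismatch_count(seq[:L], suffix) <= allowed:
                    candidates.append((L, code, seq[L:]))
            if candidates and first_L is None:
                first_L = L
        if not candidates:
            return chunks, "end"
        candidates.sort(key=lambda t: (-t[0], bank.ids[bank.idx(t[1])]))
        L, code, ext = candidates[0]
        if not ext:  # contained read: absorb and continue
            bank.used[bank.idx(code)] = True
            continue
        # branch check: cluster ALL candidate extensions (each starts at the
        # current contig end) by agreement over a shared prefix window; two
        # well-supported clusters mean an unresolvable repeat branch
        clusters: list[tuple[str, int]] = []  # (longest representative, size)
        for _, _, oext in candidates:
            if len(oext) < 10:
                continue
            placed = False
            for ci, (rep, size) in enumerate(clusters):
                w = min(len(rep), len(oext), branch_window)
                if mismatch_count(rep[:w], oext[:w]) <= 2:
                    clusters[ci] = (rep if len(rep) >= len(oext) else oext, size + 1)
                    placed = True
                    break
            if not placed:
                clusters.append((oext, 1))
        if sum(1 for _, size in clusters if size >= 2) >= 2:
            return chunks, "branch"
        bank.used[bank.idx(code)] = True
        chunks.append(ext)
        tail = (tail + ext)[-(bank.max_len + branch_scan):]
    # unreachable


def greedy_assemble(
    reads: ReadSet | list[tuple[str, str]],
    min_overlap: int = 40,
    min_identity: float = 0.97,
    source_pool: str = "",
    min_contig_len: int | None = None,
) -> list[Contig]:
    """Greedy overlap-merge assembly of (error-containing) reads.

    Deterministic under fixed input order: seeds are taken in read order,
    the longest acceptable overlap wins and ties break on read id.  Contigs
    fully contained in a longer contig (redundant seeds caused by errors in
    a read's 5' k-mer) are removed afterwards.
    """
    if isinstance(reads, ReadSet):
        items = [(r.id, r.seq) for r in reads]
    else:
        items = list(reads)
    if not items:
        raise ValueError("no reads to assemble")
    k = min(31, min_overlap)
    bank = _ReadBank(items, k)
    raw: list[str] = []
    for i in range(len(items)):
        if bank.used[i]:
            continue
        bank.used[i] = True
        seed = bank.fwd[i]
        right, _ = _extend_right(seed, bank, min_overlap, min_identity)
        fwd_seq = seed + "".join(right)
        left, _ = _extend_right(revcomp(fwd_seq), bank, min_overlap, min_identity)
        full = revcomp(revcomp(fwd_seq) + "".join(left))
        raw.append(full)

    # containment filter
    raw.sort(key=lambda s: (-len(s), s))
    if min_contig_len is None:
        min_contig_len = 0
    kept: list[str] = []
    index: KmerIndex | None = None
    for seq in raw:
        contained = False
        if kept and index is not None and len(seq) < len(kept[0]):
            hit = map_query(seq, index, min_len_frac=0.95, min_sim=0.95)
            contained = hit is not None
        if not contained and len(seq) >= min_contig_len:
            kept.append(seq)
            index = KmerIndex({str(j): s for j, s in enumerate(kept)}, k=15)
    return [
        Contig(f"{source_pool or 'asm'}_c{j:04d}", s, source_pool)
        for j, s in enumerate(kept)
    ]


# ---------------------------------------------------------------------------
# hybrid scaffolding


def _long_read_edges(
    contigs: list[Contig],
    long_reads: ReadSet,
    map_len_frac: float,
    map_sim: float,
    seed_k: int,
    edge_block_sim: float = 0.97,
) -> tuple[dict[tuple[str, str], ScaffoldEdge], dict[str, str]]:
    """Scaffold edges from long reads spanning >= 2 contigs.

    Reads are mined at the (permissive) ``map_len_frac``/``map_sim``
    thresholds; edge construction then demands near-perfect per-block
    identity (``edge_block_sim``) so that diverged repeat copies do not
    produce spurious junctions.  Per edge, supports are clustered by their
    implied gap and only the majority cluster is retained.
    """
    refs = {c.id: c.sequence for c in contigs}
    index = KmerIndex(refs, k=seed_k)
    edges: dict[tuple[str, str], ScaffoldEdge] = {}
    read_seqs: dict[str, str] = {}
    for read in long_reads:
        blocks = [
            b
            for b in map_chunks(read.seq, index)
            if b.identity >= map_sim and b.matched >= 200
        ]
        if len(blocks) < 2:
            continue
        aligned = sum(b.query_end - b.query_start for b in blocks)
        if aligned < map_len_frac * len(read.seq):
            continue
        # strict blocks only, best per contig, ordered along the read
        best: dict[str, Block] = {}
        for b in blocks:
            if b.identity < edge_block_sim:
                continue
            if b.ref_id not in best or b.matched > best[b.ref_id].matched:
                best[b.ref_id] = b
        chain = sorted(best.values(), key=lambda b: b.query_start)
        if len(chain) < 2:
            continue
        read_seqs[read.id] = read.seq
        for prev, nxt in zip(chain, chain[1:]):
            pa, pb = (
                prev.query_projection(len(read.seq), len(refs[prev.ref_id])),
                nxt.query_projection(len(read.seq), len(refs[nxt.ref_id])),
            )
            gap = pb[0] - pa[1]
            key = (prev.ref_id, nxt.ref_id)
            orient = (prev.strand, nxt.strand)
            support = {
                "read_id": read.id,
                "a_end_in_read": pa[1],
                "b_start_in_read": pb[0],
                "orientation": orient,
                "gap": gap,
            }
            if key in edges:
                edges[key].supports.append(support)
            elif (key[1], key[0]) in edges:
                # same junction seen from the opposite read strand
                rkey = (key[1], key[0])
                edges[rkey].supports.append(support | {"reversed": True})
            else:
                edges[key] = ScaffoldEdge(key[0], key[1], orient, gap, [support])
    for e in edges.values():
        _keep_majority_supports(e)
    return edges, read_seqs


def _keep_majority_supports(e: ScaffoldEdge, slack: int = 200) -> None:
    """Retain the largest gap-consistent support cluster of an edge."""
    clusters: list[list[dict]] = []
    for s in sorted(e.supports, key=lambda s: s["gap"]):
        orient = (
            s["orientation"] if not s.get("reversed")
            else (_flip(s["orientation"][1]), _flip(s["orientation"][0]))
        )
        placed = False
        for cl in clusters:
            if abs(cl[-1]["gap"] - s["gap"]) <= slack and cl[0]["_orient"] == orient:
                cl.append({**s, "_orient": orient})
                placed = True
                break
        if not placed:
            clusters.append([{**s, "_orient": orient}])
    best = max(clusters, key=len)
    e.supports = [{k: v for k, v in s.items() if k != "_orient"} for s in best]
    e.orientation = best[0]["_orient"]
    e.gap_estimate = int(np.median([s["gap"] for s in best]))


def _flip(s: str) -> str:
    return "-" if s == "+" else "+"


def _gap_fill(
    prev_id: str,
    next_id: str,
    prev_orient: str,
    edges: dict[tuple[str, str], ScaffoldEdge],
    read_seqs: dict[str, str],
    gap: int,
) -> str:
    """Sequence for a positive inter-contig gap from a spanning long read."""
    e = edges.get((prev_id, next_id)) or edges.get((next_id, prev_id))
    if e is None or gap <= 0:
        return "N" * max(gap, 10)
    best = None
    for s in e.supports:
        a_end, b_start = s["a_end_in_read"], s["b_start_in_read"]
        if b_start - a_end <= 0:
            continue
        seq = read_seqs.get(s["read_id"], "")[a_end:b_start]
        if not seq:
            continue
        if best is None or abs(len(seq) - gap) < abs(len(best[0]) - gap):
            # the support saw the junction as u -> v in its read's frame
            u, v = (e.b, e.a) if s.get("reversed") else (e.a, e.b)
            prev_strand_in_read = (
                s["orientation"][0] if u == prev_id else s["orientation"][1]
            )
            # fill is used as-is when the read runs along the scaffold
            same = prev_strand_in_read == prev_orient
            best = (seq, same)
    if best is None:
        return "N" * max(gap, 10)
    seq, same = best
    return seq if same else revcomp(seq)


def hybrid_scaffold(
    contigs: list[Contig],
    long_reads: ReadSet,
    map_len_frac: float = 0.2,
    map_sim: float = 0.9,
    merge_identity: float = 0.99,
    merge_min_overlap: int = 20,
    seed_k: int = 15,
    source_pool: str = "",
) -> list[Scaffold]:
    """Scaffold short-read contigs with long reads.

    Long reads aligning to >= 2 contigs (aligned length fraction and
    similarity thresholds) become scaffold-graph edges carrying relative
    orientation and a gap estimate.  Chains of contigs are merged greedily
    by support: an overlap junction must verify at ``merge_identity`` over
    >= ``merge_min_overlap`` bp, positive gaps are filled from a spanning
    long read (N run as fallback).  Edges whose endpoints are interior to a
    chain, whose orientation conflicts with an established chain, or whose
    junction fails verification are skipped, so the scaffold count never
    exceeds the contig count.
    """
    if not contigs:
        return []
    seqs = {c.id: c.sequence for c in contigs}
    edges, read_seqs = _long_read_edges(
        contigs, long_reads, map_len_frac, map_sim, seed_k
    )
    chains = _merge_chains(
        seqs, edges, read_seqs, merge_identity, merge_min_overlap
    )
    scaffolds: list[Scaffold] = []
    for n_out, chain in enumerate(chains):
        scaffolds.append(Scaffold(_sid(source_pool, n_out), chain, source_pool))
    return scaffolds


class _Chain:
    """A growing run of oriented contigs with verified junction strings."""

    __slots__ = ("items", "joints")

    def __init__(self, cid: str, orient: str):
        self.items = [(cid, orient)]
        self.joints: list[tuple[str, object]] = []  # ("fill", seq) | ("overlap", ov)

    def reverse(self) -> None:
        self.items = [(c, _flip(o)) for c, o in reversed(self.items)]
        self.joints = [
            (kind, revcomp(val) if kind == "fill" else val)
            for kind, val in reversed(self.joints)
        ]

    def sequence(self, seqs: dict[str, str]) -> str:
        out: list[str] = []
        for i, (cid, orient) in enumerate(self.items):
            seq = seqs[cid] if orient == "+" else revcomp(seqs[cid])
            if i == 0:
                out.append(seq)
                continue
            kind, val = self.joints[i - 1]
            if kind == "fill":
                out.append(val)
                out.append(seq)
            else:
                out.append(seq[val:])
        return "".join(out)


def _merge_chains(
    seqs: dict[str, str],
    edges: dict[tuple[str, str], "ScaffoldEdge"],
    read_seqs: dict[str, str],
    merge_identity: float,
    merge_min_overlap: int,
) -> list[str]:
    """Greedy, junction-verified chain merging of contigs.

    Edges are consumed in descending support order.  An edge joins two
    chains only when both endpoint contigs sit at chain ends with compatible
    orientations AND the implied junction verifies at the base level
    (refined overlap, or a spanning-read gap fill).  Unverifiable edges are
    skipped, so every emitted scaffold is locally consistent and the
    scaffold count can only decrease.
    """
    chain_of: dict[str, _Chain] = {}
    for cid in seqs:
        chain_of[cid] = _Chain(cid, "+")
    for (a, b), e in sorted(
        edges.items(), key=lambda kv: (-kv[1].support_count, kv[0])
    ):
        ca, cb = chain_of[a], chain_of[b]
        if ca is cb:
            continue
        sa, sb = e.orientation
        # normalise: a at the right end of ca matching strand sa
        if ca.items[-1][0] != a:
            if ca.items[0][0] != a:
                continue  # interior
            ca.reverse()
        if ca.items[-1][1] != sa:
            if len(ca.items) > 1:
                continue  # orientation conflict with an established chain
            ca.items[0] = (a, sa)
        # normalise: b at the left end of cb matching strand sb
        if cb.items[0][0] != b:
            if cb.items[-1][0] != b:
                continue
            cb.reverse()
        if cb.items[0][1] != sb:
            if len(cb.items) > 1:
                continue
            cb.items[0] = (b, sb)
        gap = e.gap_estimate
        joint: tuple[str, object] | None = None
        tail_seq = seqs[a] if sa == "+" else revcomp(seqs[a])
        head_seq = seqs[b] if sb == "+" else revcomp(seqs[b])
        if gap < 0:
            ov = -gap
            if ov < len(tail_seq) and ov < len(head_seq):
                ov2 = _refine_overlap(tail_seq, head_seq, ov, merge_identity)
                if ov2 is not None and ov2 >= merge_min_overlap:
                    joint = ("overlap", ov2)
        else:
            fill = _gap_fill(a, b, sa, edges, read_seqs, gap)
            joint = ("fill", fill)
        if joint is None:
            continue
        ca.items.extend(cb.items)
        ca.joints.append(joint)
        ca.joints.extend(cb.joints)
        for cid, _o in cb.items:
            chain_of[cid] = ca
    done = []
    seen: set[int] = set()
    for cid in sorted(seqs):
        ch = chain_of[cid]
        if id(ch) in seen:
            continue
        seen.add(id(ch))
        done.append(ch.sequence(seqs))
    return done


def _refine_overlap(
    tail: str,
    nxt: str,
    ov: int,
    merge_identity: float,
    slack: int = 48,
    probe: int = 400,
) -> int | None:
    """Find the exact suffix/prefix overlap near an estimated value.

    Gap estimates from long-read projections are accurate to a few bases;
    the true junction must be base-exact.  Scans shifts within ``slack`` of
    the estimate, scores a probe window, and returns the overlap length
    whose full extent verifies at ``merge_identity`` (None if none does).
    """
    best = None
    for d in range(-slack, slack + 1):
        ov2 = ov + d
        if ov2 < 1 or ov2 > len(tail) or ov2 > len(nxt):
            continue
        w = min(ov2, probe)
        mm = mismatch_count(tail[len(tail) - ov2:len(tail) - ov2 + w], nxt[:w])
        if best is None or mm < best[1]:
            best = (ov2, mm)
            if mm == 0:
                break
    if best is None:
        return None
    ov2 = best[0]
    w = min(ov2, probe)
    # error-bearing contigs: allow the configured merge divergence plus a
    # small floor for coverage-1 terminal bases
    if best[1] > max(3, int((1 - merge_identity) * w) + 3):
        return None
    return ov2


def _sid(pool: str, n: int) -> str:
    return f"{pool or 'hyb'}_s{n:04d}"


# ---------------------------------------------------------------------------
# read-back validation and zero-coverage splitting


def compute_coverage(
    scaffolds: list[Scaffold],
    read_sets: list[ReadSet],
    map_len_frac: float = 0.95,
    map_sim: float = 0.95,
    seed_k: int = 15,
) -> dict[str, np.ndarray]:
    """Per-base coverage from stringently mapped reads.

    Short reads must place full-length (gapless) at the thresholds; long
    reads contribute their chained block intervals when the summed aligned
    fraction and per-block identity meet the thresholds.
    """
    refs = {s.id: s.sequence for s in scaffolds}
    index = KmerIndex(refs, k=seed_k)
    diff: dict[str, np.ndarray] = {
        sid: np.zeros(len(seq) + 1, dtype=np.int32) for sid, seq in refs.items()
    }
    for rs in read_sets:
        long_mode = rs.platform == "long"
        for read in rs:
            if long_mode and len(read.seq) > 600:
                blocks = [
                    b for b in map_chunks(read.seq, index) if b.identity >= map_sim
                ]
                aligned = sum(b.query_end - b.query_start for b in blocks)
                if aligned < map_len_frac * len(read.seq):
                    continue
                for b in blocks:
                    d = diff[b.ref_id]
                    d[b.ref_start] += 1
                    d[b.ref_end] -= 1
            else:
                hit = map_query(read.seq, index, map_len_frac, map_sim)
                if hit is None:
                    continue
                d = diff[hit.ref_id]
                d[hit.ref_start] += 1
                d[hit.ref_end] -= 1
    return {sid: np.cumsum(d[:-1]) for sid, d in diff.items()}


def validate_and_split(
    scaffolds: list[Scaffold],
    read_sets: list[ReadSet],
    map_len_frac: float = 0.95,
    map_sim: float = 0.95,
    seed_k: int = 15,
) -> list[Scaffold]:
    """Split scaffolds at internal zero-coverage runs; trim uncovered ends.

    Every returned piece has minimum coverage >= 1 and carries its coverage
    vector.  The operation is idempotent: re-validating the output with the
    same reads reproduces it.
    """
    cov = compute_coverage(scaffolds, read_sets, map_len_frac, map_sim, seed_k)
    out: list[Scaffold] = []
    for s in scaffolds:
        out.extend(split_on_coverage(s, cov[s.id]))
    return out


def split_on_coverage(scaffold: Scaffold, coverage: np.ndarray) -> list[Scaffold]:
    """Split one scaffold at zero-coverage runs (the validation split rule).

    Internal zero runs separate pieces; terminal zero runs are trimmed; a
    fully uncovered scaffold yields nothing.  Pieces keep their coverage
    slice, so every output position has coverage >= 1.
    """
    covered = np.asarray(coverage) > 0
    if not covered.any():
        return []
    edges_ = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    starts, ends = edges_[::2], edges_[1::2]
    n_pieces = len(starts)
    out = []
    for j, (a, b) in enumerate(zip(starts, ends)):
        suffix = f"_{j}" if n_pieces > 1 else ""
        out.append(
            Scaffold(
                f"{scaffold.id}{suffix}",
                scaffold.sequence[a:b],
                scaffold.source_pool,
                coverage=np.asarray(coverage)[a:b].copy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# anchoring


def anchor_sequences(
    scaffolds: list[Scaffold],
    queries: list[tuple[str, str, str]],
    min_identity: float = 0.95,
    min_frac: float = 0.9,
    seed_k: int = 15,
) -> pd.DataFrame:
    """Locate marker/BES queries on scaffolds.

    Each query is reported as ``full`` (aligned fraction >= ``min_frac``),
    ``partial`` (>= 0.25) or ``absent``, with strand and coordinates.
    Anchors are also attached to the scaffold records.
    """
    if not queries:
        raise ValueError("no queries to anchor")
    refs = {s.id: s.sequence for s in scaffolds}
    by_id = {s.id: s for s in scaffolds}
    index = KmerIndex(refs, k=seed_k)
    rows = []
    for qid, seq, qtype in queries:
        hit = map_query(seq, index, min_len_frac=0.25, min_sim=min_identity)
        if hit is None:
            rows.append((qid, qtype, "absent", "", -1, -1, "."))
            continue
        frac = hit.length / len(seq)
        status = "full" if frac >= min_frac else "partial"
        rows.append((qid, qtype, status, hit.ref_id, hit.ref_start, hit.ref_end, hit.strand))
        by_id[hit.ref_id].anchors.append(
            (qid, hit.ref_start, hit.ref_end, hit.strand, qtype)
        )
    return pd.DataFrame(
        rows,
        columns=["query_id", "type", "status", "scaffold", "start", "end", "strand"],
    )


def infer_clone_spans(anchors: pd.DataFrame) -> pd.DataFrame:
    """Infer clone spans from convergent BES pairs on one scaffold.

    BES ids follow ``<clone>.F`` / ``<clone>.R``; a pair with both ends on
    the same scaffold in convergent orientation implies the clone's span and
    orientation.
    """
    bes = anchors[(anchors["type"] == "BES") & (anchors["status"] != "absent")]
    rows = []
    for clone, grp in bes.groupby(bes["query_id"].str.rsplit(".", n=1).str[0]):
        if len(grp) != 2 or grp["scaffold"].nunique() != 1:
            continue
        f = grp[grp["query_id"].str.endswith(".F")]
        r = grp[grp["query_id"].str.endswith(".R")]
        if len(f) != 1 or len(r) != 1:
            continue
        f, r = f.iloc[0], r.iloc[0]
        if f["strand"] == r["strand"]:
            continue  # not convergent
        lo = min(f["start"], r["start"])
        hi = max(f["end"], r["end"])
        orientation = "+" if (f["strand"] == "+" and f["start"] <= r["start"]) else "-"
        rows.append((clone, f["scaffold"], int(lo), int(hi), int(hi - lo), orientation))
    return pd.DataFrame(
        rows, columns=["clone_id", "scaffold", "start", "end", "span_bp", "orientation"]
    )


# ---------------------------------------------------------------------------
# assembly comparison and reporting


def count_mismatches(seq_a: str, seq_b: str) -> int:
    """Substitution count of the optimal global alignment of two sequences.

    Indels are not counted here; use :func:`bacpool.align.global_diff` for
    the full difference breakdown.  Empty input raises ``ValueError``.
    """
    return global_diff(seq_a, seq_b).substitutions


def assembly_report(per_pool: dict[str, dict[str, list[Scaffold]]]) -> pd.DataFrame:
    """Per-pool scaffold accounting with a Total row.

    ``per_pool`` maps pool id to ``{"short": [...], "hybrid": [...]}``.
    Sizes are reported in kb to 1 decimal; the hybrid scaffold count is
    asserted not to exceed the short-read-only count.
    """
    rows = []
    for pool in sorted(per_pool):
        short = per_pool[pool].get("short", [])
        hybrid = per_pool[pool].get("hybrid", [])
        if hybrid and short and len(hybrid) > len(short):
            raise AssertionError(
                f"pool {pool}: hybrid scaffold count {len(hybrid)} exceeds "
                f"short-read contig count {len(short)}"
            )
        rows.append(
            (
                pool,
                len(short),
                round(sum(len(c) for c in short) / 1000.0, 1),
                len(hybrid),
                round(sum(len(c) for c in hybrid) / 1000.0, 1),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["pool", "n_contigs_short", "kb_short", "n_scaffolds_hybrid", "kb_hybrid"],
    )
    total = pd.DataFrame(
        [
            (
                "Total",
                int(df["n_contigs_short"].sum()),
                round(float(df["kb_short"].sum()), 1),
                int(df["n_scaffolds_hybrid"].sum()),
                round(float(df["kb_hybrid"].sum()), 1),
            )
        ],
        columns=df.columns,
    )
    return pd.concat([df, total], ignore_index=True)
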