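"""Greedy assembly, hybrid scaffolding, validation splitting, anchoring."""

import numpy as np
import pytest

from bacpool.align import KmerIndex, global_diff, map_chunks, map_query, mismatch_count
from bacpool.assemble import (
    Contig,
    anchor_sequences,
    assembly_report,
    count_mismatches,
    greedy_assemble,
    hybrid_scaffold,
    infer_clone_spans,
    split_on_coverage,
    validate_and_split,
)
from bacpool.genome import revcomp
from bacpool.reads import Read, ReadSet, simulate_long_reads, simulate_short_reads


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestAlignPrimitives:
    def test_mismatch_count(self):
        assert mismatch_count("ACGT", "ACCT") == 1
        with pytest.raises(ValueError):
            mismatch_count("AC", "ACG")

    def test_map_query_finds_reverse_strand(self, rng):
        ref = _dna(rng, 2000)
        idx = KmerIndex({"r": ref}, k=15)
        hit = map_query(revcomp(ref[500:700]), idx)
        assert hit is not None and hit.strand == "-"
        assert (hit.ref_start, hit.ref_end) == (500, 700)

    def test_global_diff_counts_indels_separately(self):
        d = global_diff("ACGTACGTAA", "ACGTACGTA")
        assert d.substitutions == 0 and d.indels == 1


class TestGreedyAssemble:
    def test_tiling_reads_reassemble_template(self, rng):
        t = _dna(rng, 600)
        reads = [(f"r{i:02d}", t[s:s + 100]) for i, s in enumerate(range(0, 501, 50))]
        contigs = greedy_assemble(reads, min_overlap=30)
        assert len(contigs) == 1
        assert contigs[0].sequence in (t, revcomp(t))

    def test_single_read_contig(self, rng):
        t = _dna(rng, 200)
        contigs = greedy_assemble([("r0", t)])
        assert len(contigs) == 1
        assert contigs[0].sequence in (t, revcomp(t))

    def test_exact_interspersed_repeat_breaks_assembly(self, rng):
        # repeat longer than the read span forces an unresolvable branch
        rep = _dna(rng, 300)
        t = _dna(rng, 2000) + rep + _dna(rng, 2000) + rep + _dna(rng, 2000)
        rs = simulate_short_reads({"t": t}, 40.0, err_rate=0.0, seed=4)
        contigs = greedy_assemble(rs)
        assert len(contigs) > 1

    def test_reverse_complement_invariance(self, rng):
        t = _dna(rng, 3000)
        rs = simulate_short_reads({"t": t}, 30.0, err_rate=0.0, seed=6)
        rc = ReadSet([Read(r.id, revcomp(r.seq), r.qual) for r in rs], "short")
        canon = lambda cs: sorted(min(c.sequence, revcomp(c.sequence)) for c in cs)
        assert canon(greedy_assemble(rs)) == canon(greedy_assemble(rc))

    def test_deterministic_under_fixed_input(self, rng):
        t = _dna(rng, 2500)
        rs = simulate_short_reads({"t": t}, 25.0, seed=7)
        a = [c.sequence for c in greedy_assemble(rs)]
        b = [c.sequence for c in greedy_assemble(rs)]
        assert a == b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_assemble([])


class TestHybridScaffold:
    def test_spanning_long_read_joins_two_contigs(self, rng):
        t = _dna(rng, 9000)
        c1, c2 = Contig("c1", t[:3000]), Contig("c2", t[6000:])
        lr = ReadSet([Read("L1", t[2000:7000], "I" * 5000)], "long")
        scafs = hybrid_scaffold([c1, c2], lr)
        assert len(scafs) == 1
        # gap filled from the error-free spanning read: perfect reconstruction
        assert count_mismatches(scafs[0].sequence, t) == 0

    def test_low_aligned_fraction_read_ignored(self, rng):
        t = _dna(rng, 9000)
        c1, c2 = Contig("c1", t[:3000]), Contig("c2", t[6000:])
        junk = t[2700:3000] + _dna(rng, 1700)  # 15% of the read aligns
        lr = ReadSet([Read("L0", junk, "I" * len(junk))], "long")
        assert len(hybrid_scaffold([c1, c2], lr)) == 2

    def test_fragmented_region_healed_by_long_reads(self, midsize_genome):
        # 46 fragments of a ~270 kb region + 24x long reads -> few scaffolds
        truth = midsize_genome.seq[10_000:280_000]
        rng = np.random.default_rng(0)
        bounds = np.linspace(0, len(truth), 47).astype(int)
        contigs = []
        for i in range(46):
            s, e = bounds[i], bounds[i + 1]
            if i:
                s += int(rng.integers(0, 60))
            seq = truth[s:e]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            contigs.append(Contig(f"c{i:02d}", seq))
        lr = simulate_long_reads({"t": truth}, 24.0, seed=2)
        scafs = hybrid_scaffold(contigs, lr)
        assert len(scafs) <= 5
        idx = KmerIndex({"t": truth}, k=15)
        cov = np.zeros(len(truth) + 1, np.int32)
        for b in map_chunks(max(scafs, key=len).sequence, idx):
            cov[b.ref_start] += 1
            cov[b.ref_end] -= 1
        assert (np.cumsum(cov[:-1]) > 0).mean() >= 0.90

    def test_scaffold_count_never_exceeds_contig_count(self, rng):
        t = _dna(rng, 12_000)
        contigs = [Contig(f"c{i}", t[i * 3000:(i + 1) * 3000]) for i in range(4)]
        lr = simulate_long_reads({"t": t}, 10.0, err_rate=0.0, seed=3)
        assert len(hybrid_scaffold(contigs, lr)) <= 4


class TestValidateAndSplit:
    def test_uniform_coverage_unchanged(self, rng):
        t = _dna(rng, 4000)
        rs = simulate_short_reads({"t": t}, 30.0, err_rate=0.0, seed=5)
        out = validate_and_split([Contig("s", t)], [rs])
        assert len(out) == 1  # no internal split under uniform coverage
        assert out[0].sequence in t and len(out[0]) >= 0.98 * len(t)
        assert out[0].coverage.min() >= 1

    def test_zero_run_split_rule(self):
        s = Contig("s", "ACGTAC")
        pieces = split_on_coverage(s, np.array([5, 5, 0, 0, 7, 7]))
        assert [p.sequence for p in pieces] == ["AC", "AC"]
        assert all(p.coverage.min() >= 1 for p in pieces)

    def test_terminal_zero_runs_trimmed(self):
        s = Contig("s", "ACGTACGT")
        pieces = split_on_coverage(s, np.array([0, 1, 1, 1, 1, 1, 0, 0]))
        assert [p.sequence for p in pieces] == ["CGTAC"]

    def test_chimera_split_at_uncovered_junction(self, midsize_genome):
        g = midsize_genome
        r1, r2 = g.seq[5000:25_000], g.seq[150_000:170_000]
        novel = _dna(np.random.default_rng(9), 100)
        chim = Contig("chim", r1 + novel + r2)
        rs = simulate_short_reads({"a": r1, "b": r2}, 40.0, seed=3)
        pieces = validate_and_split([chim], [rs])
        assert len(pieces) == 2
        assert abs(len(pieces[0]) - len(r1)) <= 50

    def test_idempotent(self, midsize_genome):
        g = midsize_genome
        r1, r2 = g.seq[5000:25_000], g.seq[150_000:170_000]
        chim = Contig("chim", r1 + _dna(np.random.default_rng(9), 100) + r2)
        rs = simulate_short_reads({"a": r1, "b": r2}, 40.0, seed=3)
        once = validate_and_split([chim], [rs])
        twice = validate_and_split(once, [rs])
        assert [p.sequence for p in twice] == [p.sequence for p in once]


@pytest.fixture(scope="module")
def anchored(midsize_genome):
    g = midsize_genome
    scaf = Contig("s0", g.seq[20_000:130_000])
    marker = next(m for m in g.markers if 20_000 < m.position_bp < 125_000)
    queries = [
        (marker.marker_id, marker.amplicon, "marker"),
        ("cl1.F", g.seq[30_000:30_854], "BES"),
        ("cl1.R", revcomp(g.seq[124_146:125_000]), "BES"),
    ]
    return anchor_sequences([scaf], queries), marker


class TestAnchoring:

    def test_marker_amplicon_full_hit_plus_strand(self, anchored):
        df, marker = anchored
        row = df[df["query_id"] == marker.marker_id].iloc[0]
        assert row["status"] == "full" and row["strand"] == "+"

    def test_reverse_complemented_bes_hits_minus_strand(self, anchored):
        df, _ = anchored
        row = df[df["query_id"] == "cl1.R"].iloc[0]
        assert row["status"] == "full" and row["strand"] == "-"

    def test_convergent_pair_implies_clone_span(self, anchored):
        df, _ = anchored
        spans = infer_clone_spans(df)
        assert len(spans) == 1
        row = spans.iloc[0]
        assert row["span_bp"] == 95_000 and row["orientation"] == "+"

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            anchor_sequences([Contig("s", "ACGT" * 100)], [])


class TestCountMismatches:
    def test_identical_long_strings(self, rng):
        t = _dna(rng, 9000)
        assert count_mismatches(t, t) == 0

    def test_single_substitution(self):
        assert count_mismatches("ACGTACGT", "ACCTACGT") == 1

    def test_seven_planted_substitutions_recovered(self, rng):
        a = _dna(rng, 9000)
        b = list(a)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for pos in rng.choice(9000, 7, replace=False):
            b[pos] = flip[b[pos]]
        b = "".join(b)
        assert count_mismatches(a, b) == 7
        assert count_mismatches(b, a) == 7  # symmetric

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            count_mismatches("", "ACGT")


class TestAssemblyReport:
    def test_totals_row_and_hybrid_constraint(self, rng):
        t = _dna(rng, 2000)
        per_pool = {
            "p1": {"short": [Contig("a", t), Contig("b", t)], "hybrid": [Contig("h", t * 2)]},
            "p2": {"short": [], "hybrid": []},
        }
        df = assembly_report(per_pool)
        total = df[df["pool"] == "Total"].iloc[0]
        assert total["n_contigs_short"] == 2 and total["n_scaffolds_hybrid"] == 1
        assert total["kb_hybrid"] == 4.0

    def test_hybrid_count_increase_rejected(self, rng):
        t = _dna(rng, 500)
        per_pool = {"p": {"short": [Contig("a", t)], "hybrid": [Contig("x", t), Contig("y", t)]}}
        with pytest.raises(AssertionError):
            assembly_report(per_pool)
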