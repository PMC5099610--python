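"""Clone library, fingerprints, FPC contigs and tiling-path selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacpool.genome import GenomeTruth
from bacpool.physmap import (
    BacClone,
    CoverGapError,
    FpcContig,
    SamplingExhaustedError,
    build_fpc_contigs,
    cb_to_kb,
    cm_to_mb,
    coverage_fold,
    digest_and_clone,
    fingerprint_clone,
    minimum_cover_bruteforce,
    select_mtp,
    shared_band_count,
)


def _plain_genome(rng, n, motif="GGGGG", motif_positions=()):
    """Motif-free background (no G) with the motif planted at given spots."""
    seq = list("".join(rng.choice(list("ACT"), n)))
    for p in motif_positions:
        seq[p:p + len(motif)] = motif
    return GenomeTruth(seq="".join(seq), length_bp=n)


class TestDigestAndClone:
    def test_insert_sizes_and_mean_near_98kb(self, rng):
        # recognition sites every ~16 kb on a motif-free background
        sites = list(range(16_000, 800_000, 16_000))
        g = _plain_genome(rng, 800_000, motif_positions=sites)
        clones = digest_and_clone(
            g, site="GGGGG", partial_prob=0.05, size_window=(80_000, 120_000),
            n_clones=200, seed=1,
        )
        lens = np.array([c.insert_len_bp for c in clones])
        assert len(clones) == 200
        assert (lens >= 80_000).all() and (lens <= 120_000).all()
        assert abs(lens.mean() - 98_000) < 10_000
        # clone boundaries sit on retained cut sites (or genome ends)
        legal = set(sites) | {0, 800_000}
        assert all(c.start in legal and c.end in legal for c in clones)

    def test_requested_coverage_fold_recovered(self, midsize_genome):
        clones = digest_and_clone(midsize_genome, n_clones=30, seed=7)
        base_cov = np.zeros(midsize_genome.length_bp, dtype=np.int16)
        for c in clones:
            base_cov[c.start:c.end] += 1
        measured = base_cov.mean()
        requested = 30 * np.mean([c.insert_len_bp for c in clones]) / midsize_genome.length_bp
        assert measured == pytest.approx(requested, rel=1e-9)  # counting identity
        assert abs(measured - 5.9) / 5.9 < 0.10  # ~98 kb x 30 / 500 kb

    def test_window_excluding_complete_digest_raises(self, rng):
        g = _plain_genome(rng, 100_000, motif_positions=range(3000, 97_000, 3000))
        with pytest.raises(SamplingExhaustedError):
            digest_and_clone(g, site="GGGGG", partial_prob=1.0,
                             size_window=(50_000, 60_000), n_clones=5, seed=0)

    def test_addresses_unique(self, midsize_genome):
        clones = digest_and_clone(midsize_genome, n_clones=25, seed=3)
        assert len({c.address for c in clones}) == 25


class TestFingerprint:
    def test_band_definition(self, rng):
        g = _plain_genome(rng, 60_000, motif_positions=(10_000, 30_000))
        clone = BacClone("c", (0, 0, 0), 0, 50_000)
        fp = fingerprint_clone(clone, g, site="GGGGG", tolerance_bp=1)
        assert sorted(fp.bands) == [10_000, 20_000, 20_000]

    def test_identical_clones_identical_fingerprints(self, midsize_genome):
        a = BacClone("a", (0, 0, 0), 10_000, 110_000)
        b = BacClone("b", (0, 0, 1), 10_000, 110_000)
        fa = fingerprint_clone(a, midsize_genome)
        fb = fingerprint_clone(b, midsize_genome)
        assert fa.bands == fb.bands

    def test_overlapping_clones_share_overlap_bands(self, midsize_genome):
        g = midsize_genome
        a = BacClone("a", (0, 0, 0), 100_000, 200_000)
        b = BacClone("b", (0, 0, 1), 150_000, 250_000)
        fa, fb = (fingerprint_clone(c, g) for c in (a, b))
        # oracle: bands of the overlap interval computed directly
        ov = BacClone("ov", (0, 0, 2), 150_000, 200_000)
        fov = fingerprint_clone(ov, g)
        # internal fragments of the overlap (ends differ) must appear in both
        internal = [band for band in fov.bands[:-2]]
        shared = shared_band_count(fa, fb)
        assert shared >= len(internal) - 2


class TestFpcContigs:
    def test_two_sharing_clones_form_one_contig(self, midsize_genome):
        a = BacClone("a", (0, 0, 0), 100_000, 200_000)
        b = BacClone("b", (0, 0, 1), 150_000, 250_000)
        fps = [fingerprint_clone(c, midsize_genome) for c in (a, b)]
        contigs = build_fpc_contigs(fps, 10, [a, b])
        assert len(contigs) == 1 and len(contigs[0].clone_ids) == 2

    def test_clones_sharing_no_bands_stay_singletons(self):
        from bacpool.physmap import Fingerprint

        fa = Fingerprint("a", (100, 200, 300))
        fb = Fingerprint("b", (150, 250, 350))
        contigs = build_fpc_contigs([fa, fb], min_shared_bands=1)
        assert len(contigs) == 2 and all(c.is_singleton for c in contigs)

    def test_partition_property_and_span_accuracy(self, midsize_genome):
        clones = digest_and_clone(midsize_genome, n_clones=30, seed=7)
        fps = [fingerprint_clone(c, midsize_genome) for c in clones]
        contigs = build_fpc_contigs(fps, 10, clones)
        seen = [cid for c in contigs for cid in c.clone_ids]
        assert sorted(seen) == sorted(c.clone_id for c in clones)
        in_contigs = sum(len(c.clone_ids) for c in contigs if not c.is_singleton)
        assert in_contigs / len(clones) >= 0.90
        for c in contigs:
            if not c.is_singleton:
                span = c.true_span[1] - c.true_span[0]
                assert abs(cb_to_kb(c.cb_units) * 1000 - span) / span < 0.25


class TestTilingPath:
    def test_three_interval_example(self):
        contig = FpcContig("x", ["a", "b", "c"], 0.0, (0, 200))
        tp = select_mtp(contig, {"a": (0, 100), "b": (50, 150), "c": (90, 200)})
        assert tp.clone_ids == ["a", "c"]
        assert minimum_cover_bruteforce([(0, 100), (50, 150), (90, 200)]) == 2

    def test_single_clone_contig(self):
        tp = select_mtp(FpcContig("x", ["a"], 0.0, (0, 10)), {"a": (0, 10)})
        assert tp.clone_ids == ["a"]

    def test_disconnected_clones_raise_with_gaps(self):
        contig = FpcContig("x", ["a", "b"], 0.0, (0, 300))
        with pytest.raises(CoverGapError) as exc:
            select_mtp(contig, {"a": (0, 100), "b": (200, 300)})
        assert exc.value.gaps == [(100, 200)]

    def test_greedy_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 13))
            ivals = [(0, int(rng.integers(40, 250)))]
            for _ in range(n - 1):
                s = int(rng.integers(0, max(e for _, e in ivals)))
                ivals.append((s, s + int(rng.integers(40, 250))))
            intervals = {f"c{i}": iv for i, iv in enumerate(ivals)}
            tp = select_mtp(FpcContig("x", list(intervals), 0.0, (0, 0)), intervals)
            assert len(tp.clone_ids) == minimum_cover_bruteforce(ivals)

    def test_selection_covers_clone_union(self, midsize_genome):
        clones = digest_and_clone(midsize_genome, n_clones=30, seed=7)
        from bacpool.physmap import fingerprint_clone as fpc

        contigs = build_fpc_contigs([fpc(c, midsize_genome) for c in clones], 10, clones)
        iv = {c.clone_id: (c.start, c.end) for c in clones}
        for ctg in contigs:
            tp = select_mtp(ctg, iv)
            cov = np.zeros(midsize_genome.length_bp, bool)
            for cid in tp.clone_ids:
                cov[iv[cid][0]:iv[cid][1]] = True
            full = np.zeros_like(cov)
            for cid in ctg.clone_ids:
                full[iv[cid][0]:iv[cid][1]] = True
            assert (cov == full).all()


class TestUnitConversions:
    @pytest.mark.parametrize(
        "cb,expected", [(5177, 7040.7), (0, 0.0), (100, 136.0)]
    )
    def test_cb_to_kb(self, cb, expected):
        assert cb_to_kb(cb, 1.36) == pytest.approx(expected)

    @pytest.mark.parametrize("cm,expected", [(97, 28.5), (0, 0.0), (3.4, 1.0)])
    def test_cm_to_mb(self, cm, expected):
        assert cm_to_mb(cm, 3.4) == pytest.approx(expected, abs=0.05)

    def test_cm_to_mb_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            cm_to_mb(10, 0)

    @given(a=st.floats(0, 1e4), b=st.floats(0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_conversions_are_linear(self, a, b):
        assert cm_to_mb(a + b) == pytest.approx(cm_to_mb(a) + cm_to_mb(b), rel=1e-9, abs=1e-9)
        assert a * 1.36 + b * 1.36 == pytest.approx((a + b) * 1.36, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize(
        "n,insert,genome,expected",
        [(49152, 98, 700, 6.9), (35265, 98, 700, 4.9), (0, 98, 700, 0.0)],
    )
    def test_coverage_fold(self, n, insert, genome, expected):
        assert coverage_fold(n, insert, genome) == expected

    def test_coverage_fold_rejects_nonpositive_genome(self):
        with pytest.raises(ValueError):
            coverage_fold(10, 98, 0)
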