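"""Association statistics, frequencies, Tukey letters, qPCR ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bacpool.assoc import (
    DegenerateVarianceError,
    MissingLocusError,
    MonomorphicError,
    _tukey_letters,
    associate,
    expression_contrast,
    genotype_and_allele_freqs,
    per_family_replication,
    pfaffl_ratio,
    simulate_cross,
)
from bacpool.genome import SnpLocus


def _snp(eff=0.0, freq=0.3, snp_id="s1"):
    e = {"BW": eff, "TL": eff, "SL": eff}
    return SnpLocus(snp_id, "g", 0, "A", "T", e, freq)


def _tables(genos, values, snp_id="s1"):
    """Build genotype/trait tables from explicit per-individual data."""
    grows, trows = [], []
    for i, (g, v) in enumerate(zip(genos, values)):
        iid = f"i{i}"
        grows.append((iid, "fam1", snp_id, g[0], g[1]))
        trows.append((iid, "fam1", v, v, v))
    return (
        pd.DataFrame(grows, columns=["individual_id", "family_id", "snp_id", "allele1", "allele2"]),
        pd.DataFrame(trows, columns=["individual_id", "family_id", "BW", "TL", "SL"]),
    )


class TestSimulateCross:
    def test_tables_align_and_are_mendelian(self):
        gt, tr = simulate_cross(2, 100, [_snp()], seed=1)
        assert set(gt["individual_id"]) == set(tr["individual_id"])
        assert set(gt["allele1"]) | set(gt["allele2"]) <= {"A", "T"}

    def test_monomorphic_snp_gives_identical_genotypes(self):
        gt, _ = simulate_cross(1, 50, [_snp(freq=0.0)], seed=2)
        assert (gt["allele1"] == "A").all() and (gt["allele2"] == "A").all()

    def test_family_weights_respected(self):
        gt, tr = simulate_cross(2, 1000, [_snp()], family_weights=(0.8, 0.2), seed=3)
        sizes = tr.groupby("family_id").size()
        assert abs(sizes["fam1"] / 1000 - 0.8) < 0.05


class TestFrequencies:
    def test_hand_counted_example(self):
        genos = [("C", "C")] * 50 + [("C", "T")] * 50
        gt, _ = _tables(genos, [0.0] * 100)
        f = genotype_and_allele_freqs(gt, "s1")
        by = {(r["kind"], r["state"]): r["frequency"] for _, r in f.iterrows()}
        assert by[("genotype", "CC")] == 0.5 and by[("genotype", "CT")] == 0.5
        assert by[("allele", "C")] == 0.75 and by[("allele", "T")] == 0.25

    def test_single_individual(self):
        gt, _ = _tables([("A", "A")], [1.0])
        f = genotype_and_allele_freqs(gt, "s1")
        assert (f["frequency"] == 1.0).all()

    def test_missing_locus(self):
        gt, _ = _tables([("A", "A")], [1.0])
        with pytest.raises(MissingLocusError):
            genotype_and_allele_freqs(gt, "nope")

    @given(st.lists(st.sampled_from(["AA", "AT", "TT"]), min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_frequencies_sum_to_one(self, genos):
        gt, _ = _tables([(g[0], g[1]) for g in genos], [0.0] * len(genos))
        f = genotype_and_allele_freqs(gt, "s1")
        for kind in ("genotype", "allele"):
            assert f[f["kind"] == kind]["frequency"].sum() == pytest.approx(1.0)


class TestAssociate:
    def test_identical_groups_give_t_zero_p_one(self):
        vals = [1.0, 2.0, 3.0] * 4
        genos = [("A", "A")] * 6 + [("T", "T")] * 6
        gt, tr = _tables(genos, vals)
        res = associate(gt, tr, "s1", "BW")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_t_matches_textbook_formula(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        genos = [("A", "A")] * 10 + [("T", "T")] * 10
        gt, tr = _tables(genos, list(a) + list(b))
        res = associate(gt, tr, "s1", "BW")
        # independent oracle: pooled-variance t computed from the formula
        sp2 = ((9 * a.var(ddof=1)) + (9 * b.var(ddof=1))) / 18
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 10 + 1 / 10))
        p_hand = 2 * stats.t.sf(abs(t_hand), 18)
        assert res.statistic == pytest.approx(t_hand, abs=1e-6)
        assert res.p_value == pytest.approx(p_hand, abs=1e-6)

    def test_f_equals_t_squared_on_two_groups(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        f, _ = stats.f_oneway(a, b)
        assert abs(f - t**2) < 1e-9

    def test_three_genotype_anova_with_letters(self, rng):
        genos = [("A", "A")] * 20 + [("A", "T")] * 20 + [("T", "T")] * 20
        vals = list(rng.normal(0, 1, 20)) + list(rng.normal(1, 1, 20)) + list(
            rng.normal(4, 1, 20)
        )
        gt, tr = _tables(genos, vals)
        res = associate(gt, tr, "s1", "BW")
        assert res.test == "anova" and res.significant
        assert res.tukey_letters  # letter display produced
        # the clearly separated TT group carries its own letter
        assert res.tukey_letters["TT"] != res.tukey_letters["AA"]

    def test_monomorphic_and_degenerate_errors(self):
        gt, tr = _tables([("A", "A")] * 5, [1.0] * 5)
        with pytest.raises(MonomorphicError):
            associate(gt, tr, "s1", "BW")
        gt2, tr2 = _tables([("A", "A")] * 3 + [("T", "T")] * 3, [1.0] * 3 + [2.0] * 3)
        with pytest.raises(DegenerateVarianceError):
            associate(gt2, tr2, "s1", "BW")


class TestTukeyLetters:
    def test_letter_display_consistent_with_pairwise_tests(self, rng):
        # random 3-group instances: shared letter <-> non-significant pair
        for trial in range(30):
            r = np.random.default_rng(trial)
            shift = r.uniform(0, 3, 3)
            groups = {
                f"g{i}": r.normal(shift[i], 1, 12) for i in range(3)
            }
            letters = _tukey_letters(groups, alpha=0.05)
            res = stats.tukey_hsd(*[groups[g] for g in sorted(groups)])
            names = sorted(groups)
            for i, j in itertools.combinations(range(3), 2):
                share = bool(set(letters[names[i]]) & set(letters[names[j]]))
                nonsig = res.pvalue[i, j] >= 0.05
                assert share == nonsig


class TestPerFamily:
    def test_shared_effect_concordant_in_major_families(self):
        gt, tr = simulate_cross(
            2, 400, [_snp(eff=1.0, freq=0.5)], family_weights=(0.6, 0.4), seed=1
        )
        out = per_family_replication(gt, tr, "s1", "BW", min_family_n=50)
        tested = [(f, r, c) for f, r, c in out if r is not None]
        assert len(tested) == 2
        assert all(c for _, _, c in tested)

    def test_small_family_skipped(self):
        gt, tr = simulate_cross(
            2, 120, [_snp(eff=1.0, freq=0.5)], family_weights=(0.9, 0.1), seed=6
        )
        out = per_family_replication(gt, tr, "s1", "BW", min_family_n=50)
        skipped = [f for f, r, _ in out if r is None]
        assert "fam2" in skipped

    def test_family_confined_effect_discordant_elsewhere(self):
        # same genotypes, trait effect flipped in family 2 by construction
        rng = np.random.default_rng(7)
        grows, trows = [], []
        for i in range(200):
            fam = "fam1" if i < 100 else "fam2"
            g = ("A", "A") if i % 2 == 0 else ("T", "T")
            eff = (1.0 if g == ("T", "T") else 0.0)
            if fam == "fam2":
                eff = -eff
            v = eff + rng.normal(0, 0.3)
            grows.append((f"i{i}", fam, "s1", *g))
            trows.append((f"i{i}", fam, v, v, v))
        gt = pd.DataFrame(grows, columns=["individual_id", "family_id", "snp_id", "allele1", "allele2"])
        tr = pd.DataFrame(trows, columns=["individual_id", "family_id", "BW", "TL", "SL"])
        out = {f: c for f, r, c in per_family_replication(gt, tr, "s1", "BW", 50)}
        assert out["fam1"] != out["fam2"]


class TestExpression:
    @pytest.mark.parametrize(
        "args,expected",
        [((2.0, 1.0, 2.0, 1.0), 1.0), ((2.0, 3.0, 2.0, 0.0), 8.0), ((2.0, 0.0, 2.0, 0.0), 1.0)],
    )
    def test_pfaffl_closed_forms(self, args, expected):
        assert pfaffl_ratio(*args) == pytest.approx(expected)

    def test_pfaffl_rejects_bad_efficiency(self):
        with pytest.raises(ValueError):
            pfaffl_ratio(1.0, 1.0, 2.0, 1.0)

    def test_identical_groups_not_significant(self):
        ratios = [1.0, 1.1, 0.9, 1.0]
        direction, p, sig = expression_contrast(ratios, ratios)
        assert p == pytest.approx(1.0) and not sig

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            expression_contrast([1.0], [1.0, 2.0])

    def test_twofold_downregulation_power(self):
        # planted 2-fold difference, n=6/6, CV 10%: detected in >90% of sims
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            fast = rng.normal(0.5, 0.05, 6)
            slow = rng.normal(1.0, 0.10, 6)
            direction, p, sig = expression_contrast(fast, slow)
            hits += sig and direction == "down"
        assert hits / 200 > 0.90
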