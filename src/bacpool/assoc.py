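"""SNP genotype-growth trait association and qPCR expression contrasts.

Implements the classical single-marker workflow for a multi-family
aquaculture cross: genotype/allele frequencies, a pooled-variance two-sample
t-test when a SNP segregates as two genotype classes, one-way ANOVA plus
Tukey HSD with a compact letter display for three classes, and per-family
replication with a concordance flag.  Relative qPCR expression uses the
efficiency-corrected ratio ``E_t^dCt_t / E_r^dCt_r`` with the
calibrator-minus-sample Ct convention.

No multiple-testing correction is applied across SNP x trait combinations;
the report carries the number of tests run so users can apply their own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import TRAITS, SnpLocus

__all__ = [
    "AssociationResult",
    "simulate_cross",
    "genotype_and_allele_freqs",
    "associate",
    "per_family_replication",
    "pfaffl_ratio",
    "expression_contrast",
    "MonomorphicError",
    "DegenerateVarianceError",
    "MissingLocusError",
]


class MonomorphicError(ValueError):
    pass


class DegenerateVarianceError(ValueError):
    pass


class MissingLocusError(KeyError):
    pass


@dataclass
class AssociationResult:
    snp_id: str
    trait: str
    test: str  # "t" | "anova"
    statistic: float
    p_value: float
    group_stats: dict[str, tuple[int, float, float]]  # genotype -> (n, mean, sd)
    tukey_letters: dict[str, str] = field(default_factory=dict)
    significant: bool = False
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# simulation


def simulate_cross(
    n_families: int,
    n_offspring: int,
    snps: list[SnpLocus],
    family_weights: tuple[float, ...] | None = None,
    family_sd: float = 0.0,
    residual_sd: float = 1.0,
    trait_means: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate genotypes and growth traits for a multi-family cross.

    Two parents per family draw alleles from each SNP's population
    frequency; offspring genotypes are Mendelian.  Traits are
    ``mu + family effect + sum(additive effect x alt count) + N(0, residual)``.
    ``family_weights`` supports the uneven family contributions typical of
    a mass cross.  Returns (genotype table, trait table).
    """
    if n_families < 1 or n_offspring < 1:
        raise ValueError("family and offspring counts must be positive")
    rng = np.random.default_rng(seed)
    if family_weights is None:
        family_weights = tuple([1.0 / n_families] * n_families)
    w = np.asarray(family_weights[:n_families], dtype=float)
    w = w / w.sum()
    fam_sizes = rng.multinomial(n_offspring, w)
    if trait_means is None:
        trait_means = {"BW": 500.0, "TL": 30.0, "SL": 25.0}
    # parental alleles per family per snp: (2 parents x 2 alleles)
    geno_rows = []
    trait_rows = []
    ind = 0
    for f in range(n_families):
        fam_id = f"fam{f + 1}"
        fam_eff = {t: rng.normal(0.0, family_sd) if family_sd > 0 else 0.0 for t in TRAITS}
        parents = {
            s.snp_id: rng.random((2, 2)) < s.alt_freq for s in snps
        }  # True = alt allele
        for _ in range(fam_sizes[f]):
            ind += 1
            iid = f"ind{ind:05d}"
            alt_counts = {}
            for s in snps:
                p = parents[s.snp_id]
                a1 = p[0, int(rng.integers(0, 2))]
                a2 = p[1, int(rng.integers(0, 2))]
                alt_counts[s.snp_id] = int(a1) + int(a2)
                alleles = sorted(
                    [s.alt_allele if a1 else s.ref_allele,
                     s.alt_allele if a2 else s.ref_allele]
                )
                geno_rows.append((iid, fam_id, s.snp_id, alleles[0], alleles[1]))
            traits = {}
            for t in TRAITS:
                val = trait_means[t] + fam_eff[t] + rng.normal(0.0, residual_sd)
                for s in snps:
                    val += s.additive_effect.get(t, 0.0) * alt_counts[s.snp_id]
                traits[t] = val
            trait_rows.append((iid, fam_id, traits["BW"], traits["TL"], traits["SL"]))
    genotypes = pd.DataFrame(
        geno_rows, columns=["individual_id", "family_id", "snp_id", "allele1", "allele2"]
    )
    traits_df = pd.DataFrame(
        trait_rows, columns=["individual_id", "family_id", "BW", "TL", "SL"]
    )
    return genotypes, traits_df


# ---------------------------------------------------------------------------
# frequencies


def genotype_and_allele_freqs(genotypes: pd.DataFrame, snp_id: str) -> pd.DataFrame:
    """Genotype and allele counts and frequencies for one SNP.

    Returns a long-format frame with ``kind`` in {"genotype", "allele"};
    frequencies of each kind sum to 1.
    """
    sub = genotypes[genotypes["snp_id"] == snp_id]
    if sub.empty:
        raise MissingLocusError(snp_id)
    geno = (sub["allele1"] + sub["allele2"]).value_counts().sort_index()
    alleles = pd.concat([sub["allele1"], sub["allele2"]]).value_counts().sort_index()
    rows = []
    for g, n in geno.items():
        rows.append((snp_id, "genotype", g, int(n), n / len(sub)))
    for a, n in alleles.items():
        rows.append((snp_id, "allele", a, int(n), n / (2 * len(sub))))
    return pd.DataFrame(rows, columns=["snp_id", "kind", "state", "count", "frequency"])


# ---------------------------------------------------------------------------
# association tests


def _group_arrays(
    genotypes: pd.DataFrame, traits: pd.DataFrame, snp_id: str, trait: str
) -> dict[str, np.ndarray]:
    sub = genotypes[genotypes["snp_id"] == snp_id]
    if sub.empty:
        raise MissingLocusError(snp_id)
    merged = sub.merge(traits[["individual_id", trait]], on="individual_id")
    merged["genotype"] = merged["allele1"] + merged["allele2"]
    return {
        g: grp[trait].to_numpy(dtype=float)
        for g, grp in merged.groupby("genotype", sort=True)
    }


def _test_groups(groups: dict[str, np.ndarray], alpha: float, welch: bool = False):
    """Core two/three-class test shared by the table API and simulations."""
    usable = {g: v for g, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise MonomorphicError("fewer than two genotype classes with n >= 2")
    values = list(usable.values())
    if all(np.var(v) == 0 for v in values):
        raise DegenerateVarianceError("zero within-group variance everywhere")
    if len(usable) == 2:
        stat, p = stats.ttest_ind(values[0], values[1], equal_var=not welch)
        return "t", float(stat), float(p), usable
    stat, p = stats.f_oneway(*values)
    return "anova", float(stat), float(p), usable


def _tukey_letters(usable: dict[str, np.ndarray], alpha: float) -> dict[str, str]:
    """Tukey HSD pairwise comparisons summarized as a compact letter display.

    Groups sharing a letter are pairwise non-significant; every
    non-significant pair shares at least one letter.
    """
    names = sorted(usable)
    res = stats.tukey_hsd(*[usable[g] for g in names])
    nonsig = {
        frozenset((names[i], names[j]))
        for i, j in itertools.combinations(range(len(names)), 2)
        if res.pvalue[i, j] >= alpha
    }
    # letter assignment by greedy clique cover of the non-significance graph
    order = sorted(names, key=lambda g: -float(np.mean(usable[g])))
    letters: dict[str, str] = {g: "" for g in names}
    next_letter = 0
    covered: set[frozenset] = set()
    for g in order:
        if not letters[g]:
            clique = [g]
            for h in order:
                if h != g and all(frozenset((h, m)) in nonsig for m in clique):
                    clique.append(h)
            lab = chr(ord("a") + next_letter)
            next_letter += 1
            for m in clique:
                letters[m] += lab
            covered.update(
                frozenset((x, y)) for x, y in itertools.combinations(clique, 2)
            )
    for pair in nonsig - covered:
        x, y = sorted(pair)
        lab = chr(ord("a") + next_letter)
        next_letter += 1
        letters[x] += lab
        letters[y] += lab
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def associate(
    genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    snp_id: str,
    trait: str,
    alpha: float = 0.05,
    welch: bool = False,
) -> AssociationResult:
    """Single-marker association between a SNP's genotypes and one trait.

    Two genotype classes are compared with a pooled-variance t-test (Welch
    behind a flag); three classes with one-way ANOVA followed, when the F
    test is significant, by Tukey HSD pairwise comparisons summarized as a
    compact letter display.
    """
    groups = _group_arrays(genotypes, traits, snp_id, trait)
    test, stat, p, usable = _test_groups(groups, alpha, welch)
    gstats = {
        g: (int(v.size), float(np.mean(v)), float(np.std(v, ddof=1)))
        for g, v in usable.items()
    }
    letters: dict[str, str] = {}
    if test == "anova" and p < alpha:
        letters = _tukey_letters(usable, alpha)
    return AssociationResult(
        snp_id, trait, test, stat, p, gstats, letters, significant=p < alpha, alpha=alpha
    )


def per_family_replication(
    genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    snp_id: str,
    trait: str,
    min_family_n: int = 30,
    alpha: float = 0.05,
) -> list[tuple[str, AssociationResult | None, bool]]:
    """Within-family re-tests of a pooled association.

    Families below ``min_family_n`` are skipped (``None`` result).  The
    concordance flag marks whether the family's genotype-mean ordering
    matches the pooled analysis over shared genotype classes.
    """
    pooled = associate(genotypes, traits, snp_id, trait, alpha)
    pooled_order = sorted(pooled.group_stats, key=lambda g: pooled.group_stats[g][1])
    out = []
    for fam, g_fam in genotypes.groupby("family_id", sort=True):
        n_fam = g_fam[g_fam["snp_id"] == snp_id]["individual_id"].nunique()
        if n_fam < min_family_n:
            out.append((str(fam), None, False))
            continue
        t_fam = traits[traits["family_id"] == fam]
        try:
            res = associate(g_fam, t_fam, snp_id, trait, alpha)
        except (MonomorphicError, DegenerateVarianceError):
            out.append((str(fam), None, False))
            continue
        fam_order = sorted(res.group_stats, key=lambda g: res.group_stats[g][1])
        shared = [g for g in fam_order if g in pooled_order]
        concordant = shared == [g for g in pooled_order if g in shared]
        out.append((str(fam), res, concordant))
    return out


# ---------------------------------------------------------------------------
# qPCR expression


def pfaffl_ratio(e_target: float, dct_target: float, e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected relative expression ratio.

    ``dCt`` follows the calibrator-minus-sample convention; efficiencies are
    amplification factors in (1, 2].
    """
    for e in (e_target, e_ref):
        if not 1.0 < e <= 2.0:
            raise ValueError("amplification efficiency must be in (1, 2]")
    return float(e_target**dct_target / e_ref**dct_ref)


def expression_contrast(
    ratios_fast: np.ndarray | list[float],
    ratios_slow: np.ndarray | list[float],
    alpha: float = 0.05,
) -> tuple[str, float, bool]:
    """Two-sample t-test on log expression ratios of two growth groups.

    Returns (direction, p, significant) where direction is ``"up"`` when the
    first group's mean log-ratio exceeds the second's.
    """
    a = np.asarray(ratios_fast, dtype=float)
    b = np.asarray(ratios_slow, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("expression ratios must be positive")
    la, lb = np.log2(a), np.log2(b)
    if np.var(la) == 0 and np.var(lb) == 0:
        if np.isclose(la.mean(), lb.mean()):
            return "none", 1.0, False
        raise DegenerateVarianceError("zero variance in both groups")
    stat, p = stats.ttest_ind(la, lb, equal_var=True)
    direction = "up" if la.mean() > lb.mean() else ("down" if la.mean() < lb.mean() else "none")
    return direction, float(p), p < alpha


def association_report(results: list[AssociationResult]) -> pd.DataFrame:
    """Flat report of association results (one row per SNP x trait).

    The ``n_tests`` column repeats the total number of uncorrected tests so
    downstream users can apply their own multiplicity control.
    """
    rows = []
    for r in results:
        for g, (n, mean, sd) in sorted(r.group_stats.items()):
            rows.append(
                (
                    r.snp_id, r.trait, r.test, g, n,
                    round(mean, 2), round(sd, 2),
                    r.tukey_letters.get(g, ""),
                    r.statistic, r.p_value, r.significant, len(results),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "trait", "test", "genotype", "n", "mean", "sd",
            "letters", "statistic", "p_value", "significant", "n_tests",
        ],
    )
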