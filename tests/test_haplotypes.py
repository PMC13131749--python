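"""EM haplotype-frequency estimation against independent ML oracles, and LD."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import softmax

from dqrisk.haplotypes import (
    HaplotypeFrequencyEstimator,
    HaplotypeFrequencyTable,
    bootstrap_conditional_linkage,
    conditional_linkage,
    conditional_linkage_from_counts,
    count_phased_haplotypes,
    em_haplotype_frequencies,
    ld_from_frequencies,
    ld_metrics,
    top_haplotypes,
)
from dqrisk.simulate import sample_cohort

LOCI2 = ("L1", "L2")


def genotypes_from_haplotype_pairs(pairs, loci):
    return [
        {locus: (h1[i], h2[i]) for i, locus in enumerate(loci)}
        for h1, h2 in pairs
    ]


def sample_genotypes(hap_freqs, n, seed, loci):
    """Draw n unphased genotypes from known haplotype frequencies."""
    rng = np.random.default_rng(seed)
    haps = list(hap_freqs)
    p = np.array([hap_freqs[h] for h in haps])
    idx = rng.choice(len(haps), size=(n, 2), p=p)
    return genotypes_from_haplotype_pairs(
        [(haps[i], haps[j]) for i, j in idx], loci
    )


# --- independent oracle: full-enumeration likelihood over the simplex ------


def genotype_loglik(freq_map, genotypes, loci):
    """Log-likelihood via ordered phase enumeration (independent of the EM)."""
    total = 0.0
    for g in genotypes:
        per_locus = [g[locus] for locus in loci]
        het = [i for i, pair in enumerate(per_locus) if pair[0] != pair[1]]
        prob = 0.0
        # ordered assignment of each heterozygous locus to (chrom1, chrom2);
        # homozygous loci contribute a single fixed allele per chromosome
        for orient in itertools.product((0, 1), repeat=len(het)):
            flips = dict(zip(het, orient))
            h1 = tuple(pair[flips.get(i, 0)] for i, pair in enumerate(per_locus))
            h2 = tuple(pair[1 - flips.get(i, 0)] for i, pair in enumerate(per_locus))
            prob += freq_map.get(h1, 0.0) * freq_map.get(h2, 0.0)
        total += math.log(max(prob, 1e-300))
    return total


def ml_oracle(genotypes, loci, n_starts=8, seed=0):
    """Maximize the likelihood over the full allele-product haplotype space
    with a softmax parametrization and multi-start BFGS."""
    alleles = [sorted({a for g in genotypes for a in g[locus]}) for locus in loci]
    haps = list(itertools.product(*alleles))

    def neg_loglik(theta):
        freq = dict(zip(haps, softmax(theta)))
        return -genotype_loglik(freq, genotypes, loci)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        theta0 = np.zeros(len(haps)) if s == 0 else rng.normal(0, 2, len(haps))
        res = minimize(neg_loglik, theta0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return dict(zip(haps, softmax(best.x))), -best.fun


class TestEmAgainstOracles:
    def test_homozygous_input_equals_direct_counting(self):
        pairs = [(("a", "x"), ("a", "x"))] * 6 + [(("b", "y"), ("b", "y"))] * 4
        table = em_haplotype_frequencies(
            genotypes_from_haplotype_pairs(pairs, LOCI2), LOCI2
        )
        assert table.frequencies[("a", "x")] == pytest.approx(0.6)
        assert table.frequencies[("b", "y")] == pytest.approx(0.4)
        assert table.iterations <= 2

    def test_single_double_heterozygote_uniform_fixed_point(self):
        genotypes = [{"L1": ("a", "b"), "L2": ("x", "y")}]
        table = em_haplotype_frequencies(genotypes, LOCI2, init="uniform")
        for hap in itertools.product("ab", "xy"):
            assert table.frequencies[hap] == pytest.approx(0.25, abs=1e-12)
        assert table.iterations == 1

    def test_em_matches_d_parametrized_grid_search(self):
        """Two biallelic loci: EM equals a 1-D brute-force likelihood search.

        The EM conserves allele counts, so the MLE has margins equal to the
        observed allele frequencies; the free parameter is the disequilibrium
        D, searched exhaustively on a fine grid.
        """
        truth = {("A", "B"): 0.5, ("A", "b"): 0.3, ("a", "B"): 0.15, ("a", "b"): 0.05}
        genotypes = sample_genotypes(truth, 100, seed=21, loci=LOCI2)
        table = em_haplotype_frequencies(genotypes, LOCI2, tol=1e-10)

        # observed allele frequencies (phase-free)
        pA = np.mean([[g["L1"][0] == "A", g["L1"][1] == "A"] for g in genotypes])
        pB = np.mean([[g["L2"][0] == "B", g["L2"][1] == "B"] for g in genotypes])
        d_lo = -min(pA * pB, (1 - pA) * (1 - pB))
        d_hi = min(pA * (1 - pB), (1 - pA) * pB)
        best_d, best_ll = None, -np.inf
        for d in np.arange(d_lo, d_hi, 1e-5):
            freq = {
                ("A", "B"): pA * pB + d, ("A", "b"): pA * (1 - pB) - d,
                ("a", "B"): (1 - pA) * pB - d, ("a", "b"): (1 - pA) * (1 - pB) + d,
            }
            if min(freq.values()) < 0:
                continue
            ll = genotype_loglik(freq, genotypes, LOCI2)
            if ll > best_ll:
                best_d, best_ll = d, ll
        oracle = {
            ("A", "B"): pA * pB + best_d, ("A", "b"): pA * (1 - pB) - best_d,
            ("a", "B"): (1 - pA) * pB - best_d,
            ("a", "b"): (1 - pA) * (1 - pB) + best_d,
        }
        for hap, f in oracle.items():
            assert table.frequencies.get(hap, 0.0) == pytest.approx(f, abs=2e-3)

    @pytest.mark.parametrize("seed,n_loci", [(1, 2), (2, 3), (3, 3)])
    def test_em_equals_simplex_ml_on_tiny_instances(self, seed, n_loci):
        """≤3 loci, ≤8 distinct genotypes: EM matches direct ML within 1e-3."""
        loci = tuple(f"L{i}" for i in range(n_loci))
        rng = np.random.default_rng(seed)
        alleles = [("a", "b"), ("x", "y"), ("p", "q")][:n_loci]
        haps = list(itertools.product(*alleles))
        p = rng.dirichlet(np.ones(len(haps)) * 2)
        truth = dict(zip(haps, p))
        genotypes = sample_genotypes(truth, 40, seed=seed + 100, loci=loci)
        # collapse to at most 8 distinct genotypes
        seen, kept = set(), []
        for g in genotypes:
            key = tuple(tuple(sorted(g[locus])) for locus in loci)
            if key in seen or len(seen) < 8:
                seen.add(key)
                kept.append(g)
        table = em_haplotype_frequencies(kept, loci, tol=1e-12, n_restarts=3,
                                         random_state=0)
        oracle_freqs, oracle_ll = ml_oracle(kept, loci, seed=seed)
        assert table.log_likelihood >= oracle_ll - 1e-6
        for hap in oracle_freqs:
            assert table.frequencies.get(hap, 0.0) == pytest.approx(
                oracle_freqs[hap], abs=1e-3
            )

    def test_log_likelihood_monotone_under_tight_tolerance(self):
        # the EM asserts monotonicity internally every iteration
        truth = {("A", "B"): 0.4, ("A", "b"): 0.1, ("a", "B"): 0.2, ("a", "b"): 0.3}
        genotypes = sample_genotypes(truth, 300, seed=8, loci=LOCI2)
        table = em_haplotype_frequencies(genotypes, LOCI2, tol=1e-12, max_iter=500)
        assert table.converged

    def test_phased_counting_path_flags_method(self, eur_cohort):
        table = count_phased_haplotypes(eur_cohort, ("B", "DQA1", "DQB1"))
        assert table.method == "counting"
        assert table.n_chromosomes == 2 * len(eur_cohort)
        assert sum(table.frequencies.values()) == pytest.approx(1.0)

    def test_parameter_recovery_on_synthetic_eur(self, eur_pool):
        cohort = sample_cohort([eur_pool], n_per_ancestry=10_000, seed=2)
        table = em_haplotype_frequencies(cohort, ("B", "DQA1", "DQB1"))
        dq25 = ("DQA1*05:01", "DQB1*02:01")
        f_dq25 = sum(
            f for h, f in table.frequencies.items()
            if dq25[0] in h and dq25[1] in h
        )
        assert f_dq25 == pytest.approx(0.116, abs=0.01)
        assert conditional_linkage(table, "B*08:01", dq25) == pytest.approx(
            0.742, abs=0.03
        )


class TestEmValidation:
    def test_unknown_locus_allele_rejected(self):
        with pytest.raises(ValueError, match="loci"):
            em_haplotype_frequencies(
                [{"L1": ("a", "a"), "L9": ("x", "x")}], LOCI2
            )

    def test_locus_cap_enforced(self):
        loci = tuple(f"L{i}" for i in range(8))
        g = {l: ("a", "a") for l in loci}
        with pytest.raises(ValueError, match="7"):
            em_haplotype_frequencies([g], loci)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            em_haplotype_frequencies([], LOCI2)

    def test_nonpositive_tol_rejected(self):
        with pytest.raises(ValueError):
            em_haplotype_frequencies(
                [{"L1": ("a", "a"), "L2": ("x", "x")}], LOCI2, tol=0.0
            )

    def test_estimator_get_set_params(self):
        est = HaplotypeFrequencyEstimator(loci=LOCI2)
        est.set_params(tol=1e-4)
        assert est.get_params()["tol"] == 1e-4
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


class TestConditionalLinkage:
    def test_printed_chromosome_counts(self):
        # 103 of 119 DQB1*02:01 chromosomes linked to DQA1*05:01
        value = conditional_linkage_from_counts(103, 119)
        assert round(100 * value, 1) == 86.6

    def test_from_printed_marginals(self):
        table = HaplotypeFrequencyTable(
            ("B", "DQ"),
            {("B*08:01", "DQ2.5"): 0.086, ("B*07:02", "DQ2.5"): 0.030,
             ("B*07:02", "X"): 0.884},
            log_likelihood=0.0, n_chromosomes=2000, iterations=0, converged=True,
        )
        value = conditional_linkage(table, "B*08:01", "DQ2.5")
        # rounded printed marginals give 74.1%, not the unrounded 74.2%
        assert round(100 * value, 1) == 74.1

    def test_self_conditional_is_one(self, eur_cohort):
        table = count_phased_haplotypes(eur_cohort, ("B", "DQA1", "DQB1"))
        assert conditional_linkage(table, "B*08:01", "B*08:01") == pytest.approx(1.0)

    def test_target_in_every_given_haplotype(self):
        table = HaplotypeFrequencyTable(
            ("A", "B"), {("a1", "b1"): 0.7, ("a2", "b2"): 0.3},
            log_likelihood=0.0, n_chromosomes=10, iterations=0, converged=True,
        )
        assert conditional_linkage(table, "b1", "a1") == 1.0

    def test_zero_mass_condition_rejected(self):
        table = HaplotypeFrequencyTable(
            ("A", "B"), {("a1", "b1"): 1.0},
            log_likelihood=0.0, n_chromosomes=10, iterations=0, converged=True,
        )
        with pytest.raises(ZeroDivisionError):
            conditional_linkage(table, "b1", "a9")

    def test_bootstrap_interval_covers_point(self, eur_cohort):
        point, lo, hi = bootstrap_conditional_linkage(
            eur_cohort.head(2000), ("B", "DQA1", "DQB1"),
            "B*08:01", ("DQA1*05:01", "DQB1*02:01"), n_boot=50, seed=4,
        )
        assert lo <= point <= hi


class TestLdMetrics:
    def test_equilibrium_gives_zero(self):
        d, dp, r2 = ld_from_frequencies(0.2, 0.3, 0.06)
        assert d == pytest.approx(0.0) and r2 == pytest.approx(0.0)

    def test_perfect_ld(self):
        d, dp, r2 = ld_from_frequencies(0.1, 0.1, 0.1)
        assert dp == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        d, dp, r2 = ld_from_frequencies(0.2, 0.3, 0.1)
        assert d == pytest.approx(0.04)
        assert dp == pytest.approx(0.04 / 0.14, abs=1e-4)  # 0.2857
        assert r2 == pytest.approx(0.04**2 / (0.2 * 0.8 * 0.3 * 0.7), abs=1e-6)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_from_frequencies(0.0, 0.3, 0.0)

    def test_bounds_on_synthetic_table(self, eur_cohort):
        table = count_phased_haplotypes(eur_cohort, ("B", "DQA1", "DQB1"))
        res = ld_metrics(table, "B*08:01", "DQB1*02:01")
        assert -1.0 <= res.d_prime <= 1.0
        assert 0.0 <= res.r_squared <= 1.0
        assert res.d > 0  # B8 rides with DQ2.5 by construction


class TestTopHaplotypes:
    def make_table(self, freqs):
        return HaplotypeFrequencyTable(
            ("A",), freqs, log_likelihood=0.0, n_chromosomes=10,
            iterations=0, converged=True,
        )

    def test_ranking_and_truncation(self):
        table = self.make_table({("h1",): 0.5, ("h2",): 0.3, ("h3",): 0.2})
        assert top_haplotypes(table, 2) == [("h1",), ("h2",)]
        assert len(top_haplotypes(table, 10)) == 3

    def test_single_entry(self):
        table = self.make_table({("h1",): 1.0})
        assert top_haplotypes(table, 1) == [("h1",)]

    def test_ties_break_lexicographically(self):
        table = self.make_table({("b",): 0.5, ("a",): 0.5})
        assert top_haplotypes(table, 2) == [("a",), ("b",)]
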