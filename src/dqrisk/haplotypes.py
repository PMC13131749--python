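"""Haplotype-frequency estimation from unphased genotypes, and LD summaries.

The central estimator is the classic EM algorithm for multi-locus haplotype
frequencies: each phase-ambiguous genotype is distributed over its compatible
haplotype-pair resolutions in proportion to the current frequency products
(E-step), and expected haplotype counts are renormalized (M-step).  The
log-likelihood is non-decreasing by construction and is asserted so every
iteration.

Linkage summaries are the quantities the stratified CeD analysis reports:
conditional linkage P(allele B | chromosome carries A) — e.g. P(B8 | DQ2.5)
— and the standard pairwise D, D′ and r² between alleles at different loci.

Haplotypes are represented as tuples of allele strings aligned with the
table's ``loci`` ordering; a sklearn-style estimator
(:class:`HaplotypeFrequencyEstimator`) wraps the EM with
``fit`` / ``get_params`` semantics.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeFrequencyTable",
    "LdResult",
    "HaplotypeFrequencyEstimator",
    "em_haplotype_frequencies",
    "count_phased_haplotypes",
    "genotypes_from_cohort",
    "conditional_linkage",
    "conditional_linkage_from_counts",
    "bootstrap_conditional_linkage",
    "ld_metrics",
    "ld_from_frequencies",
    "top_haplotypes",
    "MAX_LOCI",
]

MAX_LOCI = 7

Genotype = Mapping[str, tuple]  # locus -> unordered allele pair (strings)


@dataclass
class HaplotypeFrequencyTable:
    """Estimated haplotype frequencies for one stratum.

    ``frequencies`` maps a haplotype — a tuple of allele strings aligned
    with ``loci`` — to its maximum-likelihood frequency estimate.
    """

    loci: tuple
    frequencies: dict
    log_likelihood: float
    n_chromosomes: int
    iterations: int
    converged: bool
    stratum: str = ""
    method: str = "em"

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"haplotype frequencies sum to {total!r}, not 1")
        if not math.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")

    def allele_frequency(self, allele: str) -> float:
        """Marginal frequency of an allele over the table."""
        return float(sum(f for h, f in self.frequencies.items() if allele in h))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**dict(zip(self.loci, hap)), "frequency": f, "stratum": self.stratum}
            for hap, f in sorted(
                self.frequencies.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LdResult:
    """Pairwise linkage disequilibrium between two alleles."""

    allele_a: str
    allele_b: str
    d: float
    d_prime: float
    r_squared: float


# ---------------------------------------------------------------------------
# genotype handling


def genotypes_from_cohort(
    cohort: pd.DataFrame, loci: Sequence[str]
) -> list[dict]:
    """Extract per-locus unordered allele pairs from ``{locus}_1/_2`` columns."""
    missing = [
        c for locus in loci for c in (f"{locus}_1", f"{locus}_2")
        if c not in cohort.columns
    ]
    if missing:
        raise KeyError(f"cohort table lacks allele columns: {missing}")
    out = []
    for row in cohort.itertuples(index=False):
        d = row._asdict()
        out.append(
            {locus: (d[f"{locus}_1"], d[f"{locus}_2"]) for locus in loci}
        )
    return out


def _canonical(genotype: Genotype, loci: Sequence[str]) -> tuple:
    return tuple(tuple(sorted(map(str, genotype[locus]))) for locus in loci)


def _expand_phases(geno_key: tuple) -> list[tuple]:
    """All unordered haplotype-pair resolutions of one genotype.

    The first heterozygous locus is held fixed to avoid double-counting the
    mirror-image phase.
    """
    het = [i for i, pair in enumerate(geno_key) if pair[0] != pair[1]]
    if not het:
        hap = tuple(pair[0] for pair in geno_key)
        return [(hap, hap)]
    pairs = []
    # choices for heterozygous loci after the first
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        hap_a, hap_b = [], []
        flips = dict(zip(het[1:], bits))
        for i, pair in enumerate(geno_key):
            if pair[0] == pair[1]:
                hap_a.append(pair[0]); hap_b.append(pair[1])
            elif i == het[0]:
                hap_a.append(pair[0]); hap_b.append(pair[1])
            else:
                k = flips[i]
                hap_a.append(pair[k]); hap_b.append(pair[1 - k])
        pairs.append((tuple(hap_a), tuple(hap_b)))
    return pairs


def count_phased_haplotypes(
    cohort: pd.DataFrame,
    loci: Sequence[str],
    stratum: str = "",
) -> HaplotypeFrequencyTable:
    """Direct-counting fast path for phased input (``_1``/``_2`` = chromosomes).

    Bypasses EM entirely; the table records ``method="counting"``.
    """
    loci = tuple(loci)
    counts: Counter = Counter()
    for suffix in ("_1", "_2"):
        cols = [f"{locus}{suffix}" for locus in loci]
        for hap in cohort[cols].itertuples(index=False):
            counts[tuple(hap)] += 1
    n_chrom = 2 * len(cohort)
    if n_chrom == 0:
        raise ValueError("empty cohort")
    freqs = {h: c / n_chrom for h, c in counts.items()}
    loglik = sum(c * math.log(freqs[h]) for h, c in counts.items())
    return HaplotypeFrequencyTable(
        loci, freqs, loglik, n_chrom, iterations=0, converged=True,
        stratum=stratum, method="counting",
    )


# ---------------------------------------------------------------------------
# EM


class HaplotypeFrequencyEstimator:
    """EM estimator of multi-locus haplotype frequencies (sklearn style).

    Parameters
    ----------
    loci : sequence of str
        Locus ordering; at most 7 loci (the phase-resolution space is
        enumerated explicitly and is exponential in heterozygous loci).
    tol : float
        Convergence threshold on the maximum absolute frequency change.
    max_iter : int
        Iteration cap; ``converged_`` records whether ``tol`` was reached.
    init : {"allele_freq", "uniform"} or mapping
        Initial frequencies: the product of observed allele frequencies
        (default — avoids the symmetric saddle points a uniform start can
        stall on), a uniform start, or explicit values.
    n_restarts : int
        Extra randomized (Dirichlet-perturbed) starts; the best
        log-likelihood wins.
    prune : float
        Haplotypes whose frequency drops below this are removed between
        iterations to bound the state space.
    random_state : int or None
        Seed for the randomized restarts.

    Attributes (after ``fit``)
    --------------------------
    frequencies_ : dict mapping haplotype tuple -> frequency
    log_likelihood_ : float
    n_iter_ : int
    converged_ : bool
    table_ : HaplotypeFrequencyTable
    """

    def __init__(
        self,
        loci: Sequence[str],
        tol: float = 1e-6,
        max_iter: int = 1000,
        init: str | Mapping = "allele_freq",
        n_restarts: int = 0,
        prune: float = 1e-10,
        random_state: int | None = None,
    ) -> None:
        self.loci = loci
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.n_restarts = n_restarts
        self.prune = prune
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "loci": self.loci, "tol": self.tol, "max_iter": self.max_iter,
            "init": self.init, "n_restarts": self.n_restarts,
            "prune": self.prune, "random_state": self.random_state,
        }

    def set_params(self, **params) -> "HaplotypeFrequencyEstimator":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, stratum: str = "") -> "HaplotypeFrequencyEstimator":
        """Fit haplotype frequencies from unphased genotypes.

        ``X`` is either a cohort DataFrame with ``{locus}_1/_2`` columns or a
        list of per-locus unordered allele-pair mappings.
        """
        loci = tuple(self.loci)
        if len(loci) == 0:
            raise ValueError("no loci specified")
        if len(loci) > MAX_LOCI:
            raise ValueError(
                f"at most {MAX_LOCI} loci supported, got {len(loci)}"
            )
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if isinstance(X, pd.DataFrame):
            genotypes = genotypes_from_cohort(X, loci)
        else:
            genotypes = list(X)
        if not genotypes:
            raise ValueError("at least one genotype required")
        for g in genotypes:
            extra = set(g) - set(loci)
            if extra:
                raise ValueError(
                    f"genotype carries alleles at loci not being estimated: "
                    f"{sorted(extra)}"
                )
            missing = set(loci) - set(g)
            if missing:
                raise ValueError(f"genotype missing loci {sorted(missing)}")

        geno_counts = Counter(_canonical(g, loci) for g in genotypes)
        phase_sets = {gk: _expand_phases(gk) for gk in geno_counts}

        hap_index: dict[tuple, int] = {}
        for phases in phase_sets.values():
            for ha, hb in phases:
                for h in (ha, hb):
                    hap_index.setdefault(h, len(hap_index))

        inits = [self._initial_freqs(hap_index, geno_counts, loci)]
        rng = np.random.default_rng(self.random_state)
        for _ in range(int(self.n_restarts)):
            base = inits[0]
            perturbed = rng.dirichlet(base * len(base) * 2.0 + 0.5)
            inits.append(perturbed)

        best = None
        for f0 in inits:
            result = _run_em(
                f0, hap_index, geno_counts, phase_sets,
                tol=self.tol, max_iter=self.max_iter, prune=self.prune,
            )
            if best is None or result[1] > best[1]:
                best = result
        freqs, loglik, n_iter, converged, haps = best

        self.frequencies_ = {
            h: f for h, f in zip(haps, freqs) if f > 0.0
        }
        total = sum(self.frequencies_.values())
        self.frequencies_ = {h: f / total for h, f in self.frequencies_.items()}
        self.log_likelihood_ = float(loglik)
        self.n_iter_ = int(n_iter)
        self.converged_ = bool(converged)
        self.table_ = HaplotypeFrequencyTable(
            loci, dict(self.frequencies_), self.log_likelihood_,
            2 * len(genotypes), self.n_iter_, self.converged_,
            stratum=stratum, method="em",
        )
        return self

    def _initial_freqs(self, hap_index, geno_counts, loci) -> np.ndarray:
        n_hap = len(hap_index)
        if isinstance(self.init, Mapping):
            f0 = np.full(n_hap, 1e-12)
            for hap, value in self.init.items():
                key = tuple(map(str, hap))
                if key in hap_index:
                    f0[hap_index[key]] = value
            return f0 / f0.sum()
        if self.init == "uniform":
            return np.full(n_hap, 1.0 / n_hap)
        if self.init != "allele_freq":
            raise ValueError(f"unknown init {self.init!r}")
        # product of observed allele frequencies, normalized over the
        # plausible-haplotype set
        allele_freq: dict[int, Counter] = {i: Counter() for i in range(len(loci))}
        total = 0
        for gk, count in geno_counts.items():
            total += 2 * count
            for i, pair in enumerate(gk):
                allele_freq[i][pair[0]] += count
                allele_freq[i][pair[1]] += count
        f0 = np.empty(n_hap)
        for hap, idx in hap_index.items():
            w = 1.0
            for i, allele in enumerate(hap):
                w *= allele_freq[i][allele] / total
            f0[idx] = w
        if f0.sum() <= 0:
            return np.full(n_hap, 1.0 / n_hap)
        return f0 / f0.sum()


def _run_em(f0, hap_index, geno_counts, phase_sets, tol, max_iter, prune):
    n_hap = len(hap_index)
    freqs = np.asarray(f0, dtype=float).copy()
    n_chrom = 2 * sum(geno_counts.values())

    # pre-index phase resolutions
    entries = []  # (count, [(i, j, het)])
    for gk, count in geno_counts.items():
        idx_pairs = [
            (hap_index[ha], hap_index[hb], ha != hb)
            for ha, hb in phase_sets[gk]
        ]
        entries.append((count, idx_pairs))

    prev_loglik = -np.inf
    n_iter = 0
    converged = False
    alive = np.ones(n_hap, dtype=bool)
    for n_iter in range(1, max_iter + 1):
        counts = np.zeros(n_hap)
        loglik = 0.0
        for count, idx_pairs in entries:
            weights = np.array([
                (2.0 if het else 1.0) * freqs[i] * freqs[j]
                for i, j, het in idx_pairs
            ])
            total = weights.sum()
            if total <= 0.0:
                # genotype annihilated by pruning; revive its haplotypes
                weights = np.array([
                    1.0 if (alive[i] or alive[j]) else 0.0
                    for i, j, _ in idx_pairs
                ])
                weights = np.ones(len(idx_pairs)) if weights.sum() == 0 else weights
                total = weights.sum()
                loglik += count * math.log(1e-300)
            else:
                loglik += count * math.log(total)
            post = weights / total
            for (i, j, _), p in zip(idx_pairs, post):
                counts[i] += count * p
                counts[j] += count * p
        new_freqs = counts / n_chrom
        if loglik + 1e-9 < prev_loglik:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_loglik} -> {loglik}"
            )
        delta = np.max(np.abs(new_freqs - freqs))
        freqs = new_freqs
        prev_loglik = loglik
        # prune vanishing haplotypes to bound the state space
        dead = freqs < prune
        if dead.any():
            freqs = np.where(dead, 0.0, freqs)
            s = freqs.sum()
            if s > 0:
                freqs = freqs / s
            alive = freqs > 0
        if delta < tol:
            converged = True
            break
    haps = [None] * n_hap
    for hap, idx in hap_index.items():
        haps[idx] = hap
    return freqs, prev_loglik, n_iter, converged, haps


def em_haplotype_frequencies(
    genotypes,
    loci: Sequence[str],
    tol: float = 1e-6,
    max_iter: int = 1000,
    init: str | Mapping = "allele_freq",
    n_restarts: int = 0,
    random_state: int | None = None,
    stratum: str = "",
) -> HaplotypeFrequencyTable:
    """Functional wrapper over :class:`HaplotypeFrequencyEstimator`."""
    est = HaplotypeFrequencyEstimator(
        loci=loci, tol=tol, max_iter=max_iter, init=init,
        n_restarts=n_restarts, random_state=random_state,
    )
    return est.fit(genotypes, stratum=stratum).table_


# ---------------------------------------------------------------------------
# linkage summaries


def _contains_all(hap: tuple, wanted) -> bool:
    if isinstance(wanted, str):
        wanted = (wanted,)
    return all(a in hap for a in wanted)


def conditional_linkage(
    table: HaplotypeFrequencyTable,
    target: str,
    given,
) -> float:
    """P(chromosome carries ``target`` | it carries all of ``given``).

    ``given`` is an allele string or an iterable of allele strings (e.g. the
    DQ2.5 pair ``("DQA1*05:01", "DQB1*02:01")``); computed as
    Σ f(h ∋ target ∧ given) / Σ f(h ∋ given).
    """
    denom = sum(
        f for h, f in table.frequencies.items() if _contains_all(h, given)
    )
    if denom <= 0.0:
        raise ZeroDivisionError(
            f"conditional linkage undefined: no frequency mass on {given!r}"
        )
    num = sum(
        f for h, f in table.frequencies.items()
        if _contains_all(h, given) and target in h
    )
    return num / denom


def conditional_linkage_from_counts(linked: int, total: int) -> float:
    """Conditional linkage from direct chromosome counts (linked/total)."""
    if total <= 0:
        raise ValueError("total chromosome count must be positive")
    if not 0 <= linked <= total:
        raise ValueError("linked count must be between 0 and total")
    return linked / total


def bootstrap_conditional_linkage(
    cohort: pd.DataFrame,
    loci: Sequence[str],
    target: str,
    given,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Seeded participant-level bootstrap CI for a conditional linkage.

    Resamples participants with replacement from a phased cohort, recounts
    haplotypes, and returns (point estimate, lower, upper) percentile bounds.
    """
    point = conditional_linkage(
        count_phased_haplotypes(cohort, loci), target, given
    )
    rng = np.random.default_rng(seed)
    stats = []
    n = len(cohort)
    for _ in range(n_boot):
        sample = cohort.iloc[rng.integers(0, n, size=n)]
        try:
            stats.append(
                conditional_linkage(
                    count_phased_haplotypes(sample, loci), target, given
                )
            )
        except ZeroDivisionError:
            continue
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def ld_from_frequencies(p_a: float, p_b: float, p_ab: float):
    """(D, D′, r²) from marginal and joint chromosome frequencies."""
    for name, p in (("pA", p_a), ("pB", p_b)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name}={p}: LD undefined for monomorphic allele")
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), p_b * (1 - p_a))
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else d / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return d, d_prime, r2


def ld_metrics(
    table: HaplotypeFrequencyTable, allele_a: str, allele_b: str
) -> LdResult:
    """Pairwise D, D′ and r² between two alleles from a frequency table."""
    p_a = table.allele_frequency(allele_a)
    p_b = table.allele_frequency(allele_b)
    p_ab = sum(
        f for h, f in table.frequencies.items()
        if allele_a in h and allele_b in h
    )
    d, d_prime, r2 = ld_from_frequencies(p_a, p_b, p_ab)
    return LdResult(allele_a, allele_b, d, d_prime, r2)


def top_haplotypes(table: HaplotypeFrequencyTable, k: int) -> list[tuple]:
    """The ``k`` most frequent haplotypes, ties broken by allele string."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    return [h for h, _ in ranked[:k]]
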