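"""Per-population SSR diversity statistics: He, Ho, F, HWE, null alleles.

He is Nei's unbiased gene diversity ``(2n/(2n-1)) * (1 - sum p_i^2)``; the
fixation index ``F = 1 - Ho_mean/He_mean`` is computed from locus-averaged
heterozygosities (positive under inbreeding, negative under heterozygote
excess, e.g. clonal propagation of heterozygous founders).  Hardy–Weinberg
deviation is tested with the conditional exact test (full enumeration of
genotype tables given allele counts, or a seeded Monte-Carlo permutation of
the allele vector for large tables) and, for the multi-locus F, with a
within-population allele permutation test.  Null-allele frequency uses the
Chakraborty estimator ``(He - Ho) / (He + Ho)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datasets import MISSING, GenotypeDataset

__all__ = [
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "fixation_index",
    "hwe_exact_test",
    "f_significance_test",
    "null_allele_frequency",
    "locus_summary",
    "population_table",
    "marker_screening_summary",
    "LocusSummary",
    "PopulationSummary",
]


class EnumerationTooLarge(RuntimeError):
    """Raised when an exact-test table space exceeds the enumeration cap."""


# ---------------------------------------------------------------------------
# per-locus building blocks
# ---------------------------------------------------------------------------


def _locus_calls(dataset: GenotypeDataset, population: str, locus: str) -> np.ndarray:
    """Non-missing (n, 2) calls for one population at one locus."""
    rows = dataset.population_members(population)
    if len(rows) == 0:
        raise ValueError(f"population {population!r} has no individuals")
    l = dataset.locus_number(locus)
    calls = dataset.calls[rows, l, :]
    calls = calls[calls[:, 0] != MISSING]
    return calls


def allele_frequencies(dataset: GenotypeDataset, population: str,
                       locus: str) -> dict[int, float]:
    """Allele relative frequencies among non-missing calls (two copies per
    typed individual); individuals missing at the locus are excluded."""
    calls = _locus_calls(dataset, population, locus)
    if len(calls) == 0:
        raise ValueError(f"locus {locus!r} is untyped in population {population!r}")
    alleles, counts = np.unique(calls.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


def observed_heterozygosity(dataset: GenotypeDataset, population: str,
                            locus: str) -> float:
    """Fraction of typed individuals whose two allele copies differ."""
    calls = _locus_calls(dataset, population, locus)
    if len(calls) == 0:
        raise ValueError(f"locus {locus!r} is untyped in population {population!r}")
    return float(np.mean(calls[:, 0] != calls[:, 1]))


def expected_heterozygosity(dataset: GenotypeDataset, population: str,
                            locus: str) -> float:
    """Nei's unbiased gene diversity He = (2n/(2n-1)) (1 - sum p_i^2)."""
    calls = _locus_calls(dataset, population, locus)
    n = len(calls)
    if n < 2:
        raise ValueError(
            f"He needs >= 2 typed individuals at {locus!r} in {population!r}"
        )
    _, counts = np.unique(calls.ravel(), return_counts=True)
    p = counts / (2 * n)
    return float(2 * n / (2 * n - 1) * (1.0 - np.sum(p * p)))


def fixation_index(he_mean: float, ho_mean: float) -> float:
    """F = 1 - Ho/He = (He - Ho)/He; negative when Ho exceeds He."""
    if he_mean <= 0:
        raise ValueError("fixation index undefined when mean He is zero")
    return 1.0 - ho_mean / he_mean


def null_allele_frequency(he: float, ho: float) -> float:
    """Chakraborty estimator r = (He - Ho)/(He + Ho).

    Negative values (heterozygote excess) are reported as-is.
    """
    if he + ho <= 0:
        raise ValueError("null-allele estimate undefined when He + Ho = 0")
    return (he - ho) / (he + ho)


def marker_screening_summary(positive: int, total: int) -> float:
    """Percentage of positive clones, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive must lie in [0, total]")
    return round(100.0 * positive / total, 1)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def _table_from_counts(genotype_counts) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a {(a1, a2): count} mapping to (alleles, genotype matrix)."""
    items = [((min(a), max(a)), int(c)) for (a), c in genotype_counts.items()]
    if any(c < 0 for _, c in items):
        raise ValueError("genotype counts must be non-negative")
    alleles = sorted({a for (pair, c) in items if c for a in pair})
    idx = {a: i for i, a in enumerate(alleles)}
    A = len(alleles)
    mat = np.zeros((A, A), dtype=np.int64)
    for (a1, a2), c in items:
        if c:
            mat[idx[a1], idx[a2]] += c
    return np.asarray(alleles), mat


def _log_table_prob(mat: np.ndarray, log_const: float) -> float:
    """log P(table | allele counts) under the null, up to the shared constant
    ``log_const = log N! + sum log n_a! - log (2N)!``."""
    het = mat.sum() - np.trace(mat)
    return float(log_const + het * math.log(2) - gammaln(mat[np.triu_indices_from(mat)] + 1).sum())


def _enumerate_tables(allele_counts: np.ndarray, cap: int):
    """Yield all genotype tables consistent with the allele counts.

    Tables are upper-triangular count matrices; raises
    :class:`EnumerationTooLarge` past ``cap`` tables.
    """
    A = len(allele_counts)
    pairs = [(i, j) for i in range(A) for j in range(i, A)]
    mat = np.zeros((A, A), dtype=np.int64)
    remaining = allele_counts.astype(np.int64).copy()
    produced = 0

    def rec(k: int):
        nonlocal produced
        if k == len(pairs):
            if np.all(remaining == 0):
                produced += 1
                if produced > cap:
                    raise EnumerationTooLarge
                yield mat.copy()
            return
        i, j = pairs[k]
        last_for_i = (j == A - 1)
        if i == j:
            if last_for_i:
                choices = [remaining[i] // 2] if remaining[i] % 2 == 0 else []
            else:
                choices = range(remaining[i] // 2 + 1)
            for n in choices:
                mat[i, j] = n
                remaining[i] -= 2 * n
                if remaining[i] >= 0:
                    yield from rec(k + 1)
                remaining[i] += 2 * n
                mat[i, j] = 0
        else:
            hi = min(remaining[i], remaining[j])
            choices = [remaining[i]] if last_for_i else range(hi + 1)
            for n in choices:
                if n > hi:
                    continue
                mat[i, j] = n
                remaining[i] -= n
                remaining[j] -= n
                yield from rec(k + 1)
                remaining[i] += n
                remaining[j] += n
                mat[i, j] = 0

    yield from rec(0)


def _mc_pvalue(alleles: np.ndarray, mat: np.ndarray, log_const: float,
               log_p_obs: float, reps: int, seed) -> float:
    """Monte-Carlo exact test: permute the flattened allele vector, re-pair
    consecutive copies, and compare table probabilities."""
    A = len(alleles)
    # copy counts: row + column sums each count the diagonal once, so
    # homozygous genotypes contribute two copies as required
    copy_counts = mat.sum(0) + mat.sum(1)
    allele_vec = np.repeat(np.arange(A), copy_counts)
    N = mat.sum()
    rng = np.random.default_rng(seed)
    tiled = np.tile(allele_vec, (reps, 1))
    perm = rng.permuted(tiled, axis=1)
    g1 = np.minimum(perm[:, 0::2], perm[:, 1::2])
    g2 = np.maximum(perm[:, 0::2], perm[:, 1::2])
    codes = g1 * A + g2
    if A * A <= 400:
        flat = (np.arange(reps)[:, None] * (A * A) + codes).ravel()
        table_counts = np.bincount(flat, minlength=reps * A * A).reshape(reps, A * A)
        het = N - table_counts[:, ::A + 1].sum(axis=1)
        log_p = (log_const + het * math.log(2)
                 - gammaln(table_counts + 1).sum(axis=1))
    else:  # pragma: no cover - very allele-rich loci
        log_p = np.empty(reps)
        for r in range(reps):
            _, c = np.unique(codes[r], return_counts=True)
            het = N - np.sum((codes[r] // A) == (codes[r] % A))
            log_p[r] = log_const + het * math.log(2) - gammaln(c + 1).sum()
    return float(np.mean(log_p <= log_p_obs + 1e-9))


#: Enumeration cap: fall back to Monte Carlo past this many tables.
ENUMERATION_CAP = 1_000_000


def hwe_exact_test(genotype_counts, method: str = "auto", reps: int = 100_000,
                   seed: int | np.random.SeedSequence = 0) -> float:
    """Conditional exact test of Hardy–Weinberg proportions at one locus.

    ``genotype_counts`` maps unordered allele pairs to counts, e.g.
    ``{(150, 150): 3, (150, 152): 5}``.  Under the null, a genotype table h
    has probability ``N! / prod(n_ij!) * 2^het * prod(n_a!) / (2N)!``
    conditional on the allele counts; the p-value sums the probabilities of
    all tables no more probable than the observed one.  ``method`` is
    ``"enumerate"``, ``"montecarlo"``, or ``"auto"`` (enumerate up to
    ``ENUMERATION_CAP`` tables, else Monte Carlo with ``reps`` seeded
    permutations of the allele vector).  A monomorphic locus returns 1.
    """
    if method not in ("auto", "enumerate", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")
    alleles, mat = _table_from_counts(genotype_counts)
    if mat.sum() == 0:
        raise ValueError("no genotypes")
    if len(alleles) < 2:
        return 1.0

    copy_counts = mat.sum(0) + mat.sum(1)
    N = int(mat.sum())
    log_const = float(gammaln(N + 1) + gammaln(copy_counts + 1).sum()
                      - gammaln(2 * N + 1))
    log_p_obs = _log_table_prob(mat, log_const)

    if method in ("auto", "enumerate"):
        try:
            total = 0.0
            p = 0.0
            for table in _enumerate_tables(copy_counts, ENUMERATION_CAP):
                lp = _log_table_prob(table, log_const)
                prob = math.exp(lp)
                total += prob
                if lp <= log_p_obs + 1e-9:
                    p += prob
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise RuntimeError(
                    f"enumeration probabilities sum to {total}, not 1"
                )
            return min(p, 1.0)
        except EnumerationTooLarge:
            if method == "enumerate":
                raise
    if reps < 1:
        raise ValueError("reps must be >= 1 for the Monte-Carlo test")
    return _mc_pvalue(alleles, mat, log_const, log_p_obs, reps, seed)


def hwe_test_locus(dataset: GenotypeDataset, population: str, locus: str,
                   **kwargs) -> float:
    """Convenience wrapper: exact HWE p-value for one population x locus."""
    calls = _locus_calls(dataset, population, locus)
    if len(calls) == 0:
        raise ValueError(f"locus {locus!r} is untyped in population {population!r}")
    counts: dict[tuple[int, int], int] = {}
    for a1, a2 in calls:
        key = (int(min(a1, a2)), int(max(a1, a2)))
        counts[key] = counts.get(key, 0) + 1
    return hwe_exact_test(counts, **kwargs)


# ---------------------------------------------------------------------------
# multi-locus F and its permutation test
# ---------------------------------------------------------------------------


def _pop_locus_means(dataset: GenotypeDataset, population: str
                     ) -> tuple[float, float, list[str]]:
    """(mean He, mean Ho) unweighted over loci with >= 2 typed individuals."""
    he, ho, used = [], [], []
    for locus in dataset.loci:
        calls = _locus_calls(dataset, population, locus)
        if len(calls) < 2:
            continue
        used.append(locus)
        ho.append(float(np.mean(calls[:, 0] != calls[:, 1])))
        n = len(calls)
        _, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / (2 * n)
        he.append(float(2 * n / (2 * n - 1) * (1.0 - np.sum(p * p))))
    if not used:
        raise ValueError(f"no usable loci in population {population!r}")
    return float(np.mean(he)), float(np.mean(ho)), used


def f_significance_test(dataset: GenotypeDataset, population: str,
                        reps: int = 1999,
                        seed: int | np.random.SeedSequence = 0) -> float:
    """Permutation test of the multi-locus fixation index.

    Alleles are permuted among typed individuals within the population,
    independently per locus; He depends only on allele counts and is
    invariant, so only Ho varies across permutations.  Two-sided p-value
    with add-one correction: ``p = (b + 1)/(reps + 1)`` where b counts
    permutations with ``|F_perm| >= |F_obs|``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    he_mean, ho_mean, used = _pop_locus_means(dataset, population)
    if he_mean <= 0:
        raise ValueError("F permutation test undefined when mean He is zero")
    f_obs = fixation_index(he_mean, ho_mean)

    rng = np.random.default_rng(seed)
    ho_perm = np.zeros((reps, len(used)))
    for j, locus in enumerate(used):
        calls = _locus_calls(dataset, population, locus)
        vec = calls.ravel()
        tiled = np.tile(vec, (reps, 1))
        perm = rng.permuted(tiled, axis=1)
        ho_perm[:, j] = np.mean(perm[:, 0::2] != perm[:, 1::2], axis=1)
    f_perm = 1.0 - ho_perm.mean(axis=1) / he_mean
    b = int(np.sum(np.abs(f_perm) >= abs(f_obs) - 1e-12))
    return (b + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class LocusSummary:
    """Per population x locus statistics."""

    population: str
    locus: str
    n_typed: int
    allele_freqs: dict[int, float]
    ho: float
    he: float
    hwe_p: float
    null_freq: float


@dataclass
class PopulationSummary:
    """One row of the per-population heterozygosity table."""

    population: str
    n: int
    he_mean: float
    ho_mean: float
    f: float | None
    f_p: float | None
    significant: bool


def locus_summary(dataset: GenotypeDataset, population: str, locus: str,
                  hwe_seed: int | np.random.SeedSequence = 0) -> LocusSummary:
    calls = _locus_calls(dataset, population, locus)
    ho = observed_heterozygosity(dataset, population, locus)
    he = expected_heterozygosity(dataset, population, locus)
    return LocusSummary(
        population=population,
        locus=locus,
        n_typed=len(calls),
        allele_freqs=allele_frequencies(dataset, population, locus),
        ho=ho,
        he=he,
        hwe_p=hwe_test_locus(dataset, population, locus, seed=hwe_seed),
        null_freq=null_allele_frequency(he, ho) if he + ho > 0 else float("nan"),
    )


def population_table(dataset: GenotypeDataset, reps: int = 1999,
                     seed: int | np.random.SeedSequence = 0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-population N, mean He, mean Ho, F and HWE-deviation significance.

    Columns: population, n, he, ho, f, f_p, significant — one row per
    population in input order.  F is reported as NaN when mean He is zero.
    """
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    children = root.spawn(dataset.n_populations)
    rows = []
    for pop, child in zip(dataset.populations, children):
        if len(dataset.population_members(pop)) == 0:
            raise ValueError(f"population {pop!r} is empty")
        he_mean, ho_mean, _ = _pop_locus_means(dataset, pop)
        if he_mean > 0:
            f = fixation_index(he_mean, ho_mean)
            f_p = f_significance_test(dataset, pop, reps=reps, seed=child)
        else:
            f, f_p = float("nan"), float("nan")
        rows.append({
            "population": pop,
            "n": len(dataset.population_members(pop)),
            "he": he_mean,
            "ho": ho_mean,
            "f": f,
            "f_p": f_p,
            "significant": bool(f_p < alpha) if not math.isnan(f_p) else False,
        })
    return pd.DataFrame(rows)
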