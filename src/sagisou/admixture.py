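"""Model-based admixture clustering with Gibbs sampling and Evanno's ΔK.

The model is the basic admixture model with independent allele frequencies:
each individual i has proportions q_i over K ancestral clusters
(``q_i ~ Dirichlet(alpha, ..., alpha)``), each cluster k has per-locus
allele frequencies ``p_kl ~ Dirichlet(lambda, ..., lambda)``, and every
allele copy is drawn by first choosing a source cluster from q_i and then
an allele from that cluster's frequencies.  The Gibbs sweep samples the
latent copy origins Z, then P and Q from their Dirichlet full conditionals,
and updates alpha by a Metropolis step under a uniform prior.

Model choice across K uses the ln P(D) approximation
``mean(lnL trace) - var(lnL trace)/2`` and Evanno's
``ΔK = |L''(K)| / sd(lnP(D) over runs)``, maximised over interior K.
Replicate runs are label-aligned by exhaustive column permutation against
the first run.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset

__all__ = [
    "AdmixtureModel",
    "MCMCConfig",
    "AdmixtureResult",
    "EvannoTable",
    "run_admixture_mcmc",
    "run_k_scan",
    "log_likelihood",
    "estimate_ln_prob_data",
    "evanno_delta_k",
    "align_runs",
    "membership_table",
]


@dataclass
class AdmixtureModel:
    """Priors and proposal settings of the admixture model."""

    k: int
    lambda_: float = 1.0
    alpha_init: float = 1.0
    alpha_prior_max: float = 10.0
    alpha_proposal_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if not 0 < self.alpha_init < self.alpha_prior_max:
            raise ValueError("alpha_init must lie in (0, alpha_prior_max)")


@dataclass
class MCMCConfig:
    """Chain settings.  The defaults are a desk-scale chain; the field's
    reference protocol (burn-in 50,000, 1,000,000 sweeps, 10 runs per K)
    remains available by configuration."""

    burn_in: int = 5_000
    reps: int = 20_000
    thin: int = 10
    runs_per_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("burn_in", "reps", "thin", "runs_per_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class AdmixtureResult:
    """Posterior summaries of one chain."""

    k: int
    q: np.ndarray                  # (n_individuals, k) posterior means
    p: np.ndarray                  # (k, n_loci, n_alleles) posterior means
    lnL_trace: np.ndarray          # data log-likelihood, every retained sweep
    alpha_trace: np.ndarray        # thinned alpha samples
    ln_prob_data: float
    individuals: list[str]
    allele_codes: list[np.ndarray]  # per-locus fragment sizes backing p's axis


def _index_dataset(dataset: GenotypeDataset):
    """Map calls to compact per-locus allele indices; missing -> -1."""
    n, L = dataset.n_individuals, dataset.n_loci
    codes: list[np.ndarray] = []
    max_a = 1
    idx = np.full((n, L, 2), -1, dtype=np.int64)
    for l in range(L):
        col = dataset.calls[:, l, :]
        present = col[:, 0] != MISSING
        alleles = np.unique(col[present])
        codes.append(alleles)
        max_a = max(max_a, len(alleles))
        if alleles.size:
            lookup = {int(a): i for i, a in enumerate(alleles)}
            for i in np.flatnonzero(present):
                idx[i, l, 0] = lookup[int(col[i, 0])]
                idx[i, l, 1] = lookup[int(col[i, 1])]
    n_alleles = np.array([len(c) for c in codes])
    return idx, codes, n_alleles, max_a


def log_likelihood(geno_idx: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Admixture data log-likelihood sum(ln sum_k q_ik p_k(allele)) over
    non-missing allele copies.

    ``geno_idx`` holds per-locus allele indices (missing -1), ``p`` is
    (k, L, A), ``q`` is (n, k).  An allele with zero probability under all
    clusters yields ``-inf``.
    """
    n, L, _ = geno_idx.shape
    miss = geno_idx < 0
    safe = np.where(miss, 0, geno_idx)
    # p_vals: (n, L, 2, k)
    p_vals = p.transpose(1, 2, 0)[np.arange(L)[None, :, None], safe]
    mix = np.einsum("nlck,nk->nlc", p_vals, q)
    mix = np.where(miss, 1.0, mix)
    if np.any(mix <= 0):
        return float("-inf")
    return float(np.log(mix).sum())


def _alpha_log_posterior(alpha: float, q: np.ndarray, alpha_max: float) -> float:
    if not 0 < alpha < alpha_max:
        return float("-inf")
    n, k = q.shape
    # gamma draws can underflow to exactly 0 for tiny shapes; floor them
    log_q_sum = float(np.log(np.clip(q, 1e-300, None)).sum())
    return n * (math.lgamma(k * alpha) - k * math.lgamma(alpha)) \
        + (alpha - 1.0) * log_q_sum


def run_admixture_mcmc(dataset: GenotypeDataset, model: AdmixtureModel,
                       config: MCMCConfig,
                       seed: int | np.random.SeedSequence | None = None
                       ) -> AdmixtureResult:
    """Run one seeded Gibbs chain and return posterior-mean summaries.

    The lnL trace keeps every post-burn-in sweep (it feeds the ln P(D)
    estimator); alpha is stored every ``config.thin`` sweeps; Q and P
    posterior means accumulate over all retained sweeps.
    """
    if dataset.n_individuals == 0 or dataset.n_loci == 0:
        raise ValueError("empty dataset")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    geno_idx, codes, n_alleles, max_a = _index_dataset(dataset)
    n, L = dataset.n_individuals, dataset.n_loci
    K = model.k
    miss = geno_idx < 0
    safe_idx = np.where(miss, 0, geno_idx)
    l_grid = np.arange(L)[None, :, None]
    nm = ~miss  # fixed across sweeps: flatten the observed copies once
    i_nm = np.broadcast_to(np.arange(n)[:, None, None], geno_idx.shape)[nm]
    l_nm = np.broadcast_to(np.arange(L)[None, :, None], geno_idx.shape)[nm]
    a_nm = safe_idx[nm]
    valid_mask = np.zeros((L, max_a), dtype=bool)
    for l in range(L):
        valid_mask[l, :n_alleles[l]] = True

    # initial state
    q = rng.dirichlet(np.ones(K), size=n)
    p = np.zeros((K, L, max_a))
    for l in range(L):
        a = n_alleles[l]
        if a:
            p[:, l, :a] = rng.dirichlet(np.full(a, model.lambda_), size=K)
    alpha = model.alpha_init

    total = config.burn_in + config.reps
    lnL_trace = np.empty(config.reps)
    alpha_samples = []
    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)

    p_T = p.transpose(1, 2, 0)  # view (L, A, K) of p
    for sweep in range(total):
        # -- Z: latent origin of every allele copy
        p_vals = p_T[l_grid, safe_idx]                # (n, L, 2, K)
        w = p_vals * q[:, None, None, :]
        tot = w.sum(axis=3, keepdims=True)
        # degenerate weights (all-zero) fall back to q alone
        w = np.where(tot > 0, w, q[:, None, None, :])
        cum = np.cumsum(w, axis=3)
        u = rng.random((n, L, 2, 1)) * cum[..., -1:]
        z = (u > cum).sum(axis=3)

        # -- P | Z: Dirichlet(lambda + allele counts) via gamma draws
        z_nm = z[nm]
        counts_p = np.bincount(
            (z_nm * L + l_nm) * max_a + a_nm, minlength=K * L * max_a
        ).reshape(K, L, max_a)
        g = rng.standard_gamma(model.lambda_ + counts_p)
        g = np.where(valid_mask[None, :, :], g, 0.0)
        s = g.sum(axis=2, keepdims=True)
        p = g / np.where(s > 0, s, 1.0)
        p_T = p.transpose(1, 2, 0)

        # -- Q | Z: Dirichlet(alpha + copy counts)
        counts_q = np.bincount(i_nm * K + z_nm, minlength=n * K).reshape(n, K)
        gq = np.clip(rng.standard_gamma(alpha + counts_q), 1e-300, None)
        q = gq / gq.sum(axis=1, keepdims=True)

        # -- alpha: Metropolis under Uniform(0, alpha_prior_max)
        if K > 1:
            prop = alpha + rng.normal(0.0, model.alpha_proposal_sd)
            if 0 < prop < model.alpha_prior_max:
                delta = (_alpha_log_posterior(prop, q, model.alpha_prior_max)
                         - _alpha_log_posterior(alpha, q, model.alpha_prior_max))
                if math.log(rng.random()) < delta:
                    alpha = prop

        if sweep >= config.burn_in:
            r = sweep - config.burn_in
            lnL_trace[r] = log_likelihood(geno_idx, p, q)
            q_sum += q
            p_sum += p
            if r % config.thin == 0:
                alpha_samples.append(alpha)

    q_mean = q_sum / config.reps
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    return AdmixtureResult(
        k=K,
        q=q_mean,
        p=p_sum / config.reps,
        lnL_trace=lnL_trace,
        alpha_trace=np.asarray(alpha_samples),
        ln_prob_data=estimate_ln_prob_data(lnL_trace),
        individuals=list(dataset.individuals),
        allele_codes=codes,
    )


def estimate_ln_prob_data(lnL_trace) -> float:
    """ln P(D) approximation: mean(trace) - var(trace)/2 (sample variance)."""
    trace = np.asarray(lnL_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("lnL trace needs >= 2 entries")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def run_k_scan(dataset: GenotypeDataset, k_values, config: MCMCConfig,
               model_kwargs: dict | None = None
               ) -> dict[int, list[AdmixtureResult]]:
    """Run ``config.runs_per_k`` chains for each K, with child seeds derived
    deterministically from ``config.seed``."""
    model_kwargs = model_kwargs or {}
    root = np.random.SeedSequence(config.seed)
    out: dict[int, list[AdmixtureResult]] = {}
    k_values = list(k_values)
    children = iter(root.spawn(len(k_values) * config.runs_per_k))
    for k in k_values:
        model = AdmixtureModel(k=k, **model_kwargs)
        out[k] = [
            run_admixture_mcmc(dataset, model, config, seed=next(children))
            for _ in range(config.runs_per_k)
        ]
    return out


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------


@dataclass
class EvannoTable:
    """Across-K summary: mean/sd of ln P(D), L'(K), L''(K), ΔK, optimal K.

    ``optimal_k`` is None when no interior K has a defined positive ΔK
    (e.g. ln P(D) linear in K)."""

    table: pd.DataFrame
    optimal_k: int | None


def evanno_delta_k(ln_prob_data: dict[int, list[float]]) -> EvannoTable:
    """Evanno's ΔK from per-K, per-run ln P(D) values.

    ``L'(K) = mean(K) - mean(K-1)``, ``L''(K) = |L'(K+1) - L'(K)|``,
    ``ΔK = L''(K) / sd(K)`` with sd over runs.  ΔK is defined only at
    interior K with sd > 0; the optimal K is the argmax (ties broken toward
    smaller K).  Requires >= 3 consecutive K values with >= 2 runs each.
    """
    ks = sorted(ln_prob_data)
    if len(ks) < 3:
        raise ValueError("Evanno's method needs >= 3 K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    runs = {k: np.asarray(ln_prob_data[k], dtype=float) for k in ks}
    if any(v.size < 2 for v in runs.values()):
        raise ValueError("need >= 2 runs per K")

    mean = {k: float(runs[k].mean()) for k in ks}
    sd = {k: float(runs[k].std(ddof=1)) for k in ks}
    lp = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    lpp = {k: abs(lp[k + 1] - lp[k]) for k in ks[1:-1]}
    dk = {}
    for k in ks[1:-1]:
        dk[k] = lpp[k] / sd[k] if sd[k] > 0 else float("nan")

    rows = []
    for k in ks:
        rows.append({
            "k": k,
            "mean_ln_prob": mean[k],
            "sd_ln_prob": sd[k],
            "l_prime": lp.get(k, float("nan")),
            "l_second": lpp.get(k, float("nan")),
            "delta_k": dk.get(k, float("nan")),
            "n_runs": int(runs[k].size),
        })
    table = pd.DataFrame(rows)

    defined = [(k, v) for k, v in dk.items() if not math.isnan(v)]
    optimal = None
    if defined:
        best = max(v for _, v in defined)
        if best > 0:
            optimal = min(k for k, v in defined if v == best)
    return EvannoTable(table=table, optimal_k=optimal)


# ---------------------------------------------------------------------------
# run alignment and membership tables
# ---------------------------------------------------------------------------


def _perm_cost(ref: np.ndarray, q: np.ndarray, perm) -> float:
    return float(np.abs(ref - q[:, list(perm)]).sum())


def align_runs(runs, method: str = "exhaustive"):
    """Resolve label switching across replicate runs of the same K.

    Columns of each run are permuted to minimise the total absolute
    difference from the first run; ``method='exhaustive'`` searches all k!
    permutations (k <= 8 in practice), ``'greedy'`` repeatedly matches the
    cheapest remaining column pair.  Returns
    ``(aligned_q_list, mean_q, permutations)``.
    """
    qs = [np.asarray(r.q if hasattr(r, "q") else r, dtype=float) for r in runs]
    if not qs:
        raise ValueError("no runs to align")
    shape = qs[0].shape
    if any(q.shape != shape for q in qs):
        raise ValueError("runs have mismatched q shapes")
    k = shape[1]
    ref = qs[0]

    perms: list[tuple[int, ...]] = []
    aligned: list[np.ndarray] = []
    for q in qs:
        if method == "exhaustive":
            best = min(itertools.permutations(range(k)),
                       key=lambda p: (_perm_cost(ref, q, p), p))
        elif method == "greedy":
            cost = np.array([[np.abs(ref[:, a] - q[:, b]).sum()
                              for b in range(k)] for a in range(k)])
            perm = [-1] * k
            used_a, used_b = set(), set()
            order = sorted(((cost[a, b], a, b) for a in range(k) for b in range(k)))
            for _, a, b in order:
                if a not in used_a and b not in used_b:
                    perm[a] = b
                    used_a.add(a)
                    used_b.add(b)
            best = tuple(perm)
        else:
            raise ValueError(f"unknown method {method!r}")
        perms.append(tuple(best))
        aligned.append(q[:, list(best)])
    mean_q = np.mean(aligned, axis=0)
    return aligned, mean_q, perms


def membership_table(mean_q: np.ndarray, individuals: list[str],
                     population_of: dict[str, str],
                     population_order: list[str] | None = None) -> pd.DataFrame:
    """Stacked-bar-ready long table of admixture memberships.

    Individuals are ordered by population, then by dominant-cluster
    fraction (descending), then by identifier, so the ordering is stable
    under permutation of the input rows.
    """
    mean_q = np.asarray(mean_q, dtype=float)
    if mean_q.shape[0] != len(individuals):
        raise ValueError("q rows must match individuals")
    for ind in individuals:
        if ind not in population_of:
            raise ValueError(f"individual {ind!r} has no population label")
    pops = population_order or list(dict.fromkeys(population_of[i] for i in individuals))
    unknown = {population_of[i] for i in individuals} - set(pops)
    if unknown:
        raise ValueError(f"unknown population label(s): {sorted(unknown)}")
    pop_rank = {p: r for r, p in enumerate(pops)}

    order = sorted(
        range(len(individuals)),
        key=lambda i: (pop_rank[population_of[individuals[i]]],
                       -float(mean_q[i].max()), individuals[i]),
    )
    k = mean_q.shape[1]
    rows = []
    for pos, i in enumerate(order):
        for c in range(k):
            rows.append({
                "position": pos,
                "individual": individuals[i],
                "population": population_of[individuals[i]],
                "cluster": c + 1,
                "q": float(mean_q[i, c]),
            })
    return pd.DataFrame(rows)
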