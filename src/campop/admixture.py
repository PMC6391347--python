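"""Bayesian admixture inference with replicate alignment and ΔK selection.

A Gibbs sampler for the classic admixture model with uncorrelated cluster
allele frequencies: each allele copy of each individual carries a latent
cluster of origin z drawn from the individual's admixture vector q, and is
the ALT allele with that cluster's frequency p. Priors are uniform Beta(1,1)
on frequencies and symmetric Dirichlet(1) on q. The model log-probability
proxy LnP(D) is estimated as mean(log-likelihood) − ½·var(log-likelihood)
over post-burn-in sweeps.

Supporting operations mirror the standard multi-run protocol: replicate runs
per K, label-switching alignment of replicates by optimal column assignment,
Evanno's ΔK statistic for choosing K, thresholded membership assignment, and
per-cluster Fst/He summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import MISSING, GenotypeMatrix


@dataclass
class RunResult:
    """Posterior summaries of one admixture run."""

    q_mean: np.ndarray  # (N, K) posterior mean admixture
    p_mean: np.ndarray  # (K, L) posterior mean ALT-allele frequencies
    lnpd: float  # model log-probability estimate
    per_pop_fst: np.ndarray  # (K,) divergence of each cluster from the pool
    k: int
    seed: int | None
    sample_ids: list[str] | None = None


def fit_admixture(
    genotypes: GenotypeMatrix,
    k: int,
    burnin: int = 500,
    iters: int = 1500,
    seed: int | None = None,
) -> RunResult:
    """Gibbs-sample the admixture model at a fixed cluster count.

    Parameters
    ----------
    genotypes
        Diploid biallelic dosage panel; missing genotypes contribute no
        likelihood terms and are skipped in all latent updates.
    k
        Number of clusters (1 ≤ k ≤ N).
    burnin, iters
        Discarded and retained Gibbs sweeps (each sweep updates all latent
        origins, frequencies and admixture vectors once).
    seed
        Fixes the full trajectory; identical seeds give identical results.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > genotypes.n_individuals:
        raise ValueError("k cannot exceed the number of individuals")
    if burnin < 1 or iters < 1:
        raise ValueError("burnin and iters must be >= 1")
    d = genotypes.dosages
    called = d != MISSING
    if not called.any(axis=1).all():
        bad = [genotypes.sample_ids[i]
               for i in np.flatnonzero(~called.any(axis=1))]
        raise ValueError(f"individuals with no called genotypes: {bad}")
    n, L = d.shape
    rng = np.random.default_rng(seed)

    g = np.where(called, d, 0).astype(np.int8)
    # allele of each of the two copies; heterozygote order is irrelevant
    a1 = (g >= 1) & called
    a2 = (g == 2) & called

    q = rng.dirichlet(np.ones(k), size=n)
    p = rng.uniform(0.2, 0.8, size=(k, L))

    q_sum = np.zeros((n, k))
    p_sum = np.zeros((k, L))
    loglik_trace = np.empty(iters)
    two_minus_g = np.where(called, 2 - g, 0)
    g_called = np.where(called, g, 0)

    for sweep in range(burnin + iters):
        z1 = _sample_origins(q, p, a1, rng)
        z2 = _sample_origins(q, p, a2, rng)

        # conjugate frequency update from assigned allele counts
        x = np.zeros((k, L))
        ntot = np.zeros((k, L))
        m = np.zeros((n, k))
        for c in range(k):
            in1 = (z1 == c) & called
            in2 = (z2 == c) & called
            x[c] = (in1 & a1).sum(axis=0) + (in2 & a2).sum(axis=0)
            ntot[c] = in1.sum(axis=0) + in2.sum(axis=0)
            m[:, c] = in1.sum(axis=1) + in2.sum(axis=1)
        p = rng.beta(1.0 + x, 1.0 + (ntot - x))

        # conjugate admixture update from assigned copy counts
        gam = rng.gamma(1.0 + m)
        q = gam / gam.sum(axis=1, keepdims=True)

        if sweep >= burnin:
            it = sweep - burnin
            q_sum += q
            p_sum += p
            mix = np.clip(q @ p, 1e-12, 1 - 1e-12)
            ll = g_called * np.log(mix) + two_minus_g * np.log1p(-mix)
            loglik_trace[it] = ll[called].sum()

    q_mean = q_sum / iters
    p_mean = p_sum / iters
    var = float(np.var(loglik_trace, ddof=1)) if iters > 1 else 0.0
    lnpd = float(np.mean(loglik_trace)) - 0.5 * var
    run = RunResult(
        q_mean=q_mean,
        p_mean=p_mean,
        lnpd=lnpd,
        per_pop_fst=np.zeros(k),
        k=k,
        seed=seed,
        sample_ids=list(genotypes.sample_ids),
    )
    run.per_pop_fst = cluster_fst_he(run)["fst"].to_numpy()
    return run


def _sample_origins(
    q: np.ndarray, p: np.ndarray, allele: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Latent origin of one allele copy per (individual, locus).

    Posterior weight of cluster c is q[i,c]·p[c,l] for an ALT copy and
    q[i,c]·(1−p[c,l]) for a REF copy.
    """
    n, L = allele.shape
    k = q.shape[1]
    w = np.where(allele[:, :, None], p.T[None, :, :], (1.0 - p.T)[None, :, :])
    w = w * q[:, None, :]
    cdf = np.cumsum(w, axis=2)
    tot = cdf[:, :, -1:]
    u = rng.random((n, L, 1)) * tot
    z = (u > cdf).sum(axis=2)
    return np.minimum(z, k - 1)


def align_runs(
    runs: list[np.ndarray],
) -> tuple[list[np.ndarray], np.ndarray]:
    """Align replicate Q matrices across label switching; return mean Q.

    The first run anchors the labels. Each subsequent run is permuted by the
    column assignment maximizing summed column-wise agreement (Q_refᵀ·Q_run,
    solved as an optimal K×K assignment) against the running mean of the
    already-aligned runs. Returns the aligned copies and their mean.
    """
    if not runs:
        raise ValueError("no runs to align")
    mats = [np.asarray(r, dtype=float) for r in runs]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all runs must share individuals and K")
    aligned = [mats[0]]
    ref_sum = mats[0].copy()
    for m in mats[1:]:
        ref = ref_sum / len(aligned)
        similarity = ref.T @ m  # (K, K)
        _, cols = linear_sum_assignment(-similarity)
        permuted = m[:, cols]
        aligned.append(permuted)
        ref_sum += permuted
    mean_q = ref_sum / len(aligned)
    return aligned, mean_q


@dataclass
class KSelection:
    """Replicate LnP(D) summaries and ΔK per K, with the chosen K."""

    table: pd.DataFrame  # index K; columns mean_lnpd, sd_lnpd, delta_k
    chosen_k: int


def evanno_delta_k(lnpd_table: dict[int, list[float]]) -> KSelection:
    """Evanno's ΔK model selection over a grid of K values.

    ``lnpd_table`` maps K → replicate LnP(D) values for consecutive K.
    ΔK(K) = mean over replicates of |L(K+1) − 2L(K) + L(K−1)| divided by the
    replicate standard deviation of L(K); defined only for interior K. The
    chosen K maximizes ΔK, ties broken toward smaller K; K values with zero
    replicate spread are excluded with a warning.
    """
    ks = sorted(lnpd_table)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    reps = {k: np.asarray(lnpd_table[k], dtype=float) for k in ks}
    if any(r.size < 2 for r in reps.values()):
        raise ValueError("need at least 2 replicates per K")

    rows = []
    for k in ks:
        mean = reps[k].mean()
        sd = reps[k].std(ddof=1)
        delta = np.nan
        if ks[0] < k < ks[-1]:
            second_diff = np.abs(
                reps[k + 1] - 2.0 * reps[k] + reps[k - 1]
            ).mean()
            if sd == 0:
                warnings.warn(
                    f"zero replicate spread at K={k}; delta K undefined there",
                    stacklevel=2,
                )
            else:
                delta = second_diff / sd
        rows.append({"K": k, "mean_lnpd": mean, "sd_lnpd": sd, "delta_k": delta})
    table = pd.DataFrame(rows).set_index("K")
    defined = table["delta_k"].dropna()
    if defined.empty:
        raise ValueError("delta K undefined at every interior K")
    chosen = int(defined.idxmax())  # idxmax returns the first (smallest K) tie
    return KSelection(table=table, chosen_k=chosen)


def assign_membership(q_mean: np.ndarray, threshold: float = 0.5) -> list[int | None]:
    """Cluster label per individual, or None (admixed) if no proportion
    strictly exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    q = np.asarray(q_mean, dtype=float)
    out: list[int | None] = []
    for row in q:
        best = int(np.argmax(row))
        out.append(best if row[best] > threshold else None)
    return out


def cluster_fst_he(run: RunResult) -> pd.DataFrame:
    """Per-cluster expected heterozygosity and divergence from the pool.

    He of cluster c is the mean over loci of 2p(1−p) at its posterior-mean
    frequencies; the ancestral pool averages cluster frequencies weighted by
    inferred cluster sizes (mean q columns); cluster Fst is the heterozygosity
    deficit 1 − He_c / He_pool.
    """
    p = run.p_mean
    weights = run.q_mean.mean(axis=0)
    pool = np.average(p, axis=0, weights=weights)
    he_pool = float(np.mean(2.0 * pool * (1.0 - pool)))
    he = np.mean(2.0 * p * (1.0 - p), axis=1)
    if he_pool <= 0:
        warnings.warn("degenerate pool (zero He); cluster Fst undefined",
                      stacklevel=2)
        fst = np.full(run.k, np.nan)
    else:
        fst = 1.0 - he / he_pool
    return pd.DataFrame(
        {"cluster_size": weights, "he": he, "fst": fst},
        index=[f"cluster{c + 1}" for c in range(run.k)],
    )


def structure_grid(
    genotypes: GenotypeMatrix,
    k_values,
    n_replicates: int = 3,
    burnin: int = 500,
    iters: int = 1500,
    seed: int | None = None,
) -> tuple[dict[int, list[RunResult]], dict[int, list[float]]]:
    """Replicate admixture runs over a K grid (the multi-run protocol).

    Returns the runs per K and the LnP(D) table consumable by
    :func:`evanno_delta_k`. Replicate seeds derive deterministically from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    runs: dict[int, list[RunResult]] = {}
    lnpd: dict[int, list[float]] = {}
    for k in sorted(k_values):
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
        runs[k] = [
            fit_admixture(genotypes, k, burnin=burnin, iters=iters, seed=s)
            for s in child_seeds
        ]
        lnpd[k] = [r.lnpd for r in runs[k]]
    return runs, lnpd
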