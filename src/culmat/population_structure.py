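"""Kinship and admixture structure from the filtered SNP matrix.

Two nuisance structures confound marker–trait association in a diversity
panel: fine-scale relatedness, captured as a kinship matrix used as the
random-effect covariance, and broad-scale ancestry, captured as a Q matrix
of admixture proportions used as fixed covariates.

Kinship defaults to the identity-by-state (IBS) proportion — the fraction
of markers at which two accessions carry the same call — with a centred
(VanRaden) genomic relationship matrix available as an alternative.

Admixture is fitted by maximum likelihood with an EM algorithm under the
standard admixture model with independent allele frequencies: accession i's
allele draw at site j succeeds with probability sum_k q_ik p_kj, and the
inbred dosage g_ij/2 in {0,1} is a single such draw.  The number of
ancestral groups K is chosen by the Evanno second-difference statistic
DeltaK computed over replicate fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_scoring import GenotypeMatrix

__all__ = [
    "kinship_ibs",
    "kinship_vanraden",
    "AdmixtureFit",
    "fit_admixture",
    "evanno_delta_k",
    "best_k",
    "q_covariates",
]


def kinship_ibs(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state kinship: pairwise proportion of matching calls.

    Markers missing in either accession of a pair are excluded pairwise;
    a pair with no overlapping markers gets NaN with a warning.  The
    diagonal is 1 by definition.
    """
    g = genotypes.calls.to_numpy(float)
    if g.shape[0] < 2 or g.shape[1] < 1:
        raise ValueError("need at least 2 accessions and 1 marker")
    zero = np.where(np.isfinite(g), g == 0.0, False).astype(float)
    two = np.where(np.isfinite(g), g == 2.0, False).astype(float)
    obs = np.isfinite(g).astype(float)
    matches = zero @ zero.T + two @ two.T
    overlap = obs @ obs.T
    if np.any(overlap == 0):
        warnings.warn("accession pair(s) with zero overlapping markers: NaN kinship")
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(overlap > 0, matches / overlap, np.nan)
    np.fill_diagonal(K, 1.0)
    idx = genotypes.accessions
    return pd.DataFrame(K, index=idx, columns=idx)


def kinship_vanraden(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Centred genomic relationship matrix G = Z Z' / (2 sum p(1-p)).

    Dosages are centred by twice the allele frequency; missing entries are
    mean-imputed for this computation only.
    """
    g = genotypes.calls.to_numpy(float)
    freq = np.nanmean(g, axis=0) / 2.0
    Z = np.where(np.isfinite(g), g, 2.0 * freq) - 2.0 * freq
    denom = 2.0 * np.sum(freq * (1.0 - freq))
    if denom <= 0:
        raise ValueError("all markers monomorphic; VanRaden kinship undefined")
    K = Z @ Z.T / denom
    idx = genotypes.accessions
    return pd.DataFrame(K, index=idx, columns=idx)


@dataclass
class AdmixtureFit:
    """Maximum-likelihood admixture fit at a fixed K."""

    K: int
    Q: pd.DataFrame  # n x K ancestry proportions
    allele_freqs: np.ndarray  # K x m
    loglik: float
    seed: int | None
    n_iter: int
    converged: bool
    loglik_path: np.ndarray


def _admixture_loglik(x: np.ndarray, theta: np.ndarray) -> float:
    eps = 1e-12
    theta = np.clip(theta, eps, 1.0 - eps)
    return float(np.sum(x * np.log(theta) + (1.0 - x) * np.log1p(-theta)))


def _em_fit(x, Q, P, max_iter, tol):
    """EM iterations for the haploid-equivalent admixture likelihood.

    ``x`` is the n x m matrix of allele indicators (dosage/2; missing
    entries pre-imputed with the panel frequency — imputation happens only
    here, never in the stored genotypes).
    """
    n, m = x.shape
    eps = 1e-9
    path = []
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        theta = np.clip(Q @ P, eps, 1.0 - eps)  # n x m
        ll = _admixture_loglik(x, theta)
        path.append(ll)
        # responsibilities split expected allele counts across ancestries
        r1 = x / theta  # weight for the '1' allele
        r0 = (1.0 - x) / (1.0 - theta)
        num1 = (r1.T @ Q).T * P  # K x m: sum_i r1_ij q_ik p_kj
        num0 = (r0.T @ Q).T * (1.0 - P)
        P_new = num1 / np.clip(num1 + num0, eps, None)
        # q update: average ancestry responsibility over sites
        q_num = Q * ((r1 @ P.T) + (r0 @ (1.0 - P).T))
        Q_new = q_num / q_num.sum(axis=1, keepdims=True)
        P = np.clip(P_new, 1e-6, 1.0 - 1e-6)
        Q = np.clip(Q_new, 1e-9, 1.0)
        Q = Q / Q.sum(axis=1, keepdims=True)
        if ll - prev < tol and it > 1:
            prev = ll
            break
        prev = ll
    theta = np.clip(Q @ P, eps, 1.0 - eps)
    final_ll = _admixture_loglik(x, theta)
    path.append(final_ll)
    return Q, P, final_ll, it, np.asarray(path)


def fit_admixture(
    genotypes: GenotypeMatrix,
    K: int,
    seed: int | None = 0,
    n_restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """ML admixture fit at a fixed number of ancestral populations K.

    Maximises the Bernoulli likelihood of inbred allele indicators
    g_ij/2 under draw probability sum_k q_ik p_kj by EM, taking the best
    of ``n_restarts`` random initialisations.  K=1 has the closed form
    p_j = panel allele frequency.  Missing genotypes are mean-imputed
    inside the E-step only.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    g = genotypes.calls.to_numpy(float)
    n, m = g.shape
    freq = np.nanmean(g, axis=0) / 2.0
    x = np.where(np.isfinite(g), g / 2.0, freq[None, :])
    acc = genotypes.accessions

    if K == 1:
        theta = np.tile(freq, (n, 1))
        ll = _admixture_loglik(x, theta)
        return AdmixtureFit(
            K=1,
            Q=pd.DataFrame(np.ones((n, 1)), index=acc, columns=["pop0"]),
            allele_freqs=freq[None, :],
            loglik=ll,
            seed=seed,
            n_iter=0,
            converged=True,
            loglik_path=np.array([ll]),
        )

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        Q0 = rng.dirichlet(np.ones(K), size=n)
        jitter = np.clip(
            freq[None, :] + rng.normal(0.0, 0.1, size=(K, m)), 1e-3, 1.0 - 1e-3
        )
        Q, P, ll, it, path = _em_fit(x, Q0, jitter, max_iter, tol)
        if best is None or ll > best[2]:
            best = (Q, P, ll, it, path)
    Q, P, ll, it, path = best
    return AdmixtureFit(
        K=K,
        Q=pd.DataFrame(Q, index=acc, columns=[f"pop{k}" for k in range(K)]),
        allele_freqs=P,
        loglik=ll,
        seed=seed,
        n_iter=it,
        converged=it < max_iter,
        loglik_path=path,
    )


def evanno_delta_k(replicate_logliks: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno second-difference table for choosing K.

    For each interior K on a consecutive grid with replicate fits,

        DeltaK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),

    with the replicate standard deviation (ddof=1) in the denominator.
    Zero spread gives an infinite DeltaK with a warning.  Returns a table
    indexed by K with mean/sd log-likelihood, |L''| and DeltaK (NaN at the
    grid edges); the selected K is the DeltaK argmax.
    """
    ks = sorted(replicate_logliks)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(replicate_logliks[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicate fits per K")
    means = {k: float(np.mean(replicate_logliks[k])) for k in ks}
    sds = {k: float(np.std(replicate_logliks[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        row = {"K": k, "mean_loglik": means[k], "sd_loglik": sds[k]}
        if ks[0] < k < ks[-1]:
            second = abs(means[k + 1] - 2.0 * means[k] + means[k - 1])
            row["abs_second_diff"] = second
            if sds[k] == 0:
                warnings.warn(f"zero replicate spread at K={k}; DeltaK infinite")
                row["delta_k"] = np.inf
            else:
                row["delta_k"] = second / sds[k]
        else:
            row["abs_second_diff"] = np.nan
            row["delta_k"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("K")


def best_k(evanno: pd.DataFrame) -> int:
    """K with the largest DeltaK (interior grid points only)."""
    return int(evanno["delta_k"].idxmax())


def q_covariates(fit: AdmixtureFit) -> pd.DataFrame:
    """Fixed-effect covariates from a Q matrix.

    Rows of Q sum to one, so the full matrix is collinear with an
    intercept; the last ancestry column is dropped.  K=1 yields an empty
    covariate set (structure adds nothing beyond the intercept).
    """
    return fit.Q.iloc[:, :-1].copy()
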