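"""Population structure: PCA and model-based ancestry estimation.

The ancestry model is the standard admixture likelihood: a diploid dosage
g_ij at SNP j for sample i is Binomial(2, sum_k q_ik f_kj), where q_i is the
sample's ancestry-fraction vector over K clusters and f_k the cluster allele
frequencies.  The likelihood is maximized by EM block updates from a seeded
random start (slower than quasi-Newton block relaxation but monotone and
adequate at this scale); the log-likelihood is asserted non-decreasing at
every iteration.  K is chosen by masked-entry cross-validation and per-cell
standard errors come from SNP-resampling bootstrap with greedy
frequency-correlation cluster alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix

logger = logging.getLogger("vetkey")

_EPS = 1e-6


@dataclass
class PcaResult:
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    sample_ids: list[str]


@dataclass
class AssignmentMatrix:
    Q: np.ndarray                      # samples x K, rows sum to 1
    K: int
    sample_ids: list[str]
    cluster_labels: list[str]
    SE: np.ndarray | None = None       # samples x K bootstrap standard errors
    log_likelihood: float = float("-nan")
    converged: bool = True
    F: np.ndarray | None = None        # K x SNPs cluster allele frequencies

    def __post_init__(self) -> None:
        if self.Q.shape != (len(self.sample_ids), self.K):
            raise ValueError("Q shape inconsistent with sample_ids and K")
        if (self.Q < -1e-12).any():
            raise ValueError("Q entries must be non-negative")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if self.SE is not None and (np.asarray(self.SE) < 0).any():
            raise ValueError("SE entries must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=self.cluster_labels)
        if self.SE is not None:
            for k, lab in enumerate(self.cluster_labels):
                df[f"SE_{lab}"] = self.SE[:, k]
        return df


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Column-centered PCA on mean-imputed dosages."""
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = gm.values.copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    n_components = min(n_components, gm.n_samples - 1, gm.n_snps)
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    evr = np.nan_to_num(model.explained_variance_ratio_)  # 0 for zero-variance input
    return PcaResult(scores=scores,
                     explained_variance_fraction=evr,
                     sample_ids=list(gm.sample_ids))


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

def _log_likelihood(G: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    P = np.clip(Q @ F, _EPS, 1 - _EPS)
    with np.errstate(invalid="ignore"):
        ll = G * np.log(P) + (2.0 - G) * np.log(1.0 - P)
    return float(np.nansum(ll))


def estimate_admixture(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> AssignmentMatrix:
    """Maximum-likelihood ancestry fractions via EM block updates.

    Missing genotypes are ignored in both the likelihood and the updates.
    Non-convergence after ``max_iter`` returns the best-so-far estimate with
    ``converged=False`` and a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    G = gm.values
    n, J = G.shape
    obs = ~np.isnan(G)
    G0 = np.where(obs, G, 0.0)
    G2 = np.where(obs, 2.0 - G, 0.0)

    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.1, 0.9, size=(K, J)), _EPS, 1 - _EPS)

    prev_ll = _log_likelihood(np.where(obs, G, np.nan), Q, F)
    converged = False
    for it in range(max_iter):
        P = np.clip(Q @ F, _EPS, 1 - _EPS)
        P2 = 1.0 - P
        X = G0 / P           # zero where missing
        Y = G2 / P2
        # E+M for Q: row-normalized expected allele origins
        Qn = Q * (X @ F.T + Y @ (1.0 - F).T)
        Q = Qn / Qn.sum(axis=1, keepdims=True)
        # E+M for F
        Fn = F * (Q.T @ X)
        Fd = Fn + (1.0 - F) * (Q.T @ Y)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(Fd > 0, Fn / Fd, F)
        F = np.clip(F, _EPS, 1 - _EPS)

        ll = _log_likelihood(np.where(obs, G, np.nan), Q, F)
        if ll < prev_ll - 1e-6:
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
    if not converged:
        logger.warning("admixture EM did not converge after %d iterations", max_iter)
    return AssignmentMatrix(
        Q=Q, K=K, sample_ids=list(gm.sample_ids),
        cluster_labels=[f"cluster_{k}" for k in range(K)],
        log_likelihood=prev_ll, converged=converged, F=F,
    )


def grid_search_loglik(gm: GenotypeMatrix, F: np.ndarray, grid: float = 0.01) -> float:
    """Best log-likelihood over a dense per-sample grid of q (K=2 only).

    Independent oracle for the EM optimum: given cluster frequencies, the
    likelihood separates by sample, so each sample's best grid q is found by
    enumeration.
    """
    if F.shape[0] != 2:
        raise ValueError("grid search implemented for K=2")
    qs = np.arange(0.0, 1.0 + grid / 2, grid)
    G = gm.values
    total = 0.0
    for i in range(G.shape[0]):
        g = G[i]
        ok = ~np.isnan(g)
        best = -np.inf
        for q in qs:
            p = np.clip(q * F[0, ok] + (1 - q) * F[1, ok], _EPS, 1 - _EPS)
            ll = float(np.sum(g[ok] * np.log(p) + (2 - g[ok]) * np.log(1 - p)))
            best = max(best, ll)
        total += best
    return total


# ---------------------------------------------------------------------------
# Cross-validation choice of K
# ---------------------------------------------------------------------------

def cv_choose_k(
    gm: GenotypeMatrix,
    k_range: list[int],
    folds: int = 5,
    seed: int = 0,
    mask_fraction: float = 0.10,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, int]:
    """Masked-entry cross-validation over K.

    Observed genotype entries are partitioned into ``folds`` random masks;
    for each fold and K the model is fit with the masked entries treated as
    missing and the masked dosages predicted as 2 * sum_k q_ik f_kj.  The CV
    error is the mean squared deviation over masked entries; the K with the
    minimum mean error is returned.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if any(k < 1 or k > gm.n_samples for k in k_range):
        raise ValueError("k_range must lie within [1, n_samples]")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(~np.isnan(gm.values))
    n_mask = int(round(mask_fraction * len(obs_idx)))
    if n_mask == 0:
        raise ValueError("no genotype entries to mask; increase mask_fraction")
    rows = []
    for fold in range(folds):
        sel = obs_idx[rng.choice(len(obs_idx), size=n_mask, replace=False)]
        masked = gm.values.copy()
        masked[sel[:, 0], sel[:, 1]] = np.nan
        gm_masked = GenotypeMatrix(values=masked, sample_ids=list(gm.sample_ids),
                                   snp_meta=gm.snp_meta.copy())
        truth = gm.values[sel[:, 0], sel[:, 1]]
        for K in k_range:
            fit = estimate_admixture(gm_masked, K, seed=seed + 1000 * fold + K,
                                     max_iter=max_iter)
            pred = 2.0 * np.einsum("ik,ki->i", fit.Q[sel[:, 0], :], fit.F[:, sel[:, 1]])
            err = float(np.mean((truth - pred) ** 2))
            rows.append({"fold": fold, "K": K, "cv_error": err})
    table = pd.DataFrame(rows)
    means = table.groupby("K")["cv_error"].mean()
    return table, int(means.idxmin())


# ---------------------------------------------------------------------------
# Bootstrap SEs and cluster combination
# ---------------------------------------------------------------------------

def _align_clusters(F_ref: np.ndarray, F_rep: np.ndarray) -> np.ndarray | None:
    """Greedy frequency-correlation matching; permutation or None if ambiguous."""
    K = F_ref.shape[0]
    corr = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            corr[a, b] = np.corrcoef(F_ref[a], F_rep[b])[0, 1]
    perm = np.full(K, -1)
    used = set()
    for _ in range(K):
        a, b = np.unravel_index(np.nanargmax(np.where(np.isnan(corr), -np.inf, corr)), corr.shape)
        if not np.isfinite(corr[a, b]):
            return None
        perm[a] = b
        used.add(b)
        corr[a, :] = np.nan
        corr[:, b] = np.nan
    if len(used) != K:
        return None
    return perm


def bootstrap_se(
    gm: GenotypeMatrix,
    K: int,
    B: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    point: AssignmentMatrix | None = None,
) -> AssignmentMatrix:
    """SNP-resampling bootstrap standard errors for the Q matrix.

    Each replicate resamples SNP columns with replacement, refits the model,
    aligns clusters to the point estimate by greedy correlation of cluster
    allele frequencies, and the SE is the per-cell standard deviation across
    aligned replicates.  Replicates with ambiguous alignment are dropped
    (logged).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if point is None:
        point = estimate_admixture(gm, K, seed=seed, max_iter=max_iter)
    rng = np.random.default_rng(seed + 1)
    reps = []
    for b in range(B):
        cols = rng.choice(gm.n_snps, size=gm.n_snps, replace=True)
        gm_b = gm.take_snps(cols)
        fit = estimate_admixture(gm_b, K, seed=seed + 7919 * (b + 1), max_iter=max_iter)
        perm = _align_clusters(point.F[:, cols], fit.F)
        if perm is None:
            logger.warning("bootstrap replicate %d dropped: ambiguous cluster alignment", b)
            continue
        reps.append(fit.Q[:, perm])
    if len(reps) < 2:
        raise RuntimeError("fewer than 2 alignable bootstrap replicates")
    SE = np.std(np.stack(reps), axis=0, ddof=1)
    return AssignmentMatrix(Q=point.Q, K=K, sample_ids=point.sample_ids,
                            cluster_labels=point.cluster_labels, SE=SE,
                            log_likelihood=point.log_likelihood,
                            converged=point.converged, F=point.F)


def combine_clusters(am: AssignmentMatrix, group_map: dict[str, list[str]]
                     ) -> AssignmentMatrix:
    """Sum ancestry over labeled cluster groups.

    Combined q is the sum of member assignments; the combined standard error
    is the square root of the sum of squared member SEs.  ``group_map`` must
    partition the cluster labels.
    """
    all_members = [m for members in group_map.values() for m in members]
    if sorted(all_members) != sorted(am.cluster_labels):
        raise ValueError("group_map must partition the cluster labels")
    names = list(group_map)
    cols = {lab: k for k, lab in enumerate(am.cluster_labels)}
    Q = np.column_stack([am.Q[:, [cols[m] for m in group_map[g]]].sum(axis=1)
                         for g in names])
    SE = None
    if am.SE is not None:
        SE = np.column_stack([
            np.sqrt((am.SE[:, [cols[m] for m in group_map[g]]] ** 2).sum(axis=1))
            for g in names
        ])
    return AssignmentMatrix(Q=Q, K=len(names), sample_ids=list(am.sample_ids),
                            cluster_labels=names, SE=SE,
                            log_likelihood=am.log_likelihood, converged=am.converged)
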