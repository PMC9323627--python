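"""Per-segment LD processing: perfect-LD pruning and shrinkage covariance.

A small reference panel makes the raw per-segment covariance rank
deficient; near-duplicate SNP columns can drive the weighted variance
``W' Cov W`` toward zero and blow up the segment z-score.  Two guards fix
this: (1) greedy pruning of SNP pairs in near-perfect LD (r^2 >= 0.99),
and (2) an analytic shrinkage of the correlation matrix toward the
identity (Schaefer-Strimmer), which leaves the diagonal (the sample
variances) untouched and yields a positive-definite, well-conditioned
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: floor on the shrinkage intensity; keeps the reassembled matrix strictly
#: positive definite even when the analytic intensity is exactly zero.
MIN_SHRINK = 1e-12


@dataclass
class SegmentLd:
    """Pruned SNP set and shrunk covariance for one segment."""

    kept_snp_indices: np.ndarray  # indices into the segment's SNP list, genomic order
    cov: np.ndarray  # shrunk covariance, diagonal = unshrunk sample variances
    shrink_intensity: float  # lambda* in [0, 1]
    n_ref: int

    def __post_init__(self) -> None:
        # fail fast if the PD contract is violated
        np.linalg.cholesky(self.cov)


def pearson_r2_matrix(geno: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlations between dosage columns."""
    r = np.corrcoef(geno, rowvar=False)
    return np.atleast_2d(r) ** 2


def prune_perfect_ld(
    geno: np.ndarray,
    priority: np.ndarray | None = None,
    r2_threshold: float = 0.99,
) -> np.ndarray:
    """Greedy pruning of near-perfect LD.

    Visit SNPs in decreasing priority (ties -> earlier column, i.e. smaller
    genomic position, first); keep a SNP iff its r^2 with every SNP kept so
    far is below ``r2_threshold``.  Returns kept column indices in input
    (genomic) order.

    Parameters
    ----------
    geno : (n_ref, m) dosage matrix
    priority : per-SNP priority, higher kept first (GWAS -log10 p by
        convention); uniform if omitted.
    """
    if geno.ndim != 2 or geno.shape[1] == 0:
        raise ValueError("empty SNP set")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    m = geno.shape[1]
    if priority is None:
        priority = np.zeros(m)
    priority = np.asarray(priority, dtype=float)
    if priority.shape != (m,):
        raise ValueError("priority length must match SNP count")
    if m == 1:
        return np.array([0])
    r2 = pearson_r2_matrix(geno)
    # stable sort on column index breaks priority ties toward smaller position
    order = np.argsort(-priority, kind="stable")
    kept: list[int] = []
    for j in order:
        if all(r2[j, k] < r2_threshold for k in kept):
            kept.append(int(j))
    return np.array(sorted(kept))


def shrink_covariance(
    geno: np.ndarray,
    shrink: float | None = None,
) -> SegmentLd:
    """Analytic shrinkage covariance of a segment's dosage columns.

    Off-diagonal correlations are shrunk toward zero, r*_ij = (1 - lam) r_ij,
    with the data-driven intensity

        lam = clamp( sum_{i != j} Var_hat(r_ij) / sum_{i != j} r_ij^2, 0, 1 ),

    where Var_hat(r_ij) is the empirical variance of the standardized
    cross-products (Schaefer-Strimmer, identity-correlation target).  The
    covariance is reassembled as cov_ij = r*_ij * sd_i * sd_j, so the
    diagonal keeps the unshrunk sample variances.

    ``shrink`` overrides the analytic intensity (0.0 gives the plain sample
    covariance; used for oracle comparisons).
    """
    geno = np.asarray(geno, dtype=float)
    if geno.ndim != 2 or geno.shape[1] == 0:
        raise ValueError("need an (n_ref, m) dosage matrix with m >= 1")
    n, m = geno.shape
    if n < 3:
        raise ValueError("need n_ref >= 3")
    sd = geno.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        raise ValueError("zero-variance SNP column; filter monomorphic SNPs upstream")

    if m == 1:
        lam = 0.0 if shrink is None else float(shrink)
        cov = np.array([[sd[0] ** 2]])
        return SegmentLd(np.array([0]), cov, lam, n)

    x = (geno - geno.mean(axis=0)) / sd  # standardized columns
    r = (x.T @ x) / (n - 1)
    np.fill_diagonal(r, 1.0)

    if shrink is None:
        # Var_hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - wbar_ij)^2,
        # with w_kij = x_ki x_kj; computed via gram matrices of x and x^2.
        wbar = (x.T @ x) / n
        sum_w2 = (x**2).T @ (x**2)
        ss = sum_w2 - n * wbar**2  # sum_k (w_kij - wbar_ij)^2
        var_r = n / (n - 1) ** 3 * ss
        off = ~np.eye(m, dtype=bool)
        denom = float((r[off] ** 2).sum())
        lam = 1.0 if denom == 0.0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    else:
        lam = float(shrink)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrink must be in [0, 1]")

    lam_eff = max(lam, MIN_SHRINK) if shrink is None else lam
    r_star = (1.0 - lam_eff) * r
    np.fill_diagonal(r_star, 1.0)
    cov = r_star * np.outer(sd, sd)
    return SegmentLd(np.arange(m), cov, lam, n)


def segment_ld(
    geno: np.ndarray,
    priority: np.ndarray | None = None,
    r2_threshold: float = 0.99,
    prune: bool = True,
    shrink: float | None = None,
) -> SegmentLd:
    """Prune then shrink: the full per-segment LD pipeline."""
    if prune and geno.shape[1] > 1:
        kept = prune_perfect_ld(geno, priority, r2_threshold)
    else:
        kept = np.arange(geno.shape[1])
    ld = shrink_covariance(geno[:, kept], shrink=shrink)
    return SegmentLd(kept, ld.cov, ld.shrink_intensity, ld.n_ref)
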