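"""Per-cell-type openness-weighted segment statistic.

For a segment s with SNP set Omega_s, openness weights w_j, GWAS z-scores
z_j and reference-panel dosage SDs sigma_j, the segment z-score is

    Z_s = sum_j w_j sigma_j z_j / sigma_s,    sigma_s^2 = W' Cov_hat(X_s) W,

the summary-statistics form of the t-statistic from regressing the
phenotype on the segment's openness score X_s W.  The two-sided normal
p-value p_{l,s} feeds the cross-cell-type aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ld_reference import SegmentLd

#: smallest positive double; z_to_p never underflows to exactly 0
TINY_P = 5e-324


@dataclass
class CellTypeSegmentStat:
    segment_id: str
    cell_type: str
    W_s: np.ndarray
    sigma_s2: float
    Z_s: float | None  # None when the segment is untestable
    p: float | None
    n_snps_used: int

    @property
    def testable(self) -> bool:
        return self.p is not None


def z_to_p(z: float) -> float:
    """Two-sided normal p-value 2*Phi(-|z|), floored at the smallest
    positive double so extreme z never maps to exactly 0."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    p = 2.0 * stats.norm.sf(abs(z))
    return max(float(p), TINY_P)


def segment_stat(
    z: np.ndarray,
    w: np.ndarray,
    sd: np.ndarray,
    ld: SegmentLd,
    segment_id: str = "",
    cell_type: str = "",
    rel_tol: float = 1e-12,
) -> CellTypeSegmentStat:
    """Openness-weighted z-score and p-value for one (segment, cell type).

    ``z``, ``w``, ``sd`` must already be aligned with ``ld.kept_snp_indices``
    (the post-pruning SNP set).  If sigma_s^2 falls below
    ``rel_tol * max_j (w_j sigma_j)^2`` the segment is flagged untestable
    (Z and p missing) rather than reported with an inflated score.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    sd = np.asarray(sd, dtype=float)
    m = len(ld.kept_snp_indices)
    if not (len(z) == len(w) == len(sd) == m):
        raise ValueError(
            f"z/w/sd lengths {len(z)}/{len(w)}/{len(sd)} do not match kept SNP count {m}"
        )
    if np.any(sd <= 0):
        raise ValueError("all sd must be positive")
    sigma_s2 = float(w @ ld.cov @ w)
    scale = float(np.max((w * sd) ** 2)) if m else 0.0
    if sigma_s2 < rel_tol * scale or scale == 0.0:
        return CellTypeSegmentStat(segment_id, cell_type, w, sigma_s2, None, None, m)
    Z = float(np.sum(w * sd * z) / np.sqrt(sigma_s2))
    return CellTypeSegmentStat(segment_id, cell_type, w, sigma_s2, Z, z_to_p(Z), m)
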