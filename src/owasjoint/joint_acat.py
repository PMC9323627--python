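"""Aggregation of per-cell-type segment p-values with the Cauchy
combination test (ACAT).

Each p-value is mapped to a Cauchy quantile, tan((0.5 - p) * pi); the
weighted sum T_s = sum_l eta_l tan((0.5 - p_{l,s}) pi) has approximately a
standard Cauchy tail under the null for *any* dependence structure among
the component tests, so the combined p-value is the Cauchy survival
function p_s = 1/2 - arctan(T_s)/pi.  Weights eta_l are non-negative and
sum to one (uniform by default); eta = e_k recovers the single-cell-type
test on cell type k exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: below this, tan((0.5-p)pi) is replaced by its asymptote 1/(p*pi)
SMALL_P = 1e-15
#: above this T, the combined p uses the Cauchy tail asymptote 1/(T*pi)
LARGE_T = 1e15
_TINY = 5e-324


@dataclass(frozen=True)
class AcatWeights:
    """Non-negative cell-type weights, renormalized to sum to 1."""

    eta: tuple[float, ...]

    def __init__(self, eta: Sequence[float]):
        eta = tuple(float(e) for e in eta)
        if any(e < 0 for e in eta):
            raise ValueError("eta must be non-negative")
        total = sum(eta)
        if total <= 0:
            raise ValueError("eta must have a positive sum")
        object.__setattr__(self, "eta", tuple(e / total for e in eta))

    @classmethod
    def uniform(cls, L: int) -> "AcatWeights":
        return cls([1.0] * L)

    def __len__(self) -> int:
        return len(self.eta)


@dataclass
class JointSegmentResult:
    segment_id: str
    p_by_cell_type: tuple[float | None, ...]
    T_s: float | None
    p_joint: float | None
    significant: bool = False

    @property
    def testable(self) -> bool:
        return self.p_joint is not None


def _cauchy_term(p: float) -> float:
    # tan((0.5 - p) * pi) via the cotangent identity; evaluating the
    # tangent away from its pole keeps full relative precision for tiny p
    if p < SMALL_P:
        return 1.0 / (p * math.pi)
    if p <= 0.5:
        return 1.0 / math.tan(p * math.pi)
    return -1.0 / math.tan((1.0 - p) * math.pi)


def acat(
    p: Sequence[float | None],
    eta: AcatWeights | Sequence[float] | None = None,
) -> tuple[float | None, float | None]:
    """Cauchy-combine the per-cell-type p-values.

    Missing components (None/NaN, e.g. untestable segments) are dropped and
    eta renormalized over the remainder; if all are missing the result is
    (None, None).  p-values must be in (0, 1]; they are clipped just below
    1 so the tangent stays finite.  Returns (T, p_joint) with
    0 < p_joint < 1 guaranteed.
    """
    if eta is None:
        eta = AcatWeights.uniform(len(p))
    elif not isinstance(eta, AcatWeights):
        eta = AcatWeights(eta)
    if len(eta) != len(p):
        raise ValueError("eta and p have different lengths")
    pairs = [
        (pl, el)
        for pl, el in zip(p, eta.eta)
        if pl is not None and not (isinstance(pl, float) and math.isnan(pl))
    ]
    if not pairs:
        return None, None
    if any(pl <= 0 for pl, _ in pairs):
        raise ValueError("p-values must be strictly positive")
    if any(pl > 1 for pl, _ in pairs):
        raise ValueError("p-values must be <= 1")
    w_total = sum(el for _, el in pairs)
    terms = []
    with np.errstate(over="ignore"):
        for pl, el in pairs:
            pl = min(pl, 1.0 - 1e-15)
            terms.append((el / w_total) * _cauchy_term(pl))
    T = math.fsum(terms)
    # Cauchy survival function 1/2 - atan(T)/pi, written with atan2 so the
    # tail (large |T|, tiny p_joint) keeps full relative precision; for
    # T > 1e15 this is numerically the reciprocal form 1/(T*pi)
    if T >= 0:  # covers T = +inf from overflowed terms -> p_joint at the floor
        p_joint = math.atan2(1.0, T) / math.pi
    else:
        p_joint = 1.0 - math.atan2(1.0, -T) / math.pi
    p_joint = min(max(p_joint, _TINY), 1.0 - 1e-16)
    return T, p_joint


def significance_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni threshold alpha / n_tests over the *testable* segments."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def combine_segments(
    per_cell_type: Mapping[str, Sequence],
    eta: AcatWeights | Sequence[float] | None = None,
) -> list[JointSegmentResult]:
    """Run ACAT across cell types for every segment.

    ``per_cell_type`` maps cell type -> list of CellTypeSegmentStat in a
    shared segment order.
    """
    cell_types = list(per_cell_type)
    stat_lists = [per_cell_type[ct] for ct in cell_types]
    n_seg = len(stat_lists[0])
    if any(len(sl) != n_seg for sl in stat_lists):
        raise ValueError("cell types disagree on segment count")
    results = []
    for i in range(n_seg):
        stats_i = [sl[i] for sl in stat_lists]
        seg_ids = {s.segment_id for s in stats_i}
        if len(seg_ids) != 1:
            raise ValueError(f"segment order mismatch across cell types: {seg_ids}")
        ps = tuple(s.p for s in stats_i)
        T, p_joint = acat(ps, eta)
        results.append(JointSegmentResult(stats_i[0].segment_id, ps, T, p_joint))
    return results


def call_segments(
    results: Sequence[JointSegmentResult], threshold: float
) -> list[JointSegmentResult]:
    """Flag segments with p_joint strictly below the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n_sig = 0
    for res in results:
        res.significant = res.testable and res.p_joint < threshold
        n_sig += res.significant
    logger.info("%d/%d segments significant at %.3g", n_sig, len(results), threshold)
    return list(results)


def call_genes(
    results: Sequence[JointSegmentResult],
    gene_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Gene-level calls: a gene's p is the minimum p_joint over its
    segments; it is significant iff any of those segments is.  Genes with
    no testable segment are omitted."""
    by_id = {r.segment_id: r for r in results if r.testable}
    rows = []
    for gene_id, seg_ids in gene_map.items():
        hits = [by_id[s] for s in seg_ids if s in by_id]
        if not hits:
            continue
        best = min(hits, key=lambda r: r.p_joint)
        rows.append(
            {
                "gene_id": gene_id,
                "best_segment": best.segment_id,
                "p_min": best.p_joint,
                "significant": any(r.significant for r in hits),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "best_segment", "p_min", "significant"])
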