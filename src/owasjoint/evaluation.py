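"""Replication-rate analysis of prioritized vs. non-prioritized SNPs.

Discovery-cohort SNPs with 0 < p < 0.05 are split into five p-value bins;
inside each bin, SNPs harbored by a significant joint segment
("prioritized", p_joint < 5e-8 by default) are compared with the rest on
their replication rate (fraction reaching p < 0.05 in an independent
cohort).  A one-sided exact binomial test asks whether the prioritized
group replicates more often than the non-prioritized baseline rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GwasRecord
from .owas_single import z_to_p

#: (label, lower, upper) discovery p-value bins, [lower, upper); bin I is
#: open at zero so the five bins tile (0, 0.05)
DEFAULT_BINS = [
    ("I", 0.0, 5e-6),
    ("II", 5e-6, 5e-5),
    ("III", 5e-5, 5e-4),
    ("IV", 5e-4, 5e-3),
    ("V", 5e-3, 0.05),
]


@dataclass
class BinResult:
    label: str
    p_low: float
    p_high: float
    n_prioritized: int
    n_prioritized_replicated: int
    n_other: int
    n_other_replicated: int

    @property
    def rate_prioritized(self) -> float | None:
        if self.n_prioritized == 0:
            return None
        return self.n_prioritized_replicated / self.n_prioritized

    @property
    def rate_other(self) -> float | None:
        if self.n_other == 0:
            return None
        return self.n_other_replicated / self.n_other

    @property
    def binomial_p(self) -> float | None:
        """One-sided exact binomial p: prioritized replication count vs.
        the non-prioritized rate as the null proportion."""
        if self.n_prioritized == 0 or self.n_other == 0:
            return None
        return stats.binomtest(
            self.n_prioritized_replicated,
            self.n_prioritized,
            p=self.rate_other,
            alternative="greater",
        ).pvalue


@dataclass
class ReplicationReport:
    bins: list[BinResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bins:
            rows.append(
                {
                    "bin": b.label,
                    "p_low": b.p_low,
                    "p_high": b.p_high,
                    "n_prioritized": b.n_prioritized,
                    "n_prioritized_replicated": b.n_prioritized_replicated,
                    "n_other": b.n_other,
                    "n_other_replicated": b.n_other_replicated,
                    "rate_prioritized": b.rate_prioritized,
                    "rate_other": b.rate_other,
                    "binomial_p": b.binomial_p,
                }
            )
        return pd.DataFrame(rows)


def _in_segment(chrom: str, pos: int, segments: pd.DataFrame) -> bool:
    hits = segments[
        (segments["chrom"].astype(str) == chrom)
        & (segments["start"] <= pos)
        & (segments["end"] >= pos)
    ]
    return len(hits) > 0


def replication_rates(
    discovery: Sequence[GwasRecord],
    replication: Sequence[GwasRecord],
    prioritized_segments: pd.DataFrame,
    repl_alpha: float = 0.05,
    prior_alpha: float = 5e-8,
    bins: Sequence[tuple[str, float, float]] = tuple(DEFAULT_BINS),
) -> ReplicationReport:
    """Binned replication rates of prioritized vs. other discovery SNPs.

    ``prioritized_segments`` is a table with columns chrom, start, end and
    (optionally) p_joint; rows with p_joint >= ``prior_alpha`` are ignored,
    so a pre-filtered segment table may be passed as-is.
    """
    segs = prioritized_segments
    if "p_joint" in segs.columns:
        segs = segs[segs["p_joint"] < prior_alpha]
    repl_p = {rec.variant_id: z_to_p(rec.z) for rec in replication}

    out = []
    for label, lo, hi in bins:
        n_pri = k_pri = n_oth = k_oth = 0
        for rec in discovery:
            p = z_to_p(rec.z)
            in_bin = (lo < p < hi) if lo == 0.0 else (lo <= p < hi)
            if not in_bin:
                continue
            rp = repl_p.get(rec.variant_id)
            if rp is None:
                continue  # not measured in the replication cohort
            replicated = rp < repl_alpha
            if _in_segment(rec.chrom, rec.pos, segs):
                n_pri += 1
                k_pri += replicated
            else:
                n_oth += 1
                k_oth += replicated
        out.append(BinResult(label, lo, hi, n_pri, k_pri, n_oth, k_oth))
    return ReplicationReport(out)
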