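"""Permutation-null false discovery rates for pairwise associations.

For each driver type the sample labels of every driver feature are permuted
independently, the pairwise screen is re-run with identical thresholds, and
the number of significant associations is recorded.  Two FDR summaries are
formed against the observed positive-call count: the null mean and the null
99th percentile (nearest-rank), the latter being the conservative variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .module_builder import AnalysisContext, BuilderConfig, pairwise_screen

logger = logging.getLogger(__name__)


@dataclass
class FdrEstimate:
    driver_type: str
    n_positive: int
    null_counts: np.ndarray
    fdr_mean: float | None
    fdr_q99: float | None

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts)
        if self.fdr_mean is not None and self.fdr_q99 is not None:
            if self.fdr_mean < 0 or self.fdr_q99 < 0:
                raise ValueError("FDR estimates must be nonnegative")


def _quantile_99(counts: np.ndarray) -> float:
    """Nearest-rank 99th percentile."""
    s = np.sort(counts)
    rank = int(np.ceil(0.99 * s.size)) - 1
    return float(s[max(rank, 0)])


def fdr_estimates(n_positive: int, null_counts: np.ndarray,
                  driver_type: str = "all") -> FdrEstimate:
    """Form the two FDR ratios from stored null counts.

    fdr_mean = mean(null_counts)/n_positive and fdr_q99 =
    nearest-rank-99th(null_counts)/n_positive; both are NA when there are no
    positive calls.
    """
    null_counts = np.asarray(null_counts, dtype=float)
    if null_counts.size == 0:
        raise ValueError("null_counts must be nonempty")
    if n_positive == 0:
        return FdrEstimate(driver_type, 0, null_counts, None, None)
    return FdrEstimate(driver_type, int(n_positive), null_counts,
                       float(null_counts.mean() / n_positive),
                       _quantile_99(null_counts) / n_positive)


def _permuted_context(ctx: AnalysisContext, rng: np.random.Generator
                      ) -> AnalysisContext:
    """A shallow context clone whose driver profiles are label-permuted.

    Each driver feature receives its own independent sample permutation;
    passenger data are left untouched, destroying driver-passenger linkage
    while preserving every marginal.
    """
    perm = AnalysisContext.__new__(AnalysisContext)
    perm.dataset = ctx.dataset
    perm.segments = ctx.segments
    perm.seg_by_id = ctx.seg_by_id
    perm.gene_to_segment = ctx.gene_to_segment
    perm.passengers = ctx.passengers
    perm.tf_ids = ctx.tf_ids
    perm._q_cache = {}
    n = ctx.dataset.panel.n_samples
    perm.seg_x = {sid: x[rng.permutation(n)] for sid, x in ctx.seg_x.items()}
    base_profile = AnalysisContext.driver_profile

    perms: dict[tuple[str, str], np.ndarray] = {}

    def driver_profile(driver_type: str, driver_id: str) -> np.ndarray:
        if driver_type in ("cis_cnv", "trans_cnv"):
            return perm.seg_x[driver_id]
        key = (driver_type, driver_id)
        if key not in perms:
            perms[key] = rng.permutation(n)
        return base_profile(ctx, driver_type, driver_id)[perms[key]]

    perm.driver_profile = driver_profile
    perm.passenger_q = ctx.passenger_q
    perm.segment_tfs = ctx.segment_tfs
    return perm


def permutation_null(ctx: AnalysisContext, driver_type: str, n_perm: int,
                     seed: int, threshold: float | None = None,
                     passenger_dtype: str = "mrna",
                     config: BuilderConfig | None = None) -> np.ndarray:
    """Null distribution of significant pairwise-association counts.

    Re-runs :func:`pairwise_screen` on label-permuted driver data ``n_perm``
    times with thresholds identical to the real screen.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: the 99th-percentile FDR is unstable",
                       n_perm)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for t in range(n_perm):
        pctx = _permuted_context(ctx, rng)
        hits = pairwise_screen(pctx, driver_type, threshold=threshold,
                               passenger_dtype=passenger_dtype, config=config)
        counts[t] = len(hits)
    return counts


def fdr_report(estimates: list[FdrEstimate]) -> pd.DataFrame:
    """Long-form report: (evaluation in {mean, 99%}, driver_type, FDR)."""
    rows = []
    for e in estimates:
        rows.append({"evaluation": "mean", "driver_type": e.driver_type,
                     "FDR": "NA" if e.fdr_mean is None else round(e.fdr_mean, 4)})
    for e in estimates:
        rows.append({"evaluation": "99%", "driver_type": e.driver_type,
                     "FDR": "NA" if e.fdr_q99 is None else round(e.fdr_q99, 4)})
    return pd.DataFrame(rows)
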