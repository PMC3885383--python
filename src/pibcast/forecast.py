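"""Variable-duration seizure warnings and forecast scoring.

Every block whose risk exceeds the threshold opens a fixed-length warning
(90 minutes by default); warnings that begin before the previous one ends
are merged into a single variable-duration warning. The threshold is chosen
adaptively so the realized proportion of the record spent in warning (TIW)
approximately matches a target.

Scoring uses a forecast horizon to separate forecasting from mere
detection: a seizure counts as correctly forecast (true positive) only if
some warning starts at least ``horizon`` (5 minutes by default) before the
onset and is still active at the onset. A merged warning containing no
seizure onset is one false positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import SeizureCatalog

logger = logging.getLogger("pibcast")

__all__ = ["WarningSet", "ForecastResult", "merge_intervals",
           "risk_to_warnings", "calibrate_threshold", "score_forecasts"]


@dataclass
class WarningSet:
    """Disjoint, sorted half-open warning intervals."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if np.any(self.ends <= self.starts):
            raise ValueError("empty or inverted warning interval")
        if len(self.starts) > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("warning intervals overlap; merge first")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_time(self) -> float:
        return float(np.sum(self.ends - self.starts))

    def tiw(self, span: float) -> float:
        """Realized time in warning as a proportion of the record span."""
        return self.total_time / span


def merge_intervals(starts: np.ndarray, ends: np.ndarray,
                    span: float | None = None) -> WarningSet:
    """Merge overlapping/abutting intervals; optionally clip to [0, span)."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if len(starts) == 0:
        return WarningSet(np.empty(0), np.empty(0))
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    running_end = np.maximum.accumulate(ends)
    # a new merged interval begins where the start exceeds every prior end
    new = np.ones(len(starts), dtype=bool)
    new[1:] = starts[1:] > running_end[:-1]
    m_starts = starts[new]
    m_ends = running_end[np.concatenate([np.flatnonzero(new)[1:] - 1, [len(starts) - 1]])]
    if span is not None:
        m_ends = np.minimum(m_ends, span)
        keep = m_ends > m_starts
        m_starts, m_ends = m_starts[keep], m_ends[keep]
    return WarningSet(m_starts, m_ends)


def risk_to_warnings(block_start_s: np.ndarray, risks: np.ndarray,
                     theta, persistence: float,
                     span: float | None = None) -> WarningSet:
    """Trigger and merge warnings from a per-block risk series.

    ``theta`` may be a scalar or a per-block array (per-fold thresholds).
    Each block with ``risk > theta`` opens ``[t, t + persistence)``;
    overlapping or abutting warnings merge; warnings are clipped at
    ``span`` (the record end) if given.
    """
    if persistence <= 0:
        raise ValueError("persistence must be positive")
    block_start_s = np.asarray(block_start_s, dtype=float)
    risks = np.asarray(risks, dtype=float)
    trig = block_start_s[risks > theta]
    return merge_intervals(trig, trig + persistence, span)


def calibrate_threshold(block_start_s: np.ndarray, risks: np.ndarray,
                        target_tiw: float, persistence: float,
                        span: float):
    """Choose the warning threshold matching a target time in warning.

    The realized TIW is a non-increasing step function of the threshold
    with steps at the observed risk values, so the best achievable match
    is found by bisection over the sorted unique risks. Ties (equal
    deviation) resolve to the larger threshold, i.e. less time in warning.

    Returns ``(theta, achieved_tiw)``. Degenerate input (all risks equal)
    yields a threshold above the constant (TIW 0) with a logged warning.
    """
    if not 0 < target_tiw < 1:
        raise ValueError("target_tiw must lie in (0, 1)")
    risks = np.asarray(risks, dtype=float)
    uniq = np.unique(risks)
    if len(uniq) < 2:
        logger.warning("degenerate (constant) risk series; threshold set above it")
        theta = uniq[0] if len(uniq) else 1.0
        return float(theta), 0.0
    # candidate below the minimum lets every block trigger (TIW -> 1 limit)
    uniq = np.concatenate([[uniq[0] - 1.0], uniq])

    def tiw_at(theta: float) -> float:
        return risk_to_warnings(block_start_s, risks, theta, persistence,
                                span).tiw(span)

    # smallest index whose threshold brings TIW down to <= target
    lo, hi = 0, len(uniq) - 1
    if tiw_at(uniq[lo]) <= target_tiw:
        hi = lo
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if tiw_at(uniq[mid]) <= target_tiw:
                hi = mid
            else:
                lo = mid
    candidates = sorted({uniq[lo], uniq[hi]})
    best_theta, best_dev, best_tiw = None, np.inf, None
    for theta in candidates:  # ascending: later (larger theta) wins ties
        dev = abs(tiw_at(theta) - target_tiw)
        if dev <= best_dev + 1e-15:
            best_theta, best_dev, best_tiw = theta, dev, tiw_at(theta)
    return float(best_theta), float(best_tiw)


@dataclass
class ForecastResult:
    """Counts and rates for one (threshold, record, catalog) evaluation."""

    n_seizures: int
    n_tp: int
    sensitivity: float
    n_fp_warnings: int
    fp_per_day: float
    tiw: float
    threshold: float | None = None
    target_tiw: float | None = None

    @property
    def n_fn(self) -> int:
        return self.n_seizures - self.n_tp


def _covered(starts: np.ndarray, ends: np.ndarray, onsets: np.ndarray,
             horizon: float) -> np.ndarray:
    """True positives: an interval starts <= onset - horizon and ends > onset.

    Intervals are disjoint and sorted, so starts and ends are both
    increasing and only the last interval starting early enough can still
    be active at the onset.
    """
    if len(starts) == 0:
        return np.zeros(len(onsets), dtype=bool)
    idx = np.searchsorted(starts, onsets - horizon, side="right") - 1
    hit = idx >= 0
    hit[hit] = ends[idx[hit]] > onsets[hit]
    return hit


def score_forecasts(warnings: WarningSet, catalog: SeizureCatalog,
                    horizon: float, record_span: float,
                    lead_only: bool = False,
                    threshold: float | None = None,
                    target_tiw: float | None = None) -> ForecastResult:
    """Score a warning set against a seizure catalog.

    A seizure is a true positive iff some warning interval starts at least
    ``horizon`` before its onset and is still active at the onset; else a
    false negative. A merged warning containing no seizure onset (of any
    seizure, regardless of ``lead_only``) is a false positive. With
    ``lead_only`` the sensitivity denominator is restricted to
    lead-flagged seizures; FP counts and TIW are unchanged.
    """
    onsets = catalog.onsets
    hits = _covered(warnings.starts, warnings.ends, onsets, horizon)
    if lead_only:
        if catalog.lead_flags is None:
            raise ValueError("catalog has no lead flags; run find_lead_seizures")
        scored = catalog.lead_flags
    else:
        scored = np.ones(len(onsets), dtype=bool)
    n_scored = int(scored.sum())
    n_tp = int((hits & scored).sum())
    # FP: merged interval with no onset inside [start, end)
    if len(warnings) and len(onsets):
        counts = (np.searchsorted(onsets, warnings.ends, side="left")
                  - np.searchsorted(onsets, warnings.starts, side="left"))
        n_fp = int((counts == 0).sum())
    else:
        n_fp = len(warnings)
    days = record_span / 86400.0
    return ForecastResult(
        n_seizures=n_scored,
        n_tp=n_tp,
        sensitivity=n_tp / n_scored if n_scored else np.nan,
        n_fp_warnings=n_fp,
        fp_per_day=n_fp / days,
        tiw=warnings.tiw(record_span),
        threshold=threshold,
        target_tiw=target_tiw,
    )
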