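"""Univariate feature screening: Mann-Whitney U + Benjamini-Yekutieli FDR.

Each feature column is split by case/control label and tested with a
two-sided Mann-Whitney U test; p-values are adjusted with the
Benjamini-Yekutieli step-up procedure (valid under arbitrary dependence,
which matters here because features sharing a SNP are perfectly correlated),
and features with adjusted q >= alpha are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ValidationError
from .feature_matrix import FeatureMatrix

logger = logging.getLogger(__name__)

#: smallest representable p; guards the (0, 1] domain of the BY adjustment
_TINY_P = np.nextafter(0.0, 1.0)

#: largest min-group-size for which the exact null distribution is used
EXACT_MAX_N = 8


@dataclass(frozen=True)
class FilterResult:
    """Per-feature test outcome; ``kept`` iff ``q_value < alpha``."""

    feature_id: str
    u_statistic: float
    p_value: float
    q_value: float
    kept: bool


def mannwhitney_u(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` (cases) vs ``y`` (controls).

    U counts, over all (case, control) pairs, the cases exceeding the control
    plus half the ties.  With ``method="auto"`` the p-value is exact (null
    permutation distribution) when ``min(n_x, n_y) <= 8`` and there are no
    ties, otherwise a tie-corrected normal approximation with continuity
    correction.  ``method`` may force ``"exact"`` or ``"asymptotic"``.
    Constant pooled values give ``U = n_x * n_y / 2`` and ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("mannwhitney_u: both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return x.size * y.size / 2.0, 1.0
    if method == "auto":
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and not ties) \
            else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (helper / comparator)."""
    p = _validate_p(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values, in input order.

    ``q_(i) = min(1, min_{j>=i} m * c(m) / j * p_(j))`` with
    ``c(m) = sum_{k=1..m} 1/k``; controls the FDR under arbitrary dependence.
    """
    p = _validate_p(p_values)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    adj = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _validate_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    return p


def _column_tests(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column U tests (cases vs controls)."""
    cases = values[labels == 1]
    controls = values[labels == 0]
    n1, n0 = cases.shape[0], controls.shape[0]
    if min(n1, n0) <= EXACT_MAX_N:
        us = np.empty(values.shape[1])
        ps = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            us[j], ps[j] = mannwhitney_u(cases[:, j], controls[:, j])
        return us, ps
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(cases, controls, alternative="two-sided",
                               method="asymptotic", axis=0)
    us = np.asarray(res.statistic, dtype=float)
    ps = np.asarray(res.pvalue, dtype=float)
    # constant pooled columns have zero rank variance -> define p = 1
    const = (values.max(axis=0) - values.min(axis=0)) == 0.0
    us[const] = n1 * n0 / 2.0
    ps[const] = 1.0
    ps = np.clip(np.nan_to_num(ps, nan=1.0), _TINY_P, 1.0)
    return us, ps


def filter_features(
    fm: FeatureMatrix,
    alpha: float = 0.05,
) -> tuple[FeatureMatrix, list[FilterResult]]:
    """Remove features whose case/control distributions are indistinguishable.

    Tests every column, adjusts with Benjamini-Yekutieli, keeps columns with
    ``q < alpha`` (``alpha >= 1`` saturates the threshold and keeps every
    feature).  Returns the restricted matrix plus the full result list.
    Zero kept features returns an empty matrix with a warning, not an error.
    """
    labels = fm.labels
    if len(np.unique(labels)) < 2:
        raise DataError("filter_features: need both phenotype classes")
    us, ps = _column_tests(fm.values, labels)
    qs = by_adjust(ps)
    kept = (qs < alpha) | (alpha >= 1.0)
    results = [
        FilterResult(fid, float(u), float(p), float(q), bool(k))
        for fid, u, p, q, k in zip(fm.feature_ids, us, ps, qs, kept)
    ]
    if not kept.any():
        logger.warning("filter_features: no features survive BY at alpha=%g", alpha)
    out = fm.select_columns(np.flatnonzero(kept))
    return out, results


def filter_report_frame(results: list[FilterResult]) -> pd.DataFrame:
    """Tabular form of the filter outcome (one row per tested feature)."""
    return pd.DataFrame(
        [(r.feature_id, r.u_statistic, r.p_value, r.q_value, r.kept)
         for r in results],
        columns=["feature_id", "u", "p", "q", "kept"],
    )
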