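"""ICV adjustment of regional volumes and volume-level statistics.

Regional volumes are adjusted for head size with the regression method:

    vol_adjusted = vol_observed - beta * (ICV_observed - mean(ICV))

where beta is the ordinary least-squares slope of the regional volume
on ICV over the whole sample (patients + controls pooled by default;
controls-only estimation is available and logged).  Group differences
use Welch's unequal-variance t test; volume-metric relationships are
plain Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class ICVAdjustment:
    adjusted: np.ndarray
    beta: float
    icv_mean: float


def icv_adjust(
    volumes: np.ndarray,
    icvs: np.ndarray,
    estimation_mask: np.ndarray | None = None,
) -> ICVAdjustment:
    """Remove the ICV dependence from a regional volume.

    ``estimation_mask`` restricts the beta regression to a subsample
    (e.g. controls only); adjustment is still applied to everyone and
    uses that subsample's ICV mean.
    """
    volumes = np.asarray(volumes, dtype=float)
    icvs = np.asarray(icvs, dtype=float)
    if estimation_mask is None:
        est_v, est_i = volumes, icvs
    else:
        est_v, est_i = volumes[estimation_mask], icvs[estimation_mask]
        log.info("ICV beta estimated on %d of %d subjects", len(est_v), len(volumes))
    if len(est_v) < 3:
        raise ValueError("ICV adjustment needs at least 3 subjects")
    if np.var(est_i) == 0:
        raise ValueError("zero ICV variance; adjustment undefined")
    icv_mean = float(est_i.mean())
    beta = float(np.cov(est_i, est_v, ddof=1)[0, 1] / np.var(est_i, ddof=1))
    adjusted = volumes - beta * (icvs - icv_mean)
    return ICVAdjustment(adjusted=adjusted, beta=beta, icv_mean=icv_mean)


@dataclass
class VolumeTestResult:
    mean_patient: float
    mean_control: float
    t_statistic: float
    p_value: float


def group_volume_test(adjusted: np.ndarray, is_patient: np.ndarray) -> VolumeTestResult:
    """Welch two-sample t test on adjusted volumes (patient vs control)."""
    adjusted = np.asarray(adjusted, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    x, y = adjusted[is_patient], adjusted[~is_patient]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return VolumeTestResult(float(x.mean()), float(y.mean()), 0.0, 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return VolumeTestResult(float(x.mean()), float(y.mean()), float(t), float(p))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def volume_metric_correlation(adjusted: np.ndarray, metric_auc: np.ndarray) -> CorrelationResult:
    """Pearson correlation between an adjusted volume and a graph-metric AUC."""
    v = np.asarray(adjusted, dtype=float)
    m = np.asarray(metric_auc, dtype=float)
    complete = np.isfinite(v) & np.isfinite(m)
    v, m = v[complete], m[complete]
    if len(v) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(v) == 0 or np.ptp(m) == 0:
        return CorrelationResult(np.nan, np.nan, len(v), degenerate=True)
    r, p = sps.pearsonr(v, m)
    return CorrelationResult(float(r), float(p), len(v))
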