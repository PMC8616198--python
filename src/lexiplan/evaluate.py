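"""Plan-comparison machinery: paired statistics, population DVHs,
DVH-difference confidence bands, beam-angle distributions and metric
tables.

The statistical workhorse is the two-tailed Wilcoxon signed-rank test on
paired per-subject metrics.  Zero differences are dropped before ranking
(classic treatment); for 12 or fewer remaining pairs the null
distribution is enumerated exactly over all sign assignments (conditional
on the observed tie structure), above that a normal approximation with
tie correction is used.  Callers apply the conventional p <= 0.05
significance threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import DVHCurve, dose_metric

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_MAX_N = 12

#: The standard target/OAR metric panel for paired plan comparisons.
DEFAULT_METRIC_PANEL = [
    ("PTV", "V_95%"),
    ("lungs", "D_mean"),
    ("lungs", "V_5Gy"),
    ("lungs", "V_20Gy"),
    ("heart", "D_mean"),
    ("heart", "V_5Gy"),
    ("heart", "V_30Gy"),
    ("esophagus", "D_mean"),
    ("esophagus", "V_20Gy"),
    ("esophagus", "V_60Gy"),
]


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test for paired samples.

    Returns ``(W+, p)`` where ``W+`` is the positive-rank sum after
    dropping zero differences.  All-zero differences give ``p = 1`` with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p set to 1", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        return w_plus, _exact_two_tailed_p(ranks, w_plus)
    res = stats.wilcoxon(d, correction=False, method="approx")
    return w_plus, float(res.pvalue)


def _exact_two_tailed_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact p over all 2^n sign assignments of the observed ranks."""
    n = len(ranks)
    signs = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
    w_dist = signs @ ranks
    eps = 1e-9
    p_ge = float(np.mean(w_dist >= w_plus - eps))
    p_le = float(np.mean(w_dist <= w_plus + eps))
    return min(1.0, 2.0 * min(p_ge, p_le))


def _common_axis(dvhs: list[DVHCurve]) -> np.ndarray:
    top = max(d.dose_Gy[-1] for d in dvhs)
    step = min(np.diff(d.dose_Gy).min() for d in dvhs)
    return np.arange(0.0, top + step, step)


def population_average_dvh(dvhs: list[DVHCurve]) -> DVHCurve:
    """Pointwise mean of a set of DVHs on a common resampled axis."""
    if not dvhs:
        raise ValueError("no DVHs to average")
    axis = _common_axis(dvhs)
    volumes = np.vstack([d.volume_at(axis) for d in dvhs])
    return DVHCurve(axis, volumes.mean(axis=0), dvhs[0].structure)


def paired_dvh_difference_ci(
    dvhs_a: list[DVHCurve],
    dvhs_b: list[DVHCurve],
    *,
    level: float = 95.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[DVHCurve, np.ndarray, np.ndarray]:
    """Mean paired DVH difference (A - B) with a bootstrap confidence band.

    Subjects are resampled with replacement (percentile bootstrap, seeded
    for reproducibility).  Returns ``(mean difference curve, lower band,
    upper band)`` on the common dose axis.
    """
    if len(dvhs_a) != len(dvhs_b):
        raise ValueError("paired DVH lists must have equal length")
    n = len(dvhs_a)
    if n < 2:
        raise ValueError("need at least two subjects for a confidence band")
    axis = _common_axis(list(dvhs_a) + list(dvhs_b))
    diffs = np.vstack(
        [a.volume_at(axis) - b.volume_at(axis) for a, b in zip(dvhs_a, dvhs_b)]
    )
    mean_curve = DVHCurve(axis, diffs.mean(axis=0), dvhs_a[0].structure)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = diffs[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lower = np.percentile(boot_means, alpha, axis=0)
    upper = np.percentile(boot_means, 100.0 - alpha, axis=0)
    return mean_curve, lower, upper


def beam_angle_distribution(plans, bin_deg: float = 5.0) -> dict[float, int]:
    """Histogram of plan beam angles, rounded to the nearest bin with
    wrap-around (357.5 deg rounds to 0)."""
    if not plans:
        raise ValueError("no plans given")
    counts: dict[float, int] = {}
    for plan in plans:
        for a in np.atleast_1d(plan.angles_deg):
            b = (round(float(a) / bin_deg) * bin_deg) % 360.0
            counts[b] = counts.get(b, 0) + 1
    return dict(sorted(counts.items()))


@dataclass
class PairedComparison:
    """Per-metric summary of a paired two-condition comparison."""

    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    median_a: float = field(init=False)
    median_b: float = field(init=False)
    iqr_a: float = field(init=False)
    iqr_b: float = field(init=False)
    statistic: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired value vectors must have equal length")
        self.values_a, self.values_b = a, b
        self.median_a = float(np.median(a))
        self.median_b = float(np.median(b))
        self.iqr_a = float(np.subtract(*np.percentile(a, [75, 25])))
        self.iqr_b = float(np.subtract(*np.percentile(b, [75, 25])))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.statistic, self.p_value = wilcoxon_signed_rank(a, b)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


def metrics_table(
    plans_a,
    plans_b,
    metric_panel=None,
) -> list[PairedComparison]:
    """Evaluate a dose-metric panel on paired plan cohorts.

    Metrics whose structure a plan lacks are skipped with a log entry.
    """
    panel = metric_panel or DEFAULT_METRIC_PANEL
    out = []
    for structure, metric in panel:
        try:
            va = [
                dose_metric(p.structure_dose(structure), metric, D_p=p.prescription_Gy)
                for p in plans_a
            ]
            vb = [
                dose_metric(p.structure_dose(structure), metric, D_p=p.prescription_Gy)
                for p in plans_b
            ]
        except KeyError:
            logger.info("metric %s %s unavailable, skipped", structure, metric)
            continue
        out.append(PairedComparison(f"{structure} {metric}", np.array(va), np.array(vb)))
    return out


def comparison_to_frame(comparisons: list[PairedComparison]) -> pd.DataFrame:
    """Tabular layout (median, IQR, p) mirroring a clinical metric table."""
    return pd.DataFrame(
        {
            "metric": [c.metric for c in comparisons],
            "median_A": [c.median_a for c in comparisons],
            "IQR_A": [c.iqr_a for c in comparisons],
            "median_B": [c.median_b for c in comparisons],
            "IQR_B": [c.iqr_b for c in comparisons],
            "median_diff": [float(np.median(c.differences)) for c in comparisons],
            "p": [c.p_value for c in comparisons],
        }
    )


def dvh_band_frame(curve: DVHCurve, lower: np.ndarray, upper: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dose_Gy": curve.dose_Gy,
            "mean_diff_pct": curve.volume_pct,
            "ci_lower_pct": lower,
            "ci_upper_pct": upper,
        }
    )
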