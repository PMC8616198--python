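"""DVHs, dose-volume metrics, plan normalization and constraint auditing.

Metric conventions (all cumulative):

* ``D_mean`` / ``D_max`` — arithmetic mean / maximum structure dose (Gy);
* ``V_xGy`` — percent of the structure volume receiving at least x Gy,
  computed by direct voxel counting (not DVH interpolation, which would
  introduce bin bias);
* ``V_95%`` — percent of the volume receiving at least 95 % of the
  prescribed dose ``D_p``.

The clinical audit evaluates the planning protocol's dose constraints:
PTV V_95% > 98 %, lungs V_5Gy < 65 % / V_20Gy < 35 % / D_mean < 20 Gy,
heart V_30Gy < 40 %, esophagus D_mean < 34 Gy, spinal canal
D_max < 50 Gy, brachial plexus D_max < 66 Gy (when delineated) and body
D_max < 1.07 * D_p.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose_Gy: np.ndarray
    volume_pct: np.ndarray
    structure: str = ""

    def __post_init__(self):
        self.dose_Gy = np.asarray(self.dose_Gy, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)

    def volume_at(self, dose_Gy) -> np.ndarray:
        """Volume fraction (%) at arbitrary doses, linearly interpolated."""
        return np.interp(dose_Gy, self.dose_Gy, self.volume_pct)

    def max_dose(self) -> float:
        """Highest dose with nonzero volume on the curve axis."""
        nz = np.flatnonzero(self.volume_pct > 0)
        return float(self.dose_Gy[nz[-1]]) if len(nz) else 0.0

    def resampled(self, axis: np.ndarray) -> "DVHCurve":
        return DVHCurve(axis, self.volume_at(axis), self.structure)


def compute_dvh(dose, bin_width_Gy: float = 0.1, structure: str = "") -> DVHCurve:
    """Cumulative DVH of a structure's voxel doses.

    ``volume_pct[i]`` is the percent of voxels with dose >= ``dose_Gy[i]``
    on a uniform axis from 0 to just past the maximum dose.
    """
    dose = np.asarray(dose, dtype=float)
    if dose.size == 0:
        raise ValueError(f"cannot compute a DVH of the empty structure {structure!r}")
    if bin_width_Gy <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.ceil(dose.max() / bin_width_Gy)) + 2 if dose.max() > 0 else 2
    axis = np.arange(n_bins) * bin_width_Gy
    volume = 100.0 * (dose[None, :] >= axis[:, None]).mean(axis=1)
    return DVHCurve(axis, volume, structure)


_V_GY = re.compile(r"^V_?([0-9.]+)\s*Gy$")
_V_PCT = re.compile(r"^V_?([0-9.]+)\s*%$")


def dose_metric(dose, metric: str, D_p: float | None = None) -> float:
    """Evaluate a named dose-volume metric on a structure's voxel doses.

    Supported names: ``D_mean``, ``D_max``, ``V_xGy`` (e.g. ``V_20Gy``)
    and ``V_x%`` (e.g. ``V_95%``, threshold ``x/100 * D_p``).
    """
    dose = np.asarray(dose, dtype=float)
    if dose.size == 0:
        raise ValueError("empty structure")
    if metric == "D_mean":
        return float(dose.mean())
    if metric == "D_max":
        return float(dose.max())
    m = _V_GY.match(metric)
    if m:
        return float(100.0 * (dose >= float(m.group(1))).mean())
    m = _V_PCT.match(metric)
    if m:
        if D_p is None:
            raise ValueError(f"metric {metric!r} requires the prescription dose D_p")
        return float(100.0 * (dose >= float(m.group(1)) / 100.0 * D_p).mean())
    raise ValueError(f"unknown metric name: {metric!r}")


def normalize_plan(plan, D_p: float | None = None):
    """Rescale a plan so the median PTV dose equals the prescription.

    One global factor multiplies both fluence and dose, preserving all
    dose ratios; the operation is idempotent.  For an even PTV voxel
    count the median is the midpoint of the two central order statistics.
    """
    D_p = D_p if D_p is not None else plan.prescription_Gy
    ptv = plan.structure_dose("PTV")
    med = float(np.median(ptv))
    if med <= 0:
        raise ValueError("cannot normalize: median PTV dose is zero")
    scale = D_p / med
    return dataclasses.replace(
        plan,
        fluence=plan.fluence * scale,
        dose=plan.dose * scale,
        normalized=True,
    )


@dataclass
class ConstraintRow:
    structure: str
    metric: str
    limit: float
    sense: str  # "<" or ">"
    achieved: float
    passed: bool


@dataclass
class ConstraintReport:
    rows: list[ConstraintRow] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rows)

    def to_json(self, path=None) -> str:
        payload = {
            "passed": self.passed,
            "rows": [dataclasses.asdict(r) for r in self.rows],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


#: (structure, metric, limit expressed in Gy / % or as a callable of D_p, sense)
CLINICAL_CONSTRAINTS = [
    ("PTV", "V_95%", lambda dp: 98.0, ">"),
    ("lungs", "V_5Gy", lambda dp: 65.0, "<"),
    ("lungs", "V_20Gy", lambda dp: 35.0, "<"),
    ("lungs", "D_mean", lambda dp: 20.0, "<"),
    ("heart", "V_30Gy", lambda dp: 40.0, "<"),
    ("esophagus", "D_mean", lambda dp: 34.0, "<"),
    ("spinal_canal", "D_max", lambda dp: 50.0, "<"),
    ("brachial_plexus", "D_max", lambda dp: 66.0, "<"),
    ("body", "D_max", lambda dp: 1.07 * dp, "<"),
]


def check_clinical_constraints(plan, phantom=None) -> ConstraintReport:
    """Audit a normalized plan against the clinical planning constraints.

    Optional structures (brachial plexus) are skipped with a log entry
    when absent.  ``plan`` must expose ``structure_dose(name)`` and a
    prescription; pass ``phantom`` to source the prescription from the
    phantom instead.
    """
    D_p = phantom.prescription_Gy if phantom is not None else plan.prescription_Gy
    report = ConstraintReport()
    for structure, metric, limit_fn, sense in CLINICAL_CONSTRAINTS:
        try:
            dose = plan.structure_dose(structure)
        except KeyError:
            logger.info("constraint audit: structure %r absent, skipped", structure)
            continue
        limit = float(limit_fn(D_p))
        achieved = dose_metric(dose, metric, D_p=D_p)
        passed = achieved < limit if sense == "<" else achieved > limit
        report.rows.append(
            ConstraintRow(structure, metric, limit, sense, achieved, bool(passed))
        )
    return report


# ---------------------------------------------------------------------------
# DVH CSV round-trip (columns: dose_Gy, volume_pct)

def save_dvh_csv(path, dvh: DVHCurve) -> None:
    pd.DataFrame({"dose_Gy": dvh.dose_Gy, "volume_pct": dvh.volume_pct}).to_csv(
        path, index=False
    )


def load_dvh_csv(path, structure: str = "") -> DVHCurve:
    df = pd.read_csv(path)
    for col in ("dose_Gy", "volume_pct"):
        if col not in df.columns:
            raise ValueError(f"DVH file {path} lacks required column {col!r}")
    return DVHCurve(df["dose_Gy"].to_numpy(), df["volume_pct"].to_numpy(), structure)
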