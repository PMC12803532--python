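"""Echocardiographic harmonization: Teichholz LVEF and cross-visit recalibration.

Baseline M-mode studies report linear LV dimensions; LVEF is derived with
the Teichholz cube-formula volumes.  Because the baseline and later visits
used different imaging eras, baseline LVEF and E/A are recalibrated onto
the later-visit measurement scale by aligning distribution moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, UsageError

__all__ = ["LinearMap", "teichholz_lvef", "fit_recalibration", "apply_recalibration"]


def teichholz_lvef(lvedd, lvesd):
    """LVEF (%) from end-diastolic / end-systolic dimensions (cm).

    Volume = 7.0 / (2.4 + D) * D^3 for each dimension; LVEF = 100 * (EDV - ESV) / EDV.
    Vectorized over array inputs.
    """
    lvedd = np.asarray(lvedd, dtype=float)
    lvesd = np.asarray(lvesd, dtype=float)
    if np.any(lvedd <= 0) or np.any(lvedd >= 10) or np.any(lvesd <= 0):
        raise UsageError("dimensions must satisfy 0 < lvesd < lvedd < 10 cm")
    if np.any(lvesd >= lvedd):
        raise UsageError("lvesd must be strictly smaller than lvedd")
    edv = 7.0 / (2.4 + lvedd) * lvedd**3
    esv = 7.0 / (2.4 + lvesd) * lvesd**3
    out = 100.0 * (edv - esv) / edv
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LinearMap:
    """Affine recalibration map v -> slope * v + intercept for one measure."""

    slope: float
    intercept: float
    measure: str = "lvef"

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise DataError("LinearMap.slope must be finite and nonzero")


def fit_recalibration(baseline_values, reference_mean: float,
                      reference_sd: float, measure: str = "lvef") -> LinearMap:
    """Affine map aligning the baseline distribution to reference moments.

    slope = reference_sd / baseline_sd, intercept = reference_mean - slope *
    baseline_mean.  Missing baseline values are ignored.
    """
    v = np.asarray(baseline_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise DataError("need at least 10 finite baseline values")
    base_sd = float(v.std(ddof=1))
    if base_sd == 0:
        raise DataError("baseline values have zero spread; recalibration is degenerate")
    if reference_sd <= 0:
        raise DataError("reference_sd must be > 0")
    slope = reference_sd / base_sd
    intercept = reference_mean - slope * float(v.mean())
    return LinearMap(slope=slope, intercept=intercept, measure=measure)


def apply_recalibration(map_: LinearMap, values):
    """Elementwise slope * v + intercept; NaN (missing) passes through."""
    v = np.asarray(values, dtype=float)
    out = map_.slope * v + map_.intercept
    return float(out) if out.ndim == 0 else out
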