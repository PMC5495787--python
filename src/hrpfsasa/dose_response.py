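"""Per-residue dose-response regression.

In multi-point FPOP footprinting the protein is oxidized at several radical
doses; the effective dose actually delivered is read out by an adenine
internal dosimeter as the drop in A260. A residue's oxidation fraction
varies linearly with effective dose, and the fitted slope is the residue's
apparent radical reactivity — the quantity everything downstream
normalizes. Replicates enter the regression as individual points.

Fits include an intercept by default; a through-origin fit and
inverse-variance weighting by replicate spread are available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DoseMeasurement:
    """One oxidation measurement at one effective radical dose (ΔA260)."""

    chain_id: str
    residue_seq: int
    residue_name: str
    dose: float
    oxidation: float
    replicate: int = 1

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if not 0 <= self.oxidation <= 1:
            raise ValueError("oxidation must be a fraction in [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


@dataclass(frozen=True)
class DoseResponseSlope:
    """Fitted reactivity: oxidation-fraction change per unit effective dose."""

    chain_id: str
    residue_seq: int
    residue_name: str
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n_points: int

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


class InsufficientDosesError(ValueError):
    """Fewer than three distinct dose levels: residue must be excluded."""


def effective_dose(a260_before: float, a260_after: float) -> float:
    """Effective radical dose as the adenine dosimeter response ΔA260.

    Radical reaction consumes adenine absorbance, so the reading must not
    increase; swapped inputs raise.
    """
    if a260_before < 0 or a260_after < 0:
        raise ValueError("absorbance readings must be >= 0")
    dose = a260_before - a260_after
    if dose < 0:
        raise ValueError(
            "dosimeter absorbance increased; before/after readings swapped?"
        )
    return dose


def fit_dose_response(
    points: list[DoseMeasurement],
    force_origin: bool = False,
    weighted: bool = False,
) -> DoseResponseSlope:
    """Ordinary least-squares line through (dose, oxidation) points.

    Requires ≥3 distinct dose levels (the multi-point design). With
    ``weighted`` replicate groups at each dose are weighted by their inverse
    variance (doses with fewer than 2 replicates or zero spread fall back to
    the median weight).
    """
    if not points:
        raise InsufficientDosesError("no measurements")
    keys = {p.residue_key for p in points}
    if len(keys) > 1:
        raise ValueError(f"measurements span multiple residues: {sorted(keys)}")
    x = np.array([p.dose for p in points], dtype=float)
    y = np.array([p.oxidation for p in points], dtype=float)
    distinct = np.unique(x)
    if len(distinct) < 3:
        raise InsufficientDosesError(
            f"only {len(distinct)} distinct dose(s); need >= 3"
        )
    n = len(x)
    if weighted:
        w = _replicate_weights(x, y)
        slope, intercept, slope_se = _wls(x, y, w, force_origin)
    elif force_origin:
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        intercept = 0.0
        resid = y - slope * x
        dof = max(n - 1, 1)
        slope_se = float(np.sqrt((resid @ resid) / dof / sxx))
    else:
        fit = stats.linregress(x, y)
        slope, intercept, slope_se = fit.slope, fit.intercept, fit.stderr
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    p0 = points[0]
    return DoseResponseSlope(
        p0.chain_id, p0.residue_seq, p0.residue_name,
        slope=float(slope), intercept=float(intercept),
        slope_se=float(slope_se), r_squared=r_squared, n_points=n,
    )


def _replicate_weights(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    variances = {}
    for dose in np.unique(x):
        grp = y[x == dose]
        variances[dose] = float(np.var(grp, ddof=1)) if len(grp) > 1 else np.nan
    finite = [v for v in variances.values() if np.isfinite(v) and v > 0]
    fallback = 1.0 / np.median(finite) if finite else 1.0
    for dose, var in variances.items():
        w[x == dose] = 1.0 / var if np.isfinite(var) and var > 0 else fallback
    return w


def _wls(x, y, w, force_origin):
    if force_origin:
        sxx = float(np.sum(w * x * x))
        slope = float(np.sum(w * x * y)) / sxx
        return slope, 0.0, float(np.sqrt(1.0 / sxx))
    sw = w.sum()
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = float(np.sum(w * (x - xm) ** 2))
    slope = float(np.sum(w * (x - xm) * (y - ym))) / sxx
    intercept = float(ym - slope * xm)
    return slope, intercept, float(np.sqrt(1.0 / sxx))


def filter_significant(
    slopes: list[DoseResponseSlope], z: float = 3.0
) -> list[DoseResponseSlope]:
    """Keep only slopes distinguishable from zero (slope > z · SE).

    Residues whose oxidation signal is below replicate noise produce
    meaningless slopes — and catastrophically unstable ratios when used as
    a denominator — so downstream normalization works from detectable
    signals only, as measured footprinting datasets inherently do.
    """
    return [s for s in slopes if s.slope > z * s.slope_se]


def fit_all_residues(
    measurements: list[DoseMeasurement],
    force_origin: bool = False,
    weighted: bool = False,
) -> tuple[list[DoseResponseSlope], list[tuple[tuple, str]]]:
    """Fit every residue present; returns (slopes, exclusion log).

    Residues failing the multi-point requirement are excluded with their
    reason logged rather than raising.
    """
    by_residue: dict[tuple, list[DoseMeasurement]] = {}
    for m in measurements:
        by_residue.setdefault(m.residue_key, []).append(m)
    slopes, excluded = [], []
    for key in sorted(by_residue):
        try:
            slopes.append(fit_dose_response(by_residue[key], force_origin, weighted))
        except InsufficientDosesError as exc:
            excluded.append((key, str(exc)))
    return slopes, excluded
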