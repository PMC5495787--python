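"""Empirical calibration: normalized reactivity → fractional ⟨SASA⟩.

A linear model is fitted by ordinary least squares to calibration points
(x = NPF or native:denatured slope ratio, y = fractional ⟨SASA⟩ or SASA
ratio) pooled over one or more training proteins. The fitted line converts
measured reactivity for a new protein into fractional exposure, and
multiplication by the Gly-X-Gly reference turns that into absolute ⟨SASA⟩
in Å². Model robustness is assessed with a leave-one-out jackknife, and
prediction quality against a known reference with Pearson r, RMSD (Å²) and
an R² computed against the identity line y = x — the convention for
predicted-vs-actual comparisons, where a refitted line would overstate
agreement.

Both axes carry experimental spread, but plain (unweighted) OLS is the
default; errors-in-variables fitting is deliberately not used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from hrpfsasa.gxg import GXGReference, shipped_gxg_reference


@dataclass(frozen=True)
class CalibrationPoint:
    """One residue's (normalized reactivity, fractional SASA) pair."""

    chain_id: str
    residue_seq: int
    residue_name: str
    x: float
    y: float
    x_sd: float = 0.0
    y_sd: float = 0.0
    protein_id: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("calibration point must be finite")
        if self.y < 0:
            raise ValueError("fractional SASA must be >= 0")

    @property
    def residue_key(self):
        return (self.chain_id, self.residue_seq, self.residue_name)


@dataclass
class CalibrationModel:
    """Fitted linear map x → fractional ⟨SASA⟩."""

    mode: str  # "npf" | "ratio"
    slope: float
    intercept: float
    pearson_r: float
    n: int
    training_proteins: frozenset = field(default_factory=frozenset)
    residue_filter: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "slope": self.slope,
                "intercept": self.intercept,
                "pearson_r": self.pearson_r,
                "n": self.n,
                "training_proteins": sorted(self.training_proteins),
                "residue_filter": self.residue_filter,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        doc = json.loads(text)
        return cls(
            mode=doc["mode"], slope=doc["slope"], intercept=doc["intercept"],
            pearson_r=doc["pearson_r"], n=doc["n"],
            training_proteins=frozenset(doc["training_proteins"]),
            residue_filter=doc.get("residue_filter", ""),
        )


@dataclass(frozen=True)
class PredictionResult:
    """Predicted exposure for one residue, fractional and absolute (Å²)."""

    chain_id: str
    residue_seq: int
    residue_name: str
    fractional_sasa: float
    absolute_sasa: float
    reference_sasa: float | None = None

    @property
    def residue_key(self):
        return (self.chain_id, self.residue_seq, self.residue_name)


def fit_calibration(points: list[CalibrationPoint], mode: str) -> CalibrationModel:
    """OLS fit of y on x over pooled calibration points."""
    if mode not in ("npf", "ratio"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: zero variance in x")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        mode=mode,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n=len(points),
        training_proteins=frozenset(p.protein_id for p in points if p.protein_id),
    )


def predict_sasa(
    model: CalibrationModel,
    x_new: float,
    residue: tuple[str, int, str],
    ref: GXGReference | None = None,
) -> PredictionResult:
    """Predict fractional and absolute ⟨SASA⟩ from a normalized reactivity.

    Negative fractional predictions are clipped to 0 with a warning;
    absolute ⟨SASA⟩ is fractional × the residue type's Gly-X-Gly value.
    """
    ref = ref if ref is not None else shipped_gxg_reference()
    chain, resseq, resname = residue
    if resname.upper() == "GLY":
        raise ValueError("glycine is unsupported: no side-chain reference")
    frac = model.slope * x_new + model.intercept
    if frac < 0:
        warnings.warn(
            f"negative predicted fractional SASA {frac:.3g} for "
            f"{residue}; clipped to 0"
        )
        frac = 0.0
    return PredictionResult(
        chain, resseq, resname,
        fractional_sasa=frac,
        absolute_sasa=frac * ref[resname],
    )


@dataclass
class JackknifeSummary:
    """Leave-one-out refits with their coefficient spread."""

    models: list[CalibrationModel]
    loo_predictions: list[float]  # prediction for each left-out point's x
    slope_range: tuple[float, float]
    intercept_range: tuple[float, float]


def jackknife(points: list[CalibrationPoint], mode: str) -> JackknifeSummary:
    """Leave-one-out jackknife over calibration points.

    Returns one refit per point (fitted without it) plus that model's
    prediction at the left-out x. Subsets degenerate in x are flagged with
    a NaN prediction rather than aborting the sweep.
    """
    if len(points) < 4:
        raise ValueError("jackknife needs at least 4 points")
    models, loo_pred = [], []
    for i in range(len(points)):
        subset = points[:i] + points[i + 1 :]
        try:
            m = fit_calibration(subset, mode)
        except ValueError as exc:
            warnings.warn(f"jackknife replicate {i} degenerate: {exc}")
            models.append(None)
            loo_pred.append(float("nan"))
            continue
        models.append(m)
        loo_pred.append(m.slope * points[i].x + m.intercept)
    fitted = [m for m in models if m is not None]
    slopes = [m.slope for m in fitted]
    intercepts = [m.intercept for m in fitted]
    return JackknifeSummary(
        models=models,
        loo_predictions=loo_pred,
        slope_range=(min(slopes), max(slopes)),
        intercept_range=(min(intercepts), max(intercepts)),
    )


def evaluate_predictions(predictions: list[PredictionResult]) -> dict[str, float]:
    """Score absolute-⟨SASA⟩ predictions against their references.

    Returns RMSD (Å²), Pearson r, and R² against the identity line
    (R² = 1 − Σ(pred − ref)² / Σ(ref − mean ref)²), which penalizes any
    systematic offset a refitted line would hide.
    """
    with_ref = [p for p in predictions if p.reference_sasa is not None]
    if len(with_ref) < 2:
        raise ValueError("need >= 2 predictions with reference values")
    pred = np.array([p.absolute_sasa for p in with_ref])
    ref = np.array([p.reference_sasa for p in with_ref])
    rmsd = float(np.sqrt(np.mean((pred - ref) ** 2)))
    ss_res = float(np.sum((pred - ref) ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2_identity = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    pearson = float(stats.pearsonr(pred, ref).statistic) if np.ptp(pred) > 0 else 1.0
    return {"rmsd": rmsd, "r_squared": r2_identity, "pearson_r": pearson,
            "n": len(with_ref)}
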