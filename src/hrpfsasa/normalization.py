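"""Reactivity normalization: protection factors, classes, ratios, filters.

The raw dose-response slope conflates solvent exposure with the intrinsic
chemistry of the side chain. Two normalizations disentangle them:

* **NPF** (normalized protection factor): slope divided by the residue
  type's free-amino-acid reactivity relative to proline (k/k_p). This
  works well for highly reactive residues but degrades for poorly reactive
  ones, whose apparent reactivity is dominated by sequence context.
* **Native:denatured ratio**: the slope measured in the native fold divided
  by the slope of the same residue in the fully denatured protein. Any
  residue-specific multiplicative context factor is common to numerator and
  denominator and cancels exactly. The matching structural quantity is
  ⟨SASA⟩_N / ⟨SASA⟩_D with the denatured ⟨SASA⟩ modeled by the Gly-X-Gly
  value (fully exposed).

Sulfur-containing residues (Met, Cys) are excluded by default: their
background and secondary oxidation inflate measured reactivity regardless
of exposure.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

from hrpfsasa.dose_response import DoseResponseSlope
from hrpfsasa.gxg import GXGReference, shipped_gxg_reference
from hrpfsasa.sasa import ResidueSASA

SULFUR_RESIDUES = frozenset({"MET", "CYS"})


class ReactivityTable:
    """Per-residue-type k/k_p values with reactivity-class thresholds."""

    def __init__(
        self,
        values: dict[str, float],
        high_min: float = 10.0,
        poor_max: float = 4.0,
        version: str = "custom",
    ):
        self.values = {k.upper(): float(v) for k, v in values.items()}
        for aa, v in self.values.items():
            if not v > 0:
                raise ValueError(f"k/k_p for {aa} must be > 0 (got {v})")
        if "PRO" in self.values and not abs(self.values["PRO"] - 1.0) < 1e-12:
            raise ValueError("k/k_p is defined relative to Pro; PRO must be 1")
        self.high_min = float(high_min)
        self.poor_max = float(poor_max)
        self.version = version

    def __getitem__(self, aa: str) -> float:
        aa = aa.upper()
        if aa not in self.values:
            raise KeyError(f"no k/k_p entry for residue {aa!r}")
        return self.values[aa]

    def __contains__(self, aa: str) -> bool:
        return aa.upper() in self.values

    @classmethod
    def from_yaml(cls, source) -> "ReactivityTable":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        th = doc.get("class_thresholds", {})
        return cls(
            doc["values"],
            high_min=th.get("high_min", 10.0),
            poor_max=th.get("poor_max", 4.0),
            version=doc.get("version", "unversioned"),
        )


_DEFAULT_TABLE: ReactivityTable | None = None


def default_reactivity_table() -> ReactivityTable:
    """The packaged k/k_p table (radiolysis-literature compilation)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = importlib.resources.files("hrpfsasa.data") / "kkp_reactivity.yaml"
        import io

        _DEFAULT_TABLE = ReactivityTable.from_yaml(io.StringIO(ref.read_text()))
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class NPFValue:
    """Normalized protection factor: slope ÷ (k/k_p), in slope units."""

    chain_id: str
    residue_seq: int
    residue_name: str
    npf: float

    @property
    def residue_key(self):
        return (self.chain_id, self.residue_seq, self.residue_name)


@dataclass(frozen=True)
class RatioObservation:
    """Native:denatured slope ratio paired with the matching SASA ratio."""

    chain_id: str
    residue_seq: int
    residue_name: str
    slope_ratio: float
    sasa_ratio: float
    usable: bool = True

    @property
    def residue_key(self):
        return (self.chain_id, self.residue_seq, self.residue_name)


def npf(slope: DoseResponseSlope, table: ReactivityTable | None = None) -> NPFValue:
    """Normalized protection factor of one residue (slope ÷ k/k_p)."""
    table = table if table is not None else default_reactivity_table()
    kkp = table[slope.residue_name]
    return NPFValue(
        slope.chain_id, slope.residue_seq, slope.residue_name,
        npf=slope.slope / kkp,
    )


def classify_reactivity(aa: str, table: ReactivityTable | None = None) -> str:
    """Reactivity class: ``high`` (k/k_p > 10), ``moderate`` (4–10) or
    ``poor`` (< 4); boundary values fall to the lower class (10 → moderate,
    4 → poor)."""
    table = table if table is not None else default_reactivity_table()
    kkp = table[aa]
    if kkp > table.high_min:
        return "high"
    if kkp > table.poor_max:
        return "moderate"
    return "poor"


def fractional_sasa(
    residue_sasa: ResidueSASA, ref: GXGReference | None = None
) -> float:
    """Fractional exposure: in-structure ⟨SASA⟩ ÷ Gly-X-Gly ⟨SASA⟩.

    Values slightly above 1 can occur (conformers more exposed than the
    reference sweep) and are allowed with a warning. Glycine has no
    side-chain reference and is an error.
    """
    ref = ref if ref is not None else shipped_gxg_reference()
    if residue_sasa.residue_name == "GLY":
        raise ValueError("glycine has no side-chain Gly-X-Gly reference")
    gxg = ref[residue_sasa.residue_name]
    frac = residue_sasa.mean_sasa / gxg
    if frac > 1:
        warnings.warn(
            f"fractional SASA {frac:.2f} > 1 for residue "
            f"{residue_sasa.residue_key}"
        )
    return frac


@dataclass
class ExclusionRules:
    """Residue filters applied before calibration.

    ``exclude_sulfur`` drops Met and Cys; ``min_kkp`` keeps only residues
    with k/k_p strictly above the threshold (the calibration models use
    k/k_p > 4); ``exclude_residues`` names explicit (chain, resseq) keys.
    """

    exclude_sulfur: bool = True
    min_kkp: float | None = None
    exclude_residues: frozenset = field(default_factory=frozenset)


def exclude_residues(
    data: pd.DataFrame,
    rules: ExclusionRules | None = None,
    table: ReactivityTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a residue-keyed table (columns chain, resseq, resname).

    Returns (filtered table, exclusion log) where the log records one row
    per dropped residue with the rule that removed it. With no rules the
    input passes through unchanged.
    """
    if rules is None:
        rules = ExclusionRules(exclude_sulfur=False)
    table = table if table is not None else default_reactivity_table()
    keep = []
    log_rows = []
    for idx, row in data.iterrows():
        resname = str(row["resname"]).upper()
        reason = None
        if rules.exclude_sulfur and resname in SULFUR_RESIDUES:
            reason = "sulfur-containing residue"
        elif rules.min_kkp is not None:
            kkp = table[resname]
            if not kkp > rules.min_kkp:
                reason = f"k/k_p {kkp} <= {rules.min_kkp}"
        if reason is None and (str(row["chain"]), int(row["resseq"])) in rules.exclude_residues:
            reason = "explicitly excluded"
        if reason is None:
            keep.append(idx)
        else:
            log_rows.append(
                {"chain": row["chain"], "resseq": row["resseq"],
                 "resname": resname, "reason": reason}
            )
    log = pd.DataFrame(log_rows, columns=["chain", "resseq", "resname", "reason"])
    return data.loc[keep].reset_index(drop=True), log


def native_denatured_ratio(
    native: DoseResponseSlope,
    denatured: DoseResponseSlope,
    sasa_native: ResidueSASA,
    ref: GXGReference | None = None,
    sasa_denatured: ResidueSASA | None = None,
) -> RatioObservation:
    """Slope_N/Slope_D paired with ⟨SASA⟩_N/⟨SASA⟩_D for one residue.

    The denatured ⟨SASA⟩ defaults to the Gly-X-Gly value (the fully
    denatured chain is modeled as fully exposed); a measured denatured
    ensemble value can be supplied instead. A nonpositive denatured slope
    makes the residue unusable (flagged, ratio NaN).
    """
    ref = ref if ref is not None else shipped_gxg_reference()
    if not (native.residue_key == denatured.residue_key == sasa_native.residue_key):
        raise ValueError("native/denatured/SASA inputs refer to different residues")
    denom_sasa = (
        sasa_denatured.mean_sasa if sasa_denatured is not None
        else ref[native.residue_name]
    )
    if denom_sasa <= 0:
        raise ValueError(f"denatured SASA must be > 0 for {native.residue_key}")
    if denatured.slope <= 0:
        warnings.warn(
            f"nonpositive denatured slope for {native.residue_key}; "
            "residue flagged unusable"
        )
        return RatioObservation(
            native.chain_id, native.residue_seq, native.residue_name,
            slope_ratio=float("nan"), sasa_ratio=float("nan"), usable=False,
        )
    return RatioObservation(
        native.chain_id, native.residue_seq, native.residue_name,
        slope_ratio=native.slope / denatured.slope,
        sasa_ratio=sasa_native.mean_sasa / denom_sasa,
    )
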