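"""Fully-exposed side-chain reference: Gly-X-Gly tripeptides.

Fractional solvent exposure divides a residue's in-structure side-chain
⟨SASA⟩ by the side-chain SASA of the same residue type X in an extended
Gly-X-Gly tripeptide, where the side chain is maximally solvent exposed.
The same reference models the fully denatured state in the
native:denatured ratio analysis.

The shipped table (``data/gxg_reference.csv``) is generated in-repo by
:func:`build_gxg_reference`: an extended backbone (φ = −120°, ψ = +120°,
ω = 180°) is built from standard internal coordinates, the side chain of X
is grafted from the chemical component dictionary's ideal residue geometry
(via biotite) by superposing its N/CA/C frame, and side-chain SASA is
averaged over a χ₁ rotamer sweep. Glycine, having no side-chain heavy
atom, is 0 by definition and excluded from normalization downstream.
"""

from __future__ import annotations

import importlib.resources
import io
from typing import Mapping

import numpy as np
import pandas as pd

from hrpfsasa.sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE_RADIUS,
    residue_sidechain_sasa,
)
from hrpfsasa.structure import AtomRecord, StructureModel, vdw_radius
from hrpfsasa.superpose import kabsch_fit

STANDARD_AA = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# extended-chain internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
PHI_EXTENDED, PSI_EXTENDED, OMEGA = -120.0, 120.0, 180.0


class GXGReference:
    """Map amino-acid 3-letter code → fully-exposed side-chain SASA (Å²)."""

    def __init__(self, values: Mapping[str, float]):
        vals = {k.upper(): float(v) for k, v in values.items()}
        missing = set(STANDARD_AA) - set(vals)
        if missing:
            raise ValueError(f"reference table missing residues: {sorted(missing)}")
        for aa, v in vals.items():
            if aa != "GLY" and not v > 0:
                raise ValueError(f"reference for {aa} must be > 0 (got {v})")
        self._values = vals

    def __getitem__(self, aa: str) -> float:
        aa = aa.upper()
        if aa not in self._values:
            raise KeyError(f"no Gly-X-Gly reference for residue {aa!r}")
        return self._values[aa]

    def __contains__(self, aa: str) -> bool:
        return aa.upper() in self._values

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    @classmethod
    def from_csv(cls, source) -> "GXGReference":
        df = pd.read_csv(source)
        return cls(dict(zip(df["resname"], df["sidechain_sasa_A2"])))

    def to_csv(self) -> str:
        buf = io.StringIO()
        pd.DataFrame(
            {"resname": list(self._values), "sidechain_sasa_A2": list(self._values.values())}
        ).to_csv(buf, index=False, float_format="%.3f")
        return buf.getvalue()


_SHIPPED: GXGReference | None = None


def shipped_gxg_reference() -> GXGReference:
    """The packaged reference table (lazily loaded, cached)."""
    global _SHIPPED
    if _SHIPPED is None:
        ref = importlib.resources.files("hrpfsasa.data") / "gxg_reference.csv"
        _SHIPPED = GXGReference.from_csv(io.StringIO(ref.read_text()))
    return _SHIPPED


def gxg_reference(aa: str, table: GXGReference | None = None) -> float:
    """Fully-exposed side-chain SASA (Å²) of residue type ``aa``."""
    table = table if table is not None else shipped_gxg_reference()
    return table[aa]


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Natural extension reference frame (NeRF) placement of atom D from
    A-B-C with D-C bond length, B-C-D angle and A-B-C-D dihedral (degrees)."""
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(dihedral), np.sin(angle) * np.sin(dihedral)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def extended_backbone(n_res: int, phi: float = PHI_EXTENDED, psi: float = PSI_EXTENDED):
    """Backbone N/CA/C/O coordinates of an n-residue extended chain.

    Returns a list of dicts ``{"N": xyz, "CA": xyz, "C": xyz, "O": xyz}``.
    """
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = res[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, OMEGA)
        c_next = _place_atom(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, r in enumerate(res):
        # carbonyl O anti to the next amide N (trans peptide plane)
        r["O"] = _place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi - 180.0)
    return res


def _ideal_sidechain(resname: str) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Heavy side-chain atoms of the CCD ideal residue plus its N/CA/C frame."""
    from biotite.structure.info import residue as ccd_residue

    arr = ccd_residue(resname)
    arr = arr[arr.element != "H"]
    frame = []
    for name in ("N", "CA", "C"):
        sel = arr.coord[arr.atom_name == name]
        if len(sel) != 1:
            raise ValueError(f"ideal residue {resname} lacks backbone atom {name}")
        frame.append(sel[0])
    backbone = {"N", "CA", "C", "O", "OXT"}
    mask = ~np.isin(arr.atom_name, list(backbone))
    names = list(arr.atom_name[mask])
    elements = list(arr.element[mask])
    return names, elements, arr.coord[mask].astype(float), np.array(frame, dtype=float)


def _rotate_about_axis(points, origin, axis, angle_deg):
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    k = axis
    p = points - origin
    rot = (
        p * np.cos(theta)
        + np.cross(k, p) * np.sin(theta)
        + np.outer(p @ k, k) * (1 - np.cos(theta))
    )
    return rot + origin


def build_gxg_model(
    resname: str, chi1: float = 0.0, radii: dict[str, float] | None = None
) -> StructureModel:
    """Extended Gly-X-Gly tripeptide with X's side chain at χ₁ offset ``chi1``."""
    resname = resname.upper()
    if resname not in STANDARD_AA:
        raise KeyError(f"nonstandard residue {resname!r}")
    bb = extended_backbone(3)
    atoms: list[AtomRecord] = []
    serial = 1
    roster = ["GLY", resname, "GLY"]
    for i, (rname, r) in enumerate(zip(roster, bb), start=1):
        for name in ("N", "CA", "C", "O"):
            el = name[0]
            atoms.append(
                AtomRecord(serial, name, el, rname, "A", i, r[name], vdw_radius(el, radii))
            )
            serial += 1
    if resname != "GLY":
        names, elements, coords, frame = _ideal_sidechain(resname)
        target = np.array([bb[1]["N"], bb[1]["CA"], bb[1]["C"]])
        rot, trans, _ = kabsch_fit(frame, target)
        coords = coords @ rot.T + trans
        if chi1 and "CB" in names and resname not in ("ALA", "PRO"):
            cb = coords[names.index("CB")]
            beyond = np.array([n != "CB" for n in names])
            if beyond.any():
                coords[beyond] = _rotate_about_axis(
                    coords[beyond], bb[1]["CA"], cb - bb[1]["CA"], chi1
                )
        for name, el, xyz in zip(names, elements, coords):
            atoms.append(
                AtomRecord(serial, name, el, resname, "A", 2, xyz, vdw_radius(el, radii))
            )
            serial += 1
    return StructureModel(f"GXG-{resname}", atoms)


def build_gxg_reference(
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    chi1_step: float = 60.0,
) -> GXGReference:
    """Regenerate the fully-exposed reference table for the 20 standard
    amino acids, averaging side-chain SASA over a χ₁ sweep."""
    values = {}
    for aa in STANDARD_AA:
        if aa == "GLY":
            values[aa] = 0.0
            continue
        chis = np.arange(0.0, 360.0, chi1_step) if aa not in ("ALA", "PRO") else [0.0]
        sasas = []
        for chi in chis:
            model = build_gxg_model(aa, chi1=chi)
            per_res = residue_sidechain_sasa(model, probe_radius, n_points)
            center = [r for r in per_res if r.residue_seq == 2]
            sasas.append(center[0].mean_sasa)
        values[aa] = float(np.mean(sasas))
    return GXGReference(values)
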