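"""Shrake–Rupley solvent accessible surface area.

Each atom is inflated by the probe radius (water, 1.4 Å by default) and
covered with a deterministic golden-spiral point set; the accessible area is
the exposed-point fraction times the inflated sphere area,

    SASA_i = (exposed_i / n_points) · 4π (r_i + r_probe)².

The point set is generated without any RNG, so results are bit-stable for a
fixed ``n_points``. Occlusion testing uses a KD-tree over inflated spheres;
a test point exactly tangent to a neighbouring sphere counts as exposed,
which makes coincident equal-radius atoms well-defined (each keeps its full
sphere rather than crashing or flickering with rounding).

Per-residue values are side-chain sums by default: every heavy atom except
the backbone set {N, CA, C, O, OXT}. Glycine has no side-chain heavy atom
and reports 0 (flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from hrpfsasa.structure import Ensemble, StructureModel

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class ResidueSASA:
    """Per-residue ⟨SASA⟩ (Å²) with its spread across ensemble models."""

    chain_id: str
    residue_seq: int
    residue_name: str
    mean_sasa: float
    sd_sasa: float = 0.0
    n_models: int = 1
    no_sidechain: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


@lru_cache(maxsize=8)
def unit_sphere_points(n_points: int) -> np.ndarray:
    """Deterministic golden-spiral (Fibonacci) covering of the unit sphere."""
    k = np.arange(n_points)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts.setflags(write=False)
    return pts

def shrake_rupley(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (Å²), in the order of ``model.atoms``."""
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    centers = model.coords()
    if not np.all(np.isfinite(centers)):
        raise ValueError("non-finite atom coordinates")
    inflated = model.radii() + probe_radius
    sphere = unit_sphere_points(n_points)
    tree = cKDTree(centers)
    rmax = inflated.max()
    out = np.empty(len(model.atoms))
    for i, (c, ri) in enumerate(zip(centers, inflated)):
        pts = c + ri * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(c, ri + rmax):
            if j == i:
                continue
            rj = inflated[j]
            d2 = np.einsum("ij,ij->i", pts - centers[j], pts - centers[j])
            # strict inequality: tangent points stay exposed
            exposed &= d2 >= rj * rj - 1e-9
            if not exposed.any():
                break
        out[i] = exposed.sum() / n_points * 4.0 * np.pi * ri * ri
    return out


def residue_sidechain_sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    mode: str = "sidechain",
) -> list[ResidueSASA]:
    """Per-residue SASA, side-chain atoms only (``mode="all"`` for whole residue).

    Residues with no side-chain heavy atoms (Gly) report 0 and are flagged
    ``no_sidechain``; a warning names any non-Gly residue in that state.
    """
    if mode not in ("sidechain", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    atom_sasa = shrake_rupley(model, probe_radius, n_points)
    totals: dict[tuple, float] = {}
    has_sc: dict[tuple, bool] = {}
    order: list[tuple] = []
    for atom, value in zip(model.atoms, atom_sasa):
        key = atom.residue_key
        if key not in totals:
            totals[key] = 0.0
            has_sc[key] = False
            order.append(key)
        counted = atom.is_sidechain if mode == "sidechain" else True
        if atom.is_sidechain:
            has_sc[key] = True
        if counted:
            totals[key] += value
    results = []
    for chain, resseq, resname in order:
        key = (chain, resseq, resname)
        flagged = not has_sc[key]
        if flagged and resname != "GLY":
            warnings.warn(f"residue {key} has no side-chain atoms; SASA set to 0")
        results.append(
            ResidueSASA(chain, resseq, resname,
                        mean_sasa=totals[key] if not (flagged and mode == "sidechain") else 0.0,
                        no_sidechain=flagged)
        )
    return results


def ensemble_mean_sasa(
    ensemble: Ensemble,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    mode: str = "sidechain",
) -> list[ResidueSASA]:
    """⟨SASA⟩ averaged over ensemble models (weighted if the ensemble carries
    weights), with the population SD across snapshots."""
    per_model = [
        residue_sidechain_sasa(m, probe_radius, n_points, mode)
        for m in ensemble.models
    ]
    n = len(ensemble.models)
    w = ensemble.weights if ensemble.weights is not None else np.full(n, 1.0 / n)
    results = []
    for idx, r0 in enumerate(per_model[0]):
        vals = np.array([per_model[m][idx].mean_sasa for m in range(n)])
        mean = float(np.dot(w, vals))
        # identical snapshots must give exactly zero spread
        var = 0.0 if np.ptp(vals) == 0 else float(np.dot(w, (vals - mean) ** 2))
        results.append(
            ResidueSASA(
                r0.chain_id, r0.residue_seq, r0.residue_name,
                mean_sasa=mean, sd_sasa=np.sqrt(max(var, 0.0)),
                n_models=n, no_sidechain=r0.no_sidechain,
            )
        )
    return results


def residue_sasa_to_tsv(residues: list[ResidueSASA]) -> str:
    """Serialize per-residue SASA as TSV (chain, resseq, resname, mean, sd, n)."""
    lines = ["chain\tresseq\tresname\tmean_sasa_A2\tsd_sasa_A2\tn_models"]
    for r in residues:
        lines.append(
            f"{r.chain_id}\t{r.residue_seq}\t{r.residue_name}\t"
            f"{r.mean_sasa:.4f}\t{r.sd_sasa:.4f}\t{r.n_models}"
        )
    return "\n".join(lines) + "\n"
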