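"""Least-squares rigid superposition (Kabsch) and RMSD.

Used both for backbone/all-atom RMSD between structural models and
internally for grafting template fragments onto constructed backbones.
"""

from __future__ import annotations

import numpy as np

from hrpfsasa.structure import BACKBONE_NAMES, StructureModel


def kabsch_fit(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation mapping ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with
    ``rotation @ x + translation`` the fitted map. Proper rotations only
    (reflections are excluded via the determinant correction).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise ValueError("need at least 3 paired atoms for superposition")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, trans, rmsd


def _select(model: StructureModel, selector: str) -> dict[tuple, np.ndarray]:
    atoms = {}
    for a in model.atoms:
        if selector == "backbone" and a.name not in BACKBONE_NAMES:
            continue
        atoms[(a.chain_id, a.residue_seq, a.name)] = a.coords
    return atoms


def kabsch_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    atom_selector: str = "backbone",
) -> float:
    """Optimal-superposition RMSD (Å) over matched atoms.

    ``atom_selector`` is ``"backbone"`` (N, CA, C, O, OXT) or ``"all"``
    (all heavy atoms). Atoms are paired by (chain, residue number, atom
    name); a mismatched selection — any atom present on one side only —
    is an error rather than a silent intersection.
    """
    if atom_selector not in ("backbone", "all"):
        raise ValueError(f"unknown atom selector {atom_selector!r}")
    sel_a = _select(model_a, atom_selector)
    sel_b = _select(model_b, atom_selector)
    if set(sel_a) != set(sel_b):
        only = set(sel_a).symmetric_difference(sel_b)
        raise ValueError(f"mismatched atom selections: {sorted(only)[:5]}")
    keys = sorted(sel_a)
    a = np.array([sel_a[k] for k in keys])
    b = np.array([sel_b[k] for k in keys])
    _, _, rmsd = kabsch_fit(a, b)
    return rmsd
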