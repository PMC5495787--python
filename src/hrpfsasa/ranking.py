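"""Scoring candidate structural models against a reference SASA vector.

The score is the per-residue root-mean-square deviation of SASA,

    RMSD_SASA = sqrt( Σ_n (SASA_current − SASA_ref)² / n ),

computed over the n residues present in both vectors. The reference can be
crystallographic, ensemble-averaged, or derived from footprinting
measurements; footprinting references carry only experimentally observed
residues and nothing is imputed for the rest. Candidate static structures
are scored from their single-conformer SASA.

Against a good reference, RMSD_SASA separates accurate models (backbone
RMSD < 3 Å from the true structure) from inaccurate ones (> 4 Å);
``discrimination_report`` checks that separation explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hrpfsasa.sasa import ResidueSASA, residue_sidechain_sasa
from hrpfsasa.structure import StructureModel


@dataclass
class SASAVector:
    """Ordered per-residue SASA values (Å²) with their provenance."""

    values: dict[tuple[str, int, str], float]
    source: str = "ensemble"  # crystal | ensemble | hrpf

    def __post_init__(self):
        for key, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative SASA for {key}")

    @classmethod
    def from_residue_sasa(
        cls, residues: list[ResidueSASA], source: str = "ensemble"
    ) -> "SASAVector":
        return cls({r.residue_key: r.mean_sasa for r in residues}, source)

    @classmethod
    def from_structure(
        cls,
        model: StructureModel,
        probe_radius: float = 1.4,
        n_points: int = 960,
        source: str = "crystal",
    ) -> "SASAVector":
        return cls.from_residue_sasa(
            residue_sidechain_sasa(model, probe_radius, n_points), source
        )

    def keys(self):
        return self.values.keys()


@dataclass(frozen=True)
class ModelScore:
    model_id: str
    rmsd_sasa: float
    n: int
    backbone_rmsd: float | None = None


def rmsd_sasa(
    current: SASAVector, ref: SASAVector, model_id: str = ""
) -> ModelScore:
    """RMSD between two SASA vectors over their common residues."""
    common = sorted(set(current.keys()) & set(ref.keys()))
    if not common:
        raise ValueError("no residues in common between model and reference")
    a = np.array([current.values[k] for k in common])
    b = np.array([ref.values[k] for k in common])
    value = float(np.sqrt(np.mean((a - b) ** 2)))
    return ModelScore(model_id, value, n=len(common))


def rank_models(
    candidates: list[tuple[str, StructureModel | SASAVector]],
    ref: SASAVector,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> list[ModelScore]:
    """Score candidates against the reference; ascending RMSD_SASA order.

    Structures are converted to single-conformer SASA vectors first. Ties
    are broken by model id; unscoreable candidates are skipped with a
    warning.
    """
    scores = []
    for model_id, cand in candidates:
        try:
            if isinstance(cand, StructureModel):
                vec = SASAVector.from_structure(cand, probe_radius, n_points)
            else:
                vec = cand
            scores.append(rmsd_sasa(vec, ref, model_id))
        except ValueError as exc:
            warnings.warn(f"skipping unscoreable candidate {model_id!r}: {exc}")
    return sorted(scores, key=lambda s: (s.rmsd_sasa, s.model_id))


def discrimination_report(
    scores: list[ModelScore],
    good_max: float = 3.0,
    bad_min: float = 4.0,
) -> dict:
    """Group scored models by backbone accuracy and test score separation.

    Models with backbone RMSD < ``good_max`` are "good", > ``bad_min`` are
    "bad", between is "indeterminate". ``separated`` is true when every bad
    model scores a strictly higher RMSD_SASA than every good model — i.e.
    the SASA score alone would never prefer a bad model to a good one.
    """
    if any(s.backbone_rmsd is None for s in scores):
        raise ValueError("all scores need a backbone_rmsd for discrimination")
    good = [s for s in scores if s.backbone_rmsd < good_max]
    bad = [s for s in scores if s.backbone_rmsd > bad_min]
    indeterminate = [
        s for s in scores if good_max <= s.backbone_rmsd <= bad_min
    ]
    if good and bad:
        separated = max(g.rmsd_sasa for g in good) < min(b.rmsd_sasa for b in bad)
    else:
        separated = True
    return {
        "good": good,
        "indeterminate": indeterminate,
        "bad": bad,
        "separated": separated,
    }


def scores_to_tsv(scores: list[ModelScore], good_max=3.0, bad_min=4.0) -> str:
    """Ranked TSV (model_id, rmsd_sasa_A2, n, backbone_rmsd_A, class)."""
    rows = []
    for s in scores:
        if s.backbone_rmsd is None:
            cls = ""
        elif s.backbone_rmsd < good_max:
            cls = "good"
        elif s.backbone_rmsd > bad_min:
            cls = "bad"
        else:
            cls = "indeterminate"
        rows.append(
            {
                "model_id": s.model_id,
                "rmsd_sasa_A2": round(s.rmsd_sasa, 4),
                "n": s.n,
                "backbone_rmsd_A": "" if s.backbone_rmsd is None else round(s.backbone_rmsd, 4),
                "class": cls,
            }
        )
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)
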