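"""Synthetic footprinting experiments with known ground truth.

The generator builds an idealized globular "protein" — a compact
self-avoiding Cα walk with radially attached side-chain pseudo-atoms whose
count scales with residue size — so that interior residues are genuinely
occluded and per-residue solvent exposure spans the full range. From the
structure it derives fractional-exposure ground truth and simulates
multi-point oxidation data under the generative law the analysis assumes:

    slope_i = c · (k/k_p)_i · fractional_SASA_i · context_i
    oxidation_i(dose) = slope_i · dose + ε,   ε ~ N(0, σ), clipped to [0, 1]

``context_i`` is a per-residue lognormal sequence-context factor whose
dispersion grows as intrinsic reactivity falls — poorly reactive residues
are the most context-sensitive. In the denatured simulation every residue
is fully exposed (fractional SASA 1) but keeps its context factor, so the
native:denatured slope ratio cancels context exactly.

Default conditions mirror a triplicate five-dose FPOP titration read out
by adenine dosimetry (doses on the ΔA260 scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from hrpfsasa.dose_response import DoseMeasurement
from hrpfsasa.gxg import GXGReference, STANDARD_AA
from hrpfsasa.normalization import ReactivityTable, default_reactivity_table
from hrpfsasa.sasa import ensemble_mean_sasa, residue_sidechain_sasa
from hrpfsasa.structure import AtomRecord, Ensemble, StructureModel, vdw_radius

# side-chain pseudo-atom count per residue type (coarse size proxy)
SIDECHAIN_SIZE = {
    "GLY": 0, "ALA": 1, "SER": 1, "CYS": 1, "THR": 1, "VAL": 2, "PRO": 2,
    "ASP": 2, "ASN": 2, "LEU": 2, "ILE": 2, "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 3, "HIS": 3, "PHE": 3, "ARG": 4, "TYR": 4, "TRP": 4,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic footprinting experiment."""

    seed: int = 0
    n_residues: int = 60
    sequence: list[str] | None = None
    slope_coefficient: float = 0.25  # oxidation per ΔA260 per (k/k_p · fSASA)
    context_sigma: dict = field(
        default_factory=lambda: {"high": 0.10, "moderate": 0.25, "poor": 0.60}
    )
    dose_grid: tuple = (0.01, 0.02, 0.03, 0.04, 0.05)
    n_replicates: int = 3
    noise_sd: float = 0.01
    n_snapshots: int = 8
    snapshot_jitter: float = 0.25  # Å
    n_perturbations: int = 20
    max_perturbation: float = 6.0  # Å displacement scale of the series end


def _random_sequence(rng: np.random.Generator, n: int) -> list[str]:
    # all standard types except Gly (no side chain to footprint)
    pool = [aa for aa in STANDARD_AA if aa != "GLY"]
    return [pool[i] for i in rng.integers(0, len(pool), size=n)]


def _compact_walk(rng: np.random.Generator, n: int, step: float = 3.8) -> np.ndarray:
    """Self-avoiding random walk biased toward its centroid (globule-like)."""
    coords = [np.zeros(3)]
    for _ in range(1, n):
        centroid = np.mean(coords, axis=0)
        for _attempt in range(200):
            direction = rng.normal(size=3)
            pull = centroid - coords[-1]
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                direction = direction + 0.6 * pull / norm * np.linalg.norm(direction)
            direction /= np.linalg.norm(direction)
            cand = coords[-1] + step * direction
            clashes = any(
                np.linalg.norm(cand - c) < 3.9 for c in coords[:-1]
            )
            if not clashes:
                break
        coords.append(cand)
    return np.array(coords)


def make_structures(
    config: SimulationConfig,
) -> tuple[StructureModel, list[tuple[float, StructureModel]], Ensemble]:
    """Native structure, perturbation series, and a native-like ensemble.

    The perturbation series applies one fixed random displacement field at
    growing magnitudes, giving strictly increasing backbone RMSD from the
    native model. The ensemble jitters the native coordinates to emulate
    snapshot-to-snapshot breathing.
    """
    rng = np.random.default_rng(config.seed)
    sequence = config.sequence or _random_sequence(rng, config.n_residues)
    ca = _compact_walk(rng, len(sequence))
    centroid = ca.mean(axis=0)
    atoms: list[AtomRecord] = []
    serial = 1
    rad_c = vdw_radius("C")
    for i, (aa, pos) in enumerate(zip(sequence, ca), start=1):
        atoms.append(AtomRecord(serial, "CA", "C", aa, "A", i, pos, rad_c))
        serial += 1
        out = pos - centroid
        norm = np.linalg.norm(out)
        direction = out / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        for k in range(SIDECHAIN_SIZE[aa]):
            xyz = pos + direction * 1.8 * (k + 1)
            atoms.append(
                AtomRecord(serial, f"SC{k + 1}", "C", aa, "A", i, xyz, rad_c)
            )
            serial += 1
    native = StructureModel("native", atoms)

    coords = native.coords()
    displacement = rng.normal(size=coords.shape)
    displacement /= np.sqrt(np.mean(np.sum(displacement**2, axis=1)))
    series = []
    magnitudes = np.linspace(
        config.max_perturbation / config.n_perturbations,
        config.max_perturbation,
        config.n_perturbations,
    )
    for j, mag in enumerate(magnitudes, start=1):
        moved = coords + mag * displacement
        model = StructureModel(
            f"perturb-{j:02d}",
            [replace(a, coords=c) for a, c in zip(native.atoms, moved)],
        )
        series.append((float(mag), model))

    snapshots = []
    for s in range(config.n_snapshots):
        jitter = rng.normal(scale=config.snapshot_jitter, size=coords.shape)
        snapshots.append(
            StructureModel(
                f"snap-{s + 1:02d}",
                [replace(a, coords=c) for a, c in zip(native.atoms, coords + jitter)],
            )
        )
    return native, series, Ensemble(snapshots)


def synthetic_exposure_reference(
    probe_radius: float = 1.4, n_points: int = 960
) -> GXGReference:
    """Fully-exposed side-chain SASA per residue type for the pseudo-atom
    geometry — the generator's analogue of the Gly-X-Gly table, computed
    from each residue type in isolation."""
    values = {}
    rad_c = vdw_radius("C")
    for aa in STANDARD_AA:
        if SIDECHAIN_SIZE[aa] == 0:
            values[aa] = 0.0
            continue
        atoms = [AtomRecord(1, "CA", "C", aa, "A", 1, np.zeros(3), rad_c)]
        for k in range(SIDECHAIN_SIZE[aa]):
            atoms.append(
                AtomRecord(
                    k + 2, f"SC{k + 1}", "C", aa, "A", 1,
                    np.array([1.8 * (k + 1), 0.0, 0.0]), rad_c,
                )
            )
        model = StructureModel(f"iso-{aa}", atoms)
        values[aa] = residue_sidechain_sasa(model, probe_radius, n_points)[0].mean_sasa
    return GXGReference(values)


def fractional_sasa_truth(
    structure_or_ensemble,
    reference: GXGReference,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, int, str], float]:
    """Ground-truth fractional exposure per residue (Gly omitted)."""
    if isinstance(structure_or_ensemble, Ensemble):
        residues = ensemble_mean_sasa(structure_or_ensemble, probe_radius, n_points)
    else:
        residues = residue_sidechain_sasa(structure_or_ensemble, probe_radius, n_points)
    truth = {}
    for r in residues:
        if r.residue_name == "GLY":
            continue
        truth[r.residue_key] = r.mean_sasa / reference[r.residue_name]
    return truth


def draw_context_factors(
    config: SimulationConfig,
    residue_keys: list[tuple[str, int, str]],
    table: ReactivityTable | None = None,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, int, str], float]:
    """Per-residue lognormal sequence-context factors, class-dependent
    dispersion (poor > moderate > high)."""
    from hrpfsasa.normalization import classify_reactivity

    table = table if table is not None else default_reactivity_table()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    factors = {}
    for key in residue_keys:
        sigma = config.context_sigma[classify_reactivity(key[2], table)]
        factors[key] = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
    return factors


def true_slopes(
    config: SimulationConfig,
    fsasa: dict[tuple[str, int, str], float],
    context: dict[tuple[str, int, str], float],
    denatured: bool = False,
    table: ReactivityTable | None = None,
) -> dict[tuple[str, int, str], float]:
    """Ground-truth dose-response slopes under the generative law."""
    table = table if table is not None else default_reactivity_table()
    out = {}
    for key, f in fsasa.items():
        exposure = 1.0 if denatured else f
        out[key] = config.slope_coefficient * table[key[2]] * exposure * context[key]
    return out


def simulate_hrpf(
    config: SimulationConfig,
    slopes: dict[tuple[str, int, str], float],
    rng: np.random.Generator | None = None,
) -> list[DoseMeasurement]:
    """Multi-point oxidation measurements for given ground-truth slopes.

    Oxidation is linear in dose with Gaussian replicate noise, clipped to
    [0, 1]; no intercept term (zero dose gives zero expected oxidation).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    measurements = []
    for key in sorted(slopes):
        chain, resseq, resname = key
        for dose in config.dose_grid:
            for rep in range(1, config.n_replicates + 1):
                ox = slopes[key] * dose
                if config.noise_sd > 0:
                    ox += rng.normal(0.0, config.noise_sd)
                ox = min(max(ox, 0.0), 1.0)
                measurements.append(
                    DoseMeasurement(chain, resseq, resname, dose, ox, rep)
                )
    return measurements


@dataclass
class SimulatedExperiment:
    """Everything one desk-scale experiment produces, truth included."""

    config: SimulationConfig
    native: StructureModel
    perturbation_series: list[tuple[float, StructureModel]]
    ensemble: Ensemble
    reference: GXGReference
    fsasa_truth: dict
    context: dict
    slopes_native: dict
    slopes_denatured: dict
    native_measurements: list[DoseMeasurement]
    denatured_measurements: list[DoseMeasurement]


def simulate_experiment(
    config: SimulationConfig,
    probe_radius: float = 1.4,
    n_points: int = 960,
    table: ReactivityTable | None = None,
) -> SimulatedExperiment:
    """Full generative run: structure → exposure truth → native and
    denatured multi-point measurements, all from one seeded generator."""
    table = table if table is not None else default_reactivity_table()
    native, series, ensemble = make_structures(config)
    reference = synthetic_exposure_reference(probe_radius, n_points)
    fsasa = fractional_sasa_truth(native, reference, probe_radius, n_points)
    rng = np.random.default_rng((config.seed, 0xC0FFEE))
    context = draw_context_factors(config, sorted(fsasa), table, rng)
    s_nat = true_slopes(config, fsasa, context, denatured=False, table=table)
    s_den = true_slopes(config, fsasa, context, denatured=True, table=table)
    return SimulatedExperiment(
        config=config,
        native=native,
        perturbation_series=series,
        ensemble=ensemble,
        reference=reference,
        fsasa_truth=fsasa,
        context=context,
        slopes_native=s_nat,
        slopes_denatured=s_den,
        native_measurements=simulate_hrpf(config, s_nat, rng),
        denatured_measurements=simulate_hrpf(config, s_den, rng),
    )
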