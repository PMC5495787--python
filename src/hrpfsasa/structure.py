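"""Protein structures as flat atom lists.

Structures are held as ordered lists of :class:`AtomRecord` — the minimal
substrate for solvent-accessibility calculations and superposition. PDB
input honours MODEL/ENDMDL blocks (each becomes one :class:`StructureModel`),
alternate locations (highest occupancy kept, ties broken by altloc letter)
and occupancy columns; hydrogens are dropped and HETATM records are ignored
unless explicitly retained (e.g. a heme group).

Van der Waals radii follow the NACCESS convention (Chothia-style united-atom
values for heavy elements); the set ships as editable YAML config.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_DEFAULT_RADII: dict[str, float] | None = None


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input; carries the line number."""


def load_vdw_radii(path=None) -> dict[str, float]:
    """Load the element → van der Waals radius map (Å).

    With no ``path`` the packaged NACCESS-compatible set is used and cached.
    The map carries a ``"*"`` entry: the default radius applied (with a
    warning) to elements not otherwise listed.
    """
    global _DEFAULT_RADII
    if path is None:
        if _DEFAULT_RADII is None:
            ref = importlib.resources.files("hrpfsasa.data") / "vdw_radii.yaml"
            _DEFAULT_RADII = yaml.safe_load(ref.read_text())
        return _DEFAULT_RADII
    with open(path) as fh:
        return yaml.safe_load(fh)


def vdw_radius(element: str, radii: dict[str, float] | None = None) -> float:
    radii = radii if radii is not None else load_vdw_radii()
    el = element.upper()
    if el in radii:
        return float(radii[el])
    warnings.warn(
        f"no van der Waals radius for element {element!r}; "
        f"using default {radii['*']} Å"
    )
    return float(radii["*"])


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: identity, coordinates (Å) and vdW radius (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    vdw_radius: float

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_NAMES and self.element.upper() != "H"

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


@dataclass
class StructureModel:
    """A single conformer (one snapshot, crystal structure or candidate model)."""

    model_id: str
    atoms: list[AtomRecord]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"model {self.model_id!r} has no atoms")
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_seq, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in model {self.model_id!r}")
            seen.add(key)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def residue_keys(self) -> list[tuple[str, int, str]]:
        keys, seen = [], set()
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                keys.append(a.residue_key)
        return keys

    def translated(self, shift) -> "StructureModel":
        shift = np.asarray(shift, dtype=float)
        return StructureModel(
            self.model_id,
            [replace(a, coords=a.coords + shift) for a in self.atoms],
        )

    def transformed(self, rotation, shift=(0.0, 0.0, 0.0)) -> "StructureModel":
        rotation = np.asarray(rotation, dtype=float)
        shift = np.asarray(shift, dtype=float)
        return StructureModel(
            self.model_id,
            [replace(a, coords=rotation @ a.coords + shift) for a in self.atoms],
        )


@dataclass
class Ensemble:
    """A set of conformers sharing one residue roster (e.g. MD snapshots).

    ``weights``, if given, are nonnegative and sum to 1; the default is a
    uniform average, matching plain snapshot averaging over a trajectory.
    """

    models: list[StructureModel]
    weights: np.ndarray | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble needs at least one model")
        roster = self.models[0].residue_keys()
        for m in self.models[1:]:
            other = m.residue_keys()
            if other != roster:
                offending = set(other).symmetric_difference(roster)
                raise ValueError(
                    f"residue roster mismatch in model {m.model_id!r}: "
                    f"{sorted(offending)[:5]}"
                )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.models),) or np.any(w < 0):
                raise ValueError("weights must be nonnegative, one per model")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must sum to 1")
            self.weights = w


def _parse_atom_line(line: str, lineno: int, radii) -> tuple[AtomRecord, str, float]:
    """Parse one ATOM/HETATM line → (record, altloc, occupancy)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if not element:
        # Fall back on the atom-name convention: first alphabetic character,
        # honouring the column-13 rule for 4-character names.
        stripped = name.lstrip("0123456789")
        element = stripped[:1] or "X"
    record = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        chain_id=chain,
        residue_seq=resseq,
        coords=np.array([x, y, z]),
        vdw_radius=vdw_radius(element, radii),
    )
    return record, altloc, occupancy


def parse_pdb(
    text: str,
    hetatm_retain: tuple[str, ...] = (),
    radii: dict[str, float] | None = None,
) -> list[StructureModel]:
    """Parse PDB-format text into one :class:`StructureModel` per MODEL block.

    Hydrogens are dropped; HETATM residues are ignored unless their residue
    name appears in ``hetatm_retain`` (e.g. ``("HEM",)``). For alternate
    locations only the highest-occupancy conformer is kept, ties broken by
    altloc letter order. Raises :class:`PDBParseError` on empty input or a
    malformed ATOM line (with its line number).
    """
    models: list[StructureModel] = []
    # (chain, resseq, name) -> (occupancy, altloc, record)
    current: dict[tuple, tuple[float, str, AtomRecord]] = {}
    current_id = "1"
    in_model = False

    def flush():
        nonlocal current
        if current:
            atoms = [rec for _, _, rec in current.values()]
            models.append(StructureModel(current_id, atoms))
        current = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        tag = line[:6]
        if tag.startswith("MODEL"):
            flush()
            in_model = True
            serial = line[6:].strip()
            current_id = serial or str(len(models) + 1)
        elif tag.startswith("ENDMDL"):
            flush()
            in_model = False
        elif tag in ("ATOM  ", "HETATM"):
            if tag == "HETATM" and line[17:20].strip() not in hetatm_retain:
                continue
            record, altloc, occupancy = _parse_atom_line(line, lineno, radii)
            if record.element.upper() == "H":
                continue
            key = (record.chain_id, record.residue_seq, record.residue_name,
                   record.name)
            if key in current:
                prev_occ, prev_alt, _ = current[key]
                # higher occupancy wins; on a tie the earlier altloc letter
                if (-occupancy, altloc) < (-prev_occ, prev_alt):
                    current[key] = (occupancy, altloc, record)
            else:
                current[key] = (occupancy, altloc, record)
    if not in_model:
        flush()
    if not models:
        raise PDBParseError("no ATOM records found in input")
    return models


def write_pdb(models: list[StructureModel] | StructureModel) -> str:
    """Serialize models to PDB text (MODEL/ENDMDL blocks when more than one)."""
    if isinstance(models, StructureModel):
        models = [models]
    lines = []
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for a in model.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id:1s}{a.residue_seq:4d}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
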