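"""Oxidation quantification from integrated MS intensities.

Peptide-level oxidation is the intensity fraction carried by oxidized
species (any number of +16 additions). Residue-level oxidation is
apportioned from ETD c/z fragment-ion intensities: the oxidized fraction of
each fragment grows as the fragment sweeps past oxidized residues, so the
difference between consecutive bracketing cleavages localizes oxidation to
the residues in between. Fractions are rescaled so residue-level values sum
to the peptide-level fraction; residues not bracketed by observed fragments
are reported as an unresolved range, never guessed.

The exact residue-level formula used in practice varies between groups;
this module isolates the apportionment rule behind one function so an
alternative scheme can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class SpeciesIntensity:
    """Integrated intensity of one oxidation state of a peptide."""

    peptide_id: str
    oxidation_state: int
    intensity: float

    def __post_init__(self):
        if self.oxidation_state < 0:
            raise ValueError("oxidation_state must be >= 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class FragmentIon:
    """One c- or z-series fragment with unoxidized/oxidized intensities.

    ``position`` is the cleavage index: a c-ion at position *i* covers
    residues 1..i from the N-terminus; a z-ion at position *i* covers the
    C-terminal *i* residues.
    """

    peptide_id: str
    ion_series: str
    position: int
    unoxidized_intensity: float
    oxidized_intensity: float

    def __post_init__(self):
        if self.ion_series not in ("c", "z"):
            raise ValueError("ion_series must be 'c' or 'z'")
        if self.unoxidized_intensity < 0 or self.oxidized_intensity < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class ResidueApportionment:
    """Oxidation fraction assigned to residues ``start``..``end`` (1-based,
    inclusive). ``resolved`` is true when the range is a single residue."""

    start: int
    end: int
    fraction: float

    @property
    def resolved(self) -> bool:
        return self.start == self.end


def peptide_oxidation_fraction(species: list[SpeciesIntensity]) -> float:
    """Σ intensity(oxidation state ≥ 1) / Σ intensity(all states)."""
    if not species:
        raise ValueError("no species intensities given")
    total = sum(s.intensity for s in species)
    if total == 0:
        raise ValueError("all species intensities are zero")
    oxidized = sum(s.intensity for s in species if s.oxidation_state >= 1)
    return oxidized / total


def residue_oxidation_fraction(
    peptide_fraction: float,
    fragments: list[FragmentIon],
    peptide_length: int,
) -> list[ResidueApportionment]:
    """Apportion a peptide's oxidation fraction over its residues.

    Cumulative oxidized fractions f(pos) = ox/(ox+unox) at each observed
    cleavage bound the oxidation N-terminal of that cleavage; consecutive
    differences are assigned to the residue span between cleavages, clipped
    at zero (with a warning) and rescaled to sum to ``peptide_fraction``.
    z-series positions are converted to N-terminal cleavage indices. With no
    informative fragments the whole peptide is one unresolved range.
    """
    if not 0 <= peptide_fraction <= 1:
        raise ValueError("peptide_fraction must be in [0, 1]")
    cleavage_f: dict[int, list[float]] = {}
    for frag in fragments:
        pos = frag.position if frag.ion_series == "c" else peptide_length - frag.position
        if not 0 < pos < peptide_length:
            raise ValueError(f"fragment position {frag.position} outside peptide")
        denom = frag.unoxidized_intensity + frag.oxidized_intensity
        if denom == 0:
            continue
        f = frag.oxidized_intensity / denom
        if frag.ion_series == "z":
            # z-ion carries oxidation C-terminal of the cleavage; the
            # cumulative N-terminal fraction is its complement
            f = 1.0 - f
        cleavage_f.setdefault(pos, []).append(f)

    # cleavage 0 (the intact N-terminus) anchors f at 0; the full peptide
    # anchors f at 1, so the terminal segment absorbs unlocalized oxidation
    bounds = [(0, 0.0)] + [(p, sum(v) / len(v)) for p, v in sorted(cleavage_f.items())] + [
        (peptide_length, 1.0)
    ]
    segments: list[ResidueApportionment] = []
    raw = []
    for (p0, f0), (p1, f1) in zip(bounds, bounds[1:]):
        delta = f1 - f0
        if delta < 0:
            warnings.warn(
                f"negative oxidation difference {delta:.3g} across cleavages "
                f"{p0}-{p1}; clipped to 0"
            )
            delta = 0.0
        raw.append((p0 + 1, p1, delta))
    total = sum(d for _, _, d in raw)
    for start, end, delta in raw:
        frac = peptide_fraction * (delta / total) if total > 0 else 0.0
        segments.append(ResidueApportionment(start, end, frac))
    return segments


def read_species_csv(source) -> dict[str, list[SpeciesIntensity]]:
    """Read a species-intensity CSV (peptide_id, ox_state, intensity)."""
    df = pd.read_csv(source)
    out: dict[str, list[SpeciesIntensity]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.peptide_id), []).append(
            SpeciesIntensity(str(row.peptide_id), int(row.ox_state), float(row.intensity))
        )
    return out


def read_fragment_csv(source) -> dict[str, list[FragmentIon]]:
    """Read a fragment-ion CSV (peptide_id, series, position, unox, ox)."""
    df = pd.read_csv(source)
    out: dict[str, list[FragmentIon]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.peptide_id), []).append(
            FragmentIon(
                str(row.peptide_id), str(row.series), int(row.position),
                float(row.unox), float(row.ox),
            )
        )
    return out
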