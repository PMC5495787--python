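# Methods

This note documents the models, conventions and numerical choices behind
`hrpfsasa`, and what the synthetic-data results do and do not demonstrate.

## Solvent accessible surface area

Per-atom SASA is computed by the Shrake–Rupley rolling-probe construction:
each heavy atom's van der Waals sphere is inflated by the probe radius
(default 1.4 Å, water) and covered with `n_points` test points (default
960); the accessible area is the exposed fraction times 4π(r + r_p)². Test
points are generated on a golden-spiral (Fibonacci) lattice with no random
number generator, so results are bit-stable across runs and platforms. A
point exactly tangent to a neighbouring sphere counts as exposed; this
makes the degenerate case of coincident equal-radius atoms well-defined.
Occlusion candidates are found with a KD-tree; the cost is linear in atom
count for globular geometry. At 960 points the isolated-atom error is
< 0.05% and the two-sphere overlap error against the analytic
spherical-cap formula is < 0.5% (both are recomputed by the test suite
and the acceptance script).

Radii follow the NACCESS united-atom convention (C 1.87, N 1.65, O 1.40,
S 1.85 Å…), shipped as editable YAML; unknown elements fall back to 1.80 Å
with a warning. Hydrogens are dropped at parse time, consistent with the
united-atom radii.

Per-residue values sum side-chain atoms only (all heavy atoms except
N, CA, C, O, OXT); glycine reports 0 and is flagged. A `mode="all"` flag
gives whole-residue values; side-chain-only is the default because the
footprinting chemistry probes side chains. Ensemble ⟨SASA⟩ is the
(optionally weighted) mean over snapshots with the **population** SD — the
spread descriptor of a fixed snapshot set, not an inferential estimate.

## The Gly-X-Gly reference

Fractional exposure and the denatured-state model both need the side-chain
SASA of each residue type when fully exposed. The shipped table
(`data/gxg_reference.csv`) is generated in-repo, so it is exactly
reproducible: an extended backbone (φ = −120°, ψ = +120°, ω = 180°) is
built from standard internal coordinates (N–CA 1.458, CA–C 1.525,
C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°), residue X's
side chain is grafted from the chemical component dictionary's ideal
coordinates (bundled with biotite) by superposing its N/CA/C frame, and
side-chain SASA is averaged over a χ₁ sweep in 60° steps (single conformer
for Ala/Pro). Clashing rotamers are not filtered; the sweep average is the
definition. Values range from 66 Å² (Ala) to 219 Å² (Trp). Termini carry
no OXT or charged caps — the reference is a neutral-backbone idealization.
A regeneration test confirms the shipped table is reproducible to within
the point-count discretization.

## Oxidation quantification

Peptide-level oxidation is Σ intensity(≥1 oxygen) / Σ intensity(all
states). Residue-level apportionment uses ETD c/z fragment ions: the
oxidized fraction f = ox/(ox+unox) of fragments is cumulative in the
covered residues, so the difference of f across consecutive observed
cleavages localizes oxidation to the residues between them. The intact
N-terminus anchors f at 0 and the whole peptide at 1, so unlocalized
oxidation accumulates in the terminal segment; negative differences
(fragment noise) are clipped to zero with a warning and the remainder
rescaled so residue fractions sum to the peptide fraction. Residues not
bracketed by observed fragments are reported as an aggregated range,
never guessed. Exact residue-level formulas vary between laboratories;
this rule is deliberately isolated behind one function so an alternative
can be swapped in.

## Dose response

Effective radical dose is the adenine dosimeter response ΔA260 (an
increase is rejected as swapped inputs). Each residue's oxidation fraction
is regressed on dose by unweighted OLS with an intercept; at least three
distinct doses are required, and replicates enter as individual points.
Slope, intercept, slope SE, and r² are reported. A through-origin fit and
inverse-variance replicate weighting exist behind flags; they are not the
default because standard multi-point designs neither force the origin nor
establish a reliable per-dose variance from triplicates. No conversion
from ΔA260 to molar radical concentration is attempted — the dose axis is
the dosimeter response itself, which is all the normalizations need.

`filter_significant` (keep slope > 3·SE, default z = 3) drops residues
whose signal is indistinguishable from replicate noise. It matters chiefly
for the ratio branch: a noise-level denatured slope in the denominator
produces arbitrarily wild ratios. Measured footprinting datasets contain
only residues with quantifiable oxidation, so this filter is part of
emulating real inputs, not an afterthought.

## Normalization

* **NPF** = slope ÷ (k/k_p). The k/k_p table (free-amino-acid hydroxyl
  radical rate constants relative to proline) is data, not code: it ships
  as versioned YAML compiled from the standard aqueous radiolysis
  rate-constant compilation, and any analysis is conditional on the table
  version recorded in its provenance log. Class thresholds: high k/k_p >
  10, moderate 4–10, poor < 4; boundary values fall to the lower class
  (strict inequalities).
* **Native:denatured ratio** = Slope_N/Slope_D, paired with
  ⟨SASA⟩_N/⟨SASA⟩_D where the denatured ⟨SASA⟩ defaults to the Gly-X-Gly
  value (a fully exposed chain); a measured denatured ensemble may be
  supplied instead. Because any residue-specific multiplicative context
  factor is common to both slopes, the ratio cancels it exactly — the
  formal version of the sequence-context argument, and an invariant the
  test suite exercises end-to-end.
* Sulfur-containing residues (Met, Cys) are excluded by default rule;
  optional k/k_p and explicit-key filters are available. Every exclusion
  is logged with its reason.

## Calibration and prediction

Calibration is plain OLS of fractional ⟨SASA⟩ (y) on normalized
reactivity (x), pooling points across training proteins. Although both
axes carry experimental spread, errors-in-variables fitting is
deliberately not used — the regression direction matches the prediction
task (reactivity in, exposure out), and the direction is configurable for
sensitivity analyses. Robustness is assessed by leave-one-out jackknife
(each refit's prediction at its left-out point matches a brute-force refit
loop exactly, by construction and by test). Predictions clip negative
fractional exposure to zero with a warning; absolute ⟨SASA⟩ is fractional
× the Gly-X-Gly value, so glycine is unsupported. Prediction quality uses
RMSD in Å² and R² against the identity line y = x (not a refitted line,
which would hide systematic offsets); Pearson r is reported alongside.

## Model scoring

RMSD_SASA compares per-residue SASA vectors over the intersection of
their residue keys, with n counting only compared residues. References
derived from footprinting carry only experimentally detected residues;
nothing is imputed for the rest, because imputation from the candidate
model would fabricate agreement. Candidate static structures are scored
from single-conformer SASA. The discrimination report classes models by
backbone Kabsch RMSD to the true structure (good < 3 Å, bad > 4 Å,
indeterminate between) and flags whether every bad model scores strictly
above every good one.

Kabsch superposition uses the SVD solution restricted to proper rotations;
backbone selection is {N, CA, C, OXT, O}, atoms paired by (chain, residue
number, name), with mismatched selections an error rather than a silent
intersection.

## The synthetic-data generator

`simulate` builds an idealized globular protein: a compact self-avoiding
Cα walk (3.8 Å steps, centroid-biased, ≥ 3.9 Å non-neighbour separation)
with 1–4 side-chain pseudo-atoms per residue, count scaling with residue
size, pointing radially outward. Interior residues are genuinely occluded,
so ground-truth fractional exposure (in-structure side-chain SASA divided
by the isolated-residue value, the generator's Gly-X-Gly analogue) spans
the full range. Measurements follow

    slope_i = c · (k/k_p)_i · fSASA_i · γ_i,
    oxidation(dose) = slope_i · dose + N(0, σ), clipped to [0, 1]

with γ_i a per-residue lognormal sequence-context factor whose log-SD is
largest for poorly reactive residues (0.60 / 0.25 / 0.10 for poor /
moderate / high), expressing that context dominates where intrinsic
reactivity is weak; the magnitudes are free simulator parameters. The
denatured simulation sets fSASA = 1 and keeps γ_i, so the ratio branch
cancels it. Default study conditions: 5 doses (ΔA260 0.01–0.05),
triplicate, replicate noise σ = 0.01, c = 0.25 — a titration whose most
reactive exposed residues reach tens of percent oxidation while weakly
reactive ones sit near the noise floor, as in real experiments. One seeded
generator threads through every stochastic draw; a fixed seed gives
byte-identical outputs.

What the generator does **not** emulate: real side-chain geometry and
rotamers, secondary structure, correlated conformational breathing,
multiple oxidation states and product branching, background oxidation of
sulfur residues, peptide-level digestion coverage, or dose-dependent
unfolding. Passing tests therefore demonstrate the correctness and
statistical behaviour of the analysis pipeline under its own model
assumptions — linear dose response, multiplicative context, exposure
proportionality — not instrument-level realism.

## Problem sizes and determinism

Desk-scale defaults keep every check fast: synthetic proteins of 30–60
residues, 960-point spheres, 20-structure perturbation series, 200-replicate
recovery sweeps. All stochastic tests are seeded; hypothesis-based property
tests run derandomized. The acceptance script derives every sub-seed from
its `--seed` argument.

## Known limitations

* The Gly-X-Gly table depends on the radius set and the χ₁-sweep
  convention; swapping radius sets rescales fractional exposures.
* The k/k_p table is a literature compilation; conclusions sensitive to
  individual entries are table-conditional.
* Residue-level ETD apportionment assumes single-oxidation statistics
  dominate fragment intensities.
* The ratio branch needs a measurable denatured-state slope; residues
  below the noise floor in the denatured state are unusable there.
* No mmCIF input; no errors-in-variables calibration; no nonlinear
  (depletion) dose-response kinetics.
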