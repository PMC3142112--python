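# Methods

This note documents the models and procedures implemented in `noeturn`, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Scope and design position

The package covers the computational path of a peptide NMR structure
analysis: assignment tables → secondary shifts; NOESY crosspeaks → turn
hypotheses and distance restraints; restrained refinement of capped
fragments → small ensembles; geometric turn typing.  It deliberately does
**not** reimplement explicit-solvent molecular dynamics.  The refinement
engine is a self-contained torsion-space sampler with a simple implicit
internal energy; its purpose is to express the restraint protocol (the
flat-bottom potential, time-averaged distances, the annealed
five-snapshot ensemble procedure) on desk-scale hardware, not to reproduce
a solvated force field.  This is the package's largest deliberate
simplification and everything downstream should be read in that light.

## Shift analysis

Input tables use the wide dialect common in peptide papers: one row per
residue, columns `NH / αH / βH / Others`, Greek-letter labels, multi-valued
cells ("1.554, 1.662" → HB1/HB2), and occasional typesetting artefacts
(a decimal comma such as "1,405" is read as 1.405; a comma between two full
decimals separates branch values).  Prolines have no amide proton, so empty
NH cells on D-Pro rows produce no record.

Secondary shifts are Δδ = δ_obs − δ_rc against a bundled Wishart-style
random-coil ¹H reference (NH and Hα for the 20 standard residues).
Norleucine uses the leucine values (closest isostere) and D-proline the
L-proline values (mirror-image chemistry, identical shifts).  The CSI-style
segmentation defaults — ±0.1 ppm threshold on Hα, minimum run of 4 — are
standard chemical-shift-index practice.  On both bundled assignment tables
the segmentation returns no strand or helix segment, consistent with
predominantly disordered peptides whose only regular structure is the two
turns.

## NOE-based turn inference

The qualitative logic is the standard sequential-NOE reading: extended
residues show d_αN(i,i+1) stronger than d_αN(i,i); turn residues the
reverse, plus short d_NN(i,i+1) contacts.  The package codifies this as:

* **Rule A (intensity comparison)** — residue i is *turn-flagged* when its
  intraresidue Hα–HN peak outranks its sequential Hα(i)–HN(i+1) peak.  When
  the sequential peak is absent entirely, absence is informative only where
  the peak could exist (i+1 present, not a proline) *and* an HN–HN peak
  corroborates the residue; without that guard, random peak loss fakes
  turn flags.
* **Rule B** — both residues of a non-weak sequential HN–HN peak are
  flagged.
* **Medium-range diagnostics** — a short d_αN(i,i+2) or d_NN(i,i+2)
  contact flags residue i+1.  These contacts are classic turn markers and
  are unreachable (> 0.5 nm) in extended chains, so they add robustness
  against missing sequential peaks without false positives.
* **Windows** — flagged residues are clustered (gap ≤ 1); each cluster
  becomes one 4-residue window.  A window is *anchored* on a
  turn-promoting residue q (D-Pro, or Gly with corroborating peaks) so the
  promoter sits at position i+1, provided the anchored window covers the
  whole cluster.  A window must contain ≥ 2 flags and ≥ 1 sequential
  evidence peak.
* **Types** — II′ requires the D-Pro/Gly promoter at i+1 together with the
  d_αN(i+1,i+2) + d_NN(i+2,i+3) signature (an observed d_NN(i+1,i+2) rules
  II′ out, because the II′ template has ψ(i+1) ≈ −120°, which puts the two
  amide protons far apart); type I requires consecutive d_NN peaks from
  the window start.  When intensity classes carry real information
  (synthetic or quantified data) and single peaks are missing, a
  weight-of-evidence count over the same diagnostics decides; windows with
  insufficient evidence are reported as `indeterminate` rather than
  dropped.  Overlapping windows that cannot be merged are both reported
  and flagged ambiguous.

Unquantified peaks ("observed") rank with medium intensity, so
presence/absence decides — which is exactly how the bundled crosspeak
fixtures behave.

Proline isomer state: an Hα(i−1)–Hδ(i) crosspeak calls *trans*, an
Hα(i−1)–Hα(i) crosspeak calls *cis*.  If both appear (geometrically both
distances can fall under 0.5 nm in a trans conformer) the stronger wins;
equal intensities are reported as a contradiction.

## Restraints

Each inter-residue crosspeak yields one distance restraint.  The default
calibration puts every upper bound at the 0.5 nm accepted range; an
optional ladder assigns 0.27/0.33/0.50 nm to strong/medium/weak peaks.
Ambiguous proton groups (the two proline Hδ protons, glycine Hα2/Hα3) are
treated as r⁻⁶ effective pseudo-atoms, the standard ambiguous-restraint
convention.

**Turn hydrogen bonds.**  A typed β-turn implies the backbone hydrogen
bond C=O(i)···H–N(i+3).  The pipeline adds, for every typed turn
hypothesis, an O(i)–HN(i+3) restraint with a 0.25 nm upper bound, applied
on the instantaneous distance at every step (a "rigid network" treatment,
in contrast to the time-averaged NOE restraints).  This choice is central:
the enumerated sequential NOEs alone, at uniform 0.5 nm bounds, are
numerically satisfiable by an extended chain (sequential HN–HN ≈ 0.44 nm),
so without the hydrogen-bond term the restraint set cannot drive chain
reversal.  With it, restrained refinement closes the hairpin reliably
while unrestrained controls do not.

## Restraint potential and time averaging

The flat-bottom/linearised potential uses spring constant
k = 1250 kJ mol⁻¹ nm⁻², accepted range 0.5 nm and truncation at 0.6 nm:
zero inside the range, harmonic for 0.1 nm, then linear with the constant
maximum force k·0.1 = 125 kJ mol⁻¹ nm⁻¹.  Energy and force are continuous
at both branch points.  For a restraint with its own upper bound (class
calibration, hydrogen bonds) the branch points shift with the bound while
the harmonic width and force cap stay fixed.

NOE distances are time-averaged as r̄ = ⟨r⁻³⟩⁻¹ᐟ³ with an exponential
memory (default 25 000 steps); the frozen average in force is refreshed
every `tau_update` = 5000 steps (the step-count equivalent of a 10 ps
update at the nominal 2 fs step), while restraint *forces* are evaluated
every step from the current frozen average along the instantaneous pair
direction.  The r⁻³ exponent is the conventional time-averaged-restraint
choice; r⁻⁶ and a conversion-free instantaneous mode are available.

## Refinement engine

Degrees of freedom are the backbone φ/ψ torsions (proline φ is
ring-pinned; ω stays trans; side chains ride rigidly at a default
χ₁ = −60° rotamer).  Sampling is overdamped (position) Langevin:

θ ← θ − μ ∇E Δ + √(2 k_B T μ) ξ,

with mobility μ = 2·10⁻⁵ rad² mol kJ⁻¹ per step and a 4° per-step clip as
a stability guard.  The sampler reproduces the Boltzmann variance of a
quadratic test potential within a few percent (the clip must be slack
relative to the noise amplitude for this to hold; the unit test widens it).

The internal energy is a minimal implicit model:

* **Torsion preferences** — Gaussian basins on the torus: generic L
  residues get a β basin (−120°, 130°) and an α_R basin (−63°, −43°);
  glycine gets symmetric α_R/α_L basins and a weak extended basin;
  L-proline gets ψ wells at 135° and −30°, D-proline the mirror (−135°,
  +30°).  The D-Pro ψ well near −135° is what makes the II′ geometry
  natural at position i+1.
* **Soft-sphere sterics** — quadratic overlap penalty below 0.9× summed
  element radii, spring 2000 kJ mol⁻¹ nm⁻².
* **Backbone hydrogen-bond well** — a shallow Gaussian well (0.5 kJ/mol,
  r₀ = 0.20 nm, σ = 0.04 nm) between backbone O and amide H separated by
  ≥ 2 residues.  The depth reflects aqueous solvation: solvent competes
  for backbone hydrogen bonds, so the *net* intramolecular gain for a
  solvent-exposed peptide is small.  A deep, narrow well acts like an
  implicit restraint and folds the D-Pro turn on its own, which
  contradicts the observed behaviour of unrestrained solvated peptides on
  nanosecond timescales.
* **Screened electrostatics** — a 1/(ε r²) distance-screened term on the
  amide-dipole partial charges with a strong (water-like) screening
  prefactor, saturated below 0.25 nm contact range (an unsaturated 1/r²
  attraction otherwise beats the quadratic sterics at short range and
  collapses the chain).

Gradients are analytic (Cartesian gradients mapped to torsion space via
the rotation-axis Jacobian) and match central finite differences to better
than 10⁻⁴ relative error in instantaneous mode.

**Protocol.**  Short steepest-descent minimisation, then simulated
annealing 500 K → 300 K over equilibration, then constant-300 K
production.  Step counts keep the published protocol's 3 : 5 : 1
equilibration : production : snapshot ratio — defaults 30 000 : 50 000 :
10 000 steps — so production always yields five evenly spaced snapshots.
The test-suite and acceptance runs use 6000 : 10 000 : 2000 (same ratio,
same snapshot structure) to keep desk runtimes in seconds; this is a
problem-size choice of this package, and results quoted from those runs
(closure counts, consensus calls) are statements about the scaled protocol.

## Geometric turn classification

A window i..i+3 is a turn when Cα(i)–Cα(i+3) ≤ 0.7 nm and its central
residues are not inside a ≥ 4-residue helical run (φ,ψ within ±30° of
(−60,−45)).  Types use the ideal-angle templates — I: (−60,−30)/(−90,0);
I′: (60,30)/(90,0); II: (−60,120)/(80,0); II′: (60,−120)/(−80,0) — with
±30° per angle, one angle allowed ±45°; within the Cα cutoff but outside
every template is IV/other.  Ensemble consensus reports a window when at
least `min_fraction` (default 0.6) of snapshots call it, with the type by
plurality and ties reported explicitly.  The detector is exactly invariant
under rigid motions, and mirroring coordinates maps each type to its
prime, a direct check of the sign conventions.

## Synthetic data: what it emulates and what it does not

`make_turn_peptide` plants ideal template dihedrals (plus optional
Gaussian jitter) on an otherwise extended chain; `back_calculate_noes`
emits a crosspeak for every Hα/HN/(proline Hδ) proton-group pair within
0.5 nm — the same cutoff as the restraint accepted range, keeping forward
and inverse models consistent — with intensity classes binned at
0.27/0.33 nm.  Each contact produces two symmetric crosspeaks (either side
of the NOESY diagonal) and each crosspeak is dropped independently with
the false-negative rate; a contact is lost only when both are.  Synthetic
shift tables are random-coil values plus Gaussian noise plus a small
(+0.05 ppm Hα) systematic offset at the two central turn residues — pure
plumbing to exercise the CSI path, with no claim of physical shift
prediction.

Passing closed-loop tests therefore show that the inference rules are
consistent with the package's own forward model of ideal turn geometry and
distance-thresholded peak detection.  They do not show robustness to the
things real spectra add — chemical-shift overlap, spin diffusion,
conformational averaging between exchanging states, baseline artefacts —
none of which are modelled.

The closed-loop studies plant turns only at chemically sensible positions:
type II′ where i+1 is D-Pro or Gly (elsewhere the builder warns that a
positive φ on an L-residue is strained), type I away from prolines.

## Numerical choices and degenerate inputs

* nm and kJ/mol everywhere internally; Å only at the PDB and X-PLOR
  boundaries.
* Residue geometry comes from the chemical component dictionary's ideal
  coordinates, converted to a per-residue NeRF Z-matrix rooted on the
  N–CA–C triad; the D-proline template is generated as the exact mirror
  (negated torsions) of L-proline, so the chirality relationship is exact
  by construction.  The proline ring reconstructs rigidly in the residue
  frame, which is why proline φ is pinned (±15° of −75°/+75°).
* Torsion moves rotate the C-terminal side; for proline φ only the
  carbonyl branch swings (never the ring), preserving all bond lengths
  exactly.
* Empty NOE sets, empty shift tables, zero-length production runs and
  all-satisfied restraint sets all return empty/zero results rather than
  errors; contradictory isomer evidence and atoms that cannot be resolved
  raise named validation errors.
* A non-finite gradient aborts refinement with a diagnostic snapshot
  attached to the exception.

## Known limitations

* The internal energy is a caricature: no solvent, no entropy of side
  chains, no aromatic or charge-specific chemistry.  Ensemble geometry
  beyond the restrained turns should not be over-interpreted.
* Peak intensities are presence/absence or three coarse bins; no volume
  integration or spin-diffusion correction (out of scope by design).
* The turn-inference rule set is tuned to short, mostly disordered
  peptides with isolated turns; densely structured proteins would need the
  full NOE network machinery (ARIA-style ambiguity handling) that this
  package intentionally does not provide.
* Fragment windows default to the 4-residue turn ± 2 flanking residues;
  the published refinements used 8-residue windows whose exact bounds are
  configurable here because they are not uniquely determined.
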