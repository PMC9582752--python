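# Methods

This note documents the models and numerical choices behind `gtase`: what
each component computes, the parameters that matter, what the synthetic
data emulate (and do not), and the design decisions taken where the
underlying experimental description left the procedure open.

## Reference-anchored pose geometry

The substrate-binding groove of a 4-α-glucanotransferase is reduced to a
one-dimensional axis anchored on a reference inhibitor (acarbose or a toy
analogue) bound across subsites −1…+3:

- **Axis.** Direction is the unit vector from the axis-start anchor to the
  axis-end anchor (C4A → C1 for acarbose, i.e. running donor → acceptor
  side). The origin is the orthogonal projection of the glycosidic-linker
  atom (N4A, between the −1 and +1 moieties) onto that line. Coincident
  anchors raise a degenerate-axis error.
- **Positional coordinate.** The signed projection of a pose's heavy-atom
  centroid onto the axis, in Å; negative values lie on the donor side.
  All heavy atoms enter the centroid (not only ring atoms) — the literal
  reading of "center of heavy atom coordinates". Translating a pose by
  *t* along the axis shifts its coordinate by exactly *t*.
- **Greedy sub-angstrom match.** All pose–reference heavy-atom pairs are
  ranked by distance; the globally shortest remaining pair is accepted as a
  match when its distance is strictly below the 1 Å threshold, both atoms
  are removed, and the scan repeats. The loop stops as soon as the shortest
  remaining distance reaches the threshold, which cannot change the result
  (no later pair is shorter) but skips useless iterations. The percentage
  is over the *pose's* heavy-atom count. Distance ties break
  lexicographically on (pose index, reference index), making the result
  order-stable; this greedy correspondence is coordinate-based only — no
  graph automorphism / symmetry correction, which is deliberate.
- **Subsite calibration and assignment.** Each subsite's coordinate is the
  positional coordinate of its moiety's heavy-atom centroid; the calibrated
  coordinates must increase with subsite index (…, −1, +1, +2, +3), else an
  orientation error suggests swapped axis anchors. A pose is assigned the
  nearest calibrated subsite; ties go to the more negative (donor-side)
  subsite, and anything farther than `max_distance` (default 2.0 Å — half
  a typical 4 Å glucose-unit spacing) is "unassigned". The calibration is
  cluster positions, not bin edges, so the cutoff is a package choice.
- **Residue–ligand contacts** report the minimum side-chain heavy-atom
  distance to the ligand (contact residues in the acceptor subsites are
  aromatic and interact through their side chains); glycine falls back to
  CA and the result is flagged.

## Structure I/O

PDB reading/writing is fixed-column (v3.3 layout), with MODEL/ENDMDL
multi-model support and a minimal PDBQT dialect that ignores the AutoDock
charge/type columns — docked poses are consumed, never produced, so only
the box configuration (`center_*`, `size_*`, `exhaustiveness = 100`,
`num_modes = 20`, 30 Å cube on the reference's linker atom) is emitted on
the docking side. When the element column is absent or holds an AutoDock
type, the element is inferred from the atom-name prefix. Alternate
locations keep the highest occupancy (ties prefer altloc A). Alanine
truncation keeps exactly N, CA, C, O, CB (and a terminal OXT), renames the
residue ALA, and is idempotent; glycine is rejected (no β-carbon).
Round-tripping preserves heavy-atom coordinates to the 3-decimal column
precision. Coordinates are Å throughout.

## Enzyme kinetics

- **Iodine assay.** One unit is 1 µg amylose hydrolysed per minute; the
  A660 drop is converted through an explicit calibration slope (µg amylose
  per absorbance unit — a required input, since no standard curve is
  published) and reported per mg enzyme. Negative absorbance changes are
  clipped to zero and flagged.
- **Transglycosylation factor.** Specific activity with acceptor divided
  by the no-acceptor baseline, with first-order error propagation when
  SDs are supplied; report tables round to one decimal.
- **Michaelis–Menten fitting.** The reported route is unweighted OLS on
  the double-reciprocal (Lineweaver–Burk) plot: Vmax = 1/intercept,
  KM = slope/intercept, requiring ≥ 3 distinct concentrations and positive
  velocities. A non-positive intercept (or a meaningfully negative slope)
  raises a fit failure; a slope numerically indistinguishable from zero is
  the saturation limit and returns KM = 0, Vmax = mean velocity. A direct
  nonlinear fit (`scipy.optimize.curve_fit`) is provided as a cross-check
  only.
- **kcat conversion.** The assay's velocity unit is carried symbolically;
  turnover numbers require the enzyme load explicitly: [E] (µM) =
  (mg/ml)/(Da) × 10⁶ — 0.097 mg/ml at 76,002 Da gives 1.276 µM — and
  kcat = Vmax/[E] with Vmax in µM·min⁻¹. This µM·min⁻¹ convention is a
  package convention: the original assay never states how amylose
  degradation maps to molar product, so recovery tests are self-consistent
  (generator and fitter share the convention) rather than absolute.
- **Growth rates.** k is the OLS slope of ln(density) on time inside the
  exponential window. If no window is given, the longest contiguous run of
  ≥ 4 points whose log-linear r² reaches the threshold (default 0.99) is
  used, earlier windows winning ties. The threshold trades window length
  against purity: with very low noise a tighter threshold (e.g. 0.999, as
  in the growth-rate driver) cleanly excludes lag and stationary points
  that a 0.99 cut can admit one or two of. A perfectly flat window has
  zero total variance and is treated as an exact zero-slope fit.

## Subsite-binding disproportionation model

The groove is a linear array of glucose-unit subsites (GH57 preset:
−6…−1 and +1…+3; −1 and +1 adjacent, no subsite 0). A chain of *n*
glucose units binds in a contiguous **register**, non-reducing end toward
the negative side; a register is **productive** iff it covers both −1 and
+1. Catalysis cleaves the −1/+1 bond: the acceptor-side fragment (with any
reducing-end pNP label) is released, the donor-side fragment becomes a
covalent glycosyl-enzyme intermediate, and the intermediate is resolved by
transfer onto a sugar acceptor bound at +1… (chain concatenation) or onto
water (free release).

- **Weights and rates.** A register's weight is the product of per-subsite
  affinities over its occupied subsites; units overhanging the modelled
  array weigh 1 (the array is "at least" this long). Binding is assumed
  fast relative to catalysis, so the cleavage flux through a register is
  `cleavage_rate × weight × [substrate]` — proportionality to weight makes
  register selection follow relative weights *and* lets total turnover
  scale with affinity, which is what distinguishes good from poor
  substrates (a per-event normalisation alone would equalise all species'
  turnover). Intermediates resolve at `transfer_rate × acceptor-weight ×
  [acceptor]` against `hydrolysis_rate × water activity` (water activity
  fixed at 1); the transfer/hydrolysis ratio is the dial separating a
  transfer-dominant transglycosylase from a hydrolase.
- **Overhang rules.** Cleavage registers may overhang the acceptor side by
  at most one unit past +3 (the acceptor-side fragment must otherwise sit
  on defined subsites; a +4 position is the most that is ever implicated),
  and the donor side without limit. Acceptors awaiting transfer may be any
  length — units beyond +3 protrude from the groove with neutral weight —
  so long transfer products (e.g. pNPG10 from a held G4 and a pNPG6
  acceptor) are reachable.
- **Presets.** The experimental record is qualitative about affinities, so
  the presets encode orderings, not measured numbers, and the simulator's
  acceptance is ordering-based. GH57: acceptor subsites +1, +2, +3 at 6.0
  each (three strong acceptor sites ⇒ acceptor quality glucose < maltose
  < maltotriose, multiplicatively), donor subsites permissive at 1.0;
  rates `cleavage_rate = 2×10⁻⁴`, `transfer_rate = 10⁻³`,
  `hydrolysis_rate = 0.02` per minute put a 10 mM substrate on the
  tens-of-minutes turnover scale of the time-course experiments, with
  transfer dominating hydrolysis ~100:1 at 10 mM acceptor (so glucose and
  maltose leak out only late, via hydrolysis of short intermediates). The
  GH77 contrast preset blocks +2 (affinity 0; +3 likewise), reproducing
  steric hindrance at +2: only single glucose units fit the acceptor side,
  so glucose dominates early products. These defaults are fixed; they are
  documented, overridable inputs, not fitted quantities.
- **Dynamics.** The register/resolution scheme compiles to a mass-action
  reaction network (~70 species, a few hundred reactions at the default
  length caps of 20 glucose units / pNPG12). Deterministic mode integrates
  it with LSODA at rtol 10⁻⁹/atol 10⁻¹²; glucose-unit mass is a linear
  invariant of the network (every reaction conserves it exactly), so
  conservation holds to solver precision (≤ 10⁻⁹ relative in practice).
  Stochastic mode is an exact Gillespie simulation on molecule counts
  (`system_size` molecules per amount unit), bitwise reproducible by seed,
  conserving mass exactly; at ≥ 10⁵ molecules its trajectories track the
  deterministic solution within Poisson-scale fluctuations. Transfers that
  would exceed the length cap are disabled (flux 0) and surfaced in the
  result's warnings rather than truncated: truncation would silently
  destroy glucose-unit mass, and at the default caps the suppressed flux
  is negligible for the simulated scenarios. Time is minutes; temperature
  is not modelled.

## Synthetic data

Generators are pure functions of their configs (seed included; identical
configs ⇒ bitwise-identical output) and attach their ground truth for
closed-loop recovery tests. Noise is multiplicative Gaussian
(CV-parameterised) throughout — observables are positive and the relative
error structure keeps recovery analysis simple.

- **Reference ligands**: moieties equally spaced along +x with exact
  centroids (anchor atoms are placed exactly; the remaining atoms are
  jittered and re-centred), subsites −1, +1, +2, … in order, the axis +x,
  and the origin midway between the −1 and +1 centroids.
- **Poses**: rigid translations along the axis, optional uniform random
  rotations about the centroid, then per-atom isotropic jitter. They mimic
  a docking engine's 20-mode output geometrically; the score field is a
  placeholder, not an energy model.
- **Kinetics**: Michaelis–Menten velocities at the assay's 0.32–10 mM
  six-point design, Vmax from kcat and the enzyme load.
- **Growth curves**: lag at N₀, exponential rise, hard stationary cap.

What passing recovery tests show is that the estimators invert the
generators faithfully under the stated noise; they do not validate the
biochemical assay itself (detergent effects, substrate depletion,
instrument drift and the amylose-to-molar-product mapping are outside the
generators).

## Known limitations

- The pose analysis validates on toy systems; coordinates against the real
  template structure (and its homology model) require external structure
  files and are out of the tested path.
- The simulator's affinities and rate constants are qualitative encodings;
  absolute product percentages are not meaningful, only orderings and
  conservation properties.
- Cyclisation and α-1,6 branching chemistry are not modelled; the velocity
  unit behind turnover numbers is conventional (see above).
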