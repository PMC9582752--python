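# gtase

Computational toolkit for characterising GH57-family
4-α-glucanotransferases (amylomaltases, EC 2.4.1.25) — the main amylolytic
enzymes of hyperthermophilic archaea such as *Pyrococcus*. These enzymes
disproportionate maltooligosaccharides (2 Gₘ → Gₘ₋ₖ + Gₘ₊ₖ) through a
covalent glycosyl-enzyme intermediate, and differ from the common GH77
family in *where* sugars bind: GH57 enzymes carry three strong acceptor
subsites (+1…+3) with no steric block at +2, so they release maltotriose
and longer fragments instead of glucose.

The package is organised as an analysis project: the library under
`src/gtase/` carries all computation, the numbered scripts under
`analysis/` are narrative drivers over it.

**Who it is for:** structural bioinformaticians rescoring docking poses
against a reference inhibitor, and enzymologists fitting acceptor kinetics
or simulating subsite-binding models of disproportionation.

## What it computes

- **Pose geometry** (`gtase.pose`): the substrate-binding groove is
  reduced to an axis anchored on a bound acarbose-like inhibitor
  (direction C4A → C1, origin at the projection of the −1/+1 linker atom
  N4A). Each docked pose gets a *positional coordinate*
  s = (centroid − origin)·d̂ (Å), a greedy sub-angstrom *match
  percentage* against the reference (shortest-pair correspondence,
  strict 1 Å cap), and a nearest-subsite assignment calibrated from the
  reference's own moiety centroids.
- **Structure I/O** (`gtase.structure`): fixed-column PDB and minimal
  PDBQT reading/writing, alanine-truncation mutants (side chain cut to
  CB), Vina-style docking-box config (30 Å cube, exhaustiveness 100,
  num_modes 20).
- **Kinetics** (`gtase.kinetics`): iodine-assay unit conversion,
  transglycosylation factors TF = activity(+acceptor)/activity(−acceptor),
  Michaelis–Menten fits via the Lineweaver–Burk plot
  (1/v = (K_M/V_max)(1/[S]) + 1/V_max), kcat = V_max/[E], catalytic
  efficiency kcat/K_M, and specific growth rates k from log-linear
  regression of exponential-phase growth.
- **Subsite simulator** (`gtase.subsites`): maltooligosaccharide
  disproportionation over a −6…+3 subsite array with per-subsite
  affinities; cleavage between −1 and +1, acceptor-side release,
  enzyme-held donor intermediate, resolution by transfer or hydrolysis.
  Deterministic (ODE) and exact-stochastic (Gillespie) modes, both
  conserving glucose-unit mass. Presets encode the GH57 behaviour and a
  GH77 contrast (+2 sterically blocked).
- **Synthetic data** (`gtase.synth`): seeded generators for reference
  ligands, docked-pose mimics, Michaelis–Menten datasets and growth
  curves, each carrying its ground truth.

See `docs/methods.md` for model details and design decisions.

## Worked example

Fit the three acceptors from noiseless synthetic data at the assay design
(0.32–10 mM, 0.097 mg/ml enzyme, 76,002 Da), plus transglycosylation
factors from the printed activity column:

```sh
python analysis/02_acceptor_kinetics.py
```

prints

```
transglycosylation factors (activity with acceptor / without):
  glucose        6.8 -> TF 4.5
  maltose       18.2 -> TF 12.1
  maltotriose   27.4 -> TF 18.3

Lineweaver-Burk fits on noiseless synthetic data (0.32-10 mM, 0.097 mg/ml enzyme, 76,002 Da):
  glucose      KM 6.76 mM (true 6.76), kcat 1141 min^-1 (true 1141), kcat/KM 169
  maltose      KM 1.81 mM (true 1.81), kcat 2008 min^-1 (true 2008), kcat/KM 1109
  maltotriose  KM 0.86 mM (true 0.86), kcat 2635 min^-1 (true 2635), kcat/KM 3064
```

The TF column says maltotriose accelerates amylose degradation 18.3-fold
over the acceptor-free baseline; the K_M ordering glucose > maltose >
maltotriose (6.76 > 1.81 > 0.86 mM) and the efficiency ordering
(169 < 1109 < 3064 min⁻¹·mM⁻¹) are the kinetic signature of a three-unit
acceptor site. The other drivers behave analogously:
`01_pose_geometry.py` (pose clusters at the calibrated −1/+1 subsite
coordinates), `03_growth_rates.py` (k recovered from lag/exponential/
stationary curves), `04_disproportionation.py` (GH57 preset: G3/G4 from
G5 with almost no early glucose; GH77 contrast: glucose first). A
`gtase` CLI (`analyze-poses`, `fit-kinetics`, `simulate`, `gen-fixtures`)
wraps the same stages; every run writes a seed/config manifest.

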