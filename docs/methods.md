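# Methods

This note documents the models, conventions and numerical choices behind
`dnamech`, and what the synthetic validation does and does not establish
about real trajectories.

## Units and coordinates

Coordinates in Å, times in ps, energies in kcal/mol, angles in degrees,
temperature in K. Base pairs are numbered 1..N along the Watson strand
5′→3′; the Crick partner of bp *i* carries the same number (Crick chains
are stored 5′→3′, i.e. bp N first). Genomic intervals are 1-based
inclusive in memory; BED I/O converts to 0-based half-open on disk.
`k_B·300 K = 0.596` kcal/mol.

## Helical parameters

Base frames are fit by Kabsch superposition of idealized planar base
geometries (ring atoms only) onto the observed atoms; the idealized
coordinates follow the standard reference frame layout (x into the major
groove, y toward the strand backbone, z along the helix) and are pinned in
`helical_geometry.BASE_GEOMETRY`. The bp frame is the mid frame of the
Watson base frame and the y/z-flipped Crick base frame; intra-bp and step
parameters come from the same mid-frame (CEHS-style) factorisation

    R1ᵀR2 = Rz(ω/2 − φ) Ry(Γ) Rz(ω/2 + φ),

with translations read in the mid frame. Because building coordinates
uses the exact inverse factorisation, build → measure is the identity to
~1e-11 (the tested contract is 1e-6). Range reduction of (ω, φ) is done
jointly; wrapping them independently aliases the bend phase by 180°, which
is the one numerically delicate point of the decomposition.

Strand-reversal symmetry (shift, tilt, shear, buckle change sign; the
remaining eight parameters are invariant) holds exactly and is tested.
Mirrored (left-handed) inputs are detected by the sign of the median twist
and of the alignment between base normals and strand direction.

The helical axis is a cubic smoothing spline through bp origins
(smoothing parameter `axis_smoothing`, default 1 Å²·bp of allowed
residual). x/y-displacement of a bp is its origin's offset from the axis
in the bp frame. Terminal base pairs are excluded from axis-derived
quantities (NaN, never zero-filled).

**Grooves.** Widths thread cubic splines through each strand's phosphates
and take, per interior bp level, the minimal cross-strand spline distance
separately on the major- and minor-groove side (side = sign of the
connector midpoint along the bp x-axis), minus a 5.8 Å phosphate van der
Waals correction (configurable). Depths are the distance from the
connector midpoint to the helical axis. These conventions differ by
documented offsets from other programs; cross-program reconciliation is
out of scope. Under the pinned phosphate placement, a regular
36°/3.4 Å fiber yields ~11.7 Å major and ~5.7 Å minor groove widths.

**Torsions.** Standard α..ζ and χ dihedrals (IUPAC sign convention);
BI/BII from (ε − ζ) wrapped to (−180, 180]: negative → BI.

## Deformation energy model

Each step position carries the 12-vector [6 intra-bp parameters of the
step's 3′ bp, 6 step parameters]; position *i* (bp numbering) is
represented by the step arriving at it, so a bp range a..b contains
exactly b−a+1 vectors and "per bp" means dividing by that count. The
sequence context of a step is its tetranucleotide (neighbouring bases on
both sides); terminal steps fall back to tri- then dinucleotide contexts.
Methylated cytosines are distinct context letters, so ME CpG steps get
their own parameters.

Per context, the thermal ensemble is modelled as a Gaussian mixture with
`n_substates` components (default 2, motivated by BI/BII-type bimodality;
`n_substates=1` reduces to the plain harmonic model). Stiffness
`Fˢ = k_B T Σ_s⁻¹`; substate offsets `c_s = −k_B T ln(w_s/w_max) ≥ 0` put
the zero of energy at the dominant substate's minimum. Nearest-neighbour
coupling `J(s_i, s_{i+1})` is the negative log odds ratio of observed
neighbour substate co-occurrence (Laplace-smoothed, shifted so the ground
bond is zero; independent neighbours give J ≈ 0). Evaluation assigns
substates greedily (per-position minimum, then left-to-right sweeps
against both neighbours until stable; ties break toward the lower
substate index). Contexts observed on fewer than 500 samples pool every
position sharing the central dinucleotide.

The published parameter set of the substate-coupled model this emulates
is not tabulated here, so the package estimates parameters from a
reference ensemble (and its tests fit them to the synthetic generator);
they are stand-ins, clearly labelled as such, and reproducing the
original source's values is a non-goal.

Equipartition anchors the scale: a single-substate model sampled from its
own Boltzmann distribution gives exactly (12/2)·k_B·T = 3.58 kcal/mol per
bp in expectation at 300 K, i.e. ~4 at one significant figure — the
naked-DNA thermal fluctuation energy. The binding-mechanism rule is the
printed trichotomy: bound/naked ≥ 2 → induced fit; ≤ 1 → conformational
selection; otherwise mixed (boundaries inclusive toward the outer
classes).

## Contacts

H-bond: protein side-chain donor/acceptor with DNA base partner,
heavy-atom distance ≤ 3.5 Å and donor–H…acceptor angle ≥ 135° (waived if
the topology carries no hydrogen on the donor). Hydrophobic: apolar
carbon pairs (aliphatic/aromatic carbons without attached O/N, plus the
thymine methyl and the 5-methyl carbon of methylcytosine) within 4.5 Å.
Nonspecific: any heavy-atom pair within 4.5 Å touching either molecule's
backbone (sugar-phosphate for DNA; N/CA/C/O for protein) — backbone
participation always classifies an event as nonspecific, so the partition
is exhaustive and exclusive. The exact published strength formula being
unavailable, strength is defined as the integer count of qualifying
atom-pair events per residue pair per frame, which makes every number
reproducible by recounting; this is a documented stand-in and alternative
weightings are out of scope. Retention uses strict `occupancy > 0.10`.
A contact's "dominant class" is its stronger specific class when any
specific component exists, else nonspecific.

## Interaction energies

Plain-cutoff (12 Å) inter-molecular Coulomb (k_c = 332.0637
kcal·Å/mol/e²) and Lennard-Jones with Lorentz–Berthelot combining; no
long-range correction, matching a short-range qualitative comparison and
keeping results reproducible from the parameter table alone. Specific =
side-chain↔base pairs; everything touching a backbone is nonspecific.
Distribution shape via the bimodality coefficient b = (skew² + 1)/kurtosis
(Pearson kurtosis, 3 for a Gaussian → b = 1/3); b > 5/9 flags bimodality;
zero-variance series are flagged degenerate. The element-keyed charge/LJ
table shipped for built systems is a labelled stand-in, not a force
field; continuum-solvation free energies are out of scope.

## Schlitter entropy

TS at 300 K from `S′ = (k_B/2) ln det[1 + (k_B T e²/ħ²) M^{1/2} σ
M^{1/2}]`, with σ the Cartesian covariance of the selection after
per-frame mass-weighted centroid removal (translation only, matching the
stated convention; optional `remove="trans_rot"` adds least-squares
superposition since practice differs). The dimensionless prefactor is
45.70 per amu·Å² at 300 K. Eigenvalue floor 1e-12 stabilises ln det.
Windows generalise to fractions (1.0, 0.75, 0.5) of the
post-equilibration trajectory — the 1000/750/500 ns windows of a 1 μs
production run — with the spread across windows as the uncertainty.
Windows shorter than 3 × (atom count) frames warn about ill-conditioning
but still compute (the estimate is then biased low).

## Correlations, ions, intervals

Lagged Pearson maps r_ij(τ) between per-position series; undefined
(terminal/constant) positions propagate NaN rather than zero. Default
translational parameters {shift, slide, rise, xdisp} and groove
parameters; the reported coefficients are small (< 0.3 in the emulated
regime), so hit summaries default to |r| ≥ 0.2 with ≥ 5 bp separation and
no per-cell significance machinery. Block-averaged error bars are
available but off by default.

Ions map to the nearest axis point → (level, radius from axis, azimuth
from the bp major-groove x-axis). Major groove sector (−60°, +60°),
minor sector the opposing 120°, radial range 2–10.25 Å by default —
sector conventions are pinned in config since external programs differ.
Molarity divides counts by the analytic curvilinear sector volume
Δz·(θ/2)(r₂²−r₁²) using the bin edges actually included, so a uniform
bulk cloud returns its bulk molarity by construction; counting
conservation (binned + bulk = ions × frames) is exact.

Promoter selection takes TSS ± 200 bp windows (symmetric; the one-sided
variant is a flag) overlapped by ≥ 2 distinct peak tracks, inclusive
boundaries; motif scanning is out of scope, REs are user-supplied
annotations. Model-region assembly renumbers an interval (plus flanks) to
1..L and merges adjacent methylation sites into double (both-strand) CpG
marks.

## Synthetic generator: what it emulates

Defaults are the study conditions. The 49-bp Watson sequence
`ATGGTATTTCCCGCGATATCGGACGGTTACACTACGATTAGTATGATTA` realises the RE layout
(E2F1-DP1 bp 7–14, CEBPB bp 27–34) with CpG steps at 12, 14, 20, 24, 35;
the ME state methylates four single cytosines (W12, W14, W20, W24 — RE
and linker) and one double CpG (W35/C36, CEBPB 3′-flank): six
methylcytosines.

Helical dynamics are stationary Gaussian AR(1) series (autocorrelation
time 20 frames by default — temporal persistence is needed but no value
is prescribed, so it is a fixed design choice) with B-DNA-like means per
central dinucleotide, a fixed 12×12 within-position correlation pattern,
and softer pyrimidine–purine steps. Planted effects carry the study's
stated signs, with magnitudes chosen once to sit in the regimes the study
reports:

- methylation: twist −2.5°, roll +3.0° at ME CpG steps; linker shift SD
  × 0.85 (narrowed distributions);
- CEBPB binding: linker twist +3.0°, shift +0.6 Å, slide +0.4 Å (induced
  linker changes) and mild rigidification (SD × 0.96 own site, × 0.95
  E2F1-DP1 site) — yielding a small positive deformation-energy increase
  (~0.2 kcal/mol·bp) and a TS drop of order 1 kcal/mol at the partner
  site;
- E2F1-DP1 binding: opposite mean shift at the RE 3′-steps (WT +0.40 Å,
  ME −0.55 Å) plus an ME-only slide displacement (+0.5 Å, bp 10–14), so
  binding methylated DNA costs more deformation energy than binding WT;
- WT CEBPB-bound systems inject the long-distance coupling chain
  bp 32 → 21–23 → 19–20 → E2F1-DP1 site (ρ 0.2–0.25, stronger when both
  dimers are bound); methylation removes it;
- contact scripts realise the DP1 Arg167-type readout (H-bond to Crick
  guanines in WT; hydrophobic packing against the 5-methyl carbon in ME),
  a Tyr170 hydrophobic anchor strengthened in the WT enhanceosome, stable
  CEBPB contacts independent of methylation, and backbone contacts;
- K⁺/Cl⁻: uniform 150 mM cloud in a fixed box plus a major-groove-bound
  K⁺ population at the E2F1-DP1 site, radius 9.0 Å (WT) vs 8.2 Å (ME).

Injected lagged couplings replace the target series by
`ρ·ẑ_source(t−L) + √(1−ρ²)·residual`, so the planted lagged Pearson
coefficient is exact in expectation and AR(1) persistence makes the lag
sweep peak at L. Coordinates are rebuilt by composing the exact inverse
transforms, with phosphates (and crude backbone atoms, for torsion
definitions only) at fixed positions in each base frame.

What passing tests show — and don't. The generator's Gaussian,
harmonically consistent dynamics are exactly the regime in which the
deformation model and Schlitter bound are well-specified; real MD adds
anharmonicity, sequence-dependent substate structure beyond two
components, solvent and finite-sampling artefacts that the synthetic
route cannot expose. Contact geometry is scripted along radial
directions, so angle-criterion coverage on real side-chain geometries is
limited to the explicit cutoff tests. Ion clouds ignore excluded volume
and electrostatics; only the curvilinear accounting is validated.
Groove-depth values are convention-bound, not comparable across programs.

## Problem sizes

Default study runs use 5000-frame parameter ensembles, 400 rebuilt
coordinate frames for atom-based stages, and ~5×10⁴-frame ensembles for
correlation recovery; the acceptance computation fits on a 2×10⁴-frame
reference ensemble and draws 10⁵ thermal samples. These sizes put
statistical checks comfortably inside their tolerances while keeping a
full run in minutes on one core.

## Known limitations

- The fitted deformation parameters are stand-ins estimated from the
  ensemble at hand; transferring a model between sequences works only
  where contexts overlap (pooling fallback otherwise).
- Multi-substate Boltzmann sampling uses the mixture approximation
  (bond couplings are not resampled); only the single-substate route is
  exact, and it is the one used for the equipartition-anchored result.
- Groove/axis quantities are undefined at termini by construction.
- PDB is the only trajectory writer; velocities and periodic-boundary
  reimaging beyond whole-solute handling are out of scope.
- The pipeline evaluates each system under the naked-DNA model of its own
  methylation state; comparisons across methylation states therefore
  reflect binding-induced changes, not the methylation marks themselves
  (which the per-state models absorb).
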