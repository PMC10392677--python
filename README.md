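# dnamech

Trajectory-analysis machinery for studying how promoter CpG methylation
perturbs cooperative transcription-factor DNA recognition — the system of
interest being a 49-bp hypermethylated promoter region carrying adjacent
response elements (REs) for the E2F1-DP1 heterodimer (`TTTCCCGC`, bp 7–14)
and a CEBPB homodimer (`TTACACTA`, bp 27–34), simulated as eight wild-type
(WT) / methylated (ME) × binding-state systems.

The package is aimed at computational structural biologists who have (or
want to emulate) MD trajectories of DNA or protein–DNA complexes and need
the downstream analyses as reusable, tested components:

- **Helical geometry** — base-pair frames fit to idealized base geometries,
  the 12 rigid-body parameters (shear…opening; shift…twist) via the
  mid-frame (CEHS-style) decomposition, bp axis displacement, groove widths
  and depths from phosphate splines, backbone torsions with BI/BII states.
- **Deformation energy** — a tetranucleotide-dependent harmonic model with
  Gaussian-mixture conformational substates and Ising-like
  nearest-neighbour substate coupling. Per substate *s* at one position,
  `e_s(x) = ½ (x−x₀ˢ)ᵀ Fˢ (x−x₀ˢ) + c_s` with `Fˢ = k_B T Σ_s⁻¹`, plus bond
  terms `J(s_i, s_{i+1})` from neighbour co-occurrence odds ratios. A
  single-substate model sampled at 300 K gives `(12/2)·k_B·T ≈ 3.6 ≈ 4`
  kcal/mol per bp by equipartition. A ≥2× increase of bound-DNA deformation
  energy over naked DNA classifies as induced fit, no increase as
  conformational selection, in between as mixed.
- **Dynamic contact maps** — per-frame H-bond / hydrophobic / nonspecific
  protein–DNA contacts; integer atom-event strengths; occupancy filtering
  (strictly > 10% of frames); WT-vs-ME and solo-vs-complex map comparison.
- **Interaction energies** — short-range Coulomb + Lennard-Jones between
  protein and DNA atom groups, split specific (side chain ↔ base) vs
  nonspecific (backbone-involving), with bimodality diagnostics.
- **Configurational entropy** — Schlitter's upper bound
  `S′ = (k_B/2) ln det[1 + (k_B T e²/ħ²) M^{1/2} σ M^{1/2}]` over full /
  last-75% / last-50% trajectory windows.
- **Long-distance correlations** — lagged Pearson maps between
  per-position helical/groove series, with long-distance hit summaries.
- **Groove ions** — curvilinear (level, radius, azimuth) ion histograms,
  groove molarities from analytic sector volumes, radial-shift detection.
- **Genomic site selection** — promoters with overlapping ChIP-seq peaks
  near a TSS, CpG-methylation intersection, model-region assembly
  (1-based inclusive coordinates; BED I/O converts at the boundary).
- **Synthetic data** — every input above can be generated with known
  ground truth (Gaussian AR(1) helical dynamics, planted methylation
  effects and lagged couplings, scripted contacts, 150 mM ion clouds),
  which is how the whole pipeline is validated end to end.

## Worked example

Fit the deformation model to naked-DNA ensembles and ask what protein
binding and methylation cost:

```python
from dnamech import SystemLabel, default_system_spec, generate_helical_ensemble
from dnamech import deformation_model as dm

labels = [SystemLabel("WT", "naked"), SystemLabel("WT", "CEBPB"),
          SystemLabel("ME", "naked"), SystemLabel("ME", "E2F1DP1")]
ens = {l.name: generate_helical_ensemble(default_system_spec(l, n_frames=5000, seed=0))
       for l in labels}
models = {m: dm.fit_model(ens[f"{m}_naked"], n_substates=1) for m in ("WT", "ME")}
for l in labels:
    e = dm.energy(models[l.methylation], ens[l.name], (6, 35)).mean() / 30
    e0 = dm.energy(models[l.methylation], ens[f"{l.methylation}_naked"], (6, 35)).mean() / 30
    mech = "-" if l.bound_state == "naked" else dm.classify_mechanism(e, e0)
    print(f"{l.name:<12} {e:6.2f} {e - e0:+6.2f}  {mech}")
```

prints

```
WT_naked       3.58  +0.00  -
WT_CEBPB       3.82  +0.24  mixed
ME_naked       3.58  +0.00  -
ME_E2F1DP1     3.88  +0.30  mixed
```

Naked-DNA thermal fluctuations cost ~3.6 (≈ 4 at one significant figure)
kcal/mol per bp over the analysed bp 6–35 region; CEBPB binding raises
this modestly (induced linker changes), and E2F1-DP1 binding to methylated
DNA costs more than any WT association — both well under the 2× threshold
that would signal pure induced fit, hence "mixed".

The same synthetic systems feed every other stage; `dnamech study --out
study_out` runs all eight systems through all stages and writes per-system
CSV/TSV tables plus WT-vs-ME comparison tables and a provenance manifest.

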