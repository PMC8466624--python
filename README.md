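# vhhassess

Assessment of comparative structural models of **VHH domains** (nanobodies —
the single variable domain of camelid heavy-chain-only antibodies) using the
**Protein Blocks (PB)** structural alphabet, C-alpha RMSD metrics and
template-selection scenario logic.

## The problem

A VHH is a ~120–130-residue immunoglobulin fold: four framework regions
(FR1–FR4, mostly β-strands) interleaved with three antigen-binding loops
(CDR1–CDR3). Template-based modelling predicts the frameworks well, but the
CDR loops — CDR3 above all — sample diverse conformations, and the choice of
template(s) strongly conditions the models a comparative-modelling engine
produces. Global RMSD alone hides these local effects. This package provides
the analysis layer for such benchmarks:

- **PB assignment.** Local backbone conformation is discretised with a
  16-letter structural alphabet (*a*…*p*), each letter a prototype of 8
  dihedral angles (ψ<sub>i−2</sub>, φ<sub>i−1</sub>, ψ<sub>i−1</sub>,
  φ<sub>i</sub>, ψ<sub>i</sub>, φ<sub>i+1</sub>, ψ<sub>i+1</sub>,
  φ<sub>i+2</sub>) over a five-residue window. A residue gets the letter of
  the prototype with minimal RMSDA (root mean square of the wrapped angular
  differences); *m* ≈ core α-helix, *d* ≈ central β-strand, `Z` marks
  positions without a complete window.
- **Ensemble statistics.** For an ensemble of models of one query, the
  per-position PB frequencies f<sub>x</sub> give the *equivalent number of
  PBs*

  N<sub>eq</sub> = exp(−Σ<sub>x=1..16</sub> f<sub>x</sub> ln f<sub>x</sub>),

  1 for a conformationally rigid position, 16 for a uniform distribution.
  Two ensembles are compared by ΔN<sub>eq</sub> (signed per-position
  difference) and by the per-position L1 profile distance

  ΔPB = Σ<sub>x=1..16</sub> |f¹<sub>x</sub> − f²<sub>x</sub>| ∈ [0, 2],

  0 meaning identical local sampling and 2 disjoint.
- **Geometry.** Least-squares C-alpha superposition (SVD, proper rotations
  only), global and per-region RMSD (local fit, or framework-frame fit),
  CDR loop-termini C-alpha distances, and simplified Ramachandran
  favored/allowed/unfavorable fractions.
- **Template selection.** Pairwise global alignment (Needleman–Wunsch,
  BLOSUM62, affine gaps), identity matrices, and the four scenarios
  *bestSeqIdTemp* (highest sequence identity), *bestStructTemp* (lowest
  RMSD to the solved query, a theoretical bound), *3bestSeqIdTemp* (three
  best-identity templates, reported with their mean identity MSI) and *All*;
  best-model selection by an externally supplied quality score (e.g. DOPE,
  lower = better).
- **Synthetic ensembles.** A generator that emulates a modelling engine's
  output: a reference conformation written as a PB string, rebuilt to ideal
  backbone geometry (NeRF), perturbed per model with position-dependent von
  Mises torsion noise (loose in CDR-like windows, tight in frameworks,
  segment-anchored so noise stays local), plus synthetic quality scores
  correlated with true RMSD. Every stage of the pipeline is testable with no
  downloads and no modelling engine.

## Worked example

```python
import numpy as np
from vhhassess import (EnsembleSpec, generate_ensemble, assign_pb_sequence,
                       compute_backbone_dihedrals, pb_frequency_profile,
                       neq_profile, select_best_model, superpose_calpha,
                       region_rmsd)
from vhhassess.synthetic_data import reference_chain

regions = {"FR1": (1, 15), "CDR1": (16, 20), "FR2": (21, 30), "CDR2": (31, 35),
           "FR3": (36, 50), "CDR3": (51, 62), "FR4": (63, 75)}
pb_ref = "d" * 50 + "m" * 12 + "d" * 13      # strand scaffold, helical loop
kappa = np.full(75, 500.0)                   # rigid frameworks...
kappa[50:62] = 2.0                           # ...loose CDR3-like window
spec = EnsembleSpec(pb_ref, kappa, n_models=100, seed=1,
                    anchor_segments=list(regions.values()))
models, scores = generate_ensemble(spec)

pbs = [assign_pb_sequence(compute_backbone_dihedrals(m)) for m in models]
neq = neq_profile(pb_frequency_profile(pbs))
print(f"mean Neq inside CDR3 window : {np.nanmean(neq[50:62]):.2f}")
print(f"mean Neq elsewhere          : {np.nanmean(np.r_[neq[2:50], neq[62:73]]):.2f}")

best = select_best_model(dict(zip(scores.model_id, scores.score)))
native = reference_chain(spec)
best_model = models[list(scores.model_id).index(best)]
print(f"best model by score         : {best} "
      f"(global RMSD {superpose_calpha(best_model, native).rmsd:.2f} A)")
ff = region_rmsd(best_model, native, regions, mode="frame_fit")
print("frame-fit RMSD per region   :",
      " ".join(f"{k}={v:.2f}" for k, v in ff.items()))
```

prints

```
mean Neq inside CDR3 window : 2.69
mean Neq elsewhere          : 1.22
best model by score         : model_085 (global RMSD 1.77 A)
frame-fit RMSD per region   : FR1=0.52 CDR1=0.18 FR2=0.89 CDR2=0.71 FR3=0.76 CDR3=4.33 FR4=0.40
```

The noisy window is recovered both by the entropy statistic (N<sub>eq</sub>
2.7 vs 1.2) and by the frame-fit RMSD (4.3 Å in CDR3 against ≤ 0.9 Å in
every framework): conformational diversity and structural error concentrate
exactly where the sampling noise was injected, which is the qualitative
signature this analysis is designed to expose in real model ensembles.

A command-line interface mirrors the library:
`vhhassess simulate | pb-assign | rmsd | select-templates | assess | compare`
(see `vhhassess --help`; `assess` takes a YAML config and writes a JSON
report plus per-position CSV/TSV tables, `compare` tabulates pairwise
ΔN<sub>eq</sub>/ΔPB between runs).

## Documentation

`docs/methods.md` describes the model, the numerical choices, what the
synthetic generator does and does not emulate, and known limitations.
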