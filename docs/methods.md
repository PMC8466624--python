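# Methods

## Protein Blocks assignment

The PB alphabet describes local backbone conformation with 16 prototypes
(*a*…*p*), each an 8-vector of dihedral angles over a five-residue window
centred on the assigned residue, ordered ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i),
φ(i+1), ψ(i+1), φ(i+2). The prototype table shipped in
`src/vhhassess/data/pb_reference_angles.tsv` is the canonical one published
with the alphabet (de Brevern, Etchebest & Hazout, *Proteins* 2000,
41:271–287) and used unchanged by the standard assignment tools. Assignment
computes, for every position with a fully defined window,

RMSDA(w, p) = sqrt( (1/8) Σ_k wrap(w_k − p_k)² ),

with each angular difference wrapped to [−180°, 180°], and takes the letter
of the minimal-RMSDA prototype; exact ties (measure zero on real data) break
alphabetically, making assignment deterministic. Positions 1, 2, L−1, L and
any position whose window touches a missing atom or chain break get the
placeholder `Z`. Assignment depends only on dihedrals, hence is invariant
under rigid-body motion; the tests assert this, plus exhaustive recovery of
each prototype from its own exact window.

## Ensemble statistics

Per-position PB counts over an ensemble exclude `Z` (the statistics run over
the 16 letters only; a position observed in no model is marked "no data" and
propagates NaN). From frequencies f_x:

- **Neq** = exp(−Σ f_x ln f_x), with 0·ln 0 ≡ 0. Bounds 1 ≤ Neq ≤ 16, the
  maximum attained exactly at the uniform distribution.
- **ΔNeq** is reported *signed*, Neq(A) − Neq(B) with the order fixed by the
  caller (the magnitude is what is usually plotted; the sign convention is
  therefore documented rather than assumed).
- **ΔPB** = Σ |f¹_x − f²_x| per position, in [0, 2]; it equals twice the
  total-variation distance between the two letter distributions and is a
  metric on profiles (symmetry, identity, triangle inequality are asserted
  on random profiles in the tests).

## Superposition and RMSD

Rigid superposition minimises Σ‖R·x + t − y‖² over proper rotations via the
SVD solution (`scipy.spatial.transform.Rotation.align_vectors`, which
corrects reflections); the residual is recomputed explicitly from the fitted
transform because the singular-value form loses precision to cancellation
when the fit is near-exact. Superposition requires ≥ 3 non-collinear paired
C-alpha atoms; pairs with missing atoms are dropped.

Region-wise RMSD offers two frames and reports both in the assessment
pipeline:

- `local_fit` (default): each region is superposed on its own C-alpha atoms,
  so framework and loop values are mutually independent;
- `frame_fit`: one superposition on all FR C-alpha atoms, then per-region
  RMSD without refitting — this exposes loops that swing relative to a
  well-modelled scaffold.

The choice of frame changes per-region values materially; published
region-wise numbers rarely state their frame, so both are explicit here.

CDR loop-termini geometry is the Euclidean distance between the C-alpha
atoms of the first and last residues of a region (the loop anchors).

Ramachandran classification uses deliberately simple polygons shipped as
data (`data/ramachandran_regions.json`): a favored set covering the broad
β/PPII basin (split across the ψ wrap) and the right-handed α basin, an
allowed set consisting of the negative-φ half-plane plus the left-handed α
basin, and unfavorable as the complement. These are coarse boxes for ranking
model plausibility, not a calibrated validator; fractions are percentages
over the positions with both φ and ψ defined and sum to 100.

## Sequence alignment and template selection

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62, gap open 10, gap extend 0.5, Biopython's
convention: a gap of length k costs open + (k−1)·extend; end gaps penalised
identically). An independent quadratic-space Gotoh dynamic program in the
test suite asserts score equality on random sequences. Percent identity is
identities divided by alignment columns, terminal gap columns excluded —
stable when query and template lengths differ (the common CDR3-length
situation); users can recompute it from the returned aligned strings.

Scenario logic: *bestSeqIdTemp* = argmax identity excluding self;
*bestStructTemp* = argmin C-alpha RMSD excluding self (requires solved query
structures: a theoretical upper bound, not a usable protocol);
*3bestSeqIdTemp* = top-3 by identity with MSI their arithmetic mean; *All* =
full identity ranking. All ties break by lexicographic id. Best-model
selection takes the minimum of an externally supplied score (DOPE
convention: lower is better); the score itself is an input, never computed
here. A greedy redundancy filter (keep an id only if below a pairwise
identity threshold, default 95%, against everything already kept; scan in
lexicographic order) is provided as a dataset utility.

PIR alignment files stack one or more pairwise alignments onto the common
query: template insertions relative to the query open gap columns in every
other row; templates are written as `structureX` entries and the query last
as `sequence`. Gap-only columns and inconsistent de-gapped query sequences
are rejected.

## Synthetic ensemble generator

The generator stands in for a comparative-modelling engine so the analysis
is testable end to end. Design choices:

- **Noise lives in dihedral space** (von Mises, mean 0, per-position
  concentration κ) because PBs are dihedral-defined: κ directly controls the
  PB-level diversity to be recovered. Defaults used throughout the tests and
  examples follow the study conditions this emulates: ensembles of 100
  models per query; κ = 500 in framework-like segments (σ ≈ 2.6°, the
  near-rigid template-constrained regime) and κ = 2 in CDR-like windows
  (σ ≈ 40°, loops with little usable template information); κ = ∞ is the
  exact zero-noise limit.
- **Ideal covalent geometry**: bonds N–CA 1.458 Å, CA–C 1.525 Å, C–N
  1.329 Å, C–O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°,
  CA–C–O 120.8°; ω fixed trans (180°). Coordinates are rebuilt by NeRF-style
  extension, so torsions are the only degrees of freedom and the
  build→measure round trip is exact to numerical precision (< 1e−6°,
  asserted).
- **Segment-anchored assembly.** Pure NeRF propagation levers every residue
  downstream of a noisy torsion, which real restraint-based modelling does
  not do (frameworks are template-anchored). With `anchor_segments` (usually
  the FR/CDR region map), each segment is rebuilt from the *reference*
  chain's local frame at the residue preceding the segment, and the torsion
  that orients a segment from its anchor is taken from the reference, so
  noise displaces its own segment only. The cost is a small peptide-bond
  discontinuity at segment boundaries (negligible at framework noise
  levels); PB windows spanning a noisy boundary can pick up extra letter
  diversity within ±2 positions of it. With zero noise the reference
  coordinates are reproduced exactly regardless of segmentation.
- **Synthetic quality scores** are affine in the model's true C-alpha RMSD
  to the reference plus Gaussian noise (defaults: offset −13000, slope
  150/Å, σ = 5 — DOPE-like magnitudes with lower = better and a strong
  score–quality correlation). This gives the scenario logic a realistic
  ranking signal whose fidelity degrades smoothly as `score_noise` grows.
- **Sequence families** are produced by mutating a hand-assembled VHH-like
  ancestor (synthetic, with the conserved Cys22/Cys96 pair and FR4 WGQG
  motif) at a per-position rate solved from the target mean pairwise
  identity via E[identity] = (1−p)² + p²/19; the default target of 64%
  matches the dataset this emulates, and calibration within ±3 points at
  n = 20 is asserted.
- **Determinism**: one `numpy` Generator seeded from the spec drives all
  draws in a fixed order (per model: φ noise, ψ noise, score noise), so a
  fixed seed gives bit-identical output.

What the generator does **not** emulate: side chains, physical loop-closure,
bond-length/angle variation, alignment-gap-induced insertions/deletions, or
any energy function. Tests passing on synthetic ensembles therefore
demonstrate the correctness and sensitivity of the *analysis* — that Neq,
ΔPB and region RMSD recover where sampling noise was injected — not the
accuracy of any modelling protocol on real proteins.

## A note on closed-loop PB recovery

`pb_string_to_dihedrals` maps each letter to its prototype's central (φ, ψ).
Only the repetitive prototypes — *d* (central β-strand) and *m* (core
α-helix) — have windows consistent with a repeating backbone, so only their
homogeneous runs survive the full string → torsions → coordinates → torsions
→ string loop; the other 14 letters are caps and transition motifs whose
8-angle windows demand conflicting values of the same dihedral at
overlapping positions, a property of the alphabet itself. The test suite
therefore asserts run-level recovery for *d* and *m* and exact single-window
recovery for all 16 prototypes.

## Region annotation

FR/CDR bounds are taken from explicit per-structure overrides whenever
available (the analysis-relevant case; published bounds differ between
numbering schemes). The built-in heuristic is anchor-based — conserved
cysteines near positions 22 and 92 and the FR4 WGxG motif; CDR1 = Cys1+4 …
Cys1+14, CDR2 a fixed-width window at Cys1+23, CDR3 = Cys2+3 … one before
the WGxG tryptophan — and refuses (with "supply override") rather than
guessing when anchors are missing. It is a convenience, not a numbering
implementation.

## Degenerate inputs and numerical conventions

Angles are wrapped to (−180°, 180]. Torsions with nearly collinear atoms
(residual vector norms < 1e−9) are undefined (NaN) with a warning. Missing
backbone atoms flag the residue incomplete and propagate NaN through every
dihedral, PB window and statistic that touches them. Alternate locations
resolve to the highest occupancy (ties prefer the blank altloc, then "A").
All residue ranges in the public API are 1-based inclusive on a contiguous
internal index; original author numbering and insertion codes are carried
for reporting only.

## Problem sizes in the test suite

Synthetic checks run at chain lengths 25–75, ensembles of 8–100 models, 20
seeds for selection-probability checks, 1500-axis × 1°-step rotation grids
for the superposition oracle and n = 20 sequence families for identity
calibration — sizes chosen so the full suite completes in well under a
minute while each statistical assertion retains a comfortable margin (e.g.
the Neq contrast between κ = 2 and κ = 500 windows exceeds 2:1).
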