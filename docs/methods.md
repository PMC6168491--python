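# Methods

## Minimal chemical-shift mapping

Two ¹⁵N-HSQC spectra of the same protein (apo vs complex, or two
complexes) differ by peak displacements.  Without assignments the true
peak correspondence is unknown; minimal-shift mapping replaces it by
the one-to-one matching that minimises the total weighted distance

Δδ(a, b) = √(Δδ_H² + (Δδ_N / w)²),  w = 7 by default,

and reports Δδ_min, the matched distances averaged over the matched
peaks.  Properties that follow from the construction (and are asserted
in the tests):

* Δδ_min(A, A) = 0 exactly, and Δδ_min is symmetric for equal-size
  lists under optimal matching.
* Δδ_min never overstates the true average perturbation: the optimal
  matching's total distance is bounded by the true correspondence's
  total distance.  Large individual displacements are therefore
  systematically truncated — a peak that moves far is matched to some
  nearer peak.  Δδ_min is a lower bound, useful for *comparing*
  perturbations, not for quantifying any single residue's shift.
* Optimal (exact assignment problem, solved with
  `scipy.optimize.linear_sum_assignment`) ≤ greedy (closest pair
  first) in total distance.  Both modes are provided because the
  "minimal distance" idea admits either reading; results record which
  mode produced them.  For lists of ≤ 6 peaks the optimal mode is
  verified against exhaustive enumeration over all permutations.

Unequal list sizes: min(|A|, |B|) pairs are matched; unmatched peaks
are reported but never averaged.  No distance gate is applied by
default; `max_distance` drops pairs post hoc when set.  The ¹⁵N
divisor is configurable (`WeightingScheme`) since several weighting
conventions circulate; 7 is the common one.

Asn/Gln NH₂ side-chain doublets carry no backbone information and are
excluded before matching: always when annotated, and optionally by a
doublet heuristic (two unannotated peaks sharing ¹⁵N within 0.2 ppm,
both ¹H in 6.4–7.8 ppm).  Those two thresholds are package choices
describing where amide side-chain doublets live; annotated backbone
peaks are never removed.

## Peak picking

"Noise level" is the scaled median absolute deviation
(σ = 1.4826 × MAD) of all grid intensities — robust to the sparse
signal sitting on top.  A pick is a grid point strictly greater than
its 8 neighbours with intensity above factor × σ (default factor 1.4,
a deliberately permissive setting that assumes later curation; the
i.i.d.-noise false-pick rate at that factor is bounded in the tests at
< 10% of pixels, measured ≈ 6%).  Apex positions are refined by
three-point parabolic interpolation per axis, clipped to ±0.5 grid
step; plateaus resolve to the lowest row-major index.  No lineshape
fitting is attempted.

Pixel noise on the flank of a genuine peak can raise secondary strict
maxima within ~2 linewidths of the apex.  `merge_radius` enables
resolution-limited suppression (keep the strongest pick inside the
box); choose half the closest expected peak separation, which cannot
fuse genuinely distinct peaks.  Default off, so the raw local-maximum
semantics are preserved.

## Synthetic slow-exchange series

The generator emulates what a high-affinity 1:1 complex does to an
HSQC: a fixed interface subset of peaks jumps to new positions, the
rest stay put.  Defaults: 90 (or 72, for the mutant-series scenario)
backbone amides uniform over ¹H 6.5–10.5 × ¹⁵N 103–133 ppm with
weighted pairwise separation ≥ 0.05 ppm; interface fraction 0.3 (the
true interface size of a PAH1-sized domain is unknown — this is a
flagged guess); displacement magnitudes Gamma-distributed (shape 2,
positive and right-skewed) with uniform random direction in weighted
shift space; isotropic measurement jitter σ = 0.004 ppm on every peak
of every list, including a re-measured apo.

One displacement field is drawn per scenario and shared by all labels,
scaled by each label's effect multiplier: a weaker-binding mutant
moves the same peaks in the same directions, just proportionally less.
This makes the two analysis conventions coherent — mutant-vs-WT
distances are exactly (1 − m) times the field — which is what lets a
mutant series measure per-residue contributions.  The `fig4b`
multiplier set (WT 1.0, T898A 0.80, T898E 0.70, I894A 0.52, L900A
0.42, L897A 0.07) encodes the canonical residue-importance ordering
L897 > L900 > I894 > T898 of the Tet1-SID, with each value derived
from the ratio of the corresponding published mutant-vs-WT Δδ_min to
the apo-vs-WT value; the WT mean displacement (0.47 ppm per interface
peak) was calibrated once by simulation so that the apo-vs-WT Δδ_min
averages ≈ 0.127 ppm.  These anchors shape the simulation; the
simulated Δδ_min values are emulations, not recomputations, and the
mutant-vs-WT means come out a few thousandths of a ppm high because
matching truncation affects the large apo-vs-WT displacements more
than the smaller mutant-vs-WT ones.

Slow exchange at full saturation is represented by fully displaced
peaks; the doubled apo+bound peaks of partial saturation are available
behind the `substoichiometric` flag and excluded from default
scenarios.  What the generator does **not** emulate: intensity changes
and line broadening, peak overlap/disappearance, temperature or
referencing drift between spectra, and any relation between a peak's
position and its residue identity.  Passing tests therefore certify
the analysis machinery (matching, averaging, ranking, picking) under
the stated statistical assumptions — not performance on real spectra
with exchange broadening or heavy overlap.

Rendered grids are sums of 2D Gaussians (default σ 0.02 ppm ¹H ×
0.25 ppm ¹⁵N) plus i.i.d. Gaussian noise, axes covering the peak
bounding box padded by 5 linewidths.

## SID discovery

Ideal α-helix geometry: 100° per residue.  The hydrophobic moment is
the Eisenberg vector sum divided by window length, computed on the
centred scale (so it is invariant to adding a constant; `X` contributes
the scale mean, i.e. zero).  Hydrophobic = centred scale value > 0.
A face is coherent when the minimal covering arc of the hydrophobic
residues' wheel angles is ≤ 180°.  The motif alphabets (small: A G S
C; large: L I V M F) are package definitions generalising the
A/A + L/L instances seen in known SIDs.  Conservation is 1 − H/log 21
per alignment column (gap as 21st symbol).  The combined scan score is
z-scored μH + mean conservation + motif bonus with default weights
1:1:1 — configurable, with no claim that this reproduces any
particular expert's manual inspection.  Default window length 11 (the
minimal SID); moment-based helicity scoring stands in for external
secondary-structure predictors, which are out of scope.

The bundled `TET1_SID_FIXTURE` window encodes only the functionally
characterised Tet1 residues (A893, I894, A896, L897, T898, L900, E902)
with neutral serine placeholders elsewhere; it is a synthetic stand-in,
not a database sequence.  Real-sequence scans require user-supplied
FASTA/alignments.

## Structure comparison

PDB (and mmCIF, where gemmi reads it) via gemmi; one model per read,
default the first member of an ensemble; altloc blank/'A' kept.  Helix
segments come from HELIX records; segments correspond by order, and
residues within a segment pair are matched by global sequence
alignment of the segment sequences (plain offset for equal lengths).
Backbone = N, CA, C by default (O one flag away).  Superposition is
the closed-form Kabsch solution
(`scipy.spatial.transform.Rotation.align_vectors` after centring);
the tests verify it against an independent brute-force rotation search
(30° Euler grid + Nelder-Mead refinement).  `compare_pah1_structures`
packages the whole four-helix comparison for user-supplied ensemble
files such as PDB 2RMS vs 2CZY.

## Problem sizes and numerical choices

Simulation-backed checks use 50 seeds for ordering/recovery rates, 20
seeds for picking recall/precision, 200 pairs for the matching oracle
and 1000 for optimal-vs-greedy; peak lists of 60–90 peaks and grids of
256×512 points — comfortable desk-scale sizes at which every rate
estimate has a standard error of a few percent.  Greedy matching
breaks distance ties lexicographically on (id_A, id_B); picking
plateaus break to the lowest flat index; all generators are
deterministic per seed.  Floating-point zero comparisons in tests use
absolute tolerances of 1e-6 Å (superposition) and 1e-10 ppm
(matching totals).
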