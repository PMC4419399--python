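# Methods

This note records the models, conventions and numerical choices behind
`classfrag`, and what its synthetic experiments do and do not show.

## Backbone model and geometry

A structure is the ordered list of per-residue backbone heavy atoms N, CA,
C and (optionally) O, with a 1-letter sequence. Residue indexing is 1-based
and fragment windows are inclusive; PDB serial numbers and insertion codes
are discarded in favour of sequential indices. Consecutive residues with a
CA–CA distance above 4.5 Å are treated as a chain break (a conservative
proxy for a broken peptide bond; the trans-peptide CA–CA distance is
~3.8 Å); torsions spanning a break are undefined. Undefined torsions (φ of
the first residue, ψ/ω of the last, anything across a break) are `None` —
a sentinel, never a placeholder angle.

Chains are rebuilt from torsions by sequential internal-to-Cartesian
placement (NeRF) with fixed ideal covalent geometry: bonds N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; angles N–CA–C 111.2°, CA–C–N
116.2°, C–N–CA 121.7°, CA–C–O 120.8°; ω defaults to 180° (trans). The
carbonyl O is placed anti to the next residue's N so rebuilt chains are
directly usable for hydrogen-bond-based secondary-structure assignment.
The build/measure round trip closes to well below 1e-4° for chains of at
least 200 residues. Dihedrals follow the IUPAC sign convention
(cross-checked against an independent implementation).

Optimal superposition is the SVD Kabsch solution with the determinant
correction, so reflections are excluded; degenerate (collinear) inputs go
through the same SVD without special-casing.

## Secondary structure and structural class

Secondary structure is assigned with the Kabsch–Sander electrostatic
hydrogen-bond model: the amide H is reconstructed 1 Å from N along the
previous residue's O→C axis (no H for the first residue, after a break, or
for proline), and a bond is called when

    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332 kcal/mol < −0.5.

A residue is H when it lies inside a run of two consecutive i→i+4 turns
(minimal α-helix), E when it joins a parallel or antiparallel bridge
pattern (partners ≥ 3 residues apart), and C otherwise. The assignment is
3-state by construction; when reading 8-state strings from DSSP output,
G/I collapse to H, B to E and everything else to C. An isolated extended
strand is coil — a bridge needs a partner. Agreement with an independent
DSSP implementation is tested on helix and sheet fixtures. Distances below
0.5 Å between donor/acceptor atoms are treated as clashes, not bonds.

Class assignment uses the helix/strand content thresholds employed by
CATH: helix ≥ 15 % and strand < 10 % → mainly-alpha; the reverse →
mainly-beta; both at/above threshold → alpha-beta; both below → few
secondary structures. Values exactly at a threshold count as above (the
thresholds are quoted in the literature without a boundary rule; this
choice is documented and tested, and the four rules partition the unit
square exactly). For SCOP, the same content rules decide the pure classes;
the α/β-vs-α+β split — historically a manual call — is automated here:
α/β requires a majority (> 0.5, configurable) of parallel bridges *and*
alternating helix/strand segments along the sequence (≥ 2 H↔E transitions
ignoring coil); otherwise α+β (segregated strands, antiparallel sheets).
Few-SS chains of ≤ 100 residues (configurable) map to small-protein;
longer low-content chains fall back to the dominant-content pure class —
SCOP has no few-SS class and such chains are rare and ambiguous anyway.
Externally supplied SS strings bypass the assigner, so annotations can
reproduce exactly what an external DSSP run would give.

## Template selection

Template databases are per-residue flat tables (id, chain, position,
residue, SS letter, φ/ψ/ω, CA coordinates, resolution) in the style of
fragment-picker "vall" files, loadable from TSV or compiled from a
directory of PDBs (directory mode computes torsions and SS from the
coordinates; tabular mode trusts the file). Selection keeps a template iff

* its class label equals the target's (same scheme),
* its resolution is ≤ 2.5 Å (inclusive boundary; templates without a
  resolution, e.g. NMR entries, are excluded while a cut is active), and
* it is not a homolog hit with E-value strictly below 0.05.

Homology is consumed as a precomputed hit table; the toolkit does not run
a sequence search. A difflib-based identity proxy (≥ 30 % identity over
≥ 50 % of the target) is provided for when no hit table exists — a
clearly-labelled heuristic stand-in, not equivalent to a profile search.

## Fragment picking

For each target position and fragment length (3 and 9 by default), every
admissible template window is scored

    total = w_prof · profile_score + w_ss · ss_match_score,

with `profile_score` the per-column regret of the template residue against
the position-specific profile (best attainable column score minus the
template residue's score, summed; ≥ 0, 0 iff the template maximises every
column) and `ss_match_score` the summed 1 − P(template SS letter) under
the predicted 3-state probabilities. Both weights default to 1.0. These
are deliberate simplifications of a production picker's scoring (which
also uses Ramachandran priors, solvent accessibility, etc.); they preserve
the properties that matter here — monotone, non-negative, zero exactly at
a perfect match — and are configurable. When no profile is available, a
BLOSUM62 row per target residue serves as a documented fallback.

A window is admissible when it contains no load-bearing torsion sentinel:
rebuilding a fragment never consumes the first residue's φ or the last
residue's ψ/ω, so sentinels at those edge slots (chain termini) are
harmless, while a sentinel anywhere else marks a chain break and
invalidates the window. The lowest-scoring `n_frags` windows (default 200,
the picker convention for ab initio runs) are kept per position, ties
broken by (score, template id, template start) for determinism. With
several SS-prediction sources, the budget is split into per-source quotas
(equal shares, earlier sources take the remainder; duplicates stay with
the earlier pool) — the quota selection degenerates to plain top-N with a
single source, since per-source shares are not published. Libraries are
written as Rosetta3-style text blocks and round-trip through the reader.

`library_fit` rebuilds each candidate from its torsions and reports, per
position, the minimum CA RMSD against the corresponding native window
after superposition, plus the fraction of candidates under 1 Å — the
library-quality measure used throughout.

## Decoy evaluation

GDT_TS is the mean over cut-offs 1/2/4/8 Å of the maximal fraction of CA
atoms superposable within the cut-off (strict <, following the metric's
definition); GDT-HA uses 0.5/1/2/4 Å. The exact maximisation is
combinatorial, so the score uses the standard iterative heuristic: seed on
contiguous windows, superpose, include pairs within the cut-off,
re-superpose on the included set to a fixed point (≤ 20 iterations), keep
the best fraction over seeds. Chains of ≤ 20 residues are seeded on every
window length — on such instances the score matches an exhaustive-seed
oracle to 1e-6; longer chains use the LGA-style lengths {3, 5, 7, n},
which may slightly underestimate the combinatorial optimum (tested for
dominance over the single global superposition and for rigid-transform
invariance within 0.01).

A run's aggregate GDT (RMSD) is the mean of its 10 highest GDT_TS (10
lowest RMSD) decoys; quality bins follow the standard GDT thresholds:
Poor < 40 ≤ Moderate < 60 ≤ Good < 85 ≤ HighQuality, with "informative"
meaning GDT ≥ 40. The literature words the upper boundary both as "up to
84" and "85 and above"; the continuous-score resolution here puts 85.0 in
HighQuality. Convergence indices are the 1-based generation indices of the
first decoy attaining the run's best GDT, best RMSD, and (when a single
decoy attains both) both; ties go to the earliest. The relative speed-up
of run A over B is 100·(mean_B − mean_A)/mean_B, one decimal.

Paired run comparison reports, per metric, the percentage of targets
improved / unaffected / worsened (equality judged after rounding to one
decimal, the precision benchmark tables print), the mean absolute and
relative change within each group, and a two-sided paired significance
test — Wilcoxon signed-rank by default (the benchmark p-values are
reported without naming a test; a paired t-test is available via
`test="ttest"`).

## Synthetic data: what it emulates and what it does not

The generator provides the study conditions at desk scale. Ideal-SS chains
use φ/ψ = (−57, −47) for helix and (−119, 113) for strand; coil torsions
are drawn uniformly from a broad allowed region (φ ∈ [−160, −60],
ψ ∈ [−60, 160]) with configurable Gaussian jitter (default SD 10°).
Template databases draw resolutions uniformly from [1.0, 3.5] Å and record
each template's SS letters from its generative blueprint (as a real vall
records an assignment made once on the full structure); class-blueprint
segment ranges are chosen so coil fractions are comparable across classes,
making class membership — not coil abundance — the signal separating
template pools. Paired β-strand fixtures place a second ideal strand by a
deterministic grid search maximising inter-strand hydrogen bonds
(synthetic stand-ins for real sheets, labelled as such).

Decoy sets perturb native φ/ψ with wrapped-Gaussian noise of SD σ and
rebuild with ideal geometry; generation order is the decoy order. This
reproduces the statistics the evaluation machinery consumes (quality
decaying with σ, convergence indices, top-k aggregates) but *not* the
energy landscape, compactness or error correlations of a real
fragment-assembly simulation — passing tests show the analytics are
correct, not that any predictor achieves particular accuracy on real
proteins. Likewise, synthetic profiles/SS predictions put tunable weight
(`sharpness`) on the truth: sharpness 1 is a perfect predictor,
1/3 an uninformative one.

Problem sizes in the test suite and acceptance script (40–90-residue
templates, 20-template databases, 20-repeat experiments, 40–50-decoy
sweeps) were chosen as the smallest at which the compared effects are
statistically unambiguous under seeded randomness.

## Known limitations

* The GDT search is heuristic above 20 residues; scores are lower bounds.
* The SCOP α/β discriminator automates a historically manual judgement;
  borderline folds (e.g. mixed sheets) can be assigned either way.
* The identity-proxy homolog filter is far weaker than a profile search;
  supply a real hit table for ab initio rigour.
* Fragment scoring is a two-term simplification of production pickers;
  weights are exposed but have not been tuned against real benchmarks.
* All quantitative claims in the tests concern synthetic data; no CASP- or
  PDB-scale benchmark is bundled.
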