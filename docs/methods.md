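# Methods

This note describes the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Conventions

Residue indices are 1-based; intervals are closed. A contact is an
unordered residue pair stored as *i* < *j* with a confidence in [0, 1];
duplicate pairs keep the maximum score. The package-wide contact definition
is Cβ–Cβ distance ≤ 8 Å (Cα where Cβ is undefined, i.e. glycine) at
sequence separation |*i* − *j*| ≥ 5 — the convention most contact
predictors are trained against. It is used identically for ground-truth
maps, model validation and the geometric property tests, and both the
distance cut-off and the separation are exposed as parameters so
alternative conventions can be probed.

"Top-*L*" selection (the *L* highest-confidence contacts for a chain of
length *L*, ties broken toward smaller *i*, then *j*) is the default
contact subset for every analysis stage.

## Domain boundaries from contact density

The spanning count *S*(*k*) = |{(*i*, *j*) selected : *i* < *k* ≤ *j*}|
counts selected contacts bridging position *k*. Compact domains produce
high plateaus; inter-domain linkers, bridged by few or no contacts,
produce valleys. *S* is smoothed with a Gaussian (σ = `bandwidth`,
default 3 residues); local minima within `min_margin` (default 10)
residues of a terminus are discarded; minima closer than the bandwidth to
a deeper minimum are merged into it; survivors are ranked by smoothed
density. A reported minimum *k* is read as the first residue of the
C-terminal side of the cut.

Two caveats established on synthetic data:

* smoothing can shift a call one or two residues into the sparser flank
  of a valley;
* on structureless (uniform random) maps the profile is dome-shaped, so
  the minima that exist concentrate mid-chain — boundary calls on such
  maps are not uniformly distributed and should not be interpreted
  without the accompanying repeat/validation evidence.

## Internal tandem repeats

Splitting the chain at *b* yields two intra-half submaps (cross-half
contacts are discarded and counted). Each half is binarised at its top
1.5 × (half length) contacts and compared by Jaccard overlap after
shifting the first half by an offset Δ, over the index window valid in
both halves; the statistic is the maximum over candidate splits and
|Δ| ≤ 10. Because every (b, Δ) pair with equal *b* + Δ describes the same
inter-unit alignment, the *period* *b* + Δ is reported as the canonical
repeat boundary (for a two-unit tandem it estimates the first unit's
length).

Significance: each half's contact set is replaced by a random set with
exactly the observed multiset of separations |*i* − *j*| (per separation,
positions sampled without replacement), the same maximisation is applied,
and *p* = (1 + #{null ≥ observed}) / (1 + *n*_perm). The separation
multiset is the dominant nuisance structure of contact maps (helices
impose strong banding), so preserving it makes the null conservative
against banding artefacts while destroying positional alignment.
`n_perm` < 19 is rejected (the p-grid would be coarser than 0.05);
`n_perm` = 199 is the default.

Repeats are compared in direct orientation only: a contact map is
invariant under rigid 3D inversion, so an inverted-topology repeat still
produces matching intra-unit maps; the units' membrane orientations are
inferred from topology and re-entrant geometry, not from the map.

Known limitation: an idealised, regular α-helical bundle is itself weakly
periodic — any two antiparallel helix–helix interfaces produce contact
stripes of the same slope, leaving a genuine residual overlap (~0.15
Jaccard between the halves of a 4-TM bundle even with varied helix
lengths, loop lengths, packing distances, tilts and registers). The
permutation test correctly flags this weak pseudo-symmetry in roughly a
quarter of such constructs. The test's calibration claim is therefore
stated on maps with no positional structure (type-I error ≤ 0.075 at
nominal 0.05), and a significant repeat call on a helical bundle should
be read together with its effect size (the Jaccard score): genuine
two-unit tandems score several-fold higher than the bundle floor.

## Re-entrant helix candidates

Topology predictors typically annotate a re-entrant helix–turn–helix
loop as a single membrane-spanning segment. The geometric detection rule:
a membrane segment qualifies iff its secondary-structure states contain
exactly one maximal coil run of length `min_break`–`max_break`
(defaults 2–8, bracketing observed turn lengths of 2 and 6 residues),
flanked on both sides by helical runs of ≥ `min_limb` (default 4)
residues, with the run's centre inside the middle 50% of the segment.
The rule is deterministic: with clean secondary structure its
false-positive rate on hairpin-free bundles is zero.

Packing evidence: over the top-*L* contacts between a candidate limb and
a flanking unbroken membrane segment, the Spearman correlation ρ of the
contacting index pairs is −1 for ideal antiparallel packing and +1 for
parallel; ρ is reported only at support *n* ≥ 3. The partner is the
flanking segment with the largest total support *n*₁ + *n*₂. Hairpin
geometry fixes which limb should be antiparallel: limb 1 (N-side of the
break) for a preceding partner, limb 2 for a following one. The
composite score is
*w*_geom + *w*_pack · max(0, (−ρ_anti + ρ_para)/2), defaults
0.4/0.6, so a candidate with no usable packing evidence keeps the
geometric floor of 0.4. The rule cannot distinguish a genuine re-entrant
loop from a strongly kinked TM helix; output is always labelled a
candidate.

## Hydrophobic moments

μH = (1/N) · √[(Σ Hₙ sin δn)² + (Σ Hₙ cos δn)²], n = 0…N−1, δ = 100°
per residue, with Hₙ from the packaged Fauchère–Pliska (1983) side-chain
transfer scale (H(G) = 0, so poly-glycine scores exactly 0). μH is
normalised by window length; the moment direction is reported in the
wheel frame with residue 0 at angle 0°. The default analysis window is
the 15 residues immediately preceding each re-entrant candidate's first
limb, where surface-bound amphipathic helices sit in dual-topology
transporter folds; windows that would start before residue 1 are skipped
with a warning. The implementation satisfies the homopolymer closed form
h·|sin(Nδ/2)/sin(δ/2)|/N to 1e-9 and is checked against a direct-sum
oracle.

## Model validation

`topL_precision` is the fraction of the top-*n* (default top-*L*)
predicted contacts realised in a model under the package contact
definition, with per-contact matched/mismatched lists for overlay plots.
Whether a minimum separation applies to the model contacts is a flag,
not an assumption.

## Re-entrant loop library

One entry per annotated re-entrant region: the loop plus the preceding
30 residues (the packing TM helix), clipped at residue 1; entries with
missing coordinates are flagged, not dropped. Redundancy removal is
greedy in input order at 40% global-alignment identity (matches /
alignment columns; match 1, mismatch 0, gap open −1, extend −0.5 — the
threshold, not the aligner, is the contract), making the output
order-dependent by design but deterministic for a fixed order. Clustering
consumes an externally computed structural-similarity Z matrix (symmetric
within 1e-6) and reports connected components at Z ≥ 4.5; membership in
a component is a deterministic statement, and raising the cut-off can
only refine the partition. The structural aligner itself is out of scope.

## Synthetic data

The generator composes ideal α-helical elements (1.5 Å rise, 100° per
residue, Cα/Cβ at 2.3/3.3 Å from the axis) in a 30 Å membrane slab:

* **TM helices** span the slab (optionally tilted, axially shifted, and
  at per-interface packing distances around 9.4 Å);
* **re-entrant hairpins** descend roughly half the slab and return to
  the same side, helix–turn–helix, the turn labelled coil;
* **amphipathic helices** lie along the membrane surface with their
  hydrophobic face toward the bilayer;
* **loops/linkers** are interpolated coil.

Topology labels emulate a *prediction*: hairpins are labelled as single
membrane segments and flip the predicted side — the characteristic
mis-annotation the detector exploits. Sequences are drawn from
hydrophobicity classes only (TM cores uniformly hydrophobic, regenerated
until μH < 0.25; amphipathic faces segregated, μH > 0.35; polar
loops/turns including glycines, which exercises the Cβ fallback).

A duplicated element range ("repeat plan") realises the second unit as a
proper 180° rotation of the first about an in-membrane axis when the
unit crosses the membrane an odd number of times — the pseudo-2-fold
relation of dual-topology folds, which is what makes the two intra-unit
contact maps match (an independently re-idealised copy would differ in
interface wheel phasing and destroy the repeat signal). Even-crossing
units emerge as translated copies directly. Planted truth (boundaries,
repeat units and orientation, hairpin and turn intervals, amphipathic
intervals) is recorded per construct; a planted domain boundary is
represented by the midpoint of its inter-domain linker.

Predicted maps are emulated by `corrupt_map`: each true contact retained
independently with probability `p_tp` (retained confidences uniform in
[0.5, 1]), plus `n_fp` distinct false positives at separation ≥ 5 with
confidences in [0.1, 0.5). Scores and geometry are deterministic per
seed; identical spec + seed gives byte-identical fixtures.

What this does **not** emulate: real packing irregularity (kinks,
non-ideal rotamers), correlated predictor errors (false positives
cluster around true stripes in real maps; here they are uniform),
evolutionary sequence structure, and β-structure. Passing tests
therefore demonstrate correctness and calibration of the statistics
under the stated noise model, not end-to-end performance on real
predictor output.

## Study conditions and problem sizes

The recovery and calibration runs use: 100 two-domain replicates
(L = 162, boundary at 60, p_tp = 0.8, n_fp = 0.2 L); 200 repeat-free
uniform maps (L = 140, 2L contacts) and 50 planted tandems (identical
60-residue units, p_tp = 0.85) at n_perm = 199; 50 dual-topology
replicates (L = 132, p_tp = 0.85, n_fp ≈ 0.2 L) for re-entrant recovery;
50 random ≤ 50-residue models for the precision oracle. These sizes give
stable rate estimates (binomial s.e. ≤ 5 percentage points) while a full
suite run stays in the minutes range on one CPU.

## Numerical choices

* Gaussian smoothing uses nearest-value boundary handling; plateau minima
  keep their first position.
* Offset ties in the repeat maximisation resolve to the smallest |Δ|;
  split ties to the first candidate in ascending order.
* Spearman correlations that are degenerate (constant ranks) are treated
  as absent, like insufficient support.
* Degenerate Jaccard comparisons (empty union) score 0; empty halves are
  allowed and score 0 against anything.
* The pipeline's candidate splits are the top three density minima plus
  the chain midpoint — the canonical a-priori split for a two-unit
  tandem, always reachable within the offset tolerance.
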