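# Methods

## Background and scope

Dihydroorotase (DHOase, EC 3.5.2.3) is the Zn-dependent amidohydrolase that
catalyzes the reversible cyclization of *N*-carbamoyl-L-aspartate (NCA) to
dihydroorotate (DHO), the third step of de novo pyrimidine biosynthesis.  A
flexible loop adjacent to the active site switches between two states:
**loop-in**, in which loop residues contact the bound ligand, and
**loop-out**, in which the loop is oriented away from the site.  Which state
a given crystal structure captures matters practically — loop-in templates
sterically occlude the site in docking — and the state is not a simple
function of ligand occupancy: it varies by enzyme type (I ≈ 45 kDa
Gram-positive/archaeal enzymes, II ≈ 38 kDa eubacterial/fungal enzymes,
III = the DHOase domain of the mammalian CAD protein), by species, and by
ligand identity.

`dholoop` implements the survey machinery behind such an analysis: a curated
per-structure annotation corpus with per-monomer expansion, coordinate-based
loop-state classification, rigid-body superposition with TM-score, survey
aggregation, and a dose-response (IC50) fit.  Docking, AlphaFold model
assessment, and wet-lab assay processing are out of scope.

## Curated annotation corpus

`data/survey_annotations.tsv` transcribes the published survey of 97 PDB
entries from 16 species: accession, description, normalized ligand labels,
metal annotation, author-numbered residue range, sequence identity / TM-score
/ RMSD against the *E. coli* reference entry (1J79), DHOase type, and the
curated loop state of every chain.  Two entries are excluded from analysis
and carry explicit exclusion reasons: 2OGJ (*A. fabrum*; superposes poorly
with true DHOases and lacks the conserved substrate-binding arginine — Arg20
in *E. coli*, Arg63 in *B. anthracis*, Arg65 in *A. aeolicus* — which is
replaced by a tryptophan) and 5NNL (the catalytically inactive DHOase-like
domain of *C. thermophilum* CAD).  The remaining 95 entries expand to 153
monomers.

Two conventions govern expansion:

* **Mixed occupancy.** A chain annotated `in/out` (electron density showing
  a substrate/product mixture) counts as loop-in.  This is forced by
  internal consistency: the human enzyme's published loop-in total (21 of
  52 monomers) is only reached as 12 pure-in plus 9 mixed chains.
* **Disordered loops.** A chain annotated "out" with partially unresolved
  loop residues stays loop-out and carries `disordered_loop=True`.

Because the published table lists ligands per structure while the by-ligand
summary counts monomers, the fixture carries an explicit per-chain ligand
column.  For two-ligand *E. coli* entries the substrate NCA is assigned to
the loop-in (or second) chain and DHO (or the mixture) to the other; 1J79
carries NCA on one chain and orotic acid on the disordered-out chain; chain
E of 6CTY (the single loop-out chain of the *Y. pestis* hexamer) is recorded
unligated, which is the only assignment consistent with malate's published
30-in/0-out record.  Under these assignments the corpus reproduces the
monomer-level tables exactly — totals 86/67, species rows, the type table
(I: 14 in (5 bound) / 3 out (0); II: 51 (51) / 33 (23); III: 21 (21) / 31
(17)), 117 ligand-bound monomers, and the 5-FOA (4/11), malate (30/0),
5-fluorouracil (5/0) rows.  The published by-ligand grand totals (81/36)
disagree with the published by-type bound totals (77/40); the corpus
necessarily reproduces one of them (77/40), and the by-ligand report is
emitted with its per-type breakdown so the residual is visible rather than
forced.

## Loop definitions and location

`data/loop_definitions.tsv` lists, per species, the loop motif (6–16
residues; e.g. `PAGVTTNSAAGVDPND` for *S. cerevisiae*, `PANATTNSSHGVTS` for
*E. coli*, `LNETFSELRLDS` for human) and, where the literature states one
whose width matches the motif, the author-numbered range (101–116 yeast,
105–118 *E. coli*, 1559–1570 human; where published figures disagree on a
range, the variant whose width matches the stated loop length is used).

`locate_loop` uses the range when available, checking the observed sequence
against the motif with up to two mismatches tolerated — loop point mutants
(T109S/T110A-style) must still locate.  Without a range, an exact substring
search over the chain sequence is used; zero hits or multiple hits are
errors rather than guesses.  Location is sequence-only and therefore
invariant under rigid motion.  Unresolved author numbers inside the range
become `missing_numbers`; `loop_completeness` is the resolved fraction.

## Classification rules

**Contact rule** (ligand-bound chains).  The classifier computes the
minimum heavy-atom distance between resolved loop residues and the bound
ligand.  At or below the cutoff the loop is in; above it, out.  The cutoff
defaults to **4.0 Å**, covering hydrogen bonds and van der Waals contacts;
the survey literature never quantifies "directly interacted", so the value
is a reasoned default, exposed as a parameter, and every classification
carries its evidence (per-residue minima, closest atom pair).  A
non-contacting loop with completeness < 0.7 is additionally flagged
disordered.  A fully unresolved loop is UNDETERMINED.

**Apo reference rule** (ligand-free chains).  The chain is superposed onto
a curated ligand-bound loop-in exemplar of the same type with both loops
excluded from the fitted set (core superposition).  The loop's key residue —
the one named in the definition (e.g. Gly148 in *A. aeolicus*, Gly151 in
*S. aureus*), else the middle loop residue — contributes its backbone
carbonyl oxygen, the atom observed to hold its position between apo and
holo loop-in structures.  Displacement of that oxygen from its reference
counterpart ≤ **2.0 Å** means loop-in; distance from the reference ligand's
nearest heavy atom ≥ **5.0 Å** means loop-out; the band in between is
reported UNDETERMINED rather than forced.  The thresholds bracket the one
published quantitative datum for this rule (a loop-out key residue 6.9 Å
from the ligand site).  An unresolved key residue yields UNDETERMINED with
a reason, distinct from a negative call.

**Active site detection.**  Metals are mono-/di-atomic hetero groups from
{Zn, Co, Ni, Mn, Mg, Cd}, Zn first, ordered by distance to the chain
centroid; the first three receive the α/β/γ labels used in the annotation
(reporting only — classification never depends on metal count).  A bound
ligand is a non-water hetero group with ≥ 1 heavy atom within **8.0 Å** of
a metal of the same chain (falling back to the loop centroid for metal-free
chains).  Common buffer/cryoprotectant components (glycerol, ethylene
glycol, sulfate, phosphate, PEG fragments, halides, …) are blocklisted;
acetate, cacodylate, citrate and imidazole are *not*, since the survey
annotates them as bona fide bound ligands.  Detection is monotone in the
radius and rigid-motion invariant.

## Superposition and TM-score

Chains are paired by global sequence alignment (match +1, mismatch 0, gap
−1; Biopython's `PairwiseAligner`) and fitted on Cα atoms with the
closed-form least-squares rotation (SVD with determinant correction, so
reflections are excluded; collinear inputs are rejected).  The TM-score

TM = (1/L_ref) · Σᵢ 1 / (1 + (dᵢ/d0)²),  d0 = 1.24·(L_ref − 15)^⅓ − 1.8 (floor 0.5 Å)

is normalized by the reference (first) chain's Cα count, so a chain scored
against itself gives exactly 1.0, matching the survey's convention where
the reference entry scores 1.0/0.0 against itself.  The score is maximized
by iterative subset refinement: fit on all pairs, refit on pairs with
dᵢ < 2·d0 (never fewer than 3), rescore all pairs, stop when the subset
repeats or after 20 rounds, and report the best score seen.  This is a
deliberate simplification of the full TM-align rotation search — adequate
here because the surveyed comparisons are same-fold (the published
near-identical pair lands at TM ≈ 0.999, RMSD ≈ 0.18 Å) — and sequence-order
-independent alignment is out of scope.  `superpose_chains` optionally
excludes loop segments from the fitted set so the loop's own displacement
can be measured in the superposed frame (the apo rule's core superposition).

The closed-form fit is validated against an independent hierarchically
refined Euler-angle grid-search oracle to 10⁻³ Å on small instances.

## IC50 fit

Inhibition points are (concentration μM, % inhibition).  Two routes:

* `hill_fit`: least squares on y = top / (1 + (IC50/c)^h), top fixed at
  100% unless freed.  Optimization is a deterministic coarse log-grid
  anchored to the data's own concentration range followed by Nelder-Mead
  refinement — seedless and bit-stable, and exactly scale-equivariant
  (scaling all concentrations by k scales the fitted IC50 by k).
* `log_interpolation`: the 50% crossing interpolated linearly on a log
  concentration axis between the bracketing pair — the package's reading of
  a "graphical" determination.

Both refuse with a no-crossing error when the data never bracket 50%
(the 5-fluoroorotate case: 33% at 600 μM, so IC50 > 600 μM).  On the
published myricetin points (22/35/43/71% at 2.5/5/10/20 μM) the crossing
determination gives 11.89 μM, within 5% of the published 12.48 ± 0.47 μM;
the top-fixed Hill fit prefers 10.06 μM because the 43% point at 10 μM
pulls the curve left.  Both are reported; the crossing value is used as the
headline determination since it matches the published method.

## Synthetic data

The generator builds desk-scale structures with exactly known ground truth;
it emulates geometry, not chemistry.  A chain is an idealized helical Cα+O
trace (60 core residues by default, 2.3 Å radius, 100°/1.5 Å per residue)
with the loop appended as a smooth quadratic-Bezier arc whose sequence is a
packaged motif; one sample sits exactly at the arc apex.  Loop-in chains
bulge toward the pocket, loop-out chains away.  The ligand is a rigid
planar 9-heavy-atom fragment (orotate-sized, so detection radii behave
realistically), slid along the pocket axis until the realized loop-ligand
minimum heavy-atom distance equals the requested target within 0.05 Å
(ground truth and brute-force oracle then agree by construction; the
recorded realized distance is within ±0.3 Å of the target by contract).
A Zn is placed 2.2 Å from the ligand center; requesting a contact below the
2.5 Å steric floor, or a placement colliding with the protein, is a
geometry error.  Missing loop residues are simply omitted from the output;
multi-chain files are translated copies.  Everything is deterministic given
the seed, to the byte in the written files.

`make_corpus` draws loop-in targets from [2.6, cutoff − 1] and loop-out
targets from [cutoff + 2, cutoff + 6] — at least 1 Å inside/2 Å outside the
4.0 Å cutoff — with an exact (not sampled) in/out allocation.  On a
200-chain corpus (seed 7) the pipeline recovers the truth table exactly;
this shows the machinery is correct on unambiguous geometry, *not* that the
4.0 Å cutoff resolves borderline real structures, where loop-ligand
distances near the cutoff and partial disorder are common.  Real-structure
disagreements are reported, never silently overridden.

## Problem sizes and numerical choices

Defaults keep every computation desk-scale: the validation corpus is 200
single-chain structures of ~76 residues; superposition instances are a few
hundred Cα pairs; the IC50 grid is 241 × 75 points.  Distances are exact
all-pairs computations in double precision (no spatial indexing — the
largest loop has 16 residues).  Altloc resolution keeps the highest
occupancy, ties to the lexicographically smallest label; only the first
model of multi-model files is read; author numbering is authoritative
throughout because every residue reference in the surveyed literature uses
it.  Report emission sorts keys and fixes float formats, so identical
inputs give byte-identical outputs.

## Known limitations

* The coordinate classifier's cutoffs (4.0 / 2.0 / 5.0 Å) are reasoned
  defaults, not fitted to the curated labels; near-cutoff monomers can
  legitimately disagree with visual curation.
* The TM-score uses sequence-alignment pairing, not the full TM-align
  search; scores for remote folds (TM ≲ 0.5) may be underestimated.
* Checks against deposited PDB entries require network access to fetch the
  coordinates; everything else, including the full validation suite, runs
  offline.
* The per-chain ligand map for mixed-ligand entries is curated, not derived
  from density; mixtures are annotated as the depositors assigned them.
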