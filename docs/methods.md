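# Methods

## The mining model

A candidate bacterial cis-defensin is a secreted precursor whose mature
region carries six cysteines in the CSαβ spacing

```
C x(2,18) C x(3) C x(2,12) C x(4,17) C x C
```

with the canonical cis-defensin disulfide connectivity C1–C4, C2–C5,
C3–C6. The pipeline filters precursors (size → motif → secretion), then
measures all class features on the **mature** peptide (the precursor after
signal-peptide removal). Filtering on precursors while classifying on
matures reflects how the sequences occur in protein databases: the size
window 30–130 is sized for a precursor with signal peptide, whereas tail
and loop lengths are properties of the processed peptide.

Conventions fixed throughout:

* **Coordinates** are 1-based and inclusive.
* **Size bounds are inclusive**: lengths 30 and 130 are kept.
* The motif's `x` matches **any** residue *including cysteine*; this is
  essential, since the eight-cysteine classes (III and V) place their
  extra cysteine pair inside or around the six-cysteine framework.
  Consequently the scan enumerates ordered 6-subsets of cysteine
  positions (with pruning on the sorted gap structure) rather than
  applying a plain regular expression. `X` (unknown residue) never counts
  as cysteine.

## Framework assignment and tie-breaking

A cysteine-rich mature peptide can satisfy the spacing pattern with more
than one 6-subset. The canonical assignment is chosen deterministically:

1. prefer assignments that leave the two extra cysteines *flanking* the
   framework (one before C1, one after C6) — this reproduces the
   plant-like class V pattern whenever it is available;
2. otherwise the smallest framework span (C6 − C1);
3. otherwise the leftmost (lexicographically smallest) position tuple.

Topology labels: `SIX_CYS` (no extras), `EIGHT_CYS_FLANKING` (two extras,
first and last cysteines of the mature peptide; inferred extra bond 1–8 in
full cysteine numbering), `EIGHT_CYS_INTERNAL` (one extra before C1, one
strictly between C4 and C6; the extra bond is reported over the *observed*
extra positions, deliberately sidestepping the ambiguity of numbering the
internal pair), and `OTHER` (anything else; disulfide pairing left
unresolved). Loop lengths use the operational mapping n = gap 1,
m = gap 3, c = gap 4; gaps 2 and 5 are fixed by the motif (3 and 1). The
residue-level definition of the n/m/c loops is a documented convention of
this package, not an archival fact.

## Classification

Topology is evaluated before tail length: flanking extras ⇒ V; internal
extras with tail ≤ 15 ⇒ III; six cysteines with tail in 1–4 / 8–13 /
21–53 ⇒ I / II / IV. Everything else is `UNCLASSIFIED` with a
machine-readable reason (`TAIL_GAP`, `TOPOLOGY_UNRESOLVED`). Where the
published archetype descriptions give two variants of a bound, the
configuration uses the union (class II 8–13 rather than 9–13; class IV
21–53 rather than 23–53) and exposes every bound in the config. Tail
length 0 with six cysteines is `UNCLASSIFIED` by default; the
`tail0_as_I` switch extends class I downward for users who read the
shortest-tail archetype as including tail-less matures. Class V members
that lack the extra cysteine pair (known exceptions exist where tyrosines
replace it) are *not* auto-assigned; a per-id override file
(`id<TAB>class<TAB>note`) carries such expert calls, because resolving
them originally required structure alignment, which is out of scope here.
The third β-strand of class V is likewise not predicted from sequence;
the flanking-extras topology serves as its proxy.

The optional structural-evidence gate (a two-column `id → true/false`
table produced by external structure-alignment tooling) stands in for the
secondary-structure alignment step of the original workflow; it is off by
default and the pipeline makes no attempt to reimplement it.

## Secretion heuristic

Phobius output is consumed from file and is always preferred. When
absent, a deliberately simple hydropathy heuristic stands in: a signal
peptide is a window of 7 residues with mean Kyte–Doolittle hydropathy
≥ 1.5 inside the first 35 residues, preceded within 5 residues by at
least one K/R; the cleavage site is the first A/G/S/C/T after the window
followed two residues later by a small residue (A/G/S), else window end
+ 3; a transmembrane segment is any such hydrophobic window starting
after position 40. All thresholds live in `HeuristicParams`. This
heuristic is an approximation with the right qualitative behaviour, not a
reimplementation of a trained predictor — agreement with Phobius on real
proteomes is not claimed and not tested.

## Clustering

Greedy representative clustering at 70% identity processes sequences in
decreasing length (ties: lexicographic id); a sequence joins the first
cluster whose representative it matches at ≥ threshold, else founds a new
one, so representatives end up pairwise below the threshold. Identity is
`matches / min(len a, len b)` by default (`shorter`, the convention
closer to CD-HIT) with `alignment` (matches / alignment length, gap
columns included) selectable. The aligner is an exact Needleman–Wunsch
with match 1 / mismatch 0 / gap −1 and a deterministic traceback
preference diagonal > up > left. No k-mer prefilter is used: mature
defensins are ≤ 130 residues and desk-scale sets are small, so O(n²)
exact alignment is the simpler correct tool. Bit-for-bit CD-HIT
equivalence is a non-goal (CD-HIT's word filter and banding are
approximations of exactly this computation).

## Structural metrics

* **Kabsch superposition**: closed-form least-squares rotation via SVD
  with the determinant correction to exclude reflections; requires ≥ 3
  non-collinear points.
* **Ensemble RMSD**: models are iteratively superposed onto the running
  coordinate mean (backbone N, CA, C by default) until the mean RMSD
  changes by < 1e−6 Å; the headline value is mean ± SD (ddof = 1) of
  per-model RMSD to the mean structure. The to-mean convention was chosen
  over the all-pairs mean because it matches how NMR ensembles are
  usually reported; the two differ by a model-count-dependent factor, so
  comparisons against published values carry a convention tolerance.
* **Restraint tallies**: |i−j| = 0 intraresidue, 1 sequential, 2–4 medium
  range, ≥ 5 long range — disjoint and exhaustive by construction.
  Readers exist for two-column TSV, CYANA `.upl`, and NMR-STAR
  general-distance-constraint loops (ambiguous restraints sharing a
  constraint ID count once).
* **In-silico PCR** is exact-match only: the forward primer on the plus
  strand, the reverse primer as its reverse complement downstream;
  product length = reverse-site end − forward-site start + 1; all site
  combinations are reported and absent sites yield a `NO_PRODUCT` result.
  Mismatch/degenerate-primer annealing is out of scope.

## Synthetic data: what it emulates and what it does not

The generator emits precursors that are class-true **by construction**:
a signal peptide (`M` + two K/R + eight hydrophobic residues + `A`) built
to satisfy the built-in heuristic with a known cleavage site; a tail
drawn uniformly from the class range (I: 2–4, II: 8–13, III: 3–15,
IV: 21–53, V: 4–8 — classes I/V need a floor of 2–3 residues so the
constructed cleavage region stays consistent; classes II–IV are the
archetype ranges); gaps drawn uniformly within the motif bounds; a γ-core
glycine at C5 − 2; extra cysteines placed internally (III) or flanking
(V); background residues uniform over the 19 non-cysteine amino acids.
Each draw is validated against the *real* pipeline (motif scan, secretion
heuristic, mature extraction, framework tie-break, class label) and
redrawn on any mismatch, so generation is deterministic in
(parameters, seed) and every positive survives the cascade.

What passing on this data shows: the pipeline's rules are internally
consistent and every stage fires exactly on its trigger. What it does
*not* show: performance on real proteomes — real signal peptides are not
built to satisfy the heuristic, real amino-acid composition is not
uniform, real defensins are homologous rather than independent draws, and
real databases contain truncations and annotation noise. Decoys cover
one violated rule each (size, cysteine count, one broken gap, missing
signal, transmembrane-like tail); the shuffled-positive decoy preserves
compositon and carries no rejection guarantee — its motif pass-rate is
tracked, not asserted.

Mutational families for clustering tests use a founder mature peptide and
point mutations at rate 0.03 per non-cysteine site (cysteines never
mutated). With three founders from classes I, II and IV this yields
within-family alignment-denominator identity ≥ 0.8 and between-family
≤ ~0.31, comfortably separated around the 0.70 clustering threshold; the
alignment-length denominator is used for this check because the shorter-
sequence denominator inflates identity between matures of unequal length.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: 1,000 random
sequences (≤ 130 residues, ≤ 12 cysteines) for the motif oracle, 500
synthetic precursors per class plus 300 targeted decoys for recovery,
exhaustive alignment enumeration on strings of length ≤ 6, 3 × 10-member
families for clustering, 100 random rigid motions for superposition, and
10,000 random residue pairs for the restraint partition — sizes chosen so
the whole suite completes in seconds while the enumeration oracles remain
exhaustive. Floating-point assertions use 1e−8 for superposition
identities (double-precision SVD) and 1e−12 for exact-zero cases.

## Known limitations

* The secondary-structure/structure-alignment evidence step of the
  original workflow is represented only by the optional evidence table;
  the package cannot reproduce database-scale discovery counts, which
  depend on specific NR-NCBI builds and external predictors.
* The checks against deposited experimental data (NMR ensemble RMSD over
  residues 10–36, the 340-restraint tally, the 158-bp genomic amplicon)
  require the corresponding archive files under `data/`
  (`7unx.pdb`, `bmrb31010_restraints.*`, `mxanthus_dk1622.fasta`); the
  repository ships no binary or third-party data, so those tests fail
  until the files are fetched.
* The heuristic secretion predictor is a stand-in with documented,
  configurable thresholds; Phobius files should be used whenever real
  sequences are analysed.
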