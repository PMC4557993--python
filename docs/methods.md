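# Methods

## The tandem-FN2 core model

BSP (Binder of Sperm) superfamily proteins share an 87-residue core of two
fibronectin type II (FN2) domains joined by a short linker.  `bsptools`
models this core as nine short degenerate consensus blocks at canonical
1-based positions (core frame anchored at the Block I cysteine):

| Block | Consensus            | Domain | Start | Length |
|-------|----------------------|--------|-------|--------|
| I     | `C[AV]FPFxY`         | 1FN2   | 1     | 7      |
| II    | `C[ITV]xxxS`         | 1FN2   | 15    | 6      |
| III   | `xxWCSL[DN]`         | 1FN2   | 22    | 7      |
| IV    | `[FY]xG[RY]W[KR][FY]C` | 1FN2 | 31    | 8      |
| V     | `xxD`                | linker | 40    | 3      |
| VI    | `CxFPFh[FY]`         | 2FN2   | 46    | 7      |
| VII   | `GTxxG[DESY]`        | 2FN2   | 60    | 6      |
| VIII  | `hxxxWCSL[ST]`       | 2FN2   | 67    | 9      |
| IX    | `[FY][DN]xDxxW[KR][QY]C` | 2FN2 | 78  | 10     |

`x` is a wildcard and `h` a configurable hydrophobic class (default
{A, V, L, I, M, F, W, Y} — the notation only promises "hydrophobic", so the
set is exposed rather than hard-coded).  The C-terminal domain (Blocks
VI–IX, 42 aa) is four residues longer than the N-terminal one (Blocks
I–IV, 38 aa); Block VIII is two residues longer than its 1FN2 counterpart
Block III, and Block IX two longer than Block IV.  The region between
Blocks I and II (core 10–12, the β2 strand) is deliberately not modelled
as a tenth block: it shows no clear conservation across the families.

A relaxed Block II variant (`C[ITV]xxx[AGST]`) is available for BSPH1-rich
inputs, whose terminal serine is typically replaced by another small
residue such as alanine.

### Scanning and assembly

`scan_blocks` is an exhaustive sliding-window scan: every position of the
query is tested against every block pattern, and every placement whose
mismatch count is within the per-block tolerance (default 1) is returned.
The default tolerance of 1 reflects that even canonical family members
deviate from single consensus positions; an exact mode (tolerance 0) is
available.  The scan is defined to be *identical* to this brute force — no
indexing heuristics — which the test suite enforces against an independent
re-implementation.

`assemble` selects the best mutually consistent chain of block hits by
dynamic programming.  A link between two blocks requires their start
offset to lie within the canonical core-frame offset ± `gap_slack`
(default 2, tolerating natural spacing variation).  Chains are ranked
lexicographically: most blocks, fewest total mismatches, smallest total
deviation from canonical spacing, leftmost start tuple.  The spacing-
deviation term matters in practice: weakly constrained blocks (the linker
is just `xxD`) otherwise admit shifted placements that tie on mismatch
count, and "leftmost" alone would pick the wrong one.  The ranking is a
total order, so assembly is deterministic and insensitive to input order.

An architecture is *complete* when all nine blocks chain.  Each complete
FN2 domain is checked for its two conserved disulfide bridges with
1–3 / 2–4 connectivity: in 1FN2, Block I C ↔ Block III C (core 1–25) and
Block II C ↔ Block IV C (core 15–38); in 2FN2, Block VI C ↔ Block VIII C
(core 46–72), while the fourth bridge pairs the Block IX terminal cysteine
(core 87) with a cysteine expected in the Block VI→VII gap (core 53–59).
That gap cysteine is not housed by any block, so its absence produces an
`incomplete` warning rather than invalidating the architecture.

## Family classification

BSPH1 and BSPH2 carry diagnostic fingerprints — near-exact versions of
particular blocks:

* BSPH1: Block III `HKWCSLN`, Block VI `ChFPFWY`, Block VIII `FGKKWCSLT`;
* BSPH2: Block IX `YNxDxKWKQC`, Block V `DPP`, Block IV `FxGRWRYC`, plus a
  strictly conserved `SP` dipeptide immediately after Block IX.

A component counts as matched when its block window deviates by at most
one residue (config-exposed: natural variants will not be letter-perfect).
Family scores are the matched fraction of each fingerprint set; the
decision threshold θ defaults to 2/3.  Decision rule: incomplete
architecture → `not_BSP_superfamily`; one score ≥ θ and strictly larger
→ that family; both < θ → BSP (the fingerprint-free family); a tie at or
above θ → `unclassified`.  The shared-block structure makes a double
perfect score impossible on a single consistent chain, which is asserted
on fuzzed chimeras.

BSP subfamilies (BSP1, BSP2, BSP3, BSP5) are clade-defined, not
motif-defined, so subfamily assignment is nearest labelled reference:
highest pairwise-deletion identity over the 87-position core, with an
identity floor (default 0.40) below which no subfamily is assigned, ties
resolved to the alphabetically lower label with an ambiguity flag.

Annotation reconciliation compares the family token extracted from a
free-text database symbol (longest case-insensitive match over BSPH1,
BSPH2, BSP1..5, BSP, with a synonym table handling deposits like
"BSP-30 kDa like" → BSPH2 and RSVP14/20/22 → BSP) against the
sequence-based call: `consistent`, `misannotated`, `novel` (no existing
symbol), or `unresolved` (unknown token or unclassifiable sequence).

## Distances, trees, bootstrap

Distances use pairwise deletion: for each sequence pair only the columns
where neither row is gapped contribute.  Three models convert the observed
difference fraction *p* to substitutions per site: `p` itself; `poisson`
(−ln(1−p)); and `dayhoff`, the PAM time *t* solving
E[identity](t) = 1 − p under the Dayhoff (1978) empirical replacement
model.  The generator is built from the standard Dayhoff exchangeabilities
and equilibrium frequencies (shipped as `data/dayhoff.json`), scaled to
one expected substitution per site per unit time; the identity curve is
evaluated spectrally and inverted by Brent root finding on [0, 50].  The
curve's limit is Σπ² ≈ 0.06, so p beyond ≈ 0.94 is flagged saturated; a
pair with no comparable columns is flagged undefined.  This
expected-identity inversion is one reasonable operational reading of "the
Dayhoff model" — distance definitions differ between packages — and is
documented as such; the test suite pins it to an independent dense
matrix-exponential root find.

Trees are built by the Saitou–Nei neighbor-joining agglomeration,
re-implemented here: minimize Q(i,j) = (n−2)d(i,j) − r_i − r_j with ties
broken by the smallest index pair, standard branch-length and
distance-update formulas, negative branch lengths clamped to zero (a
display convention) and flagged, and the final three lineages joined at a
trifurcation so the result is the unrooted topology.  Consistency (exact
additive input → generating topology) is property-tested up to 12 taxa
and cross-checked against scikit-bio's independent implementation.

Bootstrap supports resample alignment columns with replacement, rebuild
distances and the NJ tree per replicate, and report for each bipartition
of the full-data tree the percentage of successful replicates containing
it.  Replicates with undefined or saturated distances are dropped, tallied
and warned about.  Everything is driven by a single seed.

The pipeline does not align: synthetic panels have equal-length cores
(trivially aligned by construction), and real inputs must be pre-aligned.

## Gene-context matching

Three recurrent neighborhood patterns are encoded: BSP genes flanked by
CD177/TEX101 and LYPD3/PHLDB3/ETHE1/ZNF575; a BSPH1/BSPH2 core with
C19orf68/LIG1/CABP5/ELSPBP1 and SULT2A1/CRX; and a BSPH1/BSPH2 core where
ELSPBP1 is absent and PLA2G4C appears.  Matching is window-based (anchors
searched within 10 genes of the outermost core gene, default) and
orientation-agnostic, because databases disagree on filler gene counts and
strand conventions; a pattern needs anchor score ≥ 0.5, all its required
anchors, and no forbidden anchor.  Cross-checking flags genes whose
symbol-derived family conflicts with an attached sequence-based call,
annotated with the pattern context.

## The synthetic generator

`generate_panel` emulates superfamily precursors: an M-initiated,
hydrophobic-rich signal-peptide-like prefix (15–25 aa, cosmetic — nothing
downstream reads it), the 87-residue core, a short random suffix (the
BSPH2 suffix starts with the `SP` extension), and per-position
substitution noise ε.  Free consensus choices are drawn once per
(family, subfamily) *lineage prototype*, deterministically from the seed;
members are noisy copies of their prototype.  Per-sequence sampling would
produce panels with no group structure at free positions, defeating both
nearest-reference subfamily assignment and clade-recovery checks; the
prototype scheme is the package's stand-in for shared descent.  BSP
prototypes are rejection-sampled so that no BSPH1/BSPH2 fingerprint
component appears within one mismatch — BSPs are fingerprint-free by
definition, and unconstrained sampling occasionally lands near a
fingerprint by chance.  All lineages carry the 2FN2 gap cysteine (placed
at core 55) so canonical input validates two bridges per domain.

What the generator does **not** emulate: insertions/deletions beyond
optional linker jitter, rate heterogeneity across sites, tree-structured
evolution within a lineage (members are star-like around their prototype),
or realistic amino-acid background frequencies (uniform by default).
Passing tests therefore demonstrate algorithmic correctness under
controlled conditions, not performance on real database sequences.

Decoys are single-FN2 truncations (blocks I–IV only) and residue-shuffled
cores; at default tolerances and ε = 0 neither is ever called into a
family.

The default study panel is four members per lineage (four BSP subfamilies
plus BSPH1 and BSPH2, 24 sequences), ε up to 0.05 for tree work — sizes
chosen so that every stage, including a 100-replicate bootstrap, runs in
seconds while still exercising multi-clade recovery.

## Degenerate inputs and numerical conventions

Coordinates are 1-based inclusive everywhere.  Empty consensus strings,
non-residue symbols, window overruns, duplicate FASTA ids, empty FASTA
files, sub-3-taxon matrices and empty reference panels all raise typed
errors.  Branch lengths are serialized with `%.12g` so Newick output
round-trips byte-identically through the module's own reader; labels
containing Newick metacharacters are single-quoted.  Every pipeline report
carries a header with the tool version, seed and a hash of the
analysis-relevant configuration (output paths excluded), and reruns with
the same configuration are byte-identical.

## Known limitations

* The consensus blocks encode the printed consensus letters only, not
  position weight matrices; relative frequencies within alternative sets
  are not modelled.
* Fingerprint thresholds (≤1 mismatch per component, θ = 2/3) are package
  choices; the families' descriptions do not state numeric criteria.
* Subfamily assignment requires a labelled reference panel; subfamilies
  have no printed motifs.
* The scanner is O(sequence × blocks) brute force — appropriate for
  protein-sized inputs, not genome-scale scans.
* Real signal peptides are neither predicted nor required; the precursor
  offset is taken from annotation (or the generator).
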