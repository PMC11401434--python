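# Methods

This note documents the models and procedures tenascope implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Domain-architecture grammar

**Tenascin-type EGF-like consensus.** The scanner encodes the family's
diagnostic spacing `x C x(3) C x(5) C x(4-6) C x C x(5) G x(2) C x` as a
segment list with one variable segment (the C3–C4 spacer). `x` means *any
residue except cysteine*: the pattern's information is the cysteine
skeleton, and letting spacers consume cysteines would allow one residue to
serve two skeleton positions. Matching is greedy left-to-right and
leftmost-longest (the variable spacer is tried longest first), producing
non-overlapping annotations; EGF repeats are tandem and non-overlapping in
all real tenascin architectures, so nothing is lost. *Relaxed* mode widens
the C3–C4 spacer to 8 residues, the arrangement seen in divergent
hemichordate-type domains; strict hits are a subset of relaxed hits by
construction, and both modes are checked against an independently written
regular-expression oracle in the tests.

**Signal peptide.** A deliberately simple fallback heuristic (a run of ≥8
hydrophobic residues from {A,I,L,M,F,V,W,C} starting at position ≤12 within
the first 40 residues; the annotation ends 5 residues after the run, capped
at 40). External SIGNAL annotations always override it. It is not a
substitute for a dedicated predictor and is documented as such; fragments
(`--fragment-ids`) waive the signal clause with reason code PARTIAL.

**FN3/FReD profile detection.** A stand-in for external domain databases:
sliding windows the length of each packaged exemplar (FN3 bounds 80–110,
FReD bounds 200–260) are screened every 5 residues by edit-distance
identity (edlib), local maxima are refined to single-residue precision, and
surviving candidates are confirmed with the package's BLOSUM62 global
aligner at the default 35% identity floor. Hits are selected by descending
identity with overlaps tolerated up to 10 residues (refined boundaries
jitter a few residues around true edges) and then trimmed so reported
same-kind intervals are strictly disjoint. Pipelines meant to mirror
database annotation should supply an external TSV, which takes precedence
over builtin calls wherever they overlap.

**Classification rule.** is_tenascin ⟺ ≥1 EGF-like ∧ ≥1 FN3 ∧ a FReD
ending within 30 residues of the C-terminus ∧ signal peptide (waived for
fragments). The ≥1 thresholds are config-exposed; single-EGF tenascins
exist (the smallest lamprey paralog has one EGF-like domain), so stricter
defaults would cost recall. The 30-residue terminal window accommodates the
short tails gene predictors commonly append.

## Motif analyses

**Integrin motifs.** RGD/RGE/KGD are reported only when they start inside
the F–G loop window of an FN3 domain, IDG/IEG only inside the B–C loop
window, ELVIS only inside strand A. The windows are fractional positions on
the domain — B–C: 0.22–0.35, F–G: 0.70–0.88, strand A: ≤0.12, rounded
outward — this package's calibration of the canonical seven-strand FN3
topology, since loop identities are established but exact residue windows
are not. They are config-exposed. IEG is included in the B–C set because it
occurs as a natural IDG variant (e.g. in shark TNC).

**K(E/D)QTQST repeat blocks.** Motif instances (≤1 substitution) are
chained when successive spacings fall in 55–85 residues; chains of ≥2 units
form a block. The period default spans both the ~60 and ~70 residue
readings of the cyprinid TNX repeat unit.

**Assembly region.** The region between signal peptide and first EGF-like
domain is globally aligned to a packaged synthetic numbering reference
whose cysteines sit at positions 64, 111, 113, 140, 146 and 147 (the human
TNC numbering convention); a reference cysteine counts as conserved iff the
aligned query column is C. The conserved motifs vFnHvYnINvP and vFtHrIniP
are searched with upper-case positions required exact and at most 2
mismatches across the lower-case positions (a fully free reading of the
lower-case positions would make any mismatch budget vacuous). The heptad
scorer tries all 7 registers and window lengths 21–35; score = fraction of
a/d positions in {A,I,L,M,F,V}; windows at ≥0.6 are reported, ties breaking
leftmost then longest; RhExLE is the regex `R[AILMFV]E.LE` inside the
window. The 0.6 floor accepts ideal ~27-residue heptad regions while
rejecting random sequence, validated against the generator. Note that
perfect-score windows are not unique: a shifted register over a neutral
flank can tie, and the leftmost tie-break then wins; consumers should treat
the window as *a* maximal-scoring placement, not the only one.

**Position-frequency matrices.** Per-column frequencies include the gap
character and sum to 1; information content is log2(20) − entropy over the
gap-excluded residue distribution, with the gap fraction reported
separately (a gap-only column has IC 0).

## Phylogenetics

Pairwise global alignment uses BLOSUM62 with affine gaps costing
11 + 1·k for a gap of length k (BLAST existence/extension convention),
end gaps penalized. Percent identity divides identical columns by *all*
alignment columns. The pair is canonicalized (lexicographically) before
alignment so identity is exactly symmetric despite tie-breaking inside the
aligner. p-distances use pairwise gap deletion and error on pairs with no
comparable columns.

Neighbor joining is the canonical Saitou–Nei algorithm with two contracts
that make it testable: ties in the Q-criterion break on the
lexicographically smallest pair of node names (internal nodes are named for
their smallest descendant leaf), so output is deterministic; and negative
limb lengths are clamped to zero with the deficit moved to the sibling
edge. On additive matrices it recovers topology and branch lengths exactly
(verified against randomly generated 5–8 leaf trees and cross-checked
against an independent implementation). Branch support is the Felsenstein
bootstrap — column resampling, NJ per replicate, percentage of replicates
containing each internal bipartition of the full-data tree — fully
reproducible under a fixed seed. This distance pipeline deliberately
replaces ML inference and alignment curation: the package's claim is
clade-level classification, not branch-length estimation, and users may
supply external alignments.

Paralog assignment picks the reference FReD with the highest percent
identity; UNCLASSIFIED below 40% identity or a winning margin under 2
points. Both thresholds are module calibration and config-exposed.

## Synteny

Neighborhoods are windows of k genes (default 5) each side of a focal
locus; gene distance, not base-pair distance, defines the window because
conserved linkage tolerates intervening-gene turnover. Marker recovery is
scored as Σ present(w·b) / (1.5·Σ all(w)) with b = 1.5 for markers at gene
distance 1: normalizing by the maximum attainable weight (rather than
self-normalizing) keeps adjacency informative even when two neighborhoods
overlap — the tandem TNR/TNW arrangement puts both marker sets inside one
window. Assignment is argmax with an UNCLASSIFIED guard (floor 0.15, margin
0.05).

TNW needs special handling because its two-marker set saturates too easily:
labels are first assigned over the non-TNW sets, then a locus immediately
flanked by MRPS14 on one side and an opposite-strand TNR call on the other
is promoted to TNW (the local-duplication signature); a standalone TNW
(dispersed, coelacanth-style arrangement) is assigned only for loci with no
adjacent co-assigned locus and no adjacent COP1 — COP1 adjacency is the TNR
hallmark, and a locus flanked by both COP1 and MRPS14 is a TNR whose TNW
neighbor was lost, an arrangement that actually occurs after genome
duplication.

After a WGD, one protein symbol matches several locus copies, and degraded
copies can perfectly imitate the sibling paralog's neighborhood (a
surviving TNW copy whose TNR partner was deleted sits adjacent to COP1).
Candidate copies are therefore ranked by FReD-label agreement first, then
neighborhood preservation (fraction and count of recovered markers), then
score. A genuine single-locus disagreement still reaches the
combined-evidence rule below.

## Combined evidence

Agreement between the FReD and synteny labels wins outright. On
disagreement, a neighborhood score ≥0.3 overrides the FReD label with a
CONFLICT flag — single-domain phylogeny misplaces fast-evolving paralogs
(TNW and TNX FReDs sit on long branches) while gene neighborhoods persist.
Without synteny evidence the FReD label stands; two UNCLASSIFIED routes
give TN_UNCLASSIFIED. NOT_TENASCIN appears iff the grammar rejected the
protein.

## Synthetic data: what it emulates, what it does not

The generator plants, per paralog, the canonical architectures (TNC 14
EGF-like × 11 FN3, TNR 4 × 9, TNW 4 × 5, TNX 3 × 5), loop-positioned
integrin motifs (RGD+IDG in TNC's third FN3, IDG in TNW), an assembly
region with the reference cysteines, the conserved motif and an
RhExLE-bearing heptad window (degenerate and short for TNX, as in tetrapod
TNX), and a labelled FReD at 20% divergence from one of four templates that
share a common synthetic ancestor (pairwise template identity ~55%,
matching the divergence regime of real tenascin FReDs). Genomes carry the
paralog-diagnostic neighborhoods, optional WGD with independent per-gene duplicate
loss, and the TNR→TNW inverted tandem duplication. Decoys reproduce the
real false-positive surface: teneurin-like EGF arrays, FACIT-collagen-like
FN3 strings, short signal+FReD proteins (239 aa), and random sequence.
Sequence evolution is per-site substitution with probability rate ×
branch-length, replacement uniform over the other 19 residues, and no
indels — which keeps the expected pairwise p-distance in closed form
(for two leaves on branches with substitution probabilities p₁,p₂:
P(identical) = a₁a₂ + (1−a₁)(1−a₂)/19 with aᵢ = 1/20 + (19/20)(1−20pᵢ/19)),
the oracle used by the tests.

Deliberately **not** emulated: realistic substitution models (LG/WAG),
indels (optional nowhere; FReDs are generated equal-length, which is also
why the pipeline can build a tree without a multiple aligner),
alternative splicing, assembly fragmentation beyond the fragment flag,
gene-order rearrangement beyond WGD + local duplication + loss, and
base-pair-scale distances. Passing the benchmark therefore demonstrates
correctness of the procedures under the family's canonical structure, not
robustness to annotation noise in real proteomes — for real data, external
domain tables and curated reference FReDs are the intended inputs. All
exemplar sequences shipped in `_exemplars.py` are synthetic constructions,
not database entries.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen as the package's
standard study conditions: 10,000 (tests) / 4,000 (acceptance script)
random 500-mers for the scanner-oracle comparison, 100 random pairs ≤60
residues for the aligner oracle, 100 additive matrices of 5–8 leaves for
NJ, 1,000 replicates for the p-distance expectation, a 5-species × 4-paralog
benchmark with WGD and 20% duplicate loss for the end-to-end check, and 500
replicates for the gene-loss expectation. Every stochastic component takes
an explicit integer seed (numpy `default_rng`); reruns are bit-identical.
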