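# Methods

This note documents the generative model, the analysis pipeline, parameter
defaults, and the numerical choices made in `ignet`. Everything stated here is
computed by the code; defaults live in the dataclasses named below.

## 1. Germline model

A `GermlineReference` is three catalogs of `GermlineSegment`s (classes V, D,
J). `synthetic_reference()` builds a zebrafish-sized catalog
(`n_v=39, n_d=5, n_j=5`, seed 20130) with segment lengths chosen as multiples
of three so the reading frame is unambiguous:

* **V**: 288 nt (96 codons), drawn from sense codons so each V is an open
  reading frame; the 3' end encodes the conserved VH amino-acid motif
  EDTAVYYCAR.
* **D**: 15 nt, random.
* **J**: 48 nt, encoding a planted DH-JH motif per segment
  (J1/J4/J5 → …MVTVSS, J2 → …MVTVTS, J3 → …KVTVSS; the MVTVST variant is
  deliberately absent from the catalog).

Motif embedding is skipped when a requested segment length cannot hold the
motif, so short toy references remain constructible.

The recombination space is the product of catalog sizes:
39·5·5 = 975 V(D)J recipes, 39·5 = 195 VJ pairs
(`recombination_space_size`).

## 2. Repertoire simulator

`simulate_repertoire(ref, SimulationConfig)` draws each naive sequence by
choosing one V, one D and one J uniformly at random and concatenating them
whole. Mutations are then applied in the order substitutions → deletions →
insertions, with counts Poisson-distributed per read:

| parameter | default | meaning |
|---|---|---|
| `n_sequences` | 10000 | reads per repertoire |
| `sub_rate` | 2.0 | mean substitutions per read |
| `del_rate` | 0.05 | mean single-base deletions per read |
| `ins_rate` | 0.05 | mean single-base insertions per read |
| `origin_weights` | (0.14, 0.46, 0.36, 0.04) | P(substitution origin = A, C, G, T) |

The origin weights encode the AID signature of somatic hypermutation:
substitutions preferentially hit C and G. A substitution site is chosen by
first drawing the origin base from these weights, then a uniform position
among sites carrying that base; the replacement base is uniform over the
other three. Positions for every edit are drawn at application time, so a
deletion shifts downstream coordinates before the next edit. Every read
carries a `ReadTruth` record (segment recipe plus compact edit list,
e.g. `S12C>T;D40A;I7+G`) that `apply_edits` can replay exactly.

**Clonal expansion** (`ExpansionConfig`): one lineage (default) holding
`lineage_fraction=0.4` of reads; a founder is simulated as above and each copy
receives Poisson(`per_copy_mutations=0.5`) extra substitutions. Remaining
reads are independent naive draws.

**What the generator does not emulate**: junctional exonuclease trimming,
N/P-nucleotide addition, hotspot context (WRC/GYW) beyond the base-level
origin bias, mutation clustering along lineage phylogenies (expanded copies
mutate independently from the founder), sequencing error as a distinct
process, and allelic or copy-number variation. Segments are concatenated
whole, so true segment boundaries are exact — which is precisely what makes
assignment and mutation calls checkable against ground truth.

## 3. Segment assignment and filtering

Each read is aligned to every V and every J with affine-gap local
Smith–Waterman (`match=+1, mismatch=−2, gap_open=−5, gap_extend=−2`).
Significance uses the Karlin–Altschul formula `E = K·m·n·exp(−λS)` with
calibration constants `λ=1.28, K=0.46` for this scoring scheme; a read is
kept only if both its best V and best J hit have `E ≤ 1e-8`. With 288-nt V
segments a clean read passes with enormous margin, while unrelated random
sequence essentially never reaches threshold, so the filter's removal rate on
simulated data estimates assignment failure, not borderline noise.

For speed, candidates are prefiltered by an 11-mer word index: segments are
ranked by shared-word count and only those with count ≥ half the best
(at most `max_candidates=4`) are fully aligned; `exhaustive=True` disables
the prefilter. Ties on alignment score break lexicographically by segment
name, making assignment deterministic. The D region is reported as the read
interval between the V hit's end and the J hit's start (the short, similar D
segments do not support direct significant assignment); V/J overlap is
flagged.

## 4. Mutation calling and silent/replacement classification

Kept reads are realigned globally (Needleman–Wunsch via the same scoring) to
their assigned V and J, over windows extended to the full germline extent.
Walking the alignment columns yields substitution, deletion and insertion
records in germline coordinates. Terminal (leading/trailing) gaps are not
called as indels — they reflect window truncation, not mutation.

Silent vs replacement is decided by translating the germline codon containing
the site before and after the substitution. The V frame anchor is the V open
reading frame start; the J frame is carried through the junction from the V
anchor via `frame_anchor_j = (j_window_start − ((j_start − orf_start) mod 3))
mod 3`, so the codon grid is continuous across the read. Codons containing
gaps or ambiguity are reported `untranslatable`.

The spectrum aggregates substitutions into origin counts (A/C/G/T percent),
a 4×4 origin→replacement transition matrix, and silent/replacement counts per
base pair. Note that spectra are tallied per called event; two hits at the
same position in one read are two events.

## 5. Network construction

Identical reads collapse into weighted vertices (multiplicity = read count),
ordered by descending multiplicity then lexicographic sequence. Two distinct
sequences are joined iff they are one elementary step apart:

* **substitution** (red): equal length, Hamming distance 1;
* **deletion** (blue): length difference 1, edit distance 1;
* **deletion_plus_substitution** (green): length difference 1, edit
  distance 2. The composition is forced: with `n_del − n_ins = 1` and two
  operations total, the only solution is one deletion plus one substitution,
  so (length difference, edit distance) fully determines the type.

Pair classification uses banded edit distance with cutoff k=2 (edlib);
equal-length pairs short-circuit through a Hamming scan.

Candidate pairs are generated by a half-string pigeonhole argument rather
than all-pairs comparison: any sequence pair ≤ 2 edits apart with at most one
net deletion shares an exact half after removing at most one base, so same-
length sequences are bucketed on their two halves, and across adjacent
lengths every single-deletion variant of the longer sequence probes the
shorter group's half-buckets. Each candidate is then verified exactly; the
scheme changes speed, never results (verified against brute force in the
test suite).

Components are labeled canonically (sorted by minimal member sequence).
Export formats: Pajek `.net` (+ `.clu` component partition, plus edge-type
and label sidecars), GraphML, and TSV.

## 6. Centrality and phenotype

Degree is the unweighted vertex degree. Betweenness is computed unnormalized
(Brandes) and then divided, per connected component of size `nc`, by
`C(nc−1, 2)` — the number of reachable source/target pairs — yielding "the
proportion of shortest paths among reachable pairs passing through the
vertex" (0 for components with fewer than 3 vertices). The largest-clone
percentile is `100 · max vertex multiplicity / total reads`.

`classify_phenotype` labels a repertoire **highly_connected** iff

* largest clone percent > 10 (strict), or
* any single V segment or any single J segment carries ≥ 40% of kept reads;

otherwise **poorly_connected**. The thresholds
(`DEFAULT_CLONE_THRESHOLD=10.0`, `DEFAULT_GERMLINE_THRESHOLD=40.0`) sit far
from both modes of the simulator: random repertoires of ≥150 reads over 195
VJ recipes stay near 1/39 ≈ 2.6% per V and 20% per J with sub-1% clones,
while a 40%-lineage expansion drives all three criteria.

## 7. Motif analysis

Reads are translated in all three frames (stop codons retained as `*`) and
scanned for an amino-acid motif catalog; the default catalog holds the DH-JH
family (…T MVTVSS / MVTVTS / KVTVSS / MVTVST) and the VH motifs EDTAVYYCAR
and AVYYCAR. Matching is exact or Hamming ≤ 1 per window
(`max_mismatch=1`). Output: per-read hits (frame, offset, matched peptide)
and per-motif read fractions. `top_kmers` provides catalog-free enumeration
of frequent translated k-mers.

## 8. Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.SeedSequence([seed, stage_index])`; derived seeds are reduced
mod 2³¹. Pipeline outputs are byte-identical across runs with the same seed.
The bundled verification script (`scripts/acceptance.py`) uses package-chosen
problem sizes — e.g. 60 naive/expanded run pairs of 150 reads for phenotype
separation, and ≥20,000 substitutions for spectrum recovery — selected so
Monte-Carlo noise is small relative to the effects measured.

## 9. Limitations

* The simulator's independence assumptions (uniform segment usage, no
  junction diversity, no lineage structure within a clone) make it a null
  model, not a biological emulator; conclusions about real repertoires
  require real reads via `ignet assign --input ...`.
* Edge types cover net single-deletion steps only; a pure single-insertion
  relation is represented as the deletion edge seen from the longer
  sequence, and pairs ≥ 3 edits apart are never joined.
* D-segment identity is not called; the D region is positional.
* The Karlin–Altschul constants are calibrated for the default scoring
  scheme; changing scores without recalibrating `λ, K` distorts E-values.
* Silent/replacement calls assume the V open reading frame anchors the
  read's frame; out-of-frame junctions are classified on that grid
  regardless.
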