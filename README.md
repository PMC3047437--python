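# ignet — immunoglobulin repertoire network analysis

`ignet` analyses B-cell receptor heavy-chain repertoires as sequence-similarity
networks. The primary antibody repertoire is built by V(D)J recombination — a
zebrafish heavy chain joins one of 39 V, 5 D and 5 J germline gene segments,
giving 975 possible recipes — and is then diversified by somatic hypermutation.
Collapsing identical reads into weighted vertices and joining sequences that
differ by a single elementary step (one substitution, one deletion, or one
deletion plus one substitution) turns a repertoire into a graph whose
architecture distinguishes a naive, unselected repertoire from one shaped by
clonal expansion: naive repertoires fragment into a large number of small
components with small vertices, while responding repertoires carry large clones
and highly connected clusters.

The package is aimed at immunologists and computational biologists who want a
fully tested, ground-truth-aware re-implementation of this style of analysis:
every stage can be driven by a simulator whose reads carry their germline
recipe and exact edit list.

## What it computes

* **Simulation** — "random network" repertoires: uniform V+D+J concatenation,
  Poisson-distributed point mutations with an AID-like origin bias
  (P(origin) for A, C, G, T = 0.14, 0.46, 0.36, 0.04), rare single-base
  indels, and an optional clonal-expansion mode (a founder copied into a
  lineage with a few extra substitutions per copy).
* **Segment assignment** — affine-gap Smith–Waterman of each read against the
  V and J catalogs with a Karlin–Altschul E-value
  `E = K·m·n·exp(−λS)`; reads with `E > 1e-8` on either segment are removed.
  The D region is the read segment between the identifiable V and J parts
  (the five D genes are too similar to call directly).
* **Mutation analysis** — per-read realignment to the assigned germline;
  substitution spectra by germline base of origin; silent vs replacement
  classification through the reading frame; indel tallies.
* **Network** — weighted-vertex, typed-edge single-step graph with connected
  components; Pajek `.net`/`.clu`, GraphML and TSV export.
* **Centrality & phenotype** — degree, per-component normalized betweenness
  (the proportion of geodesics between reachable pairs through a vertex),
  largest-clone percentile (100·max vertex multiplicity / reads), and a
  two-rule phenotype call: *highly connected* iff the largest clone exceeds
  10% of reads or a single V or J segment carries ≥ 40% of them.
* **Motifs** — translation in all three frames and scanning for the conserved
  teleost VH (EDTAVYYCAR / AVYYCAR) and DH-JH (FDYWGKGT[M/K]VTV[SS/TS/ST])
  motif families, with optional one-residue tolerance.

## Worked example

```
python examples/05_phenotype_classification.py
```

prints (exact output):

```
naive     largest clone   0.7% max degree   1 max betweenness 0.000 -> poorly_connected
expanded  largest clone  23.7% max degree  40 max betweenness 0.995 -> highly_connected  (fired: largest_clone>10%, single_V_usage>=40%, single_J_usage>=40%)
```

Two 300-read repertoires from the same germline catalog: the naive one has no
clone above 0.7% of reads and essentially no connectivity, while the one
containing a single expanded lineage (40% of reads) concentrates reads into a
dominant clone (23.7%), a hub vertex of degree 40 and near-maximal
betweenness, and fires all three classifier criteria. The other scripts in
`examples/` walk through simulation, segment assignment (uniform J usage near
20% per segment, 195-row VJ grid), the mutation-origin spectrum
(~46% C / 36% G / 14% A / 4% T), random-network architecture (5,000 reads →
4,853 vertices in 4,139 components) and motif scanning.

A thin CLI mirrors the library: `ignet simulate|assign|mutations|network|
metrics|motifs|all` (see `ignet --help`).

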