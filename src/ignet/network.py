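"""Sequence-similarity network construction.

Identical reads collapse into one weighted vertex (multiplicity = number of
identical reads).  Two vertices are joined by an edge when their sequences
are one elementary step apart:

* ``substitution`` (red)  — equal length, Hamming distance 1;
* ``deletion`` (blue)     — lengths differ by 1, edit distance 1 (an
  insertion seen from the other side is the same undirected relation);
* ``deletion_plus_substitution`` (green) — lengths differ by 1, edit
  distance exactly 2.  With a length difference of 1 a distance-2 edit
  script is forced to be exactly one single-base gap plus one substitution
  (n_del − n_ins = 1 and n_del + n_ins + n_sub = 2 has the single solution
  1/0/1), so the distance test alone certifies the composition.

Pairs at two substitutions, two gaps, or anything farther get no edge: the
network connects only single-step mutational neighbours, which is why a
repertoire of independently mutated sequences fragments into a huge number
of components instead of one cluster per germline recipe.

Candidate neighbours are generated without an all-pairs scan by a
half-string pigeonhole over single-deletion variants (see
``_candidate_pairs``); every candidate is then verified by the exact
classifier.  The brute-force all-pairs construction lives in the test suite
as the oracle.
"""

from __future__ import annotations

import hashlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import networkx as nx

from .reference import IgRead

EDGE_TYPES = ("substitution", "deletion", "deletion_plus_substitution")


@dataclass
class NetworkVertex:
    vertex_id: int
    sequence: str
    multiplicity: int
    component_id: int | None = None


@dataclass(frozen=True)
class NetworkEdge:
    u: int
    v: int
    edge_type: str

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError("self-loop")
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")


@dataclass
class RepertoireNetwork:
    vertices: list[NetworkVertex]
    edges: list[NetworkEdge]
    components: list[list[int]]  # vertex ids, sorted, canonical order

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v in self.vertices:
            g.add_node(v.vertex_id, sequence=v.sequence,
                       multiplicity=v.multiplicity,
                       component=v.component_id)
        for e in self.edges:
            g.add_edge(e.u, e.v, edge_type=e.edge_type)
        return g

    @property
    def total_reads(self) -> int:
        return sum(v.multiplicity for v in self.vertices)


def collapse_reads(reads: Iterable[IgRead | str]) -> list[NetworkVertex]:
    """One vertex per distinct sequence; multiplicity = occurrence count.

    Vertex order (and therefore ids) is canonical: descending multiplicity,
    then lexicographic sequence — independent of input order.
    """
    counts = Counter(
        r.sequence if isinstance(r, IgRead) else r for r in reads
    )
    if not counts:
        raise ValueError("no reads to collapse")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [NetworkVertex(i, seq, mult) for i, (seq, mult) in enumerate(ordered)]


def classify_pair(seq_a: str, seq_b: str) -> str | None:
    """Edge type between two distinct sequences, or None.

    Uses a banded edit-distance check (k=2); the length arithmetic in the
    module docstring converts (length difference, distance) into the edge
    type without inspecting the edit script.
    """
    if seq_a == seq_b:
        return None
    la, lb = len(seq_a), len(seq_b)
    if la == lb:
        mismatches = 0
        for x, y in zip(seq_a, seq_b):
            if x != y:
                mismatches += 1
                if mismatches > 1:
                    return None
        return "substitution" if mismatches == 1 else None
    if abs(la - lb) != 1:
        return None
    d = edlib.align(seq_a, seq_b, task="distance", k=2)["editDistance"]
    if d == 1:
        return "deletion"
    if d == 2:
        return "deletion_plus_substitution"
    return None


def _deletion_variants(seq: str) -> Iterable[str]:
    for i in range(len(seq)):
        yield seq[:i] + seq[i + 1:]


def _candidate_pairs(vertices: Sequence[NetworkVertex]) -> set[tuple[int, int]]:
    """Superset of all edge pairs, without an all-pairs scan.

    Equal length: two sequences at Hamming distance 1 share their first or
    second half verbatim, so bucketing on the two halves finds them.
    Length difference 1: every blue or green partner of the longer sequence
    is at Hamming distance <= 1 from one of its single-deletion variants, so
    probing the shorter group's half-buckets with each variant's halves
    finds both edge classes.  All candidates are verified afterwards.
    """
    by_length: dict[int, list[NetworkVertex]] = defaultdict(list)
    for v in vertices:
        by_length[len(v.sequence)].append(v)

    candidates: set[tuple[int, int]] = set()

    def half_buckets(group: Sequence[NetworkVertex], length: int):
        h = length // 2
        buckets: dict[tuple[int, str], list[int]] = defaultdict(list)
        for v in group:
            buckets[(0, v.sequence[:h])].append(v.vertex_id)
            buckets[(1, v.sequence[h:])].append(v.vertex_id)
        return h, buckets

    for length, group in by_length.items():
        # same-length (substitution) candidates
        _, buckets = half_buckets(group, length)
        for bucket in buckets.values():
            if len(bucket) > 1:
                bucket = sorted(bucket)
                for i, u in enumerate(bucket):
                    for w in bucket[i + 1:]:
                        candidates.add((u, w))
        # cross-length candidates against the (length - 1) group
        shorter = by_length.get(length - 1)
        if not shorter:
            continue
        h, sbuckets = half_buckets(shorter, length - 1)
        for v in group:
            for variant in _deletion_variants(v.sequence):
                hits = (sbuckets.get((0, variant[:h]), ())
                        or ()) , (sbuckets.get((1, variant[h:]), ()) or ())
                for ids in hits:
                    for u in ids:
                        a, b = (u, v.vertex_id) if u < v.vertex_id else (
                            v.vertex_id, u)
                        candidates.add((a, b))
    return candidates


def build_network(vertices: Sequence[NetworkVertex]) -> RepertoireNetwork:
    """Connect all single-step pairs and extract connected components.

    Component ids are canonical: components sorted by their
    lexicographically smallest member sequence, so the result is invariant
    to input permutation.
    """
    seq_of = {v.vertex_id: v.sequence for v in vertices}
    edges: list[NetworkEdge] = []
    for u, w in sorted(_candidate_pairs(vertices)):
        et = classify_pair(seq_of[u], seq_of[w])
        if et is not None:
            edges.append(NetworkEdge(u, w, et))

    g = nx.Graph()
    g.add_nodes_from(seq_of)
    g.add_edges_from((e.u, e.v) for e in edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(seq_of[i] for i in c))
    verts = [NetworkVertex(v.vertex_id, v.sequence, v.multiplicity)
             for v in vertices]
    by_id = {v.vertex_id: v for v in verts}
    for cid, comp in enumerate(comps):
        for vid in comp:
            by_id[vid].component_id = cid
    return RepertoireNetwork(verts, edges, comps)


def build_network_from_reads(reads: Iterable[IgRead | str]) -> RepertoireNetwork:
    return build_network(collapse_reads(reads))


# ---------------------------------------------------------------------------
# Export / import

def _short_label(seq: str) -> str:
    return hashlib.sha1(seq.encode()).hexdigest()[:10]


def export_network(net: RepertoireNetwork, fmt: str, path: str | Path) -> None:
    """Write the network as ``pajek_net``, ``graphml`` or ``edge_tsv``.

    ``pajek_net`` writes three sidecar files next to the .net: a ``.clu``
    component partition, an ``_edgetypes.tsv`` attribute table and a
    ``_labels.tsv`` mapping the short vertex labels back to sequences.
    ``edge_tsv`` writes ``<stem>_vertices.tsv`` alongside the edge list so
    the network round-trips through :func:`read_edge_tsv`.
    """
    path = Path(path)
    if fmt == "pajek_net":
        with open(path, "w") as fh:
            fh.write(f"*Vertices {len(net.vertices)}\n")
            for v in net.vertices:
                fh.write(f'{v.vertex_id + 1} "{_short_label(v.sequence)}" '
                         f'{v.multiplicity}\n')
            fh.write("*Edges\n")
            for e in net.edges:
                fh.write(f"{e.u + 1} {e.v + 1} 1\n")
        with open(path.with_suffix(".clu"), "w") as fh:
            fh.write(f"*Vertices {len(net.vertices)}\n")
            for v in net.vertices:
                fh.write(f"{(v.component_id or 0) + 1}\n")
        with open(path.with_name(path.stem + "_edgetypes.tsv"), "w") as fh:
            fh.write("u\tv\tedge_type\n")
            for e in net.edges:
                fh.write(f"{e.u + 1}\t{e.v + 1}\t{e.edge_type}\n")
        with open(path.with_name(path.stem + "_labels.tsv"), "w") as fh:
            fh.write("label\tsequence\n")
            for v in net.vertices:
                fh.write(f"{_short_label(v.sequence)}\t{v.sequence}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), str(path))
    elif fmt == "edge_tsv":
        with open(path.with_name(path.stem + "_vertices.tsv"), "w") as fh:
            fh.write("vertex_id\tsequence\tmultiplicity\tcomponent_id\n")
            for v in net.vertices:
                fh.write(f"{v.vertex_id}\t{v.sequence}\t{v.multiplicity}\t"
                         f"{v.component_id}\n")
        with open(path, "w") as fh:
            fh.write("u\tv\tedge_type\n")
            for e in net.edges:
                fh.write(f"{e.u}\t{e.v}\t{e.edge_type}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_edge_tsv(path: str | Path) -> RepertoireNetwork:
    """Reconstruct a network from an ``edge_tsv`` export pair."""
    path = Path(path)
    vertices: list[NetworkVertex] = []
    with open(path.with_name(path.stem + "_vertices.tsv")) as fh:
        next(fh)
        for line in fh:
            vid, seq, mult, _comp = line.rstrip("\n").split("\t")
            vertices.append(NetworkVertex(int(vid), seq, int(mult)))
    edges: list[NetworkEdge] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            u, v, et = line.rstrip("\n").split("\t")
            edges.append(NetworkEdge(int(u), int(v), et))
    g = nx.Graph()
    g.add_nodes_from(v.vertex_id for v in vertices)
    g.add_edges_from((e.u, e.v) for e in edges)
    seq_of = {v.vertex_id: v.sequence for v in vertices}
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(seq_of[i] for i in c))
    by_id = {v.vertex_id: v for v in vertices}
    for cid, comp in enumerate(comps):
        for vid in comp:
            by_id[vid].component_id = cid
    return RepertoireNetwork(vertices, edges, comps)
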