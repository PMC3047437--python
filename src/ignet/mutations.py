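"""Somatic-mutation calling and spectra.

Each kept read is re-aligned (globally, affine gaps) against its assigned V
and J germline segments; differences are tallied as substitutions, deletions
or insertions.  Substitutions are classified silent vs replacement by
translating the affected germline codon before and after the change — V
segments are in frame 0 by convention of the synthetic reference, and the J
frame is carried through the junction from the V frame when both hits are
available.  Mutations in the D/junction region are excluded: only the V and J
portions have a defined germline to compare against.

The mutation spectrum summarises substitutions by their germline base of
origin (the A/C/G/T percentages whose C-dominance is the AID signature) and
by from→to pair, split into silent and replacement counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .alignment import make_global_aligner
from .assignment import AssignmentConfig, SegmentAssignment
from .reference import GermlineReference, IgRead

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Standard genetic code, DNA codons.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CodonEffect = Literal["silent", "replacement", "indel", "untranslatable"]


@dataclass(frozen=True)
class MutationRecord:
    read_id: str
    seg_class: Literal["V", "J"]
    kind: Literal["substitution", "deletion", "insertion"]
    germline_pos: int
    from_base: str
    to_base: str
    codon_effect: CodonEffect


def classify_silent_replacement(
    germline_seq: str, germline_pos: int, to_base: str, frame_anchor: int | None
) -> CodonEffect:
    """Silent iff the mutated codon encodes the same amino acid.

    ``frame_anchor`` is the germline position at which codon 0 starts (may be
    negative modulo 3 semantics via ``(pos - anchor) % 3``); None means the
    frame is unknown and the change is untranslatable.
    """
    if frame_anchor is None:
        return "untranslatable"
    offset = (germline_pos - frame_anchor) % 3
    codon_start = germline_pos - offset
    if codon_start < 0 or codon_start + 3 > len(germline_seq):
        return "untranslatable"
    codon = germline_seq[codon_start:codon_start + 3]
    mutated = codon[:offset] + to_base + codon[offset + 1:]
    return "silent" if GENETIC_CODE[codon] == GENETIC_CODE[mutated] else "replacement"


def _walk_alignment(
    alignment, read_id: str, seg_class: str, germline_seq: str,
    frame_anchor: int | None,
) -> list[MutationRecord]:
    """Emit records column by column from a (read, germline) global alignment."""
    read_blocks, germ_blocks = alignment.aligned
    records: list[MutationRecord] = []
    read_seq = str(alignment.target)
    prev_r = prev_g = 0
    first = True
    for (rs, re_), (gs, ge) in zip(read_blocks, germ_blocks):
        if not first:
            if gs > prev_g and rs == prev_r:
                for gp in range(prev_g, gs):
                    records.append(MutationRecord(
                        read_id, seg_class, "deletion", gp,
                        germline_seq[gp], "", "indel"))
            elif rs > prev_r and gs == prev_g:
                for rp in range(prev_r, rs):
                    records.append(MutationRecord(
                        read_id, seg_class, "insertion", gs, "",
                        read_seq[rp], "indel"))
        first = False
        for rp, gp in zip(range(rs, re_), range(gs, ge)):
            a, b = germline_seq[gp], read_seq[rp]
            if a != b:
                records.append(MutationRecord(
                    read_id, seg_class, "substitution", gp, a, b,
                    classify_silent_replacement(germline_seq, gp, b,
                                                frame_anchor)))
        prev_r, prev_g = re_, ge
    return records


class MutationCaller:
    """Caller bound to one reference + scoring config (reuses aligners)."""

    def __init__(self, ref: GermlineReference,
                 cfg: AssignmentConfig | None = None):
        self.ref = ref
        cfg = cfg or AssignmentConfig()
        self._aligner = make_global_aligner(cfg.match, cfg.mismatch,
                                            cfg.gap_open, cfg.gap_extend)
        self._v = {s.name: s.sequence for s in ref.v_segments}
        self._j = {s.name: s.sequence for s in ref.j_segments}

    def call(self, read: IgRead,
             assignment: SegmentAssignment) -> list[MutationRecord]:
        """Mutations in the V and J portions of one kept read."""
        if not assignment.passed_filter:
            raise ValueError(f"read {read.read_id} did not pass the filter")
        v_hit, j_hit = assignment.v_hit, assignment.j_hit
        assert v_hit is not None and j_hit is not None
        seq = read.sequence
        v_germ = self._v[v_hit.segment_name]
        j_germ = self._j[j_hit.segment_name]

        # Extend the local spans to the full germline extent so terminal
        # mismatches clipped by Smith-Waterman are still compared.
        v_start = max(0, v_hit.read_span[0] - v_hit.germline_span[0])
        v_end = min(len(seq), v_hit.read_span[1]
                    + (len(v_germ) - v_hit.germline_span[1]))
        j_start = max(0, j_hit.read_span[0] - j_hit.germline_span[0])
        j_end = min(len(seq), j_hit.read_span[1]
                    + (len(j_germ) - j_hit.germline_span[1]))
        j_start = max(j_start, v_end)  # never re-enter the V portion
        if j_end <= j_start:
            return []

        records: list[MutationRecord] = []
        v_aln = self._aligner.align(seq[v_start:v_end], v_germ)[0]
        records.extend(_walk_alignment(v_aln, read.read_id, "V", v_germ, 0))

        # Carry the reading frame across the junction: germline V position 0
        # sits at read position (v_start - shift of extended window) == read
        # ORF start; the J anchor is the germline-J position congruent to it.
        orf_start = v_hit.read_span[0] - v_hit.germline_span[0]
        j_germ_window_start = j_hit.germline_span[0] - (j_hit.read_span[0]
                                                        - j_start)
        frame_anchor_j = (j_germ_window_start
                          - ((j_start - orf_start) % 3)) % 3
        j_aln = self._aligner.align(seq[j_start:j_end], j_germ)[0]
        records.extend(_walk_alignment(j_aln, read.read_id, "J", j_germ,
                                       frame_anchor_j))
        return records

    def call_repertoire(
        self, reads: Sequence[IgRead],
        assignments: Sequence[SegmentAssignment],
    ) -> list[MutationRecord]:
        by_id = {a.read_id: a for a in assignments if a.passed_filter}
        out: list[MutationRecord] = []
        for read in reads:
            a = by_id.get(read.read_id)
            if a is not None:
                out.extend(self.call(read, a))
        return out


def call_mutations(read: IgRead, assignment: SegmentAssignment,
                   ref: GermlineReference,
                   cfg: AssignmentConfig | None = None) -> list[MutationRecord]:
    return MutationCaller(ref, cfg).call(read, assignment)


@dataclass
class MutationSpectrum:
    """Substitution counts by origin base and by from→to pair."""

    origin_counts: dict[str, int]
    transition_matrix: np.ndarray  # 4x4 from->to, diagonal zero
    silent_counts: dict[tuple[str, str], int]
    replacement_counts: dict[tuple[str, str], int]
    n_substitutions: int = 0
    n_deletions: int = 0
    n_insertions: int = 0

    @property
    def total_substitutions(self) -> int:
        return sum(self.origin_counts.values())

    def origin_percent(self) -> dict[str, float]:
        total = self.total_substitutions
        if total == 0:
            raise ValueError("empty spectrum has no percentage view")
        return {b: 100.0 * self.origin_counts[b] / total for b in BASES}

    def silent_replacement_table(self) -> pd.DataFrame:
        """Stacked per-pair table: one row per (from, to), silent and
        replacement counts side by side."""
        rows = []
        for f in BASES:
            for t in BASES:
                if f == t:
                    continue
                rows.append({
                    "from_base": f, "to_base": t,
                    "silent": self.silent_counts.get((f, t), 0),
                    "replacement": self.replacement_counts.get((f, t), 0),
                })
        return pd.DataFrame(rows)


def spectrum(records: Iterable[MutationRecord]) -> MutationSpectrum:
    origin = {b: 0 for b in BASES}
    tm = np.zeros((4, 4), dtype=int)
    silent: dict[tuple[str, str], int] = {}
    repl: dict[tuple[str, str], int] = {}
    n_sub = n_del = n_ins = 0
    for r in records:
        if r.kind == "deletion":
            n_del += 1
            continue
        if r.kind == "insertion":
            n_ins += 1
            continue
        n_sub += 1
        origin[r.from_base] += 1
        tm[_BASE_INDEX[r.from_base], _BASE_INDEX[r.to_base]] += 1
        key = (r.from_base, r.to_base)
        if r.codon_effect == "silent":
            silent[key] = silent.get(key, 0) + 1
        elif r.codon_effect == "replacement":
            repl[key] = repl.get(key, 0) + 1
    return MutationSpectrum(origin, tm, silent, repl, n_sub, n_del, n_ins)


def write_mutations_tsv(records: Sequence[MutationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tseg_class\tkind\tgermline_pos\tfrom_base\t"
                 "to_base\tcodon_effect\n")
        for r in records:
            fh.write(f"{r.read_id}\t{r.seg_class}\t{r.kind}\t{r.germline_pos}"
                     f"\t{r.from_base}\t{r.to_base}\t{r.codon_effect}\n")


def write_spectrum_tsv(spec: MutationSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("origin_base\tcount\tpercent\n")
        total = spec.total_substitutions
        for b in BASES:
            pct = 100.0 * spec.origin_counts[b] / total if total else float("nan")
            fh.write(f"{b}\t{spec.origin_counts[b]}\t{pct:.2f}\n")


def plot_silent_replacement(spec: MutationSpectrum, path) -> None:
    """Stacked bars per from→to pair: silent (white) under replacement (black)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = spec.silent_replacement_table()
    labels = table["from_base"] + ">" + table["to_base"]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(labels, table["silent"], color="white", edgecolor="black",
           label="silent")
    ax.bar(labels, table["replacement"], bottom=table["silent"],
           color="black", label="replacement")
    ax.set_ylabel("substitutions")
    ax.set_xlabel("germline base > read base")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
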