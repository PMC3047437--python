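"""Germline V/J segment assignment.

Each read is matched against the V and J catalogs by affine-gap local
alignment; reads whose best V or J hit has an E-value above the threshold
(default 1e-8) are removed, mirroring the "insufficient fit to either V or J"
filter applied to the real repertoires.  The five D segments are too similar
to call reliably, so the D region is defined operationally as the stretch of
the read between the identifiable parts of V and J and is never aligned.

For speed, candidate segments are preselected by shared-word (11-mer) counts
and only the best few are aligned in full — the same seeding idea BLAST uses.
``exhaustive=True`` turns the heuristic off and scores every segment.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .alignment import (AlignmentHit, alignment_spans_identity,
                        karlin_altschul_evalue, make_local_aligner)
from .reference import GermlineReference, GermlineSegment, IgRead


@dataclass(frozen=True)
class AssignmentConfig:
    """Scoring, E-value calibration and search heuristics.

    ``karlin_lambda``/``karlin_k`` calibrate E = K·m·n·exp(−λS) for the
    default +1/−2 scoring; ``seed_word``/``max_candidates`` control the
    word-seeding prefilter; ``v_window``/``j_window`` optionally restrict the
    V search to a read prefix and the J search to a suffix (defaults: full
    read).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    evalue_threshold: float = 1e-8
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    seed_word: int = 11
    max_candidates: int = 4
    exhaustive: bool = False
    v_window: int | None = None
    j_window: int | None = None

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")


@dataclass(frozen=True)
class SegmentAssignment:
    """Per-read V/J identity, D region and filter verdict."""

    read_id: str
    v_hit: AlignmentHit | None
    j_hit: AlignmentHit | None
    d_region: str
    passed_filter: bool
    fail_reason: str | None = None
    flags: tuple[str, ...] = ()


class _WordIndex:
    """seed_word-mer index over one germline class for candidate ranking."""

    def __init__(self, segments: Sequence[GermlineSegment], k: int):
        self.k = k
        self.words: dict[str, set[str]] = defaultdict(set)
        for seg in segments:
            s = seg.sequence
            for i in range(len(s) - k + 1):
                self.words[s[i:i + k]].add(seg.name)

    def candidates(self, read_seq: str, max_candidates: int) -> list[str]:
        counts: Counter[str] = Counter()
        k = self.k
        for i in range(len(read_seq) - k + 1):
            for name in self.words.get(read_seq[i:i + k], ()):
                counts[name] += 1
        if not counts:
            return []
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        # A decisive best candidate prunes the rest: segments sharing only a
        # common planted motif trail the true segment by a wide margin.
        cutoff = ranked[0][1] / 2
        return [name for name, c in ranked[:max_candidates] if c >= cutoff]


class SegmentAssigner:
    """Reusable assigner holding the aligner and word indexes for a reference."""

    def __init__(self, ref: GermlineReference,
                 cfg: AssignmentConfig | None = None):
        self.ref = ref
        self.cfg = cfg or AssignmentConfig()
        self._aligner = make_local_aligner(self.cfg.match, self.cfg.mismatch,
                                           self.cfg.gap_open, self.cfg.gap_extend)
        self._by_class = {
            "V": {s.name: s for s in ref.v_segments},
            "J": {s.name: s for s in ref.j_segments},
        }
        self._class_length = {
            cls: sum(len(s.sequence) for s in segs.values())
            for cls, segs in self._by_class.items()
        }
        self._index = {
            cls: _WordIndex(list(segs.values()), self.cfg.seed_word)
            for cls, segs in self._by_class.items()
        }

    # -- single-class search ------------------------------------------------
    def best_hit(self, read_seq: str, seg_class: str) -> AlignmentHit | None:
        """Maximal-score local hit over the class; ties broken by
        (lower E-value, then lexicographic name); None when nothing scores."""
        segments = self._by_class[seg_class]
        if not read_seq or not segments:
            return None
        if self.cfg.exhaustive:
            names: Iterable[str] = sorted(segments)
        else:
            names = self._index[seg_class].candidates(
                read_seq, self.cfg.max_candidates)
            if not names:
                return None
        best_name = None
        best_score = 0.0
        for name in sorted(names):
            score = float(self._aligner.score(read_seq, segments[name].sequence))
            # E-value is a monotone transform of score within one class, so
            # the tie order (score desc, evalue asc, name asc) reduces to
            # (score desc, name asc).
            if score > best_score:
                best_score, best_name = score, name
        if best_name is None or best_score <= 0:
            return None
        alignment = self._aligner.align(read_seq,
                                        segments[best_name].sequence)[0]
        read_span, germ_span, identity = alignment_spans_identity(alignment)
        evalue = karlin_altschul_evalue(
            best_score, len(read_seq), self._class_length[seg_class],
            self.cfg.karlin_lambda, self.cfg.karlin_k)
        return AlignmentHit(best_name, best_score, read_span, germ_span,
                            identity, evalue)

    # -- full read assignment ----------------------------------------------
    def assign_read(self, read: IgRead) -> SegmentAssignment:
        seq = read.sequence
        v_query = seq[: self.cfg.v_window] if self.cfg.v_window else seq
        j_offset = 0
        if self.cfg.j_window and self.cfg.j_window < len(seq):
            j_offset = len(seq) - self.cfg.j_window
        j_query = seq[j_offset:]

        v_hit = self.best_hit(v_query, "V")
        j_hit = self.best_hit(j_query, "J")
        if j_hit is not None and j_offset:
            j_hit = AlignmentHit(
                j_hit.segment_name, j_hit.score,
                (j_hit.read_span[0] + j_offset, j_hit.read_span[1] + j_offset),
                j_hit.germline_span, j_hit.identity, j_hit.evalue)

        flags: list[str] = []
        d_region = ""
        fail_reason = None
        thr = self.cfg.evalue_threshold
        if v_hit is None or j_hit is None:
            fail_reason = "no_v_hit" if v_hit is None else "no_j_hit"
            passed = False
        elif v_hit.evalue > thr or j_hit.evalue > thr:
            fail_reason = ("v_evalue" if v_hit.evalue > thr else "j_evalue")
            passed = False
        else:
            passed = True
        if v_hit is not None and j_hit is not None:
            v_end = v_hit.read_span[1]
            j_start = j_hit.read_span[0]
            if v_end <= j_start:
                d_region = seq[v_end:j_start]
            else:
                flags.append("vj_overlap")
        return SegmentAssignment(read.read_id, v_hit, j_hit, d_region,
                                 passed, fail_reason, tuple(flags))

    def assign_repertoire(self, reads: Iterable[IgRead]) -> list[SegmentAssignment]:
        return [self.assign_read(r) for r in reads]


def best_hit(read_seq: str, ref: GermlineReference, seg_class: str,
             cfg: AssignmentConfig | None = None) -> AlignmentHit | None:
    """Convenience single-call wrapper around :class:`SegmentAssigner`."""
    return SegmentAssigner(ref, cfg).best_hit(read_seq, seg_class)


def assign_read(read: IgRead, ref: GermlineReference,
                cfg: AssignmentConfig | None = None) -> SegmentAssignment:
    return SegmentAssigner(ref, cfg).assign_read(read)


def filter_repertoire(
    assignments: Sequence[SegmentAssignment],
) -> tuple[list[SegmentAssignment], list[SegmentAssignment], float]:
    """Partition by the E-value filter; returns (kept, removed, removed_fraction)."""
    kept = [a for a in assignments if a.passed_filter]
    removed = [a for a in assignments if not a.passed_filter]
    frac = len(removed) / len(assignments) if assignments else 0.0
    return kept, removed, frac


def vj_usage_table(
    kept: Sequence[SegmentAssignment], ref: GermlineReference
) -> dict[str, pd.DataFrame]:
    """Percent-of-sequences usage tables per V, per J and per (V, J) pair.

    The pair table enumerates the full |V|·|J| grid (zero-count pairs
    included) so repertoires are comparable row-for-row.
    """
    if not kept:
        raise ValueError("no kept assignments")
    n = len(kept)
    v_names = [s.name for s in ref.v_segments]
    j_names = [s.name for s in ref.j_segments]
    v_counts = Counter(a.v_hit.segment_name for a in kept)  # type: ignore[union-attr]
    j_counts = Counter(a.j_hit.segment_name for a in kept)  # type: ignore[union-attr]
    vj_counts = Counter(
        (a.v_hit.segment_name, a.j_hit.segment_name)  # type: ignore[union-attr]
        for a in kept)
    v_df = pd.DataFrame({
        "segment": v_names,
        "count": [v_counts.get(v, 0) for v in v_names],
    })
    v_df["percent"] = 100.0 * v_df["count"] / n
    j_df = pd.DataFrame({
        "segment": j_names,
        "count": [j_counts.get(j, 0) for j in j_names],
    })
    j_df["percent"] = 100.0 * j_df["count"] / n
    rows = [(v, j, vj_counts.get((v, j), 0)) for v in v_names for j in j_names]
    vj_df = pd.DataFrame(rows, columns=["v_segment", "j_segment", "count"])
    vj_df["percent"] = 100.0 * vj_df["count"] / n
    return {"v": v_df, "j": j_df, "vj": vj_df}


def write_assignments_tsv(assignments: Sequence[SegmentAssignment], path) -> None:
    cols = ("read_id", "v_name", "j_name", "v_score", "j_score", "v_evalue",
            "j_evalue", "d_region", "passed_filter", "fail_reason")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in assignments:
            v, j = a.v_hit, a.j_hit
            fh.write("\t".join([
                a.read_id,
                v.segment_name if v else "",
                j.segment_name if j else "",
                f"{v.score:g}" if v else "",
                f"{j.score:g}" if j else "",
                f"{v.evalue:.3g}" if v else "",
                f"{j.evalue:.3g}" if j else "",
                a.d_region,
                str(a.passed_filter),
                a.fail_reason or "",
            ]) + "\n")
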