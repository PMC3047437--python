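"""Local alignment primitives and Karlin–Altschul E-values.

Wraps an affine-gap Smith–Waterman (Bio.Align.PairwiseAligner in local mode)
and attaches an expectation value of the ungapped-theory form
``E = K * m * n * exp(-lambda * S)``, where m is the read length and n the
total length of the germline class searched.  The lambda/K defaults are
calibration constants for the default +1/-2 nucleotide scoring, not claimed
to match any particular BLAST build; the threshold semantics (reads whose
best V or J fit is no better than chance are discarded) are what matters
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a read against one germline segment.

    Spans are 0-based half-open: ``read_span`` on the read,
    ``germline_span`` on the segment.  ``identity`` is the matched fraction
    of aligned (non-gap) columns.
    """

    segment_name: str
    score: float
    read_span: tuple[int, int]
    germline_span: tuple[int, int]
    identity: float
    evalue: float


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float, k: float) -> float:
    """E = K·m·n·exp(−λ·S); clipped into a representable float."""
    x = math.log(k) + math.log(m) + math.log(n) - lam * score
    if x > 700.0:
        return math.inf
    return math.exp(x)


def make_local_aligner(match: float, mismatch: float,
                       gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def make_global_aligner(match: float, mismatch: float,
                        gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    """Needleman–Wunsch with free end gaps on the read side only is not
    needed here: mutation calling aligns a pre-extracted read window against
    the full segment, so a plain global alignment is appropriate."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def alignment_spans_identity(alignment) -> tuple[tuple[int, int],
                                                 tuple[int, int], float]:
    """Extract (read_span, germline_span, identity) from a Bio.Align alignment
    whose target is the read and query the segment."""
    read_blocks, germ_blocks = alignment.aligned
    if len(read_blocks) == 0:
        return (0, 0), (0, 0), 0.0
    read_span = (int(read_blocks[0][0]), int(read_blocks[-1][1]))
    germ_span = (int(germ_blocks[0][0]), int(germ_blocks[-1][1]))
    target = alignment.target
    query = alignment.query
    matches = 0
    columns = 0
    for (rs, re_), (gs, ge) in zip(read_blocks, germ_blocks):
        for a, b in zip(target[rs:re_], query[gs:ge]):
            columns += 1
            if a == b:
                matches += 1
    identity = matches / columns if columns else 0.0
    return read_span, germ_span, identity
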