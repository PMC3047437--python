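"""Germline references and repertoire reads.

The recombination space of the zebrafish immunoglobulin heavy chain is built
from 39 V, 5 D and 5 J germline gene segments; a recombined read is (up to
mutation) a concatenation of one segment from each class.  This module holds
the catalog of those segments (:class:`GermlineReference`), the per-read
record (:class:`IgRead`, optionally carrying simulation ground truth), FASTA
I/O for both, and a deterministic synthetic reference generator used whenever
a real germline download is not available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

SegClass = Literal["V", "D", "J"]

_VALID_BASES = frozenset("ACGT")

#: Sense codons of the standard genetic code (no stop codons); used by the
#: synthetic reference generator so that V segments are open in frame 0.
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input or invalid sequence characters."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment (V, D or J) with an uppercase ACGT sequence."""

    name: str
    seg_class: SegClass
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"segment {self.name!r}: empty sequence")
        if self.seg_class not in ("V", "D", "J"):
            raise ValueError(f"segment {self.name!r}: class {self.seg_class!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"segment {self.name!r}: non-ACGT characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GermlineReference:
    """Ordered V/D/J segment collections defining the recombination space."""

    v_segments: list[GermlineSegment] = field(default_factory=list)
    d_segments: list[GermlineSegment] = field(default_factory=list)
    j_segments: list[GermlineSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cls, segs in (("V", self.v_segments), ("D", self.d_segments),
                          ("J", self.j_segments)):
            names = [s.name for s in segs]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate segment names in class {cls}")
            for s in segs:
                if s.seg_class != cls:
                    raise ValueError(
                        f"segment {s.name!r} of class {s.seg_class} "
                        f"stored in class {cls}"
                    )

    def segments(self, seg_class: SegClass) -> list[GermlineSegment]:
        return {"V": self.v_segments, "D": self.d_segments,
                "J": self.j_segments}[seg_class]

    def get(self, seg_class: SegClass, name: str) -> GermlineSegment:
        for s in self.segments(seg_class):
            if s.name == name:
                return s
        raise KeyError(f"no {seg_class} segment named {name!r}")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.v_segments), len(self.d_segments), len(self.j_segments))

    def require_simulation_ready(self) -> None:
        if not (self.v_segments and self.d_segments and self.j_segments):
            raise ValueError(
                "simulation requires at least one segment per class; "
                f"have counts {self.counts}"
            )


@dataclass(frozen=True)
class Edit:
    """One applied edit, in simulator application order.

    ``pos`` indexes the sequence state at application time (0-based).
    ``ref`` is the base replaced/deleted ('' for insertions); ``alt`` the
    base introduced ('' for deletions).
    """

    kind: Literal["sub", "del", "ins"]
    pos: int
    ref: str
    alt: str

    def compact(self) -> str:
        if self.kind == "sub":
            return f"S{self.pos}{self.ref}>{self.alt}"
        if self.kind == "del":
            return f"D{self.pos}{self.ref}"
        return f"I{self.pos}+{self.alt}"

    @staticmethod
    def parse(token: str) -> "Edit":
        if token.startswith("S"):
            body = token[1:]
            ref_alt = body.lstrip("0123456789")
            pos = int(body[: len(body) - len(ref_alt)])
            ref, alt = ref_alt.split(">")
            return Edit("sub", pos, ref, alt)
        if token.startswith("D"):
            body = token[1:]
            ref = body.lstrip("0123456789")
            pos = int(body[: len(body) - len(ref)])
            return Edit("del", pos, ref, "")
        if token.startswith("I"):
            pos_s, alt = token[1:].split("+")
            return Edit("ins", int(pos_s), "", alt)
        raise ValueError(f"unparsable edit token {token!r}")


@dataclass(frozen=True)
class ReadTruth:
    """Simulation ground truth: the germline recipe and the applied edits."""

    v_name: str
    d_name: str
    j_name: str
    edits: tuple[Edit, ...] = ()

    def compact_edits(self) -> str:
        return ";".join(e.compact() for e in self.edits)


@dataclass(frozen=True)
class IgRead:
    """One heavy-chain nucleotide read, optionally with simulation truth."""

    read_id: str
    sequence: str
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.read_id!r}: non-ACGT {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, *, record_name: str = "?",
                       on_ambiguous: str = "error") -> str | None:
    """Uppercase, map U->T, and police the 4-letter alphabet.

    ``on_ambiguous='drop'`` returns None (caller drops the record with a
    warning) instead of raising on IUPAC ambiguity codes such as N.
    """
    seq = raw.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in _VALID_BASES:
            if on_ambiguous == "drop":
                log.warning(
                    "dropping record %s: ambiguous character %r at position %d",
                    record_name, ch, i,
                )
                return None
            raise FastaFormatError(
                f"record {record_name!r}: invalid character {ch!r} at position {i}"
            )
    return seq


def _route_class(name: str, class_map: Mapping[str, SegClass] | None) -> SegClass:
    if class_map is not None:
        try:
            return class_map[name]
        except KeyError:
            raise FastaFormatError(
                f"germline record {name!r} missing from class map"
            ) from None
    initial = name[:1].upper()
    if initial in ("V", "D", "J"):
        return initial  # type: ignore[return-value]
    raise FastaFormatError(
        f"germline record {name!r}: header must begin with V, D or J "
        "(or supply an explicit class map)"
    )


def read_fasta_reads(path: str | Path, *, on_ambiguous: str = "error") -> list[IgRead]:
    """Read a repertoire FASTA into a list of :class:`IgRead`."""
    path = Path(path)
    reads: list[IgRead] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), record_name=rec.id,
                                 on_ambiguous=on_ambiguous)
        if seq is None:
            continue
        if not seq:
            raise FastaFormatError(f"record {rec.id!r}: empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate read id {rec.id!r}")
        seen.add(rec.id)
        reads.append(IgRead(rec.id, seq))
    if not reads:
        log.warning("no records parsed from %s", path)
    return reads


def read_fasta_reference(
    path: str | Path,
    *,
    class_map: Mapping[str, SegClass] | None = None,
    on_ambiguous: str = "error",
) -> GermlineReference:
    """Read a germline FASTA, routing records to V/D/J classes.

    By default the header token before the first whitespace must begin with
    V, D or J (case-insensitive); ``class_map`` overrides that convention.
    """
    path = Path(path)
    buckets: dict[SegClass, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    any_record = False
    for rec in SeqIO.parse(str(path), "fasta"):
        any_record = True
        seq = normalize_sequence(str(rec.seq), record_name=rec.id,
                                 on_ambiguous=on_ambiguous)
        if seq is None:
            continue
        if not seq:
            raise FastaFormatError(f"record {rec.id!r}: empty sequence")
        cls = _route_class(rec.id, class_map)
        buckets[cls].append(GermlineSegment(rec.id, cls, seq))
    if not any_record:
        log.warning("no records parsed from %s", path)
    return GermlineReference(buckets["V"], buckets["D"], buckets["J"])


def write_fasta(records: GermlineReference | Iterable[IgRead],
                path: str | Path) -> None:
    """Write a reference or a read collection as uncompressed FASTA."""
    path = Path(path)
    if isinstance(records, GermlineReference):
        seqrecs = [
            SeqRecord(Seq(s.sequence), id=s.name, description="")
            for cls in ("V", "D", "J")
            for s in records.segments(cls)  # keeps class order stable
        ]
    else:
        seqrecs = [SeqRecord(Seq(r.sequence), id=r.read_id, description="")
                   for r in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def recombination_space_size(ref: GermlineReference, include_d: bool = True) -> int:
    """Number of distinct germline joining recipes: |V|·|D|·|J| or |V|·|J|."""
    n_v, n_d, n_j = ref.counts
    return n_v * n_d * n_j if include_d else n_v * n_j


# ---------------------------------------------------------------------------
# Synthetic default reference

#: Amino-acid motifs planted in the synthetic reference so that translated
#: reads carry the conserved teleost VH / DH-JH signatures.
V_TAIL_MOTIF = "EDTAVYYCAR"
J_MOTIFS = (
    "FDYWGKGTMVTVSS",  # the canonical DH-JH motif, on most J segments
    "FDYWGKGTMVTVTS",
    "FDYWGKGTKVTVSS",
)

_AA_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _encode_aa(motif: str) -> str:
    return "".join(_AA_CODON[aa] for aa in motif)


def _random_codons(n: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)


def synthetic_reference(
    n_v: int = 39,
    n_d: int = 5,
    n_j: int = 5,
    *,
    v_length: int = 288,
    d_length: int = 15,
    j_length: int = 48,
    seed: int = 20130,
) -> GermlineReference:
    """Deterministic synthetic V/D/J catalog with the zebrafish class counts.

    V segments are 96 sense codons in frame 0 ending with the conserved VH
    motif EDTAVYYCAR; J segments carry the DH-JH FDYWGKGT... motif family.
    All lengths are multiples of 3 so the V(D)J concatenate stays in frame.
    Segments are random otherwise and pairwise distinguishable with
    overwhelming probability.
    """
    if v_length % 3 or j_length % 3:
        raise ValueError("v_length and j_length must be codon multiples")
    rng = np.random.default_rng(seed)
    v_tail = _encode_aa(V_TAIL_MOTIF)
    if len(v_tail) > v_length:
        v_tail = ""  # motif does not fit in very short test references
    v_segs = []
    for i in range(n_v):
        body = _random_codons((v_length - len(v_tail)) // 3, rng)
        v_segs.append(GermlineSegment(f"V{i + 1:02d}", "V", body + v_tail))
    d_segs = []
    for i in range(n_d):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=d_length))
        d_segs.append(GermlineSegment(f"D{i + 1}", "D", seq))
    j_segs = []
    for i in range(n_j):
        motif = _encode_aa(J_MOTIFS[i % len(J_MOTIFS)] if i < len(J_MOTIFS)
                           else J_MOTIFS[0])
        if len(motif) > j_length:
            motif = ""
        tail = _random_codons((j_length - len(motif)) // 3, rng)
        j_segs.append(GermlineSegment(f"J{i + 1}", "J", motif + tail))
    return GermlineReference(v_segs, d_segs, j_segs)
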