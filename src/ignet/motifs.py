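"""Translation and conserved amino-acid motif scanning.

Teleost heavy chains carry conserved residues at the end of the VH region
(EDTAVYYCAR, whose AVYYCAR core is shared as far out as shark TCR V) and
across the DH-JH junction (the FDYWGKGT[M/K]VTV[SS/TS/ST] family).  This
module translates nucleotide reads in all three frames and reports, per
motif, which reads contain it — exactly (or with at most one mismatching
residue when requested).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .reference import IgRead

_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Default catalog: the DH-JH motif family and the VH-region motif (plus its
#: shark-shared core).
DEFAULT_CATALOG: dict[str, str] = {
    "dhjh_mvtvss": "FDYWGKGTMVTVSS",
    "dhjh_mvtvst": "FDYWGKGTMVTVST",
    "dhjh_mvtvts": "FDYWGKGTMVTVTS",
    "dhjh_kvtvss": "FDYWGKGTKVTVSS",
    "vh_edtavyycar": "EDTAVYYCAR",
    "vh_avyycar": "AVYYCAR",
}


@dataclass(frozen=True)
class MotifHit:
    read_id: str
    motif_name: str
    motif: str
    aa_position: int
    frame: int
    mismatches: int


def translate(seq: str, frame: int = 0) -> str:
    """Standard-code translation from ``frame``; trailing partial codon
    dropped, stop codons emitted as '*'."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate())


def load_catalog(path: str | Path) -> dict[str, str]:
    """Two-column text file: name <whitespace> motif."""
    catalog: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, motif = line.split()
        motif = motif.upper()
        bad = set(motif) - _AA
        if bad:
            raise ValueError(f"motif {name!r}: invalid residues {sorted(bad)}")
        catalog[name] = motif
    return catalog


def _scan_one(protein: str, motif: str, max_mismatch: int):
    """Yield (position, mismatches) for all windows within tolerance."""
    m = len(motif)
    exact_positions = set()
    start = protein.find(motif)
    while start != -1:
        exact_positions.add(start)
        yield start, 0
        start = protein.find(motif, start + 1)
    if max_mismatch >= 1:
        for i in range(len(protein) - m + 1):
            if i in exact_positions:
                continue
            mm = 0
            for a, b in zip(protein[i:i + m], motif):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                yield i, mm


def scan_motifs(
    reads: Iterable[IgRead],
    catalog: Mapping[str, str] | None = None,
    max_mismatch: int = 0,
) -> tuple[list[MotifHit], pd.DataFrame]:
    """Scan all three frames of every read for every catalog motif.

    Returns the full hit list plus a per-motif frequency table (fraction of
    reads with at least one hit; a read counts once per motif however many
    windows match).
    """
    if catalog is None:
        catalog = DEFAULT_CATALOG
    if not catalog:
        raise ValueError("empty motif catalog")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    hits: list[MotifHit] = []
    reads_with: Counter[str] = Counter()
    n_reads = 0
    for read in reads:
        n_reads += 1
        proteins = [translate(read.sequence, f) for f in (0, 1, 2)]
        for name, motif in catalog.items():
            found = False
            for frame, protein in enumerate(proteins):
                for pos, mm in _scan_one(protein, motif, max_mismatch):
                    hits.append(MotifHit(read.read_id, name, motif, pos,
                                         frame, mm))
                    found = True
            if found:
                reads_with[name] += 1
    freq = pd.DataFrame({
        "motif_name": list(catalog),
        "motif": [catalog[n] for n in catalog],
        "n_reads_with_hit": [reads_with.get(n, 0) for n in catalog],
    })
    freq["fraction"] = (freq["n_reads_with_hit"] / n_reads) if n_reads else 0.0
    return hits, freq


def top_kmers(reads: Iterable[IgRead], k: int = 8, top: int = 10) -> pd.DataFrame:
    """Descriptive aid: most frequent k-residue windows over all-frame
    translations (fraction of reads containing each window)."""
    counts: Counter[str] = Counter()
    n_reads = 0
    for read in reads:
        n_reads += 1
        seen: set[str] = set()
        for frame in (0, 1, 2):
            p = translate(read.sequence, frame)
            for i in range(len(p) - k + 1):
                w = p[i:i + k]
                if "*" not in w:
                    seen.add(w)
        counts.update(seen)
    rows = counts.most_common(top)
    df = pd.DataFrame(rows, columns=["kmer", "n_reads"])
    if n_reads:
        df["fraction"] = df["n_reads"] / n_reads
    return df


def write_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmotif_name\tmotif\taa_position\tframe\tmismatches\n")
        for h in hits:
            fh.write(f"{h.read_id}\t{h.motif_name}\t{h.motif}\t{h.aa_position}"
                     f"\t{h.frame}\t{h.mismatches}\n")
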