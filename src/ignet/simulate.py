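"""Synthetic repertoire generation.

Implements the random-network construction — choose one V, one D and one J
germline segment uniformly at random, concatenate them into a naive sequence,
then scatter point mutations plus rare single-base insertions and deletions —
and an optional clonal-expansion mode in which a founder sequence is copied
many times with a few extra substitutions per copy, producing the large
identical-sequence clones and mutation-linked lineages characteristic of a
responding repertoire.

Substitution origins are biased by base: the default origin weights
(A, C, G, T) = (0.14, 0.46, 0.36, 0.04) reproduce the strong preference for
mutations at C (and G on the opposite strand) expected under AID-driven
somatic hypermutation, so the downstream mutation spectrum has a known ground
truth to recover.

Edit counts are Poisson with the configured means.  Every read carries its
ground truth (segment names and the ordered edit list); replaying the edits
on the reconstructed naive sequence reproduces the read exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import Edit, GermlineReference, IgRead, ReadTruth, write_fasta

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Mutation-origin probabilities for (A, C, G, T); AID-like C/G dominance.
DEFAULT_ORIGIN_WEIGHTS = (0.14, 0.46, 0.36, 0.04)


@dataclass(frozen=True)
class ExpansionConfig:
    """Clonal-expansion block: lineages of near-identical copies.

    Each lineage takes ``lineage_fraction`` of the repertoire; every copy
    beyond the founder receives ``Poisson(per_copy_mutations)`` extra
    substitutions, so the lineage collapses into one dominant vertex plus a
    halo of single-mutation neighbours in the network.
    """

    n_lineages: int = 1
    lineage_fraction: float = 0.4
    per_copy_mutations: float = 0.5

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ValueError("n_lineages >= 1 required")
        if not 0.0 < self.lineage_fraction <= 1.0:
            raise ValueError("lineage_fraction in (0, 1] required")
        if self.n_lineages * self.lineage_fraction > 1.0 + 1e-9:
            raise ValueError("lineages exceed repertoire size")
        if self.per_copy_mutations < 0:
            raise ValueError("per_copy_mutations >= 0 required")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the random-repertoire generator.

    Rates are expected edit counts per sequence (Poisson means);
    ``origin_weights`` is the probability that a substitution originates at
    an A, C, G or T base respectively.
    """

    n_sequences: int = 10_000
    seed: int = 0
    sub_rate: float = 2.0
    del_rate: float = 0.05
    ins_rate: float = 0.05
    origin_weights: tuple[float, float, float, float] = DEFAULT_ORIGIN_WEIGHTS
    expansion: ExpansionConfig | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences >= 1 required")
        for name in ("sub_rate", "del_rate", "ins_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        w = np.asarray(self.origin_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any():
            raise ValueError("origin_weights must be four non-negative values")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("origin_weights must sum to 1")


@dataclass
class SimulatedRepertoire:
    """Reads with ground truth, plus the config and reference that made them."""

    reads: list[IgRead]
    config: SimulationConfig
    ref: GermlineReference

    def naive_sequence(self, read: IgRead) -> str:
        """Reconstruct the unmutated V+D+J concatenate behind a read."""
        t = read.truth
        if t is None:
            raise ValueError(f"read {read.read_id} has no truth record")
        return (self.ref.get("V", t.v_name).sequence
                + self.ref.get("D", t.d_name).sequence
                + self.ref.get("J", t.j_name).sequence)


def make_naive_sequence(
    ref: GermlineReference, rng: np.random.Generator
) -> tuple[str, str, str, str]:
    """Uniformly pick one segment per class and concatenate V+D+J."""
    ref.require_simulation_ready()
    v = ref.v_segments[rng.integers(len(ref.v_segments))]
    d = ref.d_segments[rng.integers(len(ref.d_segments))]
    j = ref.j_segments[rng.integers(len(ref.j_segments))]
    return v.sequence + d.sequence + j.sequence, v.name, d.name, j.name


def apply_edits(seq: str, edits: tuple[Edit, ...] | list[Edit]) -> str:
    """Replay an ordered edit list; the simulator's round-trip guarantee."""
    chars = list(seq)
    for e in edits:
        if e.kind == "sub":
            if chars[e.pos] != e.ref:
                raise ValueError(f"edit {e.compact()} does not match sequence")
            chars[e.pos] = e.alt
        elif e.kind == "del":
            if chars[e.pos] != e.ref:
                raise ValueError(f"edit {e.compact()} does not match sequence")
            del chars[e.pos]
        else:
            chars.insert(e.pos, e.alt)
    return "".join(chars)


def _draw_substitutions(
    chars: list[str],
    n_sub: int,
    origin_weights: np.ndarray,
    rng: np.random.Generator,
) -> list[Edit]:
    edits: list[Edit] = []
    for _ in range(n_sub):
        # Positions indexed by current base; renormalize the origin weights
        # over bases actually present so a draw is always realizable.
        by_base: dict[str, list[int]] = {b: [] for b in BASES}
        for i, ch in enumerate(chars):
            by_base[ch].append(i)
        avail = np.array([1.0 if by_base[b] else 0.0 for b in BASES])
        w = origin_weights * avail
        if w.sum() == 0:
            w = avail
        if w.sum() == 0:
            break
        w = w / w.sum()
        base = BASES[rng.choice(4, p=w)]
        pos = int(rng.choice(by_base[base]))
        alt = rng.choice([b for b in BASES if b != base])
        edits.append(Edit("sub", pos, base, str(alt)))
        chars[pos] = str(alt)
    return edits


def mutate_sequence(
    seq: str, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[str, tuple[Edit, ...]]:
    """Apply Poisson numbers of substitutions, deletions and insertions.

    Substitutions first (origin-biased positions, target uniform over the
    other three bases), then deletions (uniform positions), then insertions
    (uniform base, uniform slot).  Positions in the returned edit list refer
    to the sequence state at application time.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    chars = list(seq)
    weights = np.asarray(cfg.origin_weights, dtype=float)
    edits: list[Edit] = list(
        _draw_substitutions(chars, int(rng.poisson(cfg.sub_rate)), weights, rng)
    )
    n_del = int(rng.poisson(cfg.del_rate))
    if n_del >= len(chars):
        log.warning("deletion draw %d >= length %d; capping", n_del, len(chars))
        n_del = len(chars) - 1
    for _ in range(n_del):
        pos = int(rng.integers(len(chars)))
        edits.append(Edit("del", pos, chars[pos], ""))
        del chars[pos]
    for _ in range(int(rng.poisson(cfg.ins_rate))):
        pos = int(rng.integers(len(chars) + 1))
        alt = str(rng.choice(list(BASES)))
        edits.append(Edit("ins", pos, "", alt))
        chars.insert(pos, alt)
    return "".join(chars), tuple(edits)


def _extra_substitutions(
    seq: str, mean: float, origin_weights: np.ndarray, rng: np.random.Generator
) -> tuple[str, tuple[Edit, ...]]:
    chars = list(seq)
    edits = _draw_substitutions(chars, int(rng.poisson(mean)), origin_weights, rng)
    return "".join(chars), tuple(edits)


def simulate_repertoire(
    ref: GermlineReference,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedRepertoire:
    """Generate a full repertoire, expansion lineages first, then independents."""
    ref.require_simulation_ready()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    weights = np.asarray(cfg.origin_weights, dtype=float)
    reads: list[IgRead] = []

    def next_id() -> str:
        return f"sim{len(reads) + 1:06d}"

    if cfg.expansion is not None:
        size = int(round(cfg.expansion.lineage_fraction * cfg.n_sequences))
        size = max(size, 1)
        for _ in range(cfg.expansion.n_lineages):
            naive, v, d, j = make_naive_sequence(ref, rng)
            founder_seq, founder_edits = mutate_sequence(naive, cfg, rng)
            reads.append(IgRead(next_id(), founder_seq,
                                ReadTruth(v, d, j, founder_edits)))
            for _ in range(size - 1):
                copy_seq, extra = _extra_substitutions(
                    founder_seq, cfg.expansion.per_copy_mutations, weights, rng
                )
                reads.append(IgRead(next_id(), copy_seq,
                                    ReadTruth(v, d, j, founder_edits + extra)))

    while len(reads) < cfg.n_sequences:
        naive, v, d, j = make_naive_sequence(ref, rng)
        seq, edits = mutate_sequence(naive, cfg, rng)
        reads.append(IgRead(next_id(), seq, ReadTruth(v, d, j, edits)))

    return SimulatedRepertoire(reads[: cfg.n_sequences], cfg, ref)


def write_truth_table(rep: SimulatedRepertoire, path) -> None:
    """TSV ground truth: read_id, v/d/j names, compact edit string."""
    with open(path, "w") as fh:
        fh.write("read_id\tv_name\td_name\tj_name\tedits\n")
        for r in rep.reads:
            t = r.truth
            assert t is not None
            fh.write(f"{r.read_id}\t{t.v_name}\t{t.d_name}\t{t.j_name}\t"
                     f"{t.compact_edits()}\n")


def write_repertoire(rep: SimulatedRepertoire, fasta_path, truth_path=None) -> None:
    write_fasta(rep.reads, fasta_path)
    if truth_path is not None:
        write_truth_table(rep, truth_path)
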