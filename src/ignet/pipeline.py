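"""End-to-end orchestration: simulate/ingest → assign → mutations → network
→ metrics → motifs, with a run manifest for auditability.

A single global seed fans out to per-stage seeds through a stable
``SeedSequence`` derivation, so the same configuration and seed produce
byte-identical outputs, and individual stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .assignment import (AssignmentConfig, SegmentAssigner, filter_repertoire,
                         vj_usage_table, write_assignments_tsv)
from .metrics import (DEFAULT_CLONE_THRESHOLD, DEFAULT_GERMLINE_THRESHOLD,
                      centrality_report, classify_phenotype)
from .motifs import DEFAULT_CATALOG, load_catalog, scan_motifs, write_hits_tsv
from .mutations import (MutationCaller, spectrum, write_mutations_tsv,
                        write_spectrum_tsv)
from .network import build_network_from_reads, export_network
from .reference import (GermlineReference, read_fasta_reads,
                        read_fasta_reference, synthetic_reference, write_fasta)
from .simulate import SimulationConfig, simulate_repertoire, write_truth_table

log = logging.getLogger(__name__)

STAGE_NAMES = ("simulate", "assign", "mutations", "network", "metrics",
               "motifs")


@dataclass
class RunConfig:
    """One pipeline run: either an input FASTA or a simulation block."""

    out_dir: Path
    seed: int = 0
    input_fasta: Path | None = None
    reference_fasta: Path | None = None
    simulation: SimulationConfig | None = None
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    clone_threshold: float = DEFAULT_CLONE_THRESHOLD
    germline_threshold: float = DEFAULT_GERMLINE_THRESHOLD
    motif_catalog: Path | None = None
    dedupe_mutations: bool = False

    def __post_init__(self) -> None:
        if self.input_fasta is None and self.simulation is None:
            raise ValueError("either input_fasta or a simulation block "
                             "must be provided")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage derived seed (< 2**31)."""
    ss = np.random.SeedSequence([seed, STAGE_NAMES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage into ``cfg.out_dir``; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ignet")
    root.addHandler(fh)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    manifest: dict[str, object] = {
        "ignet_version": __version__,
        "seed": cfg.seed,
    }

    if cfg.reference_fasta is not None:
        ref = read_fasta_reference(cfg.reference_fasta)
        manifest["reference"] = str(cfg.reference_fasta)
        manifest["reference_sha256"] = _sha256(Path(cfg.reference_fasta))
    else:
        ref = synthetic_reference()
        manifest["reference"] = "synthetic(39V,5D,5J)"
    write_fasta(ref, out / "germline.fasta")
    manifest["reference_counts"] = "x".join(map(str, ref.counts))

    if cfg.input_fasta is not None:
        reads = read_fasta_reads(cfg.input_fasta)
        manifest["input"] = str(cfg.input_fasta)
        manifest["input_sha256"] = _sha256(Path(cfg.input_fasta))
    else:
        sim_cfg = cfg.simulation
        assert sim_cfg is not None
        rng = np.random.default_rng(stage_seed(cfg.seed, "simulate"))
        rep = simulate_repertoire(ref, sim_cfg, rng)
        reads = rep.reads
        write_fasta(reads, out / "reads.fasta")
        write_truth_table(rep, out / "truth.tsv")
        manifest["input"] = "simulated"
    manifest["n_reads_in"] = len(reads)

    assigner = SegmentAssigner(ref, cfg.assignment)
    assignments = assigner.assign_repertoire(reads)
    kept, removed, removed_fraction = filter_repertoire(assignments)
    write_assignments_tsv(assignments, out / "assignments.tsv")
    manifest["n_kept"] = len(kept)
    manifest["n_removed"] = len(removed)
    manifest["removed_fraction"] = f"{removed_fraction:.6f}"
    log.info("filter removed %.3f%% of reads", 100 * removed_fraction)

    kept_ids = {a.read_id for a in kept}
    kept_reads = [r for r in reads if r.read_id in kept_ids]

    mut_reads = kept_reads
    if cfg.dedupe_mutations:
        seen: set[str] = set()
        mut_reads = []
        for r in kept_reads:
            if r.sequence not in seen:
                seen.add(r.sequence)
                mut_reads.append(r)
    caller = MutationCaller(ref, cfg.assignment)
    records = caller.call_repertoire(mut_reads, kept)
    write_mutations_tsv(records, out / "mutations.tsv")
    spec = spectrum(records)
    write_spectrum_tsv(spec, out / "spectrum.tsv")
    manifest["n_mutation_records"] = len(records)

    net = build_network_from_reads(kept_reads if kept_reads else reads)
    export_network(net, "pajek_net", out / "network.net")
    export_network(net, "graphml", out / "network.graphml")
    export_network(net, "edge_tsv", out / "network_edges.tsv")
    manifest["n_vertices"] = len(net.vertices)
    manifest["n_edges"] = len(net.edges)
    manifest["n_components"] = len(net.components)

    report = centrality_report(net)
    if kept:
        tables = vj_usage_table(kept, ref)
        tables["v"].to_csv(out / "v_usage.tsv", sep="\t", index=False)
        tables["j"].to_csv(out / "j_usage.tsv", sep="\t", index=False)
        tables["vj"].to_csv(out / "vj_usage.tsv", sep="\t", index=False)
    else:
        tables = None
    call = classify_phenotype(report, tables, cfg.clone_threshold,
                              cfg.germline_threshold)
    with open(out / "centrality.tsv", "w") as f:
        for key in ("n_reads", "n_vertices", "n_edges", "n_components",
                    "largest_component_fraction", "n_isolated_vertices",
                    "max_degree", "mean_degree", "max_betweenness",
                    "mean_betweenness", "largest_clone_percent"):
            f.write(f"{key}\t{getattr(report, key)}\n")
    manifest["largest_clone_percent"] = f"{report.largest_clone_percent:.4f}"
    manifest["max_degree"] = report.max_degree
    manifest["phenotype"] = call.label
    manifest["criteria_fired"] = ";".join(call.criteria_fired)

    catalog = (load_catalog(cfg.motif_catalog) if cfg.motif_catalog
               else DEFAULT_CATALOG)
    hits, freq = scan_motifs(kept_reads if kept_reads else reads, catalog,
                             max_mismatch=0)
    write_hits_tsv(hits, out / "motif_hits.tsv")
    freq.to_csv(out / "motif_frequencies.tsv", sep="\t", index=False)
    manifest["n_motif_hits"] = len(hits)

    with open(out / "manifest.txt", "w") as f:
        for k in sorted(manifest):
            f.write(f"{k}={manifest[k]}\n")
    return manifest
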