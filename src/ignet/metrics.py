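"""Centrality indices and repertoire phenotype classification.

A naive repertoire fragments into many small components with small vertices
(few identical reads); a responding repertoire carries one or a few dominant
clones — big vertices, high degrees and high betweenness.  The two summary
statistics used to separate them are the largest-clone percentile
(100 · max vertex multiplicity / total reads) and the skew of germline V/J
usage: repertoires are called highly connected when the largest clone holds
more than 10% of reads, or when at least 40% of reads use one single V or J
germline segment.

Betweenness follows the "proportion of shortest paths among all pairs of
reachable nodes" definition: Brandes accumulation per vertex, normalized by
the number of reachable pairs within the vertex's own connected component
(unreachable pairs contribute nothing, and ties split fractionally over all
geodesics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .network import RepertoireNetwork

DEFAULT_CLONE_THRESHOLD = 10.0     # percent of reads in the largest clone
DEFAULT_GERMLINE_THRESHOLD = 40.0  # percent of reads on one V or one J


def degree_distribution(net: RepertoireNetwork) -> tuple[pd.Series, dict]:
    """Per-vertex degree plus {max, mean} summary."""
    g = net.to_networkx()
    deg = pd.Series({n: d for n, d in g.degree()}, dtype=int).sort_index()
    summary = {"max": int(deg.max()), "mean": float(deg.mean())}
    return deg, summary


def betweenness(net: RepertoireNetwork,
                normalized: bool = True) -> dict[int, float]:
    """Shortest-path betweenness; normalized form is the proportion of
    geodesics between reachable pairs that pass through the vertex."""
    g = net.to_networkx()
    raw = nx.betweenness_centrality(g, normalized=False)
    if not normalized:
        return {n: float(v) for n, v in raw.items()}
    out: dict[int, float] = {}
    for comp in net.components:
        nc = len(comp)
        pairs = (nc - 1) * (nc - 2) / 2  # unordered reachable pairs excl. v
        for vid in comp:
            out[vid] = float(raw[vid]) / pairs if pairs > 0 else 0.0
    return out


@dataclass
class CentralityReport:
    """Network architecture summary for one repertoire."""

    n_reads: int
    n_vertices: int
    n_edges: int
    n_components: int
    largest_component_fraction: float
    n_isolated_vertices: int
    max_degree: int
    mean_degree: float
    max_betweenness: float
    mean_betweenness: float
    largest_clone_percent: float
    degree: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]
    betweenness_values: dict[int, float] = field(repr=False, default=None)  # type: ignore[assignment]


def centrality_report(net: RepertoireNetwork) -> CentralityReport:
    deg, deg_summary = degree_distribution(net)
    btw = betweenness(net, normalized=True)
    btw_vals = list(btw.values())
    total = net.total_reads
    max_mult = max(v.multiplicity for v in net.vertices)
    return CentralityReport(
        n_reads=total,
        n_vertices=len(net.vertices),
        n_edges=len(net.edges),
        n_components=len(net.components),
        largest_component_fraction=max(len(c) for c in net.components)
        / len(net.vertices),
        n_isolated_vertices=int((deg == 0).sum()),
        max_degree=deg_summary["max"],
        mean_degree=deg_summary["mean"],
        max_betweenness=max(btw_vals),
        mean_betweenness=sum(btw_vals) / len(btw_vals),
        largest_clone_percent=100.0 * max_mult / total,
        degree=deg,
        betweenness_values=btw,
    )


@dataclass(frozen=True)
class PhenotypeCall:
    label: str  # "poorly_connected" | "highly_connected"
    criteria_fired: tuple[str, ...]
    thresholds: Mapping[str, float]


def classify_phenotype(
    report: CentralityReport,
    vj_tables: Mapping[str, pd.DataFrame] | None,
    clone_threshold: float = DEFAULT_CLONE_THRESHOLD,
    germline_threshold: float = DEFAULT_GERMLINE_THRESHOLD,
) -> PhenotypeCall:
    """Highly connected iff largest clone > clone_threshold percent (strict)
    OR any single V or J segment carries >= germline_threshold percent."""
    fired: list[str] = []
    if report.largest_clone_percent > clone_threshold:
        fired.append(f"largest_clone>{clone_threshold:g}%")
    if vj_tables is not None:
        for cls in ("v", "j"):
            table = vj_tables.get(cls)
            if table is not None and len(table) and (
                    table["percent"].max() >= germline_threshold):
                fired.append(f"single_{cls.upper()}_usage>="
                             f"{germline_threshold:g}%")
    label = "highly_connected" if fired else "poorly_connected"
    return PhenotypeCall(label, tuple(fired), {
        "clone_threshold": clone_threshold,
        "germline_threshold": germline_threshold,
    })


def compare_profiles(
    reports: Sequence[CentralityReport],
    labels: Sequence[str],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Side-by-side centrality table; adds per-group means when groups given."""
    if len(reports) != len(labels):
        raise ValueError("one label per report required")
    rows = []
    for rep, lab in zip(reports, labels):
        rows.append({
            "repertoire": lab,
            "n_reads": rep.n_reads,
            "max_degree": rep.max_degree,
            "max_betweenness": rep.max_betweenness,
            "mean_betweenness": rep.mean_betweenness,
            "largest_clone_percent": rep.largest_clone_percent,
            "n_components": rep.n_components,
            "n_isolated": rep.n_isolated_vertices,
        })
    df = pd.DataFrame(rows)
    if groups is not None:
        if len(groups) != len(reports):
            raise ValueError("one group per report required")
        df["group"] = list(groups)
    return df


def group_means(df: pd.DataFrame) -> pd.DataFrame:
    if "group" not in df.columns:
        raise ValueError("no group column; pass groups to compare_profiles")
    return df.groupby("group")[
        ["max_degree", "max_betweenness", "mean_betweenness",
         "largest_clone_percent", "n_components", "n_isolated"]
    ].mean()


def plot_profiles(df: pd.DataFrame, path) -> None:
    """Scatter of max betweenness vs largest-clone percentile, one point per
    repertoire, colored by group when present."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if "group" in df.columns:
        for grp, sub in df.groupby("group"):
            ax.scatter(sub["largest_clone_percent"], sub["max_betweenness"],
                       label=str(grp))
        ax.legend()
    else:
        ax.scatter(df["largest_clone_percent"], df["max_betweenness"])
    ax.set_xlabel("largest clone (% of reads)")
    ax.set_ylabel("max betweenness (proportion)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
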