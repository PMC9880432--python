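"""Stage-specific networks: aggregation, hubs, conservation, similarity.

A stage network is the union of the per-cell networks of all cells
assigned to that developmental stage; each edge carries its *support*,
the number of the stage's cells in which it was significant.  Downstream
analyses classify edges (and hub lncRNAs) as conserved (present in every
stage), rewired (present in exactly one) or intermediate, and quantify
between-stage similarity with Jaccard or overlap coefficients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cellnet import CellNetwork
from .data_io import StageAssignment

logger = logging.getLogger(__name__)

LABEL_CONSERVED = "conserved"
LABEL_REWIRED = "rewired"
LABEL_INTERMEDIATE = "intermediate"

STAGE_EDGE_COLUMNS = ["lncRNA", "mRNA", "support", "mean_rho_hat", "min_p"]


@dataclass
class StageNetwork:
    """Union lncRNA -> mRNA network of one developmental stage."""

    stage: str
    n_cells: int
    edges: pd.DataFrame  # columns: lncRNA, mRNA, support, mean_rho_hat, min_p

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(zip(self.edges["lncRNA"], self.edges["mRNA"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> set[str]:
        return set(self.edges["lncRNA"]) | set(self.edges["mRNA"])

    @property
    def lncrnas(self) -> set[str]:
        return set(self.edges["lncRNA"])

    @property
    def mrnas(self) -> set[str]:
        return set(self.edges["mRNA"])

    def lncrna_degrees(self) -> pd.Series:
        """Out-degree (number of targets) of each lncRNA with degree >= 1."""
        return (
            self.edges.groupby("lncRNA", sort=False)["mRNA"]
            .nunique()
            .sort_index()
        )

    def targets_of(self, lncrna: str) -> set[str]:
        return set(self.edges.loc[self.edges["lncRNA"] == lncrna, "mRNA"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(stage=self.stage, n_cells=self.n_cells)
        for row in self.edges.itertuples(index=False):
            g.add_node(row.lncRNA, bipartite=0, role="lncRNA")
            g.add_node(row.mRNA, bipartite=1, role="mRNA")
            g.add_edge(row.lncRNA, row.mRNA, support=row.support)
        return g


def aggregate_stage(
    cell_networks: Sequence[CellNetwork],
    stages: StageAssignment,
    min_support: int = 1,
) -> list[StageNetwork]:
    """Union the per-cell networks of each stage, counting edge support.

    ``min_support`` (default 1, the pure union) optionally drops edges
    significant in fewer cells.  Stage order follows the assignment.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    by_stage: dict[str, list[CellNetwork]] = {s: [] for s in stages.stages}
    for net in cell_networks:
        by_stage[stages.stage_of(net.cell_id)].append(net)
    out = []
    for stage, members in by_stage.items():
        if not members:
            raise ValueError(f"stage {stage!r} has zero cells")
        frames = [n.edges for n in members if len(n.edges)]
        if not frames:
            logger.warning("stage %r has no significant edges", stage)
            edges = pd.DataFrame(columns=STAGE_EDGE_COLUMNS)
        else:
            cat = pd.concat(frames, ignore_index=True)
            grouped = (
                cat.groupby(["lncRNA", "mRNA"], sort=True)
                .agg(
                    support=("p", "size"),
                    mean_rho_hat=("rho_hat", "mean"),
                    min_p=("p", "min"),
                )
                .reset_index()
            )
            edges = grouped[grouped["support"] >= min_support].reset_index(
                drop=True
            )
        out.append(StageNetwork(stage=stage, n_cells=len(members), edges=edges))
    return out


class StageNetworkAggregator(BaseEstimator):
    """Aggregate per-cell networks into stage networks (estimator form).

    Attributes
    ----------
    stage_networks_ : list of StageNetwork in stage order.
    stages_ : stage labels in order.
    """

    def __init__(self, min_support: int = 1) -> None:
        self.min_support = min_support

    def fit(self, X: Sequence[CellNetwork], stages: StageAssignment | None = None):
        if stages is None:
            raise ValueError("a stage assignment is required")
        self.stage_networks_ = aggregate_stage(X, stages, self.min_support)
        self.stages_ = [n.stage for n in self.stage_networks_]
        return self


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def hub_lncrnas(net: StageNetwork, fraction: float = 0.2) -> list[str]:
    """Top-degree lncRNAs of one stage network.

    Ranks the lncRNAs with degree >= 1 by descending out-degree (ties by
    ascending symbol) and returns the top ``ceil(fraction * L)``.  The
    cut is deterministic: boundary ties beyond it are not included.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"hub fraction must be in (0, 1], got {fraction}")
    degrees = net.lncrna_degrees()
    if degrees.empty:
        raise ValueError(f"stage {net.stage!r} network has no lncRNAs")
    n_hubs = math.ceil(fraction * len(degrees))
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sym for sym, _ in ranked[:n_hubs]]


def hub_table(
    stage_networks: Sequence[StageNetwork], fraction: float = 0.2
) -> pd.DataFrame:
    """Hub lncRNAs of every stage: stage, lncRNA, degree, rank."""
    rows = []
    for net in stage_networks:
        degrees = net.lncrna_degrees()
        for rank, sym in enumerate(hub_lncrnas(net, fraction), start=1):
            rows.append(
                {
                    "stage": net.stage,
                    "lncRNA": sym,
                    "degree": int(degrees[sym]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows, columns=["stage", "lncRNA", "degree", "rank"])


# ---------------------------------------------------------------------------
# conserved / rewired classification
# ---------------------------------------------------------------------------

def _classify_items(
    per_stage_sets: Sequence[frozenset], n_stages: int
) -> dict[object, tuple[int, str]]:
    counts: dict[object, int] = {}
    for s in per_stage_sets:
        for item in s:
            counts[item] = counts.get(item, 0) + 1
    out = {}
    for item, c in counts.items():
        if c == n_stages:
            label = LABEL_CONSERVED
        elif c == 1:
            label = LABEL_REWIRED
        else:
            label = LABEL_INTERMEDIATE
        out[item] = (c, label)
    return out


def classify_edges(stage_networks: Sequence[StageNetwork]) -> pd.DataFrame:
    """Classify union edges as conserved / rewired / intermediate.

    Conserved edges are "on" in all stages, rewired in exactly one.
    Returns a table with columns lncRNA, mRNA, n_stages_on, label, sorted
    by (lncRNA, mRNA).
    """
    if len(stage_networks) < 2:
        raise ValueError("classification needs at least two stages")
    classified = _classify_items(
        [net.edge_set for net in stage_networks], len(stage_networks)
    )
    rows = [
        {"lncRNA": u, "mRNA": v, "n_stages_on": c, "label": lab}
        for (u, v), (c, lab) in classified.items()
    ]
    return (
        pd.DataFrame(rows, columns=["lncRNA", "mRNA", "n_stages_on", "label"])
        .sort_values(["lncRNA", "mRNA"])
        .reset_index(drop=True)
    )


def classify_hubs(
    stage_networks: Sequence[StageNetwork], fraction: float = 0.2
) -> pd.DataFrame:
    """Classify hub lncRNAs across stages (same rules as edges)."""
    if len(stage_networks) < 2:
        raise ValueError("classification needs at least two stages")
    hub_sets = [frozenset(hub_lncrnas(n, fraction)) for n in stage_networks]
    classified = _classify_items(hub_sets, len(stage_networks))
    rows = [
        {"lncRNA": h, "n_stages_on": c, "label": lab}
        for h, (c, lab) in classified.items()
    ]
    return (
        pd.DataFrame(rows, columns=["lncRNA", "n_stages_on", "label"])
        .sort_values("lncRNA")
        .reset_index(drop=True)
    )


def classification_summary(table: pd.DataFrame) -> dict[str, float]:
    """Counts and percentages of each class over the union set."""
    total = len(table)
    counts = table["label"].value_counts().to_dict()
    out: dict[str, float] = {"total": total}
    for label in (LABEL_CONSERVED, LABEL_REWIRED, LABEL_INTERMEDIATE):
        c = int(counts.get(label, 0))
        out[f"n_{label}"] = c
        out[f"pct_{label}"] = 100.0 * c / total if total else float("nan")
    return out


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def stage_similarity(A: Iterable, B: Iterable, method: str = "jaccard") -> float:
    """Set similarity between two stages' edges or hubs, in [0, 1].

    jaccard = |A ∩ B| / |A ∪ B|; overlap = |A ∩ B| / min(|A|, |B|).
    Two empty sets are defined as perfectly similar (1.0).
    """
    a, b = set(A), set(B)
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "overlap":
        if not a or not b:
            return 0.0
        return inter / min(len(a), len(b))
    raise ValueError(f"method must be 'jaccard' or 'overlap', got {method!r}")


def similarity_matrix(
    stage_networks: Sequence[StageNetwork],
    what: str = "edges",
    method: str = "jaccard",
    hub_fraction: float = 0.2,
) -> pd.DataFrame:
    """Symmetric S x S similarity matrix over stage edge or hub sets."""
    if what == "edges":
        sets = [net.edge_set for net in stage_networks]
    elif what == "hubs":
        sets = [frozenset(hub_lncrnas(n, hub_fraction)) for n in stage_networks]
    else:
        raise ValueError(f"what must be 'edges' or 'hubs', got {what!r}")
    labels = [net.stage for net in stage_networks]
    S = len(sets)
    mat = np.ones((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            mat[i, j] = mat[j, i] = stage_similarity(sets[i], sets[j], method)
    return pd.DataFrame(mat, index=labels, columns=labels)
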