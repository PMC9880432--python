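"""Per-cell lncRNA-mRNA association networks from a neighborhood statistic.

For a candidate pair (u, v) and a focal cell k, each gene defines a
*neighborhood* (box): with ``n = max(1, floor(box_fraction * m))``, the
box half-width is the distance of the n-th nearest cell to the focal
cell's expression value, and the neighborhood is every cell within that
distance.  The focal cell is always a member (distance zero), and cells
tied at the boundary are all included, so the box is a function of the
expression values alone — deterministic, and robust to the heavy
zero-ties of single-cell data (an index-based tie-break would hand every
zero-inflated gene the same arbitrary subset of zero cells, creating
spurious overlap between independent genes).  If u and v are
independent, the overlap ``m_uv`` of the two neighborhoods is what
uniform mixing predicts, ``m_u * m_v / m``.  The statistic

    rho = m_uv / m - (m_u / m) * (m_v / m)

standardised by its null standard deviation

    sigma = sqrt(m_u * m_v * (m - m_u) * (m - m_v) / (m**4 * (m - 1)))

is approximately standard normal under independence, giving a per-cell
p-value for each candidate pair.  Edges with p below ``alpha`` (upper
tail by default: only positive association counts as regulation) form a
bipartite lncRNA -> mRNA network for that cell.  The statistic is only
evaluated on a user-supplied prior interaction list, never on all pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .data_io import ExpressionMatrix, InteractionList

logger = logging.getLogger(__name__)

#: columns of a per-cell edge table
CELL_EDGE_COLUMNS = ["lncRNA", "mRNA", "rho", "rho_hat", "p"]


class DegenerateMarginError(ValueError):
    """A neighborhood covers no cells or all cells; the null s.d. is zero."""


@dataclass(frozen=True)
class NeighborhoodCounts:
    """Neighborhood sizes for one (pair, cell) instance.

    ``m`` cells total; ``m_u`` and ``m_v`` are the two marginal
    neighborhood sizes and ``m_uv`` the size of their intersection.
    """

    m: int
    m_u: int
    m_v: int
    m_uv: int

    def __post_init__(self) -> None:
        if not (1 <= self.m_u <= self.m and 1 <= self.m_v <= self.m):
            raise ValueError(f"marginal counts out of range: {self}")
        if not (0 <= self.m_uv <= min(self.m_u, self.m_v)):
            raise ValueError(f"overlap count out of range: {self}")
        if self.m_uv < self.m_u + self.m_v - self.m:
            raise ValueError(f"overlap below inclusion-exclusion bound: {self}")


@dataclass(frozen=True)
class EdgeStat:
    """Raw and normalised neighborhood statistic with its p-value."""

    rho: float
    rho_hat: float
    sigma_null: float
    p: float
    mu_null: float = 0.0


def box_size(m: int, box_fraction: float) -> int:
    """Neighborhood size: ``max(1, floor(box_fraction * m))``."""
    if not (0.0 < box_fraction <= 1.0):
        raise ValueError(f"box_fraction must be in (0, 1], got {box_fraction}")
    return max(1, math.floor(box_fraction * m))


def neighborhood(
    values: Sequence[float], k: int, box_fraction: float = 0.1
) -> np.ndarray:
    """Indices of the cells inside cell *k*'s expression box for one gene.

    With ``n = max(1, floor(box_fraction * m))``, returns a sorted
    integer array of every cell whose ``|x_j - x_k|`` is at most the
    distance of the n-th nearest cell (the focal cell itself counts as
    the nearest).  Boundary ties are all included, so the result depends
    only on the expression values; cell *k* is always a member.
    """
    x = np.asarray(values, dtype=float)
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least two cells")
    if not (0 <= k < m):
        raise IndexError(f"cell index {k} out of range for {m} cells")
    n = box_size(m, box_fraction)
    dist = np.abs(x - x[k])
    radius = np.partition(dist, n - 1)[n - 1]
    return np.flatnonzero(dist <= radius)


def _neighborhood_matrix(values: np.ndarray, n: int) -> np.ndarray:
    """Boolean (m, m) matrix; row k flags the neighborhood of cell k."""
    x = np.asarray(values, dtype=float)
    dist = np.abs(x[:, None] - x[None, :])
    radius = np.partition(dist, n - 1, axis=1)[:, n - 1]
    return dist <= radius[:, None]


def neighborhood_counts(
    u_values: Sequence[float],
    v_values: Sequence[float],
    k: int,
    box_fraction: float = 0.1,
) -> NeighborhoodCounts:
    """Neighborhood sizes and overlap for one pair at one focal cell."""
    u = np.asarray(u_values, dtype=float)
    v = np.asarray(v_values, dtype=float)
    if u.shape != v.shape:
        raise ValueError("expression vectors must have equal length")
    nu = neighborhood(u, k, box_fraction)
    nv = neighborhood(v, k, box_fraction)
    return NeighborhoodCounts(
        m=u.shape[0],
        m_u=nu.size,
        m_v=nv.size,
        m_uv=np.intersect1d(nu, nv, assume_unique=True).size,
    )


def normalized_stat(c: NeighborhoodCounts, tail: str = "upper") -> EdgeStat:
    """Standardise the neighborhood overlap and attach a normal p-value.

    Raises :class:`DegenerateMarginError` when a marginal neighborhood is
    empty or covers every cell (null variance zero).
    """
    m, m_u, m_v, m_uv = c.m, c.m_u, c.m_v, c.m_uv
    if m_u in (0, m) or m_v in (0, m):
        raise DegenerateMarginError(
            f"degenerate neighborhood margin (m_u={m_u}, m_v={m_v}, m={m})"
        )
    rho = m_uv / m - (m_u / m) * (m_v / m)
    sigma = math.sqrt(
        m_u * m_v * (m - m_u) * (m - m_v) / (float(m) ** 4 * (m - 1))
    )
    rho_hat = rho / sigma
    return EdgeStat(rho=rho, rho_hat=rho_hat, sigma_null=sigma, p=_pvalue(rho_hat, tail))


def _pvalue(rho_hat: float | np.ndarray, tail: str):
    if tail == "upper":
        return norm.sf(rho_hat)
    if tail == "two-sided":
        return 2.0 * norm.sf(np.abs(rho_hat))
    raise ValueError(f"tail must be 'upper' or 'two-sided', got {tail!r}")


# ---------------------------------------------------------------------------
# vectorised engine
# ---------------------------------------------------------------------------

def _usable_pairs(
    expr: ExpressionMatrix, priors: InteractionList
) -> list[tuple[str, str]]:
    """Prior pairs whose lncRNA and mRNA are both measured (roles checked
    when present); absent-gene pairs are skipped with a warning."""
    if expr.gene_role is not None:
        left = set(expr.lncrnas)
        right = set(expr.mrnas)
    else:
        left = right = set(expr.genes)
    usable = [(u, v) for u, v in priors if u in left and v in right]
    skipped = len(priors) - len(usable)
    if skipped:
        logger.warning(
            "skipped %d prior pair(s) referencing genes absent from the matrix",
            skipped,
        )
    if not usable:
        raise ValueError("no usable prior pairs overlap the expression matrix")
    return usable


def _pair_cell_stats(
    expr: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    box_fraction: float,
    tail: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rho, rho_hat, p), each of shape (n_pairs, m), for all prior pairs.

    Neighborhood masks and sizes are computed once per distinct gene.
    Tie expansion makes the marginal sizes data-dependent, so the null
    s.d. varies per (pair, cell).  Degenerate instances — a neighborhood
    covering every cell, where the null variance is zero — carry no
    evidence and are reported as rho_hat = 0, p = 1.
    """
    m = expr.n_cells
    n = box_size(m, box_fraction)
    if n == m:
        raise DegenerateMarginError(
            "box_fraction covers every cell; the null variance is zero"
        )
    genes = {g for pair in pairs for g in pair}
    masks = {g: _neighborhood_matrix(expr.gene_values(g), n) for g in genes}
    sizes = {g: masks[g].sum(axis=1) for g in genes}
    rho = np.empty((len(pairs), m))
    rho_hat = np.empty((len(pairs), m))
    for i, (u, v) in enumerate(pairs):
        m_uv = (masks[u] & masks[v]).sum(axis=1)
        m_u, m_v = sizes[u], sizes[v]
        rho[i] = m_uv / m - m_u * m_v / float(m) ** 2
        var = m_u * m_v * (m - m_u) * (m - m_v) / (float(m) ** 4 * (m - 1))
        ok = var > 0
        rho_hat[i] = np.where(ok, rho[i] / np.sqrt(np.where(ok, var, 1.0)), 0.0)
    # degenerate entries sit at rho_hat = 0, i.e. p = 0.5 (upper) or 1.0:
    # never significant at any conventional alpha
    return rho, rho_hat, _pvalue(rho_hat, tail)


@dataclass
class CellNetwork:
    """Bipartite lncRNA -> mRNA network of a single cell."""

    cell_id: str
    edges: pd.DataFrame  # columns: lncRNA, mRNA, rho, rho_hat, p

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            zip(self.edges["lncRNA"], self.edges["mRNA"])
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_node(row.lncRNA, bipartite=0, role="lncRNA")
            g.add_node(row.mRNA, bipartite=1, role="mRNA")
            g.add_edge(row.lncRNA, row.mRNA, rho=row.rho, rho_hat=row.rho_hat, p=row.p)
        return g


class CellNetworkInference(BaseEstimator):
    """Infer one bipartite lncRNA -> mRNA network per cell.

    Parameters
    ----------
    box_fraction : float, default 0.1
        Fraction of cells in each gene's neighborhood.
    alpha : float, default 0.05
        Per-(pair, cell) significance cutoff on the raw p-value; no
        multiple-testing correction is applied at this step.
    tail : {"upper", "two-sided"}, default "upper"
        Upper-tail tests count only positive association as regulation.

    Attributes
    ----------
    cell_networks_ : list of CellNetwork, one per cell in input order.
    pairs_ : list of usable (lncRNA, mRNA) prior pairs.
    rho_hat_, p_ : (n_pairs, n_cells) arrays of the normalised statistic
        and its p-value.
    n_cells_ : number of cells seen during fit.
    """

    def __init__(
        self,
        box_fraction: float = 0.1,
        alpha: float = 0.05,
        tail: str = "upper",
    ) -> None:
        self.box_fraction = box_fraction
        self.alpha = alpha
        self.tail = tail

    def fit(self, X: ExpressionMatrix, priors: InteractionList | None = None):
        if priors is None:
            raise ValueError("a prior interaction list is required")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        pairs = _usable_pairs(X, priors)
        rho, rho_hat, p = _pair_cell_stats(X, pairs, self.box_fraction, self.tail)
        sig = p < self.alpha
        lnc = np.array([u for u, _ in pairs])
        mrna = np.array([v for _, v in pairs])
        networks = []
        for j, cell in enumerate(X.cells):
            idx = np.flatnonzero(sig[:, j])
            networks.append(
                CellNetwork(
                    cell_id=cell,
                    edges=pd.DataFrame(
                        {
                            "lncRNA": lnc[idx],
                            "mRNA": mrna[idx],
                            "rho": rho[idx, j],
                            "rho_hat": rho_hat[idx, j],
                            "p": p[idx, j],
                        }
                    ),
                )
            )
        self.pairs_ = pairs
        self.rho_ = rho
        self.rho_hat_ = rho_hat
        self.p_ = p
        self.cell_networks_ = networks
        self.n_cells_ = X.n_cells
        return self


def cell_network(
    expr: ExpressionMatrix,
    priors: InteractionList,
    k: int,
    box_fraction: float = 0.1,
    alpha: float = 0.05,
    tail: str = "upper",
) -> CellNetwork:
    """Network of a single cell (index *k*); see :class:`CellNetworkInference`."""
    if not (0 <= k < expr.n_cells):
        raise IndexError(f"cell index {k} out of range")
    est = CellNetworkInference(box_fraction, alpha, tail).fit(expr, priors)
    return est.cell_networks_[k]


def all_cell_networks(
    expr: ExpressionMatrix,
    priors: InteractionList,
    box_fraction: float = 0.1,
    alpha: float = 0.05,
    tail: str = "upper",
) -> list[CellNetwork]:
    """One :class:`CellNetwork` per cell, in the matrix's cell order."""
    est = CellNetworkInference(box_fraction, alpha, tail).fit(expr, priors)
    return est.cell_networks_


def write_cell_edges(networks: Iterable[CellNetwork], path) -> None:
    """Optional per-cell edge dump: cell_id, lncRNA, mRNA, rho_hat, p."""
    rows = []
    for net in networks:
        df = net.edges[["lncRNA", "mRNA", "rho_hat", "p"]].copy()
        df.insert(0, "cell_id", net.cell_id)
        rows.append(df)
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["cell_id", "lncRNA", "mRNA", "rho_hat", "p"])
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
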