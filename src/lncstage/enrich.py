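"""Hypergeometric over-representation analysis and validation overlap.

The enrichment p-value of a network's gene list against an annotated set
(e.g. autism-associated genes) is the upper hypergeometric tail

    p = 1 - sum_{t=0}^{r-1} C(S, t) C(N-S, M-t) / C(N, M) = P(X >= r)

with N genes in the universe, S of them annotated, M genes in the
network and r of those annotated.  Multiple gene-set tests are adjusted
by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import InteractionList


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts entering the hypergeometric tail test."""

    N: int  # universe size
    S: int  # annotated genes in the universe
    M: int  # genes in the tested network
    r: int  # annotated genes in the tested network

    def __post_init__(self) -> None:
        if not (0 <= self.S <= self.N):
            raise ValueError(f"need 0 <= S <= N, got {self}")
        if not (0 <= self.M <= self.N):
            raise ValueError(f"need 0 <= M <= N, got {self}")
        if not (0 <= self.r <= min(self.S, self.M)):
            raise ValueError(f"need 0 <= r <= min(S, M), got {self}")
        if self.r < self.M - (self.N - self.S):
            raise ValueError(f"r below the inclusion-exclusion bound: {self}")


@dataclass
class EnrichmentResult:
    set_name: str
    input: EnrichmentInput
    p_raw: float
    p_adj: float | None = None

    @property
    def significant(self) -> bool:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        return p < 0.05


def hypergeom_enrichment(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    Computed through the log-gamma based survival function, numerically
    stable for large counts; r = 0 gives exactly 1.
    """
    return float(hypergeom.sf(inp.r - 1, inp.N, inp.S, inp.M))


def network_gene_enrichment(
    net,
    annotated: Iterable[str],
    universe: Iterable[str],
    which: str = "both",
) -> EnrichmentResult:
    """Enrichment of a stage network's genes in an annotated gene set.

    *which* selects the genes counted as "in the network": ``both``
    (default; lncRNAs and mRNAs jointly), ``lncRNA`` or ``mRNA``.
    Genes outside the universe are ignored on both sides.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    annotated = set(annotated) & universe
    if which == "both":
        net_genes = net.genes
    elif which == "lncRNA":
        net_genes = net.lncrnas
    elif which == "mRNA":
        net_genes = net.mrnas
    else:
        raise ValueError(f"which must be 'both', 'lncRNA' or 'mRNA', got {which!r}")
    net_genes = set(net_genes) & universe
    inp = EnrichmentInput(
        N=len(universe),
        S=len(annotated),
        M=len(net_genes),
        r=len(net_genes & annotated),
    )
    return EnrichmentResult(
        set_name=getattr(net, "stage", "network"),
        input=inp,
        p_raw=hypergeom_enrichment(inp),
    )


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = list(p_values)
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def ora_table(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha_adj: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a gene list in each of several gene sets.

    Returns a table with columns set, N, S, M, r, p_raw, p_adj,
    significant; BH adjustment runs across all collections.
    """
    if not collections:
        raise ValueError("need at least one gene-set collection")
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    rows = []
    for name, genes in collections.items():
        annotated = set(genes) & universe
        inp = EnrichmentInput(
            N=len(universe),
            S=len(annotated),
            M=len(query),
            r=len(query & annotated),
        )
        rows.append(
            {
                "set": name,
                "N": inp.N,
                "S": inp.S,
                "M": inp.M,
                "r": inp.r,
                "p_raw": hypergeom_enrichment(inp),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"])
    table["significant"] = table["p_adj"] < alpha_adj
    return table


def validated_fraction(
    predicted: InteractionList | Iterable[tuple[str, str]],
    validated: InteractionList | Iterable[tuple[str, str]],
) -> float:
    """Fraction of predicted pairs present in the validated list."""
    pred = set(tuple(p) for p in predicted)
    if not pred:
        raise ValueError("empty predicted interaction list")
    val = set(tuple(p) for p in validated)
    return len(pred & val) / len(pred)
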