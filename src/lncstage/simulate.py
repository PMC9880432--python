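"""Synthetic multi-stage single-cell datasets with planted regulation.

The generator emulates the shape of a multi-stage single-cell study:
several developmental stages with unequal cell counts, a zero-heavy
overdispersed count matrix, and a prior interaction list that is a
superset of the planted true edges.  Dependence between a planted
lncRNA and its mRNA target is induced through a latent Gaussian copula
(correlation ``rho_sim`` in the stages where the edge is active) whose
marginals are negative binomial, followed by independent dropout
zero-masking.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm

from .data_io import (
    ROLE_LNCRNA,
    ROLE_MRNA,
    ExpressionMatrix,
    InteractionList,
    StageAssignment,
)
from .stagenet import StageNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults emulate the shape of a five-stage developing-neocortex
    study: 276 cells split 26/26/123/24/77 across stages, a small lncRNA
    panel against a larger mRNA background, 20 planted interactions
    hidden in a ten-fold larger prior list, strong latent correlation
    and moderate dropout.
    """

    n_stages: int = 5
    cells_per_stage: tuple[int, ...] = (26, 26, 123, 24, 77)
    n_lnc: int = 30
    n_mrna: int = 200
    n_true_edges: int = 20
    rho_sim: float = 0.9
    dropout_rate: float = 0.3
    decoy_prior_multiplier: int = 10
    nb_mean: float = 8.0
    nb_dispersion: float = 0.4
    stages_on: tuple[frozenset[str], ...] | None = None  # None = all stages
    seed: int = 0

    def __post_init__(self) -> None:
        cps = tuple(int(c) for c in self.cells_per_stage)
        object.__setattr__(self, "cells_per_stage", cps)
        if len(cps) != self.n_stages:
            raise ValueError(
                f"cells_per_stage has {len(cps)} entries for {self.n_stages} stages"
            )
        if min(self.n_stages, self.n_lnc, self.n_mrna, self.n_true_edges) < 1:
            raise ValueError("all counts must be >= 1")
        if any(c < 1 for c in cps):
            raise ValueError("every stage needs at least one cell")
        if not (0.0 <= self.rho_sim < 1.0):
            raise ValueError("rho_sim must be in [0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_true_edges > self.n_mrna:
            raise ValueError(
                "planted edges need distinct mRNA targets: "
                f"{self.n_true_edges} > {self.n_mrna}"
            )
        n_decoy = self.decoy_prior_multiplier * self.n_true_edges
        if self.n_true_edges + n_decoy > self.n_lnc * self.n_mrna:
            raise ValueError("prior list larger than the bipartite pair universe")
        if self.stages_on is not None:
            so = tuple(frozenset(s) for s in self.stages_on)
            object.__setattr__(self, "stages_on", so)
            if len(so) != self.n_true_edges:
                raise ValueError("stages_on must give one stage set per true edge")
            valid = set(self.stage_labels)
            for s in so:
                if not s:
                    raise ValueError("each true edge must be active in >= 1 stage")
                if not s <= valid:
                    raise ValueError(f"unknown stage labels in {sorted(s)}")

    @property
    def stage_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_stages)]

    @property
    def n_cells(self) -> int:
        return sum(self.cells_per_stage)


@dataclass(frozen=True)
class GroundTruth:
    """Planted edges (with the stages they are active in) and decoy priors."""

    true_edges: tuple[tuple[str, str], ...]
    stages_on: Mapping[tuple[str, str], frozenset[str]]
    decoy_edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if set(self.true_edges) & set(self.decoy_edges):
            raise ValueError("true and decoy edges overlap")

    def active_in(self, stage: str) -> set[tuple[str, str]]:
        return {e for e in self.true_edges if stage in self.stages_on[e]}


@dataclass
class SimulatedDataset:
    """Bundle of everything the pipeline needs, plus the ground truth."""

    expression: ExpressionMatrix  # raw counts, roles attached
    annotation: dict[str, str]
    stages: StageAssignment
    priors: InteractionList
    truth: GroundTruth
    config: SimulationConfig


def _nb_params(mean: float, dispersion: float) -> tuple[float, float]:
    # var = mean + dispersion * mean^2; scipy's (n, p) parametrisation
    n = 1.0 / dispersion
    return n, n / (n + mean)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic dataset under *cfg* (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    lnc_names = [f"LNC{i:04d}" for i in range(cfg.n_lnc)]
    mrna_names = [f"MR{i:05d}" for i in range(cfg.n_mrna)]
    genes = lnc_names + mrna_names
    annotation = {g: ROLE_LNCRNA for g in lnc_names}
    annotation.update({g: ROLE_MRNA for g in mrna_names})

    # planted edges: lncRNAs may repeat, mRNA targets are distinct so each
    # target's latent draw is tied to exactly one regulator
    true_lnc = rng.choice(cfg.n_lnc, size=cfg.n_true_edges, replace=True)
    true_mrna = rng.choice(cfg.n_mrna, size=cfg.n_true_edges, replace=False)
    true_edges = tuple(
        (lnc_names[i], mrna_names[j]) for i, j in zip(true_lnc, true_mrna)
    )
    if cfg.stages_on is None:
        stages_on = {e: frozenset(cfg.stage_labels) for e in true_edges}
    else:
        stages_on = dict(zip(true_edges, cfg.stages_on))

    # decoys: uniform distinct pairs outside the true set
    n_decoy = cfg.decoy_prior_multiplier * cfg.n_true_edges
    true_flat = {i * cfg.n_mrna + j for i, j in zip(true_lnc, true_mrna)}
    candidates = np.setdiff1d(
        np.arange(cfg.n_lnc * cfg.n_mrna), np.fromiter(true_flat, dtype=int)
    )
    decoy_flat = rng.choice(candidates, size=n_decoy, replace=False)
    decoy_edges = tuple(
        (lnc_names[idx // cfg.n_mrna], mrna_names[idx % cfg.n_mrna])
        for idx in decoy_flat
    )
    prior_pairs = list(true_edges) + list(decoy_edges)
    rng.shuffle(prior_pairs)  # planted edges are not positionally marked

    # stage assignment
    cell_ids, stage_map = [], {}
    for stage, n_c in zip(cfg.stage_labels, cfg.cells_per_stage):
        for i in range(n_c):
            cid = f"{stage}_c{i + 1:03d}"
            cell_ids.append(cid)
            stage_map[cid] = stage

    # latent Gaussian layer: independent everywhere, then tie each planted
    # target to its regulator in the stages where the edge is active
    m = cfg.n_cells
    Z = rng.standard_normal((len(genes), m))
    gene_index = {g: i for i, g in enumerate(genes)}
    stage_cols: dict[str, np.ndarray] = {}
    start = 0
    for stage, n_c in zip(cfg.stage_labels, cfg.cells_per_stage):
        stage_cols[stage] = np.arange(start, start + n_c)
        start += n_c
    rho = cfg.rho_sim
    for (u, v) in true_edges:
        iu, iv = gene_index[u], gene_index[v]
        for stage in sorted(stages_on[(u, v)]):
            cols = stage_cols[stage]
            eps = rng.standard_normal(cols.size)
            Z[iv, cols] = rho * Z[iu, cols] + np.sqrt(1.0 - rho * rho) * eps

    n_nb, p_nb = _nb_params(cfg.nb_mean, cfg.nb_dispersion)
    counts = nbinom.ppf(norm.cdf(Z), n_nb, p_nb)
    if cfg.dropout_rate > 0:
        counts[rng.random(counts.shape) < cfg.dropout_rate] = 0.0

    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=cell_ids), dict(annotation)
    )
    return SimulatedDataset(
        expression=expr,
        annotation=annotation,
        stages=StageAssignment(stage_map),
        priors=InteractionList(tuple(prior_pairs), tag="prior"),
        truth=GroundTruth(
            true_edges=true_edges,
            stages_on=stages_on,
            decoy_edges=decoy_edges,
        ),
        config=cfg,
    )


def evaluate_recovery(
    stage_networks: Sequence[StageNetwork], truth: GroundTruth
) -> pd.DataFrame:
    """Per-stage precision/recall of planted edges and decoy hit rate.

    recall = recovered planted edges / planted edges active in the
    stage; precision = recovered planted edges / all inferred edges
    (NaN with a warning when the network is empty); decoy_fpr = fraction
    of decoy priors appearing as edges.
    """
    rows = []
    for net in stage_networks:
        inferred = net.edge_set
        active = truth.active_in(net.stage)
        tp = len(inferred & active)
        if inferred:
            precision = tp / len(inferred)
        else:
            logger.warning("stage %r network is empty; precision undefined", net.stage)
            precision = float("nan")
        recall = tp / len(active) if active else float("nan")
        decoy_hits = len(inferred & set(truth.decoy_edges))
        rows.append(
            {
                "stage": net.stage,
                "n_inferred": len(inferred),
                "n_active_true": len(active),
                "tp": tp,
                "precision": precision,
                "recall": recall,
                "decoy_fpr": decoy_hits / len(truth.decoy_edges)
                if truth.decoy_edges
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
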