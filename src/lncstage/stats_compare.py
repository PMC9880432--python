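"""Distribution comparisons and the method-comparison harness.

Covers the biomarker case study (per-stage distributions of predicted
target counts or annotated-target fractions over a fixed lncRNA
biomarker panel, compared between stages with two-sample
Kolmogorov-Smirnov tests) and the benchmarking harness (random edge
baseline, per-stage validated fractions, paired t-test between methods).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import InteractionList
from .enrich import validated_fraction
from .stagenet import StageNetwork

logger = logging.getLogger(__name__)


@dataclass
class TargetDistribution:
    """Per-biomarker values (target counts or annotated fractions) in one stage."""

    stage: str
    values: pd.Series  # index: biomarker lncRNA symbols
    kind: str = "count"  # "count" or "fraction"


def biomarker_distributions(
    stage_networks: Sequence[StageNetwork],
    biomarkers: Sequence[str],
    gene_set: Iterable[str] | None = None,
) -> list[TargetDistribution]:
    """Predicted-target distributions of a biomarker panel per stage.

    Without *gene_set*, values are target counts.  With it, values are
    the fraction of each biomarker's targets inside the set; biomarkers
    with no targets contribute 0 (logged), so every stage yields one
    value per biomarker.
    """
    if not biomarkers:
        raise ValueError("empty biomarker list")
    annotated = set(gene_set) if gene_set is not None else None
    out = []
    for net in stage_networks:
        vals = {}
        for b in biomarkers:
            targets = net.targets_of(b)
            if annotated is None:
                vals[b] = float(len(targets))
            elif targets:
                vals[b] = len(targets & annotated) / len(targets)
            else:
                logger.info(
                    "biomarker %r has no targets in stage %r; fraction set to 0",
                    b,
                    net.stage,
                )
                vals[b] = 0.0
        out.append(
            TargetDistribution(
                stage=net.stage,
                values=pd.Series(vals, index=list(biomarkers), dtype=float),
                kind="count" if annotated is None else "fraction",
            )
        )
    return out


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], mode: str = "asymp"
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the
    p-value uses the asymptotic two-sided distribution by default
    (*mode* ``"exact"`` enumerates the exact null distribution, sensible
    for small samples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two nonempty samples")
    if mode not in ("asymp", "exact", "auto"):
        raise ValueError(f"mode must be 'asymp', 'exact' or 'auto', got {mode!r}")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=mode)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def significance_stars(p: float) -> str:
    """Star convention: *** <0.001, ** <0.01, * <0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ks_matrix(
    distributions: Sequence[TargetDistribution], mode: str = "asymp"
) -> pd.DataFrame:
    """Symmetric stage x stage matrix of KS p-values (diagonal 1)."""
    labels = [d.stage for d in distributions]
    S = len(distributions)
    mat = np.ones((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            _, p = ks_two_sample(
                distributions[i].values.to_numpy(),
                distributions[j].values.to_numpy(),
                mode=mode,
            )
            mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=labels, columns=labels)


def random_baseline(
    lncrnas: Sequence[str],
    mrnas: Sequence[str],
    n_edges: int,
    seed: int | np.random.Generator = 0,
) -> InteractionList:
    """Uniformly sampled distinct lncRNA -> mRNA pairs (random method).

    Reproducible under *seed*; raises if more distinct pairs are
    requested than the bipartite product allows.
    """
    lncrnas = list(lncrnas)
    mrnas = list(mrnas)
    total = len(lncrnas) * len(mrnas)
    if n_edges < 1 or n_edges > total:
        raise ValueError(
            f"cannot draw {n_edges} distinct pairs from {total} possible"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flat = rng.choice(total, size=n_edges, replace=False)
    pairs = tuple(
        (lncrnas[idx // len(mrnas)], mrnas[idx % len(mrnas)]) for idx in flat
    )
    return InteractionList(pairs, tag="random")


def paired_ttest(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Classic paired t-test on x - y (df = n - 1, two-sided p).

    Raises on length mismatch, fewer than two pairs, or all-zero
    differences (zero variance makes t undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0.0):
        raise ValueError("differences have zero variance; t is undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def per_stage_validated_fractions(
    per_stage_edges: Mapping[str, Iterable[tuple[str, str]]],
    validated: InteractionList | Iterable[tuple[str, str]],
) -> pd.Series:
    """Validated fraction of each stage's predicted edge set."""
    return pd.Series(
        {
            stage: validated_fraction(list(edges), validated)
            for stage, edges in per_stage_edges.items()
        },
        dtype=float,
    )


def compare_methods(
    fractions: pd.DataFrame, reference: str | None = None
) -> pd.DataFrame:
    """Paired t-tests of a reference method against every other method.

    *fractions* is a stages x methods table of validated fractions (the
    pairing is over stages).  Returns one row per non-reference method
    with columns method, t, p.
    """
    if fractions.shape[1] < 2:
        raise ValueError("need at least two methods to compare")
    if reference is None:
        reference = fractions.columns[0]
    if reference not in fractions.columns:
        raise ValueError(f"unknown reference method {reference!r}")
    rows = []
    for method in fractions.columns:
        if method == reference:
            continue
        t, p = paired_ttest(
            fractions[reference].to_numpy(), fractions[method].to_numpy()
        )
        rows.append({"method": method, "t": t, "p": p})
    return pd.DataFrame(rows, columns=["method", "t", "p"])
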