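"""End-to-end pipeline: preprocess -> per-cell nets -> stage nets -> analyses.

Every run writes a deterministic set of TSV outputs plus ``manifest.json``
recording input checksums, parameter values, package version and seed, so
a run can be reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cellnet import CellNetworkInference, write_cell_edges
from .data_io import (
    load_annotation,
    load_expression,
    load_gene_list,
    load_gene_sets,
    load_interactions,
    load_stages,
    preprocess,
    write_edges,
)
from .enrich import network_gene_enrichment, bh_adjust, validated_fraction
from .stagenet import (
    StageNetworkAggregator,
    classification_summary,
    classify_edges,
    classify_hubs,
    hub_table,
    similarity_matrix,
)
from .stats_compare import (
    biomarker_distributions,
    compare_methods,
    ks_matrix,
    random_baseline,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run.

    Parameter defaults: neighborhood fraction 0.1, per-test alpha 0.05,
    hub fraction 0.2, Jaccard similarity, pure-union stage aggregation
    (min_support 1).
    """

    expression: str
    annotation: str
    priors: str
    stages: str
    out_dir: str
    validated: str | None = None
    gene_sets: str | None = None
    biomarkers: str | None = None
    box_fraction: float = 0.1
    alpha: float = 0.05
    hub_fraction: float = 0.2
    similarity: str = "jaccard"
    min_support: int = 1
    tail: str = "upper"
    seed: int = 0
    write_cell_networks: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a key=value config file; keyword overrides win."""
        values: dict[str, object] = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ValueError(f"{path}: expected key=value, got {ln!r}")
            key, val = (part.strip() for part in ln.split("=", 1))
            values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls._coerce(values)

    @classmethod
    def _coerce(cls, values: dict) -> "RunConfig":
        casts = {
            "box_fraction": float,
            "alpha": float,
            "hub_fraction": float,
            "min_support": int,
            "seed": int,
            "write_cell_networks": lambda v: str(v).lower() in ("1", "true", "yes"),
        }
        out = {}
        for key, val in values.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            out[key] = casts[key](val) if key in casts and isinstance(val, str) else val
        return cls(**out)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline and return the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = _stage("data_io")(_load_and_preprocess)(cfg)
    cell_nets = _stage("cellnet")(_infer_cell_networks)(cfg, expr)
    stage_nets = _stage("stagenet")(_aggregate_and_analyse)(cfg, cell_nets, out)
    if cfg.write_cell_networks:
        write_cell_edges(cell_nets, out / "cell_edges.tsv")
    _stage("enrich")(_enrichment_outputs)(cfg, expr, stage_nets, out)
    _stage("stats_compare")(_comparison_outputs)(cfg, expr, stage_nets, out)
    _write_manifest(cfg, out)
    return out


def _load_and_preprocess(cfg: RunConfig):
    raw = load_expression(cfg.expression)
    return preprocess(raw, load_annotation(cfg.annotation))


def _infer_cell_networks(cfg: RunConfig, expr):
    priors = load_interactions(cfg.priors, tag="prior")
    est = CellNetworkInference(
        box_fraction=cfg.box_fraction, alpha=cfg.alpha, tail=cfg.tail
    ).fit(expr, priors)
    return est.cell_networks_


def _aggregate_and_analyse(cfg: RunConfig, cell_nets, out: Path):
    stages = load_stages(cfg.stages)
    stages.validate_against([n.cell_id for n in cell_nets])
    agg = StageNetworkAggregator(min_support=cfg.min_support).fit(cell_nets, stages)
    nets = agg.stage_networks_
    write_edges(nets, out / "stage_edges.tsv")
    hub_table(nets, cfg.hub_fraction).to_csv(
        out / "hubs.tsv", sep="\t", index=False
    )
    edge_cls = classify_edges(nets)
    edge_cls.to_csv(out / "edge_classification.tsv", sep="\t", index=False)
    classify_hubs(nets, cfg.hub_fraction).to_csv(
        out / "hub_classification.tsv", sep="\t", index=False
    )
    pd.Series(classification_summary(edge_cls)).to_csv(
        out / "edge_classification_summary.tsv",
        sep="\t",
        header=False,
        float_format=_FLOAT_FMT,
    )
    for what in ("edges", "hubs"):
        similarity_matrix(
            nets, what=what, method=cfg.similarity, hub_fraction=cfg.hub_fraction
        ).to_csv(
            out / f"similarity_{what}.tsv", sep="\t", float_format=_FLOAT_FMT
        )
    return nets


def _enrichment_outputs(cfg: RunConfig, expr, stage_nets, out: Path):
    if cfg.gene_sets is None:
        return
    collections = load_gene_sets(cfg.gene_sets)
    universe = set(expr.genes)
    rows = []
    for net in stage_nets:
        for name, genes in collections.items():
            res = network_gene_enrichment(net, genes, universe)
            rows.append(
                {
                    "stage": net.stage,
                    "set": name,
                    "N": res.input.N,
                    "S": res.input.S,
                    "M": res.input.M,
                    "r": res.input.r,
                    "p_raw": res.p_raw,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"])
    table["significant"] = table["p_adj"] < 0.05
    table.to_csv(
        out / "enrichment.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )


def _comparison_outputs(cfg: RunConfig, expr, stage_nets, out: Path):
    if cfg.biomarkers is not None:
        biomarkers = load_gene_list(cfg.biomarkers)
        dists = biomarker_distributions(stage_nets, biomarkers)
        ks_matrix(dists).to_csv(
            out / "biomarker_ks_pvalues.tsv", sep="\t", float_format=_FLOAT_FMT
        )
        pd.DataFrame(
            {d.stage: d.values for d in dists}
        ).to_csv(
            out / "biomarker_target_counts.tsv",
            sep="\t",
            index_label="lncRNA",
            float_format=_FLOAT_FMT,
        )
    if cfg.validated is None:
        return
    validated = load_interactions(cfg.validated, tag="validated")
    rows = []
    fracs = {}
    for i, net in enumerate(stage_nets):
        edges = net.edge_set
        if not edges:
            logger.warning("stage %r empty; skipped in comparison", net.stage)
            continue
        rand = random_baseline(
            expr.lncrnas, expr.mrnas, n_edges=len(edges), seed=cfg.seed + i
        )
        fracs[net.stage] = {
            "inferred": validated_fraction(edges, validated),
            "random": validated_fraction(rand, validated),
        }
    frac_df = pd.DataFrame(fracs).T
    frac_df.index.name = "stage"
    frac_df.to_csv(
        out / "validated_fractions.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    if len(frac_df) >= 2:
        try:
            compare_methods(frac_df, reference="inferred").to_csv(
                out / "method_comparison.tsv",
                sep="\t",
                index=False,
                float_format=_FLOAT_FMT,
            )
        except ValueError as exc:  # degenerate differences
            logger.warning("paired t-test skipped: %s", exc)


def _write_manifest(cfg: RunConfig, out: Path) -> None:
    inputs = {}
    for key in ("expression", "annotation", "priors", "stages", "validated",
                "gene_sets", "biomarkers"):
        path = getattr(cfg, key)
        if path is not None:
            inputs[key] = {"path": str(path), "sha256": _sha256(path)}
    manifest = {
        "package": "lncstage",
        "version": __version__,
        "inputs": inputs,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k
            not in (
                "expression",
                "annotation",
                "priors",
                "stages",
                "validated",
                "gene_sets",
                "biomarkers",
                "out_dir",
            )
        },
        "outputs": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
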