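"""Config-driven pipeline runner.

A pipeline is a YAML document::

    seed: 0
    stages:
      - stage: simulate
        mode: csr
        n_cells_per_type: {A: 100, B: 100}
      - stage: clq
        radius_um: 30

Stages execute in order against a shared cell table; each appends its
results (obs columns, uns entries).  Stage dependencies are checked before
execution — e.g. the CLQ stage refuses to run without cell-type labels —
and unknown stage names or parameters are rejected outright.  A manifest
(stage, parameters, seed, duration) is written next to the result table;
identical config and seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from anndata import AnnData

from . import niche_expression, single_cell, spatial_stats, synthetic_data
from .io_core import read_cell_table, write_cell_table
from .types import ValidationError

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError("pipeline config must be a mapping")
    unknown = set(config) - {"seed", "stages", "input"}
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ValidationError("config must list 'stages'")
    return config


def _require(table: AnnData, column: str, stage: str, needed_by: str) -> None:
    if table is None:
        raise ValidationError(
            f"stage {stage!r} needs a cell table; run 'simulate' or provide 'input'"
        )
    if column and column not in table.obs:
        raise ValidationError(
            f"stage {stage!r} requires obs[{column!r}] — run {needed_by!r} first"
        )


_STAGE_PARAMS = {
    "simulate": {"mode", "n_cells_per_type", "field_size_um",
                 "interaction_radius_um", "strength"},
    "simulate_expression": {"n_cells", "n_genes", "cluster_means", "de_spec",
                            "dispersion"},
    "qc": {"min_total"},
    "normalize": set(),
    "cluster": {"method", "resolution", "knn_k", "transform",
                "arcsinh_cofactor", "scaling", "max_components"},
    "clq": {"radius_um", "kernel", "sigma_um", "n_perm", "alpha", "pairs"},
    "cooccur": {"radius_um", "n_perm"},
    "niche": {"radius_um", "method", "resolution", "type_column"},
    "pathway": {"weights_csv", "aggregate_by"},
}


def run_pipeline(config_path, out_dir, seed: int | None = None) -> Path:
    """Execute a YAML pipeline; write ``table.h5ad`` and ``manifest.json``.

    ``seed`` overrides the config's seed.  Returns the output directory.
    """
    config = load_config(config_path)
    if seed is None:
        seed = int(config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table: AnnData | None = None
    if "input" in config:
        table = read_cell_table(config["input"])

    manifest: list[dict] = []
    for entry in config["stages"]:
        entry = dict(entry)
        stage = entry.pop("stage", None)
        if stage not in _STAGE_PARAMS:
            raise ValidationError(
                f"unknown stage {stage!r}; known stages: {sorted(_STAGE_PARAMS)}"
            )
        unknown = set(entry) - _STAGE_PARAMS[stage]
        if unknown:
            raise ValidationError(
                f"stage {stage!r}: unknown parameters {sorted(unknown)}"
            )
        t0 = time.perf_counter()
        table = _run_stage(stage, entry, table, seed)
        manifest.append(
            {
                "stage": stage,
                "params": {k: _jsonable(v) for k, v in entry.items()},
                "seed": seed,
                "duration_s": round(time.perf_counter() - t0, 4),
            }
        )
        logger.info("stage %s done in %.2fs", stage, manifest[-1]["duration_s"])

    if table is not None:
        write_cell_table(table, out_dir / "table.h5ad")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def _run_stage(stage: str, params: dict, table: AnnData | None, seed: int) -> AnnData:
    if stage == "simulate":
        spec = synthetic_data.PatternSpec(seed=seed, **params)
        return synthetic_data.gen_labeled_pattern(spec)
    if stage == "simulate_expression":
        return synthetic_data.gen_expression(seed=seed, **params)
    if stage == "qc":
        _require(table, "", stage, "")
        return single_cell.qc_filter_umi(table, **params)
    if stage == "normalize":
        _require(table, "", stage, "")
        return single_cell.normalize_log(table)
    if stage == "cluster":
        _require(table, "", stage, "")
        max_components = params.pop("max_components", 50)
        method = params.pop("method", "leiden")
        cp = single_cell.ClusteringParams(seed=seed, **params)
        work = single_cell.transform_scale(table, cp) if cp.transform != "none" else table
        if work.n_vars >= 3:
            work = single_cell.pca_select(work, max_components=max_components)
        return single_cell.graph_cluster(work, cp, method=method)
    if stage == "clq":
        _require(table, "cell_type", stage, "cluster/annotate")
        radius = params.pop("radius_um", 20.0)
        kernel = params.pop("kernel", "uniform")
        sigma = params.pop("sigma_um", None)
        graph = spatial_stats.build_neighbor_graph(table, radius, kernel, sigma)
        pairs = params.pop("pairs", None)
        if pairs is not None:
            pairs = [tuple(p) for p in pairs]
        res = spatial_stats.clq_significance(graph, table, pairs=pairs, seed=seed, **params)
        out = table.copy()
        out.uns["global_clq"] = res.global_clq.to_dict()
        out.uns["clq_calls"] = res.to_tidy().to_dict(orient="list")
        for (a, b), vals in res.local_clq.items():
            out.obs[f"lclq_{a}_{b}"] = vals
        return out
    if stage == "cooccur":
        _require(table, "cell_type", stage, "cluster/annotate")
        df = spatial_stats.cooccurrence_permutation(table, seed=seed, **params)
        out = table.copy()
        out.uns["cooccurrence"] = df.to_dict(orient="list")
        return out
    if stage == "niche":
        type_column = params.pop("type_column", "cell_type")
        _require(table, type_column, stage, "cluster/annotate")
        radius = params.pop("radius_um", 30.0)
        comp = niche_expression.neighborhood_composition(
            table, radius, type_column=type_column
        )
        res = niche_expression.detect_niches(comp, seed=seed, **params)
        out = table.copy()
        out.obs["niche"] = res.niche.astype(str)
        out.uns["niche_profiles"] = res.niche_profiles.rename(index=str)
        return out
    if stage == "pathway":
        _require(table, "", stage, "")
        from .types import PathwayModel

        model = PathwayModel.from_csv(params.pop("weights_csv"))
        scores = niche_expression.pathway_scores(table, model, **params)
        out = table.copy()
        if scores.index.equals(out.obs_names.to_frame().index):
            out.obsm["pathway_scores"] = scores.to_numpy()
        out.uns["pathway_scores"] = scores.to_dict()
        return out
    raise ValidationError(f"unhandled stage {stage!r}")  # pragma: no cover
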