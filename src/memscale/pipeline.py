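"""End-to-end multi-scale analysis pipeline.

For each species emphasis (abundant -> Hellinger, rare -> chi-square) the
pipeline transforms the community table, ordinates it (PCA), approximates
it with forward-selected environmental variables (RDA) and examines the
leftover structure (PRA); each ordination's first two axes are decomposed
across MEM spatial scales with the smoothed-scalogram R^2max permutation
test. Selected MEMs are split by Moran's-I sign into broad-medium and
fine sets and fed, with the selected environment, into variation
partitioning; a second partition splits the environment itself into
temperature, land-use and distance groups. One master seed derives every
stage seed, so identical configurations reproduce bit-identical bundles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import build_gabriel_graph
from .inference import forward_select, variation_partition
from .io import SiteTable
from .mem import mem_basis, split_by_sign
from .ordination import ExplanatoryMatrix, pca, pra, rda, rda_permutation_test
from .scalogram import r2max_test
from .transform import TRANSFORMS

logger = logging.getLogger("memscale")

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "write_results"]


def _default_emphases():
    return {"abundant": "hellinger", "rare": "chisq"}


@dataclass
class PipelineConfig:
    """Run-level knobs; the defaults mirror the analysis the package targets."""

    seed: int = 0
    nperm: int = 999
    n_groups: int = 8
    alpha: float = 0.05
    n_axes: int = 2
    emphases: dict = field(default_factory=_default_emphases)
    mem_selection_on: str = "raw"   # "raw" table or "detrended" (environment removed)
    env_groups: dict = None         # name -> column list; None: infer from names

    def __post_init__(self):
        if self.nperm < 99:
            raise ValueError("nperm must be >= 99")
        if self.mem_selection_on not in ("raw", "detrended"):
            raise ValueError("mem_selection_on must be 'raw' or 'detrended'")


def infer_env_groups(columns) -> dict:
    """Split environmental columns into temperature / distance / land-use
    groups by naming convention (monthly temps end in 'T', distance starts
    with 'dist')."""
    groups = {"temperature": [], "distance": [], "landuse": []}
    for c in columns:
        if c.endswith("T"):
            groups["temperature"].append(c)
        elif c.startswith("dist"):
            groups["distance"].append(c)
        else:
            groups["landuse"].append(c)
    return {k: v for k, v in groups.items() if v}


@dataclass
class ResultBundle:
    """Nested, JSON-serializable record of one pipeline run."""

    metadata: dict
    emphases: dict

    def to_dict(self) -> dict:
        return {"metadata": self.metadata, "emphases": self.emphases}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _scalogram_dict(sc) -> dict:
    return {
        "smoothed_r2": [float(v) for v in sc.smoothed],
        "r2max": float(sc.r2max),
        "argmax_component": int(sc.argmax_component),
        "p_value": float(sc.p_value),
        "null_upper95": [float(v) for v in sc.null_upper95],
        "nperm": int(sc.nperm),
    }


def _ordination_dict(res) -> dict:
    d = {
        "eigenvalues": [float(v) for v in res.eigenvalues[:10]],
        "proportion": [float(v) for v in res.proportion[:10]],
        "total_inertia": float(res.total_inertia),
    }
    if res.r2 is not None:
        d["r2"] = float(res.r2)
        d["adj_r2"] = float(res.adj_r2)
        d["proportion_constrained"] = [float(v) for v in res.proportion_constrained[:10]]
    return d


def _selection_dict(sel) -> dict:
    return {
        "selected": list(sel.selected),
        "stopping_reason": sel.stopping_reason,
        "global_r2": float(sel.global_r2),
        "global_adj_r2": float(sel.global_adj_r2),
        "table": sel.table.to_dict(orient="records"),
    }


def _partition_dict(part) -> dict:
    return {
        "set_names": list(part.set_names),
        "fractions": {k: float(v) for k, v in part.fractions.items()},
        "residual": float(part.residual),
        "pvalues": {k: float(v) for k, v in part.pvalues.items()},
        "union_adj_r2": {k: float(v) for k, v in part.union_adj_r2.items()},
    }


def _axis_scalograms(result, basis, config, seeds, label, out):
    n_axes = min(config.n_axes, result.site_scores.shape[1])
    for axis in range(n_axes):
        t0 = time.perf_counter()
        sc = r2max_test(result.site_scores[:, axis], basis,
                        n_groups=config.n_groups, nperm=config.nperm,
                        seed=int(next(seeds)))
        out[f"{label}_axis{axis + 1}"] = _scalogram_dict(sc)
        logger.debug("scalogram %s axis %d: %.3fs", label, axis + 1, time.perf_counter() - t0)


def run_pipeline(site_table: SiteTable, config: PipelineConfig = None) -> ResultBundle:
    """Run the full multi-scale analysis on one site table."""
    config = config if config is not None else PipelineConfig()
    t_start = time.perf_counter()
    n = site_table.n
    logger.info("pipeline start: %d sites, %d env vars, %d species",
                n, site_table.env.shape[1], site_table.counts.shape[1])

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4096))

    W = build_gabriel_graph(site_table.coords)
    basis = mem_basis(W)  # raises if disconnected
    logger.info("Gabriel graph: %d edges; MEM basis: %d eigenvectors", len(W.edges), basis.k)
    mem_frame = pd.DataFrame(basis.vectors, columns=[f"MEM{k + 1}" for k in range(basis.k)])

    env_X = site_table.explanatory()
    env_groups = config.env_groups or infer_env_groups(site_table.env.columns)

    emphases_out = {}
    for emphasis, transform_name in config.emphases.items():
        t0 = time.perf_counter()
        out = {"transform": transform_name}
        Yt = TRANSFORMS[transform_name](site_table.community())

        pca_res = pca(Yt)
        out["pca"] = _ordination_dict(pca_res)
        scal = {}
        _axis_scalograms(pca_res, basis, config, stage_seeds, "pca", scal)

        sel_env = forward_select(Yt, site_table.env, alpha=config.alpha,
                                 nperm=config.nperm, seed=int(next(stage_seeds)))
        out["env_selection"] = _selection_dict(sel_env)

        if sel_env.selected:
            X_sel = site_table.explanatory(sel_env.selected)
            rda_res = rda(Yt, X_sel)
            out["rda"] = _ordination_dict(rda_res)
            out["rda"]["p_value"] = rda_permutation_test(
                Yt, X_sel, nperm=config.nperm, seed=int(next(stage_seeds)))
            _axis_scalograms(rda_res, basis, config, stage_seeds, "rda", scal)
            pra_res = pra(Yt, X_sel)
            out["pra"] = _ordination_dict(pra_res)
            if pra_res.site_scores.shape[1]:
                _axis_scalograms(pra_res, basis, config, stage_seeds, "pra", scal)
        else:
            logger.warning("emphasis %s: no environmental variable selected; skipping RDA/PRA", emphasis)
        out["scalograms"] = scal

        mem_target = Yt
        if config.mem_selection_on == "detrended" and sel_env.selected:
            from .ordination import partial_residuals
            mem_target = partial_residuals(Yt, site_table.explanatory(sel_env.selected))
        sel_mem = forward_select(mem_target, mem_frame, alpha=config.alpha,
                                 nperm=config.nperm, seed=int(next(stage_seeds)))
        out["mem_selection"] = _selection_dict(sel_mem)

        sel_idx = [int(v[3:]) - 1 for v in sel_mem.selected]
        broad_all, fine_all = split_by_sign(basis)
        broad = [i for i in sel_idx if i in set(broad_all)]
        fine = [i for i in sel_idx if i in set(fine_all)]
        out["mem_split"] = {"broad_medium": [f"MEM{i + 1}" for i in broad],
                            "fine": [f"MEM{i + 1}" for i in fine]}

        subsets = {}
        if sel_env.selected:
            subsets["environment"] = site_table.env[list(sel_env.selected)]
        if broad:
            subsets["space_broad"] = mem_frame.iloc[:, broad]
        if fine:
            subsets["space_fine"] = mem_frame.iloc[:, fine]
        if len(subsets) >= 2:
            part = variation_partition(Yt, subsets, nperm=config.nperm,
                                       seed=int(next(stage_seeds)))
            out["partition_env_space"] = _partition_dict(part)
        else:
            logger.warning("emphasis %s: <2 nonempty subsets, skipping env-vs-space partition", emphasis)

        env_sub = {g: [c for c in cols if c in sel_env.selected]
                   for g, cols in env_groups.items()}
        env_sub = {g: cols for g, cols in env_sub.items() if cols}
        if 2 <= len(env_sub) <= 3:
            part_env = variation_partition(
                Yt, {g: site_table.env[cols] for g, cols in env_sub.items()},
                nperm=config.nperm, seed=int(next(stage_seeds)))
            out["partition_within_env"] = _partition_dict(part_env)

        emphases_out[emphasis] = out
        logger.info("emphasis %s done in %.2fs", emphasis, time.perf_counter() - t0)

    metadata = {
        "seed": config.seed,
        "nperm": config.nperm,
        "n_groups": config.n_groups,
        "alpha": config.alpha,
        "n_sites": n,
        "n_mems": basis.k,
        "n_edges": len(W.edges),
        "mem_selection_on": config.mem_selection_on,
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }
    return ResultBundle(metadata=metadata, emphases=emphases_out)


def write_results(bundle: ResultBundle, out_dir) -> list:
    """Serialize a bundle: per-emphasis CSV tables plus one JSON summary.

    Returns the manifest of written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []

    def _write_csv(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False)
        manifest.append(path)

    for emphasis, res in bundle.emphases.items():
        for key in ("env_selection", "mem_selection"):
            rows = res.get(key, {}).get("table", [])
            df = pd.DataFrame(rows, columns=["variable", "order", "R2", "R2Cum", "AdjR2Cum", "F", "pval"])
            _write_csv(df, f"{emphasis}_{key}.csv")
        scal_rows = []
        for label, sc in res.get("scalograms", {}).items():
            for comp, (r2v, lim) in enumerate(zip(sc["smoothed_r2"], sc["null_upper95"]), start=1):
                scal_rows.append({"scalogram": label, "component": comp,
                                  "R2": r2v, "null_upper95": lim})
        _write_csv(pd.DataFrame(scal_rows), f"{emphasis}_scalograms.csv")

    summary = out_dir / "summary.json"
    summary.write_text(bundle.to_json())
    manifest.append(summary)
    log_path = out_dir / "run.log"
    meta = bundle.metadata
    log_path.write_text(
        f"seed={meta['seed']} nperm={meta['nperm']} n_sites={meta['n_sites']} "
        f"n_mems={meta['n_mems']} runtime_s={meta['runtime_s']}\n"
    )
    manifest.append(log_path)
    # the bundle must round-trip: read-back equals the in-memory dict
    assert json.loads(summary.read_text()) == bundle.to_dict()
    return manifest
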