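"""End-to-end orchestration: simulate/load -> U1 -> U2 -> D -> dynamics -> drivers.

Stages communicate only through written CSV artifacts plus one JSON run
manifest, so the pipeline is restartable stage by stage and usable from
other languages.  The manifest records the full configuration in effect
(CCD form, returns-to-scale, frontier mode, pooling, transform), the seed,
input checksums, per-stage output paths and warnings such as the number of
clipped U2 scores or infeasible super-efficiency LPs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .coupling import ccd_table, region_year_means
from .critic_index import score_panel
from .driver_regression import DEFAULT_TAUS, quantile_table
from .panel_io import (
    AdjacencyMatrix,
    PanelDataset,
    load_adjacency,
    load_panel,
    write_adjacency,
    write_panel,
)
from .regional_inequality import dagum_decompose, kde_curve, shape_descriptors
from .sbm_dea import efficiency_panel
from .spatial_markov import (
    classify_quartiles,
    morans_i,
    spatial_transition_matrices,
    transition_matrix,
)
from .synthetic_data import SyntheticTruth, generate_panel

__all__ = ["PipelineError", "default_config", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def default_config(seed: int = 0, out_dir: str = "out") -> dict:
    return {
        "seed": seed,
        "out_dir": out_dir,
        "simulate": {},  # SyntheticTruth overrides; remove to use "input"
        "critic": {"pooling": "pooled"},
        "dea": {"rts": "CRS", "frontier": "per_year"},
        "ccd": {"form": "sqrt_product", "alpha": 0.5, "clip_u2": True},
        "markov": {"lags": [1, 2, 3], "pooling": "pooled", "conditional": True},
        "moran": {"permutations": 999},
        "qreg": {"taus": list(DEFAULT_TAUS), "n_boot": 200, "transform": "log-z"},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str, path: Path | None = None) -> None:
    manifest["stages"][name] = {
        "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "output": str(path) if path else None,
    }


def run_all(config: Mapping[str, Any]) -> dict:
    """Run the full chain from one config dict; returns the run manifest."""
    cfg = dict(config)
    base = default_config()
    for key in ("critic", "dea", "ccd", "markov", "moran", "qreg"):
        cfg[key] = {**base[key], **dict(cfg.get(key) or {})}
    if "input" not in cfg:
        cfg.setdefault("simulate", {})
    cfg.setdefault("out_dir", "out")
    seed = int(cfg.get("seed", 0))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    # validation-first: a conditional Markov stage needs an adjacency source
    if cfg["markov"].get("conditional") and "simulate" not in cfg:
        if not (cfg.get("input") or {}).get("adjacency"):
            raise PipelineError(
                "config: markov.conditional=true requires an adjacency input"
            )

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "config": json.loads(json.dumps(cfg, default=str)),
        "stages": {},
        "inputs": {},
        "warnings": {},
    }

    # -- stage: data -------------------------------------------------------
    truth = None
    if "simulate" in cfg:
        truth = SyntheticTruth(seed=seed, **(cfg["simulate"] or {}))
        gen = generate_panel(truth)
        panel, adjacency = gen.panel, gen.adjacency
        write_panel(panel, out / "panel.csv")
        write_adjacency(adjacency, out / "adjacency.csv")
        truth.to_json(out / "truth.json")
        manifest["inputs"]["panel"] = _sha256(out / "panel.csv")
        manifest["inputs"]["adjacency"] = _sha256(out / "adjacency.csv")
        _stage(manifest, "simulate", out / "panel.csv")
    else:
        inp = cfg.get("input") or {}
        if "panel" not in inp:
            raise PipelineError("config: neither a simulate block nor input.panel")
        panel = load_panel(inp["panel"])
        manifest["inputs"]["panel"] = _sha256(Path(inp["panel"]))
        adjacency = None
        if inp.get("adjacency"):
            adjacency = load_adjacency(inp["adjacency"], panel.units)
            manifest["inputs"]["adjacency"] = _sha256(Path(inp["adjacency"]))
        _stage(manifest, "load")

    region_of = panel.region_of

    # -- stage: CRITIC weights and U1 -------------------------------------
    try:
        weights, u1 = score_panel(panel, pooling=cfg["critic"]["pooling"])
    except Exception as exc:
        raise PipelineError(f"weights: {exc}") from exc
    wdf = pd.DataFrame(
        {"S": weights.S, "R": weights.R, "C": weights.C, "W": weights.W}
    )
    wdf.rename_axis("indicator").to_csv(out / "weights.csv")
    u1.reset_index().to_csv(out / "u1_scores.csv", index=False)
    _stage(manifest, "weights", out / "weights.csv")

    # -- stage: DEA efficiency U2 ------------------------------------------
    try:
        eff = efficiency_panel(
            panel, frontier_mode=cfg["dea"]["frontier"], rts=cfg["dea"]["rts"]
        )
    except Exception as exc:
        raise PipelineError(f"dea: {exc}") from exc
    eff.to_csv(out / "u2_scores.csv", index=False)
    manifest["warnings"]["infeasible_super_sbm"] = int(
        (eff["status"] == "infeasible").sum()
    )
    _stage(manifest, "dea", out / "u2_scores.csv")

    # -- stage: coupling coordination --------------------------------------
    u2 = eff.set_index(["unit", "year"])["TE"]
    try:
        table = ccd_table(
            u1,
            u2,
            alpha=cfg["ccd"]["alpha"],
            beta=1.0 - cfg["ccd"]["alpha"],
            form=cfg["ccd"]["form"],
            clip_u2=cfg["ccd"]["clip_u2"],
        )
    except Exception as exc:
        raise PipelineError(f"ccd: {exc}") from exc
    table.to_csv(out / "ccd.csv", index=False)
    manifest["warnings"]["clipped_u2"] = int(table["u2_clipped"].sum())
    levels = pd.concat(
        {
            "U1": region_year_means(table, region_of, "U1"),
            "U2": region_year_means(table, region_of, "U2"),
            "D": region_year_means(table, region_of, "D"),
        },
        axis=1,
    )
    levels.to_csv(out / "region_year_levels.csv")
    _stage(manifest, "ccd", out / "ccd.csv")

    # -- stage: Dagum Gini + KDE -------------------------------------------
    D_wide = table.pivot(index="unit", columns="year", values="D")
    gini_rows = []
    kde_rows = []
    for year in panel.years:
        vals = D_wide[year].to_numpy()
        groups = [region_of[u] for u in D_wide.index]
        try:
            res = dagum_decompose(vals, groups)
        except Exception as exc:
            raise PipelineError(f"gini: year {year}: {exc}") from exc
        row = {
            "year": year,
            "G": res.G,
            "G_within": res.G_within,
            "G_between": res.G_between,
            "G_trans": res.G_trans,
            "contrib_within": res.contributions["within"],
            "contrib_between": res.contributions["between"],
            "contrib_trans": res.contributions["transvariation"],
        }
        row.update({f"G_{g}": v for g, v in res.group_ginis.items()})
        row.update({f"G_{a}_{b}": v for (a, b), v in res.pair_ginis.items()})
        gini_rows.append(row)
        for scope, sel in [("National", None)] + [
            (r, r) for r in sorted(set(groups))
        ]:
            vv = vals if sel is None else vals[np.array(groups) == sel]
            if len(vv) < 2 or np.ptp(vv) == 0:
                continue
            curve = kde_curve(vv)
            desc = shape_descriptors(curve)
            for x, f in zip(curve.grid, curve.density):
                kde_rows.append(
                    {"year": year, "scope": scope, "x": x, "density": f}
                )
            desc.update({"year": year, "scope": scope, "h": curve.h})
    pd.DataFrame(gini_rows).to_csv(out / "gini.csv", index=False)
    pd.DataFrame(kde_rows).to_csv(out / "kde.csv", index=False)
    _stage(manifest, "gini", out / "gini.csv")
    _stage(manifest, "kde", out / "kde.csv")

    # -- stage: Markov + Moran ---------------------------------------------
    try:
        states = classify_quartiles(D_wide, pooling=cfg["markov"]["pooling"])
    except Exception as exc:
        raise PipelineError(f"markov: {exc}") from exc
    markov_rows = []
    for lag in cfg["markov"]["lags"]:
        tm = transition_matrix(states, lag)
        for i, a in enumerate(tm.frame.index):
            markov_rows.append(
                {
                    "lag": lag,
                    "condition": "traditional",
                    "from_state": a,
                    **{b: tm.probs[i, j] for j, b in enumerate(tm.frame.columns)},
                    "n_i": int(tm.counts[i].sum()),
                }
            )
        if cfg["markov"].get("conditional") and adjacency is not None:
            cond = spatial_transition_matrices(states, D_wide, adjacency, lag)
            for lab, tmc in cond.items():
                for i, a in enumerate(tmc.frame.index):
                    markov_rows.append(
                        {
                            "lag": lag,
                            "condition": lab,
                            "from_state": a,
                            **{
                                b: tmc.probs[i, j]
                                for j, b in enumerate(tmc.frame.columns)
                            },
                            "n_i": int(tmc.counts[i].sum()),
                        }
                    )
    pd.DataFrame(markov_rows).to_csv(out / "markov.csv", index=False)
    _stage(manifest, "markov", out / "markov.csv")

    moran_rows = []
    if adjacency is not None:
        for i, year in enumerate(panel.years):
            res = morans_i(
                D_wide[year].reindex(list(adjacency.units)).to_numpy(),
                adjacency,
                n_permutations=int(cfg["moran"]["permutations"]),
                seed=seed * 1000 + i,
            )
            moran_rows.append(
                {
                    "year": year,
                    "I": res.I,
                    "expected": res.expected,
                    "p_value": res.p_value,
                    "z": res.z,
                }
            )
        pd.DataFrame(moran_rows).to_csv(out / "moran.csv", index=False)
        _stage(manifest, "moran", out / "moran.csv")

    # -- stage: quantile regression ----------------------------------------
    try:
        qt = quantile_table(
            panel,
            table.set_index(["unit", "year"])["D"],
            taus=tuple(cfg["qreg"]["taus"]),
            transform=cfg["qreg"]["transform"],
            n_boot=int(cfg["qreg"]["n_boot"]),
            seed=seed,
        )
    except Exception as exc:
        raise PipelineError(f"qreg: {exc}") from exc
    flat = qt.copy()
    flat.columns = [f"{stat}_{tau}" for tau, stat in qt.columns]
    flat.rename_axis("driver").to_csv(out / "qreg.csv")
    manifest["n_obs_qreg"] = int(qt.attrs["n_obs"])
    _stage(manifest, "qreg", out / "qreg.csv")

    if truth is not None:
        manifest["truth"] = truth.to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
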