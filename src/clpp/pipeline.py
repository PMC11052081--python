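"""End-to-end orchestration: simulate -> profile -> community -> network.

Every stage reads and writes plain CSV/TSV so intermediates stay diffable;
a JSON run manifest records the config snapshot, seeds, input hashes and
per-stage output hashes, which makes replays checkable by hash comparison.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    anosim,
    bray_curtis,
    load_asv_table,
    load_metadata,
    load_taxonomy,
    shannon_evenness,
)
from .ecoplate import correct_all_plates, load_layout, load_readings
from .errors import PipelineError
from .metrics import profile
from .network import cooccurrence_network, edge_sign_summary
from .simulate import (
    CommunitySimConfig,
    PlateSimConfig,
    layout_to_frame,
    readings_to_frame,
    simulate_asv_table,
    simulate_plate,
)

DEMO_CONFIG: dict[str, Any] = {
    "seed": 42,
    "simulate": {
        "community": {},
        "plates": {"n_plates": 4},
    },
    "profile": {"reference_time": "auto", "richness_threshold": 0.5},
    "community": {"group": "layer", "permutations": 999},
    "network": {"stratify_by": "layer", "top": 200, "r_threshold": 0.6, "alpha": 0.05},
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return json.loads(json.dumps(dict(config)))  # deep copy, JSON-serializable check


def _stage_simulate(cfg: dict, seed: int, inputs_dir: Path) -> dict[str, Path]:
    inputs_dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    sim = cfg.get("simulate") or {}
    if "community" in sim:
        ccfg = CommunitySimConfig(**{**sim["community"], "seed": seed})
        table, taxonomy, meta = simulate_asv_table(ccfg)
        out["asv_table"] = inputs_dir / "asv_table.tsv"
        table.to_csv(out["asv_table"], sep="\t")
        out["taxonomy"] = inputs_dir / "taxonomy.tsv"
        taxonomy.to_csv(out["taxonomy"], sep="\t")
        out["metadata"] = inputs_dir / "metadata.csv"
        meta.to_csv(out["metadata"])
    if "plates" in sim:
        pcfg_args = dict(sim["plates"])
        n_plates = int(pcfg_args.pop("n_plates", 4))
        rng = np.random.default_rng(seed + 1)
        layout = load_layout()
        frames = []
        for i in range(n_plates):
            pcfg = PlateSimConfig(**{**pcfg_args, "seed": seed + 10 + i})
            affinity = {
                s: float(rng.uniform(0.2, 1.0)) for s in layout.substrates
            }
            _, readings = simulate_plate(
                pcfg, affinity, layout, sample_id=f"plate{i + 1}", plate_id=f"P{i + 1}"
            )
            frames.append(readings_to_frame(readings))
        out["layout"] = inputs_dir / "layout.csv"
        layout_to_frame(layout).to_csv(out["layout"], index=False)
        out["readings"] = inputs_dir / "readings.csv"
        pd.concat(frames, ignore_index=True).to_csv(out["readings"], index=False)
    return out


def _stage_profile(cfg: dict, inputs: dict[str, Path], out_dir: Path) -> dict[str, Path]:
    pcfg = cfg.get("profile") or {}
    layout = load_layout(inputs.get("layout"))
    readings = load_readings(inputs["readings"], layout)
    series_by_sample = correct_all_plates(readings, layout)
    ref = pcfg.get("reference_time", "auto")
    rows = []
    ts_rows = []
    for sample in sorted(series_by_sample):
        prof = profile(
            series_by_sample[sample],
            reference_time_h=ref,
            richness_threshold=float(pcfg.get("richness_threshold", 0.5)),
        )
        row = {
            "sample": sample,
            "reference_time_h": prof.reference_time_h,
            "awcd_ref": prof.awcd_series.loc[prof.reference_time_h],
            "richness": prof.richness_r,
            "simpson_D": prof.simpson_d,
            "shannon_H": prof.shannon_h,
            "t_exp_start_h": prof.phase.t_exp_start,
            "t_stable_start_h": prof.phase.t_stable_start,
        }
        for cat in prof.awcd_by_category.index:
            row[f"awcd_{cat}"] = prof.awcd_by_category.loc[cat, prof.reference_time_h]
        rows.append(row)
        for t, v in prof.awcd_series.items():
            ts_rows.append({"sample": sample, "time_h": t, "awcd": v})
    out = {
        "profile": out_dir / "profile.csv",
        "awcd_timeseries": out_dir / "awcd_timeseries.csv",
    }
    pd.DataFrame(rows).to_csv(out["profile"], index=False)
    pd.DataFrame(ts_rows).to_csv(out["awcd_timeseries"], index=False)
    return out


def _stage_community(cfg: dict, inputs: dict[str, Path], out_dir: Path, seed: int) -> dict[str, Path]:
    ccfg = cfg.get("community") or {}
    table = load_asv_table(inputs["asv_table"])
    meta = load_metadata(inputs["metadata"]).loc[table.index]
    dist = bray_curtis(table)
    div = shannon_evenness(table)
    group_col = ccfg.get("group", "layer")
    res = anosim(
        dist,
        meta[group_col].to_numpy(),
        n_permutations=int(ccfg.get("permutations", 999)),
        seed=seed,
    )
    out = {
        "distances": out_dir / "distances.tsv",
        "diversity": out_dir / "diversity.csv",
        "anosim": out_dir / "anosim.json",
    }
    dist.to_csv(out["distances"], sep="\t")
    div.to_csv(out["diversity"])
    with open(out["anosim"], "w") as fh:
        json.dump(
            {
                "group": group_col,
                "R": res.r_statistic,
                "p": res.p_value,
                "permutations": res.n_permutations,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return out


def _stage_network(cfg: dict, inputs: dict[str, Path], out_dir: Path, seed: int) -> dict[str, Path]:
    ncfg = cfg.get("network") or {}
    table = load_asv_table(inputs["asv_table"])
    tax_path = inputs.get("taxonomy")
    if tax_path is None or not Path(tax_path).exists():
        raise PipelineError(f"network stage: taxonomy file not found: {tax_path}")
    taxonomy = load_taxonomy(tax_path)
    meta = load_metadata(inputs["metadata"]).loc[table.index]
    strat_col = ncfg.get("stratify_by", "layer")
    strata = sorted(meta[strat_col].dropna().unique())
    out: dict[str, Path] = {}
    summary = {}
    for stratum in strata:
        sub = table.loc[meta[strat_col] == stratum]
        net = cooccurrence_network(
            sub,
            taxonomy,
            top_k=int(ncfg.get("top", 200)),
            r_threshold=float(ncfg.get("r_threshold", 0.6)),
            alpha=float(ncfg.get("alpha", 0.05)),
            seed=seed,
        )
        out[f"edges_{stratum}"] = out_dir / f"edges_{stratum}.tsv"
        net.edges.to_csv(out[f"edges_{stratum}"], sep="\t", index=False)
        out[f"nodes_{stratum}"] = out_dir / f"nodes_{stratum}.tsv"
        net.node_table().to_csv(out[f"nodes_{stratum}"], sep="\t", index=False)
        signs = edge_sign_summary(net)
        overall = signs[signs["stratum"] == "overall"]
        summary[str(stratum)] = {
            "n_nodes": len(net.nodes),
            "n_edges": int(net.graph.number_of_edges()),
            "n_modules": len(set(net.partition.values())),
            "modularity_Q": net.modularity_q,
            "positive_edge_fraction": (
                float(overall["positive_fraction"].iloc[0]) if len(overall) else None
            ),
            "sign_summary": signs.to_dict(orient="records"),
        }
    out["network_summary"] = out_dir / "network_summary.json"
    with open(out["network_summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order and write a manifest.

    Returns the manifest dict; it is also written to ``out_dir/manifest.json``.
    Stage failures raise :class:`PipelineError` naming the stage.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    inputs: dict[str, Path] = {}
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "inputs": {},
        "stages": {},
    }

    def run_stage(name: str, fn, *args) -> dict[str, Path]:
        try:
            outputs = fn(*args)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "outputs": {k: str(p) for k, p in outputs.items()},
            "hashes": {k: _sha256(p) for k, p in outputs.items()},
        }
        return outputs

    if cfg.get("simulate"):
        sim_out = run_stage("simulate", _stage_simulate, cfg, seed, out_dir / "inputs")
        inputs.update(sim_out)
    for key in ("layout", "readings", "asv_table", "taxonomy", "metadata"):
        if key in (cfg.get("inputs") or {}):
            inputs[key] = Path(cfg["inputs"][key])
    manifest["inputs"] = {
        k: {"path": str(p), "sha256": _sha256(Path(p))}
        for k, p in inputs.items()
        if Path(p).exists()
    }

    if "readings" in inputs and cfg.get("profile") is not None:
        run_stage("profile", _stage_profile, cfg, inputs, out_dir)
    if "asv_table" in inputs and cfg.get("community") is not None:
        run_stage("community", _stage_community, cfg, inputs, out_dir, seed)
    if "asv_table" in inputs and cfg.get("network") is not None:
        run_stage("network", _stage_network, cfg, inputs, out_dir, seed)

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def replay(manifest: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Re-run a pipeline from its manifest's config snapshot and seed."""
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = json.load(fh)
    return run_pipeline(manifest["config"], out_dir)


def report(manifest: Mapping[str, Any] | str | Path) -> str:
    """Human-readable summary of a completed run."""
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = json.load(fh)
    stages = manifest.get("stages", {})
    lines = [
        f"clpp run (package version {manifest.get('package_version')}, seed {manifest.get('seed')})",
        "",
    ]
    layout = load_layout()
    lines.append(
        f"layout: {len(layout.substrates)} substrates in {len(layout.categories)} "
        f"carbon categories, {len(layout.control_wells)} control wells"
    )
    if "profile" in stages:
        prof = pd.read_csv(stages["profile"]["outputs"]["profile"])
        lines.append("")
        lines.append("per-sample CLPP indices:")
        lines.append(prof.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    if "community" in stages:
        with open(stages["community"]["outputs"]["anosim"]) as fh:
            an = json.load(fh)
        lines.append("")
        lines.append(
            f"ANOSIM ({an['group']}): R = {an['R']:.4f}, p = {an['p']:.4f} "
            f"({an['permutations']} permutations)"
        )
    if "network" in stages:
        with open(stages["network"]["outputs"]["network_summary"]) as fh:
            nets = json.load(fh)
        lines.append("")
        lines.append("co-occurrence networks:")
        for stratum in sorted(nets):
            s = nets[stratum]
            if s["n_edges"] == 0:
                lines.append(f"  {stratum}: omitted (no edges passed the filter)")
                continue
            lines.append(
                f"  {stratum}: {s['n_nodes']} nodes, {s['n_edges']} edges, "
                f"{s['n_modules']} modules, Q = {s['modularity_Q']:.4f}, "
                f"positive edges = {100 * s['positive_edge_fraction']:.1f}%"
            )
    lines.append("")
    return "\n".join(lines)
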