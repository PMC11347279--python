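"""Config-driven orchestration: wildtype-vs-mutant(-vs-drug) comparison runs.

A run executes the analysis stages (per-domain RMSD/RMSF, S6-style
clustering, pore profiling, helix propensity, domain angles, motif
exposure) for each named condition and reports the deltas of every scalar
metric against the first (reference) condition. Conditions are either
synthetic presets — which is how the pipeline is exercised end to end with
known ground truth — or structure/trajectory files on disk.

Outputs are deterministic for a fixed config: every CSV/JSON carries a
provenance header (config hash, seed, package version) and reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_trajectory
from .exposure import MotifDefinition, motif_exposure
from .geometry import angle_timeseries
from .metrics import rmsd_series, rmsf_profile
from .pore import PoreAxis, pore_timeseries
from .secondary import helix_propensity
from .structure import DomainDefinition, SelectionSpec, Structure, Trajectory
from .synth import (
    ChannelLayout,
    ChannelSpec,
    MotionSchedule,
    linear_schedule,
    make_channel,
    make_helix_trajectory,
    make_trajectory,
    step_schedule,
)

__all__ = ["RunConfig", "ComparisonReport", "validate_config", "load_config",
           "run_pipeline", "build_preset", "PRESETS"]

PRESETS = ("null", "collapse", "hinge", "unfold", "collapse+hinge+unfold")

_KNOWN_TOP_KEYS = {"seed", "output_dir", "n_frames", "noise_sigma", "stages",
                   "parameters", "conditions"}
_KNOWN_STAGES = {"rmsd", "rmsf", "cluster", "pore", "ss", "angles", "sasa"}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "channelgauge_out"
    n_frames: int = 24
    noise_sigma: float = 0.25
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in _KNOWN_STAGES})
    parameters: dict[str, dict] = field(default_factory=dict)
    conditions: dict[str, dict] = field(default_factory=lambda: {
        "wildtype": {"preset": "null"},
        "mutant": {"preset": "collapse+hinge+unfold"},
    })

    def canonical_json(self) -> str:
        # output_dir is a destination, not a scientific parameter: two runs
        # of the same analysis into different folders share one hash.
        return json.dumps({
            "seed": self.seed,
            "n_frames": self.n_frames, "noise_sigma": self.noise_sigma,
            "stages": dict(sorted(self.stages.items())),
            "parameters": {k: dict(sorted(v.items()))
                           for k, v in sorted(self.parameters.items())},
            "conditions": {k: dict(sorted(v.items()))
                           for k, v in sorted(self.conditions.items())},
        }, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load YAML or TOML (auto-detected by suffix, YAML fallback)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        raw = tomllib.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    errors = validate_config(raw)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errors))
    return _config_from_dict(raw)


def _config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    cfg = RunConfig()
    for key in ("seed", "output_dir", "n_frames", "noise_sigma"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "stages" in raw:
        cfg.stages.update(raw["stages"])
    if "parameters" in raw:
        cfg.parameters = {k: dict(v) for k, v in raw["parameters"].items()}
    if "conditions" in raw:
        cfg.conditions = {k: dict(v) for k, v in raw["conditions"].items()}
    return cfg


def validate_config(raw: Mapping[str, Any]) -> list[str]:
    """Collect all config problems (never fail-fast); empty list = valid."""
    errors: list[str] = []
    if not isinstance(raw, Mapping):
        return ["config root must be a mapping"]
    for key in raw:
        if key not in _KNOWN_TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")
    if "n_frames" in raw and (not isinstance(raw["n_frames"], int) or raw["n_frames"] < 2):
        errors.append("n_frames must be an integer >= 2")
    for stage in raw.get("stages", {}):
        if stage not in _KNOWN_STAGES:
            errors.append(f"unknown stage {stage!r}")
    params = raw.get("parameters", {})
    pore = params.get("pore", {})
    if "dz" in pore and not (isinstance(pore["dz"], (int, float)) and pore["dz"] > 0):
        errors.append("parameters.pore.dz must be > 0")
    sasa_p = params.get("sasa", {})
    if "n_points" in sasa_p and sasa_p["n_points"] < 92:
        errors.append("parameters.sasa.n_points must be >= 92")
    conditions = raw.get("conditions", {})
    if conditions and len(conditions) < 1:
        errors.append("at least one condition required")
    for name, cond in conditions.items():
        if "preset" in cond:
            if cond["preset"] not in PRESETS:
                errors.append(f"condition {name!r}: unknown preset {cond['preset']!r}")
        elif "topology" in cond:
            if "trajectory" not in cond:
                errors.append(f"condition {name!r}: trajectory path missing")
            stages_on = raw.get("stages", {s: True for s in _KNOWN_STAGES})
            if stages_on.get("angles", True) and "domains" not in cond:
                errors.append(
                    f"condition {name!r}: angles stage needs domain definitions"
                )
        else:
            errors.append(f"condition {name!r}: needs 'preset' or 'topology'")
        doms = cond.get("domains")
        if doms:
            try:
                defs = {n: DomainDefinition.make(n, r) for n, r in doms.items()}
                for dname, hname in (("PAS", "hinge_PAS"), ("CNBD", "hinge_CNBD")):
                    if dname in defs and hname in defs and defs[dname].overlaps(defs[hname]):
                        errors.append(
                            f"condition {name!r}: domain {dname} overlaps its hinge"
                        )
            except Exception as exc:  # malformed ranges
                errors.append(f"condition {name!r}: bad domain definition: {exc}")
    return errors


# ---------------------------------------------------------------------------
# Synthetic presets

def _channel_schedule(preset: str, noise: float, seed: int) -> MotionSchedule:
    hinge = {}
    pore_fn = None
    translations = {}
    if "hinge" in preset:
        hinge = {"PAS": linear_schedule(-20.0), "CNBD": linear_schedule(+10.0)}
        translations = {"occluder": ((40.0, 0.0, -15.0), step_schedule(1.0, at=0.5))}
    if "collapse" in preset:
        def pore_fn(z: float, tf: float) -> float:
            return 5.0 - 2.5 * tf * float(np.exp(-((z - 4.0) ** 2) / 8.0))
    return MotionSchedule(
        pore_radius=pore_fn,
        hinge_drift_deg=hinge,
        translations=translations,
        noise_sigma=noise,
        seed=seed,
    )


def build_preset(preset: str, seed: int, n_frames: int,
                 noise_sigma: float = 0.25) -> dict:
    """Build the synthetic condition: channel + peptide trajectories + manifest."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    spec = ChannelSpec(
        z_range=(-12.0, 12.0),
        ring_spacing=1.0,
        motif_surface=("K21-Q25",),
        motif_interface=("Y54-A57",),
    )
    structure, layout = make_channel(spec)
    schedule = _channel_schedule(preset, noise_sigma, seed)
    channel_traj, channel_manifest = make_trajectory(
        structure, schedule, n_frames, layout
    )
    unfolded = "unfold" in preset
    peptide_traj, peptide_manifest = make_helix_trajectory(
        40, n_frames,
        unfold_range=(8, 32),
        unfold_flags=[unfolded] * n_frames,
        noise_sigma=0.0,
        seed=seed + 1,
    )
    return {
        "preset": preset,
        "channel": channel_traj,
        "layout": layout,
        "peptide": peptide_traj,
        "manifest": {"channel": channel_manifest, "peptide": peptide_manifest},
    }


# ---------------------------------------------------------------------------
# Stages

def _stage_rmsd(cond: dict, params: dict) -> dict:
    traj: Trajectory = cond["channel"]
    layout: ChannelLayout = cond["layout"]
    ref = traj.topology
    out = {}
    for dom_name in ("PAS", "TMD", "CNBD"):
        dom = layout.domains[dom_name]
        per_chain = []
        for chain in layout.chain_ids:
            lo, hi = dom.ranges[chain][0]
            sel = SelectionSpec.make(chains=[chain], res_range=(lo, hi))
            series = rmsd_series(traj, ref, sel, sel, domain=dom_name)
            per_chain.append(series.values)
        mean_series = np.mean(per_chain, axis=0)
        out[dom_name] = {
            "series": mean_series,
            "mean_A": float(mean_series.mean()),
            "final_A": float(mean_series[-1]),
        }
    return out


def _stage_rmsf(cond: dict, params: dict) -> dict:
    traj: Trajectory = cond["channel"]
    layout: ChannelLayout = cond["layout"]
    out = {}
    for dom_name in ("PAS", "TMD", "CNBD"):
        lo, hi = layout.domains[dom_name].ranges[layout.chain_ids[0]][0]
        sel = SelectionSpec.make(res_range=(lo, hi))
        prof = rmsf_profile(traj, sel, layout.chain_ids)
        out[dom_name] = {
            "res_ids": prof.res_ids,
            "rmsf": prof.rmsf,
            "mean_A": float(prof.rmsf.mean()),
        }
    return out


def _stage_cluster(cond: dict, params: dict) -> dict:
    traj: Trajectory = cond["channel"]
    layout: ChannelLayout = cond["layout"]
    lo, hi = layout.domains["TMD"].ranges[layout.chain_ids[0]][0]
    sel = SelectionSpec.make(res_range=(lo, hi), atom_names=["CA"])
    k_lo, k_hi = params.get("k_scan", (2, 6))
    result = cluster_trajectory(
        traj, sel,
        k_scan=range(k_lo, k_hi + 1),
        stride=params.get("stride", 1),
        plateau_threshold=params.get("plateau_threshold", 0.01),
    )
    return {
        "chosen_k": result.chosen_k,
        "rule": result.chosen_rule,
        "dbi_by_k": result.dbi_by_k,
        "ssr_sst_by_k": result.ssr_sst_by_k,
        "populations": result.populations,
        "labels": result.labels,
    }


def _stage_pore(cond: dict, params: dict) -> dict:
    traj: Trajectory = cond["channel"]
    axis = PoreAxis(
        z_range=tuple(params.get("z_range", (-12.0, 12.0))),
        dz=params.get("dz", 1.0),
    )
    lo, hi = cond["layout"].domains["TMD"].ranges["A"][0]
    sel = SelectionSpec.make(res_range=(lo, hi))
    profile = pore_timeseries(
        traj, axis, selection=sel,
        search_radius=params.get("search_radius", 10.0),
    )
    imin = int(np.argmin(profile.mean))
    return {
        "z": profile.z,
        "mean": profile.mean,
        "sd": profile.sd,
        "min_mean_radius_A": float(profile.mean[imin]),
        "z_of_min_A": float(profile.z[imin]),
    }


def _stage_ss(cond: dict, params: dict) -> dict:
    traj: Trajectory = cond["peptide"]
    lo, hi = cond["manifest"]["peptide"]["unfold_range"] or (1, 1)
    dom = DomainDefinition.make("linker_helix", {"A": [(lo, hi)]})
    prop = helix_propensity(traj, dom, condition=cond["preset"])
    return {
        "res_ids": prop.res_ids["A"],
        "propensity": prop.fractions["A"],
        "domain_mean": prop.domain_mean,
    }


def _stage_angles(cond: dict, params: dict) -> dict:
    traj: Trajectory = cond["channel"]
    layout: ChannelLayout = cond["layout"]
    out = {}
    for dom_name, hinge_name in (("PAS", "hinge_PAS"), ("CNBD", "hinge_CNBD")):
        series = angle_timeseries(
            traj,
            layout.domains[dom_name],
            layout.domains[hinge_name],
            layout.domains["TMD"],
            window_fraction=params.get("window_fraction", 0.1),
        )
        out[dom_name] = {
            "series": series.averaged,
            "drift_deg": series.drift_deg,
            "initial_deg": float(series.averaged[: max(1, len(series.averaged) // 10)].mean()),
        }
    return out


def _stage_sasa(cond: dict, params: dict) -> dict:
    traj: Trajectory = cond["channel"]
    layout: ChannelLayout = cond["layout"]
    out = {}
    for mid, (dom, (lo, hi)) in layout.motifs.items():
        motif = MotifDefinition(mid, "A", (lo, hi),
                                "KFERQ-related" if mid == "K21-Q25" else "tyrosine-based")
        exp = motif_exposure(
            traj, motif,
            threshold=params.get("threshold", 0.25),
            n_points=params.get("n_points", 240),
        )
        out[mid] = {
            "relative": exp.relative,
            "mean_relative": float(exp.relative.mean()),
            "exposed_fraction": float(exp.exposed.mean()),
        }
    return out


_STAGE_FNS = {
    "rmsd": _stage_rmsd,
    "rmsf": _stage_rmsf,
    "cluster": _stage_cluster,
    "pore": _stage_pore,
    "ss": _stage_ss,
    "angles": _stage_angles,
    "sasa": _stage_sasa,
}

#: Scalar metrics extracted per stage for the condition-vs-reference deltas.
_SCALARS = {
    "rmsd": lambda r: {f"rmsd_mean_{d}_A": r[d]["mean_A"] for d in r},
    "rmsf": lambda r: {f"rmsf_mean_{d}_A": r[d]["mean_A"] for d in r},
    "cluster": lambda r: {"chosen_k": float(r["chosen_k"])},
    "pore": lambda r: {"min_mean_radius_A": r["min_mean_radius_A"]},
    "ss": lambda r: {"helix_propensity_mean": r["domain_mean"]},
    "angles": lambda r: {f"angle_drift_{d}_deg": r[d]["drift_deg"] for d in r},
    "sasa": lambda r: {f"exposed_fraction_{m}": r[m]["exposed_fraction"] for m in r},
}


@dataclass
class ComparisonReport:
    config_hash: str
    seed: int
    conditions: dict[str, dict]          # condition -> stage -> result
    scalars: dict[str, dict[str, float]]  # condition -> metric -> value
    deltas: dict[str, dict[str, float]]   # condition -> metric -> value - ref
    failed: dict[str, list[str]]
    reference: str


def _load_condition(name: str, cond_cfg: dict, cfg: RunConfig) -> dict:
    if "preset" in cond_cfg:
        return build_preset(
            cond_cfg["preset"], cfg.seed, cfg.n_frames, cfg.noise_sigma
        )
    from .structure import read_structure, read_trajectory

    top = read_structure(cond_cfg["topology"])
    traj = read_trajectory(cond_cfg["trajectory"], top)
    domains = {
        n: DomainDefinition.make(n, r) for n, r in cond_cfg.get("domains", {}).items()
    }
    layout = ChannelLayout(spec=None, domains=domains, rings=[], motifs={},
                           chain_ids=tuple(sorted(top.chains)))
    return {"preset": name, "channel": traj, "layout": layout,
            "peptide": traj, "manifest": {"peptide": {"unfold_range": None}}}


def run_pipeline(cfg: RunConfig) -> ComparisonReport:
    """Run all enabled stages for every condition and write the report.

    A failing stage is recorded and later independent stages still run.
    The first condition listed is the reference for all deltas.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    header = (f"# channelgauge v{__version__} config={chash} seed={cfg.seed}\n")

    conditions: dict[str, dict] = {}
    scalars: dict[str, dict[str, float]] = {}
    failed: dict[str, list[str]] = {}
    for name, cond_cfg in cfg.conditions.items():
        cond = _load_condition(name, cond_cfg, cfg)
        results: dict[str, Any] = {}
        failed[name] = []
        for stage, fn in _STAGE_FNS.items():
            if not cfg.stages.get(stage, True):
                continue
            try:
                results[stage] = fn(cond, cfg.parameters.get(stage, {}))
            except Exception as exc:
                failed[name].append(f"{stage}: {exc}")
        conditions[name] = results
        scalars[name] = {}
        for stage, res in results.items():
            scalars[name].update(_SCALARS[stage](res))

    ref_name = next(iter(cfg.conditions))
    deltas = {
        name: {
            metric: vals[metric] - scalars[ref_name].get(metric, np.nan)
            for metric in vals
        }
        for name, vals in scalars.items()
        if name != ref_name
    }

    # Deterministic outputs: one scalar table + per-stage CSVs.
    rows = []
    for name, vals in scalars.items():
        for metric, value in sorted(vals.items()):
            rows.append({"condition": name, "metric": metric, "value": f"{value:.6f}"})
    with open(outdir / "scalars.csv", "w") as fh:
        fh.write(header)
        pd.DataFrame(rows).to_csv(fh, index=False)
    report_payload = {
        "config_hash": chash,
        "seed": cfg.seed,
        "version": __version__,
        "reference": ref_name,
        "scalars": {k: {m: round(v, 6) for m, v in sorted(sv.items())}
                    for k, sv in sorted(scalars.items())},
        "deltas": {k: {m: round(v, 6) for m, v in sorted(dv.items())}
                   for k, dv in sorted(deltas.items())},
        "failed_stages": {k: v for k, v in sorted(failed.items())},
    }
    (outdir / "report.json").write_text(json.dumps(report_payload, indent=2,
                                                   sort_keys=True) + "\n")
    return ComparisonReport(
        config_hash=chash,
        seed=cfg.seed,
        conditions=conditions,
        scalars=scalars,
        deltas=deltas,
        failed=failed,
        reference=ref_name,
    )
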