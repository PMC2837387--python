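"""Run configuration: loading, validation, fixtures and batch orchestration.

Configs are TOML or YAML with blocks mirroring the model parameter tables
(``gene``, ``expression``, ``repressilator``) plus run protocol fields
(``mode``, ``t_stop``, ``sample_dt``, ``n_runs``, ``seed``).  All parameter
names are the standard symbols (``k_init``, ``tau_oc``, ``k_pause``,
``d_pause``, ``k_f``, ``k_tr``, ``tau1`` ... ``deg_p_r``); unknown keys are
rejected.  Per-run seeds are derived deterministically as
``seed + run_index`` so batches reproduce bit-exactly regardless of
scheduling.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, analysis
from .engine import DelaySpec
from .expression import ExpressionParams, simulate_gene_expression
from .network import RepressilatorParams, simulate_repressilator
from .transcription import PauseSiteSpec, TranscriptionParams, simulate_transcription

__all__ = ["RunConfig", "load_config", "run_batch", "generate_fixture", "FIXTURES"]

MODES = ("gene", "gene_expression", "repressilator")

# accepted key aliases: table symbol -> dataclass field
_GENE_ALIASES = {
    "length": "N", "rnap": "n_rnap",
}
_DELAY_FIELDS = {"tau_oc": ("gaussian", 40.0, 4.0), "tau3": ("gaussian", 420.0, 140.0)}


@dataclass(frozen=True)
class RunConfig:
    mode: str = "gene"
    gene: TranscriptionParams = field(default_factory=TranscriptionParams)
    pause_sites: tuple[PauseSiteSpec, ...] = ()
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    repressilator: RepressilatorParams | None = None
    t_stop: float = 3300.0
    sample_dt: float = 1.0
    n_runs: int = 1
    seed: int = 0
    output_dir: str = "txnsim_out"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")
        if self.t_stop <= 0:
            raise ValueError("t_stop must be positive")


def _as_delay(value, default: tuple) -> DelaySpec:
    if isinstance(value, DelaySpec):
        return value
    if isinstance(value, (int, float)):
        return DelaySpec("constant", float(value))
    if isinstance(value, dict):
        kind = value.get("kind", default[0])
        return DelaySpec(kind, float(value.get("mean", default[1])),
                         float(value.get("std", default[2])))
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return DelaySpec("gaussian", float(value[0]), float(value[1]))
    raise ValueError(f"cannot interpret delay specification {value!r}")


def _build_params(cls, block: dict, aliases: dict, label: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    errors = []
    for key, value in block.items():
        name = aliases.get(key, key)
        if name not in fields:
            errors.append(key)
            continue
        if name in _DELAY_FIELDS:
            value = _as_delay(value, _DELAY_FIELDS[name])
        elif fields[name].type in ("int", int):
            value = int(value)
        else:
            value = float(value)
        kwargs[name] = value
    if errors:
        raise ValueError(f"unknown keys in {label} block: {sorted(errors)}")
    return cls(**kwargs)


def _parse(data: dict) -> RunConfig:
    data = dict(data)
    gene_block = dict(data.pop("gene", {}))
    sites = [
        PauseSiteSpec(
            position=int(s["position"]),
            occurrence_prob=float(s.get("occurrence_prob", 1.0)),
            mean_duration=float(s["mean_duration"]),
            premature_term_prob=float(s.get("premature_term_prob", 0.0)),
            once_per_rnap=bool(s.get("once_per_rnap", True)),
        )
        for s in gene_block.pop("pause_sites", [])
    ]
    gene = _build_params(TranscriptionParams, gene_block, _GENE_ALIASES, "gene")
    expr = _build_params(ExpressionParams, dict(data.pop("expression", {})), {}, "expression")
    rep = None
    if "repressilator" in data:
        rblock = dict(data.pop("repressilator", {}))
        unknown = set(rblock) - {"k_r", "k_u", "k_dp", "deg_p_r"}
        if unknown:
            raise ValueError(f"unknown keys in repressilator block: {sorted(unknown)}")
        rep = RepressilatorParams(transcription=gene, expression=expr,
                                  **{k: float(v) for k, v in rblock.items()})
    run_keys = {"mode", "t_stop", "sample_dt", "n_runs", "seed", "output_dir"}
    unknown = set(data) - run_keys
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig(
        mode=str(data.get("mode", "gene")),
        gene=gene,
        pause_sites=tuple(sites),
        expression=expr,
        repressilator=rep,
        t_stop=float(data.get("t_stop", 3300.0)),
        sample_dt=float(data.get("sample_dt", 1.0)),
        n_runs=int(data.get("n_runs", 1)),
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "txnsim_out")),
    )
    if cfg.mode == "repressilator" and cfg.repressilator is None:
        cfg = dataclasses.replace(cfg, repressilator=RepressilatorParams(
            transcription=gene, expression=expr))
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a TOML or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text()) or {}
    else:
        data = tomllib.loads(path.read_text())
    return _parse(data)


def config_to_dict(cfg: RunConfig) -> dict:
    """JSON-serializable echo of a configuration (for manifests)."""

    def delay(d: DelaySpec):
        return {"kind": d.kind, "mean": d.param1, "std": d.param2}

    out = {
        "mode": cfg.mode,
        "t_stop": cfg.t_stop,
        "sample_dt": cfg.sample_dt,
        "n_runs": cfg.n_runs,
        "seed": cfg.seed,
        "gene": dataclasses.asdict(cfg.gene),
        "expression": dataclasses.asdict(cfg.expression),
    }
    if cfg.pause_sites:
        out["gene"]["pause_sites"] = [dataclasses.asdict(s) for s in cfg.pause_sites]
    out["gene"]["tau_oc"] = delay(cfg.gene.tau_oc)
    out["expression"]["tau3"] = delay(cfg.expression.tau3)
    if cfg.repressilator is not None:
        r = cfg.repressilator
        out["repressilator"] = {
            "k_r": r.k_r, "k_u": r.k_u, "k_dp": r.k_dp, "deg_p_r": r.deg_p_r,
        }
    return out


def run_batch(cfg: RunConfig, out_dir=None) -> list[Path]:
    """Execute ``n_runs`` simulations, writing per-run CSVs and a manifest.

    Run ``k`` uses seed ``cfg.seed + k``.  Outputs per run: a time-series
    CSV, an event-log CSV (completion times and counters) and an analysis
    JSON; plus one ``manifest.json`` echoing the configuration and package
    version.  Returns the list of written paths.
    """
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for k in range(cfg.n_runs):
        seed = cfg.seed + k
        tag = f"run{k:03d}"
        if cfg.mode == "gene":
            ts, log = simulate_transcription(
                cfg.gene, cfg.pause_sites, t_stop=cfg.t_stop, seed=seed,
                sample_dt=cfg.sample_dt)
            logs = [log]
        elif cfg.mode == "gene_expression":
            ts, log = simulate_gene_expression(
                cfg.gene, cfg.expression, t_stop=cfg.t_stop, seed=seed,
                sample_dt=cfg.sample_dt, pause_sites=cfg.pause_sites)
            logs = [log]
        else:
            ts, logs = simulate_repressilator(
                cfg.repressilator, t_stop=cfg.t_stop, seed=seed,
                sample_dt=cfg.sample_dt)
        ts_path = out / f"{tag}_timeseries.csv"
        ts.to_csv(ts_path, index=False)
        written.append(ts_path)

        ev = pd.DataFrame(
            [
                {"time": t, "event_type": "completion", "position": cfg.gene.N,
                 "gene": gi, "run_id": k}
                for gi, g in enumerate(logs)
                for t in g.completion_times
            ],
            columns=["time", "event_type", "position", "gene", "run_id"],
        )
        ev_path = out / f"{tag}_events.csv"
        ev.to_csv(ev_path, index=False)
        written.append(ev_path)

        summary = _summarize(cfg, ts, logs)
        an_path = out / f"{tag}_analysis.json"
        an_path.write_text(json.dumps(summary, indent=2))
        written.append(an_path)

    manifest = {"config": config_to_dict(cfg), "version": __version__}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written.append(mpath)
    return written


def _summarize(cfg: RunConfig, ts: pd.DataFrame, logs) -> dict:
    summary: dict = {}
    if cfg.mode == "repressilator":
        P = ts[["P1", "P2", "P3"]].to_numpy().T
        b = [analysis.kmeans_binarize(p) for p in P]
        summary["entropy_nats"] = analysis.tuple_entropy(*b)
        try:
            summary["period_s"] = analysis.estimate_period(P, cfg.sample_dt)
        except ValueError:
            summary["period_s"] = None
        total = P.sum(axis=0)
        if total.mean() > 0:
            summary["cv_P_total"] = analysis.coefficient_of_variation(total)
    else:
        log = logs[0]
        mb = analysis.microburst_stats(log.completion_times)
        summary["microbursts"] = {
            "episode_count": mb.episode_count,
            "fraction_fast_intervals": mb.fraction_fast_intervals,
            "largest_burst_size": mb.largest_burst_size,
            "window_s": mb.window,
        }
        summary["n_completions"] = log.n_completions
        rna = ts["rna"].to_numpy()
        if rna.mean() > 0:
            summary["cv_rna"] = analysis.coefficient_of_variation(rna)
        if "protein" in ts and ts["protein"].mean() > 0:
            summary["cv_protein"] = analysis.coefficient_of_variation(
                ts["protein"].to_numpy())
            summary["transient_s"] = analysis.initial_transient(
                ts["protein"].to_numpy(), cfg.sample_dt)
    return summary


# ------------------------------------------------------------------ fixtures

def _longpause_gene(term_prob: float, with_site: bool) -> dict:
    gene: dict = {"N": 400, "k_init": 10.0}
    if with_site:
        gene["pause_sites"] = [
            {"position": 200, "occurrence_prob": 0.5, "mean_duration": 60.0,
             "premature_term_prob": term_prob}
        ]
    return gene


FIXTURES: dict[str, dict] = {
    "default_gene": {"mode": "gene", "t_stop": 3300.0},
    "toy_gene_50nt": {"mode": "gene", "t_stop": 2000.0, "gene": {"N": 50}},
    "longpause_A": {"mode": "gene", "t_stop": 20000.0,
                    "gene": _longpause_gene(0.0, False)},
    "longpause_B": {"mode": "gene", "t_stop": 20000.0,
                    "gene": _longpause_gene(0.0, True)},
    "longpause_C": {"mode": "gene", "t_stop": 20000.0,
                    "gene": _longpause_gene(0.25, True)},
    "repressilator": {"mode": "repressilator", "t_stop": 100000.0,
                      "sample_dt": 100.0, "repressilator": {}},
}


def generate_fixture(name: str) -> RunConfig:
    """Ready-to-run configurations for the study scenarios.

    ``longpause_A/B/C`` are the 400-nt templates with a fast initiation rate
    (completion headway ~40 +/- 4 s); B adds the 50%-occurrence, 60 s
    long-pause site at nucleotide 200 and C additionally terminates 25% of
    long-paused RNAPs.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return _parse(json.loads(json.dumps(FIXTURES[name])))
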