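"""Configuration schema, per-stage seeding, and the end-to-end pipeline.

The pipeline reproduces the full workflow at configurable scale: generate a
surrogate Purkinje-cell recording and respiratory events, build the master
rate template, construct an AST population with the requested rate
covariance and event-locked modulation, drive the CN point model, and
report output statistics and the event-aligned PSTH.

Runs are exactly reproducible: one top-level seed is expanded into
per-stage seeds with a counter-based scheme, every numeric setting lives in
the config mapping (YAML-serializable), and the run manifest records the
config snapshot, package version, per-stage seeds and SHA-256 digests of
every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cn_point_model import NeuronParams, SynapseLayout, simulate
from .event_psth import assess_significance, compute_psth, score_modulation, shifted_controls
from .io_fixtures import (
    SurrogateSpec,
    generate_respiration_events,
    generate_surrogate_recording,
    write_event_times,
    write_spike_times,
)
from .population_builder import (
    PopulationSpec,
    build_population,
    respiratory_modulation_waveform,
)
from .rate_template import build_template, rescale_to_rate

__all__ = ["DEFAULT_CONFIG", "load_config", "stage_seed", "run_pipeline", "RunManifest"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "duration": 20.0,
    "pc": {"rate": 64.9, "lv": 0.31, "slow_sd": 0.10, "slow_timescale": 1.0},
    "mf": {"rate": 20.4, "lv": 0.7},
    "respiration": {"rate": 3.9, "interval_cv": 0.413},
    "modulation": {"depth": 0.114, "bms": 1.0, "bmf": 0.5},
    "population": {"n_pc": 50, "n_mf": 48, "sf": 0.5},
    "synapses": {"g_in": 16.0, "g_ex": 3.5, "std_enabled": True},
    "psth": {"window": 0.5, "smoothing": 0.03, "n_controls": 100,
             "threshold_sd": 3.0, "min_run": 10},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config, filling unset values from :data:`DEFAULT_CONFIG`."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: counter-based expansion of the top
    seed with the stage name, independent of stage execution order."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass(frozen=True)
class RunManifest:
    config: dict
    seeds: dict
    version: str
    outputs: dict  # file name -> sha256 digest

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir, plots: bool = False) -> RunManifest:
    """Execute the full workflow and write a report to *out_dir*.

    Stages: fixtures → master templates → AST population → CN simulation →
    statistics and event-aligned PSTH.  Returns the :class:`RunManifest`
    (also written as ``manifest.json``); re-running with the same config
    produces byte-identical CSV outputs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    seeds = {s: stage_seed(seed, s) for s in
             ("fixtures", "events", "population", "mf_population", "simulate", "controls")}
    dur = float(config["duration"])

    # --- fixtures ---------------------------------------------------------
    pc_cfg = config["pc"]
    src = generate_surrogate_recording(SurrogateSpec(
        mean_rate=pc_cfg["rate"], target_lv=pc_cfg["lv"],
        slow_fluctuation_sd=pc_cfg["slow_sd"], slow_timescale=pc_cfg["slow_timescale"],
        duration=dur, seed=seeds["fixtures"], label="pc_master"))
    events = generate_respiration_events(
        rate=config["respiration"]["rate"],
        interval_cv=config["respiration"]["interval_cv"],
        duration=dur, seed=seeds["events"])
    write_spike_times(src, out / "pc_master_spikes.csv")
    write_event_times(events, out / "respiration_events.csv")

    # --- templates --------------------------------------------------------
    master = build_template(src)
    master_mf = rescale_to_rate(master, config["mf"]["rate"])
    wave = respiratory_modulation_waveform(depth=config["modulation"]["depth"])

    # --- population -------------------------------------------------------
    pop_cfg = config["population"]
    mod_cfg = config["modulation"]
    pc_trains = build_population(master, PopulationSpec(
        n_trains=pop_cfg["n_pc"], sf=pop_cfg["sf"], bmf=mod_cfg["bmf"],
        bms=mod_cfg["bms"], uniform_rate=pc_cfg["rate"], lv=pc_cfg["lv"],
        seed=seeds["population"]), waveform=wave, events=events)
    mf_trains = build_population(master_mf, PopulationSpec(
        n_trains=pop_cfg["n_mf"], sf=1.0, uniform_rate=config["mf"]["rate"],
        lv=config["mf"]["lv"], seed=seeds["mf_population"]))

    # --- CN simulation ----------------------------------------------------
    syn = config["synapses"]
    layout = SynapseLayout(n_pc=pop_cfg["n_pc"], n_mf=pop_cfg["n_mf"],
                           g_in=syn["g_in"], g_ex=syn["g_ex"],
                           std_enabled=syn["std_enabled"])
    res = simulate(pc_trains, mf_trains, layout, NeuronParams(), duration=dur)
    write_spike_times(res.train, out / "cn_output_spikes.csv")

    # --- statistics & PSTH report ----------------------------------------
    from .spike_stats import summarize

    rows = []
    for tr in (pc_trains[:1] + [res.train]):
        s = summarize(tr)
        rows.append({"label": "pc_ast_0" if tr is pc_trains[0] else "cn_output",
                     "rate_hz": s.mean_rate, "cv": s.cv, "lv": s.lv,
                     "n_spikes": s.n_spikes})
    pd.DataFrame(rows).to_csv(out / "stats.csv", index=False, float_format="%.6g")

    p_cfg = config["psth"]
    psth = compute_psth(res.train, events, window=p_cfg["window"],
                        smoothing=p_cfg["smoothing"])
    controls = shifted_controls(res.train, events, n_controls=p_cfg["n_controls"],
                                window=p_cfg["window"], smoothing=p_cfg["smoothing"],
                                seed=seeds["controls"])
    sig = assess_significance(psth, controls, p_cfg["threshold_sd"], p_cfg["min_run"])
    score = score_modulation(psth, controls, p_cfg["threshold_sd"], p_cfg["min_run"])
    pd.DataFrame({
        "lag_s": psth.lags, "rate_hz": psth.rate,
        "control_mean": controls.mean, "control_sd": controls.sd,
        "z": sig.z_per_bin,
    }).to_csv(out / "cn_psth.csv", index=False, float_format="%.6g")
    summary = {
        "cn_rate_hz": res.train.mean_rate,
        "psth_significant": bool(sig.significant),
        "psth_peak_rate_increase_hz": score.peak_rate_increase,
        "psth_peak_percent": score.peak_percent,
        "psth_spikes_per_event": score.spikes_per_event,
        "mean_i_inh_pa": res.mean_i_inh,
        "mean_i_exc_pa": res.mean_i_exc,
        "mean_i_net_pa": res.mean_i_net,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if plots:  # pragma: no cover - optional, needs matplotlib
        _plot_report(out, psth, controls)

    outputs = {p.name: _digest(p) for p in sorted(out.glob("*"))
               if p.is_file() and p.name != "manifest.json"}
    manifest = RunManifest(config=config, seeds=seeds, version=__version__,
                           outputs=outputs)
    manifest.save(out / "manifest.json")
    return manifest


def _plot_report(out: Path, psth, controls) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(psth.lags, psth.rate, "k", label="CN PSTH")
    ax.plot(psth.lags, controls.mean, "b", label="control mean")
    ax.fill_between(psth.lags, controls.mean - 2 * controls.sd,
                    controls.mean + 2 * controls.sd, color="c", alpha=0.3,
                    label="±2 SD")
    ax.set_xlabel("lag from inspiration (s)")
    ax.set_ylabel("rate (Hz)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "cn_psth.png", dpi=120)
    plt.close(fig)
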