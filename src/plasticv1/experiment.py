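"""Experiment runner: configuration, seed sweeps, metric reports.

A run is reproducible from its config file alone: the config fixes the
variant, sizes, stimulus source and seed(s); every output file embeds the
config hash and seed.  A failing metric is isolated — its error is
recorded and the remaining metrics still run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import (
    UndefinedMetric,
    correlation_vs_similarity,
    ei_ratio,
    image_reconstruction_error,
    measure_tuning,
    mean_pairwise_correlation,
    mutual_information_per_spike,
    orientation_diversity_index,
    population_obw,
    population_sparseness,
    receptive_field_maps,
)
from .network import NetworkConfig, build_network, load_checkpoint, present_stimulus, save_checkpoint, train
from .stimuli import NATURAL_R_MAX, on_off_split, sample_patch
from .synthetic import generate_scene_set

__all__ = ["ExperimentConfig", "run_experiment", "aggregate_sweep", "METRIC_NAMES"]

METRIC_NAMES = ("sparseness", "odi", "obw", "ei_ratio", "mi_per_spike", "ire", "correlation")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    variant: str = "EI2/1"
    seeds: list = field(default_factory=lambda: list(range(20)))
    scale_factor: float | None = 0.25
    n_stimuli: int = 50_000
    n_scenes: int = 10
    scene_size: int = 128
    metrics: list = field(default_factory=lambda: ["sparseness", "odi"])
    outdir: str = "results"
    log_every: int = 1000
    checkpoint: str | None = None     # start from a checkpoint instead of training
    # desk-scale measurement sizes
    n_probe_stimuli: int = 300        # natural patches for response metrics
    n_mi_reps: int = 100
    n_mi_stimuli: int = 60
    tuning_reps: int = 5
    tuning_phases: int = 3
    tuning_freqs: int = 3
    ei_scenes: int = 50
    ei_reps: int = 5

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad = [m for m in data.get("metrics", []) if m not in METRIC_NAMES]
        if bad:
            raise ValueError(f"unknown metrics: {bad}; choose from {METRIC_NAMES}")
        return cls(**data)


def _probe_responses(net, scenes, n_stimuli, rng):
    """Spike counts (n_stimuli, n_exc) on random natural patches."""
    counts = np.zeros((n_stimuli, net.config.n_exc))
    for s in range(n_stimuli):
        scene = scenes[int(rng.integers(len(scenes)))]
        rates = on_off_split(sample_patch(scene, rng), NATURAL_R_MAX)
        _, tr = present_stimulus(net, rates, plastic=False, record=False)
        counts[s] = tr["spikes_e"].sum(axis=0)
    return counts


def _run_metrics(net, scenes, cfg: ExperimentConfig, rng) -> dict:
    """Compute the requested metrics; failures are recorded, not raised."""
    out: dict = {}
    probe_counts = None
    tuning = None
    for name in cfg.metrics:
        try:
            if name in ("sparseness", "correlation", "mi_per_spike") and probe_counts is None:
                probe_counts = _probe_responses(net, scenes, cfg.n_probe_stimuli, rng)
            if name in ("odi", "obw") and tuning is None:
                tuning = measure_tuning(
                    net, n_reps=cfg.tuning_reps, n_phases=cfg.tuning_phases,
                    n_freqs=cfg.tuning_freqs,
                )
            if name == "sparseness":
                vals = []
                for row in probe_counts:
                    try:
                        vals.append(population_sparseness(row))
                    except UndefinedMetric:
                        pass
                out[name] = float(np.mean(vals)) if vals else np.nan
            elif name == "odi":
                out[name] = orientation_diversity_index(tuning.preferred)
            elif name == "obw":
                out[name] = float(np.nanmean(population_obw(tuning)))
            elif name == "ei_ratio":
                res = ei_ratio(net, scenes, n_scenes=cfg.ei_scenes, n_reps=cfg.ei_reps)
                out[name] = res["ratio"]
            elif name == "mi_per_spike":
                counts = _mi_counts(net, scenes, cfg, rng)
                vals = []
                for j in range(counts.shape[2]):
                    try:
                        vals.append(mutual_information_per_spike(counts[:, :, j]))
                    except UndefinedMetric:
                        pass
                out[name] = float(np.mean(vals)) if vals else np.nan
            elif name == "ire":
                out[name] = image_reconstruction_error(net, scenes[0], n_reps=5)
            elif name == "correlation":
                out[name] = mean_pairwise_correlation(probe_counts)[0]
        except Exception as exc:  # partial-failure isolation
            out[name] = np.nan
            out[f"{name}_error"] = f"{type(exc).__name__}: {exc}"
    return out


def _mi_counts(net, scenes, cfg: ExperimentConfig, rng) -> np.ndarray:
    """Counts (n_stimuli, n_reps, n_exc) on a fixed repeated stimulus set."""
    stim = []
    for _ in range(cfg.n_mi_stimuli):
        scene = scenes[int(rng.integers(len(scenes)))]
        stim.append(on_off_split(sample_patch(scene, rng), NATURAL_R_MAX))
    counts = np.zeros((cfg.n_mi_stimuli, cfg.n_mi_reps, net.config.n_exc))
    for k, rates in enumerate(stim):
        for i in range(cfg.n_mi_reps):
            _, tr = present_stimulus(net, rates, plastic=False, record=False)
            counts[k, i] = tr["spikes_e"].sum(axis=0)
    return counts


def run_experiment(cfg: ExperimentConfig, reference_weights: dict | None = None) -> Path:
    """Train (or load) one network per seed, measure, and write reports.

    Writes ``<outdir>/metrics.csv`` (one row per seed) and
    ``<outdir>/summary.csv`` (mean ± sd per metric), both stamped with the
    config hash, plus the resolved config itself.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    chash = cfg.config_hash()

    rows = []
    for seed in cfg.seeds:
        if cfg.checkpoint:
            net = load_checkpoint(cfg.checkpoint)
            scenes = generate_scene_set(
                cfg.n_scenes, np.random.default_rng(seed + 7_000_000), size=cfg.scene_size
            )
        else:
            net_cfg = NetworkConfig(
                variant=cfg.variant, seed=seed, scale_factor=cfg.scale_factor,
                n_stimuli=cfg.n_stimuli,
            )
            net = build_network(net_cfg, reference_weights=reference_weights)
            scenes = generate_scene_set(
                cfg.n_scenes, np.random.default_rng(seed + 7_000_000), size=cfg.scene_size
            )
            if cfg.n_stimuli > 0:
                train(net, scenes, n_stimuli=cfg.n_stimuli, log_every=cfg.log_every)
        rng = np.random.default_rng(seed + 13_000_000)
        row = {"seed": seed, "config_hash": chash, **_run_metrics(net, scenes, cfg, rng)}
        rows.append(row)

    df = pd.DataFrame(rows)
    df.to_csv(outdir / "metrics.csv", index=False)
    aggregate_sweep(df, cfg.metrics).to_csv(outdir / "summary.csv")
    return outdir


def aggregate_sweep(df: pd.DataFrame, metrics: list) -> pd.DataFrame:
    """Mean ± sd per metric across the seed sweep."""
    present = [m for m in metrics if m in df.columns]
    agg = df[present].agg(["mean", "std", "count"]).T
    agg.index.name = "metric"
    return agg
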