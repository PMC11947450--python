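"""File contracts, run configuration and the end-to-end analysis driver.

Tables travel as CSV with a fixed header contract, fits and configs as JSON,
movies and response grids as HDF5 named datasets.  Every run writes a
manifest holding the package version, the configuration hash, input hashes
and per-stage timing, so deterministic stages can be verified to reproduce
identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import IntegrityError, SchemaError
from .neural import (TRIAL_TABLE_COLUMNS, modulation_index, responsive_test,
                     shuffle_null_classification)
from .stimulus import CloudMovie, CloudSpec
from .synthetic import generate_population, generate_recording

__all__ = [
    "load_trial_table",
    "save_trial_table",
    "save_movie",
    "load_movie",
    "RunConfig",
    "RunManifest",
    "run_protocol_analysis",
    "sha256_file",
]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Requires the documented header, finite values, and unique
    (neuron, condition, trial) keys.
    """
    table = pd.read_csv(path)
    for col in TRIAL_TABLE_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"trial table is missing required column {col!r}")
    for col in ("baseline_value", "stim_value"):
        vals = table[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.isfinite(vals)):
            raise SchemaError(f"column {col!r} contains non-numeric or non-finite values")
    keys = table[["neuron_id", "condition_id", "trial_index"]]
    if keys.duplicated().any():
        raise IntegrityError("duplicate (neuron, condition, trial) keys in trial table")
    return table


def save_trial_table(table: pd.DataFrame, path) -> None:
    for col in TRIAL_TABLE_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"trial table is missing required column {col!r}")
    table.to_csv(path, index=False)


def save_movie(movie: CloudMovie, path) -> None:
    """Write frames + geometry + spec JSON to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=movie.frames, compression="gzip")
        fh.attrs["deg_per_px"] = movie.deg_per_px
        fh.attrs["rendering_id"] = movie.rendering_id
        fh.attrs["spec_json"] = movie.spec.to_json()


def load_movie(path) -> CloudMovie:
    import h5py

    with h5py.File(path, "r") as fh:
        frames = fh["frames"][...]
        spec = CloudSpec.from_json(fh.attrs["spec_json"])
        return CloudMovie(frames=frames, deg_per_px=float(fh.attrs["deg_per_px"]),
                          spec=spec, rendering_id=int(fh.attrs["rendering_id"]))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one synthetic protocol analysis run."""

    protocol: str = "ori-bandwidth"
    n_neurons: int = 200
    n_trials: int = 20
    suppression_regime: str = "narrow-specific"
    noise_sigma: float = 0.02
    seed: int = 0
    alpha: float = 0.05
    n_planned_comparisons: int = 2
    n_shuffles: int = 1000
    classify_selectivity: bool = False
    input_hashes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise SchemaError("alpha must be > 0")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    version: str
    config_hash: str
    input_hashes: dict
    output_hashes: dict
    stage_seconds: dict
    warnings: tuple = ()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_protocol_analysis(config: RunConfig, out_dir) -> RunManifest:
    """synth -> analyze on synthetic data; writes tables, results and manifest.

    Stages: generate a ground-truth population and trial table, test
    responsiveness per (neuron, condition), count responsive neurons per
    condition, compute broad-vs-narrow modulation indices, optionally run
    the shuffle-null bandwidth-selectivity classification.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path, expected in config.input_hashes.items():
        actual = sha256_file(path)
        if actual != expected:
            raise IntegrityError(f"input {path} hash mismatch: {actual} != {expected}")

    timing: dict = {}
    t0 = time.perf_counter()
    population = generate_population(
        config.n_neurons, seed=config.seed,
        suppression_regime=config.suppression_regime, noise_sigma=config.noise_sigma,
    )
    dataset = generate_recording(population, protocol=config.protocol,
                                 n_trials=config.n_trials, seed=config.seed + 1)
    timing["synth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    trials_path = out / "trials.csv"
    save_trial_table(dataset.trial_table, trials_path)
    table = dataset.trial_table
    conditions = [c.name for c in dataset.conditions]
    counts = {c: 0 for c in conditions}
    amplitudes: dict = {c: {} for c in conditions}
    responsive: dict = {c: {} for c in conditions}
    for (nid, cond), grp in table.groupby(["neuron_id", "condition_id"]):
        p, flag = responsive_test(grp["stim_value"], grp["baseline_value"], config.alpha)
        responsive[cond][nid] = flag
        amplitudes[cond][nid] = float(np.median(
            grp["stim_value"].to_numpy() - grp["baseline_value"].to_numpy()))
        if flag:
            counts[cond] += 1

    results: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "bonferroni_alpha": config.alpha / config.n_planned_comparisons,
        "n_shuffles": config.n_shuffles,
        "responsive_counts": counts,
    }
    if "narrow" in conditions and "broad" in conditions:
        omis = []
        for nid in sorted(amplitudes["narrow"]):
            rn, rb = amplitudes["narrow"][nid], amplitudes["broad"][nid]
            if rn + rb != 0:
                omis.append(modulation_index(rn, rb))
        results["mean_omi"] = float(np.mean(omis)) if omis else None
        if counts["narrow"] > 0:
            results["recruitment_modulation"] = modulation_index(
                counts["narrow"], counts["broad"])
    if config.classify_selectivity and {"narrow", "mid", "broad"} <= set(conditions):
        classes = []
        for nid, grp in table.groupby("neuron_id"):
            resp = {
                c: (grp[grp["condition_id"] == c]["stim_value"].to_numpy()
                    - grp[grp["condition_id"] == c]["baseline_value"].to_numpy())
                for c in ("narrow", "mid", "broad")
            }
            res = shuffle_null_classification(resp, n_shuffles=config.n_shuffles,
                                              seed=config.seed + 2 + int(nid))
            classes.append((nid, res.classification))
        pd.DataFrame(classes, columns=["neuron_id", "classification"]).to_csv(
            out / "selectivity.csv", index=False)
    timing["analyze"] = time.perf_counter() - t0

    results_path = out / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)

    outputs = {p.name: sha256_file(p) for p in sorted(out.glob("*.csv"))}
    outputs["results.json"] = sha256_file(results_path)
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(),
        input_hashes=dict(config.input_hashes), output_hashes=outputs,
        stage_seconds=timing,
    )
    manifest.save(out / "manifest.json")
    return manifest
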