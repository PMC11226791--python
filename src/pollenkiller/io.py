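"""Config parsing and tabular output for model runs."""

from __future__ import annotations

from pathlib import Path
from typing import Any, TextIO

import numpy as np
import pandas as pd
import yaml

from .model import (
    GENOTYPE_NAMES,
    HAPLOTYPES,
    ModelParams,
    StopRule,
    genotype_frequencies_from_haplotype_homozygotes,
    haplotype_frequencies,
)

__all__ = ["RunConfig", "load_run_config", "trajectory_frame", "write_trajectory"]


class RunConfig:
    """A parsed trajectory-run configuration: parameters, start state, stop rule."""

    def __init__(self, params: ModelParams, theta0: np.ndarray, stop: StopRule):
        self.params = params
        self.theta0 = theta0
        self.stop = stop


def load_run_config(source: str | Path | TextIO | dict[str, Any]) -> RunConfig:
    """Read a YAML run configuration.

    Recognized keys: ``r``, ``s``, ``k``, ``R`` (model parameters);
    ``init_freqs`` — either a mapping of genotype names (``"Ab|Ab": 0.1``)
    to frequencies or of haplotype names (``"Ab": 0.1``) to homozygote
    frequencies; ``stop_mode`` ("absolute" or "relative_1pct"),
    ``stop_threshold`` and ``max_generations``.
    """
    if isinstance(source, dict):
        cfg = source
    elif isinstance(source, (str, Path)) and Path(source).exists():
        cfg = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        cfg = yaml.safe_load(source)
    else:
        cfg = yaml.safe_load(source)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")

    params = ModelParams(
        r=float(cfg.get("r", 0.0)),
        s=float(cfg.get("s", 0.0)),
        k=float(cfg.get("k", 1.0)),
        R=float(cfg.get("R", 10.0)),
    )
    init = cfg.get("init_freqs")
    if init is None:
        raise ValueError("config must provide init_freqs")
    if any("|" in key for key in init):
        theta0 = np.zeros(len(GENOTYPE_NAMES))
        for name, val in init.items():
            theta0[GENOTYPE_NAMES.index(name)] = float(val)
        if abs(theta0.sum() - 1.0) > 1e-9:
            raise ValueError("init_freqs must sum to 1")
    else:
        theta0 = genotype_frequencies_from_haplotype_homozygotes(
            {name: float(val) for name, val in init.items()}
        )
    stop = StopRule(
        mode=cfg.get("stop_mode", "absolute"),
        threshold=float(cfg.get("stop_threshold", 1e-3)),
        max_generations=int(cfg.get("max_generations", 10_000)),
    )
    return RunConfig(params, theta0, stop)


def trajectory_frame(trajectory: np.ndarray) -> pd.DataFrame:
    """Trajectory as a table: generation, 4 haplotype and 10 genotype frequencies."""
    traj = np.asarray(trajectory, dtype=float)
    haps = np.array([haplotype_frequencies(t) for t in traj])
    df = pd.DataFrame(
        np.column_stack([np.arange(len(traj)), haps, traj]),
        columns=["generation", *HAPLOTYPES, *GENOTYPE_NAMES],
    )
    df["generation"] = df["generation"].astype(int)
    return df


def write_trajectory(trajectory: np.ndarray, path: str | Path | TextIO) -> None:
    """Write a trajectory as TSV with 12 significant digits."""
    trajectory_frame(trajectory).to_csv(path, sep="\t", index=False, float_format="%.12g")
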