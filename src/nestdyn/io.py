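"""Readers, writers, configuration, and provenance for the pipeline.

CSV with a header row is the canonical interchange format: interaction
event logs, expression tables (three files: matrix, gene annotations,
individual annotations), densities (two columns: r, f), and long-format
trajectories.  Frame stacks are multi-page TIFF or directories of
grayscale PNG.  Every run can write a provenance record (config + seed +
package version) next to its outputs.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .meanfield import PopulationDensity
from .observables import ExpressionTable, validate_event_log

__all__ = [
    "read_event_log", "write_event_log",
    "read_expression", "write_expression",
    "read_density", "write_density",
    "write_trajectory",
    "read_frames", "write_frames",
    "load_config", "write_provenance",
]


def write_event_log(log: pd.DataFrame, path) -> None:
    validate_event_log(log).to_csv(path, index=False)


def read_event_log(path) -> pd.DataFrame:
    log = pd.read_csv(path)
    return validate_event_log(log)


def write_expression(table: ExpressionTable, directory) -> None:
    """Write matrix.csv, genes.csv, individuals.csv under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(d / "matrix.csv")
    table.genes.to_csv(d / "genes.csv")
    table.individuals.to_csv(d / "individuals.csv")


def read_expression(directory) -> ExpressionTable:
    d = Path(directory)
    values = pd.read_csv(d / "matrix.csv", index_col=0)
    genes = pd.read_csv(d / "genes.csv", index_col=0)
    genes["queen_gene"] = genes["queen_gene"].astype(bool)
    individuals = pd.read_csv(d / "individuals.csv", index_col=0)
    return ExpressionTable(values=values, genes=genes, individuals=individuals)


def write_density(density: PopulationDensity, path) -> None:
    density.to_frame().to_csv(path, index=False)


def read_density(path, r_max: float | None = None) -> PopulationDensity:
    df = pd.read_csv(path)
    c = df["r"].to_numpy()
    f = df["f"].to_numpy()
    # reconstruct edges from centers (uniform grid assumed)
    dx = np.diff(c)
    if not np.allclose(dx, dx[0]):
        raise ValueError("density grid must be uniform")
    edges = np.concatenate([[c[0] - dx[0] / 2], c + dx[0] / 2])
    return PopulationDensity(edges=edges, f=f)


def write_trajectory(traj, directory) -> None:
    """Write states.csv (long format) and events.csv for a NestTrajectory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(d / "states.csv", index=False)
    traj.events_frame().to_csv(d / "events.csv", index=False)


def write_frames(frames: np.ndarray, path) -> None:
    """Write a frame stack as multi-page TIFF (or PNGs if path is a dir)."""
    import tifffile

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames)
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(frames):
            iio.imwrite(path / f"frame{k:04d}.png", frame)


def read_frames(path) -> np.ndarray:
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"no PNG frames under {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        import tifffile

        frames = tifffile.imread(path)
    if frames.ndim != 3:
        raise ValueError("expected a grayscale frame stack")
    return frames


def load_config(path, allowed_keys=None) -> dict:
    """YAML config loader; rejects unknown keys when a schema is given."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def write_provenance(directory, command: str, config: dict, seed) -> None:
    from . import __version__

    record = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "written": datetime.now(timezone.utc).isoformat(),
    }
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)
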