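"""File formats and session bundles.

Everything is plain text: CSV streams (RFC-4180, header row, '.' decimal,
UTF-8), JSON results and manifests, YAML/JSON configuration, PNG image
sequences with a JSON frame index. Readers validate column contracts and
report the first offending line; writers are lossless for round-trips.

A session bundle is a directory of pipeline artifacts plus ``manifest.json``
recording, per artifact, its sha256, the checksum of the producing
configuration and the seed — so mixed-provenance bundles are detectable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .baseplate import READ_COLUMNS
from .config import RunConfig, config_checksum

GROUND_TRUTH_COLUMNS = ["time_s", "animal_id", "x_cm", "y_cm", "posture",
                        "tag_height_cm", "tag_axis_x", "tag_axis_y", "tag_axis_z",
                        "temp_c"]
TRACK_COLUMNS = ["time_s", "animal_id", "antenna", "raw_antenna", "x_cm", "y_cm", "source"]
BIN_COLUMNS = ["window_start_s", "window_end_s", "animal_id", "n_transitions",
               "distance_cm", "mean_temp_c", "n_temp_reads", "phase"]


class FormatError(ValueError):
    """Malformed stream file; message carries the file and line number."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def _first_bad_line(mask: np.ndarray) -> int:
    # +2: one for the header line, one for 1-based numbering
    return int(np.flatnonzero(mask)[0]) + 2


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_reads(path: str | Path, n_antennae: int = 12) -> pd.DataFrame:
    """Read and validate a read-stream CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    _require_columns(df, READ_COLUMNS, path)
    if len(df) == 0:
        return df
    ant = df["antenna"].to_numpy()
    bad = (ant < 0) | (ant >= n_antennae)
    if bad.any():
        raise FormatError(
            f"{path}, line {_first_bad_line(bad)}: antenna {ant[bad.argmax()]} "
            f"outside 0..{n_antennae - 1}")
    t = df["time_s"].to_numpy(dtype=float)
    non_mono = np.diff(t) < 0
    if non_mono.any():
        raise FormatError(
            f"{path}, line {_first_bad_line(np.concatenate([[False], non_mono]))}: "
            "non-monotone timestamps")
    return df


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, GROUND_TRUTH_COLUMNS, path)
    for aid, sub in df.groupby("animal_id"):
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise FormatError(f"{path}: non-monotone timestamps for {aid}")
    return df


def read_tracks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, path)
    return df


def read_bins(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, BIN_COLUMNS, path)
    return df


def merge_bins(activity: pd.DataFrame, temperature: pd.DataFrame) -> pd.DataFrame:
    """Join activity and temperature windows into the single bins table."""
    temp = temperature.rename(columns={"n_reads": "n_temp_reads"})
    out = activity.merge(
        temp[["window_start_s", "animal_id", "mean_temp_c", "n_temp_reads"]],
        on=["window_start_s", "animal_id"], how="left")
    out["n_temp_reads"] = out["n_temp_reads"].fillna(0).astype(int)
    return out[BIN_COLUMNS]


# --------------------------------------------------------------------------
# frames

def write_frames(frames: np.ndarray, fps: float, directory: str | Path,
                 t0_s: float = 0.0) -> Path:
    """PNG image sequence plus an index JSON (frame number -> timestamp)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for i, frame in enumerate(frames):
        name = f"frame_{i:06d}.png"
        iio.imwrite(directory / name, frame)
        index[str(i)] = t0_s + i / fps
    (directory / "index.json").write_text(json.dumps(index, indent=0) + "\n")
    return directory


def read_frames(directory: str | Path) -> tuple[np.ndarray, dict]:
    import imageio.v3 as iio

    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    frames = [iio.imread(directory / f"frame_{int(i):06d}.png")
              for i in sorted(index, key=int)]
    return np.stack(frames), index


# --------------------------------------------------------------------------
# session bundles

MANIFEST_NAME = "manifest.json"


def file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dir_sha256(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(file_sha256(f).encode())
    return h.hexdigest()


class SessionBundle:
    """Artifact directory + manifest for one simulated cage session."""

    def __init__(self, directory: str | Path):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)

    @property
    def manifest_path(self) -> Path:
        return self.dir / MANIFEST_NAME

    def manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {"artifacts": {}}

    def record(self, name: str, cfg: RunConfig, seed: int) -> None:
        path = self.dir / name
        checksum = _dir_sha256(path) if path.is_dir() else file_sha256(path)
        man = self.manifest()
        man["artifacts"][name] = {
            "sha256": checksum,
            "config_checksum": config_checksum(cfg),
            "seed": seed,
        }
        self.manifest_path.write_text(json.dumps(man, indent=2, sort_keys=True) + "\n")

    def require(self, name: str, produced_by: str) -> Path:
        path = self.dir / name
        if not path.exists():
            raise FileNotFoundError(
                f"missing artifact {name!r}: run the {produced_by!r} step first")
        return path

    def config_checksums(self) -> set[str]:
        return {a["config_checksum"] for a in self.manifest()["artifacts"].values()}

    def verify(self) -> None:
        """Check stored checksums match files and provenance is uniform."""
        man = self.manifest()
        for name, meta in man["artifacts"].items():
            path = self.dir / name
            if not path.exists():
                raise FileNotFoundError(f"manifest lists missing artifact {name!r}")
            actual = _dir_sha256(path) if path.is_dir() else file_sha256(path)
            if actual != meta["sha256"]:
                raise ValueError(f"artifact {name!r} does not match its manifest checksum")
        if len(self.config_checksums()) > 1:
            raise ValueError("bundle mixes artifacts from different configurations")
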