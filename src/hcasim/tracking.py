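"""From raw tag reads to per-animal tracks and windowed activity/temperature.

The reader snaps positions to antenna centroids, so a stationary animal near
a cell boundary can "flicker" between two antennae. The flicker filter
accepts an antenna change only when the immediately following read confirms
it on the same new antenna (2-consecutive rule; a majority-of-3 variant is
available); unconfirmed one-read excursions are replaced by the held
antenna. Filtering is idempotent, never reorders time, and raw reads are
retained (samples carry a provenance ``source`` flag), so the raw stream is
recoverable from a Track.

Tracks live on the scan-cycle grid: cycles with a read carry the assigned
centroid (source ``read``, or ``filtered`` when the filter overrode the raw
antenna); read gaps up to ``max_gap_s`` are filled by linear interpolation
(source ``interpolated``); longer gaps stay ``missing``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, AntennaArray, SimConfig
from .cohort import CohortTruth, is_dark

TRACK_SOURCES = ("read", "filtered", "interpolated", "missing")
MISSING = -1

ACTIVITY_COLUMNS = ["window_start_s", "window_end_s", "animal_id",
                    "n_transitions", "distance_cm", "phase"]
TEMP_COLUMNS = ["window_start_s", "window_end_s", "animal_id",
                "mean_temp_c", "n_reads", "phase"]


@dataclass
class Track:
    """Per-animal filtered/interpolated position series on the cycle grid."""

    animal_id: str
    t: np.ndarray          # cycle start times, strictly increasing
    raw_antenna: np.ndarray    # int, MISSING where no read that cycle
    antenna: np.ndarray        # filtered antenna labels
    x: np.ndarray
    y: np.ndarray
    source: np.ndarray     # int codes into TRACK_SOURCES

    def to_frame(self) -> pd.DataFrame:
        src = np.array(TRACK_SOURCES)[self.source]
        return pd.DataFrame({
            "time_s": self.t, "animal_id": self.animal_id,
            "antenna": self.antenna, "raw_antenna": self.raw_antenna,
            "x_cm": self.x, "y_cm": self.y, "source": src,
        })


def assignments_from_reads(reads: pd.DataFrame, animal_id: str, n_cycles: int) -> np.ndarray:
    """Per-cycle antenna assignment for one animal (MISSING where unread)."""
    out = np.full(n_cycles, MISSING, dtype=int)
    sub = reads[reads["tag_id"] == animal_id]
    cyc = sub["cycle"].to_numpy(dtype=int)
    keep = (cyc >= 0) & (cyc < n_cycles)
    out[cyc[keep]] = sub["antenna"].to_numpy(dtype=int)[keep]
    return out


def flicker_filter(assignments: np.ndarray, rule: str = "two_consecutive") -> np.ndarray:
    """Suppress unconfirmed single-read antenna excursions.

    Operates on the chronological non-missing subsequence; missing entries
    are preserved untouched.
    """
    if rule not in ("two_consecutive", "majority_of_3"):
        raise ValueError(f"unknown flicker rule {rule!r}")
    arr = np.asarray(assignments)
    out = arr.copy()
    idx = np.flatnonzero(arr != MISSING)
    if idx.size == 0:
        return out
    vals = arr[idx]
    filt = vals.copy()
    if rule == "two_consecutive":
        held = vals[0]
        for i in range(len(vals)):
            if vals[i] == held:
                filt[i] = held
            elif i + 1 < len(vals) and vals[i + 1] == vals[i]:
                held = vals[i]
                filt[i] = held
            else:
                filt[i] = held
    else:  # majority_of_3: a sample outvoted by equal neighbours is replaced
        for i in range(1, len(vals) - 1):
            if vals[i - 1] == vals[i + 1] and vals[i] != vals[i - 1]:
                filt[i] = vals[i - 1]
    out[idx] = filt
    return out


def interpolate_track(assignments: np.ndarray, raw_assignments: np.ndarray,
                      array: AntennaArray, animal_id: str = "rat1",
                      max_gap_s: float = 5.0) -> Track:
    """Build a Track from filtered per-cycle assignments.

    Read cycles take the assigned antenna centroid; gaps no longer than
    ``max_gap_s`` are filled by linear (x, y) interpolation and flagged
    ``interpolated``; longer gaps (and unbounded ends) stay ``missing``.
    """
    assignments = np.asarray(assignments)
    n = len(assignments)
    cycle_s = array.cycle_duration_s
    t = np.arange(n) * cycle_s
    centroids = array.centroids()
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    source = np.full(n, TRACK_SOURCES.index("missing"), dtype=int)
    antenna = assignments.copy()

    obs = np.flatnonzero(assignments != MISSING)
    if obs.size:
        x[obs] = centroids[assignments[obs], 0]
        y[obs] = centroids[assignments[obs], 1]
        source[obs] = np.where(assignments[obs] == np.asarray(raw_assignments)[obs],
                               TRACK_SOURCES.index("read"),
                               TRACK_SOURCES.index("filtered"))
        holes = np.flatnonzero(assignments == MISSING)
        inner = holes[(holes > obs[0]) & (holes < obs[-1])]
        if inner.size:
            left = obs[np.searchsorted(obs, inner) - 1]
            right = obs[np.searchsorted(obs, inner)]
            ok = (t[right] - t[left]) <= max_gap_s
            fill = inner[ok]
            if fill.size:
                frac = (t[fill] - t[left[ok]]) / (t[right[ok]] - t[left[ok]])
                x[fill] = x[left[ok]] + frac * (x[right[ok]] - x[left[ok]])
                y[fill] = y[left[ok]] + frac * (y[right[ok]] - y[left[ok]])
                source[fill] = TRACK_SOURCES.index("interpolated")
    return Track(animal_id, t, np.asarray(raw_assignments).copy(), antenna, x, y, source)


def tracks_from_reads(reads: pd.DataFrame, array: AntennaArray, duration_s: float,
                      animal_ids: list[str], analysis: Optional[AnalysisConfig] = None
                      ) -> dict[str, Track]:
    """Full read -> filter -> interpolate chain for every animal."""
    analysis = analysis or AnalysisConfig()
    n_cycles = int(duration_s / array.cycle_duration_s)
    out = {}
    for aid in animal_ids:
        raw = assignments_from_reads(reads, aid, n_cycles)
        filt = flicker_filter(raw, analysis.flicker_rule)
        out[aid] = interpolate_track(filt, raw, array, aid, analysis.max_gap_s)
    return out


def tracks_from_truth(truth: CohortTruth, array: AntennaArray) -> dict[str, Track]:
    """Idealized detector: nearest-antenna assignment of the true tag
    position at each cycle time (no noise, no dropout). Useful as a
    measurement-free reference when recovering generator parameters."""
    cycle_s = array.cycle_duration_s
    n_cycles = int(truth.cfg.duration_s / cycle_s)
    t = np.arange(n_cycles) * cycle_s
    centroids = array.centroids()
    out = {}
    for a, aid in enumerate(truth.animal_ids):
        px = np.interp(t, truth.t, truth.tag_x[a])
        py = np.interp(t, truth.t, truth.tag_y[a])
        d2 = (px[:, None] - centroids[None, :, 0]) ** 2 + (py[:, None] - centroids[None, :, 1]) ** 2
        ant = np.argmin(d2, axis=1)
        out[aid] = interpolate_track(ant, ant, array, aid)
    return out


def _phase_labels(starts: np.ndarray, cfg: SimConfig) -> np.ndarray:
    return np.where(is_dark(starts, cfg), "dark", "light")


def count_transitions(track: Track, cfg: SimConfig, bin_size_s: float = 900.0) -> pd.DataFrame:
    """Transitions (filtered antenna changes between consecutive non-missing
    samples) and centroid-to-centroid distance, summed per window."""
    if bin_size_s <= 0:
        raise ValueError("bin_size_s must be positive")
    n_bins = int(np.ceil(cfg.duration_s / bin_size_s))
    starts = np.arange(n_bins) * bin_size_s
    ok = track.source != TRACK_SOURCES.index("missing")
    lab_ok = ok & (track.antenna != MISSING)
    idx = np.flatnonzero(lab_ok)
    trans = np.zeros(n_bins)
    dist = np.zeros(n_bins)
    if idx.size >= 2:
        a = track.antenna[idx]
        tt = track.t[idx]
        changed = a[1:] != a[:-1]
        seg_bin = np.minimum((tt[1:] / bin_size_s).astype(int), n_bins - 1)
        trans = np.bincount(seg_bin, weights=changed.astype(float), minlength=n_bins)
        seg = np.hypot(np.diff(track.x[idx]), np.diff(track.y[idx]))
        dist = np.bincount(seg_bin, weights=seg, minlength=n_bins)
    return pd.DataFrame({
        "window_start_s": starts,
        "window_end_s": starts + bin_size_s,
        "animal_id": track.animal_id,
        "n_transitions": trans.astype(int),
        "distance_cm": dist,
        "phase": _phase_labels(starts, cfg),
    })[ACTIVITY_COLUMNS]


def bin_temperature(reads: pd.DataFrame, cfg: SimConfig, bin_size_s: float = 900.0,
                    min_reads: int = 3) -> pd.DataFrame:
    """Per-animal windowed mean of non-clamped temperature readings;
    windows with fewer than ``min_reads`` readings are reported missing."""
    n_bins = int(np.ceil(cfg.duration_s / bin_size_s))
    starts = np.arange(n_bins) * bin_size_s
    ids = sorted(reads["tag_id"].unique()) if len(reads) else []
    rows = []
    usable = reads[~reads["clamped"].astype(bool)] if len(reads) else reads
    for aid in ids:
        sub = usable[usable["tag_id"] == aid]
        b = np.minimum((sub["time_s"].to_numpy() / bin_size_s).astype(int), n_bins - 1)
        count = np.bincount(b, minlength=n_bins)
        total = np.bincount(b, weights=sub["temp_c"].to_numpy(), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            mean = np.where(count >= min_reads, total / np.maximum(count, 1), np.nan)
        rows.append(pd.DataFrame({
            "window_start_s": starts,
            "window_end_s": starts + bin_size_s,
            "animal_id": aid,
            "mean_temp_c": mean,
            "n_reads": count,
            "phase": _phase_labels(starts, cfg),
        }))
    if not rows:
        return pd.DataFrame(columns=TEMP_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TEMP_COLUMNS]


def activity_bins(tracks: dict[str, Track], cfg: SimConfig,
                  bin_size_s: float = 900.0) -> pd.DataFrame:
    return pd.concat([count_transitions(tr, cfg, bin_size_s) for tr in tracks.values()],
                     ignore_index=True)
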