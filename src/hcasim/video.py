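"""Synthetic side-view video and whole-cage motion analytics.

The renderer projects the cage orthographically along its depth axis onto a
small grayscale frame (default 320 x 180 at 25 fps): a static background
with a tunnel fixture, one filled ellipse per rat whose height roughly
doubles during rearing/climbing (with a small deterministic vertical sway,
since a motion detector only sees change), plus optional additive pixel
noise. Vertical activity is defined exactly as in the hardware system:
any differenced pixel above a horizontal line (8 cm at the far wall)
exceeding an intensity threshold marks a frame as vertical; runs of
vertical frames form episodes which can be attributed to individuals using
the RFID-derived track x-positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CameraConfig
from .cohort import CohortTruth, POSTURES
from .tracking import Track, TRACK_SOURCES

_REARING = POSTURES.index("rearing")
_CLIMBING = POSTURES.index("climbing")

BACKGROUND = 30
TUNNEL = 60
RAT = 160

BODY_LENGTH_CM = 16.0
BODY_HEIGHT_CM = {"walking": 6.0, "resting": 5.0}
REAR_WIDTH_CM = 8.0
REAR_HEIGHT_CM = 11.0       # base of the sway band; top stays above 8 cm
REAR_SWAY_CM = 2.0          # triangle-wave amplitude
REAR_SWAY_STEP_CM = 0.5     # per-frame change: guarantees visible motion
CLIMB_HEIGHT_CM = 12.5


@dataclass
class FrameStream:
    """A rendered grayscale frame stack with its spatial calibration."""

    frames: np.ndarray  # (n_frames, height, width) uint8
    fps: float
    camera: CameraConfig
    t0_s: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_time(self, i: int) -> float:
        return self.t0_s + i / self.fps


@dataclass
class VerticalEpisode:
    start_frame: int
    end_frame: int  # inclusive
    peak_row: int
    animal_id: Optional[str] = None


def _background(cam: CameraConfig) -> np.ndarray:
    bg = np.full((cam.height_px, cam.width_px), BACKGROUND, dtype=np.uint8)
    # tunnel fixture: a block resting on the floor, left of centre
    h = int(6 * cam.px_per_cm)
    w = int(12 * cam.px_per_cm)
    c0 = int(0.18 * cam.width_px)
    bg[cam.floor_row - h:cam.floor_row, c0:c0 + w] = TUNNEL
    return bg


def _draw_ellipse(img: np.ndarray, cx: float, cy: float, a: float, b: float,
                  value: int) -> None:
    from skimage.draw import ellipse

    rr, cc = ellipse(cy, cx, b, a, shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def render_frames(truth: CohortTruth, cam: CameraConfig, t0_s: float = 0.0,
                  duration_s: Optional[float] = None, seed: int = 0,
                  noise: bool = True) -> FrameStream:
    """Render a frame stream from ground truth; deterministic given seed."""
    if duration_s is None:
        duration_s = truth.cfg.duration_s - t0_s
    n_frames = int(round(duration_s * cam.fps))
    rng = np.random.default_rng(seed)
    bg = _background(cam)
    frames = np.empty((n_frames, cam.height_px, cam.width_px), dtype=np.uint8)
    times = t0_s + np.arange(n_frames) / cam.fps

    n_animals = truth.n_animals
    if n_animals and len(truth.t):
        xs = np.stack([np.interp(times, truth.t, truth.x[a]) for a in range(n_animals)])
        post_idx = np.minimum((times / truth.cfg.timestep_s).astype(int),
                              len(truth.t) - 1)
        posts = truth.posture[:, post_idx]
    else:
        xs = np.zeros((0, n_frames))
        posts = np.zeros((0, n_frames), np.int8)

    sway_period = int(round(2 * REAR_SWAY_CM / REAR_SWAY_STEP_CM))  # frames per ramp pair
    for i in range(n_frames):
        img = bg.copy()
        for a in range(n_animals):
            x_px = xs[a, i] * cam.px_per_cm
            p = posts[a, i]
            if p in (_REARING, _CLIMBING):
                base = REAR_HEIGHT_CM if p == _REARING else CLIMB_HEIGHT_CM
                phase = (i + a * 3) % sway_period
                tri = phase if phase < sway_period // 2 else sway_period - phase
                h_cm = base + tri * REAR_SWAY_STEP_CM
                half_h = h_cm / 2 * cam.px_per_cm
                half_w = REAR_WIDTH_CM / 2 * cam.px_per_cm
            else:
                h_cm = BODY_HEIGHT_CM["resting" if POSTURES[p] == "resting" else "walking"]
                half_h = h_cm / 2 * cam.px_per_cm
                half_w = BODY_LENGTH_CM / 2 * cam.px_per_cm
            _draw_ellipse(img, x_px, cam.floor_row - half_h, half_w, half_h, RAT)
        frames[i] = img

    if noise and cam.noise_sd > 0:
        noise_arr = rng.normal(0.0, cam.noise_sd, size=frames.shape)
        frames = np.clip(frames.astype(np.float32) + noise_arr, 0, 255)
        frames = np.round(frames).astype(np.uint8)
    return FrameStream(frames, cam.fps, cam, t0_s)


def pixel_motion(frames: np.ndarray, diff_threshold: float = 10.0) -> pd.DataFrame:
    """Per frame-pair count of changed pixels (|difference| > threshold).

    The count for pair (i-1, i) is indexed to frame i; a single frame
    yields an empty series.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, h, w) stack")
    if frames.shape[0] < 2:
        return pd.DataFrame({"frame": pd.Series(dtype=int),
                             "changed_pixels": pd.Series(dtype=int)})
    d = np.abs(np.diff(frames.astype(np.int16), axis=0))
    counts = (d > diff_threshold).sum(axis=(1, 2))
    return pd.DataFrame({"frame": np.arange(1, frames.shape[0]),
                         "changed_pixels": counts.astype(int)})


def _vertical_mask(frames: np.ndarray, line_row: int, diff_threshold: float) -> np.ndarray:
    """Boolean per-frame flag: any supra-threshold differenced pixel above
    (i.e. at a smaller row index than) ``line_row``. Frame 0 is False."""
    frames = np.asarray(frames)
    n = frames.shape[0]
    mask = np.zeros(n, dtype=bool)
    if n < 2 or line_row <= 0:
        return mask
    d = np.abs(np.diff(frames[:, :line_row, :].astype(np.int16), axis=0))
    mask[1:] = (d > diff_threshold).any(axis=(1, 2))
    return mask


def vertical_activity(frames: np.ndarray, line_row: int, diff_threshold: float = 10.0,
                      min_frames: int = 3) -> list[VerticalEpisode]:
    """Segment vertical-motion frames into episodes.

    Quiet gaps shorter than ``min_frames`` are bridged (they do not split an
    episode); only runs of at least ``min_frames`` vertical frames count.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    frames = np.asarray(frames)
    if line_row < 0 or line_row > frames.shape[1]:
        raise ValueError("line_row outside frame")
    mask = _vertical_mask(frames, line_row, diff_threshold)
    # bridge short gaps
    merged = mask.copy()
    idx = np.flatnonzero(mask)
    for j in range(len(idx) - 1):
        gap = idx[j + 1] - idx[j] - 1
        if 0 < gap < min_frames:
            merged[idx[j]:idx[j + 1]] = True
    episodes: list[VerticalEpisode] = []
    n = len(merged)
    i = 0
    d_above = None
    while i < n:
        if merged[i]:
            j = i
            while j + 1 < n and merged[j + 1]:
                j += 1
            if j - i + 1 >= min_frames:
                if d_above is None:
                    d_above = np.abs(np.diff(frames[:, :line_row, :].astype(np.int16), axis=0))
                seg = d_above[max(i - 1, 0):j] > diff_threshold
                rows = np.flatnonzero(seg.any(axis=(0, 2)))
                peak = int(rows.min()) if rows.size else line_row
                episodes.append(VerticalEpisode(i, j, peak))
            i = j + 1
        else:
            i += 1
    return episodes


def episode_motion_centroid_x(frames: np.ndarray, episode: VerticalEpisode,
                              line_row: int, diff_threshold: float = 10.0) -> Optional[float]:
    """Mean column (px) of supra-threshold above-line pixels at mid-episode."""
    mid = (episode.start_frame + episode.end_frame) // 2
    lo = max(mid - 1, 0)
    frames = np.asarray(frames)
    if mid >= frames.shape[0]:
        return None
    d = np.abs(frames[mid, :line_row, :].astype(np.int16)
               - frames[lo, :line_row, :].astype(np.int16))
    ys, xs = np.nonzero(d > diff_threshold)
    if xs.size == 0:
        return None
    return float(xs.mean())


def assign_episode_identity(episodes: Sequence[VerticalEpisode], tracks: dict[str, Track],
                            frames: np.ndarray, stream: FrameStream, line_row: int,
                            diff_threshold: float = 10.0,
                            max_track_age_s: float = 2.5) -> list[VerticalEpisode]:
    """Attribute each episode to the animal whose track x-position is
    horizontally nearest the episode's motion centroid at mid-episode;
    exact ties or missing positions leave the episode unassigned."""
    cam = stream.camera
    missing_code = TRACK_SOURCES.index("missing")
    out = []
    for ep in episodes:
        cx_px = episode_motion_centroid_x(frames, ep, line_row, diff_threshold)
        assigned = None
        if cx_px is not None:
            t_mid = stream.frame_time((ep.start_frame + ep.end_frame) // 2)
            cx_cm = cx_px / cam.px_per_cm
            dists = {}
            for aid, tr in tracks.items():
                ok = tr.source != missing_code
                if not ok.any():
                    continue
                tt = tr.t[ok]
                k = int(np.clip(np.searchsorted(tt, t_mid), 1, len(tt) - 1)) if len(tt) > 1 else 0
                k = k if abs(tt[k] - t_mid) < abs(tt[k - 1] - t_mid) else k - 1
                if abs(tt[k] - t_mid) > max_track_age_s:
                    continue
                dists[aid] = abs(tr.x[ok][k] - cx_cm)
            if dists:
                best = min(dists.values())
                winners = [aid for aid, d in dists.items() if d == best]
                if len(winners) == 1:
                    assigned = winners[0]
        out.append(VerticalEpisode(ep.start_frame, ep.end_frame, ep.peak_row, assigned))
    return out


def frame_accuracy(labels_auto, labels_manual) -> float:
    """Percent frame-by-frame agreement between two binary label series."""
    a = np.asarray(labels_auto, dtype=bool)
    b = np.asarray(labels_manual, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"label series lengths differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty label series")
    return 100.0 * float((a == b).mean())


def episodes_to_frame(episodes: Sequence[VerticalEpisode]) -> pd.DataFrame:
    return pd.DataFrame([
        {"start_frame": e.start_frame, "end_frame": e.end_frame,
         "peak_row": e.peak_row, "animal_id": e.animal_id or ""}
        for e in episodes
    ], columns=["start_frame", "end_frame", "peak_row", "animal_id"])


def labels_from_episodes(episodes: Sequence[VerticalEpisode], n_frames: int) -> np.ndarray:
    lab = np.zeros(n_frames, dtype=bool)
    for e in episodes:
        lab[e.start_frame:e.end_frame + 1] = True
    return lab
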