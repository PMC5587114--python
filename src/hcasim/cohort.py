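"""Ground-truth cohort generator.

Simulates group-housed rats on the cage floor as bounded correlated random
walks whose step rate is modulated by circadian phase (piecewise-constant
light/dark intensity), a two-state rest/active semi-Markov process, and
injectable husbandry perturbations. Each animal additionally carries a
subcutaneous tag whose height/orientation follow an implant-site preset and
the current posture, and a subcutaneous temperature with a dark-phase
elevation plus slow AR(1) noise.

Perturbations act on the generator *schedule*: they transform the
per-timestep activity multiplier and temperature offset timelines before any
path is sampled, and are the identity outside their window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import (
    IMPLANT_SITES,
    ConfigError,
    PerturbationEvent,
    SimConfig,
    calibration_constants,
)

POSTURES = ("walking", "resting", "rearing", "climbing")
_POSTURE_CODE = {name: i for i, name in enumerate(POSTURES)}

_DEFAULT_EVENT_DURATION_S = {
    "cage_change": 2700.0,  # activity elevated for ~45 min after a cage change
    "single_housing": 16 * 3600.0,
    "gavage": 600.0,  # brief spike around the dosing procedure
}


def is_dark(t, cfg: SimConfig):
    """Boolean dark-phase indicator; t = 0 is lights-on."""
    tod = np.asarray(t, dtype=float) % cfg.day_length_s
    return tod >= cfg.light_length_s


def circadian_intensity(t, cfg: SimConfig):
    """Step-rate multiplier: 1 in the light phase, the configured
    dark:light ratio in the dark phase (piecewise constant)."""
    dark = is_dark(t, cfg)
    out = np.where(dark, cfg.dark_light_activity_ratio, 1.0)
    return out if out.shape else float(out)


_SITES = calibration_constants()["sites"]


def tag_pose_for_site(site: str, posture: str):
    """Preset tag geometry for an implant site and posture.

    Returns ``(height_cm, axis, lateral_offset_cm)`` where ``axis`` is the
    canonical unit tag axis for an animal heading along +x (the simulator
    rotates it by heading and adds pitch wobble). Heights are calibration
    constants chosen so simulated read rates reproduce the in vivo site
    ordering; they are not measured anatomy.
    """
    if site not in IMPLANT_SITES:
        raise ConfigError(f"unknown implant site {site!r}; expected one of {IMPLANT_SITES}")
    if posture not in POSTURES:
        raise ConfigError(f"unknown posture {posture!r}; expected one of {POSTURES}")
    preset = _SITES[site]
    height = float(preset["height_cm"][posture])
    tilt = np.deg2rad(preset["rear_tilt_deg"]) if posture in ("rearing", "climbing") else 0.0
    if preset["orientation"] == "vertical":
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = np.array([np.cos(tilt), 0.0, np.sin(tilt)])
    return height, axis, float(preset["lateral_offset_cm"])


@dataclass
class RateTimeline:
    """Per-timestep generator schedule: activity multiplier and temperature
    offset. Perturbations edit this; the movement sampler consumes it."""

    t: np.ndarray
    activity_multiplier: np.ndarray
    temp_offset_c: np.ndarray

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "RateTimeline":
        n = int(round(cfg.duration_s / cfg.timestep_s))
        t = np.arange(n) * cfg.timestep_s
        return cls(t, np.ones(n), np.zeros(n))

    def copy(self) -> "RateTimeline":
        return RateTimeline(self.t, self.activity_multiplier.copy(), self.temp_offset_c.copy())


def apply_perturbation(timeline: RateTimeline, event: PerturbationEvent) -> RateTimeline:
    """Fold one perturbation into the schedule; identity outside its window.

    cage_change / gavage multiply the step rate by ``magnitude`` for the
    event duration; single_housing subtracts ``magnitude`` degC from the
    true temperature for the event duration.
    """
    duration = event.duration_s
    t_end = timeline.t[-1] + (timeline.t[1] - timeline.t[0]) if len(timeline.t) > 1 else 0.0
    if len(timeline.t) and event.t0_s >= t_end:
        raise ConfigError(
            f"event {event.kind} at t0={event.t0_s}s starts beyond the session end ({t_end}s)"
        )
    out = timeline.copy()
    window = (out.t >= event.t0_s) & (out.t < event.t0_s + duration)
    mag = event.effective_magnitude()
    if event.kind in ("cage_change", "gavage"):
        out.activity_multiplier[window] *= mag
    elif event.kind == "single_housing":
        out.temp_offset_c[window] -= mag
    else:  # pragma: no cover - pydantic forbids this
        raise ConfigError(f"unknown perturbation kind {event.kind!r}")
    return out


def default_event(kind: str, t0_s: float, duration_s: float | None = None,
                  magnitude: float | None = None) -> PerturbationEvent:
    """Convenience constructor with per-kind default durations."""
    if duration_s is None:
        if kind not in _DEFAULT_EVENT_DURATION_S:
            raise ConfigError(f"unknown perturbation kind {kind!r}")
        duration_s = _DEFAULT_EVENT_DURATION_S[kind]
    return PerturbationEvent(kind=kind, t0_s=t0_s, duration_s=duration_s, magnitude=magnitude)


@dataclass
class CohortTruth:
    """Ground-truth state series for one cage.

    Arrays are (n_animals, n_samples) float32 unless noted; ``axis`` is
    (n_animals, n_samples, 3). ``posture`` uses codes indexing POSTURES.
    """

    cfg: SimConfig
    t: np.ndarray  # (n_samples,) float64 seconds
    x: np.ndarray
    y: np.ndarray
    tag_x: np.ndarray
    tag_y: np.ndarray
    tag_height: np.ndarray
    axis: np.ndarray
    temp: np.ndarray
    posture: np.ndarray  # int8
    step: np.ndarray  # bool, True where a step was taken
    events: list[PerturbationEvent] = field(default_factory=list)

    @property
    def n_animals(self) -> int:
        return self.x.shape[0]

    @property
    def animal_ids(self) -> list[str]:
        return [f"rat{i + 1}" for i in range(self.n_animals)]

    @property
    def dark(self) -> np.ndarray:
        return is_dark(self.t, self.cfg)

    def step_counts_by_phase(self):
        """(dark_steps, light_steps) per animal."""
        dark = self.dark
        dark_counts = (self.step & dark).sum(axis=1)
        light_counts = (self.step & ~dark).sum(axis=1)
        return dark_counts, light_counts

    def path_length_per_bin(self, bin_size_s: float) -> np.ndarray:
        """(n_animals, n_bins) true path length (cm) per time bin; segment
        lengths are attributed to the bin of their later endpoint."""
        n_bins = int(np.ceil(self.cfg.duration_s / bin_size_s)) if len(self.t) else 0
        out = np.zeros((self.n_animals, n_bins))
        if len(self.t) < 2:
            return out
        seg_bin = np.minimum((self.t[1:] / bin_size_s).astype(int), max(n_bins - 1, 0))
        for a in range(self.n_animals):
            seg = np.hypot(np.diff(self.x[a].astype(float)), np.diff(self.y[a].astype(float)))
            out[a] = np.bincount(seg_bin, weights=seg, minlength=n_bins)
        return out

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        """Long-format ground-truth table (optionally time-decimated)."""
        sl = slice(None, None, stride)
        frames = []
        for a, aid in enumerate(self.animal_ids):
            frames.append(pd.DataFrame({
                "time_s": self.t[sl],
                "animal_id": aid,
                "x_cm": self.x[a, sl].astype(float),
                "y_cm": self.y[a, sl].astype(float),
                "posture": np.array(POSTURES)[self.posture[a, sl]],
                "tag_height_cm": self.tag_height[a, sl].astype(float),
                "tag_axis_x": self.axis[a, sl, 0].astype(float),
                "tag_axis_y": self.axis[a, sl, 1].astype(float),
                "tag_axis_z": self.axis[a, sl, 2].astype(float),
                "temp_c": self.temp[a, sl].astype(float),
            }))
        return pd.concat(frames, ignore_index=True)

    def event_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"kind": e.kind, "t0_s": e.t0_s, "duration_s": e.duration_s,
             "magnitude": e.effective_magnitude()} for e in self.events
        ], columns=["kind", "t0_s", "duration_s", "magnitude"])


def _fold(raw: np.ndarray, limit: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [0, limit] (billiard fold)."""
    m = np.mod(raw, 2.0 * limit)
    return np.where(m > limit, 2.0 * limit - m, m)


def _rest_state(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """True where resting; alternating exponential bouts, phase-aware means."""
    resting = np.zeros(n, dtype=bool)
    dt = cfg.timestep_s
    pos = 0.0
    idx = 0
    state_rest = rng.random() < 0.5
    total = n * dt
    while pos < total:
        dark = bool(is_dark(pos, cfg))
        rest_mean, active_mean = cfg.rest_bout_params.means_for_phase(dark)
        mean = rest_mean if state_rest else active_mean
        bout = rng.exponential(mean)
        j = min(n, int(round((pos + bout) / dt)))
        if state_rest:
            resting[idx:j] = True
        idx = j
        pos += bout
        state_rest = not state_rest
    return resting


def _poisson_events(n: int, cfg: SimConfig, rate_light_h: float, rate_dark_h: float,
                    duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of phase-inhomogeneous Poisson events (thinning)."""
    mask = np.zeros(n, dtype=bool)
    rate_max = max(rate_light_h, rate_dark_h)
    if rate_max <= 0 or n == 0:
        return mask
    total = n * cfg.timestep_s
    n_ev = rng.poisson(rate_max * total / 3600.0)
    times = np.sort(rng.uniform(0, total, n_ev))
    dark = is_dark(times, cfg)
    rates = np.where(dark, rate_dark_h, rate_light_h)
    keep = rng.random(n_ev) < rates / rate_max
    width = max(1, int(round(duration_s / cfg.timestep_s)))
    for t0 in times[keep]:
        i = int(t0 / cfg.timestep_s)
        mask[i:i + width] = True
    return mask


def _ar1(n: int, sd: float, tau_s: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    phi = float(np.exp(-dt / tau_s))
    w = rng.standard_normal(n) * sd * np.sqrt(1.0 - phi * phi)
    w[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -phi], w)


def simulate_cohort(cfg: SimConfig, events: Sequence[PerturbationEvent] = ()) -> CohortTruth:
    """Simulate the full cohort; identical config + seed => identical output."""
    n = int(round(cfg.duration_s / cfg.timestep_s))
    dt = cfg.timestep_s
    timeline = RateTimeline.from_config(cfg)
    for ev in events:
        timeline = apply_perturbation(timeline, ev)
    t = timeline.t

    shape = (cfg.n_animals, n)
    x = np.zeros(shape, np.float32)
    y = np.zeros(shape, np.float32)
    tag_x = np.zeros(shape, np.float32)
    tag_y = np.zeros(shape, np.float32)
    tag_h = np.zeros(shape, np.float32)
    axis = np.zeros(shape + (3,), np.float32)
    temp = np.zeros(shape, np.float32)
    posture = np.zeros(shape, np.int8)
    step = np.zeros(shape, bool)

    if n == 0:
        return CohortTruth(cfg, t, x, y, tag_x, tag_y, tag_h, axis, temp,
                           posture, step, list(events))

    dark = is_dark(t, cfg)
    intensity = np.where(dark, cfg.dark_light_activity_ratio, 1.0)
    p_base = np.clip(cfg.base_step_rate_hz * intensity * timeline.activity_multiplier * dt, 0, 1)

    site = _SITES[cfg.implant_site]
    heights = np.array([site["height_cm"][p] for p in POSTURES], np.float32)
    vertical_axis = site["orientation"] == "vertical"
    rear_tilt = np.deg2rad(site["rear_tilt_deg"])
    offset = float(site["lateral_offset_cm"])

    root = np.random.SeedSequence(cfg.seed)
    for a, ss in enumerate(root.spawn(cfg.n_animals)):
        rng = np.random.default_rng(ss)
        resting = _rest_state(n, cfg, rng)
        stepped = rng.random(n) < p_base
        stepped &= ~resting
        rearing = _poisson_events(n, cfg, cfg.vertical_events.rearing_per_h_light,
                                  cfg.vertical_events.rearing_per_h_dark,
                                  cfg.vertical_events.rearing_duration_s, rng)
        climbing = _poisson_events(n, cfg, cfg.vertical_events.climbing_per_h_light,
                                   cfg.vertical_events.climbing_per_h_dark,
                                   cfg.vertical_events.climbing_duration_s, rng)
        post = np.zeros(n, np.int8)
        post[resting] = _POSTURE_CODE["resting"]
        post[rearing] = _POSTURE_CODE["rearing"]
        post[climbing] = _POSTURE_CODE["climbing"]

        dtheta = np.where(stepped, rng.standard_normal(n) * cfg.heading_turn_sd_rad, 0.0)
        theta = rng.uniform(0, 2 * np.pi) + np.cumsum(dtheta)
        lengths = np.where(
            stepped,
            np.abs(rng.standard_normal(n) * cfg.step_length_sd_cm + cfg.step_length_mean_cm),
            0.0,
        )
        xr = rng.uniform(0, cfg.cage_length_cm) + np.cumsum(lengths * np.cos(theta))
        yr = rng.uniform(0, cfg.cage_width_cm) + np.cumsum(lengths * np.sin(theta))
        xa = _fold(xr, cfg.cage_length_cm)
        ya = _fold(yr, cfg.cage_width_cm)

        wobble = _ar1(n, np.deg2rad(cfg.pitch_wobble_sd_deg), cfg.pitch_wobble_tau_s, dt, rng)
        if vertical_axis:
            tilt_from_z = np.abs(wobble)
            ax = np.sin(tilt_from_z) * np.cos(theta)
            ay = np.sin(tilt_from_z) * np.sin(theta)
            az = np.cos(tilt_from_z)
        else:
            pitch = wobble + np.where(post >= _POSTURE_CODE["rearing"], rear_tilt, 0.0)
            ax = np.cos(pitch) * np.cos(theta)
            ay = np.cos(pitch) * np.sin(theta)
            az = np.sin(pitch)

        txa = np.clip(xa + offset * -np.sin(theta), 0, cfg.cage_length_cm)
        tya = np.clip(ya + offset * np.cos(theta), 0, cfg.cage_width_cm)

        base = cfg.temp_baseline_c + cfg.temp_dark_elevation_c * dark + timeline.temp_offset_c
        animal_offset = rng.standard_normal() * cfg.temp_animal_sd_c
        temp_a = base + animal_offset + _ar1(n, cfg.temp_noise_sd_c, cfg.temp_noise_tau_s, dt, rng)

        x[a], y[a] = xa, ya
        tag_x[a], tag_y[a] = txa, tya
        tag_h[a] = heights[post]
        axis[a, :, 0], axis[a, :, 1], axis[a, :, 2] = ax, ay, az
        temp[a] = temp_a
        posture[a] = post
        step[a] = stepped

    return CohortTruth(cfg, t, x, y, tag_x, tag_y, tag_h, axis, temp,
                       posture, step, list(events))
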