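"""Baseplate RFID reader simulation.

The 12 transceiver coils are polled sequentially (75 ms activation inside a
90 ms slot; 1080 ms full cycle). Tag-coil coupling projects the magnetic
field of the active coil - modelled as a single circular current loop,
evaluated exactly via complete elliptic integrals - onto the tag axis:

    strength = field_scale * gain * |B(r) . axis|

The loop (rather than point-dipole) field matters at cage scale: close to
the plate the field is strongest near the winding and falls off steeply
with height, which is what makes low implant sites read so much better; a
point dipole misses this because its horizontal coupling 3hd/|r|^5 peaks
near h = d/2 and is therefore almost height-insensitive over the
anatomically plausible 2-6 cm range. A tag is readable
on an activation when its (noise-scaled) coupling stays above
``read_threshold`` continuously for at least ``min_dwell_ms`` (the charge
time); among readable tags only the strongest is reported, and a tag is
reported at most once per full cycle (on its strongest antenna). Temperature
reads add truncated-uniform error, clamp to the transponder range
(33.0-43.0 degC) and quantize to 0.1 degC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AntennaArray, CouplingModel, ConfigError
from .cohort import CohortTruth

READ_COLUMNS = ["time_s", "cycle", "antenna", "tag_id", "temp_c", "clamped"]


@dataclass(frozen=True)
class TagRead:
    """One successful tag observation on one antenna activation."""

    t: float
    cycle: int
    antenna: int
    tag_id: str
    temp_c: Optional[float] = None
    clamped: bool = False


def max_read_frequency(array: AntennaArray) -> float:
    """Theoretical per-tag read-rate ceiling: one read per full scan cycle."""
    return 1.0 / array.cycle_duration_s


def active_antenna(t: float, array: AntennaArray) -> Optional[int]:
    """Antenna energized at time ``t`` (seconds), or None during settle gaps."""
    if t < 0:
        raise ValueError("t must be >= 0")
    slot_s = array.slot_duration_ms / 1000.0
    within_cycle = t % array.cycle_duration_s
    slot = int(within_cycle // slot_s)
    if within_cycle - slot * slot_s < array.active_duration_ms / 1000.0:
        return array.effective_read_order()[slot]
    return None


def _field_projection(dx, dy, h, ax, ay, az, a):
    """|B . axis| for a horizontal circular loop of radius ``a`` (cm) centred
    at the origin, carrying unit current; exact elliptic-integral form."""
    from scipy.special import ellipe, ellipk

    rho = np.hypot(dx, dy)
    ap = (a + rho) ** 2 + h * h
    alt = (a - rho) ** 2 + h * h
    k = ellipk(4.0 * a * rho / ap)
    e = ellipe(4.0 * a * rho / ap)
    denom = np.sqrt(ap)
    bz = (k + e * (a * a - rho * rho - h * h) / alt) / denom
    safe_rho = np.maximum(rho, 1e-9)
    brho = np.where(rho > 1e-9,
                    (h / (safe_rho * denom)) * (-k + e * (a * a + rho * rho + h * h) / alt),
                    0.0)
    radial = (dx * ax + dy * ay) / safe_rho
    return np.abs(np.where(rho > 1e-9, brho * radial, 0.0) + bz * az)


def coupling(tag_height, tag_axis, lateral_offset, model: CouplingModel,
             antenna_xy: tuple[float, float] = (0.0, 0.0)):
    """Signal strength for a tag ``lateral_offset`` cm along +x from the
    active coil centre at ``tag_height`` cm, with unit axis ``tag_axis``."""
    tag_height = np.asarray(tag_height, dtype=float)
    if np.any(tag_height <= 0):
        raise ValueError("tag_height must be positive")
    ax, ay, az = (float(c) for c in tag_axis)
    dx = np.asarray(lateral_offset, dtype=float)
    proj = _field_projection(dx, np.zeros_like(dx), tag_height, ax, ay, az,
                             model.coil_radius_cm)
    return model.field_scale * model.gain * proj


def _required_run(model: CouplingModel, dt_ms: float) -> int:
    """Contiguous supra-threshold samples needed for a successful charge.

    Readable when run_samples * dt >= min_dwell - dt/2; the half-sample
    guard makes the rule exact at the sweep resolutions used for
    verification while staying faithful at coarse simulation sampling.
    """
    return max(1, int(np.ceil(model.min_dwell_ms / dt_ms - 0.5)))


def _has_run(above: np.ndarray, k: int) -> np.ndarray:
    """Row-wise: any run of >= k consecutive True in (n, m) boolean array."""
    n, m = above.shape
    if k > m:
        return np.zeros(n, dtype=bool)
    out = np.zeros(n, dtype=bool)
    for start in range(m - k + 1):
        out |= above[:, start:start + k].all(axis=1)
    return out


def resolve_reads(poses: dict, antenna_xy: tuple[float, float], model: CouplingModel,
                  times: np.ndarray, noise: Optional[dict] = None) -> Optional[tuple[str, float]]:
    """Resolve one antenna activation given sampled tag poses.

    ``poses`` maps tag_id -> dict with arrays ``x, y, h, axis`` ((n,3))
    sampled at ``times`` (seconds, uniform) inside the activation window;
    ``noise`` optionally maps tag_id -> multiplicative coupling factor for
    this activation. Returns ``(tag_id, mean_strength)`` for the single
    reported tag, or None when no tag achieves the charge dwell.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 1:
        return None
    dt_ms = (times[1] - times[0]) * 1000.0 if len(times) > 1 else model.min_dwell_ms
    k = _required_run(model, dt_ms)
    best: Optional[tuple[str, float]] = None
    for tag_id, p in poses.items():
        h = np.asarray(p["h"], dtype=float)
        dx = np.asarray(p["x"], dtype=float) - antenna_xy[0]
        dy = np.asarray(p["y"], dtype=float) - antenna_xy[1]
        axis = np.asarray(p["axis"], dtype=float).reshape(-1, 3)
        factor = 1.0 if noise is None else float(noise.get(tag_id, 1.0))
        strength = (model.field_scale * model.gain * factor
                    * _field_projection(dx, dy, h, axis[:, 0], axis[:, 1], axis[:, 2],
                                        model.coil_radius_cm))
        above = (strength >= model.read_threshold)[None, :]
        if not _has_run(above, k)[0]:
            continue
        mean_strength = float(strength.mean())
        if best is None or mean_strength > best[1]:
            best = (tag_id, mean_strength)
    return best


def minimum_successful_dwell(model: CouplingModel, dwells_ms: Sequence[float] = tuple(range(10, 151, 10)),
                             height_cm: float = 3.0, dt_ms: float = 1.0) -> Optional[float]:
    """Smallest supra-threshold dwell that yields a read (crossing sweep).

    A vertical-axis tag crosses the active coil centre at constant speed,
    chosen so that its time inside the supra-threshold chord equals each
    candidate dwell; noise is off. Returns the smallest dwell (ms) for
    which :func:`resolve_reads` reports the tag, or None if none succeeds.
    """
    from scipy.optimize import brentq

    def margin(x):
        return float(coupling(height_cm, (0.0, 0.0, 1.0), x, model)) - model.read_threshold

    if margin(0.0) <= 0:
        raise ValueError("tag is below threshold even above the coil centre")
    x_star = brentq(margin, 0.0, 100.0)
    chord_cm = 2.0 * x_star
    active_s = 0.075
    times = np.arange(0.0, active_s, dt_ms / 1000.0)
    entry_t = times[5]  # enter the chord exactly on a sample point
    for dwell in sorted(dwells_ms):
        speed = chord_cm / (dwell / 1000.0)
        x = -x_star + speed * (times - entry_t)
        pose = {"tag": {"x": x, "y": np.zeros_like(x),
                        "h": np.full_like(x, height_cm),
                        "axis": np.tile([0.0, 0.0, 1.0], (len(x), 1))}}
        if resolve_reads(pose, (0.0, 0.0), model, times) is not None:
            return float(dwell)
    return None


def temperature_reading(true_temp: float, model: CouplingModel,
                        rng: np.random.Generator) -> tuple[float, bool]:
    """Transponder temperature read: truncated-uniform error, clamped to the
    recording range and quantized. Returns (reading_degC, clamped_flag)."""
    lo, hi = model.temp_range_c
    raw = float(true_temp) + rng.uniform(-model.temp_accuracy_c, model.temp_accuracy_c)
    clamped = raw < lo or raw > hi
    value = min(max(raw, lo), hi)
    q = model.temp_quantum_c
    return float(np.round(value / q) * q), bool(clamped)


def simulate_readstream(truth: CohortTruth, array: AntennaArray, model: CouplingModel,
                        seed: int, duration_s: Optional[float] = None,
                        chunk_cycles: int = 20000) -> pd.DataFrame:
    """Run the polling schedule over a simulated session.

    Returns a chronologically ordered read-stream table with columns
    ``time_s, cycle, antenna, tag_id, temp_c, clamped``; at most one read
    per antenna activation and per tag per cycle.
    """
    cycle_s = array.cycle_duration_s
    avail = truth.cfg.duration_s
    if duration_s is None:
        duration_s = avail
    if duration_s > avail + 1e-9:
        raise ConfigError(
            f"ground truth covers {avail}s but a {duration_s}s session was requested")
    n_cycles = int(duration_s / cycle_s)
    if n_cycles == 0 or len(truth.t) == 0:
        return pd.DataFrame(columns=READ_COLUMNS).astype(
            {"time_s": float, "cycle": int, "antenna": int, "tag_id": str,
             "temp_c": float, "clamped": bool})

    rng = np.random.default_rng(seed)
    centroids = array.centroids()
    order = np.asarray(array.effective_read_order())
    n_ant = array.n_antennae
    slot_s = array.slot_duration_ms / 1000.0
    active_s = array.active_duration_ms / 1000.0
    n_sub = model.n_dwell_samples
    dt_sub = active_s / n_sub
    k_run = _required_run(model, dt_sub * 1000.0)
    sub_off = (np.arange(n_sub) + 0.5) * dt_sub
    n_animals = truth.n_animals
    ids = truth.animal_ids

    frames = []
    for c0 in range(0, n_cycles, chunk_cycles):
        c1 = min(c0 + chunk_cycles, n_cycles)
        cycles = np.arange(c0, c1)
        act_start = (cycles[:, None] * cycle_s + np.arange(n_ant) * slot_s).ravel()
        n_act = act_start.size
        ant_idx = np.tile(order, c1 - c0)
        cx = centroids[ant_idx, 0][:, None]
        cy = centroids[ant_idx, 1][:, None]
        t_sub = act_start[:, None] + sub_off  # (n_act, n_sub), ascending when raveled

        readable = np.zeros((n_animals, n_act), dtype=bool)
        strength = np.zeros((n_animals, n_act))
        for a in range(n_animals):
            flat = t_sub.ravel()
            px = np.interp(flat, truth.t, truth.tag_x[a]).reshape(t_sub.shape)
            py = np.interp(flat, truth.t, truth.tag_y[a]).reshape(t_sub.shape)
            ph = np.interp(flat, truth.t, truth.tag_height[a]).reshape(t_sub.shape)
            pax = np.interp(flat, truth.t, truth.axis[a, :, 0]).reshape(t_sub.shape)
            pay = np.interp(flat, truth.t, truth.axis[a, :, 1]).reshape(t_sub.shape)
            paz = np.interp(flat, truth.t, truth.axis[a, :, 2]).reshape(t_sub.shape)
            proj = _field_projection(px - cx, py - cy, ph, pax, pay, paz,
                                     model.coil_radius_cm)
            if model.coupling_noise_sd > 0:
                factor = np.exp(model.coupling_noise_sd * rng.standard_normal(n_act))
            else:
                factor = np.ones(n_act)
            s = model.field_scale * model.gain * factor[:, None] * proj
            readable[a] = _has_run(s >= model.read_threshold, k_run)
            strength[a] = s.mean(axis=1)

        # strongest readable tag wins each activation
        masked = np.where(readable, strength, -np.inf)
        winner = np.argmax(masked, axis=0)
        any_readable = readable.any(axis=0)
        winner = np.where(any_readable, winner, -1)

        # one read per tag per cycle: keep its strongest winning activation
        win2 = winner.reshape(-1, n_ant)
        str_by_act = np.take_along_axis(
            strength, np.clip(winner, 0, None)[None, :], axis=0)[0].reshape(-1, n_ant)
        for a in range(n_animals):
            mask = win2 == a
            has = mask.any(axis=1)
            if not has.any():
                continue
            s_mask = np.where(mask, str_by_act, -np.inf)
            best_slot = np.argmax(s_mask, axis=1)
            cyc = cycles[has]
            slot = best_slot[has]
            t_read = cyc * cycle_s + slot * slot_s
            antenna = order[slot]
            true_t = np.interp(t_read, truth.t, truth.temp[a])
            raw = true_t + rng.uniform(-model.temp_accuracy_c, model.temp_accuracy_c,
                                       size=true_t.size)
            lo, hi = model.temp_range_c
            clamped = (raw < lo) | (raw > hi)
            val = np.round(np.clip(raw, lo, hi) / model.temp_quantum_c) * model.temp_quantum_c
            frames.append(pd.DataFrame({
                "time_s": t_read, "cycle": cyc, "antenna": antenna,
                "tag_id": ids[a], "temp_c": val, "clamped": clamped}))

    if not frames:
        return pd.DataFrame(columns=READ_COLUMNS).astype(
            {"time_s": float, "cycle": int, "antenna": int, "tag_id": str,
             "temp_c": float, "clamped": bool})
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["time_s", "antenna"], kind="mergesort").reset_index(drop=True)
    return out[READ_COLUMNS]


def read_rates(reads: pd.DataFrame, duration_s: float, ids: Sequence[str]) -> pd.Series:
    """Mean per-tag read rate (Hz) over a session."""
    counts = reads.groupby("tag_id").size() if len(reads) else pd.Series(dtype=float)
    return pd.Series({i: counts.get(i, 0) / duration_s for i in ids}, dtype=float)
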