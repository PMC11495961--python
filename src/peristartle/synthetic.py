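"""Synthetic courtship-bout generator.

Emulates the statistical structure of pose-tracked courtship recordings
so every downstream stage (cleaning, RD, Δ, bootstrap, exit scoring) is
testable end to end: 30 fps bouts of a few hundred to ~1000 frames, two
status groups of courting males (9 bower owners, 8 subordinates in the
default configuration), 4–32 bouts per male, display elements placed by
a renewal process and split into high-intensity (body ripple / mock
attack, long right-skewed durations of 36.69 ± 35.92 frames) and
low-intensity types, per-frame Gaussian keypoint jitter, rare
single-frame mis-detections, startle displacements of the beak
time-locked to element onsets, and bower exits following high-intensity
elements with a per-status probability.

The receiver is modelled as stationary (a single static pose per bout,
matching the inclusion criterion of the tracking analysis); the startle
is a transient displacement pulse of the beak only.  During a pulse the
beak zig-zags along *x* so that each pulse frame contributes a
frame-to-frame displacement of exactly the configured magnitude — the
injected RD contribution is therefore known in closed form, which is
what makes parameter-recovery oracles possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as ps_io
from .exceptions import ConfigurationError

#: Bouts shorter than this cannot hold one element plus a usable window.
MIN_BOUT_FRAMES = 30

HIGH_ELEMENT_TYPES = ("body_ripple", "mock_attack")
LOW_ELEMENT_TYPES = (
    "body_shudder", "decoration_toss", "wing_flick", "wing_droop", "head_bob",
    "head_tilt", "bowing", "crouch_display", "hop", "run_around", "pivot",
    "tail_flick", "neck_stretch", "bill_wipe", "vocal_display", "freeze", "strut",
)


def _per_status(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {"owner": float(value["owner"]), "subordinate": float(value["subordinate"])}
    return {"owner": float(value), "subordinate": float(value)}


@dataclass
class SimulationConfig:
    """Generator parameters; defaults reproduce the study's structure.

    Magnitudes expressed "in body heights" are fractions of the bird's
    per-bout body height; per-status parameters accept either a single
    number or a ``{"owner": ..., "subordinate": ...}`` mapping.
    """

    n_owners: int = 9
    n_subordinates: int = 8
    bouts_per_male: tuple[int, int] = (4, 32)
    bout_length_frames: tuple[int, int] = (300, 1000)
    fps: float = 30.0
    body_height_px: tuple[float, float] = (100.0, 10.0)  # mean, sd
    jitter_sd: float = 0.01  # body heights per axis per frame
    misdetect_rate: float = 2e-5  # per frame per keypoint
    misdetect_magnitude: tuple[float, float] = (0.15, 0.75)  # body heights
    element_rate: float = 4.0  # elements per 100 frames
    high_fraction: float = 0.4
    high_duration_frames: tuple[float, float] = (36.69, 35.92)  # mean, sd
    low_duration_frames: tuple[float, float] = (8.0, 5.0)
    low_event_fraction: float = 0.5  # share of low elements that are 1-frame events
    min_element_gap: int = 15  # frames between an element's end and the next start
    startle_magnitude: float | Mapping[str, float] = field(
        default_factory=lambda: {"owner": 0.1, "subordinate": 0.0}
    )
    startle_latency_frames: tuple[int, int] = (2, 3)
    startle_duration_frames: int = 3
    startle_probability: float = 0.5
    exit_probability: float | Mapping[str, float] = field(
        default_factory=lambda: {"owner": 0.2, "subordinate": 0.2}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("startle_probability", "high_fraction", "low_event_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.misdetect_rate <= 1.0:
            raise ConfigurationError("misdetect_rate must lie in [0, 1]")
        for name in ("bouts_per_male", "bout_length_frames", "startle_latency_frames",
                     "misdetect_magnitude"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} range ({lo}, {hi}) is empty")
        if self.bout_length_frames[0] < MIN_BOUT_FRAMES:
            raise ConfigurationError(
                f"bouts shorter than {MIN_BOUT_FRAMES} frames cannot hold an "
                "element plus a peri-event window"
            )
        for status, mag in _per_status(self.startle_magnitude).items():
            if mag < 0:
                raise ConfigurationError(f"startle_magnitude[{status}] must be >= 0")
        for status, p in _per_status(self.exit_probability).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"exit_probability[{status}] must lie in [0, 1]")
        if self.element_rate <= 0:
            raise ConfigurationError("element_rate must be positive")
        if self.startle_duration_frames < 1 or self.startle_latency_frames[0] < 1:
            raise ConfigurationError("startle pulse must start and last >= 1 frame")


def _place_elements(config: SimulationConfig, n: int, rng: np.random.Generator):
    """Renewal-process element stream: (start, duration, type, class, kind)."""
    mean_gap = 100.0 / config.element_rate
    exp_scale = max(mean_gap - config.min_element_gap, 1.0)
    elements = []
    t = config.min_element_gap + int(round(rng.exponential(exp_scale)))
    while True:
        if t + 2 > n - 1:
            break
        if rng.random() < config.high_fraction:
            mu, sd = config.high_duration_frames
            dur = int(np.clip(round(rng.normal(mu, sd)), 2, n - 1 - t))
            etype = HIGH_ELEMENT_TYPES[rng.integers(len(HIGH_ELEMENT_TYPES))]
            elements.append((t, dur, etype, "high", "duration"))
        elif rng.random() < config.low_event_fraction:
            etype = LOW_ELEMENT_TYPES[rng.integers(len(LOW_ELEMENT_TYPES))]
            elements.append((t, 1, etype, "low", "event"))
            dur = 1
        else:
            mu, sd = config.low_duration_frames
            dur = int(np.clip(round(rng.normal(mu, sd)), 2, n - 1 - t))
            etype = LOW_ELEMENT_TYPES[rng.integers(len(LOW_ELEMENT_TYPES))]
            elements.append((t, dur, etype, "low", "duration"))
        dur = elements[-1][1]
        t = t + dur + config.min_element_gap + int(round(rng.exponential(exp_scale)))
    return elements


def _zigzag_offsets(pulse: np.ndarray) -> np.ndarray:
    """x-offsets whose frame-to-frame change has magnitude ``pulse[t]``.

    The offset flips direction whenever it is above zero, so it stays
    bounded near the pulse amplitude instead of drifting.
    """
    offsets = np.zeros_like(pulse)
    o = 0.0
    for t, p in enumerate(pulse):
        if p > 0:
            o = o + p if o <= 0 else o - p
        offsets[t] = o
    return offsets


def simulate_bout(
    config: SimulationConfig,
    bout_id: str,
    status: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    """Generate one bout: keypoint track, display events and exits."""
    lo, hi = config.bout_length_frames
    n = int(rng.integers(lo, hi + 1))
    if n < MIN_BOUT_FRAMES:
        raise ConfigurationError(
            f"bout {bout_id!r}: {n} frames is too short for an element plus window"
        )
    height = max(float(rng.normal(*config.body_height_px)), 1.0)
    beak_x = float(rng.uniform(300, 900))
    beak_y = float(rng.uniform(150, 400))
    # Static pose in image coordinates: ITJ below the beak by one body
    # height, feet below the ITJ.
    base = {
        "beak_tip": (beak_x, beak_y),
        "left_itj": (beak_x - 0.15 * height, beak_y + height),
        "right_itj": (beak_x + 0.15 * height, beak_y + height),
        "left_foot": (beak_x - 0.12 * height, beak_y + 1.4 * height),
        "right_foot": (beak_x + 0.12 * height, beak_y + 1.4 * height),
    }

    elements = _place_elements(config, n, rng)

    magnitude = _per_status(config.startle_magnitude)[status] * height
    lat_lo, lat_hi = config.startle_latency_frames
    pulse = np.zeros(n)
    for start, dur, etype, eclass, kind in elements:
        # latency is drawn whenever an element elicits a startle, even at
        # zero magnitude, so RNG streams are comparable across magnitudes
        if rng.random() < config.startle_probability:
            lat = int(rng.integers(lat_lo, lat_hi + 1))
            f0, f1 = start + lat, start + lat + config.startle_duration_frames
            pulse[max(f0, 1): min(f1, n)] += magnitude

    jitter_sd_px = config.jitter_sd * height
    coords: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for keypoint in ps_io.KEYPOINTS:
        bx, by = base[keypoint]
        x = bx + rng.normal(0.0, jitter_sd_px, n) if jitter_sd_px > 0 else np.full(n, bx)
        y = by + rng.normal(0.0, jitter_sd_px, n) if jitter_sd_px > 0 else np.full(n, by)
        coords[keypoint] = (x, y)
    bx, by = coords["beak_tip"]
    coords["beak_tip"] = (bx + _zigzag_offsets(pulse), by)

    if config.misdetect_rate > 0:
        for keypoint in ps_io.KEYPOINTS:
            hits = np.flatnonzero(rng.random(n) < config.misdetect_rate)
            for t in hits:
                angle = rng.uniform(0.0, 2.0 * np.pi)
                mag = rng.uniform(*config.misdetect_magnitude) * height
                x, y = coords[keypoint]
                x[t] += mag * np.cos(angle)
                y[t] += mag * np.sin(angle)

    frames = np.arange(n)
    parts = [
        pd.DataFrame(
            {"bout_id": bout_id, "frame": frames, "keypoint": keypoint,
             "x": coords[keypoint][0], "y": coords[keypoint][1], "valid": True}
        )
        for keypoint in sorted(ps_io.KEYPOINTS)
    ]
    track = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["frame", "keypoint"], kind="stable")
        .reset_index(drop=True)
    )

    event_rows = [
        {"bout_id": bout_id, "element_type": etype, "intensity_class": eclass,
         "kind": kind, "start_frame": start, "duration_frames": dur}
        for start, dur, etype, eclass, kind in elements
    ]

    exit_prob = _per_status(config.exit_probability)[status]
    exit_rows = []
    for start, dur, etype, eclass, kind in elements:
        if eclass == "high" and rng.random() < exit_prob:
            frame = min(start + dur + int(rng.integers(1, 6)), n - 1)
            exit_rows.append({"bout_id": bout_id, "frame": frame})

    return track, event_rows, exit_rows


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> ps_io.Dataset:
    """Generate a full multi-male dataset as a validated :class:`Dataset`.

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs
    produce byte-identical output.
    """
    if config.n_owners + config.n_subordinates <= 0:
        raise ConfigurationError("at least one male is required")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    males = [(f"owner_{i + 1:02d}", "owner") for i in range(config.n_owners)]
    males += [(f"sub_{i + 1:02d}", "subordinate") for i in range(config.n_subordinates)]

    tracks, events, exits, meta = [], [], [], []
    base_date = pd.Timestamp("2018-09-01")
    for male_id, status in males:
        lo, hi = config.bouts_per_male
        n_bouts = int(rng.integers(lo, hi + 1))
        for b in range(n_bouts):
            bout_id = f"{male_id}_b{b + 1:02d}"
            date = (base_date + pd.Timedelta(days=int(rng.integers(0, 90)))).date()
            track, ev, ex = simulate_bout(config, bout_id, status, rng)
            tracks.append(track)
            events.extend(ev)
            exits.extend(ex)
            meta.append({"bout_id": bout_id, "male_id": male_id, "status": status,
                         "date": str(date), "fps": config.fps})

    tracks_df = pd.concat(tracks, ignore_index=True)
    events_df = pd.DataFrame(
        events, columns=["bout_id", "element_type", "intensity_class", "kind",
                         "start_frame", "duration_frames"]
    )
    exits_df = pd.DataFrame(exits, columns=["bout_id", "frame"])
    if exits_df.empty:
        exits_df = exits_df.astype({"bout_id": str, "frame": np.int64})
    meta_df = pd.DataFrame(meta)
    return ps_io.assemble_dataset(tracks_df, meta_df, events_df, exits_df)


def expected_delta_mean(
    config: SimulationConfig, status: str, window_post: int
) -> float:
    """Closed-form expectation of the injected Δ_mean for one element.

    Enumerates the generator's pulse placement directly: for each
    equally likely latency, counts how many pulse frames fall inside the
    post window of ``window_post`` frames, multiplies by the pulse
    amplitude, averages over latencies and scales by the startle
    probability.  The jitter contributes equally to baseline and post in
    expectation, so it cancels from Δ_mean.
    """
    magnitude = _per_status(config.startle_magnitude)[status]
    lat_lo, lat_hi = config.startle_latency_frames
    total = 0.0
    n_lat = lat_hi - lat_lo + 1
    for lat in range(lat_lo, lat_hi + 1):
        frames_in_post = max(
            0, min(lat + config.startle_duration_frames - 1, window_post - 1) - lat + 1
        )
        total += magnitude * frames_in_post / window_post
    return config.startle_probability * total / n_lat
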