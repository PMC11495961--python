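"""Relative displacement and peri-event startle statistics.

The movement signal is *relative displacement* (RD): the frame-to-frame
Euclidean displacement of the beak tip divided by the bird's per-bout
mean body height,

    RD[t] = ||beak[t] − beak[t−1]|| / mean body height,

a dimensionless amplitude of head movement per frame expressed as a
fraction of body size (RD = 0.15 means a head movement of 15% of body
height).  RD is undefined at frame 0 and wherever the beak is invalid in
the frame or its predecessor.

The startle statistic Δ compares RD just after a display element with
RD just before it.  For an element starting at frame *s* with a
baseline of *b* frames and a post window of *w* frames,

    baseline = RD[s−b+1 … s],   post = RD[s … s+w−1]

(the occurrence frame *s* belongs to both segments), and

    Δ_mean = mean(post) − mean(baseline)
    Δ_max  = max(post)  − max(baseline).

Positive Δ indicates a movement increase after the element — a startle;
negative Δ a decrease — freezing.  Under the default strict missing
policy a record is produced only when every frame of both segments lies
inside the bout with RD defined; otherwise the event is skipped with a
logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import BodyMetrics
from .exceptions import DegenerateGeometryError, EmptyGroupError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Peri-event window: ``baseline`` frames before (and including) the
    element start, ``post`` frames from the start onward."""

    baseline: int = 10
    post: int = 10

    def __post_init__(self) -> None:
        if self.baseline < 1 or self.post < 1:
            raise ParameterError("baseline and post window sizes must be >= 1")

    @property
    def span(self) -> int:
        """Total number of distinct frames covered (shared frame counted once)."""
        return self.baseline + self.post - 1


@dataclass(frozen=True)
class MissingPolicy:
    """How to treat undefined RD frames inside a window.

    ``strict`` (default) skips any event whose window contains an
    undefined frame.  ``tolerant`` averages over the defined frames
    provided each segment retains at least ``min_coverage`` of its
    nominal length.
    """

    mode: str = "strict"
    min_coverage: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "tolerant"):
            raise ParameterError(f"unknown missing policy {self.mode!r}")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ParameterError("min_coverage must be in (0, 1]")


STRICT = MissingPolicy("strict")


@dataclass
class RDSeries:
    """Per-bout relative-displacement series.

    ``rd`` holds NaN where the signal is undefined; ``defined`` is the
    matching boolean mask.
    """

    bout_id: str
    rd: np.ndarray
    defined: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.rd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bout_id": self.bout_id, "frame": np.arange(self.n_frames),
             "rd": self.rd, "defined": self.defined}
        )


def window_duration_ms(frames: int, fps: float = 30.0) -> float:
    """Duration of a window of ``frames`` frames in milliseconds."""
    return 1000.0 * frames / fps


def relative_displacement(
    tracks: pd.DataFrame, metrics: BodyMetrics
) -> dict[str, RDSeries]:
    """Compute the RD series for every bout in a track table.

    Raises :class:`DegenerateGeometryError` if a bout's mean body height
    is zero or undefined.
    """
    series: dict[str, RDSeries] = {}
    beak = tracks.loc[tracks["keypoint"] == "beak_tip"]
    for bout_id, group in beak.groupby("bout_id", sort=True):
        height = float(metrics.means.get(bout_id, np.nan))
        if not np.isfinite(height) or height <= 0:
            raise DegenerateGeometryError(
                f"bout {bout_id!r}: mean body height {height} is not positive"
            )
        group = group.sort_values("frame")
        n = int(group["frame"].max()) + 1
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        frames = group["frame"].to_numpy()
        ok = group["valid"].to_numpy(dtype=bool)
        x[frames[ok]] = group["x"].to_numpy()[ok]
        y[frames[ok]] = group["y"].to_numpy()[ok]
        rd = np.full(n, np.nan)
        rd[1:] = np.hypot(np.diff(x), np.diff(y)) / height
        defined = np.isfinite(rd)
        rd[~defined] = np.nan
        series[bout_id] = RDSeries(bout_id=bout_id, rd=rd, defined=defined)
    return series


def _segment_bounds(start: int, window: WindowSpec) -> tuple[int, int, int, int]:
    """(baseline_lo, baseline_hi, post_lo, post_hi) inclusive."""
    return start - window.baseline + 1, start, start, start + window.post - 1


def peri_event_delta(
    rd: RDSeries,
    start_frame: int,
    window: WindowSpec,
    policy: MissingPolicy = STRICT,
) -> tuple[dict | None, str | None]:
    """Δ statistics for one event; ``(record, None)`` or ``(None, reason)``.

    The record dict carries ``delta_mean``, ``delta_max`` and the number
    of defined frames in each segment.
    """
    b_lo, b_hi, p_lo, p_hi = _segment_bounds(start_frame, window)
    if b_lo < 0:
        return None, "incomplete baseline"
    if p_hi >= rd.n_frames:
        return None, "incomplete post"
    base = rd.rd[b_lo : b_hi + 1]
    post = rd.rd[p_lo : p_hi + 1]
    n_base = int(np.isfinite(base).sum())
    n_post = int(np.isfinite(post).sum())
    if policy.mode == "strict":
        if n_base < window.baseline:
            return None, "undefined rd in baseline"
        if n_post < window.post:
            return None, "undefined rd in post"
    else:
        if n_base < policy.min_coverage * window.baseline:
            return None, "insufficient baseline coverage"
        if n_post < policy.min_coverage * window.post:
            return None, "insufficient post coverage"
    record = {
        "start_frame": int(start_frame),
        "delta_mean": float(np.nanmean(post) - np.nanmean(base)),
        "delta_max": float(np.nanmax(post) - np.nanmax(base)),
        "n_baseline_defined": n_base,
        "n_post_defined": n_post,
    }
    return record, None


def peri_event_deltas(
    rd_map: dict[str, RDSeries],
    events: pd.DataFrame,
    metadata: pd.DataFrame,
    window: WindowSpec,
    policy: MissingPolicy = STRICT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Δ records for every display event, joined with male identity.

    Returns ``(records, skipped)``; ``skipped`` lists events dropped
    under the missing policy together with the reason.
    """
    meta = metadata.set_index("bout_id")
    rows, skips = [], []
    for event in events.itertuples():
        rd = rd_map.get(event.bout_id)
        if rd is None:
            skips.append({"bout_id": event.bout_id, "start_frame": event.start_frame,
                          "reason": "no track for bout"})
            continue
        record, reason = peri_event_delta(rd, int(event.start_frame), window, policy)
        if record is None:
            skips.append({"bout_id": event.bout_id, "start_frame": event.start_frame,
                          "reason": reason})
            continue
        record.update(
            bout_id=event.bout_id,
            element_type=event.element_type,
            intensity_class=event.intensity_class,
            male_id=meta.loc[event.bout_id, "male_id"],
            status=meta.loc[event.bout_id, "status"],
            baseline=window.baseline,
            post=window.post,
        )
        rows.append(record)
    columns = ["bout_id", "male_id", "status", "element_type", "intensity_class",
               "start_frame", "baseline", "post", "delta_mean", "delta_max",
               "n_baseline_defined", "n_post_defined"]
    records = pd.DataFrame(rows, columns=columns)
    skipped = pd.DataFrame(skips, columns=["bout_id", "start_frame", "reason"])
    if len(skipped):
        logger.info("peri_event_deltas: skipped %d of %d events", len(skipped),
                    len(events))
    return records, skipped


def delta_at_all_frames(
    rd: RDSeries, window: WindowSpec, statistic: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Δ treating every frame of a bout as a pseudo-event start.

    Returns ``(delta, eligible)`` arrays of length ``n_frames``.  A
    frame is eligible iff its full baseline and post segments lie inside
    the bout with RD defined everywhere (strict policy); ``delta`` is
    NaN elsewhere.  This vectorised profile is the workhorse of the
    bootstrap null, which must evaluate Δ at arbitrary random frames.
    """
    if statistic not in ("mean", "max"):
        raise ParameterError(f"unknown statistic {statistic!r}")
    n = rd.n_frames
    b, w = window.baseline, window.post
    s = pd.Series(rd.rd)
    # rolling(b) at t covers [t-b+1, t]; shift(-(w-1)) realigns a
    # trailing window to the leading segment [t, t+w-1].
    if statistic == "mean":
        base_stat = s.rolling(b, min_periods=b).mean()
        post_stat = s.rolling(w, min_periods=w).mean().shift(-(w - 1))
    else:
        base_stat = s.rolling(b, min_periods=b).max()
        post_stat = s.rolling(w, min_periods=w).max().shift(-(w - 1))
    ok = pd.Series(rd.defined.astype(float))
    base_ok = ok.rolling(b, min_periods=b).sum() == b
    post_ok = (ok.rolling(w, min_periods=w).sum() == w).shift(-(w - 1), fill_value=False)
    eligible = (base_ok & post_ok).to_numpy(dtype=bool)
    eligible[: b - 1] = False
    if w > 1:
        eligible[-(w - 1):] = False
    delta = np.where(eligible, (post_stat - base_stat).to_numpy(), np.nan)
    return delta, eligible


@dataclass
class GroupStatistic:
    """Average-of-individual-averages Δ summary.

    The group-level statistic is the *unweighted* mean of per-male mean
    Δ values, so males contributing many elements do not dominate.
    """

    statistic: str
    individual_means: pd.DataFrame  # male_id, status, mean, n_elements
    group_means: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.group_means = self.individual_means.groupby("status")["mean"].mean()

    def for_status(self, status: str) -> float:
        if status not in self.group_means.index:
            raise EmptyGroupError(f"no individuals with status {status!r}")
        return float(self.group_means[status])


def group_statistic(
    deltas: pd.DataFrame, statistic: str = "delta_mean"
) -> GroupStatistic:
    """Per-individual mean Δ and the unweighted per-status mean of means.

    ``deltas`` must carry ``male_id``, ``status`` and the requested Δ
    column (as produced by :func:`peri_event_deltas`).
    """
    if deltas.empty:
        raise EmptyGroupError("no delta records to summarise")
    per_male = (
        deltas.groupby(["male_id", "status"])[statistic]
        .agg(mean="mean", n_elements="size")
        .reset_index()
    )
    return GroupStatistic(statistic=statistic, individual_means=per_male)
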