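"""Body-size computation and velocity-based track cleaning.

Pose detectors occasionally lock onto a branch or bower decoration
instead of the bird, producing single-frame coordinate jumps far larger
than any plausible movement.  Cleaning normalises frame-to-frame
keypoint displacement by the bird's per-bout mean body height (vertical
beak-to-ITJ extent) and removes records that jump more than a hard
threshold (default 0.5 body heights per frame, i.e. an instantaneous
velocity of one body height per frame).  Displacements between the soft
and hard thresholds (default 0.25–0.5) are plausible but sudden; they
are flagged for inspection and retained.

Displacements are computed once on the raw series (a single filtering
pass): removing a record does not create new candidate jumps between its
former neighbours.  An iterative variant that re-evaluates surviving
neighbours to a fixed point is available via ``iterative=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MissingKeypointError, ParameterError
from .io import ITJ_KEYPOINTS

HARD_THRESHOLD = 0.5
SOFT_THRESHOLD = 0.25


@dataclass
class BodyMetrics:
    """Per-bout body-height series and their means.

    ``per_frame`` has columns ``bout_id, frame, body_height`` (NaN where
    the beak or both ITJs are invalid); ``means`` maps bout_id to the
    mean body height over frames where it is defined.
    """

    per_frame: pd.DataFrame
    means: pd.Series

    def mean_for(self, bout_id: str) -> float:
        return float(self.means[bout_id])


@dataclass
class CleaningReport:
    """Outcome of a :func:`filter_jumps` pass.

    ``records`` lists every displacement above the soft threshold with
    columns ``bout_id, frame, keypoint, displacement_bh, action``
    (action ∈ {removed, flagged}).  Data-loss fractions are reported
    against both plausible denominators — frames, and frame×keypoint
    records — because either convention is defensible.
    """

    hard_threshold: float
    soft_threshold: float
    removed: int
    flagged: int
    records: pd.DataFrame
    n_frames: int
    n_records: int

    @property
    def loss_fraction_frames(self) -> float:
        return self.removed / self.n_frames if self.n_frames else 0.0

    @property
    def loss_fraction_records(self) -> float:
        return self.removed / self.n_records if self.n_records else 0.0

    def summary(self) -> str:
        return (
            f"cleaning: removed {self.removed} (> {self.hard_threshold} body "
            f"heights/frame), flagged {self.flagged} "
            f"({self.soft_threshold}-{self.hard_threshold}]; data loss "
            f"{100 * self.loss_fraction_frames:.4f}% of {self.n_frames} frames, "
            f"{100 * self.loss_fraction_records:.4f}% of {self.n_records} records"
        )


def compute_body_metrics(tracks: pd.DataFrame) -> BodyMetrics:
    """Per-frame and per-bout body height from beak and ITJ positions.

    Body height in a frame is the absolute difference between the beak
    *y* and the mean *y* of the valid ITJ keypoints (mean of both sides
    when both are valid, the valid side otherwise).  The per-bout mean
    is taken over frames where the height is defined.

    Raises
    ------
    MissingKeypointError
        If a bout lacks the beak tip or has no ITJ keypoint at all.
    """
    frames_list = []
    means = {}
    for bout_id, group in tracks.groupby("bout_id", sort=True):
        wide_y = group.pivot_table(index="frame", columns="keypoint", values="y")
        valid = group.pivot_table(
            index="frame", columns="keypoint", values="valid", aggfunc="first"
        ).astype(bool)
        if "beak_tip" not in wide_y.columns:
            raise MissingKeypointError(f"bout {bout_id!r}: no beak_tip keypoint")
        itj_cols = [k for k in ITJ_KEYPOINTS if k in wide_y.columns]
        if not itj_cols:
            raise MissingKeypointError(
                f"bout {bout_id!r}: no inter-tarsal-joint keypoint"
            )
        beak_y = wide_y["beak_tip"].where(valid["beak_tip"])
        itj_y = wide_y[itj_cols].where(valid[itj_cols])
        itj_mean = itj_y.mean(axis=1)  # mean of available/valid sides
        height = (itj_mean - beak_y).abs()
        frames_list.append(
            pd.DataFrame(
                {
                    "bout_id": bout_id,
                    "frame": height.index.to_numpy(),
                    "body_height": height.to_numpy(),
                }
            )
        )
        means[bout_id] = float(height.mean())
    per_frame = pd.concat(frames_list, ignore_index=True)
    return BodyMetrics(per_frame=per_frame, means=pd.Series(means, name="body_height_mean"))


def _pass_once(
    tracks: pd.DataFrame, means: pd.Series, hard: float, soft: float
) -> tuple[pd.DataFrame, list[dict]]:
    """One filtering pass on the currently-valid series."""
    out = tracks.copy()
    hits: list[dict] = []
    for (bout_id, keypoint), group in out.groupby(["bout_id", "keypoint"], sort=True):
        height = float(means[bout_id])
        sub = group.loc[group["valid"]].sort_values("frame")
        if len(sub) < 2:
            continue
        dx = np.diff(sub["x"].to_numpy())
        dy = np.diff(sub["y"].to_numpy())
        disp = np.hypot(dx, dy) / height
        later = sub.index.to_numpy()[1:]  # record the displacement lands on
        frames = sub["frame"].to_numpy()[1:]
        for idx, frame, d in zip(later, frames, disp):
            if d > hard:
                out.loc[idx, "valid"] = False
                hits.append(
                    {"bout_id": bout_id, "frame": int(frame), "keypoint": keypoint,
                     "displacement_bh": float(d), "action": "removed"}
                )
            elif d > soft:
                hits.append(
                    {"bout_id": bout_id, "frame": int(frame), "keypoint": keypoint,
                     "displacement_bh": float(d), "action": "flagged"}
                )
    return out, hits


def filter_jumps(
    tracks: pd.DataFrame,
    metrics: BodyMetrics,
    hard: float = HARD_THRESHOLD,
    soft: float = SOFT_THRESHOLD,
    iterative: bool = False,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Invalidate implausible keypoint jumps and flag borderline ones.

    Per keypoint, frame-to-frame Euclidean displacement (in units of the
    bout's mean body height) is evaluated on the raw series; records
    whose incoming displacement exceeds ``hard`` are marked
    ``valid=False``, displacements in ``(soft, hard]`` are listed as
    flagged but retained.  A record invalidated for one keypoint leaves
    the other keypoints of that frame untouched.

    With ``iterative=True`` the pass is repeated on the surviving series
    until no further removals occur.
    """
    if hard <= soft:
        raise ParameterError(
            f"hard threshold ({hard}) must exceed soft threshold ({soft})"
        )
    bad = metrics.means[metrics.means <= 0]
    if not bad.empty:
        raise ParameterError(
            f"non-positive mean body height for bout(s): {sorted(bad.index)}"
        )

    out, hits = _pass_once(tracks, metrics.means, hard, soft)
    if iterative:
        while any(h["action"] == "removed" for h in hits):
            nxt, new_hits = _pass_once(out, metrics.means, hard, soft)
            new_removed = [h for h in new_hits if h["action"] == "removed"]
            if not new_removed:
                # keep the final pass's flag list alongside earlier removals
                hits = [h for h in hits if h["action"] == "removed"] + new_hits
                break
            out = nxt
            hits = [h for h in hits if h["action"] == "removed"] + new_hits

    records = pd.DataFrame(
        hits, columns=["bout_id", "frame", "keypoint", "displacement_bh", "action"]
    )
    report = CleaningReport(
        hard_threshold=hard,
        soft_threshold=soft,
        removed=int((records["action"] == "removed").sum()),
        flagged=int((records["action"] == "flagged").sum()),
        records=records,
        n_frames=int(tracks.groupby("bout_id")["frame"].nunique().sum()),
        n_records=len(tracks),
    )
    return out, report
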