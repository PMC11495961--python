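"""Reading, writing and joining the pipeline's CSV interchange formats.

Three plain-CSV tables (comma separator, dot decimal, UTF-8, header row
required) carry everything the analysis needs:

``tracks.csv``
    ``bout_id,frame,keypoint,x,y[,confidence][,valid]`` — one row per
    (bout, frame, keypoint).  Coordinates are in pixels, image
    convention (*y* increases downward), frames are 0-based and
    contiguous within each bout.  An optional per-keypoint
    ``confidence`` column (emitted by some pose-estimation exports) is
    accepted and ignored.  ``valid`` is written by the cleaning stage;
    absent means all-true.

``annotations.csv``
    ``bout_id,male_id,status,date,element_type,intensity_class,kind,
    start_frame,duration_frames`` — per-bout metadata plus one row per
    display-element occurrence.  A row with an empty ``element_type``
    contributes metadata only.  ``intensity_class`` may be left empty,
    in which case it is filled from the shipped element-type mapping
    (body ripple and mock attack are high-intensity; everything else is
    low-intensity).

``exits.csv``
    ``bout_id,frame`` — one row per bower-exit event.

:func:`assemble_dataset` joins the three tables into a :class:`Dataset`
after referential and bounds validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    BoundsError,
    FormatError,
    ParseError,
    ReferentialError,
    VocabularyError,
)

#: Tracked morphological landmarks.
KEYPOINTS = ("beak_tip", "left_foot", "right_foot", "left_itj", "right_itj")
#: The two inter-tarsal-joint keypoints whose vertical offset from the
#: beak defines body height.
ITJ_KEYPOINTS = ("left_itj", "right_itj")
#: Courter bower-ownership status labels.
STATUSES = ("owner", "subordinate")
#: Display-element intensity classes.
INTENSITY_CLASSES = ("high", "low")

TRACK_COLUMNS = ("bout_id", "frame", "keypoint", "x", "y")
ANNOTATION_COLUMNS = (
    "bout_id",
    "male_id",
    "status",
    "date",
    "element_type",
    "intensity_class",
    "kind",
    "start_frame",
    "duration_frames",
)
EXIT_COLUMNS = ("bout_id", "frame")


def default_intensity_map() -> dict[str, str]:
    """Element-type → intensity-class mapping shipped with the package.

    Element types absent from the table default to ``"low"``: only body
    ripple and mock attack — the vigorous close-range moves — are
    high-intensity.
    """
    with resources.files("peristartle.data").joinpath("intensity_map.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        table = pd.read_csv(fh)
    return dict(zip(table["element_type"], table["intensity_class"]))


def _require_columns(frame: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric(frame: pd.DataFrame, column: str, path, integer: bool = False) -> pd.Series:
    """Coerce a column to numeric, reporting the first bad CSV line."""
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.isna() & frame[column].notna()
    if bad.any():
        # +2: header line plus 1-based numbering.
        line = int(frame.index[bad][0]) + 2
        raise ParseError(
            f"{path}: non-numeric value {frame[column][bad].iloc[0]!r} "
            f"in column {column!r} at line {line}"
        )
    if values.isna().any():
        line = int(frame.index[values.isna()][0]) + 2
        raise ParseError(f"{path}: empty value in column {column!r} at line {line}")
    return values.astype(np.int64 if integer else float)


def read_keypoint_csv(path) -> pd.DataFrame:
    """Load a keypoint-track table, validating schema and vocabulary.

    Returns a DataFrame with columns ``bout_id, frame, keypoint, x, y,
    valid`` sorted by (bout, frame, keypoint).  Frames must be
    contiguous integers starting at 0 within each bout.
    """
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, TRACK_COLUMNS, path)
    unknown = set(raw["keypoint"].unique()) - set(KEYPOINTS)
    if unknown:
        raise VocabularyError(
            f"{path}: unknown keypoint label(s): {sorted(unknown)}; "
            f"expected one of {list(KEYPOINTS)}"
        )
    tracks = pd.DataFrame(
        {
            "bout_id": raw["bout_id"].astype(str),
            "frame": _numeric(raw, "frame", path, integer=True),
            "keypoint": raw["keypoint"].astype(str),
            "x": _numeric(raw, "x", path),
            "y": _numeric(raw, "y", path),
        }
    )
    if "valid" in raw.columns:
        tracks["valid"] = raw["valid"].str.lower().isin(("true", "1"))
    else:
        tracks["valid"] = True
    tracks = tracks.sort_values(["bout_id", "frame", "keypoint"], kind="stable")
    tracks = tracks.reset_index(drop=True)
    _check_contiguous(tracks, path)
    return tracks


def _check_contiguous(tracks: pd.DataFrame, path) -> None:
    for (bout, keypoint), group in tracks.groupby(["bout_id", "keypoint"], sort=False):
        frames = group["frame"].to_numpy()
        if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
            raise FormatError(
                f"{path}: frames for bout {bout!r}, keypoint {keypoint!r} are not "
                "contiguous integers starting at 0"
            )


def write_keypoint_csv(tracks: pd.DataFrame, path) -> None:
    """Write a keypoint-track table in the documented dialect."""
    out = tracks.loc[:, ["bout_id", "frame", "keypoint", "x", "y", "valid"]]
    out.to_csv(path, index=False)


def read_annotations(
    path,
    intensity_map: Mapping[str, str] | None = None,
    bout_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load per-bout metadata and display events from one annotations table.

    Returns ``(metadata, events)``.  ``metadata`` has one row per bout
    (``bout_id, male_id, status, date, fps``); ``events`` one row per
    element occurrence, sorted by (bout, start frame), with
    ``intensity_class`` filled from the default mapping where the column
    is empty or absent.  When ``bout_lengths`` is supplied, events
    extending past the end of their bout raise :class:`BoundsError`
    (otherwise that check is deferred to :func:`assemble_dataset`).
    """
    if intensity_map is None:
        intensity_map = default_intensity_map()
    raw = pd.read_csv(path, dtype=str)
    _require_columns(
        raw, ("bout_id", "male_id", "status", "date", "element_type"), path
    )
    raw["bout_id"] = raw["bout_id"].astype(str)

    bad_status = set(raw["status"].dropna().unique()) - set(STATUSES)
    if bad_status:
        raise VocabularyError(
            f"{path}: unknown status label(s): {sorted(bad_status)}; "
            f"expected one of {list(STATUSES)}"
        )

    meta = raw.loc[:, ["bout_id", "male_id", "status", "date"]].drop_duplicates()
    if "fps" in raw.columns:
        fps = pd.to_numeric(raw["fps"], errors="coerce").fillna(30.0)
        meta = meta.join(fps.rename("fps"))
    else:
        meta["fps"] = 30.0
    conflicting = meta.groupby("bout_id").size()
    conflicting = conflicting[conflicting > 1]
    if not conflicting.empty:
        raise ReferentialError(
            f"{path}: bout(s) mapped to more than one (male, status, date): "
            f"{sorted(conflicting.index)}"
        )
    meta = meta.sort_values("bout_id").reset_index(drop=True)

    has_event = raw["element_type"].notna() & (raw["element_type"].str.strip() != "")
    events = raw.loc[has_event].copy()
    if events.empty:
        events = pd.DataFrame(
            columns=["bout_id", "element_type", "intensity_class", "kind",
                     "start_frame", "duration_frames"]
        ).astype({"start_frame": np.int64, "duration_frames": np.int64})
    else:
        events["start_frame"] = _numeric(events, "start_frame", path, integer=True)
        if "duration_frames" in events.columns and events["duration_frames"].notna().all():
            events["duration_frames"] = _numeric(events, "duration_frames", path, integer=True)
        else:
            events["duration_frames"] = 1
        if "intensity_class" not in events.columns:
            events["intensity_class"] = pd.Series(pd.NA, index=events.index, dtype=object)
        events["intensity_class"] = events["intensity_class"].astype(object)
        blank = events["intensity_class"].isna() | (
            events["intensity_class"].astype(str).str.strip() == ""
        )
        events.loc[blank, "intensity_class"] = [
            intensity_map.get(t, "low") for t in events.loc[blank, "element_type"]
        ]
        bad_class = set(events["intensity_class"].unique()) - set(INTENSITY_CLASSES)
        if bad_class:
            raise VocabularyError(
                f"{path}: unknown intensity class(es): {sorted(bad_class)}"
            )
        if "kind" not in events.columns or events["kind"].isna().any():
            events["kind"] = np.where(events["duration_frames"] == 1, "event", "duration")
        mismatched = (events["kind"] == "event") & (events["duration_frames"] != 1)
        if mismatched.any():
            raise FormatError(
                f"{path}: 'event' elements must have duration_frames = 1 "
                f"(bout {events.loc[mismatched, 'bout_id'].iloc[0]!r})"
            )
        events = events.loc[
            :,
            ["bout_id", "element_type", "intensity_class", "kind",
             "start_frame", "duration_frames"],
        ]
    events = events.sort_values(["bout_id", "start_frame"], kind="stable")
    events = events.reset_index(drop=True)
    if bout_lengths is not None:
        _check_event_bounds(events, bout_lengths)
    return meta, events


def _check_event_bounds(events: pd.DataFrame, bout_lengths: Mapping[str, int]) -> None:
    for row in events.itertuples():
        length = bout_lengths.get(row.bout_id)
        if length is not None and row.start_frame + row.duration_frames > length:
            raise BoundsError(
                f"event {row.element_type!r} at frame {row.start_frame} "
                f"(duration {row.duration_frames}) extends past the end of "
                f"bout {row.bout_id!r} ({length} frames)"
            )


def read_exits(path) -> pd.DataFrame:
    """Load the bower-exit table (``bout_id, frame``)."""
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, EXIT_COLUMNS, path)
    if raw.empty:
        return pd.DataFrame({"bout_id": pd.Series(dtype=str),
                             "frame": pd.Series(dtype=np.int64)})
    exits = pd.DataFrame(
        {
            "bout_id": raw["bout_id"].astype(str),
            "frame": _numeric(raw, "frame", path, integer=True),
        }
    )
    return exits.sort_values(["bout_id", "frame"], kind="stable").reset_index(drop=True)


def write_annotations(metadata: pd.DataFrame, events: pd.DataFrame, path) -> None:
    """Write metadata and events back into the single annotations table."""
    merged = events.merge(metadata, on="bout_id", how="left")
    meta_only = metadata.loc[~metadata["bout_id"].isin(events["bout_id"])].copy()
    for col in ("element_type", "intensity_class", "kind"):
        meta_only[col] = ""
    meta_only["start_frame"] = ""
    meta_only["duration_frames"] = ""
    out = pd.concat([merged, meta_only], ignore_index=True)
    out = out.loc[:, list(ANNOTATION_COLUMNS)]
    out.to_csv(path, index=False)


def write_exits(exits: pd.DataFrame, path) -> None:
    exits.loc[:, list(EXIT_COLUMNS)].to_csv(path, index=False)


@dataclass
class Dataset:
    """Joined view of tracks, bout metadata, display events and exits.

    Construct through :func:`assemble_dataset`, which validates
    referential integrity and event bounds.
    """

    tracks: pd.DataFrame
    metadata: pd.DataFrame
    events: pd.DataFrame
    exits: pd.DataFrame
    bout_lengths: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lengths = (
            self.tracks.groupby("bout_id")["frame"].max().astype(int) + 1
        )
        self.bout_lengths = lengths

    @property
    def bout_ids(self) -> list[str]:
        return sorted(self.metadata["bout_id"].unique())

    @property
    def male_ids(self) -> list[str]:
        return sorted(self.metadata["male_id"].unique())

    def male_of_bout(self) -> pd.Series:
        return self.metadata.set_index("bout_id")["male_id"]

    def status_of_male(self) -> pd.Series:
        return (
            self.metadata.loc[:, ["male_id", "status"]]
            .drop_duplicates()
            .set_index("male_id")["status"]
        )

    def males_with_status(self, status: str) -> list[str]:
        by_male = self.status_of_male()
        return sorted(male for male, s in by_male.items() if s == status)

    def summary(self) -> pd.DataFrame:
        """Per-male bout and element counts (high/low split)."""
        events = self.events.merge(self.metadata, on="bout_id")
        rows = []
        for male, group in self.metadata.groupby("male_id"):
            sub = events.loc[events["male_id"] == male]
            rows.append(
                {
                    "male_id": male,
                    "status": group["status"].iloc[0],
                    "n_bouts": group["bout_id"].nunique(),
                    "n_frames": int(
                        self.bout_lengths.reindex(group["bout_id"]).sum()
                    ),
                    "n_elements": len(sub),
                    "n_high": int((sub["intensity_class"] == "high").sum()),
                    "n_low": int((sub["intensity_class"] == "low").sum()),
                }
            )
        return pd.DataFrame(rows).sort_values("male_id").reset_index(drop=True)


def assemble_dataset(
    tracks: pd.DataFrame,
    metadata: pd.DataFrame,
    events: pd.DataFrame,
    exits: pd.DataFrame,
) -> Dataset:
    """Join the four tables into a validated :class:`Dataset`.

    The result is order-insensitive: all tables are re-sorted into a
    canonical order, so permuting input rows yields an identical
    dataset.
    """
    tracks = tracks.sort_values(["bout_id", "frame", "keypoint"], kind="stable")
    tracks = tracks.reset_index(drop=True)
    metadata = metadata.sort_values("bout_id").reset_index(drop=True)
    events = events.sort_values(
        ["bout_id", "start_frame", "element_type"], kind="stable"
    ).reset_index(drop=True)
    exits = exits.sort_values(["bout_id", "frame"], kind="stable").reset_index(drop=True)

    known = set(tracks["bout_id"]) & set(metadata["bout_id"])
    orphans = sorted(
        (set(events["bout_id"]) | set(exits["bout_id"]) | set(tracks["bout_id"])
         | set(metadata["bout_id"])) - known
    )
    if orphans:
        raise ReferentialError(
            "bout_id(s) missing from tracks and/or metadata: " + ", ".join(orphans)
        )

    lengths = tracks.groupby("bout_id")["frame"].max().astype(int) + 1
    _check_event_bounds(events, lengths)
    out_of_range = exits.merge(lengths.rename("length"), on="bout_id")
    bad = out_of_range["frame"] >= out_of_range["length"]
    if bad.any():
        row = out_of_range.loc[bad].iloc[0]
        raise BoundsError(
            f"exit at frame {int(row['frame'])} outside bout "
            f"{row['bout_id']!r} ({int(row['length'])} frames)"
        )
    return Dataset(tracks=tracks, metadata=metadata, events=events, exits=exits)


def write_dataset(dataset: Dataset, outdir, manifest: dict | None = None) -> None:
    """Write a dataset as the three CSVs plus a small JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_keypoint_csv(dataset.tracks, outdir / "tracks.csv")
    write_annotations(dataset.metadata, dataset.events, outdir / "annotations.csv")
    write_exits(dataset.exits, outdir / "exits.csv")
    payload = {
        "n_bouts": len(dataset.bout_ids),
        "n_males": len(dataset.male_ids),
        "n_events": len(dataset.events),
        "n_exits": len(dataset.exits),
    }
    if manifest:
        payload.update(manifest)
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_dataset(indir) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    tracks = read_keypoint_csv(indir / "tracks.csv")
    metadata, events = read_annotations(indir / "annotations.csv")
    exits_path = indir / "exits.csv"
    if exits_path.exists():
        exits = read_exits(exits_path)
    else:
        exits = pd.DataFrame({"bout_id": pd.Series(dtype=str),
                              "frame": pd.Series(dtype=np.int64)})
    return assemble_dataset(tracks, metadata, events, exits)
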