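"""Marker-trajectory I/O for the whip-throwing task.

A recording is a time-indexed array of 3-D positions for a named marker set:
the hand marker (V-th metacarpal head), ten whip markers ``w1``..``w10``
ordered tip -> thong base, two handle markers ``h1`` (distal) / ``h2``
(proximal), and three target markers ``t1``..``t3`` (``t1`` on the free end
of the target spring).  Missing samples are represented by a boolean gap
mask, never by sentinel coordinates.

Two on-disk dialects are supported, dispatched on file extension:

* wide TSV — header ``frame`` then ``<label>_X/_Y/_Z`` columns, one row per
  frame, positions in metres; blank cells mark gaps.  Sampling rate is kept
  in a ``# sampling_rate_hz:`` comment on the first line.
* C3D — read through the optional :mod:`ezc3d` dependency.

Lab-frame convention used throughout the package: ``x`` points horizontally
from the participant toward the target, ``z`` is vertical up, and ``y``
completes a right-handed frame (participant's left).  ``target_direction``
defaults to ``+x``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSchema",
    "MarkerDataset",
    "SchemaError",
    "FormatError",
    "default_schema",
    "read_markers",
    "write_markers",
    "gap_report",
    "simultaneous_gap_counts",
]

WHIP_MARKERS = tuple(f"w{i}" for i in range(1, 11))  # w1 = tip ... w10 = base
HANDLE_MARKERS = ("h1", "h2")
TARGET_MARKERS = ("t1", "t2", "t3")
HAND_MARKER = "hand"


class SchemaError(ValueError):
    """A file or dataset does not satisfy the marker schema."""


class FormatError(ValueError):
    """A marker file is structurally malformed."""


@dataclass(frozen=True)
class MarkerSchema:
    """Names and geometry of the marker set.

    Parameters
    ----------
    marker_names
        Ordered labels; must be unique and include the whip, handle and
        target markers plus at least one hand marker.
    whip_arclength
        Length of the flexible thong in metres (1.60 m for the study whip).
    handle_length
        Length of the rigid handle in metres (0.24 m).
    inter_marker_spacing
        Arclength between adjacent whip markers from w10 down to w3
        (0.19 m).
    distal_spacing
        Arclength between the two most distal whip markers w2 and w1
        (0.06 m).
    base_offset
        Arclength from the handle end (h1) to the first whip marker w10.
    target_direction
        Unit 3-vector pointing from the participant toward the target in
        the lab frame.
    """

    marker_names: tuple[str, ...] = (
        (HAND_MARKER,) + WHIP_MARKERS + HANDLE_MARKERS + TARGET_MARKERS
    )
    whip_arclength: float = 1.60
    handle_length: float = 0.24
    inter_marker_spacing: float = 0.19
    distal_spacing: float = 0.06
    base_offset: float = 0.02
    target_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        names = list(self.marker_names)
        if len(set(names)) != len(names):
            raise SchemaError("marker names must be unique")
        if self.whip_arclength <= 0:
            raise SchemaError("whip_arclength must be positive")
        spacings = (self.inter_marker_spacing, self.distal_spacing, self.base_offset)
        if any(s <= 0 for s in spacings):
            raise SchemaError("marker spacings must be positive")
        if self.chain_length() > self.whip_arclength + 1e-12:
            raise SchemaError(
                "implied marker chain length exceeds the whip arclength"
            )
        d = np.asarray(self.target_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0):
            raise SchemaError("target_direction must be a unit vector")

    def whip_segment_lengths(self) -> np.ndarray:
        """Arclengths of the h1->w10->...->w1 chain (10 segments)."""
        # h1->w10, then w10->w3 at the regular spacing (7 gaps), w3->w2 at the
        # regular spacing, and the short w2->w1 gap at the tip.
        return np.array(
            [self.base_offset]
            + [self.inter_marker_spacing] * 8
            + [self.distal_spacing]
        )

    def chain_length(self) -> float:
        """Arclength from h1 to the tip marker w1."""
        return float(self.whip_segment_lengths().sum())

    def index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise SchemaError(f"marker {name!r} not in schema") from None


@dataclass
class MarkerDataset:
    """3-D marker positions with a gap mask.

    ``positions`` has shape (frames, markers, 3) in metres; entries are NaN
    exactly where ``gap_mask`` is True.  ``sampling_rate`` is in Hz.
    """

    positions: np.ndarray
    sampling_rate: float
    gap_mask: np.ndarray = None  # type: ignore[assignment]
    schema: MarkerSchema = field(default_factory=MarkerSchema)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise FormatError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.schema.marker_names):
            raise SchemaError("positions second axis must match schema markers")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.isnan(self.positions).any(axis=2)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.positions.shape[:2]:
            raise FormatError("gap_mask must have shape (frames, markers)")
        self.positions = self.positions.copy()
        self.positions[self.gap_mask] = np.nan
        if not np.isfinite(self.positions[~self.gap_mask]).all():
            raise FormatError("positions must be finite where not gapped")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def marker(self, name: str) -> np.ndarray:
        """Positions of one marker, shape (frames, 3), NaN where gapped."""
        return self.positions[:, self.schema.index(name), :]

    def copy(self) -> "MarkerDataset":
        return MarkerDataset(
            self.positions.copy(), self.sampling_rate, self.gap_mask.copy(), self.schema
        )

    def slice_frames(self, start: int, stop: int) -> "MarkerDataset":
        return MarkerDataset(
            self.positions[start:stop].copy(),
            self.sampling_rate,
            self.gap_mask[start:stop].copy(),
            self.schema,
        )


def default_schema() -> MarkerSchema:
    """The study marker set: 1.6 m thong, 0.24 m handle, 19/6 cm spacings."""
    return MarkerSchema()


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_RATE_COMMENT = "# sampling_rate_hz:"


def _read_tsv(path: str, schema: MarkerSchema) -> MarkerDataset:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        rate = 500.0
        if first.startswith(_RATE_COMMENT):
            rate = float(first[len(_RATE_COMMENT):].strip())
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t")
    missing = [
        name
        for name in schema.marker_names
        if f"{name}_X" not in df.columns
    ]
    if missing:
        raise SchemaError(f"file {path!r} is missing required labels: {missing}")
    n = len(df)
    pos = np.full((n, len(schema.marker_names), 3), np.nan)
    for j, name in enumerate(schema.marker_names):
        for k, ax in enumerate("XYZ"):
            col = df[f"{name}_{ax}"]
            pos[:, j, k] = pd.to_numeric(col, errors="coerce").to_numpy()
    return MarkerDataset(pos, rate, np.isnan(pos).any(axis=2), schema)


def _write_tsv(dataset: MarkerDataset, path: str) -> None:
    cols: dict[str, np.ndarray] = {"frame": np.arange(dataset.n_frames)}
    for j, name in enumerate(dataset.schema.marker_names):
        for k, ax in enumerate("XYZ"):
            cols[f"{name}_{ax}"] = dataset.positions[:, j, k]
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_RATE_COMMENT} {dataset.sampling_rate:.6f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10f", na_rep="")


# ---------------------------------------------------------------------------
# C3D dialect (optional dependency)
# ---------------------------------------------------------------------------


def _read_c3d(path: str, schema: MarkerSchema) -> MarkerDataset:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' dependency "
            "(pip install whipkin[c3d]); alternatively export the recording "
            "as wide TSV"
        ) from exc
    c3d = ezc3d.c3d(path)  # pragma: no cover - optional dependency
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]  # (4, markers, frames)
    unit = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["m"])[0]
    scale = 0.001 if str(unit).lower().startswith("mm") else 1.0
    missing = [n for n in schema.marker_names if n not in labels]
    if missing:
        raise SchemaError(f"file {path!r} is missing required labels: {missing}")
    n = pts.shape[2]
    pos = np.full((n, len(schema.marker_names), 3), np.nan)
    for j, name in enumerate(schema.marker_names):
        pos[:, j, :] = pts[:3, labels.index(name), :].T * scale
    pos[~np.isfinite(pos)] = np.nan
    return MarkerDataset(pos, rate, np.isnan(pos).any(axis=2), schema)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_markers(path: str, schema: MarkerSchema | None = None) -> MarkerDataset:
    """Read a marker file (TSV or C3D, by extension) into a dataset.

    Gap mask is set wherever any coordinate of a marker is absent or
    non-finite; positions are returned in metres.
    """
    schema = schema or default_schema()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".c3d":
        return _read_c3d(path, schema)
    if ext in (".tsv", ".txt", ".csv"):
        return _read_tsv(path, schema)
    raise FormatError(f"unrecognised marker file extension: {ext!r}")


def write_markers(dataset: MarkerDataset, path: str) -> None:
    """Write a dataset as wide TSV; round-trips positions to <=1e-9 m."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".tsv", ".txt", ".csv"):
        raise FormatError("write_markers only writes the TSV dialect")
    _write_tsv(dataset, path)


def gap_report(dataset: MarkerDataset) -> pd.DataFrame:
    """Run-length encode the gap mask.

    Returns a DataFrame with one row per maximal run of missing frames:
    columns ``marker``, ``start_frame``, ``length``.
    """
    rows = []
    mask = dataset.gap_mask
    for j, name in enumerate(dataset.schema.marker_names):
        col = mask[:, j]
        if not col.any():
            continue
        padded = np.concatenate(([False], col, [False]))
        d = np.diff(padded.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            rows.append({"marker": name, "start_frame": int(s), "length": int(e - s)})
    return pd.DataFrame(rows, columns=["marker", "start_frame", "length"])


def simultaneous_gap_counts(dataset: MarkerDataset) -> np.ndarray:
    """Per-frame count of simultaneously missing markers."""
    return dataset.gap_mask.sum(axis=1).astype(int)
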