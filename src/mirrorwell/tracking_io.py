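"""Keypoint-table IO, likelihood quality control and prediction scoring.

The pose-estimation network emits, per frame and per view, eight named
landmarks with pixel coordinates and a detection likelihood in [0, 1].
QC follows two rules: a frame is valid only if *every* landmark's
likelihood is strictly above the threshold (default 0.7), and a whole
video is excluded when strictly more than one third of its frames fail
that test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

LANDMARKS: tuple[str, ...] = (
    "nostril",
    "eye_left",
    "eye_right",
    "swim_bladder",
    "tail_1",
    "tail_2",
    "tail_3",
    "tail_4",
)

Dialect = Literal["dlc_csv", "plain_csv"]

__all__ = [
    "LANDMARKS",
    "KeypointFrame",
    "TrackSet",
    "QCResult",
    "read_keypoint_table",
    "write_keypoint_table",
    "read_keypoint_h5",
    "write_keypoint_h5",
    "filter_frames",
    "qc_video",
    "evaluate_keypoints",
]


@dataclass(frozen=True)
class KeypointFrame:
    """One frame's eight landmarks: (8, 2) pixel coords + (8,) likelihoods."""

    frame_index: int
    coords: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        lik = np.asarray(self.likelihood, dtype=float)
        if coords.shape != (len(LANDMARKS), 2) or lik.shape != (len(LANDMARKS),):
            raise SchemaError(
                f"frame {self.frame_index}: expected (8, 2) coords and (8,) "
                f"likelihoods, got {coords.shape} / {lik.shape}"
            )
        if self.frame_index < 0:
            raise SchemaError("frame_index must be >= 0")
        if np.any((lik < 0) | (lik > 1)):
            raise SchemaError(f"frame {self.frame_index}: likelihood outside [0, 1]")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "likelihood", lik)

    def coord(self, landmark: str) -> np.ndarray:
        return self.coords[LANDMARKS.index(landmark)]


@dataclass(frozen=True)
class TrackSet:
    """Ordered per-frame keypoint data for one well and one view.

    Arrays: ``frame_index`` (n,), ``coords`` (n, 8, 2), ``likelihood``
    (n, 8).  Frame indices must be strictly increasing.
    """

    view_label: str
    frame_index: np.ndarray
    coords: np.ndarray
    likelihood: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_index, dtype=int)
        coords = np.asarray(self.coords, dtype=float)
        lik = np.asarray(self.likelihood, dtype=float)
        n = len(idx)
        if coords.shape != (n, len(LANDMARKS), 2) or lik.shape != (n, len(LANDMARKS)):
            raise SchemaError(
                f"inconsistent array shapes: {coords.shape}, {lik.shape} for {n} frames"
            )
        if n > 1 and np.any(np.diff(idx) <= 0):
            raise FormatError("frame indices must be strictly increasing")
        object.__setattr__(self, "frame_index", idx)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "likelihood", lik)

    def __len__(self) -> int:
        return len(self.frame_index)

    def frame(self, position: int) -> KeypointFrame:
        return KeypointFrame(
            frame_index=int(self.frame_index[position]),
            coords=self.coords[position],
            likelihood=self.likelihood[position],
        )

    def frames(self) -> Iterable[KeypointFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "frame": np.repeat(self.frame_index, len(LANDMARKS)),
                "landmark": list(LANDMARKS) * n,
                "u": self.coords[:, :, 0].ravel(),
                "v": self.coords[:, :, 1].ravel(),
                "likelihood": self.likelihood.ravel(),
            }
        )

    def take(self, mask_or_positions: np.ndarray) -> "TrackSet":
        return replace(
            self,
            frame_index=self.frame_index[mask_or_positions],
            coords=self.coords[mask_or_positions],
            likelihood=self.likelihood[mask_or_positions],
        )


@dataclass(frozen=True)
class QCResult:
    include: bool
    fraction_below: float
    n_frames: int
    n_failing: int


def _trackset_from_long(df: pd.DataFrame, view_label: str, source_id: str) -> TrackSet:
    present = set(df["landmark"].unique())
    missing = [lm for lm in LANDMARKS if lm not in present]
    if missing:
        raise SchemaError(f"missing landmark column(s): {', '.join(missing)}")
    frames = np.sort(df["frame"].unique())
    pivot_u = df.pivot_table(index="frame", columns="landmark", values="u")
    pivot_v = df.pivot_table(index="frame", columns="landmark", values="v")
    pivot_l = df.pivot_table(index="frame", columns="landmark", values="likelihood")
    cols = list(LANDMARKS)
    if pivot_u[cols].isna().any().any():
        raise FormatError("missing landmark rows for some frames")
    coords = np.stack(
        [pivot_u.loc[frames, cols].to_numpy(), pivot_v.loc[frames, cols].to_numpy()],
        axis=-1,
    )
    lik = pivot_l.loc[frames, cols].to_numpy()
    return TrackSet(
        view_label=view_label,
        frame_index=frames,
        coords=coords,
        likelihood=lik,
        source_id=source_id,
    )


def read_keypoint_table(
    path: str | Path,
    dialect: Dialect = "dlc_csv",
    view_label: str = "top",
    source_id: str | None = None,
) -> TrackSet:
    """Read a per-frame keypoint table.

    ``dlc_csv`` parses the DeepLabCut three-row header
    (scorer / bodyparts / coords); ``plain_csv`` expects long-format columns
    ``frame,landmark,u,v,likelihood``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    source = source_id if source_id is not None else path.stem
    if dialect == "plain_csv":
        df = pd.read_csv(path)
        required = {"frame", "landmark", "u", "v", "likelihood"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{path}: plain_csv needs columns {sorted(required)}, got "
                f"{list(df.columns)}"
            )
        return _trackset_from_long(df, view_label, source)
    if dialect == "dlc_csv":
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        bodyparts = raw.columns.get_level_values(1)
        missing = [lm for lm in LANDMARKS if lm not in set(bodyparts)]
        if missing:
            raise SchemaError(f"{path}: missing landmark column(s): {', '.join(missing)}")
        frames = raw.index.to_numpy(dtype=int)
        if len(frames) > 1 and np.any(np.diff(frames) <= 0):
            raise FormatError(f"{path}: non-monotone frame index")
        n = len(frames)
        coords = np.empty((n, len(LANDMARKS), 2))
        lik = np.empty((n, len(LANDMARKS)))
        for j, lm in enumerate(LANDMARKS):
            sub = raw.xs(lm, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            for col in ("x", "y", "likelihood"):
                if col not in sub.columns:
                    raise SchemaError(f"{path}: landmark {lm} missing coord {col!r}")
            coords[:, j, 0] = sub["x"].to_numpy(dtype=float)
            coords[:, j, 1] = sub["y"].to_numpy(dtype=float)
            lik[:, j] = sub["likelihood"].to_numpy(dtype=float)
        return TrackSet(
            view_label=view_label,
            frame_index=frames,
            coords=coords,
            likelihood=lik,
            source_id=source,
        )
    raise FormatError(f"unknown dialect {dialect!r}")


def write_keypoint_table(
    track: TrackSet, path: str | Path, dialect: Dialect = "dlc_csv", scorer: str = "mirrorwell"
) -> None:
    """Write a :class:`TrackSet` so that re-reading reproduces it exactly."""
    path = Path(path)
    if dialect == "plain_csv":
        track.to_dataframe().to_csv(path, index=False)
        return
    if dialect == "dlc_csv":
        columns = pd.MultiIndex.from_tuples(
            [(scorer, lm, coord) for lm in LANDMARKS for coord in ("x", "y", "likelihood")],
            names=["scorer", "bodyparts", "coords"],
        )
        n = len(track)
        data = np.empty((n, len(LANDMARKS) * 3))
        for j in range(len(LANDMARKS)):
            data[:, 3 * j] = track.coords[:, j, 0]
            data[:, 3 * j + 1] = track.coords[:, j, 1]
            data[:, 3 * j + 2] = track.likelihood[:, j]
        pd.DataFrame(data, index=track.frame_index, columns=columns).to_csv(path)
        return
    raise FormatError(f"unknown dialect {dialect!r}")


def write_keypoint_h5(track: TrackSet, path: str | Path) -> None:
    """HDF5 mirror of the CSV schema (datasets: frame_index/coords/likelihood)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("frame_index", data=track.frame_index)
        f.create_dataset("coords", data=track.coords)
        f.create_dataset("likelihood", data=track.likelihood)
        f.attrs["view_label"] = track.view_label
        f.attrs["source_id"] = track.source_id
        f.attrs["landmarks"] = ",".join(LANDMARKS)


def read_keypoint_h5(path: str | Path) -> TrackSet:
    import h5py

    with h5py.File(path, "r") as f:
        return TrackSet(
            view_label=str(f.attrs["view_label"]),
            frame_index=f["frame_index"][()],
            coords=f["coords"][()],
            likelihood=f["likelihood"][()],
            source_id=str(f.attrs["source_id"]),
        )


def _frame_passes(track: TrackSet, likelihood_threshold: float) -> np.ndarray:
    """Boolean mask: all eight landmarks strictly above the threshold."""
    return np.all(track.likelihood > likelihood_threshold, axis=1)


def filter_frames(
    track: TrackSet, likelihood_threshold: float = 0.7
) -> tuple[TrackSet, np.ndarray]:
    """Keep only frames in which every landmark passes the likelihood test.

    Returns the kept :class:`TrackSet` and the dropped frame indices.  The
    inequality is strict: a landmark at exactly the threshold fails.
    """
    if not 0.0 <= likelihood_threshold <= 1.0:
        raise ValueError("likelihood_threshold must be in [0, 1]")
    if len(track) == 0:
        raise FormatError("cannot filter an empty track")
    passes = _frame_passes(track, likelihood_threshold)
    return track.take(passes), track.frame_index[~passes]


def qc_video(
    track: TrackSet,
    likelihood_threshold: float = 0.7,
    exclusion_fraction: float = 1.0 / 3.0,
) -> QCResult:
    """Video-level inclusion decision.

    The video is excluded iff the fraction of frames failing the
    all-landmark likelihood test is strictly greater than
    ``exclusion_fraction`` ("over one third" read literally: exactly one
    third still passes).
    """
    if len(track) == 0:
        raise FormatError("cannot QC an empty track")
    passes = _frame_passes(track, likelihood_threshold)
    n_fail = int(np.sum(~passes))
    fraction = n_fail / len(track)
    return QCResult(
        include=not (fraction > exclusion_fraction),
        fraction_below=fraction,
        n_frames=len(track),
        n_failing=n_fail,
    )


def evaluate_keypoints(
    predicted: TrackSet, truth: TrackSet, radius: float = 5.0
) -> dict[str, float]:
    """Score predictions against ground truth.

    Returns the root-mean-square Euclidean pixel error over all
    landmark-frames and the hit rate: the fraction of landmark-frames whose
    error is <= ``radius`` pixels.
    """
    if len(predicted) != len(truth) or np.any(
        predicted.frame_index != truth.frame_index
    ):
        raise FormatError("predicted and truth tracks cover different frames")
    err = np.linalg.norm(predicted.coords - truth.coords, axis=-1)
    return {
        "rmse_px": float(np.sqrt(np.mean(err**2))),
        "hit_rate": float(np.mean(err <= radius)),
        "radius_px": float(radius),
    }
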