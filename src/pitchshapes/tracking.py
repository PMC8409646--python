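"""Player-tracking input: frames of 2D positions in pitch coordinates.

A :class:`TrackingFrame` holds one team's player positions (metres) at one
instant. The convex hull of the outfield players — the goalkeeper is
excluded, since their position would distort the outfield block — is the
shape analysed downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, DegenerateShapeError

logger = logging.getLogger(__name__)

#: Standard pitch dimensions in metres (length x width).
PITCH_LENGTH_M = 105.0
PITCH_WIDTH_M = 68.0

#: Default column mapping for tracking files.
DEFAULT_COLUMNS: dict[str, str] = {
    "team": "team",
    "half": "half",
    "time_s": "time_s",
    "player_id": "player_id",
    "x_m": "x_m",
    "y_m": "y_m",
    "is_goalkeeper": "is_goalkeeper",
}


@dataclass(frozen=True)
class TrackingFrame:
    """One team's positions at one instant.

    Parameters
    ----------
    team_id : str
        Team identifier.
    t : float
        Time in seconds from the start of the half.
    half : int
        1 or 2.
    positions : ndarray of shape (n_players, 2)
        (x, y) in metres, pitch coordinates.
    goalkeeper_index : int or None
        Index into ``positions`` of the goalkeeper, if known.
    """

    team_id: str
    t: float
    half: int
    positions: np.ndarray
    goalkeeper_index: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise DataError("positions must be an (n, 2) array")
        if not np.all(np.isfinite(pos)):
            raise DataError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        gk = self.goalkeeper_index
        if gk is not None and not (0 <= gk < len(pos)):
            raise DataError(f"goalkeeper_index {gk} out of range")

    @property
    def n_players(self) -> int:
        return len(self.positions)


def exclude_goalkeeper(frame: TrackingFrame) -> TrackingFrame:
    """Return a frame with the goalkeeper removed (order preserved).

    If no goalkeeper is flagged the frame is returned unchanged. Raises
    :class:`DegenerateShapeError` if fewer than 3 players remain.
    """
    if frame.goalkeeper_index is None:
        return frame
    keep = np.ones(frame.n_players, dtype=bool)
    keep[frame.goalkeeper_index] = False
    remaining = frame.positions[keep]
    if len(remaining) < 3:
        raise DegenerateShapeError(
            f"only {len(remaining)} players remain after goalkeeper removal; "
            "need at least 3 for a polygon"
        )
    return replace(frame, positions=remaining, goalkeeper_index=None)


def _resolve_columns(dialect: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    if dialect is None:
        return dict(DEFAULT_COLUMNS)
    if isinstance(dialect, (str, Path)):
        with open(dialect) as fh:
            dialect = yaml.safe_load(fh)
    cols = dict(DEFAULT_COLUMNS)
    cols.update(dialect)
    return cols


def load_tracking(
    path: str | Path,
    dialect: Mapping[str, str] | str | Path | None = None,
) -> list[TrackingFrame]:
    """Read tracking frames from a delimited text file.

    Parameters
    ----------
    path : path
        CSV/TSV file with one row per (team, instant, player). The
        delimiter is sniffed.
    dialect : mapping, YAML path, or None
        Column mapping overriding :data:`DEFAULT_COLUMNS`. The
        ``is_goalkeeper`` column is optional.

    Returns
    -------
    list of TrackingFrame
        One frame per (team, half, instant), ordered by team, half, time.
        Rows with missing coordinates are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"tracking file not found: {path}")
    cols = _resolve_columns(dialect)
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise DataError(f"no frames in {path}: file is empty or unreadable") from None

    required = [cols["team"], cols["half"], cols["time_s"], cols["x_m"], cols["y_m"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"missing mapped columns {missing} in {path}")

    n_before = len(df)
    df = df.dropna(subset=[cols["x_m"], cols["y_m"]])
    dropped = n_before - len(df)
    if dropped:
        logger.warning("dropped %d rows with missing coordinates", dropped)

    has_gk = cols["is_goalkeeper"] in df.columns
    frames: list[TrackingFrame] = []
    keys = [cols["team"], cols["half"], cols["time_s"]]
    for (team, half, t), grp in df.groupby(keys, sort=True):
        positions = grp[[cols["x_m"], cols["y_m"]]].to_numpy(dtype=float)
        gk_index = None
        if has_gk:
            flags = grp[cols["is_goalkeeper"]].to_numpy()
            hits = np.flatnonzero(flags.astype(bool))
            if len(hits):
                gk_index = int(hits[0])
        frames.append(
            TrackingFrame(
                team_id=str(team),
                t=float(t),
                half=int(half),
                positions=positions,
                goalkeeper_index=gk_index,
            )
        )
    if not frames:
        raise DataError(f"no frames in {path}")
    return frames
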