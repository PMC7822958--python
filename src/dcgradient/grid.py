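"""Channel geometry and the stream/level analysis skeleton.

The probe covers the forehead with a diamond lattice of measurement
channels.  Within each hemisphere the analyzed channels form four
parallel *streams* running rostro-caudally, each comprising four
*levels* (level 1 = most rostral).  Channels that lie between adjacent
optodes of a rectangular optode grid sit on lattice diagonals, so the
distance between rostro-caudally neighboring channels is
``inter_optode_distance / sqrt(2)`` (3 cm optode spacing gives the
familiar 2.1 cm diagonal channel distance).

The full montage has 38 channels; only the 32 channels with a
stream/level assignment (2 hemispheres x 4 streams x 4 levels) enter the
statistical analysis.  The extra midline channels are carried with
``analyzed=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

HEMISPHERES = ("left", "right")
N_STREAMS = 4
N_LEVELS = 4


@dataclass(frozen=True)
class ChannelGrid:
    """Optode-derived channel layout with hemisphere/stream/level labels.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per channel with columns ``id`` (str), ``x``/``y``
        (positions in cm; +y is rostral), ``hemisphere`` (``left`` /
        ``right`` or missing for midline channels), ``stream`` and
        ``level`` (1-based ints, NaN for non-analyzed channels) and
        ``analyzed`` (bool).
    inter_optode_distance_cm : float
        Source-detector spacing of the optode lattice.
    """

    table: pd.DataFrame
    inter_optode_distance_cm: float = 3.0

    @property
    def diagonal_channel_distance_cm(self) -> float:
        """Distance between diagonally adjacent channels on the lattice."""
        return self.inter_optode_distance_cm / np.sqrt(2.0)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def analyzed(self) -> pd.DataFrame:
        """Sub-table of channels carrying a stream/level assignment."""
        return self.table[self.table["analyzed"]]

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def n_analyzed(self) -> int:
        return int(self.table["analyzed"].sum())

    def channel_id(self, hemisphere: str, stream: int, level: int) -> str:
        """Return the id of the analyzed channel at a grid position."""
        t = self.analyzed
        m = (
            (t["hemisphere"] == hemisphere)
            & (t["stream"] == stream)
            & (t["level"] == level)
        )
        if m.sum() != 1:
            raise ConfigurationError(
                f"no unique channel at hemisphere={hemisphere!r}, "
                f"stream={stream}, level={level}"
            )
        return str(t.loc[m, "id"].iloc[0])

    def positions(self, ids: list[str] | None = None) -> np.ndarray:
        """(n, 2) array of channel positions, ordered like ``ids``."""
        t = self.table.set_index("id")
        if ids is None:
            ids = self.channel_ids
        return t.loc[ids, ["x", "y"]].to_numpy(dtype=float)

    def to_config(self) -> dict:
        channels = []
        for _, row in self.table.iterrows():
            channels.append(
                {
                    "id": str(row["id"]),
                    "x": float(row["x"]),
                    "y": float(row["y"]),
                    "hemisphere": None if pd.isna(row["hemisphere"]) else str(row["hemisphere"]),
                    "stream": None if pd.isna(row["stream"]) else int(row["stream"]),
                    "level": None if pd.isna(row["level"]) else int(row["level"]),
                    "analyzed": bool(row["analyzed"]),
                }
            )
        return {
            "inter_optode_distance_cm": float(self.inter_optode_distance_cm),
            "channels": channels,
        }


def default_layout(full: bool = False, inter_optode_distance_cm: float = 3.0) -> dict:
    """Build the default schematic forehead layout.

    The analyzed sub-grid has, per hemisphere, 4 streams x 4 levels on a
    diamond lattice: successive levels within a stream are diagonal
    lattice neighbors (offset by half the optode spacing in both x and
    y), so their distance is ``inter_optode_distance / sqrt(2)``.

    With ``full=True`` six additional midline channels (no stream/level
    assignment) are appended, giving the 38-channel montage; the default
    is the 32-channel analyzed sub-grid.
    """
    a = inter_optode_distance_cm
    channels = []
    for hemisphere, sign in (("left", -1.0), ("right", 1.0)):
        for stream in range(1, N_STREAMS + 1):
            for level in range(1, N_LEVELS + 1):
                # diamond lattice: odd levels are shifted laterally by a/2
                x = sign * (a / 2.0 + (stream - 1) * a + (level % 2) * (a / 2.0))
                y = -(level - 1) * (a / 2.0)
                channels.append(
                    {
                        "id": f"{hemisphere[0].upper()}{stream}-{level}",
                        "x": x,
                        "y": y,
                        "hemisphere": hemisphere,
                        "stream": stream,
                        "level": level,
                        "analyzed": True,
                    }
                )
    if full:
        for k in range(6):
            channels.append(
                {
                    "id": f"M{k + 1}",
                    "x": 0.0,
                    "y": -k * (a / 2.0),
                    "hemisphere": None,
                    "stream": None,
                    "level": None,
                    "analyzed": False,
                }
            )
    return {"inter_optode_distance_cm": a, "channels": channels}


def build_channel_grid(layout: dict | None = None) -> ChannelGrid:
    """Validate a layout config and return a :class:`ChannelGrid`.

    Raises
    ------
    ConfigurationError
        On duplicate channel ids, duplicate or missing stream/level
        assignments, or levels that are not strictly ordered
        rostro-caudally (decreasing y) within a stream.
    """
    if layout is None:
        layout = default_layout()
    try:
        table = pd.DataFrame(layout["channels"])
        a = float(layout.get("inter_optode_distance_cm", 3.0))
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed layout config: {exc}") from exc
    required = {"id", "x", "y", "hemisphere", "stream", "level"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"layout lacks channel fields: {sorted(missing)}")
    if "analyzed" not in table.columns:
        table["analyzed"] = table["stream"].notna() & table["level"].notna()
    table["analyzed"] = table["analyzed"].astype(bool)
    if a <= 0:
        raise ConfigurationError("inter_optode_distance_cm must be > 0")

    ids = table["id"].astype(str)
    if ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise ConfigurationError(f"duplicate channel ids: {dup}")
    table["id"] = ids

    analyzed = table[table["analyzed"]]
    if analyzed.empty:
        raise ConfigurationError("layout has no analyzed (stream/level) channels")
    # the analyzed sub-grid must be a complete streams x levels rectangle
    # within each hemisphere present (4 x 4 in the default montage)
    for hemisphere in sorted(analyzed["hemisphere"].dropna().unique()):
        sub = analyzed[analyzed["hemisphere"] == hemisphere]
        streams = sorted(int(s) for s in sub["stream"].unique())
        levels = sorted(int(v) for v in sub["level"].unique())
        seen: dict[tuple[int, int], str] = {}
        for _, row in sub.iterrows():
            key = (int(row["stream"]), int(row["level"]))
            if key in seen:
                raise ConfigurationError(
                    f"duplicate assignment {hemisphere} stream {key[0]} "
                    f"level {key[1]}: {seen[key]} and {row['id']}"
                )
            seen[key] = row["id"]
        for stream in streams:
            for level in levels:
                if (stream, level) not in seen:
                    raise ConfigurationError(
                        f"layout missing {hemisphere} stream {stream} level {level}"
                    )
        # rostral (low level) channels must lie anterior to caudal ones
        for stream in streams:
            chain = sub[sub["stream"] == stream].sort_values("level")
            ys = chain["y"].to_numpy(dtype=float)
            if not np.all(np.diff(ys) < 0):
                raise ConfigurationError(
                    f"levels of {hemisphere} stream {stream} are not strictly "
                    "ordered rostro-caudally (y must decrease with level)"
                )
    return ChannelGrid(table=table.reset_index(drop=True), inter_optode_distance_cm=a)
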