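"""Stream/level connection extraction and hemisphere labelling.

From a full directed-coherence matrix, only influences between directly
neighboring levels along each rostro-caudal stream enter the
statistics: per hemisphere, 4 streams x 3 adjacent level pairs = 12
connections, each read out in both directions (rostro-caudal =
influence from the lower, more rostral level onto the higher one), for
48 rows per measurement.  Hemispheres are relabelled ipsi-/contralateral
with respect to the hemisphere of disease onset, taken as the
hemisphere in which the disease process began, i.e. contralateral to
the first symptomatic body side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import DCMatrix
from .exceptions import DataError
from .grid import ChannelGrid

DIRECTIONS = ("rostro-caudal", "caudo-rostral")


def extract_stream_connections(
    dc: DCMatrix,
    grid: ChannelGrid,
    participant: str | None = None,
    state: str | None = None,
) -> pd.DataFrame:
    """Long-format table of neighboring-level DC values along each stream.

    Columns: hemisphere, stream, level_pair (``"1-2"`` etc.), direction,
    dc, plus participant/state identifiers when given.
    """
    index = {c: i for i, c in enumerate(dc.channel_ids)}
    analyzed = grid.analyzed
    missing = sorted(set(analyzed["id"]) - set(index))
    if missing:
        raise DataError(f"channels absent from DC matrix: {missing}")
    rows = []
    for hemisphere in sorted(analyzed["hemisphere"].unique()):
        for stream in sorted(analyzed["stream"].unique()):
            chain = analyzed[
                (analyzed["hemisphere"] == hemisphere) & (analyzed["stream"] == stream)
            ].sort_values("level")
            ids = list(chain["id"])
            levels = [int(v) for v in chain["level"]]
            for (la, ca), (lb, cb) in zip(
                zip(levels[:-1], ids[:-1]), zip(levels[1:], ids[1:])
            ):
                pair = f"{la}-{lb}"
                i_a, i_b = index[ca], index[cb]
                rows.append(
                    (hemisphere, stream, pair, "rostro-caudal", float(dc.dc[i_b, i_a]))
                )
                rows.append(
                    (hemisphere, stream, pair, "caudo-rostral", float(dc.dc[i_a, i_b]))
                )
    table = pd.DataFrame(
        rows, columns=["hemisphere", "stream", "level_pair", "direction", "dc"]
    )
    if table["dc"].isna().any():
        bad = table[table["dc"].isna()]
        raise DataError(
            "DC matrix has missing values for stream connections: "
            f"{bad[['hemisphere', 'stream', 'level_pair']].to_dict('records')[:3]}"
        )
    if participant is not None:
        table.insert(0, "participant", participant)
    if state is not None:
        table.insert(1 if participant is not None else 0, "state", state)
    return table


def label_hemispheres(table: pd.DataFrame, side_of_onset) -> pd.DataFrame:
    """Attach ipsi/contra labels relative to the hemisphere of disease onset.

    ``side_of_onset`` refers to the body side of first motor symptoms;
    the *hemisphere* of disease onset is the contralateral one, which is
    labelled ``ipsi``.  ``side_of_onset`` may be a single string or a
    mapping/Series from participant id to side; rows whose side is
    missing raise a :class:`DataError` (such participants must be
    excluded upstream).
    """
    out = table.copy()
    if isinstance(side_of_onset, str):
        sides = pd.Series(side_of_onset, index=out.index)
    else:
        if "participant" not in out.columns:
            raise DataError("per-participant sides require a 'participant' column")
        mapping = dict(side_of_onset)
        sides = out["participant"].map(mapping)
    if sides.isna().any():
        missing = sorted(out.loc[sides.isna(), "participant"].unique())
        raise DataError(f"no record of side of disease onset for: {missing}")
    bad = ~sides.isin(["left", "right"])
    if bad.any():
        raise DataError(f"invalid side_of_onset values: {sorted(sides[bad].unique())}")
    onset_hemisphere = sides.map({"left": "right", "right": "left"})
    out["hemisphere_label"] = np.where(
        out["hemisphere"] == onset_hemisphere, "ipsi", "contra"
    )
    return out


def project_summary(
    table: pd.DataFrame,
    covariate: str | None = None,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Mean DC by direction x level pair, optionally split by covariate terciles.

    Tercile (or ``n_groups``-tile) boundaries are computed on the
    participant-level covariate values, not on connection rows, so the
    groups partition participants.  Empty cells are kept as NaN rows and
    flagged in the ``empty`` column rather than raising.
    """
    if table.empty:
        raise DataError("cannot summarize an empty connection table")
    keys = ["direction", "level_pair"]
    work = table.copy()
    if covariate is not None:
        per_participant = work.groupby("participant")[covariate].first()
        groups = pd.qcut(per_participant, n_groups, labels=False, duplicates="drop")
        work["covariate_group"] = work["participant"].map(groups)
        keys = ["covariate_group"] + keys
    agg = work.groupby(keys, observed=True)["dc"].agg(["mean", "count"]).reset_index()
    agg = agg.rename(columns={"mean": "dc_mean", "count": "n"})
    agg["empty"] = agg["n"] == 0
    return agg


def participant_tercile_sizes(values: pd.Series, n_groups: int = 3) -> list[int]:
    """Group sizes of an ``n_groups``-tile split of participant-level values."""
    groups = pd.qcut(values, n_groups, labels=False, duplicates="drop")
    return groups.value_counts().sort_index().tolist()
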