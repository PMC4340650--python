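"""Long-format plate-table parsing shared by the growth and reporter modules.

The on-disk schema is one row per readout:
``time_h, well, channel, value`` with channel in {OD, GFP}.  A well map
(YAML file or plain dict) attaches strain / reporter metadata to wells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .errors import PlateFormatError

REQUIRED_COLUMNS = ("time_h", "well", "channel", "value")


def load_well_map(well_map) -> dict | None:
    """Accept a dict, a YAML path, or None."""
    if well_map is None or isinstance(well_map, dict):
        return well_map
    with open(well_map) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise PlateFormatError("well map must be a mapping of well -> metadata")
    return loaded


def read_plate_long(path, well_map=None) -> tuple[pd.DataFrame, dict | None]:
    """Parse and validate a long-format plate CSV.

    Returns the validated frame (sorted by well, channel, time) and the
    loaded well map.  Raises :class:`PlateFormatError` naming offending
    rows for missing columns, non-numeric values, duplicated
    (well, channel, time) readouts, or wells absent from the map.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing required columns: {missing}")

    for col in ("time_h", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # 1-based + header
            raise PlateFormatError(
                f"non-numeric {col!r} values at file rows {rows}")
        if coerced.isna().any():
            rows = ", ".join(str(i + 2) for i in df.index[coerced.isna()][:5])
            raise PlateFormatError(f"empty {col!r} values at file rows {rows}")
        df[col] = coerced

    dup = df.duplicated(subset=["well", "channel", "time_h"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise PlateFormatError(
            "duplicated readout for well "
            f"{first['well']!r} channel {first['channel']!r} "
            f"at t={first['time_h']} h")

    wmap = load_well_map(well_map)
    if wmap is not None:
        unmapped = sorted(set(df["well"]) - set(wmap))
        if unmapped:
            raise PlateFormatError(f"wells absent from the well map: {unmapped}")

    return df.sort_values(["well", "channel", "time_h"],
                          kind="stable").reset_index(drop=True), wmap


def well_series(df: pd.DataFrame, well: str,
                channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, value) arrays for one well/channel, time-sorted."""
    sub = df[(df["well"] == well) & (df["channel"] == channel)]
    if sub.empty:
        raise PlateFormatError(f"well {well!r} has no {channel} channel")
    return (sub["time_h"].to_numpy(dtype=float),
            sub["value"].to_numpy(dtype=float))
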