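"""Tab-separated serialisation of trajectories, profiles and summaries.

Every file starts with a comment line naming the package version and the
effective seed, then a mandatory header row.  Floats are written with 17
significant digits so trajectories round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .adaptation import Trajectory

__all__ = [
    "write_table",
    "read_table",
    "write_trajectory",
    "read_trajectory",
]


def _stamp(seed) -> str:
    return f"# her6switch {__version__} seed={seed}\n"


def write_table(df: pd.DataFrame, path, seed="none") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_stamp(seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_trajectory(traj: Trajectory, path, seed="none") -> None:
    write_table(traj.to_frame(), path, seed=seed)


def read_trajectory(path) -> Trajectory:
    df = read_table(path)
    y = df["Y"].to_numpy() if "Y" in df.columns else None
    return Trajectory(
        t=df["time"].to_numpy(),
        m=df["m"].to_numpy(),
        h=df["h"].to_numpy(),
        X=df["X"].to_numpy(),
        Y=y,
    )
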