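"""2AFC velocity comparison: proportion-"faster" grids and PSE extraction.

Responses are tabulated per subject into a comparison-velocity x noise-level
grid of the proportion of "faster" judgments relative to the 6 deg/s
zero-noise reference, marginalizing the presentation order.  The point of
subjective equality (PSE) per noise level is the velocity at which the
proportion crosses 0.5, found by piecewise-linear interpolation along the
velocity axis; cells that sit exactly at 0.5 are averaged into one PSE, and a
non-monotone profile is resolved by taking the first upward crossing scanning
from low to high velocity (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PseEstimate", "tabulate", "pse_from_grid", "pse_table"]


@dataclass
class PseEstimate:
    subject: int
    noise: float
    pse: float
    flag: str


def tabulate(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-cell counts and proportion of "faster" responses.

    Returns one row per (subject, velocity, noise) with ``n``, ``n_faster``
    and ``prop``; cells absent from the data are not fabricated.
    """
    for col in ("subject", "velocity", "noise", "response"):
        if col not in trials.columns:
            raise ValueError(f"missing column {col!r}")
    bad = set(trials["response"].unique()) - {"faster", "slower"}
    if bad:
        raise ValueError(f"responses must be 'faster'/'slower', got {sorted(bad)}")
    grid = (
        trials.assign(faster=lambda d: (d["response"] == "faster").astype(int))
        .groupby(["subject", "velocity", "noise"], as_index=False)
        .agg(n=("faster", "size"), n_faster=("faster", "sum"))
    )
    grid["prop"] = grid["n_faster"] / grid["n"]
    return grid


def _pse_one(vel: np.ndarray, prop: np.ndarray) -> tuple[float, str]:
    """0.5-crossing of one proportion-vs-velocity profile."""
    flags = []
    if np.any(np.diff(prop) < 0):
        flags.append("non-monotone")
    exact = np.isclose(prop, 0.5)
    if exact.any():
        if exact.sum() > 1:
            flags.append("multiple-crossing")
        return float(vel[exact].mean()), ",".join(flags)
    for i in range(len(vel) - 1):
        lo, hi = prop[i], prop[i + 1]
        if lo < 0.5 < hi:  # first upward crossing
            pse = vel[i] + (0.5 - lo) / (hi - lo) * (vel[i + 1] - vel[i])
            return float(pse), ",".join(flags)
    flags.append("out-of-range")
    return float("nan"), ",".join(flags)


def pse_from_grid(grid: pd.DataFrame) -> list[PseEstimate]:
    """PSE per subject per noise level from a tabulated proportion grid."""
    out = []
    for (subject, noise), sub in grid.groupby(["subject", "noise"]):
        sub = sub.sort_values("velocity")
        ok = sub["prop"].notna()
        if ok.sum() < 2:
            out.append(PseEstimate(int(subject), float(noise), float("nan"), "too-few-cells"))
            continue
        pse, flag = _pse_one(
            sub.loc[ok, "velocity"].to_numpy(float), sub.loc[ok, "prop"].to_numpy(float)
        )
        out.append(PseEstimate(int(subject), float(noise), pse, flag))
    return out


def pse_table(trials: pd.DataFrame) -> pd.DataFrame:
    """End-to-end: 2AFC trials -> tidy PSE table feeding the slope model."""
    estimates = pse_from_grid(tabulate(trials))
    return pd.DataFrame(
        [
            {"subject": e.subject, "noise": e.noise, "pse_deg_s": e.pse, "flag": e.flag}
            for e in estimates
        ]
    )
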