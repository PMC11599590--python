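"""Exponential decay of deletion frequency with inter-microhomology distance.

Deletions between two copies of an exact repeat ("microhomology", MH) of
size ``s`` separated by ``d`` intervening bases occur with frequency well
described by ``y_s = A * exp(B * d)`` with ``A > 0`` and ``B < 0``: longer
microhomologies that lie closer together are used more often.  This module
collects (s, d, y) observations from outcome profiles and fits the law per
MH size (2..15) and cell line by nonlinear least squares.

The distance ``d`` is the number of bases strictly between the two repeat
copies, i.e. ``deletion size - s``; start-to-start distance differs by the
constant ``s`` and only changes the interpretation of ``A``
(``--distance-def`` selects between the two).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .indel_core import TargetSite, annotate

__all__ = [
    "MHRegressionFit",
    "collect_observations",
    "fit_exponential",
    "fit_all",
    "MH_SIZE_RANGE",
]

log = logging.getLogger(__name__)

MH_SIZE_RANGE = range(2, 16)


@dataclass
class MHRegressionFit:
    """Result of fitting ``y = A * exp(B * d)`` for one (MH size, line)."""

    s: int
    line: str
    A: float
    B: float
    n_obs: int
    converged: bool
    rss: float = float("nan")
    reason: str = ""


def _exp_model(d: np.ndarray, A: float, B: float) -> np.ndarray:
    return A * np.exp(B * d)


def collect_observations(
    profiles: pd.DataFrame,
    targets: Iterable[TargetSite],
    mh_min: int = 2,
    distance_def: str = "gap",
) -> pd.DataFrame:
    """One observation per microhomology deletion outcome per (target, line).

    ``s`` is the MH length, ``d`` the inter-repeat distance (``gap``:
    ``del_size - s``; ``start``: ``del_size``), ``y`` the outcome frequency.
    Observations with ``s > 15`` are retained but excluded from fitting by
    default.
    """
    if distance_def not in ("gap", "start"):
        raise ValueError("distance_def must be 'gap' or 'start'")
    tmap = {t.id: t for t in targets}
    rows = []
    for tid, line, outcome, freq in zip(
        profiles["target"], profiles["line"], profiles["outcome"], profiles["freq"]
    ):
        ann = annotate(tmap[tid], outcome)
        if ann.ins_size > 0 or ann.mh_len < mh_min:
            continue
        d = ann.del_size - ann.mh_len if distance_def == "gap" else ann.del_size
        rows.append((line, tid, outcome, ann.mh_len, d, freq))
    return pd.DataFrame(rows, columns=["line", "target", "outcome", "s", "d", "y"])


def fit_exponential(d: np.ndarray, y: np.ndarray, s: int = 0, line: str = "") -> MHRegressionFit:
    """Least-squares fit of ``y = A * exp(B * d)``.

    Initialization ``A0 = max(y)``, ``B0 = -0.1``.  Underdetermined input
    (fewer than 3 observations or fewer than 2 distinct distances) yields an
    explicit no-fit result rather than NaN parameters from a silent failure.
    """
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(d) < 3 or len(np.unique(d)) < 2:
        return MHRegressionFit(s, line, np.nan, np.nan, len(d), False, reason="underdetermined")
    try:
        popt, _ = curve_fit(_exp_model, d, y, p0=(float(y.max()), -0.1), maxfev=10_000)
    except RuntimeError as exc:
        return MHRegressionFit(s, line, np.nan, np.nan, len(d), False, reason=str(exc))
    A, B = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - _exp_model(d, A, B)) ** 2))
    return MHRegressionFit(s, line, A, B, len(d), True, rss=rss)


def fit_all(
    profiles: pd.DataFrame,
    targets: Iterable[TargetSite],
    mh_min: int = 2,
    distance_def: str = "gap",
) -> pd.DataFrame:
    """Fit the exponential law for every MH size 2..15 in every cell line.

    Returns a tidy table with one row per (line, s) including no-fit rows
    (``converged == False``).
    """
    obs = collect_observations(profiles, targets, mh_min=mh_min, distance_def=distance_def)
    rows = []
    for line in sorted(profiles["line"].unique()):
        line_obs = obs[obs["line"] == line]
        for s in MH_SIZE_RANGE:
            sub = line_obs[line_obs["s"] == s]
            fit = fit_exponential(sub["d"].to_numpy(), sub["y"].to_numpy(), s=s, line=line)
            if not fit.converged:
                log.debug("no fit for line=%s s=%d: %s", line, s, fit.reason)
            rows.append(
                {
                    "line": line,
                    "s": s,
                    "A": fit.A,
                    "B": fit.B,
                    "n_obs": fit.n_obs,
                    "converged": fit.converged,
                    "rss": fit.rss,
                }
            )
    return pd.DataFrame(rows)
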