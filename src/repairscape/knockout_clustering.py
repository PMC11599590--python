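"""Outcome x knockout fold-change matrix, embedding, clustering and summaries.

Outcomes that respond similarly to repair-gene knockouts share a repair
mechanism.  This module builds the (target, outcome) x knockout-line matrix
of log2 fold changes versus control, embeds it in two dimensions with UMAP,
groups rows by k-means on the embedding, and quantifies cluster composition
(category distributions weighted by control frequency), per-knockout
enrichment, and deletion directionality per cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .indel_core import CATEGORIES, TargetSite, annotate

__all__ = [
    "LFCMatrix",
    "EmbeddingResult",
    "build_lfc_matrix",
    "embed",
    "cluster",
    "cluster_composition",
    "cluster_knockout_enrichment",
    "directionality_summary",
]

log = logging.getLogger(__name__)


@dataclass
class LFCMatrix:
    """Retained (target, outcome) rows x knockout lines, entries are LFCs.

    ``values`` is indexed by ``(target, outcome)``; ``meta`` is row-aligned
    with columns ``category, del_size, mh_len, control_freq, directionality``
    (directionality is NaN for non-deletions).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def lines(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EmbeddingResult:
    """2-D embedding coordinates and cluster labels for the matrix rows."""

    coords: np.ndarray
    labels: np.ndarray | None
    n_neighbors: int
    min_dist: float
    seed: int


def build_lfc_matrix(
    profiles: pd.DataFrame,
    targets: Iterable[TargetSite],
    control_line: str,
    pc: float = 0.001,
    min_lines: int = 10,
    mh_min: int = 2,
) -> LFCMatrix:
    """Build the outcome-response matrix with the two presence filters.

    Rows are (target, outcome) pairs observed in the control line AND in at
    least ``min_lines`` knockout lines; remaining entries are
    ``log2((f_ko + pc) / (f_ctrl + pc))`` with absent frequencies taken as
    0, so the matrix has no missing values.  The frequency mass removed by
    the filters is logged.
    """
    lines = sorted(l for l in profiles["line"].unique() if l != control_line)
    if len(lines) < 2:
        raise ValueError("need at least 2 knockout lines besides the control")
    if control_line not in set(profiles["line"]):
        raise ValueError(f"control line {control_line!r} absent from profiles")

    wide = profiles.pivot_table(
        index=["target", "outcome"], columns="line", values="freq", fill_value=0.0
    ).reindex(columns=[control_line] + lines, fill_value=0.0)

    in_control = wide[control_line] > 0
    n_ko = (wide[lines] > 0).sum(axis=1)
    keep = in_control & (n_ko >= min_lines)
    removed = wide[~keep]
    if len(removed):
        log.info(
            "presence filters removed %d of %d rows (mean control frequency "
            "of removed rows %.4f)",
            len(removed), len(wide), float(removed[control_line].mean()),
        )
    wide = wide[keep]
    if wide.empty:
        raise ValueError("no (target, outcome) rows survive the presence filters")

    f_ctrl = wide[control_line].to_numpy()[:, None]
    lfc = np.log2((wide[lines].to_numpy() + pc) / (f_ctrl + pc))
    values = pd.DataFrame(lfc, index=wide.index, columns=lines)

    tmap = {t.id: t for t in targets}
    meta_rows = []
    for (tid, outcome), f0 in zip(wide.index, wide[control_line]):
        ann = annotate(tmap[tid], outcome, mh_min)
        meta_rows.append(
            {
                "category": ann.category.value,
                "del_size": ann.del_size,
                "mh_len": ann.mh_len,
                "control_freq": float(f0),
                "directionality": ann.directionality,
            }
        )
    meta = pd.DataFrame(meta_rows, index=wide.index)
    return LFCMatrix(values, meta)


def embed(
    matrix: LFCMatrix,
    n_neighbors: int = 50,
    min_dist: float = 0.0,
    seed: int = 0,
) -> EmbeddingResult:
    """UMAP embedding of the LFC matrix rows, deterministic per seed.

    ``n_neighbors`` is clipped (with a warning) when the matrix has fewer
    than ``n_neighbors + 1`` rows.
    """
    X = matrix.values.to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValueError("LFC matrix contains non-finite entries")
    n = len(X)
    if n_neighbors + 1 > n:
        warnings.warn(
            f"n_neighbors={n_neighbors} clipped to {n - 1} for {n} rows", stacklevel=2
        )
        n_neighbors = n - 1
    import umap  # deferred: numba compilation is slow to import

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_neighbors=n_neighbors, min_dist=min_dist, n_components=2, random_state=seed
        )
        coords = reducer.fit_transform(X)
    return EmbeddingResult(np.asarray(coords, dtype=float), None, n_neighbors, min_dist, seed)


def cluster(coords: np.ndarray, k: int = 7, seed: int = 0, n_init: int = 50) -> np.ndarray:
    """k-means labels (1..k) on embedding coordinates, deterministic per seed."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite entries")
    if k > len(coords):
        raise ValueError(f"k={k} exceeds number of rows {len(coords)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(coords) + 1


def cluster_composition(
    labels: np.ndarray,
    categories: pd.Series | np.ndarray,
    control_freqs: pd.Series | np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster/category composition tables in percent.

    ``E``: distribution of each category over clusters -- each *column*
    (category) sums to 100%.  ``F``: category make-up of each cluster --
    each *row* (cluster) sums to 100%.  Rows are weighted by control-line
    frequency when ``control_freqs`` is given, else counted equally.
    """
    labels = np.asarray(labels)
    categories = np.asarray(categories)
    w = np.ones(len(labels)) if control_freqs is None else np.asarray(control_freqs, float)
    df = pd.DataFrame({"cluster": labels, "category": categories, "w": w})
    mass = (
        df.pivot_table(index="cluster", columns="category", values="w",
                       aggfunc="sum", fill_value=0.0)
        .reindex(columns=[c for c in CATEGORIES if c in set(categories)], fill_value=0.0)
    )
    E = 100.0 * mass / mass.sum(axis=0)
    F = 100.0 * mass.div(mass.sum(axis=1), axis=0)
    return E, F


def cluster_knockout_enrichment(labels: np.ndarray, matrix: LFCMatrix) -> pd.DataFrame:
    """Mean LFC of each cluster minus the overall mean, per knockout column.

    Entry (cluster c, knockout g) is positive when outcomes in c respond
    more (are relatively enriched) in knockout g than the average outcome.
    Columns have size-weighted mean zero.  Empty clusters yield NaN rows
    with a warning.
    """
    labels = np.asarray(labels)
    X = matrix.values
    overall = X.mean(axis=0)
    rows = {}
    for c in sorted(set(labels)):
        mask = labels == c
        if not mask.any():
            warnings.warn(f"cluster {c} is empty", stacklevel=2)
            rows[c] = pd.Series(np.nan, index=X.columns)
        else:
            rows[c] = X[mask].mean(axis=0) - overall
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    return out


def directionality_summary(
    matrix: LFCMatrix, labels: np.ndarray, mh_min: int = 2
) -> pd.DataFrame:
    """Per-cluster deletion directionality of non-homologous deletions.

    Restricted to pure deletions with ``mh_len < mh_min``.  Returns one row
    per cluster (clusters without qualifying deletions are omitted with a
    warning) plus a ``library`` row with the overall average.
    """
    labels = np.asarray(labels)
    meta = matrix.meta
    qualifying = (meta["mh_len"] >= 0) & (meta["mh_len"] < mh_min) & (meta["del_size"] > 0)
    rows = []
    for c in sorted(set(labels)):
        mask = qualifying.to_numpy() & (labels == c)
        if not mask.any():
            warnings.warn(f"cluster {c} has no non-homologous deletions", stacklevel=2)
            continue
        d = meta.loc[mask, "directionality"]
        rows.append({"cluster": str(c), "n": int(mask.sum()),
                     "mean_directionality": float(d.mean())})
    d_all = meta.loc[qualifying, "directionality"]
    rows.append({"cluster": "library", "n": int(qualifying.sum()),
                 "mean_directionality": float(d_all.mean())})
    return pd.DataFrame(rows)
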