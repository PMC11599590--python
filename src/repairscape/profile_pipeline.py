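"""From read-count tables to outcome profiles, category aggregates and LFCs.

The stages mirror a knockout screen's processing order: filter targets on
per-sample mutated-read coverage, drop single-read outcomes, pool
replicates and timepoints into one profile per (target, line), aggregate
into the ten outcome categories, compute pseudocounted log2 fold changes
versus the control line, and summarize 1 bp-insertion templating by
cut-flank pair with bootstrap confidence intervals.

Profiles are long-format DataFrames with columns
``target, line, outcome, count, total, freq`` where ``freq = count / total``
and ``total`` is the pooled mutated read count of the (target, line) pair.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .indel_core import CATEGORIES, FlankMatch, TargetSite, annotate

__all__ = [
    "filter_and_pool",
    "aggregate_categories",
    "lfc",
    "summarize_lfc",
    "insertion_flank_summary",
]

log = logging.getLogger(__name__)

PROFILE_COLUMNS = ["target", "line", "outcome", "count", "total", "freq"]


def filter_and_pool(records: pd.DataFrame, min_reads: int = 100) -> pd.DataFrame:
    """Filter raw counts and pool replicates/timepoints into profiles.

    * Any target with fewer than ``min_reads`` mutated reads in any
      observed (line, replicate, timepoint) sample -- including samples in
      which it is entirely absent -- is dropped everywhere, so surviving
      targets are comparable across lines.
    * Outcomes observed in exactly one read summed across all samples are
      dropped.
    * Surviving counts are summed over replicates and timepoints into one
      profile per (target, line).
    """
    required = {"target", "line", "replicate", "timepoint", "outcome", "count"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("empty records table")

    # coverage filter against the full observed sample grid
    sample_totals = (
        records.groupby(["target", "line", "replicate", "timepoint"], sort=False)["count"]
        .sum()
        .unstack(["line", "replicate", "timepoint"], fill_value=0)
    )
    ok = (sample_totals >= min_reads).all(axis=1)
    kept_targets = set(sample_totals.index[ok])
    dropped = set(sample_totals.index[~ok])
    if dropped:
        log.info("coverage filter (<%d reads): dropped %d targets", min_reads, len(dropped))
    if not kept_targets:
        raise ValueError(f"no targets survive the >= {min_reads} read coverage filter")
    df = records[records["target"].isin(kept_targets)]

    # single-read outcomes across all samples
    outcome_totals = df.groupby(["target", "outcome"], sort=False)["count"].transform("sum")
    singles = outcome_totals == 1
    if singles.any():
        log.info("dropped %d single-read (target, outcome) rows", int(singles.sum()))
    df = df[~singles]

    pooled = (
        df.groupby(["target", "line", "outcome"], sort=False, as_index=False)["count"]
        .sum()
        .sort_values(["target", "line", "outcome"], kind="mergesort", ignore_index=True)
    )
    totals = pooled.groupby(["target", "line"], sort=False)["count"].transform("sum")
    pooled["total"] = totals
    pooled["freq"] = pooled["count"] / totals
    return pooled


def _target_map(targets: Iterable[TargetSite]) -> dict[str, TargetSite]:
    return {t.id: t for t in targets}


def aggregate_categories(
    profiles: pd.DataFrame, targets: Iterable[TargetSite], mh_min: int = 2
) -> pd.DataFrame:
    """Ten-component category frequency vectors, one row per (target, line).

    Component ``c`` is the summed frequency of outcomes classified as ``c``;
    rows sum to 1.
    """
    tmap = _target_map(targets)
    df = profiles.copy()
    df["category"] = [
        annotate(tmap[t], o, mh_min).category.value
        for t, o in zip(df["target"], df["outcome"])
    ]
    table = (
        df.pivot_table(
            index=["target", "line"], columns="category", values="freq",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
    )
    table.columns.name = None
    return table


def lfc(
    profiles: pd.DataFrame,
    control_line: str,
    pc: float = 0.001,
    unit: str = "category",
    targets: Iterable[TargetSite] | None = None,
    mh_min: int = 2,
) -> pd.DataFrame:
    """Per-target log2 fold changes of outcome or category frequencies.

    ``lfc = log2((f_ko + pc) / (f_ctrl + pc))`` with pseudocount ``pc`` in
    frequency units.  ``unit`` is ``"category"`` (requires ``targets`` for
    classification) or ``"outcome"``.  Units absent from both lines give an
    LFC of 0 and are flagged ``absent_in_both``.  Returns a long table with
    columns ``unit, target, line, lfc, absent_in_both``.
    """
    if pc <= 0:
        raise ValueError("pseudocount must be > 0")
    lines = [l for l in profiles["line"].unique() if l != control_line]
    if control_line not in set(profiles["line"]):
        raise ValueError(f"control line {control_line!r} not present in profiles")

    out = []
    if unit == "category":
        if targets is None:
            raise ValueError("category LFCs require the target library")
        wide = aggregate_categories(profiles, targets, mh_min)
        ctrl = wide.xs(control_line, level="line")
        for line in lines:
            ko = wide.xs(line, level="line")
            common = ko.index.intersection(ctrl.index)
            k, c = ko.loc[common], ctrl.loc[common]
            vals = np.log2((k + pc) / (c + pc))
            absent = (k == 0) & (c == 0)
            long = vals.stack().rename("lfc").reset_index()
            long.columns = ["target", "unit", "lfc"]
            long["line"] = line
            long["absent_in_both"] = absent.stack().to_numpy()
            out.append(long)
    elif unit == "outcome":
        cols = ["target", "outcome", "freq"]
        ctrl = profiles.loc[profiles["line"] == control_line, cols]
        for line in lines:
            ko = profiles.loc[profiles["line"] == line, cols]
            merged = ko.merge(
                ctrl, on=["target", "outcome"], how="outer", suffixes=("_ko", "_ctrl")
            )
            # keep only targets measured in both lines
            both = set(ko["target"]) & set(ctrl["target"])
            merged = merged[merged["target"].isin(both)].fillna(0.0)
            long = pd.DataFrame(
                {
                    "target": merged["target"],
                    "unit": merged["outcome"],
                    "lfc": np.log2((merged["freq_ko"] + pc) / (merged["freq_ctrl"] + pc)),
                    "absent_in_both": (merged["freq_ko"] == 0) & (merged["freq_ctrl"] == 0),
                }
            )
            long["line"] = line
            out.append(long)
    else:
        raise ValueError("unit must be 'category' or 'outcome'")
    res = pd.concat(out, ignore_index=True)
    return res[["unit", "target", "line", "lfc", "absent_in_both"]]


def summarize_lfc(lfc_table: pd.DataFrame) -> pd.DataFrame:
    """Mean LFC over targets per (line, unit)."""
    return (
        lfc_table.groupby(["line", "unit"], sort=False)["lfc"]
        .agg(mean_lfc="mean", n_targets="size")
        .reset_index()
    )


def _bootstrap_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI of the mean, resampling targets."""
    n = len(values)
    if n == 1:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def insertion_flank_summary(
    profiles: pd.DataFrame,
    targets: Iterable[TargetSite],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """1 bp-insertion statistics per cut-flank pair for one cell line.

    ``absolute``: per flank pair, mean over targets of the total 1 bp
    insertion frequency (fraction of mutated reads).  ``share``: per flank
    pair, mean over targets of the PAM-proximal share
    ``proximal / (proximal + distal)`` of templated 1 bp cut insertions;
    targets with identical flanking nucleotides are excluded.  Both carry
    percentile bootstrap 95% CIs over targets (``n_boot`` resamples,
    deterministic per seed).
    """
    lines = profiles["line"].unique()
    if len(lines) != 1:
        raise ValueError("insertion_flank_summary expects profiles from exactly one line")
    tmap = _target_map(targets)
    rng = np.random.default_rng(seed)

    per_target = []
    for tid, grp in profiles.groupby("target", sort=True):
        target = tmap[tid]
        abs_freq = prox = dist = 0.0
        for o, f in zip(grp["outcome"], grp["freq"]):
            ann = annotate(target, o)
            if not ann.is_1bp_insertion:
                continue
            abs_freq += f
            if ann.flank_match is FlankMatch.PROXIMAL_ONLY:
                prox += f
            elif ann.flank_match is FlankMatch.DISTAL_ONLY:
                dist += f
        per_target.append(
            {
                "target": tid,
                "distal": target.pam_distal,
                "proximal": target.pam_proximal,
                "abs_freq": abs_freq,
                "share": prox / (prox + dist) if prox + dist > 0 else np.nan,
            }
        )
    pt = pd.DataFrame(per_target)
    pt["flank_pair"] = pt["distal"] + "/" + pt["proximal"]

    def summarize(frame: pd.DataFrame, col: str) -> pd.DataFrame:
        rows = []
        for pair, grp in frame.groupby("flank_pair", sort=True):
            vals = grp[col].dropna().to_numpy()
            if len(vals) == 0:
                log.warning("flank pair %s: no qualifying targets, omitted", pair)
                continue
            lo, hi = _bootstrap_ci(vals, n_boot, rng)
            rows.append(
                {
                    "flank_pair": pair,
                    "n_targets": len(vals),
                    "mean": float(vals.mean()),
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
        return pd.DataFrame(rows)

    absolute = summarize(pt, "abs_freq")
    share = summarize(pt[pt["distal"] != pt["proximal"]], "share")
    return {"absolute": absolute, "share": share, "per_target": pt}
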