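"""Synthetic target libraries and read-count datasets with planted structure.

The generator emulates the statistical shape of a self-targeting Cas9
screen: a library of NGG-targeted sites with balanced cut-flanking
dinucleotides, per-cell-line outcome distributions with planted category
effects (knockout log2 fold changes), flank-dependent 1 bp-insertion
templating biases, exponential microhomology-distance deletion weights, and
multinomial read sampling at configurable depth with replicates.

Every planted quantity is recoverable by construction:

* microhomology deletions of size ``s`` at inter-repeat distance ``d`` are
  assigned frequency ``A_s * exp(B_s * d)`` directly (frequency units);
* the total 1 bp-insertion frequency and its PAM-proximal share are set
  exactly per cut-flank pair;
* a category multiplier ``m`` scales that category's mass to exactly
  ``m``-fold its control mass (the unmodified categories absorb the
  remainder), so the planted log2 fold change is exactly ``log2(m)``;
* the non-microhomology deletion baseline decays geometrically in deletion
  size and absorbs whatever mass the planted components leave.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .indel_core import (
    CATEGORIES,
    OutcomeCategory,
    TargetSite,
    annotate,
    enumerate_outcomes,
    format_descriptor,
)

__all__ = [
    "GenerativeParams",
    "GroundTruth",
    "TargetDistribution",
    "make_library",
    "ground_truth_distribution",
    "sample_dataset",
    "make_archetype_dataset",
    "DEFAULT_MH_LAW",
    "DEFAULT_INSERTION_BIAS",
    "PRESET_MULTIPLIERS",
    "preset_params",
]

_BASES = ("A", "C", "G", "T")

# Exponential microhomology law per MH size s: weight A_s * exp(B_s * d),
# d = deletion size - s.  Longer microhomologies are both more likely (larger
# A) and less distance-penalized (less negative B).
DEFAULT_MH_LAW: dict[int, tuple[float, float]] = {
    s: (min(0.05, 0.006 * 1.3 ** (s - 2)), -0.18 + 0.008 * (s - 2)) for s in range(2, 16)
}

# Per cut-flank pair (PAM-distal base, PAM-proximal base): total 1 bp
# insertion frequency and PAM-proximal share of it.  Calibrated to the
# screen-scale picture: distal T/A sites are ~3x more insertion-prone than
# G/C (29% vs 9.7% of mutated reads), the T/G pair is almost purely distal
# (0.5% proximal) and G/T almost purely proximal (56%).
def _default_insertion_bias() -> dict[tuple[str, str], tuple[float, float]]:
    bias: dict[tuple[str, str], tuple[float, float]] = {}
    for d in _BASES:
        for p in _BASES:
            total = 0.29 if d in "TA" else 0.097
            share = 0.15
            if d == p:
                share = 0.0  # single BOTH-matching outcome, no proximal copy
            bias[(d, p)] = (total, share)
    bias[("T", "G")] = (0.29, 0.005)
    bias[("G", "T")] = (0.097, 0.56)
    return bias


DEFAULT_INSERTION_BIAS = _default_insertion_bias()

# Direction/magnitude of category multipliers for the screen's knockout
# lines, transcribed from the reported mean category fold changes.  These
# presets are illustrative defaults, not fitted values.
PRESET_MULTIPLIERS: dict[str, dict[str, float]] = {
    "control": {},
    "Nbn": {
        "DEL_MED_MH": 0.25, "DEL_MED_NOMH": 0.30, "DEL_LONG_MH": 0.25,
        "DEL_LONG_NOMH": 0.35, "INS_DIST": 2.5, "INS_PROX": 2.5, "DEL_1": 2.5,
    },
    "Polq": {"DEL_MED_MH": 0.33, "DEL_LONG_NOMH": 3.0, "INS_DIST": 1.4, "INS_PROX": 1.4},
    "Lig4": {
        "INS_DIST": 0.02, "INS_PROX": 0.5, "DEL_1": 0.4,
        "DEL_MED_MH": 1.2, "DEL_LONG_MH": 1.3, "DEL_LONG_NOMH": 1.5,
    },
    "Xlf": {"INS_DIST": 0.28, "INS_PROX": 0.4, "DEL_1": 0.4, "DEL_MED_MH": 1.3, "DEL_LONG_MH": 1.3},
    "Xrcc5": {
        "INS_DIST": 0.12, "INS_PROX": 0.054, "DEL_1": 0.4,
        "DEL_LONG_MH": 1.5, "DEL_LONG_NOMH": 1.6,
    },
    "Prkdc": {"INS_PROX": 0.20, "INS_DIST": 0.8},
    "Polm": {"INS_PROX": 0.35, "INS_DIST": 0.8},
    "Poll": {"INS_DIST": 0.6, "INS_PROX": 0.6},
}


@dataclass
class GenerativeParams:
    """Per-cell-line generative parameters.

    ``category_multipliers`` plant log2 fold changes versus the control:
    category ``c`` with multiplier ``m`` receives exactly ``m`` times its
    control mass.  The control line has all multipliers equal to 1.
    """

    line: str
    category_multipliers: dict[str, float] = dc_field(default_factory=dict)
    mh_law: dict[int, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_MH_LAW)
    )
    insertion_bias: dict[tuple[str, str], tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_INSERTION_BIAS)
    )
    other_ins_weight: float = 2e-4  # untemplated / off-cut insertion weight each
    nonmh_ratio: float = 0.85  # geometric size decay of the non-MH deletion baseline
    read_depth: float = 1000.0  # expected mutated reads per (target, replicate, timepoint)
    n_replicates: int = 2
    n_timepoints: int = 1
    fixed_depth: bool = False  # exact read_depth instead of Poisson jitter

    def __post_init__(self) -> None:
        valid = set(CATEGORIES)
        for cat, m in self.category_multipliers.items():
            if cat not in valid:
                raise ValueError(f"unknown outcome category {cat!r}")
            if not np.isfinite(m) or m < 0:
                raise ValueError(f"multiplier for {cat} must be finite and >= 0")
        for s, (A, B) in self.mh_law.items():
            if not (2 <= s <= 15):
                raise ValueError("mh_law is defined for MH sizes 2..15")
            if A < 0 or not np.isfinite(A) or not np.isfinite(B):
                raise ValueError("mh_law weights must be finite with A >= 0")
        for pair, (total, share) in self.insertion_bias.items():
            if not (0 <= total < 1 and 0 <= share <= 1):
                raise ValueError(f"insertion bias for {pair} out of range")
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates")
        if self.n_timepoints < 1:
            raise ValueError("need at least one timepoint")

    @property
    def is_control(self) -> bool:
        return all(m == 1 for m in self.category_multipliers.values())


def preset_params(line: str, **overrides) -> GenerativeParams:
    """Generative parameters for a named knockout preset."""
    if line not in PRESET_MULTIPLIERS:
        raise KeyError(f"no preset for line {line!r}; known: {sorted(PRESET_MULTIPLIERS)}")
    return GenerativeParams(
        line=line, category_multipliers=dict(PRESET_MULTIPLIERS[line]), **overrides
    )


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

_PROTOSPACER_START = 13  # fixed layout: 13 nt context, 20 nt protospacer, NGG PAM
_SEQ_LEN = 79  # exactly 30 bases 5' of the cut, 49 bases 3' of it


def make_library(
    n_targets: int,
    seed: int,
    length: int = _SEQ_LEN,
    flank_pair: tuple[str, str] | None = None,
) -> list[TargetSite]:
    """Generate a deterministic library of random NGG-bearing targets.

    Cut-flanking dinucleotides cycle through all 16 (PAM-distal,
    PAM-proximal) pairs so that flank-stratified analyses are populated
    evenly; ``flank_pair`` instead fixes one pair for every target.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if length < _SEQ_LEN:
        raise ValueError(f"length must be >= {_SEQ_LEN}")
    rng = np.random.default_rng(seed)
    pam_start = _PROTOSPACER_START + 20
    cut = pam_start - 3
    pairs = [(d, p) for d in _BASES for p in _BASES]
    order = rng.permutation(16)
    targets = []
    for i in range(n_targets):
        seq = list(rng.choice(_BASES, size=length))
        seq[pam_start + 1] = "G"
        seq[pam_start + 2] = "G"
        d, p = flank_pair if flank_pair is not None else pairs[order[i % 16]]
        seq[cut - 1] = d
        seq[cut] = p
        targets.append(
            TargetSite(f"T{i:04d}", "".join(seq), _PROTOSPACER_START, pam_start)
        )
    return targets


# ---------------------------------------------------------------------------
# ground-truth distributions
# ---------------------------------------------------------------------------


@dataclass
class TargetDistribution:
    """Exact outcome distribution at one target for one cell line."""

    target_id: str
    line: str
    descriptors: list[str]
    probs: np.ndarray
    renormalized: bool = False  # True when exact multiplier semantics were infeasible

    def as_series(self) -> pd.Series:
        return pd.Series(self.probs, index=self.descriptors, name=self.line)


@lru_cache(maxsize=None)
def _candidate_annotations(target: TargetSite):
    """Per-target candidate outcomes with descriptor/category/mh/size arrays."""
    outcomes = enumerate_outcomes(target)
    descriptors = [format_descriptor(o) for o in outcomes]
    anns = [annotate(target, d) for d in descriptors]
    categories = np.array([a.category.value for a in anns])
    mh = np.array([a.mh_len for a in anns])
    del_size = np.array([a.del_size for a in anns])
    ins_size = np.array([a.ins_size for a in anns])
    return outcomes, descriptors, categories, mh, del_size, ins_size


def _base_weights(target: TargetSite, params: GenerativeParams) -> tuple[list[str], np.ndarray]:
    """Control-line frequencies (sum to 1) before category multipliers."""
    outcomes, descriptors, categories, mh, del_size, ins_size = _candidate_annotations(target)
    n = len(outcomes)
    w = np.zeros(n)

    is_del = ins_size == 0
    # microhomology deletions: planted exponential law in frequency units
    for i in np.nonzero(is_del & (mh >= 2))[0]:
        s = min(int(mh[i]), 15)
        A, B = params.mh_law.get(s, (0.0, 0.0))
        d = int(del_size[i]) - int(mh[i])
        w[i] = A * np.exp(B * d)

    # untemplated / off-cut insertions: small flat baseline
    w[~is_del] = params.other_ins_weight

    # templated 1 bp insertions at the cut: exact total and proximal share
    cut = target.cut
    distal_base, proximal_base = target.pam_distal, target.pam_proximal
    total, share = params.insertion_bias[(distal_base, proximal_base)]
    from .indel_core import canonicalize

    idx = {d: i for i, d in enumerate(descriptors)}
    d_desc = format_descriptor(canonicalize(target, cut, cut, distal_base))
    if distal_base == proximal_base:
        w[idx[d_desc]] = total  # single BOTH-matching outcome
    else:
        p_desc = format_descriptor(canonicalize(target, cut, cut, proximal_base))
        w[idx[d_desc]] = total * (1 - share)
        w[idx[p_desc]] = total * share

    # non-MH deletions fill the remaining mass with a geometric size decay
    nonmh = is_del & (mh < 2)
    remainder = 1.0 - w.sum()
    if remainder <= 0:
        raise ValueError(
            f"target {target.id}: planted components exceed unit mass "
            f"({w.sum():.3f}); reduce mh_law amplitudes or insertion bias"
        )
    base = params.nonmh_ratio ** (del_size[nonmh] - 1)
    w[nonmh] = remainder * base / base.sum()
    return descriptors, w


def ground_truth_distribution(target: TargetSite, params: GenerativeParams) -> TargetDistribution:
    """Exact outcome distribution for one (target, cell line).

    Categories with a multiplier ``m != 1`` receive exactly ``m`` times
    their control mass; unmodified categories are rescaled to absorb the
    remainder, so the planted log2 fold change of a modified category is
    exactly ``log2(m)``.  When that is infeasible (modified mass exceeding
    1, or no unmodified mass left) the distribution falls back to plain
    renormalization and is flagged ``renormalized``.
    """
    descriptors, w = _base_weights(target, params)
    multipliers = {c: m for c, m in params.category_multipliers.items() if m != 1}
    renormalized = False
    if multipliers:
        _, _, categories, _, _, _ = _candidate_annotations(target)
        mvec = np.array([multipliers.get(c, 1.0) for c in categories])
        modified = mvec != 1.0
        scaled_mass = float((w * mvec)[modified].sum())
        free_mass = float(w[~modified].sum())
        if scaled_mass < 1.0 and free_mass > 0:
            w = w * mvec
            w[~modified] *= (1.0 - scaled_mass) / free_mass
        else:
            w = w * mvec
            renormalized = True
    total = w.sum()
    if total <= 0:
        raise ValueError(f"target {target.id}: degenerate all-zero outcome weights")
    return TargetDistribution(target.id, params.line, descriptors, w / total, renormalized)


@dataclass
class GroundTruth:
    """Exact per-(line, target) distributions plus the planted parameters."""

    distributions: dict[tuple[str, str], TargetDistribution]  # (line, target_id) -> dist
    params: dict[str, GenerativeParams]
    seed: int

    def distribution(self, line: str, target_id: str) -> pd.Series:
        return self.distributions[(line, target_id)].as_series()

    def category_masses(self, line: str, target: TargetSite, mh_min: int = 2) -> pd.Series:
        """True category frequency vector for one (line, target)."""
        dist = self.distributions[(line, target.id)]
        masses = pd.Series(0.0, index=list(CATEGORIES))
        for desc, p in zip(dist.descriptors, dist.probs):
            masses[annotate(target, desc, mh_min).category.value] += p
        return masses

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "lines": {
                name: {
                    "category_multipliers": p.category_multipliers,
                    "read_depth": p.read_depth,
                    "n_replicates": p.n_replicates,
                    "n_timepoints": p.n_timepoints,
                }
                for name, p in self.params.items()
            },
            "distributions": [
                {
                    "line": d.line,
                    "target": d.target_id,
                    "outcomes": d.descriptors,
                    "probs": [float(x) for x in d.probs],
                    "renormalized": d.renormalized,
                }
                for d in self.distributions.values()
            ],
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------


def sample_dataset(
    library: list[TargetSite],
    params_per_line: list[GenerativeParams],
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a multi-line read-count dataset from the generative model.

    For every (target, line, replicate, timepoint) the mutated read depth is
    Poisson around ``read_depth`` (or fixed) and outcome counts are a
    multinomial draw from the exact distribution.  Deterministic per seed.
    Returns the long-format counts table (zero rows omitted) and the ground
    truth; optionally writes ``targets.fasta``, ``targets.tsv``,
    ``counts.tsv`` and ``truth.json`` to ``out_dir``.
    """
    if not params_per_line:
        raise ValueError("need at least one cell line")
    if not any(p.is_control for p in params_per_line):
        raise ValueError("at least one line must be a control (all multipliers 1)")
    names = [p.line for p in params_per_line]
    if len(set(names)) != len(names):
        raise ValueError("cell line names must be unique")

    rng = np.random.default_rng(seed)
    rows_target: list[str] = []
    rows_line: list[str] = []
    rows_rep: list[int] = []
    rows_tp: list[int] = []
    rows_outcome: list[str] = []
    rows_count: list[int] = []
    dists: dict[tuple[str, str], TargetDistribution] = {}

    for params in params_per_line:
        for target in library:
            dist = ground_truth_distribution(target, params)
            dists[(params.line, target.id)] = dist
            for rep in range(1, params.n_replicates + 1):
                for tp in range(1, params.n_timepoints + 1):
                    depth = (
                        int(round(params.read_depth))
                        if params.fixed_depth
                        else int(rng.poisson(params.read_depth))
                    )
                    if depth == 0:
                        continue
                    counts = rng.multinomial(depth, dist.probs)
                    nz = np.nonzero(counts)[0]
                    rows_target.extend([target.id] * len(nz))
                    rows_line.extend([params.line] * len(nz))
                    rows_rep.extend([rep] * len(nz))
                    rows_tp.extend([tp] * len(nz))
                    rows_outcome.extend(dist.descriptors[i] for i in nz)
                    rows_count.extend(int(counts[i]) for i in nz)

    counts_df = pd.DataFrame(
        {
            "target": rows_target,
            "line": rows_line,
            "replicate": rows_rep,
            "timepoint": rows_tp,
            "outcome": rows_outcome,
            "count": rows_count,
        }
    )
    truth = GroundTruth(dists, {p.line: p for p in params_per_line}, seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rio.write_library(library, out / "targets.fasta", out / "targets.tsv")
        rio.write_counts(counts_df, out / "counts.tsv")
        truth.to_json(out / "truth.json")
    return counts_df, truth


# ---------------------------------------------------------------------------
# planted response archetypes (for the clustering stage)
# ---------------------------------------------------------------------------


def make_archetype_dataset(
    n_targets: int = 60,
    outcomes_per_target: int = 10,
    n_lines: int = 8,
    k_archetypes: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
    depth: int = 100_000,
    pc: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame, list[TargetSite]]:
    """Profiles with planted knockout-response archetypes for clustering tests.

    Each retained (target, outcome) row is assigned one of ``k_archetypes``
    response archetypes; its log2 fold change in knockout line ``l`` is the
    archetype value plus Gaussian noise of ``noise_sd``.  Knockout
    frequencies are derived from control frequencies through the
    pseudocounted fold-change definition, then converted to read counts.

    Returns ``(profiles, truth, library)`` where ``profiles`` is a pooled
    profile table covering the control line and ``n_lines`` knockouts, and
    ``truth`` maps each (target, outcome) row to its archetype.
    """
    rng = np.random.default_rng(seed)
    library = make_library(n_targets, seed=int(rng.integers(2**31)))
    lines = [f"KO{j:02d}" for j in range(n_lines)]
    # strong, balanced archetype patterns: each archetype is depleted in its
    # own block of lines and mildly enriched elsewhere
    arch = np.full((k_archetypes, n_lines), 0.5)
    block = max(1, n_lines // k_archetypes)
    for j in range(k_archetypes):
        arch[j, j * block : (j + 1) * block] = -4.0

    recs = []
    truth_rows = []
    for target in library:
        _, descriptors, _, _, _, _ = _candidate_annotations(target)
        chosen = rng.choice(len(descriptors), size=outcomes_per_target, replace=False)
        f0 = rng.dirichlet(np.full(outcomes_per_target, 2.0))
        groups = rng.integers(0, k_archetypes, size=outcomes_per_target)
        for line in ["control"] + lines:
            if line == "control":
                freqs = f0
            else:
                li = lines.index(line)
                lfc = arch[groups, li] + rng.normal(0, noise_sd, size=outcomes_per_target)
                freqs = np.maximum((f0 + pc) * 2.0**lfc - pc, 1e-6)
            counts = np.maximum(np.round(freqs * depth).astype(int), 1)
            for j, ci in enumerate(chosen):
                recs.append((target.id, line, 1, 1, descriptors[ci], int(counts[j])))
        for j, ci in enumerate(chosen):
            truth_rows.append((target.id, descriptors[ci], int(groups[j])))

    counts_df = pd.DataFrame(
        recs, columns=["target", "line", "replicate", "timepoint", "outcome", "count"]
    )
    truth = pd.DataFrame(truth_rows, columns=["target", "outcome", "archetype"])
    from .profile_pipeline import filter_and_pool

    profiles = filter_and_pool(counts_df, min_reads=1)
    return profiles, truth, library
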