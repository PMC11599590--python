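"""Per-cell-line predictive models of Cas9 outcome profiles.

The model is a conditional softmax over each target's enumerated candidate
outcomes: every insertion of 1-2 nt within 3 nt of the cut and every
deletion of 1-30 nt touching the cut.  Candidates are encoded as binary
feature vectors (size, boundary offsets, inserted sequence, microhomology,
nucleotide context, and selected pairwise combinations); a single weight
vector theta shared across targets scores each candidate, and the predicted
profile of a target is ``softmax(X_t @ theta)`` over its candidates.

Training minimizes the KL divergence from the measured profile (with a
0.5-read pseudocount on every enumerated outcome) to the prediction, summed
over training targets, plus an L2 penalty -- equivalently, penalized
multinomial maximum likelihood.  Evaluation reports per-target KL
divergences and Pearson correlations at three granularities: individual
outcomes, the ten outcome categories, and per-target in-frame fraction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .indel_core import (
    CATEGORIES,
    FlankMatch,
    OutcomeSpec,
    TargetSite,
    annotate,
    deletion_split,
    enumerate_outcomes,
    equivalent_start_range,
    format_descriptor,
)

__all__ = [
    "FeatureRegistry",
    "CandidateSet",
    "PredictorModel",
    "EvaluationReport",
    "ConvergenceError",
    "enumerate_candidates",
    "featurize",
    "train",
    "predict_profile",
    "kl_divergence",
    "evaluate",
    "split_targets",
]

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")
_DINUCS = tuple(a + b for a in _BASES for b in _BASES)


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails to converge and partial models are refused."""


def _size_class(L: int) -> str:
    if L == 1:
        return "1"
    if L == 2:
        return "2"
    return "MED" if L <= 9 else "LONG"


def _mh_class(mh: int) -> str:
    return str(mh) if mh <= 2 else "3P"


class FeatureRegistry:
    """Named, versioned binary feature registry shared by model and data.

    The registry fixes the feature order, so a model's weight vector is only
    meaningful together with the registry hash it was trained against.
    """

    VERSION = "v1"

    def __init__(self) -> None:
        names: list[str] = ["DEL", "INS"]
        names += [f"DEL_SIZE_{L}" for L in range(1, 31)]
        names += [f"SIZECLASS_{c}" for c in ("1", "2", "MED", "LONG")]
        names += [f"LEFT_{i}" for i in range(0, 31)]
        names += [f"RIGHT_{i}" for i in range(0, 31)]
        names += [f"MH_{m}" for m in range(0, 16)]
        names += [f"MHCLASS_{c}" for c in ("0", "1", "2", "3P")]
        names += ["INS_LEN_1", "INS_LEN_2"]
        names += [f"INS_SEQ_{b}" for b in _BASES + _DINUCS]
        names += [f"INS_GAP_{g}" for g in range(-3, 4)]
        names += [f"CAT_{c}" for c in CATEGORIES]
        names += [f"FLANKMATCH_{m.value}" for m in FlankMatch]
        names += [f"DELCTX_L_{b}" for b in _BASES]
        names += [f"DELCTX_R_{b}" for b in _BASES]
        names += [f"CTX_DISTAL_{b}" for b in _BASES]
        names += [f"CTX_PROX_{b}" for b in _BASES]
        names += ["LEFT_ONLY", "RIGHT_ONLY"]
        # pairwise combinations
        names += [f"INS1_{b}_X_DISTAL_{d}" for b in _BASES for d in _BASES]
        names += [f"INS1_{b}_X_PROX_{p}" for b in _BASES for p in _BASES]
        names += [
            f"SIZECLASS_{s}_X_MHCLASS_{m}"
            for s in ("1", "2", "MED", "LONG")
            for m in ("0", "1", "2", "3P")
        ]
        names += [
            f"{side}_X_SIZECLASS_{s}"
            for side in ("LEFT_ONLY", "RIGHT_ONLY")
            for s in ("1", "2", "MED", "LONG")
        ]
        self.names: tuple[str, ...] = tuple(names)
        self.index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    @property
    def hash(self) -> str:
        payload = self.VERSION + "|" + ",".join(self.names)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def active_features(self, target: TargetSite, o: OutcomeSpec) -> list[str]:
        """Names of the features active for one canonical outcome."""
        ann = annotate(target, format_descriptor(o))
        seq, cut = target.sequence, target.cut
        active = [f"CAT_{ann.category.value}"]
        if o.is_pure_deletion:
            L = o.del_size
            mh = ann.mh_len
            left, right = deletion_split(target, o)
            sc, mc = _size_class(L), _mh_class(mh)
            active += ["DEL", f"SIZECLASS_{sc}", f"MHCLASS_{mc}",
                       f"SIZECLASS_{sc}_X_MHCLASS_{mc}"]
            if L <= 30:
                active.append(f"DEL_SIZE_{L}")
            active += [f"LEFT_{min(left, 30)}", f"RIGHT_{min(right, 30)}",
                       f"MH_{min(mh, 15)}"]
            if o.del_start - 1 >= 0:
                active.append(f"DELCTX_L_{seq[o.del_start - 1]}")
            if o.del_end < len(seq):
                active.append(f"DELCTX_R_{seq[o.del_end]}")
            if right == 0:
                active += ["LEFT_ONLY", f"LEFT_ONLY_X_SIZECLASS_{sc}"]
            if left == 0:
                active += ["RIGHT_ONLY", f"RIGHT_ONLY_X_SIZECLASS_{sc}"]
        elif o.is_pure_insertion:
            k = o.ins_size
            if k > 2:
                raise ValueError("insertions longer than 2 nt are outside the model grammar")
            s_min, s_max = equivalent_start_range(target, o)
            gap = min(max(s_min, cut), s_max)  # equivalent gap nearest the cut
            ins = (seq[: o.del_start] + o.ins_seq + seq[o.del_end :])[gap : gap + k] \
                if gap != o.del_start else o.ins_seq
            offset = max(-3, min(3, gap - cut))
            distal, prox = seq[cut - 1], seq[cut]
            active += ["INS", f"INS_LEN_{k}", f"INS_SEQ_{ins}", f"INS_GAP_{offset}",
                       f"CTX_DISTAL_{distal}", f"CTX_PROX_{prox}"]
            if ann.flank_match is not None:
                active.append(f"FLANKMATCH_{ann.flank_match.value}")
            if k == 1:
                active += [f"INS1_{ins}_X_DISTAL_{distal}", f"INS1_{ins}_X_PROX_{prox}"]
        else:
            raise ValueError("mixed insertion-deletion outcomes are outside the model grammar")
        return active

    def featurize(self, target: TargetSite, outcomes: list[OutcomeSpec]) -> np.ndarray:
        X = np.zeros((len(outcomes), len(self.names)))
        for i, o in enumerate(outcomes):
            for name in self.active_features(target, o):
                X[i, self.index[name]] = 1.0
        return X


@dataclass
class CandidateSet:
    """Enumerated candidate outcomes of one target plus their features."""

    target_id: str
    outcomes: list[OutcomeSpec]
    descriptors: list[str]
    features: np.ndarray
    registry_hash: str


_DEFAULT_REGISTRY: FeatureRegistry | None = None


def default_registry() -> FeatureRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = FeatureRegistry()
    return _DEFAULT_REGISTRY


def enumerate_candidates(
    target: TargetSite, registry: FeatureRegistry | None = None
) -> CandidateSet:
    """Candidate outcomes of a target, canonical, deduplicated and featurized."""
    registry = registry or default_registry()
    outcomes = enumerate_outcomes(target)
    descriptors = [format_descriptor(o) for o in outcomes]
    X = registry.featurize(target, outcomes)
    return CandidateSet(target.id, outcomes, descriptors, X, registry.hash)


def featurize(
    candidate_set: CandidateSet, target: TargetSite, registry: FeatureRegistry | None = None
) -> np.ndarray:
    """(Re-)featurize a candidate set against a registry."""
    registry = registry or default_registry()
    return registry.featurize(target, candidate_set.outcomes)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class PredictorModel:
    """Shared weight vector over the feature registry plus training config."""

    theta: np.ndarray
    registry_hash: str
    feature_names: tuple[str, ...]
    config: dict = field(default_factory=dict)
    converged: bool = True
    loss_history: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "registry_version": FeatureRegistry.VERSION,
                    "registry_hash": self.registry_hash,
                    "feature_names": list(self.feature_names),
                    "theta": [float(x) for x in self.theta],
                    "config": self.config,
                    "converged": self.converged,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictorModel":
        d = json.loads(Path(path).read_text())
        return cls(
            theta=np.asarray(d["theta"], dtype=float),
            registry_hash=d["registry_hash"],
            feature_names=tuple(d["feature_names"]),
            config=d.get("config", {}),
            converged=d.get("converged", True),
        )


def _measured_vector(
    cand: CandidateSet, counts: pd.Series | None, pseudocount: float
) -> tuple[np.ndarray, float]:
    """Pseudocounted measured distribution over the candidate outcomes.

    Returns the renormalized vector and the raw-read mass of measured
    outcomes that fall outside the enumeration limits (dropped).
    """
    vec = np.full(len(cand.outcomes), pseudocount, dtype=float)
    dropped = 0.0
    if counts is not None:
        pos = {d: i for i, d in enumerate(cand.descriptors)}
        for desc, c in counts.items():
            i = pos.get(desc)
            if i is None:
                dropped += float(c)
            else:
                vec[i] += float(c)
    return vec / vec.sum(), dropped


def _profiles_to_counts(profiles: pd.DataFrame) -> dict[str, pd.Series]:
    lines = profiles["line"].unique() if "line" in profiles.columns else ["?"]
    if len(lines) != 1:
        raise ValueError("train/evaluate expect profiles from exactly one cell line")
    return {
        tid: grp.set_index("outcome")["count"]
        for tid, grp in profiles.groupby("target", sort=True)
    }


def _stack(candidate_sets: dict[str, CandidateSet], counts: dict[str, pd.Series],
           pseudocount: float):
    X_parts, p_parts, seg_starts = [], [], [0]
    total_dropped = 0.0
    for tid in sorted(candidate_sets):
        cand = candidate_sets[tid]
        p, dropped = _measured_vector(cand, counts.get(tid), pseudocount)
        if dropped:
            log.debug("target %s: %.1f reads outside enumeration limits dropped", tid, dropped)
        total_dropped += dropped
        X_parts.append(cand.features)
        p_parts.append(p)
        seg_starts.append(seg_starts[-1] + len(p))
    if total_dropped:
        log.info("dropped %.1f reads outside enumeration limits in total", total_dropped)
    X = np.vstack(X_parts)
    p = np.concatenate(p_parts)
    starts = np.array(seg_starts[:-1])
    seg_ids = np.repeat(np.arange(len(starts)), np.diff(seg_starts))
    return X, p, starts, seg_ids


def _softmax_segments(scores: np.ndarray, starts: np.ndarray, seg_ids: np.ndarray) -> np.ndarray:
    mx = np.maximum.reduceat(scores, starts)
    e = np.exp(scores - mx[seg_ids])
    z = np.add.reduceat(e, starts)
    return e / z[seg_ids]


def train(
    candidate_sets: dict[str, CandidateSet],
    measured_profiles: pd.DataFrame | dict[str, pd.Series],
    lambda_: float = 0.01,
    seed: int = 0,
    pseudocount: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    allow_partial: bool = False,
    registry: FeatureRegistry | None = None,
) -> PredictorModel:
    """Fit the shared weight vector by penalized KL minimization.

    Minimizes ``sum_t KL(measured~_t || softmax(X_t theta)) + lambda ||theta||^2``
    where ``measured~`` adds ``pseudocount`` reads to every enumerated
    outcome.  The optimizer is L-BFGS with analytic gradients; the start is
    ``theta = 0`` so training is deterministic (``seed`` is recorded for
    provenance).  Non-convergence raises :class:`ConvergenceError` unless
    ``allow_partial`` is set.
    """
    registry = registry or default_registry()
    for cand in candidate_sets.values():
        if cand.registry_hash != registry.hash:
            raise ValueError(f"candidate set {cand.target_id} built against a different registry")
    counts = (
        _profiles_to_counts(measured_profiles)
        if isinstance(measured_profiles, pd.DataFrame)
        else dict(measured_profiles)
    )
    X, p, starts, seg_ids = _stack(candidate_sets, counts, pseudocount)
    Xp = X.T @ p  # constant part of the gradient
    plogp = float(np.sum(p[p > 0] * np.log(p[p > 0])))

    def objective(theta: np.ndarray):
        scores = X @ theta
        mx = np.maximum.reduceat(scores, starts)
        e = np.exp(scores - mx[seg_ids])
        z = np.add.reduceat(e, starts)
        logz = np.log(z) + mx
        q = e / z[seg_ids]
        # sum_t sum_i p ln(p/q) = plogp - p.scores + sum_t logz_t
        loss = plogp - float(p @ scores) + float(logz.sum()) + lambda_ * float(theta @ theta)
        grad = X.T @ q - Xp + 2.0 * lambda_ * theta
        return loss, grad

    history: list[float] = []

    def cb(theta: np.ndarray) -> None:
        history.append(objective(theta)[0])

    theta0 = np.zeros(len(registry))
    history.append(objective(theta0)[0])
    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
    )
    converged = bool(res.success)
    if not converged and not allow_partial:
        raise ConvergenceError(f"optimizer did not converge: {res.message}")
    config = {
        "lambda": lambda_, "pseudocount": pseudocount, "seed": seed, "tol": tol,
        "train_targets": sorted(candidate_sets),
    }
    return PredictorModel(res.x, registry.hash, registry.names, config, converged, history)


def predict_profile(model: PredictorModel, candidate_set: CandidateSet) -> pd.Series:
    """Predicted outcome distribution (softmax over the target's candidates)."""
    if candidate_set.registry_hash != model.registry_hash:
        raise ValueError("candidate set registry hash does not match the model")
    scores = candidate_set.features @ model.theta
    scores -= scores.max()
    e = np.exp(scores)
    return pd.Series(e / e.sum(), index=candidate_set.descriptors, name=candidate_set.target_id)


# ---------------------------------------------------------------------------
# divergences and evaluation
# ---------------------------------------------------------------------------


def kl_divergence(p, q, pseudo: float = 0.0) -> float:
    """``sum_i p_i ln(p_i / q_i)`` after optional smoothing and renormalization.

    ``p`` and ``q`` must share a support (aligned arrays, or Series aligned
    on the union of their indices with missing mass 0 before smoothing).
    """
    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        idx = p.index.union(q.index)
        p = p.reindex(idx, fill_value=0.0).to_numpy()
        q = q.reindex(idx, fill_value=0.0).to_numpy()
    p = np.asarray(p, dtype=float) + pseudo
    q = np.asarray(q, dtype=float) + pseudo
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("zero total mass after smoothing")
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("q has zero mass where p is positive; smooth first")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def symmetrized_kl(p, q, pseudo: float = 0.0) -> float:
    return 0.5 * (kl_divergence(p, q, pseudo) + kl_divergence(q, p, pseudo))


@dataclass
class EvaluationReport:
    """Per-target divergences and pooled correlations at three granularities."""

    per_target: pd.DataFrame
    mean_kl: float
    mean_kl_sym: float
    r_outcomes: float
    r_categories: float
    r_inframe: float


def evaluate(
    model: PredictorModel,
    candidate_sets: dict[str, CandidateSet],
    measured_profiles: pd.DataFrame | dict[str, pd.Series],
    targets: Iterable[TargetSite],
    pseudocount: float = 0.5,
    mh_min: int = 2,
) -> EvaluationReport:
    """Evaluate a model on held-out targets.

    Reports the per-target KL divergence between the pseudocounted measured
    profile and the prediction (forward and symmetrized), and pooled
    Pearson correlations for individual outcome frequencies, ten-category
    aggregates, and per-target in-frame fraction.
    """
    if not candidate_sets:
        raise ValueError("empty test set")
    counts = (
        _profiles_to_counts(measured_profiles)
        if isinstance(measured_profiles, pd.DataFrame)
        else dict(measured_profiles)
    )
    tmap = {t.id: t for t in targets}
    rows = []
    meas_all, pred_all = [], []
    cat_meas, cat_pred = [], []
    inframe_meas, inframe_pred = [], []
    for tid in sorted(candidate_sets):
        cand = candidate_sets[tid]
        target = tmap[tid]
        p, _ = _measured_vector(cand, counts.get(tid), pseudocount)
        q = predict_profile(model, cand).to_numpy()
        kl = kl_divergence(p, q)
        kls = 0.5 * (kl + kl_divergence(q, p))
        rows.append({"target": tid, "kl": kl, "kl_sym": kls})
        meas_all.append(p)
        pred_all.append(q)
        cats = np.array([annotate(target, d, mh_min).category.value for d in cand.descriptors])
        inframe = np.array([annotate(target, d, mh_min).in_frame for d in cand.descriptors])
        cat_meas.append([p[cats == c].sum() for c in CATEGORIES])
        cat_pred.append([q[cats == c].sum() for c in CATEGORIES])
        inframe_meas.append(float(p[inframe].sum()))
        inframe_pred.append(float(q[inframe].sum()))

    per_target = pd.DataFrame(rows)
    meas = np.concatenate(meas_all)
    pred = np.concatenate(pred_all)
    r_out = float(pearsonr(meas, pred).statistic)
    r_cat = float(pearsonr(np.ravel(cat_meas), np.ravel(cat_pred)).statistic)
    if len(inframe_meas) >= 2:
        r_if = float(pearsonr(inframe_meas, inframe_pred).statistic)
    else:
        log.warning("in-frame correlation needs >= 2 targets; reporting NaN")
        r_if = float("nan")
    return EvaluationReport(
        per_target=per_target,
        mean_kl=float(per_target["kl"].mean()),
        mean_kl_sym=float(per_target["kl_sym"].mean()),
        r_outcomes=r_out,
        r_categories=r_cat,
        r_inframe=r_if,
    )


def replicate_kl(
    counts: pd.DataFrame, candidate_sets: dict[str, CandidateSet], pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-target KL divergence between the first two replicates of one line.

    A reproducibility floor for model evaluation: a model matching the
    measurement process cannot beat replicate-vs-replicate divergence in
    expectation.
    """
    reps = sorted(counts["replicate"].unique())
    if len(reps) < 2:
        raise ValueError("need at least two replicates")
    rows = []
    for tid in sorted(candidate_sets):
        cand = candidate_sets[tid]
        sub = counts[counts["target"] == tid]
        vecs = []
        for rep in reps[:2]:
            series = (
                sub[sub["replicate"] == rep].groupby("outcome")["count"].sum()
            )
            vecs.append(_measured_vector(cand, series, pseudocount)[0])
        rows.append({"target": tid, "kl": kl_divergence(vecs[0], vecs[1])})
    return pd.DataFrame(rows)


def split_targets(
    target_ids: Iterable[str], test_fraction: float = 0.1, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random train/test split by target (no outcome-level leakage)."""
    ids = sorted(target_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_test = max(1, int(round(test_fraction * len(ids))))
    return sorted(ids[n_test:]), sorted(ids[:n_test])
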