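"""Configuration, end-to-end orchestration and run provenance.

A run is described by a single YAML/JSON config (:class:`RunConfig`,
unknown keys rejected; defaults match the library defaults).  The
end-to-end driver executes simulate -> profile -> lfc -> mhfit -> cluster
-> train -> evaluate, writes every artifact as TSV/JSON, and records a
machine-readable manifest with content hashes and seeds; deterministic
stages are byte-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from . import knockout_clustering as kc
from . import mh_regression as mhr
from . import outcome_predictor as op
from . import profile_pipeline as pp
from . import synthetic_data as sd

__all__ = ["RunConfig", "run_end_to_end", "write_manifest"]

log = logging.getLogger(__name__)

SCHEMA_ID = "repairscape-run/1"


def _strict_dataclass(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateConfig:
    n_targets: int = 50
    lines: list[str] = field(default_factory=lambda: ["control", "Nbn", "Polq"])
    read_depth: float = 1000.0
    n_replicates: int = 2
    n_timepoints: int = 1
    fixed_depth: bool = False


@dataclass
class RunConfig:
    """Parameters for every pipeline stage; unknown keys are rejected."""

    schema: str = SCHEMA_ID
    out_dir: str = "run_out"
    targets_fasta: str | None = None  # None -> simulate
    targets_tsv: str | None = None
    counts_tsv: str | None = None
    control_line: str = "control"
    seed: int = 0
    min_reads: int = 100
    pc: float = 0.001
    mh_min: int = 2
    distance_def: str = "gap"
    n_neighbors: int = 50
    min_dist: float = 0.0
    min_lines: int = 10
    k_clusters: int = 7
    lambda_: float = 0.01
    test_fraction: float = 0.1
    n_boot: int = 1000
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def __post_init__(self) -> None:
        if self.schema != SCHEMA_ID:
            raise ValueError(f"unsupported config schema {self.schema!r}")
        if isinstance(self.simulate, dict):
            self.simulate = _strict_dataclass(SimulateConfig, self.simulate)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _strict_dataclass(cls, data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out: Path, config: RunConfig, t0: float, extra: dict | None = None) -> Path:
    """Record inputs, per-file content hashes, seeds and wall time."""
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "schema": SCHEMA_ID,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "wall_time_s": round(time.time() - t0, 3),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    manifest.update(extra or {})
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_end_to_end(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    A stage failure aborts with the failing stage named; partial outputs
    are moved under ``<out_dir>/failed``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- inputs ---------------------------------------------------
        if config.counts_tsv is None:
            stage = "simulate"
            sim = config.simulate
            library = sd.make_library(sim.n_targets, seed=config.seed)
            params = []
            for line in sim.lines:
                p = sd.preset_params(
                    line,
                    read_depth=sim.read_depth,
                    n_replicates=sim.n_replicates,
                    n_timepoints=sim.n_timepoints,
                    fixed_depth=sim.fixed_depth,
                )
                params.append(p)
            counts, _truth = sd.sample_dataset(library, params, seed=config.seed, out_dir=out)
        else:
            stage = "load"
            library = rio.read_library(config.targets_fasta, config.targets_tsv)
            counts = rio.read_counts(config.counts_tsv)

        # --- profile --------------------------------------------------
        stage = "profile"
        profiles = pp.filter_and_pool(counts, min_reads=config.min_reads)
        rio.write_tsv(profiles, out / "profiles.tsv",
                      comments=["pooled outcome profiles; freq = count / total mutated reads"])
        categories = pp.aggregate_categories(profiles, library, mh_min=config.mh_min)
        rio.write_tsv(categories.reset_index(), out / "categories.tsv",
                      comments=[f"ten-category frequency vectors (mh_min={config.mh_min})"])

        # --- lfc ------------------------------------------------------
        stage = "lfc"
        lfc_table = pp.lfc(profiles, config.control_line, pc=config.pc,
                           unit="category", targets=library, mh_min=config.mh_min)
        rio.write_tsv(lfc_table, out / "lfc.tsv",
                      comments=[f"log2 fold change vs {config.control_line}, pseudocount {config.pc}"])

        # --- mhfit ----------------------------------------------------
        stage = "mhfit"
        mhfits = mhr.fit_all(profiles, library, mh_min=config.mh_min,
                             distance_def=config.distance_def)
        rio.write_tsv(mhfits, out / "mhfits.tsv",
                      comments=[f"y = A*exp(B*d), distance_def={config.distance_def}"])

        # --- cluster --------------------------------------------------
        stage = "cluster"
        ko_lines = [l for l in profiles["line"].unique() if l != config.control_line]
        if len(ko_lines) >= 2:
            matrix = kc.build_lfc_matrix(
                profiles, library, config.control_line, pc=config.pc,
                min_lines=min(config.min_lines, len(ko_lines)), mh_min=config.mh_min,
            )
            emb = kc.embed(matrix, n_neighbors=config.n_neighbors,
                           min_dist=config.min_dist, seed=config.seed)
            k = min(config.k_clusters, len(matrix))
            labels = kc.cluster(emb.coords, k=k, seed=config.seed)
            emb_df = matrix.values.index.to_frame(index=False)
            emb_df[["x", "y"]] = emb.coords
            emb_df["cluster"] = labels
            rio.write_tsv(emb_df, out / "embedding.tsv",
                          comments=[f"UMAP n_neighbors={emb.n_neighbors} min_dist={emb.min_dist} seed={config.seed}"])
            E, F = kc.cluster_composition(labels, matrix.meta["category"],
                                          matrix.meta["control_freq"])
            rio.write_tsv(E.reset_index(), out / "composition_e.tsv",
                          comments=["columns sum to 100%"])
            rio.write_tsv(F.reset_index(), out / "composition_f.tsv",
                          comments=["rows sum to 100%"])
            rio.write_tsv(kc.cluster_knockout_enrichment(labels, matrix).reset_index(),
                          out / "enrichment.tsv",
                          comments=["mean cluster LFC minus overall mean, per knockout"])
        else:
            log.warning("fewer than 2 knockout lines: clustering stage skipped")

        # --- train / evaluate ----------------------------------------
        stage = "train"
        ctrl_profiles = profiles[profiles["line"] == config.control_line]
        cands = {t.id: op.enumerate_candidates(t) for t in library
                 if t.id in set(ctrl_profiles["target"])}
        train_ids, test_ids = op.split_targets(cands, config.test_fraction, seed=config.seed)
        model = op.train({t: cands[t] for t in train_ids},
                         ctrl_profiles[ctrl_profiles["target"].isin(train_ids)],
                         lambda_=config.lambda_, seed=config.seed)
        model.to_json(out / "model_control.json")

        stage = "evaluate"
        report = op.evaluate(model, {t: cands[t] for t in test_ids},
                             ctrl_profiles[ctrl_profiles["target"].isin(test_ids)],
                             library, mh_min=config.mh_min)
        rio.write_tsv(report.per_target, out / "evaluation_per_target.tsv",
                      comments=["held-out per-target KL divergences"])
        summary = pd.DataFrame(
            [{"mean_kl": report.mean_kl, "mean_kl_sym": report.mean_kl_sym,
              "r_outcomes": report.r_outcomes, "r_categories": report.r_categories,
              "r_inframe": report.r_inframe, "n_test_targets": len(test_ids)}]
        )
        rio.write_tsv(summary, out / "evaluation_summary.tsv")

        write_manifest(out, config, t0)
        return out
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
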