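"""End-to-end workflow: expression + pathways -> PAS -> cloud -> enrichment/screen.

``run_pipeline`` ties the stages together under a single serializable
configuration, writes every stage's table plus a machine-readable run
manifest (config hash, package version, seed), and is deterministic:
re-running the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .drug_screen import load_library, rank_drugs
from .enrichment import enrich
from .errors import ConfigurationError, PascloudError
from .expression_data import normalize, read_design, read_expression
from .pas_engine import (
    TolerancePolicy,
    build_cloud,
    gene_audit_table,
    profile,
)
from .pathway_model import load_pathways

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("pascloud")


@dataclass(frozen=True)
class RunConfig:
    """Flat, serializable configuration for one pipeline run.

    Optional stages switch on when their input path is set: ``gene_list``
    enables enrichment, ``drug_manifest`` enables screening.
    """

    expression: str
    design: str
    pathways: str
    out_dir: str
    gene_list: str | None = None
    drug_manifest: str | None = None
    universe: str | None = None
    normalization: str = "quantile"
    fold_upper: float = 1.5
    fold_lower: float = 2.0 / 3.0
    sd_multiplier: float = 2.0
    pseudocount: float | None = None
    min_control_n: int = 3
    cloud_threshold: float = 0.0
    screen_mode: str = "mimic"
    seed: int = 0
    log_level: str = "INFO"

    def policy(self) -> TolerancePolicy:
        return TolerancePolicy(
            fold_upper=self.fold_upper,
            fold_lower=self.fold_lower,
            sd_multiplier=self.sd_multiplier,
            pseudocount=self.pseudocount,
            min_control_n=self.min_control_n,
        )

    def config_hash(self) -> str:
        """Hash of every setting except the output location."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a flat YAML config; keyword overrides win over file values."""
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown config keys {sorted(unknown)}"
            )
        merged = {**data, **{k: v for k, v in overrides.items() if v is not None}}
        return cls(**merged)


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# pascloud {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages and write artifacts into ``cfg.out_dir``.

    Always emits ``gene_audit.tsv``, ``pas_profile.tsv`` and ``cloud.tsv``;
    ``enrichment.tsv`` and ``drug_ranking.tsv`` appear when their inputs
    are configured.  A ``run_manifest.json`` records the config, its hash,
    the package version, and per-stage timings.  Any stage failure aborts
    with a stage-labeled error and leaves an ``INCOMPLETE`` marker file.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    timings: dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        db = load_pathways(cfg.pathways)
        matrix = normalize(read_expression(cfg.expression), cfg.normalization)
        design = read_design(cfg.design)
        policy = cfg.policy()
        timings[stage] = time.perf_counter() - t0

        stage = "pas"
        t0 = time.perf_counter()
        prof = profile(matrix, design, db, policy)
        audit = gene_audit_table(matrix, design, db, policy)
        _write_table(audit, out / "gene_audit.tsv", cfg_hash, index=False)
        pas_frame = prof.to_frame()
        pas_frame.index.name = "pathway_id"
        _write_table(pas_frame, out / "pas_profile.tsv", cfg_hash, index=True)
        timings[stage] = time.perf_counter() - t0

        stage = "cloud"
        t0 = time.perf_counter()
        cloud = build_cloud(prof, threshold=cfg.cloud_threshold)
        _write_table(cloud.to_frame(), out / "cloud.tsv", cfg_hash, index=False)
        timings[stage] = time.perf_counter() - t0

        if cfg.gene_list:
            stage = "enrichment"
            t0 = time.perf_counter()
            genes = [
                line.strip()
                for line in Path(cfg.gene_list).read_text(encoding="utf-8").splitlines()
                if line.strip() and not line.startswith("#")
            ]
            universe = None
            if cfg.universe:
                universe = [
                    line.strip()
                    for line in Path(cfg.universe).read_text(encoding="utf-8").splitlines()
                    if line.strip()
                ]
            results = enrich(genes, db, universe=universe)
            enr = pd.DataFrame(
                [
                    (
                        r.pathway_id,
                        r.overlap_count,
                        round(r.overlap_pct, 1),
                        r.odds_ratio,
                        r.p_value,
                        r.p_adjusted,
                    )
                    for r in results
                ],
                columns=[
                    "pathway_id",
                    "overlap_count",
                    "overlap_pct",
                    "odds_ratio",
                    "p_value",
                    "p_adjusted",
                ],
            )
            _write_table(enr, out / "enrichment.tsv", cfg_hash, index=False)
            timings[stage] = time.perf_counter() - t0

        if cfg.drug_manifest:
            stage = "screen"
            t0 = time.perf_counter()
            library = load_library(cfg.drug_manifest, db, policy)
            ranking = rank_drugs(library, cloud, cfg.screen_mode)
            _write_table(ranking.to_frame(), out / "drug_ranking.tsv", cfg_hash, index=False)
            timings[stage] = time.perf_counter() - t0
    except PascloudError as exc:
        raise PascloudError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg_hash,
        "version": __version__,
        "seed": cfg.seed,
        "stage_seconds": {k: round(v, 4) for k, v in timings.items()},
    }
    # timings and output location vary run to run; the summary hash must not
    stable = {
        "config_hash": cfg_hash,
        "version": __version__,
        "seed": cfg.seed,
    }
    manifest["summary_hash"] = hashlib.sha256(
        json.dumps(stable, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    marker.unlink()
    return out
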