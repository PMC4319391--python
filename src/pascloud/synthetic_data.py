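"""Seeded synthetic expression experiments with known pathway ground truth.

The generator emulates the case/control contrasts the screening method is
built for: per-gene log-normal baseline expression with planted
multiplicative fold changes on the member genes of chosen pathways —
activators multiplied by the fold f, repressors by 1/f — so that a planted
fold f > 1 activates the pathway and the expected aggregate PAS under full
flag passage has the closed form ``sum_members |arr| * log10(f)``
(``(m_a + m_r) * log10(f)`` for unit role weights).

A companion generator builds drug libraries containing known mimics (same
planted pathways and folds as the target, optionally attenuated) and decoys
(disjoint random pathways, or reciprocal folds for reversal tests), giving
every screening mode a recoverable ground truth.

Randomness: a single global seed drives a named stream per component
(pathway database, experiment matrix, each drug), so adding a stage never
perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_data import ExpressionMatrix, Group, GroupDesign, write_design
from .pathway_model import (
    GeneRole,
    Pathway,
    PathwayDatabase,
    Role,
    write_pathways,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "DrugExperiment",
    "LibraryTruth",
    "generate_pathway_db",
    "simulate_experiment",
    "simulate_drug_library",
    "write_experiment",
]

# named sub-streams off the global seed
_STREAM_DB = 0
_STREAM_MATRIX = 1
_STREAM_DRUGS = 2


def generate_pathway_db(
    n_pathways: int = 10,
    size_range: tuple[int, int] = (6, 10),
    activator_fraction: float = 0.7,
    seed: int = 0,
) -> PathwayDatabase:
    """Random pathway database with disjoint member sets.

    Genes are synthetic symbols ``G0001``...; each member is an activator
    with probability ``activator_fraction``, else a repressor, with at
    least one activator and one repressor per pathway so both expression
    directions are exercised.  Disjoint membership keeps planted folds from
    leaking across pathways.
    """
    if not 0 < activator_fraction < 1:
        raise ValidationError("activator_fraction must be in (0, 1)")
    lo, hi = size_range
    if lo < 2:
        raise ValidationError("pathways need >= 2 members (one per role)")
    rng = np.random.default_rng([seed, _STREAM_DB])
    pathways: list[Pathway] = []
    gene_counter = 0
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        roles = [
            Role.ACTIVATOR if u < activator_fraction else Role.REPRESSOR
            for u in rng.random(size)
        ]
        # guarantee both roles appear
        roles[0] = Role.ACTIVATOR
        roles[1] = Role.REPRESSOR
        members = []
        for role in roles:
            gene_counter += 1
            arr = 1.0 if role is Role.ACTIVATOR else -1.0
            members.append(GeneRole(gene_id=f"G{gene_counter:04d}", role=role, arr=arr))
        pathways.append(
            Pathway(pathway_id=f"P{k + 1:02d}", name=f"synthetic pathway {k + 1}",
                    members=tuple(members))
        )
    return PathwayDatabase(pathways=tuple(pathways))


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic case/control experiment.

    ``planted`` maps pathway_id -> fold f (> 1 activates: activators x f,
    repressors x 1/f; f < 1 represses).  Baselines are drawn per gene,
    uniform on ``baseline_log10_mean_range``; every sample value is
    ``10**(baseline + N(0, biological_sd))``.
    """

    db: PathwayDatabase
    planted: Mapping[str, float] = field(default_factory=dict)
    n_case: int = 5
    n_control: int = 5
    baseline_log10_mean_range: tuple[float, float] = (1.0, 3.0)
    biological_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", dict(self.planted))
        for pid, f in self.planted.items():
            if pid not in self.db:
                raise ValidationError(f"planted pathway {pid!r} not in database")
            if not f > 0:
                raise ValidationError(f"planted fold for {pid!r} must be > 0")
        if self.n_case < 1:
            raise ValidationError("n_case must be >= 1")
        if self.n_control < 3:
            raise ValidationError("n_control must be >= 3")
        if self.biological_sd < 0:
            raise ValidationError("biological_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, and the PAS it should produce under full BTIF passage."""

    planted: Mapping[str, float]
    expected_pas: Mapping[str, float]


def _expected_pas(db: PathwayDatabase, planted: Mapping[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    for pid, f in planted.items():
        p = db[pid]
        # activator: arr>0, level x f  -> arr*log10(f) = |arr| log10 f
        # repressor: arr<0, level x 1/f -> arr*log10(1/f) = |arr| log10 f
        out[pid] = float(
            sum(abs(m.arr) for m in p.members if m.role is not Role.NEUTRAL)
            * np.log10(f)
        )
    return out


def _case_fold_factors(
    db: PathwayDatabase, planted: Mapping[str, float], genes: Sequence[str]
) -> np.ndarray:
    """Per-gene multiplicative factor applied to case samples."""
    factor = {g: 1.0 for g in genes}
    for pid, f in planted.items():
        for m in db[pid].members:
            if m.gene_id not in factor:
                continue
            if m.role is Role.ACTIVATOR:
                factor[m.gene_id] *= f
            elif m.role is Role.REPRESSOR:
                factor[m.gene_id] /= f
    return np.array([factor[g] for g in genes])


def simulate_experiment(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, GroupDesign, GroundTruth]:
    """Generate one seeded case/control expression experiment.

    Deterministic given ``spec.seed``; case samples are named ``case_1``...
    and controls ``ctrl_1``....
    """
    rng = np.random.default_rng([spec.seed, _STREAM_MATRIX])
    genes = sorted(spec.db.universe)
    n_genes = len(genes)
    n_samples = spec.n_case + spec.n_control
    lo, hi = spec.baseline_log10_mean_range

    baseline = rng.uniform(lo, hi, size=n_genes)
    noise = rng.normal(0.0, spec.biological_sd, size=(n_genes, n_samples))
    values = 10.0 ** (baseline[:, None] + noise)

    fold = _case_fold_factors(spec.db, spec.planted, genes)
    values[:, : spec.n_case] *= fold[:, None]

    case_ids = [f"case_{i + 1}" for i in range(spec.n_case)]
    ctrl_ids = [f"ctrl_{i + 1}" for i in range(spec.n_control)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=case_ids + ctrl_ids)
    )
    design = GroupDesign(
        assignment={
            **{s: Group.CASE for s in case_ids},
            **{s: Group.CONTROL for s in ctrl_ids},
        }
    )
    truth = GroundTruth(
        planted=dict(spec.planted),
        expected_pas=_expected_pas(spec.db, spec.planted),
    )
    return matrix, design, truth


@dataclass(frozen=True)
class DrugExperiment:
    """One drug's treated/untreated expression pair, ready for profiling."""

    drug_id: str
    matrix: ExpressionMatrix
    design: GroupDesign


@dataclass(frozen=True)
class LibraryTruth:
    """Which library drugs are planted mimics and which are decoys."""

    mimic_ids: tuple[str, ...]
    decoy_ids: tuple[str, ...]
    decoy_mode: str


def simulate_drug_library(
    spec: SimulationSpec,
    target_truth: GroundTruth,
    n_mimics: int = 1,
    n_decoys: int = 9,
    decoy_mode: str = "random_pathways",
    seed: int | None = None,
    attenuation: float = 1.0,
) -> tuple[list[DrugExperiment], LibraryTruth]:
    """Drug library with planted mimics and decoys for the target cloud.

    Mimics plant the target's pathways at fold ``f ** attenuation``
    (attenuation in (0, 1] weakens the mimic).  ``random_pathways`` decoys
    plant the same number of pathways drawn from the non-target pathways,
    at the target's folds; ``reversed`` decoys plant the target's pathways
    at reciprocal folds (for minimize-mode tests).  Every drug has its own
    named random stream off ``seed`` (default: the spec's seed).
    """
    if decoy_mode not in ("random_pathways", "reversed"):
        raise ValidationError(f"unknown decoy_mode {decoy_mode!r}")
    if not 0 < attenuation <= 1:
        raise ValidationError("attenuation must be in (0, 1]")
    if not target_truth.planted:
        raise ValidationError("target ground truth has no planted pathways")
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, _STREAM_DRUGS])

    target_pids = sorted(target_truth.planted)
    others = [pid for pid in spec.db.pathway_ids if pid not in target_truth.planted]
    if decoy_mode == "random_pathways" and len(others) < len(target_pids):
        raise ValidationError(
            f"need >= {len(target_pids)} non-target pathways for decoys, "
            f"have {len(others)}"
        )

    folds = [target_truth.planted[pid] for pid in target_pids]
    experiments: list[DrugExperiment] = []
    mimic_ids: list[str] = []
    decoy_ids: list[str] = []

    def _make(drug_id: str, planted: Mapping[str, float], drug_seed: int) -> None:
        sub = SimulationSpec(
            db=spec.db,
            planted=planted,
            n_case=spec.n_case,
            n_control=spec.n_control,
            baseline_log10_mean_range=spec.baseline_log10_mean_range,
            biological_sd=spec.biological_sd,
            seed=drug_seed,
        )
        matrix, design, _ = simulate_experiment(sub)
        experiments.append(DrugExperiment(drug_id=drug_id, matrix=matrix, design=design))

    for i in range(n_mimics):
        drug_id = f"mimic_{i + 1}"
        planted = {pid: f**attenuation for pid, f in target_truth.planted.items()}
        _make(drug_id, planted, int(rng.integers(0, 2**31 - 1)))
        mimic_ids.append(drug_id)

    for i in range(n_decoys):
        drug_id = f"decoy_{i + 1}"
        if decoy_mode == "random_pathways":
            picked = rng.choice(len(others), size=len(target_pids), replace=False)
            planted = {others[int(j)]: f for j, f in zip(sorted(picked), folds)}
        else:
            planted = {pid: 1.0 / f for pid, f in target_truth.planted.items()}
        _make(drug_id, planted, int(rng.integers(0, 2**31 - 1)))
        decoy_ids.append(drug_id)

    truth = LibraryTruth(
        mimic_ids=tuple(mimic_ids),
        decoy_ids=tuple(decoy_ids),
        decoy_mode=decoy_mode,
    )
    return experiments, truth


def write_experiment(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    design: GroupDesign,
    db: PathwayDatabase,
    truth: GroundTruth,
    library: Sequence[DrugExperiment] | None = None,
) -> Path:
    """Write a simulated experiment (and optional drug library) to disk.

    Emits ``expression.tsv``, ``design.tsv``, ``pathways.gmt`` and
    ``truth.yaml``; with a library, per-drug expression/design files plus a
    ``library/manifest.tsv`` consumable by the screening stage.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(out / "expression.tsv", sep="\t")
    write_design(design, out / "design.tsv")
    write_pathways(db, out / "pathways.gmt")
    with (out / "truth.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "planted": {k: float(v) for k, v in truth.planted.items()},
                "expected_pas": {k: float(v) for k, v in truth.expected_pas.items()},
            },
            fh,
            sort_keys=True,
        )
    if library:
        lib_dir = out / "library"
        lib_dir.mkdir(exist_ok=True)
        with (lib_dir / "manifest.tsv").open("w", encoding="utf-8") as fh:
            fh.write("drug_id\texpr_path\tdesign_path\n")
            for drug in library:
                drug.matrix.values.to_csv(lib_dir / f"{drug.drug_id}.expr.tsv", sep="\t")
                write_design(drug.design, lib_dir / f"{drug.drug_id}.design.tsv")
                fh.write(
                    f"{drug.drug_id}\t{drug.drug_id}.expr.tsv\t{drug.drug_id}.design.tsv\n"
                )
    return out
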