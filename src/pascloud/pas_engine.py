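"""Pathway activation strength (PAS) scoring and the signaling pathway cloud.

The method quantifies how strongly each signaling pathway is activated or
repressed in a case condition relative to controls, from expression alone:

* ECR (enhanced-to-control ratio): a gene's expression in a case sample
  divided by the gene's mean expression over the control group (both sides
  stabilized by a small pseudocount).
* BTIF (beyond tolerance interval flag): 1 only if the ECR exceeds the fold
  tolerance (> 3/2 or < 2/3) AND the case value deviates from the control
  mean by more than ``sd_multiplier`` control standard deviations; 0
  otherwise.  BTIF gates each gene's contribution, suppressing noise-level
  fluctuation.
* PAS for a pathway p in a case sample: sum over member genes n of
  ``arr_n * btif_n * log10(ecr_n)`` — positive means net activation,
  negative net repression.
* SPCD is the multiplicative counterpart: the product of activator
  expression levels divided by the product of repressor levels; when levels
  are ECRs with unit role weights and all flags raised, ``10**PAS == SPCD``.

The *signaling pathway cloud* is the set of pathways whose aggregate |PAS|
clears a threshold, labeled activated or repressed by sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .expression_data import (
    ControlStats,
    ExpressionMatrix,
    GroupDesign,
    control_stats,
)
from .pathway_model import Pathway, PathwayDatabase, Role

__all__ = [
    "TolerancePolicy",
    "GeneSignal",
    "PasProfile",
    "CloudEntry",
    "PathwayCloud",
    "compute_ecr",
    "compute_btif",
    "compute_pas",
    "compute_spcd",
    "profile",
    "build_cloud",
]

#: floor for the auto-resolved pseudocount
_PSEUDOCOUNT_FLOOR = 1e-12
#: auto pseudocount = this fraction of the matrix median
_PSEUDOCOUNT_MEDIAN_FRACTION = 1e-8


@dataclass(frozen=True)
class TolerancePolicy:
    """Thresholds deciding when a gene's change is beyond tolerance.

    Defaults are the method's printed constants: fold bounds 3/2 and 2/3 and
    an SD multiplier of two.  ``pseudocount=None`` means "resolve from the
    data" as ``max(1e-8 * matrix median, 1e-12)``; an explicit value must be
    positive.  ``use_sd_criterion=False`` drops the SD criterion so BTIF
    depends on the fold bounds alone (diagnostic use).
    """

    fold_upper: float = 1.5
    fold_lower: float = 2.0 / 3.0
    sd_multiplier: float = 2.0
    pseudocount: float | None = None
    min_control_n: int = 3
    use_sd_criterion: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fold_lower < 1 < self.fold_upper:
            raise ConfigurationError(
                "fold thresholds must satisfy 0 < fold_lower < 1 < fold_upper, "
                f"got {self.fold_lower}, {self.fold_upper}"
            )
        if not self.sd_multiplier > 0:
            raise ConfigurationError("sd_multiplier must be > 0")
        if self.pseudocount is not None and not self.pseudocount > 0:
            raise ConfigurationError("pseudocount must be > 0 when set")
        if self.min_control_n < 2:
            raise ConfigurationError("min_control_n must be >= 2")

    def resolve_pseudocount(self, values: np.ndarray | None = None) -> float:
        """Concrete pseudocount for a given matrix (or the floor if no data)."""
        if self.pseudocount is not None:
            return self.pseudocount
        if values is None or np.asarray(values).size == 0:
            return _PSEUDOCOUNT_FLOOR
        med = float(np.median(np.asarray(values, dtype=float)))
        return max(_PSEUDOCOUNT_MEDIAN_FRACTION * med, _PSEUDOCOUNT_FLOOR)

    def resolved_for(self, m: ExpressionMatrix) -> "TolerancePolicy":
        return replace(self, pseudocount=self.resolve_pseudocount(m.values.to_numpy()))


@dataclass(frozen=True)
class GeneSignal:
    """Per-gene, per-case-sample evidence entering the pathway score."""

    gene_id: str
    sample_id: str
    ecr: float
    btif: int

    def __post_init__(self) -> None:
        if not self.ecr > 0 or not math.isfinite(self.ecr):
            raise ValidationError(
                f"{self.gene_id}/{self.sample_id}: ECR must be finite and > 0"
            )
        if self.btif not in (0, 1):
            raise ValidationError(f"{self.gene_id}: BTIF must be 0 or 1")

    def contribution(self, arr: float) -> float:
        """arr * btif * log10(ecr) — this gene's additive PAS term."""
        return arr * self.btif * math.log10(self.ecr)


def compute_ecr(
    case_value: float, control_mean: float, policy: TolerancePolicy
) -> float:
    """Enhanced-to-control ratio with symmetric pseudocount stabilization.

    Returns ``(case_value + pc) / (control_mean + pc)``: strictly positive
    and finite even when the control mean is zero.
    """
    pc = policy.resolve_pseudocount()
    return (case_value + pc) / (control_mean + pc)


def compute_btif(
    ecr: float,
    case_value: float,
    control_mean: float,
    control_sd: float,
    policy: TolerancePolicy,
) -> int:
    """Beyond-tolerance flag: both the fold and SD criteria must hold.

    With zero control SD (perfectly constant controls) the SD criterion
    reduces to "the case value differs from the control mean at all".
    """
    beyond_fold = ecr > policy.fold_upper or ecr < policy.fold_lower
    if not beyond_fold:
        return 0
    if not policy.use_sd_criterion:
        return 1
    deviation = abs(case_value - control_mean)
    if control_sd == 0:
        return 1 if deviation > 0 else 0
    return 1 if deviation > policy.sd_multiplier * control_sd else 0


def compute_pas(
    pathway: Pathway, signals: Mapping[str, GeneSignal] | Iterable[GeneSignal]
) -> float | None:
    """Sum of member contributions ``arr * btif * log10(ecr)`` for one sample.

    Members absent from ``signals`` (not measured) are skipped.  Returns
    ``None`` — the undefined-PAS marker — when no member has a signal at
    all; an all-flags-zero pathway returns exactly 0.0 instead.
    """
    if not isinstance(signals, Mapping):
        signals = {s.gene_id: s for s in signals}
    total = 0.0
    n_measured = 0
    for member in pathway.members:
        sig = signals.get(member.gene_id)
        if sig is None:
            continue
        n_measured += 1
        total += sig.contribution(member.arr)
    if n_measured == 0:
        return None
    return total


def compute_spcd(pathway: Pathway, levels: Mapping[str, float]) -> float | None:
    """Product of activator levels over product of repressor levels.

    ``levels`` maps gene_id to a strictly positive expression level (or ECR).
    Neutral members are ignored; members absent from ``levels`` are skipped.
    Returns ``None`` when the pathway has no measured activators and no
    measured repressors.  The proportionality constant is fixed at 1: only
    ratios and orderings of SPCD are meaningful.
    """
    num = 1.0
    den = 1.0
    n_used = 0
    for member in pathway.members:
        if member.role is Role.NEUTRAL:
            continue
        level = levels.get(member.gene_id)
        if level is None:
            continue
        if not level > 0:
            raise ValidationError(
                f"{member.gene_id}: SPCD requires strictly positive levels"
            )
        n_used += 1
        if member.role is Role.ACTIVATOR:
            num *= level
        else:
            den *= level
    if n_used == 0:
        return None
    return num / den


@dataclass(frozen=True)
class PasProfile:
    """PAS per pathway per case sample, with per-pathway aggregates.

    ``per_sample`` is a pathway-by-case-sample DataFrame (NaN marks an
    undefined PAS: no pathway member measured).  ``aggregate`` is the
    arithmetic mean over case samples; ``sd`` the sample SD (NaN for a
    single case sample).  ``n_members``/``n_measured`` report pathway
    coverage by the expression matrix.
    """

    per_sample: pd.DataFrame
    aggregate: pd.Series
    sd: pd.Series
    n_members: pd.Series
    n_measured: pd.Series

    @property
    def pathway_ids(self) -> pd.Index:
        return self.per_sample.index

    def to_frame(self) -> pd.DataFrame:
        """Flat per-pathway table: coverage, per-sample PAS, aggregate, SD."""
        out = pd.DataFrame(
            {
                "n_members": self.n_members,
                "n_measured": self.n_measured,
            }
        )
        for col in self.per_sample.columns:
            out[f"PAS[{col}]"] = self.per_sample[col]
        out["PAS_aggregate"] = self.aggregate
        out["PAS_sd"] = self.sd
        return out


def _signal_arrays(
    m: ExpressionMatrix,
    d: GroupDesign,
    policy: TolerancePolicy,
    stats: ControlStats | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ControlStats, float]:
    """Vectorized ECR and BTIF for every gene x case sample.

    Returns (ecr, btif, control stats, resolved pseudocount); frames are
    gene-by-case-sample.
    """
    if stats is None:
        stats = control_stats(m, d, min_control_n=policy.min_control_n)
    else:
        d.validate_against(m, min_control_n=policy.min_control_n)
    pc = policy.resolve_pseudocount(m.values.to_numpy())
    case = m.values[list(d.case_samples)]
    mean = stats.mean.to_numpy()[:, None]
    sd = stats.sd.to_numpy()[:, None]
    case_arr = case.to_numpy()

    ecr = (case_arr + pc) / (mean + pc)
    beyond_fold = (ecr > policy.fold_upper) | (ecr < policy.fold_lower)
    if policy.use_sd_criterion:
        deviation = np.abs(case_arr - mean)
        sd_ok = np.where(sd == 0, deviation > 0, deviation > policy.sd_multiplier * sd)
        btif = beyond_fold & sd_ok
    else:
        btif = beyond_fold
    ecr_df = pd.DataFrame(ecr, index=m.gene_ids, columns=case.columns)
    btif_df = pd.DataFrame(
        btif.astype(np.int8), index=m.gene_ids, columns=case.columns
    )
    return ecr_df, btif_df, stats, pc


def gene_audit_table(
    m: ExpressionMatrix,
    d: GroupDesign,
    db: PathwayDatabase,
    policy: TolerancePolicy | None = None,
) -> pd.DataFrame:
    """Long-format per-gene audit: ECR, BTIF and contribution per pathway term.

    One row per (pathway, member gene, case sample) for members present in
    the matrix; lets every PAS value be traced back to its gene-level terms.
    """
    policy = policy or TolerancePolicy()
    ecr, btif, _, _ = _signal_arrays(m, d, policy)
    log_ecr = np.log10(ecr)
    rows: list[dict] = []
    for p in db:
        for member in p.members:
            g = member.gene_id
            if g not in ecr.index:
                continue
            for s in ecr.columns:
                e = float(ecr.at[g, s])
                b = int(btif.at[g, s])
                rows.append(
                    {
                        "pathway_id": p.pathway_id,
                        "gene_id": g,
                        "sample_id": s,
                        "arr": member.arr,
                        "ecr": e,
                        "btif": b,
                        "contribution": member.arr * b * float(log_ecr.at[g, s]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "gene_id",
            "sample_id",
            "arr",
            "ecr",
            "btif",
            "contribution",
        ],
    )


def profile(
    m: ExpressionMatrix,
    d: GroupDesign,
    db: PathwayDatabase,
    policy: TolerancePolicy | None = None,
) -> PasProfile:
    """PAS for every pathway and case sample, plus per-pathway aggregates.

    Pathway members absent from the matrix are skipped and reported via
    ``n_measured``; a pathway with no measured member gets NaN (undefined)
    rather than 0.  Deterministic for fixed inputs and policy.
    """
    policy = policy or TolerancePolicy()
    ecr, btif, _, _ = _signal_arrays(m, d, policy)
    contrib = btif.to_numpy() * np.log10(ecr.to_numpy())
    gene_pos = {g: i for i, g in enumerate(ecr.index)}
    case_cols = list(ecr.columns)

    pas = np.full((len(db), len(case_cols)), np.nan)
    n_members = np.zeros(len(db), dtype=int)
    n_measured = np.zeros(len(db), dtype=int)
    for i, p in enumerate(db):
        n_members[i] = len(p)
        idx = [gene_pos[m_.gene_id] for m_ in p.members if m_.gene_id in gene_pos]
        arrs = np.array(
            [m_.arr for m_ in p.members if m_.gene_id in gene_pos], dtype=float
        )
        n_measured[i] = len(idx)
        if idx:
            pas[i] = arrs @ contrib[idx, :]

    per_sample = pd.DataFrame(pas, index=list(db.pathway_ids), columns=case_cols)
    return PasProfile(
        per_sample=per_sample,
        aggregate=per_sample.mean(axis=1),
        sd=per_sample.std(axis=1, ddof=1),
        n_members=pd.Series(n_members, index=per_sample.index),
        n_measured=pd.Series(n_measured, index=per_sample.index),
    )


@dataclass(frozen=True)
class CloudEntry:
    pathway_id: str
    pas: float
    label: str  # "activated" | "repressed"


@dataclass(frozen=True)
class PathwayCloud:
    """Pathways whose aggregate |PAS| clears the threshold, labeled by sign.

    Entries are sorted by descending |PAS|, ties broken by pathway_id.
    """

    entries: tuple[CloudEntry, ...]
    threshold: float = 0.0

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(e.pathway_id for e in self.entries)

    @property
    def pas_by_id(self) -> Mapping[str, float]:
        return {e.pathway_id: e.pas for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.pathway_id, e.pas, e.label) for e in self.entries],
            columns=["pathway_id", "PAS", "label"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, threshold: float = 0.0) -> "PathwayCloud":
        entries = tuple(
            CloudEntry(str(r.pathway_id), float(r.PAS), str(r.label))
            for r in df.itertuples(index=False)
        )
        return cls(entries=entries, threshold=threshold)


def build_cloud(p: PasProfile, threshold: float = 0.0) -> PathwayCloud:
    """Signaling pathway cloud: pathways with |aggregate PAS| > threshold.

    Undefined (NaN) aggregates are excluded.  The default threshold 0 keeps
    every pathway with any nonzero PAS.
    """
    if threshold < 0:
        raise ConfigurationError("cloud threshold must be >= 0")
    entries = [
        CloudEntry(
            pathway_id=str(pid),
            pas=float(val),
            label="activated" if val > 0 else "repressed",
        )
        for pid, val in p.aggregate.items()
        if math.isfinite(val) and abs(val) > threshold
    ]
    entries.sort(key=lambda e: (-abs(e.pas), e.pathway_id))
    return PathwayCloud(entries=tuple(entries), threshold=threshold)
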