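"""Expression matrices, case/control designs, and control-group statistics.

Expression values are linear-scale and non-negative (arbitrary units);
log-transformed input must be de-logged upstream, since the activation
score mixes ratios and logarithms explicitly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Group",
    "ExpressionMatrix",
    "GroupDesign",
    "ControlStats",
    "read_expression",
    "read_design",
    "normalize",
    "control_stats",
]

DEFAULT_MIN_CONTROL_N = 3


class Group(enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample grid of linear-scale, non-negative expression levels.

    Wraps a pandas DataFrame with upper-cased, unique gene symbols as the
    index and unique sample ids as columns.  Construction validates: no
    missing cells, no negative values, no duplicate genes or samples.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        df = df.set_axis([str(g).upper() for g in df.index], axis=0)
        df = df.set_axis([str(s) for s in df.columns], axis=1)
        dup_g = df.index[df.index.duplicated()].unique()
        if len(dup_g):
            raise ValidationError(f"duplicate gene rows: {', '.join(dup_g)}")
        dup_s = df.columns[df.columns.duplicated()].unique()
        if len(dup_s):
            raise ValidationError(f"duplicate sample ids: {', '.join(dup_s)}")
        arr = df.to_numpy(dtype=float, na_value=np.nan)
        if np.isnan(arr).any():
            g, s = map(int, np.argwhere(np.isnan(arr))[0])
            raise ValidationError(
                f"missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = map(int, np.argwhere(arr < 0)[0])
            raise ValidationError(
                f"negative value {arr[g, s]} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        object.__setattr__(self, "values", df.astype(float))

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[samples])


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of sample ids to case/control groups."""

    assignment: Mapping[str, Group] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        if not self.case_samples:
            raise ValidationError("design has no case samples")
        if not self.control_samples:
            raise ValidationError("design has no control samples")

    @property
    def case_samples(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g is Group.CASE)

    @property
    def control_samples(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g is Group.CONTROL)

    def validate_against(
        self, m: ExpressionMatrix, min_control_n: int = DEFAULT_MIN_CONTROL_N
    ) -> None:
        """Check every assigned sample exists and the control group is big enough."""
        missing = [s for s in self.assignment if s not in m.sample_ids]
        if missing:
            raise ValidationError(
                f"design samples absent from matrix: {', '.join(missing)}"
            )
        if len(self.control_samples) < min_control_n:
            raise ConfigurationError(
                f"{len(self.control_samples)} control samples < "
                f"required minimum {min_control_n}"
            )


@dataclass(frozen=True)
class ControlStats:
    """Per-gene control-group mean and sample SD (n-1 denominator), linear scale."""

    mean: pd.Series
    sd: pd.Series
    n_control: int


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV: first row sample ids, first column gene symbols."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def read_design(path: str | Path) -> GroupDesign:
    """Read a 2-column TSV (sample_id, group) with group in {case, control}.

    A header line is accepted and skipped if its second field is not a group.
    """
    assignment: dict[str, Group] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(
                    f"design line {line_no}: expected 2 tab-separated fields"
                )
            sample, group_tok = fields[0], fields[1].strip().lower()
            if line_no == 1 and group_tok not in ("case", "control"):
                continue  # header
            try:
                group = Group(group_tok)
            except ValueError:
                raise ValidationError(
                    f"design line {line_no}: unknown group {fields[1]!r} "
                    "(expected case or control)"
                ) from None
            if sample in assignment:
                raise ValidationError(
                    f"design line {line_no}: sample {sample!r} assigned twice"
                )
            assignment[sample] = group
    return GroupDesign(assignment=assignment)


def write_design(d: GroupDesign, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in d.assignment.items():
            fh.write(f"{s}\t{g.value}\n")


def _quantile_normalize(arr: np.ndarray) -> np.ndarray:
    """Replace each column by the mean order statistics across columns.

    Within-column ranks are preserved; ties receive the mean of the tied
    target values (implemented by linear interpolation at average ranks,
    which coincides with that mean because the targets enter linearly).
    """
    n_genes = arr.shape[0]
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    positions = np.arange(n_genes, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, target)
    return out


def normalize(m: ExpressionMatrix, method: str = "quantile") -> ExpressionMatrix:
    """Normalize columns so samples are comparable.

    method="none" returns the input unchanged; method="quantile" maps every
    column onto the mean order statistics across columns (classic quantile
    normalization, applied to all samples jointly).
    """
    if method == "none":
        return m
    if method == "quantile":
        arr = _quantile_normalize(m.values.to_numpy(dtype=float))
        return ExpressionMatrix(
            pd.DataFrame(arr, index=m.gene_ids, columns=m.sample_ids)
        )
    raise ValueError(f"unknown normalization method {method!r}")


def control_stats(
    m: ExpressionMatrix,
    d: GroupDesign,
    min_control_n: int = DEFAULT_MIN_CONTROL_N,
) -> ControlStats:
    """Per-gene mean and sample SD over the control columns only."""
    d.validate_against(m, min_control_n=min_control_n)
    ctrl = m.values[list(d.control_samples)]
    return ControlStats(
        mean=ctrl.mean(axis=1),
        sd=ctrl.std(axis=1, ddof=1),
        n_control=ctrl.shape[1],
    )
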