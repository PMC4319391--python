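"""In-silico drug screening against a target pathway cloud.

A drug's *signature* is its own aggregate PAS profile, computed from
drug-treated vs untreated expression exactly as the target condition's
profile is.  Drugs are ranked by how well the signature matches the target
cloud in one of three modes:

* ``mimic`` — reproduce the cloud: cosine similarity between the drug and
  target PAS vectors restricted to the cloud's pathways.
* ``minimize`` — reverse the cloud: cosine against the negated target
  (``minimize(v, t) == mimic(v, -t)`` exactly).
* ``exaggerate`` — amplify the cloud: the signed ratio of the drug vector's
  projection onto the target to the target's own squared magnitude,
  ``(v . t) / |t|^2``; scores above 1 certify beyond-target amplitude.

Pathways where the drug has no defined PAS contribute 0 to the score but
lower the reported coverage fraction, so sparse drug data is visible rather
than silently favorable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_data import ExpressionMatrix, GroupDesign, read_design, read_expression
from .pas_engine import PathwayCloud, TolerancePolicy, profile
from .pathway_model import PathwayDatabase

__all__ = [
    "DrugSignature",
    "ScreenMode",
    "DrugScore",
    "RankedDrug",
    "DrugRanking",
    "drug_profile",
    "score_drug",
    "rank_drugs",
    "read_signature",
    "write_signature",
    "load_library",
]


class ScreenMode(enum.Enum):
    MIMIC = "mimic"
    MINIMIZE = "minimize"
    EXAGGERATE = "exaggerate"


@dataclass(frozen=True)
class DrugSignature:
    """A drug's aggregate PAS per pathway (NaN = undefined for that pathway)."""

    drug_id: str
    pas: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.pas, dtype=float)
        if s.index.duplicated().any():
            raise ValidationError(f"drug {self.drug_id}: duplicate pathway ids")
        if np.isinf(s.to_numpy()).any():
            raise ValidationError(f"drug {self.drug_id}: non-finite PAS value")
        object.__setattr__(self, "pas", s)


def drug_profile(
    treated: ExpressionMatrix,
    design: GroupDesign,
    db: PathwayDatabase,
    policy: TolerancePolicy | None = None,
    drug_id: str = "drug",
) -> DrugSignature:
    """Drug signature from a treated-vs-untreated expression pair.

    Treated samples are the design's "case" group, untreated the "control";
    the PAS computation is identical to the target condition's.
    """
    prof = profile(treated, design, db, policy)
    return DrugSignature(drug_id=drug_id, pas=prof.aggregate)


@dataclass(frozen=True)
class DrugScore:
    score: float
    coverage: float  # fraction of cloud pathways where the drug PAS is defined
    zero_signal: bool  # drug vector identically zero on the cloud


def _vectors(
    sig: DrugSignature, target: PathwayCloud
) -> tuple[np.ndarray, np.ndarray, float]:
    t = np.array([target.pas_by_id[p] for p in target.pathway_ids])
    v = np.zeros(len(t))
    defined = 0
    for i, p in enumerate(target.pathway_ids):
        val = sig.pas.get(p, np.nan)
        if math.isfinite(val):
            v[i] = val
            defined += 1
    return v, t, defined / len(t)


def score_drug(
    sig: DrugSignature,
    target: PathwayCloud,
    mode: ScreenMode | str,
    weighted: bool = False,
) -> DrugScore:
    """Match score of one drug signature against the target cloud.

    ``weighted=True`` weights each pathway by |target PAS| in the cosine
    (mimic/minimize modes), emphasizing the cloud's strongest pathways.
    """
    mode = ScreenMode(mode)
    if len(target) == 0:
        raise ValidationError("target cloud is empty")
    v, t, coverage = _vectors(sig, target)
    norm_v = float(np.linalg.norm(v))
    if norm_v == 0.0:
        return DrugScore(score=0.0, coverage=coverage, zero_signal=True)

    if mode is ScreenMode.EXAGGERATE:
        score = float(v @ t / (t @ t))
    else:
        tt = -t if mode is ScreenMode.MINIMIZE else t
        if weighted:
            w = np.abs(t)
            num = float((w * v) @ tt)
            den = math.sqrt(float(w @ (v * v)) * float(w @ (tt * tt)))
        else:
            num = float(v @ tt)
            den = norm_v * float(np.linalg.norm(tt))
        score = num / den
    return DrugScore(score=score, coverage=coverage, zero_signal=False)


@dataclass(frozen=True)
class RankedDrug:
    rank: int
    drug_id: str
    score: float
    coverage: float
    zero_signal: bool


@dataclass(frozen=True)
class DrugRanking:
    """Drugs ordered by descending score; ties broken by drug_id."""

    mode: ScreenMode
    records: tuple[RankedDrug, ...]

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(r.drug_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.rank, r.drug_id, r.score, r.coverage, int(r.zero_signal))
                for r in self.records
            ],
            columns=["rank", "drug_id", "score", "coverage", "zero_signal"],
        )


def rank_drugs(
    library: Iterable[DrugSignature],
    target: PathwayCloud,
    mode: ScreenMode | str,
    weighted: bool = False,
) -> DrugRanking:
    """Rank every drug in the library against the target cloud."""
    mode = ScreenMode(mode)
    library = list(library)
    if not library:
        raise ValidationError("drug library is empty")
    scored = [
        (sig.drug_id, score_drug(sig, target, mode, weighted=weighted))
        for sig in library
    ]
    scored.sort(key=lambda item: (-item[1].score, item[0]))
    records = tuple(
        RankedDrug(
            rank=i + 1,
            drug_id=drug_id,
            score=s.score,
            coverage=s.coverage,
            zero_signal=s.zero_signal,
        )
        for i, (drug_id, s) in enumerate(scored)
    )
    return DrugRanking(mode=mode, records=records)


def write_signature(sig: DrugSignature, path: str | Path) -> None:
    """Write a precomputed signature as 2-column TSV (pathway_id, PAS)."""
    df = pd.DataFrame({"pathway_id": sig.pas.index, "PAS": sig.pas.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path, drug_id: str | None = None) -> DrugSignature:
    """Read a precomputed signature TSV (pathway_id, PAS)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected 2 columns (pathway_id, PAS)")
    index = pd.Index(df.iloc[:, 0].astype(str)).rename(None)
    pas = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=index)
    return DrugSignature(drug_id=drug_id or Path(path).stem, pas=pas)


def load_library(
    manifest_path: str | Path,
    db: PathwayDatabase,
    policy: TolerancePolicy | None = None,
) -> list[DrugSignature]:
    """Load a drug library from a manifest TSV.

    Rows are either ``drug_id<TAB>expr_path<TAB>design_path`` (expression
    pair, profiled on the fly) or ``drug_id<TAB>signature_path`` (a
    precomputed PAS TSV).  Relative paths resolve against the manifest's
    directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    sigs: list[DrugSignature] = []
    with manifest_path.open(encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if line_no == 1 and fields[0].strip().lower() == "drug_id":
                continue  # header
            if len(fields) == 3:
                drug_id, expr_p, design_p = fields
                expr = read_expression(base / expr_p)
                design = read_design(base / design_p)
                sigs.append(drug_profile(expr, design, db, policy, drug_id=drug_id))
            elif len(fields) == 2:
                drug_id, sig_p = fields
                sigs.append(read_signature(base / sig_p, drug_id=drug_id))
            else:
                raise ValidationError(
                    f"manifest line {line_no}: expected 2 or 3 tab-separated fields"
                )
    if not sigs:
        raise ValidationError(f"{manifest_path}: empty drug manifest")
    return sigs
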