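"""Pathways as role-annotated gene sets.

A pathway here is a flat membership list: each member gene carries a signed
activator/repressor role (ARR) weight encoding whether its product activates
(arr > 0) or represses (arr < 0) the pathway, or is a neutral bystander
(arr = 0).  No topology is modeled — the activation score downstream treats
all members of equal |arr| as equally important.

The on-disk format is a role-annotated GMT dialect: one pathway per line,
tab-separated ``pathway_id``, ``description``, then gene tokens of the form
``GENE:role[:weight]`` with role in {act, rep, neu}.  Plain GMT without role
tokens is rejected because the activation score is undefined without
activator/repressor assignment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .errors import ParseError, ValidationError

__all__ = [
    "Role",
    "GeneRole",
    "Pathway",
    "PathwayDatabase",
    "load_pathways",
    "write_pathways",
    "gene_universe",
]


class Role(enum.Enum):
    """Activator/repressor/neutral role of a gene product in a pathway."""

    ACTIVATOR = "act"
    REPRESSOR = "rep"
    NEUTRAL = "neu"


_DEFAULT_ARR = {Role.ACTIVATOR: 1.0, Role.REPRESSOR: -1.0, Role.NEUTRAL: 0.0}


@dataclass(frozen=True)
class GeneRole:
    """One pathway member: gene symbol plus signed role weight.

    ``arr`` is the discrete activator/repressor role value: positive for
    activators, negative for repressors, zero for neutral members, with
    |arr| <= 1 (graded weights below 1 mark weak roles).
    """

    gene_id: str
    role: Role
    arr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_id", self.gene_id.upper())
        if not self.gene_id:
            raise ValidationError("empty gene_id")
        if self.role is Role.ACTIVATOR and not self.arr > 0:
            raise ValidationError(
                f"{self.gene_id}: activator requires arr > 0, got {self.arr}"
            )
        if self.role is Role.REPRESSOR and not self.arr < 0:
            raise ValidationError(
                f"{self.gene_id}: repressor requires arr < 0, got {self.arr}"
            )
        if self.role is Role.NEUTRAL and self.arr != 0:
            raise ValidationError(
                f"{self.gene_id}: neutral requires arr = 0, got {self.arr}"
            )
        if abs(self.arr) > 1:
            raise ValidationError(
                f"{self.gene_id}: |arr| must be <= 1, got {self.arr}"
            )


@dataclass(frozen=True)
class Pathway:
    """A named, non-empty collection of role-annotated member genes."""

    pathway_id: str
    name: str
    members: tuple[GeneRole, ...]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValidationError("empty pathway_id")
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id}: no members")
        seen: set[str] = set()
        for m in self.members:
            if m.gene_id in seen:
                raise ValidationError(
                    f"pathway {self.pathway_id}: duplicate gene {m.gene_id}"
                )
            seen.add(m.gene_id)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(m.gene_id for m in self.members)

    @property
    def arr_map(self) -> Mapping[str, float]:
        """gene_id -> signed ARR weight."""
        return {m.gene_id: m.arr for m in self.members}

    @property
    def activators(self) -> tuple[GeneRole, ...]:
        return tuple(m for m in self.members if m.role is Role.ACTIVATOR)

    @property
    def repressors(self) -> tuple[GeneRole, ...]:
        return tuple(m for m in self.members if m.role is Role.REPRESSOR)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PathwayDatabase:
    """An ordered collection of pathways with unique ids."""

    pathways: tuple[Pathway, ...]
    _by_id: Mapping[str, Pathway] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_id: dict[str, Pathway] = {}
        for p in self.pathways:
            if p.pathway_id in by_id:
                raise ValidationError(f"duplicate pathway_id {p.pathway_id}")
            by_id[p.pathway_id] = p
        object.__setattr__(self, "_by_id", by_id)

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member gene ids across the database."""
        out: set[str] = set()
        for p in self.pathways:
            out.update(p.gene_ids)
        return frozenset(out)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(p.pathway_id for p in self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)


def _parse_token(token: str, line_no: int) -> GeneRole:
    parts = token.split(":")
    if len(parts) not in (2, 3) or not parts[0]:
        raise ParseError(
            f"line {line_no}: malformed gene token {token!r} "
            "(expected GENE:role[:weight])"
        )
    gene, role_tok = parts[0], parts[1]
    try:
        role = Role(role_tok)
    except ValueError:
        raise ParseError(
            f"line {line_no}: unknown role {role_tok!r} in token {token!r} "
            "(expected act, rep or neu)"
        ) from None
    if len(parts) == 3:
        try:
            magnitude = float(parts[2])
        except ValueError:
            raise ParseError(
                f"line {line_no}: non-numeric weight in token {token!r}"
            ) from None
        if not 0 < magnitude <= 1:
            raise ParseError(
                f"line {line_no}: weight must be in (0, 1], got {magnitude} "
                f"in token {token!r}"
            )
        if role is Role.NEUTRAL:
            raise ParseError(
                f"line {line_no}: neutral gene cannot carry a weight "
                f"(token {token!r})"
            )
        # sign is forced by the role; the file supplies only the magnitude
        arr = magnitude if role is Role.ACTIVATOR else -magnitude
    else:
        arr = _DEFAULT_ARR[role]
    return GeneRole(gene_id=gene, role=role, arr=arr)


def load_pathways(path: str | Path, dialect: str = "role_gmt") -> PathwayDatabase:
    """Load a pathway database from a role-annotated GMT file.

    Parameters
    ----------
    path:
        Tab-separated UTF-8 file, one pathway per line:
        ``id<TAB>description<TAB>GENE:role[:weight]...``.
    dialect:
        Only ``"role_gmt"`` is supported; the role token is mandatory.
    """
    if dialect != "role_gmt":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    pathways: list[Pathway] = []
    seen_ids: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"line {line_no}: expected >= 3 tab-separated fields "
                    f"(id, description, genes...), got {len(fields)}"
                )
            pid, name = fields[0], fields[1]
            if pid in seen_ids:
                raise ValidationError(
                    f"line {line_no}: duplicate pathway_id {pid!r}"
                )
            members = tuple(_parse_token(tok, line_no) for tok in fields[2:])
            try:
                pathways.append(Pathway(pathway_id=pid, name=name, members=members))
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from None
            seen_ids.add(pid)
    return PathwayDatabase(pathways=tuple(pathways))


def _format_member(m: GeneRole) -> str:
    if m.arr == _DEFAULT_ARR[m.role]:
        return f"{m.gene_id}:{m.role.value}"
    return f"{m.gene_id}:{m.role.value}:{abs(m.arr):g}"


def write_pathways(db: PathwayDatabase, path: str | Path) -> None:
    """Write the database back to the role-annotated GMT dialect.

    Members are emitted sorted by gene_id so the output is byte-stable.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in db:
            members = sorted(p.members, key=lambda m: m.gene_id)
            tokens = "\t".join(_format_member(m) for m in members)
            fh.write(f"{p.pathway_id}\t{p.name}\t{tokens}\n")


def gene_universe(db: PathwayDatabase) -> frozenset[str]:
    """Set of all gene ids appearing in any pathway of ``db``."""
    return db.universe
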