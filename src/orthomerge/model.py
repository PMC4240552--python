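"""Core domain types shared by every stage of the consensus pipeline.

The atom of all clusterings is :class:`ProteinRef`, a globally unique
``(species, protein)`` identifier.  A :class:`GroupSet` holds one input
method's prediction as a partition of its universe; :class:`MetaResult`
holds the final consensus groups with full provenance.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

_TOKEN_FORBIDDEN = re.compile(r"[\s|]")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True, order=True)
class ProteinRef:
    """A globally unique protein identifier: a species label plus accession.

    Ordering is lexicographic on ``(species, protein)`` and is total and
    stable; it is used for every deterministic tie-break in the pipeline.
    """

    species: str
    protein: str

    def __post_init__(self) -> None:
        for name in ("species", "protein"):
            value = getattr(self, name)
            if not value:
                raise ValidationError(f"ProteinRef.{name} must be non-empty")
            if _TOKEN_FORBIDDEN.search(value):
                raise ValidationError(
                    f"ProteinRef.{name} {value!r} contains whitespace or '|'"
                )

    def __str__(self) -> str:
        return f"{self.species}|{self.protein}"

    @classmethod
    def parse(cls, token: str) -> "ProteinRef":
        species, sep, protein = token.partition("|")
        if not sep:
            raise ValidationError(f"token {token!r} has no '|' separator")
        return cls(species, protein)


_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(_AA + "X")


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the 20 standard residues plus X."""

    ref: ProteinRef
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"empty sequence for {self.ref}")
        residues = self.residues.upper()
        bad = set(residues) - _VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"sequence {self.ref} contains invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GroupSet:
    """One method's prediction: a named partition into groups of size >= 2.

    Disjointness and the no-singleton rule are enforced at construction;
    resolution of overlapping input groups happens earlier, at load time.
    """

    method_name: str
    groups: list[frozenset[ProteinRef]]

    def __post_init__(self) -> None:
        seen: set[ProteinRef] = set()
        for g in self.groups:
            if len(g) < 2:
                raise ValidationError(
                    f"GroupSet {self.method_name!r}: group of size {len(g)} < 2"
                )
            overlap = seen & g
            if overlap:
                raise ValidationError(
                    f"GroupSet {self.method_name!r}: protein(s) "
                    f"{sorted(map(str, overlap))[:3]} occur in two groups"
                )
            seen |= g
        self._universe = seen

    @property
    def universe(self) -> frozenset[ProteinRef]:
        return frozenset(self._universe)

    def group_of(self) -> dict[ProteinRef, int]:
        """Map each protein to the index of its group."""
        out: dict[ProteinRef, int] = {}
        for idx, g in enumerate(self.groups):
            for p in g:
                out[p] = idx
        return out

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class MetaParams:
    """Tunable thresholds of the consensus run.

    ``evalue_threshold``, ``min_coverage`` and ``min_size`` are the three
    thresholds of the seed-selection and profile-expansion stages; the
    defaults (1e-10, 0.40, 4) are the recommended operating point.
    """

    evalue_threshold: float = 1e-10
    min_coverage: float = 0.40
    min_size: int = 4
    rng_seed: int = 0
    backend: str = "builtin"
    n_decoys: int = 60
    pseudocount: float = 1.0
    gap_open: float = 5.5
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not (self.evalue_threshold > 0):
            raise ValidationError("evalue_threshold must be positive")
        if not (0 < self.min_coverage <= 1):
            raise ValidationError("min_coverage must be in (0, 1]")
        if self.min_size < 2:
            raise ValidationError("min_size must be >= 2")
        if self.backend not in ("builtin", "external"):
            raise ValidationError(f"unknown backend {self.backend!r}")
        if self.n_decoys < 50:
            raise ValidationError("n_decoys must be >= 50")

    def replace(self, **kw) -> "MetaParams":
        return dataclasses.replace(self, **kw)


@dataclass
class MetaGroup:
    """One final consensus group with provenance.

    ``seed_members`` were co-grouped by every method of ``method_subset`` at
    level ``level``; ``profile_added_members`` were recruited by the profile
    stage.  ``leftover_flag`` marks small two-method intersections appended
    after the main loop.
    """

    group_id: str
    members: frozenset[ProteinRef]
    level: int
    method_subset: frozenset[str]
    seed_members: frozenset[ProteinRef]
    profile_added_members: frozenset[ProteinRef]
    leftover_flag: bool = False

    def __post_init__(self) -> None:
        if self.seed_members | self.profile_added_members != self.members:
            raise ValidationError("seed + profile members must equal members")
        if self.seed_members & self.profile_added_members:
            raise ValidationError("seed and profile members must be disjoint")
        if self.leftover_flag and self.profile_added_members:
            raise ValidationError("leftover groups cannot have profile members")


@dataclass
class MetaResult:
    """Final ortholog groups plus the proteins left unassigned."""

    final_groups: list[MetaGroup]
    unassigned: frozenset[ProteinRef]
    params: MetaParams
    rng_seed: int
    random_choices: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[ProteinRef] = set()
        for g in self.final_groups:
            if seen & g.members:
                raise ValidationError("final groups are not pairwise disjoint")
            seen |= g.members
        if seen & self.unassigned:
            raise ValidationError("unassigned overlaps final groups")

    @property
    def assigned(self) -> frozenset[ProteinRef]:
        out: set[ProteinRef] = set()
        for g in self.final_groups:
            out |= g.members
        return frozenset(out)

    def as_groupset(self, method_name: str = "meta") -> GroupSet:
        return GroupSet(method_name, [g.members for g in self.final_groups])


EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


@dataclass
class AnnotationStore:
    """GO DAG + protein annotations, and EC annotations.

    ``go_parents`` maps each term to its set of parents (the DAG is checked
    acyclic at load); ``go_namespace`` tags each term with its aspect.
    GO annotations are evidence-filtered: only experimental codes
    (EXP, IDA, IPI, IMP, IGI, IEP) are retained.
    """

    go_parents: dict[str, frozenset[str]]
    go_namespace: dict[str, str]
    go_annotations: dict[ProteinRef, frozenset[tuple[str, str]]]
    ec_annotations: dict[ProteinRef, frozenset[str]]

    def go_terms_of(self, p: ProteinRef, namespace: str | None = None) -> set[str]:
        terms = {t for t, _ev in self.go_annotations.get(p, ())}
        if namespace is not None:
            terms = {t for t in terms if self.go_namespace.get(t) == namespace}
        return terms

    def namespaces(self) -> set[str]:
        return set(self.go_namespace.values())

    def go_ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` including itself."""
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.go_parents.get(t, ()))
        return out


@dataclass
class ReferenceGroups:
    """Manually curated reference ortholog groups used for benchmarking."""

    refogs: dict[str, frozenset[ProteinRef]]
    universe: frozenset[ProteinRef]

    def __post_init__(self) -> None:
        seen: set[ProteinRef] = set()
        for rid, members in self.refogs.items():
            if seen & members:
                raise ValidationError(f"reference groups overlap at {rid}")
            seen |= members
            if not members <= self.universe:
                raise ValidationError(f"refog {rid} has members outside universe")

    def as_groupset(self, method_name: str = "reference") -> GroupSet:
        return GroupSet(
            method_name, [m for m in self.refogs.values() if len(m) >= 2]
        )


def sorted_refs(refs: Iterable[ProteinRef]) -> list[ProteinRef]:
    return sorted(refs)


def group_sort_key(members: frozenset[ProteinRef]):
    """Deterministic group ordering: descending size, then smallest member."""
    return (-len(members), min(members))
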