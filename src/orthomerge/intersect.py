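"""Seed-group construction by partition intersection.

At level ``i`` every size-``i`` subset of the N input methods is examined:
two proteins fall in the same cell of a subset's common refinement iff they
are co-grouped by every method of the subset.  Cells reaching ``min_size``
become candidate seeds; a protein claimed by candidate cells of different
subsets stays in the largest cell, with genuine ties resolved by the run's
seeded RNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .model import GroupSet, ProteinRef, ValidationError, group_sort_key

logger = logging.getLogger(__name__)


@dataclass
class SeedGroup:
    """An intermediate (seed) group: an intersection of ``level`` methods.

    ``method_subset`` is the first contributing subset in deterministic
    order; if the identical cell arose from several subsets, all of them are
    recorded in ``all_subsets``.
    """

    members: frozenset[ProteinRef]
    level: int
    method_subset: frozenset[str]
    all_subsets: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.all_subsets:
            self.all_subsets = [self.method_subset]


def comembership_cells(
    groupsets: Sequence[GroupSet],
    subset: Iterable[str],
    pool: Iterable[ProteinRef],
) -> list[tuple[frozenset[ProteinRef], frozenset[str]]]:
    """Cells of the common refinement of the partitions named in ``subset``.

    Restricted to proteins of ``pool`` that belong to some group in *every*
    method of the subset (absence is not a wildcard).  Singleton cells are
    discarded.  Cells are returned in deterministic order: descending size,
    then lexicographically smallest member.
    """
    subset = frozenset(subset)
    by_name = {gs.method_name: gs for gs in groupsets}
    unknown = subset - set(by_name)
    if unknown:
        raise ValidationError(f"unknown method(s) in subset: {sorted(unknown)}")
    pool = set(pool)
    maps = [by_name[name].group_of() for name in sorted(subset)]
    cells: dict[tuple[int, ...], set[ProteinRef]] = {}
    for p in pool:
        key = []
        for m in maps:
            idx = m.get(p)
            if idx is None:
                break
            key.append(idx)
        else:
            cells.setdefault(tuple(key), set()).add(p)
    out = [
        (frozenset(cell), subset) for cell in cells.values() if len(cell) >= 2
    ]
    out.sort(key=lambda cs: group_sort_key(cs[0]))
    return out


@dataclass
class _Cell:
    members: set[ProteinRef]
    subsets: list[frozenset[str]]
    alive: bool = True

    def key(self):
        return (-len(self.members), min(self.members))


def intersect_level(
    groupsets: Sequence[GroupSet],
    i: int,
    pool: Iterable[ProteinRef],
    min_size: int,
    rng: np.random.Generator,
    random_log: list[dict] | None = None,
) -> tuple[list[SeedGroup], list[tuple[frozenset[ProteinRef], frozenset[str]]]]:
    """Select the seed groups of level ``i``.

    Evaluates the common refinement of every size-``i`` method subset over
    ``pool``; cells of size >= ``min_size`` become candidates.  Identical
    cells from different subsets are kept once with all contributing subsets
    recorded.  A protein claimed by several candidate cells stays in the
    largest one (equal sizes: uniform random choice from ``rng``); a cell
    dropping below ``min_size`` is demoted.  Returns the selected seeds and,
    at ``i == 2``, the rejected cells of size 2..min_size-1 for the final
    leftover step.
    """
    n = len(groupsets)
    if not (2 <= i <= n):
        raise ValidationError(f"level i={i} outside [2, N={n}]")
    pool = set(pool)
    names = [gs.method_name for gs in groupsets]

    candidates: dict[frozenset[ProteinRef], _Cell] = {}
    rejected: dict[frozenset[ProteinRef], frozenset[str]] = {}
    for combo in combinations(names, i):
        for cell, subset in comembership_cells(groupsets, combo, pool):
            if len(cell) >= min_size:
                if cell in candidates:
                    candidates[cell].subsets.append(subset)
                else:
                    candidates[cell] = _Cell(set(cell), [subset])
            elif i == 2 and len(cell) >= 2:
                rejected.setdefault(cell, subset)

    cells = sorted(candidates.values(), key=_Cell.key)

    # Iterative conflict resolution: only genuine size ties consult the RNG.
    while True:
        claims: dict[ProteinRef, list[_Cell]] = {}
        for c in cells:
            if not c.alive:
                continue
            for p in c.members:
                claims.setdefault(p, []).append(c)
        conflicted = sorted(p for p, cs in claims.items() if len(cs) > 1)
        if not conflicted:
            break
        p = conflicted[0]
        contenders = sorted(claims[p], key=_Cell.key)
        top = len(contenders[0].members)
        tied = [c for c in contenders if len(c.members) == top]
        if len(tied) == 1:
            winner = tied[0]
        else:
            pick = int(rng.integers(len(tied)))
            winner = tied[pick]
            if random_log is not None:
                random_log.append(
                    {
                        "level": i,
                        "protein": str(p),
                        "competing_cells": [
                            sorted(map(str, c.members)) for c in tied
                        ],
                        "chosen": pick,
                    }
                )
            logger.debug("tie for %s among %d equal cells: kept index %d",
                         p, len(tied), pick)
        for c in contenders:
            if c is winner:
                continue
            c.members.discard(p)
            if len(c.members) < min_size:
                c.alive = False
                if i == 2 and len(c.members) >= 2:
                    remnant = frozenset(c.members)
                    rejected.setdefault(remnant, c.subsets[0])

    def subset_key(s: frozenset[str]):
        return tuple(sorted(s))

    seeds = [
        SeedGroup(
            members=frozenset(c.members),
            level=i,
            method_subset=min(c.subsets, key=subset_key),
            all_subsets=sorted(c.subsets, key=subset_key),
        )
        for c in cells
        if c.alive
    ]
    seeds.sort(key=lambda s: group_sort_key(s.members))
    rejected_list = sorted(rejected.items(), key=lambda cs: group_sort_key(cs[0]))
    return seeds, rejected_list
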