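"""The consensus loop: seed intersection, profile expansion, finalization.

``run_meta`` iterates the level counter ``i`` from N (all methods agree)
down to 2.  At each level it selects seed groups by partition intersection,
builds one profile per seed, recruits unassigned proteins whose profile hit
passes the E-value and coverage thresholds, and finalizes the resulting
groups — finalized proteins never re-enter later levels.  After level 2,
small two-method intersections (size 2..min_size-1) are appended as
leftover groups.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .align import build_msa
from .intersect import SeedGroup, intersect_level
from .model import (
    GroupSet,
    MetaGroup,
    MetaParams,
    MetaResult,
    ProteinRef,
    ProteinSequence,
    ValidationError,
    group_sort_key,
)
from .profile import ProfileHit, build_profile, calibrate_profile, score_sequence

logger = logging.getLogger(__name__)


def _builtin_hits(
    seed_seqs: dict[str, list[ProteinSequence]],
    targets: list[ProteinSequence],
    database_size: int,
    params: MetaParams,
    rng: np.random.Generator,
) -> list[ProfileHit]:
    """Builtin backend: log-odds profiles with Gumbel-calibrated E-values."""
    decoy_pool = sorted(targets, key=lambda s: s.ref)
    hits: list[ProfileHit] = []
    for group_id in sorted(seed_seqs):
        msa = build_msa(seed_seqs[group_id])
        profile = build_profile(
            msa,
            pseudocount=params.pseudocount,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
            group_id=group_id,
        )
        profile = calibrate_profile(
            profile, decoy_pool, params.n_decoys, rng, database_size
        )
        for seq in decoy_pool:
            hits.append(score_sequence(profile, seq))
    return hits


def select_assignments(
    hits: Sequence[ProfileHit], params: MetaParams
) -> dict[ProteinRef, str]:
    """Pick at most one group per protein from threshold-passing hits.

    Eligibility: E-value strictly below the threshold, and the smaller of
    the two coverages at or above ``min_coverage``.  Preference: lowest
    E-value, then highest min-coverage, then smallest group id.
    """
    best: dict[ProteinRef, tuple[float, float, str]] = {}
    for hit in hits:
        if hit.evalue >= params.evalue_threshold:
            continue
        if hit.min_coverage < params.min_coverage:
            continue
        key = (hit.evalue, -hit.min_coverage, hit.group_id)
        if hit.protein not in best or key < best[hit.protein]:
            best[hit.protein] = key
    return {p: k[2] for p, k in best.items()}


def _resolve_leftovers(
    cells: list[tuple[frozenset[ProteinRef], frozenset[str]]],
    pool: set[ProteinRef],
    rng: np.random.Generator,
    random_log: list[dict],
) -> list[tuple[frozenset[ProteinRef], frozenset[str]]]:
    """Trim leftover 2-method cells to the remaining pool and make them disjoint.

    Cells are processed in deterministic order (descending size, then
    smallest member); overlaps keep the protein in the larger remaining
    cell, equal sizes consulting the RNG, mirroring the seed-conflict rule.
    """
    live = [(set(c) & pool, subset) for c, subset in cells]
    live = [(c, s) for c, s in live if len(c) >= 2]
    out: list[tuple[frozenset[ProteinRef], frozenset[str]]] = []
    seen_members: set[ProteinRef] = set()
    seen_cells: set[frozenset[ProteinRef]] = set()
    while True:
        live = [(c - seen_members, s) for c, s in live]
        live = [(c, s) for c, s in live if len(c) >= 2]
        if not live:
            break
        live.sort(key=lambda cs: group_sort_key(frozenset(cs[0])))
        top_size = len(live[0][0])
        tied = [cs for cs in live if len(cs[0]) == top_size]
        if len(tied) > 1 and any(
            tied[0][0] & other[0] for other in tied[1:]
        ):
            pick = int(rng.integers(len(tied)))
            chosen = tied[pick]
            random_log.append(
                {
                    "stage": "leftover",
                    "competing_cells": [sorted(map(str, c)) for c, _ in tied],
                    "chosen": pick,
                }
            )
        else:
            chosen = live[0]
        cell = frozenset(chosen[0])
        if cell not in seen_cells:
            out.append((cell, chosen[1]))
            seen_cells.add(cell)
        seen_members |= cell
        live = live[1:] if chosen is live[0] else [
            cs for cs in live if cs is not chosen
        ]
    out.sort(key=lambda cs: group_sort_key(cs[0]))
    return out


def run_meta(
    groupsets: Sequence[GroupSet],
    proteome: dict[ProteinRef, ProteinSequence] | None,
    params: MetaParams | None = None,
    *,
    skip_missing_sequences: bool = False,
    aligner_bin: str | None = None,
    hmmer_bin: str | None = None,
) -> MetaResult:
    """Run the full consensus pipeline over N >= 2 method predictions.

    With ``proteome=None`` the profile-expansion stage is disabled and the
    result is the pure intersection consensus.  Proteins predicted by some
    method but absent from the proteome raise an error unless
    ``skip_missing_sequences`` drops them with a warning.
    """
    params = params or MetaParams()
    if len(groupsets) < 2:
        raise ValidationError("the consensus needs N >= 2 input methods")
    names = [gs.method_name for gs in groupsets]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate method names: {names}")

    universe: set[ProteinRef] = set()
    for gs in groupsets:
        universe |= gs.universe

    expansion = proteome is not None
    if expansion:
        # proteome-only proteins join the pool as recruitment candidates
        universe |= set(proteome)
        missing = sorted(p for p in universe if p not in proteome)
        if missing and not skip_missing_sequences:
            raise ValidationError(
                f"{len(missing)} grouped protein(s) lack a sequence, "
                f"e.g. {missing[:3]}"
            )
        if missing:
            logger.warning("dropping %d proteins without sequences", len(missing))
            universe -= set(missing)

    rng = np.random.default_rng(params.rng_seed)
    random_log: list[dict] = []
    pool = set(universe)
    final: list[MetaGroup] = []
    leftover_cells: list[tuple[frozenset[ProteinRef], frozenset[str]]] = []
    reached_level_2 = False

    i = len(groupsets)
    while True:
        seeds, rejected = intersect_level(
            groupsets, i, pool, params.min_size, rng, random_log
        )
        if i == 2:
            reached_level_2 = True
            leftover_cells = rejected

        assigned: dict[ProteinRef, str] = {}
        seed_by_key: dict[str, SeedGroup] = {
            f"L{i}S{k}": seed for k, seed in enumerate(seeds)
        }
        if expansion and seeds:
            seed_members: set[ProteinRef] = set()
            for seed in seeds:
                seed_members |= seed.members
            targets = sorted(pool - seed_members)
            if targets:
                target_seqs = [proteome[p] for p in targets]
                seed_seqs = {
                    key: [proteome[p] for p in sorted(seed.members)]
                    for key, seed in seed_by_key.items()
                }
                if params.backend == "external":
                    from .external import external_hits

                    hits = external_hits(
                        seed_seqs, target_seqs, len(targets),
                        aligner_bin=aligner_bin, hmmer_bin=hmmer_bin,
                    )
                else:
                    hits = _builtin_hits(
                        seed_seqs, target_seqs, len(targets), params, rng
                    )
                assigned = select_assignments(hits, params)

        added_by_key: dict[str, set[ProteinRef]] = {k: set() for k in seed_by_key}
        for protein, key in assigned.items():
            added_by_key[key].add(protein)
        for key, seed in seed_by_key.items():
            members = seed.members | added_by_key[key]
            final.append(
                MetaGroup(
                    group_id=key,
                    members=frozenset(members),
                    level=i,
                    method_subset=seed.method_subset,
                    seed_members=seed.members,
                    profile_added_members=frozenset(added_by_key[key]),
                )
            )
            pool -= members

        if i > 2 and pool:
            i -= 1
            continue
        break

    if reached_level_2:
        for k, (cell, subset) in enumerate(
            _resolve_leftovers(leftover_cells, pool, rng, random_log)
        ):
            final.append(
                MetaGroup(
                    group_id=f"LFT{k}",
                    members=cell,
                    level=2,
                    method_subset=subset,
                    seed_members=cell,
                    profile_added_members=frozenset(),
                    leftover_flag=True,
                )
            )
            pool -= cell

    final.sort(key=lambda g: group_sort_key(g.members))
    for k, g in enumerate(final, start=1):
        g.group_id = f"G{k}"
    return MetaResult(
        final_groups=final,
        unassigned=frozenset(pool),
        params=params,
        rng_seed=params.rng_seed,
        random_choices=random_log,
    )
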