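"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity at tiny problem sizes and stays
independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from orthomerge.model import GroupSet, ProteinRef


def bruteforce_cells(
    groupsets: list[GroupSet],
    subset: set[str],
    pool: set[ProteinRef],
) -> set[frozenset[ProteinRef]]:
    """Cells of the common refinement via O(n^2) pairwise co-membership.

    A protein participates only if every method of the subset groups it;
    two proteins share a cell iff co-grouped by every method of the subset.
    Cells of size 1 are discarded.
    """
    chosen = [gs for gs in groupsets if gs.method_name in subset]
    assert len(chosen) == len(subset)
    maps = [gs.group_of() for gs in chosen]
    eligible = sorted(p for p in pool if all(p in m for m in maps))
    cells: list[set[ProteinRef]] = []
    for p in eligible:
        placed = False
        for cell in cells:
            q = next(iter(cell))
            if all(m[p] == m[q] for m in maps):
                cell.add(p)
                placed = True
                break
        if not placed:
            cells.append({p})
    return {frozenset(c) for c in cells if len(c) >= 2}


def bruteforce_pairs(groups: list[frozenset[ProteinRef]]) -> set[frozenset]:
    """All co-grouped pairs by exhaustive double loop."""
    pairs = set()
    for g in groups:
        members = sorted(g)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs


def sw_score_oracle(
    scores: np.ndarray, seq: list[int], gap_open: float, gap_extend: float
) -> float:
    """Plain-python affine-gap local alignment score (Gotoh recurrences)."""
    L, M = scores.shape[0], len(seq)
    NEG = float("-inf")
    H = [[0.0] * (M + 1) for _ in range(L + 1)]
    E = [[NEG] * (M + 1) for _ in range(L + 1)]
    F = [[NEG] * (M + 1) for _ in range(L + 1)]
    best = 0.0
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + scores[i - 1][seq[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_maximal_cliques(nodes, edges) -> list[frozenset]:
    """Maximal cliques by exhaustive subset enumeration (tiny graphs only)."""
    nodes = sorted(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(
            frozenset((a, b)) in edge_set
            for a, b in itertools.combinations(sub, 2)
        )

    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if is_clique(sub):
                cliques.append(frozenset(sub))
    return [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]


def sim_rel_oracle(c1: str, c2: str, p: dict, parents: dict) -> float:
    """Relevance similarity by explicit enumeration of all common ancestors."""
    import math

    def up(t):
        out = {t}
        frontier = [t]
        while frontier:
            x = frontier.pop()
            for q in parents.get(x, ()):  # noqa: B023
                if q not in out:
                    out.add(q)
                    frontier.append(q)
        return out

    ic = {t: -math.log(v) for t, v in p.items()}
    denom = ic[c1] + ic[c2]
    if denom == 0:
        return 0.0
    return max(
        [
            (2 * ic[a] / denom) * (1 - p[a])
            for a in up(c1) & up(c2)
        ],
        default=0.0,
    )


def random_partition(
    rng: np.random.Generator, proteins: list[ProteinRef], max_groups: int
) -> list[frozenset[ProteinRef]]:
    """A random partition into non-singleton groups (leftovers unassigned)."""
    n_groups = int(rng.integers(1, max_groups + 1))
    labels = rng.integers(0, n_groups, size=len(proteins))
    groups: dict[int, set] = {}
    for p, lab in zip(proteins, labels):
        groups.setdefault(int(lab), set()).add(p)
    return [frozenset(g) for g in groups.values() if len(g) >= 2]


def random_groupsets(
    rng: np.random.Generator, n_proteins: int, n_methods: int
) -> tuple[list[GroupSet], list[ProteinRef]]:
    """Random per-method partitions over a shared protein universe."""
    proteins = [
        ProteinRef(f"s{int(rng.integers(1, 4))}", f"p{k}")
        for k in range(n_proteins)
    ]
    groupsets = []
    for m in range(n_methods):
        # each method covers a random subset of the universe
        mask = rng.random(n_proteins) < 0.9
        covered = [p for p, keep in zip(proteins, mask) if keep]
        groups = random_partition(rng, covered, max(2, n_proteins // 6))
        if not groups:
            groups = [frozenset(proteins[:2])]
        groupsets.append(GroupSet(f"m{m + 1}", groups))
    return groupsets, proteins
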