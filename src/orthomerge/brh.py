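"""Best-reciprocal-hit input method with score-ratio and length filters.

From an all-vs-all similarity table (BLAST ``-outfmt 6``-like subset), a
hit survives iff its raw score reaches ``min_score_ratio`` of *both*
self-scores and its alignment covers ``min_len_ratio`` of the shorter
sequence.  Mutual best surviving hits across species become ortholog
pairs, and fully connected cliques of the pair graph become groups; the
per-species-best-hit structure keeps every clique at one protein per
species and makes clique search cheap.

The two thresholds are method parameters with defaults (0.5, 0.5) chosen
as a conventional operating point; tune them to the score scale of the
similarity search that produced the table.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import networkx as nx

from .model import GroupSet, ProteinRef, ValidationError, group_sort_key


class SimilarityTable:
    """Best-per-ordered-pair similarity records plus self-alignment scores."""

    def __init__(
        self,
        records: list[tuple[ProteinRef, ProteinRef, float, int]],
        self_scores: dict[ProteinRef, float],
    ) -> None:
        for p, s in self_scores.items():
            if s <= 0:
                raise ValidationError(f"non-positive self-score for {p}")
        best: dict[tuple[ProteinRef, ProteinRef], tuple[float, int]] = {}
        for q, s, score, alen in records:
            key = (q, s)
            if key not in best or score > best[key][0]:
                best[key] = (float(score), int(alen))
        self.hits = best
        self.self_scores = dict(self_scores)

    @classmethod
    def from_tsv(cls, hits_path: str | Path, self_path: str | Path) -> "SimilarityTable":
        """Load hits (query, subject, raw_score, alignment_length) and
        self-scores (protein, raw_score) from TSV files."""
        records = []
        with open(hits_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 4:
                    raise ValidationError(
                        f"{hits_path}:{lineno}: expected 4 TSV fields"
                    )
                records.append(
                    (
                        ProteinRef.parse(f[0]),
                        ProteinRef.parse(f[1]),
                        float(f[2]),
                        int(f[3]),
                    )
                )
        self_scores: dict[ProteinRef, float] = {}
        with open(self_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 2:
                    raise ValidationError(
                        f"{self_path}:{lineno}: expected 2 TSV fields"
                    )
                self_scores[ProteinRef.parse(f[0])] = float(f[1])
        return cls(records, self_scores)


def brh_pairs(
    table: SimilarityTable,
    seq_lengths: dict[ProteinRef, int],
    min_score_ratio: float = 0.5,
    min_len_ratio: float = 0.5,
) -> set[frozenset[ProteinRef]]:
    """Mutual best cross-species hits passing both filters.

    A hit (q, s) passes iff score/self(q) and score/self(s) both reach
    ``min_score_ratio`` and the alignment length reaches ``min_len_ratio``
    of the shorter sequence.  Per protein and foreign species, the best
    passing hit (highest score, ties to the lexicographically smallest
    subject) is kept; a pair is emitted iff the choice is mutual.
    """
    if not (0 <= min_score_ratio <= 1 and 0 <= min_len_ratio <= 1):
        raise ValidationError("BRH thresholds must be in [0, 1]")
    # best passing hit per (query, foreign species)
    best: dict[tuple[ProteinRef, str], tuple[float, ProteinRef]] = {}
    for (q, s), (score, alen) in table.hits.items():
        if q == s or q.species == s.species:
            continue
        for p in (q, s):
            if p not in table.self_scores:
                raise ValidationError(f"missing self-score for {p}")
            if p not in seq_lengths:
                raise ValidationError(f"missing sequence length for {p}")
        if score / table.self_scores[q] < min_score_ratio:
            continue
        if score / table.self_scores[s] < min_score_ratio:
            continue
        if alen < min_len_ratio * min(seq_lengths[q], seq_lengths[s]):
            continue
        key = (q, s.species)
        cur = best.get(key)
        if cur is None or (score, _neg_ref(s)) > (cur[0], _neg_ref(cur[1])):
            best[key] = (score, s)
    pairs: set[frozenset[ProteinRef]] = set()
    for (q, _species), (_score, s) in best.items():
        back = best.get((s, q.species))
        if back is not None and back[1] == q:
            pairs.add(frozenset((q, s)))
    return pairs


class _NegRef:
    """Inverts ProteinRef ordering so max() prefers the smaller ref on ties."""

    __slots__ = ("ref",)

    def __init__(self, ref: ProteinRef) -> None:
        self.ref = ref

    def __lt__(self, other: "_NegRef") -> bool:
        return self.ref > other.ref

    def __gt__(self, other: "_NegRef") -> bool:
        return self.ref < other.ref

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegRef) and self.ref == other.ref


def _neg_ref(ref: ProteinRef) -> _NegRef:
    return _NegRef(ref)


def clique_groups(
    pairs: set[frozenset[ProteinRef]], method_name: str = "brh"
) -> GroupSet:
    """Partition the BRH graph into fully connected ortholog groups.

    Maximal cliques are enumerated (Bron-Kerbosch via networkx); each
    protein is assigned to the largest maximal clique containing it, ties
    going to the clique with the lexicographically smallest member set.
    Cliques reduced below size 2 by those assignments are dropped.
    """
    graph = nx.Graph()
    for pair in pairs:
        a, b = sorted(pair)
        if a.species == b.species:
            raise ValidationError(f"same-species pair {a} - {b}")
        graph.add_edge(a, b)
    if graph.number_of_nodes() == 0:
        return GroupSet(method_name, [])

    cliques = [frozenset(c) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    assignment: dict[ProteinRef, int] = {}
    for idx, clique in enumerate(cliques):
        for p in clique:
            if p not in assignment:
                assignment[p] = idx
    groups: dict[int, set[ProteinRef]] = defaultdict(set)
    for p, idx in assignment.items():
        groups[idx].add(p)
    kept = [frozenset(g) for g in groups.values() if len(g) >= 2]
    kept.sort(key=group_sort_key)
    return GroupSet(method_name, kept)
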