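"""Evaluation of ortholog clusterings.

Three families of measures:

* pairwise clustering agreement — Jaccard coefficient on co-grouped
  protein pairs, and counts of exactly identical groups;
* accuracy against curated reference groups — fission events (a reference
  group split over n predicted groups counts n-1 fissions) and fusion
  events (more than 3 foreign proteins added to a reference group's
  best-matching predicted group);
* functional-annotation conservation — Schlicker relevance similarity of
  GO terms (experimental evidence only) or EC numbers between co-grouped
  annotated proteins, aggregated by best-match averaging.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnnotationStore,
    GroupSet,
    MetaParams,
    MetaResult,
    ProteinRef,
    ReferenceGroups,
    ValidationError,
)

Pair = frozenset  # of two ProteinRefs


def _groups_of(clustering: GroupSet | MetaResult) -> list[frozenset[ProteinRef]]:
    if isinstance(clustering, MetaResult):
        return [g.members for g in clustering.final_groups]
    return list(clustering.groups)


def ortholog_pairs(clustering: GroupSet | MetaResult) -> set[Pair]:
    """All unordered within-group pairs; a size-k group yields k(k-1)/2."""
    pairs: set[Pair] = set()
    for g in _groups_of(clustering):
        for a, b in itertools.combinations(sorted(g), 2):
            pairs.add(frozenset((a, b)))
    return pairs


def jaccard(a: set[Pair], b: set[Pair]) -> float:
    """|A n B| / |A u B| on co-grouped pairs; 1.0 when both sets are empty
    (documented convention, unreachable for clusterings with real groups)."""
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def count_identical_groups(a: GroupSet, b: GroupSet) -> int:
    """Number of groups of ``a`` whose member set exactly equals one of ``b``."""
    b_groups = set(b.groups)
    return sum(1 for g in a.groups if g in b_groups)


# ---------------------------------------------------------------------------
# fusion / fission accounting against reference groups
# ---------------------------------------------------------------------------

@dataclass
class RefogRecord:
    fissions: int
    fusion: bool
    covered: bool

    @property
    def accurate(self) -> bool:
        return self.covered and self.fissions == 0 and not self.fusion


@dataclass
class RefogReport:
    per_refog: dict[str, RefogRecord]
    pct_accurate: float
    total_fusions: int
    total_fissions: int
    pct_fusion_affected: float
    pct_fission_affected: float
    pct_both: float


def fusion_fission(
    predicted: GroupSet | MetaResult, refs: ReferenceGroups
) -> RefogReport:
    """Count fusion and fission events per reference group.

    Predicted groups are first restricted to the benchmark universe.  For a
    reference group R, the predicted groups overlapping R number n, giving
    max(n-1, 0) fissions; the best-matching group (largest overlap, ties to
    the larger group then the lexicographically smallest) causes a fusion
    iff it contains more than 3 proteins outside R.  A reference group is
    predicted accurately iff it is covered by at least one group and shows
    neither event.
    """
    if not refs.refogs:
        raise ValidationError("reference groups are empty")
    restricted = [
        g & refs.universe for g in _groups_of(predicted) if g & refs.universe
    ]
    per: dict[str, RefogRecord] = {}
    for rid in sorted(refs.refogs):
        members = refs.refogs[rid]
        overlapping = [g for g in restricted if g & members]
        fissions = max(len(overlapping) - 1, 0)
        fusion = False
        if overlapping:
            best = max(
                overlapping,
                key=lambda g: (len(g & members), len(g), _neg_key(g)),
            )
            fusion = len(best - members) > 3
        per[rid] = RefogRecord(
            fissions=fissions, fusion=fusion, covered=bool(overlapping)
        )
    n = len(per)
    fused = sum(1 for r in per.values() if r.fusion)
    fissioned = sum(1 for r in per.values() if r.fissions > 0)
    both = sum(1 for r in per.values() if r.fusion and r.fissions > 0)
    return RefogReport(
        per_refog=per,
        pct_accurate=100.0 * sum(r.accurate for r in per.values()) / n,
        total_fusions=fused,
        total_fissions=sum(r.fissions for r in per.values()),
        pct_fusion_affected=100.0 * fused / n,
        pct_fission_affected=100.0 * fissioned / n,
        pct_both=100.0 * both / n,
    )


class _NegGroup:
    """Reverses lexicographic group comparison so max() prefers smaller."""

    __slots__ = ("key",)

    def __init__(self, g: frozenset[ProteinRef]) -> None:
        self.key = tuple(sorted(g))

    def __lt__(self, other: "_NegGroup") -> bool:
        return self.key > other.key

    def __gt__(self, other: "_NegGroup") -> bool:
        return self.key < other.key

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegGroup) and self.key == other.key


def _neg_key(g: frozenset[ProteinRef]) -> _NegGroup:
    return _NegGroup(g)


# ---------------------------------------------------------------------------
# information content and Schlicker relevance similarity
# ---------------------------------------------------------------------------

@dataclass
class IcTable:
    """Relative annotation frequency (descendants included) and IC = -ln p."""

    p: dict[str, float]
    ic: dict[str, float]
    parents: dict[str, frozenset[str]]

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        return out


def _propagated_counts(
    parents: Mapping[str, frozenset[str]],
    term_sets: Iterable[Iterable[str]],
) -> tuple[dict[str, int], int]:
    direct: dict[str, int] = {}
    total = 0
    for terms in term_sets:
        for t in terms:
            direct[t] = direct.get(t, 0) + 1
            total += 1
    counts: dict[str, int] = {}
    for term, k in direct.items():
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(parents.get(t, ()))
        for t in seen:
            counts[t] = counts.get(t, 0) + k
    return counts, total


def ic_table(store: AnnotationStore, namespace: str) -> IcTable:
    """Information-content table for one GO namespace.

    p(term) is the fraction of the namespace's annotations falling on the
    term or any descendant; ic = -ln p.  Terms never annotated (directly or
    below) are excluded.
    """
    term_sets = [
        [t for t, _ev in anns if store.go_namespace.get(t) == namespace]
        for anns in store.go_annotations.values()
    ]
    counts, total = _propagated_counts(store.go_parents, term_sets)
    if total == 0:
        raise ValidationError(f"no annotations in namespace {namespace!r}")
    p = {t: c / total for t, c in counts.items()}
    parents = {
        t: frozenset(q for q in store.go_parents.get(t, ()) if q in p)
        for t in p
    }
    return IcTable(
        p=p, ic={t: -math.log(v) for t, v in p.items()}, parents=parents
    )


EC_ROOT = "EC"


def ec_nodes(ec: str) -> str:
    """Map an EC string (wildcards allowed as suffix) to its tree node."""
    fields = [f for f in ec.split(".") if f and f != "-"]
    if not fields:
        return EC_ROOT
    return ".".join(fields)


def ec_ic_table(store: AnnotationStore) -> IcTable:
    """Information-content table over the 4-level EC prefix tree.

    Every annotated EC string becomes a node under a virtual root; a
    wildcard such as ``1.2.-.-`` annotates the internal node ``1.2``.
    """
    parents: dict[str, frozenset[str]] = {EC_ROOT: frozenset()}
    term_sets: list[list[str]] = []
    for anns in store.ec_annotations.values():
        nodes = []
        for ec in anns:
            node = ec_nodes(ec)
            nodes.append(node)
            while node != EC_ROOT:
                parts = node.split(".")
                parent = ".".join(parts[:-1]) if len(parts) > 1 else EC_ROOT
                parents.setdefault(node, frozenset((parent,)))
                node = parent
        term_sets.append(nodes)
    counts, total = _propagated_counts(parents, term_sets)
    if total == 0:
        raise ValidationError("no EC annotations")
    p = {t: c / total for t, c in counts.items()}
    kept_parents = {
        t: frozenset(q for q in parents.get(t, ()) if q in p) for t in p
    }
    return IcTable(
        p=p, ic={t: -math.log(v) for t, v in p.items()}, parents=kept_parents
    )


def sim_rel(c1: str, c2: str, table: IcTable) -> float:
    """Schlicker relevance similarity of two terms.

    max over common ancestors a (self included) of
    (2 ic(a) / (ic(c1) + ic(c2))) * (1 - p(a)); 0 when the only common
    ancestor is the root or when both terms are roots.
    """
    for c in (c1, c2):
        if c not in table.ic:
            raise ValidationError(f"term {c!r} absent from the IC table")
    denom = table.ic[c1] + table.ic[c2]
    if denom == 0.0:
        return 0.0
    common = table.ancestors(c1) & table.ancestors(c2)
    best = 0.0
    for a in common:
        value = (2.0 * table.ic[a] / denom) * (1.0 - table.p[a])
        if value > best:
            best = value
    return best


def best_match_average(
    terms1: Sequence[str], terms2: Sequence[str], table: IcTable
) -> float:
    """Average of row-max means and column-max means of the sim_rel matrix."""
    matrix = np.array(
        [[sim_rel(a, b, table) for b in terms2] for a in terms1]
    )
    return float((matrix.max(axis=1).mean() + matrix.max(axis=0).mean()) / 2.0)


def pair_functional_similarity(
    p1: ProteinRef,
    p2: ProteinRef,
    store: AnnotationStore,
    mode: str,
    tables: Mapping[str, IcTable] | None = None,
) -> float | None:
    """Annotation similarity of two proteins, or None when either lacks
    annotation in scope (such pairs are skipped, never scored 0).

    GO mode: best-match average per namespace annotated on both sides,
    averaged over those namespaces.  EC mode: best-match average on the EC
    prefix tree.
    """
    tables = tables if tables is not None else build_ic_tables(store, mode)
    if mode == "EC":
        t1 = [ec_nodes(e) for e in store.ec_annotations.get(p1, ())]
        t2 = [ec_nodes(e) for e in store.ec_annotations.get(p2, ())]
        table = tables["EC"]
        t1 = sorted(set(t for t in t1 if t in table.ic))
        t2 = sorted(set(t for t in t2 if t in table.ic))
        if not t1 or not t2:
            return None
        return best_match_average(t1, t2, table)
    if mode != "GO":
        raise ValidationError(f"unknown mode {mode!r}")
    scores = []
    for ns, table in sorted(tables.items()):
        t1 = sorted(t for t in store.go_terms_of(p1, ns) if t in table.ic)
        t2 = sorted(t for t in store.go_terms_of(p2, ns) if t in table.ic)
        if t1 and t2:
            scores.append(best_match_average(t1, t2, table))
    if not scores:
        return None
    return float(np.mean(scores))


def build_ic_tables(store: AnnotationStore, mode: str) -> dict[str, IcTable]:
    if mode == "EC":
        return {"EC": ec_ic_table(store)}
    tables = {}
    for ns in sorted(store.namespaces()):
        try:
            tables[ns] = ic_table(store, ns)
        except ValidationError:
            continue
    return tables


@dataclass
class FunctionBenchmark:
    n_annotated_pairs: int
    mean_similarity: float | None
    sd: float | None


def function_benchmark(
    clustering: GroupSet | MetaResult, store: AnnotationStore, mode: str
) -> FunctionBenchmark:
    """Score every co-grouped pair whose two proteins are both annotated.

    Returns the number of scored pairs and the mean and standard deviation
    of their similarities — the two axes of the functional conservation
    benchmark.
    """
    tables = build_ic_tables(store, mode)
    scores: list[float] = []
    for pair in sorted(ortholog_pairs(clustering), key=lambda p: tuple(sorted(p))):
        p1, p2 = sorted(pair)
        s = pair_functional_similarity(p1, p2, store, mode, tables)
        if s is not None:
            scores.append(s)
    if not scores:
        return FunctionBenchmark(0, None, None)
    arr = np.asarray(scores)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return FunctionBenchmark(len(arr), float(arr.mean()), sd)


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------

def parameter_sweep(
    groupsets,
    proteome,
    refs: ReferenceGroups,
    evalues: Sequence[float],
    coverages: Sequence[float],
    min_sizes: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Run the consensus over a parameter grid and tabulate accuracy.

    One row per (evalue, coverage, min_size) combination, all runs sharing
    the same seed, reporting the fusion/fission aggregates against
    ``refs``.
    """
    from .meta import run_meta

    if not (evalues and coverages and min_sizes):
        raise ValidationError("parameter grid must be non-empty")
    rows = []
    for ev, cov, size in itertools.product(evalues, coverages, min_sizes):
        params = MetaParams(
            evalue_threshold=ev, min_coverage=cov, min_size=size, rng_seed=seed
        )
        result = run_meta(groupsets, proteome, params)
        report = fusion_fission(result, refs)
        rows.append(
            {
                "evalue": ev,
                "min_coverage": cov,
                "min_size": size,
                "n_groups": len(result.final_groups),
                "pct_accurate": report.pct_accurate,
                "total_fusions": report.total_fusions,
                "total_fissions": report.total_fissions,
                "pct_fusion_affected": report.pct_fusion_affected,
                "pct_fission_affected": report.pct_fission_affected,
                "pct_both": report.pct_both,
            }
        )
    return pd.DataFrame(rows)
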