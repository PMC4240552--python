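"""Readers and writers for every external file format the tool touches.

Formats
-------
* groups file — one group per line, optional ``GROUPID:`` prefix, then
  whitespace-separated ``species|protein`` tokens (OrthoMCL-style).
* FASTA — proteome sequences; the first header token must parse as
  ``species|protein``.
* GAF 2.x — GO annotations; evidence-filtered at load.
* TSV — GO DAG edges (child, parent, namespace), EC annotations
  (protein, EC), reference groups (refog_id, protein).
* JSON — provenance report written next to the result groups file.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio import SeqIO

from .model import (
    EXPERIMENTAL_EVIDENCE,
    AnnotationStore,
    GroupSet,
    MetaResult,
    ProteinRef,
    ProteinSequence,
    ReferenceGroups,
    ValidationError,
    group_sort_key,
)

logger = logging.getLogger(__name__)


class ParseError(ValidationError):
    """A malformed input file; message names the file and line."""


# ---------------------------------------------------------------------------
# groups files
# ---------------------------------------------------------------------------

def _parse_group_line(line: str, path: str, lineno: int) -> list[ProteinRef]:
    body = line
    head, sep, rest = line.partition(":")
    if sep and "|" not in head:
        body = rest
    refs = []
    for token in body.split():
        try:
            refs.append(ProteinRef.parse(token))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return refs


def load_group_file(path: str | Path, method_name: str | None = None) -> GroupSet:
    """Load one method's groups file, enforcing the partition invariants.

    A protein listed in several groups is kept only in its largest group
    (ties broken by the earliest line); singleton groups are dropped.  Both
    resolutions are logged.
    """
    path = Path(path)
    raw: list[tuple[int, list[ProteinRef]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            refs = _parse_group_line(line, str(path), lineno)
            if refs:
                raw.append((lineno, refs))
    if not raw:
        raise ParseError(f"{path}: no groups found (empty file)")

    # Resolve duplicate membership: keep each protein in its largest group,
    # ties by the smallest line number.
    occurrences: dict[ProteinRef, list[tuple[int, int]]] = defaultdict(list)
    for idx, (lineno, refs) in enumerate(raw):
        for ref in set(refs):
            occurrences[ref].append((idx, lineno))
    keep_in: dict[ProteinRef, int] = {}
    n_dupes = 0
    for ref, occs in occurrences.items():
        if len(occs) > 1:
            n_dupes += 1
            best = max(occs, key=lambda il: (len(set(raw[il[0]][1])), -il[1]))
            logger.warning(
                "%s: %s occurs in %d groups; kept in group at line %d",
                path, ref, len(occs), best[1],
            )
            keep_in[ref] = best[0]
        else:
            keep_in[ref] = occs[0][0]

    groups: list[frozenset[ProteinRef]] = []
    n_singletons = 0
    for idx, (lineno, refs) in enumerate(raw):
        members = frozenset(r for r in set(refs) if keep_in[r] == idx)
        if len(members) >= 2:
            groups.append(members)
        elif members:
            n_singletons += 1
    if n_singletons:
        logger.info("%s: dropped %d singleton group(s)", path, n_singletons)
    if n_dupes:
        logger.info("%s: resolved %d duplicated protein(s)", path, n_dupes)
    if not groups:
        raise ParseError(f"{path}: no groups of size >= 2 after filtering")
    return GroupSet(method_name or path.stem, groups)


def load_predictions(paths: Sequence[str | Path]) -> list[GroupSet]:
    """Load one GroupSet per file, in input order; method names must differ."""
    out = [load_group_file(p) for p in paths]
    names = [g.method_name for g in out]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate method names among inputs: {names}")
    return out


def write_groups(groups: Iterable[frozenset[ProteinRef]], path: str | Path) -> None:
    """Write groups in the dialect ``load_group_file`` reads.

    Group ids are regenerated deterministically: ``Gk`` by descending size,
    then lexicographically smallest member.
    """
    ordered = sorted(groups, key=group_sort_key)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, members in enumerate(ordered, start=1):
            toks = " ".join(str(m) for m in sorted(members))
            fh.write(f"G{k}: {toks}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_fasta(
    path: str | Path, map_nonstandard_to_x: bool = True
) -> dict[ProteinRef, ProteinSequence]:
    """Load a proteome; headers' first token must parse as species|protein."""
    out: dict[ProteinRef, ProteinSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        ref = ProteinRef.parse(record.id)
        if ref in out:
            raise ParseError(f"{path}: duplicate header {record.id!r}")
        residues = str(record.seq).upper()
        if not residues:
            raise ParseError(f"{path}: empty sequence for {record.id!r}")
        if map_nonstandard_to_x:
            residues = "".join(
                c if c in "ACDEFGHIKLMNPQRSTVWYX" else "X" for c in residues
            )
        out[ref] = ProteinSequence(ref, residues)
    if not out:
        raise ParseError(f"{path}: no FASTA records")
    return out


def write_fasta(
    seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sorted(seqs, key=lambda s: s.ref):
            fh.write(f">{s.ref}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations (GAF + DAG TSV + EC TSV)
# ---------------------------------------------------------------------------

def load_dag(path: str | Path) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Load a GO DAG from a TSV of (child, parent, namespace) edges.

    A line with an empty parent field declares a root term.  The DAG is
    checked acyclic.
    """
    parents: dict[str, set[str]] = defaultdict(set)
    namespace: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 TSV fields")
            child, parent, ns = fields
            parents.setdefault(child, set())
            namespace[child] = ns
            if parent:
                parents[child].add(parent)
                parents.setdefault(parent, set())
                namespace.setdefault(parent, ns)
    graph = nx.DiGraph(
        (child, parent) for child, ps in parents.items() for parent in ps
    )
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValidationError(f"{path}: GO DAG contains a cycle: {cycle}")
    return {t: frozenset(ps) for t, ps in parents.items()}, namespace


def load_gaf(
    path: str | Path, known_terms: frozenset[str] | set[str]
) -> dict[ProteinRef, frozenset[tuple[str, str]]]:
    """Load GAF 2.x annotations, keeping only experimental evidence codes.

    The GAF DB-object id (column 2) must be a ``species|protein`` token.
    """
    kept: dict[ProteinRef, set[tuple[str, str]]] = defaultdict(set)
    missing: set[str] = set()
    n_kept = n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected >= 9 GAF columns")
            obj_id, term, evidence = fields[1], fields[4], fields[6]
            if evidence not in EXPERIMENTAL_EVIDENCE:
                n_dropped += 1
                continue
            if term not in known_terms:
                missing.add(term)
                continue
            kept[ProteinRef.parse(obj_id)].add((term, evidence))
            n_kept += 1
    if missing:
        raise ValidationError(
            f"{path}: GO terms absent from the DAG: {sorted(missing)}"
        )
    logger.info("%s: kept %d annotations, dropped %d non-experimental",
                path, n_kept, n_dropped)
    return {p: frozenset(ts) for p, ts in kept.items()}


_EC_OK = frozenset("0123456789-")


def load_ec(path: str | Path) -> dict[ProteinRef, frozenset[str]]:
    """Load EC annotations from a TSV of (protein, EC number)."""
    out: dict[ProteinRef, set[str]] = defaultdict(set)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 TSV fields")
            token, ec = fields
            parts = ec.split(".")
            if len(parts) != 4 or any(set(p) - _EC_OK or not p for p in parts):
                raise ParseError(f"{path}:{lineno}: malformed EC {ec!r}")
            out[ProteinRef.parse(token)].add(ec)
    return {p: frozenset(es) for p, es in out.items()}


def load_annotations(
    gaf_path: str | Path | None,
    dag_path: str | Path | None,
    ec_path: str | Path | None = None,
) -> AnnotationStore:
    """Assemble the annotation store from GAF + DAG (+ optional EC) files."""
    go_parents: dict[str, frozenset[str]] = {}
    go_namespace: dict[str, str] = {}
    go_annotations: dict[ProteinRef, frozenset[tuple[str, str]]] = {}
    if dag_path is not None:
        go_parents, go_namespace = load_dag(dag_path)
    if gaf_path is not None:
        if dag_path is None:
            raise ValidationError("a GAF file requires a DAG file")
        go_annotations = load_gaf(gaf_path, frozenset(go_parents))
    ec = load_ec(ec_path) if ec_path is not None else {}
    return AnnotationStore(go_parents, go_namespace, go_annotations, ec)


# ---------------------------------------------------------------------------
# reference groups
# ---------------------------------------------------------------------------

def load_refogs(path: str | Path) -> ReferenceGroups:
    """Load reference groups from a TSV of (refog_id, species|protein)."""
    refogs: dict[str, set[ProteinRef]] = defaultdict(set)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 TSV fields")
            rid, token = fields
            refogs[rid].add(ProteinRef.parse(token))
    universe = frozenset(p for ms in refogs.values() for p in ms)
    return ReferenceGroups(
        {rid: frozenset(ms) for rid, ms in refogs.items()}, universe
    )


def write_refogs(refs: ReferenceGroups, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid in sorted(refs.refogs):
            for p in sorted(refs.refogs[rid]):
                fh.write(f"{rid}\t{p}\n")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_result(result: MetaResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the groups file, unassigned list and JSON provenance report.

    The groups file round-trips through ``load_group_file`` with identical
    co-membership pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups_path = out_dir / "meta_groups.txt"
    unassigned_path = out_dir / "unassigned.txt"
    provenance_path = out_dir / "provenance.json"

    ordered = sorted(result.final_groups, key=lambda g: group_sort_key(g.members))
    with open(groups_path, "w", encoding="utf-8", newline="\n") as fh:
        for k, g in enumerate(ordered, start=1):
            toks = " ".join(str(m) for m in sorted(g.members))
            fh.write(f"G{k}: {toks}\n")
    with open(unassigned_path, "w", encoding="utf-8", newline="\n") as fh:
        for p in sorted(result.unassigned):
            fh.write(f"{p}\n")

    provenance = {
        "rng_seed": result.rng_seed,
        "params": {
            "evalue_threshold": result.params.evalue_threshold,
            "min_coverage": result.params.min_coverage,
            "min_size": result.params.min_size,
            "backend": result.params.backend,
            "n_decoys": result.params.n_decoys,
            "pseudocount": result.params.pseudocount,
            "gap_open": result.params.gap_open,
            "gap_extend": result.params.gap_extend,
        },
        "n_final_groups": len(result.final_groups),
        "n_unassigned": len(result.unassigned),
        "groups": [
            {
                "group_id": f"G{k}",
                "level": g.level,
                "method_subset": sorted(g.method_subset),
                "leftover": g.leftover_flag,
                "seed_members": sorted(map(str, g.seed_members)),
                "profile_added_members": sorted(map(str, g.profile_added_members)),
            }
            for k, g in enumerate(ordered, start=1)
        ],
        "random_choices": result.random_choices,
    }
    with open(provenance_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "groups": groups_path,
        "unassigned": unassigned_path,
        "provenance": provenance_path,
    }
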