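"""Seeded generator of ground-truth ortholog groups and noisy predictions.

The generator emulates the inputs of a real consensus run: true ortholog
groups across S species with diverged member sequences, decoy proteins
with no family, GO/EC annotations concentrated within groups, and N
"method predictions" derived from the truth by controlled fission, fusion,
dropout and relocation errors.  Everything is a pure function of its seed.

Sequence evolution is substitution-only (star topology from one ancestor
per group, per-site substitution at a group-specific rate); there are no
indels, no rate heterogeneity and no phylogenetic structure, which keeps
alignment-based oracles exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as omio
from .model import (
    AnnotationStore,
    GroupSet,
    ProteinRef,
    ProteinSequence,
    ReferenceGroups,
    ValidationError,
)
from .profile import AA_ORDER, ROBINSON_BACKGROUND

GO_NAMESPACE = "biological_process"
GO_ROOT = "T:0000"


@dataclass(frozen=True)
class ErrorModel:
    """Per-method error rates applied to the truth partition."""

    p_fission: float = 0.0
    p_fusion: float = 0.0
    p_dropout: float = 0.0
    p_relocate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_fission", "p_fusion", "p_dropout", "p_relocate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SimParams:
    """Study conditions of a synthetic run.

    ``group_size_range`` bounds the per-species member count of each true
    group; ``divergence_range`` bounds the per-site substitution
    probability drawn once per group; ``annotation_fidelity`` is the
    probability that a member inherits its group's GO leaf term rather
    than a random one.
    """

    n_species: int = 6
    n_groups: int = 40
    group_size_range: tuple[int, int] = (1, 2)
    seq_length_mean: float = 100.0
    seq_length_sd: float = 15.0
    divergence_range: tuple[float, float] = (0.05, 0.5)
    n_decoy_proteins: int = 20
    annotation_fidelity: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_groups < 1:
            raise ValidationError("need >= 2 species and >= 1 group")
        lo, hi = self.group_size_range
        if not (0 <= lo <= hi) or hi < 1:
            raise ValidationError("invalid group_size_range")
        lo, hi = self.divergence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("divergence_range must be within [0, 1]")
        if not (0.0 <= self.annotation_fidelity <= 1.0):
            raise ValidationError("annotation_fidelity must be in [0, 1]")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=ROBINSON_BACKGROUND)
    return "".join(AA_ORDER[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            # substitute with a different residue drawn from the background
            cur = out[i]
            while True:
                repl = AA_ORDER[int(rng.choice(20, p=ROBINSON_BACKGROUND))]
                if repl != cur:
                    break
            out[i] = repl
    return "".join(out)


def _draw_length(rng: np.random.Generator, params: SimParams) -> int:
    return max(30, int(round(rng.normal(params.seq_length_mean,
                                        params.seq_length_sd))))


def simulate_truth(
    params: SimParams,
) -> tuple[dict[ProteinRef, ProteinSequence], ReferenceGroups, AnnotationStore]:
    """Generate the proteome, the true groups and their annotations.

    Each group has one random ancestor sequence; members are independent
    substitution-mutated copies at the group's divergence rate.  Each group
    carries a distinct leaf of a 3-level GO DAG (root, 5 internal nodes,
    one leaf per group) and a distinct synthetic EC serial under a shared
    3-level prefix.
    """
    rng = np.random.default_rng(params.rng_seed)
    species = [f"sp{j + 1}" for j in range(params.n_species)]

    proteome: dict[ProteinRef, ProteinSequence] = {}
    refogs: dict[str, frozenset[ProteinRef]] = {}

    n_internal = 5
    go_parents: dict[str, frozenset[str]] = {GO_ROOT: frozenset()}
    go_namespace: dict[str, str] = {GO_ROOT: GO_NAMESPACE}
    internal = []
    for j in range(n_internal):
        term = f"T:i{j + 1}"
        go_parents[term] = frozenset((GO_ROOT,))
        go_namespace[term] = GO_NAMESPACE
        internal.append(term)
    leaves = []
    for k in range(params.n_groups):
        term = f"T:g{k + 1:04d}"
        go_parents[term] = frozenset((internal[k % n_internal],))
        go_namespace[term] = GO_NAMESPACE
        leaves.append(term)

    go_annotations: dict[ProteinRef, frozenset[tuple[str, str]]] = {}
    ec_annotations: dict[ProteinRef, frozenset[str]] = {}

    lo, hi = params.group_size_range
    for k in range(params.n_groups):
        ancestor = _random_sequence(rng, _draw_length(rng, params))
        divergence = rng.uniform(*params.divergence_range)
        members: list[ProteinRef] = []
        for sp in species:
            count = int(rng.integers(lo, hi + 1))
            for m in range(count):
                ref = ProteinRef(sp, f"g{k + 1:04d}m{m + 1}")
                proteome[ref] = ProteinSequence(
                    ref, _mutate(rng, ancestor, divergence)
                )
                members.append(ref)
        if len(members) < 2:
            # a group needs at least two members to carry any signal;
            # force one extra member in a random second species
            sp = species[int(rng.integers(params.n_species))]
            suffix = 1
            while ProteinRef(sp, f"g{k + 1:04d}m{suffix}") in proteome:
                suffix += 1
            ref = ProteinRef(sp, f"g{k + 1:04d}m{suffix}")
            proteome[ref] = ProteinSequence(
                ref, _mutate(rng, ancestor, divergence)
            )
            members.append(ref)
        refogs[f"OG{k + 1:04d}"] = frozenset(members)
        for ref in members:
            if rng.random() < params.annotation_fidelity:
                term = leaves[k]
            else:
                term = leaves[int(rng.integers(params.n_groups))]
            go_annotations[ref] = frozenset(((term, "IDA"),))
            ec_annotations[ref] = frozenset((f"1.1.{k // 50 + 1}.{k % 50 + 1}",))

    for d in range(params.n_decoy_proteins):
        sp = species[d % params.n_species]
        ref = ProteinRef(sp, f"decoy{d + 1}")
        proteome[ref] = ProteinSequence(
            ref, _random_sequence(rng, _draw_length(rng, params))
        )

    truth = ReferenceGroups(refogs, frozenset(proteome))
    store = AnnotationStore(go_parents, go_namespace, go_annotations,
                            ec_annotations)
    return proteome, truth, store


def perturb_prediction(
    truth: ReferenceGroups,
    error_model: ErrorModel,
    rng: np.random.Generator,
    method_name: str = "perturbed",
) -> GroupSet:
    """Derive one noisy method prediction from the truth partition.

    Per group: fission splits it at a random point into two; fusion merges
    it with another randomly chosen group.  Per protein: dropout removes
    it; relocation moves it to a random other group.  Singletons created
    by the perturbation are dropped, so the output is a valid partition.
    """
    groups = [sorted(truth.refogs[rid]) for rid in sorted(truth.refogs)]

    # fission pass
    fissioned: list[list[ProteinRef]] = []
    for g in groups:
        if len(g) >= 2 and rng.random() < error_model.p_fission:
            perm = [g[i] for i in rng.permutation(len(g))]
            cut = int(rng.integers(1, len(g)))
            fissioned.append(sorted(perm[:cut]))
            fissioned.append(sorted(perm[cut:]))
        else:
            fissioned.append(list(g))

    # fusion pass (union-find over fissioned fragments)
    parent = list(range(len(fissioned)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in range(len(fissioned)):
        if len(fissioned) > 1 and rng.random() < error_model.p_fusion:
            j = int(rng.integers(len(fissioned) - 1))
            if j >= idx:
                j += 1
            parent[find(idx)] = find(j)
    merged: dict[int, list[ProteinRef]] = {}
    for idx, frag in enumerate(fissioned):
        merged.setdefault(find(idx), []).extend(frag)
    out_groups = [sorted(ms) for _root, ms in sorted(merged.items())]

    # per-protein dropout and relocation
    final: list[set[ProteinRef]] = [set(g) for g in out_groups]
    for gi, g in enumerate(out_groups):
        for p in g:
            r = rng.random()
            if r < error_model.p_dropout:
                final[gi].discard(p)
            elif r < error_model.p_dropout + error_model.p_relocate and len(
                final
            ) > 1:
                j = int(rng.integers(len(final) - 1))
                if j >= gi:
                    j += 1
                final[gi].discard(p)
                final[j].add(p)

    kept = sorted(
        (frozenset(g) for g in final if len(g) >= 2),
        key=lambda g: tuple(sorted(g)),
    )
    return GroupSet(method_name, list(kept))


def make_method_suite(
    truth: ReferenceGroups,
    n_methods: int,
    error_models: list[ErrorModel] | ErrorModel,
    seed: int,
) -> list[GroupSet]:
    """One perturbed GroupSet per method, each with its own derived seed."""
    if n_methods < 2:
        raise ValidationError("need at least 2 methods")
    if isinstance(error_models, ErrorModel):
        error_models = [error_models] * n_methods
    if len(error_models) != n_methods:
        raise ValidationError("one error model per method required")
    children = np.random.SeedSequence(seed).spawn(n_methods)
    return [
        perturb_prediction(
            truth,
            error_models[k],
            np.random.default_rng(children[k]),
            method_name=f"sim_m{k + 1}",
        )
        for k in range(n_methods)
    ]


# ---------------------------------------------------------------------------
# the 12-protein smoke fixture
# ---------------------------------------------------------------------------

SMOKE_SEED = 42


def smoke_fixture() -> tuple[
    list[GroupSet], dict[ProteinRef, ProteinSequence]
]:
    """A hand-designed 12-protein fixture with a fully traceable consensus.

    Nine proteins in two sequence families plus three decoys.  Family one
    is {a, b, c, d, e}, family two is {f, g, h, i}; the three methods
    disagree exactly enough that the level-3 intersection seeds {a, b, c,
    d}, the profile stage recruits e, and level 2 seeds {f, g, h, i},
    leaving the decoys unassigned.
    """
    rng = np.random.default_rng(SMOKE_SEED)
    species = {"a": "A", "b": "B", "c": "C", "d": "A", "e": "B",
               "f": "C", "g": "A", "h": "B", "i": "C"}
    refs = {name: ProteinRef(sp, name) for name, sp in species.items()}

    anc1 = _random_sequence(rng, 120)
    anc2 = _random_sequence(rng, 120)
    proteome: dict[ProteinRef, ProteinSequence] = {}
    for name in "abcde":
        proteome[refs[name]] = ProteinSequence(
            refs[name], _mutate(rng, anc1, 0.02)
        )
    for name in "fghi":
        proteome[refs[name]] = ProteinSequence(
            refs[name], _mutate(rng, anc2, 0.02)
        )
    for d, sp in enumerate("ABC"):
        ref = ProteinRef(sp, f"decoy{d + 1}")
        proteome[ref] = ProteinSequence(ref, _random_sequence(rng, 120))

    def g(*names: str) -> frozenset[ProteinRef]:
        return frozenset(refs[n] for n in names)

    m1 = GroupSet("M1", [g("a", "b", "c", "d", "e"), g("f", "g", "h", "i")])
    m2 = GroupSet("M2", [g("a", "b", "c", "d"), g("e", "f", "g", "h", "i")])
    m3 = GroupSet("M3", [g("a", "b", "c", "d", "f"), g("e", "g", "h", "i")])
    return [m1, m2, m3], proteome


def write_simulation(
    out_dir: str | Path,
    params: SimParams,
    n_methods: int = 4,
    error_models: list[ErrorModel] | ErrorModel | None = None,
) -> dict[str, Path]:
    """Write FASTA + N groups files + reference TSV + annotation files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome, truth, store = simulate_truth(params)
    if error_models is None:
        error_models = ErrorModel(0.1, 0.1, 0.05, 0.02)
    methods = make_method_suite(truth, n_methods, error_models,
                                params.rng_seed)

    paths: dict[str, Path] = {}
    paths["fasta"] = out_dir / "proteome.fasta"
    omio.write_fasta(proteome.values(), paths["fasta"])
    for gs in methods:
        p = out_dir / f"{gs.method_name}.groups.txt"
        omio.write_groups(gs.groups, p)
        paths[gs.method_name] = p
    paths["refogs"] = out_dir / "reference_groups.tsv"
    omio.write_refogs(truth, paths["refogs"])
    paths["dag"] = out_dir / "go_dag.tsv"
    with open(paths["dag"], "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(store.go_parents):
            parents = sorted(store.go_parents[term])
            ns = store.go_namespace[term]
            if parents:
                for parent in parents:
                    fh.write(f"{term}\t{parent}\t{ns}\n")
            else:
                fh.write(f"{term}\t\t{ns}\n")
    paths["gaf"] = out_dir / "annotations.gaf"
    with open(paths["gaf"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("!gaf-version: 2.2\n")
        for ref in sorted(store.go_annotations):
            for term, ev in sorted(store.go_annotations[ref]):
                cols = ["SIM", str(ref), ref.protein, "", term, "SIM:ref",
                        ev, "", "P", "", "", "protein", f"taxon:{ref.species}",
                        "20240101", "SIM"]
                fh.write("\t".join(cols) + "\n")
    paths["ec"] = out_dir / "ec_annotations.tsv"
    with open(paths["ec"], "w", encoding="utf-8", newline="\n") as fh:
        for ref in sorted(store.ec_annotations):
            for ec in sorted(store.ec_annotations[ref]):
                fh.write(f"{ref}\t{ec}\n")
    return paths


def write_smoke(out_dir: str | Path) -> dict[str, Path]:
    """Write the golden 12-protein fixture as files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    methods, proteome = smoke_fixture()
    paths: dict[str, Path] = {}
    paths["fasta"] = out_dir / "proteome.fasta"
    omio.write_fasta(proteome.values(), paths["fasta"])
    for gs in methods:
        p = out_dir / f"{gs.method_name}.groups.txt"
        omio.write_groups(gs.groups, p)
        paths[gs.method_name] = p
    return paths
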