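import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from orthomerge.model import AnnotationStore, MetaParams, ProteinRef
from orthomerge.simulate import smoke_fixture


@pytest.fixture(scope="session")
def smoke():
    """The golden 12-protein fixture: (method GroupSets, proteome)."""
    return smoke_fixture()


@pytest.fixture(scope="session")
def smoke_result(smoke):
    from orthomerge.meta import run_meta

    methods, proteome = smoke
    return run_meta(methods, proteome, MetaParams(rng_seed=42))


def _ref(token: str) -> ProteinRef:
    return ProteinRef.parse(token)


@pytest.fixture()
def tiny_store():
    """A 7-term GO DAG over one namespace plus EC annotations.

    Corpus of 10 GO annotations: term ``c`` covers 2 of them (p=0.2), so
    sim_rel(c, c) = 1 - 0.2 = 0.8.
    """
    parents = {
        "root": frozenset(),
        "i1": frozenset({"root"}),
        "i2": frozenset({"root"}),
        "c": frozenset({"i1"}),
        "d": frozenset({"i1"}),
        "e": frozenset({"i2"}),
        "f": frozenset({"i2"}),
    }
    namespace = {t: "bp" for t in parents}
    annotations = {}
    # 10 direct annotations: c x2, d x3, e x4, f x1
    direct = ["c", "c", "d", "d", "d", "e", "e", "e", "e", "f"]
    for k, term in enumerate(direct):
        annotations[_ref(f"S|p{k}")] = frozenset({(term, "IDA")})
    ec = {
        _ref("S|p0"): frozenset({"1.1.1.1"}),
        _ref("S|p1"): frozenset({"1.1.1.1"}),
        _ref("S|p2"): frozenset({"1.1.2.1"}),
        _ref("S|p3"): frozenset({"2.3.1.5"}),
    }
    return AnnotationStore(parents, namespace, annotations, ec)
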