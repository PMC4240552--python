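"""Multiple alignment of seed-group members (builtin backend).

The builtin aligner is a deterministic center-star progressive alignment:
the center is the sequence with the best total pairwise global-alignment
score (BLOSUM62, affine gaps, open 11 / extend 1), and the remaining
sequences are merged against it under the "once a gap, always a gap" rule.
Input order never matters: sequences are processed in lexicographic
ProteinRef order.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .model import ProteinRef, ProteinSequence, ValidationError

GAP = "-"


@dataclass
class Msa:
    """A multiple sequence alignment; all rows share one column count."""

    rows: list[tuple[ProteinRef, str]]
    column_count: int

    def __post_init__(self) -> None:
        for ref, aligned in self.rows:
            if len(aligned) != self.column_count:
                raise ValidationError(
                    f"row {ref} has {len(aligned)} columns, "
                    f"expected {self.column_count}"
                )

    def ungapped(self, idx: int) -> str:
        return self.rows[idx][1].replace(GAP, "")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_global(a: str, b: str) -> tuple[float, str, str]:
    """Best global alignment of two sequences; first optimum is returned.

    Biopython enumerates co-optimal alignments in a fixed order, so the
    choice is deterministic for identical inputs.
    """
    alignment = next(iter(_ALIGNER.align(a, b)))
    return float(alignment.score), str(alignment[0]), str(alignment[1])


def _merge_into_star(
    master_center: str, rows: list[str], aln_center: str, aln_new: str
) -> tuple[str, list[str], str]:
    """Merge one pairwise (center, new) alignment into the growing MSA.

    Walks the two gapped renderings of the center simultaneously, inserting
    gaps on whichever side lacks a column ("once a gap, always a gap").
    """
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_new: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(aln_center):
        a = master_center[i] if i < len(master_center) else None
        b = aln_center[j] if j < len(aln_center) else None
        if a is not None and b is not None and (a == b or (a != GAP and b != GAP)):
            out_master.append(a)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(aln_new[j])
            i += 1
            j += 1
        elif a == GAP and (b != GAP or b is None):
            # column exists only in the master rendering
            out_master.append(a)
            for r, row in enumerate(rows):
                out_rows[r].append(row[i])
            out_new.append(GAP)
            i += 1
        else:
            # column exists only in the new pairwise rendering
            out_master.append(GAP)
            for r in range(len(rows)):
                out_rows[r].append(GAP)
            out_new.append(aln_new[j])
            j += 1
    return (
        "".join(out_master),
        ["".join(r) for r in out_rows],
        "".join(out_new),
    )


def build_msa(seqs: list[ProteinSequence]) -> Msa:
    """Center-star progressive alignment of two or more sequences."""
    if len(seqs) < 2:
        raise ValidationError("an alignment needs at least 2 sequences")
    ordered = sorted(seqs, key=lambda s: s.ref)

    if len(ordered) == 2:
        score, a, b = pairwise_global(ordered[0].residues, ordered[1].residues)
        return Msa([(ordered[0].ref, a), (ordered[1].ref, b)], len(a))

    n = len(ordered)
    totals = [0.0] * n
    pair_aln: dict[tuple[int, int], tuple[float, str, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            score, a, b = pairwise_global(ordered[i].residues, ordered[j].residues)
            pair_aln[(i, j)] = (score, a, b)
            totals[i] += score
            totals[j] += score
    # center maximizes the total score; ties go to the smallest ProteinRef,
    # which is the smallest index since `ordered` is sorted
    center = max(range(n), key=lambda k: (totals[k], -k))

    master_center = ordered[center].residues
    rows: list[str] = []
    row_refs: list[ProteinRef] = []
    for k in range(n):
        if k == center:
            continue
        if (center, k) in pair_aln:
            _, aln_c, aln_k = pair_aln[(center, k)]
        else:
            _, aln_k, aln_c = pair_aln[(k, center)]
        master_center, rows, new_row = _merge_into_star(
            master_center, rows, aln_c, aln_k
        )
        rows.append(new_row)
        row_refs.append(ordered[k].ref)

    all_rows = [(ordered[center].ref, master_center)] + list(zip(row_refs, rows))
    all_rows.sort(key=lambda ra: ra[0])
    msa = Msa(all_rows, len(master_center))
    # invariant: de-gapping each row reproduces its input sequence
    by_ref = {s.ref: s.residues for s in ordered}
    for ref, aligned in msa.rows:
        if aligned.replace(GAP, "") != by_ref[ref]:
            raise AssertionError(f"alignment corrupted sequence {ref}")
    return msa
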