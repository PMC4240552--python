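"""External profile backend: shells out to an MSA program and HMMER.

Reproduces the builtin backend's contract — the same :class:`ProfileHit`
semantics — with profile HMMs built by ``hmmbuild`` and searched with
``hmmsearch`` (full-sequence E-value, domain alignment spans for
coverage).  The aligner defaults to ``muscle`` when present, falling back
to ``mafft``.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .model import ProteinSequence, ValidationError
from .profile import ProfileHit


def find_aligner(preferred: str | None = None) -> list[str]:
    """Locate the MSA binary and return its invocation prefix."""
    if preferred:
        exe = shutil.which(preferred)
        if exe is None:
            raise ValidationError(f"aligner binary {preferred!r} not found")
        name = Path(preferred).name
    else:
        for name in ("muscle", "mafft"):
            exe = shutil.which(name)
            if exe:
                break
        else:
            raise ValidationError("no MSA binary (muscle or mafft) on PATH")
    if name.startswith("mafft"):
        return [exe, "--anysymbol", "--auto", "--quiet"]
    return [exe, "-align"]


def _write_fasta(seqs: list[ProteinSequence], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            fh.write(f">{s.ref}\n{s.residues}\n")


def external_hits(
    seed_seqs: dict[str, list[ProteinSequence]],
    targets: list[ProteinSequence],
    database_size: int,
    aligner_bin: str | None = None,
    hmmer_bin: str | None = None,
) -> list[ProfileHit]:
    """Score every target against every seed profile via MUSCLE/MAFFT + HMMER."""
    if not targets:
        return []
    hmmsearch = shutil.which(hmmer_bin or "hmmsearch")
    hmmbuild = shutil.which(
        str(Path(hmmer_bin).parent / "hmmbuild") if hmmer_bin else "hmmbuild"
    )
    if hmmsearch is None or hmmbuild is None:
        raise ValidationError("hmmsearch/hmmbuild not found on PATH")
    align_cmd = find_aligner(aligner_bin)

    hits: list[ProfileHit] = []
    by_ref = {s.ref: s for s in targets}
    with tempfile.TemporaryDirectory(prefix="orthomerge_ext_") as tmp:
        tmpdir = Path(tmp)
        target_fa = tmpdir / "targets.fa"
        _write_fasta(targets, target_fa)
        for group_id in sorted(seed_seqs):
            seqs = sorted(seed_seqs[group_id], key=lambda s: s.ref)
            seed_fa = tmpdir / f"{group_id}.fa"
            aln_fa = tmpdir / f"{group_id}.aln.fa"
            hmm = tmpdir / f"{group_id}.hmm"
            dom = tmpdir / f"{group_id}.domtbl"
            _write_fasta(seqs, seed_fa)
            if "muscle" in align_cmd[0]:
                subprocess.run(
                    align_cmd + [str(seed_fa), "-output", str(aln_fa)],
                    check=True, capture_output=True,
                )
            else:
                with open(aln_fa, "w") as out:
                    subprocess.run(
                        align_cmd + [str(seed_fa)],
                        check=True, stdout=out, stderr=subprocess.DEVNULL,
                    )
            subprocess.run(
                [hmmbuild, "--amino", str(hmm), str(aln_fa)],
                check=True, capture_output=True,
            )
            proc = subprocess.run(
                [
                    hmmsearch, "-Z", str(database_size), "--domtblout", str(dom),
                    "-E", "1000000", "--domE", "1000000",
                    str(hmm), str(target_fa),
                ],
                check=True, capture_output=True, text=True,
            )
            del proc
            hits.extend(_parse_domtbl(dom, group_id, by_ref))
    return hits


def _parse_domtbl(path: Path, group_id: str, by_ref) -> list[ProfileHit]:
    """Fold per-domain rows into one hit per target sequence.

    The full-sequence E-value is thresholded; coverage is the union of
    domain alignment spans over the sequence and the profile length.
    """
    from .model import ProteinRef

    per_seq: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.split()
            ref = ProteinRef.parse(f[0])
            qlen = int(f[5])
            full_evalue = float(f[6])
            hmm_from, hmm_to = int(f[15]), int(f[16])
            ali_from, ali_to = int(f[17]), int(f[18])
            score = float(f[7])
            entry = per_seq.setdefault(
                ref, {"evalue": full_evalue, "score": score, "qlen": qlen,
                      "seq_spans": [], "hmm_spans": []},
            )
            entry["seq_spans"].append((ali_from, ali_to))
            entry["hmm_spans"].append((hmm_from, hmm_to))
    out = []
    for ref, entry in sorted(per_seq.items()):
        seq_len = len(by_ref[ref].residues)
        out.append(
            ProfileHit(
                protein=ref,
                group_id=group_id,
                raw_score=entry["score"],
                evalue=entry["evalue"],
                seq_coverage=_span_cover(entry["seq_spans"]) / seq_len,
                profile_coverage=_span_cover(entry["hmm_spans"]) / entry["qlen"],
            )
        )
    return out


def _span_cover(spans: list[tuple[int, int]]) -> int:
    covered: set[int] = set()
    for a, b in spans:
        covered.update(range(a, b + 1))
    return len(covered)
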