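# orthomerge

Consensus prediction of ortholog groups from the outputs of several
orthology methods.

Orthologs — genes in different species descended from one ancestral gene
by speciation — are the backbone of comparative genomics and of function
transfer between genomes.  Dozens of prediction methods exist
(reciprocal-best-hit graphs, Markov clustering, tree reconciliation, …)
and they disagree substantially.  `orthomerge` turns that disagreement
into a signal: groups asserted jointly by several methods are trusted as
*seeds*, and sensitivity is then recovered by profile search.

The pipeline, for N input methods:

1. Set `i = N`.
2. For every size-`i` subset of methods, compute the cells of the common
   refinement of their partitions — proteins co-grouped by *all* `i`
   methods.  Cells with ≥ `min_size` members (default 4) become seed
   groups; a protein claimed twice stays in the largest cell (ties
   resolved by a seeded RNG).
3. Align each seed group, build a position-specific profile, and score
   every unassigned protein against every profile.  A protein is
   recruited iff E-value < 1e-10 and the alignment covers ≥ 40% of both
   the sequence and the profile; the best profile wins (lowest E-value,
   then highest coverage).
4. Finalize these groups, remove their proteins from the pool, decrement
   `i`, and repeat while `i ≥ 2` and unassigned proteins remain.  Small
   two-method cells (size 2–3) are appended at the end as leftover
   groups.

The package also ships the matching evaluation suite — Jaccard agreement
on co-grouped pairs, fusion/fission accounting against curated reference
groups, Schlicker information-content similarity of GO/EC annotations —
a filtered best-reciprocal-hit input method with clique grouping, and a
seeded synthetic-data generator so the whole pipeline is testable with no
external data.  See `docs/methods.md` for the model details and design
choices.

## Worked example

Generate the bundled 12-protein demonstration fixture (two sequence
families plus three decoys, three disagreeing "methods") and run the
consensus:

```sh
orthomerge simulate --out-dir data --preset smoke
orthomerge run \
    --groups data/M1.groups.txt --groups data/M2.groups.txt \
    --groups data/M3.groups.txt \
    --fasta data/proteome.fasta --seed 42 --out-dir out
cat out/meta_groups.txt
```

```
G1: A|a A|d B|b B|e C|c
G2: A|g B|h C|f C|i
```

`G1` is the first family: the three methods only agree on
`{a, b, c, d}`, which seeds a group at level 3 (all three methods), and
the profile stage then recruits `e` — each method had placed `e`
somewhere, but never consistently.  `G2` is the second family, seeded at
level 2 where two methods agree.  `out/unassigned.txt` lists the three
decoys, which no profile accepts:

```
A|decoy1
B|decoy2
C|decoy3
```

`out/provenance.json` records the seed, the thresholds and, per group,
the level, the contributing methods and which members came from seeding
versus profile recruitment, so any run can be reproduced exactly.

Evaluation against a reference clustering and annotation files:

```sh
orthomerge eval --groups out/meta_groups.txt --groups data/M1.groups.txt \
    --refs reference_groups.tsv --gaf annotations.gaf --dag go_dag.tsv \
    --ec ec_annotations.tsv --out-dir eval_out
```

Other commands: `orthomerge simulate` (full synthetic datasets with
controlled error rates), `orthomerge sweep` (accuracy over a parameter
grid), `orthomerge brh` (best-reciprocal-hit groups from a similarity
table).  `orthomerge COMMAND --help` lists all flags.

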