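# Methods

## The consensus model

`orthomerge` predicts ortholog groups by combining the group predictions of
N independent orthology methods.  The premise is that co-membership
asserted by several methods of different designs (graph-based,
tree-based) is far more reliable than any single method's call, but that a
naive intersection of all methods loses too many true orthologs.  The
pipeline therefore alternates two moves:

1. **Seed intersection.**  With a level counter `i` starting at N, every
   size-`i` subset of the methods is examined.  Two proteins fall in the
   same *cell* of a subset iff every method of the subset places them in
   one group; the cells of this common refinement that reach the
   `min_size` threshold become *seed groups*.  A protein claimed by
   candidate cells of different subsets stays in the largest cell; genuine
   size ties are resolved uniformly at random from the run's single seeded
   generator, and every such draw is logged in the provenance report.  A
   cell that drops below `min_size` after losing a protein is demoted.
2. **Profile expansion.**  Each seed group is aligned, turned into a
   position-specific scoring profile, and every still-unassigned protein
   (including proteome entries no method grouped) is scored against every
   profile.  A protein joins a seed iff its E-value is strictly below
   `evalue_threshold` *and* the alignment covers at least `min_coverage`
   of **both** the sequence and the profile (the minimum of the two
   coverages is thresholded, since both lengths matter).  Among several
   eligible profiles the lowest E-value wins, then the highest
   min-coverage, then the smallest group id.  Profiles are never updated
   within a pass: assignment is single-pass against fixed profiles.

Groups finalized at level `i` (seed plus recruits) are removed from the
pool and never touched again; the loop repeats with `i-1` while `i > 2`
and unassigned proteins remain.  After level 2, the two-method cells of
size 2..`min_size`-1 that were never selected are appended as *leftover*
groups (trimmed to the remaining pool, made disjoint by the same
largest-cell / random-tie rule).  Everything left over is reported
unassigned.

Determinism: with a fixed seed the whole run is reproducible
byte-for-byte, including regenerated group ids (`Gk` by descending size,
then smallest member).  All orderings used for iteration and tie-breaking
derive from the total lexicographic order on `(species, protein)`.

## Parameters

| parameter          | default | meaning |
|--------------------|---------|---------|
| `evalue_threshold` | 1e-10   | strict upper bound on the profile-hit E-value |
| `min_coverage`     | 0.40    | minimum aligned fraction of both sequence and profile |
| `min_size`         | 4       | minimum seed-cell size; smaller 2-method cells become leftovers |
| `n_decoys`         | 60      | decoy count per profile for E-value calibration |
| `pseudocount`      | 1.0     | prior mass blended into column frequencies |
| `gap_open`/`gap_extend` | 5.5 / 0.5 bits | affine penalties of the profile local alignment |

The first three are the thresholds that define the method's operating
point; the defaults are the recommended values (higher `min_size`
suppresses spurious seeds at the cost of coverage; looser E-values mainly
add fusion errors — the `sweep` command tabulates these trade-offs against
a reference set).

## The builtin profile backend

The default backend is fully self-contained and deterministic, so that
every score can be checked against an independent dynamic-programming
oracle:

* **Alignment** — center-star progressive alignment.  Pairwise global
  alignments use BLOSUM62 with affine gaps (open 11, extend 1, the BLAST
  protein convention); the center sequence maximizes the total pairwise
  score (ties to the smallest ProteinRef) and the remaining rows merge
  under "once a gap, always a gap".  Input order cannot matter because
  rows are processed in lexicographic order.
* **Profile** — columns with more than 50% gaps are excluded from the
  match states.  Column frequencies use Henikoff position-based sequence
  weights and are blended with the background (Robinson–Robinson amino
  acid frequencies, overridable) by `pseudocount` total prior mass:
  `f = (n f_obs + c bg) / (n + c)`, so the background carries weight 1/2
  at one sequence and decays as the row count grows.  Match scores are
  `log2(f / bg)` bits; the unknown residue X scores 0 everywhere.
* **Scoring** — Smith–Waterman local alignment of the sequence against
  the match columns with affine penalties in bits (5.5 / 0.5, the
  half-bit equivalent of BLOSUM62's 11/1).  Start coordinates propagate
  through the recurrence, so coverage (aligned span over full length, on
  both sides) needs no traceback; score ties prefer diagonal, then
  gap-in-profile, then gap-in-sequence, making the reported spans
  deterministic.
* **E-values** — per profile, `n_decoys` sequences are drawn with
  replacement from the current unassigned pool and residue-shuffled
  (composition and length preserved, positional signal destroyed), scored,
  and fitted with a Gumbel by the method of moments
  (`lambda = pi / (sd sqrt 6)`, `mu = mean - gamma / lambda`).  Then
  `E(s) = D (1 - exp(-exp(-lambda (s - mu))))` with the database size `D`
  equal to the number of unassigned proteins at the start of the pass —
  the size of the search space the profile actually faces, reset each
  iteration.

The **external backend** (`--backend external`) swaps the alignment and
scoring machinery for an MSA binary (`muscle` if present, else `mafft`)
plus HMMER's `hmmbuild`/`hmmsearch`, thresholding the full-sequence
E-value (with `-Z` pinned to the pass's database size) and computing
coverage from the union of domain alignment spans.  The two backends
expose identical hit semantics; swapping them changes scores, never the
control flow.

## The BRH input method

The bundled best-reciprocal-hit method filters an all-vs-all similarity
table before best-hit selection: a hit survives iff its raw score reaches
`min_score_ratio` of the self-score of *both* query and subject, and its
alignment length reaches `min_len_ratio` of the shorter sequence
(symmetric, the standard choice).  Mutual per-species best hits become
ortholog pairs; groups are maximal cliques of the pair graph (each protein
joins the largest clique containing it, ties to the lexicographically
smallest member set), so every group is fully connected and has at most
one protein per species.  The two thresholds default to 0.5/0.5; these
are conventional placeholders, not derived values — calibrate them to the
score scale of the similarity search that produced the table.

## Evaluation measures

* **Jaccard** on co-grouped pairs: `|A∩B| / |A∪B|`; defined as 1.0 when
  both pair sets are empty (a documented convention that real clusterings
  never trigger).
* **Fusion/fission against reference groups.**  Predicted groups are
  restricted to the benchmark universe first.  A reference group
  overlapped by n predicted groups counts `n-1` fissions; its best-match
  group (largest overlap, ties to the larger group, then lexicographic)
  causes a fusion iff it contains more than 3 proteins outside the
  reference group.  Fusion is judged on the best-match group only — the
  orthoBench-style mapping of each reference group to one predicted
  group — and is binary per reference group.  "Accurate" additionally
  requires that at least one predicted group overlaps the reference group,
  so a completely missed group is never counted accurate despite showing
  zero events.
* **Schlicker relevance similarity.**  Per namespace,
  `p(term)` is the fraction of annotations on the term or any descendant
  and `ic = -ln p`; `sim_rel(c1, c2) = max over common ancestors a of
  (2 ic(a) / (ic(c1)+ic(c2))) (1 - p(a))`, which is 0 whenever the root is
  the only common ancestor and `1 - p(c)` for identical terms.  Term sets
  are compared by the best-match *average* (mean of row-max means and
  column-max means); GO scores average over the namespaces annotated on
  both proteins (missing namespaces are excluded, not zeroed), and EC
  numbers live on a 4-level prefix tree under a virtual root with
  wildcards (`1.2.-.-`) annotating internal nodes.  Pairs where either
  protein lacks annotation are skipped, never scored 0.  GO annotations
  are evidence-filtered at load to the experimental codes EXP, IDA, IPI,
  IMP, IGI, IEP.

## The synthetic generator

`simulate` produces everything a run needs with no external data: true
groups across S species (one random ancestor per group, members are
independent substitution-mutated copies at a per-group rate drawn from
`divergence_range`), decoy proteins with no family, a 3-level GO DAG
(root, 5 internal nodes, one leaf per group) with annotations inherited
at `annotation_fidelity`, synthetic EC serials per group, and N method
predictions perturbed by per-group fission/fusion and per-protein
dropout/relocation.  All outputs are pure functions of the seed.

What it does *not* emulate: insertions and deletions (substitution-only
evolution keeps the alignment oracles exact; an indel-free world is
kinder to profile search than real proteomes), phylogenetic tree
structure, rate heterogeneity across sites, domain shuffling, splice
variants, and the correlated errors real orthology methods make on the
same hard families.  Passing the synthetic recovery tests therefore shows
the machinery is correct and that the consensus logic beats its noisy
inputs under controlled error models — not that it attains any particular
accuracy on real proteomes.

Test and acceptance runs use 40 groups over 6 species (1–2 members per
species per group, sequences ~100 residues, divergence 0.05–0.3, 20
decoys) with four input methods at p_fission = p_fusion = 0.1,
p_dropout = 0.05, p_relocate = 0.02 — small enough to iterate quickly,
large enough that every code path (all levels, conflicts, leftovers,
recruitment) is exercised.

## Numerical and degenerate-input choices

* E-value survival uses `-expm1(-exp(z))` with an early-out for large
  `z`, so tiny E-values keep full precision and huge scores cannot
  overflow.
* Zero decoy-score variance aborts calibration with an error rather than
  fabricating a null.
* A local-alignment optimum of 0 reports coverage 0 and E = D.
* Input groups that overlap within one method are resolved at load (the
  protein stays in its largest group, ties to the earliest line) and
  singletons are dropped, so every loaded prediction is a partition.
* Identical cells arising from different method subsets are kept once,
  with all contributing subsets recorded.
* `run_meta` without a proteome runs the pure intersection consensus
  (profile stage disabled); grouped proteins missing from the supplied
  proteome are an error unless explicitly skipped.

## Known limitations

* The builtin profile is a position-specific scoring matrix with local
  alignment, not a full profile HMM; insert-state emission and
  state-transition probabilities are approximated by the affine gap
  penalties.  Use the external HMMER backend when exact HMM semantics
  matter.
* Center-star alignment is O(k²) pairwise alignments per seed and less
  accurate than modern progressive aligners on divergent families.
* Leftover handling trusts two-method agreement for very small cells;
  with only two input methods the leftovers are simply all small
  agreement cells, which can be noisy.
* The fusion definition counts foreign proteins only within the benchmark
  universe, so fusions with never-benchmarked proteins are invisible to
  the report (matching standard benchmark practice).
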