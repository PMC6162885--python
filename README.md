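# paretoprimer

Multi-objective design of PCR primer sets for bacterial 16S rRNA amplicon
sequencing.

## The problem

Amplicon surveys of microbial communities amplify the 16S rRNA gene with
"broad-spectrum" primers placed in its conserved blocks.  Because those
blocks are conserved but not identical across taxa, practitioners use
degenerate primers — or, more generally, a **primer-set-pair**: a set of
non-degenerate forward primers plus a set of non-degenerate reverse primers
used together.  A good set-pair has to balance three competing goals:

* **Efficiency (E ∈ [0, 10])** — how well each oligo behaves in the PCR:
  melting temperature, GC content, 3′-end composition, homopolymers,
  self-/cross-dimers, hairpins, Tm spread across the set, and the spread of
  amplicon lengths.  Each constraint is scored as a fuzzy ramp in [0, 1]
  (1 when comfortably satisfied, 0 when clearly violated, linear in
  between); E is the sum of ten such terms.
* **Coverage (C ∈ [0, 1])** — the fraction of a reference collection of 16S
  sequences matched by at least one forward and one reverse primer.  A
  primer matches when its 3′-terminal 5-nt *seed* matches a template window
  exactly and the remainder has at most 2 mismatches; amplicons deviating
  more than 100 nt from the median ("target") length do not count.
* **Matching-bias (M ≥ 0)** — the coefficient of variation (SD/mean) of the
  number of forward×reverse primer combinations matching each covered
  sequence.  Species matched by more combinations are over-amplified in
  quantitative studies, so M is minimized.

No single set-pair optimizes all three at once, so the tool approximates
the **Pareto front**: set-pair *p* dominates *p′* iff **f**(p) ≠ **f**(p′),
E(p) ≥ E(p′), C(p) ≥ C(p′) and M(p) ≤ M(p′).  The search is a restart-driven
scalarized local search: each restart samples a front member and a weight
vector **α** uniformly from the unit simplex, then hill-climbs

    α_E · E/10 + α_C · C + α_M · max(0, 1 − M)

by best-improvement over single-base edits (substitutions anywhere,
additions/removals at the extremities) of one primer at a time, until no
edit improves the scalarization.  Every solution ever scored is kept in an
archive; the front is computed on demand.  Runs are fully deterministic
given a seed.

## Worked example

Inputs are a FASTA of reference 16S sequences and a TSV of initial
(possibly degenerate) candidate pairs with columns
`id  forward  reverse  domain  amplicon_length` (the last two optional).
Here the reference set is synthetic: 20 sequences of 800 nt, half carrying
forward-site variant `TCCTACGGGAGGCAGCAG`, half a variant differing at
three non-seed positions, all sharing one reverse site — so the starting
pair covers exactly half the references, and a one-base repair covering
both variants exists.

```
paretoprimer optimize --refset ref.fasta --init candidates.tsv \
    --amplicon-min 700 --amplicon-max 800 --restarts 10 --seed 42 \
    --out-prefix run
```

prints

```
archive: 11 solutions -> run.archive.tsv
front:   1 solutions -> run.front.tsv
```

and the front file contains

```
forward             reverse            E     C_fraction  C_count  M    provenance    restart
TTCTACGGGAGGCAGCAG  TCACGGCACGAGCTGAC  10.0  1.0         20       0.0  local-search  1
```

The search replaced the second base C→T, which leaves ≤ 2 mismatches
against *both* planted site variants: coverage rises from 0.5 to 1.0 while
efficiency stays at 10 and bias at 0 — on this fixture the front collapses
to a single dominating solution.  On realistic reference sets the front
retains several incomparable trade-offs; `--runs N` merges N independent
searches and reports their mean pairwise front Jaccard index as a
heterogeneity diagnostic.

The same machinery is available as a library (`paretoprimer.Evaluator`,
`score_vector`, `multi_objective_search`, ...), and
`paretoprimer score` evaluates candidates without searching.

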