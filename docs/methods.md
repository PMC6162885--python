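# Methods

This note documents the models, scoring rules, numerical conventions and
design decisions behind paretoprimer, and what the synthetic fixtures do and
do not demonstrate.

## Objectives

A candidate solution is a *primer-set-pair* `(F, R)`: a non-empty set of
forward and a non-empty set of reverse non-degenerate primers (A/C/G/T,
5′→3′).  It is scored by three objectives against a reference collection of
16S sequences (sense strand):

### Efficiency E ∈ [0, 10]

Sum of ten terms, each in [0, 1].  Seven single-primer terms are averaged
over all primers of F ∪ R:

| term | rule (defaults) |
|---|---|
| melting temperature | ramp: 0 at ≤ 50 °C, 1 at ≥ 52 °C |
| GC fraction | 1 on [0.5, 0.7]; 0 below 0.4 or above 0.7; linear on [0.4, 0.5) |
| weak 3′ end | 0 iff the last 3 bases are all A/T |
| strong 3′ end | 0 iff more than 3 of the last 5 bases are G/C |
| homopolymers | 1 for runs ≤ 4 nt, 0.5 for a longest run of 5, 0 beyond |
| self-dimer | max gap-free matches m of the primer vs its reverse complement; 1 at m ≤ 8, 0 at m ≥ 11 |
| hairpin | 0 iff the reverse complement of the last 5 bases aligns gap-free to an upstream window with the 3′-terminal base pairing and ≥ 3 of the 4 preceding bases pairing |

Three set-pair terms: Tm spread over all primers (1 at ≤ 3 °C, 0 at ≥ 5 °C),
worst forward×reverse dimer (same 8/11 ramp), and amplicon-length spread —
median minus first percentile of all amplicon lengths on the reference set
(1 at ≤ 50 nt, 0 at ≥ 100 nt).  All thresholds and ramp endpoints are
user-configurable (`EfficiencyConfig`, flat YAML via `--config`).

The GC term is implemented as the rising ramp `(f_GC − 0.4)/0.1` on
[0.4, 0.5), the only direction consistent with the plateau of 1 at 0.5.

**Tm model.**  Nearest-neighbour duplex thermodynamics via Biopython's
`Tm_NN`.  Defaults: the unified Allawi–SantaLucia parameter table
(`unified97`), monovalent cation 50 mM, total oligo concentration 500 nM
(equal strand concentrations, the C_T/4 approximation), entropic salt
correction.  Table and conditions are exposed in `ThermoParams`
(`breslauer86`, `santalucia96`, `unified97`, `santalucia04`).  The defaults
were chosen as the standard modern parameter set; absolute Tm values — and
therefore the Tm and Tm-range terms near their thresholds — shift by one or
two degrees across published tables, so cross-study comparisons of E at the
second decimal are parameter-sensitive.  The test suite cross-checks the
implementation against an independently hand-typed nearest-neighbour
calculation to within 1.5 °C.

**Hairpin window.**  The fold-back probe is the reverse complement of the
3′-terminal 5 bases; alignments overlapping the probe's own source
positions are excluded (a palindromic 3′ end pairing with itself is not a
physical hairpin).

### Coverage C ∈ [0, 1]

A primer matches a sequence when some gap-free window matches the primer's
3′-terminal 5-nt seed exactly and the remaining positions with ≤ 2
mismatches.  Reverse primers are matched against the antisense strand and
reported in sense coordinates.  Reference letters outside A/C/G/T
(ambiguity codes) are counted as mismatches everywhere, including the seed
— coverage is never claimed through ambiguity.

For each (f, r) combination and sequence, the amplicon is the **shortest**
product over valid site pairs (reverse site strictly downstream of the
forward site; the product spans both primer footprints, forward-site start
through reverse-site end, 1-based inclusive).  PCR kinetics favour the
shortest product when a primer binds multiply.  The *target length* is the
median of all amplicon lengths; combinations deviating more than 100 nt
from it are discarded.  A sequence is covered iff ≥ 1 combination survives.

### Matching-bias M ≥ 0

The coefficient of variation (population SD / mean) of the surviving
combination counts across **covered** sequences.  Uncovered sequences are
excluded from the CV: they are already penalized through C, and including
zeros would double-count the same failure.  The ±100 nt filter is applied
to the counts before computing the CV.  When nothing is covered, M is
reported as a large finite sentinel (10⁶) so Pareto dominance stays well
defined and such solutions are dominated by anything that amplifies.

### Percentiles

Nearest-rank percentile (the ⌈q·n⌉-th order statistic); the median of an
even-sized sample is the mean of the two central order statistics.  Both
are deterministic and exact on integer lengths.

## Search

* **Dominance**: `a ≺ b` iff the score vectors differ, E and C are no worse
  and M is no worse.  The front keeps non-dominated entries, one per
  distinct score vector (first occurrence in archive order).
* **Scalarization**: weights drawn uniformly from the unit simplex
  (exponential-spacings construction).  Objectives are normalized to [0, 1]
  with *fixed* normalizers — E/10, C as a fraction, and bias mapped via
  max(0, 1 − M) — rather than by the archive maximum, so the scalarized
  objective is stationary across restarts and runs.
* **Neighbourhood** of one primer: every single-base substitution, every
  single-base addition at either extremity, and removal of either terminal
  base, subject to length bounds.  The initial candidate filter uses the
  literature box 17–21 nt; local-search moves use a wider configurable
  [15, 25] nt so the search can leave the initial box without drifting into
  extreme lengths.  Edits duplicating a primer already in the same set are
  dropped.
* **Best-improvement local search**: for each primer, score the full
  neighbourhood, adopt the best strictly-improving neighbour, repeat on the
  edited primer until it admits no improvement, then advance; the cycle over
  primers repeats until a complete pass changes nothing.  Ties are broken by
  a fixed enumeration order (position ascending; substitution before
  addition before removal; bases A < C < G < T), making the whole search
  deterministic.  The returned solution is a verified local optimum: tests
  re-scan every neighbourhood and confirm nothing improves the scalarized
  score.
* **Restarts/runs**: each restart recomputes the front, samples a start
  uniformly from it and a fresh weight vector, and archives the local
  optimum.  Multiple runs execute sequentially with child seeds derived
  from the master seed and are merged before the final front; the mean
  pairwise Jaccard index between per-run front solution lists is reported
  as a heterogeneity diagnostic.
* **Initial candidates** (probeBase-style TSV) are kept when every expanded
  primer is 17–21 nt, the domain tag is Bacteria or Universal (a missing
  tag is treated as eligible — user lists often lack tags, exclusion is
  opt-in), and the amplicon length (supplied metadata, else the computed
  median on the reference set) lies in the requested range.  Degenerate
  candidates are expanded over the full 15-code IUPAC alphabet.

## Synthetic reference sets

`generate_synthetic_refset` emulates what a broad-spectrum primer sees in a
16S collection: random "variable" background with conserved blocks planted
at fixed positions (forward sites as the primer sequence, reverse sites as
its reverse complement), each carried by a Bernoulli fraction of sequences
and degraded by an independent per-position substitution process.  The
generator records exactly which sites were written and which positions
mutated, so expected coverage and bias are known by construction: exactly
at substitution rate 0, binomially at rate > 0.

Default fixture conditions used across tests and the acceptance script:
800 nt sequences, a forward site at position 50 and a reverse site at 740
(707 nt amplicon, matching the ~700–800 nt target range the candidate
filter uses), 10–50 sequences for search tests and 200–400 where binomial
statistics need resolution.  The two-variant recovery fixture plants a
second forward-site allele differing at three non-seed positions in half
the sequences; the exact-match starting primer then covers exactly half,
and a single substitution (toward the variant) yields ≤ 2 mismatches
against both alleles — a planted optimum with coverage 1.0 and bias 0,
reachable within the tested restart budget.

What the synthetic fixtures do **not** emulate: real 16S length variation
(~1.5 kb with indels), correlated taxon structure, chimeras, or ambiguity
codes at conserved positions.  Passing the recovery and statistics tests
shows the matching rule, the objectives and the search are implemented
correctly and consistently; it does not certify primer performance on any
real database — for that, users should supply a current reference FASTA
(e.g. an OTU-representative set) and their own candidate list.

The three bundled example set-pairs ship with their reported
reference-scale efficiency scores (9.66, 9.93, 10).  Nine of the ten
efficiency terms are independent of the reference set; the test suite
evaluates the amplicon-range term on a synthetic planted-site stand-in with
uniform amplicon lengths (as reported for the original reference
collection, 701–708 nt) and reproduces the reported row within 0.15, the
third pair exactly 10.  Coverage and bias of those set-pairs on external
databases depend on database version and curation and are out of scope.

## Known limitations

* Dimer and hairpin terms count complementary matches only — no ΔG/free
  energy duplex model, by design.
* Tm uses a single monovalent-salt correction; divalent cations and dNTPs
  are not modelled.
* The matching engine is the naive seed-anchored rule evaluated exactly
  (vectorized per window); no k-mer index. It is the correctness contract,
  adequate up to tens of thousands of reference sequences, not for
  million-sequence databases.
* Archives keep every solution ever scored; no pruning or diversity
  maintenance beyond dominance.
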