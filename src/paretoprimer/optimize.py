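"""Pareto dominance, scalarized best-improvement local search and the
restart-driven multi-objective search over primer-set-pairs.

The three objectives are efficiency E (maximized, scale 0-10), coverage C
(maximized, fraction) and matching-bias M (minimized, a coefficient of
variation).  A set-pair dominates another when its objective vector differs
and is at least as good in every component.  The search keeps an *archive*
of every solution ever scored; the Pareto front is computed on demand.

Each restart draws a weight vector uniformly from the unit simplex, picks a
front member uniformly at random, and hill-climbs the scalarized objective

    alpha_E * E/10 + alpha_C * C + alpha_M * max(0, 1 - M)

by best-improvement local search over single-base edits of one primer at a
time (substitutions anywhere, additions and removals at the extremities),
until no edit of any primer improves the scalarization.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matching import Evaluator, ScoreVector
from .seqcore import PrimerSetPair, expand_pair

__all__ = [
    "Weights",
    "ArchiveEntry",
    "SearchConfig",
    "UserInputError",
    "dominates",
    "pareto_front",
    "sample_weights",
    "scalarize",
    "weighted_score",
    "neighborhood",
    "local_search",
    "select_initial",
    "multi_objective_search",
    "run_search",
    "archive_jaccard",
]

log = logging.getLogger(__name__)

BASES = "ACGT"


class UserInputError(ValueError):
    """Invalid user-supplied inputs (candidate files, filters, config)."""


@dataclass(frozen=True)
class Weights:
    """Non-negative scalarization weights on the unit simplex."""

    e: float
    c: float
    m: float

    def __post_init__(self) -> None:
        if min(self.e, self.c, self.m) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.e + self.c + self.m - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class ArchiveEntry:
    pair: PrimerSetPair
    score: ScoreVector
    provenance: str = "initial"  # "initial" or "local-search"
    restart: int = -1


@dataclass(frozen=True)
class SearchConfig:
    """Search-space bounds and budget.

    ``init_len_*`` bound primer lengths when filtering initial candidates;
    ``move_len_*`` bound the lengths reachable by local-search edits (wider,
    so the search may leave the initial box without drifting into extreme
    primer lengths).
    """

    amplicon_min: int
    amplicon_max: int
    init_len_min: int = 17
    init_len_max: int = 21
    move_len_min: int = 15
    move_len_max: int = 25
    n_restarts: int = 20
    n_runs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplicon_min >= self.amplicon_max:
            raise ValueError("amplicon_min must be < amplicon_max")
        if self.move_len_min < 6:
            raise ValueError("move_len_min must leave room for seed + 1")
        if self.n_restarts < 0 or self.n_runs < 1:
            raise ValueError("invalid search budget")


# --------------------------------------------------------------------------
# Pareto machinery


def dominates(a: ScoreVector, b: ScoreVector) -> bool:
    """True iff a is at least as good everywhere and not identical (E and C
    maximized, M minimized)."""
    if a.key == b.key:
        return False
    return a.e >= b.e and a.c_fraction >= b.c_fraction and a.m <= b.m


def pareto_front(archive: Sequence[ArchiveEntry]) -> list[ArchiveEntry]:
    """Non-dominated entries, in archive order, one per distinct score vector.

    Entries sharing a score vector are represented by their first occurrence.
    Implemented as a sort-and-sweep over descending efficiency: a candidate
    can only be dominated by entries that precede it in the sorted order, so
    each one is checked against the kept set only.
    """
    if not archive:
        raise ValueError("empty archive has no Pareto front")
    firsts: list[ArchiveEntry] = []
    seen: set[tuple[float, float, float]] = set()
    for entry in archive:
        if entry.score.key not in seen:
            seen.add(entry.score.key)
            firsts.append(entry)
    order = sorted(
        range(len(firsts)),
        key=lambda i: (
            -firsts[i].score.e,
            -firsts[i].score.c_fraction,
            firsts[i].score.m,
        ),
    )
    kept: list[int] = []
    for i in order:
        s = firsts[i].score
        if not any(dominates(firsts[j].score, s) for j in kept):
            kept.append(i)
    return [firsts[i] for i in sorted(kept)]


def sample_weights(rng: np.random.Generator) -> Weights:
    """Uniform draw from the 2-simplex via exponential spacings."""
    g = rng.exponential(size=3)
    g = g / g.sum()
    # guard the sum-to-one invariant against rounding
    return Weights(float(g[0]), float(g[1]), float(1.0 - g[0] - g[1]))


def scalarize(score: ScoreVector, weights: Weights) -> float:
    """Weighted sum of the normalized objectives, each mapped into [0, 1]:
    E/10, C as a fraction, and 1 - M clamped at 0 (bias is minimized)."""
    return (
        weights.e * (score.e / 10.0)
        + weights.c * score.c_fraction
        + weights.m * max(0.0, 1.0 - score.m)
    )


def weighted_score(
    pair: PrimerSetPair, weights: Weights, evaluator: Evaluator
) -> float:
    return scalarize(evaluator.score(pair), weights)


# --------------------------------------------------------------------------
# Local search


def _edits(primer: str, len_min: int, len_max: int) -> list[str]:
    """Single edits of one primer in deterministic enumeration order:
    substitutions (position ascending, bases A<C<G<T), then additions
    (prepend before append, bases A<C<G<T), then removals (first, then last),
    subject to the length bounds."""
    out: list[str] = []
    n = len(primer)
    for i, cur in enumerate(primer):
        for b in BASES:
            if b != cur:
                out.append(primer[:i] + b + primer[i + 1:])
    if n < len_max:
        for b in BASES:
            out.append(b + primer)
        for b in BASES:
            out.append(primer + b)
    if n > len_min:
        out.append(primer[1:])
        out.append(primer[:-1])
    return out


def neighborhood(
    pair: PrimerSetPair,
    index: int,
    len_min: int = 15,
    len_max: int = 25,
) -> list[PrimerSetPair]:
    """All set-pairs reachable by one edit of the ``index``-th primer
    (canonical order: forward set then reverse set, each sorted).  Edits that
    would duplicate another primer already in the same set are dropped."""
    nf = len(pair.forward)
    if not 0 <= index < len(pair):
        raise IndexError(f"primer index {index} out of range")
    in_forward = index < nf
    members = pair.forward if in_forward else pair.reverse
    pos = index if in_forward else index - nf
    primer = members[pos]
    others = set(members) - {primer}
    out = []
    for edited in _edits(primer, len_min, len_max):
        if edited in others:
            continue
        new_members = tuple(members[:pos] + (edited,) + members[pos + 1:])
        if in_forward:
            out.append(PrimerSetPair(new_members, pair.reverse))
        else:
            out.append(PrimerSetPair(pair.forward, new_members))
    return out


def local_search(
    start: PrimerSetPair,
    weights: Weights,
    evaluator: Evaluator,
    cfg: SearchConfig,
) -> PrimerSetPair:
    """Best-improvement hill climbing to a verified local optimum.

    Cycles through the primers of the current set-pair; for each primer the
    full single-edit neighbourhood is scored and the best strictly-improving
    neighbour adopted, repeatedly, until that primer admits no improvement;
    the whole cycle repeats until a complete pass changes nothing.
    """
    current = start
    best = weighted_score(current, weights, evaluator)
    improved = True
    while improved:
        improved = False
        for index in range(len(current)):
            while True:
                candidates = neighborhood(
                    current, index, cfg.move_len_min, cfg.move_len_max
                )
                best_cand = None
                best_cand_score = best
                for cand in candidates:
                    s = weighted_score(cand, weights, evaluator)
                    if s > best_cand_score:
                        best_cand, best_cand_score = cand, s
                if best_cand is None:
                    break
                # keep refining the edited primer: find its index in the
                # re-sorted set-pair before rescanning
                if best_cand.forward != current.forward:
                    edited = (set(best_cand.forward) - set(current.forward)).pop()
                    index = best_cand.forward.index(edited)
                else:
                    edited = (set(best_cand.reverse) - set(current.reverse)).pop()
                    index = len(best_cand.forward) + best_cand.reverse.index(edited)
                current, best = best_cand, best_cand_score
                improved = True
    return current


# --------------------------------------------------------------------------
# Initial solutions and the outer search


def select_initial(
    candidates: Sequence,
    evaluator: Evaluator,
    cfg: SearchConfig,
) -> list[ArchiveEntry]:
    """Filter, expand and score initial (possibly degenerate) primer pairs.

    A candidate survives when every expanded primer length lies within the
    initial bounds (default 17-21 nt), its target domain is Bacteria or
    Universal (missing domain tags are kept), and its amplicon length - the
    supplied expected length if present, else the median amplicon length on
    the reference set - falls inside the configured range.
    """
    archive: list[ArchiveEntry] = []
    for cand in candidates:
        try:
            pair = expand_pair(cand.forward, cand.reverse)
        except ValueError as exc:
            raise UserInputError(f"candidate {cand.id!r}: {exc}") from exc
        if cand.domain is not None and cand.domain.lower() not in (
            "bacteria",
            "universal",
        ):
            continue
        if not all(
            cfg.init_len_min <= len(p) <= cfg.init_len_max for p in pair.primers
        ):
            continue
        if cand.amplicon_length is not None:
            amplen: float | None = float(cand.amplicon_length)
        else:
            amplen = evaluator.profile(pair).target_length
        if amplen is None or not (cfg.amplicon_min <= amplen <= cfg.amplicon_max):
            continue
        archive.append(ArchiveEntry(pair, evaluator.score(pair), "initial"))
    if not archive:
        raise UserInputError(
            "no candidate primer pair survived the initial filters; widen the "
            "amplicon range or primer length bounds, or check domain tags"
        )
    return archive


def multi_objective_search(
    cfg: SearchConfig,
    evaluator: Evaluator,
    init: Sequence[ArchiveEntry],
    rng: np.random.Generator | None = None,
) -> list[ArchiveEntry]:
    """Restart loop: sample a front member and a weight vector, hill-climb the
    scalarization, append the result to the archive.  Returns the archive."""
    if not init:
        raise ValueError("initial archive is empty")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    archive = list(init)
    for r in range(1, cfg.n_restarts + 1):
        front = pareto_front(archive)
        start = front[int(rng.integers(len(front)))]
        alpha = sample_weights(rng)
        result = local_search(start.pair, alpha, evaluator, cfg)
        score = evaluator.score(result)
        log.info(
            "restart %d: alpha=(%.3f, %.3f, %.3f) start=(%.3f, %.3f, %.3f) "
            "end=(%.3f, %.3f, %.3f)",
            r, alpha.e, alpha.c, alpha.m, *start.score.key, *score.key,
        )
        archive.append(ArchiveEntry(result, score, "local-search", r))
    return archive


def run_search(
    candidates: Sequence,
    evaluator: Evaluator,
    cfg: SearchConfig,
) -> tuple[list[ArchiveEntry], list[ArchiveEntry], float]:
    """Run ``cfg.n_runs`` independent searches sequentially and merge.

    Each run draws its restart randomness from a child seed derived from
    ``cfg.seed``, so the merged result is deterministic.  Returns the merged
    archive, its Pareto front, and the mean pairwise Jaccard index between
    the per-run front solution lists (a run-heterogeneity statistic; 1.0 by
    convention when fewer than two runs are requested).
    """
    init = select_initial(candidates, evaluator, cfg)
    master = np.random.default_rng(cfg.seed)
    child_seeds = master.integers(2**31, size=cfg.n_runs)
    archive: list[ArchiveEntry] = list(init)
    run_fronts: list[list[PrimerSetPair]] = []
    for k in range(cfg.n_runs):
        rng = np.random.default_rng(int(child_seeds[k]))
        run_archive = multi_objective_search(cfg, evaluator, init, rng)
        run_fronts.append([e.pair for e in pareto_front(run_archive)])
        archive.extend(run_archive[len(init):])
    if len(run_fronts) > 1:
        vals = [
            archive_jaccard(run_fronts[i], run_fronts[j])
            for i in range(len(run_fronts))
            for j in range(i + 1, len(run_fronts))
        ]
        jaccard = float(np.mean(vals))
    else:
        jaccard = 1.0
    return archive, pareto_front(archive), jaccard


def archive_jaccard(
    a: Sequence[PrimerSetPair], b: Sequence[PrimerSetPair]
) -> float:
    """Jaccard index between two solution lists (set-pair identity: equal
    forward and reverse sets).  Both empty is defined as 1."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
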