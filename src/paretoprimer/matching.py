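"""Seed-anchored primer matching, amplicon derivation, coverage and
matching-bias against a reference collection of 16S sequences.

A primer matches a reference sequence when some gap-free window matches the
primer's 3'-terminal 5-nt *seed* exactly and the remaining 5' positions with
at most 2 mismatches.  Forward primers are matched on the sense strand;
reverse primers on the antisense strand (equivalently, the sense strand is
compared against the reverse complement of the primer, whose seed then sits
at the 5' end of the sense window).  Reference letters outside A/C/G/T are
conservatively treated as mismatches, including inside the seed.

From per-primer match sites the module derives, for every (forward, reverse)
combination and every sequence, the shortest valid amplicon (forward site
start through reverse site end, reverse site strictly downstream).  The
median of all such lengths is the *target amplicon length*; combinations
whose amplicon deviates from it by more than 100 nt do not count.  A
sequence is *covered* when at least one combination survives; the
*matching-bias* is the coefficient of variation (population SD over mean)
of the surviving combination counts across covered sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from . import efficiency as _eff
from .seqcore import PrimerSetPair, PrimerError, reverse_complement

__all__ = [
    "SEED_LEN",
    "MAX_NONSEED_MISMATCHES",
    "DEFAULT_LENGTH_TOLERANCE",
    "BIAS_SENTINEL",
    "ReferenceSet",
    "MatchSite",
    "MatchProfile",
    "ScoreVector",
    "find_matches",
    "amplicon_for_combination",
    "build_profile",
    "coverage",
    "matching_bias",
    "score_vector",
    "Evaluator",
]

SEED_LEN = 5
MAX_NONSEED_MISMATCHES = 2
DEFAULT_LENGTH_TOLERANCE = 100
#: Worst-case matching-bias reported when a set-pair covers nothing; large and
#: finite so Pareto dominance stays well defined.
BIAS_SENTINEL = 1e6

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence; any non-ACGT letter becomes a never-matching code."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ReferenceSet:
    """An ordered collection of reference sequences (sense strand, 5'->3')."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s): {', '.join(dup)}")
        for rid, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")

    @classmethod
    def of(cls, records: Iterable[tuple[str, str]]) -> "ReferenceSet":
        return cls(tuple((rid, seq.upper()) for rid, seq in records))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)


@dataclass(frozen=True)
class MatchSite:
    """A primer binding site in 1-based inclusive sense-strand coordinates."""

    seq_id: str
    start: int
    end: int
    strand: Literal["forward", "reverse"]
    mismatches: int


@dataclass(frozen=True)
class ScoreVector:
    """The objective triple: efficiency E (max 10), coverage C (fraction,
    with the covered count retained) and matching-bias M (CV, minimized)."""

    e: float
    c_fraction: float
    c_count: int
    m: float

    @property
    def key(self) -> tuple[float, float, float]:
        return (self.e, self.c_fraction, self.m)


@dataclass
class MatchProfile:
    """Amplicon bookkeeping for one set-pair against one reference set."""

    #: shortest amplicon length per (forward primer, reverse primer, seq id)
    lengths: dict[tuple[str, str, str], int]
    #: all present amplicon lengths, sorted ascending
    all_lengths: list[int]
    #: median amplicon length (None when no amplicon exists)
    target_length: float | None
    #: per sequence id: combinations within +-tolerance of the target
    counts: dict[str, int]
    #: per sequence id: combinations with any amplicon (before the filter)
    counts_prefilter: dict[str, int]
    length_tolerance: int = DEFAULT_LENGTH_TOLERANCE


def _site_positions(primer: str, enc_seq: np.ndarray, orientation: str) -> np.ndarray:
    """0-based window start positions where the primer binds; with per-site
    mismatch counts stacked as a (k, 2) array [[start, mismatches], ...]."""
    m = len(primer)
    n = enc_seq.shape[0]
    if n < m:
        return np.empty((0, 2), dtype=np.int64)
    if orientation == "forward":
        probe = _encode(primer)
        seed = slice(m - SEED_LEN, m)
        rest = slice(0, m - SEED_LEN)
    elif orientation == "reverse":
        # the sense strand carries the reverse complement of the primer; the
        # primer's 3' seed maps to the first SEED_LEN sense positions
        probe = _encode(reverse_complement(primer))
        seed = slice(0, SEED_LEN)
        rest = slice(SEED_LEN, m)
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown orientation {orientation!r}")
    windows = np.lib.stride_tricks.sliding_window_view(enc_seq, m)
    neq = windows != probe
    seed_ok = ~neq[:, seed].any(axis=1)
    mism = neq[:, rest].sum(axis=1)
    hit = seed_ok & (mism <= MAX_NONSEED_MISMATCHES)
    starts = np.nonzero(hit)[0]
    return np.stack([starts, mism[starts].astype(np.int64)], axis=1)


def find_matches(
    primer: str,
    seq: str,
    orientation: Literal["forward", "reverse"],
    seq_id: str = "",
) -> list[MatchSite]:
    """All binding sites of a primer on one reference sequence.

    ``orientation`` selects whether the primer is matched as a forward primer
    (sense strand, seed at the window's 3' end) or as a reverse primer
    (antisense strand; sites still reported in sense coordinates).
    """
    if len(primer) < SEED_LEN + 1:
        raise PrimerError(
            f"primer {primer!r} shorter than seed + 1 = {SEED_LEN + 1} nt"
        )
    sites = _site_positions(primer, _encode(seq.upper()), orientation)
    m = len(primer)
    return [
        MatchSite(seq_id, int(s) + 1, int(s) + m, orientation, int(k))
        for s, k in sites
    ]


def _shortest_amplicon(
    fwd_sites: np.ndarray, rev_sites: np.ndarray, primer_len_f: int, primer_len_r: int
) -> int | None:
    """Shortest product length over site pairs with the reverse site strictly
    downstream of the forward site (1-based inclusive span, both footprints)."""
    if fwd_sites.shape[0] == 0 or rev_sites.shape[0] == 0:
        return None
    best: int | None = None
    f_ends = fwd_sites[:, 0] + primer_len_f  # 0-based exclusive end == 1-based end
    r_starts = rev_sites[:, 0] + 1  # 1-based start
    r_ends = rev_sites[:, 0] + primer_len_r
    for fs, fe in zip(fwd_sites[:, 0] + 1, f_ends):
        for rs, re in zip(r_starts, r_ends):
            if rs > fe:
                length = int(re - fs + 1)
                if best is None or length < best:
                    best = length
    return best


def amplicon_for_combination(f: str, r: str, seq: str) -> int | None:
    """Shortest amplicon of one (forward, reverse) combination on a sequence."""
    enc = _encode(seq.upper())
    return _shortest_amplicon(
        _site_positions(f, enc, "forward"),
        _site_positions(r, enc, "reverse"),
        len(f),
        len(r),
    )


def build_profile(
    pair: PrimerSetPair,
    refset: ReferenceSet,
    length_tolerance: int = DEFAULT_LENGTH_TOLERANCE,
) -> MatchProfile:
    """Amplicons of every (forward, reverse, sequence) triple, the target
    (median) length, and per-sequence combination counts before and after the
    +-``length_tolerance`` filter around the target."""
    ev = Evaluator(refset, length_tolerance=length_tolerance)
    return ev.profile(pair)


def coverage(profile: MatchProfile, refset: ReferenceSet) -> tuple[int, float]:
    """Covered sequence count and fraction (count >= 1 after the filter)."""
    covered = sum(1 for rid in refset.ids if profile.counts.get(rid, 0) >= 1)
    return covered, covered / len(refset)


def matching_bias(profile: MatchProfile, sentinel: float = BIAS_SENTINEL) -> float:
    """Coefficient of variation (population SD / mean) of combination counts
    across covered sequences; ``sentinel`` when nothing is covered."""
    counts = np.array([c for c in profile.counts.values() if c >= 1], dtype=float)
    if counts.size == 0:
        return sentinel
    return float(counts.std() / counts.mean())


class Evaluator:
    """Caching scorer binding a reference set to thermo/efficiency settings.

    Matching a primer against the reference set and computing its melting
    temperature depend only on the primer itself, so both are memoized; the
    local search re-evaluates thousands of set-pairs that differ in a single
    primer and hits the caches for everything else.
    """

    def __init__(
        self,
        refset: ReferenceSet,
        params: _eff.ThermoParams = _eff.DEFAULT_THERMO,
        cfg: _eff.EfficiencyConfig = _eff.DEFAULT_CONFIG,
        length_tolerance: int = DEFAULT_LENGTH_TOLERANCE,
        bias_sentinel: float = BIAS_SENTINEL,
    ) -> None:
        self.refset = refset
        self.params = params
        self.cfg = cfg
        self.length_tolerance = length_tolerance
        self.bias_sentinel = bias_sentinel
        self._enc = [(_encode(seq)) for _, seq in refset.records]
        self._sites: dict[tuple[str, str], list[np.ndarray]] = {}
        self._scores: dict[PrimerSetPair, ScoreVector] = {}

    # -- cached primitives -------------------------------------------------

    def sites(self, primer: str, orientation: str) -> list[np.ndarray]:
        key = (primer, orientation)
        got = self._sites.get(key)
        if got is None:
            got = [_site_positions(primer, enc, orientation) for enc in self._enc]
            self._sites[key] = got
        return got

    # -- profile and objectives -------------------------------------------

    def profile(self, pair: PrimerSetPair) -> MatchProfile:
        lengths: dict[tuple[str, str, str], int] = {}
        ids = self.refset.ids
        fwd_sites = {f: self.sites(f, "forward") for f in pair.forward}
        rev_sites = {r: self.sites(r, "reverse") for r in pair.reverse}
        for f in pair.forward:
            for r in pair.reverse:
                for i, rid in enumerate(ids):
                    length = _shortest_amplicon(
                        fwd_sites[f][i], rev_sites[r][i], len(f), len(r)
                    )
                    if length is not None:
                        lengths[(f, r, rid)] = length
        all_lengths = sorted(lengths.values())
        target = _eff.median(all_lengths) if all_lengths else None
        counts = {rid: 0 for rid in ids}
        counts_pre = {rid: 0 for rid in ids}
        tol = self.length_tolerance
        for (f, r, rid), length in lengths.items():
            counts_pre[rid] += 1
            if target is not None and abs(length - target) <= tol:
                counts[rid] += 1
        return MatchProfile(
            lengths=lengths,
            all_lengths=all_lengths,
            target_length=target,
            counts=counts,
            counts_prefilter=counts_pre,
            length_tolerance=tol,
        )

    def score(self, pair: PrimerSetPair) -> ScoreVector:
        got = self._scores.get(pair)
        if got is not None:
            return got
        profile = self.profile(pair)
        breakdown = _eff.efficiency_score(
            pair,
            params=self.params,
            cfg=self.cfg,
            amplicon_lengths=profile.all_lengths,
        )
        count, fraction = coverage(profile, self.refset)
        bias = matching_bias(profile, self.bias_sentinel)
        sv = ScoreVector(breakdown.total, fraction, count, bias)
        self._scores[pair] = sv
        return sv


def score_vector(
    pair: PrimerSetPair,
    refset: ReferenceSet,
    params: _eff.ThermoParams = _eff.DEFAULT_THERMO,
    cfg: _eff.EfficiencyConfig = _eff.DEFAULT_CONFIG,
) -> ScoreVector:
    """The (E, C, M) objective triple of a set-pair on a reference set."""
    return Evaluator(refset, params, cfg).score(pair)
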