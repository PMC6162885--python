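"""Fuzzy efficiency scoring of primer-set-pairs.

The efficiency score is a sum of ten terms, each in [0, 1], so the total
ranges from 0 (hopeless) to 10 (every constraint perfectly satisfied).
Seven terms encode single-primer constraints and are averaged over all
primers in the set-pair:

* melting temperature (nearest-neighbour model) above ~52 degC,
* GC fraction in [0.5, 0.7],
* 3'-terminal trinucleotide not all A/T,
* at most 3 G/C among the last 5 bases,
* no homopolymer runs longer than 4 nt,
* weak self-complementarity (self-dimer),
* no hairpin-forming fold-back of the 3' end.

Three terms describe the set-pair as a whole: the spread of melting
temperatures across all primers, the worst forward-x-reverse dimer, and the
spread of amplicon lengths on a reference sequence collection (median minus
first percentile).

Hard constraints are encoded as fuzzy ramps: 1 when comfortably satisfied,
0 when clearly violated, linear in between.  Every threshold and ramp
endpoint is configurable through :class:`EfficiencyConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .seqcore import PrimerSetPair, PrimerError, max_gapfree_matches, reverse_complement

__all__ = [
    "ThermoParams",
    "FuzzyRamp",
    "EfficiencyConfig",
    "EfficiencyBreakdown",
    "DEFAULT_THERMO",
    "DEFAULT_CONFIG",
    "melting_temperature",
    "score_tm",
    "score_gc",
    "score_end3_at",
    "score_end3_gc",
    "score_homopolymer",
    "score_self_dimer",
    "score_hairpin",
    "score_tm_range",
    "score_cross_dimer",
    "score_amplicon_range",
    "nearest_rank_percentile",
    "median",
    "efficiency_score",
]

#: Nearest-neighbour parameter tables (Biopython names them DNA_NN1..4).
NN_TABLES = {
    "breslauer86": _mt.DNA_NN1,
    "santalucia96": _mt.DNA_NN2,
    "unified97": _mt.DNA_NN3,
    "santalucia04": _mt.DNA_NN4,
}


@dataclass(frozen=True)
class ThermoParams:
    """Reaction conditions and parameter table for the duplex Tm model.

    ``primer_nM`` is the total oligonucleotide concentration; the model uses
    the standard non-self-complementary approximation C_T/4 (realized as equal
    strand concentrations of ``primer_nM / 2`` each).
    """

    table: str = "unified97"
    monovalent_mM: float = 50.0
    primer_nM: float = 500.0

    def __post_init__(self) -> None:
        if self.table not in NN_TABLES:
            raise ValueError(
                f"unknown nearest-neighbour table {self.table!r}; "
                f"choose one of {sorted(NN_TABLES)}"
            )
        if self.monovalent_mM <= 0 or self.primer_nM <= 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class FuzzyRamp:
    """Linear membership ramp: 0 at ``zero_at``, 1 at ``one_at``, clamped.

    The direction is implied by the ordering of the two anchors, so the same
    type serves "at least" constraints (zero_at < one_at) and "at most"
    constraints (one_at < zero_at).
    """

    zero_at: float
    one_at: float

    def __post_init__(self) -> None:
        if self.zero_at == self.one_at:
            raise ValueError("degenerate ramp: zero_at == one_at")

    def __call__(self, x: float) -> float:
        t = (x - self.zero_at) / (self.one_at - self.zero_at)
        return min(1.0, max(0.0, t))


@dataclass(frozen=True)
class EfficiencyConfig:
    """Thresholds and ramps of the ten efficiency terms (all user-settable)."""

    tm_ramp: FuzzyRamp = FuzzyRamp(50.0, 52.0)
    gc_plateau_low: float = 0.5
    gc_plateau_high: float = 0.7
    gc_ramp_low: float = 0.4          # below this the GC term is 0
    self_dimer_ramp: FuzzyRamp = FuzzyRamp(11.0, 8.0)
    cross_dimer_ramp: FuzzyRamp = FuzzyRamp(11.0, 8.0)
    hairpin_seed_len: int = 5
    hairpin_min_preceding: int = 3    # of the 4 positions before the 3' terminus
    homopolymer_soft: int = 4         # longest run fully tolerated
    homopolymer_hard: int = 5         # runs beyond this score 0
    tm_range_ramp: FuzzyRamp = FuzzyRamp(5.0, 3.0)
    amplicon_range_ramp: FuzzyRamp = FuzzyRamp(100.0, 50.0)
    thermo: ThermoParams = field(default_factory=ThermoParams)


DEFAULT_THERMO = ThermoParams()
DEFAULT_CONFIG = EfficiencyConfig()


def melting_temperature(p: str, params: ThermoParams = DEFAULT_THERMO) -> float:
    """Nearest-neighbour melting temperature of a primer, in degC."""
    if len(p) < 2:
        raise PrimerError("melting temperature needs at least a dinucleotide")
    half = params.primer_nM / 2.0
    return float(
        _mt.Tm_NN(
            p,
            nn_table=NN_TABLES[params.table],
            Na=params.monovalent_mM,
            dnac1=half,
            dnac2=half,
            saltcorr=5,
        )
    )


def score_tm(tm: float, cfg: EfficiencyConfig = DEFAULT_CONFIG) -> float:
    """1 if Tm at/above the upper anchor (default 52), 0 at/below the lower (50)."""
    return cfg.tm_ramp(tm)


def score_gc(p: str, cfg: EfficiencyConfig = DEFAULT_CONFIG) -> float:
    """GC-fraction term: plateau of 1 on [0.5, 0.7], hard 0 above 0.7 and
    below 0.4, linearly rising on [0.4, 0.5)."""
    f = (p.count("G") + p.count("C")) / len(p)
    if cfg.gc_plateau_low <= f <= cfg.gc_plateau_high:
        return 1.0
    if f > cfg.gc_plateau_high or f < cfg.gc_ramp_low:
        return 0.0
    return (f - cfg.gc_ramp_low) / (cfg.gc_plateau_low - cfg.gc_ramp_low)


def score_end3_at(p: str) -> float:
    """0 iff the last three bases are all A or T (weak 3' clamp)."""
    if len(p) < 3:
        raise PrimerError("3'-end term needs at least 3 bases")
    return 0.0 if set(p[-3:]) <= {"A", "T"} else 1.0


def score_end3_gc(p: str) -> float:
    """0 iff more than 3 of the last five bases are G or C (over-strong 3' end)."""
    if len(p) < 5:
        raise PrimerError("3'-end GC term needs at least 5 bases")
    return 0.0 if sum(c in "GC" for c in p[-5:]) > 3 else 1.0


def score_homopolymer(p: str, cfg: EfficiencyConfig = DEFAULT_CONFIG) -> float:
    """1 for runs <= 4 nt, 0.5 for a longest run of exactly 5, else 0."""
    longest = max(len(list(g)) for _, g in groupby(p))
    if longest <= cfg.homopolymer_soft:
        return 1.0
    if longest <= cfg.homopolymer_hard:
        return 0.5
    return 0.0


def score_self_dimer(p: str, cfg: EfficiencyConfig = DEFAULT_CONFIG) -> float:
    """Fuzzy penalty on the best gap-free self-complementarity of a primer."""
    m = max_gapfree_matches(p, reverse_complement(p))
    return cfg.self_dimer_ramp(float(m))


def has_hairpin(p: str, cfg: EfficiencyConfig = DEFAULT_CONFIG) -> bool:
    """True if the 3' end of the primer can fold back onto an upstream region.

    The last ``hairpin_seed_len`` bases are reverse-complemented and slid
    gap-free along the primer (excluding windows overlapping their own source
    positions).  A fold-back counts if the 3'-terminal base pairs and at least
    ``hairpin_min_preceding`` of the 4 preceding bases pair as well.
    """
    k = cfg.hairpin_seed_len
    if len(p) < 2 * k:
        raise PrimerError(f"hairpin term needs at least {2 * k} bases")
    frag = reverse_complement(p[-k:])  # frag[j] pairs p[len(p)-1-j]
    n = len(p)
    for off in range(0, n - 2 * k + 1):  # window [off, off+k) must avoid [n-k, n)
        if p[off] != frag[0]:  # 3'-terminal base must pair
            continue
        preceding = sum(p[off + j] == frag[j] for j in range(1, k))
        if preceding >= cfg.hairpin_min_preceding:
            return True
    return False


def score_hairpin(p: str, cfg: EfficiencyConfig = DEFAULT_CONFIG) -> float:
    return 0.0 if has_hairpin(p, cfg) else 1.0


def score_tm_range(
    pair: PrimerSetPair,
    params: ThermoParams = DEFAULT_THERMO,
    cfg: EfficiencyConfig = DEFAULT_CONFIG,
) -> float:
    """Fuzzy penalty on the Tm spread (max - min) across all primers."""
    tms = [melting_temperature(p, params) for p in pair.primers]
    return cfg.tm_range_ramp(max(tms) - min(tms))


def score_cross_dimer(pair: PrimerSetPair, cfg: EfficiencyConfig = DEFAULT_CONFIG) -> float:
    """Fuzzy penalty on the worst forward-x-reverse gap-free complementarity."""
    m = max(
        max_gapfree_matches(f, reverse_complement(r))
        for f in pair.forward
        for r in pair.reverse
    )
    return cfg.cross_dimer_ramp(float(m))


def nearest_rank_percentile(sorted_values: Sequence[float], q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th smallest value (q in (0, 1])."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("percentile of empty data")
    rank = max(1, math.ceil(q * n))
    return sorted_values[rank - 1]


def median(sorted_values: Sequence[float]) -> float:
    """Median of pre-sorted values; mean of the central pair for even n."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("median of empty data")
    mid = n // 2
    if n % 2:
        return sorted_values[mid]
    return (sorted_values[mid - 1] + sorted_values[mid]) / 2.0


def score_amplicon_range(
    lengths: Iterable[float], cfg: EfficiencyConfig = DEFAULT_CONFIG
) -> float:
    """Fuzzy penalty on amplicon-length spread: median minus first percentile."""
    ordered = sorted(lengths)
    if not ordered:
        raise ValueError("amplicon-range term needs at least one amplicon length")
    delta = median(ordered) - nearest_rank_percentile(ordered, 0.01)
    return cfg.amplicon_range_ramp(delta)


@dataclass(frozen=True)
class EfficiencyBreakdown:
    """The ten efficiency terms (each in [0, 1]) and their sum."""

    tm: float
    gc: float
    end3_at: float
    end3_gc: float
    homopolymer: float
    self_dimer: float
    hairpin: float
    tm_range: float
    cross_dimer: float
    amplicon_range: float

    @property
    def total(self) -> float:
        return (
            self.tm + self.gc + self.end3_at + self.end3_gc + self.homopolymer
            + self.self_dimer + self.hairpin
            + self.tm_range + self.cross_dimer + self.amplicon_range
        )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in (
            "tm", "gc", "end3_at", "end3_gc", "homopolymer", "self_dimer",
            "hairpin", "tm_range", "cross_dimer", "amplicon_range")}
        d["total"] = self.total
        return d


def efficiency_score(
    pair: PrimerSetPair,
    refset=None,
    params: ThermoParams = DEFAULT_THERMO,
    cfg: EfficiencyConfig = DEFAULT_CONFIG,
    amplicon_lengths: Sequence[int] | None = None,
) -> EfficiencyBreakdown:
    """Full ten-term efficiency breakdown of a primer-set-pair.

    Single-primer terms are arithmetic means over all primers (forward and
    reverse together).  The amplicon-range term needs amplicon lengths on a
    reference set: pass ``refset`` (lengths are computed via the matching
    engine) or ``amplicon_lengths`` directly.  A set-pair that yields no
    amplicon at all gets an amplicon-range term of 0.
    """
    primers = pair.primers
    n = len(primers)

    def mean(fn) -> float:
        return sum(fn(p) for p in primers) / n

    if amplicon_lengths is None:
        if refset is not None:
            from .matching import build_profile

            amplicon_lengths = build_profile(pair, refset).all_lengths
        else:
            amplicon_lengths = []
    amp = score_amplicon_range(amplicon_lengths, cfg) if len(amplicon_lengths) else 0.0

    return EfficiencyBreakdown(
        tm=mean(lambda p: score_tm(melting_temperature(p, params), cfg)),
        gc=mean(lambda p: score_gc(p, cfg)),
        end3_at=mean(score_end3_at),
        end3_gc=mean(score_end3_gc),
        homopolymer=mean(lambda p: score_homopolymer(p, cfg)),
        self_dimer=mean(lambda p: score_self_dimer(p, cfg)),
        hairpin=mean(lambda p: score_hairpin(p, cfg)),
        tm_range=score_tm_range(pair, params, cfg),
        cross_dimer=score_cross_dimer(pair, cfg),
        amplicon_range=amp,
    )
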