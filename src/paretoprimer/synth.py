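"""Synthetic reference-set generator with known ground truth.

Emulates the conserved/variable architecture a broad-spectrum 16S primer
sees: random "variable" background with short conserved blocks planted at
fixed positions.  A forward site is planted as the primer sequence itself;
a reverse site as the reverse complement of the reverse primer (so the
primer binds the antisense strand).  Each site is carried by an independent
Bernoulli fraction of the sequences and mutated by an independent
per-position substitution process.  Because the generator records exactly
which sites were planted, where, and which positions were mutated, expected
coverage and matching-bias are known by construction and the matching engine
can be checked against them exactly (rate 0) or statistically (rate > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .matching import SEED_LEN, MAX_NONSEED_MISMATCHES, ReferenceSet
from .seqcore import reverse_complement, validate_primer

__all__ = ["PlantedSite", "SyntheticRefSpec", "SiteTruth", "generate_synthetic_refset"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSite:
    """A primer binding site to embed in every generated sequence.

    ``position`` is the 0-based start of the site on the sense strand.  For
    ``orientation == "reverse"`` the reverse complement of ``primer`` is
    written there.  ``fraction`` is the probability a given sequence carries
    the site; ``substitution_rate`` the per-position mutation probability."""

    primer: str
    position: int
    orientation: Literal["forward", "reverse"] = "forward"
    fraction: float = 1.0
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        validate_primer(self.primer, min_len=SEED_LEN + 1)
        if not (0.0 <= self.fraction <= 1.0 and 0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("fraction and substitution_rate must lie in [0, 1]")
        if self.position < 0:
            raise ValueError("site position must be non-negative")

    @property
    def span(self) -> tuple[int, int]:
        return self.position, self.position + len(self.primer)


@dataclass(frozen=True)
class SyntheticRefSpec:
    n_sequences: int
    length: int
    sites: tuple[PlantedSite, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("need at least one sequence of positive length")
        spans = sorted(s.span for s in self.sites)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("planted sites overlap")
        for s in self.sites:
            if s.span[1] > self.length:
                raise ValueError("planted site extends past sequence end")


@dataclass(frozen=True)
class SiteTruth:
    """What the generator actually wrote for one (sequence, site) pair."""

    seq_id: str
    site_index: int
    present: bool
    n_mutations: int
    seed_mutated: bool

    @property
    def matchable(self) -> bool:
        """Would the planted primer still match under the seed/mismatch rule
        (seed intact, at most 2 mismatches elsewhere)?"""
        return (
            self.present
            and not self.seed_mutated
            and self.n_mutations <= MAX_NONSEED_MISMATCHES
        )


def _seed_positions(site: PlantedSite) -> range:
    """Sense-strand offsets (within the site) holding the primer's 3' seed."""
    n = len(site.primer)
    if site.orientation == "forward":
        return range(n - SEED_LEN, n)
    return range(0, SEED_LEN)


def generate_synthetic_refset(
    spec: SyntheticRefSpec,
) -> tuple[ReferenceSet, list[SiteTruth]]:
    """Generate the reference set and its per-(sequence, site) ground truth.

    Deterministic for a given spec (the seed is part of the spec)."""
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    truth: list[SiteTruth] = []
    for i in range(spec.n_sequences):
        seq = _BASES[rng.integers(4, size=spec.length)].copy()
        seq_id = f"synth{i:04d}"
        for j, site in enumerate(spec.sites):
            present = bool(rng.random() < site.fraction)
            n_mut = 0
            seed_mut = False
            if present:
                planted = site.primer
                if site.orientation == "reverse":
                    planted = reverse_complement(planted)
                block = np.frombuffer(planted.encode(), dtype=np.uint8).copy()
                seedpos = set(_seed_positions(site))
                for k in range(len(block)):
                    if rng.random() < site.substitution_rate:
                        current = block[k]
                        options = [b for b in _BASES if b != current]
                        block[k] = options[int(rng.integers(3))]
                        n_mut += 1
                        if k in seedpos:
                            seed_mut = True
                seq[site.position : site.position + len(block)] = block
            truth.append(SiteTruth(seq_id, j, present, n_mut, seed_mut))
        records.append((seq_id, seq.tobytes().decode("ascii")))
    return ReferenceSet.of(records), truth
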