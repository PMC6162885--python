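"""Sequence primitives: IUPAC alphabet handling, reverse complement,
degenerate-primer expansion and gap-free match counting.

A *primer* here is always a concrete (non-degenerate) oligonucleotide over
``{A, C, G, T}``, written 5'->3'.  A *degenerate* primer may use any of the
15 IUPAC nucleotide codes and stands for the set of concrete primers obtained
by taking the Cartesian product of the per-position base options.  A
*primer-set-pair* couples a set of forward primers with a set of reverse
primers and is the search state of the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

__all__ = [
    "AlphabetError",
    "PrimerError",
    "IUPAC_OPTIONS",
    "reverse_complement",
    "degeneracy",
    "expand_degenerate",
    "expand_pair",
    "max_gapfree_matches",
    "validate_primer",
    "PrimerSetPair",
]

#: Concrete base options for each IUPAC nucleotide code (15 codes).
IUPAC_OPTIONS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Degenerate codes complement to degenerate codes (R<->Y, K<->M, B<->V, D<->H;
# S, W and N are self-complementary).
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class PrimerError(ValueError):
    """A primer violates a structural invariant (length, degeneracy, ...)."""


def _check_iupac(seq: str, what: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in IUPAC_OPTIONS:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i + 1} of {what} {seq!r}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (5'->3' in, 5'->3' out)."""
    _check_iupac(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate string stands for."""
    _check_iupac(seq)
    d = 1
    for ch in seq:
        d *= len(IUPAC_OPTIONS[ch])
    return d


def expand_degenerate(seq: str) -> tuple[str, ...]:
    """Expand a degenerate primer into all concrete primers.

    Returns the full Cartesian product of per-position base options, in
    lexicographic position-major order; a non-degenerate input yields a
    1-tuple of itself.
    """
    _check_iupac(seq, "degenerate primer")
    if not seq:
        raise PrimerError("empty degenerate primer")
    return tuple("".join(p) for p in product(*(IUPAC_OPTIONS[c] for c in seq)))


def validate_primer(seq: str, min_len: int = 5, max_len: int | None = None) -> str:
    """Validate a concrete primer (A/C/G/T only, length bounds); returns it."""
    if len(seq) < min_len:
        raise PrimerError(f"primer {seq!r} shorter than {min_len} nt")
    if max_len is not None and len(seq) > max_len:
        raise PrimerError(f"primer {seq!r} longer than {max_len} nt")
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise PrimerError(
                f"primer {seq!r} has non-concrete base {ch!r} at position {i + 1}"
            )
    return seq


@dataclass(frozen=True)
class PrimerSetPair:
    """A set of forward and a set of reverse concrete primers.

    Primers within each set are stored sorted so that two set-pairs with the
    same membership compare and hash equal regardless of construction order.
    """

    forward: tuple[str, ...]
    reverse: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, primers in (("forward", self.forward), ("reverse", self.reverse)):
            if not primers:
                raise PrimerError(f"{name} primer set is empty")
            if len(set(primers)) != len(primers):
                raise PrimerError(f"duplicate primer in {name} set")
            for p in primers:
                validate_primer(p)
        object.__setattr__(self, "forward", tuple(sorted(self.forward)))
        object.__setattr__(self, "reverse", tuple(sorted(self.reverse)))

    @classmethod
    def of(cls, forward: Iterable[str], reverse: Iterable[str]) -> "PrimerSetPair":
        return cls(tuple(forward), tuple(reverse))

    @property
    def primers(self) -> tuple[str, ...]:
        """All primers, forward first, each set sorted (the canonical order)."""
        return self.forward + self.reverse

    def __len__(self) -> int:
        return len(self.forward) + len(self.reverse)


def expand_pair(fwd: str, rev: str) -> PrimerSetPair:
    """Expand a (possibly degenerate) primer pair into a primer-set-pair."""
    return PrimerSetPair.of(expand_degenerate(fwd), expand_degenerate(rev))


def max_gapfree_matches(a: str, b: str) -> int:
    """Maximum number of identical aligned letters over all gap-free offsets.

    All relative shifts with at least one overlapping position are considered;
    no end-anchoring.  Used for dimer screening as
    ``max_gapfree_matches(p, reverse_complement(q))``.
    """
    if not a or not b:
        raise PrimerError("max_gapfree_matches requires non-empty sequences")
    la, lb = len(a), len(b)
    best = 0
    # offset o aligns a[i] with b[i - o]; overlap requires -(lb-1) <= o <= la-1
    for o in range(-(lb - 1), la):
        lo = max(0, o)
        hi = min(la, lb + o)
        m = 0
        for i in range(lo, hi):
            if a[i] == b[i - o]:
                m += 1
        if m > best:
            best = m
    return best
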