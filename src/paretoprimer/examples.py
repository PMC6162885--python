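"""Bundled example primer-set-pairs.

Three previously reported optimized bacterial 16S primer-set-pairs whose
forward primers bind between hypervariable regions V2 and V3 (E. coli
positions 355-358) and whose reverse primers bind between V6 and V7
(positions 1059-1063), producing ~701-708 nt amplicons.  Their reported
efficiency scores on a GreenGenes 85% OTU bacterial representative set were
9.66, 9.93 and 10; the efficiency terms that do not depend on the reference
set are reproduced by this package's defaults (see the test suite).
"""

from __future__ import annotations

from .seqcore import PrimerSetPair

EXAMPLE_SET_PAIR_1 = PrimerSetPair.of(
    forward=(
        "TCCTACGGGAGGCAGCA",
        "TCCTACCGGAGGCACCA",
        "TCCTACGGGCGAATGCAG",
        "CCTACGCGAGGCTGCAA",
        "CCTACGCGAGGCAGCAA",
        "CCTACGGAAGGCAGCAG",
        "CCTACGGGTGGCTGCAG",
        "CTACGGTGGGCTGCAGT",
    ),
    reverse=(
        "TCACGGCACGAGCTGAC",
        "GACACGAGCTGACGACA",
    ),
)

EXAMPLE_SET_PAIR_2 = PrimerSetPair.of(
    forward=(
        "TCCTACGGGAGGCAGCA",
        "TCCTACCGGAGGCACCA",
        "TCCTACGGGTGGTTGCAG",
        "TCCTACGGAAGGCAGCAG",
        "CCTACGCGAGGCAGCAA",
        "CCTACGCGAGGCTGCAA",
        "CCTACGGGCGAATGCAG",
        "CTACGGTTGGCTGCAGT",
    ),
    reverse=(
        "TCACGGCACGAGCTGAC",
        "ACGACACGAGCTGACGAC",
    ),
)

EXAMPLE_SET_PAIR_3 = PrimerSetPair.of(
    forward=(
        "CTCCTACGGAAGGCAGCA",
        "TCCTACGGGAGCCTGCA",
        "TCCTACGGAAGGGTGCAG",
        "CCTACGGGTTGCAGCAG",
        "CCTACGCGAGGCAGCAA",
        "CCTACGCGTGGTTGCAG",
        "TCTACGGACGGCAGCAA",
        "CTACGTGCGGTTGCAGT",
    ),
    reverse=(
        "ACGACACGAGCTGACGA",
        "ACGACACGAGCTGACAAC",
        "CACCACGAGCTGACGAC",
        "CAACACGAGCTGACGAGAG",
    ),
)

EXAMPLE_SET_PAIRS: tuple[PrimerSetPair, ...] = (
    EXAMPLE_SET_PAIR_1,
    EXAMPLE_SET_PAIR_2,
    EXAMPLE_SET_PAIR_3,
)

#: Reported reference-scale efficiency scores of the three example set-pairs.
REPORTED_EFFICIENCY: tuple[float, float, float] = (9.66, 9.93, 10.0)
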