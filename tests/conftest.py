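"""Shared fixtures: synthetic reference sets with planted primer sites."""

from __future__ import annotations

import numpy as np
import pytest

from paretoprimer.matching import ReferenceSet
from paretoprimer.synth import PlantedSite, SyntheticRefSpec, generate_synthetic_refset

# A well-behaved forward primer (GC 0.67, Tm ~58.5, clean 3' end) and the
# variant of its binding site differing at three non-seed positions (1, 5, 12).
FWD_A = "TCCTACGGGAGGCAGCAG"
FWD_B_SITE = "TTCTAAGGGAGGTAGCAG"
REV = "TCACGGCACGAGCTGAC"

FWD_POS = 50
REV_POS = 740
SEQ_LEN = 800
AMPLICON_LEN = REV_POS + len(REV) - FWD_POS  # 707 nt, identical in every sequence


def make_two_variant_refset(n: int = 20, seed: int = 7) -> ReferenceSet:
    """n sequences, half carrying the A forward-site variant, half the B
    variant; all carrying the same reverse site.  Substitution rate 0, so
    ground truth is exact: a primer matching only variant A covers n/2."""
    records = []
    for tag, site_seq, s in (("a", FWD_A, seed), ("b", FWD_B_SITE, seed + 1)):
        spec = SyntheticRefSpec(
            n // 2,
            SEQ_LEN,
            (
                PlantedSite(site_seq, FWD_POS, "forward"),
                PlantedSite(REV, REV_POS, "reverse"),
            ),
            seed=s,
        )
        refset, _ = generate_synthetic_refset(spec)
        records.extend((f"{tag}_{rid}", seq) for rid, seq in refset.records)
    return ReferenceSet.of(records)


def make_clean_refset(n: int = 10, seed: int = 11) -> ReferenceSet:
    """n sequences all carrying exact A forward and reverse sites."""
    spec = SyntheticRefSpec(
        n,
        SEQ_LEN,
        (
            PlantedSite(FWD_A, FWD_POS, "forward"),
            PlantedSite(REV, REV_POS, "reverse"),
        ),
        seed=seed,
    )
    refset, _ = generate_synthetic_refset(spec)
    return refset


@pytest.fixture(scope="session")
def two_variant_refset() -> ReferenceSet:
    return make_two_variant_refset()


@pytest.fixture(scope="session")
def clean_refset() -> ReferenceSet:
    return make_clean_refset()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
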