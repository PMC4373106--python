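import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from synscaf.io_formats import PairwiseAlignment
from synscaf.synthetic import (
    EvolutionParams,
    FixtureParams,
    NoiseParams,
    generate_fixture,
)


def aln(qid, qs, qe, qlen, rid, rs, re, rlen, strand="+", matches=None, score=None):
    """Shorthand alignment constructor for tests."""
    if matches is None:
        matches = min(qe - qs, re - rs)
    if score is None:
        score = float(matches)
    return PairwiseAlignment(qid, qs, qe, qlen, rid, rs, re, rlen, strand, matches, score)


@pytest.fixture(scope="session")
def zero_noise_fixture():
    """Small divergence-only fixture: 2 chromosomes, 20 scaffolds, no noise."""
    params = FixtureParams(
        n_chromosomes=2,
        chromosome_length_range=(900_000, 1_100_000),
        evolution=EvolutionParams(
            substitution_rate=0.10, indel_rate=0.0, n_inversions=0, n_translocations=0
        ),
        n_breaks_per_chrom=9,
        gap_range=(500, 10_000),
        noise=NoiseParams(),
        seed=7,
    )
    return generate_fixture(params)
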