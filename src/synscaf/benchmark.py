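"""The scaled-down validation benchmark.

The full-genome validation (fragment a finished genome into its scaffolds,
rebuild it against a related reference, and score the links against the
known layout) is reproduced here at desk scale: five ~4 Mb chromosomes, 10%
nucleotide divergence with short indels, five inversions and three
translocations planted per genome, fragmentation into ~200 scaffolds, a
noisy alignment set, and mate-pair mode with the three standard insert
classes at 1/1000 of the full-scale pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import evaluate_against_truth
from .pipeline import RunConfig, run_scaffold
from .synthetic import EvolutionParams, FixtureParams, NoiseParams, generate_fixture

__all__ = ["BenchmarkRun", "benchmark_fixture_params", "run_benchmark"]


def benchmark_fixture_params(seed: int) -> FixtureParams:
    """Study conditions of the scaled-down validation benchmark."""
    return FixtureParams(
        n_chromosomes=5,
        chromosome_length_range=(3_500_000, 4_500_000),
        evolution=EvolutionParams(
            substitution_rate=0.10,
            indel_rate=0.01,
            mean_indel_len=5.0,
            n_inversions=5,
            n_translocations=3,
        ),
        n_breaks_per_chrom=44,  # ~200 scaffolds after the scaffold-size floor
        gap_range=(500, 10_000),
        noise=NoiseParams(dropout_rate=0.05, spurious_rate=0.10, jitter_bp=500),
        seed=seed,
    )


@dataclass
class BenchmarkRun:
    seed: int
    correct_link_rate: float
    junction_rate: float
    n50_ratio: float
    n_scaffolds: int
    n_scaffolds_linked: int


def run_benchmark(
    base_seed: int = 1,
    n_runs: int = 10,
    mode: str = "matepair",
    scale: float = 0.001,
) -> list[BenchmarkRun]:
    """Run the benchmark over ``n_runs`` fixtures derived from ``base_seed``."""
    state = np.random.SeedSequence(base_seed).generate_state(2 * n_runs)
    runs: list[BenchmarkRun] = []
    for i in range(n_runs):
        fixture_seed = int(state[2 * i] & 0x7FFFFFFF)
        pipeline_seed = int(state[2 * i + 1] & 0x7FFFFFFF)
        fx = generate_fixture(benchmark_fixture_params(fixture_seed))
        res = run_scaffold(
            fx.scaffolds, fx.alignments,
            RunConfig(mode=mode, scale=scale, seed=pipeline_seed),
        )
        rep = evaluate_against_truth(
            res.superscaffolds, fx.truth, {s.id: s.length for s in res.scaffolds}
        )
        runs.append(
            BenchmarkRun(
                seed=fixture_seed,
                correct_link_rate=rep.correct_link_rate or 0.0,
                junction_rate=rep.junction_rate or 0.0,
                n50_ratio=rep.n50_ratio,
                n_scaffolds=len(fx.scaffolds),
                n_scaffolds_linked=rep.n_scaffolds_linked,
            )
        )
    return runs
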