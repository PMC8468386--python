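"""Default synthetic screening benchmark.

Defines one fixed protocol so tests, scripts, and documentation all
measure the same thing: build the default synthetic vendor library,
take a diverse sample of planted actives as seeds (three analogs per
series — first, middle, and last of the enumeration, emulating a
published set of known actives spanning each chemotype), run the
first-round selection at T2D >= 0.65 with the actives-learned property
profile and a diversity pick of 105 compounds, and score recall of the
planted actives against the expected recall of a uniformly random
selection of equal size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from focuslib.chem_io import Compound, CompoundLibrary
from focuslib.pipeline import PipelineConfig, run_first_round
from focuslib.synthetic import GeneratorConfig, GroundTruth, generate_library

#: first-round selection size of the default benchmark
DEFAULT_SELECTION_K = 105


def benchmark_seeds(library: CompoundLibrary, truth: GroundTruth, per_series: int = 3) -> list[Compound]:
    """A diverse known-actives seed set: ``per_series`` analogs per
    series, spread across each series' enumeration order."""
    seeds: list[Compound] = []
    labels = sorted(set(truth.table["label"]) - {"decoy"},
                    key=lambda s: int(s.split("_")[1]))
    for label in labels:
        ids = [str(i) for i in truth.table.index[truth.table["label"] == label]]
        if not ids:
            continue
        if per_series >= len(ids):
            picks = ids
        else:
            pos = np.linspace(0, len(ids) - 1, per_series).round().astype(int)
            picks = [ids[p] for p in sorted(set(pos.tolist()))]
        seeds.extend(library.by_id(cid) for cid in picks)
    return seeds


@dataclass
class BenchmarkResult:
    generator_seed: int
    n_library: int
    n_planted: int
    n_selected: int
    recall: float
    random_recall_expected: float


def first_round_benchmark(
    generator_seed: int,
    n_decoys: int = GeneratorConfig().n_decoys,
    selection_k: int = DEFAULT_SELECTION_K,
) -> BenchmarkResult:
    """Run the default first-round benchmark for one generator seed.

    ``random_recall_expected`` is the analytic expectation for a
    uniform selection of the same size: n_selected / n_library
    (every planted active is equally likely to be drawn).
    """
    lib, truth = generate_library(GeneratorConfig(n_decoys=n_decoys, rng_seed=generator_seed))
    seeds = benchmark_seeds(lib, truth)
    config = PipelineConfig(
        round="first",
        t2d_round1=0.65,
        property_filter=True,
        coverage=0.90,
        diversity_k=selection_k,
        rng_seed=generator_seed,
    )
    result = run_first_round(seeds, lib, config)
    planted = set(truth.planted_ids())
    selected = set(result.ids())
    n_sel = len(selected)
    recall = len(selected & planted) / len(planted) if planted else 0.0
    return BenchmarkResult(
        generator_seed=generator_seed,
        n_library=len(lib),
        n_planted=len(planted),
        n_selected=n_sel,
        recall=recall,
        random_recall_expected=n_sel / len(lib) if len(lib) else 0.0,
    )
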