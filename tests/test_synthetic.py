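"""Synthetic library generator and simulated screening oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from focuslib.fingerprints import compute_fingerprint, fingerprint_library, similarity_matrix, tanimoto
from focuslib.synthetic import (
    ActivityModel,
    GeneratorConfig,
    generate_library,
    scaffold_reference_smiles,
    simulate_screen,
)


class TestGenerateLibrary:
    def test_single_series_construction(self):
        lib, truth = generate_library(
            GeneratorConfig(n_decoys=0, n_series=1, analogs_per_series=5, rng_seed=1)
        )
        assert len(lib) <= 6
        assert set(truth.table["label"]) == {"series_1"}
        assert truth.latent_seed_ids == ["S1_1"]

    def test_deterministic_under_seed(self):
        a, _ = generate_library(GeneratorConfig(n_decoys=50, rng_seed=4))
        b, _ = generate_library(GeneratorConfig(n_decoys=50, rng_seed=4))
        assert [(c.id, c.smiles) for c in a] == [(c.id, c.smiles) for c in b]

    def test_all_unique_canonical_smiles(self):
        lib, _ = generate_library(GeneratorConfig(n_decoys=200, rng_seed=2))
        smiles = [c.smiles for c in lib]
        assert len(smiles) == len(set(smiles))

    def test_default_config_similarity_structure(self):
        """Planted analogs stay in their scaffold's neighborhood and
        series are tighter within than across (full-matrix oracle)."""
        config = GeneratorConfig()
        lib, truth = generate_library(config)
        planted = [c for c in lib if c.source == "synthetic:series"]
        fps = {c.id: compute_fingerprint(c) for c in planted}
        scaffold_fp = {
            label: compute_fingerprint(
                scaffold_reference_smiles(config.scaffold_pool[int(label.split("_")[1]) - 1])
            )
            for label in sorted(set(truth.table["label"]) - {"decoy"})
        }
        by_series: dict[str, list] = {}
        for c in planted:
            label = str(truth.table.loc[c.id, "label"])
            assert tanimoto(fps[c.id], scaffold_fp[label]) >= 0.4
            by_series.setdefault(label, []).append(fps[c.id])
        within, cross = [], []
        for label, series_fps in by_series.items():
            mat = similarity_matrix(series_fps)
            n = len(series_fps)
            within.append((mat.sum() - n) / (n * (n - 1)))
        for la, lb in itertools.combinations(sorted(by_series), 2):
            sims = [tanimoto(a, b) for a in by_series[la] for b in by_series[lb]]
            cross.append(float(np.mean(sims)))
        assert float(np.mean(within)) > float(np.mean(cross))

    def test_pool_shortfall_is_warning_not_error(self, caplog):
        config = GeneratorConfig(
            n_decoys=10_000, n_series=1, analogs_per_series=5, rng_seed=3
        )
        with caplog.at_level("WARNING"):
            lib, _ = generate_library(config)
        n_decoys = sum(1 for c in lib if c.id.startswith("D"))
        assert n_decoys < 10_000
        assert any("shortfall" in rec.message for rec in caplog.records)

    def test_invalid_pool_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(scaffold_pool=("not_smiles",))


@pytest.fixture(scope="module")
def campaign():
    lib, truth = generate_library(
        GeneratorConfig(n_decoys=150, n_series=3, analogs_per_series=10, rng_seed=6)
    )
    return lib, truth


class TestSimulateScreen:
    def test_latent_seed_scores_100_without_noise(self, campaign):
        lib, truth = campaign
        screen = simulate_screen(
            lib, truth, ActivityModel(noise_sd=0.0), rng_seed=6
        ).set_index("compound_id")
        for sid in truth.latent_seed_ids:
            assert screen.loc[sid, "percent_inhibition"] == pytest.approx(100.0)

    def test_activity_equals_max_seed_similarity_without_noise(self, campaign):
        lib, truth = campaign
        screen = simulate_screen(
            lib, truth, ActivityModel(noise_sd=0.0), rng_seed=6
        ).set_index("compound_id")
        seed_fps = [
            compute_fingerprint(lib.by_id(sid)) for sid in truth.latent_seed_ids
        ]
        for comp in list(lib)[::17]:
            expected = 100.0 * max(
                tanimoto(compute_fingerprint(comp), sfp) for sfp in seed_fps
            )
            assert screen.loc[comp.id, "percent_inhibition"] == pytest.approx(expected)

    def test_noiseless_ranking_preserves_tie_structure(self, campaign):
        lib, truth = campaign
        screen = simulate_screen(lib, truth, ActivityModel(noise_sd=0.0), rng_seed=0)
        fps = fingerprint_library(list(lib))
        seed_fps = [compute_fingerprint(lib.by_id(s)) for s in truth.latent_seed_ids]
        best = np.zeros(len(fps))
        for sfp in seed_fps:
            from focuslib.fingerprints import bulk_similarity

            best = np.maximum(best, bulk_similarity(sfp, fps))
        inh = screen["percent_inhibition"].to_numpy()
        np.testing.assert_allclose(inh, 100.0 * best)

    def test_cliff_count_exact(self):
        lib, truth = generate_library(
            GeneratorConfig(n_decoys=0, n_series=10, analogs_per_series=10, rng_seed=8)
        )
        assert len(truth.planted_ids()) == 100
        model = ActivityModel(kind="similarity_cliff", noise_sd=0.0, cliff_rate=0.3)
        screen = simulate_screen(lib, truth, model, rng_seed=8).set_index("compound_id")
        # a cliff compound's activity collapses to baseline (0 without noise)
        n_silenced = int(
            sum(
                screen.loc[cid, "percent_inhibition"] == 0.0
                for cid in truth.planted_ids()
            )
        )
        assert n_silenced == 30

    def test_deterministic_under_seed(self, campaign):
        lib, truth = campaign
        a = simulate_screen(lib, truth, rng_seed=11)
        b = simulate_screen(lib, truth, rng_seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_ic50_monotone_in_signal(self, campaign):
        lib, truth = campaign
        screen = simulate_screen(lib, truth, ActivityModel(noise_sd=0.0), rng_seed=1)
        with_ic50 = screen.dropna(subset=["ic50"]).sort_values("percent_inhibition")
        assert (with_ic50["ic50"].diff().dropna() <= 1e-12).all()
        assert (with_ic50["percent_inhibition"] >= 50.0).all()


def test_cliffs_reduce_first_round_hit_rate_mean_over_seeds():
    """Activity cliffs lower the hit rate of a fixed-size first-round
    selection relative to the smooth activity model (mean over seeds)."""
    from focuslib.benchmark import benchmark_seeds
    from focuslib.pipeline import PipelineConfig, run_first_round

    linear_rates, cliff_rates = [], []
    for seed in range(10):
        lib, truth = generate_library(
            GeneratorConfig(n_decoys=500, n_series=5, analogs_per_series=12, rng_seed=seed)
        )
        seeds = benchmark_seeds(lib, truth, per_series=2)
        selection = run_first_round(
            seeds, lib,
            PipelineConfig(property_filter=False, diversity_k=30, rng_seed=seed),
        )
        ids = selection.ids()
        for model, rates in (
            (ActivityModel(noise_sd=5.0), linear_rates),
            (ActivityModel(kind="similarity_cliff", noise_sd=5.0, cliff_rate=0.3), cliff_rates),
        ):
            screen = simulate_screen(lib, truth, model, rng_seed=seed).set_index("compound_id")
            hits = int((screen.loc[ids, "percent_inhibition"] >= 50.0).sum())
            rates.append(hits / len(ids))
    assert float(np.mean(cliff_rates)) < float(np.mean(linear_rates))
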