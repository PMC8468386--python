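"""Selection strategies: thresholding, tuner, group fusion, top-k,
bioisosteric expansion, fragment disconnection."""

from __future__ import annotations

import numpy as np
import pytest

from focuslib.chem_io import Compound, canonical_smiles
from focuslib.fingerprints import SimilarityRecord, bulk_similarity, compute_fingerprint
from focuslib.search import (
    TransformRule,
    TunerConfig,
    disconnect_fragments,
    expand_seeds_bioisosteric,
    group_fusion_scores,
    load_transform_rules,
    select_by_threshold,
    top_k_per_seed,
    tune_threshold,
)
from tests.conftest import full_fingerprint, make_compound, subset_fingerprint


def dummy_compound(cid: str) -> Compound:
    return Compound(id=cid, smiles="C", raw_smiles="C")


def scored_library(similarities):
    """Dummy compounds plus engineered fingerprints whose Tanimoto to
    full_fingerprint() equals each requested similarity (on a 1% grid)."""
    compounds = [dummy_compound(f"c{i:04d}") for i in range(len(similarities))]
    fps = [subset_fingerprint(s) for s in similarities]
    return compounds, fps


SEED = dummy_compound("seed")
SEED_FP = full_fingerprint()


class TestSelectByThreshold:
    def test_exact_duplicate_only_at_threshold_one(self, druglike_library):
        seed = druglike_library[2]
        records = select_by_threshold(seed, druglike_library, 1.0)
        assert [r.candidate_id for r in records] == [seed.id]

    def test_above_max_score_empty(self):
        compounds, fps = scored_library([0.3, 0.5, 0.7])
        records = select_by_threshold(
            SEED, compounds, 0.9, seed_fp=SEED_FP, library_fps=fps
        )
        assert records == []

    def test_matches_bruteforce_filter(self, rng):
        sims = rng.integers(0, 101, size=20) / 100.0
        compounds, fps = scored_library(sims)
        records = select_by_threshold(
            SEED, compounds, 0.65, seed_fp=SEED_FP, library_fps=fps
        )
        scores = bulk_similarity(SEED_FP, fps)
        expected = sorted(
            (
                (c.id, float(s))
                for c, s in zip(compounds, scores)
                if s >= 0.65
            ),
            key=lambda pair: (-pair[1], pair[0]),
        )
        assert [(r.candidate_id, r.t2d) for r in records] == expected

    def test_threshold_zero_rejected(self, druglike_library):
        with pytest.raises(ValueError):
            select_by_threshold(druglike_library[0], druglike_library, 0.0)


def reference_tuner(sims, config: TunerConfig):
    """Independent straightforward transcription of the tuning rule."""
    t = config.start_threshold
    step = config.coarse_step
    prev = 0
    fine = False
    trajectory = []
    for _ in range(config.max_iterations):
        count = int(np.sum(np.asarray(sims) >= t))
        trajectory.append((t, count))
        if config.window_min <= count <= config.window_max:
            return t, count, "in_window", trajectory
        if count < config.window_min:
            if t <= config.floor:
                return t, count, "floor_reached", trajectory
            d = -1
        else:
            if t >= 1.0:
                return t, count, "max_iter", trajectory
            d = +1
        if prev and d != prev and not fine:
            fine, step = True, config.fine_step
        prev = d
        t = min(1.0, max(config.floor, t * (1 + d * step)))
    return trajectory[-1][0], trajectory[-1][1], "max_iter", trajectory


class TestTuneThreshold:
    def test_in_window_immediately(self):
        compounds, fps = scored_library([0.80] * 120 + [0.10] * 50)
        result = tune_threshold(
            SEED, compounds, TunerConfig(), seed_fp=SEED_FP, library_fps=fps
        )
        assert result.status == "in_window"
        assert result.final_threshold == 0.75
        assert result.hit_count == 120
        assert len(result.trajectory) == 1
        assert len(result.records) == 120

    def test_one_coarse_step_down(self):
        # 12 candidates >= 0.75; 68 more in [0.7125, 0.75) -> 80 at 0.75*0.95
        compounds, fps = scored_library([0.76] * 12 + [0.72] * 68 + [0.10] * 30)
        result = tune_threshold(
            SEED, compounds, TunerConfig(), seed_fp=SEED_FP, library_fps=fps
        )
        assert result.status == "in_window"
        assert result.final_threshold == pytest.approx(0.7125)
        assert result.hit_count == 80
        assert [c for _, c in result.trajectory] == [12, 80]

    def test_floor_reached_when_window_unreachable(self):
        compounds, fps = scored_library([0.65] * 30 + [0.10] * 100)
        result = tune_threshold(
            SEED, compounds, TunerConfig(), seed_fp=SEED_FP, library_fps=fps
        )
        assert result.status == "floor_reached"
        assert result.final_threshold == pytest.approx(0.60)
        assert result.hit_count == 30

    def test_hit_set_returned_at_final_threshold(self):
        compounds, fps = scored_library([0.80] * 60 + [0.10] * 10)
        result = tune_threshold(
            SEED, compounds, TunerConfig(), seed_fp=SEED_FP, library_fps=fps
        )
        assert {r.candidate_id for r in result.records} == {
            c.id for c, s in zip(compounds, [0.80] * 60 + [0.10] * 10) if s >= result.final_threshold
        }

    @pytest.mark.parametrize("trial", range(20))
    def test_terminates_and_matches_reference_rule(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(20, 900))
        sims = (rng.beta(2.0, rng.uniform(1.0, 6.0), size=n) * 100).astype(int) / 100.0
        compounds, fps = scored_library(sims)
        config = TunerConfig(window_min=10, window_max=60, max_iterations=40)
        result = tune_threshold(SEED, compounds, config, seed_fp=SEED_FP, library_fps=fps)
        t_ref, count_ref, status_ref, traj_ref = reference_tuner(sims, config)
        assert len(result.trajectory) <= config.max_iterations
        assert result.status == status_ref
        assert result.final_threshold == pytest.approx(t_ref)
        assert result.hit_count == count_ref
        assert result.trajectory == pytest.approx(traj_ref)

    def test_in_window_found_when_coarse_path_contains_window(self):
        # counts at the descending coarse grid 0.75, 0.7125, 0.676..:
        # place an in-window count two steps down
        t2 = 0.75 * 0.95 * 0.95
        compounds, fps = scored_library(
            [round(t2 + 0.01, 2)] * 55 + [0.10] * 5
        )
        config = TunerConfig()
        result = tune_threshold(SEED, compounds, config, seed_fp=SEED_FP, library_fps=fps)
        assert result.status == "in_window"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            tune_threshold(SEED, [], TunerConfig())


class TestGroupFusion:
    def test_single_reference_reduces_to_plain_ranking(self, druglike_library):
        ref = druglike_library[3]
        ranked = group_fusion_scores(druglike_library, [ref])
        fps = [compute_fingerprint(c) for c in druglike_library]
        sims = bulk_similarity(compute_fingerprint(ref), fps)
        expected = sorted(
            zip((c.id for c in druglike_library), sims.tolist()),
            key=lambda p: (-p[1], p[0]),
        )
        assert [(cid, pytest.approx(s)) for cid, s in expected] == ranked

    def test_candidate_identical_to_reference(self, druglike_library):
        r1, r2 = druglike_library[0], druglike_library[5]
        ranked = dict(group_fusion_scores(druglike_library, [r1, r2]))
        t_r2 = bulk_similarity(
            compute_fingerprint(r2), [compute_fingerprint(r1)]
        )[0]
        assert ranked[r1.id] == pytest.approx(1.0 + t_r2)

    def test_matches_bruteforce_double_loop(self, rng):
        from tests.conftest import random_fingerprint

        cand_fps = [random_fingerprint(rng) for _ in range(50)]
        ref_fps = [random_fingerprint(rng) for _ in range(5)]
        compounds = [dummy_compound(f"c{i:02d}") for i in range(50)]
        refs = [dummy_compound(f"r{i}") for i in range(5)]
        ranked = dict(
            group_fusion_scores(
                compounds, refs, library_fps=cand_fps, reference_fps=ref_fps
            )
        )
        from tests.test_fingerprints import naive_tanimoto

        for c, cfp in zip(compounds, cand_fps):
            expected = sum(naive_tanimoto(cfp.bits, rfp.bits) for rfp in ref_fps)
            assert ranked[c.id] == pytest.approx(expected, abs=1e-12)

    def test_identical_references_scale_plain_similarity(self, druglike_library):
        ref = druglike_library[4]
        single = dict(group_fusion_scores(druglike_library, [ref]))
        triple = dict(group_fusion_scores(druglike_library, [ref, ref, ref]))
        for cid in single:
            assert triple[cid] == pytest.approx(3 * single[cid])

    def test_empty_references_rejected(self, druglike_library):
        with pytest.raises(ValueError):
            group_fusion_scores(druglike_library, [])


class TestTopKPerSeed:
    def _records(self, seed_id, sims, prefix):
        return [
            SimilarityRecord(f"{prefix}{i:02d}", seed_id, s)
            for i, s in enumerate(sims)
        ]

    def test_disjoint_candidate_sets_union(self):
        recs = self._records("s1", [0.9] * 10, "a") + self._records("s2", [0.8] * 10, "b")
        assert len(top_k_per_seed(recs, 10)) == 20

    def test_shared_top_candidate_attributed_to_better_seed(self):
        shared_hi = SimilarityRecord("shared", "s1", 0.95)
        shared_lo = SimilarityRecord("shared", "s2", 0.90)
        recs = (
            [shared_hi, shared_lo]
            + self._records("s1", [0.5] * 9, "a")
            + self._records("s2", [0.4] * 9, "b")
        )
        out = top_k_per_seed(recs, 10)
        assert len(out) == 19
        winner = next(r for r in out if r.candidate_id == "shared")
        assert winner.seed_id == "s1"

    def test_ties_at_rank_k_break_by_id(self):
        recs = self._records("s1", [0.9, 0.7, 0.7, 0.7, 0.5], "c")
        out = top_k_per_seed(recs, 3)
        expected = sorted(recs, key=lambda r: (-r.t2d, r.candidate_id))[:3]
        assert [r.candidate_id for r in out] == [r.candidate_id for r in expected]

    def test_group_fusion_mode_uses_external_scores(self):
        recs = self._records("s1", [0.9, 0.8, 0.7], "g")
        scores = {"g00": 0.1, "g01": 2.5, "g02": 1.0}
        out = top_k_per_seed(recs, 2, mode="group_fusion", group_scores=scores)
        assert [r.candidate_id for r in out] == ["g01", "g02"]

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            top_k_per_seed([], 0)
        with pytest.raises(ValueError):
            top_k_per_seed([], 1, mode="group_fusion")


class TestBioisostericExpansion:
    def test_empty_rules_identity(self, druglike_library):
        seeds = list(druglike_library)[:3]
        assert expand_seeds_bioisosteric(seeds, []) == seeds

    def test_benzamidine_to_aminopyridine(self):
        rules = [
            r for r in load_transform_rules()
            if r.name == "carboxamidine_to_2_aminopyridine"
        ]
        seed = make_compound("NC(=N)c1ccccc1", "benzamidine")
        out = expand_seeds_bioisosteric([seed], rules)
        smiles = {c.smiles for c in out}
        assert seed.smiles in smiles
        # hand-derived rewrite: amidine replaced by 6-aminopyridin-2-yl
        assert canonical_smiles("Nc1cccc(-c2ccccc2)n1") in smiles
        product = next(c for c in out if c.id != "benzamidine")
        assert "benzamidine" in product.source

    def test_rule_matching_nothing_is_identity(self):
        rule = TransformRule(name="acid_to_tetrazole", pattern="[CX3](=O)[OX2H1]",
                             replacement="c1nnn[nH]1")
        seed = make_compound("c1ccccc1", "bz")
        assert expand_seeds_bioisosteric([seed], [rule]) == [seed]

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            TransformRule(name="bad", pattern="[[[", replacement="C")

    def test_bundled_rules_compile(self):
        rules = load_transform_rules()
        assert len(rules) >= 4


class TestDisconnectFragments:
    def test_ring_only_molecule_is_its_own_fragment(self):
        comp = make_compound("c1ccccc1", "bz")
        frags = disconnect_fragments([comp])
        assert [f.smiles for f in frags] == ["c1ccccc1"]

    def test_amide_cut_gives_capped_pieces(self):
        comp = make_compound("O=C(Nc1ccccc1)c1ccccc1", "npb")
        frags = disconnect_fragments([comp])
        # hand enumeration: cut the amide C-N, cap with H
        assert {f.smiles for f in frags} == {
            canonical_smiles("O=Cc1ccccc1"),
            canonical_smiles("Nc1ccccc1"),
        }

    def test_shared_fragment_deduplicated(self):
        a = make_compound("O=C(Nc1ccccc1)c1ccccc1", "a")
        b = make_compound("O=C(Nc1ccccc1)C1CCCCC1", "b")
        frags = disconnect_fragments([a, b])
        smiles = [f.smiles for f in frags]
        assert smiles.count(canonical_smiles("Nc1ccccc1")) == 1

    def test_small_fragments_discarded(self):
        # acetanilide: amide cut leaves acetaldehyde (2 heavy atoms) -> dropped
        comp = make_compound("CC(=O)Nc1ccccc1", "acetanilide")
        frags = disconnect_fragments([comp])
        assert {f.smiles for f in frags} == {canonical_smiles("Nc1ccccc1")}
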