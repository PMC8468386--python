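"""Two-round focused-library workflow and screening-outcome reporting.

Round one retrieves candidates around known-active seeds (fixed
threshold or the iterative tuner), merges per-seed hit lists, and
shrinks the union by an actives-learned property profile and diversity
selection. Round two re-searches around the confirmed first-round hits
under one of four strategies: a stricter plain 2D threshold with
per-seed top-k, the 2D/3D fusion score, a group-fusion merge, or
top-k-plus-diverse. Every stage logs its in/out counts so the funnel is
auditable, and re-running with identical inputs and configuration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from focuslib.chem_io import Compound, CompoundLibrary
from focuslib.diversity import maxmin_select
from focuslib.fingerprints import (
    DEFAULT_PARAMS,
    FingerprintParams,
    SimilarityRecord,
    fingerprint_library,
)
from focuslib.properties import apply_profile, learn_property_profile
from focuslib.search import (
    TunerConfig,
    group_fusion_scores,
    select_by_threshold,
    top_k_per_seed,
    tune_threshold,
)
from focuslib.shape3d import FusionConfig, embed_library, fusion_filter, t3d

STRATEGIES = ("plain_2d", "fused_2d3d", "group_fusion_merge", "topk_plus_diverse")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one selection round."""

    round: str = "first"  # "first" | "second"
    strategy: str = "plain_2d"
    t2d_round1: float = 0.65
    t2d_round2: float = 0.80
    fusion_cutoff: float = 1.5
    group_fusion_t2d: float = 0.70
    use_tuner: bool = False
    tuner: TunerConfig = TunerConfig()
    property_filter: bool = True
    coverage: float = 0.90
    diversity_k: int | None = None
    top_k: int = 10
    exclusion_list: frozenset[str] = frozenset()
    rng_seed: int = 42
    fingerprint: FingerprintParams = DEFAULT_PARAMS
    t3d_provider: str = "shape_overlap"
    t3d_params: Mapping = field(default_factory=dict)
    n_conformers: int = 5

    def __post_init__(self) -> None:
        if self.round not in ("first", "second"):
            raise ValueError(f"unknown round {self.round!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in ("t2d_round1", "t2d_round2", "group_fusion_t2d"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")

    def snapshot(self) -> dict:
        snap = asdict(self)
        snap["exclusion_list"] = sorted(self.exclusion_list)
        snap["t3d_params"] = dict(self.t3d_params)
        return snap


@dataclass(frozen=True)
class ScreeningResult:
    """One assay readout; inhibition is % at the stated concentration."""

    compound_id: str
    percent_inhibition: float
    ic50: float | None = None
    assay_tag: str = ""

    def __post_init__(self) -> None:
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError("ic50 must be positive when present")


@dataclass
class FocusedLibrary:
    """Ranked selection with per-stage audit trail."""

    members: list[SimilarityRecord]
    config_snapshot: dict
    log: list[dict] = field(default_factory=list)
    unscored: list[SimilarityRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [r.candidate_id for r in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def content_hash(self) -> str:
        """Stable hash over members, log, and config (for re-run checks)."""
        payload = json.dumps(
            {
                "members": [
                    (r.candidate_id, r.seed_id, round(r.t2d, 12),
                     None if r.t3d is None else round(r.t3d, 12), r.stage)
                    for r in self.members
                ],
                "log": self.log,
                "config": self.config_snapshot,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def _log(log: list[dict], stage: str, n_in: int, n_out: int) -> None:
    log.append({"stage": stage, "n_in": n_in, "n_out": n_out})


def _merge_dedup(
    per_seed_records: Iterable[Sequence[SimilarityRecord]],
) -> list[SimilarityRecord]:
    """Union of per-seed hit lists, keeping the best-scoring record per
    candidate (ties attribute to the id-ascending seed)."""
    best: dict[str, SimilarityRecord] = {}
    for records in per_seed_records:
        for rec in records:
            held = best.get(rec.candidate_id)
            if held is None or (rec.t2d, held.seed_id) > (held.t2d, rec.seed_id):
                best[rec.candidate_id] = rec
    out = sorted(best.values(), key=lambda r: (-r.t2d, r.candidate_id))
    return out


def _apply_common_filters(
    records: list[SimilarityRecord],
    seeds: Sequence[Compound],
    library: CompoundLibrary | Sequence[Compound],
    config: PipelineConfig,
    log: list[dict],
    warnings: list[str],
) -> list[SimilarityRecord]:
    """Exclusion list, actives-learned property filter, diversity pick."""
    compounds = {c.id: c for c in library}

    if config.exclusion_list:
        n_in = len(records)
        records = [r for r in records if r.candidate_id not in config.exclusion_list]
        _log(log, "exclusion_list", n_in, len(records))

    if config.property_filter:
        n_in = len(records)
        if len(seeds) >= 2 and records:
            profile = learn_property_profile(seeds, coverage=config.coverage)
            subset = [compounds[r.candidate_id] for r in records]
            kept_ids, _ = apply_profile(subset, profile)
            kept = set(kept_ids)
            records = [r for r in records if r.candidate_id in kept]
        else:
            warnings.append("property filter skipped: needs >= 2 seeds")
        _log(log, "property_filter", n_in, len(records))

    if config.diversity_k is not None and records:
        n_in = len(records)
        subset = [compounds[r.candidate_id] for r in records]
        picked = set(
            maxmin_select(subset, config.diversity_k, params=config.fingerprint).selected_ids
        )
        records = [r for r in records if r.candidate_id in picked]
        _log(log, "diversity", n_in, len(records))

    return records


def run_first_round(
    seeds: Sequence[Compound],
    library: CompoundLibrary,
    config: PipelineConfig = PipelineConfig(),
) -> FocusedLibrary:
    """First-round selection: per-seed similarity search, merge, filters.

    Candidates structurally identical to a seed are excluded (they are
    already known actives). An empty post-filter library is a warning,
    not an error.
    """
    log: list[dict] = []
    warnings: list[str] = []
    compounds = list(library)
    library_fps = fingerprint_library(compounds, config.fingerprint)
    seed_fps = fingerprint_library(seeds, config.fingerprint)
    seed_smiles = {s.smiles for s in seeds}

    per_seed: list[list[SimilarityRecord]] = []
    for seed, sfp in zip(seeds, seed_fps):
        if config.use_tuner:
            result = tune_threshold(
                seed, compounds, config.tuner,
                params=config.fingerprint, seed_fp=sfp, library_fps=library_fps,
            )
            per_seed.append(result.records)
        else:
            per_seed.append(
                select_by_threshold(
                    seed, compounds, config.t2d_round1,
                    params=config.fingerprint, seed_fp=sfp, library_fps=library_fps,
                    stage="first_round:threshold",
                )
            )
    merged = _merge_dedup(per_seed)
    _log(log, "similarity_search", len(compounds), len(merged))

    n_in = len(merged)
    by_id = {c.id: c for c in compounds}
    merged = [r for r in merged if by_id[r.candidate_id].smiles not in seed_smiles]
    _log(log, "drop_seed_duplicates", n_in, len(merged))

    merged = _apply_common_filters(merged, seeds, compounds, config, log, warnings)
    if not merged:
        warnings.append("first round produced an empty library")
    return FocusedLibrary(
        members=merged, config_snapshot=config.snapshot(), log=log, warnings=warnings
    )


def run_second_round(
    first_round_hits: Sequence[Compound],
    library: CompoundLibrary,
    config: PipelineConfig,
) -> FocusedLibrary:
    """Second-round (hit validation/expansion) selection.

    Strategy dispatch; the stage tag of every record marks which branch
    admitted it.
    """
    if not first_round_hits:
        raise ValueError("second round requires at least one first-round hit")
    log: list[dict] = []
    warnings: list[str] = []
    compounds = list(library)
    by_id = {c.id: c for c in compounds}
    hit_smiles = {h.smiles for h in first_round_hits}
    library_fps = fingerprint_library(compounds, config.fingerprint)
    hit_fps = fingerprint_library(first_round_hits, config.fingerprint)

    def search(threshold: float, stage: str) -> list[SimilarityRecord]:
        per_seed = [
            select_by_threshold(
                hit, compounds, threshold,
                params=config.fingerprint, seed_fp=hfp, library_fps=library_fps,
                stage=stage,
            )
            for hit, hfp in zip(first_round_hits, hit_fps)
        ]
        merged = _merge_dedup(per_seed)
        merged = [r for r in merged if by_id[r.candidate_id].smiles not in hit_smiles]
        return merged

    if config.strategy == "plain_2d":
        merged = search(config.t2d_round2, "second_round:plain_2d")
        _log(log, "similarity_search", len(compounds), len(merged))
        n_in = len(merged)
        members = top_k_per_seed(merged, config.top_k, mode="most_similar")
        _log(log, "top_k_per_seed", n_in, len(members))
        members = _apply_common_filters(
            members, first_round_hits, compounds, config, log, warnings
        )
        unscored: list[SimilarityRecord] = []

    elif config.strategy == "fused_2d3d":
        merged = search(config.t2d_round1, "second_round:fused")
        _log(log, "similarity_search", len(compounds), len(merged))
        if config.property_filter and len(first_round_hits) >= 2 and merged:
            n_in = len(merged)
            profile = learn_property_profile(first_round_hits, coverage=config.coverage)
            kept_ids, _ = apply_profile(
                [by_id[r.candidate_id] for r in merged], profile
            )
            kept = set(kept_ids)
            merged = [r for r in merged if r.candidate_id in kept]
            _log(log, "property_filter", n_in, len(merged))
        # 3D stage: conformers for the surviving candidates and their seeds
        n_in = len(merged)
        needed = sorted({r.candidate_id for r in merged})
        conf_sets, failed = embed_library(
            [by_id[cid] for cid in needed],
            n=config.n_conformers, rng_seed=config.rng_seed,
        )
        seed_confs, seed_failed = embed_library(
            list(first_round_hits), n=config.n_conformers, rng_seed=config.rng_seed
        )
        scored: list[SimilarityRecord] = []
        for rec in merged:
            cs, ss = conf_sets.get(rec.candidate_id), seed_confs.get(rec.seed_id)
            if cs is None or ss is None:
                scored.append(rec)  # t3d stays absent -> routed to unscored
            else:
                score = t3d(cs, ss, provider=config.t3d_provider, params=config.t3d_params)
                scored.append(replace(rec, t3d=score))
        members, unscored = fusion_filter(
            scored, FusionConfig(cutoff=config.fusion_cutoff,
                                 t3d_provider=config.t3d_provider,
                                 t3d_params=dict(config.t3d_params))
        )
        _log(log, "fusion_filter", n_in, len(members))
        if failed or seed_failed:
            warnings.append(f"embedding failed for {len(failed) + len(seed_failed)} structure(s)")
        if config.diversity_k is not None and members:
            n_in = len(members)
            picked = set(
                maxmin_select(
                    [by_id[r.candidate_id] for r in members],
                    config.diversity_k, params=config.fingerprint,
                ).selected_ids
            )
            members = [r for r in members if r.candidate_id in picked]
            _log(log, "diversity", n_in, len(members))

    elif config.strategy == "group_fusion_merge":
        base = search(config.group_fusion_t2d, "second_round:group_fusion")
        _log(log, "similarity_search", len(compounds), len(base))
        # branch A: most-similar top-k per seed, no property filter
        branch_a = top_k_per_seed(
            [replace(r, stage="gf_most_similar") for r in base],
            config.top_k, mode="most_similar",
        )
        # branch B: property-filtered set, ranked by group fusion score
        filtered = base
        if config.property_filter and len(first_round_hits) >= 2 and base:
            profile = learn_property_profile(first_round_hits, coverage=config.coverage)
            kept_ids, _ = apply_profile(
                [by_id[r.candidate_id] for r in base], profile
            )
            kept = set(kept_ids)
            filtered = [r for r in base if r.candidate_id in kept]
        gf_ids = sorted({r.candidate_id for r in filtered})
        gf_subset = [by_id[cid] for cid in gf_ids]
        gf_scores = dict(
            group_fusion_scores(
                gf_subset, list(first_round_hits),
                params=config.fingerprint, reference_fps=hit_fps,
            )
        )
        branch_b = top_k_per_seed(
            [replace(r, stage="gf_group_fusion") for r in filtered],
            config.top_k, mode="group_fusion", group_scores=gf_scores,
        )
        _log(log, "branch_most_similar", len(base), len(branch_a))
        _log(log, "branch_group_fusion", len(filtered), len(branch_b))
        # merge, removing overlaps; branch A record wins on a shared candidate
        best: dict[str, SimilarityRecord] = {}
        for rec in branch_b + branch_a:
            best[rec.candidate_id] = rec
        members = sorted(best.values(), key=lambda r: (-r.t2d, r.candidate_id))
        _log(log, "merge_dedup", len(branch_a) + len(branch_b), len(members))
        unscored = []

    else:  # topk_plus_diverse
        merged = search(config.t2d_round2, "second_round:topk_plus_diverse")
        _log(log, "similarity_search", len(compounds), len(merged))
        topk = top_k_per_seed(
            [replace(r, stage="topk") for r in merged], config.top_k, mode="most_similar"
        )
        diverse: list[SimilarityRecord] = []
        if merged:
            picked = maxmin_select(
                [by_id[r.candidate_id] for r in merged],
                config.top_k, params=config.fingerprint,
            ).selected_ids
            picked_set = set(picked)
            diverse = [
                replace(r, stage="diverse") for r in merged if r.candidate_id in picked_set
            ]
        best = {}
        for rec in diverse + topk:  # top-k provenance wins on overlap
            best[rec.candidate_id] = rec
        members = sorted(best.values(), key=lambda r: (-r.t2d, r.candidate_id))
        _log(log, "topk_plus_diverse_merge", len(topk) + len(diverse), len(members))
        unscored = []

    if not members:
        warnings.append("second round produced an empty library")
    return FocusedLibrary(
        members=members,
        config_snapshot=config.snapshot(),
        log=log,
        unscored=unscored,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# hit-rate arithmetic and enrichment reporting
# ---------------------------------------------------------------------------

def hit_rate(n_hits: int, n_tested: int, convention: str = "truncate_1dp") -> float:
    """Hit rate as a percentage, 100 * n_hits / n_tested.

    Conventions: ``truncate_1dp`` drops digits past the first decimal
    (21.15 -> 21.1), ``round_int`` rounds to the nearest integer, and
    ``exact`` returns full precision.
    """
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if not 0 <= n_hits <= n_tested:
        raise ValueError("need 0 <= n_hits <= n_tested")
    rate = 100.0 * n_hits / n_tested
    if convention == "truncate_1dp":
        return math.floor(rate * 10.0 + 1e-9) / 10.0
    if convention == "round_int":
        return float(math.floor(rate + 0.5))
    if convention == "exact":
        return rate
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class HitCriterion:
    """An activity cut, e.g. inhibition >= 50 % at the assay concentration."""

    name: str
    field: str  # "percent_inhibition" | "ic50"
    comparator: str  # "<", "<=", ">", ">="
    limit: float

    def __post_init__(self) -> None:
        if self.field not in ("percent_inhibition", "ic50"):
            raise ValueError(f"unknown readout field {self.field!r}")
        if self.comparator not in ("<", "<=", ">", ">="):
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def passes(self, value: float) -> bool:
        return {
            "<": value < self.limit,
            "<=": value <= self.limit,
            ">": value > self.limit,
            ">=": value >= self.limit,
        }[self.comparator]


def _screen_frame(results: Sequence[ScreeningResult] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        frame = pd.DataFrame([asdict(r) for r in results])
    if "compound_id" not in frame.columns or "percent_inhibition" not in frame.columns:
        raise ValueError("screening results need compound_id and percent_inhibition")
    if "ic50" not in frame.columns:
        frame["ic50"] = np.nan
    return frame.set_index("compound_id")


@dataclass
class EnrichmentReport:
    per_criterion: dict[str, dict]
    missing_ids: list[str]
    n_selected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.per_criterion, orient="index")

    def to_text(self) -> str:
        lines = [f"selection size: {self.n_selected}"]
        if self.missing_ids:
            lines.append(f"missing screening data for {len(self.missing_ids)} compound(s)")
        for name, row in self.per_criterion.items():
            lines.append(
                f"{name}: {row['n_hits']}/{row['n_evaluable']} hits, "
                f"hit rate {row['hit_rate_truncate_1dp']}% "
                f"(exact {row['hit_rate_exact']:.2f}%), "
                f"fold enrichment {row['fold_enrichment']:.2f}"
                if row["fold_enrichment"] is not None
                else f"{name}: {row['n_hits']}/{row['n_evaluable']} hits"
            )
        return "\n".join(lines)


def enrichment_report(
    selection_ids: Sequence[str],
    screening_results: Sequence[ScreeningResult] | pd.DataFrame,
    hit_criteria: Sequence[HitCriterion],
) -> EnrichmentReport:
    """Hit counts/rates per criterion for a selection, with the
    fold-enrichment over a random selection of equal size.

    The random baseline is the expectation over uniform draws: the
    criterion's hit rate across the whole screened table. Compounds in
    the selection without screening data are reported as missing, not
    silently treated as inactive. A criterion referencing a readout
    absent from the table (e.g. IC50 never measured) is an error.
    """
    frame = _screen_frame(screening_results)
    selection = list(dict.fromkeys(selection_ids))
    missing = [cid for cid in selection if cid not in frame.index]
    present = [cid for cid in selection if cid in frame.index]

    per_criterion: dict[str, dict] = {}
    for crit in hit_criteria:
        col = frame[crit.field]
        if col.isna().all():
            raise ValueError(
                f"criterion {crit.name!r} references readout {crit.field!r} "
                "with no measured values"
            )
        sel_values = col.loc[present].dropna()
        n_hits = int(sel_values.map(crit.passes).sum())
        n_eval = int(len(sel_values))
        all_values = col.dropna()
        baseline = float(all_values.map(crit.passes).mean()) * 100.0
        per_criterion[crit.name] = {
            "n_hits": n_hits,
            "n_evaluable": n_eval,
            "hit_rate_truncate_1dp": hit_rate(n_hits, n_eval, "truncate_1dp") if n_eval else None,
            "hit_rate_round_int": hit_rate(n_hits, n_eval, "round_int") if n_eval else None,
            "hit_rate_exact": hit_rate(n_hits, n_eval, "exact") if n_eval else None,
            "baseline_rate_exact": baseline,
            "fold_enrichment": (
                (hit_rate(n_hits, n_eval, "exact") / baseline)
                if n_eval and baseline > 0
                else None
            ),
        }
    return EnrichmentReport(
        per_criterion=per_criterion, missing_ids=missing, n_selected=len(selection)
    )
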