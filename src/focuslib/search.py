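"""Seed-driven selection strategies.

Covers the core selection logic of a two-round similarity campaign:
fixed-threshold retrieval, the iterative threshold tuner that walks the
Tanimoto cut-off until a per-seed hit list of practical size (50-500 by
default) is reached, group-fusion ranking against multiple references,
per-seed top-k union, bioisosteric seed expansion via SMARTS rewrites,
and rule-based fragment disconnection of known actives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from focuslib.chem_io import Compound, CompoundLibrary
from focuslib.fingerprints import (
    DEFAULT_PARAMS,
    Fingerprint,
    FingerprintParams,
    SimilarityRecord,
    bulk_similarity,
    compute_fingerprint,
    fingerprint_library,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thresholded selection
# ---------------------------------------------------------------------------

def select_by_threshold(
    seed: Compound,
    library: CompoundLibrary | Sequence[Compound],
    threshold: float,
    *,
    params: FingerprintParams = DEFAULT_PARAMS,
    seed_fp: Fingerprint | None = None,
    library_fps: Sequence[Fingerprint] | None = None,
    stage: str = "threshold",
) -> list[SimilarityRecord]:
    """All candidates with T2D >= threshold, sorted by (T2D desc, id asc).

    Fingerprints may be passed in to amortize their cost across seeds.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    compounds = list(library)
    if not compounds:
        return []
    if seed_fp is None:
        seed_fp = compute_fingerprint(seed, params)
    if library_fps is None:
        library_fps = fingerprint_library(compounds, params)
    sims = bulk_similarity(seed_fp, library_fps)
    records = [
        SimilarityRecord(
            candidate_id=c.id,
            seed_id=seed.id,
            t2d=float(s),
            stage=stage,
            candidate_smiles=c.smiles,
        )
        for c, s in zip(compounds, sims)
        if s >= threshold
    ]
    records.sort(key=lambda r: (-r.t2d, r.candidate_id))
    return records


# ---------------------------------------------------------------------------
# iterative threshold tuner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TunerConfig:
    """Controls the iterative threshold search.

    The threshold starts at ``start_threshold`` and is stepped by
    ``coarse_step`` (relative by default: t <- t*(1±step)) until the
    hit count lands in [window_min, window_max]; on the first direction
    reversal the step narrows to ``fine_step``. The threshold never
    drops below ``floor``.
    """

    start_threshold: float = 0.75
    window_min: int = 50
    window_max: int = 500
    coarse_step: float = 0.05
    fine_step: float = 0.025
    floor: float = 0.60
    max_iterations: int = 50
    relative_steps: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.floor <= self.start_threshold <= 1.0:
            raise ValueError("need 0 < floor <= start_threshold <= 1")
        if not self.window_min < self.window_max:
            raise ValueError("need window_min < window_max")
        if not 0.0 < self.fine_step < self.coarse_step < 1.0:
            raise ValueError("need 0 < fine_step < coarse_step < 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class TunerResult:
    seed_id: str
    final_threshold: float
    hit_count: int
    status: str  # in_window | floor_reached | max_iter
    trajectory: list[tuple[float, int]]
    records: list[SimilarityRecord] = field(default_factory=list)


def tune_threshold(
    seed: Compound,
    library: CompoundLibrary | Sequence[Compound],
    config: TunerConfig = TunerConfig(),
    *,
    params: FingerprintParams = DEFAULT_PARAMS,
    seed_fp: Fingerprint | None = None,
    library_fps: Sequence[Fingerprint] | None = None,
) -> TunerResult:
    """Walk the similarity threshold until the hit count is in-window.

    Too few hits lowers the threshold, too many raises it; the step
    switches from coarse to fine on the first reversal so the walk
    cannot cycle between the same two coarse thresholds indefinitely.
    The hit set at the final threshold is returned with the result.
    """
    compounds = list(library)
    if not compounds:
        raise ValueError("tune_threshold requires a non-empty library")
    if seed_fp is None:
        seed_fp = compute_fingerprint(seed, params)
    if library_fps is None:
        library_fps = fingerprint_library(compounds, params)
    sims = bulk_similarity(seed_fp, library_fps)

    def count_at(t: float) -> int:
        return int(np.count_nonzero(sims >= t))

    t = config.start_threshold
    step = config.coarse_step
    prev_direction = 0  # -1 lowered, +1 raised
    fine_engaged = False
    trajectory: list[tuple[float, int]] = []
    status = "max_iter"
    for _ in range(config.max_iterations):
        count = count_at(t)
        trajectory.append((t, count))
        if config.window_min <= count <= config.window_max:
            status = "in_window"
            break
        if count < config.window_min:
            if t <= config.floor:
                status = "floor_reached"
                break
            direction = -1
        else:
            if t >= 1.0:
                # cannot raise further; counting again changes nothing
                status = "max_iter"
                break
            direction = +1
        if prev_direction != 0 and direction != prev_direction and not fine_engaged:
            fine_engaged = True
            step = config.fine_step
        prev_direction = direction
        if config.relative_steps:
            t = t * (1.0 + direction * step)
        else:
            t = t + direction * step
        t = min(1.0, max(config.floor, t))

    final_t, final_count = trajectory[-1]
    records = [
        SimilarityRecord(
            candidate_id=c.id,
            seed_id=seed.id,
            t2d=float(s),
            stage="tuned_threshold",
            candidate_smiles=c.smiles,
        )
        for c, s in zip(compounds, sims)
        if s >= final_t
    ]
    records.sort(key=lambda r: (-r.t2d, r.candidate_id))
    return TunerResult(
        seed_id=seed.id,
        final_threshold=final_t,
        hit_count=final_count,
        status=status,
        trajectory=trajectory,
        records=records,
    )


# ---------------------------------------------------------------------------
# group fusion
# ---------------------------------------------------------------------------

def group_fusion_scores(
    library: CompoundLibrary | Sequence[Compound],
    references: Sequence[Compound],
    *,
    params: FingerprintParams = DEFAULT_PARAMS,
    library_fps: Sequence[Fingerprint] | None = None,
    reference_fps: Sequence[Fingerprint] | None = None,
) -> list[tuple[str, float]]:
    """Rank candidates by the sum of their Tanimoto similarities to all
    reference compounds (group fusion), descending; ties by id.
    """
    if not references:
        raise ValueError("group fusion requires at least one reference")
    compounds = list(library)
    if library_fps is None:
        library_fps = fingerprint_library(compounds, params)
    if reference_fps is None:
        reference_fps = fingerprint_library(references, params)
    fused = np.zeros(len(compounds), dtype=float)
    for rfp in reference_fps:
        fused += bulk_similarity(rfp, library_fps)
    ranked = sorted(
        zip((c.id for c in compounds), fused.tolist()),
        key=lambda pair: (-pair[1], pair[0]),
    )
    return ranked


def top_k_per_seed(
    records: Iterable[SimilarityRecord],
    k: int,
    mode: str = "most_similar",
    group_scores: Mapping[str, float] | None = None,
) -> list[SimilarityRecord]:
    """Per seed, the k best records; union deduplicated by candidate.

    ``most_similar`` ranks by T2D; ``group_fusion`` ranks by an external
    fused-score mapping (candidate_id -> score). When two seeds share a
    candidate, the record with the higher key survives the merge.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("most_similar", "group_fusion"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "group_fusion" and group_scores is None:
        raise ValueError("group_fusion mode requires group_scores")

    def key(rec: SimilarityRecord) -> float:
        if mode == "most_similar":
            return rec.t2d
        return float(group_scores[rec.candidate_id])

    by_seed: dict[str, list[SimilarityRecord]] = {}
    for rec in records:
        by_seed.setdefault(rec.seed_id, []).append(rec)

    best: dict[str, SimilarityRecord] = {}
    for seed_id in sorted(by_seed):
        ranked = sorted(by_seed[seed_id], key=lambda r: (-key(r), r.candidate_id))
        for rec in ranked[:k]:
            held = best.get(rec.candidate_id)
            if held is None or (key(rec), held.seed_id) > (key(held), rec.seed_id):
                best[rec.candidate_id] = rec
    merged = sorted(best.values(), key=lambda r: (-key(r), r.candidate_id))
    return merged


# ---------------------------------------------------------------------------
# bioisosteric seed expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformRule:
    """A substructure rewrite: SMARTS pattern -> replacement fragment.

    ``replacement`` is a SMILES fragment; its first atom bonds to the
    atoms that were attached to the matched substructure. Bidirectional
    rules are additionally applied in reverse (replacement matched as a
    query, pattern used as the fragment), which is only meaningful for
    rules whose two sides are both valid as queries.
    """

    name: str
    pattern: str
    replacement: str
    bidirectional: bool = False

    def __post_init__(self) -> None:
        if Chem.MolFromSmarts(self.pattern) is None:
            raise ValueError(f"rule {self.name!r}: pattern does not compile")
        if Chem.MolFromSmiles(self.replacement) is None:
            raise ValueError(f"rule {self.name!r}: replacement does not parse")


def load_transform_rules(path: str | Path | None = None) -> list[TransformRule]:
    """Load rewrite rules from YAML; ``None`` loads the bundled
    bioisostere table (literature-common replacement pairs)."""
    if path is None:
        text = resources.files("focuslib.data").joinpath("bioisosteres.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError("transform rule file must be a YAML list of rules")
    rules = []
    for entry in raw:
        try:
            rules.append(
                TransformRule(
                    name=entry["name"],
                    pattern=entry["pattern"],
                    replacement=entry["replacement"],
                    bidirectional=bool(entry.get("bidirectional", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid transform rule entry {entry!r}: {exc}") from exc
    return rules


def _apply_rewrite(mol: Chem.Mol, query: Chem.Mol, fragment: Chem.Mol) -> list[str]:
    """Canonical SMILES of all sanitizable single-site rewrite products."""
    products: list[str] = []
    try:
        outs = AllChem.ReplaceSubstructs(mol, query, fragment)
    except Exception:  # noqa: BLE001 - rewrite failures are skipped, not fatal
        return products
    for out in outs:
        try:
            Chem.SanitizeMol(out)
        except Exception:  # noqa: BLE001
            continue
        smi = Chem.MolToSmiles(out)
        if "." not in smi:  # rewrites must not disconnect the molecule
            products.append(smi)
    return products


def expand_seeds_bioisosteric(
    seeds: Sequence[Compound], rules: Sequence[TransformRule]
) -> list[Compound]:
    """Apply every matching rewrite rule to every seed.

    Originals are retained; each product is canonicalized, deduplicated
    against the originals and other products, and tagged with the
    parent seed id and rule name. Rewrites that yield invalid molecules
    are skipped with a log entry.
    """
    out: list[Compound] = list(seeds)
    seen = {s.smiles for s in seeds}
    for seed in seeds:
        mol = seed.mol()
        for rule in rules:
            pairs = [(Chem.MolFromSmarts(rule.pattern), Chem.MolFromSmiles(rule.replacement))]
            if rule.bidirectional:
                rev_q = Chem.MolFromSmarts(rule.replacement)
                rev_f = Chem.MolFromSmiles(rule.pattern)
                if rev_q is not None and rev_f is not None:
                    pairs.append((rev_q, rev_f))
            n_products = 0
            for query, fragment in pairs:
                if fragment is None:
                    continue
                for smi in _apply_rewrite(mol, query, fragment):
                    if smi in seen:
                        continue
                    seen.add(smi)
                    n_products += 1
                    out.append(
                        Compound(
                            id=f"{seed.id}::{rule.name}::{n_products}",
                            smiles=smi,
                            raw_smiles=smi,
                            source=f"bioisostere:{rule.name}<-{seed.id}",
                        )
                    )
            if n_products:
                logger.info("rule %s on %s: %d product(s)", rule.name, seed.id, n_products)
    return out


# ---------------------------------------------------------------------------
# fragment disconnection
# ---------------------------------------------------------------------------

#: default cut chemistry: acyclic bonds joining two ring systems, amide
#: C-N, ester C-O. The bond broken is the one between map atoms 1 and 2.
DEFAULT_CUT_SMARTS = (
    "[R:1]-!@[R:2]",
    "[CX3:1](=O)-!@[NX3:2]",
    "[CX3:1](=O)-!@[OX2:2][#6]",
)


def load_cut_rules(path: str | Path | None = None) -> list[str]:
    """Cut-rule SMARTS list from YAML; ``None`` gives the defaults."""
    if path is None:
        return list(DEFAULT_CUT_SMARTS)
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list) or not all(isinstance(s, str) for s in raw):
        raise ValueError("cut rule file must be a YAML list of SMARTS strings")
    return raw


def _matching_bonds(mol: Chem.Mol, cut_smarts: Sequence[str]) -> list[int]:
    bonds: set[int] = set()
    for smarts in cut_smarts:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"cut SMARTS does not compile: {smarts!r}")
        mapno_to_qidx = {
            a.GetAtomMapNum(): a.GetIdx() for a in patt.GetAtoms() if a.GetAtomMapNum()
        }
        if set(mapno_to_qidx) != {1, 2}:
            raise ValueError(f"cut SMARTS must map exactly atoms :1 and :2: {smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(
                match[mapno_to_qidx[1]], match[mapno_to_qidx[2]]
            )
            if bond is not None and not bond.IsInRing():
                bonds.add(bond.GetIdx())
    return sorted(bonds)


def disconnect_fragments(
    compounds: Sequence[Compound],
    cut_smarts: Sequence[str] = DEFAULT_CUT_SMARTS,
    min_heavy_atoms: int = 4,
) -> list[Compound]:
    """Cut each compound at all bonds matching the cut rules.

    Open valences are capped with hydrogen. Fragments with fewer than
    ``min_heavy_atoms`` heavy atoms are discarded, and fragments are
    deduplicated by canonical SMILES across all inputs (first-seen
    provenance kept). A molecule with no matching bonds is its own sole
    fragment.
    """
    out: list[Compound] = []
    seen: set[str] = set()
    n = 0
    for comp in compounds:
        mol = comp.mol()
        bonds = _matching_bonds(mol, cut_smarts)
        if bonds:
            cut = Chem.FragmentOnBonds(mol, bonds, addDummies=True)
            # cap open valences: dummies -> explicit H, then strip
            edit = Chem.RWMol(cut)
            for atom in edit.GetAtoms():
                if atom.GetAtomicNum() == 0:
                    atom.SetAtomicNum(1)
                    atom.SetIsotope(0)
            capped = edit.GetMol()
            Chem.SanitizeMol(capped)
            frags = Chem.GetMolFrags(Chem.RemoveHs(capped), asMols=True)
        else:
            frags = [mol]
        for frag in frags:
            if frag.GetNumHeavyAtoms() < min_heavy_atoms:
                continue
            smi = Chem.MolToSmiles(frag)
            if smi in seen:
                continue
            seen.add(smi)
            n += 1
            out.append(
                Compound(
                    id=f"F{n}",
                    smiles=smi,
                    raw_smiles=smi,
                    source=f"fragment<-{comp.id}",
                )
            )
    return out
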