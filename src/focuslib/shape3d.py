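"""Pluggable 3D similarity (T3D) and the 2D/3D fusion score.

The fusion score adds the 2D fingerprint Tanimoto (T2D) and a 3D
similarity (T3D) in [0, 1] and keeps candidates with T2D + T3D above a
cut-off (default 1.5), weighting both views equally.

T3D is produced by a registered provider so scoring engines can be
swapped without touching the pipeline. The default ``shape_overlap``
provider computes an analytic Gaussian shape-overlap Tanimoto: heavy
atoms are spherical Gaussians, each conformer is placed in its own
canonical inertial frame (centered, principal axes ordered by variance,
signs fixed by the third moment), and the best overlap over all
conformer pairs is reported. Placing each molecule in its own canonical
frame makes the score exactly symmetric; the price is that the
alignment is rigid and moment-based, not a flexible superposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from focuslib.chem_io import Compound
from focuslib.fingerprints import SimilarityRecord

logger = logging.getLogger(__name__)

#: Gaussian width for atom spheres (1/Angstrom^2); ~carbon vdW scale.
GAUSSIAN_ALPHA = 0.6


class EmbeddingError(RuntimeError):
    """Raised when 3D embedding fails for a compound."""


@dataclass
class ConformerSet:
    """Heavy-atom 3D coordinates (Angstrom) for one compound."""

    compound_id: str
    coordinates: list[np.ndarray]  # each (n_heavy, 3)
    method: str = "etkdg"
    rng_seed: int = 42
    minimized: bool = True

    def __post_init__(self) -> None:
        if not self.coordinates:
            raise ValueError("ConformerSet requires at least one conformer")
        n = self.coordinates[0].shape[0]
        for c in self.coordinates:
            if c.ndim != 2 or c.shape != (n, 3):
                raise ValueError("conformers must share an (n_heavy, 3) shape")

    @property
    def n_conformers(self) -> int:
        return len(self.coordinates)


def embed_conformers(
    compound: Compound | str,
    n: int = 10,
    rng_seed: int = 42,
    minimize: bool = True,
    max_embed_iterations: int = 0,
) -> ConformerSet:
    """Generate up to ``n`` 3D conformers (ETKDG), deterministically.

    Raises :class:`EmbeddingError` when no conformer can be embedded;
    batch callers should catch it per compound (see
    :func:`embed_library`).
    """
    if isinstance(compound, str):
        compound = Compound(id="", smiles=compound)
    mol = Chem.AddHs(compound.mol())
    params = AllChem.ETKDGv3()
    params.randomSeed = int(rng_seed)
    if max_embed_iterations:
        params.maxIterations = int(max_embed_iterations)
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params)
    if not conf_ids:
        raise EmbeddingError(f"embedding failed for {compound.id!r}")
    if minimize:
        try:
            AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=200)
        except Exception:  # noqa: BLE001 - fall back to unminimized geometry
            logger.warning("MMFF minimization failed for %r", compound.id)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    coords = [
        np.array(mol.GetConformer(cid).GetPositions())[heavy] for cid in conf_ids
    ]
    return ConformerSet(
        compound_id=compound.id,
        coordinates=coords,
        rng_seed=rng_seed,
        minimized=minimize,
    )


def embed_library(
    compounds: Sequence[Compound],
    n: int = 10,
    rng_seed: int = 42,
    minimize: bool = True,
) -> tuple[dict[str, ConformerSet], list[str]]:
    """Embed a batch; returns (id -> conformers, ids that failed)."""
    out: dict[str, ConformerSet] = {}
    failed: list[str] = []
    for comp in compounds:
        try:
            out[comp.id] = embed_conformers(comp, n=n, rng_seed=rng_seed, minimize=minimize)
        except EmbeddingError:
            failed.append(comp.id)
            logger.warning("skipping unembeddable compound %r", comp.id)
    return out, failed


# ---------------------------------------------------------------------------
# default provider: canonical-frame Gaussian shape overlap
# ---------------------------------------------------------------------------

def canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Place a point set in its canonical inertial frame.

    Centered at the centroid; axes are principal components ordered by
    decreasing variance; the sign of the first two axes is fixed so the
    third moment of the projections is non-negative, and the third axis
    completes a right-handed system. Deterministic for fixed input.
    """
    x = np.asarray(coords, dtype=float)
    x = x - x.mean(axis=0)
    if x.shape[0] == 1:
        return x
    cov = x.T @ x / x.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)
    axes = eigvec[:, ::-1].T  # rows, by decreasing variance
    for i in range(2):
        proj = x @ axes[i]
        skew = float(np.sum(proj**3))
        if skew < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return x @ axes.T


def gaussian_overlap_volume(a: np.ndarray, b: np.ndarray, alpha: float = GAUSSIAN_ALPHA) -> float:
    """Analytic overlap of two sets of identical spherical Gaussians.

    V_AB = (pi/(2 alpha))^{3/2} * sum_ij exp(-(alpha/2) d_ij^2).
    """
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    prefactor = (np.pi / (2.0 * alpha)) ** 1.5
    return float(prefactor * np.exp(-(alpha / 2.0) * d2).sum())


def _shape_overlap_provider(a: ConformerSet, b: ConformerSet, params: Mapping) -> float:
    alpha = float(params.get("alpha", GAUSSIAN_ALPHA))
    best = 0.0
    frames_a = [canonical_frame(c) for c in a.coordinates]
    frames_b = [canonical_frame(c) for c in b.coordinates]
    for fa in frames_a:
        vaa = gaussian_overlap_volume(fa, fa, alpha)
        for fb in frames_b:
            vbb = gaussian_overlap_volume(fb, fb, alpha)
            vab = gaussian_overlap_volume(fa, fb, alpha)
            tan = vab / (vaa + vbb - vab)
            best = max(best, tan)
    return min(1.0, max(0.0, best))


_PROVIDERS: dict[str, Callable[[ConformerSet, ConformerSet, Mapping], float]] = {}


def register_t3d_provider(
    name: str, fn: Callable[[ConformerSet, ConformerSet, Mapping], float]
) -> None:
    """Register a T3D provider under ``name``.

    Contract: symmetric in its two arguments, scores in [0, 1], and
    self-score 1 (within 1e-6) for identical conformer sets.
    """
    _PROVIDERS[name] = fn


register_t3d_provider("shape_overlap", _shape_overlap_provider)


def t3d(
    a: ConformerSet,
    b: ConformerSet,
    provider: str = "shape_overlap",
    params: Mapping | None = None,
) -> float:
    """3D similarity between two conformer sets via a named provider."""
    fn = _PROVIDERS.get(provider)
    if fn is None:
        raise ValueError(
            f"unknown t3d provider {provider!r}; registered: {sorted(_PROVIDERS)}"
        )
    score = float(fn(a, b, params or {}))
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"provider {provider!r} returned out-of-range score {score}")
    return score


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

#: cut-off guidance by campaign round: a loose 3D bar for first-round
#: discovery, stricter for second-round hit validation.
T3D_PRESETS = {"t3d_round1": 0.3, "t3d_round2": 0.5}


@dataclass(frozen=True)
class FusionConfig:
    cutoff: float = 1.5
    t3d_provider: str = "shape_overlap"
    t3d_params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 2.0:
            raise ValueError("fusion cutoff must be in [0, 2] (sum of two unit scores)")


def fusion_score(t2d_score: float, t3d_score: float) -> float:
    """Combined score T2D + T3D (both must lie in [0, 1])."""
    if not 0.0 <= t2d_score <= 1.0:
        raise ValueError(f"t2d out of [0,1]: {t2d_score}")
    if not 0.0 <= t3d_score <= 1.0:
        raise ValueError(f"t3d out of [0,1]: {t3d_score}")
    return t2d_score + t3d_score


def fusion_filter(
    records: Sequence[SimilarityRecord], config: FusionConfig = FusionConfig()
) -> tuple[list[SimilarityRecord], list[SimilarityRecord]]:
    """Keep records with T2D + T3D >= cutoff.

    Returns (kept sorted by fusion desc then id, unscored). Records
    without a T3D (e.g. embedding failures) go to the unscored list
    rather than being silently dropped.
    """
    kept: list[SimilarityRecord] = []
    unscored: list[SimilarityRecord] = []
    for rec in records:
        if rec.t3d is None:
            unscored.append(rec)
        elif fusion_score(rec.t2d, rec.t3d) >= config.cutoff:
            kept.append(rec)
    kept.sort(key=lambda r: (-(r.fusion or 0.0), r.candidate_id))
    return kept, unscored
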