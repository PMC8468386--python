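"""2D fingerprints and Tanimoto similarity (T2D).

Default fingerprint is a folded binary circular fingerprint of radius 2
on 2048 bits (ECFP4-like), the modern default for connectivity-based
similarity searching; thresholds calibrated on hashed connectivity
fingerprints transfer across this family. Scores from different
fingerprint parameterizations are not comparable, so every pairwise
operation checks that the parameters match.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from focuslib.chem_io import Compound

logger = logging.getLogger(__name__)

STAGE_UNSET = "unset"


@dataclass(frozen=True)
class FingerprintParams:
    """Generation parameters; part of every fingerprint's identity."""

    kind: str = "circular"  # "circular" (Morgan) or "path_hashed" (RDKit path)
    radius_or_pathlen: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.kind not in ("circular", "path_hashed"):
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.n_bits <= 0 or self.radius_or_pathlen < 0:
            raise ValueError("invalid fingerprint parameters")


DEFAULT_PARAMS = FingerprintParams()

_GENERATORS: dict[FingerprintParams, object] = {}


def _generator(params: FingerprintParams):
    gen = _GENERATORS.get(params)
    if gen is None:
        if params.kind == "circular":
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=params.radius_or_pathlen, fpSize=params.n_bits
            )
        else:
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(
                maxPath=params.radius_or_pathlen, fpSize=params.n_bits
            )
        _GENERATORS[params] = gen
    return gen


@dataclass(frozen=True)
class Fingerprint:
    """Binary feature set: on-bit indices plus generation parameters."""

    bits: frozenset[int]
    params: FingerprintParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.params.n_bits for b in self.bits):
            raise ValueError("bit index outside [0, n_bits)")

    def to_bitvect(self) -> DataStructs.ExplicitBitVect:
        bv = DataStructs.ExplicitBitVect(self.params.n_bits)
        for b in self.bits:
            bv.SetBit(int(b))
        return bv


@dataclass(frozen=True)
class SimilarityRecord:
    """A scored (candidate, seed) pair with selection-stage provenance."""

    candidate_id: str
    seed_id: str
    t2d: float
    t3d: float | None = None
    stage: str = STAGE_UNSET
    candidate_smiles: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.t2d <= 1.0:
            raise ValueError(f"t2d out of [0,1]: {self.t2d}")
        if self.t3d is not None and not 0.0 <= self.t3d <= 1.0:
            raise ValueError(f"t3d out of [0,1]: {self.t3d}")

    @property
    def fusion(self) -> float | None:
        return None if self.t3d is None else self.t2d + self.t3d


def compute_fingerprint(
    compound: Compound | str, params: FingerprintParams = DEFAULT_PARAMS
) -> Fingerprint:
    """Fingerprint a compound (or SMILES string) under ``params``.

    Deterministic: the same canonical SMILES and parameters always give
    the same bit set.
    """
    if isinstance(compound, str):
        compound = Compound(id="", smiles=compound)
    bv = _generator(params).GetFingerprint(compound.mol())
    return Fingerprint(bits=frozenset(bv.GetOnBits()), params=params)


def fingerprint_library(
    compounds: Iterable[Compound], params: FingerprintParams = DEFAULT_PARAMS
) -> list[Fingerprint]:
    return [compute_fingerprint(c, params) for c in compounds]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between two fingerprints.

    The degenerate empty-vs-empty case is defined as 0 (with a warning);
    fingerprints generated under different parameters are not comparable
    and raise ``ValueError``.
    """
    if a.params != b.params:
        raise ValueError(f"fingerprint params differ: {a.params} vs {b.params}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    return len(a.bits & b.bits) / union


def bulk_similarity(seed: Fingerprint, library_fps: Sequence[Fingerprint]) -> np.ndarray:
    """Tanimoto of ``seed`` against each library fingerprint, in order.

    Uses the toolkit's vectorized bit-vector kernel; exactly equivalent
    to calling :func:`tanimoto` per pair.
    """
    if not library_fps:
        return np.empty(0, dtype=float)
    for fp in library_fps:
        if fp.params != seed.params:
            raise ValueError("mixed fingerprint params in bulk_similarity")
    if not seed.bits:
        # RDKit defines 0/0 as 0 as well, but go through the scalar path
        # so the degenerate-pair warning fires consistently.
        return np.array([tanimoto(seed, fp) for fp in library_fps], dtype=float)
    seed_bv = seed.to_bitvect()
    sims = DataStructs.BulkTanimotoSimilarity(seed_bv, [fp.to_bitvect() for fp in library_fps])
    return np.asarray(sims, dtype=float)


def similarity_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Full symmetric pairwise Tanimoto matrix (diagonal 1 for non-empty)."""
    n = len(fps)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        mat[i, i] = 1.0 if fps[i].bits else 0.0
        if i + 1 < n:
            row = bulk_similarity(fps[i], fps[i + 1 :])
            mat[i, i + 1 :] = row
            mat[i + 1 :, i] = row
    return mat
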