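"""Shared fixtures: tiny in-memory libraries and synthetic bit-sets."""

from __future__ import annotations

import numpy as np
import pytest

from focuslib.chem_io import Compound, CompoundLibrary, canonical_smiles
from focuslib.fingerprints import Fingerprint, FingerprintParams

DRUGLIKE_SMILES = [
    ("CCO", "ethanol"),
    ("c1ccccc1", "benzene"),
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("CC(=O)Nc1ccc(O)cc1", "paracetamol"),
    ("CN1C=NC2=C1C(=O)N(C)C(=O)N2C", "caffeine"),
    ("c1ccc2[nH]ccc2c1", "indole"),
    ("c1ccc2ncccc2c1", "quinoline"),
    ("O=C(O)c1ccccc1", "benzoic_acid"),
    ("Nc1ccccc1", "aniline"),
    ("O=C(Nc1ccccc1)c1ccccc1", "n_phenylbenzamide"),
    ("CCN(CC)CC", "triethylamine"),
    ("OCC(O)CO", "glycerol"),
]


def make_compound(smiles: str, cid: str) -> Compound:
    canon = canonical_smiles(smiles)
    assert canon is not None
    return Compound(id=cid, smiles=canon, raw_smiles=smiles)


@pytest.fixture(scope="session")
def druglike_library() -> CompoundLibrary:
    comps = [make_compound(s, cid) for s, cid in DRUGLIKE_SMILES]
    return CompoundLibrary(name="druglike", compounds=comps)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_fingerprint(
    rng: np.random.Generator,
    n_on: int = 40,
    params: FingerprintParams = FingerprintParams(),
) -> Fingerprint:
    bits = rng.choice(params.n_bits, size=n_on, replace=False)
    return Fingerprint(bits=frozenset(int(b) for b in bits), params=params)


def subset_fingerprint(similarity: float, params=FingerprintParams(), base: int = 100) -> Fingerprint:
    """Fingerprint sharing round(similarity*base) of the first ``base``
    bits of the reference fingerprint full_fingerprint(base)."""
    k = int(round(similarity * base))
    return Fingerprint(bits=frozenset(range(k)), params=params)


def full_fingerprint(base: int = 100, params=FingerprintParams()) -> Fingerprint:
    return Fingerprint(bits=frozenset(range(base)), params=params)
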