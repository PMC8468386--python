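"""Physico-chemical descriptors, rule filters, and actives-learned
property-space ("middle 90%") filtering.

The descriptor set is the eight parameters that drug-likeness rules
(Lipinski, Veber) and property-space work conventionally use: molecular
weight, calculated logP (atom-contribution estimate), H-bond donor and
acceptor counts, topological polar surface area, rotatable bonds, ring
count, and heavy atoms. A :class:`PropertyProfile` learned from known
actives keeps, per descriptor, the central ``coverage`` fraction of the
actives' empirical distribution (linear-interpolation percentiles), so
outliers among the actives do not inflate the admitted ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from focuslib.chem_io import Compound

DESCRIPTORS = ("mw", "clogp", "hbd", "hba", "tpsa", "rotb", "rings", "heavy_atoms")


@dataclass(frozen=True)
class PropertyVector:
    mw: float
    clogp: float
    hbd: int
    hba: int
    tpsa: float
    rotb: int
    rings: int
    heavy_atoms: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTORS}

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        for name in ("hbd", "hba", "rotb", "rings", "heavy_atoms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def compute_properties(compound: Compound | str) -> PropertyVector:
    """Descriptor vector for a compound (or SMILES string)."""
    if isinstance(compound, str):
        compound = Compound(id="", smiles=compound)
    mol = compound.mol()
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        rotb=Lipinski.NumRotatableBonds(mol),
        rings=rdMolDescriptors.CalcNumRings(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
    )


def properties_table(compounds: Iterable[Compound]) -> pd.DataFrame:
    """Descriptor table (index: compound id) for a collection."""
    rows = {c.id: compute_properties(c).as_dict() for c in compounds}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(DESCRIPTORS))


@dataclass
class PropertyProfile:
    """Per-descriptor closed intervals learned from actives."""

    intervals: dict[str, tuple[float, float]]
    coverage: float = 0.90
    n_actives: int = 0
    percentile_convention: str = "linear"

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"{name}: lo > hi in profile")

    def contains(self, props: PropertyVector | Mapping[str, float]) -> list[str]:
        """Names of descriptors whose value falls outside the profile."""
        values = props.as_dict() if isinstance(props, PropertyVector) else props
        violations = []
        for name, (lo, hi) in self.intervals.items():
            v = values[name]
            if not lo <= v <= hi:
                violations.append(name)
        return violations


def learn_property_profile(
    actives: Sequence[Compound] | pd.DataFrame, coverage: float = 0.90
) -> PropertyProfile:
    """Learn per-descriptor [lo, hi] intervals covering the central
    ``coverage`` fraction of the actives' values.

    Bounds are the empirical percentiles P_(1-c)/2 and P_(1+c)/2 under
    the linear-interpolation convention; coverage 1.0 gives [min, max].
    ``actives`` may be compounds or a precomputed descriptor table.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    table = actives if isinstance(actives, pd.DataFrame) else properties_table(actives)
    if len(table) < 2:
        raise ValueError("profile requires at least 2 actives")
    lo_q = (1.0 - coverage) / 2.0 * 100.0
    hi_q = (1.0 + coverage) / 2.0 * 100.0
    intervals = {}
    for name in table.columns:
        values = table[name].to_numpy(dtype=float)
        lo, hi = np.percentile(values, [lo_q, hi_q], method="linear")
        intervals[name] = (float(lo), float(hi))
    return PropertyProfile(intervals=intervals, coverage=coverage, n_actives=len(table))


def apply_profile(
    library: Sequence[Compound] | pd.DataFrame,
    profile: PropertyProfile,
    mode: str = "all_within",
    max_violations: int = 0,
) -> tuple[list[str], dict[str, list[str]]]:
    """Filter a library against a learned profile.

    ``all_within`` keeps compounds inside every interval (inclusive
    bounds); ``max_k_outside`` tolerates up to ``max_violations``
    descriptors out of range. Returns (surviving ids in input order,
    per-compound violation report for the removed).
    """
    if mode not in ("all_within", "max_k_outside"):
        raise ValueError(f"unknown mode {mode!r}")
    allowed = 0 if mode == "all_within" else max_violations
    table = library if isinstance(library, pd.DataFrame) else properties_table(library)
    kept: list[str] = []
    report: dict[str, list[str]] = {}
    for cid, row in table.iterrows():
        violations = profile.contains(row.to_dict())
        if len(violations) <= allowed:
            kept.append(str(cid))
        else:
            report[str(cid)] = violations
    return kept, report


# ---------------------------------------------------------------------------
# named rule filters
# ---------------------------------------------------------------------------

_COMPARATORS = {
    "<": lambda v, lim: v < lim,
    "<=": lambda v, lim: v <= lim,
    ">": lambda v, lim: v > lim,
    ">=": lambda v, lim: v >= lim,
}


@dataclass(frozen=True)
class RuleFilter:
    """Named clause-based filter, e.g. Lipinski's rule of five."""

    name: str
    clauses: tuple[tuple[str, str, float], ...]  # (descriptor, comparator, limit)
    max_violations: int = 0

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("rule filter needs at least one clause")
        for descriptor, comparator, _ in self.clauses:
            if descriptor not in DESCRIPTORS:
                raise ValueError(f"unknown descriptor {descriptor!r}")
            if comparator not in _COMPARATORS:
                raise ValueError(f"unknown comparator {comparator!r}")


#: standard published limits; the fragment variant uses strict "<" on a
#: tightened MW bound (fragment screening wants small, lean molecules).
LIPINSKI_RO5 = RuleFilter(
    "lipinski_ro5",
    (("mw", "<=", 500.0), ("clogp", "<=", 5.0), ("hbd", "<=", 5.0), ("hba", "<=", 10.0)),
)
VEBER = RuleFilter("veber", (("rotb", "<=", 10.0), ("tpsa", "<=", 140.0)))
FRAGMENT_RO3_VARIANT = RuleFilter(
    "fragment_ro3_variant", (("mw", "<", 250.0), ("clogp", "<", 3.0))
)

NAMED_RULES = {
    r.name: r for r in (LIPINSKI_RO5, VEBER, FRAGMENT_RO3_VARIANT)
}


def apply_rule(
    compound: Compound | PropertyVector, rule: RuleFilter
) -> tuple[bool, list[str]]:
    """Evaluate a rule filter; returns (passed, violated clause names).

    Passes iff the number of violated clauses is <= ``max_violations``.
    """
    props = (
        compound if isinstance(compound, PropertyVector) else compute_properties(compound)
    )
    values = props.as_dict()
    violations = [
        f"{descriptor} {comparator} {limit:g}"
        for descriptor, comparator, limit in rule.clauses
        if not _COMPARATORS[comparator](values[descriptor], limit)
    ]
    return len(violations) <= rule.max_violations, violations
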