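"""Compound data model, structure normalization, and file I/O.

Compounds are stored as canonical SMILES (RDKit convention). Loading a
library parses, normalizes (salt stripping on by default, stereo kept),
canonicalizes, and deduplicates by canonical SMILES, keeping the
first-seen record so downstream selections are deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparsable vendor record; failures are
# counted in the dedup report instead.
RDLogger.DisableLog("rdApp.error")

#: organic subset used to decide which salt fragment to keep
_ORGANIC = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}


class EmptyLibraryError(ValueError):
    """Raised when a library file yields zero valid records."""


class NormalizationError(ValueError):
    """Raised when a structure cannot be normalized (e.g. no organic fragment)."""


@dataclass(frozen=True)
class Compound:
    """A single structure with provenance.

    ``smiles`` is the canonical form; ``raw_smiles`` is the string as
    read from the source. ``flags`` records normalization events
    (``salt_stripped``, ``stereo_removed``, ``parse_warning``).
    """

    id: str
    smiles: str
    raw_smiles: str = ""
    source: str = ""
    flags: frozenset[str] = frozenset()

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - canonical SMILES always reparse
            raise ValueError(f"stored SMILES no longer parses: {self.smiles!r}")
        return m


@dataclass
class DedupReport:
    n_input: int = 0
    n_kept: int = 0
    n_duplicates: int = 0
    n_failures: int = 0


@dataclass
class CompoundLibrary:
    """Ordered, deduplicated collection of compounds."""

    name: str
    compounds: list[Compound] = field(default_factory=list)
    dedup_report: DedupReport = field(default_factory=DedupReport)

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __getitem__(self, i: int) -> Compound:
        return self.compounds[i]

    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def by_id(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES for ``smiles``, or None if unparsable/empty."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [
        f
        for f in frags
        if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        and all(a.GetAtomicNum() in _ORGANIC for a in f.GetAtoms())
    ]
    if not organic:
        return None
    # largest by heavy-atom count; canonical SMILES breaks ties
    return max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def normalize(
    compound: Compound, strip_salts: bool = True, keep_stereo: bool = True
) -> Compound:
    """Normalize a compound: salt stripping and optional stereo removal.

    With ``strip_salts`` the largest organic fragment is retained;
    counter-ions and solvents are dropped and ``salt_stripped`` flagged.
    With ``keep_stereo=False`` all stereo descriptors are erased and
    ``stereo_removed`` flagged (only when stereo was present).
    """
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise NormalizationError(f"unparsable structure for {compound.id!r}")
    flags = set(compound.flags)
    if strip_salts and len(Chem.GetMolFrags(mol)) > 1:
        frag = _largest_organic_fragment(mol)
        if frag is None:
            raise NormalizationError(
                f"{compound.id!r}: no organic fragment to keep after salt stripping"
            )
        Chem.SanitizeMol(frag)
        mol = frag
        flags.add("salt_stripped")
    if not keep_stereo:
        before = Chem.MolToSmiles(mol)
        Chem.RemoveStereochemistry(mol)
        if Chem.MolToSmiles(mol) != before:
            flags.add("stereo_removed")
    return replace(compound, smiles=Chem.MolToSmiles(mol), flags=frozenset(flags))


def _build_library(
    name: str,
    records: Iterable[tuple[str, str]],
    source: str,
    strip_salts: bool,
    keep_stereo: bool,
) -> CompoundLibrary:
    """Parse, normalize, and dedup (id, smiles) records into a library."""
    report = DedupReport()
    seen_smiles: set[str] = set()
    seen_ids: set[str] = set()
    compounds: list[Compound] = []
    for cid, raw in records:
        report.n_input += 1
        mol = Chem.MolFromSmiles(raw)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            report.n_failures += 1
            logger.warning("%s: unparsable record %r (%r)", name, cid, raw)
            continue
        comp = Compound(id=cid, smiles=Chem.MolToSmiles(mol), raw_smiles=raw, source=source)
        try:
            comp = normalize(comp, strip_salts=strip_salts, keep_stereo=keep_stereo)
        except NormalizationError:
            report.n_failures += 1
            logger.warning("%s: normalization failed for %r", name, cid)
            continue
        if comp.smiles in seen_smiles:
            report.n_duplicates += 1
            continue
        if comp.id in seen_ids:
            # same id, different structure: disambiguate, keep both
            comp = replace(comp, id=f"{comp.id}#{report.n_input}")
        seen_smiles.add(comp.smiles)
        seen_ids.add(comp.id)
        compounds.append(comp)
    report.n_kept = len(compounds)
    return CompoundLibrary(name=name, compounds=compounds, dedup_report=report)


def read_smiles_file(
    path: str | Path,
    has_header: bool = False,
    strip_salts: bool = True,
    keep_stereo: bool = True,
) -> CompoundLibrary:
    """Read a two-column .smi file ("SMILES<ws>ID"; ID optional).

    Records missing an identifier are assigned ``L<line>``. Parse
    failures are counted, never fatal; a file with zero valid records
    raises :class:`EmptyLibraryError`.
    """
    path = Path(path)
    name = path.stem

    def records() -> Iterator[tuple[str, str]]:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if has_header and lineno == 1:
                    continue
                parts = line.split()
                if not parts:
                    continue
                smiles = parts[0]
                cid = parts[1] if len(parts) > 1 else f"L{lineno}"
                yield cid, smiles

    lib = _build_library(name, records(), str(path), strip_salts, keep_stereo)
    if not lib.compounds:
        raise EmptyLibraryError(f"{path}: no valid records")
    return lib


def read_sdf(
    path: str | Path,
    id_property: str | None = None,
    strip_salts: bool = True,
    keep_stereo: bool = True,
) -> CompoundLibrary:
    """Read an SDF (V2000/V3000); the molecule name (or ``id_property``)
    supplies the identifier, falling back to ``L<record>``."""
    path = Path(path)
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    except OSError as exc:
        if path.exists() and path.stat().st_size == 0:
            raise EmptyLibraryError(f"{path}: no valid records") from exc
        raise
    report = DedupReport()
    seen_smiles: set[str] = set()
    compounds: list[Compound] = []
    for i, mol in enumerate(supplier, start=1):
        report.n_input += 1
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            report.n_failures += 1
            logger.warning("%s: unparsable SDF record %d", path, i)
            continue
        if id_property and mol.HasProp(id_property):
            cid = mol.GetProp(id_property)
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            cid = mol.GetProp("_Name").strip()
        else:
            cid = f"L{i}"
        raw = Chem.MolToSmiles(mol)
        comp = Compound(id=cid, smiles=raw, raw_smiles=raw, source=str(path))
        try:
            comp = normalize(comp, strip_salts=strip_salts, keep_stereo=keep_stereo)
        except NormalizationError:
            report.n_failures += 1
            continue
        if comp.smiles in seen_smiles:
            report.n_duplicates += 1
            continue
        seen_smiles.add(comp.smiles)
        compounds.append(comp)
    report.n_kept = len(compounds)
    if not compounds:
        raise EmptyLibraryError(f"{path}: no valid records")
    return CompoundLibrary(name=path.stem, compounds=compounds, dedup_report=report)


def write_smiles_file(library: CompoundLibrary, path: str | Path) -> None:
    """Write a library as a two-column .smi file."""
    with open(path, "w") as fh:
        for c in library:
            fh.write(f"{c.smiles} {c.id}\n")


SELECTION_COLUMNS = (
    "candidate_id",
    "candidate_smiles",
    "seed_id",
    "t2d",
    "t3d",
    "fusion",
    "stage",
    "rank",
)


def write_selection_csv(records: Sequence, path: str | Path) -> None:
    """Write similarity records to CSV with a fixed column order.

    Scores are written with 6 decimal places so the file round-trips
    exactly at that precision. Rank is 1-based in the given order.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SELECTION_COLUMNS)
        for rank, rec in enumerate(records, start=1):
            writer.writerow(
                [
                    rec.candidate_id,
                    getattr(rec, "candidate_smiles", ""),
                    rec.seed_id,
                    _fmt(rec.t2d),
                    _fmt(rec.t3d),
                    _fmt(rec.fusion),
                    getattr(rec, "stage", ""),
                    rank,
                ]
            )


def read_selection_csv(path: str | Path) -> list[dict]:
    """Read a selection CSV back into a list of dicts (scores as floats)."""
    rows: list[dict] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            for key in ("t2d", "t3d", "fusion"):
                row[key] = float(row[key]) if row[key] != "" else None
            row["rank"] = int(row["rank"])
            rows.append(row)
    return rows


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6f}"
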