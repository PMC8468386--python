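"""Synthetic vendor library, planted analog series, and a simulated
screening oracle.

Emulates the inputs of a similarity-driven screening campaign without
any external data: a catalog of unique drug-like structures containing
analog series built around seed scaffolds (in-series compounds share a
core and differ in substituents) mixed with decoys assembled from a
disjoint scaffold/substituent pool. Activity follows the similarity
property principle: the latent activity of a compound is proportional
to its best 2D Tanimoto similarity to a hidden pharmacophore compound
per series, plus assay noise; activity cliffs can be injected by
silencing a random fraction of the planted actives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from focuslib.chem_io import Compound, CompoundLibrary, DedupReport
from focuslib.fingerprints import (
    DEFAULT_PARAMS,
    FingerprintParams,
    bulk_similarity,
    compute_fingerprint,
    fingerprint_library,
)

logger = logging.getLogger(__name__)

#: series scaffolds: drug-like cores (15-19 heavy atoms) with two
#: attachment points. Cores are large relative to the substituents so
#: in-series analogs stay similar to their parent scaffold.
SERIES_SCAFFOLDS = (
    "O=C(N[*:1])c1ccc2ncc(-c3ccc([*:2])cc3)cc2c1",    # quinoline carboxamide
    "c1ccc2[nH]c(-c3ccc(C([*:1])=O)cc3)nc2c1C[*:2]",  # 2-arylbenzimidazole
    "O=S(=O)(N[*:1])c1ccc(-c2cccc(O[*:2])c2)cc1",     # biphenyl sulfonamide
    "c1cc2c(N[*:1])ncnc2cc1Oc1ccc([*:2])cc1",         # quinazolin-4-amine
    "O=C(c1cc2ccccc2o1)N1CCN(C[*:1])CC1C[*:2]",       # benzofuran piperazine amide
    "O=C(N[*:1])c1ccc2sc(-c3ccc(O[*:2])cc3)nc2c1",    # arylbenzothiazole amide
    "O=C1N(C[*:1])C(=O)c2cc(-c3ccccc3O[*:2])ccc21",   # phenyl isoindolinedione
    "c1cnc2c(c1)cc(C(=O)N(C[*:1])Cc1ccccc1)n2C[*:2]",  # pyrrolopyridine amide
    "O=c1cc(-c2ccc(O[*:1])cc2)oc2cc(N[*:2])ccc12",    # flavone
    "c1ccc(-n2nccc2C(=O)N(C[*:1])C)c(OC[*:2])c1",     # pyrazole anilide
)

#: substituents for series enumeration (attachment at [*:1]); all small
#: (1-5 heavy atoms) so analogs stay inside their scaffold's similarity
#: neighborhood.
SERIES_SUBSTITUENTS = (
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]CCCC", "[*:1]C(C)C",
    "[*:1]CC(C)C", "[*:1]C(C)CC", "[*:1]CO", "[*:1]CCO", "[*:1]CCCO",
    "[*:1]COC", "[*:1]CCOC", "[*:1]CC#N", "[*:1]CCC#N", "[*:1]CCN",
    "[*:1]CF", "[*:1]C(F)F", "[*:1]C(F)(F)F", "[*:1]CC(F)F",
    "[*:1]C(=O)C", "[*:1]C(=O)N", "[*:1]C(=O)NC", "[*:1]CC(=O)N",
    "[*:1]C1CC1", "[*:1]CC1CC1", "[*:1]C1CCC1", "[*:1]C1CCOC1",
    "[*:1]CSC", "[*:1]CC(C)O", "[*:1]C(C)O", "[*:1]CCN(C)C", "[*:1]CCCC#N",
)

#: disjoint pools for decoys.
DECOY_SCAFFOLDS = (
    "O=C(O[*:1])c1ccccc1N[*:2]",                 # anthranilate ester
    "c1ccc2c(c1)OCO2",                            # benzodioxole (tailed below)
    "C1CN([*:1])CCN1c1ccccc1[*:2]",              # phenylpiperazine
    "O=c1cc([*:1])oc2ccc([*:2])cc12",            # coumarin
    "c1ccc(-c2nnc([*:1])o2)cc1[*:2]",            # phenyl-oxadiazole
    "O=C(N[*:1])C1CCN(C(=O)[*:2])CC1",           # piperidine diamide
    "c1ccc2c(c1)nn(C[*:1])c2C[*:2]",             # indazole
    "C1CCC(N[*:1])CC1",                           # cyclohexylamine (tailed below)
    "O=S(=O)(c1ccccc1)N1CCC([*:1])CC1C[*:2]",    # sulfonyl piperidine
    "c1cnc(N[*:1])nc1N[*:2]",                    # diaminopyrimidine
    "O=C(N[*:1])c1cccnc1O[*:2]",                 # nicotinamide ether
    "c1ccc(CN2CCOCC2)c([*:1])c1O[*:2]",          # morpholinomethyl phenol
    "O=C1CC(c2ccccc2)N([*:1])N1[*:2]",           # pyrazolidinone
    "c1csc(-c2ccc([*:1])nc2[*:2])c1",            # thienylpyridine
    "O=C(N1CCOCC1)c1ccc([*:1])c([*:2])c1",       # morpholine benzamide
)

DECOY_SUBSTITUENTS = (
    "[*:1]Cl", "[*:1]Br", "[*:1]I", "[*:1]N", "[*:1]O", "[*:1]NC",
    "[*:1]N(C)C", "[*:1]OC(C)C", "[*:1]SC", "[*:1]S(=O)(=O)C",
    "[*:1]C#C", "[*:1]C=C", "[*:1]CNC(=O)C", "[*:1]c1cccnc1",
    "[*:1]c1ncccn1", "[*:1]C1CCNCC1", "[*:1]CC(=O)O", "[*:1]CCS",
    "[*:1]Cc1ccc(Cl)cc1", "[*:1]CCCN", "[*:1]COC(=O)C", "[*:1]CCBr",
    "[*:1]c1cccc(N)c1", "[*:1]CC1CC1",
)


@dataclass(frozen=True)
class ActivityModel:
    kind: str = "similarity_linear"  # or "similarity_cliff"
    noise_sd: float = 10.0  # percent-inhibition units
    cliff_rate: float = 0.0
    ic50_inhibition_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("similarity_linear", "similarity_cliff"):
            raise ValueError(f"unknown activity model {self.kind!r}")
        if not 0.0 <= self.cliff_rate <= 1.0:
            raise ValueError("cliff_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_decoys: int = 5000
    n_series: int = 10
    analogs_per_series: int = 30
    scaffold_pool: tuple[str, ...] = SERIES_SCAFFOLDS
    substituent_pool: tuple[str, ...] = SERIES_SUBSTITUENTS
    decoy_scaffold_pool: tuple[str, ...] = DECOY_SCAFFOLDS
    decoy_substituent_pool: tuple[str, ...] = DECOY_SUBSTITUENTS
    rng_seed: int = 0
    activity_model: ActivityModel = ActivityModel()

    def __post_init__(self) -> None:
        for pool in (self.scaffold_pool, self.substituent_pool,
                     self.decoy_scaffold_pool, self.decoy_substituent_pool):
            for smi in pool:
                if Chem.MolFromSmiles(smi) is None:
                    raise ValueError(f"pool SMILES does not parse: {smi!r}")
        if self.n_series > 0 and self.n_series > len(self.scaffold_pool):
            raise ValueError("n_series exceeds scaffold pool size")


@dataclass
class GroundTruth:
    """Per-compound provenance and the latent pharmacophore seeds."""

    table: pd.DataFrame  # index compound_id; columns: label, scaffold_smiles
    latent_seed_ids: list[str] = field(default_factory=list)

    def series_of(self, cid: str) -> str:
        return str(self.table.loc[cid, "label"])

    def planted_ids(self) -> list[str]:
        return [str(i) for i in self.table.index[self.table["label"] != "decoy"]]


def _attach(scaffold: str, sub1: str, sub2: str | None) -> str | None:
    """Join substituents onto a scaffold at its dummy attachment points."""
    mol = Chem.MolFromSmiles(scaffold)
    if mol is None:
        return None
    maps = {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0}
    combined = mol
    if 1 in maps:
        combined = Chem.CombineMols(combined, Chem.MolFromSmiles(sub1))
    if 2 in maps and sub2 is not None:
        s2 = Chem.MolFromSmiles(sub2)
        # reuse the pool's [*:1] fragments at the second site
        for a in s2.GetAtoms():
            if a.GetAtomMapNum() == 1:
                a.SetAtomMapNum(2)
        combined = Chem.CombineMols(combined, s2)
    try:
        product = Chem.molzip(combined)
        Chem.SanitizeMol(product)
    except Exception:  # noqa: BLE001 - invalid combination, caller skips
        return None
    # drop any unused attachment points by capping with H
    if any(a.GetAtomicNum() == 0 for a in product.GetAtoms()):
        edit = Chem.RWMol(product)
        for a in edit.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomicNum(1)
                a.SetAtomMapNum(0)
        product = Chem.RemoveHs(edit.GetMol())
        Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def scaffold_reference_smiles(scaffold: str, cap: str = "C") -> str:
    """The scaffold with attachment points capped (methyl by default).

    The methyl-capped core is the minimal member of its analog series
    (it is the first enumerated analog), so it is the natural reference
    structure for in-series similarity; H-capping instead would perturb
    the attachment-atom environments of every circular fingerprint.
    """
    smi = _attach(scaffold, f"[*:1]{cap}", f"[*:1]{cap}")
    if smi is None:
        raise ValueError(f"cannot cap scaffold {scaffold!r}")
    return smi


def generate_library(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[CompoundLibrary, GroundTruth]:
    """Build the synthetic vendor catalog and its ground truth.

    Analog series are enumerated lexicographically over substituent
    combinations at each scaffold's attachment points; decoys are
    random combinations from the disjoint decoy pools. Everything is
    canonical-SMILES deduplicated; if the pools cannot reach the
    requested counts the shortfall is logged and the actual counts are
    reported in the library's dedup report. Deterministic under
    ``rng_seed``. The first enumerated analog of each series is that
    series' latent pharmacophore seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    report = DedupReport()
    seen: set[str] = set()
    compounds: list[Compound] = []
    rows: list[dict] = []
    latent_ids: list[str] = []

    for s in range(config.n_series):
        scaffold = config.scaffold_pool[s]
        label = f"series_{s + 1}"
        n_made = 0
        pairs = itertools.product(config.substituent_pool, config.substituent_pool)
        for sub1, sub2 in pairs:
            if n_made >= config.analogs_per_series:
                break
            report.n_input += 1
            smi = _attach(scaffold, sub1, sub2)
            if smi is None:
                report.n_failures += 1
                continue
            if smi in seen:
                report.n_duplicates += 1
                continue
            seen.add(smi)
            n_made += 1
            cid = f"S{s + 1}_{n_made}"
            compounds.append(
                Compound(id=cid, smiles=smi, raw_smiles=smi, source="synthetic:series")
            )
            rows.append(
                {"compound_id": cid, "label": label,
                 "scaffold_smiles": scaffold_reference_smiles(scaffold)}
            )
            if n_made == 1:
                latent_ids.append(cid)
        if n_made < config.analogs_per_series:
            logger.warning(
                "series %d shortfall: %d/%d analogs", s + 1, n_made,
                config.analogs_per_series,
            )

    n_decoy_made = 0
    max_attempts = max(20 * config.n_decoys, 1000)
    attempts = 0
    while n_decoy_made < config.n_decoys and attempts < max_attempts:
        attempts += 1
        report.n_input += 1
        scaffold = config.decoy_scaffold_pool[rng.integers(len(config.decoy_scaffold_pool))]
        sub1 = config.decoy_substituent_pool[rng.integers(len(config.decoy_substituent_pool))]
        sub2 = config.decoy_substituent_pool[rng.integers(len(config.decoy_substituent_pool))]
        smi = _attach(scaffold, sub1, sub2)
        if smi is None:
            report.n_failures += 1
            continue
        if smi in seen:
            report.n_duplicates += 1
            continue
        seen.add(smi)
        n_decoy_made += 1
        cid = f"D{n_decoy_made}"
        compounds.append(
            Compound(id=cid, smiles=smi, raw_smiles=smi, source="synthetic:decoy")
        )
        rows.append({"compound_id": cid, "label": "decoy", "scaffold_smiles": ""})
    if n_decoy_made < config.n_decoys:
        logger.warning("decoy shortfall: %d/%d", n_decoy_made, config.n_decoys)

    report.n_kept = len(compounds)
    library = CompoundLibrary(
        name=f"synthetic_seed{config.rng_seed}", compounds=compounds, dedup_report=report
    )
    truth = GroundTruth(
        table=pd.DataFrame(rows).set_index("compound_id"), latent_seed_ids=latent_ids
    )
    return library, truth


def simulate_screen(
    library: CompoundLibrary,
    ground_truth: GroundTruth,
    activity_model: ActivityModel | None = None,
    rng_seed: int = 0,
    params: FingerprintParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Simulated % inhibition for every library member.

    ``similarity_linear``: inhibition = 100 * max Tanimoto to any
    latent pharmacophore seed, plus Gaussian noise. With
    ``similarity_cliff`` a fixed fraction of planted (in-series)
    compounds is silenced to baseline noise. Compounds whose noiseless
    inhibition clears the IC50 threshold get an IC50 from a monotone
    map of inhibition. Deterministic under ``rng_seed``.
    """
    model = activity_model or ActivityModel()
    rng = np.random.default_rng(rng_seed)
    compounds = list(library)
    if not set(ground_truth.table.index) >= {c.id for c in compounds}:
        raise ValueError("ground truth does not cover the library")
    fps = fingerprint_library(compounds, params)
    by_id = {c.id: c for c in compounds}
    seed_fps = [
        compute_fingerprint(by_id[sid], params) for sid in ground_truth.latent_seed_ids
    ]
    best = np.zeros(len(compounds))
    for sfp in seed_fps:
        best = np.maximum(best, bulk_similarity(sfp, fps))

    signal = 100.0 * best
    if model.kind == "similarity_cliff" and model.cliff_rate > 0:
        planted = [i for i, c in enumerate(compounds)
                   if ground_truth.table.loc[c.id, "label"] != "decoy"]
        n_cliff = int(round(model.cliff_rate * len(planted)))
        cliff_idx = rng.choice(planted, size=n_cliff, replace=False)
        signal[cliff_idx] = 0.0

    noise = rng.normal(0.0, model.noise_sd, size=len(compounds)) if model.noise_sd else 0.0
    inhibition = signal + noise

    # IC50 (uM) assigned where the noiseless signal clears the cut:
    # 10 uM at the threshold, down to 10 nM at 100 % inhibition.
    thr = model.ic50_inhibition_threshold
    ic50 = np.full(len(compounds), np.nan)
    active = signal >= thr
    span = max(100.0 - thr, 1e-9)
    ic50[active] = 10.0 ** (1.0 - 3.0 * (signal[active] - thr) / span)

    return pd.DataFrame(
        {
            "compound_id": [c.id for c in compounds],
            "percent_inhibition": inhibition,
            "ic50": ic50,
            "assay_tag": f"simulated:{model.kind}",
        }
    )
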