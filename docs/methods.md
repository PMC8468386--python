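# Methods

This note records the models, conventions, and design choices behind
`focuslib`, in the spirit of a package reference manual: what is
computed, under which assumptions, with which defaults, and what the
synthetic benchmark does and does not demonstrate.

## Similarity model

Compounds are canonicalized to RDKit canonical SMILES; no other
canonicalization convention is supported, and the convention is fixed
so that deduplication and caching are reproducible. Loading strips
salts by default (largest organic fragment kept, `salt_stripped`
flagged) and keeps stereochemistry: 2D fingerprints ignore stereo
anyway, but the 3D stage does not. Duplicate structures keep the
first-seen record, preserving input order for deterministic
tie-breaking downstream.

The default fingerprint is a folded binary circular fingerprint,
radius 2 on 2048 bits (ECFP4-like), generated by RDKit's Morgan
generator. Hashed path fingerprints are available under the same
interface. Similarity is the Tanimoto coefficient on bit sets; scores
from different fingerprint parameterizations are never comparable, so
all pairwise operations verify parameter equality and raise otherwise.
The degenerate empty-vs-empty comparison is defined as 0 with a
warning. Bulk searches use RDKit's vectorized bit-vector kernel, which
the test suite pins against a naive set-arithmetic implementation.

## Iterative threshold tuner

A fixed cut-off retrieves wildly different hit counts for different
seeds. The tuner starts at T2D = 0.75 and walks the threshold
multiplicatively — `t ← t × (1 ± step)` with step 5 % — until the hit
count enters the 50–500 window, raising it when there are too many
hits and lowering it when too few. On the first direction reversal the
step narrows to 2.5 % and stays fine, which prevents cycling between
two coarse thresholds; the walk is clamped to [0.60, 1]. Termination
states: `in_window`, `floor_reached` (count still below 50 at the
0.60 floor), or `max_iter` (default budget 50 iterations). The steps
are interpreted as *relative* ("by 5 %"); absolute stepping is
available via `TunerConfig(relative_steps=False)`. The hit set at the
final threshold is returned with the trajectory so the audit trail is
complete.

## Group fusion

With several reference actives, each candidate's similarities to all
references are summed ("fused") and candidates are ranked by the fused
score. With a single reference this reduces to plain similarity
ranking; with n identical references it is exactly n times the plain
score (both are tested). Per-seed top-k selections merge with
candidate-level deduplication, keeping the record with the higher key
and attributing ties to the id-ascending seed.

## Property-space filter

Eight descriptors are computed (MW, Crippen cLogP, Lipinski HBD/HBA,
TPSA, rotatable bonds, ring count, heavy atoms) — the parameters the
standard drug-likeness rules use. A profile learned from ≥ 2 actives
keeps, per descriptor, the central `coverage` fraction (default 0.90)
of the actives' empirical distribution, i.e. the interval between the
P5 and P95 linear-interpolation percentiles; coverage 1.0 degenerates
to [min, max] and never excludes a profile-building active. Intervals
are closed; filtering is per-descriptor (independent), not joint, with
an optional violation allowance (`max_k_outside`). Rule filters use
the standard published limits — Lipinski (MW ≤ 500, cLogP ≤ 5,
HBD ≤ 5, HBA ≤ 10), Veber (RotB ≤ 10, TPSA ≤ 140 Å²) — and a strict
fragment variant (MW < 250, cLogP < 3.0, strict `<`). Absolute cLogP
values are estimator-dependent; agreement with other estimators is out
of scope.

## 3D similarity and the fusion score

T3D providers are registered under a name and must be symmetric,
bounded in [0, 1], and self-scoring 1 (±1e-6) on identical conformer
sets. The default `shape_overlap` provider models each heavy atom as a
spherical Gaussian (width α = 0.6 Å⁻²) and computes the analytic
first-order overlap volume

    V_AB = (π / 2α)^{3/2} · Σ_ij exp(−(α/2)·d_ij²),

scoring shape Tanimoto `V_AB / (V_AA + V_BB − V_AB)`, maximized over
all conformer pairs. Each conformer is placed in its own canonical
inertial frame (centroid-centered, principal axes ordered by variance,
axis signs fixed by the third moment, right-handed), which makes the
score exactly symmetric and deterministic at the cost of a rigid,
moment-based alignment rather than a flexible superposition. Conformers
come from RDKit ETKDGv3 (default 5–10 per molecule, seed recorded,
MMFF-minimized); embedding failures flag the compound and leave its
T3D absent rather than aborting a batch.

The fusion score is the plain sum `T2D + T3D`, weighting both views
equally; candidates pass at `fusion ≥ cutoff` with default cutoff 1.5.
Round-specific T3D guidance is exposed as presets (`t3d_round1 = 0.3`,
`t3d_round2 = 0.5`), not hard-coded behavior. Records lacking T3D are
routed to an `unscored` list, never silently dropped.

## Diversity and clustering

MaxMin picking starts from the candidate with the largest mean
distance to all others and greedily adds the candidate maximizing its
minimum distance to the chosen set (metric: 1 − Tanimoto, a true
metric; ties always break by candidate id ascending). For metric
distances greedy MaxMin is a ½-approximation to the optimal min
pairwise distance, verified exhaustively on small fixtures. Clustering
is leader-style sphere exclusion: candidates ordered by neighbor count
at the threshold become centroids and absorb unassigned neighbors.
Maximum-common-substructure clustering was deliberately not used: MCS
is NP-hard, parameter-sensitive, and unnecessary for the role the
cluster step plays here; the substitution is an intentional design
choice. No explicit-diversity-index score is computed.

## Pipeline conventions

Stage order in round one: per-seed search → merge/dedup → drop
candidates identical to a seed → exclusion list → property filter
(learned from the seeds, applied after the merge in one pass) →
diversity. Every stage logs (n_in, n_out); funnel monotonicity is an
invariant. "Visual inspection" steps are represented by the exclusion
list only — there is no interactive stage. External scores (e.g.
docking) enter through a CSV import rather than any built-in docking.

Hit rates are `100 · hits / tested` under three conventions:
truncation to one decimal (the convention that reproduces most printed
campaign figures, e.g. 22/104 → 21.1), nearest-integer rounding
(11/48 → 23), and exact. Enrichment reports compare a selection's hit
rate per criterion against the analytic random baseline — the
criterion's hit rate over the whole screened table, which is the
expectation for a uniform equal-size selection.

Determinism: no pipeline stage uses hidden randomness; the only RNG
consumers are conformer embedding and the synthetic generator/screen,
both seeded from the configuration. Re-running any pipeline with the
same inputs is bit-identical, summarized by a SHA-256 content hash
over members, stage log, and configuration.

## Synthetic benchmark

The generator emulates a vendor catalog: 10 analog series of 30
compounds each, built by attaching small substituents (1–5 heavy
atoms) at two attachment points of drug-like scaffolds (15–19 heavy
atoms), plus 5000 decoys assembled from a disjoint scaffold and
substituent pool; everything is canonical-SMILES unique. Series
enumeration is lexicographic over substituent pairs, so the first
analog of each series is the methyl-capped core; that compound doubles
as the series' latent pharmacophore seed and as the scaffold reference
for similarity contracts (every planted analog keeps T2D ≥ 0.4 to its
scaffold; within-series similarity exceeds cross-series similarity on
average — both asserted against the full similarity matrix).

Simulated activity follows the similarity property principle
literally: % inhibition = 100 × (best Tanimoto to any latent seed) +
Gaussian noise (default SD 10, a typical single-point assay spread).
The cliff variant silences a fixed fraction of planted actives to
baseline noise, modeling activity cliffs; with cliffs present the
first-round hit rate drops relative to the smooth model, which the
suite asserts as a mean over 10 generator seeds. IC50 values are
assigned above 50 % inhibition by a fixed monotone map (10 µM at
threshold down to 10 nM at 100 %).

The default benchmark takes 3 analogs per series (first, middle, last
of the enumeration) as the known-actives seed set — emulating a
published set of ~30 actives spanning each chemotype — and runs the
first round at T2D ≥ 0.65 with the 90 % property profile and a
diversity cap of 105 compounds. Over 20 generator seeds, mean recall
of planted actives is compared with the equal-size random expectation
(selection size / catalog size).

What passing this benchmark shows: the selection machinery composes
correctly and concentrates planted actives far above chance under an
activity model where similarity is, by construction, informative. What
it does not show: performance on real SAR landscapes — real activity
is not a monotone function of ECFP similarity, real catalogs are far
larger and more redundant, and real actives are not enumerated analog
series. The cliff model reintroduces one known failure mode but not
others (selectivity cliffs, assay artifacts, aggregation).

## Numerical choices and degenerate inputs

- Ties everywhere break by candidate id ascending; merges attribute
  shared candidates to the higher-scoring (then id-ascending) seed.
- Thresholds are validated to (0, 1]; fusion cutoffs to [0, 2].
- Percentile convention: NumPy linear interpolation, recorded in the
  profile object.
- Truncation adds 1e-9 before flooring to keep exactly-representable
  rates (e.g. 20.0) from truncating down.
- Empty selections are warnings, not errors; empty references, empty
  libraries for the tuner, and unknown strategies/providers are
  errors.
- Benchmark problem sizes (5300-compound catalogs, 20 generator seeds,
  10 seeds for the cliff comparison) were chosen to exercise the full
  default generator while keeping a complete run in the minutes range
  on a single CPU.

## Known limitations

- The shape provider's moment-based alignment underestimates the
  similarity of genuinely superposable but differently-oriented
  flexible molecules; it is a contract-complete default, not a
  replacement for flexible-alignment engines, and outputs are labeled
  with the provider name.
- Bioisostere rewrites attach the replacement fragment by its first
  atom; multi-attachment rewrites (ring fusions) are out of scope, and
  chemically unreasonable products are only filtered by valence
  sanitization.
- The fragment cut rules are a small RECAP-like subset (ring–ring
  linkers, amide C–N, ester C–O), configurable via YAML.
- Group-fusion scores are size-biased like all Tanimoto sums; no size
  correction is applied.
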