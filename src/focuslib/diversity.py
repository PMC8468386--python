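"""Diversity selection and clustering for focused-library reduction.

After similarity search and property filtering, a focused library can
still hold far more close analogs than a screening budget allows.
Greedy MaxMin picking keeps a subset whose members are mutually distant
in fingerprint space so structural classes are evenly represented, and
leader-style clustering groups candidates around high-neighbor-count
centroids at a Tanimoto threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from focuslib.chem_io import Compound
from focuslib.fingerprints import (
    DEFAULT_PARAMS,
    FingerprintParams,
    fingerprint_library,
    similarity_matrix,
)


@dataclass
class DiversityResult:
    selected_ids: list[str]
    min_pairwise_distance: float
    mean_nn_distance: float


def _distance_matrix(
    candidates: Sequence[Compound],
    distances: np.ndarray | None,
    params: FingerprintParams,
) -> np.ndarray:
    if distances is not None:
        dist = np.asarray(distances, dtype=float)
        n = len(candidates)
        if dist.shape != (n, n):
            raise ValueError("distance matrix shape does not match candidates")
        return dist
    fps = fingerprint_library(candidates, params)
    return 1.0 - similarity_matrix(fps)


def maxmin_select(
    candidates: Sequence[Compound],
    k: int,
    *,
    distances: np.ndarray | None = None,
    params: FingerprintParams = DEFAULT_PARAMS,
) -> DiversityResult:
    """Greedy MaxMin diversity pick of ``k`` candidates.

    The metric is 1 - Tanimoto unless a precomputed distance matrix is
    given. Start: the candidate with the lowest mean similarity to all
    others (ties by id ascending); then repeatedly add the candidate
    whose minimum distance to the chosen set is largest (same
    tie-break). Deterministic and permutation-invariant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not candidates:
        raise ValueError("candidates must be non-empty")
    ids = [c.id for c in candidates]
    n = len(ids)
    dist = _distance_matrix(candidates, distances, params)

    order = sorted(range(n), key=lambda i: ids[i])  # id-ascending tie-break
    if n == 1:
        chosen = [0]
    else:
        mean_dist = (dist.sum(axis=1) - np.diag(dist)) / (n - 1)
        start = max(order, key=lambda i: mean_dist[i])  # lowest mean similarity
        chosen = [start]
        min_dist = dist[start].copy()
        while len(chosen) < min(k, n):
            remaining = [i for i in order if i not in chosen]
            nxt = max(remaining, key=lambda i: min_dist[i])
            chosen.append(nxt)
            min_dist = np.minimum(min_dist, dist[nxt])

    sel = chosen
    if len(sel) >= 2:
        sub = dist[np.ix_(sel, sel)]
        off = sub[~np.eye(len(sel), dtype=bool)].reshape(len(sel), len(sel) - 1)
        min_pd = float(off.min())
        mean_nn = float(off.min(axis=1).mean())
    else:
        min_pd = mean_nn = float("nan")
    return DiversityResult(
        selected_ids=[ids[i] for i in sel],
        min_pairwise_distance=min_pd,
        mean_nn_distance=mean_nn,
    )


def cluster_by_similarity(
    candidates: Sequence[Compound],
    threshold: float,
    *,
    similarities: np.ndarray | None = None,
    params: FingerprintParams = DEFAULT_PARAMS,
) -> list[list[str]]:
    """Leader clustering on Tanimoto similarity.

    Candidates are processed in order of decreasing neighbor count at
    the threshold (ties by id ascending); each unassigned candidate in
    turn becomes a centroid and absorbs every unassigned candidate with
    similarity >= threshold to it. Every candidate is assigned exactly
    once; each cluster is listed centroid-first.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if not candidates:
        return []
    ids = [c.id for c in candidates]
    n = len(ids)
    if similarities is None:
        sim = similarity_matrix(fingerprint_library(candidates, params))
    else:
        sim = np.asarray(similarities, dtype=float)
        if sim.shape != (n, n):
            raise ValueError("similarity matrix shape does not match candidates")
    neighbor_counts = (sim >= threshold).sum(axis=1)
    order = sorted(range(n), key=lambda i: (-neighbor_counts[i], ids[i]))
    assigned = np.zeros(n, dtype=bool)
    clusters: list[list[str]] = []
    for centroid in order:
        if assigned[centroid]:
            continue
        members = [
            i for i in range(n) if not assigned[i] and sim[centroid, i] >= threshold
        ]
        if centroid not in members:
            members.append(centroid)
        for i in members:
            assigned[i] = True
        members_sorted = [centroid] + sorted(
            (i for i in members if i != centroid), key=lambda i: ids[i]
        )
        clusters.append([ids[i] for i in members_sorted])
    return clusters
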