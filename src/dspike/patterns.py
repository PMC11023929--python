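"""Population-vector similarity during DS2 and stimulus-identity decoding.

Population vectors are per-unit spike counts in a 200 ms window centred on
each DS2 peak, max-normalized per unit; units firing above 5 Hz on average
or silent in every window are excluded.  Pairwise Pearson and cosine
similarities are tested against a null that independently permutes each
unit's event axis.  Stimulus identity (tone vs puff, evoked vs spontaneous)
is decoded with a perceptron under stratified 10-fold cross-validation and a
label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.linear_model import Perceptron
from sklearn.model_selection import StratifiedKFold, permutation_test_score

from .core import EventTable, SpikeTable


@dataclass
class PopulationVectorSet:
    matrix: np.ndarray          # units x events, entries in [0, 1]
    unit_ids: list
    event_times: np.ndarray

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_events(self) -> int:
        return self.matrix.shape[1]


def population_vectors(
    spikes: SpikeTable,
    events: EventTable,
    window_s: float = 0.2,
    max_mean_rate_hz: float = 5.0,
    session_duration: float | None = None,
) -> PopulationVectorSet:
    """Max-normalized per-unit spike counts in the event-centred window
    ``[peak - w/2, peak + w/2)``; high-rate (> 5 Hz mean) and event-silent
    units are excluded."""
    if len(events) == 0:
        raise ValueError("population_vectors requires at least one event")
    if session_duration is None:
        session_duration = max(
            (t[-1] for t in spikes.spike_times.values() if t.size), default=0.0
        )
    half = window_s / 2.0
    rows, ids = [], []
    for uid in spikes.unit_ids:
        st = spikes.spike_times[uid]
        if session_duration > 0 and st.size / session_duration > max_mean_rate_hz:
            continue
        counts = (
            np.searchsorted(st, events.peak_time + half)
            - np.searchsorted(st, events.peak_time - half)
        ).astype(float)
        if counts.max() <= 0:
            continue
        rows.append(counts / counts.max())
        ids.append(uid)
    if not rows:
        raise ValueError("all units excluded; no population vectors")
    return PopulationVectorSet(np.stack(rows), ids, events.peak_time.copy())


def _pairwise(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson and cosine similarity between the columns of ``matrix``;
    Pearson is NaN for zero-variance columns."""
    X = matrix.T  # events x units
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.corrcoef(X)
    pearson[sd == 0, :] = np.nan
    pearson[:, sd == 0] = np.nan
    norms = np.linalg.norm(X, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    cosine = (X @ X.T) / np.outer(norms, norms)
    return pearson, cosine


def vector_similarity(
    vectors: PopulationVectorSet,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Pairwise similarity matrices and per-pair shuffle p-values.

    The null independently permutes each unit's event axis; the p-value for
    a pair is ``(1 + #{null >= observed}) / (1 + n_shuffles)``.
    """
    if vectors.n_events < 2:
        raise ValueError("similarity needs at least 2 events")
    rng = rng or np.random.default_rng()
    m = vectors.matrix
    pearson, cosine = _pairwise(m)
    ge_p = np.zeros_like(pearson)
    ge_c = np.zeros_like(cosine)
    for _ in range(n_shuffles):
        shuffled = np.stack([row[rng.permutation(m.shape[1])] for row in m])
        np_, nc = _pairwise(shuffled)
        ge_p += (np_ >= pearson).astype(float)
        ge_c += (nc >= cosine).astype(float)
    p_pearson = (1.0 + ge_p) / (1.0 + n_shuffles)
    p_cosine = (1.0 + ge_c) / (1.0 + n_shuffles)
    p_pearson[np.isnan(pearson)] = np.nan
    return {
        "pearson": pearson, "cosine": cosine,
        "p_pearson": p_pearson, "p_cosine": p_cosine,
    }


def cluster_order(
    vectors: PopulationVectorSet, n_clusters: int = 2
) -> dict:
    """Ward-linkage agglomerative ordering of units and events.

    Returns display leaf orders for both axes and flat cluster labels at a
    ``n_clusters`` cut; deterministic given the input matrix.
    """
    m = vectors.matrix
    out: dict = {}
    if m.shape[0] >= 2:
        zu = linkage(m, method="ward", metric="euclidean")
        out["unit_order"] = leaves_list(zu)
        out["unit_labels"] = fcluster(zu, t=n_clusters, criterion="maxclust")
    else:
        out["unit_order"] = np.arange(m.shape[0])
        out["unit_labels"] = np.ones(m.shape[0], dtype=int)
    if m.shape[1] >= 2:
        ze = linkage(m.T, method="ward", metric="euclidean")
        out["event_order"] = leaves_list(ze)
        out["event_labels"] = fcluster(ze, t=n_clusters, criterion="maxclust")
    else:
        out["event_order"] = np.arange(m.shape[1])
        out["event_labels"] = np.ones(m.shape[1], dtype=int)
    return out


def stimulus_identity_test(
    vectors: np.ndarray,
    labels,
    n_permutations: int = 1000,
    n_folds: int = 10,
    random_state: int = 0,
) -> tuple[float, float]:
    """Perceptron decoding of stimulus identity with stratified k-fold
    cross-validation and a label-permutation test.

    ``vectors`` is events x units; returns ``(accuracy, p_value)`` where the
    p-value counts permutations scoring at least as well as the observed
    labels (never exactly zero).
    """
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("stimulus_identity_test needs at least two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} events; stratified "
            f"{n_folds}-fold needs at least {n_folds} per class"
        )
    clf = Perceptron(max_iter=1000, tol=1e-3, random_state=random_state)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    score, _, p_value = permutation_test_score(
        clf, X, y, cv=cv, n_permutations=n_permutations,
        random_state=random_state, scoring="accuracy",
    )
    return float(score), float(p_value)
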