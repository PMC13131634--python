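"""Population-level attractor geometry: motifs, occupancy, distances.

Stable equilibria pooled across subjects within one condition are clustered
on the unit sphere (spherical K-means, cosine dissimilarity) into "motifs" —
recurring activation patterns. The number of motifs is selected by a
clustering-instability criterion. Observed neural volumes are then labeled
by their most cosine-similar motif, giving per-subject meta-state occupancy
fractions and mean Euclidean distances to each motif centroid, which feed
the behavioral feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MotifSet",
    "kmeans_cosine",
    "select_k_by_instability",
    "label_volumes",
    "occupancy_and_distances",
    "build_feature_table",
]


@dataclass
class MotifSet:
    """K motif centroids (unit vectors) for one condition."""

    centroids: np.ndarray  # (K, n)
    labels: tuple[str, ...] = ()
    condition: str = ""

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=np.float64))
        if not self.labels:
            self.labels = tuple(f"motif_{i+1}" for i in range(self.K))
        self.labels = tuple(self.labels)
        if len(self.labels) != self.K:
            raise ValueError("one label per centroid required")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]


def _unit_rows(points: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(points, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm point has no direction (cosine undefined)")
    return points / norms[:, None]


def kmeans_cosine(points: np.ndarray, K: int, restarts: int = 10,
                  rng: np.random.Generator | None = None,
                  max_iter: int = 300):
    """Spherical K-means: cluster directions by cosine dissimilarity.

    Points are unit-normalized; assignment maximizes the dot product with
    the centroids and each centroid is the renormalized mean of its cluster.
    The best of ``restarts`` random initializations (by total within-cluster
    cosine dissimilarity) is returned as ``(assignments, centroids)``.
    """
    pts = _unit_rows(np.atleast_2d(np.asarray(points, dtype=np.float64)))
    P = pts.shape[0]
    if not (1 <= K <= P):
        raise ValueError(f"need 1 <= K <= {P}, got K={K}")
    rng = rng if rng is not None else np.random.default_rng()
    best = (np.inf, None, None)
    for _ in range(max(1, restarts)):
        centroids = pts[rng.choice(P, size=K, replace=False)].copy()
        assign = np.full(P, -1)
        for _ in range(max_iter):
            sim = pts @ centroids.T
            new_assign = np.argmax(sim, axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for k in range(K):
                members = pts[assign == k]
                if len(members) == 0:
                    # Re-seed an empty cluster at the worst-fit point.
                    worst = np.argmin(np.max(sim, axis=1))
                    centroids[k] = pts[worst]
                else:
                    mean = members.mean(axis=0)
                    nrm = np.linalg.norm(mean)
                    centroids[k] = mean / nrm if nrm > 1e-12 else members[0]
        objective = float(np.sum(1.0 - (pts * centroids[assign]).sum(axis=1)))
        if objective < best[0]:
            best = (objective, assign.copy(), centroids.copy())
    return best[1], best[2]


def _matched_disagreement(labels_a: np.ndarray, labels_b: np.ndarray, K: int) -> float:
    """Fraction of points whose labels disagree after optimal (Hungarian)
    matching of the two labelings' cluster indices."""
    conf = np.zeros((K, K))
    for a, b in zip(labels_a, labels_b):
        conf[a, b] += 1
    row, col = linear_sum_assignment(-conf)
    agree = conf[row, col].sum()
    return float(1.0 - agree / len(labels_a))


def select_k_by_instability(points: np.ndarray, k_range=range(2, 11),
                            n_resamples: int = 50,
                            rng: np.random.Generator | None = None,
                            restarts: int = 5):
    """Choose the number of motifs by clustering instability.

    For each K, the points are repeatedly split into random halves; each half
    is clustered independently, all points are then assigned to each half's
    centroids, and the two full labelings are compared after optimal label
    matching. Instability is the mean disagreement fraction over resamples.
    The selected K is the smallest local minimum of the instability curve
    (below both neighbors), falling back to the global minimum when the
    curve has no interior local minimum.

    Returns ``(k_opt, instability)`` with the curve indexed like ``k_range``.
    """
    pts = _unit_rows(np.atleast_2d(np.asarray(points, dtype=np.float64)))
    P = pts.shape[0]
    ks = list(k_range)
    if P < 2 * max(ks):
        raise ValueError("not enough points to split for the largest K")
    rng = rng if rng is not None else np.random.default_rng()
    curve = np.empty(len(ks))
    for j, K in enumerate(ks):
        vals = np.empty(n_resamples)
        for r in range(n_resamples):
            perm = rng.permutation(P)
            half = P // 2
            la = lb = None
            for idx, store in ((perm[:half], "a"), (perm[half:], "b")):
                _, cents = kmeans_cosine(pts[idx], K, restarts=restarts, rng=rng)
                lab = np.argmax(pts @ cents.T, axis=1)
                if store == "a":
                    la = lab
                else:
                    lb = lab
            vals[r] = _matched_disagreement(la, lb, K)
        curve[j] = vals.mean()
    k_opt = None
    for j in range(1, len(ks) - 1):
        # Non-strict on the left: perfectly stable solutions tie at zero
        # instability, and the largest K on such a plateau is the finest
        # stable partition.
        if curve[j] <= curve[j - 1] and curve[j] < curve[j + 1]:
            k_opt = ks[j]
            break
    if k_opt is None:
        k_opt = ks[int(np.argmin(curve))]
    return k_opt, curve


def label_volumes(states: np.ndarray, motifs: MotifSet) -> np.ndarray:
    """Assign each volume (column of ``states``) to its most cosine-similar
    motif. Ties break toward the lowest motif index; zero-norm volumes get
    the null label -1 (excluded from occupancy)."""
    states = np.asarray(states, dtype=np.float64)
    norms = np.linalg.norm(states, axis=0)
    cents = _unit_rows(motifs.centroids)
    labels = np.full(states.shape[1], -1, dtype=int)
    ok = norms > 1e-12
    sim = cents @ (states[:, ok] / norms[ok])
    labels[ok] = np.argmax(sim, axis=0)
    return labels


def occupancy_and_distances(states: np.ndarray, motifs: MotifSet):
    """Meta-state occupancy and mean distance to each motif centroid.

    Occupancy is the fraction of (nonzero) volumes labeled with each motif
    (cosine labeling; sums to 1). The mean distance to motif k is the
    Euclidean distance from every volume (not only those assigned to k) to
    centroid k, averaged over volumes.
    """
    states = np.asarray(states, dtype=np.float64)
    labels = label_volumes(states, motifs)
    valid = labels >= 0
    if not valid.any():
        raise ValueError("no nonzero volumes to label")
    occupancy = np.array([(labels[valid] == k).mean() for k in range(motifs.K)])
    diffs = states[None, :, :] - motifs.centroids[:, :, None]
    mean_dist = np.linalg.norm(diffs, axis=1).mean(axis=1)
    return occupancy, mean_dist


def build_feature_table(subjects: dict, motifs: MotifSet,
                        rest_motifs: MotifSet | None = None,
                        drop_first_occupancy: bool = True) -> pd.DataFrame:
    """Per-subject dynamical features for behavioral modeling.

    ``subjects`` maps subject id to a dict with keys:

    - ``"topology_rest"`` / ``"topology_task"``: topology class labels,
      turned into the binary ``Bifurc`` indicator (classes differ);
    - ``"states_task"``: (n, T) deconvolved task-condition volumes;
    - optionally ``"states_rest"``: (n, T) resting volumes, scored against
      ``rest_motifs``.

    Emits one row per subject: ``Bifurc``, occupancy columns ``<motif>_time``
    (the first motif's occupancy is dropped by default — occupancies sum to
    one, so one column is collinear with the rest), and distance columns
    ``d<motif>``; rest-condition distances get a ``_rest`` suffix.
    """
    rows = []
    for sid, sub in subjects.items():
        row = {"subject": sid,
               "Bifurc": int(sub["topology_rest"] != sub["topology_task"])}
        occ, dist = occupancy_and_distances(sub["states_task"], motifs)
        for k, name in enumerate(motifs.labels):
            if not (drop_first_occupancy and k == 0):
                row[f"{name}_time"] = occ[k]
        for k, name in enumerate(motifs.labels):
            row[f"d{name}"] = dist[k]
        if rest_motifs is not None and "states_rest" in sub:
            _, dist_r = occupancy_and_distances(sub["states_rest"], rest_motifs)
            for k, name in enumerate(rest_motifs.labels):
                row[f"d{name}_rest"] = dist_r[k]
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")
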