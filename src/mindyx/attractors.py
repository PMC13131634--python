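"""Attractor identification and topology classification.

From many random initial conditions, noise-free trajectories are classified
as converged to a stable equilibrium (per-parcel step changes below a
tolerance over a trailing window) or settled onto a stable limit cycle
(trajectory entered and later left a neighborhood of its final state).
Equilibria are deduplicated by single-linkage grouping, cycles by a mean
point-to-orbit distance, and the resulting set is labeled monostable,
multistable, or oscillatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .model import MindyXParams, step
from .simulate import Trajectory, simulate_noise_free_multi

__all__ = [
    "Equilibrium",
    "LimitCycle",
    "AttractorSet",
    "detect_equilibrium",
    "detect_limit_cycle",
    "cluster_equilibria",
    "find_attractors",
    "classify_topology",
    "bifurcation_flag",
]


@dataclass
class Equilibrium:
    """A stable fixed point with the number of initial conditions in its
    (sampled) basin of attraction."""

    x_star: np.ndarray
    basin_count: int = 1


@dataclass
class LimitCycle:
    """One period of a stable closed orbit (parcels x period states)."""

    orbit: np.ndarray
    period: int
    basin_count: int = 1


@dataclass
class AttractorSet:
    """All attractors found under one constant input, plus the topology."""

    equilibria: list
    cycles: list
    input: np.ndarray | None
    topology: str = ""
    unclassified_flag: bool = False

    @property
    def n_equilibria(self) -> int:
        return len(self.equilibria)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def detect_equilibrium(traj: Trajectory | np.ndarray, tol: float = 1e-6,
                       window: int = 10) -> Equilibrium | None:
    """Final state, if the trajectory has converged to a fixed point.

    Converged means |x_{t+1,i} - x_{t,i}| < tol for every parcel i at every
    step in the trailing ``window`` steps.
    """
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj)
    if states.shape[1] <= window:
        raise ValueError("trajectory shorter than the detection window")
    tail = states[:, -(window + 1):]
    if np.all(np.abs(np.diff(tail, axis=1)) < tol):
        return Equilibrium(x_star=states[:, -1].copy())
    return None


def detect_limit_cycle(traj: Trajectory | np.ndarray,
                       radius: float = 0.5) -> LimitCycle | None:
    """A periodic orbit, if the trajectory revisits its final state.

    The criterion: the trajectory entered and then left the Euclidean ball of
    ``radius`` around its final state at least once. The interval between
    the last two entries into that ball — one full revolution ending in the
    final approach — is taken as the period, and the states over it as one
    period of the orbit.
    """
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj)
    d = np.linalg.norm(states - states[:, -1:], axis=0)
    inside = d < radius
    # Entry events: crossings from outside into the neighborhood. Fewer than
    # two entries means the trajectory never left and came back (monotone
    # convergence, or an unresolved transient) - not a cycle.
    entries = np.flatnonzero(inside[1:] & ~inside[:-1]) + 1
    if entries.size < 2:
        return None
    start, end = int(entries[-2]), int(entries[-1])
    period = end - start
    if period < 2:
        return None
    return LimitCycle(orbit=states[:, start:end].copy(), period=period)


def cluster_equilibria(points, threshold: float = 0.1) -> list:
    """Group candidate equilibria by single-linkage at a Euclidean threshold.

    Points connected by a chain of below-threshold links are merged;
    each group is represented by its centroid, with ``basin_count`` equal to
    the group size.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        raise ValueError("no points to cluster")
    if pts.shape[0] == 1:
        return [Equilibrium(x_star=pts[0].copy(), basin_count=1)]
    labels = fcluster(linkage(pts, method="single"), t=threshold,
                      criterion="distance")
    out = []
    for lab in np.unique(labels):
        grp = pts[labels == lab]
        out.append(Equilibrium(x_star=grp.mean(axis=0), basin_count=len(grp)))
    return out


def _orbit_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean minimum point-to-orbit Euclidean distance."""
    D = cdist(a.T, b.T)
    return 0.5 * (D.min(axis=1).mean() + D.min(axis=0).mean())


def _orbit_spacing(orbit: np.ndarray) -> float:
    """Mean distance between consecutive sampled points of the orbit."""
    if orbit.shape[1] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(orbit, axis=1), axis=0).mean())


def _dedup_cycles(cycles: list, threshold: float) -> list:
    out: list[LimitCycle] = []
    for c in cycles:
        for kept in out:
            # Two discretizations of the same orbit can be phase-shifted by
            # up to half the sampling spacing, so the merge threshold is
            # floored at the coarser orbit's own spacing.
            thr = max(threshold,
                      _orbit_spacing(c.orbit), _orbit_spacing(kept.orbit))
            if _orbit_distance(c.orbit, kept.orbit) < thr:
                kept.basin_count += 1
                break
        else:
            out.append(c)
    return out


def classify_topology(attrs: AttractorSet) -> str:
    """Label the landscape: oscillatory if any stable limit cycle exists,
    else multistable if several equilibria, else monostable."""
    if attrs.n_equilibria == 0 and attrs.n_cycles == 0:
        raise ValueError("empty attractor set cannot be classified")
    if attrs.n_cycles >= 1:
        return "oscillatory"
    return "multistable" if attrs.n_equilibria >= 2 else "monostable"


def bifurcation_flag(type_rest: str, type_task: str) -> bool:
    """True iff the topology class differs between the two conditions."""
    valid = {"monostable", "multistable", "oscillatory"}
    if type_rest not in valid or type_task not in valid:
        raise ValueError(f"topology labels must be in {sorted(valid)}")
    return type_rest != type_task


def find_attractors(params: MindyXParams, u_const: np.ndarray | None = None,
                    n_init: int = 120, steps: int = 1600,
                    max_steps: int = 25600,
                    rng: np.random.Generator | None = None,
                    tol: float = 1e-6, window: int = 10,
                    cycle_radius: float = 0.5,
                    cluster_threshold: float = 0.1) -> AttractorSet:
    """Multi-start noise-free attractor search under one constant input.

    Initial conditions are i.i.d. standard normal. Each trajectory is first
    tested for equilibrium convergence, then for a limit cycle; unresolved
    trajectories are extended by doubling the step count up to ``max_steps``.
    Equilibria are merged by single-linkage at ``cluster_threshold``; cycles
    are deduplicated at ``cycle_radius``. If any trajectory remains
    unresolved at ``max_steps`` the set is flagged (the numerical procedure
    may have failed for that model) rather than silently dropped.
    """
    rng = rng if rng is not None else np.random.default_rng()
    X0 = rng.standard_normal((params.n, n_init))
    eq_points, cycles = [], []
    unresolved = False

    states, _ = simulate_noise_free_multi(params, u_const, X0, steps)
    pending = []  # (final_state, total_steps) of unresolved trajectories
    for j in range(n_init):
        traj = states[:, j, :]
        eq = detect_equilibrium(traj, tol=tol, window=window)
        if eq is not None:
            eq_points.append(eq.x_star)
            continue
        lc = detect_limit_cycle(traj, radius=cycle_radius)
        if lc is not None:
            cycles.append(lc)
            continue
        pending.append((traj[:, -1], steps))

    # Extend unresolved trajectories (slowly converging models) by doubling.
    while pending:
        nxt = []
        for x_last, done in pending:
            if done >= max_steps:
                unresolved = True
                continue
            extra = min(done, max_steps - done)
            seg, _ = simulate_noise_free_multi(params, u_const,
                                              x_last[:, None], extra)
            traj = seg[:, 0, :]
            eq = detect_equilibrium(traj, tol=tol, window=window)
            if eq is not None:
                eq_points.append(eq.x_star)
                continue
            lc = detect_limit_cycle(traj, radius=cycle_radius)
            if lc is not None:
                cycles.append(lc)
                continue
            nxt.append((traj[:, -1], done + extra))
        pending = nxt

    equilibria = cluster_equilibria(eq_points, cluster_threshold) if eq_points else []
    cycles = _dedup_cycles(cycles, cycle_radius)
    attrs = AttractorSet(equilibria=equilibria, cycles=cycles,
                         input=None if u_const is None else np.asarray(u_const, float),
                         unclassified_flag=unresolved)
    if equilibria or cycles:
        attrs.topology = classify_topology(attrs)
    return attrs
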