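"""Structured coalescent for PAR windows linked to a non-recombining SDR.

Looking backward in time, the sampled copies of a PAR window live in two
demes: the Y-linked pool (1/4 of the 2N chromosome copies) and the X-linked
pool (3/4).  Male-meiosis recombination between the window and the SDR moves
lineages between pools: Y->X at r per generation, X->Y at r/3 (only the
third of X-linked copies residing in males can have come off a Y).  Female
recombination never changes linkage state and is ignored.  At ``t_sweep``
generations ago the neo-Y arose in a single individual; the sweep is
modelled as an instantaneous common-ancestor event for all lineages then in
the Y pool, after which the population is panmictic.  Population-size epochs
rescale both pools.  Mutations follow the infinite-sites model at rate
theta/2 per unit of 2*Ne generations of branch length.

Each window is treated as a non-recombining locus (windows are about one
rho unit wide); correlations between windows are ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LABEL_X, LABEL_Y, HaplotypePanel

__all__ = [
    "SimParams",
    "SimSample",
    "simulate_window",
    "simulate_region",
    "null_scan_min_pvalues",
    "calibrate_critical_p",
]

_DEME_X, _DEME_Y = 0, 1


@dataclass
class SimParams:
    """Parameters of one simulated window.

    ``rho_distance`` is the genetic distance to the SDR in rho = 4*Ne*r
    units; ``theta`` the window's scaled mutation rate 4*Ne*mu;
    ``demography`` a list of (time_generations, diploid_size) epochs with
    times increasing into the past (first entry must start at 0).
    ``t_sweep`` is when (backwards) the neo-Y arose: X/Y structure ends
    there and, if ``sweep`` is True, all lineages then in the Y pool merge
    instantaneously.  ``t_sweep=None`` keeps the two demes forever (pure
    island model); ``single_deme=True`` collapses the model to a panmictic
    control.
    """

    ne: float = 1e5
    n_x: int = 15
    n_y: int = 15
    rho_distance: float = 60.0
    theta: float = 2.5
    t_sweep: float | None = 306_000.0
    sweep: bool = True
    demography: list[tuple[float, float]] | None = None
    single_deme: bool = False
    window_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.ne <= 0 or self.theta < 0:
            raise ValueError("ne must be positive and theta non-negative")
        if self.rho_distance < 0:
            raise ValueError("rho_distance must be non-negative")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("need at least one sampled copy per class")
        if self.demography is None:
            self.demography = [(0.0, self.ne)]  # constant size by default
        times = [t for t, _ in self.demography]
        sizes = [s for _, s in self.demography]
        if times[0] != 0.0:
            raise ValueError("first demographic epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch times must be strictly increasing")
        if any(s <= 0 for s in sizes):
            raise ValueError("epoch sizes must be positive")
        if (
            not self.single_deme
            and self.t_sweep is None
            and self.rho_distance == 0.0
        ):
            raise ValueError(
                "zero recombination with no sweep never joins the demes"
            )

    @classmethod
    def with_expansion(cls, ne: float = 1e5, t_sweep: float = 306_000.0,
                       ancestral_fraction: float = 0.2, **kw) -> "SimParams":
        """Default recent-expansion history: ancestral size
        ``ancestral_fraction * ne`` before ``0.5 * t_sweep``."""
        demography = [(0.0, ne), (0.5 * t_sweep, ancestral_fraction * ne)]
        return cls(ne=ne, t_sweep=t_sweep, demography=demography, **kw)

    def to_dict(self) -> dict:
        return {
            "ne": self.ne, "n_x": self.n_x, "n_y": self.n_y,
            "rho_distance": self.rho_distance, "theta": self.theta,
            "t_sweep": self.t_sweep, "sweep": self.sweep,
            "demography": self.demography,
            "single_deme": self.single_deme, "window_bp": self.window_bp,
        }


@dataclass
class SimSample:
    panel: HaplotypePanel
    newick: str
    tmrca: float                      # generations
    total_branch_length: float        # generations
    y_monophyletic: bool
    summaries: dict = field(default_factory=dict)


def _epoch_size(demography: list[tuple[float, float]], t: float) -> float:
    size = demography[0][1]
    for start, s in demography:
        if t >= start:
            size = s
        else:
            break
    return size


def _next_breakpoint(
    demography: list[tuple[float, float]], t_sweep: float | None, t: float
) -> float:
    cands = [start for start, _ in demography if start > t]
    if t_sweep is not None and t_sweep > t:
        cands.append(t_sweep)
    return min(cands) if cands else math.inf


def _simulate_genealogy(
    params: SimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Run the event loop; returns (node_times, left, right, root, y_mono).

    Leaves 0..n_x-1 are X-linked, n_x..n-1 Y-linked.  Internal nodes are
    appended as they arise; ``left``/``right`` are child pointers (-1 for
    leaves).
    """
    n_x, n_y = params.n_x, params.n_y
    n = n_x + n_y
    r_m = params.rho_distance / (4.0 * params.ne)
    times = [0.0] * n
    left = [-1] * n
    right = [-1] * n

    panmictic = params.single_deme
    active: list[tuple[int, int]] = []
    for i in range(n_x):
        active.append((i, _DEME_X))
    for i in range(n_y):
        active.append((n_x + i, _DEME_Y))
    if panmictic:
        active = [(node, _DEME_X) for node, _ in active]

    t = 0.0
    t_sweep = None if panmictic else params.t_sweep
    swept = False

    def merge(nodes: list[int], when: float) -> int:
        cur = nodes[0]
        for other in nodes[1:]:
            times.append(when)
            left.append(cur)
            right.append(other)
            cur = len(times) - 1
        return cur

    while len(active) > 1:
        size = _epoch_size(params.demography, t)
        m_x = 1.5 * size if not panmictic else 2.0 * size  # copies in X pool
        m_y = 0.5 * size
        k_x = sum(1 for _, d in active if d == _DEME_X)
        k_y = len(active) - k_x
        rate_cx = k_x * (k_x - 1) / 2.0 / m_x
        rate_cy = 0.0 if panmictic else k_y * (k_y - 1) / 2.0 / m_y
        rate_yx = 0.0 if panmictic else k_y * r_m
        rate_xy = 0.0 if panmictic else k_x * (r_m / 3.0)
        total = rate_cx + rate_cy + rate_yx + rate_xy
        bp = _next_breakpoint(params.demography, t_sweep, t)
        dt = rng.exponential(1.0 / total) if total > 0 else math.inf
        if t + dt >= bp:
            t = bp
            if t_sweep is not None and not swept and t >= t_sweep:
                swept = True
                y_nodes = [node for node, d in active if d == _DEME_Y]
                x_nodes = [(node, _DEME_X) for node, d in active if d == _DEME_X]
                if y_nodes and params.sweep:
                    anc = merge(y_nodes, t)
                    active = x_nodes + [(anc, _DEME_X)]
                else:
                    active = x_nodes + [(node, _DEME_X) for node in y_nodes]
                panmictic = True
            if math.isinf(bp) and total == 0:
                raise RuntimeError("genealogy cannot converge (no events possible)")
            continue
        t += dt
        u = rng.random() * total
        if u < rate_cx:
            pool = [i for i, (_, d) in enumerate(active) if d == _DEME_X]
            i1, i2 = rng.choice(len(pool), size=2, replace=False)
            a, b = active[pool[i1]][0], active[pool[i2]][0]
            parent = merge([a, b], t)
            active = [lin for j, lin in enumerate(active)
                      if j not in (pool[i1], pool[i2])]
            active.append((parent, _DEME_X))
        elif u < rate_cx + rate_cy:
            pool = [i for i, (_, d) in enumerate(active) if d == _DEME_Y]
            i1, i2 = rng.choice(len(pool), size=2, replace=False)
            a, b = active[pool[i1]][0], active[pool[i2]][0]
            parent = merge([a, b], t)
            active = [lin for j, lin in enumerate(active)
                      if j not in (pool[i1], pool[i2])]
            active.append((parent, _DEME_Y))
        elif u < rate_cx + rate_cy + rate_yx:
            pool = [i for i, (_, d) in enumerate(active) if d == _DEME_Y]
            j = pool[int(rng.integers(len(pool)))]
            active[j] = (active[j][0], _DEME_X)
        else:
            pool = [i for i, (_, d) in enumerate(active) if d == _DEME_X]
            j = pool[int(rng.integers(len(pool)))]
            active[j] = (active[j][0], _DEME_Y)

    root = active[0][0]
    times_arr = np.array(times)
    left_arr = np.array(left + [-1] * (len(times) - len(left)))
    right_arr = np.array(right + [-1] * (len(times) - len(right)))

    # Y monophyly: the smallest clade containing all Y leaves holds only Y leaves
    y_leaves = set(range(n_x, n))
    leaf_sets: dict[int, set[int]] = {}

    def leaves_under(node: int) -> set[int]:
        if node in leaf_sets:
            return leaf_sets[node]
        if left_arr[node] < 0:
            s = {node}
        else:
            s = leaves_under(int(left_arr[node])) | leaves_under(int(right_arr[node]))
        leaf_sets[node] = s
        return s

    leaves_under(root)
    mrca = root
    # walk down while one child still contains all Y leaves
    moved = True
    while moved:
        moved = False
        for child in (int(left_arr[mrca]), int(right_arr[mrca])):
            if child >= 0 and y_leaves <= leaves_under(child):
                mrca = child
                moved = True
                break
    y_mono = leaves_under(mrca) == y_leaves
    return times_arr, left_arr, right_arr, root, y_mono


def _newick(times: np.ndarray, left: np.ndarray, right: np.ndarray,
            root: int, names: list[str], scale: float) -> str:
    def build(node: int, parent_time: float) -> str:
        bl = (parent_time - times[node]) / scale
        if left[node] < 0:
            return f"{names[node]}:{bl:.6g}"
        inner = f"({build(int(left[node]), times[node])},{build(int(right[node]), times[node])})"
        return f"{inner}:{bl:.6g}"
    body = f"({build(int(left[root]), times[root])},{build(int(right[root]), times[root])})"
    return body + ";"


def _drop_mutations(
    times: np.ndarray, left: np.ndarray, right: np.ndarray, root: int,
    n_leaves: int, theta: float, ne: float, window_bp: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites mutations: returns (positions, allele matrix)."""
    n_nodes = times.size
    parent = np.full(n_nodes, -1)
    for v in range(n_nodes):
        for c in (left[v], right[v]):
            if c >= 0:
                parent[c] = v
    blen = np.zeros(n_nodes)
    has_parent = parent >= 0
    blen[has_parent] = times[parent[has_parent]] - times[has_parent]
    total = float(blen.sum())
    mu_per_gen = theta / (4.0 * ne)
    n_mut = rng.poisson(total * mu_per_gen)
    if n_mut == 0:
        return (np.empty(0, dtype=np.int64),
                np.zeros((n_leaves, 0), dtype=np.int8))
    # leaf sets per node
    desc = [np.zeros(n_leaves, dtype=bool) for _ in range(n_nodes)]
    order = np.argsort(times, kind="stable")
    for v in order:
        if left[v] < 0:
            desc[v][v] = True
        else:
            desc[v] = desc[int(left[v])] | desc[int(right[v])]
    branches = rng.choice(n_nodes, size=n_mut, p=blen / total)
    matrix = np.zeros((n_leaves, n_mut), dtype=np.int8)
    for j, b in enumerate(branches):
        matrix[desc[int(b)], j] = 1
    n_avail = max(window_bp, n_mut)
    positions = np.sort(rng.choice(n_avail, size=n_mut, replace=False)) + 1
    return positions.astype(np.int64), matrix


def simulate_window(
    params: SimParams, seed: int | np.random.Generator
) -> SimSample:
    """Simulate one window: genealogy, mutations, per-replicate summaries."""
    from .windowed_popgen import _fst_components, _pi_sum, tajimas_d

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times, left, right, root, y_mono = _simulate_genealogy(params, rng)
    positions, matrix = _drop_mutations(
        times, left, right, root, params.n_x + params.n_y,
        params.theta, params.ne, params.window_bp, rng,
    )
    labels = np.array([LABEL_X] * params.n_x + [LABEL_Y] * params.n_y)
    names = [f"X{i + 1:02d}" for i in range(params.n_x)] + [
        f"Y{i + 1:02d}" for i in range(params.n_y)
    ]
    panel = HaplotypePanel("sim", positions, matrix, labels, names)
    num, den = _fst_components(matrix[: params.n_x], matrix[params.n_x:])
    fst = num / den if den > 0 else None
    blen_total = 0.0
    for v in range(times.size):
        for c in (left[v], right[v]):
            if c >= 0:
                blen_total += times[v] - times[c]
    summaries = {
        "fst": fst,
        "pi": _pi_sum(matrix),  # mean pairwise differences (count, not per bp)
        "pi_y": _pi_sum(matrix[params.n_x:]),
        "tajima_d": tajimas_d(matrix),
        "n_snps": matrix.shape[1],
        "y_monophyletic": y_mono,
    }
    newick = _newick(times, left, right, root, names, scale=2.0 * params.ne)
    return SimSample(
        panel=panel,
        newick=newick,
        tmrca=float(times[root]),
        total_branch_length=blen_total,
        y_monophyletic=y_mono,
        summaries=summaries,
    )


def simulate_region(
    params: SimParams,
    distances: list[float],
    n_reps: int,
    seed: int,
) -> tuple[pd.DataFrame, dict[float, np.ndarray]]:
    """Independent window replicates at each rho-distance to the SDR.

    Returns a summary frame (mean and upper quantiles of F_ST by distance)
    and the raw per-replicate F_ST arrays.
    """
    if any(d < 0 for d in distances):
        raise ValueError("distances must be non-negative")
    rows = []
    raw: dict[float, np.ndarray] = {}
    ss = np.random.SeedSequence(seed).spawn(max(len(distances), 1))
    for d, sub_seed in zip(distances, ss):
        rng = np.random.default_rng(sub_seed)
        fsts = []
        for _ in range(n_reps):
            base = params.to_dict()
            base["rho_distance"] = d
            sample = simulate_window(SimParams(**base), rng)
            if sample.summaries["fst"] is not None:
                fsts.append(sample.summaries["fst"])
        arr = np.array(fsts)
        raw[d] = arr
        rows.append(
            {
                "rho_distance": d,
                "n_reps": n_reps,
                "n_defined": arr.size,
                "fst_mean": float(arr.mean()) if arr.size else np.nan,
                "fst_q95": float(np.quantile(arr, 0.95)) if arr.size else np.nan,
                "fst_q99": float(np.quantile(arr, 0.99)) if arr.size else np.nan,
            }
        )
    return pd.DataFrame(rows), raw


def null_scan_min_pvalues(
    params: SimParams,
    distances: list[float],
    n_sims: int,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Per-simulation minimum permutation p over a region of null windows.

    Each simulation draws one independent window per distance, runs the
    same balanced-relabelling test the scan uses, and keeps the smallest
    p-value — the familywise statistic calibrated by
    :func:`calibrate_critical_p`.
    """
    from .permutation_scan import permutation_pvalue

    labels = np.array([LABEL_X] * params.n_x + [LABEL_Y] * params.n_y)
    rng = np.random.default_rng(seed)
    out = np.ones(n_sims)
    for i in range(n_sims):
        best = 1.0
        for d in distances:
            base = params.to_dict()
            base["rho_distance"] = d
            sample = simulate_window(SimParams(**base), rng)
            if sample.panel.n_sites == 0:
                continue
            try:
                _, p = permutation_pvalue(
                    sample.panel.alleles, labels, n_perm, rng
                )
            except ValueError:
                continue
            best = min(best, p)
        out[i] = best
    return out


def calibrate_critical_p(
    min_pvalues: np.ndarray, familywise_rate: float = 0.2
) -> float:
    """Largest p threshold whose familywise null rejection rate <= target.

    ``min_pvalues`` holds, for each simulated null scan, the minimum window
    p-value.  Returns 0.0 when no achievable threshold keeps the rate at or
    below ``familywise_rate``, and 1.0 when the rate never exceeds it.
    """
    v = np.asarray(min_pvalues, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one simulated null scan")
    if v.size < 100:
        warnings.warn(
            f"only {v.size} null scans; critical-p calibration is coarse"
        )
    if not (0.0 <= familywise_rate <= 1.0):
        raise ValueError("familywise_rate must be in [0, 1]")
    n = v.size
    if np.mean(v <= 1.0) <= familywise_rate or familywise_rate == 1.0:
        return 1.0
    for c in np.unique(v)[::-1]:
        if np.mean(v <= c) <= familywise_rate:
            return float(c)
    return 0.0
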