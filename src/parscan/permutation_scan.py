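"""Model-free scan for X-Y differentiation outliers in the PAR.

Per window, the null distribution of F_ST comes from randomly relabelling
haplotypes as X or Y (keeping the label counts balanced); the empirical
p-value is the proportion of relabellings with F_ST greater than or equal
to the observed value (ties count).  Multiple testing is handled with
Storey-Tibshirani q-values; a window is called significant when q <= fdr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LABEL_X, LABEL_Y, MISSING, HaplotypePanel, Window, tile_windows
from .windowed_popgen import _fst_components, count_focal_snps

__all__ = [
    "ScanConfig",
    "ScanResult",
    "permutation_pvalue",
    "storey_qvalues",
    "scan_focal_region",
]

_PERM_CHUNK = 20_000  # permutations per vectorized block


@dataclass
class ScanConfig:
    focal_start_bp: int = 7_500_000
    focal_end_bp: int = 11_500_000
    window_size: int = 10_000
    min_snps: int = 10
    snp_filter_exclusive: bool = False  # True: require n_snps > min_snps
    n_perm: int = 1_000_000
    fdr: float = 0.2
    add_one: bool = False  # conservative (count+1)/(n_perm+1) variant
    randomize_ties: bool = False  # exact-uniform diagnostic variant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focal_end_bp <= self.focal_start_bp:
            raise ValueError("focal interval is empty")
        if self.n_perm < 1_000:
            raise ValueError("n_perm must be at least 10^3")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must be in (0, 1)")
        if self.window_size <= 0 or self.min_snps < 0:
            raise ValueError("window_size/min_snps out of range")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "focal_start_bp", "focal_end_bp", "window_size", "min_snps",
            "snp_filter_exclusive", "n_perm", "fdr", "add_one",
            "randomize_ties", "seed")}


@dataclass
class ScanResult:
    frame: pd.DataFrame
    config: ScanConfig
    n_windows_tested: int
    seed: int
    null_summary: dict = field(default_factory=dict)


def _balanced_label_matrix(
    rng: np.random.Generator, n_perm: int, n_hap: int, n_x: int
) -> np.ndarray:
    """Boolean (n_perm, n_hap) matrix of uniform balanced X-assignments."""
    ranks = rng.random((n_perm, n_hap)).argsort(axis=1).argsort(axis=1)
    return ranks < n_x


def _permuted_fst(
    matrix: np.ndarray, x_mask: np.ndarray
) -> np.ndarray:
    """Window F_ST for each relabelling in ``x_mask`` (rows = relabellings)."""
    valid = (matrix != MISSING).astype(np.float64)
    derived = (matrix == 1).astype(np.float64)
    tot_valid = valid.sum(axis=0)
    tot_der = derived.sum(axis=0)
    p = x_mask.astype(np.float64)
    nx = p @ valid
    cx = p @ derived
    ny = tot_valid[None, :] - nx
    cy = tot_der[None, :] - cx
    with np.errstate(divide="ignore", invalid="ignore"):
        hx = 2.0 * cx * (nx - cx) / (nx * (nx - 1.0))
        hy = 2.0 * cy * (ny - cy) / (ny * (ny - 1.0))
        hb = (cx / nx) * (1.0 - cy / ny) + (cy / ny) * (1.0 - cx / nx)
    ok = (nx >= 2) & (ny >= 2) & np.isfinite(hb) & (hb > 0)
    num = np.where(ok, hb - 0.5 * (hx + hy), 0.0).sum(axis=1)
    den = np.where(ok, hb, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = num / den
    fst[den == 0] = -np.inf  # undefined permuted F_ST can never beat observed
    return fst


def permutation_pvalue(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator,
    add_one: bool = False,
    randomize_ties: bool = False,
) -> tuple[float, float]:
    """Permutation p-value for window F_ST under balanced label swaps.

    ``matrix`` holds the window's haplotypes (rows) over sites; ``labels``
    are "X"/"Y" strings.  Returns (observed F_ST, p).  Requires equal label
    counts — the null is defined over balanced relabellings only.

    By default ties (permuted F_ST exactly equal to the observed value)
    count toward the numerator, which makes p conservative on the discrete
    null.  ``randomize_ties=True`` instead counts each tie with an
    independent U(0,1) weight — the classical randomized p-value, exactly
    uniform under exchangeability — which is the right variant for
    calibration diagnostics, not for reporting.
    """
    labels = np.asarray(labels)
    n_x = int(np.sum(labels == LABEL_X))
    n_y = int(np.sum(labels == LABEL_Y))
    if n_x != n_y:
        raise ValueError(
            f"balanced design required: {n_x} X vs {n_y} Y haplotypes"
        )
    matrix = np.asarray(matrix)
    x_rows = labels == LABEL_X
    obs_mask = x_rows[None, :]
    obs = float(_permuted_fst(matrix, obs_mask)[0])
    if not np.isfinite(obs):
        raise ValueError("observed F_ST undefined (no informative sites)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_hap = matrix.shape[0]
    hits = 0.0
    done = 0
    while done < n_perm:
        chunk = min(_PERM_CHUNK, n_perm - done)
        masks = _balanced_label_matrix(rng, chunk, n_hap, n_x)
        fst = _permuted_fst(matrix, masks)
        above = fst >= obs - 1e-12
        if randomize_ties:
            ties = above & (fst <= obs + 1e-12)
            hits += float(np.sum(above & ~ties))
            hits += float(np.sum(rng.random(int(ties.sum()))))
        else:
            hits += float(np.sum(above))  # ties count toward the tail
        done += chunk
    if add_one:
        return obs, (hits + 1) / (n_perm + 1)
    return obs, hits / n_perm


def storey_qvalues(
    p_values: np.ndarray,
    pi0: float | None = None,
    smooth_min_m: int = 100,
) -> np.ndarray:
    """Storey-Tibshirani q-values.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic
    smoother evaluated at the largest lambda, clipped to (0, 1]; with fewer
    than ``smooth_min_m`` tests the estimate is unstable and pi0 falls back
    to 1 (the Benjamini-Hochberg limit).  Pass ``pi0`` to override.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < smooth_min_m:
            pi0 = 1.0
        else:
            lams = np.arange(0.05, 0.951, 0.05)
            pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lams])
            coef = np.polyfit(lams, pi0_l, 3)
            pi0 = float(np.polyval(coef, lams[-1]))
            pi0 = min(1.0, max(pi0, 1.0 / m))
    if not (0.0 < pi0 <= 1.0):
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up monotonization
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def scan_focal_region(
    panel: HaplotypePanel, config: ScanConfig
) -> ScanResult:
    """Run the permutation + q-value scan over the focal region.

    Windows tile the chromosome from position 1; those inside
    [focal_start_bp, focal_end_bp) passing the SNP-count filter are tested.
    Per-window permutation streams are split off the master seed so results
    are reproducible and independent of window order.
    """
    focal = (panel.labels == LABEL_X) | (panel.labels == LABEL_Y)
    sub_alleles = panel.alleles[focal]
    sub_labels = panel.labels[focal]
    windows = [
        w
        for w in tile_windows(panel.chrom, config.focal_end_bp - 1, config.window_size)
        if w.start_bp >= config.focal_start_bp and w.end_bp <= config.focal_end_bp
    ]
    tested: list[tuple[Window, int, float, float]] = []
    skipped = []
    seeds = np.random.SeedSequence(config.seed).spawn(len(windows))
    for w, ss in zip(windows, seeds):
        n_snps = count_focal_snps(panel, w)
        passes = n_snps > config.min_snps if config.snp_filter_exclusive \
            else n_snps >= config.min_snps
        if not passes:
            skipped.append((w, n_snps))
            continue
        sl = panel.site_slice(w)
        matrix = sub_alleles[:, sl]
        rng = np.random.default_rng(ss)
        obs, p = permutation_pvalue(
            matrix, sub_labels, config.n_perm, rng, add_one=config.add_one,
            randomize_ties=config.randomize_ties,
        )
        tested.append((w, n_snps, obs, p))
    if not tested:
        warnings.warn("no windows passed the SNP-count filter; empty scan result")
        frame = pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "n_snps", "fst",
                     "p_emp", "q_value", "significant"]
        )
        return ScanResult(frame, config, 0, config.seed)
    pvals = np.array([t[3] for t in tested])
    qvals = storey_qvalues(pvals)
    frame = pd.DataFrame(
        {
            "chrom": [t[0].chrom for t in tested],
            "start_bp": [t[0].start_bp for t in tested],
            "end_bp": [t[0].end_bp for t in tested],
            "n_snps": [t[1] for t in tested],
            "fst": [t[2] for t in tested],
            "p_emp": pvals,
            "q_value": qvals,
            "significant": qvals <= config.fdr,
        }
    )
    return ScanResult(
        frame=frame,
        config=config,
        n_windows_tested=len(tested),
        seed=config.seed,
        null_summary={
            "n_windows_skipped": len(skipped),
            "n_significant": int(np.sum(qvals <= config.fdr)),
        },
    )
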