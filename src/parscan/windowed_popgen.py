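"""Per-window population-genetic statistics for phased sex-chromosome panels.

F_ST is the Hudson estimator 1 - Hw/Hb computed from mean pairwise
differences, aggregated across a window as a ratio of averages (sum of
site numerators over sum of site denominators).  pi and K (dxy) are mean
pairwise differences per bp of window length.  Gene trees are
neighbour-joining on pairwise difference counts; a window is "XY consistent"
when the unrooted tree contains the X|Y bipartition.  All statistics are
invariant to haplotype row order and to 0<->1 allele relabelling, and
tolerate missing calls (MISSING) by per-site pair exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LABEL_SISTER, LABEL_X, LABEL_Y, MISSING, HaplotypePanel, VariantTable, Window

__all__ = [
    "site_fst",
    "window_fst",
    "window_pi",
    "window_dxy",
    "tajimas_d",
    "depth_ratio",
    "gene_tree_consistency",
    "detect_boundary",
    "dnds",
    "DnDsRecord",
    "stats_frame",
    "tree_frame",
]


# ---------------------------------------------------------------- F_ST

def _site_counts(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(derived count, valid count) per site, ignoring MISSING."""
    valid = matrix != MISSING
    derived = (matrix == 1) & valid
    return derived.sum(axis=0).astype(float), valid.sum(axis=0).astype(float)


def _within_het(c: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Mean pairwise difference within a group per site: 2c(n-c)/(n(n-1))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, h, np.nan)


def _between_het(cx, nx, cy, ny) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        px, py = cx / nx, cy / ny
        h = px * (1 - py) + py * (1 - px)
    return np.where((nx >= 1) & (ny >= 1), h, np.nan)


def site_fst(freq_x: float, n_x: int, freq_y: float, n_y: int) -> float | None:
    """Hudson site F_ST = 1 - Hw/Hb from group frequencies and sample sizes.

    Hw averages the within-X and within-Y mean pairwise differences; Hb is
    the between-group mean pairwise difference.  Returns None when Hb = 0
    (monomorphic across both groups); negative estimates are clamped to 0.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("need at least two haplotypes per group")
    cx, cy = freq_x * n_x, freq_y * n_y
    hx = 2.0 * cx * (n_x - cx) / (n_x * (n_x - 1.0))
    hy = 2.0 * cy * (n_y - cy) / (n_y * (n_y - 1.0))
    hb = freq_x * (1 - freq_y) + freq_y * (1 - freq_x)
    if hb == 0.0:
        return None
    return max(0.0, 1.0 - 0.5 * (hx + hy) / hb)


def _fst_components(
    x_matrix: np.ndarray, y_matrix: np.ndarray
) -> tuple[float, float]:
    """Window (numerator, denominator) sums for ratio-of-averages F_ST.

    Per site: numerator Hb - Hw (unclamped), denominator Hb.  Sites with
    fewer than two valid haplotypes in either group, or Hb = 0, contribute
    nothing.
    """
    cx, nx = _site_counts(x_matrix)
    cy, ny = _site_counts(y_matrix)
    hx = _within_het(cx, nx)
    hy = _within_het(cy, ny)
    hb = _between_het(cx, nx, cy, ny)
    ok = ~np.isnan(hx) & ~np.isnan(hy) & ~np.isnan(hb) & (hb > 0)
    hw = 0.5 * (hx + hy)
    num = float(np.sum((hb - hw)[ok]))
    den = float(np.sum(hb[ok]))
    return num, den


def window_fst(panel: HaplotypePanel, window: Window) -> float | None:
    """Ratio-of-averages Hudson F_ST between X- and Y-labelled haplotypes."""
    sub = panel.in_window(window)
    num, den = _fst_components(sub.select(LABEL_X), sub.select(LABEL_Y))
    if den == 0.0:
        return None
    return num / den


# ---------------------------------------------------------------- diversity

def _pi_sum(matrix: np.ndarray) -> float:
    """Sum over sites of mean pairwise difference within ``matrix``."""
    c, n = _site_counts(matrix)
    h = _within_het(c, n)
    return float(np.nansum(h))


def window_pi(
    panel_or_matrix, window: Window, label: str | None = None
) -> float | None:
    """Nucleotide diversity per bp: mean pairwise differences / window size."""
    if isinstance(panel_or_matrix, HaplotypePanel):
        sub = panel_or_matrix.in_window(window)
        matrix = sub.alleles if label is None else sub.select(label)
    else:
        matrix = np.asarray(panel_or_matrix)
    if matrix.shape[0] < 2:
        return None
    return _pi_sum(matrix) / window.size


def window_dxy(
    panel_a: np.ndarray | HaplotypePanel,
    panel_b: np.ndarray | HaplotypePanel,
    window: Window,
    label_a: str | None = None,
    label_b: str | None = None,
) -> float:
    """Mean between-group pairwise divergence (K) per bp of window."""
    def to_matrix(p, label):
        if isinstance(p, HaplotypePanel):
            sub = p.in_window(window)
            return sub.alleles if label is None else sub.select(label)
        m = np.asarray(p)
        return m
    a = to_matrix(panel_a, label_a)
    b = to_matrix(panel_b, label_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("dxy requires at least one haplotype per panel")
    ca, na = _site_counts(a)
    cb, nb = _site_counts(b)
    hb = _between_het(ca, na, cb, nb)
    return float(np.nansum(hb)) / window.size


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(
    panel_or_matrix, window: Window | None = None, label: str | None = None
) -> float | None:
    """Tajima's D with the standard 1989 constants; None when S=0 or n<4."""
    if isinstance(panel_or_matrix, HaplotypePanel):
        sub = panel_or_matrix.in_window(window) if window else panel_or_matrix
        matrix = sub.alleles if label is None else sub.select(label)
    else:
        matrix = np.asarray(panel_or_matrix)
    n = matrix.shape[0]
    if n < 4:
        return None
    c, nv = _site_counts(matrix)
    seg = (c > 0) & (c < nv)
    s = int(np.sum(seg))
    if s == 0:
        return None
    pi = _pi_sum(matrix)
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return (pi - s / a1) / float(np.sqrt(var))


# ---------------------------------------------------------------- depth

def depth_ratio(
    table: VariantTable,
    sons: list[str],
    daughters: list[str],
    window: Window,
) -> float | None:
    """Sons/daughters mean depth ratio in a window.

    Each individual's depths are first divided by that individual's mean over
    all sites in the table (library-size normalization); the ratio is then
    (mean normalized son depth) / (mean normalized daughter depth).
    """
    if not sons or not daughters:
        raise ValueError("need at least one son and one daughter")
    son_idx = [table.sample_index(s) for s in sons]
    dau_idx = [table.sample_index(s) for s in daughters]
    dp = table.dp.astype(float)
    dp[dp < 0] = np.nan
    ind_mean = np.nanmean(dp, axis=0)
    if np.any(ind_mean == 0):
        return None
    norm = dp / ind_mean[None, :]
    in_win = (table.positions >= window.start_bp) & (table.positions < window.end_bp)
    if not np.any(in_win):
        return None
    son_mean = float(np.nanmean(norm[np.ix_(in_win, son_idx)]))
    dau_mean = float(np.nanmean(norm[np.ix_(in_win, dau_idx)]))
    if dau_mean == 0 or np.isnan(dau_mean) or np.isnan(son_mean):
        return None
    return son_mean / dau_mean


# ---------------------------------------------------------------- gene trees

def _pairwise_difference_matrix(matrix: np.ndarray) -> np.ndarray:
    """Counts of differing sites for all haplotype pairs (missing excluded)."""
    n = matrix.shape[0]
    valid = matrix != MISSING
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = (matrix[i] != matrix) & both
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return d


def gene_tree_consistency(
    panel: HaplotypePanel, window: Window
) -> tuple[bool | None, str | None]:
    """Neighbour-joining tree of X+Y haplotypes; True iff Y is monophyletic.

    Monophyly is evaluated as presence of the X|Y bipartition in the
    unrooted tree.  Returns (None, None) when the window has no variation or
    fewer than 3 haplotypes per class.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    sub = panel.in_window(window)
    focal = (sub.labels == LABEL_X) | (sub.labels == LABEL_Y)
    matrix = sub.alleles[focal]
    labels = sub.labels[focal]
    names = [n for n, keep in zip(sub.names, focal) if keep]
    n_x = int(np.sum(labels == LABEL_X))
    n_y = int(np.sum(labels == LABEL_Y))
    if n_x < 3 or n_y < 3:
        raise ValueError("need at least 3 X and 3 Y haplotypes")
    d = _pairwise_difference_matrix(matrix)
    if not np.any(d > 0):
        return None, None
    tree = nj(DistanceMatrix(d, ids=names))
    y_set = frozenset(n for n, lab in zip(names, labels) if lab == LABEL_Y)
    all_set = frozenset(names)
    consistent = False
    for node in tree.non_tips(include_self=True):
        tips = frozenset(t.name for t in node.tips())
        if tips == y_set or (all_set - tips) == y_set:
            consistent = True
            break
    return consistent, str(tree).strip()


def detect_boundary(
    values, window_starts
) -> int | None:
    """Binary-segmentation change point over an ordered window series.

    Splits the series at the index minimizing within-segment squared error
    (equivalently maximizing the between-segment mean difference) and
    returns the start position of the first window right of the change
    point — the first PAR window when the SDR lies leftmost.  Returns None
    for a constant series (no boundary detectable).
    """
    v = np.asarray([np.nan if x is None else float(x) for x in values], dtype=float)
    starts = np.asarray(window_starts, dtype=np.int64)
    if v.size != starts.size:
        raise ValueError("values and window_starts must align")
    ok = ~np.isnan(v)
    v, starts = v[ok], starts[ok]
    if v.size < 2 or np.all(v == v[0]):
        return None
    best_k, best_gain = None, -np.inf
    total_mean = v.mean()
    sse_total = float(np.sum((v - total_mean) ** 2))
    for k in range(1, v.size):
        left, right = v[:k], v[k:]
        sse = float(np.sum((left - left.mean()) ** 2)
                    + np.sum((right - right.mean()) ** 2))
        gain = sse_total - sse
        if gain > best_gain:
            best_gain, best_k = gain, k
    return int(starts[best_k])


# ---------------------------------------------------------------- dN/dS

@dataclass
class DnDsRecord:
    gene_id: str
    nd: float          # nonsynonymous differences
    sd: float          # synonymous differences
    n_sites: float     # nonsynonymous sites (Nei-Gojobori)
    s_sites: float     # synonymous sites
    dn: float | None
    ds: float | None
    ratio: float | None
    n_codons: int = 0


def _codon_table() -> dict[str, str]:
    from Bio.Data import CodonTable

    t = CodonTable.unambiguous_dna_by_id[1]
    table = dict(t.forward_table)
    for stop in t.stop_codons:
        table[stop] = "*"
    return table


_CODONS = _codon_table()
_BASES = "ACGT"


def _syn_sites(codon: str) -> float:
    """Synonymous site count of a codon (stops count as nonsynonymous)."""
    aa = _CODONS[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODONS[alt] == aa:
                syn += 1.0
    return syn / 3.0


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average syn/nonsyn step counts over all equal-weight mutation paths."""
    from itertools import permutations

    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    non_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        syn = non = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODONS[cur] == "*" or _CODONS[nxt] == "*":
                non += 1.0  # changes through stop codons count as nonsynonymous
            elif _CODONS[cur] == _CODONS[nxt]:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        syn_total += syn
        non_total += non
        n_paths += 1
    return syn_total / n_paths, non_total / n_paths


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def dnds(cds_a: str, cds_b: str, gene_id: str = "gene") -> DnDsRecord:
    """Nei-Gojobori pathway-counting dN/dS between two aligned CDS.

    Codons containing ambiguous bases (non-ACGT) in either sequence are
    skipped; internal stop codons are an error.  Jukes-Cantor correction is
    applied when the raw proportions are below 3/4; the ratio is undefined
    (None) when ds is 0 or uncorrectable.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("CDS must be aligned to equal length")
    if len(a) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    sd = nd = 0.0
    s_sites = n_sites = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if _CODONS[ca] == "*" or _CODONS[cb] == "*":
            if i + 3 < len(a):
                raise ValueError(f"internal stop codon at position {i + 1}")
            continue  # terminal stop excluded from counting
        n_codons += 1
        s_a, s_b = _syn_sites(ca), _syn_sites(cb)
        s_sites += 0.5 * (s_a + s_b)
        n_sites += 3.0 - 0.5 * (s_a + s_b)
        syn, non = _path_counts(ca, cb)
        sd += syn
        nd += non
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps) if s_sites > 0 else None
    dn = _jukes_cantor(pn) if n_sites > 0 else None
    ratio = None
    if ds is not None and dn is not None and ds > 0:
        ratio = dn / ds
    return DnDsRecord(
        gene_id=gene_id, nd=nd, sd=sd, n_sites=n_sites, s_sites=s_sites,
        dn=dn, ds=ds, ratio=ratio, n_codons=n_codons,
    )


# ---------------------------------------------------------------- tables

def count_focal_snps(panel: HaplotypePanel, window: Window) -> int:
    """Sites polymorphic among the X+Y (focal) haplotypes in the window."""
    sub = panel.in_window(window)
    focal = sub.alleles[(sub.labels == LABEL_X) | (sub.labels == LABEL_Y)]
    c, n = _site_counts(focal)
    return int(np.sum((c > 0) & (c < n)))


def stats_frame(
    panel: HaplotypePanel,
    windows: list[Window],
    table: VariantTable | None = None,
    sons: list[str] | None = None,
    daughters: list[str] | None = None,
) -> pd.DataFrame:
    """Per-window statistics table (10 kb scale by default)."""
    has_sister = bool(np.any(panel.labels == LABEL_SISTER))
    rows = []
    for w in windows:
        sub = panel.in_window(w)
        focal_mask = (sub.labels == LABEL_X) | (sub.labels == LABEL_Y)
        fst = window_fst(panel, w)
        rec = {
            "chrom": w.chrom,
            "start_bp": w.start_bp,
            "end_bp": w.end_bp,
            "n_snps": count_focal_snps(panel, w),
            # negative ratio-of-averages estimates are reported as 0
            "fst": fst if fst is None else max(0.0, fst),
            "pi_x": window_pi(sub.select(LABEL_X), w),
            "pi_y": window_pi(sub.select(LABEL_Y), w),
            "pi_all": window_pi(sub.alleles[focal_mask], w),
            "k_xy": window_dxy(sub.select(LABEL_X), sub.select(LABEL_Y), w),
            "tajima_d": tajimas_d(sub.alleles[focal_mask], w),
        }
        if has_sister:
            rec["k_species"] = window_dxy(
                sub.alleles[focal_mask], sub.select(LABEL_SISTER), w
            )
        else:
            rec["k_species"] = np.nan
        if table is not None and sons and daughters:
            rec["depth_ratio"] = depth_ratio(table, sons, daughters, w)
        else:
            rec["depth_ratio"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def tree_frame(panel: HaplotypePanel, windows: list[Window]) -> pd.DataFrame:
    """XY gene-tree consistency per (100 kb) window, with Newick trees."""
    rows = []
    for w in windows:
        try:
            consistent, newick = gene_tree_consistency(panel, w)
        except ValueError:
            consistent, newick = None, None
        rows.append(
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "xy_consistent": consistent,
                "newick": newick,
            }
        )
    return pd.DataFrame(rows)
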