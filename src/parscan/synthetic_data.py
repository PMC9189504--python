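"""Synthetic pedigree-cross data with known truth.

Generates phased X/Y/sister haplotype panels over a chromosome split into a
non-recombining SDR and a recombining PAR, optionally plants windows with an
X-Y allele-frequency differential, and renders hybrid crosses (father,
mother, one son, one daughter) into a multi-sample VCF with realistic
QUAL/GQ/DP noise.  Every generated object is paired with a TruthSet so
downstream phasing and scan results can be checked exactly.

Haplotypes come from a parametric mosaic model, not an ancestral
recombination graph: per-site derived-allele frequencies are drawn from a
neutral-like 1/i spectrum, X-Y divergence is injected per stratum, and
species divergence as fixed differences.  The coalescent_sim module provides
the model-faithful null; this module provides controlled truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import LABEL_SISTER, LABEL_X, LABEL_Y, MISSING, HaplotypePanel, Trio, Window

__all__ = [
    "Stratum",
    "PanelConfig",
    "CrossDesign",
    "TruthSet",
    "simulate_sex_panels",
    "plant_sas_window",
    "simulate_crosses",
]


class InvalidConfigError(ValueError):
    """Raised for non-positive lengths/intensities or impossible designs."""


@dataclass(frozen=True)
class Stratum:
    """SDR block with its own degeneration level.

    ``y_depth_factor`` scales read depth of the Y copy in males (1.0 = no
    degeneration); ``xy_divergence_scale`` is the per-10kb intensity of fixed
    X-Y differences.
    """

    start_bp: int
    end_bp: int
    y_depth_factor: float = 1.0
    xy_divergence_scale: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.y_depth_factor <= 1.0):
            raise InvalidConfigError("y_depth_factor must be in (0, 1]")
        if self.xy_divergence_scale < 0:
            raise InvalidConfigError("xy_divergence_scale must be >= 0")
        if self.end_bp <= self.start_bp:
            raise InvalidConfigError("stratum end must exceed start")


@dataclass
class PanelConfig:
    """Generator parameters for :func:`simulate_sex_panels`."""

    chrom: str = "chr9"
    chrom_length_bp: int = 12_000_000
    sdr_boundary_bp: int = 6_900_000  # SDR = [1, boundary), PAR = [boundary, L]
    snp_per_10kb: float = 10.0
    species_divergence_per_10kb: float = 10.0
    n_x: int = 15
    n_y: int = 15
    n_sister: int = 26
    strata: list[Stratum] | None = None

    def __post_init__(self) -> None:
        if self.chrom_length_bp <= 0:
            raise InvalidConfigError("chromosome length must be positive")
        if self.snp_per_10kb <= 0:
            raise InvalidConfigError("SNP intensity must be positive")
        if self.species_divergence_per_10kb < 0:
            raise InvalidConfigError("species divergence scale must be >= 0")
        if not (1 <= self.sdr_boundary_bp <= self.chrom_length_bp):
            raise InvalidConfigError("SDR boundary outside the chromosome")
        if min(self.n_x, self.n_y) < 2 or self.n_sister < 1:
            raise InvalidConfigError("need >=2 X, >=2 Y and >=1 sister haplotype")
        if self.strata is None:
            if self.sdr_boundary_bp > 1:
                self.strata = [
                    Stratum(1, self.sdr_boundary_bp, y_depth_factor=0.5,
                            xy_divergence_scale=5.0)
                ]
            else:
                self.strata = []
        for s in self.strata:
            if s.end_bp > self.sdr_boundary_bp:
                raise InvalidConfigError("strata must lie inside the SDR")

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "chrom_length_bp": self.chrom_length_bp,
            "sdr_boundary_bp": self.sdr_boundary_bp,
            "snp_per_10kb": self.snp_per_10kb,
            "species_divergence_per_10kb": self.species_divergence_per_10kb,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "n_sister": self.n_sister,
            "strata": [
                (s.start_bp, s.end_bp, s.y_depth_factor, s.xy_divergence_scale)
                for s in (self.strata or [])
            ],
        }


@dataclass
class CrossDesign:
    """Pedigree layout for :func:`simulate_crosses`.

    The default reproduces the study design scale: 15 crosses, 13 mothers
    with one mother used three times, one son and one daughter per cross,
    58 individuals in total.
    """

    n_crosses: int = 15
    n_mothers: int = 13
    mother_reuse: Mapping[str, int] | None = None  # mother id -> #crosses
    mean_depth: float = 28.0
    depth_dispersion: float = 10.0  # gamma shape of the overdispersed depth model
    genotyping_error: float = 0.0   # per-allele flip probability
    missing_rate: float = 0.0       # per-genotype dropout probability

    def __post_init__(self) -> None:
        if self.n_crosses < 1 or self.n_mothers < 1:
            raise InvalidConfigError("need at least one cross and one mother")
        if self.n_mothers > self.n_crosses:
            raise InvalidConfigError("more mothers than crosses")
        if self.mother_reuse is None:
            extra = self.n_crosses - self.n_mothers
            self.mother_reuse = {self.mother_names[0]: 1 + extra}
        total = sum(
            self.mother_reuse.get(m, 1) for m in self.mother_names
        )
        if total != self.n_crosses:
            raise InvalidConfigError(
                f"mother usage sums to {total}, expected {self.n_crosses}"
            )
        if not (0 <= self.genotyping_error < 0.5 and 0 <= self.missing_rate < 1):
            raise InvalidConfigError("error/missing rates out of range")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise InvalidConfigError("depth parameters must be positive")

    @property
    def father_names(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(self.n_crosses)]

    @property
    def mother_names(self) -> list[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_mothers)]

    @property
    def son_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_crosses)]

    @property
    def daughter_names(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_crosses)]

    @property
    def sample_names(self) -> list[str]:
        return (self.father_names + self.mother_names
                + self.son_names + self.daughter_names)

    @property
    def n_individuals(self) -> int:
        return self.n_crosses + self.n_mothers + 2 * self.n_crosses

    def cross_mothers(self) -> list[str]:
        """Mother assigned to each cross, honouring the reuse map."""
        out: list[str] = []
        for m in self.mother_names:
            out.extend([m] * self.mother_reuse.get(m, 1))
        return out[: self.n_crosses]

    def pedigree(self) -> list[Trio]:
        mothers = self.cross_mothers()
        trios = []
        for i in range(self.n_crosses):
            trios.append(Trio(self.son_names[i], self.father_names[i], mothers[i], "M"))
            trios.append(Trio(self.daughter_names[i], self.father_names[i], mothers[i], "F"))
        return trios


@dataclass
class TruthSet:
    """Everything the generator knows that the pipeline must recover."""

    sdr_boundary_bp: int
    strata: list[Stratum] = field(default_factory=list)
    planted_sas: list[tuple[Window, float]] = field(default_factory=list)
    phase_truth: dict[str, np.ndarray] = field(default_factory=dict)
    positions: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for window, delta in self.planted_sas:
            if window.start_bp < self.sdr_boundary_bp:
                raise InvalidConfigError("planted window lies inside the SDR")
            if not (0.0 <= delta <= 1.0):
                raise InvalidConfigError("delta must be in [0, 1]")


def _sfs_frequencies(rng: np.random.Generator, n_sites: int, n_hap: int) -> np.ndarray:
    """Derived-allele counts drawn from a neutral-like 1/i spectrum."""
    counts = np.arange(1, n_hap)
    w = 1.0 / counts
    return rng.choice(counts, size=n_sites, p=w / w.sum())


def _poisson_positions(
    rng: np.random.Generator, start_bp: int, end_bp: int, per_10kb: float
) -> np.ndarray:
    """Uniformly scattered positions at the given per-10kb intensity."""
    span = end_bp - start_bp
    if span <= 0 or per_10kb <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(per_10kb * span / 10_000.0)
    return rng.integers(start_bp, end_bp, size=n).astype(np.int64)


def simulate_sex_panels(
    config: PanelConfig, seed: int
) -> tuple[HaplotypePanel, TruthSet]:
    """Generate X/Y/sister haplotypes with SDR + PAR architecture.

    Inside the SDR, Y haplotypes are identical to one another (no
    recombination since the sweep) and carry stratum-specific fixed
    differences from the X; inside the PAR, X and Y labels are exchangeable.
    Sister-species haplotypes are monomorphic, differing from the focal
    ancestral state only at species-divergence sites.
    """
    rng = np.random.default_rng(seed)
    n_focal = config.n_x + config.n_y
    n_total = n_focal + config.n_sister
    x_rows = np.arange(config.n_x)
    y_rows = np.arange(config.n_x, n_focal)
    sister_rows = np.arange(n_focal, n_total)

    pos_chunks: list[np.ndarray] = []
    col_chunks: list[np.ndarray] = []

    def add_sites(positions: np.ndarray, fill) -> None:
        if positions.size == 0:
            return
        cols = np.zeros((n_total, positions.size), dtype=np.int8)
        fill(cols)
        pos_chunks.append(positions)
        col_chunks.append(cols)

    boundary = config.sdr_boundary_bp
    # PAR polymorphism: exchangeable across X and Y rows
    par_pos = _poisson_positions(rng, boundary, config.chrom_length_bp + 1,
                                 config.snp_per_10kb)
    if par_pos.size:
        counts = _sfs_frequencies(rng, par_pos.size, n_focal)

        def fill_par(cols: np.ndarray) -> None:
            for j, c in enumerate(counts):
                carriers = rng.choice(n_focal, size=c, replace=False)
                cols[carriers, j] = 1

        add_sites(par_pos, fill_par)

    # SDR polymorphism: segregates on the X only; Y copies are clonal
    if boundary > 1:
        sdr_pos = _poisson_positions(rng, 1, boundary, config.snp_per_10kb)
        if sdr_pos.size:
            counts = _sfs_frequencies(rng, sdr_pos.size, config.n_x)

            def fill_sdr(cols: np.ndarray) -> None:
                for j, c in enumerate(counts):
                    carriers = rng.choice(x_rows, size=c, replace=False)
                    cols[carriers, j] = 1

            add_sites(sdr_pos, fill_sdr)

    # fixed X-Y differences per stratum
    for stratum in config.strata or []:
        div_pos = _poisson_positions(rng, stratum.start_bp, stratum.end_bp,
                                     stratum.xy_divergence_scale)

        def fill_div(cols: np.ndarray) -> None:
            cols[y_rows, :] = 1

        add_sites(div_pos, fill_div)

    # species divergence: sister fixed derived, focal ancestral
    spd_pos = _poisson_positions(rng, 1, config.chrom_length_bp + 1,
                                 config.species_divergence_per_10kb)

    def fill_species(cols: np.ndarray) -> None:
        cols[sister_rows, :] = 1

    add_sites(spd_pos, fill_species)

    if pos_chunks:
        positions = np.concatenate(pos_chunks)
        alleles = np.concatenate(col_chunks, axis=1)
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        alleles = alleles[:, order]
        keep = np.ones(positions.size, dtype=bool)
        keep[1:] = np.diff(positions) > 0  # drop positional collisions
        positions = positions[keep]
        alleles = alleles[:, keep]
    else:
        positions = np.empty(0, dtype=np.int64)
        alleles = np.zeros((n_total, 0), dtype=np.int8)

    labels = np.array(
        [LABEL_X] * config.n_x + [LABEL_Y] * config.n_y
        + [LABEL_SISTER] * config.n_sister
    )
    names = (
        [f"X{i + 1:02d}" for i in range(config.n_x)]
        + [f"Y{i + 1:02d}" for i in range(config.n_y)]
        + [f"T{i + 1:02d}" for i in range(config.n_sister)]
    )
    panel = HaplotypePanel(config.chrom, positions, alleles, labels, names)
    truth = TruthSet(
        sdr_boundary_bp=boundary,
        strata=list(config.strata or []),
        positions=positions.copy(),
        seed=seed,
    )
    return panel, truth


def plant_sas_window(
    panel: HaplotypePanel,
    window: Window,
    delta: float,
    sdr_boundary_bp: int = 0,
    n_sites: int = 1,
    seed: int = 0,
    truth: TruthSet | None = None,
) -> HaplotypePanel:
    """Inject an X-Y allele-frequency differential of ``delta`` into a window.

    At ``n_sites`` sites inside the window the derived allele is fixed on the
    X and set to frequency ``1 - delta`` on the Y (rounded to the nearest
    achievable count).  Refuses windows overlapping the SDR, where the signal
    would be confounded with recombination suppression.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    if window.start_bp < sdr_boundary_bp:
        raise ValueError(
            f"window {window.label} overlaps the SDR (boundary "
            f"{sdr_boundary_bp}); refusing to plant a confounded signal"
        )
    out = panel.copy()
    if delta == 0.0:
        return out
    sl = out.site_slice(window)
    sites = np.arange(sl.start, sl.stop)
    if sites.size == 0:
        raise ValueError(f"no sites in window {window.label} to plant at")
    rng = np.random.default_rng(seed)
    x_rows = np.flatnonzero(out.labels == LABEL_X)
    y_rows = np.flatnonzero(out.labels == LABEL_Y)
    n_y = y_rows.size
    cy = int(round((1.0 - delta) * n_y))
    chosen = sites[: min(n_sites, sites.size)]
    for s in chosen:
        out.alleles[x_rows, s] = 1
        out.alleles[y_rows, s] = 0
        if cy:
            out.alleles[rng.choice(y_rows, size=cy, replace=False), s] = 1
    if truth is not None:
        truth.planted_sas.append((window, delta))
    return out


def _depth_factor_by_site(
    positions: np.ndarray, strata: list[Stratum]
) -> np.ndarray:
    """Per-site Y-copy depth factor (1.0 outside degenerate strata)."""
    factor = np.ones(positions.size)
    for s in strata:
        mask = (positions >= s.start_bp) & (positions < s.end_bp)
        factor[mask] = s.y_depth_factor
    return factor


def simulate_crosses(
    panel: HaplotypePanel,
    design: CrossDesign,
    seed: int,
    truth: TruthSet | None = None,
) -> tuple["VariantTable", TruthSet]:
    """Render crosses from a haplotype panel into a genotyped VariantTable.

    Father ``i`` carries (X_i, Y_i); each mother carries two sister-species
    haplotypes.  Sons inherit the father's Y, daughters his X; both inherit
    one maternal haplotype.  Depth is overdispersed-Poisson around the
    per-individual mean, with the Y copy of males scaled by the stratum's
    ``y_depth_factor``.  Genotyping error (per-allele flips) and missingness
    are applied after phase truth is recorded.
    """
    from .core import VariantTable

    rng = np.random.default_rng(seed)
    n_x = int(np.sum(panel.labels == LABEL_X))
    n_y = int(np.sum(panel.labels == LABEL_Y))
    n_sister = int(np.sum(panel.labels == LABEL_SISTER))
    if design.n_crosses > min(n_x, n_y):
        raise InvalidConfigError(
            f"design needs {design.n_crosses} X and Y haplotypes, panel has "
            f"{n_x} X / {n_y} Y"
        )
    if 2 * design.n_mothers > n_sister:
        raise InvalidConfigError(
            f"design needs {2 * design.n_mothers} sister haplotypes, panel has {n_sister}"
        )

    x_h = panel.select(LABEL_X)
    y_h = panel.select(LABEL_Y)
    s_h = panel.select(LABEL_SISTER)
    n_sites = panel.n_sites
    samples = design.sample_names
    n_samp = len(samples)
    idx = {name: j for j, name in enumerate(samples)}

    hap_a = np.zeros((n_samp, n_sites), dtype=np.int8)  # paternal / first copy
    hap_b = np.zeros((n_samp, n_sites), dtype=np.int8)  # maternal / second copy
    is_male = np.zeros(n_samp, dtype=bool)
    # depth factor of copy A per individual per site (Y copies degenerate)
    strata = truth.strata if truth is not None else []
    site_factor = _depth_factor_by_site(panel.positions, strata)
    a_is_y = np.zeros(n_samp, dtype=bool)

    mothers_of_cross = design.cross_mothers()
    mother_haps = {
        m: (s_h[2 * j], s_h[2 * j + 1]) for j, m in enumerate(design.mother_names)
    }
    phase_truth: dict[str, np.ndarray] = {}
    for i in range(design.n_crosses):
        f, m = design.father_names[i], mothers_of_cross[i]
        son, dau = design.son_names[i], design.daughter_names[i]
        hap_a[idx[f]] = y_h[i]
        hap_b[idx[f]] = x_h[i]
        is_male[idx[f]] = True
        a_is_y[idx[f]] = True
        ma, mb = mother_haps[m]
        hap_a[idx[m]] = ma
        hap_b[idx[m]] = mb
        son_mat = ma if rng.random() < 0.5 else mb
        dau_mat = ma if rng.random() < 0.5 else mb
        hap_a[idx[son]] = y_h[i]
        hap_b[idx[son]] = son_mat
        is_male[idx[son]] = True
        a_is_y[idx[son]] = True
        hap_a[idx[dau]] = x_h[i]
        hap_b[idx[dau]] = dau_mat
        phase_truth[son] = y_h[i].copy()
        phase_truth[dau] = x_h[i].copy()

    # depth model: per-individual mean, gamma-Poisson per genotype, Y-copy scaling
    ind_mean = design.mean_depth * rng.uniform(0.85, 1.15, size=n_samp)
    copy_a_factor = np.where(
        a_is_y[:, None], site_factor[None, :], 1.0
    )  # (n_samp, n_sites)
    mean_matrix = ind_mean[:, None] * (copy_a_factor + 1.0) / 2.0
    shape = design.depth_dispersion
    lam = rng.gamma(shape, mean_matrix / shape)
    dp = rng.poisson(lam).astype(np.int32).T  # (n_sites, n_samp)

    gt = np.stack([hap_a.T, hap_b.T], axis=2).astype(np.int8)  # (sites, samp, 2)
    # randomize the unordered genotype presentation
    swap = rng.random(gt.shape[:2]) < 0.5
    gt_out = gt.copy()
    gt_out[swap] = gt[swap][:, ::-1]

    if design.genotyping_error > 0:
        flips = rng.random(gt_out.shape) < design.genotyping_error
        gt_out = np.where(flips, 1 - gt_out, gt_out)
    if design.missing_rate > 0:
        drop = rng.random(gt_out.shape[:2]) < design.missing_rate
        gt_out[drop] = MISSING

    gq = np.full((n_sites, n_samp), 99, dtype=np.int16)
    qual = np.full(n_sites, 999.0)

    table = VariantTable(
        chrom=panel.chrom,
        positions=panel.positions.copy(),
        qual=qual,
        samples=samples,
        gt=gt_out,
        gq=gq,
        dp=dp,
        ref=np.full(n_sites, "A", dtype="U8"),
        alt=np.full(n_sites, "G", dtype="U8"),
    )
    out_truth = truth if truth is not None else TruthSet(
        sdr_boundary_bp=0, positions=panel.positions.copy()
    )
    out_truth.phase_truth = phase_truth
    out_truth.seed = seed
    return table, out_truth
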