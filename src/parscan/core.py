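"""Core in-memory data structures shared across the pipeline.

Two array-backed containers do most of the work: :class:`HaplotypePanel`
(phased chromosome copies by variant site) and :class:`VariantTable`
(unphased multi-sample genotypes with per-site QUAL and per-genotype GQ/DP).
Positions are 1-based throughout, matching VCF; windows are half-open
``[start, start + size)`` intervals tiling the chromosome from position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

MISSING = -1  # sentinel for missing allele / genotype calls

LABEL_X = "X"
LABEL_Y = "Y"
LABEL_SISTER = "S"


@dataclass
class Window:
    """Half-open genomic interval [start_bp, end_bp) with 1-based start."""

    chrom: str
    start_bp: int
    end_bp: int

    @property
    def size(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


def tile_windows(chrom: str, length_bp: int, size: int, start: int = 1) -> list[Window]:
    """Non-overlapping windows of ``size`` bp tiling [start, length_bp]."""
    if size <= 0 or length_bp <= 0:
        raise ValueError("window size and chromosome length must be positive")
    out = []
    pos = start
    while pos <= length_bp:
        out.append(Window(chrom, pos, pos + size))
        pos += size
    return out


@dataclass
class HaplotypePanel:
    """Phased haplotypes: rows are chromosome copies, columns variant sites.

    ``alleles`` holds 0/1 codes (biallelic sites) with ``MISSING`` for
    unresolved calls.  ``labels`` assigns each row to a class: "X" or "Y"
    for the focal species, "S" for sister-species haplotypes.
    """

    chrom: str
    positions: np.ndarray          # (n_sites,) int64, 1-based, strictly increasing
    alleles: np.ndarray            # (n_hap, n_sites) int8
    labels: np.ndarray             # (n_hap,) unicode
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions / alleles shape mismatch")
        if self.labels.size != self.alleles.shape[0]:
            raise ValueError("labels / alleles shape mismatch")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not self.names:
            self.names = [f"hap{i}" for i in range(self.alleles.shape[0])]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def select(self, label: str) -> np.ndarray:
        """Allele matrix restricted to rows with the given label."""
        return self.alleles[self.labels == label]

    def site_slice(self, window: Window) -> slice:
        lo = int(np.searchsorted(self.positions, window.start_bp, side="left"))
        hi = int(np.searchsorted(self.positions, window.end_bp, side="left"))
        return slice(lo, hi)

    def in_window(self, window: Window) -> "HaplotypePanel":
        sl = self.site_slice(window)
        return HaplotypePanel(
            self.chrom,
            self.positions[sl],
            self.alleles[:, sl],
            self.labels,
            list(self.names),
        )

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            self.chrom,
            self.positions.copy(),
            self.alleles.copy(),
            self.labels.copy(),
            list(self.names),
        )


@dataclass
class VariantTable:
    """Unphased multi-sample genotype matrix with QUAL/GQ/DP annotations.

    ``gt`` has shape (n_sites, n_samples, 2) with allele indices or MISSING.
    ``n_alleles`` counts REF + ALT alleles at each site (2 == biallelic).
    """

    chrom: str
    positions: np.ndarray           # (n_sites,) int64
    qual: np.ndarray                # (n_sites,) float64
    samples: list[str]
    gt: np.ndarray                  # (n_sites, n_samples, 2) int8
    gq: np.ndarray                  # (n_sites, n_samples) int16
    dp: np.ndarray                  # (n_sites, n_samples) int32
    ref: np.ndarray | None = None   # (n_sites,) unicode
    alt: np.ndarray | None = None   # (n_sites,) unicode (first ALT)
    n_alleles: np.ndarray | None = None
    is_snp: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_sites = len(self.positions)
        n_samp = len(self.samples)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=np.float64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=np.int16)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        if self.gt.shape != (n_sites, n_samp, 2):
            raise ValueError("gt must have shape (n_sites, n_samples, 2)")
        if self.n_alleles is None:
            self.n_alleles = np.full(n_sites, 2, dtype=np.int16)
        if self.is_snp is None:
            self.is_snp = np.ones(n_sites, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in table") from None

    def site_mean_depth(self) -> np.ndarray:
        """Per-site mean DP across samples with non-missing depth."""
        dp = self.dp.astype(float)
        ok = dp >= 0
        with np.errstate(invalid="ignore"):
            out = np.where(ok, dp, np.nan)
        return np.nanmean(out, axis=1)

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            chrom=self.chrom,
            positions=self.positions[mask],
            qual=self.qual[mask],
            samples=list(self.samples),
            gt=self.gt[mask],
            gq=self.gq[mask],
            dp=self.dp[mask],
            ref=None if self.ref is None else self.ref[mask],
            alt=None if self.alt is None else self.alt[mask],
            n_alleles=self.n_alleles[mask],
            is_snp=self.is_snp[mask],
        )


@dataclass(frozen=True)
class Trio:
    """One phasing trio: an offspring with its father and mother."""

    child: str
    father: str
    mother: str
    sex: str  # "M" (son) or "F" (daughter)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


def iter_pedigree_trios(rows: Sequence[Trio]) -> Iterator[Trio]:
    seen: set[str] = set()
    for trio in rows:
        if trio.child in seen:
            raise ValueError(f"duplicated offspring {trio.child!r} in pedigree")
        seen.add(trio.child)
        yield trio
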