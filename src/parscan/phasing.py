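"""Variant filtering and trio-based phasing of paternal sex chromosomes.

The phasing rule: at a site where an offspring is heterozygous, the paternal
allele is the one present in the father and absent in the mother.  Trios in
which father, mother and offspring are all heterozygous are unphasable;
offspring homozygous for an allele absent from a parent are Mendelian errors
and the site is dropped for that trio.  Offspring homozygous sites that pass
the Mendel check are phased trivially (the transmitted allele is the
homozygous one) and flagged distinctly in provenance.

Sons' paternal haplotypes are labelled Y, daughters' X (XY system).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    LABEL_X,
    LABEL_Y,
    MISSING,
    HaplotypePanel,
    Trio,
    VariantTable,
    iter_pedigree_trios,
)

__all__ = [
    "FilterThresholds",
    "PhasedPanel",
    "filter_variants",
    "phase_trio_site",
    "phase_panel",
]

# per-(trio, site) outcome codes
PHASED = 0        # heterozygous offspring, unique paternal allele
PHASED_HOM = 1    # homozygous offspring, transmitted allele trivially known
UNPHASABLE = 2    # offspring and both parents heterozygous
MENDEL_ERROR = 3  # offspring homozygous for an allele absent in a parent
UNINFORMATIVE = 4 # no allele is present in father and absent in mother
NO_CALL = 5       # a trio member's genotype is missing

CODE_NAMES = {
    PHASED: "phased",
    PHASED_HOM: "phased_hom",
    UNPHASABLE: "unphasable",
    MENDEL_ERROR: "mendel_error",
    UNINFORMATIVE: "uninformative",
    NO_CALL: "no_call",
}


@dataclass(frozen=True)
class FilterThresholds:
    """Site/genotype quality thresholds applied before phasing.

    Site mean depth is the across-sample mean at the site; the depth cap is
    ``max_depth_factor`` times the median of site mean depths over the
    chromosome (guarding against collapsed paralogues).  Genotypes below
    ``min_gq`` are set to missing rather than dropping the whole site.
    """

    min_qual: float = 999.0
    min_gq: int = 20
    min_mean_depth: float = 10.0
    max_depth_factor: float = 1.5
    biallelic_snps_only: bool = True
    max_missing_offspring: int = 5

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_gq, self.min_mean_depth) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_depth_factor <= 1:
            raise ValueError("max_depth_factor must exceed 1")
        if self.max_missing_offspring < 0:
            raise ValueError("max_missing_offspring must be non-negative")


@dataclass
class PhasedPanel:
    """Paternal haplotypes recovered from trios, as a labelled panel."""

    panel: HaplotypePanel                  # rows = offspring paternal haplotypes
    crosses: list[str] = field(default_factory=list)  # father id per row
    code_tally: dict[str, int] = field(default_factory=dict)
    n_sites_input: int = 0
    n_sites_dropped_missing: int = 0


def filter_variants(
    table: VariantTable, thresholds: FilterThresholds | None = None
) -> tuple[VariantTable, dict[str, int]]:
    """Apply site and genotype filters; returns (table, filter-reason tally).

    Reasons are tallied in application order (a site removed for low QUAL is
    not also counted against the depth filters).  Site order is preserved.
    """
    t = thresholds or FilterThresholds()
    if table.gq is None or table.dp is None:
        raise ValueError("VariantTable must carry GQ and DP fields")
    tally: dict[str, int] = {}
    keep = np.ones(table.n_sites, dtype=bool)

    if t.biallelic_snps_only:
        ok = (table.n_alleles == 2) & table.is_snp
        tally["not_biallelic_snp"] = int(np.sum(keep & ~ok))
        keep &= ok

    ok = np.nan_to_num(table.qual, nan=-1.0) >= t.min_qual
    tally["low_qual"] = int(np.sum(keep & ~ok))
    keep &= ok

    mean_dp = table.site_mean_depth()
    ok = mean_dp >= t.min_mean_depth
    tally["low_mean_depth"] = int(np.sum(keep & ~ok))
    keep &= ok

    median_dp = float(np.median(mean_dp)) if table.n_sites else 0.0
    ok = mean_dp <= t.max_depth_factor * median_dp
    tally["high_mean_depth"] = int(np.sum(keep & ~ok))
    keep &= ok

    out = table.subset_sites(keep)
    # genotype-level GQ mask: below-threshold calls become missing
    low_gq = (out.gq < t.min_gq) & (out.gq != MISSING)
    low_gq |= out.gq == MISSING
    tally["genotypes_masked_low_gq"] = int(np.sum(low_gq & np.any(out.gt != MISSING, axis=2)))
    out.gt = out.gt.copy()
    out.gt[low_gq] = MISSING
    tally["sites_retained"] = out.n_sites
    return out, tally


def phase_trio_site(
    father_gt: tuple[int, int],
    mother_gt: tuple[int, int],
    child_gt: tuple[int, int],
) -> tuple[int, int]:
    """Phase one (father, mother, child) genotype triple at one site.

    Returns ``(paternal_allele, code)``; the allele is ``MISSING`` unless the
    code is PHASED or PHASED_HOM.  Codes are data, not exceptions.
    """
    trio = (*father_gt, *mother_gt, *child_gt)
    if any(a == MISSING or a is None for a in trio):
        return MISSING, NO_CALL
    f0, f1, m0, m1, c0, c1 = (int(a) for a in trio)
    in_f = lambda a: a == f0 or a == f1
    in_m = lambda a: a == m0 or a == m1
    if c0 == c1:
        if not in_f(c0) or not in_m(c0):
            return MISSING, MENDEL_ERROR
        return c0, PHASED_HOM
    cand = [a for a in (c0, c1) if in_f(a) and not in_m(a)]
    if len(cand) == 1:
        return cand[0], PHASED
    if len(cand) == 2:
        # neither child allele is in the mother: Mendelian violation
        return MISSING, MENDEL_ERROR
    if f0 != f1 and m0 != m1:
        return MISSING, UNPHASABLE
    return MISSING, UNINFORMATIVE


def _phase_trio_vector(
    f: np.ndarray, m: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized phase_trio_site over all sites for one trio.

    ``f``, ``m``, ``c`` have shape (n_sites, 2).  Must agree with the scalar
    rule exactly (property-tested).
    """
    n = f.shape[0]
    allele = np.full(n, MISSING, dtype=np.int8)
    code = np.full(n, NO_CALL, dtype=np.int8)
    missing = (
        np.any(f == MISSING, axis=1)
        | np.any(m == MISSING, axis=1)
        | np.any(c == MISSING, axis=1)
    )
    ok = ~missing
    in_f = lambda a: (a == f[:, 0]) | (a == f[:, 1])
    in_m = lambda a: (a == m[:, 0]) | (a == m[:, 1])
    c0, c1 = c[:, 0], c[:, 1]
    hom = ok & (c0 == c1)
    hom_bad = hom & (~in_f(c0) | ~in_m(c0))
    hom_good = hom & ~hom_bad
    code[hom_bad] = MENDEL_ERROR
    code[hom_good] = PHASED_HOM
    allele[hom_good] = c0[hom_good]

    het = ok & (c0 != c1)
    cand0 = in_f(c0) & ~in_m(c0)
    cand1 = in_f(c1) & ~in_m(c1)
    one0 = het & cand0 & ~cand1
    one1 = het & cand1 & ~cand0
    code[one0] = PHASED
    allele[one0] = c0[one0]
    code[one1] = PHASED
    allele[one1] = c1[one1]
    both = het & cand0 & cand1
    code[both] = MENDEL_ERROR
    none = het & ~cand0 & ~cand1
    all_het = none & (f[:, 0] != f[:, 1]) & (m[:, 0] != m[:, 1])
    code[all_het] = UNPHASABLE
    code[none & ~all_het] = UNINFORMATIVE
    return allele, code


def phase_panel(
    table: VariantTable,
    pedigree: Sequence[Trio],
    max_missing_offspring: int = 5,
) -> PhasedPanel:
    """Phase every trio at every site and assemble the paternal panel.

    Sites where more than ``max_missing_offspring`` offspring (across all
    families) lack a phased call are dropped.  Expects an already-filtered
    table (see :func:`filter_variants`).
    """
    trios = list(iter_pedigree_trios(pedigree))
    for trio in trios:
        for who in (trio.child, trio.father, trio.mother):
            if who not in table.samples:
                raise ValueError(f"pedigree sample {who!r} not in VCF")
    n_sites = table.n_sites
    n_off = len(trios)
    alleles = np.full((n_off, n_sites), MISSING, dtype=np.int8)
    codes = np.full((n_off, n_sites), NO_CALL, dtype=np.int8)
    for k, trio in enumerate(trios):
        f = table.gt[:, table.sample_index(trio.father)].astype(np.int16)
        m = table.gt[:, table.sample_index(trio.mother)].astype(np.int16)
        c = table.gt[:, table.sample_index(trio.child)].astype(np.int16)
        alleles[k], codes[k] = _phase_trio_vector(f, m, c)

    phased_mask = (codes == PHASED) | (codes == PHASED_HOM)
    n_missing_per_site = n_off - phased_mask.sum(axis=0)
    keep = n_missing_per_site <= max_missing_offspring

    tally = {
        name: int(np.sum(codes == code)) for code, name in CODE_NAMES.items()
    }
    labels = np.array([LABEL_Y if t.sex == "M" else LABEL_X for t in trios])
    panel = HaplotypePanel(
        table.chrom,
        table.positions[keep],
        alleles[:, keep],
        labels,
        [t.child for t in trios],
    )
    return PhasedPanel(
        panel=panel,
        crosses=[t.father for t in trios],
        code_tally=tally,
        n_sites_input=n_sites,
        n_sites_dropped_missing=int(np.sum(~keep)),
    )


def filter_report_frame(tally: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        {"reason": list(tally.keys()), "count": list(tally.values())}
    )
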