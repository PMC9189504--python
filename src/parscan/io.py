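"""File I/O: VCFv4.2, pedigree TSV, haplotype-panel TSV, provenance headers.

VCF reading goes through :mod:`pysam`; writing emits plain uncompressed
VCF text so outputs remain diff-able.  All tabular outputs carry ``##``
header lines recording the package version, seed and config hash so any
artifact can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pysam

from . import __version__
from .core import MISSING, HaplotypePanel, Trio, VariantTable

_GT_CODE = {0: "0", 1: "1", MISSING: "."}


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serializable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, config: Any = None) -> list[str]:
    lines = [f"##parscan_version={__version__}"]
    if seed is not None:
        lines.append(f"##seed={seed}")
    if config is not None:
        lines.append(f"##config_hash={config_hash(config)}")
    return lines


def write_vcf(
    table: VariantTable,
    path: str | Path,
    seed: int | None = None,
    config: Any = None,
) -> None:
    """Write a VariantTable as uncompressed VCFv4.2 with GT:GQ:DP genotypes."""
    path = Path(path)
    ref = table.ref if table.ref is not None else np.full(table.n_sites, "A")
    alt = table.alt if table.alt is not None else np.full(table.n_sites, "G")
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        fh.write(f"##contig=<ID={table.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            fields = [
                table.chrom,
                str(int(table.positions[i])),
                ".",
                str(ref[i]),
                str(alt[i]),
                f"{table.qual[i]:g}",
                "PASS",
                ".",
                "GT:GQ:DP",
            ]
            for j in range(len(table.samples)):
                a, b = table.gt[i, j]
                if a == MISSING or b == MISSING:
                    g = "./."
                else:
                    g = f"{_GT_CODE.get(int(a), str(int(a)))}/{_GT_CODE.get(int(b), str(int(b)))}"
                gq = table.gq[i, j]
                dp = table.dp[i, j]
                fields.append(
                    f"{g}:{gq if gq >= 0 else '.'}:{dp if dp >= 0 else '.'}"
                )
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path, chrom: str | None = None) -> VariantTable:
    """Load a (single-chromosome) VCF into a VariantTable.

    Raises a format error when GQ or DP are absent from FORMAT, rather than
    silently passing sites through the depth/quality filters.
    """
    path = str(path)
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    if "GQ" not in vcf.header.formats or "DP" not in vcf.header.formats:
        raise ValueError(f"{path}: VCF FORMAT must declare GQ and DP")
    positions: list[int] = []
    quals: list[float] = []
    refs: list[str] = []
    alts: list[str] = []
    nall: list[int] = []
    snp: list[bool] = []
    gts: list[list[tuple[int, int]]] = []
    gqs: list[list[int]] = []
    dps: list[list[int]] = []
    seen_chrom = chrom
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        if chrom is not None and rec.chrom != chrom:
            continue
        if seen_chrom is None:
            seen_chrom = rec.chrom
        elif rec.chrom != seen_chrom:
            raise ValueError(
                f"{path}: multiple chromosomes present; pass chrom= explicitly"
            )
        positions.append(rec.pos)
        quals.append(rec.qual if rec.qual is not None else float("nan"))
        refs.append(rec.ref or "N")
        alts.append(rec.alts[0] if rec.alts else ".")
        alleles = [rec.ref or ""] + list(rec.alts or ())
        nall.append(len(alleles))
        snp.append(all(len(a) == 1 for a in alleles if a not in (".", "")))
        row_gt, row_gq, row_dp = [], [], []
        for s in samples:
            smp = rec.samples[s]
            gt = smp.get("GT", (None, None))
            if gt is None or len(gt) < 2 or gt[0] is None or gt[1] is None:
                row_gt.append((MISSING, MISSING))
            else:
                row_gt.append((int(gt[0]), int(gt[1])))
            gq = smp.get("GQ")
            dp = smp.get("DP")
            row_gq.append(int(gq) if gq is not None else MISSING)
            row_dp.append(int(dp) if dp is not None else MISSING)
        gts.append(row_gt)
        gqs.append(row_gq)
        dps.append(row_dp)
    vcf.close()
    n = len(positions)
    return VariantTable(
        chrom=seen_chrom or "chrom",
        positions=np.array(positions, dtype=np.int64),
        qual=np.array(quals, dtype=float),
        samples=samples,
        gt=np.array(gts, dtype=np.int8).reshape(n, len(samples), 2),
        gq=np.array(gqs, dtype=np.int16).reshape(n, len(samples)),
        dp=np.array(dps, dtype=np.int32).reshape(n, len(samples)),
        ref=np.array(refs, dtype="U8"),
        alt=np.array(alts, dtype="U8"),
        n_alleles=np.array(nall, dtype=np.int16),
        is_snp=np.array(snp, dtype=bool),
    )


def write_pedigree(trios: Iterable[Trio], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("child\tfather\tmother\tsex\n")
        for t in trios:
            fh.write(f"{t.child}\t{t.father}\t{t.mother}\t{t.sex}\n")


def read_pedigree(path: str | Path) -> list[Trio]:
    trios = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for want in ("child", "father", "mother", "sex"):
            if want not in idx:
                raise ValueError(f"pedigree missing column {want!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            trios.append(
                Trio(
                    child=parts[idx["child"]],
                    father=parts[idx["father"]],
                    mother=parts[idx["mother"]],
                    sex=parts[idx["sex"]],
                )
            )
    return trios


def write_panel(
    panel: HaplotypePanel,
    path: str | Path,
    seed: int | None = None,
    config: Any = None,
) -> None:
    """Site-by-haplotype TSV: one row per site, one column per haplotype."""
    with Path(path).open("w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        fh.write("##labels=" + ",".join(panel.labels) + "\n")
        fh.write("chrom\tpos\t" + "\t".join(panel.names) + "\n")
        for i in range(panel.n_sites):
            row = "\t".join(
                "." if a == MISSING else str(int(a)) for a in panel.alleles[:, i]
            )
            fh.write(f"{panel.chrom}\t{int(panel.positions[i])}\t{row}\n")


def read_panel(path: str | Path) -> HaplotypePanel:
    labels: list[str] | None = None
    names: list[str] = []
    chrom = "chrom"
    positions: list[int] = []
    rows: list[list[int]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##labels="):
                labels = line.split("=", 1)[1].split(",")
                continue
            if line.startswith("##"):
                continue
            if line.startswith("chrom\t"):
                names = line.split("\t")[2:]
                continue
            if not line:
                continue
            parts = line.split("\t")
            chrom = parts[0]
            positions.append(int(parts[1]))
            rows.append([MISSING if a == "." else int(a) for a in parts[2:]])
    if labels is None:
        raise ValueError(f"{path}: missing ##labels header")
    alleles = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(labels), 0), dtype=np.int8)
    )
    return HaplotypePanel(chrom, np.array(positions, dtype=np.int64), alleles,
                          np.array(labels), names)


def write_tsv(
    df,
    path: str | Path,
    seed: int | None = None,
    config: Any = None,
) -> None:
    """Write a pandas DataFrame as TSV with provenance ## header lines."""
    with Path(path).open("w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
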