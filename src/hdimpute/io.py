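"""Readers and writers for VCF 4.2, PLINK-text (.ped/.map) and TSV side files.

Only biallelic SNPs are handled. The alternate-allele orientation is fixed by
the marker map (REF is always written as ``A`` and ALT as ``G`` for simulated
data; PLINK allele ``A`` maps to the reference allele and ``B`` to the
alternate), so dosage codes are comparable across panels and formats. VCF
parsing is delegated to cyvcf2; the plain-text writers and the PLINK parser
are local because they emit/consume exactly the subset of the formats the
pipeline produces.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    PANEL_BOTH,
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    Pedigree,
)

_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | os.PathLike,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    haplotypes: HaplotypePanel | None = None,
) -> None:
    """Write a VCF 4.2 file; phased with ``|`` when ``haplotypes`` is given.

    Panel membership is carried in an INFO ``PANEL`` tag so a VCF round trip
    preserves the marker map.
    """
    mmap = marker_map.subset(genotypes.marker_ids)
    if not np.array_equal(mmap.marker_ids, genotypes.marker_ids):
        genotypes = genotypes.subset(markers=mmap.marker_ids)
        if haplotypes is not None:
            haplotypes = haplotypes.subset(markers=mmap.marker_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PANEL,Number=1,Type=String,Description="Chip panel membership">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in np.unique(mmap.chromosomes):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in genotypes.animal_ids)
            + "\n"
        )
        chroms = mmap.chromosomes
        poss = mmap.positions_bp
        panels = mmap.panels
        for j, mid in enumerate(mmap.marker_ids):
            if haplotypes is not None:
                h1 = haplotypes.alleles[0::2, j]
                h2 = haplotypes.alleles[1::2, j]
                gts = "\t".join(f"{a}|{b}" for a, b in zip(h1, h2))
            else:
                col = genotypes.calls[:, j]
                gts = "\t".join(_GT_UNPHASED[int(c)] for c in col)
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t{mid}\tA\tG\t.\t.\tPANEL={panels[j]}\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike):
    """Read a biallelic-SNP VCF.

    Returns ``(GenotypeMatrix, MarkerMap, HaplotypePanel | None)``; the panel
    is returned only when every genotype in the file is phased and complete.
    """
    vcf = VCF(str(path))
    animal_ids = np.asarray(vcf.samples, dtype=object)
    rows = []
    calls_rows = []
    hap_rows = []
    all_phased = True
    for rec_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ValueError(f"record {rec_no} ({var.ID}): not biallelic")
        geno = np.asarray(var.genotypes, dtype=object)
        a1 = np.array([g[0] for g in geno], dtype=np.int64)
        a2 = np.array([g[1] for g in geno], dtype=np.int64)
        ploidy_ok = all(len(g) == 3 for g in geno)
        if not ploidy_ok:
            raise ValueError(f"record {rec_no} ({var.ID}): mixed ploidy")
        code = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)
        phased = all(bool(g[2]) for g in geno) and (code != MISSING).all()
        all_phased = all_phased and phased
        if phased:
            hap_rows.append((a1.astype(np.int8), a2.astype(np.int8)))
        panel = var.INFO.get("PANEL") or PANEL_BOTH
        rows.append((var.ID, int(var.CHROM), int(var.POS), panel))
        calls_rows.append(code)
    if not rows:
        raise ValueError(f"no records in VCF {path}")
    mmap = MarkerMap(
        pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "panel"])
    )
    marker_ids = np.asarray([r[0] for r in rows], dtype=object)
    calls = np.column_stack(calls_rows)
    g = GenotypeMatrix(animal_ids, marker_ids, calls)
    # re-order columns to map order in case input was unsorted
    g = g.subset(markers=mmap.marker_ids)
    panel = None
    if all_phased and hap_rows:
        alleles = np.empty((2 * len(animal_ids), len(rows)), dtype=np.int8)
        for j, (a1, a2) in enumerate(hap_rows):
            alleles[0::2, j] = a1
            alleles[1::2, j] = a2
        # columns currently in file order; put in map order
        col_idx = {m: j for j, m in enumerate(marker_ids)}
        cols = np.array([col_idx[m] for m in mmap.marker_ids])
        panel = HaplotypePanel(animal_ids, mmap.marker_ids, alleles[:, cols])
    return g, mmap, panel


def write_plink(prefix: str | os.PathLike, genotypes: GenotypeMatrix, marker_map: MarkerMap) -> None:
    """Write PLINK-text ``.ped``/``.map`` (allele A = reference, B = alternate)."""
    mmap = marker_map.subset(genotypes.marker_ids)
    g = genotypes.subset(markers=mmap.marker_ids)
    with open(f"{prefix}.map", "w") as fh:
        for mid, chrom, pos in zip(mmap.marker_ids, mmap.chromosomes, mmap.positions_bp):
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\n")
    pair = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            alleles = " ".join(pair[int(c)] for c in g.calls[i])
            fh.write(f"FAM {aid} 0 0 0 -9 {alleles}\n")


def read_plink(prefix: str | os.PathLike):
    """Read PLINK-text ``.ped``/``.map``; returns (GenotypeMatrix, MarkerMap)."""
    rows = []
    with open(f"{prefix}.map") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{prefix}.map line {ln}: expected 4 fields, got {len(parts)}")
            chrom, mid, _cm, pos = parts
            rows.append((mid, int(chrom), int(pos), PANEL_BOTH))
    if not rows:
        raise ValueError(f"{prefix}.map is empty")
    marker_ids = [r[0] for r in rows]
    code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2, ("0", "0"): MISSING}
    animal_ids = []
    calls = []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(marker_ids):
                raise ValueError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * len(marker_ids)} fields, got {len(parts)}"
                )
            animal_ids.append(parts[1])
            alleles = parts[6:]
            try:
                row = [code[(alleles[2 * j], alleles[2 * j + 1])] for j in range(len(marker_ids))]
            except KeyError as exc:
                raise ValueError(f"{prefix}.ped line {ln}: invalid allele pair {exc.args[0]}") from None
            calls.append(row)
    mmap = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "panel"]))
    g = GenotypeMatrix(np.asarray(animal_ids, dtype=object), np.asarray(marker_ids, dtype=object), np.asarray(calls, dtype=np.int8))
    return g.subset(markers=mmap.marker_ids), mmap


def read_genotypes(path: str | os.PathLike, fmt: str):
    """Dispatching reader; ``fmt`` is ``"VCF"`` or ``"PLINK_TEXT"``.

    For PLINK, ``path`` is the file prefix (without extension).
    Returns ``(GenotypeMatrix, MarkerMap)``.
    """
    fmt = fmt.upper()
    if fmt == "VCF":
        g, mmap, _ = read_vcf(path)
        return g, mmap
    if fmt == "PLINK_TEXT":
        return read_plink(path)
    raise ValueError(f"unknown genotype format: {fmt}")


def write_marker_map(path: str | os.PathLike, marker_map: MarkerMap) -> None:
    t = marker_map.table.rename(columns={"marker_id": "id", "chromosome": "chrom", "position_bp": "pos_bp"})
    t.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | os.PathLike) -> MarkerMap:
    t = pd.read_csv(path, sep="\t", dtype={"id": str})
    t = t.rename(columns={"id": "marker_id", "chrom": "chromosome", "pos_bp": "position_bp"})
    return MarkerMap(t)


def write_pedigree(path: str | os.PathLike, ped: Pedigree) -> None:
    t = ped.table.rename(columns={"animal_id": "id", "sire_id": "sire", "dam_id": "dam"})
    t.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    t = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str, "breed": str})
    t = t.rename(columns={"id": "animal_id", "sire": "sire_id", "dam": "dam_id"})
    return Pedigree(t)
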