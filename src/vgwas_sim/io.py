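"""Readers and writers for genotype and phenotype interchange formats.

Supported: Hudson ms-style text (read/write), VCF (read via cyvcf2, minimal
GT-only write), PLINK-style whitespace phenotype files (FID IID PHENO), and a
TSV of per-sample causal-locus doses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MsReplicate",
    "read_ms",
    "write_ms",
    "read_vcf",
    "write_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_dose_tsv",
]


@dataclass
class MsReplicate:
    """One ms replicate: segregating-site count, unit-interval positions and
    binary haplotype strings."""

    segsites: int
    positions: np.ndarray
    haplotypes: list[str]

    def __post_init__(self):
        for h in self.haplotypes:
            if len(h) != self.segsites:
                raise ValueError(
                    f"haplotype length {len(h)} != segsites {self.segsites}"
                )
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be non-decreasing")


def _as_text_stream(source):
    if hasattr(source, "read"):
        return source
    return open(source)


def _replicate_to_matrix(rep: MsReplicate, ploidy: int) -> GenotypeMatrix:
    if rep.segsites == 0:
        logger.warning("replicate with 0 segregating sites; empty matrix")
        n = len(rep.haplotypes) // ploidy if rep.haplotypes else 0
        return GenotypeMatrix(
            doses=np.zeros((max(n, 0), 0), dtype=np.int8),
            positions=np.array([]), ploidy=ploidy,
        )
    haps = np.array(
        [np.frombuffer(h.encode(), dtype=np.uint8) - ord("0")
         for h in rep.haplotypes], dtype=np.int8
    )
    if ploidy == 2:
        if haps.shape[0] % 2:
            raise ValueError(
                f"odd haplotype count ({haps.shape[0]}) cannot be paired into "
                "diploid individuals"
            )
        # ms convention: consecutive haplotypes 2k, 2k+1 form individual k
        haps = haps.reshape(-1, 2, haps.shape[1]).sum(axis=1).astype(np.int8)
    # ms positions may tie at float precision; nudge into strict increase
    pos = rep.positions.astype(float).copy()
    for i in range(1, pos.size):
        if pos[i] <= pos[i - 1]:
            pos[i] = np.nextafter(pos[i - 1], np.inf)
    return GenotypeMatrix(doses=haps, positions=pos, ploidy=ploidy)


def read_ms(source, ploidy: int = 1) -> list[GenotypeMatrix]:
    """Parse ms-style text into one GenotypeMatrix per replicate.

    Replicates are delimited by ``//`` and carry ``segsites:`` and
    ``positions:`` header lines followed by 0/1 haplotype rows.  At
    ploidy=2, consecutive haplotype pairs are summed into individuals.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    stream = _as_text_stream(source)
    matrices: list[GenotypeMatrix] = []
    line = stream.readline()
    while line:
        if line.strip().startswith("//"):
            header = stream.readline()
            if not header.strip().startswith("segsites:"):
                raise ValueError(f"expected 'segsites:' after '//', got {header!r}")
            segsites = int(header.split(":")[1])
            positions = np.array([])
            if segsites > 0:
                pos_line = stream.readline()
                if not pos_line.strip().startswith("positions:"):
                    raise ValueError(
                        f"expected 'positions:' line, got {pos_line!r}"
                    )
                positions = np.array(
                    [float(x) for x in pos_line.split(":")[1].split()]
                )
                if positions.size != segsites:
                    raise ValueError(
                        f"{positions.size} positions but segsites: {segsites}"
                    )
            haplotypes = []
            pos_in_file = stream.tell()
            hline = stream.readline()
            while hline and hline.strip() and not hline.strip().startswith("//"):
                token = hline.strip()
                if set(token) - {"0", "1"}:
                    raise ValueError(f"malformed haplotype row: {token!r}")
                haplotypes.append(token)
                pos_in_file = stream.tell()
                hline = stream.readline()
            if hline.strip().startswith("//"):
                stream.seek(pos_in_file)  # hand the delimiter back
                line = stream.readline()
            else:
                line = stream.readline()
            matrices.append(
                _replicate_to_matrix(
                    MsReplicate(segsites, positions, haplotypes), ploidy
                )
            )
            continue
        line = stream.readline()
    if not matrices:
        raise ValueError("no '//' replicate delimiter found in ms input")
    return matrices


def write_ms(matrices, path_or_stream, command_line: str = "ms") -> None:
    """Write GenotypeMatrix objects as ms-style text (haplotype rows).

    Diploid matrices are emitted as unphased-equivalent haplotype pairs:
    dose 2 -> (1,1), dose 0 -> (0,0), dose 1 -> (1,0).
    """
    own = not hasattr(path_or_stream, "write")
    out = open(path_or_stream, "w") if own else path_or_stream
    try:
        out.write(f"{command_line}\n0 0 0\n")
        for gm in matrices:
            out.write("\n//\n")
            out.write(f"segsites: {gm.n_loci}\n")
            if gm.n_loci == 0:
                continue
            pos = gm.positions.astype(float)
            if pos.size and pos.max() > 1:
                pos = pos / (pos.max() + 1)  # rescale bp to unit interval
            out.write("positions: " + " ".join(f"{p:.6f}" for p in pos) + "\n")
            if gm.ploidy == 1:
                rows = gm.doses
            else:
                first = (gm.doses >= 1).astype(np.int8)
                second = (gm.doses == 2).astype(np.int8)
                rows = np.empty((2 * gm.n_samples, gm.n_loci), dtype=np.int8)
                rows[0::2] = first
                rows[1::2] = second
            for row in rows:
                out.write("".join(map(str, row.tolist())) + "\n")
    finally:
        if own:
            out.close()


def read_vcf(path, impute_missing: bool = True) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into minor(ALT)-allele doses.

    Dose is the per-sample ALT count.  Multi-allelic records are skipped
    with a warning.  Missing genotypes are mean-imputed (default) or raise,
    and the imputation count is logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    doses, positions, ids = [], [], []
    n_skipped = n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            logger.warning("skipping multi-allelic record at %s:%d",
                           var.CHROM, var.POS)
            continue
        # gts012: 0/1/2 = ALT dose, 3 = missing
        g = np.asarray(var.gt_types, dtype=float)
        miss = g == 3
        if miss.any():
            n_missing += int(miss.sum())
            if not impute_missing:
                raise ValueError(
                    f"missing genotypes at {var.CHROM}:{var.POS} and "
                    "impute_missing=False"
                )
            g[miss] = g[~miss].mean() if (~miss).any() else 0.0
        doses.append(g)
        positions.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    vcf.close()
    if n_missing:
        logger.info("mean-imputed %d missing genotype calls", n_missing)
    if not doses:
        raise ValueError(f"no biallelic records with GT found in {path}")
    dose = np.asarray(doses).T
    # imputation can leave fractional doses; GenotypeMatrix stores integers,
    # so round (imputed entries only differ by < 1 dose unit)
    return GenotypeMatrix(
        doses=np.rint(dose).astype(np.int8),
        positions=np.asarray(positions, dtype=np.int64),
        ploidy=2,
        locus_ids=ids,
        sample_ids=samples,
    )


def write_vcf(gm: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Minimal GT-only VCF writer (phased pairs for diploids)."""
    gt_map_hap = {0: "0", 1: "1"}
    gt_map_dip = {0: "0|0", 1: "1|0", 2: "1|1"}
    gt_map = gt_map_hap if gm.ploidy == 1 else gt_map_dip
    pos = gm.positions
    if pos.size and (pos.dtype.kind == "f") and pos.max() <= 1:
        pos = np.maximum(1, (pos * 1_000_000).astype(np.int64))
        for i in range(1, pos.size):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_loci):
            gts = "\t".join(gt_map[int(d)] for d in gm.doses[:, j])
            out.write(f"{chrom}\t{int(pos[j])}\t{gm.locus_ids[j]}\tA\tT\t.\t"
                      f"PASS\t.\tGT\t{gts}\n")


def write_phenotypes(y, sample_ids, path) -> None:
    """PLINK-dialect phenotype file: FID IID PHENO, whitespace-delimited,
    full floating precision."""
    y = np.asarray(y, dtype=float)
    if len(sample_ids) != y.size:
        raise ValueError(
            f"{y.size} phenotypes but {len(sample_ids)} sample ids"
        )
    if y.size == 0:
        raise ValueError("empty phenotype vector")
    with open(path, "w") as out:
        for sid, val in zip(sample_ids, y):
            out.write(f"{sid} {sid} {float(val)!r}\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a FID IID PHENO file back into a DataFrame."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["FID", "IID", "PHENO"],
                     float_precision="round_trip")
    return df


def write_dose_tsv(gm: GenotypeMatrix, path, loci=None) -> None:
    """Per-sample dose columns for (causal) loci as a TSV."""
    sub = gm if loci is None else gm.subset_loci(loci)
    df = pd.DataFrame(sub.doses, index=sub.sample_ids, columns=sub.locus_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
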