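"""Synthetic genotype matrices: independent Hardy-Weinberg loci and
haplotype-copying LD blocks.

The generators stand in for coalescent population simulators when all an
experiment needs is control over minor-allele frequencies and a "low LD"
versus "high LD" regime.  They make no attempt at genealogies, demography or
calibrated recombination maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "generate_hwe", "generate_ld_blocks"]


@dataclass
class GenotypeMatrix:
    """Samples x loci minor-allele dose matrix.

    doses
        (n_samples, n_loci) integer array; values in {0..ploidy}.
    positions
        Per-locus coordinate, strictly increasing: floats in (0,1) for
        ms-style segments or integer base pairs.
    ploidy
        1 (haploid 0/1 doses) or 2 (diploid 0/1/2 doses).
    locus_ids, sample_ids
        Stable identifiers; autogenerated when omitted.
    """

    doses: np.ndarray
    positions: np.ndarray
    ploidy: int
    locus_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.doses = np.asarray(self.doses)
        self.positions = np.asarray(self.positions)
        if self.doses.ndim != 2:
            raise ValueError("doses must be 2-D (samples x loci)")
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.doses.size and (self.doses.min() < 0 or self.doses.max() > self.ploidy):
            raise ValueError("dose values must lie in [0, ploidy]")
        if self.positions.shape != (self.n_loci,):
            raise ValueError(
                f"{self.n_loci} loci but {self.positions.size} positions"
            )
        if self.n_loci > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.locus_ids is None:
            self.locus_ids = [f"L{i}" for i in range(self.n_loci)]
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(self.n_samples)]
        if len(self.locus_ids) != self.n_loci:
            raise ValueError("locus_ids length mismatch")
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.doses.shape[0]

    @property
    def n_loci(self) -> int:
        return self.doses.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Per-locus minor(=counted)-allele frequency: dose sum / (ploidy n)."""
        return self.doses.mean(axis=0) / self.ploidy

    def maf(self) -> np.ndarray:
        """Allele frequency folded to [0, 0.5]."""
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def subset_loci(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            doses=self.doses[:, indices],
            positions=self.positions[indices],
            ploidy=self.ploidy,
            locus_ids=[self.locus_ids[i] for i in indices],
            sample_ids=self.sample_ids,
        )


def _positions(n_loci: int, segment_length: float, rng) -> np.ndarray:
    """Distinct sorted uniform positions over [0, segment_length)."""
    pos = np.sort(rng.random(n_loci))
    # enforce strict increase even under float ties
    while np.any(np.diff(pos) <= 0):
        pos = np.sort(rng.random(n_loci))
    if segment_length == 1.0:
        return pos
    bp = np.unique(np.floor(pos * segment_length).astype(np.int64))
    while bp.size < n_loci:  # collisions after rounding to bp
        extra = rng.integers(0, int(segment_length), size=n_loci - bp.size)
        bp = np.unique(np.concatenate([bp, extra]))
    return bp[:n_loci]


def generate_hwe(n_samples: int, maf, ploidy: int = 1, seed=None,
                 segment_length: float = 1.0) -> GenotypeMatrix:
    """Independent loci at specified minor-allele frequencies.

    Doses at locus *i* are Binomial(ploidy, maf_i) draws — Hardy-Weinberg
    genotype frequencies for diploids.  MAFs must lie in (0, 0.5].
    """
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError(f"MAF must lie in (0, 0.5], got {maf}")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    doses = rng.binomial(ploidy, maf, size=(n_samples, maf.size)).astype(np.int8)
    return GenotypeMatrix(
        doses=doses,
        positions=_positions(maf.size, segment_length, rng),
        ploidy=ploidy,
    )


def generate_ld_blocks(n_samples: int, n_loci: int, block_size: int,
                       within_block_r2: float, seed=None, ploidy: int = 1,
                       maf=None, segment_length: float = 25e6) -> GenotypeMatrix:
    """Blocks of correlated loci via haplotype copying.

    Within a block, each haplotype's allele at locus j equals its allele at
    locus j-1 with probability rho = sqrt(within_block_r2) and is otherwise a
    fresh Bernoulli(maf_j) draw.  Marginal frequencies are preserved and the
    dose correlation between loci d apart is ~ rho^d, so adjacent loci reach
    the requested r2 and correlation decays with distance.  Blocks are
    mutually independent.  Default segment length 25 Mb.

    ``maf`` may be a scalar, a length-n_loci vector, or None (drawn uniformly
    from [0.1, 0.5] per block, shared within the block so copying preserves
    marginals exactly).
    """
    if not 0 <= within_block_r2 < 1:
        raise ValueError("within_block_r2 must lie in [0, 1)")
    if block_size > n_loci:
        raise ValueError(f"block_size {block_size} exceeds n_loci {n_loci}")
    rng = np.random.default_rng(seed)
    n_hap = n_samples * ploidy
    rho = float(np.sqrt(within_block_r2))

    if maf is None:
        block_maf = None
    else:
        maf = np.broadcast_to(np.atleast_1d(np.asarray(maf, float)),
                              (n_loci,)).copy()
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("MAF must lie in (0, 0.5]")

    haps = np.empty((n_hap, n_loci), dtype=np.int8)
    for start in range(0, n_loci, block_size):
        stop = min(start + block_size, n_loci)
        if maf is None:
            q = np.full(stop - start, rng.uniform(0.1, 0.5))
        else:
            q = maf[start:stop]
        col = rng.random(n_hap) < q[0]
        haps[:, start] = col
        for j in range(start + 1, stop):
            copy = rng.random(n_hap) < rho
            fresh = rng.random(n_hap) < q[j - start]
            col = np.where(copy, col, fresh)
            haps[:, j] = col

    doses = haps.reshape(n_samples, ploidy, n_loci).sum(axis=1).astype(np.int8)
    return GenotypeMatrix(
        doses=doses,
        positions=_positions(n_loci, segment_length, rng),
        ploidy=ploidy,
    )
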