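"""Causal-locus selection: explicit indices or a seeded search over a
minor-allele-frequency window with optional minimum spacing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["LocusCriteria", "SelectionError", "select_loci"]


class SelectionError(ValueError):
    """Criteria cannot be satisfied by the given genotype matrix."""


@dataclass(frozen=True)
class LocusCriteria:
    """Search criteria for causal loci.

    n_loci loci are drawn uniformly at random (under ``seed``) from those
    whose estimated MAF lies in [maf_min, maf_max], subject to a pairwise
    position spacing of at least ``min_spacing``.  ``explicit_ids`` (locus
    ids or integer indices) bypasses the search entirely.
    """

    n_loci: int = 1
    maf_min: float = 0.0
    maf_max: float = 0.5
    explicit_ids: tuple | None = None
    min_spacing: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.explicit_ids is None:
            if not 0 <= self.maf_min < self.maf_max <= 0.5:
                raise ValueError(
                    f"need 0 <= maf_min < maf_max <= 0.5, got "
                    f"[{self.maf_min}, {self.maf_max}]"
                )
            if self.n_loci < 1:
                raise ValueError("n_loci must be >= 1")


def _resolve_explicit(gm: GenotypeMatrix, ids) -> list[int]:
    maf = gm.maf()
    out = []
    for ident in ids:
        if isinstance(ident, (int, np.integer)):
            idx = int(ident)
            if not 0 <= idx < gm.n_loci:
                raise SelectionError(f"locus index {idx} out of range")
        else:
            try:
                idx = gm.locus_ids.index(ident)
            except ValueError:
                raise SelectionError(f"locus id {ident!r} not in matrix") from None
        if maf[idx] == 0:
            raise SelectionError(
                f"explicit locus {gm.locus_ids[idx]} is monomorphic"
            )
        out.append(idx)
    return out


def select_loci(gm: GenotypeMatrix, criteria: LocusCriteria) -> list[int]:
    """Return exactly ``criteria.n_loci`` locus indices matching the criteria.

    MAF is estimated from the matrix (allele count / (ploidy * n), folded to
    <= 0.5).  Eligible loci are sampled uniformly without replacement under
    the criteria seed; when ``min_spacing`` is set, candidates conflicting
    with already-chosen loci are discarded in draw order.  Raises
    :class:`SelectionError` with the eligible count when the criteria
    over-constrain — bounds are never silently relaxed.
    """
    if gm.n_loci == 0:
        raise SelectionError("empty genotype matrix")
    if criteria.explicit_ids is not None:
        return _resolve_explicit(gm, criteria.explicit_ids)

    maf = gm.maf()
    eligible = np.flatnonzero(
        (maf >= criteria.maf_min) & (maf <= criteria.maf_max) & (maf > 0)
    )
    if eligible.size < criteria.n_loci:
        raise SelectionError(
            f"{criteria.n_loci} loci requested but only {eligible.size} have "
            f"MAF in [{criteria.maf_min}, {criteria.maf_max}]"
        )
    rng = np.random.default_rng(criteria.seed)
    order = rng.permutation(eligible)
    if criteria.min_spacing is None:
        chosen = order[: criteria.n_loci].tolist()
    else:
        chosen = []
        for idx in order:
            if all(abs(gm.positions[idx] - gm.positions[j]) >= criteria.min_spacing
                   for j in chosen):
                chosen.append(int(idx))
                if len(chosen) == criteria.n_loci:
                    break
        if len(chosen) < criteria.n_loci:
            raise SelectionError(
                f"only {len(chosen)} of {criteria.n_loci} loci satisfy "
                f"min_spacing={criteria.min_spacing} among {eligible.size} "
                "eligible loci"
            )
    return sorted(int(i) for i in chosen)
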