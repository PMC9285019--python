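"""Competition and complementarity indices derived from fitted models.

From a fit of the hyperbolic yield-density model the package derives:

* normalized coefficients ``b11/b0`` and ``b12/b0`` (m²/plant), which control
  for plant-size bias when comparing species;
* relative competitive ability ``RC = b11/b12`` — the number of companion
  plants whose effect on the focal species equals one conspecific plant
  (RC > 1: the species feels itself more than the companion);
* the niche differentiation index ``NDI = RC_a x RC_b`` of a pair — above one
  indicates complementarity (net intraspecific competition exceeds net
  interspecific competition);
* theoretical maxima: weight of an isolated plant ``1/b0`` (g/plant) and
  asymptotic stand yield ``1/b11`` (g/m²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .yield_density import BicultureFit, MonocultureFit

__all__ = [
    "CompetitionIndices",
    "PairComplementarity",
    "indices_from_fit",
    "ndi",
    "competitive_hierarchy",
    "indices_to_frame",
]


@dataclass(frozen=True)
class CompetitionIndices:
    """Derived indices for one focal species (in a pair, or in monoculture)."""

    focal: str
    companion: str | None
    intra_norm: float  # b11/b0, m²/plant
    inter_norm: float | None  # b12/b0, m²/plant; None for monoculture
    rc: float | None  # b11/b12; None when undefined
    max_weight: float  # 1/b0, g/plant
    max_yield: float  # 1/b11, g/m²


@dataclass(frozen=True)
class PairComplementarity:
    """Niche differentiation index of an unordered species pair."""

    species_a: str
    species_b: str
    ndi: float


def indices_from_fit(fit: MonocultureFit | BicultureFit) -> CompetitionIndices:
    """Normalized coefficients, RC, and theoretical maxima from one fit.

    RC is the ratio of raw coefficients b11/b12, identical to the ratio of
    the normalized ones (the intercept cancels). A zero interspecific
    coefficient leaves RC undefined (reported as None with a warning).
    """
    is_bi = isinstance(fit, BicultureFit)
    focal = fit.focal if is_bi else fit.species
    if not (fit.b0 > 0 and fit.b11 > 0):
        raise ValueError(f"indices for {focal!r}: coefficients must be positive")
    inter_norm = rc = None
    companion = None
    if is_bi:
        companion = fit.companion
        inter_norm = fit.b12 / fit.b0
        if fit.b12 > 0:
            rc = fit.b11 / fit.b12
        else:
            warnings.warn(f"RC undefined for {focal!r} vs {companion!r}: b12 = 0")
    return CompetitionIndices(
        focal=focal,
        companion=companion,
        intra_norm=fit.b11 / fit.b0,
        inter_norm=inter_norm,
        rc=rc,
        max_weight=1.0 / fit.b0,
        max_yield=1.0 / fit.b11,
    )


def ndi(fit_a: BicultureFit, fit_b: BicultureFit) -> PairComplementarity:
    """Niche differentiation index from the two sides of one biculture.

    ``fit_a`` and ``fit_b`` must be the two reciprocal fits of the same pair
    (a with companion b, and b with companion a). NDI is the product of the
    two RCs and is invariant to the order of the arguments.
    """
    if (fit_a.focal, fit_a.companion) != (fit_b.companion, fit_b.focal):
        raise ValueError(
            f"mismatched pair: ({fit_a.focal},{fit_a.companion}) vs "
            f"({fit_b.focal},{fit_b.companion})"
        )
    rc_a = indices_from_fit(fit_a).rc
    rc_b = indices_from_fit(fit_b).rc
    if rc_a is None or rc_b is None:
        raise ValueError("NDI undefined: an RC of the pair is undefined (b12 = 0)")
    a, b = sorted((fit_a.focal, fit_b.focal))
    return PairComplementarity(species_a=a, species_b=b, ndi=rc_a * rc_b)


def competitive_hierarchy(
    indices: Iterable[CompetitionIndices],
) -> tuple[list[str], pd.DataFrame, bool]:
    """Rank species from most to least competitive by pairwise RC wins.

    Species ``a`` beats ``b`` when RC of ``b`` against ``a`` is below one
    (``b`` feels ``a`` more strongly than itself). Species are ordered by
    win count; ties are broken by mean RC across a species' own bicultures,
    then by code. Returns ``(order, win_matrix, tied)`` where the win matrix
    row/column entry [a, b] is 1 when a beats b, so callers can apply a
    different rule.

    Requires an RC for every ordered pair of the species involved.
    """
    pair_rc: dict[tuple[str, str], float] = {}
    for idx in indices:
        if idx.companion is None:
            continue
        if idx.rc is None:
            raise ValueError(f"RC missing for pair ({idx.focal}, {idx.companion})")
        pair_rc[(idx.focal, idx.companion)] = idx.rc
    species = sorted({s for p in pair_rc for s in p})
    missing = [
        (a, b) for a in species for b in species if a != b and (a, b) not in pair_rc
    ]
    if missing:
        raise ValueError(f"incomplete pair coverage, missing: {missing}")
    win = pd.DataFrame(0, index=species, columns=species, dtype=int)
    for a in species:
        for b in species:
            if a != b and pair_rc[(b, a)] < 1.0:
                win.loc[a, b] = 1
    wins = win.sum(axis=1)
    mean_rc = {
        a: float(np.mean([pair_rc[(a, b)] for b in species if b != a])) for a in species
    }
    order = sorted(species, key=lambda s: (-wins[s], -mean_rc[s], s))
    tied = len(set(wins)) < len(species)
    return order, win, tied


def indices_to_frame(
    indices: Sequence[CompetitionIndices],
    complementarities: Sequence[PairComplementarity] = (),
) -> pd.DataFrame:
    """Export indices as a table keyed by (treatment, focal species)."""
    ndi_map = {frozenset((c.species_a, c.species_b)): c.ndi for c in complementarities}
    rows = []
    for idx in indices:
        treatment = (
            idx.focal
            if idx.companion is None
            else "".join(sorted((idx.focal, idx.companion)))
        )
        rows.append(
            {
                "treatment": treatment,
                "species": idx.focal,
                "b11_over_b0": idx.intra_norm,
                "b12_over_b0": idx.inter_norm if idx.inter_norm is not None else np.nan,
                "rc": idx.rc if idx.rc is not None else np.nan,
                "ndi": ndi_map.get(
                    frozenset((idx.focal, idx.companion or idx.focal)), np.nan
                ),
                "max_weight_g": idx.max_weight,
                "max_yield_g_m2": idx.max_yield,
            }
        )
    return pd.DataFrame(rows)
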