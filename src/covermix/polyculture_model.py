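"""Predict per-species biomass in 3-4-species mixtures from biculture fits.

For a focal species *a* in a mixture of r species, the prediction model is

    Y_a = N_a / (b̄_a0 + b̄_aa N_a + Σ_i b_ai N_i),

where b̄_a0 and b̄_aa are the unweighted means of the intercept and
intraspecific coefficient of *a* over its bicultures with the other members
of the mixture, and each interspecific term b_ai is taken directly from the
(a, i) biculture fit. Indirect (higher-order) interactions among companions
are assumed negligible and are not modelled; the mixture model is assembled
from pairwise fits only, never refitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .data_model import SpeciesParams, registry_by_code
from .yield_density import BicultureFit

__all__ = ["PolycultureModel", "assemble", "predict"]


@dataclass(frozen=True)
class PolycultureModel:
    """Assembled prediction model for one species set.

    Per focal species ``a``: ``b0_bar[a]`` (plants/g) and ``b_intra_bar[a]``
    (m²/g) are means over the |set|-1 bicultures of ``a`` within the set;
    ``b_inter[(a, i)]`` (m²/g) is the interspecific coefficient of companion
    ``i`` on ``a`` from the (a, i) biculture fit. ``provenance`` records
    which pair fits contributed to each focal species' averages.
    """

    species_set: tuple[str, ...]
    b0_bar: dict[str, float]
    b_intra_bar: dict[str, float]
    b_inter: dict[tuple[str, str], float]
    provenance: dict[str, tuple[str, ...]]


def assemble(
    species_set: Iterable[str],
    biculture_fits: Mapping[tuple[str, str], BicultureFit] | Iterable[BicultureFit],
) -> PolycultureModel:
    """Build the mixture model for a species set from pairwise fits.

    Needs a :class:`BicultureFit` for every ordered pair within the set.
    A 2-species set is allowed and reduces exactly to the biculture fit for
    each focal species (mean over a single element).
    """
    species = tuple(dict.fromkeys(species_set))
    if not 2 <= len(species) <= 4:
        raise ValueError(f"species set size must be 2-4, got {len(species)}")
    if isinstance(biculture_fits, Mapping):
        fits = dict(biculture_fits)
    else:
        fits = {(f.focal, f.companion): f for f in biculture_fits}
    missing = [
        (a, i) for a in species for i in species if a != i and (a, i) not in fits
    ]
    if missing:
        raise ValueError(f"missing biculture fit(s): {missing}")
    b0_bar: dict[str, float] = {}
    b_intra_bar: dict[str, float] = {}
    b_inter: dict[tuple[str, str], float] = {}
    provenance: dict[str, tuple[str, ...]] = {}
    for a in species:
        pair_fits = [fits[(a, i)] for i in species if i != a]
        for f in pair_fits:
            if not (f.b0 > 0 and f.b11 >= 0 and f.b12 >= 0):
                raise ValueError(f"invalid coefficients in fit ({f.focal},{f.companion})")
        b0_bar[a] = float(np.mean([f.b0 for f in pair_fits]))
        b_intra_bar[a] = float(np.mean([f.b11 for f in pair_fits]))
        for f in pair_fits:
            b_inter[(a, f.companion)] = f.b12
        provenance[a] = tuple(
            "".join(sorted((a, f.companion))) for f in pair_fits
        )
    return PolycultureModel(
        species_set=species,
        b0_bar=b0_bar,
        b_intra_bar=b_intra_bar,
        b_inter=b_inter,
        provenance=provenance,
    )


def predict(
    model: PolycultureModel,
    densities: Mapping[str, float],
    *,
    registry: Iterable[SpeciesParams] | None = None,
    discount_germination: bool = False,
) -> dict[str, float]:
    """Per-species predicted biomass (g/m²) at the given densities.

    ``densities`` may be observed plants/m² (validation mode) or planned
    seeds/m² (planning mode); with ``discount_germination=True`` and a
    registry, seed densities are multiplied by each species' germination
    fraction before prediction. The default applies no discount.

    A density beyond 1.2 x the recommended monoculture rate (when a registry
    is supplied) triggers an extrapolation warning but prediction proceeds.
    """
    unknown = set(densities) - set(model.species_set)
    if unknown:
        raise ValueError(f"density supplied for species outside the set: {sorted(unknown)}")
    n = {a: float(densities.get(a, 0.0)) for a in model.species_set}
    if any(v < 0 for v in n.values()):
        raise ValueError("densities must be >= 0")
    if registry is not None:
        by_code = registry_by_code(registry)
        for a, v in n.items():
            if a in by_code and v > 1.2 * by_code[a].rec_rate_seeds:
                warnings.warn(
                    f"density {v:g} for {a!r} exceeds 1.2x the recommended rate; "
                    "prediction extrapolates beyond the fitted design"
                )
        if discount_germination:
            n = {a: v * by_code[a].germination if a in by_code else v for a, v in n.items()}
    out: dict[str, float] = {}
    for a in model.species_set:
        if n[a] == 0:
            out[a] = 0.0
            continue
        denom = model.b0_bar[a] + model.b_intra_bar[a] * n[a]
        for i in model.species_set:
            if i != a:
                denom += model.b_inter[(a, i)] * n[i]
        out[a] = n[a] / denom
    return out
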