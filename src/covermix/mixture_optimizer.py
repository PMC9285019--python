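"""Grid enumeration of candidate seeding-rate mixtures and Pareto selection.

Candidates live on a per-species integer grid: each species' seeding density
is k x increment seeds/m², with the increment set to 5% of its maximum
(1.2 x recommended) rate, truncated to a whole seed. Candidates keep 3-4
species and a total "budget" of at most 120% of recommended rates, i.e.
Σ_i density_i / rec_i <= 1.2. Each candidate is scored by the assembled
mixture models (predicted per-species biomass, total), Pielou's evenness of
the predicted biomass shares, and seed cost; the Pareto-optimal set on
(total biomass, evenness) is extracted exactly by dominance, and a shortlist
with evenness above a floor is reported with costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import SpeciesParams
from .polyculture_model import PolycultureModel, predict

__all__ = [
    "MixtureCandidate",
    "MixtureEvaluation",
    "species_increments",
    "generate_candidates",
    "evenness",
    "seed_cost",
    "simulate_all",
    "pareto_front",
    "shortlist",
    "evaluations_to_frame",
]


@dataclass(frozen=True)
class MixtureCandidate:
    """One point on the seeding-rate grid.

    ``densities[s] = levels[s] * increments[s]`` exactly (seeds/m²);
    ``proportions[s]`` is the exact fraction of the recommended rate.
    """

    levels: dict[str, int]
    increments: dict[str, int]
    densities: dict[str, float]
    proportions: dict[str, float]
    n_species: int

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, k in self.levels.items() if k > 0)


@dataclass(frozen=True)
class MixtureEvaluation:
    """Scored candidate: per-species biomass (g/m²), total, evenness, cost."""

    candidate: MixtureCandidate
    biomass: dict[str, float]
    total_biomass: float
    evenness: float
    cost: float


def species_increments(
    registry: Sequence[SpeciesParams],
    increment_fraction: float = 0.05,
    max_fraction: float = 1.2,
) -> dict[str, int]:
    """Whole-seed grid increments: floor(frac x max_frac x recommended rate).

    Truncation (not rounding) to a whole seed; an increment that truncates
    to zero is an error.
    """
    out: dict[str, int] = {}
    for sp in registry:
        inc = math.floor(increment_fraction * max_fraction * sp.rec_rate_seeds)
        if inc <= 0:
            raise ValueError(
                f"increment for {sp.code!r} rounds to zero "
                f"(rate {sp.rec_rate_seeds} seeds/m² too small for the grid)"
            )
        out[sp.code] = inc
    return out


def generate_candidates(
    registry: Sequence[SpeciesParams],
    increment_fraction: float = 0.05,
    max_fraction: float = 1.2,
    min_species: int = 3,
    max_species: int = 4,
) -> list[MixtureCandidate]:
    """Enumerate all grid candidates within the budget constraint.

    Per species, levels run from 0 while level x increment stays within
    ``max_fraction`` x the recommended rate. A candidate is kept when the
    number of nonzero species is within [min_species, max_species] and the
    sum of exact per-species proportions of the recommended rates does not
    exceed ``max_fraction`` (strictly-exceeding candidates are excluded).
    """
    if not registry:
        raise ValueError("registry is empty")
    if not 0 < increment_fraction < max_fraction:
        raise ValueError("need 0 < increment_fraction < max_fraction")
    inc = species_increments(registry, increment_fraction, max_fraction)
    codes = [sp.code for sp in registry]
    rec = {sp.code: sp.rec_rate_seeds for sp in registry}
    kmax = {c: math.floor(max_fraction * rec[c] / inc[c]) for c in codes}
    # tiny slack so exact-boundary sums are kept despite float representation
    budget = max_fraction + 1e-9
    out: list[MixtureCandidate] = []
    for ks in product(*(range(kmax[c] + 1) for c in codes)):
        n_species = sum(1 for k in ks if k > 0)
        if not min_species <= n_species <= max_species:
            continue
        props = {c: k * inc[c] / rec[c] for c, k in zip(codes, ks)}
        if sum(props.values()) > budget:
            continue
        out.append(
            MixtureCandidate(
                levels=dict(zip(codes, ks)),
                increments=dict(inc),
                densities={c: float(k * inc[c]) for c, k in zip(codes, ks)},
                proportions=props,
                n_species=n_species,
            )
        )
    return out


def evenness(biomass: Mapping[str, float] | Sequence[float]) -> float:
    """Pielou's evenness J of biomass shares.

    J = (-Σ p_i ln p_i) / ln S with p_i the biomass share of species i and S
    the number of species in the mixture (zero-biomass members included in
    S, with the convention 0 ln 0 = 0). J = 1 iff all shares are equal.
    Undefined (error) for fewer than two species or zero total biomass.
    """
    vals = np.asarray(
        list(biomass.values()) if isinstance(biomass, Mapping) else biomass, dtype=float
    )
    if len(vals) < 2:
        raise ValueError("evenness needs at least two species")
    if np.any(vals < 0):
        raise ValueError("biomass must be >= 0")
    total = vals.sum()
    if total <= 0:
        raise ValueError("evenness undefined for zero total biomass")
    p = vals / total
    nz = p[p > 0]
    shannon = float(-(nz * np.log(nz)).sum())
    return shannon / math.log(len(vals))


def seed_cost(candidate: MixtureCandidate, registry: Sequence[SpeciesParams]) -> float:
    """Seed cost of a candidate, currency/ha.

    cost = Σ_i proportion_i x rec_rate_mass_i (g/m²) / germination_i
           x 10 (kg/ha per g/m²) x price_i (currency/kg)

    The germination divisor converts the live-seed target to the bulk mass
    actually purchased. Cost is exactly linear in the seeding densities.
    """
    by_code = {sp.code: sp for sp in registry}
    missing = [c for c, k in candidate.levels.items() if k > 0 and c not in by_code]
    if missing:
        raise ValueError(f"species not in registry: {missing}")
    cost = 0.0
    for c, p in candidate.proportions.items():
        if p == 0:
            continue
        sp = by_code[c]
        cost += p * sp.rec_rate_mass / sp.germination * 10.0 * sp.price_per_kg
    return cost


def simulate_all(
    candidates: Iterable[MixtureCandidate],
    models: Mapping[frozenset, PolycultureModel],
    registry: Sequence[SpeciesParams],
) -> list[MixtureEvaluation]:
    """Score every candidate with the model of exactly its species subset.

    Biomass is predicted from the seeding densities (seeds/m², undiscounted);
    evenness uses the predicted shares over the candidate's nonzero species.
    """
    out: list[MixtureEvaluation] = []
    for cand in candidates:
        subset = frozenset(cand.species)
        model = models.get(subset)
        if model is None:
            raise ValueError(f"no polyculture model for subset {sorted(subset)}")
        dens = {s: cand.densities[s] for s in cand.species}
        biomass = predict(model, dens)
        out.append(
            MixtureEvaluation(
                candidate=cand,
                biomass=biomass,
                total_biomass=float(sum(biomass.values())),
                evenness=evenness({s: biomass[s] for s in cand.species}),
                cost=seed_cost(cand, registry),
            )
        )
    return out


def pareto_front(
    evaluations: Sequence[MixtureEvaluation],
    objectives: tuple[str, str] = ("total_biomass", "evenness"),
) -> list[MixtureEvaluation]:
    """Non-dominated evaluations under weak dominance (both objectives maximized).

    x dominates y iff x >= y in both objectives and x > y in at least one;
    exact objective-space duplicates are all retained. Seed cost is not an
    objective; it is reported for the shortlisted front.
    """
    if not evaluations:
        raise ValueError("no evaluations")
    a = np.array([getattr(e, objectives[0]) for e in evaluations])
    b = np.array([getattr(e, objectives[1]) for e in evaluations])
    n = len(a)
    dominated = np.zeros(n, dtype=bool)
    chunk = 1024
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ge = (a[:, None] >= a[None, sl]) & (b[:, None] >= b[None, sl])
        gt = (a[:, None] > a[None, sl]) | (b[:, None] > b[None, sl])
        dominated[sl] |= (ge & gt).any(axis=0)
    return [e for e, d in zip(evaluations, dominated) if not d]


def shortlist(
    front: Sequence[MixtureEvaluation], evenness_min: float = 0.8
) -> pd.DataFrame:
    """Front members with evenness above the floor, as an ordered table.

    Ordered by decreasing total biomass (and increasing evenness, which on a
    two-objective front is the same ordering). Columns report per-species
    proportions and biomasses, the total proportion, total biomass, evenness,
    and seed cost. Empty result yields an empty table with a notice attr.
    """
    if not front:
        raise ValueError("front is empty")
    keep = [e for e in front if e.evenness > evenness_min]
    keep.sort(key=lambda e: (-e.total_biomass, e.evenness))
    codes = list(front[0].candidate.levels)  # registry order
    rows = []
    for e in keep:
        row: dict = {"mixture": "".join(s for s in codes if s in e.candidate.species)}
        for c in codes:
            row[f"prop_{c}"] = e.candidate.proportions.get(c, 0.0)
        row["total_proportion"] = sum(e.candidate.proportions.values())
        for c in codes:
            row[f"biomass_{c}"] = e.biomass.get(c, 0.0)
        row["total_biomass"] = e.total_biomass
        row["evenness"] = e.evenness
        row["cost"] = e.cost
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df.attrs["notice"] = f"no front member has evenness > {evenness_min}"
    return df


def evaluations_to_frame(evaluations: Sequence[MixtureEvaluation]) -> pd.DataFrame:
    """Full evaluation table (one row per candidate) for export."""
    codes = list(evaluations[0].candidate.levels) if evaluations else []
    rows = []
    for e in evaluations:
        row: dict = {}
        for c in codes:
            row[f"level_{c}"] = e.candidate.levels.get(c, 0)
            row[f"seeds_{c}"] = e.candidate.densities.get(c, 0.0)
            row[f"prop_{c}"] = e.candidate.proportions.get(c, 0.0)
            row[f"biomass_{c}"] = e.biomass.get(c, 0.0)
        row["n_species"] = e.candidate.n_species
        row["total_biomass"] = e.total_biomass
        row["evenness"] = e.evenness
        row["cost"] = e.cost
        rows.append(row)
    return pd.DataFrame(rows)
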