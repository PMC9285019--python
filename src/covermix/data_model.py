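"""Domain types, species registry, and delimited-file I/O.

Two kinds of density appear throughout the package and are never unit-punned:

* ``plants/m²`` — observed densities of emerged plants, the scale on which
  the yield-density models are fitted;
* ``seeds/m²`` — planned seeding densities, the scale on which mixtures are
  designed and optimized.

Field names carry the distinction (``density`` on a :class:`PlotObservation`
is plants/m²; a seeding plan's columns are seeds/m²).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SpeciesParams",
    "PlotObservation",
    "DesignTemplate",
    "ValidationError",
    "DEFAULT_SPECIES",
    "MONOCULTURE_PROPORTIONS",
    "BICULTURE_PROPORTIONS",
    "default_design_template",
    "load_species_config",
    "write_species_config",
    "read_plot_observations",
    "write_plot_observations",
    "proportion_to_density",
    "density_to_proportion",
    "registry_by_code",
]


class ValidationError(ValueError):
    """An input record violated a domain invariant."""


@dataclass(frozen=True)
class SpeciesParams:
    """Agronomic and economic constants for one species.

    Parameters
    ----------
    code
        Short label, e.g. ``"M"`` for pearl millet.
    name
        Full common name.
    rec_rate_mass
        Recommended monoculture seeding rate, g seed/m².
    rec_rate_seeds
        Recommended monoculture seeding rate, seeds/m².
    germination
        Germination fraction in (0, 1] from the seed label.
    price_per_kg
        Seed price, currency per kg.
    """

    code: str
    name: str
    rec_rate_mass: float
    rec_rate_seeds: float
    germination: float
    price_per_kg: float

    def __post_init__(self) -> None:
        for f in ("rec_rate_mass", "rec_rate_seeds", "germination", "price_per_kg"):
            v = getattr(self, f)
            if not v > 0:
                raise ValidationError(
                    f"species {self.code!r}: field {f!r} must be strictly positive, got {v!r}"
                )
        if self.germination > 1:
            raise ValidationError(
                f"species {self.code!r}: germination must be <= 1, got {self.germination!r}"
            )
        if not self.code:
            raise ValidationError("species code must be non-empty")

    @property
    def seeds_per_gram(self) -> float:
        """Seed count per gram, derived from the two recommended rates."""
        return self.rec_rate_seeds / self.rec_rate_mass


#: Default registry: the four warm-season annual cover crops the bundled
#: reference coefficients describe (two C4 grasses, two legumes).
DEFAULT_SPECIES: tuple[SpeciesParams, ...] = (
    SpeciesParams("M", "pearl millet", 2.1, 292.0, 0.80, 3.13),
    SpeciesParams("S", "sorghum sudangrass", 6.6, 218.0, 0.85, 3.66),
    SpeciesParams("H", "sunn hemp", 5.6, 146.0, 0.80, 5.69),
    SpeciesParams("C", "cowpea", 7.0, 72.0, 0.80, 4.52),
)


@dataclass
class PlotObservation:
    """One plot's observed per-species densities and biomasses.

    ``density`` maps species code to emerged plants/m² (symbol N) and
    ``biomass`` maps species code to shoot dry matter in g/m² (symbol Y).
    """

    plot_id: str
    site_year: str
    block: str
    species_set: frozenset[str]
    density: dict[str, float]
    biomass: dict[str, float]
    target_proportions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.species_set = frozenset(self.species_set)
        for sp in set(self.density) | set(self.biomass):
            if sp not in self.species_set:
                raise ValidationError(
                    f"plot {self.plot_id!r}: species {sp!r} has data but is not in species_set"
                )
        for sp in self.species_set:
            n = self.density.get(sp, 0.0)
            y = self.biomass.get(sp, 0.0)
            if n < 0:
                raise ValidationError(f"plot {self.plot_id!r}: negative density for {sp!r}")
            if y < 0:
                raise ValidationError(f"plot {self.plot_id!r}: negative biomass for {sp!r}")
            if n == 0 and y > 0:
                raise ValidationError(
                    f"plot {self.plot_id!r}: biomass > 0 with zero density for {sp!r}"
                )


#: Monoculture proportions of the recommended rate in the restricted
#: response-surface design (two levels above 1.0 to reach the yield asymptote).
MONOCULTURE_PROPORTIONS: tuple[float, ...] = (0.4, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2)

#: The eight biculture rate combinations (proportion of each species'
#: recommended monoculture rate), all at or below replacement level.
BICULTURE_PROPORTIONS: tuple[tuple[float, float], ...] = (
    (0.2, 0.2),
    (0.2, 0.4),
    (0.2, 0.6),
    (0.3, 0.3),
    (0.4, 0.2),
    (0.4, 0.4),
    (0.5, 0.5),
    (0.6, 0.2),
)


@dataclass(frozen=True)
class DesignTemplate:
    """Treatment list: rows of (species codes, proportion of recommended rate)."""

    rows: tuple[tuple[tuple[str, ...], dict[str, float]], ...]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def default_design_template(codes: Sequence[str]) -> DesignTemplate:
    """Restricted response-surface template for a species list.

    Monocultures at the eight standard proportions, every unordered pair at the
    eight biculture combinations, every 3-species subset at 1/3 each and (when
    four or more species are given) every 4-species subset at 1/4 each.
    """
    from itertools import combinations

    rows: list[tuple[tuple[str, ...], dict[str, float]]] = []
    for sp in codes:
        for p in MONOCULTURE_PROPORTIONS:
            rows.append(((sp,), {sp: p}))
    for a, b in combinations(codes, 2):
        for pa, pb in BICULTURE_PROPORTIONS:
            rows.append(((a, b), {a: pa, b: pb}))
    for size in (3, 4):
        for subset in combinations(codes, size):
            rows.append((tuple(subset), {sp: 1.0 / size for sp in subset}))
    return DesignTemplate(tuple(rows))


# ---------------------------------------------------------------------------
# Species config I/O

_SPECIES_COLUMNS = [
    "code",
    "name",
    "rec_rate_mass_g_m2",
    "rec_rate_seeds_m2",
    "germination",
    "price_per_kg",
]


def _read_delimited(path) -> pd.DataFrame:
    # comma default, tab accepted
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def load_species_config(path) -> list[SpeciesParams]:
    """Read a species registry from delimited text.

    Required columns: ``code, name, rec_rate_mass_g_m2, rec_rate_seeds_m2,
    germination, price_per_kg``. Raises :class:`ValidationError` naming the
    offending field on missing columns, non-positive values, or duplicate
    codes, and checks that the two recommended rates imply a consistent
    seeds-per-gram (the derived field is populated on the returned records).
    """
    df = _read_delimited(path)
    missing = [c for c in _SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"species config missing column(s): {', '.join(missing)}")
    registry: list[SpeciesParams] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        code = str(row["code"]).strip()
        if code in seen:
            raise ValidationError(f"duplicate species code {code!r}")
        seen.add(code)
        registry.append(
            SpeciesParams(
                code=code,
                name=str(row["name"]).strip(),
                rec_rate_mass=float(row["rec_rate_mass_g_m2"]),
                rec_rate_seeds=float(row["rec_rate_seeds_m2"]),
                germination=float(row["germination"]),
                price_per_kg=float(row["price_per_kg"]),
            )
        )
    return registry


def write_species_config(path, registry: Iterable[SpeciesParams]) -> None:
    df = pd.DataFrame(
        [
            {
                "code": sp.code,
                "name": sp.name,
                "rec_rate_mass_g_m2": sp.rec_rate_mass,
                "rec_rate_seeds_m2": sp.rec_rate_seeds,
                "germination": sp.germination,
                "price_per_kg": sp.price_per_kg,
            }
            for sp in registry
        ]
    )
    df.to_csv(path, index=False)


def registry_by_code(registry: Iterable[SpeciesParams]) -> dict[str, SpeciesParams]:
    return {sp.code: sp for sp in registry}


# ---------------------------------------------------------------------------
# Observation I/O (long format: one row per plot x species)

_OBS_COLUMNS = ["plot_id", "site_year", "block", "species", "density", "biomass"]


def read_plot_observations(
    path,
    registry: Iterable[SpeciesParams] | None = None,
    *,
    on_invalid: str = "error",
) -> list[PlotObservation]:
    """Read long-format plot observations from delimited text.

    One row per plot x species with columns ``plot_id, site_year, block,
    species, density`` (plants/m²) ``, biomass`` (g/m²). Rows are grouped into
    :class:`PlotObservation` records and invariants enforced.

    ``on_invalid`` controls what happens to a record violating the
    zero-density/positive-biomass invariant: ``"error"`` (default) raises,
    ``"drop"`` discards the offending plot with a warning, ``"keep"`` keeps it
    with the biomass zeroed and a warning.
    """
    import warnings

    if on_invalid not in ("error", "drop", "keep"):
        raise ValueError(f"on_invalid must be error/drop/keep, got {on_invalid!r}")
    df = _read_delimited(path)
    if df.empty and not set(_OBS_COLUMNS) <= set(df.columns):
        return []
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"observation file missing column(s): {', '.join(missing)}")
    known = None if registry is None else set(registry_by_code(registry))
    out: list[PlotObservation] = []
    for (plot_id, site_year, block), grp in df.groupby(
        ["plot_id", "site_year", "block"], dropna=False, sort=False
    ):
        density: dict[str, float] = {}
        biomass: dict[str, float] = {}
        for _, row in grp.iterrows():
            sp = str(row["species"]).strip()
            if known is not None and sp not in known:
                raise ValidationError(f"plot {plot_id!r}: unknown species code {sp!r}")
            n = float(row["density"])
            y = float(row["biomass"])
            if n < 0 or y < 0:
                raise ValidationError(
                    f"plot {plot_id!r}: negative density or biomass for {sp!r}"
                )
            density[sp] = n
            biomass[sp] = y
        bad = [sp for sp in density if density[sp] == 0 and biomass[sp] > 0]
        if bad:
            msg = f"plot {plot_id!r}: biomass > 0 with zero density for {bad}"
            if on_invalid == "error":
                raise ValidationError(msg)
            warnings.warn(msg)
            if on_invalid == "drop":
                continue
            for sp in bad:
                biomass[sp] = 0.0
        out.append(
            PlotObservation(
                plot_id=str(plot_id),
                site_year=str(site_year),
                block="" if pd.isna(block) else str(block),
                species_set=frozenset(density),
                density=density,
                biomass=biomass,
            )
        )
    return out


def write_plot_observations(path, observations: Iterable[PlotObservation]) -> None:
    rows = []
    for obs in observations:
        for sp in sorted(obs.species_set):
            rows.append(
                {
                    "plot_id": obs.plot_id,
                    "site_year": obs.site_year,
                    "block": obs.block,
                    "species": sp,
                    "density": obs.density.get(sp, 0.0),
                    "biomass": obs.biomass.get(sp, 0.0),
                }
            )
    pd.DataFrame(rows, columns=_OBS_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Proportion <-> seeding density

def proportion_to_density(p: float, sp: SpeciesParams) -> float:
    """Seeds/m² planned when seeding ``p`` x the recommended monoculture rate."""
    if p < 0:
        raise ValidationError(f"proportion must be >= 0, got {p!r}")
    return p * sp.rec_rate_seeds


def density_to_proportion(density: float, sp: SpeciesParams) -> float:
    """Inverse of :func:`proportion_to_density` (exact round trip)."""
    if density < 0:
        raise ValidationError(f"density must be >= 0, got {density!r}")
    return density / sp.rec_rate_seeds
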