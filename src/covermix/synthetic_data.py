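"""Synthetic response-surface and polyculture trials with known ground truth.

The generator emulates the structure of a restricted response-surface field
trial: monocultures of each species at eight proportions of the recommended
rate, every biculture at eight rate combinations, and replicated 3-4-species
polycultures at replacement rates. Emergence is binomial at the seed level
(establishment = germination fraction by default) and biomass follows the
hyperbolic competition models exactly — the biculture equation for 1-2
species plots, the pairwise-assembled mixture equation for polycultures —
times a site-year scalar and multiplicative lognormal noise. All randomness
flows from one integer seed, so a fixed seed reproduces a trial bit-for-bit
and the noiseless limit (sigma=0, establishment=1) returns the model
predictions themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .data_model import (
    DesignTemplate,
    PlotObservation,
    SpeciesParams,
    default_design_template,
    registry_by_code,
)
from .polyculture_model import assemble, predict
from .yield_density import BicultureFit, predict_biculture, predict_monoculture

__all__ = ["TruthSet", "default_truth", "make_design", "simulate_trial", "make_validation_set"]


@dataclass(frozen=True)
class TruthSet:
    """Generating coefficients and noise settings for a synthetic trial.

    ``mono[s] = (b0, b11)``; ``pairs[(focal, companion)] = (b0, b11, b12)``;
    ``site_year_effects`` are multiplicative biomass scalars by site-year
    name; ``sigma`` is the lognormal (or relative Gaussian) noise scale on
    biomass; ``establishment`` is the per-species emergence probability.
    """

    mono: dict[str, tuple[float, float]]
    pairs: dict[tuple[str, str], tuple[float, float, float]]
    site_year_effects: dict[str, float] = field(default_factory=dict)
    sigma: float = 0.1
    establishment: dict[str, float] = field(default_factory=dict)
    noise: str = "lognormal"  # or "gaussian" (additive, sd = sigma x mean)

    def __post_init__(self) -> None:
        for k, v in {**self.mono, **self.pairs}.items():
            if any(c < 0 for c in v) or v[0] <= 0:
                raise ValueError(f"non-positive truth coefficients for {k!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for s, e in self.establishment.items():
            if not 0 < e <= 1:
                raise ValueError(f"establishment for {s!r} must be in (0, 1]")
        if self.noise not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def pair_fits(self) -> dict[tuple[str, str], BicultureFit]:
        nan_se = {"b0": float("nan"), "b11": float("nan"), "b12": float("nan")}
        return {
            (f, c): BicultureFit(
                focal=f, companion=c, b0=b0, b11=b11, b12=b12, se=dict(nan_se),
                r2=float("nan"), n_obs=0,
            )
            for (f, c), (b0, b11, b12) in self.pairs.items()
        }


def default_truth(
    registry: Sequence[SpeciesParams],
    sigma: float = 0.1,
    harmonize: bool = True,
) -> TruthSet:
    """Truth set seeded from the bundled reference coefficients.

    With ``harmonize=True`` (default), each focal species' intercept and
    intraspecific coefficient are replaced by their mean over that species'
    bicultures, and the monoculture truth reuses the same values. This makes
    every data stratum lie on one consistent surface per focal species, so a
    noiseless simulate -> fit -> assemble -> predict pipeline closes exactly
    — the property the generator exists to test. ``harmonize=False`` keeps
    the stratum-specific reference values (more faithful to real data, where
    the monoculture-only and biculture re-fits of b0/b11 differ).
    """
    codes = [sp.code for sp in registry]
    ref_pairs = {
        (f, c): v for (f, c), v in reference.BICULTURE_TABLE.items()
        if f in codes and c in codes
    }
    pairs: dict[tuple[str, str], tuple[float, float, float]] = {}
    mono: dict[str, tuple[float, float]] = {}
    if harmonize:
        for a in codes:
            mine = [(b0, intra * b0) for (f, c), (b0, intra, _, _) in ref_pairs.items() if f == a]
            if not mine:
                continue
            b0_h = float(np.mean([m[0] for m in mine]))
            b11_h = float(np.mean([m[1] for m in mine]))
            mono[a] = (b0_h, b11_h)
            for (f, c), (b0, intra, inter, _) in ref_pairs.items():
                if f == a:
                    pairs[(f, c)] = (b0_h, b11_h, inter * b0)
    else:
        for (f, c), (b0, intra, inter, _) in ref_pairs.items():
            pairs[(f, c)] = (b0, intra * b0, inter * b0)
        for s, (b0, intra, _) in reference.MONOCULTURE_TABLE.items():
            if s in codes:
                mono[s] = (b0, intra * b0)
    return TruthSet(
        mono=mono,
        pairs=pairs,
        sigma=sigma,
        establishment={sp.code: sp.germination for sp in registry},
    )


def make_design(
    registry: Sequence[SpeciesParams],
    template: DesignTemplate | None = None,
    mono_reps: int = 1,
    bi_reps: int = 1,
    poly_reps: int = 5,
) -> pd.DataFrame:
    """Seeding plan: one row per plot, one ``seeds_<code>`` column per species.

    Replicate counts apply per stratum (monoculture / biculture / polyculture
    template rows); a count of zero omits that stratum.
    """
    codes = [sp.code for sp in registry]
    by_code = registry_by_code(registry)
    if template is None:
        template = default_design_template(codes)
    rows = []
    plot = 0
    for species, props in template.rows:
        reps = {1: mono_reps, 2: bi_reps}.get(len(species), poly_reps)
        for rep in range(reps):
            plot += 1
            row: dict = {"plot_id": f"P{plot:04d}", "block": str(rep + 1)}
            for c in codes:
                row[f"seeds_{c}"] = (
                    props.get(c, 0.0) * by_code[c].rec_rate_seeds if c in species else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _plot_biomass(
    truth: TruthSet, present: list[str], density: Mapping[str, float]
) -> dict[str, float]:
    """Noise-free expected biomass for one plot under the truth coefficients."""
    out: dict[str, float] = {}
    if len(present) == 1:
        a = present[0]
        if a not in truth.mono:
            raise KeyError(f"no monoculture truth for species {a!r}")
        b0, b11 = truth.mono[a]
        out[a] = float(predict_monoculture(b0, b11, density[a]))
    elif len(present) == 2:
        a, b = present
        for f, c in ((a, b), (b, a)):
            if (f, c) not in truth.pairs:
                raise KeyError(f"no pair truth for ({f}, {c})")
            b0, b11, b12 = truth.pairs[(f, c)]
            out[f] = float(predict_biculture(b0, b11, b12, density[f], density[c]))
    else:
        fits = truth.pair_fits()
        missing = [
            (f, c) for f in present for c in present if f != c and (f, c) not in fits
        ]
        if missing:
            raise KeyError(f"no pair truth for {missing}")
        model = assemble(present, fits)
        out = predict(model, {s: density[s] for s in present})
    return out


def simulate_trial(
    plan: pd.DataFrame,
    truth: TruthSet,
    seed: int,
    site_year: str = "SY1",
) -> list[PlotObservation]:
    """Simulate observed densities and biomasses for a seeding plan.

    Emergence: plants/m² ~ Binomial(round(seeds/m²), establishment). Biomass:
    the competition-model expectation for the plot's emerged densities, times
    the site-year scalar (1 when the site-year has no entry), times noise.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    codes = [c.removeprefix("seeds_") for c in plan.columns if c.startswith("seeds_")]
    scalar = truth.site_year_effects.get(site_year, 1.0)
    out: list[PlotObservation] = []
    for _, row in plan.iterrows():
        sown = {c: float(row[f"seeds_{c}"]) for c in codes}
        present = [c for c in codes if sown[c] > 0]
        density: dict[str, float] = {}
        for c in present:
            estab = truth.establishment.get(c, 1.0)
            density[c] = float(rng.binomial(int(round(sown[c])), estab))
        expected = _plot_biomass(truth, present, density)
        biomass: dict[str, float] = {}
        for c in present:
            y = expected[c] * scalar
            if truth.sigma > 0 and y > 0:
                if truth.noise == "lognormal":
                    y *= rng.lognormal(0.0, truth.sigma)
                else:
                    y = max(y + rng.normal(0.0, truth.sigma * y), 0.0)
            biomass[c] = float(y) if density[c] > 0 else 0.0
        out.append(
            PlotObservation(
                plot_id=str(row["plot_id"]),
                site_year=site_year,
                block=str(row.get("block", "")),
                species_set=frozenset(present),
                density=density,
                biomass=biomass,
            )
        )
    return out


def make_validation_set(
    truth: TruthSet,
    registry: Sequence[SpeciesParams],
    site_years: int = 9,
    blocks: int = 5,
    seed: int = 0,
) -> list[PlotObservation]:
    """Multi-site polyculture-only observations for exercising validation.

    Every 3- and 4-species subset of the registry is planted at replacement
    rates in each block of each site-year. Site-year scalars come from
    ``truth.site_year_effects`` keyed ``"SY1".."SYk"`` (default 1.0).
    """
    codes = [sp.code for sp in registry]
    by_code = registry_by_code(registry)
    subsets = [list(s) for r in (3, 4) for s in combinations(codes, r)]
    rows = []
    plot = 0
    for s in subsets:
        for b in range(blocks):
            plot += 1
            row: dict = {"plot_id": f"V{plot:04d}", "block": str(b + 1)}
            for c in codes:
                row[f"seeds_{c}"] = by_code[c].rec_rate_seeds / len(s) if c in s else 0.0
            rows.append(row)
    plan = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    out: list[PlotObservation] = []
    for i in range(site_years):
        name = f"SY{i + 1}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        obs = simulate_trial(plan, truth, seed=sub_seed, site_year=name)
        for o in obs:
            o.plot_id = f"{name}-{o.plot_id}"
        out.extend(obs)
    return out
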