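"""Bundled reference coefficient estimates for the four default species.

These are published yield-density coefficient estimates from a New York
restricted response-surface field trial of the four default cover crops
(pearl millet M, sorghum sudangrass S, sunn hemp H, cowpea C). They ship with
the package so that index derivation, polyculture assembly, and seeding-rate
optimization work out of the box with no external data.

The published table reports the intercept ``b0`` (plants/g) together with the
competition coefficients *normalized by the intercept* (``b11/b0`` and
``b12/b0``, m²/plant); :func:`biculture_fits` denormalizes them back to the
raw m²/g scale used by the model equations. Normalized values are printed to
four decimals, so quantities recomputed from them carry ~0.1-0.5% rounding
noise relative to the originally published derived indices.
"""

from __future__ import annotations

import numpy as np

from .yield_density import BicultureFit, MonocultureFit

__all__ = [
    "MONOCULTURE_TABLE",
    "BICULTURE_TABLE",
    "monoculture_fits",
    "biculture_fits",
    "fit_from_normalized",
]

#: species -> (b0 [plants/g], b11/b0 [m²/plant], r2)
MONOCULTURE_TABLE: dict[str, tuple[float, float, float]] = {
    "M": (0.1336, 0.0210, 0.19),
    "S": (0.0491, 0.0377, 0.66),
    "H": (0.1606, 0.0132, 0.44),
    "C": (0.0930, 0.0356, 0.86),
}

#: (focal, companion) -> (b0, b11/b0, b12/b0, r2)
BICULTURE_TABLE: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("M", "S"): (0.1319, 0.0213, 0.0622, 0.75),
    ("S", "M"): (0.0658, 0.0266, 0.0025, 0.59),
    ("M", "H"): (0.1646, 0.0161, 0.0175, 0.83),
    ("H", "M"): (0.2091, 0.0088, 0.0060, 0.90),
    ("M", "C"): (0.1920, 0.0134, 0.0041, 0.46),
    ("C", "M"): (0.0970, 0.0335, 0.0342, 0.94),
    ("S", "H"): (0.0839, 0.0203, 0.0078, 0.57),
    ("H", "S"): (0.1502, 0.0146, 0.0289, 0.95),
    ("S", "C"): (0.0644, 0.0279, 0.0226, 0.24),
    ("C", "S"): (0.1007, 0.0317, 0.0412, 0.78),
    ("H", "C"): (0.1548, 0.0141, 0.0106, 0.89),
    ("C", "H"): (0.0931, 0.0355, 0.0369, 0.97),
}


def fit_from_normalized(
    focal: str,
    companion: str | None,
    b0: float,
    intra_norm: float,
    inter_norm: float | None = None,
    r2: float = float("nan"),
    n_obs: int = 0,
) -> MonocultureFit | BicultureFit:
    """Build a fit record from intercept-normalized coefficients.

    Denormalization: b11 = (b11/b0) x b0 and b12 = (b12/b0) x b0. Standard
    errors are unknown for table-imported records (NaN).
    """
    if companion is None:
        return MonocultureFit(
            species=focal,
            b0=b0,
            b11=intra_norm * b0,
            se={"b0": np.nan, "b11": np.nan},
            r2=r2,
            n_obs=n_obs,
        )
    if inter_norm is None:
        raise ValueError("inter_norm required for a biculture record")
    return BicultureFit(
        focal=focal,
        companion=companion,
        b0=b0,
        b11=intra_norm * b0,
        b12=inter_norm * b0,
        se={"b0": np.nan, "b11": np.nan, "b12": np.nan},
        r2=r2,
        n_obs=n_obs,
    )


def monoculture_fits() -> dict[str, MonocultureFit]:
    """The reference monoculture fits, denormalized."""
    return {
        sp: fit_from_normalized(sp, None, b0, intra, r2=r2)
        for sp, (b0, intra, r2) in MONOCULTURE_TABLE.items()
    }


def biculture_fits() -> dict[tuple[str, str], BicultureFit]:
    """The reference biculture fits for all twelve ordered pairs, denormalized."""
    return {
        (f, c): fit_from_normalized(f, c, b0, intra, inter, r2=r2)
        for (f, c), (b0, intra, inter, r2) in BICULTURE_TABLE.items()
    }
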