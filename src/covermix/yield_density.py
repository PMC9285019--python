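"""Hyperbolic yield-density competition models and their nonlinear fits.

The monoculture model relates stand biomass Y (g/m²) of a species to its
emerged density N (plants/m²),

    Y = N / (b0 + b11 N),

so per-plant weight w = Y/N = 1/(b0 + b11 N) declines hyperbolically with
crowding. 1/b0 (g/plant) is the virtual weight of an isolated plant and 1/b11
(g/m²) the asymptotic maximum stand yield (law of constant final yield). The
biculture expansion adds a companion term,

    Y1 = N1 / (b0 + b11 N1 + b12 N2),

where b12 (m²/g) measures interspecific competition of the companion on the
focal species. Fits are unweighted nonlinear least squares on the biomass
scale, initialized from the exact linearization of the inverse per-plant
weight, 1/w = b0 + b11 N1 + b12 N2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data_model import PlotObservation

__all__ = [
    "MonocultureFit",
    "BicultureFit",
    "FitError",
    "predict_monoculture",
    "predict_biculture",
    "linearized_fit",
    "fit_monoculture",
    "fit_biculture",
    "fits_to_frame",
    "frame_to_fits",
]

#: Lower box bound for all coefficients during optimization.
COEF_FLOOR = 1e-9
#: Relative convergence tolerance on the objective.
FTOL = 1e-10
MAX_ITER = 500


class FitError(RuntimeError):
    """Nonlinear fit could not be performed or did not converge."""


@dataclass(frozen=True)
class MonocultureFit:
    """Fitted monoculture yield-density model for one species."""

    species: str
    b0: float  # plants/g, intercept
    b11: float  # m²/g, intraspecific competition
    se: dict[str, float]
    r2: float
    n_obs: int
    boundary: bool = False  # a coefficient pinned at the lower bound

    @property
    def coefficients(self) -> dict[str, float]:
        return {"b0": self.b0, "b11": self.b11}


@dataclass(frozen=True)
class BicultureFit:
    """Fitted biculture yield-density model for a focal species in a pair."""

    focal: str
    companion: str
    b0: float
    b11: float
    b12: float  # m²/g, interspecific competition of companion on focal
    se: dict[str, float]
    r2: float
    n_obs: int
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.focal == self.companion:
            raise ValueError("focal and companion species must differ")

    @property
    def coefficients(self) -> dict[str, float]:
        return {"b0": self.b0, "b11": self.b11, "b12": self.b12}


def predict_monoculture(b0: float, b11: float, N: float | np.ndarray) -> float | np.ndarray:
    """Stand biomass Y = N/(b0 + b11 N), g/m²; asymptote 1/b11."""
    N = np.asarray(N, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(N > 0, N / (b0 + b11 * N), 0.0)
    return float(out) if out.ndim == 0 else out


def predict_biculture(
    b0: float, b11: float, b12: float, N1: float | np.ndarray, N2: float | np.ndarray
) -> float | np.ndarray:
    """Focal biomass Y1 = N1/(b0 + b11 N1 + b12 N2), g/m².

    Reduces to :func:`predict_monoculture` at N2 = 0 and is strictly
    decreasing in N2 when b12 > 0 and N1 > 0.
    """
    N1 = np.asarray(N1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(N1 > 0, N1 / (b0 + b11 * N1 + b12 * N2), 0.0)
    return float(out) if out.ndim == 0 else out


def _extract_arrays(
    observations: Iterable[PlotObservation], focal: str, companion: str | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Pull (N_focal, N_companion, Y_focal) from the relevant plots.

    For a monoculture fit: the focal species' monoculture plots. For a
    biculture fit: the focal monoculture plots plus the focal-companion
    biculture plots (the combined response-surface data). Plots where the
    focal species has zero density are dropped (per-plant weight undefined);
    the count of dropped plots is returned for diagnostics.
    """
    wanted = {focal} if companion is None else {focal, companion}
    n1, n2, y = [], [], []
    dropped = 0
    for obs in observations:
        if not obs.species_set <= wanted or focal not in obs.species_set:
            continue
        nf = obs.density.get(focal, 0.0)
        if nf <= 0:
            dropped += 1
            continue
        n1.append(nf)
        n2.append(obs.density.get(companion, 0.0) if companion else 0.0)
        y.append(obs.biomass.get(focal, 0.0))
    return np.array(n1), np.array(n2), np.array(y), dropped


def linearized_fit(
    observations: Iterable[PlotObservation],
    focal: str,
    companion: str | None = None,
) -> np.ndarray:
    """Starting values from OLS on the inverse per-plant weight.

    Since 1/w = b0 + b11 N1 (+ b12 N2) is linear in the coefficients, an
    ordinary least-squares fit of N/Y on (1, N1[, N2]) recovers them exactly
    on noiseless data. Coefficients are floored at a small positive epsilon;
    under noise this serves only to initialize the nonlinear fit.
    """
    N1, N2, Y, _ = _extract_arrays(observations, focal, companion)
    p = 2 if companion is None else 3
    if len(N1) < p:
        raise FitError(
            f"linearized fit for {focal!r} needs >= {p} usable plots, got {len(N1)}"
        )
    if np.any(Y <= 0):
        raise FitError(f"linearized fit for {focal!r}: nonpositive biomass at positive density")
    X = np.column_stack([np.ones_like(N1), N1] + ([N2] if companion else []))
    if np.linalg.matrix_rank(X) < p:
        raise FitError(f"linearized fit for {focal!r}: singular design")
    beta, *_ = np.linalg.lstsq(X, N1 / Y, rcond=None)
    return np.clip(beta, COEF_FLOOR, None)


def _nls(N1, N2, Y, x0, n_par):
    def residuals(b):
        if n_par == 2:
            return N1 / (b[0] + b[1] * N1) - Y
        return N1 / (b[0] + b[1] * N1 + b[2] * N2) - Y

    res = least_squares(
        residuals,
        x0[:n_par],
        bounds=(COEF_FLOOR, np.inf),
        ftol=FTOL,
        xtol=FTOL,
        gtol=FTOL,
        max_nfev=MAX_ITER,
    )
    if not res.success:
        raise FitError(
            f"nonlinear fit did not converge: status {res.status}, "
            f"{res.nfev} evaluations, cost {res.cost:.3g}"
        )
    # asymptotic covariance from the Jacobian at the solution
    n, p = len(Y), n_par
    dof = max(n - p, 1)
    rss = float(2 * res.cost)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    boundary = bool(np.any(res.x <= COEF_FLOOR * 10))
    return res.x, se, boundary


def _standardized_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Squared Pearson correlation of observed vs fitted, each z-scored."""
    so, sf = observed.std(ddof=1), fitted.std(ddof=1)
    if so == 0 or sf == 0 or len(observed) < 3:
        return float("nan")
    r = np.corrcoef((observed - observed.mean()) / so, (fitted - fitted.mean()) / sf)[0, 1]
    return float(r**2)


def _initial(observations, focal, companion, N1, N2, Y):
    try:
        x0 = linearized_fit(observations, focal, companion)
        if np.all(x0 > COEF_FLOOR):
            return x0
    except FitError:
        pass
    # fallback: crude moment-style starting values
    b0 = float(np.median(N1 / Y)) if np.all(Y > 0) else 1.0
    b11 = 1.0 / float(Y.max()) if Y.max() > 0 else 1.0
    return np.array([b0, b11, b11 / 2.0])[: (2 if companion is None else 3)]


def fit_monoculture(observations: Iterable[PlotObservation], focal: str) -> MonocultureFit:
    """Fit Y = N/(b0 + b11 N) to the focal species' monoculture plots.

    Unweighted least squares on the biomass scale, coefficients constrained
    positive, initialized from :func:`linearized_fit`. Requires at least three
    monoculture plots with distinct positive densities. A coefficient pinned
    at the lower bound sets the ``boundary`` flag and emits a warning.
    """
    N1, N2, Y, dropped = _extract_arrays(observations, focal, None)
    if len(N1) < 3:
        raise FitError(f"monoculture fit for {focal!r} needs >= 3 plots, got {len(N1)}")
    if len(np.unique(N1)) < 2:
        raise FitError(f"monoculture fit for {focal!r}: all densities equal, not identifiable")
    x0 = _initial(observations, focal, None, N1, N2, Y)
    x, se, boundary = _nls(N1, N2, Y, x0, 2)
    if boundary:
        warnings.warn(f"monoculture fit for {focal!r}: coefficient at lower bound")
    fitted = predict_monoculture(x[0], x[1], N1)
    return MonocultureFit(
        species=focal,
        b0=float(x[0]),
        b11=float(x[1]),
        se={"b0": float(se[0]), "b11": float(se[1])},
        r2=_standardized_r2(Y, fitted),
        n_obs=len(N1),
        boundary=boundary,
    )


def fit_biculture(
    observations: Iterable[PlotObservation], focal: str, companion: str
) -> BicultureFit:
    """Fit the expanded model to combined monoculture + biculture plots.

    The response-surface convention: the data for a focal species in a pair
    are its monoculture plots plus the plots of that species pair, so b0 and
    b11 are re-estimated jointly with b12 (and may differ from the
    monoculture-only fit). Missing monoculture plots produce a warning, not an
    error.
    """
    N1, N2, Y, dropped = _extract_arrays(observations, focal, companion)
    if len(N1) < 3:
        raise FitError(
            f"biculture fit for {focal!r} with {companion!r} needs >= 3 plots, got {len(N1)}"
        )
    if not np.any(N2 == 0):
        warnings.warn(
            f"biculture fit for {focal!r} with {companion!r}: no monoculture plots present"
        )
    if not np.any(N2 > 0):
        # companion never present: b12 unidentifiable, pinned at the floor
        warnings.warn(
            f"biculture fit for {focal!r} with {companion!r}: companion density always "
            "zero, b12 unidentifiable (boundary)"
        )
        x0 = _initial(observations, focal, None, N1, N2, Y)
        x2, se2, _ = _nls(N1, N2, Y, x0, 2)
        x = np.array([x2[0], x2[1], COEF_FLOOR])
        se = np.array([se2[0], se2[1], np.nan])
        boundary = True
    else:
        x0 = _initial(observations, focal, companion, N1, N2, Y)
        x, se, boundary = _nls(N1, N2, Y, x0, 3)
    if boundary:
        warnings.warn(
            f"biculture fit for {focal!r} with {companion!r}: coefficient at lower bound"
        )
    fitted = predict_biculture(x[0], x[1], x[2], N1, N2)
    return BicultureFit(
        focal=focal,
        companion=companion,
        b0=float(x[0]),
        b11=float(x[1]),
        b12=float(x[2]),
        se={"b0": float(se[0]), "b11": float(se[1]), "b12": float(se[2])},
        r2=_standardized_r2(Y, fitted),
        n_obs=len(N1),
        boundary=boundary,
    )


def fits_to_frame(fits: Sequence[MonocultureFit | BicultureFit]) -> pd.DataFrame:
    """Serialize fits to a table with raw and normalized coefficients."""
    rows = []
    for f in fits:
        is_bi = isinstance(f, BicultureFit)
        focal = f.focal if is_bi else f.species
        companion = f.companion if is_bi else ""
        treatment = "".join(sorted((focal, companion))) if is_bi else focal
        rows.append(
            {
                "treatment": treatment,
                "species": focal,
                "companion": companion,
                "b0": f.b0,
                "b11": f.b11,
                "b12": f.b12 if is_bi else np.nan,
                "b11_over_b0": f.b11 / f.b0,
                "b12_over_b0": f.b12 / f.b0 if is_bi else np.nan,
                "se_b0": f.se.get("b0", np.nan),
                "se_b11": f.se.get("b11", np.nan),
                "se_b12": f.se.get("b12", np.nan),
                "r2": f.r2,
                "n_obs": f.n_obs,
                "boundary": f.boundary,
            }
        )
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> list[MonocultureFit | BicultureFit]:
    """Rebuild fit records from a table written by :func:`fits_to_frame`."""
    fits: list[MonocultureFit | BicultureFit] = []
    for _, row in df.iterrows():
        companion = row.get("companion", "")
        companion = "" if pd.isna(companion) else str(companion)
        se = {
            k: float(row.get(f"se_{k}", np.nan))
            for k in (("b0", "b11", "b12") if companion else ("b0", "b11"))
        }
        common = dict(
            b0=float(row["b0"]),
            b11=float(row["b11"]),
            se=se,
            r2=float(row.get("r2", np.nan)),
            n_obs=int(row.get("n_obs", 0)),
            boundary=bool(row.get("boundary", False)),
        )
        if companion:
            fits.append(
                BicultureFit(
                    focal=str(row["species"]), companion=companion,
                    b12=float(row["b12"]), **common,
                )
            )
        else:
            fits.append(MonocultureFit(species=str(row["species"]), **common))
    return fits
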