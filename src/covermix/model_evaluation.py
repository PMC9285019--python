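"""Four-indicator validation battery for predicted vs observed biomass.

Within each group (species, or site-year x species), observed and predicted
biomass are independently z-scored (sample SD), then four indicators are
computed on the standardized pairs:

1. RMSE — root mean squared difference (dimensionless);
2. slope — simple linear regression of observed on predicted, which under
   independent standardization equals the Pearson correlation;
3. a bias test — two-sided t-test of slope != 1 with n-2 df;
4. r² — coefficient of determination of the same regression (= slope² here).

A prediction is classified successful when RMSE is low, slope > 0.5, the
bias test is non-significant, and r² > 0.5. Independent standardization makes
all four indicators invariant to positive affine rescaling of either vector,
so the battery scores *pattern* agreement across a group, not absolute level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationReport",
    "SuccessThresholds",
    "zscore_by_group",
    "evaluate",
    "classify_success",
    "reports_to_frame",
]


@dataclass(frozen=True)
class SuccessThresholds:
    """Cutoffs for the success classification.

    ``rmse_max`` has no published convention; the default 0.75 on the
    standardized scale is this package's choice and is flagged as such in
    exported reports.
    """

    rmse_max: float = 0.75
    slope_min: float = 0.5
    alpha: float = 0.05
    r2_min: float = 0.5


@dataclass(frozen=True)
class ValidationReport:
    group: Hashable
    n: int
    rmse: float
    slope: float
    bias_p: float
    r2: float
    success: bool


def zscore_by_group(
    values: Sequence[float], groups: Sequence[Hashable]
) -> tuple[np.ndarray, list[Hashable]]:
    """Z-score values within each group (sample SD, ddof=1).

    Returns the standardized array (NaN for members of excluded groups) and
    the list of groups excluded for zero variance or fewer than two records.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(list(groups))
    out = np.full(len(s), np.nan)
    excluded: list[Hashable] = []
    for key, idx in s.groupby(g.values).groups.items():
        vals = s.loc[idx]
        sd = vals.std(ddof=1)
        if len(vals) < 2 or not sd > 0:
            excluded.append(key)
            warnings.warn(f"group {key!r} excluded from standardization (zero variance)")
            continue
        out[idx] = (vals - vals.mean()) / sd
    return out, excluded


def evaluate(
    predicted: Sequence[float],
    observed: Sequence[float],
    groups: Sequence[Hashable],
    thresholds: SuccessThresholds = SuccessThresholds(),
) -> list[ValidationReport]:
    """Run the four-indicator battery per group on paired vectors.

    Observed and predicted are standardized independently within each group;
    groups with fewer than three pairs or zero variance are skipped with a
    warning. Regression orientation: observed is the response, predicted the
    regressor (symmetric in the slope under standardization).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have the same length")
    g = pd.Series(list(groups))
    if len(g) != len(pred):
        raise ValueError("groups must have the same length as the data")
    reports: list[ValidationReport] = []
    for key, idx in g.groupby(g.values).groups.items():
        p, o = pred[idx], obs[idx]
        n = len(p)
        if n < 3:
            warnings.warn(f"group {key!r} skipped: n={n} < 3")
            continue
        sp_, so_ = p.std(ddof=1), o.std(ddof=1)
        if not (sp_ > 0 and so_ > 0):
            warnings.warn(f"group {key!r} skipped: zero variance")
            continue
        pz = (p - p.mean()) / sp_
        oz = (o - o.mean()) / so_
        rmse = float(np.sqrt(np.mean((oz - pz) ** 2)))
        reg = stats.linregress(pz, oz)
        slope = float(reg.slope)
        if rmse < 1e-10:
            # numerically perfect agreement: the t-statistic is 0/0 noise
            bias_p = 1.0
        elif reg.stderr > 0:
            t = (slope - 1.0) / reg.stderr
            bias_p = float(2 * stats.t.sf(abs(t), df=n - 2))
        else:
            bias_p = 1.0 if slope == 1.0 else 0.0
        r2 = float(reg.rvalue**2)
        report = ValidationReport(
            group=key, n=n, rmse=rmse, slope=slope, bias_p=bias_p, r2=r2, success=False
        )
        reports.append(
            ValidationReport(
                **{**report.__dict__, "success": classify_success(report, thresholds)}
            )
        )
    return reports


def classify_success(
    report: ValidationReport, thresholds: SuccessThresholds = SuccessThresholds()
) -> bool:
    """Success iff RMSE <= rmse_max, slope > slope_min, bias_p >= alpha, r² > r2_min."""
    return bool(
        report.rmse <= thresholds.rmse_max
        and report.slope > thresholds.slope_min
        and report.bias_p >= thresholds.alpha
        and report.r2 > thresholds.r2_min
    )


def reports_to_frame(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    """One row per group with the four indicators, n, and the success flag.

    The RMSE cutoff behind ``success`` is a package convention (see
    :class:`SuccessThresholds`), noted in the exported table.
    """
    df = pd.DataFrame(
        [
            {
                "group": str(r.group),
                "n": r.n,
                "rmse": r.rmse,
                "slope": r.slope,
                "bias_p": r.bias_p,
                "r2": r.r2,
                "success": r.success,
            }
            for r in reports
        ]
    )
    df.attrs["note"] = "rmse_max threshold is a package convention, not a published value"
    return df
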