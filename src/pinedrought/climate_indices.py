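"""Monthly drought indices: Thornthwaite PET, SPI and SPEI.

SPI standardizes scale-aggregated precipitation through a per-calendar-month
zero-inflated gamma fit; SPEI standardizes the climatic water balance
(precipitation minus potential evapotranspiration) through a three-parameter
log-logistic distribution fitted by unbiased probability-weighted moments.
Both map the fitted cumulative probability to standard-normal quantiles, so
an index of -1.5 means that month's aggregate sits at the 6.7th percentile
of its calendar-month climatology.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gamma as gamma_fn

__all__ = [
    "thornthwaite_pet",
    "standardized_index",
    "spi",
    "spei",
    "drought_index_table",
]

_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


def _check_contiguous(df: pd.DataFrame) -> None:
    idx = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
    if len(idx) and not np.all(np.diff(idx) == 1):
        raise ValueError("climate series months are not contiguous")


def _day_length(latitude: float, month: np.ndarray) -> np.ndarray:
    """Mean day length (hours) per month from latitude and solar declination."""
    doy = _MID_MONTH_DOY[month - 1]
    decl = 0.4093 * np.sin(2.0 * np.pi * doy / 365.25 - 1.405)
    lat = np.deg2rad(latitude)
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    return 24.0 * ws / np.pi


def thornthwaite_pet(
    climate: pd.DataFrame, latitude: float | None = None
) -> pd.Series:
    """Thornthwaite monthly potential evapotranspiration (mm).

    Uses the annual heat index computed from each calendar year's monthly
    mean temperatures, with day-length and month-length corrections. PET is
    zero for months with mean temperature <= 0 deg C.
    """
    if latitude is None:
        latitude = climate.attrs.get("latitude")
    if latitude is None:
        raise ValueError("latitude required for Thornthwaite PET")
    if not (-90.0 <= latitude <= 90.0):
        raise ValueError("latitude must be in [-90, 90] degrees")
    if len(climate) < 12:
        raise ValueError("need at least 12 consecutive months")
    _check_contiguous(climate)

    temp = climate["temp"].to_numpy(dtype=float)
    month = climate["month"].to_numpy(dtype=int)
    year = climate["year"].to_numpy(dtype=int)

    tpos = np.clip(temp, 0.0, None)
    monthly_i = (tpos / 5.0) ** 1.514
    heat_index = pd.Series(monthly_i).groupby(year).transform("sum").to_numpy()
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * tpos / heat_index) ** a
    pet = np.where((tpos <= 0.0) | (heat_index <= 0.0), 0.0, pet)
    n_hours = _day_length(latitude, month)
    ndays = _DAYS_IN_MONTH[month - 1]
    pet = pet * (n_hours / 12.0) * (ndays / 30.0)
    return pd.Series(pet, index=climate.index, name="pet")


# ---------------------------------------------------------------------------
# distribution fits
# ---------------------------------------------------------------------------

def _fit_gamma_zero_cdf(sample: np.ndarray):
    """CDF of a zero-inflated gamma fitted by MLE on the positive part."""
    q0 = float(np.mean(sample <= 0.0))
    pos = sample[sample > 0.0]
    if len(pos) < 3 or np.std(pos) == 0:
        return None
    shape, _, scale = stats.gamma.fit(pos, floc=0.0)

    def cdf(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        body = q0 + (1.0 - q0) * stats.gamma.cdf(x, shape, scale=scale)
        return np.where(x <= 0.0, q0, body)

    return cdf


def _unbiased_pwm(x: np.ndarray, r: int) -> float:
    """Unbiased probability-weighted moment w_r = E[X (1-F(X))^r]."""
    x = np.sort(x)
    n = len(x)
    j = np.arange(1, n + 1)
    w = np.ones(n)
    for k in range(r):
        w *= (n - j - k) / (n - 1.0 - k)
    return float(np.mean(w * x))


def _fit_loglogistic_cdf(sample: np.ndarray, _reflect: bool = True):
    """CDF of a 3-parameter log-logistic fitted by unbiased PWMs.

    F(x) = [1 + (alpha/(x - gamma))^beta]^-1 for x > gamma; the fit follows
    the standard PWM solution used for SPEI-type indices. Left-skewed
    samples (invalid shape) are handled by fitting the negated sample and
    returning the complementary CDF.
    """
    if np.std(sample) == 0:
        return None
    w0 = _unbiased_pwm(sample, 0)
    w1 = _unbiased_pwm(sample, 1)
    w2 = _unbiased_pwm(sample, 2)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    beta = (2.0 * w1 - w0) / denom if denom != 0 else np.nan
    if not np.isfinite(beta) or beta <= 1.0:
        if _reflect:
            neg = _fit_loglogistic_cdf(-sample, _reflect=False)
            if neg is not None:
                return lambda x: 1.0 - neg(-np.asarray(x, dtype=float))
        return None
    g = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g
    if not np.isfinite(alpha) or alpha <= 0:
        return None
    gamma0 = w0 - alpha * g

    def cdf(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = np.clip(x - gamma0, 1e-12, None)
        return 1.0 / (1.0 + (alpha / z) ** beta)

    return cdf


def _empirical_cdf(sample: np.ndarray):
    """Gringorten plotting-position fallback for ill-conditioned fits."""
    srt = np.sort(sample)
    n = len(srt)

    def cdf(x: np.ndarray) -> np.ndarray:
        ranks = np.searchsorted(srt, np.asarray(x, dtype=float), side="right")
        return (ranks - 0.44) / (n + 0.12)

    return cdf


# ---------------------------------------------------------------------------
# standardized index
# ---------------------------------------------------------------------------

def standardized_index(
    values: pd.Series,
    years: np.ndarray,
    months: np.ndarray,
    scale: int = 3,
    distribution: str = "gamma",
    reference_period: tuple[int, int] | None = None,
) -> pd.Series:
    """Standardize a monthly water quantity into an SPI/SPEI-type index.

    ``values`` is aggregated with a trailing ``scale``-month moving sum; for
    each calendar month the chosen distribution is fitted to the aggregates
    of the reference years and each aggregate mapped to a standard-normal
    quantile. The leading ``scale - 1`` months are returned as NaN.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if distribution not in ("gamma", "loglogistic"):
        raise ValueError("distribution must be 'gamma' or 'loglogistic'")
    vals = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    months = np.asarray(months, dtype=int)
    if distribution == "gamma" and np.any(vals < 0):
        raise ValueError("gamma-based index requires non-negative values")

    agg = pd.Series(vals).rolling(scale).sum().to_numpy()
    if reference_period is None:
        ref_lo, ref_hi = int(years.min()), int(years.max())
    else:
        ref_lo, ref_hi = reference_period
        if ref_lo < years.min() or ref_hi > years.max():
            raise ValueError("reference period outside the data span")
    in_ref = (years >= ref_lo) & (years <= ref_hi)

    out = np.full(len(vals), np.nan)
    valid = ~np.isnan(agg)
    for m in range(1, 13):
        sel = (months == m) & valid
        if not sel.any():
            continue
        ref_sel = sel & in_ref
        sample = agg[ref_sel]
        if len(sample) < 10:
            raise ValueError(
                f"fewer than 10 reference years for calendar month {m}"
            )
        if np.std(sample) == 0:
            warnings.warn(
                f"constant aggregates for calendar month {m}; index set to 0",
                stacklevel=2,
            )
            out[sel] = 0.0
            continue
        if distribution == "gamma":
            cdf = _fit_gamma_zero_cdf(sample)
        else:
            cdf = _fit_loglogistic_cdf(sample)
        if cdf is None:
            warnings.warn(
                f"distribution fit failed for calendar month {m}; "
                "using empirical plotting positions",
                stacklevel=2,
            )
            cdf = _empirical_cdf(sample)
        p = np.clip(cdf(agg[sel]), 1e-8, 1.0 - 1e-8)
        out[sel] = stats.norm.ppf(p)
    return pd.Series(out, index=values.index if hasattr(values, "index") else None)


def spi(
    climate: pd.DataFrame,
    scale: int = 3,
    reference_period: tuple[int, int] | None = None,
) -> pd.Series:
    """Standardized precipitation index (gamma with zero inflation)."""
    _check_contiguous(climate)
    return standardized_index(
        climate["precip"],
        climate["year"].to_numpy(),
        climate["month"].to_numpy(),
        scale=scale,
        distribution="gamma",
        reference_period=reference_period,
    ).rename("spi")


def spei(
    climate: pd.DataFrame,
    scale: int = 3,
    latitude: float | None = None,
    reference_period: tuple[int, int] | None = None,
) -> pd.Series:
    """Standardized precipitation-evapotranspiration index (log-logistic)."""
    _check_contiguous(climate)
    pet = thornthwaite_pet(climate, latitude=latitude)
    balance = climate["precip"] - pet
    return standardized_index(
        balance,
        climate["year"].to_numpy(),
        climate["month"].to_numpy(),
        scale=scale,
        distribution="loglogistic",
        reference_period=reference_period,
    ).rename("spei")


def drought_index_table(
    climate: pd.DataFrame,
    scale: int = 3,
    latitude: float | None = None,
    reference_period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """year/month table with SPI and SPEI columns at the given scale."""
    out = climate[["year", "month"]].copy()
    out["spi"] = spi(climate, scale=scale, reference_period=reference_period)
    out["spei"] = spei(
        climate, scale=scale, latitude=latitude, reference_period=reference_period
    )
    out["scale"] = scale
    return out
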