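"""Growth-rate, q-rate and yield estimation from batch time series.

Model: exponential growth X(t) = X0 exp(mu t) with, for each extracellular
metabolite, M(t) = M0 + (q X0 / mu)(exp(mu t) - 1).  q is signed: negative
for consumption (substrate), positive for production.  Errors are treated as
multiplicative with constant coefficient of variation (default 5 %), so the
growth fit is an ordinary least squares on log X and the metabolite fits are
weighted linear least squares with known sigma.  A fit window (contiguous,
>= 6 points where available) is selected by maximizing R^2 on log-biomass to
exclude lag/stationary observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "GrowthFit",
    "RateFit",
    "PhysioParams",
    "fit_growth",
    "fit_qrates",
    "fit_physiology",
    "compute_yields",
    "DEFAULT_OD_TO_CDW",
]

DEFAULT_OD_TO_CDW = 0.563  # gCDW per OD600 unit


@dataclass
class TimeSeries:
    """Batch culture observations: time (h), biomass, concentrations (mM)."""

    time: np.ndarray
    biomass: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    biomass_unit: str = "od600"  # or "gcdw"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time points must be strictly increasing")
        if len(self.biomass) != len(self.time):
            raise ValueError("biomass length mismatch")
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "biomass": self.biomass})
        for k, v in self.concentrations.items():
            df[k] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, biomass_unit: str = "od600") -> "TimeSeries":
        other = [c for c in df.columns if c not in ("time", "biomass")]
        return cls(
            df["time"].to_numpy(),
            df["biomass"].to_numpy(),
            {c: df[c].to_numpy() for c in other},
            biomass_unit,
        )


@dataclass
class GrowthFit:
    mu: float
    x0: float  # gCDW/L
    sd_mu: float
    sd_x0: float
    window: tuple[int, int]  # [start, stop) indices of the fitted window
    r2: float
    is_growing: bool
    conversion_factor: float
    # covariance of (log X0, mu) from the log-linear fit; lets downstream
    # consumers propagate trajectory uncertainty at any time point
    cov: np.ndarray = None

    def logx_var(self, t: float) -> float:
        """Variance of the fitted log-trajectory at time t."""
        if self.cov is None:
            return (self.sd_x0 / max(self.x0, 1e-12)) ** 2 + (t * self.sd_mu) ** 2
        return float(self.cov[0, 0] + 2 * t * self.cov[0, 1] + t * t * self.cov[1, 1])


@dataclass
class RateFit:
    q: float  # mmol gCDW^-1 h^-1, negative = consumption
    m0: float
    sd_q: float
    sd_m0: float


@dataclass
class PhysioParams:
    mu: float
    x0: float
    sd_mu: float
    sd_x0: float
    rates: dict[str, RateFit]
    conversion_factor: float = DEFAULT_OD_TO_CDW


def _r2(t: np.ndarray, logx: np.ndarray, i0: int, i1: int) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(t[i0:i1], logx[i0:i1])[0, 1]
    return r * r if np.isfinite(r) else 0.0


def _select_window(
    t: np.ndarray, logx: np.ndarray, min_points: int = 6, gain: float = 0.005
) -> tuple[int, int]:
    """Trim lag/stationary points greedily from either end.

    An endpoint is dropped only if it improves R^2 of the log-linear fit by
    more than ``gain`` — on lag-free data the full series is kept (shorter
    windows winning on noise alone would inflate the parameter variance),
    while a genuine lag or plateau degrades R^2 strongly enough to be cut.
    """
    n = len(t)
    i0, i1 = 0, n
    while i1 - i0 > max(min_points, 4):
        base = _r2(t, logx, i0, i1)
        trimmed = [(_r2(t, logx, i0 + 1, i1), i0 + 1, i1), (_r2(t, logx, i0, i1 - 1), i0, i1 - 1)]
        r2_best, j0, j1 = max(trimmed)
        if r2_best > base + gain:
            i0, i1 = j0, j1
        else:
            break
    return i0, i1


def fit_growth(
    ts: TimeSeries,
    cv: float = 0.05,
    conversion_factor: float = DEFAULT_OD_TO_CDW,
    window: tuple[int, int] | str = "auto",
) -> GrowthFit:
    """Weighted exponential fit of the biomass trajectory.

    With constant-CV multiplicative noise, OLS on log X is the exact weighted
    least squares of X(t) = X0 exp(mu t).  Parameter SDs come from the OLS
    covariance.  Biomass in OD600 is converted to gCDW/L with the
    configurable conversion factor (mu itself is conversion-independent).
    """
    if len(ts.time) < 4:
        raise ValueError("need at least 4 biomass points")
    if np.any(~np.isfinite(ts.biomass)) or np.any(ts.biomass <= 0):
        raise ValueError("biomass must be positive and finite")
    factor = conversion_factor if ts.biomass_unit == "od600" else 1.0
    x = ts.biomass * factor
    logx = np.log(x)
    if window == "auto":
        window = _select_window(ts.time, logx)
    i0, i1 = window
    t, ly = ts.time[i0:i1], logx[i0:i1]
    if len(t) < 4:
        raise ValueError("fit window has fewer than 4 points")

    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, ly, rcond=None)
    resid = ly - X @ coef
    dof = max(len(t) - 2, 1)
    s2 = max(float(resid @ resid) / dof, (cv * 1e-6) ** 2)  # guard exact data
    cov = s2 * np.linalg.inv(X.T @ X)
    mu = float(coef[1])
    x0 = float(np.exp(coef[0]))
    sd_mu = float(np.sqrt(cov[1, 1]))
    sd_x0 = float(x0 * np.sqrt(cov[0, 0]))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    growing = mu > max(1e-6, 2 * sd_mu)
    return GrowthFit(mu, x0, sd_mu, sd_x0, (i0, i1), r2, growing, factor, cov=cov)


def fit_qrates(
    ts: TimeSeries,
    growth: GrowthFit,
    cv: float = 0.05,
    floor: float = 1e-3,
    use_observed_biomass: bool = False,
) -> dict[str, RateFit]:
    """Per-metabolite weighted linear fit of M(t) = M0 + (q/mu)(X(t) - X0).

    Linear in (M0, q) once the growth fit fixes (mu, X0).  The regressor is
    the fitted trajectory X0 e^{mu t} (noise-free given the growth fit);
    ``use_observed_biomass=True`` substitutes the measured biomass at each
    sampling time, which is more robust when the exponential model is in
    doubt but injects the biomass CV into the slope.  Weights are 1/sd^2
    with sd = cv * max(|M|, floor), augmented in observed-biomass mode by
    the regressor noise.  Metabolite columns with fewer than 3 finite values
    are skipped with a warning.
    """
    mu, x0 = growth.mu, growth.x0
    if mu <= 0:
        raise ValueError("q-rate fit requires a growing culture (mu > 0)")
    if use_observed_biomass:
        x = ts.biomass * growth.conversion_factor
    else:
        x = x0 * np.exp(mu * ts.time)
    g = (x - x0) / mu  # gCDW h / L accumulated per unit q
    out: dict[str, RateFit] = {}
    for name, m in ts.concentrations.items():
        ok = np.isfinite(m)
        if ok.sum() < 3:
            warnings.warn(f"metabolite {name!r}: fewer than 3 points, skipped", stacklevel=2)
            continue
        X = np.column_stack([np.ones(ok.sum()), g[ok]])
        sd_m = cv * np.maximum(np.abs(m[ok]), floor)
        q = 0.0
        # two passes: the second folds the regressor noise (biomass CV, only
        # present in observed-biomass mode), scaled by the pass-1 slope, into
        # the per-point error budget
        x_cv = cv if use_observed_biomass else 0.0
        for _ in range(2):
            sd = np.hypot(sd_m, abs(q) * x_cv * x[ok] / mu)
            W = 1.0 / sd
            Xw, yw = X * W[:, None], m[ok] * W
            coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            cov = np.linalg.inv(Xw.T @ Xw)  # known-sigma covariance
            q = float(coef[1])
        # add the shared growth-trajectory uncertainty: q scales with the
        # fitted biomass at the leverage-weighted time of the regression
        lever = (X[:, 1] ** 2) / np.maximum(sd**2, 1e-30)
        t_star = float(np.sum(lever * ts.time[ok]) / max(np.sum(lever), 1e-30))
        sd_scale = np.sqrt(max(growth.logx_var(t_star), 0.0))
        sd_q = float(np.hypot(np.sqrt(cov[1, 1]), abs(q) * sd_scale))
        out[name] = RateFit(q=q, m0=float(coef[0]),
                            sd_q=sd_q, sd_m0=float(np.sqrt(cov[0, 0])))
    return out


def fit_physiology(
    ts: TimeSeries, cv: float = 0.05, conversion_factor: float = DEFAULT_OD_TO_CDW
) -> PhysioParams:
    g = fit_growth(ts, cv=cv, conversion_factor=conversion_factor)
    rates = fit_qrates(ts, g, cv=cv)
    return PhysioParams(g.mu, g.x0, g.sd_mu, g.sd_x0, rates, g.conversion_factor)


def compute_yields(
    params: PhysioParams,
    substrate: str,
    molar_masses: dict[str, float],
    carbon_counts: dict[str, int],
) -> pd.DataFrame:
    """Biomass and product yields from fitted q-rates.

    Y_X/S = mu / (|q_S| MW_S 1e-3) in g g^-1; product yields |q_P/q_S| in
    mol mol^-1, converted to Cmol Cmol^-1 with carbon counts and to g g^-1
    with molar masses.
    """
    if substrate not in params.rates:
        raise ValueError(f"substrate {substrate!r} has no fitted rate")
    qs = params.rates[substrate].q
    if qs >= 0:
        raise ValueError("substrate must be consumed (q_S < 0)")
    mw_s = molar_masses[substrate]
    rows = [
        {
            "species": "biomass",
            "yield_g_per_g": params.mu / (abs(qs) * mw_s * 1e-3),
            "yield_mol_per_mol": np.nan,
            "yield_cmol_per_cmol": np.nan,
        }
    ]
    for name, rf in params.rates.items():
        if name == substrate or rf.q <= 0:
            continue
        mol = abs(rf.q / qs)
        rows.append(
            {
                "species": name,
                "yield_g_per_g": mol * molar_masses[name] / mw_s,
                "yield_mol_per_mol": mol,
                "yield_cmol_per_cmol": mol * carbon_counts[name] / carbon_counts[substrate],
            }
        )
    return pd.DataFrame(rows).set_index("species")
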