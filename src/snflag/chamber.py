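"""Closed-chamber flux inversion for acetylene-reduction and CO2 exchange.

A plant sits sealed in a leaky chamber.  Nitrogenase reduces injected
acetylene to ethylene, so the substrate-saturated acetylene-reduction rate
(Vmax, proportional to SNF) is recovered from the ethylene accumulation rate
after correcting for the first-order chamber leak (keff) and for
Michaelis–Menten substrate limitation as the acetylene itself decays through
the leak:

    Vmax(t) = (dE/dt + keff * E(t)) * (Km / (A0 * exp(-keff*t)) + 1) * n

with mole fractions in ppm, time in hours, and n = P*V/(R*T) the molar
content of the chamber, so the result is in umol h^-1.  Net plant CO2
exchange (NPE) uses the same leak correction:

    NPE(t) = (dCO2/dt + keff * (CO2(t) - CO2_ambient)) * n

with the chamber-source sign convention: positive NPE means the plant adds
CO2 to the chamber air (respiration); negative means net uptake.  Dark-phase
NPE is therefore whole-symbiosis respiration directly, and apparent
photosynthesis is the light-minus-dark difference.

Uncertainty is propagated by parametric bootstrap: slope and A0 normal,
keff and Km gamma, percentile CIs from the draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .config import ChamberConfig, SpeciesParams

logger = logging.getLogger(__name__)

S_PER_H = 3600.0


class ChamberError(ValueError):
    """Invalid gas time series or flux-inversion input."""


@dataclass
class GasTimeSeries:
    """One incubation's analyzer trace.

    Times are seconds since acetylene injection; the background phase (plant
    sealed, no acetylene) carries negative times.  Mole fractions: ethylene in
    ppb, CO2 in ppm, water vapor as a fraction of moist air.
    """

    time_s: np.ndarray
    ethylene_ppb: np.ndarray
    co2_ppm: np.ndarray
    h2o_frac: np.ndarray
    a0_ppm: float
    phase: np.ndarray  # per-sample: "background" | "acetylene" | "dark"
    dilution_corrected: bool = False
    background_slope_ppb_s: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ethylene_ppb = np.asarray(self.ethylene_ppb, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        self.h2o_frac = np.asarray(self.h2o_frac, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time_s.size
        for name in ("ethylene_ppb", "co2_ppm", "h2o_frac", "phase"):
            if getattr(self, name).size != n:
                raise ChamberError(f"channel {name} length != time length")
        if n and np.any(np.diff(self.time_s) <= 0):
            raise ChamberError("time must be strictly increasing")
        finite_h2o = self.h2o_frac[np.isfinite(self.h2o_frac)]
        if finite_h2o.size and (finite_h2o.min() < 0 or finite_h2o.max() > 0.1):
            raise ChamberError("h2o fraction out of the plausible [0, 0.1] range")
        if not self.a0_ppm > 0:
            raise ChamberError("a0 must be positive")
        known = {"background", "acetylene", "dark"}
        if n and not set(self.phase) <= known:
            raise ChamberError(f"unknown phase labels: {set(self.phase) - known}")

    def mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    def select(self, phase: str) -> "GasTimeSeries":
        m = self.mask(phase)
        return replace(
            self,
            time_s=self.time_s[m],
            ethylene_ppb=self.ethylene_ppb[m],
            co2_ppm=self.co2_ppm[m],
            h2o_frac=self.h2o_frac[m],
            phase=self.phase[m],
        )


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of one channel over a time window.

    Units are per second (ppb s^-1 for ethylene, ppm s^-1 for CO2); the flux
    math converts to hours.  ``intercept`` is the fitted value at the window
    midpoint, the flux-evaluation time.
    """

    slope: float
    slope_sd: float
    intercept: float
    window_start: float
    window_end: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ChamberError("slope estimate needs >= 3 points")
        if self.slope_sd < 0:
            raise ChamberError("slope SE cannot be negative")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.window_start + self.window_end)


@dataclass(frozen=True)
class FluxEstimate:
    """A flux with its parametric-bootstrap sample.

    ``point`` is the all-means evaluation (umol h^-1); ``draws`` the bootstrap
    sample; ``ci`` the 2.5/97.5 percentile interval.
    """

    point: float
    draws: np.ndarray
    ci: tuple[float, float]
    eval_time_s: float
    kind: str
    seed: int | None = None
    n_dropped: int = 0

    def scaled(self, factor: float, kind: str | None = None) -> "FluxEstimate":
        lo, hi = np.percentile(self.draws * factor, [2.5, 97.5]) if self.draws.size else (
            self.point * factor,
            self.point * factor,
        )
        return FluxEstimate(
            point=self.point * factor,
            draws=self.draws * factor,
            ci=(float(lo), float(hi)),
            eval_time_s=self.eval_time_s,
            kind=kind or self.kind,
            seed=self.seed,
            n_dropped=self.n_dropped,
        )


def _percentile_ci(draws: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# trace corrections


def correct_water_dilution(series: GasTimeSeries) -> GasTimeSeries:
    """Convert ethylene and CO2 to dry-air mole fractions, x_dry = x_wet/(1-h2o).

    Rising humidity in the sealed chamber dilutes the measured trace-gas
    signal; this undoes it.  Refuses to run twice.
    """
    if series.dilution_corrected:
        raise ChamberError("series is already dilution-corrected")
    if np.any(~np.isfinite(series.h2o_frac)):
        raise ChamberError("h2o channel has missing values")
    if np.any(series.h2o_frac >= 1.0):
        raise ChamberError("h2o fraction >= 1")
    factor = 1.0 / (1.0 - series.h2o_frac)
    return replace(
        series,
        ethylene_ppb=series.ethylene_ppb * factor,
        co2_ppm=series.co2_ppm * factor,
        dilution_corrected=True,
    )


def subtract_background(
    series: GasTimeSeries,
    *,
    min_background_s: float = 600.0,
    on_short: str = "warn",
) -> GasTimeSeries:
    """Remove the plant's native ethylene production from the acetylene phase.

    The background-phase ethylene slope (OLS, typically negligible) is
    subtracted as a linear-in-time term from acetylene-phase ethylene, taking
    t = 0 (injection) as the anchor.  The slope is kept on the returned series
    as ``background_slope_ppb_s``.
    """
    bg = series.mask("background")
    if not bg.any():
        raise ChamberError("no background phase in series")
    t_bg = series.time_s[bg]
    # inclusive span: n samples at rate dt cover n*dt seconds
    span = t_bg.max() - t_bg.min()
    if t_bg.size > 1:
        span += float(np.median(np.diff(t_bg)))
    if span < min_background_s:
        msg = f"background phase spans {span:.0f} s < {min_background_s:.0f} s"
        if on_short == "error":
            raise ChamberError(msg)
        warnings.warn(msg + "; applying zero background correction", stacklevel=2)
        return replace(series, background_slope_ppb_s=0.0)
    slope, _, _ = _ols(t_bg, series.ethylene_ppb[bg])
    ace = series.mask("acetylene")
    ethylene = series.ethylene_ppb.copy()
    ethylene[ace] = ethylene[ace] - slope * series.time_s[ace]
    return replace(series, ethylene_ppb=ethylene, background_slope_ppb_s=float(slope))


# ---------------------------------------------------------------------------
# slopes


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS of y on t: (slope, slope SE, fitted value at mean t)."""
    n = t.size
    tc = t - t.mean()
    sxx = float(tc @ tc)
    if sxx == 0.0:
        raise ChamberError("degenerate time window")
    slope = float(tc @ y) / sxx
    mean_y = float(y.mean())
    resid = y - (mean_y + slope * tc)
    if n > 2:
        sigma2 = float(resid @ resid) / (n - 2)
    else:
        sigma2 = 0.0
    se = float(np.sqrt(max(sigma2, 0.0) / sxx))
    return slope, se, mean_y


def estimate_slope(
    series: GasTimeSeries,
    channel: str,
    window_start: float | None = None,
    window_end: float | None = None,
    *,
    phase: str = "acetylene",
) -> SlopeEstimate:
    """OLS slope of a channel over a window (default: last 300 s of the phase).

    The intercept is evaluated at the window midpoint (more precisely at the
    mean sample time, which coincides for regular sampling), the time at which
    the flux equations are evaluated.
    """
    sub = series.select(phase)
    if sub.time_s.size == 0:
        raise ChamberError(f"no samples in phase {phase!r}")
    if window_end is None:
        window_end = float(sub.time_s.max())
    if window_start is None:
        window_start = window_end - 300.0
    if window_start < sub.time_s.min() - 1e-9 or window_end > sub.time_s.max() + 1e-9:
        raise ChamberError("window outside the series time range")
    m = (sub.time_s >= window_start) & (sub.time_s <= window_end)
    if m.sum() < 3:
        raise ChamberError("fewer than 3 points in slope window")
    t = sub.time_s[m]
    y = getattr(sub, _channel_attr(channel))[m]
    slope, se, y_mid = _ols(t, y)
    return SlopeEstimate(
        slope=slope,
        slope_sd=se,
        intercept=y_mid,
        window_start=float(t.min()),
        window_end=float(t.max()),
        n_points=int(m.sum()),
    )


def _channel_attr(channel: str) -> str:
    try:
        return {"ethylene": "ethylene_ppb", "co2": "co2_ppm", "h2o": "h2o_frac"}[channel]
    except KeyError:
        raise ChamberError(f"unknown channel {channel!r}") from None


def max_moving_slope(
    series: GasTimeSeries,
    channel: str = "ethylene",
    window_points: int = 480,
    *,
    equilibration_s: float = 120.0,
) -> SlopeEstimate:
    """Maximum-slope window of a moving OLS regression.

    Used when nitrogenase activity declines under acetylene exposure: a
    ``window_points``-wide regression slides over the post-equilibration
    acetylene phase and the window with the steepest slope (the maximum rate
    before the decline) is returned.
    """
    sub = series.select("acetylene")
    m = sub.time_s >= equilibration_s
    t = sub.time_s[m]
    y = getattr(sub, _channel_attr(channel))[m]
    n = t.size
    if n < window_points:
        raise ChamberError(
            f"post-equilibration phase has {n} points < window of {window_points}"
        )
    # vectorised rolling OLS via cumulative sums
    w = window_points
    ct = np.concatenate(([0.0], np.cumsum(t)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    ctt = np.concatenate(([0.0], np.cumsum(t * t)))
    cty = np.concatenate(([0.0], np.cumsum(t * y)))
    st = ct[w:] - ct[:-w]
    sy = cy[w:] - cy[:-w]
    stt = ctt[w:] - ctt[:-w]
    sty = cty[w:] - cty[:-w]
    sxx = stt - st * st / w
    sxy = sty - st * sy / w
    slopes = sxy / sxx
    best = int(np.argmax(slopes))
    t_w = t[best : best + w]
    y_w = y[best : best + w]
    slope, se, y_mid = _ols(t_w, y_w)
    return SlopeEstimate(
        slope=slope,
        slope_sd=se,
        intercept=y_mid,
        window_start=float(t_w.min()),
        window_end=float(t_w.max()),
        n_points=w,
    )


# ---------------------------------------------------------------------------
# flux inversion


def acetylene_at(a0_ppm: float, keff_per_h: float, t_s) -> np.ndarray | float:
    """Acetylene remaining at t seconds after injection: A0 * exp(-keff * t)."""
    if not a0_ppm > 0:
        raise ChamberError("a0 must be positive")
    if keff_per_h < 0:
        raise ChamberError("keff cannot be negative")
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s < 0):
        raise ChamberError("acetylene decay is defined for t >= 0 only")
    out = a0_ppm * np.exp(-keff_per_h * t_s / S_PER_H)
    return float(out) if out.ndim == 0 else out


def _vmax_formula(slope_ppm_h, e_ppm, keff, km, a0, t_h, n_mol):
    """Vmax in umol h^-1; vectorised over any broadcastable arguments."""
    leak_corrected = slope_ppm_h + keff * e_ppm
    saturation = km / (a0 * np.exp(-keff * t_h)) + 1.0
    return leak_corrected * saturation * n_mol


def vmax_point(
    slope: SlopeEstimate,
    e_t_ppb: float,
    cfg: ChamberConfig,
    sp: SpeciesParams,
    a0_ppm: float,
    t_s: float,
    keff: float | None = None,
) -> float:
    """Substrate-saturated acetylene-reduction rate (umol h^-1) at time t.

    ``keff`` overrides the configured leak rate (e.g. 0 for a sealed chamber).
    Negative results are returned as-is; whether a rate is below detection is
    decided downstream.
    """
    if not a0_ppm > 0:
        raise ChamberError("a0 must be positive")
    keff = cfg.keff_mean if keff is None else keff
    if keff < 0:
        raise ChamberError("keff cannot be negative")
    return float(
        _vmax_formula(
            slope.slope * S_PER_H / 1e3,
            e_t_ppb / 1e3,
            keff,
            sp.km,
            a0_ppm,
            t_s / S_PER_H,
            cfg.molar_content,
        )
    )


def bootstrap_vmax(
    slope: SlopeEstimate,
    series: GasTimeSeries,
    cfg: ChamberConfig,
    sp: SpeciesParams,
    n_draws: int = 10_000,
    seed: int = 0,
) -> FluxEstimate:
    """Parametric bootstrap of Vmax.

    Draws dE/dt and A0 from normals, keff and Km from gammas, and evaluates
    the inversion per draw.  The point value is the all-means evaluation; the
    CI is the 2.5/97.5 percentile of the draws.
    """
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} < 100: CI will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    t_s = slope.midpoint
    e_ppb = slope.intercept
    d_slope = rng.normal(slope.slope, slope.slope_sd, n_draws) * S_PER_H / 1e3
    d_a0 = rng.normal(series.a0_ppm, cfg.a0_rel_sd * series.a0_ppm, n_draws)
    k_shape, k_rate = cfg.keff_gamma
    d_keff = rng.gamma(k_shape, 1.0 / k_rate, n_draws)
    m_shape, m_rate = sp.km_gamma
    d_km = rng.gamma(m_shape, 1.0 / m_rate, n_draws)
    draws = _vmax_formula(
        d_slope, e_ppb / 1e3, d_keff, d_km, d_a0, t_s / S_PER_H, cfg.molar_content
    )
    finite = np.isfinite(draws) & (d_a0 > 0)
    n_dropped = int(n_draws - finite.sum())
    if n_dropped:
        logger.info("bootstrap_vmax dropped %d non-finite draws", n_dropped)
    draws = draws[finite]
    point = vmax_point(slope, e_ppb, cfg, sp, series.a0_ppm, t_s)
    return FluxEstimate(
        point=point,
        draws=draws,
        ci=_percentile_ci(draws),
        eval_time_s=t_s,
        kind="vmax",
        seed=seed,
        n_dropped=n_dropped,
    )


def npe_point(
    slope: SlopeEstimate, co2_t_ppm: float, cfg: ChamberConfig, keff: float | None = None
) -> float:
    """Net plant CO2 exchange (umol h^-1), chamber-source sign convention."""
    keff = cfg.keff_mean if keff is None else keff
    return float(
        (slope.slope * S_PER_H + keff * (co2_t_ppm - cfg.ambient_co2))
        * cfg.molar_content
    )


def bootstrap_npe(
    slope: SlopeEstimate,
    cfg: ChamberConfig,
    n_draws: int = 10_000,
    seed: int = 0,
    *,
    kind: str = "npe_light",
) -> FluxEstimate:
    """Parametric bootstrap of NPE: dCO2/dt normal, keff gamma."""
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} < 100: CI will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    co2_t = slope.intercept
    d_slope = rng.normal(slope.slope, slope.slope_sd, n_draws) * S_PER_H
    k_shape, k_rate = cfg.keff_gamma
    d_keff = rng.gamma(k_shape, 1.0 / k_rate, n_draws)
    draws = (d_slope + d_keff * (co2_t - cfg.ambient_co2)) * cfg.molar_content
    finite = np.isfinite(draws)
    n_dropped = int(n_draws - finite.sum())
    draws = draws[finite]
    return FluxEstimate(
        point=npe_point(slope, co2_t, cfg),
        draws=draws,
        ci=_percentile_ci(draws),
        eval_time_s=slope.midpoint,
        kind=kind,
        seed=seed,
        n_dropped=n_dropped,
    )


def apparent_photosynthesis(light: FluxEstimate, dark: FluxEstimate) -> FluxEstimate:
    """Light-minus-dark NPE, differenced draw-by-draw.

    Under the chamber-source convention the result is negative when the plant
    photosynthesises; report |value| as the apparent photosynthetic rate.
    """
    if light.draws.size != dark.draws.size:
        raise ChamberError("light and dark bootstrap sizes differ")
    draws = light.draws - dark.draws
    return FluxEstimate(
        point=light.point - dark.point,
        draws=draws,
        ci=_percentile_ci(draws) if draws.size else (light.point - dark.point,) * 2,
        eval_time_s=light.eval_time_s,
        kind="apparent_photosynthesis",
        seed=light.seed,
    )


def ethylene_to_snf(vmax: FluxEstimate, sp: SpeciesParams) -> FluxEstimate:
    """Convert acetylene reduction to N fixation: divide by mol-C2H4 per mol-N.

    A pure rescaling of the point value and every draw, so downstream
    regulation-rate (r) and lag (tL) estimates are unaffected.
    """
    if sp.conversion_factor is None or not sp.conversion_factor > 0:
        raise ChamberError(f"no valid conversion factor for {sp.species}")
    return vmax.scaled(1.0 / sp.conversion_factor, kind="snf")
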