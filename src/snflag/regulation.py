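"""Grouped maximum-likelihood fitting of the lagged sigmoid to SNF trajectories.

Repeated whole-plant SNF measurements (normalised by whole-symbiosis
respiration to factor out growth) are fit with
SNF(t) = K / (1 + exp(-r (t - tL))) under a Gaussian iid error model.  Each
of K, tL, r and sigma can be shared at a configurable level of organisation
(per plant, global, by symbiosis, by growing temperature, by biome, or their
two-way combinations); the canonical structure gives every plant its own K
and tL while r is shared within groups.  Competing sharing structures are
compared by finite-sample-corrected AIC (AICc), with a likelihood-ratio test
breaking near-ties (dAICc < 2) between nested candidates.  Uncertainty comes
from a parametric bootstrap: parameter vectors drawn from a multivariate
normal centred at the MLE with the inverse-Hessian covariance, pushed through
any functional of the parameters (e.g. the day of 95% upregulation).

The surface follows the statsmodels idiom: ``LaggedSigmoidModel`` is built
from a tidy DataFrame and ``fit()`` returns a ``LaggedSigmoidResults`` with
estimates, AICc, ``summary()``, ``timescales()`` and ``bootstrap_ci()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .sigmoid import LN19, TimescaleSet, sigmoid_snf

logger = logging.getLogger(__name__)

#: sharing level -> metadata columns defining the groups
LEVELS: dict[str, tuple[str, ...]] = {
    "global": (),
    "per_plant": ("plant_id",),
    "by_species": ("species",),
    "by_symbiosis": ("symbiosis",),
    "by_growth_temp": ("growth_temp",),
    "by_biome": ("biome",),
    "by_biome_x_temp": ("biome", "growth_temp"),
    "by_symbiosis_x_temp": ("symbiosis", "growth_temp"),
}

_R_MAG_BOUNDS = (1e-4, 10.0)


class RegulationError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class GroupingSpec:
    """Parameter-sharing structure for one candidate model.

    Defaults mirror the canonical structure: per-plant K and tL, one global
    r, one shared observation sigma.  ``sigma`` accepts "shared" as an alias
    for "global".
    """

    k: str = "per_plant"
    tl: str = "per_plant"
    r: str = "global"
    sigma: str = "shared"
    name: str | None = None

    def __post_init__(self) -> None:
        for fam in ("k", "tl", "r"):
            if getattr(self, fam) not in LEVELS:
                raise RegulationError(f"unknown sharing level {getattr(self, fam)!r}")
        if self.sigma_level not in LEVELS:
            raise RegulationError(f"unknown sigma level {self.sigma!r}")

    @property
    def sigma_level(self) -> str:
        return "global" if self.sigma == "shared" else self.sigma

    @property
    def label(self) -> str:
        return self.name or f"K:{self.k}|tL:{self.tl}|r:{self.r}|s:{self.sigma_level}"


def _group_index(df: pd.DataFrame, level: str) -> tuple[np.ndarray, list]:
    cols = LEVELS[level]
    if not cols:
        return np.zeros(len(df), dtype=int), ["all"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RegulationError(f"level {level!r} needs columns {missing}")
    if len(cols) == 1:
        keys = df[cols[0]].astype(str)
    else:
        keys = df[list(cols)].astype(str).agg("|".join, axis=1)
    codes, uniques = pd.factorize(keys, sort=True)
    return codes.astype(int), list(uniques)


class LaggedSigmoidModel:
    """Lagged-sigmoid regulation model for one direction of N switch.

    Parameters
    ----------
    data
        Tidy DataFrame with at least ``plant_id``, ``day``, ``snf_norm`` and
        any metadata columns the grouping needs (``species``, ``symbiosis``,
        ``biome``, ``growth_temp``).
    direction
        "up" (r constrained positive) or "down" (negative).
    grouping
        Parameter-sharing structure; defaults to per-plant K/tL, global r.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        direction: str,
        grouping: GroupingSpec | None = None,
    ):
        if direction not in ("up", "down"):
            raise RegulationError("direction must be 'up' or 'down'")
        required = {"plant_id", "day", "snf_norm"}
        if not required <= set(data.columns):
            raise RegulationError(f"data needs columns {sorted(required)}")
        data = data.reset_index(drop=True)
        if not np.all(np.isfinite(data["snf_norm"])):
            raise RegulationError("snf_norm contains non-finite values")
        if np.any(data["day"] < 0):
            raise RegulationError("days since switch must be >= 0")
        self.data = data
        self.direction = direction
        self.grouping = grouping or GroupingSpec()
        self.t = data["day"].to_numpy(dtype=float)
        self.y = data["snf_norm"].to_numpy(dtype=float)
        self.nobs = len(data)
        self.k_idx, self.k_groups = _group_index(data, self.grouping.k)
        self.tl_idx, self.tl_groups = _group_index(data, self.grouping.tl)
        self.r_idx, self.r_groups = _group_index(data, self.grouping.r)
        self.s_idx, self.s_groups = _group_index(data, self.grouping.sigma_level)
        self.n_params = (
            len(self.k_groups) + len(self.tl_groups) + len(self.r_groups) + len(self.s_groups)
        )
        counts = data.groupby([data["plant_id"].astype(str)]).size()
        min_obs = int(counts.min())
        if self.grouping.k == "per_plant" and self.grouping.tl == "per_plant" and min_obs < 4:
            raise RegulationError(
                f"need >= 4 observations per plant for per-plant (K, tL); min is {min_obs}"
            )

    # -- parameter packing ---------------------------------------------------

    @property
    def _slices(self) -> dict[str, slice]:
        nk, ntl, nr = len(self.k_groups), len(self.tl_groups), len(self.r_groups)
        return {
            "logK": slice(0, nk),
            "tL": slice(nk, nk + ntl),
            "r": slice(nk + ntl, nk + ntl + nr),
            "logsig": slice(nk + ntl + nr, self.n_params),
        }

    def _unpack(self, theta: np.ndarray):
        s = self._slices
        return (
            np.exp(theta[s["logK"]]),
            theta[s["tL"]],
            theta[s["r"]],
            np.exp(theta[s["logsig"]]),
        )

    def param_dict(self, theta: np.ndarray) -> dict[str, dict[str, float]]:
        """Natural-scale parameters keyed by family then group label."""
        K, tL, r, sig = self._unpack(np.asarray(theta, dtype=float))
        return {
            "K": dict(zip(map(str, self.k_groups), K)),
            "tL": dict(zip(map(str, self.tl_groups), tL)),
            "r": dict(zip(map(str, self.r_groups), r)),
            "sigma": dict(zip(map(str, self.s_groups), sig)),
        }

    # -- likelihood ----------------------------------------------------------

    def predict(self, theta: np.ndarray) -> np.ndarray:
        K, tL, r, _ = self._unpack(theta)
        return K[self.k_idx] * expit(r[self.r_idx] * (self.t - tL[self.tl_idx]))

    def nll(self, theta: np.ndarray) -> float:
        """Gaussian iid negative log likelihood at an internal parameter vector."""
        K, tL, r, sig = self._unpack(np.asarray(theta, dtype=float))
        yhat = K[self.k_idx] * expit(r[self.r_idx] * (self.t - tL[self.tl_idx]))
        s = sig[self.s_idx]
        z = (self.y - yhat) / s
        return float(
            np.sum(np.log(s)) + 0.5 * float(z @ z) + 0.5 * self.nobs * np.log(2.0 * np.pi)
        )

    def nll_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """NLL plus its analytic gradient on the internal scale (for L-BFGS-B)."""
        theta = np.asarray(theta, dtype=float)
        K, tL, r, sig = self._unpack(theta)
        dt = self.t - tL[self.tl_idx]
        S = expit(r[self.r_idx] * dt)
        Ko = K[self.k_idx]
        yhat = Ko * S
        s = sig[self.s_idx]
        e = self.y - yhat
        inv_s2 = 1.0 / (s * s)
        value = float(
            np.sum(np.log(s)) + 0.5 * float((e * e) @ inv_s2)
            + 0.5 * self.nobs * np.log(2.0 * np.pi)
        )
        w = -e * inv_s2  # d nll / d yhat
        KSS = Ko * S * (1.0 - S)
        g_logK = np.bincount(self.k_idx, weights=w * yhat, minlength=len(self.k_groups))
        g_tL = np.bincount(
            self.tl_idx, weights=-w * KSS * r[self.r_idx], minlength=len(self.tl_groups)
        )
        g_r = np.bincount(self.r_idx, weights=w * KSS * dt, minlength=len(self.r_groups))
        g_logsig = np.bincount(
            self.s_idx, weights=1.0 - e * e * inv_s2, minlength=len(self.s_groups)
        )
        return value, np.concatenate([g_logK, g_tL, g_r, g_logsig])

    # -- starting values -----------------------------------------------------

    def _plant_heuristics(self) -> pd.DataFrame:
        """Per-plant (K, tL, r) starting heuristics from the raw trajectories."""
        rows = []
        sign = 1.0 if self.direction == "up" else -1.0
        for pid, sub in self.data.groupby(self.data["plant_id"].astype(str)):
            t = sub["day"].to_numpy(dtype=float)
            y = sub["snf_norm"].to_numpy(dtype=float)
            order = np.argsort(t)
            t, y = t[order], y[order]
            k0 = max(float(np.max(y)), 1e-12) if self.direction == "up" else max(
                float(y[0]), float(np.max(y)) * 0.5, 1e-12
            )
            half = 0.5 * k0
            # first crossing of half-max in the direction of change
            crossing = None
            for i in range(1, t.size):
                lo, hi = sorted((y[i - 1], y[i]))
                if lo <= half <= hi and y[i] != y[i - 1]:
                    crossing = t[i - 1] + (half - y[i - 1]) * (t[i] - t[i - 1]) / (
                        y[i] - y[i - 1]
                    )
                    break
            tl0 = crossing if crossing is not None else float(np.median(t))
            lo_t = _first_cross(t, y, 0.05 * k0)
            hi_t = _first_cross(t, y, 0.95 * k0)
            span = abs(hi_t - lo_t) if (lo_t is not None and hi_t is not None) else (
                0.5 * (t.max() - t.min() + 1.0)
            )
            span = max(span, 1.0)
            r0 = sign * 2.0 * LN19 / span
            rows.append({"plant_id": pid, "k0": k0, "tl0": tl0, "r0": r0})
        return pd.DataFrame(rows).set_index("plant_id")

    def _base_start(self) -> np.ndarray:
        heur = self._plant_heuristics()
        pid = self.data["plant_id"].astype(str)

        def group_mean(groups, idx, col):
            vals = np.empty(len(groups))
            per_obs = heur.loc[pid, col].to_numpy(dtype=float)
            for g in range(len(groups)):
                vals[g] = float(np.mean(per_obs[idx == g]))
            return vals

        K0 = group_mean(self.k_groups, self.k_idx, "k0")
        tL0 = group_mean(self.tl_groups, self.tl_idx, "tl0")
        r0 = group_mean(self.r_groups, self.r_idx, "r0")
        sig0 = np.full(len(self.s_groups), max(0.1 * float(np.mean(K0)), 1e-9))
        return np.concatenate([np.log(K0), tL0, r0, np.log(sig0)])

    #: deterministic (r multiplier, tL shift as a fraction of the day span)
    _PERTURBATIONS = [
        (1.0, 0.0), (0.5, 0.0), (2.0, 0.0), (1.0, -0.15), (1.0, 0.15),
        (0.5, -0.15), (0.5, 0.15), (2.0, -0.15), (2.0, 0.15), (4.0, 0.0),
        (0.25, 0.0), (1.0, -0.3), (1.0, 0.3), (2.0, -0.3), (2.0, 0.3),
        (0.25, 0.15), (4.0, -0.15), (0.5, 0.3), (0.5, -0.3), (4.0, 0.15),
    ]

    def starting_values(self, n_starts: int = 20) -> list[np.ndarray]:
        """Deterministic multi-start list derived from data quantiles."""
        base = self._base_start()
        s = self._slices
        span = float(self.t.max() - self.t.min()) or 1.0
        starts = []
        for mult, shift in self._PERTURBATIONS[: max(1, n_starts)]:
            x = base.copy()
            x[s["r"]] = np.clip(
                x[s["r"]] * mult,
                *((_R_MAG_BOUNDS[0], _R_MAG_BOUNDS[1]) if self.direction == "up"
                  else (-_R_MAG_BOUNDS[1], -_R_MAG_BOUNDS[0])),
            )
            x[s["tL"]] = x[s["tL"]] + shift * span
            starts.append(x)
        return starts

    def _bounds(self) -> list[tuple[float, float]]:
        s = self._slices
        yscale = max(float(np.max(np.abs(self.y))), 1e-12)
        span = float(self.t.max() - self.t.min()) or 1.0
        bounds: list[tuple[float, float]] = [(None, None)] * self.n_params
        for i in range(*s["logK"].indices(self.n_params)):
            bounds[i] = (np.log(yscale) - 12.0, np.log(yscale) + 12.0)
        for i in range(*s["tL"].indices(self.n_params)):
            bounds[i] = (float(self.t.min()) - 2 * span, float(self.t.max()) + 2 * span)
        rb = (
            (_R_MAG_BOUNDS[0], _R_MAG_BOUNDS[1])
            if self.direction == "up"
            else (-_R_MAG_BOUNDS[1], -_R_MAG_BOUNDS[0])
        )
        for i in range(*s["r"].indices(self.n_params)):
            bounds[i] = rb
        for i in range(*s["logsig"].indices(self.n_params)):
            bounds[i] = (np.log(yscale) - 20.0, np.log(yscale) + 6.0)
        return bounds

    # -- fitting ---------------------------------------------------------------

    def fit(self, n_starts: int = 20, starts=None, raise_on_failure: bool = False):
        """Bounded quasi-Newton ML with deterministic multi-start.

        Returns a :class:`LaggedSigmoidResults`; its ``converged`` flag is
        False if no start converged (such fits are excluded from model
        selection).
        """
        if starts is None:
            starts = self.starting_values(n_starts)
        bounds = self._bounds()
        best = None
        any_success = False
        for x0 in starts:
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
            try:
                res = optimize.minimize(
                    self.nll_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": 500},
                )
            except (FloatingPointError, ValueError):
                continue
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            any_success = any_success or bool(res.success)
        if best is None:
            if raise_on_failure:
                raise ConvergenceError(f"no start produced a finite fit: {self.grouping.label}")
            theta = self._base_start()
            return LaggedSigmoidResults(self, theta, self.nll(theta), converged=False)
        if not any_success:
            # a line search can terminate abnormally at the optimum (e.g. a
            # near-degenerate sigma on noiseless data); accept the point as
            # converged if a restart cannot improve it
            retry = optimize.minimize(
                self.nll_and_grad, best.x, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200},
            )
            improvement = best.fun - retry.fun
            if retry.fun <= best.fun:
                best = retry
            any_success = bool(retry.success) or improvement < 1e-6 * (1.0 + abs(best.fun))
        if not any_success:
            logger.warning("fit did not converge for %s", self.grouping.label)
        return LaggedSigmoidResults(self, best.x, float(best.fun), converged=any_success)

    @classmethod
    def from_tables(
        cls,
        measurements: pd.DataFrame,
        meta: pd.DataFrame,
        direction: str,
        grouping: GroupingSpec | None = None,
    ) -> "LaggedSigmoidModel":
        """Build from a measurement table plus a per-plant metadata table."""
        merged = measurements.merge(meta, on="plant_id", how="left", validate="m:1")
        return cls(merged, direction=direction, grouping=grouping)


def _first_cross(t: np.ndarray, y: np.ndarray, level: float):
    for i in range(1, t.size):
        lo, hi = sorted((y[i - 1], y[i]))
        if lo <= level <= hi and y[i] != y[i - 1]:
            return t[i - 1] + (level - y[i - 1]) * (t[i] - t[i - 1]) / (y[i] - y[i - 1])
    return None


def aicc(nll: float, k: int, n: int) -> float:
    """Finite-sample-corrected AIC: 2 nll + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise RegulationError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class BootstrapCI:
    point: float
    ci: tuple[float, float]
    draws: np.ndarray


class LaggedSigmoidResults:
    """MLE results of one grouping structure.

    Carries the internal parameter vector (log K, tL, r, log sigma), the NLL,
    AICc, a finite-difference covariance approximation for the parametric
    bootstrap, and derived timescales.
    """

    def __init__(self, model: LaggedSigmoidModel, theta: np.ndarray, nll: float, converged: bool):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.nll = float(nll)
        self.converged = bool(converged)

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def aicc(self) -> float:
        return aicc(self.nll, self.n_params, self.nobs)

    @property
    def params(self) -> dict[str, dict[str, float]]:
        return self.model.param_dict(self.theta)

    @cached_property
    def cov_params(self) -> np.ndarray:
        """Inverse observed-information covariance on the internal scale."""
        H = _numerical_hessian(self.model.nll, self.theta)
        try:
            np.linalg.cholesky(H)
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn(
                "Hessian not positive definite; falling back to independent "
                "normals from the diagonal",
                stacklevel=2,
            )
            diag = np.abs(np.diag(H))
            diag[diag < 1e-300] = 1e-300
            cov = np.diag(1.0 / diag)
        return cov

    def bse(self) -> np.ndarray:
        return np.sqrt(np.abs(np.diag(self.cov_params)))

    # -- derived quantities ----------------------------------------------------

    def plant_params(self) -> pd.DataFrame:
        """Per-plant (K, r, tL) resolved through the sharing structure."""
        m = self.model
        K, tL, r, _ = m._unpack(self.theta)
        rows = []
        seen = set()
        for i in range(m.nobs):
            pid = str(m.data["plant_id"].iloc[i])
            if pid in seen:
                continue
            seen.add(pid)
            row = {"plant_id": pid, "K": K[m.k_idx[i]], "tL": tL[m.tl_idx[i]], "r": r[m.r_idx[i]]}
            for col in ("species", "symbiosis", "biome", "growth_temp"):
                if col in m.data.columns:
                    row[col] = m.data[col].iloc[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def timescales(self, per: str = "plant") -> pd.DataFrame:
        """Regulation timescales (days): t05, t95 and the 5-to-95 transition.

        ``per="plant"`` resolves every plant's (K, r, tL); ``per="r_group"``
        reports one row per r-sharing group using the group's mean tL and K.
        """
        direction = self.model.direction
        if per == "plant":
            pp = self.plant_params()
            rows = []
            for _, row in pp.iterrows():
                ts = TimescaleSet.from_params(row["K"], row["r"], row["tL"], direction, row["plant_id"])
                rows.append({"label": ts.label, "t05": ts.t05, "t95": ts.t95,
                             "t05_to_95": ts.t05_to_95, "r": ts.r, "tL": ts.tL, "K": ts.K})
            return pd.DataFrame(rows)
        if per == "r_group":
            m = self.model
            K, tL, r, _ = m._unpack(self.theta)
            rows = []
            for g, label in enumerate(m.r_groups):
                in_g = m.r_idx == g
                ts = TimescaleSet.from_params(
                    float(np.mean(K[m.k_idx[in_g]])), float(r[g]),
                    float(np.mean(tL[m.tl_idx[in_g]])), direction, str(label),
                )
                rows.append({"label": ts.label, "t05": ts.t05, "t95": ts.t95,
                             "t05_to_95": ts.t05_to_95, "r": ts.r, "tL": ts.tL, "K": ts.K})
            return pd.DataFrame(rows)
        raise RegulationError("per must be 'plant' or 'r_group'")

    def bootstrap_ci(self, functional, n_draws: int = 10_000, seed: int = 0) -> BootstrapCI:
        """Parametric-bootstrap 95% CI of any functional of the parameters.

        Parameter vectors are drawn from a multivariate normal centred at the
        MLE (covariance from the inverse Hessian), transformed to the natural
        scale, and pushed through ``functional(params_dict) -> float``.
        """
        if not self.converged:
            raise ConvergenceError("bootstrap on a non-converged fit")
        rng = np.random.default_rng(seed)
        cov = self.cov_params
        try:
            draws_theta = rng.multivariate_normal(self.theta, cov, size=n_draws,
                                                  method="cholesky")
        except np.linalg.LinAlgError:
            warnings.warn("covariance not PD; drawing independent normals", stacklevel=2)
            draws_theta = rng.normal(self.theta, np.sqrt(np.abs(np.diag(cov))),
                                     size=(n_draws, self.theta.size))
        vals = np.empty(n_draws)
        for i in range(n_draws):
            vals[i] = functional(self.model.param_dict(draws_theta[i]))
        vals = vals[np.isfinite(vals)]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return BootstrapCI(point=float(functional(self.params)), ci=(float(lo), float(hi)),
                           draws=vals)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Lagged sigmoid regulation fit",
            "=" * 64,
            f"direction: {m.direction}    grouping: {m.grouping.label}",
            f"n_obs: {self.nobs}    n_params: {self.n_params}    converged: {self.converged}",
            f"NLL: {self.nll:.4f}    AICc: {self.aicc:.4f}",
            "-" * 64,
            f"{'param':<28}{'estimate':>12}{'approx SE':>12}",
        ]
        bse = self.bse()
        s = m._slices
        K, tL, r, sig = m._unpack(self.theta)
        fams = [
            ("K", m.k_groups, K, s["logK"], True),
            ("tL", m.tl_groups, tL, s["tL"], False),
            ("r", m.r_groups, r, s["r"], False),
            ("sigma", m.s_groups, sig, s["logsig"], True),
        ]
        for fam, groups, vals, sl, logscale in fams:
            ses = bse[sl]
            for name, v, se in zip(groups, vals, ses):
                se_nat = se * abs(v) if logscale else se  # delta method for log params
                lines.append(f"{fam + '[' + str(name) + ']':<28}{v:>12.5g}{se_nat:>12.3g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curves, one colour per r-group (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        pp = self.plant_params()
        tgrid = np.linspace(m.t.min(), m.t.max(), 200)
        for _, row in pp.iterrows():
            sub = m.data[m.data["plant_id"].astype(str) == row["plant_id"]]
            ax.plot(sub["day"], sub["snf_norm"], "o", ms=3, alpha=0.5)
            ax.plot(tgrid, sigmoid_snf(tgrid, row["K"], row["r"], row["tL"]), lw=0.8)
        ax.set_xlabel("days since N switch")
        ax.set_ylabel("SNF / whole-symbiosis respiration")
        return ax


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# model selection


def is_nested(simple: LaggedSigmoidResults, complex_: LaggedSigmoidResults) -> bool:
    """True if the simpler model's sharing partitions coarsen the complex one's.

    For every parameter family, each group of the complex model must fall
    entirely inside one group of the simple model (so fixing parameters equal
    across the complex model's groups reproduces the simple model).
    """
    pairs = [
        (simple.model.k_idx, complex_.model.k_idx),
        (simple.model.tl_idx, complex_.model.tl_idx),
        (simple.model.r_idx, complex_.model.r_idx),
        (simple.model.s_idx, complex_.model.s_idx),
    ]
    for idx_s, idx_c in pairs:
        mapping: dict[int, int] = {}
        for c, s in zip(idx_c, idx_s):
            if mapping.setdefault(int(c), int(s)) != int(s):
                return False
    return simple.n_params <= complex_.n_params


def lrt(nested: LaggedSigmoidResults, full: LaggedSigmoidResults) -> float:
    """Likelihood-ratio p-value: chi2(2*(nll_nested - nll_full), df = dk)."""
    if not is_nested(nested, full):
        raise RegulationError("LRT requires a nested pair")
    df = full.n_params - nested.n_params
    if df < 1:
        raise RegulationError("LRT needs df >= 1")
    deviance = 2.0 * (nested.nll - full.nll)
    if deviance < -1e-6 * max(1.0, abs(full.nll)):
        raise RegulationError(
            f"negative deviance {deviance:.3g}: the full model fits worse; "
            "optimisation likely failed"
        )
    return float(stats.chi2.sf(max(deviance, 0.0), df))


@dataclass
class SelectionResult:
    best: LaggedSigmoidResults
    table: pd.DataFrame
    lrt_p: float | None = None
    dropped: list[str] = field(default_factory=list)


def model_selection(fits: list[LaggedSigmoidResults], alpha: float = 0.05) -> SelectionResult:
    """Pick the best sharing structure by AICc, with an LRT near-tie rule.

    Candidates are ranked by AICc (non-converged fits dropped with a logged
    reason).  If the top two differ by dAICc < 2 and are nested, the more
    complex one is retained only if the likelihood-ratio test rejects at
    ``alpha``; ties break toward fewer parameters.
    """
    if not fits:
        raise RegulationError("no candidate fits")
    data_id = id(fits[0].model.data) if len(fits) else None
    for f in fits[1:]:
        if f.nobs != fits[0].nobs:
            raise RegulationError("candidates were fit on different data")
    dropped = [f.model.grouping.label for f in fits if not f.converged]
    for lbl in dropped:
        logger.warning("model_selection: dropping non-converged fit %s", lbl)
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ConvergenceError("all candidate fits failed to converge")
    rows = []
    for f in fits:
        rows.append({"model": f.model.grouping.label, "n_params": f.n_params,
                     "nll": f.nll, "aicc": f.aicc})
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["daicc"] = table["aicc"] - table["aicc"].iloc[0]
    ranked = sorted(fits, key=lambda f: f.aicc)
    best = ranked[0]
    lrt_p = None
    if len(ranked) > 1 and ranked[1].aicc - ranked[0].aicc < 2.0:
        a, b = ranked[0], ranked[1]
        simple, complex_ = (a, b) if a.n_params <= b.n_params else (b, a)
        if is_nested(simple, complex_):
            lrt_p = lrt(simple, complex_)
            best = complex_ if lrt_p < alpha else simple
    return SelectionResult(best=best, table=table, lrt_p=lrt_p, dropped=dropped)


# ---------------------------------------------------------------------------
# cohort utilities


def fit_model(
    data: pd.DataFrame,
    meta: pd.DataFrame | None,
    spec: GroupingSpec,
    direction: str,
    n_starts: int = 20,
) -> LaggedSigmoidResults:
    """Convenience wrapper: build the model (merging metadata) and fit."""
    if meta is not None:
        model = LaggedSigmoidModel.from_tables(data, meta, direction, spec)
    else:
        model = LaggedSigmoidModel(data, direction, spec)
    return model.fit(n_starts=n_starts)


def summarize_cohort(values) -> dict[str, float]:
    """Median, SD (n-1), CV = SD/mean and range of a cohort of timescales."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise RegulationError("need >= 2 finite values for SD/CV")
    sd = float(np.std(v, ddof=1))
    return {
        "median": float(np.median(v)),
        "sd": sd,
        "cv": sd / float(np.mean(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }


def exclude_nonfixing(
    data: pd.DataFrame, threshold: float, value_col: str = "snf_norm"
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop plants whose maximum observed SNF never reaches ``threshold``.

    Mirrors the pre-analysis removal of plants that failed to upregulate;
    every exclusion is returned in a machine-readable log.
    """
    log: list[dict] = []
    keep_ids = []
    for pid, sub in data.groupby(data["plant_id"].astype(str)):
        peak = float(sub[value_col].max())
        if peak < threshold:
            log.append({"plant_id": pid, "reason": "max_snf_below_threshold",
                        "max_snf_norm": peak, "threshold": threshold})
        else:
            keep_ids.append(pid)
    kept = data[data["plant_id"].astype(str).isin(keep_ids)].reset_index(drop=True)
    return kept, log
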