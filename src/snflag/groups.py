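"""Cross-plant inference on extracted half-regulation times (tL).

Per-plant tL estimates (from the per-plant-tL fit family) are compared across
the experimental factors — symbiotic association, growing temperature, biome
of origin and their two-way interactions — with ordinary ANOVA linear models
ranked by AICc, and regressed on continuous covariates (plant size proxied by
day-0 whole-symbiosis respiration, or maximum SNF).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .regulation import RegulationError, aicc

DEFAULT_FORMULAS = (
    "tl ~ 1",
    "tl ~ symbiosis",
    "tl ~ growth_temp",
    "tl ~ biome",
    "tl ~ species",
    "tl ~ symbiosis * growth_temp",
    "tl ~ biome * growth_temp",
)


def _usable_formula(df: pd.DataFrame, formula: str) -> bool:
    rhs = formula.split("~", 1)[1]
    factors = [tok.strip() for tok in rhs.replace("*", "+").replace(":", "+").split("+")]
    for f in factors:
        if f in ("1", ""):
            continue
        if f not in df.columns:
            return False
        if df[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has one level; dropping formula {formula!r}",
                          stacklevel=3)
            return False
    return True


def anova_tl(records: pd.DataFrame, formulas=DEFAULT_FORMULAS) -> dict:
    """Fit tL-on-factors linear models, rank by AICc, report F-tests.

    Parameters
    ----------
    records
        One row per retained plant with columns ``tl`` plus any factors the
        formulas reference.

    Returns
    -------
    dict with ``ranking`` (DataFrame: formula, n_params, nll, aicc, daicc),
    ``best`` (formula string), ``anova`` (per-formula type-II ANOVA tables),
    and ``fits`` (the statsmodels results).
    """
    if "tl" not in records.columns:
        raise RegulationError("records need a 'tl' column")
    n = len(records)
    usable = [f for f in formulas if _usable_formula(records, f)]
    if not usable:
        raise RegulationError("no usable formulas for these records")
    rows, anovas, fits = [], {}, {}
    for formula in usable:
        res = smf.ols(formula, data=records).fit()
        k = int(res.df_model) + 2  # coefficients + intercept + sigma
        nll = -float(res.llf)
        rows.append({"formula": formula, "n_params": k, "nll": nll,
                     "aicc": aicc(nll, k, n)})
        fits[formula] = res
        if res.df_model > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                anovas[formula] = anova_lm(res, typ=2)
    ranking = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    ranking["daicc"] = ranking["aicc"] - ranking["aicc"].iloc[0]
    return {"ranking": ranking, "best": ranking["formula"].iloc[0],
            "anova": anovas, "fits": fits}


def covariate_test(records: pd.DataFrame, covariate: str) -> dict:
    """Simple linear regression of tL on one covariate.

    Reports the slope (days per covariate unit), its SE and p-value, and the
    implied tL change across the observed covariate range.
    """
    if len(records) < 3:
        raise RegulationError("need >= 3 records for a covariate test")
    x = records[covariate].to_numpy(dtype=float)
    y = records["tl"].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise RegulationError(f"covariate {covariate!r} has non-finite values")
    if np.ptp(x) == 0:
        raise RegulationError(f"covariate {covariate!r} is constant: slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    return {
        "slope": slope,
        "se": float(res.bse[1]),
        "p": float(res.pvalues[1]),
        "effect_across_range": slope * float(np.ptp(x)),
        "n": len(records),
        "r_squared": float(res.rsquared),
    }
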