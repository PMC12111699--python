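"""Hematology–trait association scan.

Each of the 15 CBC parameters is tested, one at a time, for association with
ADG, ADFI and G:F in a linear mixed model with breed and pen as fixed
effects, sire as a random effect, and age plus the parameter as covariates.
The scan reports the parameter's coefficient (trait units per parameter
unit), its SE, a Wald p-value, the model R² and the increment over a
baseline model containing only breed, pen, age and sire.

Also houses the growth-curve trait derivation: ADG from serial body weights
via a quadratic regression of weight on day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixedmodel import build_design, fit_reml, model_r2, wald_p
from .synthetic_data import CBC_PARAMS

__all__ = ["TRAITS", "baseline_r2", "scan", "adg_from_weights", "derive_traits"]

TRAITS = ["ADG", "ADFI", "GF"]
SIGNIFICANCE_THRESHOLD = 0.1  # flag associations with nominal p below this


def baseline_r2(trait: np.ndarray, meta: pd.DataFrame) -> float:
    """Model R² of the baseline design: breed + pen fixed, age, sire random."""
    d = build_design(meta)
    fit = fit_reml(np.asarray(trait, float), d)
    return model_r2(fit, trait)


def scan(
    traits: pd.DataFrame,
    cbc: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(trait, parameter) mixed-model association scan, 45 rows.

    Output is trait-major, CBC parameters in instrument panel order; columns:
    trait, parameter, reg, se, r2, delta_r2, p, significant.
    """
    missing = [p for p in CBC_PARAMS if p not in cbc.columns]
    if missing:
        raise ValueError(f"CBC panel is missing parameters: {missing}")
    for df_ in (traits, cbc):
        if not np.array_equal(
            df_["animal_id"].to_numpy(), meta["animal_id"].to_numpy()
        ):
            raise ValueError("inputs must cover the same animals in order")
    if "GF" in traits.columns and {"ADG", "ADFI"} <= set(traits.columns):
        ratio = traits["ADG"].to_numpy() / traits["ADFI"].to_numpy()
        if np.max(np.abs(ratio - traits["GF"].to_numpy())) > 1e-10:
            raise ValueError("GF column inconsistent with ADG/ADFI")

    baselines = {
        t: baseline_r2(traits[t].to_numpy(float), meta) for t in TRAITS
    }
    rows = []
    for t in TRAITS:
        y = traits[t].to_numpy(float)
        for p in CBC_PARAMS:
            d = build_design(meta, covariates={p: cbc[p].to_numpy(float)})
            fit = fit_reml(y, d)
            if p in d.x_names:
                reg = fit.coef(p)
                se = fit.se(p)
                pval = wald_p(fit, p)
            else:  # parameter aliased with the baseline design
                reg, se, pval = np.nan, np.nan, np.nan
            r2 = model_r2(fit, y)
            rows.append(
                {
                    "trait": t,
                    "parameter": p,
                    "reg": reg,
                    "se": se,
                    "r2": r2,
                    "delta_r2": r2 - baselines[t],
                    "p": pval,
                    "significant": bool(pval < SIGNIFICANCE_THRESHOLD)
                    if np.isfinite(pval)
                    else False,
                }
            )
    return pd.DataFrame(rows)


def adg_from_weights(
    weights: pd.DataFrame,
    days: tuple[int, int] = (0, 84),
    use_fitted_initial: bool = True,
) -> pd.Series:
    """ADG per animal from a quadratic regression of body weight on day.

    Fits BW = a + b·day + c·day² per animal by OLS; total gain is the fitted
    curve solved at the trial end minus its value at the start (or minus the
    raw day-0 weight when ``use_fitted_initial`` is False), divided by the
    trial length.  Expects long format: animal_id, day, weight_kg.
    """
    d0, d1 = days
    span = d1 - d0
    out = {}
    for animal, grp in weights.groupby("animal_id", sort=True):
        x = grp["day"].to_numpy(float)
        y = grp["weight_kg"].to_numpy(float)
        if len(np.unique(x)) < 3:
            raise ValueError(
                f"animal {animal}: need >= 3 distinct days for a quadratic fit"
            )
        c2, c1, c0 = np.polyfit(x, y, 2)
        f = lambda d: c0 + c1 * d + c2 * d * d
        start = f(d0) if use_fitted_initial else float(y[np.argmin(x)])
        out[animal] = (f(d1) - start) / span
    return pd.Series(out, name="ADG")


def derive_traits(
    weights: pd.DataFrame, adfi: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Assemble the trait table from weights + intake: ADG, ADFI, GF."""
    adg = adg_from_weights(weights)
    if isinstance(adfi, pd.DataFrame):
        adfi = adfi.set_index("animal_id")["ADFI"]
    adfi = adfi.reindex(adg.index)
    if (adfi <= 0).any():
        raise ValueError("ADFI must be positive")
    return pd.DataFrame(
        {
            "animal_id": adg.index,
            "ADG": adg.to_numpy(),
            "ADFI": adfi.to_numpy(),
            "GF": adg.to_numpy() / adfi.to_numpy(),
        }
    ).reset_index(drop=True)
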