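"""Dose-response fitting and single-concentration drug-screen analytics.

Three hyperbolic binding-equation forms (Hill coefficient fixed at 1) describe
how a contractility parameter y responds to compound concentration x (uM):

    increase:        y = y0 + Bm * x / (EC50 + x)
    decrease:        y = y0 - Bm * x / (EC50 + x)
    full_inhibition: y = y0 - y0 * x / (EC50 + x)   (= y0 * EC50 / (EC50 + x))

Fits are weighted nonlinear least squares on dose-level means (weights
1/SE^2), matching the practice of fitting the mean +/- SE points of a
dose-response plot. Screens report the fractional change
100 * (treated mean / baseline mean) - 100 per parameter, with
non-contractile (zero-shortening) cells included in the % shortening average
but excluded from the kinetic (TTP90/TTB90) averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr, t as t_dist

from .hstats import NestedDataset, fit_two_level

EQUATION_FORMS = ("increase", "decrease", "full_inhibition")


def binding_curve(form: str, x, y0: float, bm: float | None, ec50: float):
    """Evaluate one of the three binding-equation forms at doses ``x`` (uM)."""
    x = np.asarray(x, dtype=float)
    occ = x / (ec50 + x)
    if form == "increase":
        return y0 + bm * occ
    if form == "decrease":
        return y0 - bm * occ
    if form == "full_inhibition":
        return y0 * (1.0 - occ)
    raise ValueError(f"unknown equation form {form!r}")


@dataclass
class DoseResponseFit:
    """Fitted binding-equation parameters with Jacobian-based errors."""

    equation_form: str
    y0: float
    ec50_um: float
    bm: float | None = None
    y0_se: float = np.nan
    bm_se: float = np.nan
    ec50_se: float = np.nan
    r2: float = np.nan
    n_points: int = 0
    unfittable: bool = False

    @property
    def max_pct_change(self) -> float:
        """Maximal fractional effect, 100*Bm/y0 (100 for full inhibition)."""
        if self.equation_form == "full_inhibition":
            return 100.0
        return 100.0 * self.bm / self.y0

    def predict(self, x):
        bm = self.y0 if self.equation_form == "full_inhibition" else self.bm
        return binding_curve(self.equation_form, x, self.y0, bm, self.ec50_um)


def fit_dose_response(
    doses_um,
    responses,
    form: str,
    weighted: bool = True,
) -> DoseResponseFit:
    """Fit a binding equation to per-cell responses grouped by dose.

    ``doses_um`` and ``responses`` are per-cell vectors; dose-level means and
    standard errors are computed internally and the curve is fitted to the
    means, inverse-variance weighted by default. Parameters are constrained
    positive. A fit whose EC50 exceeds 10x the top tested dose is flagged
    ``unfittable`` rather than reported as a genuine potency estimate.
    """
    if form not in EQUATION_FORMS:
        raise ValueError(f"unknown equation form {form!r}")
    doses_um = np.asarray(doses_um, dtype=float)
    responses = np.asarray(responses, dtype=float)
    ok = np.isfinite(responses)
    doses_um, responses = doses_um[ok], responses[ok]
    levels = np.unique(doses_um)
    if levels.size < 4:
        raise ValueError("fit_dose_response requires >= 4 distinct doses")
    means = np.array([responses[doses_um == d].mean() for d in levels])
    sds = np.array([responses[doses_um == d].std(ddof=1)
                    if (doses_um == d).sum() > 1 else 0.0 for d in levels])
    ns = np.array([(doses_um == d).sum() for d in levels])
    ses = sds / np.sqrt(ns)

    _check_monotone(levels, means, ses, form)

    sigma = None
    if weighted:
        floor = np.max(ses) * 1e-3 if np.any(ses > 0) else 1.0
        sigma = np.maximum(ses, max(floor, 1e-12))
        if not np.any(ses > 0):
            sigma = None                      # noiseless data: unweighted

    span = float(np.abs(means.max() - means.min()))
    y0_guess = max(float(means[np.argmin(levels)]), 1e-9)
    pos = levels[levels > 0]
    ec50_guess = float(np.median(pos))

    if form == "full_inhibition":
        def model(x, y0, ec50):
            return binding_curve(form, x, y0, None, ec50)
        p0 = [y0_guess, ec50_guess]
    else:
        def model(x, y0, bm, ec50):
            return binding_curve(form, x, y0, bm, ec50)
        p0 = [y0_guess, max(span, 1e-9), ec50_guess]

    popt, pcov = curve_fit(
        model, levels, means, p0=p0, sigma=sigma, absolute_sigma=False,
        bounds=(np.zeros(len(p0)) + 1e-12, np.inf), maxfev=20000,
    )
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    pred = model(levels, *popt)
    ss_res = float(np.sum((means - pred) ** 2))
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if form == "full_inhibition":
        fit = DoseResponseFit(
            equation_form=form, y0=float(popt[0]), ec50_um=float(popt[1]),
            y0_se=float(perr[0]), ec50_se=float(perr[1]),
            r2=r2, n_points=int(levels.size),
        )
    else:
        fit = DoseResponseFit(
            equation_form=form, y0=float(popt[0]), bm=float(popt[1]),
            ec50_um=float(popt[2]), y0_se=float(perr[0]), bm_se=float(perr[1]),
            ec50_se=float(perr[2]), r2=r2, n_points=int(levels.size),
        )
    if fit.ec50_um > 10.0 * float(levels.max()):
        fit.unfittable = True
        warnings.warn(
            "EC50 exceeds 10x the top tested dose: saturation not reached, "
            "fit flagged unfittable", stacklevel=2,
        )
    return fit


def _check_monotone(levels, means, ses, form):
    """Warn when the dose trend contradicts the requested form beyond noise."""
    pos = levels > 0
    if pos.sum() < 3:
        return
    rho, _ = spearmanr(levels[pos], means[pos])
    expected = 1.0 if form == "increase" else -1.0
    drift = float(np.abs(means.max() - means.min()))
    noise = float(np.nanmax(ses)) if np.any(ses > 0) else 0.0
    if np.isfinite(rho) and rho * expected < 0 and drift > 3.0 * noise:
        warnings.warn(
            "dose-level means trend against the requested equation form",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# single-concentration screens
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Fractional changes for one compound vs its baseline arm."""

    compound: str
    frac_change_pct_shortening: float
    frac_change_ttp90: float
    frac_change_ttb90: float
    n_baseline: int
    n_treated: int
    n_excluded_baseline: int      # non-contractile, excluded from kinetics
    n_excluded_treated: int


def _mean_with_zeros(frame: pd.DataFrame) -> float:
    """Mean % shortening including non-contractile cells as exact zeros."""
    vals = frame["pct_shortening"].to_numpy(dtype=float)
    vals = np.where(frame["contractile"].to_numpy(dtype=bool), vals, 0.0)
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else np.nan


def _kinetic_mean(frame: pd.DataFrame, col: str) -> float:
    """Mean of a rate parameter over contractile cells only."""
    sub = frame.loc[frame["contractile"].astype(bool), col].to_numpy(dtype=float)
    sub = sub[np.isfinite(sub)]
    return float(np.mean(sub)) if sub.size else np.nan


def fractional_change(treated_mean: float, baseline_mean: float) -> float:
    """y = 100 * (mean with compound / mean baseline) - 100."""
    if not np.isfinite(baseline_mean) or baseline_mean == 0:
        return np.nan
    if not np.isfinite(treated_mean):
        return np.nan
    return 100.0 * (treated_mean / baseline_mean) - 100.0


def screen_compound(
    baseline: pd.DataFrame,
    treated: pd.DataFrame,
    compound: str = "",
) -> ScreenResult:
    """Fractional-change summary for one compound at a single concentration.

    Inputs are per-cell parameter tables from
    :func:`myoscreen.transients.analyze_record`. Zero-shortening cells are
    included in the % shortening averages (avoiding selection bias toward
    contracting cells) but excluded from TTP90/TTB90 averages, since rate
    processes are undefined without contraction. With no contractile cells
    in an arm the kinetic fractional changes are reported missing.
    """
    base_pct = _mean_with_zeros(baseline)
    trt_pct = _mean_with_zeros(treated)
    res = ScreenResult(
        compound=compound,
        frac_change_pct_shortening=fractional_change(trt_pct, base_pct),
        frac_change_ttp90=fractional_change(
            _kinetic_mean(treated, "ttp90_s"), _kinetic_mean(baseline, "ttp90_s")),
        frac_change_ttb90=fractional_change(
            _kinetic_mean(treated, "ttb90_s"), _kinetic_mean(baseline, "ttb90_s")),
        n_baseline=len(baseline),
        n_treated=len(treated),
        n_excluded_baseline=int((~baseline["contractile"].astype(bool)).sum()),
        n_excluded_treated=int((~treated["contractile"].astype(bool)).sum()),
    )
    return res


def aggregate_screens(
    replicates: list[tuple[pd.DataFrame, pd.DataFrame]],
    compound: str = "",
    parameter: str = "pct_shortening",
    alpha: float = 0.05,
) -> dict:
    """Hierarchical summary of replicate screens of one compound.

    ``replicates`` holds (baseline, treated) per-cell tables, one pair per
    preparation. Each treated cell's value is expressed as a fractional
    change relative to its own preparation's baseline mean, the per-cell
    fractional data are pooled as a nested dataset (preparation = cluster)
    and summarised both ways. The significance call (fractional change != 0)
    is made with the simple one-sample t-test and with the cluster-corrected
    t, and a flag marks compounds whose call flips between the two.
    """
    if len(replicates) < 1:
        raise ValueError("aggregate_screens requires >= 1 replicate")
    values, clusters = [], []
    for i, (base, treat) in enumerate(replicates):
        if parameter == "pct_shortening":
            base_mean = _mean_with_zeros(base)
            cell_vals = np.where(
                treat["contractile"].to_numpy(dtype=bool),
                treat["pct_shortening"].to_numpy(dtype=float), 0.0)
        else:
            base_mean = _kinetic_mean(base, parameter)
            cell_vals = treat.loc[
                treat["contractile"].astype(bool), parameter
            ].to_numpy(dtype=float)
        if not np.isfinite(base_mean) or base_mean == 0:
            continue
        frac = 100.0 * cell_vals / base_mean - 100.0
        frac = frac[np.isfinite(frac)]
        values.append(frac)
        clusters.append(np.full(frac.size, i))
    if not values:
        raise ValueError("no usable replicate data for aggregation")
    values = np.concatenate(values)
    clusters = np.concatenate(clusters)

    simple_mean = float(np.mean(values))
    simple_se = float(np.std(values, ddof=1) / np.sqrt(values.size))
    out = {
        "compound": compound,
        "parameter": parameter,
        "n_replicates": len(replicates),
        "n_cells": int(values.size),
        "simple_mean": simple_mean,
        "simple_se": simple_se,
    }
    tstat = simple_mean / simple_se if simple_se > 0 else 0.0
    simple_p = float(2.0 * t_dist.sf(abs(tstat), values.size - 1))
    out["simple_p"] = simple_p

    if len(np.unique(clusters)) < 2:
        warnings.warn("single replicate: simple statistics only", stacklevel=2)
        out.update(hierarchical_mean=np.nan, hierarchical_se=np.nan,
                   hierarchical_p=np.nan, icc=np.nan, significance_flip=False)
        return out

    fit = fit_two_level(NestedDataset(values=values, cluster_ids=clusters,
                                      condition=compound))
    ht = fit.grand_mean / fit.se if fit.se > 0 else 0.0
    hier_p = float(2.0 * t_dist.sf(abs(ht), fit.eff_df))
    out.update(
        hierarchical_mean=fit.grand_mean,
        hierarchical_se=fit.se,
        hierarchical_p=hier_p,
        icc=fit.icc,
        eff_df=fit.eff_df,
        significance_flip=bool((simple_p < alpha) != (hier_p < alpha)),
    )
    return out
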