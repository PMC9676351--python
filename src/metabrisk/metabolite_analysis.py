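"""Metabolite quantification and stage-association testing.

Named metabolites are quantified as trapezoidal integrals of the spectrum
over their chemical-shift windows.  Each metabolite is then tested for
association with disease stage (relapse-free early vs metastatic) in its
own logistic model adjusted for serum acquisition time, with
Benjamini-Hochberg control of the false-discovery rate across the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConfigurationError, InputError
from .regions import MetaboliteSpec
from .spectral_processing import Spectrum, integrate_interval


@dataclass(frozen=True)
class MetaboliteProfile:
    """Integrated-area concentrations of one sample, arbitrary units."""

    sample_id: str
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, v in self.concentrations.items():
            if not np.isfinite(v):
                raise InputError(f"non-finite concentration for {name}")


@dataclass(frozen=True)
class AssociationResult:
    """Per-metabolite logistic-regression result (metastatic = 1).

    ``beta`` is the log odds of metastatic disease per standard deviation
    of the (standardized) concentration, adjusted for acquisition time.
    """

    metabolite: str
    beta: float
    se: float
    wald_p: float
    p_adjusted: float
    significant: bool
    direction: str  # up_in_aBC | down_in_aBC | none
    converged: bool = True


def quantify_metabolites(
    spectrum: Spectrum, region_table: Sequence[MetaboliteSpec]
) -> MetaboliteProfile:
    """Sum of trapezoidal region integrals per metabolite."""
    conc = {}
    for m in region_table:
        total = 0.0
        for lo, hi in m.ppm_regions:
            if lo < spectrum.ascending().ppm[0] or hi > spectrum.ascending().ppm[-1]:
                raise ConfigurationError(
                    f"{m.name}: region ({lo}, {hi}) outside the spectral range"
                )
            total += integrate_interval(spectrum, lo, hi)
        conc[m.name] = total
    return MetaboliteProfile(spectrum.sample_id, conc)


def quantify_cohort(
    spectra: Sequence[Spectrum], region_table: Sequence[MetaboliteSpec]
) -> pd.DataFrame:
    """Samples x metabolites concentration table."""
    profiles = [quantify_metabolites(s, region_table) for s in spectra]
    return pd.DataFrame(
        [p.concentrations for p in profiles], index=[p.sample_id for p in profiles]
    )


def bh_adjust(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, significant mask at ``alpha``); adjusted
    values are capped at 1 and monotone in the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def metabolite_association(
    profiles: pd.DataFrame,
    stage_labels: pd.Series,
    acquisition_dates: pd.Series,
    alpha: float = 0.05,
    standardize: bool = True,
    positive_label: str = "aBC",
    negative_label: str = "eBC_FFDR",
) -> list[AssociationResult]:
    """One adjusted logistic model per metabolite, BH-corrected.

    Only samples labelled ``negative_label`` or ``positive_label`` enter
    the fits (relapsed early patients are excluded).  The acquisition-time
    covariate is years since the earliest included sample.  Models that
    fail to converge (e.g. complete separation) are flagged and excluded
    from the BH family with a warning.
    """
    labels = stage_labels.reindex(profiles.index)
    keep = labels.isin([positive_label, negative_label])
    if keep.sum() == 0:
        raise InputError("no samples in the two compared stage groups")
    sub = profiles.loc[keep]
    y = (labels.loc[keep] == positive_label).astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise InputError("both stage groups must be present")
    dates = pd.to_datetime(acquisition_dates.reindex(sub.index))
    if dates.isna().any():
        raise InputError("missing acquisition dates for association fits")
    t_years = ((dates - dates.min()).dt.days / 365.25).to_numpy()
    # a degenerate time covariate (single acquisition date) is collinear
    # with the intercept; drop it instead of fitting a singular model
    use_time = np.ptp(t_years) > 0

    fits: list[dict] = []
    for name in profiles.columns:
        c = sub[name].to_numpy(dtype=float)
        sd = c.std(ddof=1)
        if standardize and sd > 0:
            c = (c - c.mean()) / sd
        cols = [c, t_years] if use_time else [c]
        X = sm.add_constant(np.column_stack(cols))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True)) and np.all(
                np.isfinite(res.bse)
            )
            beta, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
        except (PerfectSeparationError, np.linalg.LinAlgError):
            converged, beta, se, p = False, np.nan, np.nan, np.nan
        if converged and not (np.isfinite(p) and 0 < p <= 1):
            converged = False
        fits.append({"metabolite": name, "beta": beta, "se": se, "p": p,
                     "converged": converged})

    ok = [f for f in fits if f["converged"]]
    dropped = [f["metabolite"] for f in fits if not f["converged"]]
    if dropped:
        warnings.warn(
            f"{len(dropped)} non-converged metabolite models excluded from "
            f"BH correction: {dropped}"
        )
    if ok:
        adjusted, signif = bh_adjust([f["p"] for f in ok], alpha=alpha)
    adj_map = {f["metabolite"]: (a, s) for f, a, s in zip(ok, adjusted, signif)} if ok else {}

    results = []
    for f in fits:
        if f["converged"]:
            p_adj, sig = adj_map[f["metabolite"]]
            direction = (
                ("up_in_aBC" if f["beta"] > 0 else "down_in_aBC") if sig else "none"
            )
            results.append(
                AssociationResult(
                    metabolite=f["metabolite"], beta=f["beta"], se=f["se"],
                    wald_p=f["p"], p_adjusted=float(p_adj), significant=bool(sig),
                    direction=direction,
                )
            )
        else:
            results.append(
                AssociationResult(
                    metabolite=f["metabolite"], beta=np.nan, se=np.nan,
                    wald_p=np.nan, p_adjusted=np.nan, significant=False,
                    direction="none", converged=False,
                )
            )
    return results


def association_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.wald_p for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
            "converged": [r.converged for r in results],
        }
    )
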