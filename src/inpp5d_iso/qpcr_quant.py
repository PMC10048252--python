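"""qPCR standard-curve quantitation, relative expression and linear models.

Copy numbers are read off a log-linear standard curve
``Cq = intercept + slope * log10(copies)`` fit by least squares to a
dilution series; amplification efficiency is ``10^(-1/slope) - 1`` (1.0 at
the ideal slope of -3.32 Cq per decade).  Expression analyses work on
log10 copy numbers: isoform assays are modelled against a reference
(the microglial gene ITGAM, or the full-length ex10-ex12 assay for
isoform-vs-isoform comparisons) by ordinary least squares on z-scored
variables, so coefficients are standardized betas and a sole predictor's
beta equals its Pearson correlation.  Neuropathology enters as a low/high
indicator, genotype as an additive 0/1/2 minor-allele dose by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "StandardCurve",
    "RelativeExpression",
    "ExpressionModelFit",
    "ChxTrendResult",
    "fit_standard_curve",
    "cq_to_copies",
    "relative_expression",
    "average_replicates",
    "quantify_plate",
    "fit_expression_model",
    "genotype_dose",
    "chx_trend",
]


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear Cq-vs-copies calibration.

    slope: Cq per log10(copies), negative for a working assay;
    intercept: Cq at a single copy; efficiency: per-cycle amplification
    gain, ideally 1.0.  ``accepted`` is False for rejected (non-negative
    slope) fits.
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    accepted: bool = True


def fit_standard_curve(standards) -> StandardCurve:
    """Least-squares fit of Cq on log10(copies) over a dilution series.

    ``standards`` is an iterable of (copies, Cq) pairs or a DataFrame with
    ``copies`` and ``cq`` columns; at least two distinct copy levels are
    required.  A non-negative slope yields a warning and a rejected curve.
    """
    if isinstance(standards, pd.DataFrame):
        copies = standards["copies"].to_numpy(dtype=float)
        cq = standards["cq"].to_numpy(dtype=float)
    else:
        pairs = list(standards)
        copies = np.array([p[0] for p in pairs], dtype=float)
        cq = np.array([p[1] for p in pairs], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("standard copies must be > 0")
    if np.unique(copies).size < 2:
        raise ValueError("need at least 2 distinct copy levels to fit a "
                         "standard curve")
    res = stats.linregress(np.log10(copies), cq)
    accepted = bool(res.slope < 0)
    if not accepted:
        warnings.warn("standard curve has non-negative slope; curve rejected",
                      stacklevel=2)
        efficiency = float("nan")
    else:
        efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         efficiency=float(efficiency),
                         r_squared=float(res.rvalue ** 2), accepted=accepted)


def cq_to_copies(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((Cq - intercept)/slope).

    Sub-single-copy results are returned as-is (the caller flags
    below-range wells); they are not an error.
    """
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    assay: str
    reference_assay: str
    target_copies: float
    reference_copies: float
    ratio: float
    log_ratio: float


def relative_expression(target_copies: float, reference_copies: float,
                        sample_id: str = "", assay: str = "",
                        reference_assay: str = "") -> RelativeExpression:
    """Target/reference copy ratio with its log10."""
    if target_copies <= 0 or reference_copies <= 0:
        raise ValueError("copy numbers must be > 0")
    ratio = target_copies / reference_copies
    return RelativeExpression(sample_id=sample_id, assay=assay,
                              reference_assay=reference_assay,
                              target_copies=float(target_copies),
                              reference_copies=float(reference_copies),
                              ratio=float(ratio),
                              log_ratio=float(np.log10(ratio)))


def average_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq per sample x assay (replicates averaged before quantitation)."""
    return (plate.groupby(["sample_id", "assay"], as_index=False)
            .agg(cq=("cq", "mean"), n_replicates=("cq", "size")))


def quantify_plate(plate: pd.DataFrame, curve: StandardCurve) -> pd.DataFrame:
    """Quantify all unknown wells of a plate against a standard curve.

    Returns one row per sample x assay with the replicate-mean Cq, derived
    copies and a ``below_range`` flag for sub-single-copy results.
    """
    unknowns = plate[plate.get("well_type", "unknown") == "unknown"] \
        if "well_type" in plate.columns else plate
    means = average_replicates(unknowns)
    means["copies"] = [cq_to_copies(c, curve) for c in means["cq"]]
    means["below_range"] = means["copies"] < 1.0
    return means


# --------------------------------------------------------------------------
# linear models

@dataclass
class ExpressionModelFit:
    response: str
    predictors: list
    standardized_beta: dict
    p_value: dict
    r_squared: float
    adj_r_squared: float
    nobs: int


def genotype_dose(genotypes, minor_allele: str) -> np.ndarray:
    """Additive genotype coding: minor-allele count 0/1/2."""
    return np.array([g.count(minor_allele) for g in genotypes], dtype=float)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def fit_expression_model(table: pd.DataFrame, response: str,
                         predictors: list[str]) -> ExpressionModelFit:
    """OLS of a (log-scale) response on z-scored predictors.

    All variables are z-scored, so coefficients are standardized betas and
    a sole predictor's beta equals its Pearson correlation with the
    response.  Raises on constant or collinear predictor columns, naming
    the offenders.
    """
    if len(table) < len(predictors) + 2:
        raise ValueError("need at least predictors+2 observations")
    cols = [response] + list(predictors)
    data = table[cols].astype(float)
    constant = [c for c in predictors if data[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    z = data.apply(_zscore)
    X = sm.add_constant(z[list(predictors)].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = z[list(predictors)].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear columns "
                         f"include {list(worst)}")
    fit = sm.OLS(z[response].to_numpy(), X).fit()
    betas = dict(zip(predictors, fit.params[1:]))
    pvals = dict(zip(predictors, fit.pvalues[1:]))
    return ExpressionModelFit(response=response, predictors=list(predictors),
                              standardized_beta=betas, p_value=pvals,
                              r_squared=float(fit.rsquared),
                              adj_r_squared=float(fit.rsquared_adj),
                              nobs=int(fit.nobs))


# --------------------------------------------------------------------------
# CHX trend

@dataclass
class ChxTrendResult:
    slope: float              # D47-fraction change per hour, CHX arm
    p_slope: float
    vehicle_slope: float
    contrast: float           # CHX slope minus vehicle slope
    p_contrast: float
    spearman_rho: float
    p_spearman: float


def chx_trend(timecourse: pd.DataFrame) -> ChxTrendResult:
    """Trend of the PTC-isoform fraction under translation blockade.

    Fits the CHX-arm slope of D47 fraction on hours by OLS (an NMD target
    accumulates when translation, and hence NMD, is blocked), the arm
    contrast via a treatment-by-time interaction, and a Spearman rank
    correlation as a distribution-free check.
    """
    chx = timecourse[timecourse["treatment"] == "CHX"]
    veh = timecourse[timecourse["treatment"] == "vehicle"]
    for arm, name in ((chx, "CHX"), (veh, "vehicle")):
        if arm["time_h"].nunique() < 2:
            raise ValueError(f"{name} arm needs >= 2 timepoints")

    def arm_fit(df):
        X = sm.add_constant(df["time_h"].to_numpy())
        return sm.OLS(df["d47_fraction"].to_numpy(), X).fit()

    f_chx = arm_fit(chx)
    f_veh = arm_fit(veh)
    is_chx = (timecourse["treatment"] == "CHX").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(timecourse)),
                         timecourse["time_h"].to_numpy(), is_chx,
                         timecourse["time_h"].to_numpy() * is_chx])
    full = sm.OLS(timecourse["d47_fraction"].to_numpy(), X).fit()
    if chx["d47_fraction"].nunique() > 1:
        rho, p_rho = stats.spearmanr(chx["time_h"], chx["d47_fraction"])
    else:                       # flat series: no rank trend to measure
        rho, p_rho = 0.0, 1.0
    return ChxTrendResult(slope=float(f_chx.params[1]),
                          p_slope=float(f_chx.pvalues[1]),
                          vehicle_slope=float(f_veh.params[1]),
                          contrast=float(full.params[3]),
                          p_contrast=float(full.pvalues[3]),
                          spearman_rho=float(rho),
                          p_spearman=float(p_rho))
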