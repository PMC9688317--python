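"""Median-effect dose-response fitting and Loewe-additivity synergy scoring.

The median-effect model fa/fu = (D/Dm)^m (fa = fraction affected, fu = 1-fa)
linearizes to log(fa/fu) = m log D - m log Dm, so (Dm, m) come from a
least-squares line on (log10 D, log10(fa/fu)). Drug-pair synergy at an effect
level fa is quantified by the combination index

    CI = d1/Dx1 + d2/Dx2,

where (d1, d2) is the combination dose pair producing fa and Dx_i is the
single-agent dose producing the same fa. CI < 1 indicates synergy, CI = 1
Loewe additivity (a drug is exactly additive with itself), CI > 1 antagonism.
The isobologram at fixed fa draws the segment between the single-agent
intercepts (Dx1, 0) and (0, Dx2); combination points below it are synergistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MedianEffectFit",
    "MedianEffectModel",
    "CombinationIndexResult",
    "fit_median_effect",
    "dose_for_fa",
    "dose_for_fa_params",
    "fa_for_dose",
    "compute_ci",
    "classify_ci",
    "isobologram",
    "single_agent_exceedance",
]

#: classification tolerance around CI = 1
DEFAULT_CI_TOL = 0.05


@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters for one drug.

    ``monotone`` is False when the fitted slope is not positive (the data do
    not describe a cytotoxic dose-response); such fits are flagged, never
    silently accepted.
    """

    drug: str
    dm: float
    m: float
    r: float
    n_points: int
    monotone: bool = True


@dataclass
class CombinationIndexResult:
    fa: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    ci: float
    classification: str


def fa_for_dose(dm: float, m: float, dose) -> np.ndarray:
    """Forward median-effect model: fraction affected at a dose."""
    dose = np.asarray(dose, dtype=float)
    ratio = (dose / dm) ** m
    return ratio / (1 + ratio)


def dose_for_fa_params(dm: float, m: float, fa: float) -> float:
    """Invert the median-effect model: Dx = Dm (fa/(1-fa))^(1/m)."""
    if not 0 < fa < 1:
        raise ValueError("fa must lie strictly in (0, 1)")
    return dm * (fa / (1 - fa)) ** (1 / m)


class MedianEffectModel(BaseEstimator):
    """Median-effect dose-response estimator.

    Fits the log-linearized model by ordinary least squares on
    (log10 dose, log10(fa/fu)). Points with fa in {0, 1} have an undefined
    logit and are excluded with a warning rather than clipped (clipping
    silently biases the slope).

    Parameters
    ----------
    drug : str
        Label carried into the fit result.

    Attributes
    ----------
    dm_ : float
        Median-effect dose (dose giving fa = 0.5).
    m_ : float
        Slope of the median-effect line.
    r_ : float
        Correlation coefficient of the linearized fit.
    n_points_ : int
        Number of usable dose points.
    monotone_ : bool
        True when m_ > 0.
    """

    def __init__(self, drug: str = "drug"):
        self.drug = drug

    def fit(self, dose, fa):
        dose = np.asarray(dose, dtype=float)
        fa = np.asarray(fa, dtype=float)
        if dose.ndim != 1 or dose.shape != fa.shape:
            raise ValueError("dose and fa must be 1-d arrays of equal length")
        if (dose <= 0).any():
            raise ValueError("doses must be positive")
        if ((fa < 0) | (fa > 1)).any():
            raise ValueError("fa must lie in [0, 1]")
        usable = (fa > 0) & (fa < 1)
        n_dropped = int((~usable).sum())
        if n_dropped:
            warnings.warn(
                f"{self.drug}: excluded {n_dropped} point(s) with fa in {{0, 1}} "
                "(logit undefined)",
                stacklevel=2,
            )
        if usable.sum() < 2:
            raise ValueError("need at least 2 dose points with fa strictly in (0, 1)")
        x = np.log10(dose[usable])
        y = np.log10(fa[usable] / (1 - fa[usable]))
        if np.allclose(x, x[0]):
            raise ValueError("all usable doses identical; slope undefined")
        res = stats.linregress(x, y)
        self.m_ = float(res.slope)
        self.r_ = float(res.rvalue) if not np.isnan(res.rvalue) else 1.0
        self.n_points_ = int(usable.sum())
        self.monotone_ = self.m_ > 0
        if self.monotone_:
            self.dm_ = float(10 ** (-res.intercept / res.slope))
        else:
            warnings.warn(
                f"{self.drug}: non-positive median-effect slope ({self.m_:.3g}); "
                "fit flagged non-monotone",
                stacklevel=2,
            )
            self.dm_ = float("nan")
        return self

    def predict(self, dose) -> np.ndarray:
        """Fraction affected at the given dose(s)."""
        check_is_fitted(self, "m_")
        return fa_for_dose(self.dm_, self.m_, dose)

    def dose_for_fa(self, fa: float) -> float:
        """Single-agent dose producing effect level fa."""
        check_is_fitted(self, "m_")
        return dose_for_fa_params(self.dm_, self.m_, fa)

    @property
    def result_(self) -> MedianEffectFit:
        check_is_fitted(self, "m_")
        return MedianEffectFit(
            drug=self.drug,
            dm=self.dm_,
            m=self.m_,
            r=self.r_,
            n_points=self.n_points_,
            monotone=self.monotone_,
        )


def fit_median_effect(records: pd.DataFrame, drug: str | None = None) -> MedianEffectFit:
    """Fit a median-effect line to a ``dose, fa`` viability table."""
    if drug is None:
        drug = str(records["drug"].iloc[0]) if "drug" in records else "drug"
    model = MedianEffectModel(drug=drug).fit(records["dose"], records["fa"])
    return model.result_


def dose_for_fa(fit: MedianEffectFit, fa: float) -> float:
    """Single-agent dose producing effect level fa under a fitted model."""
    if not fit.monotone:
        raise ValueError(f"{fit.drug}: non-monotone fit cannot be inverted")
    return dose_for_fa_params(fit.dm, fit.m, fa)


def classify_ci(ci: float, tol: float = DEFAULT_CI_TOL) -> str:
    if ci < 1 - tol:
        return "synergy"
    if ci > 1 + tol:
        return "antagonism"
    return "additive"


def compute_ci(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    combo_records: pd.DataFrame,
    ratio: float | None = None,
    tol: float = DEFAULT_CI_TOL,
) -> list[CombinationIndexResult]:
    """Combination index for each observed combination effect level.

    ``combo_records`` either carries explicit component doses (columns
    ``d1, d2, fa``) or, for a fixed-ratio design, a total ``dose`` column
    with ``ratio`` giving d1:d2 so d1 = ratio/(1+ratio) * dose. Records with
    fa in {0, 1} have no finite equi-effective dose and are skipped with a
    warning.
    """
    if {"d1", "d2"}.issubset(combo_records.columns):
        d1s = combo_records["d1"].to_numpy(dtype=float)
        d2s = combo_records["d2"].to_numpy(dtype=float)
    elif ratio is not None and "dose" in combo_records.columns:
        total = combo_records["dose"].to_numpy(dtype=float)
        d1s = ratio / (1 + ratio) * total
        d2s = total / (1 + ratio)
    else:
        raise ValueError("combo records need either d1/d2 columns or a dose column with ratio")
    fas = combo_records["fa"].to_numpy(dtype=float)
    out: list[CombinationIndexResult] = []
    for d1, d2, fa in zip(d1s, d2s, fas):
        if not 0 < fa < 1:
            warnings.warn(f"skipping combo point with fa={fa} (no finite Dx)", stacklevel=2)
            continue
        dx1 = dose_for_fa(fit1, fa)
        dx2 = dose_for_fa(fit2, fa)
        ci = d1 / dx1 + d2 / dx2
        out.append(
            CombinationIndexResult(
                fa=float(fa), d1=float(d1), d2=float(d2), dx1=dx1, dx2=dx2,
                ci=float(ci), classification=classify_ci(ci, tol),
            )
        )
    return out


def ci_table(results: list[CombinationIndexResult]) -> pd.DataFrame:
    """Tabular view of combination-index results."""
    return pd.DataFrame(
        [
            {"fa": r.fa, "d1": r.d1, "d2": r.d2, "Dx1": r.dx1, "Dx2": r.dx2,
             "CI": r.ci, "class": r.classification}
            for r in results
        ]
    )


def isobologram(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    fa: float,
    combo_points: pd.DataFrame | None = None,
    tol: float = DEFAULT_CI_TOL,
) -> dict:
    """Isobologram coordinates at a fixed effect level.

    Returns the additivity-line intercepts (Dx1, 0) and (0, Dx2) plus, for
    each combination point, its (d1, d2) coordinates and a flag: ``below``
    the line (synergy, d1/Dx1 + d2/Dx2 < 1 - tol), ``on`` it (within tol), or
    ``above`` (antagonism).
    """
    dx1 = dose_for_fa(fit1, fa)
    dx2 = dose_for_fa(fit2, fa)
    points = []
    if combo_points is not None:
        for _, row in combo_points.iterrows():
            d1, d2 = float(row["d1"]), float(row["d2"])
            ci = d1 / dx1 + d2 / dx2
            if abs(ci - 1) <= tol:
                flag = "on"
            elif ci < 1:
                flag = "below"
            else:
                flag = "above"
            points.append({"d1": d1, "d2": d2, "ci": ci, "flag": flag})
    return {"fa": fa, "intercepts": [(dx1, 0.0), (0.0, dx2)], "points": points}


def single_agent_exceedance(fa_combo: float, fa_drug1: float, fa_drug2: float) -> float:
    """Excess effect of the combination over the best single agent."""
    for v in (fa_combo, fa_drug1, fa_drug2):
        if not 0 <= v <= 1:
            raise ValueError("fractions affected must lie in [0, 1]")
    return fa_combo - max(fa_drug1, fa_drug2)
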