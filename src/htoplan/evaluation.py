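"""Agreement and error statistics for correction-angle raters.

Planned correction angles have no gold standard: different orthopedists
mark slightly different landmarks.  Agreement between raters (human or
algorithmic) is therefore quantified with the intraclass correlation
coefficient — by default ICC(2,1), the two-way random-effects,
single-rater, absolute-agreement form, appropriate when raters are meant
to be interchangeable — together with Bland–Altman bias and 95% limits of
agreement and simple absolute-error summaries.  Angle case-mix
distributions are modelled with a maximum-likelihood skew-normal fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "RatingTable",
    "ICCUndefinedError",
    "AgreementReport",
    "SkewNormalFit",
    "icc",
    "bland_altman",
    "error_summary",
    "mean_observer",
    "fit_skew_normal",
    "agreement_report",
    "read_rating_table",
]


class ICCUndefinedError(ValueError):
    """ICC cannot be computed (e.g. zero between-subject variance)."""


@dataclass
class RatingTable:
    """Angles (degrees) for the same legs judged by several raters.

    Rows are legs/images, columns are raters.  Missing values are not
    allowed; ICC needs at least 2 raters and 3 legs.
    """

    values: np.ndarray
    raters: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rating table must be 2-D (legs x raters)")
        if self.values.shape[1] != len(self.raters):
            raise ValueError("rater names must match the number of columns")
        if self.values.shape[1] < 2 or self.values.shape[0] < 3:
            raise ValueError("need >= 2 raters and >= 3 legs")
        if not np.isfinite(self.values).all():
            raise ValueError("rating table contains non-finite entries")

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "RatingTable":
        return RatingTable(df.to_numpy(dtype=float), [str(c) for c in df.columns])

    def to_long(self) -> pd.DataFrame:
        n, k = self.values.shape
        return pd.DataFrame(
            {
                "target": np.repeat(np.arange(n), k),
                "rater": np.tile(self.raters, n),
                "score": self.values.ravel(),
            }
        )


def read_rating_table(path) -> RatingTable:
    """Read a rating table from CSV with a header row of rater names."""
    return RatingTable.from_frame(pd.read_csv(path))


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    form: str


#: row position of each form in the pingouin output (stable across the
#: ICC1/ICC(1,1) naming change between pingouin versions)
_FORM_ROW = {"icc1": 0, "icc2": 1, "icc3": 2, "icc1k": 3, "icc2k": 4, "icc3k": 5}


def icc(table: RatingTable, form: str = "icc2") -> ICCResult:
    """Intraclass correlation coefficient with its 95% CI and p-value.

    ``form`` selects the ICC variant; the default ``icc2`` is ICC(2,1),
    two-way random effects, single rater, absolute agreement.  The CI comes
    from the standard F-distribution construction and the p-value tests
    ICC = 0.  A degenerate table (e.g. zero between-subject variance with
    no residual spread) raises :class:`ICCUndefinedError`.
    """
    row_idx = _FORM_ROW.get(form.lower())
    if row_idx is None:
        raise ValueError(f"unknown ICC form {form!r}")
    long = table.to_long()
    res = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="score"
    )
    row = res.iloc[row_idx]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci = row[ci_col]
    value = float(row["ICC"])
    if not np.isfinite(value):
        raise ICCUndefinedError("ICC undefined for this table (degenerate variance)")
    return ICCResult(
        icc=value,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(row["pval"]),
        form=str(row["Type"]),
    )


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    fraction_within: float


def bland_altman(a, b, limit_factor: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman bias and limits of agreement of two angle series.

    ``bias = mean(a - b)``, limits ``bias +- limit_factor * sd(a - b)``.
    The exact 1.96 normal quantile is used by default (no small-sample t
    correction).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - limit_factor * sd, bias + limit_factor * sd
    within = float(np.mean((diff >= lo) & (diff <= hi)))
    return BlandAltmanResult(bias=bias, loa_low=lo, loa_high=hi, sd_diff=sd, fraction_within=within)


def error_summary(pred, ref) -> dict[str, float]:
    """Median/mean/min/max of the absolute differences |pred - ref|."""
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if pred.shape != ref.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError("series must be 1-D, non-empty and of equal length")
    err = np.abs(pred - ref)
    return {
        "median": float(np.median(err)),
        "mean": float(err.mean()),
        "min": float(err.min()),
        "max": float(err.max()),
    }


def mean_observer(table: RatingTable) -> np.ndarray:
    """Row-wise mean across rater columns (the 'mean rater')."""
    return table.values.mean(axis=1)


@dataclass
class SkewNormalFit:
    shape: float
    location: float
    scale: float
    log_likelihood: float

    @property
    def mean(self) -> float:
        delta = self.shape / np.sqrt(1 + self.shape**2)
        return self.location + self.scale * delta * np.sqrt(2 / np.pi)


def fit_skew_normal(angles) -> SkewNormalFit:
    """Maximum-likelihood skew-normal fit of an angle sample.

    Reduces to the normal fit for symmetric data (shape near 0).  Raises on
    degenerate (constant) or non-convergent input.
    """
    angles = np.asarray(angles, float)
    if angles.size < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(angles) == 0:
        raise ValueError("constant data: scale would be zero")
    a, loc, scale = stats.skewnorm.fit(angles)
    ll = float(np.sum(stats.skewnorm.logpdf(angles, a, loc, scale)))
    if not (np.isfinite(ll) and scale > 0):
        raise RuntimeError(
            f"skew-normal fit did not converge (a={a:.3g}, loc={loc:.3g}, scale={scale:.3g})"
        )
    return SkewNormalFit(shape=float(a), location=float(loc), scale=float(scale), log_likelihood=ll)


@dataclass
class AgreementReport:
    """ICC, Bland–Altman and error summary for a pair of raters."""

    icc: ICCResult
    bland_altman: BlandAltmanResult
    errors: dict[str, float]
    names: tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "raters": list(self.names),
            "icc": self.icc.icc,
            "icc_ci95": [self.icc.ci_low, self.icc.ci_high],
            "icc_p_value": self.icc.p_value,
            "icc_form": self.icc.form,
            "bias": self.bland_altman.bias,
            "loa": [self.bland_altman.loa_low, self.bland_altman.loa_high],
            "errors": self.errors,
        }


def agreement_report(a, b, names: tuple[str, str] = ("A", "B"), form: str = "icc2") -> AgreementReport:
    """Full pairwise agreement analysis of two angle series."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    table = RatingTable(np.stack([a, b], axis=1), list(names))
    return AgreementReport(
        icc=icc(table, form=form),
        bland_altman=bland_altman(a, b),
        errors=error_summary(a, b),
        names=tuple(names),
    )


def bland_altman_plot(a, b, ax=None):
    """Draw the Bland–Altman scatter with bias and limits of agreement."""
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, s=14)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of the two raters (deg)")
    ax.set_ylabel("difference (deg)")
    return ax
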