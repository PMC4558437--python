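"""Clinical-duration model: yearly binning, quadratic fit, preclinical estimate.

PD subjects are grouped by whole years of clinical duration (bin ``k`` holds
durations in ``(k−1, k]``, with exact zeros in bin 1); bins with fewer than
``min_n`` subjects are excluded.  The per-bin mean SRR is regressed on the
year index with an ordinary-least-squares quadratic
``y = a x² + b x + c``, and the preclinical period is estimated by solving
the fitted curve for the healthy-control mean SRR: since uptake declines with
time, the solution lies at negative x and its magnitude is the number of
years of presymptomatic decline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "YearBin",
    "QuadraticModel",
    "PreclinicalEstimate",
    "bin_by_year",
    "fit_quadratic",
    "estimate_preclinical_duration",
]


@dataclass
class YearBin:
    year: int
    n: int
    mean_srr: float
    sd_srr: float


@dataclass
class QuadraticModel:
    a: float
    b: float
    c: float
    r_squared: float = float("nan")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


@dataclass
class PreclinicalEstimate:
    years: float            # |root|, rounded to 0.1 year
    years_exact: float      # unrounded magnitude
    root: float             # the (negative) duration solving the model


def bin_by_year(records: pd.DataFrame, min_n: int = 10, max_year: int = 15
                ) -> list[YearBin]:
    """Group PD records into yearly duration bins and drop sparse bins.

    ``records`` needs ``duration_years`` and an SRR column (``srr`` if
    present, else ``srr_true``).
    """
    col = "srr" if "srr" in records.columns else "srr_true"
    dur = records["duration_years"].to_numpy(dtype=float)
    srr = records[col].to_numpy(dtype=float)
    valid = ~np.isnan(dur) & ~np.isnan(srr)
    dur, srr = dur[valid], srr[valid]
    bins: list[YearBin] = []
    for k in range(1, max_year + 1):
        sel = (dur > k - 1) & (dur <= k)
        if k == 1:
            sel |= dur == 0
        vals = srr[sel]
        if len(vals) < min_n:
            continue
        bins.append(YearBin(year=k, n=len(vals), mean_srr=float(vals.mean()),
                            sd_srr=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0))
    if not bins:
        raise ValueError(f"no duration bin holds at least {min_n} subjects")
    return bins


def fit_quadratic(bins: list[YearBin]) -> QuadraticModel:
    """Unweighted least-squares quadratic of the bin mean SRRs on the year index."""
    if len(bins) < 3:
        raise ValueError(f"need at least 3 bins to fit a quadratic, got {len(bins)}")
    x = np.array([b.year for b in bins], dtype=float)
    y = np.array([b.mean_srr for b in bins], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct years")
    a, b, c = np.polyfit(x, y, 2)
    resid = y - (a * x**2 + b * x + c)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return QuadraticModel(a=float(a), b=float(b), c=float(c), r_squared=r2)


def estimate_preclinical_duration(model: QuadraticModel,
                                  healthy_mean_srr: float) -> PreclinicalEstimate:
    """Extrapolate the duration curve back to the healthy-control mean SRR.

    Solves ``a x² + b x + c = healthy_mean_srr`` and takes the negative root
    nearest zero; its magnitude is the estimated preclinical duration.
    """
    at_onset = float(model.predict(0.0))
    if healthy_mean_srr == at_onset:
        return PreclinicalEstimate(years=0.0, years_exact=0.0, root=0.0)
    if healthy_mean_srr < at_onset:
        raise ValueError("healthy mean SRR must exceed the model value at onset "
                         "(x = 0); extrapolation must go to negative durations")
    a, b, c = model.a, model.b, model.c
    if a == 0:
        if b == 0:
            raise ValueError("degenerate model: no dependence on duration")
        roots = np.array([(healthy_mean_srr - c) / b])
    else:
        disc = b * b - 4 * a * (c - healthy_mean_srr)
        if disc < 0:
            raise ValueError("the fitted curve never reaches the healthy mean SRR "
                             "(no real root)")
        sq = float(np.sqrt(disc))
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    neg = roots[roots < 0]
    if neg.size == 0:
        raise ValueError("both roots are non-negative; preclinical extrapolation "
                         "is ill-posed for this model")
    root = float(neg[np.argmax(neg)])          # negative root nearest zero
    exact = abs(root)
    return PreclinicalEstimate(years=round(exact, 1), years_exact=exact, root=root)
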