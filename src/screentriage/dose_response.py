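"""Four-parameter logistic (4PL) dose-response fitting and activity classes.

The model is

    f(x) = A + (D - A) / (1 + (x / C)^B)

with D the response as x -> 0, A the response as x -> infinity, B the
Hill slope and C the inflection concentration (the IC50 for a
symmetric curve).  Fits are least-squares over all replicate points
jointly.  Fitted IC50 values are capped to the measured concentration
range: a fit whose C lands above the top tested dose (or that fails to
converge, or shows an inverted slope against an evident response
trend) is flagged erroneous and its IC50 reduced to the highest tested
concentration, so no compound is reported more potent or weaker than
the assay can resolve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

MICROMOLAR = "micromolar"
HIGH_NANOMOLAR = "high_nanomolar"
NANOMOLAR = "nanomolar"


class DoseResponseDomainError(ValueError):
    """Non-positive concentration or scale parameter."""


class InsufficientDataError(ValueError):
    """Fewer than four distinct concentrations available for a 4PL fit."""


def four_pl(x, A: float, B: float, C: float, D: float):
    """Evaluate the 4PL model; x and C in the same (positive) units."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DoseResponseDomainError("concentrations must be positive")
    if C <= 0:
        raise DoseResponseDomainError("inflection C must be positive")
    return A + (D - A) / (1.0 + (x / C) ** B)


def pic50(ic50_um: float) -> float:
    """pIC50 = -log10 of the molar IC50, for an IC50 given in uM."""
    if ic50_um <= 0:
        raise DoseResponseDomainError("IC50 must be positive")
    return -math.log10(ic50_um * 1e-6)


def classify_activity(pic50_value: float) -> str:
    """Bin a pIC50 into micromolar (<6), high nanomolar ([6,7)), nanomolar (>=7)."""
    if not math.isfinite(pic50_value):
        raise DoseResponseDomainError("pIC50 must be finite")
    if pic50_value < 6.0:
        return MICROMOLAR
    if pic50_value < 7.0:
        return HIGH_NANOMOLAR
    return NANOMOLAR


SUB_MICROMOLAR_CLASSES = frozenset({HIGH_NANOMOLAR, NANOMOLAR})


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters and derived potency summary for one compound."""

    compound_id: str
    A: float
    B: float
    C: float
    D: float
    ic50: float               # uM, capped to the tested range
    pic50: float
    capped: bool
    erroneous: bool
    activity_class: str
    rmse: float
    note: str = ""


def _initial_guesses(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    # D = response at the lowest dose, A = at the highest; C = dose whose
    # mean response is nearest the half-range crossing; B = 1.
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    lo_mask = xs == xs.min()
    hi_mask = xs == xs.max()
    D0 = float(ys[lo_mask].mean())
    A0 = float(ys[hi_mask].mean())
    half = 0.5 * (A0 + D0)
    concs = np.unique(xs)
    means = np.array([ys[xs == c].mean() for c in concs])
    C0 = float(concs[int(np.argmin(np.abs(means - half)))])
    return A0, 1.0, max(C0, 1e-6), D0


def fit_dose_response(
    measurements: pd.DataFrame,
    dose_series: tuple[float, ...] | None = None,
    compound_id: str | None = None,
    max_restarts: int = 3,
) -> FourPLFit:
    """Joint least-squares 4PL fit over all replicate points of one compound.

    ``measurements`` needs columns ``conc_uM`` and ``response`` (and
    optionally ``compound_id``).  The fit starts from analytic guesses
    and is retried from perturbed initializations, keeping the best
    residual.  IC50 capping and the erroneous-fit rule are applied as
    described in the module docstring.
    """
    if compound_id is None:
        ids = measurements.get("compound_id")
        compound_id = str(ids.iloc[0]) if ids is not None and len(ids) else ""
    x = measurements["conc_uM"].to_numpy(float)
    y = measurements["response"].to_numpy(float)
    if np.any(x <= 0):
        raise DoseResponseDomainError("concentrations must be positive")
    if len(np.unique(x)) < 4:
        raise InsufficientDataError(
            f"{compound_id}: need >= 4 distinct concentrations, got {len(np.unique(x))}"
        )
    if dose_series is None:
        dose_series = tuple(sorted(np.unique(x), reverse=True))
    top, bottom = max(dose_series), min(dose_series)

    flat = bool(np.ptp(y) == 0.0)
    best = None
    if not flat:
        A0, B0, C0, D0 = _initial_guesses(x, y)
        rng = np.random.default_rng(0)  # fixed: restarts are part of the algorithm
        inits = [(A0, B0, C0, D0)]
        for _ in range(max_restarts):
            inits.append(
                (
                    A0 + rng.normal(0, 5),
                    B0 * rng.uniform(0.5, 2.0),
                    C0 * rng.uniform(0.3, 3.0),
                    D0 + rng.normal(0, 5),
                )
            )
        for p0 in inits:
            try:
                popt, _ = curve_fit(
                    four_pl,
                    x,
                    y,
                    p0=p0,
                    bounds=([-np.inf, -20.0, 1e-9, -np.inf], [np.inf, 20.0, 1e9, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            resid = y - four_pl(x, *popt)
            sse = float(resid @ resid)
            if best is None or sse < best[1]:
                best = (popt, sse)

    if best is None:
        # Non-convergent or flat curve: report the weakest measurable potency.
        note = "flat responses" if flat else "fit did not converge"
        A = D = float(y.mean())
        fit_pic50 = pic50(top)
        return FourPLFit(
            compound_id=compound_id,
            A=A, B=float("nan"), C=float("nan"), D=D,
            ic50=top, pic50=fit_pic50, capped=True, erroneous=True,
            activity_class=classify_activity(fit_pic50),
            rmse=float(np.sqrt(np.mean((y - y.mean()) ** 2))),
            note=note,
        )

    (A, B, C, D), sse = best
    rmse = float(np.sqrt(sse / len(y)))

    # Erroneous-fit rule: C beyond the top dose, or a negative Hill slope
    # while the responses clearly rise with concentration.
    note = ""
    erroneous = False
    if C > top:
        erroneous, note = True, f"C={C:.3g} uM above top dose"
    elif B < 0 and len(np.unique(y)) > 1:
        rho = spearmanr(x, y).statistic
        # with B<0 the fitted curve decreases toward high dose when A<D;
        # flag when the data trend contradicts the fitted orientation
        if np.isfinite(rho) and rho > 0 and A < D:
            erroneous, note = True, "inverted slope against rising response trend"

    if erroneous:
        ic50, capped = top, True
    else:
        ic50 = float(min(max(C, bottom), top))
        capped = ic50 != C
    fit_pic50 = pic50(ic50)
    return FourPLFit(
        compound_id=compound_id,
        A=float(A), B=float(B), C=float(C), D=float(D),
        ic50=ic50, pic50=fit_pic50, capped=capped, erroneous=erroneous,
        activity_class=classify_activity(fit_pic50),
        rmse=rmse, note=note,
    )


def fit_all(measurements: pd.DataFrame, dose_series=None) -> pd.DataFrame:
    """Fit every compound in a long-format dose-response table."""
    rows = []
    for cid, grp in measurements.groupby("compound_id", sort=True):
        f = fit_dose_response(grp, dose_series=dose_series, compound_id=str(cid))
        rows.append(
            {
                "compound_id": f.compound_id,
                "A": f.A, "D": f.D, "B": f.B, "C": f.C,
                "ic50_uM": f.ic50, "pic50": f.pic50,
                "capped": f.capped, "erroneous": f.erroneous,
                "activity_class": f.activity_class, "rmse": f.rmse,
            }
        )
    return pd.DataFrame(rows)
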