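"""Four-parameter logistic dose-response fitting and monotone-response QC.

The 4PL model used throughout is the dose-ratio ("variable slope") form

    response(d) = bottom + (top - bottom) / (1 + (d / ec50)**hill)

so that response(ec50) = (bottom + top) / 2 exactly, response -> top as
d -> 0 and response -> bottom as d -> inf for hill > 0.  A decreasing
curve (the screen's expected ALK-reporter behavior) therefore has
top > bottom and hill > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DEFAULT_DOSES_MOLAR",
    "FourPLFit",
    "four_pl",
    "fit_4pl",
    "monotonic_response_qc",
]

#: Follow-up screen dilution series: five 10-fold dilutions, 20 uM down to 2 nM.
DEFAULT_DOSES_MOLAR: tuple[float, ...] = (2e-9, 2e-8, 2e-7, 2e-6, 2e-5)


def four_pl(dose, bottom, top, ec50, hill):
    """Evaluate the four-parameter logistic at ``dose`` (molar)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


@dataclass
class FourPLFit:
    """Result of a 4PL least-squares fit.

    ``top >= bottom`` after canonicalization (the model is invariant under
    swapping bottom/top while negating hill, so the fit is re-expressed with
    top on top).  ``ec50`` is on the molar scale; optimization is performed
    on log10(ec50) internally for stability.
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    degenerate: bool = False
    message: str = ""
    ci_ec50: tuple[float, float] | None = None
    n_points: int = 0

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)


def _validate_series(doses, responses):
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if doses.size == 0:
        raise ValueError("empty dose-response series")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (molar)")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    return doses, responses


def fit_4pl(doses, responses, degenerate_tol: float = 1e-6) -> FourPLFit:
    """Fit the 4PL by least squares.

    Parameters
    ----------
    doses, responses : array-like
        Paired observations; replicates are expressed as repeated doses.
        At least 4 distinct doses are required.
    degenerate_tol : float
        If the response range is below this tolerance the series is flat:
        no EC50 is estimable and a degenerate fit is returned.

    Initialization is data-driven: bottom = min response, top = max
    response, ec50 = geometric mean dose, hill = +1 for decreasing series
    (responses fall with dose) else -1.
    """
    doses, responses = _validate_series(doses, responses)
    if np.unique(doses).size < 4:
        raise ValueError("at least 4 distinct doses are required")

    span = float(responses.max() - responses.min())
    if span < degenerate_tol:
        return FourPLFit(
            bottom=float(responses.mean()),
            top=float(responses.mean()),
            ec50=float("nan"),
            hill=float("nan"),
            rss=float(np.sum((responses - responses.mean()) ** 2)),
            converged=False,
            degenerate=True,
            message="flat responses: response range below tolerance",
            n_points=doses.size,
        )

    log_doses = np.log10(doses)
    slope_sign = np.corrcoef(log_doses, responses)[0, 1]
    hill0 = 1.0 if slope_sign < 0 else -1.0
    p0 = (float(responses.min()), float(responses.max()),
          float(np.mean(log_doses)), hill0)

    def model(d, bottom, top, log_ec50, hill):
        return bottom + (top - bottom) / (1.0 + (d / 10.0 ** log_ec50) ** hill)

    try:
        with warnings.catch_warnings():
            # a singular covariance on an exact fit is expected, not an error
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, doses, responses, p0=p0, maxfev=20000,
                ftol=1e-14, xtol=1e-14,
            )
        converged = True
        message = ""
    except RuntimeError as exc:  # optimizer failure is a result, not a crash
        popt = p0
        converged = False
        message = str(exc)

    bottom, top, log_ec50, hill = (float(v) for v in popt)
    if top < bottom:  # exact reparameterization: swap asymptotes, flip slope
        bottom, top, hill = top, bottom, -hill
    resid = responses - model(doses, bottom, top, log_ec50, hill)
    return FourPLFit(
        bottom=bottom,
        top=top,
        ec50=10.0 ** log_ec50,
        hill=hill,
        rss=float(np.sum(resid ** 2)),
        converged=converged,
        message=message,
        n_points=doses.size,
    )


def monotonic_response_qc(doses, responses, rho_threshold: float = -0.8):
    """Monotone dose-response QC: does the signal fall as dose rises?

    Computes the Spearman rank correlation between dose and the mean
    response at each distinct dose; the series passes when
    rho <= rho_threshold.  A series with no response variation has an
    undefined rho and fails with a reason.

    Returns
    -------
    (passed, rho) : (bool, float)
        rho is NaN when undefined.
    """
    doses, responses = _validate_series(doses, responses)
    uniq = np.unique(doses)
    if uniq.size < 4:
        raise ValueError("at least 4 distinct doses are required")
    means = np.array([responses[doses == d].mean() for d in uniq])
    if np.all(means == means[0]):
        return False, float("nan")
    rho = stats.spearmanr(uniq, means).statistic
    if not np.isfinite(rho):
        return False, float("nan")
    return bool(rho <= rho_threshold), float(rho)
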