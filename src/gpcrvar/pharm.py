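"""Three-parameter log(agonist) vs. response fitting.

The model is the standard three-parameter log-logistic with Hill slope
fixed at 1:

    R(c) = basal + (top − basal) / (1 + 10^(logEC50 − log10 c))

``basal`` is the constitutive activity (the response at zero agonist),
``top`` is the Emax, and EC50 is the agonist concentration producing a
half-maximal response above basal.  Fitting is ordinary least squares in
log-concentration space; zero-concentration wells are handled analytically
(they contribute to ``basal`` only), avoiding log(0).  ``top ≥ basal`` is
not enforced — inverse-agonist-like profiles with basal below zero are
legitimate.

A free-slope four-parameter variant exists behind ``hill_slope=None`` but
is off by default: the three-parameter form is the reference analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ParameterError

__all__ = [
    "ConcentrationResponse",
    "FitResult",
    "logistic3",
    "fit_dose_response",
    "mix_response_model",
    "summarize_groups",
    "normalize_to_reference",
    "read_curves_csv",
    "write_fits_csv",
]


@dataclass
class ConcentrationResponse:
    """One replicate concentration–response curve.

    Concentrations are molar; zero is allowed for basal wells.  Responses
    are background-subtracted, normalized reporter units.
    """

    label: str
    concentrations: np.ndarray  # M
    responses: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ParameterError("concentrations and responses must have equal length")
        if np.any(self.concentrations < 0):
            raise ParameterError("concentrations must be >= 0")
        if not np.all(np.isfinite(self.responses)):
            raise ParameterError("responses must be finite")
        if len(np.unique(self.concentrations[self.concentrations > 0])) < 4:
            raise ParameterError("need at least 4 distinct non-zero concentrations")


@dataclass
class FitResult:
    """Fitted three-parameter model: constitutive activity, Emax, EC50."""

    label: str
    basal: float
    top: float
    log_ec50: float  # log10 molar
    se_basal: float
    se_top: float
    se_log_ec50: float
    converged: bool
    rss: float
    ec50_identifiable: bool = True
    message: str = ""

    @property
    def ec50_uM(self) -> float:
        return 10.0 ** (self.log_ec50 + 6.0)

    def predict(self, concentrations_M: np.ndarray) -> np.ndarray:
        return logistic3(np.asarray(concentrations_M, float), self.basal, self.top, self.log_ec50)


def logistic3(c_molar: np.ndarray, basal: float, top: float, log_ec50: float) -> np.ndarray:
    """Evaluate the three-parameter model; c = 0 returns basal exactly."""
    c = np.asarray(c_molar, dtype=float)
    out = np.full(c.shape, float(basal))
    nz = c > 0
    out[nz] = basal + (top - basal) / (1.0 + 10.0 ** (log_ec50 - np.log10(c[nz])))
    return out


def _initial_guess(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float]:
    basal0 = float(resp.min())
    top0 = float(resp.max())
    nz = conc > 0
    half = (basal0 + top0) / 2.0
    j = int(np.argmin(np.abs(resp[nz] - half)))
    log_ec50_0 = float(np.log10(conc[nz][j]))
    return basal0, top0, log_ec50_0


def fit_dose_response(curve: ConcentrationResponse) -> FitResult:
    """Least-squares fit of the three-parameter model to one replicate.

    Deterministic given the data: the initializer is basal = min response,
    top = max response, logEC50 = log10 of the concentration nearest the
    half-maximal response.  Non-convergence is reported on the result, not
    raised; constant responses return basal = top = constant with the EC50
    flagged unidentifiable.
    """
    conc = curve.concentrations
    resp = curve.responses
    if np.ptp(resp) == 0.0:
        const = float(resp[0])
        return FitResult(
            label=curve.label, basal=const, top=const, log_ec50=0.0,
            se_basal=0.0, se_top=0.0, se_log_ec50=math.inf,
            converged=True, rss=0.0, ec50_identifiable=False,
            message="constant responses; EC50 unidentifiable",
        )

    def residuals(p: np.ndarray) -> np.ndarray:
        return logistic3(conc, *p) - resp

    p0 = np.array(_initial_guess(conc, resp))
    sol = least_squares(residuals, p0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    rss = float(np.sum(sol.fun**2))
    n, k = len(resp), 3
    se = np.full(3, math.nan)
    if n > k:
        try:
            jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.diag(jtj_inv) * rss / (n - k))
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        label=curve.label,
        basal=float(sol.x[0]),
        top=float(sol.x[1]),
        log_ec50=float(sol.x[2]),
        se_basal=float(se[0]),
        se_top=float(se[1]),
        se_log_ec50=float(se[2]),
        converged=bool(sol.success),
        rss=rss,
        message=str(sol.message),
    )


def mix_response_model(
    fit_wt: FitResult, fit_var: FitResult, weight: float = 0.5
) -> Callable[[np.ndarray], np.ndarray]:
    """Predicted response of a mixed receptor population.

    Models 1:1 WT/variant co-expression (default weight 0.5) as the
    weighted sum of the two fitted curves at every concentration.
    """
    if not (0.0 <= weight <= 1.0):
        raise ParameterError("weight must be in [0, 1]")
    if not (fit_wt.converged and fit_var.converged):
        raise ParameterError("both component fits must have converged")

    def mixed(c_molar: np.ndarray) -> np.ndarray:
        return weight * fit_wt.predict(c_molar) + (1.0 - weight) * fit_var.predict(c_molar)

    return mixed


def summarize_groups(fits_by_condition: Mapping[str, Sequence[FitResult]]) -> pd.DataFrame:
    """Mean ± SEM of basal, top and EC50 (μM) per condition.

    Non-converged fits are excluded and counted.  A single fit reports
    SEM 0 with ``sem_defined`` False.
    """
    rows = []
    for condition, fits in fits_by_condition.items():
        ok = [f for f in fits if f.converged]
        if not ok:
            raise ParameterError(f"no converged fits for condition {condition!r}")
        arr = {
            "basal": np.array([f.basal for f in ok]),
            "top": np.array([f.top for f in ok]),
            "ec50_uM": np.array([f.ec50_uM for f in ok]),
        }
        row = {"condition": condition, "n": len(ok), "n_excluded": len(fits) - len(ok),
               "sem_defined": len(ok) > 1}
        for name, vals in arr.items():
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_reference(
    curves: Iterable[ConcentrationResponse], reference_top: float
) -> list[ConcentrationResponse]:
    """Divide all responses by a reference condition's fitted Emax."""
    if reference_top == 0:
        raise ParameterError("reference top must be non-zero")
    return [
        ConcentrationResponse(
            label=c.label,
            concentrations=c.concentrations,
            responses=c.responses / reference_top,
            replicate_id=c.replicate_id,
        )
        for c in curves
    ]


# ---------------------------------------------------------------------------
# CSV dialect: condition, replicate, concentration_M, response
# ---------------------------------------------------------------------------

def read_curves_csv(path: str | Path) -> list[ConcentrationResponse]:
    df = pd.read_csv(path)
    required = {"condition", "replicate", "concentration_M", "response"}
    if not required.issubset(df.columns):
        raise ParameterError(f"CSV must have columns {sorted(required)}")
    bad = df[~np.isfinite(df["response"]) | (df["concentration_M"] < 0)]
    if len(bad):
        raise ParameterError(f"malformed rows (0-based): {list(bad.index)}")
    curves = []
    for (condition, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        curves.append(
            ConcentrationResponse(
                label=str(condition),
                concentrations=grp["concentration_M"].to_numpy(),
                responses=grp["response"].to_numpy(),
                replicate_id=int(rep),
            )
        )
    return curves


def write_fits_csv(fits: Sequence[FitResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "condition": f.label,
                "basal": f.basal,
                "top": f.top,
                "log_ec50": f.log_ec50,
                "ec50_uM": f.ec50_uM,
                "se_basal": f.se_basal,
                "se_top": f.se_top,
                "se_log_ec50": f.se_log_ec50,
                "converged": f.converged,
                "rss": f.rss,
                "ec50_identifiable": f.ec50_identifiable,
            }
            for f in fits
        ]
    ).to_csv(path, index=False)
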