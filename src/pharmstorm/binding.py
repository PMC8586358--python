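"""Equilibrium binding and concentration-response curve fitting.

Two models cover the pipeline's pharmacology readouts:

* one-site saturation binding (Hill slope fixed at 1),
      ``response = Bmax * c / (c + Kd)``
  used for plasma-membrane saturation binding of a fluorescent ligand, where
  the response is a localization-point ratio or relative occupancy;

* the four-parameter log-logistic concentration-response curve,
      ``response = baseline + (Emax - baseline) / (1 + 10**((logEC50 - log10 c) * h))``
  used for functional assays (BRET G-protein activation, cAMP), with the
  Hill slope ``h`` and the baseline optionally fixed.

Both fits are unweighted ordinary least squares (optional 1/Y^2 weighting),
run from a multi-start grid of log-spaced Kd/EC50 initializations (4 starts
per decade across the sampled concentration range) to avoid local minima.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import ValidationError

_TINY = 1e-12


@dataclass
class BindingSeries:
    """(concentration, response) observations with replicate structure.

    Concentrations are in nM (any single concentration unit works as long as
    it is consistent; fitted Kd/EC50 come back in the same unit).
    """

    concentration: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, float)
        self.response = np.asarray(self.response, float)
        if self.concentration.shape != self.response.shape:
            raise ValidationError("concentration and response must have equal length")
        if np.any(self.concentration < 0):
            raise ValidationError("concentrations must be >= 0")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.concentration), int)
        else:
            self.replicate = np.asarray(self.replicate)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BindingSeries":
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(df["concentration_nm"].to_numpy(), df["response"].to_numpy(), rep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"concentration_nm": self.concentration, "response": self.response, "replicate": self.replicate}
        )

    def _check_fittable(self) -> None:
        pos = self.concentration[self.concentration > 0]
        if len(np.unique(self.concentration)) < 4:
            raise ValidationError("need >= 4 distinct concentrations to fit")
        if len(pos) == 0 or np.log10(pos.max() / pos.min()) < 2:
            raise ValidationError("concentrations must span >= 2 log units")


@dataclass
class BindingFitResult:
    model: str
    kd_or_ec50: float
    bmax_or_emax: float
    hill_slope: float
    baseline: float
    se_estimates: dict = field(default_factory=dict)
    converged: bool = False
    sse: float = np.inf
    n_points: int = 0

    @property
    def kd(self) -> float:
        return self.kd_or_ec50

    @property
    def ec50(self) -> float:
        return self.kd_or_ec50

    def predict(self, concentration) -> np.ndarray:
        c = np.asarray(concentration, float)
        if self.model == "one_site":
            return one_site(c, self.kd_or_ec50, self.bmax_or_emax)
        return sigmoid(c, np.log10(self.kd_or_ec50), self.bmax_or_emax, self.baseline, self.hill_slope)

    def residuals(self, series: BindingSeries) -> np.ndarray:
        return series.response - self.predict(series.concentration)


def one_site(c, kd, bmax) -> np.ndarray:
    c = np.asarray(c, float)
    return bmax * c / (c + kd)


def sigmoid(c, log_ec50, emax, baseline, hill) -> np.ndarray:
    """Log-logistic response; c = 0 maps to the baseline (limit for h > 0)."""
    c = np.asarray(c, float)
    out = np.full(c.shape, float(baseline))
    pos = c > 0
    expo = np.clip((log_ec50 - np.log10(c[pos])) * hill, -300, 300)
    out[pos] = baseline + (emax - baseline) / (1.0 + 10.0**expo)
    return out


def _start_grid(concentrations: np.ndarray, per_decade: int = 4) -> np.ndarray:
    pos = concentrations[concentrations > 0]
    lo, hi = np.log10(pos.min() / 10.0), np.log10(pos.max() * 10.0)
    n = max(2, int(np.ceil((hi - lo) * per_decade)) + 1)
    return np.logspace(lo, hi, n)


def _weights(series: BindingSeries, weighting: str | None) -> np.ndarray | None:
    if weighting is None:
        return None
    if weighting == "1/y2":
        return 1.0 / np.maximum(np.abs(series.response), _TINY)
    raise ValidationError(f"unknown weighting {weighting!r}")


def fit_one_site(series: BindingSeries, weighting: str | None = None) -> BindingFitResult:
    """Fit the one-site saturation model ``Bmax*c/(c+Kd)`` (Hill slope 1).

    Non-convergence is reported through the ``converged`` flag, never
    silently; all-zero responses raise because Kd is unidentifiable.
    """
    series._check_fittable()
    if np.allclose(series.response, 0):
        raise ValidationError("all responses are zero; Kd is not identifiable")
    c, y = series.concentration, series.response
    sigma = _weights(series, weighting)
    bmax0 = float(np.max(y))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for kd0 in _start_grid(c):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    one_site, c, y, p0=[kd0, bmax0], sigma=sigma,
                    bounds=([_TINY, -np.inf], [np.inf, np.inf]), maxfev=5000,
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((y - one_site(c, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return BindingFitResult("one_site", np.nan, np.nan, 1.0, 0.0, converged=False, n_points=len(y))
    sse, popt, pcov = best
    perr = np.sqrt(np.abs(np.diag(pcov)))
    return BindingFitResult(
        model="one_site",
        kd_or_ec50=float(popt[0]),
        bmax_or_emax=float(popt[1]),
        hill_slope=1.0,
        baseline=0.0,
        se_estimates={"kd": float(perr[0]), "bmax": float(perr[1])},
        converged=bool(np.all(np.isfinite(popt))),
        sse=sse,
        n_points=len(y),
    )


def fit_sigmoid(
    series: BindingSeries,
    slope_fixed: float | None = None,
    baseline_fixed: float | None = None,
    weighting: str | None = None,
) -> BindingFitResult:
    """Fit the sigmoidal (log-logistic) concentration-response model.

    Free parameters are logEC50, Emax, and optionally the baseline and the
    Hill slope; ``slope_fixed=1`` with ``baseline_fixed=0`` reduces the model
    to the one-site form (then EC50 coincides with Kd).
    """
    series._check_fittable()
    c, y = series.concentration, series.response
    sigma = _weights(series, weighting)
    names = ["log_ec50", "emax"]
    lo, hi = [-np.inf, -np.inf], [np.inf, np.inf]
    if baseline_fixed is None:
        names.append("baseline")
        lo.append(-np.inf)
        hi.append(np.inf)
    if slope_fixed is None:
        names.append("hill")
        lo.append(0.05)
        hi.append(10.0)

    def model(cc, *params):
        p = dict(zip(names, params))
        return sigmoid(
            cc,
            p["log_ec50"],
            p["emax"],
            p.get("baseline", baseline_fixed if baseline_fixed is not None else 0.0),
            p.get("hill", slope_fixed if slope_fixed is not None else 1.0),
        )

    emax0, base0 = float(np.max(y)), float(np.min(y))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for ec50_start in _start_grid(c):
        p0 = [np.log10(ec50_start), emax0]
        if baseline_fixed is None:
            p0.append(base0)
        if slope_fixed is None:
            p0.append(1.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, c, y, p0=p0, sigma=sigma, bounds=(lo, hi), maxfev=10000
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((y - model(c, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return BindingFitResult(
            "sigmoid_logec50", np.nan, np.nan, slope_fixed or np.nan,
            baseline_fixed if baseline_fixed is not None else np.nan,
            converged=False, n_points=len(y),
        )
    sse, popt, pcov = best
    p = dict(zip(names, popt))
    perr = dict(zip(names, np.sqrt(np.abs(np.diag(pcov)))))
    return BindingFitResult(
        model="sigmoid_logec50",
        kd_or_ec50=float(10.0 ** p["log_ec50"]),
        bmax_or_emax=float(p["emax"]),
        hill_slope=float(p.get("hill", slope_fixed if slope_fixed is not None else 1.0)),
        baseline=float(p.get("baseline", baseline_fixed if baseline_fixed is not None else 0.0)),
        se_estimates={k: float(v) for k, v in perr.items()},
        converged=bool(np.all(np.isfinite(popt))),
        sse=sse,
        n_points=len(y),
    )
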