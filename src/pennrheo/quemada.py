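"""Steady-state Quemada constitutive model for shear-thinning colloidal dispersions.

The model expresses the dispersion viscosity through an effective volume
fraction that the flow "feels" when primary particles aggregate into
clusters which trap continuous phase:

    eta(gamma_dot) = eta_f * (1 - phi_e / phi_m)^-2
    phi_e          = phi_p * (1 + C * S)
    S(gamma_dot)   = (S0 + theta * S_inf) / (1 + theta),   theta = gamma_dot_c * gamma_dot

``S`` is the structural parameter (fraction of primary particles bound in
clusters), interpolating between its zero-shear plateau ``S0`` and its
infinite-shear plateau ``S_inf`` through the Peclet number
``theta = Pe = 6*pi*eta_f*a^3*gamma_dot / (kB*T)``.  ``C = 1/varphi - 1`` is a
compactness factor (``varphi`` the intra-cluster packing fraction) and
``phi_m`` the jamming volume fraction at which the viscosity diverges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KB",
    "QuemadaParams",
    "FlowCurve",
    "JammingError",
    "peclet_prefactor",
    "structure_parameter",
    "effective_volume_fraction",
    "viscosity",
    "flow_curve",
    "fit_flow_curve",
    "QuemadaFlowCurveModel",
    "QuemadaFitResults",
    "read_flow_curve",
    "write_flow_curve",
]

#: Boltzmann constant, exact 2019 SI value (J/K).
KB = 1.380649e-23


class JammingError(ValueError):
    """Raised when the effective volume fraction reaches the packing limit."""


def peclet_prefactor(a: float, eta_f: float, T: float) -> float:
    """Peclet-number prefactor ``gamma_dot_c = 6*pi*eta_f*a^3 / (kB*T)`` in seconds.

    The Peclet number at shear rate ``gamma_dot`` is ``gamma_dot_c * gamma_dot``:
    the ratio of the hydrodynamic to the Brownian relaxation rate of a
    primary particle of radius ``a`` suspended in a fluid of viscosity
    ``eta_f`` at temperature ``T``.
    """
    if eta_f <= 0:
        raise ValueError(f"eta_f must be positive, got {eta_f}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    if a < 0:
        raise ValueError(f"particle radius must be non-negative, got {a}")
    return 6.0 * math.pi * eta_f * a**3 / (KB * T)


@dataclass(frozen=True)
class QuemadaParams:
    """Physical parameter set defining one dispersion.

    Parameters
    ----------
    S0, S_inf : float
        Structural parameter at zero / infinite shear, ``0 <= S_inf <= S0 <= 1``.
    C : float
        Compactness factor ``1/varphi - 1`` (dimensionless, >= 0).
    phi_m : float
        Maximum (jamming) volume fraction, in (0, 1].
    eta_f : float
        Continuous-phase viscosity (Pa s, > 0).
    gamma_dot_c : float, optional
        Peclet prefactor (s).  Either given directly or derived from a
        particle radius ``a`` (m) and temperature ``T`` (K).
    """

    S0: float = 1.0
    S_inf: float = 0.0
    C: float = 2.0
    phi_m: float = 0.64
    eta_f: float = 1e-3
    gamma_dot_c: float | None = None
    a: float | None = None
    T: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.S_inf <= self.S0 <= 1.0):
            raise ValueError(
                f"require 0 <= S_inf <= S0 <= 1, got S0={self.S0}, S_inf={self.S_inf}"
            )
        if self.eta_f <= 0:
            raise ValueError(f"eta_f must be positive, got {self.eta_f}")
        if not (0.0 < self.phi_m <= 1.0):
            raise ValueError(f"phi_m must lie in (0, 1], got {self.phi_m}")
        if self.C < 0:
            raise ValueError(f"C must be non-negative, got {self.C}")
        if self.gamma_dot_c is None:
            if self.a is None or self.T is None:
                raise ValueError("either gamma_dot_c or (a, T) must be supplied")
            object.__setattr__(
                self, "gamma_dot_c", peclet_prefactor(self.a, self.eta_f, self.T)
            )
        elif self.a is not None and self.T is not None:
            derived = peclet_prefactor(self.a, self.eta_f, self.T)
            if not math.isclose(self.gamma_dot_c, derived, rel_tol=1e-12):
                raise ValueError(
                    f"gamma_dot_c={self.gamma_dot_c} inconsistent with "
                    f"6*pi*eta_f*a^3/(kB*T)={derived}"
                )
        if self.gamma_dot_c < 0:
            raise ValueError(f"gamma_dot_c must be non-negative, got {self.gamma_dot_c}")

    def replace(self, **kw) -> "QuemadaParams":
        return replace(self, **kw)

    def max_phi_p(self) -> float:
        """Largest primary volume fraction below jamming at zero shear."""
        return self.phi_m / (1.0 + self.C * self.S0)

    def to_dict(self) -> dict:
        return {
            "S0": self.S0,
            "S_inf": self.S_inf,
            "C": self.C,
            "phi_m": self.phi_m,
            "eta_f_Pa_s": self.eta_f,
            "gamma_dot_c_s": self.gamma_dot_c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuemadaParams":
        return cls(
            S0=d["S0"],
            S_inf=d["S_inf"],
            C=d["C"],
            phi_m=d["phi_m"],
            eta_f=d.get("eta_f_Pa_s", d.get("eta_f")),
            gamma_dot_c=d.get("gamma_dot_c_s", d.get("gamma_dot_c")),
        )


def structure_parameter(gamma_dot, params: QuemadaParams):
    """Steady-state structural parameter ``S = (S0 + theta*S_inf)/(1 + theta)``.

    ``theta = gamma_dot_c * gamma_dot`` is the Peclet number.  The result
    interpolates monotonically between ``S0`` (gamma_dot = 0) and ``S_inf``
    (gamma_dot -> inf).
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rates must be non-negative")
    theta = params.gamma_dot_c * g
    out = (params.S0 + theta * params.S_inf) / (1.0 + theta)
    return out if out.ndim else float(out)


def effective_volume_fraction(phi_p, S, C):
    """Effective volume fraction ``phi_e = phi_p * (1 + C*S)``."""
    phi_p = np.asarray(phi_p, dtype=float)
    if np.any(phi_p < 0) or np.any(phi_p > 1):
        raise ValueError("phi_p must lie in [0, 1]")
    if np.any(np.asarray(S) < 0) or C < 0:
        raise ValueError("S and C must be non-negative")
    out = phi_p * (1.0 + C * np.asarray(S, dtype=float))
    return out if out.ndim else float(out)


def viscosity(phi_e, phi_m: float, eta_f: float):
    """Quemada viscosity ``eta = eta_f * (1 - phi_e/phi_m)^-2``.

    Raises
    ------
    JammingError
        If any ``phi_e >= phi_m`` (the viscosity diverges at the packing
        limit; the divergence is reported, never returned as inf).
    """
    phi_e = np.asarray(phi_e, dtype=float)
    if np.any(phi_e < 0):
        raise ValueError("phi_e must be non-negative")
    if np.any(phi_e >= phi_m):
        worst = float(np.max(phi_e))
        raise JammingError(
            f"effective volume fraction {worst} reaches the jamming limit phi_m={phi_m}"
        )
    out = eta_f * (1.0 - phi_e / phi_m) ** -2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FlowCurve:
    """A viscosity-vs-shear-rate curve for one formulation."""

    shear_rates: np.ndarray
    viscosities: np.ndarray
    phi_p: float | None = None
    params: QuemadaParams | None = None

    def __post_init__(self) -> None:
        sr = np.asarray(self.shear_rates, dtype=float)
        visc = np.asarray(self.viscosities, dtype=float)
        if sr.shape != visc.shape:
            raise ValueError("shear_rates and viscosities must have equal length")
        object.__setattr__(self, "shear_rates", sr)
        object.__setattr__(self, "viscosities", visc)

    def __len__(self) -> int:
        return len(self.shear_rates)


def flow_curve(shear_rates: Sequence[float], phi_p: float, params: QuemadaParams) -> FlowCurve:
    """Evaluate the full constitutive composition over a shear-rate grid.

    Raises :class:`JammingError` naming the offending shear rate if the
    zero-shear effective volume fraction exceeds ``phi_m``.
    """
    sr = np.asarray(shear_rates, dtype=float)
    S = structure_parameter(sr, params)
    phi_e = effective_volume_fraction(phi_p, S, params.C)
    jammed = phi_e >= params.phi_m
    if np.any(jammed):
        bad = sr[np.argmax(jammed)]
        raise JammingError(
            f"jamming at shear rate {bad} 1/s: phi_e={float(np.max(phi_e)):.4g} "
            f">= phi_m={params.phi_m} (phi_p={phi_p})"
        )
    eta = viscosity(phi_e, params.phi_m, params.eta_f)
    return FlowCurve(sr, np.asarray(eta), phi_p=phi_p, params=params)


# ---------------------------------------------------------------------------
# Fitting a measured flow curve
# ---------------------------------------------------------------------------

_FIT_PARAMS = ("gamma_dot_c", "CS0", "CS_inf", "phi_m", "eta_f")
_BOUNDS = {
    "gamma_dot_c": (0.0, np.inf),
    "CS0": (0.0, 50.0),
    "CS_inf": (0.0, 50.0),
    "phi_m": (1e-3, 1.0),
    "eta_f": (1e-12, np.inf),
}


@dataclass
class QuemadaFitResults:
    """Results of a least-squares Quemada fit in log10-viscosity space."""

    params: QuemadaParams
    phi_p: float
    free: tuple
    values: dict
    residual: float            # sum of squared log10 residuals
    success: bool
    degenerate: bool = False   # S0 == S_inf identifiability limit
    message: str = ""
    n_points: int = 0

    def predicted(self, shear_rates) -> np.ndarray:
        return flow_curve(shear_rates, self.phi_p, self.params).viscosities

    def summary(self) -> str:
        lines = [
            "Quemada flow-curve fit (least squares on log10 eta)",
            f"  points: {self.n_points}   free: {', '.join(self.free)}",
            f"  residual (sum sq log10): {self.residual:.4g}   success: {self.success}",
        ]
        for k in _FIT_PARAMS:
            if k in self.values:
                mark = "*" if k in self.free else " "
                lines.append(f"  {mark} {k:12s} = {self.values[k]:.6g}")
        if self.degenerate:
            lines.append(
                "  warning: constant curve with both plateaus free -> "
                "(CS0, CS_inf) only identified through their common value"
            )
        return "\n".join(lines)


class QuemadaFlowCurveModel:
    """Fit the steady-state Quemada model to a measured flow curve.

    The fit is parameterised by the identifiable combinations
    ``(gamma_dot_c, C*S0, C*S_inf, phi_m, eta_f)``: viscosity depends on
    ``C`` and ``S`` only through their product, so the plateau products are
    what a flow curve determines.  The fitted ``QuemadaParams`` is reported
    with the convention ``S0 = 1`` (hence ``C = CS0, S_inf = CS_inf/CS0``)
    unless ``CS0 = 0``.

    Parameters
    ----------
    curve : FlowCurve
        Measured shear rates and viscosities (all positive).
    phi_p : float
        Primary-particle volume fraction of the sample.
    """

    def __init__(self, curve: FlowCurve, phi_p: float | None = None):
        if np.any(curve.viscosities <= 0) or np.any(curve.shear_rates < 0):
            raise ValueError("fit requires positive viscosities and non-negative rates")
        self.curve = curve
        self.phi_p = phi_p if phi_p is not None else curve.phi_p
        if self.phi_p is None:
            raise ValueError("phi_p must be supplied (on the curve or explicitly)")

    def fit(
        self,
        free: Iterable[str] = ("gamma_dot_c", "CS0", "CS_inf"),
        fixed: dict | None = None,
        n_starts: int = 3,
        seed: int = 0,
    ) -> QuemadaFitResults:
        free = tuple(free)
        for name in free:
            if name not in _FIT_PARAMS:
                raise ValueError(f"unknown free parameter {name!r}")
        n_distinct = len(np.unique(self.curve.shear_rates))
        if n_distinct < len(free):
            raise ValueError(
                f"need at least {len(free)} distinct shear rates, got {n_distinct}"
            )
        values = {"gamma_dot_c": 1.0, "CS0": 1.0, "CS_inf": 0.0,
                  "phi_m": 0.64, "eta_f": 1e-3}
        if fixed:
            values.update(fixed)

        sr = self.curve.shear_rates
        log_eta = np.log10(self.curve.viscosities)
        phi_p = self.phi_p

        def model_log_eta(v: dict) -> np.ndarray:
            theta = v["gamma_dot_c"] * sr
            CS = (v["CS0"] + theta * v["CS_inf"]) / (1.0 + theta)
            phi_e = phi_p * (1.0 + CS)
            arg = np.maximum(1.0 - phi_e / v["phi_m"], 1e-12)
            return np.log10(v["eta_f"]) - 2.0 * np.log10(arg)

        def residuals(x: np.ndarray) -> np.ndarray:
            v = dict(values)
            v.update(zip(free, x))
            return model_log_eta(v) - log_eta

        lo = np.array([_BOUNDS[k][0] for k in free])
        hi = np.array([_BOUNDS[k][1] for k in free])
        rng = np.random.default_rng(seed)

        # multi-start: default init plus randomised perturbations, mildly
        # nonconvex in gamma_dot_c so a single start can stall
        starts = [np.array([values[k] for k in free], dtype=float)]
        median_rate = float(np.median(sr[sr > 0])) if np.any(sr > 0) else 1.0
        for _ in range(max(0, n_starts - 1)):
            x0 = starts[0].copy()
            for i, k in enumerate(free):
                if k == "gamma_dot_c":
                    x0[i] = 10 ** rng.uniform(-2, 2) / median_rate
                else:
                    x0[i] = x0[i] * 10 ** rng.uniform(-0.5, 0.5) + rng.uniform(0, 0.1)
            starts.append(np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi, x0)))

        best = None
        for x0 in starts:
            try:
                sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-15,
                                    ftol=1e-15, gtol=1e-15)
            except Exception:  # pragma: no cover - optimizer failure path
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("flow-curve fit failed to converge from any start")

        fitted = dict(values)
        fitted.update(zip(free, best.x))
        resid = float(np.sum(residuals(best.x) ** 2))

        degenerate = (
            "CS0" in free and "CS_inf" in free
            and float(np.ptp(log_eta)) < 1e-10
        )

        CS0, CS_inf = fitted["CS0"], fitted["CS_inf"]
        if CS0 > 0:
            qp = QuemadaParams(S0=1.0, S_inf=min(CS_inf / CS0, 1.0), C=CS0,
                               phi_m=fitted["phi_m"], eta_f=fitted["eta_f"],
                               gamma_dot_c=fitted["gamma_dot_c"])
        else:
            qp = QuemadaParams(S0=0.0, S_inf=0.0, C=0.0, phi_m=fitted["phi_m"],
                               eta_f=fitted["eta_f"], gamma_dot_c=fitted["gamma_dot_c"])
        return QuemadaFitResults(
            params=qp, phi_p=phi_p, free=free, values=fitted, residual=resid,
            success=bool(best.success), degenerate=degenerate,
            message=best.message, n_points=len(sr),
        )


def fit_flow_curve(curve: FlowCurve, free=("gamma_dot_c", "CS0", "CS_inf"),
                   phi_p: float | None = None, **kw) -> QuemadaFitResults:
    """Functional wrapper around :class:`QuemadaFlowCurveModel`."""
    return QuemadaFlowCurveModel(curve, phi_p=phi_p).fit(free=free, **kw)


def write_flow_curve(curve: FlowCurve, path) -> None:
    """Write a flow curve as CSV (columns shear_rate_per_s, viscosity_Pa_s)."""
    import pandas as pd

    pd.DataFrame({
        "shear_rate_per_s": curve.shear_rates,
        "viscosity_Pa_s": curve.viscosities,
    }).to_csv(path, index=False, float_format="%.17g")


def read_flow_curve(path, phi_p: float | None = None) -> FlowCurve:
    """Read a measured or simulated flow curve from CSV.

    The file must have a header with columns ``shear_rate_per_s`` and
    ``viscosity_Pa_s`` (decimal points, no locale variants).
    """
    import pandas as pd

    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse flow-curve file {path}: {exc}") from exc
    missing = {"shear_rate_per_s", "viscosity_Pa_s"} - set(df.columns)
    if missing:
        raise ValueError(
            f"flow-curve file {path} is missing column(s) {sorted(missing)}"
        )
    return FlowCurve(df["shear_rate_per_s"].to_numpy(dtype=float),
                     df["viscosity_Pa_s"].to_numpy(dtype=float), phi_p=phi_p)
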