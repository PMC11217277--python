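"""Named ground-truth parameter presets for the synthetic benchmark.

``case1`` is the default generator: the stated constants (T = 293 K, C = 2,
S0 = 1, S_inf = 0, eta_f = 1e-3 Pa s) with a primary-particle radius of
0.5 um, giving a Peclet prefactor gamma_dot_c ~ 0.58 s so the shear-thinning
transition falls inside the simulated window log10(shear rate) in [-5, 3].

``case1_literal`` uses a = 5 nm instead (gamma_dot_c ~ 5.8e-7 s), for which
theta stays below ~6e-4 over the whole window and the flow curves are
essentially flat plateaus; it is provided for completeness.
"""

from __future__ import annotations

from .quemada import QuemadaParams

__all__ = ["get_preset", "PRESETS"]


def _case1(a: float) -> QuemadaParams:
    return QuemadaParams(S0=1.0, S_inf=0.0, C=2.0, phi_m=0.64, eta_f=1e-3,
                         a=a, T=293.0)


PRESETS: dict[str, QuemadaParams] = {
    "case1": _case1(0.5e-6),
    "case1_literal": _case1(5e-9),
    # emulsion-scale droplets (a = 1 um): gamma_dot_c ~ 4.7 s
    "emulsion": _case1(1e-6),
}


def get_preset(name: str) -> QuemadaParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
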