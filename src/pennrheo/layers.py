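"""Network layers: dense affine layers and physics-encoded activations.

The physics activations are the Quemada relations themselves, written so
that a scalar weight plays the role of a physical constant:

* ``s_activation_case1(x, w)   = 1 / (10^x * w + 1)`` — steady-state
  structural parameter with S0 = 1, S_inf = 0; ``w`` is the Peclet
  prefactor ``gamma_dot_c`` and ``x = log10(shear rate)``.
* ``s_activation_case2(x1, x2, x3, w) = (x1 + 10^x3 * w * x2) / (10^x3 * w + 1)``
  — the general steady state with plateaus S0 = x1, S_inf = x2.
* ``phi_e_activation(x1, x2, w) = x1 * (x2 * w + 1)`` — effective volume
  fraction with ``w`` the compactness factor C (x1 = phi_p, x2 = S).
* ``eta_activation(x, w, b) = -2*log10(1 - x*w) + b`` — log10 viscosity
  with ``w = 1/phi_m`` and ``b = log10(eta_f)``.

With the weights set to the generator's constants the composition is an
exact reparameterisation of the constitutive model, which is what makes a
trained network's weights physically interpretable.

Each layer implements ``forward`` (caching what backward needs) and
``backward`` (returning input gradients and accumulating parameter
gradients) — plain numpy reverse-mode differentiation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "s_activation_case1",
    "s_activation_case2",
    "phi_e_activation",
    "eta_activation",
    "ETA_GUARD",
    "Dense",
    "SLayerCase1",
    "SLayerCase2",
    "PhiELayer",
    "EtaLayer",
]

LN10 = np.log(10.0)

#: Lower guard on the log argument of the viscosity activation.  Early
#: training iterates can push ``x*w`` past 1 (an unphysical, jammed state);
#: the activation then evaluates at the guard with zero gradient instead of
#: producing NaN.
ETA_GUARD = 1e-6


def s_activation_case1(x, w):
    """``S = 1 / (10^x * w + 1)``; finite for all finite x when w >= 0."""
    return 1.0 / (10.0 ** np.asarray(x, dtype=float) * w + 1.0)


def s_activation_case2(x1, x2, x3, w):
    """``S = (x1 + 10^x3 * w * x2) / (10^x3 * w + 1)``."""
    u = 10.0 ** np.asarray(x3, dtype=float) * w
    return (np.asarray(x1, dtype=float) + u * np.asarray(x2, dtype=float)) / (u + 1.0)


def phi_e_activation(x1, x2, w):
    """``phi_e = x1 * (x2 * w + 1)``."""
    return np.asarray(x1, dtype=float) * (np.asarray(x2, dtype=float) * w + 1.0)


def eta_activation(x, w, b, guard: float = ETA_GUARD):
    """``log10 eta = -2 * log10(max(1 - x*w, guard)) + b``."""
    arg = np.maximum(1.0 - np.asarray(x, dtype=float) * w, guard)
    return -2.0 * np.log10(arg) + b


# ---------------------------------------------------------------------------
# Trainable layers (forward/backward)
# ---------------------------------------------------------------------------

class _Layer:
    """Base: ``params`` and ``grads`` are parallel lists of ndarrays."""

    params: list
    grads: list

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(_Layer):
    """Affine layer ``y = act(x W + b)`` with Glorot-uniform init.

    ``activation`` is one of ``relu``, ``linear``, ``sigmoid``.
    """

    def __init__(self, n_in: int, n_out: int, activation: str = "relu",
                 rng: np.random.Generator | None = None):
        if n_in < 1 or n_out < 1:
            raise ValueError("layer widths must be positive")
        if activation not in ("relu", "linear", "sigmoid"):
            raise ValueError(f"unknown activation {activation!r}")
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            y = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-z))
        else:
            y = z
        self._cache = (x, z, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z, y = self._cache
        if self.activation == "relu":
            dz = dy * (z > 0.0)
        elif self.activation == "sigmoid":
            dz = dy * y * (1.0 - y)
        else:
            dz = dy
        self.grads[0] += x.T @ dz
        self.grads[1] += dz.sum(axis=0)
        return dz @ self.W.T


class _PhysicsScalarLayer(_Layer):
    """Shared plumbing for layers with scalar physical weights.

    ``log_scale=True`` reparameterises each weight as ``w = 10^u`` and
    trains ``u``, useful when the physical target is orders of magnitude
    away from O(1) (e.g. the nanoparticle preset's gamma_dot_c ~ 6e-7 s).
    """

    def __init__(self, values: dict, log_scale: bool = False):
        self.log_scale = log_scale
        self.names = list(values)
        self.params = []
        for name, v in values.items():
            raw = np.log10(v) if (log_scale and name.startswith("w")) else float(v)
            self.params.append(np.array([raw], dtype=float))
        self.grads = [np.zeros(1) for _ in self.params]
        self._cache = None

    def _value(self, i: int) -> float:
        raw = float(self.params[i][0])
        if self.log_scale and self.names[i].startswith("w"):
            return 10.0 ** raw
        return raw

    def _add_grad(self, i: int, dL_dw: float) -> None:
        if self.log_scale and self.names[i].startswith("w"):
            dL_dw = dL_dw * LN10 * self._value(i)   # chain through w = 10^u
        self.grads[i][0] += dL_dw

    def get_values(self) -> dict:
        return {name: self._value(i) for i, name in enumerate(self.names)}

    def set_values(self, **kw) -> None:
        for name, v in kw.items():
            i = self.names.index(name)
            raw = np.log10(v) if (self.log_scale and name.startswith("w")) else float(v)
            self.params[i][0] = raw


class SLayerCase1(_PhysicsScalarLayer):
    """Structural-parameter layer, 1 input (log10 shear rate) -> S."""

    def __init__(self, w_S: float = 1.0, log_scale: bool = False):
        super().__init__({"w_S": w_S}, log_scale=log_scale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self._value(0)
        t = 10.0 ** x * w
        S = 1.0 / (t + 1.0)
        self._cache = (x, t, S)
        return S

    def backward(self, dS: np.ndarray) -> np.ndarray:
        x, t, S = self._cache
        w = self._value(0)
        dS_dt = -(S * S)
        self._add_grad(0, float(np.sum(dS * dS_dt * 10.0 ** x)))
        return dS * dS_dt * LN10 * t   # d/dx


class SLayerCase2(_PhysicsScalarLayer):
    """Structural layer, 3 inputs [S0_hat, Sinf_hat, log10 shear rate] -> S."""

    def __init__(self, w_S: float = 1.0, log_scale: bool = False):
        super().__init__({"w_S": w_S}, log_scale=log_scale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
        w = self._value(0)
        T = 10.0 ** x3
        u = T * w
        S = (x1 + u * x2) / (u + 1.0)
        self._cache = (x1, x2, T, u, S)
        return S[:, None]

    def backward(self, dS: np.ndarray) -> np.ndarray:
        x1, x2, T, u, S = self._cache
        dS = dS[:, 0]
        denom = u + 1.0
        dS_du = (x2 - x1) / denom**2
        self._add_grad(0, float(np.sum(dS * dS_du * T)))
        dx = np.empty((len(x1), 3))
        dx[:, 0] = dS / denom
        dx[:, 1] = dS * u / denom
        dx[:, 2] = dS * dS_du * LN10 * u
        return dx


class PhiELayer(_PhysicsScalarLayer):
    """Effective-volume-fraction layer, 2 inputs [phi_p, S] -> phi_e."""

    def __init__(self, w_C: float = 1.0, log_scale: bool = False):
        super().__init__({"w_C": w_C}, log_scale=log_scale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x1, x2 = x[:, 0], x[:, 1]
        w = self._value(0)
        self._cache = (x1, x2)
        return (x1 * (x2 * w + 1.0))[:, None]

    def backward(self, dphi: np.ndarray) -> np.ndarray:
        x1, x2 = self._cache
        w = self._value(0)
        dphi = dphi[:, 0]
        self._add_grad(0, float(np.sum(dphi * x1 * x2)))
        dx = np.empty((len(x1), 2))
        dx[:, 0] = dphi * (x2 * w + 1.0)
        dx[:, 1] = dphi * x1 * w
        return dx


class EtaLayer(_PhysicsScalarLayer):
    """Viscosity layer, 1 input (phi_e) -> log10 eta.

    The log argument is clipped at ``ETA_GUARD``; inside the clipped
    (jammed) region the gradient is zero, so the optimizer is pushed back
    only by batch members still on the physical branch.
    """

    def __init__(self, w_m: float = 1.0, b_f: float = 0.0, log_scale: bool = False):
        super().__init__({"w_m": w_m, "b_f": b_f}, log_scale=log_scale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self._value(0)
        b = self._value(1)
        raw = 1.0 - x * w
        clipped = raw < ETA_GUARD
        arg = np.where(clipped, ETA_GUARD, raw)
        self._cache = (x, arg, clipped)
        return -2.0 * np.log10(arg) + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, arg, clipped = self._cache
        w = self._value(0)
        live = ~clipped
        dy_darg = np.where(live, -2.0 / (LN10 * arg), 0.0)
        self._add_grad(0, float(np.sum(dy * dy_darg * (-x))))
        self._add_grad(1, float(np.sum(dy)))
        return dy * dy_darg * (-w)
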