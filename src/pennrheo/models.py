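"""Model architectures: baseline dense regressors and physics-encoded stacks.

Two families are built here:

* ``DenseNetSpec`` — plain multilayer perceptrons (ReLU hidden layers,
  linear scalar output) mapping the log-space inputs straight to
  log10(viscosity).  Signatures like ``"2-32-8-1"`` read input width,
  hidden widths, output width.
* ``PeNNSpec`` — physics-encoded networks whose final three layers *are*
  the constitutive relations (structure parameter, effective volume
  fraction, viscosity) with four trainable physical scalars
  ``w_S ~ gamma_dot_c``, ``w_C ~ C``, ``w_m ~ 1/phi_m``,
  ``b_f ~ log10(eta_f)``.  The case-1 stack (signature ``2-1-1-1``) is
  pure physics; the case-2 stack (``4-6-2-1-1-1``) prepends a small dense
  surrogate whose two outputs stand in for the structural plateaus
  S0 and S_inf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

from .layers import Dense, EtaLayer, PhiELayer, SLayerCase1, SLayerCase2
from .quemada import QuemadaParams

__all__ = [
    "DenseNetSpec",
    "PeNNSpec",
    "PhysicsParams",
    "build_model",
    "parse_signature",
    "set_physics_params",
    "extract_physics_params",
]


def parse_signature(sig: str):
    """Parse an architecture signature string like ``"2-32-8-1"``."""
    try:
        widths = [int(tok) for tok in sig.split("-")]
    except ValueError:
        raise ValueError(f"malformed architecture signature {sig!r}") from None
    if len(widths) < 2 or any(w < 1 for w in widths):
        raise ValueError(f"malformed architecture signature {sig!r}")
    return widths


@dataclass(frozen=True)
class DenseNetSpec:
    """Plain dense regressor: ReLU hidden layers, linear scalar output."""

    input_width: int
    hidden_widths: tuple
    output_width: int = 1
    hidden_activation: str = "relu"

    def __post_init__(self):
        if self.output_width != 1:
            raise ValueError("regression head must have output width 1")
        if self.input_width < 1 or any(w < 1 for w in self.hidden_widths):
            raise ValueError("widths must be positive")

    @classmethod
    def from_signature(cls, sig: str) -> "DenseNetSpec":
        w = parse_signature(sig)
        return cls(input_width=w[0], hidden_widths=tuple(w[1:-1]), output_width=w[-1])

    @property
    def signature(self) -> str:
        return "-".join(map(str, (self.input_width, *self.hidden_widths,
                                  self.output_width)))


@dataclass(frozen=True)
class PeNNSpec:
    """Physics-encoded stack for case 1 (``2-1-1-1``) or case 2 (``4-6-2-1-1-1``).

    ``surrogate_activation`` is the activation of the 2-unit surrogate
    output layer (``sigmoid`` keeps the plateau estimates in (0,1);
    ``relu`` is the blanket-rule variant).  ``surrogate_inputs`` routes
    either all four raw inputs (``"all"``, the default, matching the
    4-6-2 dense stack) or only the formulation surrogates
    (``"p_only"``, a 2-6-2 stack in which phi_p and the shear rate bypass
    the dense path entirely).  ``log_scale_weights`` trains physical
    scalars as ``w = 10^u`` for badly scaled targets.
    """

    case: str = "case1"
    surrogate_widths: tuple = (6, 2)
    surrogate_activation: str = "sigmoid"
    surrogate_inputs: str = "all"
    log_scale_weights: bool = False
    init: dict = field(default_factory=lambda: {"w_S": 1.0, "w_C": 1.0,
                                                "w_m": 1.0, "b_f": 0.0})

    def __post_init__(self):
        if self.case not in ("case1", "case2"):
            raise ValueError(f"case must be 'case1' or 'case2', got {self.case!r}")
        if self.surrogate_inputs not in ("all", "p_only"):
            raise ValueError("surrogate_inputs must be 'all' or 'p_only'")
        if self.case == "case2" and self.surrogate_widths[-1] != 2:
            raise ValueError("case-2 surrogate must end in 2 units (S0, S_inf)")

    @property
    def input_width(self) -> int:
        return 2 if self.case == "case1" else 4

    @property
    def signature(self) -> str:
        if self.case == "case1":
            return "2-1-1-1"
        return "-".join(map(str, (4, *self.surrogate_widths, 1, 1, 1)))


@dataclass(frozen=True)
class PhysicsParams:
    """The four trainable physical scalars of a PeNN and their meanings."""

    w_S: float   # ~ gamma_dot_c (s)
    w_C: float   # ~ C
    w_m: float   # ~ 1/phi_m
    b_f: float   # ~ log10(eta_f)

    def as_quemada(self, S0: float = 1.0, S_inf: float = 0.0) -> QuemadaParams:
        return QuemadaParams(S0=S0, S_inf=S_inf, C=self.w_C, phi_m=1.0 / self.w_m,
                             eta_f=10.0 ** self.b_f, gamma_dot_c=self.w_S)


class _Network:
    """Common interface: params/grads lists, forward(X)->(n,), backward."""

    spec: DenseNetSpec | PeNNSpec
    layers: list

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.spec.input_width:
            raise ValueError(
                f"model expects {self.spec.input_width} input columns, "
                f"got {X.shape[1]}"
            )
        return self.forward(X)

    def get_weights(self) -> list:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def state_dict(self) -> dict:
        return {
            "signature": self.spec.signature,
            "kind": type(self).__name__,
            "weights": [p.tolist() for p in self.params],
        }


class DenseNet(_Network):
    """Baseline multilayer perceptron in log space."""

    def __init__(self, spec: DenseNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = [spec.input_width, *spec.hidden_widths, spec.output_width]
        self.layers = []
        for i in range(len(widths) - 1):
            act = spec.hidden_activation if i < len(widths) - 2 else "linear"
            self.layers.append(Dense(widths[i], widths[i + 1], act, rng))

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = X
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = dy[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class PeNNCase1(_Network):
    """Pure physics stack: inputs (log10 shear rate, phi_p) -> log10 eta."""

    def __init__(self, spec: PeNNSpec, seed: int = 0):
        if spec.case != "case1":
            raise ValueError("PeNNCase1 requires a case1 spec")
        self.spec = spec
        ls = spec.log_scale_weights
        self.s_layer = SLayerCase1(spec.init["w_S"], log_scale=ls)
        self.phi_layer = PhiELayer(spec.init["w_C"], log_scale=ls)
        self.eta_layer = EtaLayer(spec.init["w_m"], spec.init["b_f"], log_scale=ls)
        self.layers = [self.s_layer, self.phi_layer, self.eta_layer]

    def forward(self, X: np.ndarray) -> np.ndarray:
        log_g, phi_p = X[:, 0], X[:, 1]
        S = self.s_layer.forward(log_g)
        phi_e = self.phi_layer.forward(np.column_stack([phi_p, S]))
        return self.eta_layer.forward(phi_e[:, 0])

    def backward(self, dy: np.ndarray) -> None:
        dphi_e = self.eta_layer.backward(dy)
        dx_phi = self.phi_layer.backward(dphi_e[:, None])
        self.s_layer.backward(dx_phi[:, 1])


class PeNNCase2(_Network):
    """Dense surrogate for (S0, S_inf) feeding the physics stack.

    Inputs are (log10 shear rate, phi_p, p1, p2).  The surrogate sees all
    four inputs (routing ``"all"``) or only (p1, p2) (``"p_only"``); its
    two outputs enter the three-input structural layer together with the
    raw log10 shear rate, and phi_p bypasses straight to the effective
    volume-fraction layer.
    """

    def __init__(self, spec: PeNNSpec, seed: int = 0):
        if spec.case != "case2":
            raise ValueError("PeNNCase2 requires a case2 spec")
        self.spec = spec
        rng = np.random.default_rng(seed)
        n_in = 4 if spec.surrogate_inputs == "all" else 2
        widths = [n_in, *spec.surrogate_widths]
        self.dense_layers = []
        for i in range(len(widths) - 1):
            act = "relu" if i < len(widths) - 2 else spec.surrogate_activation
            self.dense_layers.append(Dense(widths[i], widths[i + 1], act, rng))
        ls = spec.log_scale_weights
        self.s_layer = SLayerCase2(spec.init["w_S"], log_scale=ls)
        self.phi_layer = PhiELayer(spec.init["w_C"], log_scale=ls)
        self.eta_layer = EtaLayer(spec.init["w_m"], spec.init["b_f"], log_scale=ls)
        self.layers = [*self.dense_layers, self.s_layer, self.phi_layer,
                       self.eta_layer]

    def _surrogate_input(self, X: np.ndarray) -> np.ndarray:
        return X if self.spec.surrogate_inputs == "all" else X[:, 2:4]

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = self._surrogate_input(X)
        for layer in self.dense_layers:
            h = layer.forward(h)
        S = self.s_layer.forward(np.column_stack([h[:, 0], h[:, 1], X[:, 0]]))
        phi_e = self.phi_layer.forward(np.column_stack([X[:, 1], S[:, 0]]))
        return self.eta_layer.forward(phi_e[:, 0])

    def backward(self, dy: np.ndarray) -> None:
        dphi_e = self.eta_layer.backward(dy)
        dx_phi = self.phi_layer.backward(dphi_e[:, None])
        dx_s = self.s_layer.backward(dx_phi[:, 1][:, None])
        g = dx_s[:, 0:2]
        for layer in reversed(self.dense_layers):
            g = layer.backward(g)

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d(output)/d(inputs) per row, for routing diagnostics."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = self._surrogate_input(X)
        for layer in self.dense_layers:
            h = layer.forward(h)
        S = self.s_layer.forward(np.column_stack([h[:, 0], h[:, 1], X[:, 0]]))
        phi_e = self.phi_layer.forward(np.column_stack([X[:, 1], S[:, 0]]))
        self.eta_layer.forward(phi_e[:, 0])
        dphi_e = self.eta_layer.backward(np.ones(len(X)))
        dx_phi = self.phi_layer.backward(dphi_e[:, None])
        dx_s = self.s_layer.backward(dx_phi[:, 1][:, None])
        g = dx_s[:, 0:2]
        for layer in reversed(self.dense_layers):
            g = layer.backward(g)
        grad = np.zeros_like(X)
        grad[:, 0] += dx_s[:, 2]            # shear rate into the S layer
        grad[:, 1] += dx_phi[:, 0]          # phi_p into the phi_e layer
        if self.spec.surrogate_inputs == "all":
            grad += g
        else:
            grad[:, 2:4] += g
        return grad


def build_model(spec: DenseNetSpec | PeNNSpec, seed: int = 0) -> _Network:
    """Instantiate a differentiable model from its spec, seeded."""
    if isinstance(spec, DenseNetSpec):
        return DenseNet(spec, seed)
    if isinstance(spec, PeNNSpec):
        return PeNNCase1(spec, seed) if spec.case == "case1" else PeNNCase2(spec, seed)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def _require_penn(model) -> None:
    if not isinstance(model, (PeNNCase1, PeNNCase2)):
        raise TypeError(
            f"{type(model).__name__} is not a physics-encoded network"
        )


def set_physics_params(model, params: QuemadaParams):
    """Inject ground-truth physical constants into a PeNN's scalar weights.

    Afterwards a case-1 PeNN is pointwise identical to the generator
    (the activations are exact reparameterisations of the constitutive
    relations).
    """
    _require_penn(model)
    model.s_layer.set_values(w_S=params.gamma_dot_c)
    model.phi_layer.set_values(w_C=params.C)
    model.eta_layer.set_values(w_m=1.0 / params.phi_m,
                               b_f=float(np.log10(params.eta_f)))
    return model


def extract_physics_params(model) -> PhysicsParams:
    """Read the current physical scalars out of a PeNN."""
    _require_penn(model)
    return PhysicsParams(
        w_S=model.s_layer.get_values()["w_S"],
        w_C=model.phi_layer.get_values()["w_C"],
        w_m=model.eta_layer.get_values()["w_m"],
        b_f=model.eta_layer.get_values()["b_f"],
    )


def save_model(model: _Network, path) -> None:
    state = model.state_dict()
    if isinstance(model, (PeNNCase1, PeNNCase2)):
        pp = extract_physics_params(model)
        state["physics_params"] = {"w_S": pp.w_S, "w_C": pp.w_C,
                                   "w_m": pp.w_m, "b_f": pp.b_f}
        state["spec"] = {
            "case": model.spec.case,
            "surrogate_widths": list(model.spec.surrogate_widths),
            "surrogate_activation": model.spec.surrogate_activation,
            "surrogate_inputs": model.spec.surrogate_inputs,
            "log_scale_weights": model.spec.log_scale_weights,
        }
    with open(path, "w") as fh:
        json.dump(state, fh, indent=1)


def load_model(path) -> _Network:
    with open(path) as fh:
        state = json.load(fh)
    if state["kind"] == "DenseNet":
        model = DenseNet(DenseNetSpec.from_signature(state["signature"]))
    else:
        s = state["spec"]
        spec = PeNNSpec(case=s["case"],
                        surrogate_widths=tuple(s["surrogate_widths"]),
                        surrogate_activation=s["surrogate_activation"],
                        surrogate_inputs=s["surrogate_inputs"],
                        log_scale_weights=s["log_scale_weights"])
        model = build_model(spec)
    model.set_weights([np.asarray(w, dtype=float) for w in state["weights"]])
    return model
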