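"""Synthetic flow-curve datasets for the viscosity-regression benchmark.

Datasets live in log space: inputs are ``log10(shear rate)`` and the
primary-particle volume fraction ``phi_p`` (case 1), plus two formulation
surrogates ``p1, p2`` in [0, 1] (case 2) that set the structural plateaus
via ``S0 = p1`` and ``S_inf = p1 * p2`` (an ordering-safe mapping:
S_inf <= S0 for every point of the unit square).  Targets are
``log10(viscosity)``.

Grid datasets emulate a rheometer campaign: for each of ``n_phi``
equispaced volume-fraction levels, ``N_shear`` equispaced points of
log10(shear rate) (many rates per sample, few samples).  Rows are split
75/25 into train/holdout by a seeded permutation.  The separate random
*test* set draws all inputs uniformly, so it contains volume fractions
never seen on the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .quemada import JammingError, QuemadaParams, flow_curve
from .presets import get_preset

__all__ = [
    "DatasetSpec",
    "Dataset",
    "generate_dataset",
    "split_train_holdout",
    "sample_test_set",
    "write_dataset",
    "read_dataset",
    "p_to_structure",
]

logger = logging.getLogger(__name__)

CASE1_COLUMNS = ["log10_shear_rate", "phi_p"]
CASE2_COLUMNS = ["log10_shear_rate", "phi_p", "p1", "p2"]
TARGET_COLUMN = "log10_viscosity"


def p_to_structure(p1, p2):
    """Map the formulation surrogates to structural plateaus.

    ``S0 = p1`` and ``S_inf = p1 * p2`` keeps both plateaus in [0, 1] and
    guarantees ``S_inf <= S0`` for every (p1, p2) in the unit square.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return p1, p1 * p2


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for one grid dataset (provenance object, fully deterministic)."""

    case: str = "case1"
    n_phi: int = 3
    N_shear: int = 300
    phi_range: tuple = (0.01, 0.2)
    log_shear_range: tuple = (-5.0, 3.0)
    p1_levels: tuple = (0.25, 0.75)
    p2_levels: tuple = (0.25, 0.75)
    params: QuemadaParams = field(default_factory=lambda: get_preset("case1"))
    holdout_fraction: float = 0.25
    val_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case not in ("case1", "case2"):
            raise ValueError(f"case must be 'case1' or 'case2', got {self.case!r}")
        if self.n_phi < 1 or self.N_shear < 1:
            raise ValueError("n_phi and N_shear must be >= 1")
        if not (self.phi_range[0] <= self.phi_range[1]
                and self.log_shear_range[0] <= self.log_shear_range[1]):
            raise ValueError("ranges must be ordered (lo <= hi)")
        for f in (self.holdout_fraction, self.val_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError(f"fractions must lie in (0, 1), got {f}")

    @property
    def n_rows(self) -> int:
        n = self.n_phi * self.N_shear
        if self.case == "case2":
            n *= len(self.p1_levels) * len(self.p2_levels)
        return n

    @property
    def input_columns(self) -> list:
        return CASE1_COLUMNS if self.case == "case1" else CASE2_COLUMNS

    def replace(self, **kw) -> "DatasetSpec":
        return replace(self, **kw)


@dataclass
class Dataset:
    """Input/target table in log space with split membership and provenance."""

    frame: pd.DataFrame
    spec: DatasetSpec | None = None

    @property
    def input_columns(self) -> list:
        return CASE2_COLUMNS if "p1" in self.frame.columns else CASE1_COLUMNS

    @property
    def inputs(self) -> np.ndarray:
        return self.frame[self.input_columns].to_numpy(dtype=float)

    @property
    def targets(self) -> np.ndarray:
        return self.frame[TARGET_COLUMN].to_numpy(dtype=float)

    @property
    def split_labels(self) -> np.ndarray:
        return self.frame["split"].to_numpy()

    def partition(self, label: str) -> "Dataset":
        sub = self.frame[self.frame["split"] == label].reset_index(drop=True)
        return Dataset(sub, spec=self.spec)

    def __len__(self) -> int:
        return len(self.frame)


def split_train_holdout(n_rows: int, holdout_fraction: float, seed: int) -> np.ndarray:
    """Seeded random train/holdout labels.

    Exactly ``round(holdout_fraction * n_rows)`` rows (round half away from
    zero) are labelled ``holdout``; the permutation is drawn from
    ``numpy.random.default_rng(seed)``, so identical seeds give identical
    labels.
    """
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError(f"holdout_fraction must lie in (0, 1), got {holdout_fraction}")
    if n_rows < 2:
        raise ValueError("need at least 2 rows to split")
    n_holdout = int(np.floor(holdout_fraction * n_rows + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    labels = np.full(n_rows, "train", dtype=object)
    labels[perm[:n_holdout]] = "holdout"
    return labels


def _evaluate_targets(inputs: np.ndarray, case: str, params: QuemadaParams) -> np.ndarray:
    """log10 viscosity for each input row via the constitutive model."""
    log_g = inputs[:, 0]
    phi_p = inputs[:, 1]
    out = np.empty(len(inputs))
    if case == "case1":
        keys = [(None, None)] * len(inputs)
    else:
        keys = list(zip(inputs[:, 2], inputs[:, 3]))
    for i in range(len(inputs)):
        p = params
        if case == "case2":
            S0, S_inf = p_to_structure(keys[i][0], keys[i][1])
            p = params.replace(S0=float(S0), S_inf=float(S_inf))
        try:
            fc = flow_curve([10.0 ** log_g[i]], phi_p[i], p)
        except JammingError as exc:
            raise JammingError(
                f"jamming at grid point log10_shear_rate={log_g[i]}, "
                f"phi_p={phi_p[i]}: {exc}"
            ) from exc
        out[i] = np.log10(fc.viscosities[0])
    return out


def _evaluate_targets_fast(inputs: np.ndarray, case: str, params: QuemadaParams) -> np.ndarray:
    """Vectorised equivalent of :func:`_evaluate_targets` (checked against it in tests)."""
    log_g = inputs[:, 0]
    g = 10.0 ** log_g
    theta = params.gamma_dot_c * g
    if case == "case1":
        S0 = np.full(len(inputs), params.S0)
        S_inf = np.full(len(inputs), params.S_inf)
    else:
        S0, S_inf = p_to_structure(inputs[:, 2], inputs[:, 3])
    S = (S0 + theta * S_inf) / (1.0 + theta)
    phi_e = inputs[:, 1] * (1.0 + params.C * S)
    if np.any(phi_e >= params.phi_m):
        bad = int(np.argmax(phi_e >= params.phi_m))
        raise JammingError(
            f"jamming at grid point log10_shear_rate={log_g[bad]}, "
            f"phi_p={inputs[bad, 1]}: phi_e={phi_e[bad]:.4g} >= phi_m={params.phi_m}"
        )
    return np.log10(params.eta_f) - 2.0 * np.log10(1.0 - phi_e / params.phi_m)


def generate_dataset(spec: DatasetSpec) -> Dataset:
    """Build the grid dataset described by ``spec``.

    The grid itself is seed-free (equispaced levels including endpoints);
    only the train/holdout split uses ``spec.seed``.
    """
    phi_levels = np.linspace(*spec.phi_range, spec.n_phi)
    log_g = np.linspace(*spec.log_shear_range, spec.N_shear)

    if spec.case == "case1":
        mesh = np.array(np.meshgrid(log_g, phi_levels, indexing="ij"))
        inputs = mesh.reshape(2, -1).T
        cols = CASE1_COLUMNS
    else:
        mesh = np.array(np.meshgrid(log_g, phi_levels, np.asarray(spec.p1_levels),
                                    np.asarray(spec.p2_levels), indexing="ij"))
        inputs = mesh.reshape(4, -1).T
        cols = CASE2_COLUMNS

    targets = _evaluate_targets_fast(inputs, spec.case, spec.params)
    labels = split_train_holdout(len(inputs), spec.holdout_fraction, spec.seed)

    frame = pd.DataFrame(inputs, columns=cols)
    frame[TARGET_COLUMN] = targets
    frame["split"] = labels
    return Dataset(frame, spec=spec)


def sample_test_set(
    n_tst: int,
    phi_range: tuple = (0.01, 0.2),
    log_shear_range: tuple = (-5.0, 3.0),
    case: str = "case1",
    params: QuemadaParams | None = None,
    seed: int = 0,
    p1_levels: Sequence[float] = (0.25, 0.75),
    p2_levels: Sequence[float] = (0.25, 0.75),
    p_sampling: str = "levels",
) -> Dataset:
    """Random test set: (phi_p, log10 shear rate) uniform over the stated ranges.

    The test set probes generalization to volume fractions never seen on
    the grid.  For case 2 the formulation surrogates are by default drawn
    from the trained formulation levels (``p_sampling="levels"``) — new
    volume fractions of known formulations, the way a rheology campaign
    revisits its samples; ``p_sampling="uniform"`` draws p1, p2 uniformly
    over [0, 1] instead, additionally probing unseen formulations.

    Jamming is excluded up front at the worst case (phi_p at its upper
    bound, zero shear, S0 at its maximum) so sampling cannot fail midway.
    """
    if p_sampling not in ("levels", "uniform"):
        raise ValueError("p_sampling must be 'levels' or 'uniform'")
    if params is None:
        params = get_preset("case1")
    S0_max = params.S0 if case == "case1" else 1.0
    worst_phi_e = phi_range[1] * (1.0 + params.C * S0_max)
    if worst_phi_e >= params.phi_m:
        raise JammingError(
            f"phi_p up to {phi_range[1]} can jam: worst-case phi_e="
            f"{worst_phi_e:.4g} >= phi_m={params.phi_m}"
        )
    rng = np.random.default_rng(seed)
    log_g = rng.uniform(*log_shear_range, n_tst)
    phi_p = rng.uniform(*phi_range, n_tst)
    if case == "case1":
        inputs = np.column_stack([log_g, phi_p])
        cols = CASE1_COLUMNS
    else:
        if p_sampling == "levels":
            p1 = rng.choice(np.asarray(p1_levels, dtype=float), n_tst)
            p2 = rng.choice(np.asarray(p2_levels, dtype=float), n_tst)
        else:
            p1 = rng.uniform(0.0, 1.0, n_tst)
            p2 = rng.uniform(0.0, 1.0, n_tst)
        inputs = np.column_stack([log_g, phi_p, p1, p2])
        cols = CASE2_COLUMNS
    frame = pd.DataFrame(inputs, columns=cols)
    frame[TARGET_COLUMN] = (
        _evaluate_targets_fast(inputs, case, params) if n_tst else np.empty(0)
    )
    frame["split"] = "test"
    return Dataset(frame, spec=None)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as CSV with a ``#``-prefixed provenance header line."""
    with open(path, "w") as fh:
        if dataset.spec is not None:
            s = dataset.spec
            fh.write(
                f"# pennrheo dataset case={s.case} n_phi={s.n_phi} "
                f"N_shear={s.N_shear} seed={s.seed}\n"
            )
        else:
            fh.write("# pennrheo dataset\n")
        dataset.frame.to_csv(fh, index=False, float_format="%.17g")


def read_dataset(path) -> Dataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    Unknown columns are ignored with a logged warning; a missing required
    column raises a parse error naming it.
    """
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse dataset file {path}: {exc}") from exc
    required = set(CASE1_COLUMNS) | {TARGET_COLUMN, "split"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(
            f"dataset file {path} is missing required column(s) {sorted(missing)} "
            f"(line 2, header row)"
        )
    known = set(CASE2_COLUMNS) | {TARGET_COLUMN, "split"}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown dataset columns %s in %s", extra, path)
        frame = frame.drop(columns=extra)
    order = [c for c in CASE2_COLUMNS if c in frame.columns] + [TARGET_COLUMN, "split"]
    return Dataset(frame[order], spec=None)
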