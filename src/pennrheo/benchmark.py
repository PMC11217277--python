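"""Model comparison across the dataset grid with nonparametric statistics.

The benchmark trains every model on every grid cell (``n_phi`` volume
fraction levels x ``N_shear`` rates per level), evaluates each trained
model on one shared random test set, and compares models across cells
with a Friedman rank test (blocks = datasets, treatments = models)
followed by pairwise two-sided Wilcoxon signed-rank tests on the test-set
mse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import DatasetSpec, sample_test_set
from .models import PeNNSpec
from .training import TrainConfig, ViscosityNetwork, evaluate

__all__ = [
    "DEFAULT_GRID",
    "run_grid",
    "friedman_test",
    "wilcoxon_pairwise",
    "mse_ratio_summary",
    "ComparisonReport",
    "compare_models",
    "plot_benchmark",
]

DEFAULT_GRID = tuple((n, N) for n in (3, 5, 7) for N in (20, 50, 100, 300, 500))


def _model_id(spec) -> str:
    prefix = "PeNN" if isinstance(spec, PeNNSpec) else "NN"
    return f"{prefix} {spec.signature}"


def run_grid(
    model_specs: list,
    grid=DEFAULT_GRID,
    case: str = "case2",
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    n_test: int = 10_000,
    base_spec: DatasetSpec | None = None,
    existing: pd.DataFrame | None = None,
    penn_config: TrainConfig | None = None,
    progress=None,
) -> pd.DataFrame:
    """Train every model on every grid cell; evaluate on a shared test set.

    Returns a table with one row per (dataset, model): columns
    ``dataset_id, n_phi, N_shear, model_id, mse, r_squared, seed, failed``.
    Pass a previously returned table as ``existing`` to resume: completed
    rows are kept, only missing (dataset, model) pairs are run.  A
    training abort marks the row ``failed`` and the sweep continues.

    ``penn_config`` optionally overrides ``config`` for physics-encoded
    models — typically to give them validation-selected restarts
    (``n_restarts``), since their loss surface is multimodal while the
    dense baselines' is effectively not at these sizes.
    """
    if not grid or not model_specs:
        raise ValueError("grid and model_specs must be non-empty")
    base = base_spec or DatasetSpec(case=case)
    ss = np.random.SeedSequence(seed)
    test_seed, *cell_seeds = [int(s) for s in ss.generate_state(1 + len(grid)) >> 1]
    test_set = sample_test_set(n_test, case=case, params=base.params,
                               seed=test_seed, p1_levels=base.p1_levels,
                               p2_levels=base.p2_levels)

    done = set()
    rows = []
    if existing is not None:
        rows = existing.to_dict("records")
        done = {(r["dataset_id"], r["model_id"]) for r in rows if not r["failed"]}

    for (n_phi, N_shear), cell_seed in zip(grid, cell_seeds):
        dataset_id = f"n{n_phi}-N{N_shear}"
        spec = base.replace(n_phi=n_phi, N_shear=N_shear, seed=cell_seed)
        dataset = None
        for mspec in model_specs:
            model_id = _model_id(mspec)
            if (dataset_id, model_id) in done:
                continue
            if dataset is None:
                from .data import generate_dataset
                dataset = generate_dataset(spec)
            row = {"dataset_id": dataset_id, "n_phi": n_phi, "N_shear": N_shear,
                   "model_id": model_id, "mse": np.nan, "r_squared": np.nan,
                   "seed": cell_seed, "failed": False}
            try:
                cfg = (penn_config if (penn_config is not None
                                       and isinstance(mspec, PeNNSpec))
                       else config)
                res = ViscosityNetwork(dataset, mspec, seed=cell_seed).fit(
                    cfg.replace(seed=cell_seed))
                m = evaluate(res.model, test_set)
                row["mse"] = m["mse"]
                row["r_squared"] = m["r_squared"]
            except (FloatingPointError, ValueError) as exc:
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
            if progress is not None:
                progress(row)
    table = pd.DataFrame(rows)
    return table.sort_values(["n_phi", "N_shear", "model_id"]).reset_index(drop=True)


def _metric_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a benchmark table to blocks (datasets) x treatments (models)."""
    ok = table[~table["failed"]]
    return ok.pivot(index="dataset_id", columns="model_id", values="mse")


def friedman_test(metric_matrix) -> tuple:
    """Friedman rank test over blocks x treatments.

    Within each block the treatments are ranked (lower metric = rank 1,
    midranks on ties); the statistic is
    ``12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)`` with ``R_j`` the rank
    sums, referred to a chi-square with ``k - 1`` degrees of freedom.
    A matrix with every block constant yields statistic 0, p = 1.
    """
    M = np.asarray(metric_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    n, k = M.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, M)
    R = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * float(np.sum(R**2)) - 3.0 * n * (k + 1)
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    return float(statistic), p


def wilcoxon_pairwise(metric_matrix) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank p for every unordered treatment pair.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 remaining pairs, else the normal approximation with
    continuity correction.  All-zero differences give p = 1 (degenerate
    pair, no evidence of difference).
    """
    if isinstance(metric_matrix, pd.DataFrame):
        cols = list(metric_matrix.columns)
        M = metric_matrix.to_numpy(dtype=float)
    else:
        M = np.asarray(metric_matrix, dtype=float)
        cols = list(range(M.shape[1]))
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 paired observations and >= 2 treatments")
    out = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for i, j in combinations(range(len(cols)), 2):
        d = M[:, i] - M[:, j]
        nz = d[d != 0.0]
        if len(nz) == 0:
            p = 1.0
        else:
            method = "exact" if len(nz) <= 25 else "approx"
            p = float(stats.wilcoxon(nz, alternative="two-sided",
                                     correction=True, method=method).pvalue)
        out.iloc[i, j] = out.iloc[j, i] = p
    return out


def mse_ratio_summary(table: pd.DataFrame, baseline_models: list,
                      penn_model: str) -> pd.DataFrame:
    """Per-baseline min/median/max of (baseline mse) / (PeNN mse) across cells."""
    M = _metric_matrix(table)
    wanted = [*baseline_models, penn_model]
    missing = [m for m in wanted if m not in M.columns or M[m].isna().any()]
    if missing:
        raise ValueError(f"benchmark table incomplete for model(s): {missing}")
    rows = []
    for b in baseline_models:
        ratio = M[b] / M[penn_model]
        rows.append({"baseline": b, "min": float(ratio.min()),
                     "median": float(ratio.median()), "max": float(ratio.max())})
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Friedman + pairwise Wilcoxon results over one benchmark table."""

    friedman_statistic: float
    friedman_p: float
    wilcoxon_p: pd.DataFrame
    ratio_summary: pd.DataFrame | None
    n_blocks: int
    model_ids: list

    def to_dict(self) -> dict:
        return {
            "friedman_statistic": self.friedman_statistic,
            "friedman_p": self.friedman_p,
            "wilcoxon_p": {f"{a} vs {b}": float(self.wilcoxon_p.loc[a, b])
                           for a, b in combinations(self.model_ids, 2)},
            "ratio_summary": (None if self.ratio_summary is None
                              else self.ratio_summary.to_dict("records")),
            "n_blocks": self.n_blocks,
            "models": self.model_ids,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary(self) -> str:
        lines = [
            f"Model comparison over {self.n_blocks} datasets x "
            f"{len(self.model_ids)} models",
            f"  Friedman chi-square = {self.friedman_statistic:.4g}, "
            f"p = {self.friedman_p:.3g}",
            "  pairwise Wilcoxon signed-rank (two-sided):",
        ]
        for a, b in combinations(self.model_ids, 2):
            lines.append(f"    {a} vs {b}: p = {float(self.wilcoxon_p.loc[a, b]):.4g}")
        if self.ratio_summary is not None:
            lines.append("  mse ratio (baseline / PeNN) across datasets:")
            for _, r in self.ratio_summary.iterrows():
                lines.append(f"    {r['baseline']}: min {r['min']:.3g}, "
                             f"median {r['median']:.3g}, max {r['max']:.3g}")
        return "\n".join(lines)


def compare_models(table: pd.DataFrame, penn_model: str | None = None) -> ComparisonReport:
    """Build the full comparison report from a benchmark table."""
    M = _metric_matrix(table).sort_index()
    stat, p = friedman_test(M)
    wp = wilcoxon_pairwise(M)
    ratios = None
    if penn_model is None:
        penns = [c for c in M.columns if c.startswith("PeNN")]
        penn_model = penns[0] if penns else None
    if penn_model is not None:
        baselines = [c for c in M.columns if c != penn_model]
        ratios = mse_ratio_summary(table, baselines, penn_model)
    return ComparisonReport(friedman_statistic=stat, friedman_p=p, wilcoxon_p=wp,
                            ratio_summary=ratios, n_blocks=M.shape[0],
                            model_ids=list(M.columns))


def plot_benchmark(table: pd.DataFrame, path=None):
    """Grouped log-scale bar chart of test-set mse per grid cell and model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = _metric_matrix(table)
    order = (table[~table["failed"]]
             .drop_duplicates("dataset_id")
             .sort_values(["n_phi", "N_shear"])["dataset_id"].tolist())
    M = M.loc[order]
    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(M))
    width = 0.8 / len(M.columns)
    for i, col in enumerate(M.columns):
        ax.bar(x + i * width, M[col], width, label=col)
    ax.set_yscale("log")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(M.index, rotation=45, ha="right")
    ax.set_ylabel("test-set mse (log10 viscosity)")
    ax.set_xlabel("dataset (n volume-fraction levels, N rates)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
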