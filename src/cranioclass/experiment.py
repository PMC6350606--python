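"""The learning-rate x momentum grid experiment.

Runs the boosted network over the 3x3 hyperparameter grid
eta, alpha in {0.1, 0.5, 0.9}, repeating each cell with fresh stratified
70/30 splits (training-only min-max normalization), and tabulates
training/testing accuracy and MSE per cell — the protocol used to pick
the operating point and to compare the [6; 6; 2] and [6; 12; 2]
architectures. Every repeat is deterministic under the master seed and
failed repeats are recorded with their cause, never dropped silently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import data as dm
from .boost import EnsembleModel, ensemble_labels, ensemble_outputs, train_adaboost
from .data import MeasurementDataset, one_hot
from .errors import CranioError, DataFormatError
from .network import NetworkConfig, compute_mse

GRID_ETAS: tuple[float, ...] = (0.1, 0.5, 0.9)
GRID_ALPHAS: tuple[float, ...] = (0.1, 0.5, 0.9)

#: Default architectures under comparison.
NARROW = (6, 6, 2)
WIDE = (6, 12, 2)


@dataclass(frozen=True)
class RepeatResult:
    """One (cell, repeat) outcome; ``error`` is set when the run failed."""

    train_acc: float = float("nan")
    train_mse: float = float("nan")
    test_acc: float = float("nan")
    test_mse: float = float("nan")
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class GridReport:
    """All repeats of the 3x3 grid for one architecture."""

    architecture: tuple[int, int, int]
    repeats: int
    master_seed: int
    cells: dict[tuple[float, float], list[RepeatResult]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for eta in GRID_ETAS:
            for alpha in GRID_ALPHAS:
                self.cells.setdefault((eta, alpha), [])

    def summary(self) -> pd.DataFrame:
        """Per-cell means and maxima over the successful repeats."""
        rows = []
        for (eta, alpha), results in self.cells.items():
            ok = [r for r in results if r.ok]
            def agg(fn, attr):
                return fn([getattr(r, attr) for r in ok]) if ok else float("nan")
            rows.append({
                "eta": eta, "alpha": alpha,
                "mean_train_acc": agg(np.mean, "train_acc"),
                "best_train_acc": agg(np.max, "train_acc"),
                "mean_train_mse": agg(np.mean, "train_mse"),
                "mean_test_acc": agg(np.mean, "test_acc"),
                "best_test_acc": agg(np.max, "test_acc"),
                "mean_test_mse": agg(np.mean, "test_mse"),
                "n_ok": len(ok), "n_failed": len(results) - len(ok),
            })
        return pd.DataFrame(rows)

    @property
    def best_cell(self) -> tuple[float, float]:
        """(eta, alpha) with the highest mean test accuracy (grid order on ties)."""
        summary = self.summary()
        idx = int(summary["mean_test_acc"].to_numpy().argmax())
        row = summary.iloc[idx]
        return (float(row["eta"]), float(row["alpha"]))


def _derived_seed(master_seed: int, *parts: int) -> int:
    """Deterministic sub-seed below 2**31."""
    value = int(master_seed)
    for part in parts:
        value = (value * 6364136223846793005 + int(part) + 1) % 2**64
    return value % 2**31


def _ensemble_metrics(model: EnsembleModel, ds: MeasurementDataset, split: str):
    X, sex = ds.subset_arrays(split)
    acc = 100.0 * float((ensemble_labels(model, X) == sex).mean())
    mse = compute_mse(ensemble_outputs(model, X), one_hot(sex))
    return acc, mse


def prepare_split(
    dataset: MeasurementDataset,
    seed: int,
    train_fraction: float = 0.7,
    normalization: str = "minmax",
) -> MeasurementDataset:
    """The study protocol: stratified 70/30 split, then training-only
    normalization. Accepts raw or already-processed data (re-derived
    from original units either way)."""
    base = dm.strip(dataset)
    ds = dm.split_train_test(base, train_fraction=train_fraction, seed=seed, stratified=True)
    return dm.normalize(ds, mode=normalization)


def run_grid(
    dataset: MeasurementDataset,
    architecture: tuple[int, int, int] = WIDE,
    repeats: int = 10,
    T: int = 4,
    master_seed: int = 0,
    max_epochs: int = 2000,
    lambda_reg: float = 2.0 ** -25,
    mse_goal: float = 0.0,
    resplit: bool = True,
    normalization: str = "minmax",
) -> GridReport:
    """Train the boosted network in every grid cell, ``repeats`` times each.

    With ``resplit`` (default) each repeat draws a fresh stratified
    70/30 split from a repeat-specific seed; otherwise one split is
    shared by all repeats. Network seeds are derived per (cell, repeat)
    from the master seed, so the whole report is reproducible bit for bit.
    """
    if repeats < 1:
        raise DataFormatError("repeats must be at least 1")
    report = GridReport(architecture=tuple(architecture), repeats=repeats, master_seed=master_seed)
    splits: dict[int, MeasurementDataset] = {}
    for r in range(repeats):
        split_seed = _derived_seed(master_seed, 0xA11CE, r) if resplit \
            else _derived_seed(master_seed, 0xA11CE, 0)
        if split_seed not in splits:
            splits[split_seed] = prepare_split(dataset, split_seed, normalization=normalization)
        ds = splits[split_seed]
        for ci, eta in enumerate(GRID_ETAS):
            for cj, alpha in enumerate(GRID_ALPHAS):
                config = NetworkConfig(
                    layer_sizes=architecture, eta=eta, alpha=alpha,
                    lambda_reg=lambda_reg, max_epochs=max_epochs, mse_goal=mse_goal,
                    seed=_derived_seed(master_seed, ci, cj, r),
                )
                try:
                    model = train_adaboost(ds, T=T, config=config)
                    train_acc, train_mse = _ensemble_metrics(model, ds, dm.TRAIN)
                    test_acc, test_mse = _ensemble_metrics(model, ds, dm.TEST)
                    result = RepeatResult(train_acc, train_mse, test_acc, test_mse)
                except CranioError as exc:
                    result = RepeatResult(error=f"{type(exc).__name__}: {exc}")
                report.cells[(eta, alpha)].append(result)
    return report


# -- rendering ---------------------------------------------------------


def _blocks(report: GridReport) -> list[tuple[str, str, str, np.ndarray]]:
    """(block, metric, column, 3x3 value grid) in table order."""
    summary = report.summary().set_index(["eta", "alpha"])
    out = []
    for block, acc_col, mse_col in (
        ("training", "mean_train_acc", "mean_train_mse"),
        ("testing", "mean_test_acc", "mean_test_mse"),
    ):
        for metric, col in (("accuracy_pct", acc_col), ("mse", mse_col)):
            grid = np.array([
                [summary.loc[(eta, alpha), col] for alpha in GRID_ALPHAS]
                for eta in GRID_ETAS
            ])
            out.append((block, metric, col, grid))
    return out


def render_tables(report: GridReport, fmt: str = "text") -> str:
    """Render per-cell mean accuracy/MSE as two blocks (training, testing),
    eta rows by alpha columns, with the best accuracy starred."""
    if fmt not in ("text", "csv", "markdown"):
        raise DataFormatError(f"unknown format {fmt!r}")
    if fmt == "csv":
        buf = io.StringIO()
        rows = []
        for block, metric, _, grid in _blocks(report):
            for i, eta in enumerate(GRID_ETAS):
                for j, alpha in enumerate(GRID_ALPHAS):
                    rows.append((block, metric, eta, alpha, grid[i, j]))
        pd.DataFrame(rows, columns=["block", "metric", "eta", "alpha", "value"]).to_csv(
            buf, index=False
        )
        return buf.getvalue()

    lines = [f"Architecture [{'; '.join(map(str, report.architecture))}], "
             f"{report.repeats} repeat(s), mean over successful repeats"]
    for block, metric, col, grid in _blocks(report):
        star = np.unravel_index(np.nanargmax(grid), grid.shape) if "acc" in col else None
        lines.append("")
        lines.append(f"Performance {block} — {metric}")
        if fmt == "markdown":
            lines.append("| eta \\ alpha | " + " | ".join(str(a) for a in GRID_ALPHAS) + " |")
            lines.append("|---" * (len(GRID_ALPHAS) + 1) + "|")
        else:
            lines.append("eta\\alpha  " + "  ".join(f"{a:>8}" for a in GRID_ALPHAS))
        for i, eta in enumerate(GRID_ETAS):
            cells = []
            for j in range(len(GRID_ALPHAS)):
                text = f"{grid[i, j]:.3f}"
                if star is not None and (i, j) == star:
                    text = f"*{text}*" if fmt == "markdown" else f"{text}*"
                cells.append(text)
            if fmt == "markdown":
                lines.append(f"| {eta} | " + " | ".join(cells) + " |")
            else:
                lines.append(f"{eta:<9}  " + "  ".join(f"{c:>8}" for c in cells))
    return "\n".join(lines) + "\n"


def compare_architectures(
    dataset: MeasurementDataset,
    repeats: int = 10,
    master_seed: int = 0,
    **grid_kwargs,
) -> tuple[GridReport, GridReport, pd.DataFrame]:
    """Run both architectures on identical splits and seeds.

    Returns (narrow report, wide report, verdict); the verdict names the
    architecture with the higher mean test accuracy per cell ("tie" when
    equal).
    """
    narrow = run_grid(dataset, architecture=NARROW, repeats=repeats,
                      master_seed=master_seed, **grid_kwargs)
    wide = run_grid(dataset, architecture=WIDE, repeats=repeats,
                    master_seed=master_seed, **grid_kwargs)
    sn = narrow.summary().set_index(["eta", "alpha"])
    sw = wide.summary().set_index(["eta", "alpha"])
    rows = []
    for eta in GRID_ETAS:
        for alpha in GRID_ALPHAS:
            a_n = sn.loc[(eta, alpha), "mean_test_acc"]
            a_w = sw.loc[(eta, alpha), "mean_test_acc"]
            if np.isnan(a_n) or np.isnan(a_w) or a_n == a_w:
                winner = "tie"
            else:
                arch = WIDE if a_w > a_n else NARROW
                winner = f"[{'; '.join(map(str, arch))}]"
            rows.append({"eta": eta, "alpha": alpha, "narrow_test_acc": a_n,
                         "wide_test_acc": a_w, "winner": winner})
    return narrow, wide, pd.DataFrame(rows)
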