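"""Monte Carlo comparison of the three cut-off selection methods.

For each cell of a (pre-test probability x sample size x scenario) design,
``n_reps`` datasets of fixed composition are generated — exactly
``round(N * P(D))`` diseased values, the rest healthy — and all three methods
are applied to each. Means and sample SDs of the cut-off, sensitivity and
specificity over replications quantify bias (against the analytic density
crossing point) and precision of each method. Regression coefficient
summaries of the logistic fits are kept alongside, since their dependence on
P(D) before and after the pre-test-odds correction is part of what the
experiment measures.

Every replication draws from its own RNG substream derived from the master
seed and the cell coordinates, so any single cell or replication can be
reproduced in isolation and results do not depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutoff_methods import (
    CutoffEstimate,
    DiagnosticDataset,
    Method,
    build_table,
    optimize_cutoff,
    se_sp,
)
from .distributions import Scenario
from .logistic_lr import InvertedPredictorError, LogisticFit, fit_logistic, lr_cutoff

__all__ = [
    "ExperimentDesign",
    "ReplicationResult",
    "MonteCarloSummary",
    "generate_dataset",
    "replication_rng",
    "run_replication",
    "run_experiment",
    "summary_ranges",
    "format_range_report",
]

#: Pre-test probability grid used throughout the study.
DEFAULT_PD_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))

#: Summary columns in output order.
SUMMARY_COLUMNS = [
    "scenario",
    "n_total",
    "p_d",
    "method",
    "mean_cutoff",
    "sd_cutoff",
    "mean_se",
    "sd_se",
    "mean_sp",
    "sd_sp",
    "n_valid",
    "n_failed",
    "n_nonconverged",
    "mean_alpha0",
    "sd_alpha0",
    "mean_alpha1",
    "sd_alpha1",
    "mean_alpha0_corrected",
    "sd_alpha0_corrected",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """One scenario's simulation design: sample size, P(D) grid, repetitions."""

    scenario: Scenario
    n_total: int
    p_d_grid: tuple[float, ...] = DEFAULT_PD_GRID
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_d_grid", tuple(float(p) for p in self.p_d_grid))
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        for p_d in self.p_d_grid:
            n_diseased = self.n_total * p_d
            if abs(n_diseased - round(n_diseased)) > 1e-9:
                raise ValueError(
                    f"n_total * p_d = {self.n_total} * {p_d} is not an integer"
                )
            if round(n_diseased) < 1 or round(self.n_total * (1 - p_d)) < 1:
                raise ValueError(f"p_d = {p_d} leaves one class empty at N={self.n_total}")


def generate_dataset(
    scenario: Scenario, n_total: int, p_d: float, rng: np.random.Generator
) -> DiagnosticDataset:
    """Draw one dataset of fixed composition round(N * P(D)) diseased.

    The label split is deterministic, not binomial: exactly ``round(N*p_d)``
    values come from the diseased distribution and the rest from the healthy
    one. Healthy values are drawn before diseased ones, so a given generator
    state always produces the same dataset.
    """
    n_diseased_f = n_total * p_d
    if abs(n_diseased_f - round(n_diseased_f)) > 1e-9:
        raise ValueError(f"n_total * p_d = {n_total} * {p_d} is not an integer")
    n_diseased = int(round(n_diseased_f))
    n_healthy = n_total - n_diseased
    healthy_values = scenario.healthy.sample(n_healthy, rng)
    diseased_values = scenario.diseased.sample(n_diseased, rng)
    values = np.concatenate([healthy_values, diseased_values])
    labels = np.concatenate(
        [np.zeros(n_healthy, dtype=np.int8), np.ones(n_diseased, dtype=np.int8)]
    )
    return DiagnosticDataset(values, labels, p_d=p_d)


def replication_rng(seed: int, n_total: int, p_d: float, rep: int) -> np.random.Generator:
    """The RNG substream for one replication, independent of execution order."""
    pd_key = int(round(p_d * 1000))
    return np.random.default_rng(np.random.SeedSequence([seed, n_total, pd_key, rep]))


@dataclass
class ReplicationResult:
    """All three methods applied to one dataset.

    ``estimates[Method.LIKELIHOOD_RATIO]`` is None when the fitted slope was
    not positive (the LR cut-off root does not exist); the logistic fit itself
    is kept for coefficient summaries whenever fitting succeeded.
    """

    estimates: dict[Method, CutoffEstimate | None]
    fit: LogisticFit | None
    lr_failed: bool = False


def run_replication(data: DiagnosticDataset) -> ReplicationResult:
    """Apply the MI, Youden and LR methods to one dataset.

    Sensitivity and specificity for every method are evaluated on the same
    dataset at that method's cut-off (x >= cut-off positive); the LR cut-off
    is used as a continuous value, without snapping to the search grid.
    """
    if not data.both_classes_present:
        raise ValueError("both diagnostic classes must be present")
    estimates: dict[Method, CutoffEstimate | None] = {
        Method.MUTUAL_INFORMATION: optimize_cutoff(data, Method.MUTUAL_INFORMATION),
        Method.YOUDEN: optimize_cutoff(data, Method.YOUDEN),
    }
    fit = fit_logistic(data)
    lr_failed = False
    try:
        cutoff = lr_cutoff(fit)
    except InvertedPredictorError:
        estimates[Method.LIKELIHOOD_RATIO] = None
        lr_failed = True
    else:
        se, sp = se_sp(build_table(data, cutoff))
        estimates[Method.LIKELIHOOD_RATIO] = CutoffEstimate(
            method=Method.LIKELIHOOD_RATIO,
            cutoff=cutoff,
            sensitivity=se,
            specificity=sp,
        )
    return ReplicationResult(estimates=estimates, fit=fit, lr_failed=lr_failed)


@dataclass
class MonteCarloSummary:
    """Per-(P(D), method) means and SDs over replications, as a long table."""

    scenario_name: str
    n_total: int
    n_reps: int
    seed: int
    table: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        """Write the long-format summary at full precision."""
        self.table.to_csv(path, index=False)

    def cell(self, p_d: float, method: Method | str) -> pd.Series:
        method = Method(method).value
        mask = (np.isclose(self.table["p_d"], p_d)) & (self.table["method"] == method)
        rows = self.table[mask]
        if len(rows) != 1:
            raise KeyError(f"no unique summary row for p_d={p_d}, method={method}")
        return rows.iloc[0]


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def run_experiment(design: ExperimentDesign) -> MonteCarloSummary:
    """Run the full replication study for one scenario and sample size.

    Returns a long-format summary with one row per (P(D), method): mean and
    sample SD (n-1 denominator) of cut-off, sensitivity and specificity over
    the valid replications, plus failure and non-convergence counts. LR rows
    additionally carry mean/SD of the raw and pre-test-odds-corrected logistic
    coefficients over all fitted replications. Bit-identical for an identical
    design.
    """
    rows: list[dict] = []
    methods = (Method.MUTUAL_INFORMATION, Method.YOUDEN, Method.LIKELIHOOD_RATIO)
    for p_d in design.p_d_grid:
        cutoffs = {m: [] for m in methods}
        ses = {m: [] for m in methods}
        sps = {m: [] for m in methods}
        alpha0s: list[float] = []
        alpha1s: list[float] = []
        alpha0cs: list[float] = []
        n_nonconverged = 0
        for rep in range(design.n_reps):
            rng = replication_rng(design.seed, design.n_total, p_d, rep)
            data = generate_dataset(design.scenario, design.n_total, p_d, rng)
            result = run_replication(data)
            for m in methods:
                est = result.estimates[m]
                if est is None:
                    continue
                cutoffs[m].append(est.cutoff)
                ses[m].append(est.sensitivity)
                sps[m].append(est.specificity)
            if result.fit is not None:
                alpha0s.append(result.fit.alpha0)
                alpha1s.append(result.fit.alpha1)
                alpha0cs.append(result.fit.alpha0_corrected)
                if not result.fit.converged:
                    n_nonconverged += 1
        for m in methods:
            cut = np.asarray(cutoffs[m])
            n_valid = cut.size
            mean_cut, sd_cut = _mean_sd(cut)
            mean_se, sd_se = _mean_sd(np.asarray(ses[m]))
            mean_sp, sd_sp = _mean_sd(np.asarray(sps[m]))
            row = {
                "scenario": design.scenario.name,
                "n_total": design.n_total,
                "p_d": p_d,
                "method": m.value,
                "mean_cutoff": mean_cut,
                "sd_cutoff": sd_cut,
                "mean_se": mean_se,
                "sd_se": sd_se,
                "mean_sp": mean_sp,
                "sd_sp": sd_sp,
                "n_valid": n_valid,
                "n_failed": design.n_reps - n_valid,
                "n_nonconverged": n_nonconverged if m is Method.LIKELIHOOD_RATIO else 0,
                "mean_alpha0": np.nan,
                "sd_alpha0": np.nan,
                "mean_alpha1": np.nan,
                "sd_alpha1": np.nan,
                "mean_alpha0_corrected": np.nan,
                "sd_alpha0_corrected": np.nan,
            }
            if m is Method.LIKELIHOOD_RATIO and alpha0s:
                row["mean_alpha0"], row["sd_alpha0"] = _mean_sd(np.asarray(alpha0s))
                row["mean_alpha1"], row["sd_alpha1"] = _mean_sd(np.asarray(alpha1s))
                (
                    row["mean_alpha0_corrected"],
                    row["sd_alpha0_corrected"],
                ) = _mean_sd(np.asarray(alpha0cs))
            rows.append(row)
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return MonteCarloSummary(
        scenario_name=design.scenario.name,
        n_total=design.n_total,
        n_reps=design.n_reps,
        seed=design.seed,
        table=table,
    )


_RANGE_ROUNDING = {
    "mean_cutoff": 1,
    "sd_cutoff": 1,
    "mean_se": 2,
    "sd_se": 2,
    "mean_sp": 2,
    "sd_sp": 2,
}


def summary_ranges(summary: MonteCarloSummary) -> pd.DataFrame:
    """Min/max over P(D) of each summary column, per method.

    Mirrors the "a - b" range presentation of the study's summary table:
    cut-offs rounded to one decimal, sensitivities/specificities to two.
    Cells from P(D) values where every replication failed are excluded with
    a warning.
    """
    rows = []
    for method, group in summary.table.groupby("method", sort=False):
        missing = group["mean_cutoff"].isna()
        if missing.any():
            warnings.warn(
                f"{method}: {int(missing.sum())} p_d cell(s) have no valid "
                "replications and are excluded from the ranges",
                stacklevel=2,
            )
            group = group[~missing]
        row = {"scenario": summary.scenario_name, "n_total": summary.n_total, "method": method}
        for col, digits in _RANGE_ROUNDING.items():
            col_values = group[col].dropna()
            if col_values.empty:
                row[f"{col}_min"] = np.nan
                row[f"{col}_max"] = np.nan
            else:
                row[f"{col}_min"] = round(float(col_values.min()), digits)
                row[f"{col}_max"] = round(float(col_values.max()), digits)
        rows.append(row)
    return pd.DataFrame(rows)


_METHOD_TITLES = {
    "mutual_information": "Mutual information",
    "youden": "Youden",
    "likelihood_ratio": "Likelihood ratio",
}


def format_range_report(ranges: pd.DataFrame) -> str:
    """Human-readable range report, one block per scenario/N."""
    lines: list[str] = []
    for (scenario, n_total), group in ranges.groupby(["scenario", "n_total"]):
        lines.append(f"{scenario}, N = {n_total}")
        header = f"  {'':12s}" + "".join(
            f"{_METHOD_TITLES.get(m, m):>28s}" for m in group["method"]
        )
        lines.append(header)
        for quantity, mean_col, sd_col, digits in (
            ("Cut-off", "mean_cutoff", "sd_cutoff", 1),
            ("Se", "mean_se", "sd_se", 2),
            ("Sp", "mean_sp", "sd_sp", 2),
        ):
            cells = []
            for _, row in group.iterrows():
                mean_rng = f"{row[f'{mean_col}_min']:.{digits}f} - {row[f'{mean_col}_max']:.{digits}f}"
                sd_rng = f"{row[f'{sd_col}_min']:.{digits}f} - {row[f'{sd_col}_max']:.{digits}f}"
                cells.append(f"{mean_rng:>15s} ({sd_rng})")
            lines.append(f"  {quantity:12s}" + "".join(f"{c:>28s}" for c in cells))
        lines.append("")
    return "\n".join(lines)
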