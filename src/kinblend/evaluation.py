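"""Cross-validated predictive ability over the blending grid.

Repeated random 60/40 train/test splits; for each replicate, each kinship
variant, and each blending weight, variance components are re-estimated by
REML on the training set, breeding values of test individuals are predicted
as the conditional mean given training phenotypes, and three kinds of
statistics are recorded:

* per-trait predictive correlation between held-out (pre-corrected)
  phenotypes and predicted breeding values, and the corresponding MSE;
* per ordered trait pair (x, y), the realized regression: the OLS slope of
  the test-set phenotype of x on the predicted breeding value of y;
* the expected genetic regression implied by the REML estimates,
  ``b_xy = r_G(x,y) * sigma_G(x) / sigma_G(y)``, for comparison with the
  realized slopes.

Splits are shared across all (variant, lambda) cells within a replicate, so
comparisons along the grid are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import LAMBDA_GRID, KinshipMatrix, blend_kernels
from .mtgblup import MTModelFit, MTModelSpec, predict_dgv, reml_fit

logger = logging.getLogger("kinblend")

__all__ = [
    "CVScheme",
    "CVReport",
    "make_splits",
    "run_cv",
    "expected_regressions",
    "realized_regression",
    "summarize_report",
]


@dataclass(frozen=True)
class CVScheme:
    """Replicate count, split fraction, blending grid, and kernel variants."""

    n_reps: int = 20
    train_frac: float = 0.6
    seed: int = 0
    lambda_grid: tuple[float, ...] = LAMBDA_GRID
    g_variants: tuple[str, ...] = ("GV",)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if any(not 0.0 <= lam <= 1.0 for lam in self.lambda_grid):
            raise ValueError("lambda grid values must lie in [0, 1]")


@dataclass
class CVReport:
    """Long-format cross-validation results.

    ``results`` columns: variant, lam, rep, trait_or_pair, metric, value.
    Metrics: ``predictive_corr`` and ``mse`` per trait; ``realized_b`` and
    ``expected_b`` per ordered pair "x->y"; ``converged`` per cell.
    """

    results: pd.DataFrame
    scheme: CVScheme
    failures: list = field(default_factory=list)

    def summaries(self) -> pd.DataFrame:
        return summarize_report(self)


def make_splits(ids: list[str], scheme: CVScheme) -> list[tuple[list[str], list[str]]]:
    """Independent uniform train/test partitions, one per replicate.

    Training size is ``round(train_frac * n)``; partitions are disjoint and
    exhaustive, deterministic given the scheme seed.
    """
    ids = [str(i) for i in ids]
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 individuals to split")
    n_train = int(round(scheme.train_frac * n))
    rng = np.random.default_rng(scheme.seed)
    splits = []
    for _ in range(scheme.n_reps):
        perm = rng.permutation(n)
        train = [ids[i] for i in sorted(perm[:n_train])]
        test = [ids[i] for i in sorted(perm[n_train:])]
        splits.append((train, test))
    return splits


def realized_regression(pheno_x: np.ndarray, dgv_y: np.ndarray) -> float:
    """OLS slope (with intercept) of test phenotypes on predicted breeding
    values; NaN when the predictor has (numerically) zero variance."""
    x = np.asarray(dgv_y, dtype=float)
    y = np.asarray(pheno_x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 test individuals for a regression")
    vx = x.var(ddof=1)
    if not np.isfinite(vx) or vx <= 1e-300 * max(1.0, np.abs(x).max() ** 2):
        return float("nan")
    return float(np.cov(x, y, ddof=1)[0, 1] / vx)


def expected_regressions(fit: MTModelFit, lam: float | None = None) -> pd.DataFrame:
    """Expected genetic regressions from REML estimates:
    ``b_xy = r_G(x,y) * sqrt(Q_xx) / sqrt(Q_yy)`` per ordered pair."""
    Q = fit.params.Q
    names = fit.spec.trait_names
    rows = []
    sg = np.sqrt(np.clip(np.diag(Q), 0.0, None))
    for i, x in enumerate(names):
        for j, y in enumerate(names):
            if i == j:
                continue
            if sg[i] <= 0 or sg[j] <= 0:
                b = np.nan
                logger.warning("zero genetic variance: expected regression "
                               "%s->%s undefined", x, y)
            else:
                b = fit.genetic_corr.iloc[i, j] * sg[i] / sg[j]
            rows.append({"pair": f"{x}->{y}", "lam": lam, "expected_b": b})
    return pd.DataFrame(rows)


def _kernel_grid(
    A: KinshipMatrix, g_matrices: dict[str, KinshipMatrix], scheme: CVScheme
) -> dict[tuple[str, float], KinshipMatrix]:
    kernels = {}
    for variant in scheme.g_variants:
        if variant not in g_matrices:
            raise KeyError(f"no G matrix supplied for variant {variant!r}")
        G = g_matrices[variant].align(list(A.ids))
        for lam in scheme.lambda_grid:
            kernels[(variant, lam)] = blend_kernels(G, A, lam)
    return kernels


def run_cv(
    phenotypes: pd.DataFrame,
    A: KinshipMatrix,
    g_matrices: dict[str, KinshipMatrix],
    scheme: CVScheme,
    compute_se: bool = False,
) -> CVReport:
    """Full cross-validation over replicates, variants, and the lambda grid.

    ``phenotypes`` holds pre-corrected traits indexed by id; ``A`` and each
    G matrix must cover those ids.  Convergence failures are recorded per
    cell and skipped, not fatal.
    """
    ids = [str(i) for i in phenotypes.index]
    traits = [str(c) for c in phenotypes.columns]
    kernels = _kernel_grid(A.align(ids), {k: v for k, v in g_matrices.items()}, scheme)
    splits = make_splits(ids, scheme)
    rows = []
    failures = []
    for rep, (train, test) in enumerate(splits):
        for (variant, lam), K in kernels.items():
            try:
                spec = MTModelSpec(phenotypes.loc[train], K)
                fit = reml_fit(spec, compute_se=compute_se)
                pred = predict_dgv(fit, K, train, test)
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                logger.warning("CV cell failed (rep=%d, variant=%s, lam=%.1f): %s",
                               rep, variant, lam, exc)
                failures.append({"rep": rep, "variant": variant, "lam": lam,
                                 "error": str(exc)})
                continue
            Y_test = phenotypes.loc[test]
            G_hat = pred.values
            base = {"variant": variant, "lam": lam, "rep": rep}
            rows.append({**base, "trait_or_pair": "", "metric": "converged",
                         "value": float(fit.converged)})
            for t in traits:
                y, g = Y_test[t].to_numpy(float), G_hat[t].to_numpy(float)
                corr = (np.corrcoef(y, g)[0, 1]
                        if g.std() > 0 and y.std() > 0 else np.nan)
                rows.append({**base, "trait_or_pair": t,
                             "metric": "predictive_corr", "value": corr})
                rows.append({**base, "trait_or_pair": t, "metric": "mse",
                             "value": float(np.mean((y - g) ** 2))})
            exp_b = expected_regressions(fit, lam).set_index("pair")["expected_b"]
            for x in traits:
                for y in traits:
                    if x == y:
                        continue
                    pair = f"{x}->{y}"
                    slope = realized_regression(
                        Y_test[x].to_numpy(float), G_hat[y].to_numpy(float)
                    )
                    rows.append({**base, "trait_or_pair": pair,
                                 "metric": "realized_b", "value": slope})
                    rows.append({**base, "trait_or_pair": pair,
                                 "metric": "expected_b", "value": exp_b[pair]})
    results = pd.DataFrame(
        rows, columns=["variant", "lam", "rep", "trait_or_pair", "metric", "value"]
    )
    n_cells = scheme.n_reps * len(kernels)
    if failures and len(failures) > 0.5 * n_cells:
        logger.warning("more than half of all CV cells failed to converge")
    return CVReport(results=results, scheme=scheme, failures=failures)


def summarize_report(report: CVReport) -> pd.DataFrame:
    """Mean, SD, and median across replicates per (variant, lambda, metric)."""
    if report.results.empty:
        raise ValueError("empty CV report")
    grp = report.results.groupby(
        ["variant", "lam", "trait_or_pair", "metric"], sort=True
    )["value"]
    out = grp.agg(mean="mean", sd="std", median="median", n_reps="count")
    return out.reset_index()
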