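"""Fixed-effect pre-correction of phenotypes.

Raw phenotypes are residualized on categorical nuisance factors (sex,
hatch, pen, ...) before entering the GBLUP stage, so the mixed model only
carries a per-trait intercept.  All factors are treated as fixed effects:
with the balanced categorical designs produced by the simulator this
removes the nuisance signal exactly, which keeps the correction testable
against simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CorrectionSpec", "precorrect"]


@dataclass(frozen=True)
class CorrectionSpec:
    """Which categorical factors to remove, per trait.

    ``factors`` lists factor column names applied to every trait;
    ``per_trait`` optionally overrides the list for individual traits.
    """

    factors: tuple[str, ...] = ()
    per_trait: dict = field(default_factory=dict)

    def factors_for(self, trait: str) -> tuple[str, ...]:
        return tuple(self.per_trait.get(trait, self.factors))


def _design(df: pd.DataFrame, factors: tuple[str, ...]) -> np.ndarray:
    """Intercept plus reference-coded dummies; errors on confounding."""
    n = len(df)
    cols = [np.ones((n, 1))]
    for f in factors:
        if f not in df.columns:
            raise KeyError(f"nuisance factor {f!r} not in phenotype table")
        d = pd.get_dummies(df[f].astype("category"), drop_first=True, dtype=float)
        if d.shape[1] == 0:
            raise ValueError(f"nuisance factor {f!r} has fewer than 2 levels")
        cols.append(d.to_numpy())
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient nuisance design: factors {list(factors)} are confounded"
        )
    return X


def precorrect(
    pheno_raw: pd.DataFrame, spec: CorrectionSpec, traits: list[str] | None = None
) -> pd.DataFrame:
    """Per-trait OLS residuals after regression on intercept + factor dummies.

    ``pheno_raw`` is indexed by individual id and mixes numeric trait
    columns with categorical nuisance columns; ``traits`` defaults to every
    column not named as a factor anywhere in ``spec``.  The output holds
    only the corrected trait columns, each centered at zero.
    """
    factor_cols = set(spec.factors)
    for fs in spec.per_trait.values():
        factor_cols.update(fs)
    if traits is None:
        traits = [c for c in pheno_raw.columns if c not in factor_cols]
    out = {}
    for trait in traits:
        y = pheno_raw[trait].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"missing values in trait {trait!r}")
        X = _design(pheno_raw, spec.factors_for(trait))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out[trait] = resid - resid.mean()
    corrected = pd.DataFrame(out, index=pheno_raw.index)
    corrected.index.name = pheno_raw.index.name or "id"
    return corrected
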