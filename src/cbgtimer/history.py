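"""Trial-history regression of lick times.

Mice choosing when to lick have only their recent history to go on: the lick
times of previous trials and whether those licks were rewarded.  A linear
model predicts the upcoming lick time from previous lick times (``T``),
previous reward outcomes (``R``) and their interactions (``T x R``) at lags
1..k.  Forty-two regressor sets — the seven non-empty families of
``{T, R, T x R}`` crossed with maximum lags 1–6 — are compared by five-fold
cross-validation, scored by the median-absolute-deviation explained::

    MAD_explained = 1 - R1 / R2

where ``R1`` is the median absolute held-out residual of the model and ``R2``
that of the intercept-only null model (whose own score is exactly 0).

The module follows the statsmodels idiom: :class:`TrialHistoryRegression` is
built from trials, ``fit()`` returns a :class:`TrialHistoryResults` carrying
coefficients, the cross-validation table and a ``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import Session, Trial

__all__ = [
    "HistorySpec",
    "TrialHistoryRegression",
    "TrialHistoryResults",
    "fit_history_regression",
    "default_spec_grid",
]

_FAMILIES = ("T", "R", "TxR")


@dataclass(frozen=True)
class HistorySpec:
    """One regressor set: which families enter and up to which lag."""

    families: tuple[str, ...]
    max_lag: int

    def columns(self) -> list[str]:
        return [f"{fam}_{k}" for fam in self.families for k in range(1, self.max_lag + 1)]

    def label(self) -> str:
        return "+".join(self.families) + f" lag{self.max_lag}"


def default_spec_grid(max_lag: int = 6) -> list[HistorySpec]:
    """The 42-model grid: non-empty families of {T, R, TxR} x lags 1..6."""
    grid: list[HistorySpec] = []
    for r in range(1, len(_FAMILIES) + 1):
        for fams in itertools.combinations(_FAMILIES, r):
            for lag in range(1, max_lag + 1):
                grid.append(HistorySpec(families=fams, max_lag=lag))
    return grid


class TrialHistoryRegression:
    """Linear model of lick time on trial history.

    Parameters
    ----------
    trials
        Behavioral trials in session order.
    missing
        How to form lagged regressors across no-lick / no-cue trials:
        ``"carry"`` (default) uses the most recent preceding trial with a
        lick for every lag, keeping the design matrix complete; ``"drop"``
        discards target trials whose immediate predecessors lack a lick.
    """

    def __init__(self, trials: Sequence[Trial], missing: str = "carry"):
        if missing not in ("carry", "drop"):
            raise ValueError("missing must be 'carry' or 'drop'")
        self.trials = list(trials)
        self.missing = missing
        self._table = self._history_table()

    @classmethod
    def from_session(cls, session: Session, **kwargs) -> "TrialHistoryRegression":
        return cls(session.trials, **kwargs)

    def _history_table(self) -> pd.DataFrame:
        """Per licked cue trial: response plus lagged T, R, TxR up to lag 6."""
        licked = [
            (i, t) for i, t in enumerate(self.trials) if t.cue_present and t.licked
        ]
        rows = []
        for pos, (i, t) in enumerate(licked):
            if self.missing == "carry":
                # history = previous licked trials, regardless of gaps
                hist = licked[:pos]
            else:
                hist = licked[:pos]
                # require the immediate predecessors in session order to be licked
                if pos >= 1 and i - licked[pos - 1][0] != 1:
                    continue
            if len(hist) < 6:
                continue
            row = {"trial": i, "LT": t.first_lick_time}
            for k in range(1, 7):
                _, prev = hist[-k]
                row[f"T_{k}"] = prev.first_lick_time
                row[f"R_{k}"] = float(prev.rewarded)
                row[f"TxR_{k}"] = prev.first_lick_time * float(prev.rewarded)
            rows.append(row)
        return pd.DataFrame(rows)

    def design(self, spec: HistorySpec) -> tuple[np.ndarray, np.ndarray]:
        cols = spec.columns()
        X = sm.add_constant(self._table[cols].to_numpy(float), has_constant="add")
        y = self._table["LT"].to_numpy(float)
        return X, y

    def fit(
        self,
        specs: Sequence[HistorySpec] | None = None,
        folds: int = 5,
        min_trials: int = 50,
    ) -> "TrialHistoryResults":
        """Cross-validate the model grid, select by MAD explained, refit."""
        n = len(self._table)
        if n < min_trials:
            raise ValueError(f"insufficient usable trials: {n} < {min_trials}")
        if specs is None:
            specs = default_spec_grid()
        y = self._table["LT"].to_numpy(float)
        fold_idx = np.array_split(np.arange(n), folds)

        records = []
        for spec in specs:
            X, _ = self.design(spec)
            model_resid, null_resid = [], []
            for held in fold_idx:
                train = np.setdiff1d(np.arange(n), held)
                beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
                model_resid.append(y[held] - X[held] @ beta)
                null_resid.append(y[held] - y[train].mean())
            r1 = float(np.median(np.abs(np.concatenate(model_resid))))
            r2 = float(np.median(np.abs(np.concatenate(null_resid))))
            records.append(
                {
                    "model": spec.label(),
                    "families": "+".join(spec.families),
                    "max_lag": spec.max_lag,
                    "mad_explained": 1.0 - r1 / r2 if r2 > 0 else 0.0,
                    "spec": spec,
                }
            )
        table = pd.DataFrame(records).sort_values("mad_explained", ascending=False)
        best_spec: HistorySpec = table.iloc[0]["spec"]

        X, y = self.design(best_spec)
        ols = sm.OLS(y, X).fit()
        params = pd.Series(ols.params, index=["const"] + best_spec.columns())
        return TrialHistoryResults(
            model=self,
            spec=best_spec,
            params=params,
            sm_results=ols,
            mad_explained=float(table.iloc[0]["mad_explained"]),
            model_table=table.drop(columns="spec").reset_index(drop=True),
        )

    def fit_spec(self, spec: HistorySpec) -> "TrialHistoryResults":
        """Refit a single named spec on all data (no model selection)."""
        X, y = self.design(spec)
        ols = sm.OLS(y, X).fit()
        params = pd.Series(ols.params, index=["const"] + spec.columns())
        resid = y - X @ ols.params
        null = np.median(np.abs(y - y.mean()))
        mad = 1.0 - np.median(np.abs(resid)) / null if null > 0 else 0.0
        return TrialHistoryResults(
            model=self, spec=spec, params=params, sm_results=ols,
            mad_explained=float(mad), model_table=None,
        )


@dataclass
class TrialHistoryResults:
    """Selected trial-history model refit on all data."""

    model: TrialHistoryRegression
    spec: HistorySpec
    params: pd.Series
    sm_results: object
    mad_explained: float
    model_table: pd.DataFrame | None

    def predict(self) -> pd.Series:
        """Predicted lick time per usable trial (indexed by session trial)."""
        X, _ = self.model.design(self.spec)
        return pd.Series(X @ self.params.to_numpy(), index=self.model._table["trial"].to_numpy())

    def summary(self) -> str:
        lines = [
            "Trial-history regression",
            f"  selected model : {self.spec.label()}",
            f"  usable trials  : {len(self.model._table)}",
            f"  MAD explained  : {self.mad_explained:.4f} (cross-validated)"
            if self.model_table is not None
            else f"  MAD explained  : {self.mad_explained:.4f} (in-sample)",
            "",
            "  coefficient        estimate        SE",
        ]
        ses = np.asarray(self.sm_results.bse)
        for name, est, se in zip(self.params.index, self.params.to_numpy(), ses):
            lines.append(f"  {name:<16} {est:>10.4f} {se:>9.4f}")
        return "\n".join(lines)


def fit_history_regression(
    trials: Sequence[Trial],
    max_lag: int = 6,
    folds: int = 5,
    missing: str = "carry",
) -> TrialHistoryResults:
    """Convenience wrapper: grid search over the 42-model grid and refit."""
    model = TrialHistoryRegression(trials, missing=missing)
    return model.fit(specs=default_spec_grid(max_lag), folds=folds)
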