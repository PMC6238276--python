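"""Model calibration from (Co, Ha, La, Va, SN) observation tables.

Stage models are fitted by stepwise multiple linear regression (forward
entry / backward removal on partial-F p-values, final coefficients by
ordinary least squares).  The unified model
``SN = Va (a Ha + b Co + c) / (d La)`` is only identified up to a common
scale of (a, b, c) against 1/d and the Va set, so fitting requires either
``d`` and the variety table to be fixed (then (a, b, c) is a linear
least-squares problem on transformed predictors) or (a, b, c, d) fixed
(then each variety's Va is a one-parameter projection).

Fit quality is summarized by R², adjusted R², RMSE (population
denominator n) and REP = 100·RMSE / mean(observed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, IdentifiabilityError, InputError
from .models import StageModel, UnifiedModel


@dataclass(frozen=True)
class FitMetrics:
    r2: float
    adj_r2: float
    rmse: float
    rep: float


def fit_metrics(pred, obs, n_predictors: int) -> FitMetrics:
    """R², adjusted R², RMSE and REP of predictions against observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise InputError("pred and obs must be 1-D arrays of equal length")
    n = len(obs)
    if n < n_predictors + 2:
        raise InputError(f"need at least {n_predictors + 2} observations, got {n}")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0.0:
        raise DegenerateDataError("degenerate observations: zero variance")
    sse = float(((obs - pred) ** 2).sum())
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
    rmse = float(np.sqrt(sse / n))
    rep = 100.0 * rmse / float(obs.mean()) if obs.mean() != 0 else float("inf")
    return FitMetrics(r2=r2, adj_r2=adj, rmse=rmse, rep=rep)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float((resid**2).sum())


def _partial_f_pvalue(
    sse_small: float, sse_big: float, n: int, p_big: int
) -> float:
    """p-value of the F test comparing nested OLS fits (1 extra parameter).

    ``p_big`` counts regression parameters of the larger model including
    the intercept.  An exactly-zero residual in the larger model yields
    p = 0 (the added predictor is judged maximally significant), which is
    the relevant limit for noiseless recovery problems.
    """
    df2 = n - p_big
    if df2 <= 0:
        return 1.0
    if sse_big <= 0.0:
        return 0.0 if sse_small > sse_big else 1.0
    f = (sse_small - sse_big) / (sse_big / df2)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, 1, df2))


def stepwise_mlr(
    table: pd.DataFrame,
    candidates: tuple[str, ...] = ("Ha", "Co"),
    alpha_in: float = 0.05,
    alpha_out: float = 0.10,
) -> tuple[StageModel, FitMetrics]:
    """Stepwise multiple linear regression of SN_true on the candidates.

    Predictors enter when their partial-F p-value is below ``alpha_in`` and
    leave when it rises above ``alpha_out``; the loop runs until stable.
    Excluded predictors get a zero coefficient in the returned
    :class:`~seedlingcount.models.StageModel`.
    """
    if len(table) < 10:
        raise InputError(f"need >= 10 rows for stepwise regression, got {len(table)}")
    if "SN_true" not in table.columns:
        raise InputError("observation table lacks an SN_true column")
    unknown = [c for c in candidates if c not in ("Ha", "Co")]
    if unknown:
        raise InputError(f"candidates must be among ('Ha', 'Co'), got {unknown}")
    y = table["SN_true"].to_numpy(dtype=float)
    n = len(y)
    cols = {name: table[name].to_numpy(dtype=float) for name in candidates}

    def design(selected: list[str]) -> np.ndarray:
        return np.column_stack([cols[s] for s in selected] + [np.ones(n)])

    selected: list[str] = []
    if ((y - y.mean()) ** 2).sum() == 0.0:
        warnings.warn("constant response: intercept-only model", stacklevel=2)
    else:
        while True:
            changed = False
            _, sse_cur = _ols(design(selected), y)
            # forward entry
            best_p, best_name = None, None
            for name in candidates:
                if name in selected:
                    continue
                _, sse_new = _ols(design(selected + [name]), y)
                p = _partial_f_pvalue(sse_cur, sse_new, n, len(selected) + 2)
                if p < alpha_in and (best_p is None or p < best_p):
                    best_p, best_name = p, name
            if best_name is not None:
                selected.append(best_name)
                changed = True
            # backward removal
            if selected:
                _, sse_full = _ols(design(selected), y)
                worst_p, worst_name = None, None
                for name in selected:
                    reduced = [s for s in selected if s != name]
                    _, sse_red = _ols(design(reduced), y)
                    p = _partial_f_pvalue(sse_red, sse_full, n, len(selected) + 1)
                    if p > alpha_out and (worst_p is None or p > worst_p):
                        worst_p, worst_name = p, name
                if worst_name is not None:
                    selected.remove(worst_name)
                    changed = True
            if not changed:
                break
        if not selected:
            warnings.warn(
                "no predictor entered the model: intercept-only fit", stacklevel=2
            )

    beta, _ = _ols(design(selected), y)
    coef = dict.fromkeys(candidates, 0.0)
    for name, value in zip(selected, beta[:-1]):
        coef[name] = float(value)
    intercept = float(beta[-1])

    variety = None
    if "variety" in table.columns and table["variety"].nunique() == 1:
        variety = str(table["variety"].iloc[0])
    stage = None
    if "stage" in table.columns and table["stage"].nunique() == 1:
        stage = int(table["stage"].iloc[0])

    model = StageModel(
        coef_Ha=coef.get("Ha", 0.0),
        coef_Co=coef.get("Co", 0.0),
        intercept=intercept,
        variety=variety,
        stage=stage,
    )
    pred = model.coef_Ha * cols.get("Ha", 0.0) + model.coef_Co * cols.get(
        "Co", 0.0
    ) + intercept
    pred = np.broadcast_to(np.asarray(pred, dtype=float), y.shape)
    if ((y - y.mean()) ** 2).sum() == 0.0:
        rmse = float(np.sqrt(((y - pred) ** 2).mean()))
        rep = 100.0 * rmse / float(y.mean()) if y.mean() != 0 else float("inf")
        return model, FitMetrics(r2=0.0, adj_r2=0.0, rmse=rmse, rep=rep)
    return model, fit_metrics(pred, y, n_predictors=max(1, len(selected)))


def fit_unified(
    table: pd.DataFrame, fixed: dict | None = None
) -> tuple[UnifiedModel, FitMetrics]:
    """Fit the unified model with part of its parameters held fixed.

    ``fixed`` must pin down the model's free scale: either ``{"d": ...,
    "Va": {variety: Va, ...}}`` (then a, b, c are fitted by OLS) or
    ``{"a": ..., "b": ..., "c": ..., "d": ...}`` (then each variety's Va is
    fitted).  Anything less raises :class:`IdentifiabilityError`.
    """
    fixed = dict(fixed or {})
    if table.empty:
        raise InputError("empty observation table")
    if table["La"].nunique() < 2:
        raise InputError("table must span at least two distinct La values")
    y = table["SN_true"].to_numpy(dtype=float)
    ha = table["Ha"].to_numpy(dtype=float)
    co = table["Co"].to_numpy(dtype=float)
    la = table["La"].to_numpy(dtype=float)
    varieties = table["variety"].astype(str).to_numpy()

    has_abc = all(k in fixed for k in ("a", "b", "c"))
    if "d" in fixed and "Va" in fixed and not has_abc:
        d = float(fixed["d"])
        va_table = {str(k): float(v) for k, v in fixed["Va"].items()}
        missing = sorted(set(varieties) - set(va_table))
        if missing:
            raise InputError(f"fixed Va table lacks varieties {missing}")
        va = np.array([va_table[v] for v in varieties])
        scale = va / (d * la)
        X = np.column_stack([scale * ha, scale * co, scale])
        (a, b, c), _ = _ols(X, y)
        model = UnifiedModel(a=float(a), b=float(b), c=float(c), d=d,
                             variety_table=va_table)
        n_par = 3
    elif has_abc and "d" in fixed:
        a, b, c, d = (float(fixed[k]) for k in ("a", "b", "c", "d"))
        base = (a * ha + b * co + c) / (d * la)
        va_table = {}
        for name in sorted(set(varieties)):
            sel = varieties == name
            denom = float((base[sel] ** 2).sum())
            if denom == 0.0:
                raise DegenerateDataError(
                    f"cannot fit Va for {name}: zero predictor"
                )
            va_table[name] = float((base[sel] * y[sel]).sum() / denom)
        model = UnifiedModel(a=a, b=b, c=c, d=d, variety_table=va_table)
        n_par = len(va_table)
    else:
        raise IdentifiabilityError(
            "model not identifiable: (a, b, c) and 1/d share a common scale; "
            "fix d together with the Va table, or fix (a, b, c, d)"
        )

    va = np.array([model.variety_table[v] for v in varieties])
    pred = va * (model.a * ha + model.b * co + model.c) / (model.d * la)
    return model, fit_metrics(pred, y, n_predictors=n_par)


def train_validate_split(
    table: pd.DataFrame, by: str | float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an observation table for calibration and validation.

    ``by`` is either a site label (rows whose ``site`` equals it form the
    training set, the rest validation) or a training fraction in (0, 1),
    drawn without replacement with a seeded generator.
    """
    if table.empty:
        raise InputError("empty observation table")
    if isinstance(by, str):
        if "site" not in table.columns:
            raise InputError("table has no 'site' column for a site-keyed split")
        sites = set(table["site"].astype(str))
        if by not in sites:
            raise InputError(f"unknown site key {by!r}; sites present: {sorted(sites)}")
        train = table[table["site"].astype(str) == by]
        valid = table[table["site"].astype(str) != by]
        return train.reset_index(drop=True), valid.reset_index(drop=True)
    frac = float(by)
    if not 0.0 < frac < 1.0:
        raise InputError(f"training fraction must lie in (0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(table))
    n_train = int(round(frac * len(table)))
    train = table.iloc[np.sort(idx[:n_train])]
    valid = table.iloc[np.sort(idx[n_train:])]
    return train.reset_index(drop=True), valid.reset_index(drop=True)
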