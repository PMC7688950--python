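"""Feature screening and multivariate regression on expression mean and CV².

Features are first screened one at a time by Spearman rank correlation
against the response (|rho| > 0.2 by default); the selected set is then fit
jointly by ordinary least squares on z-scored features, and per-coefficient
t statistics / two-sided p-values are reported.  Responses default to
log10-transformed mean and CV².  A forward-backward stepwise selector is
available as an alternative to the correlation filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class CollinearityError(ValueError):
    """OLS design matrix is rank-deficient."""

    def __init__(self, features: list[str]):
        self.features = features
        super().__init__(f"collinear or constant features: {features}")


@dataclass
class ScreenResult:
    """Per-feature Spearman rho against one response, with the selection flag.

    Constant features have undefined rho: they are masked (NaN) and never
    selected.
    """

    response: str
    table: pd.DataFrame  # index feature; columns rho, n, selected
    threshold: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "response", self.response)
        out.to_csv(path, sep="\t", index_label="feature")


@dataclass
class RegressionModel:
    response: str
    features: list[str]
    coefficients: pd.Series  # includes "const"
    standard_errors: pd.Series
    t_stats: pd.Series
    p_values: pd.Series
    r_squared: float
    n: int
    alpha: float = 0.05
    qvalues: pd.Series | None = field(default=None, repr=False)

    @property
    def significant(self) -> list[str]:
        p = self.p_values.drop("const")
        return list(p.index[p < self.alpha])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_stats,
                "p": self.p_values,
            }
        )
        df["significant"] = df["p"] < self.alpha
        if self.qvalues is not None:
            df["q_bh"] = self.qvalues
        df.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def prepare_responses(expression: pd.DataFrame, log10: bool = True) -> pd.DataFrame:
    """Turn an aggregated expression table (mean_avg, cv2_avg) into response
    columns; log10 by default since both span several decades."""
    expr = expression.set_index("clone_id") if "clone_id" in expression.columns else expression
    out = pd.DataFrame(index=expr.index)
    if log10:
        out["log10_mean"] = np.log10(expr["mean_avg"])
        out["log10_cv2"] = np.log10(expr["cv2_avg"])
    else:
        out["mean"] = expr["mean_avg"]
        out["cv2"] = expr["cv2_avg"]
    return out


def spearman_screen(
    X: pd.DataFrame,
    y: pd.Series,
    threshold: float = 0.2,
    response_name: str = "response",
    min_n: int = 3,
) -> ScreenResult:
    """Spearman rho of each feature against ``y`` on pairwise-complete rows
    (average ranks for ties); select features with |rho| > threshold."""
    rows = {}
    for feat in X.columns:
        pair = pd.concat([X[feat], y], axis=1, join="inner").dropna()
        n = len(pair)
        if n < min_n or pair[feat].nunique() <= 1 or pair.iloc[:, 1].nunique() <= 1:
            rows[feat] = {"rho": np.nan, "n": n, "selected": False}
            continue
        rho = stats.spearmanr(pair[feat], pair.iloc[:, 1]).statistic
        rows[feat] = {"rho": rho, "n": n, "selected": bool(abs(rho) > threshold)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "feature"
    return ScreenResult(response=response_name, table=table, threshold=threshold)


def _design(
    X: pd.DataFrame, y: pd.Series, features: list[str], standardize: bool
) -> tuple[pd.DataFrame, pd.Series]:
    data = pd.concat([X[features], y.rename("__y__")], axis=1, join="inner").dropna()
    Z = data[features].astype(float)
    if standardize and features:
        sd = Z.std(ddof=1)
        Z = (Z - Z.mean()) / sd.replace(0, np.nan)
    return sm.add_constant(Z, has_constant="add"), data["__y__"]


def fit_model(
    X: pd.DataFrame,
    y: pd.Series,
    features: list[str] | None = None,
    response_name: str = "response",
    standardize: bool = True,
    alpha: float = 0.05,
    bh_qvalues: bool = False,
) -> RegressionModel:
    """OLS of ``y`` on the selected features (z-scored by default) plus an
    intercept; rows with a missing value in any selected feature are dropped
    listwise.  Raises :class:`CollinearityError` on rank-deficient designs,
    naming the offending features."""
    features = list(X.columns) if features is None else list(features)
    design, yy = _design(X, y, features, standardize)
    if len(yy) <= len(features) + 1:
        raise ValueError(
            f"need n > k+1 observations (n={len(yy)}, k={len(features)})"
        )
    bad = [c for c in design.columns if c != "const" and design[c].isna().any()]
    if bad or np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        if not bad:
            corr = design.drop(columns="const").corr().abs()
            np.fill_diagonal(corr.values, 0)
            bad = sorted(set(corr.index[(corr > 0.9999).any(axis=1)]))
        raise CollinearityError(bad or features)
    res = sm.OLS(yy, design).fit()
    q = None
    if bh_qvalues:
        p = res.pvalues.drop("const")
        q = pd.Series(
            sm.stats.multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index
        )
    return RegressionModel(
        response=response_name,
        features=features,
        coefficients=res.params,
        standard_errors=res.bse,
        t_stats=res.tvalues,
        p_values=res.pvalues,
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        alpha=alpha,
        qvalues=q,
    )


def screen_and_fit(
    X: pd.DataFrame,
    y: pd.Series,
    rho_threshold: float = 0.2,
    response_name: str = "response",
    alpha: float = 0.05,
) -> tuple[ScreenResult, RegressionModel]:
    """Correlation filter followed by OLS — the default analysis route."""
    screen = spearman_screen(X, y, rho_threshold, response_name)
    model = fit_model(X, y, screen.selected, response_name, alpha=alpha)
    return screen, model


def _criterion_value(res, criterion: str) -> float:
    return res.aic if criterion == "aic" else res.bic


def stepwise_fit(
    X: pd.DataFrame,
    y: pd.Series,
    candidates: list[str] | None = None,
    criterion: str = "aic",
    response_name: str = "response",
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_iter: int = 200,
    alpha: float = 0.05,
) -> RegressionModel:
    """Forward-backward stepwise selection followed by OLS.

    ``criterion='aic'``/``'bic'`` accepts the move that most improves the
    information criterion; ``'pvalue'`` enters the strongest candidate with
    p < alpha_enter and removes terms with p > alpha_remove.
    """
    if criterion not in ("aic", "bic", "pvalue"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    candidates = list(X.columns) if candidates is None else list(candidates)
    current: list[str] = []

    def _fit(feats: list[str]):
        design, yy = _design(X, y, feats, standardize=True)
        return sm.OLS(yy, design).fit()

    for _ in range(max_iter):
        changed = False
        res = _fit(current)
        # forward
        remaining = [f for f in candidates if f not in current and X[f].nunique() > 1]
        if remaining:
            trials = {f: _fit(current + [f]) for f in remaining}
            if criterion == "pvalue":
                pvals = {f: r.pvalues[f] for f, r in trials.items()}
                best = min(pvals, key=pvals.get)
                if pvals[best] < alpha_enter:
                    current.append(best)
                    changed = True
            else:
                base = _criterion_value(res, criterion)
                scores = {f: _criterion_value(r, criterion) for f, r in trials.items()}
                best = min(scores, key=scores.get)
                if scores[best] < base - 1e-9:
                    current.append(best)
                    changed = True
        # backward
        if current:
            res = _fit(current)
            if criterion == "pvalue":
                p = res.pvalues.drop("const")
                worst = p.idxmax()
                if p[worst] > alpha_remove:
                    current.remove(worst)
                    changed = True
            else:
                base = _criterion_value(res, criterion)
                scores = {
                    f: _criterion_value(_fit([g for g in current if g != f]), criterion)
                    for f in current
                }
                worst = min(scores, key=scores.get)
                if scores[worst] < base - 1e-9:
                    current.remove(worst)
                    changed = True
        if not changed:
            break

    if not current:
        design, yy = _design(X, y, [], standardize=True)
        res = sm.OLS(yy, design).fit()
        return RegressionModel(
            response=response_name, features=[],
            coefficients=res.params, standard_errors=res.bse,
            t_stats=res.tvalues, p_values=res.pvalues,
            r_squared=float(res.rsquared), n=int(res.nobs), alpha=alpha,
        )
    return fit_model(X, y, current, response_name, alpha=alpha)


def orthogonality_report(
    model_mean: RegressionModel, model_cv2: RegressionModel
) -> dict[str, list[str]]:
    """Partition significant features into mean-only / cv2-only / shared."""
    a, b = set(model_mean.significant), set(model_cv2.significant)
    return {
        "mean_only": sorted(a - b),
        "cv2_only": sorted(b - a),
        "shared": sorted(a & b),
    }


def write_partition(partition: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(partition, fh, indent=2)
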