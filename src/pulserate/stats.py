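"""Stability percentiles, group tests, and the winsorized decay-rate regression.

The decay-rate modeling follows the analysis behind the TF / extended-me3 /
CTS comparison: log10 decay rates are winsorized at the top and bottom 1%,
regressed on the three binary features with or without all interaction terms
(coefficients beta0..beta7), and the fits are repeated on stratified
bootstrap resamples that draw the same number of genes (the minimum group
size by default) from each of the 8 nonoverlapping feature combinations,
giving every group equal weight regardless of its frequency.

With equal resample sizes per cell, both OLS fits are exact linear functions
of the 8 cell means, which is how the bootstrap is vectorized here; a test
verifies the reduction against a literal refit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

FEATURES = ("TF", "me3", "CTS")
COEF_NAMES = ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "beta7")
COEF_TERMS = ("intercept", "TF", "me3", "CTS", "TF:me3", "TF:CTS", "me3:CTS", "TF:me3:CTS")
# significance stars: * p<0.05, ** p<1e-9, *** p<1e-39
STAR_THRESHOLDS = (0.05, 1e-9, 1e-39)

CELLS = tuple(itertools.product((0, 1), repeat=3))  # (TF, me3, CTS)


def _cell_design(interactions: bool) -> np.ndarray:
    rows = []
    for t, m, c in CELLS:
        row = [1, t, m, c]
        if interactions:
            row += [t * m, t * c, m * c, t * m * c]
        rows.append(row)
    return np.array(rows, dtype=float)


def stability_percentile(decay: pd.Series) -> pd.Series:
    """Rank-transform decay rates to stability percentiles in (0, 100].

    Higher stability (lower decay) gets a higher percentile; ties share the
    average rank.
    """
    decay = decay.dropna()
    if len(decay) < 2:
        raise ValueError("need at least 2 genes")
    ranks = sps.rankdata(-decay.to_numpy(), method="average")
    return pd.Series(100.0 * ranks / len(decay), index=decay.index, name="stability_percentile")


def assign_stars(p: float) -> str:
    return "*" * sum(p < t for t in STAR_THRESHOLDS)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # exact null for small samples without ties; tie-corrected normal otherwise
    method = "exact" if min(len(x), len(y)) < 20 and len(np.unique(np.r_[x, y])) == len(x) + len(y) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_stability_test(
    decay: pd.Series, percentiles: pd.Series, group: set[str] | pd.Index
) -> dict:
    """Two-sided Mann-Whitney U of a gene group's decay rates vs all others."""
    group = set(group) & set(decay.index)
    other = [g for g in decay.index if g not in group]
    if not group or not other:
        raise ValueError("group and complement must both be nonempty")
    x = decay.loc[sorted(group)].to_numpy(float)
    y = decay.loc[other].to_numpy(float)
    u, p = _mannwhitney(x, y)
    return {
        "n_group": len(group),
        "n_other": len(other),
        "median_percentile": float(percentiles.loc[sorted(group)].median()),
        "U": u,
        "p": p,
        "stars": assign_stars(p),
    }


def composition_enrichment(
    group: set[str] | pd.Index, feature: pd.Series
) -> tuple[float, float]:
    """Fraction of a group carrying a feature, with Fisher-exact enrichment p.

    ``feature`` is a boolean Series over the gene universe; the 2x2 table
    compares the group against the rest of the universe (two-sided test).
    """
    universe = feature.index
    group = set(group) & set(universe)
    if not group:
        raise ValueError("empty group")
    in_group = universe.isin(group)
    a = int((feature[in_group]).sum())
    b = int(len(group) - a)
    c = int(feature[~in_group].sum())
    d = int((~in_group).sum() - c)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return a / len(group), float(p)


def odds_ratio_ci(table: np.ndarray, alpha: float = 0.05) -> dict:
    """Odds ratio with Woolf (log-normal) CI and Fisher-exact p.

    Haldane-Anscombe 0.5 correction is applied to all cells when any cell is
    zero; a fully empty row or column leaves the OR undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined: empty row or column")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    if (t == 0).any():
        t = t + 0.5
    a, b, c, d = t.ravel()
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return {
        "odds_ratio": float(or_),
        "ci_low": float(np.exp(np.log(or_) - z * se)),
        "ci_high": float(np.exp(np.log(or_) + z * se)),
        "p": float(p),
    }


def winsorize_log(decay: pd.Series, tail: float = 0.01) -> pd.Series:
    """log10-transform decay rates and winsorize both tails.

    Values below the ``tail`` quantile (linear-interpolation convention) are
    set to it, values above the ``1 - tail`` quantile likewise.
    """
    if (decay <= 0).any() or decay.isna().any():
        raise ValueError("decay rates must be positive and non-missing")
    if not 0 <= tail < 0.5:
        raise ValueError("tail must lie in [0, 0.5)")
    y = np.log10(decay.to_numpy(float))
    lo, hi = np.quantile(y, [tail, 1 - tail])
    return pd.Series(np.clip(y, lo, hi), index=decay.index, name="log10_decay")


@dataclass
class RegressionResult:
    """OLS fit of log10 decay on the three features (optionally interactions)."""

    model: str                      # 'with_interactions' | 'without_interactions'
    params: pd.Series               # indexed by beta0.. with term names as attrs
    pvalues: pd.Series
    terms: tuple[str, ...]
    nobs: int
    cell_means: pd.Series           # observed mean per occupied cell
    sm_result: object = field(repr=False, default=None)

    def fitted_cell_means(self) -> pd.Series:
        D = _cell_design(self.model == "with_interactions")
        fitted = D @ self.params.to_numpy()
        return pd.Series(fitted, index=[str(c) for c in CELLS])


def _flags_matrix(flags: pd.DataFrame) -> np.ndarray:
    cols = {c.lower(): c for c in flags.columns}
    try:
        mat = flags[[cols["tf"], cols["me3"], cols["cts"]]].to_numpy()
    except KeyError as exc:
        raise ValueError("flags must have tf, me3, cts columns") from exc
    return mat.astype(float)


def fit_linear_model(
    y: pd.Series, flags: pd.DataFrame, interactions: bool = True
) -> RegressionResult:
    """OLS of y on [1, TF, me3, CTS] (+ all interactions if requested).

    With interactions the model is saturated: fitted values equal the 8 cell
    means whenever all cells are occupied; an empty cell makes the design
    rank-deficient and raises an error naming the cell.
    """
    X3 = _flags_matrix(flags.loc[y.index])
    yv = y.to_numpy(float)
    cols = [np.ones(len(yv)), X3[:, 0], X3[:, 1], X3[:, 2]]
    if interactions:
        cols += [
            X3[:, 0] * X3[:, 1],
            X3[:, 0] * X3[:, 2],
            X3[:, 1] * X3[:, 2],
            X3[:, 0] * X3[:, 1] * X3[:, 2],
        ]
        occupied = {tuple(int(v) for v in row) for row in X3}
        missing = [c for c in CELLS if c not in occupied]
        if missing:
            raise ValueError(f"empty design cell(s) {missing} (TF, me3, CTS)")
    X = np.column_stack(cols)
    terms = COEF_TERMS[: X.shape[1]]
    res = sm.OLS(yv, X).fit()
    names = COEF_NAMES[: X.shape[1]]
    cell_labels = [str(tuple(int(v) for v in row)) for row in X3]
    cell_means = pd.Series(yv).groupby(cell_labels).mean()
    return RegressionResult(
        model="with_interactions" if interactions else "without_interactions",
        params=pd.Series(res.params, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        terms=terms,
        nobs=len(yv),
        cell_means=cell_means,
        sm_result=res,
    )


@dataclass
class BootstrapResult:
    """Stratified-bootstrap coefficient distributions for both models."""

    draws_interaction: pd.DataFrame     # n_iter x 8
    draws_additive: pd.DataFrame        # n_iter x 4
    per_group_n: int
    group_sizes: pd.Series

    def frac_positive(self, model: str = "additive") -> pd.Series:
        draws = self.draws_additive if model == "additive" else self.draws_interaction
        return (draws > 0).mean()

    def summary(self) -> pd.DataFrame:
        rows = []
        for model, draws in (
            ("without_interactions", self.draws_additive),
            ("with_interactions", self.draws_interaction),
        ):
            q = draws.quantile([0.025, 0.5, 0.975])
            for name in draws.columns:
                rows.append(
                    {
                        "model": model,
                        "coefficient": name,
                        "q2.5": q.loc[0.025, name],
                        "median": q.loc[0.5, name],
                        "q97.5": q.loc[0.975, name],
                        "frac_positive": float((draws[name] > 0).mean()),
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_model(
    y: pd.Series,
    flags: pd.DataFrame,
    n_iter: int = 10000,
    per_group_n: int | str = "min",
    seed: int | None = None,
) -> BootstrapResult:
    """Refit both models on stratified resamples of the 8 feature groups.

    Each iteration draws ``per_group_n`` genes with replacement from every
    nonoverlapping (TF, me3, CTS) group ('min' = the smallest group's size)
    and refits the models with and without interactions.  Because every cell
    contributes the same number of observations, both OLS solutions reduce to
    fixed linear maps of the 8 resampled cell means, which is how the loop is
    vectorized.
    """
    X3 = _flags_matrix(flags.loc[y.index]).astype(int)
    yv = y.to_numpy(float)
    idx_by_cell = []
    for cell in CELLS:
        members = np.flatnonzero((X3 == np.array(cell)).all(axis=1))
        if members.size == 0:
            raise ValueError(f"empty group {cell} (TF, me3, CTS)")
        idx_by_cell.append(members)
    sizes = pd.Series([m.size for m in idx_by_cell], index=[str(c) for c in CELLS])
    n = int(sizes.min()) if per_group_n == "min" else int(per_group_n)
    if n < 1:
        raise ValueError("per_group_n must be >= 1")

    rng = np.random.default_rng(seed)
    means = np.empty((n_iter, 8))
    for j, members in enumerate(idx_by_cell):
        draws = rng.integers(0, members.size, size=(n_iter, n))
        means[:, j] = yv[members[draws]].mean(axis=1)

    D8 = _cell_design(True)
    D4 = _cell_design(False)
    beta_int = means @ np.linalg.inv(D8).T
    beta_add = means @ np.linalg.pinv(D4).T
    return BootstrapResult(
        draws_interaction=pd.DataFrame(beta_int, columns=list(COEF_NAMES)),
        draws_additive=pd.DataFrame(beta_add, columns=list(COEF_NAMES[:4])),
        per_group_n=n,
        group_sizes=sizes,
    )


def group_mean_changes(y: pd.Series, flags: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean change between matched feature-positive/negative groups.

    For each feature and each of the 4 settings of the other two features:
    delta = mean(y | feature=1, context) - mean(y | feature=0, context).
    Pairs with an empty cell are reported with a missing delta, not zero.
    """
    X3 = _flags_matrix(flags.loc[y.index]).astype(int)
    yv = y.to_numpy(float)
    rows = []
    for fi, feature in enumerate(FEATURES):
        others = [i for i in range(3) if i != fi]
        for ctx in itertools.product((0, 1), repeat=2):
            in_ctx = (X3[:, others[0]] == ctx[0]) & (X3[:, others[1]] == ctx[1])
            pos = in_ctx & (X3[:, fi] == 1)
            neg = in_ctx & (X3[:, fi] == 0)
            delta = yv[pos].mean() - yv[neg].mean() if pos.any() and neg.any() else np.nan
            rows.append(
                {
                    "feature": feature,
                    "context": f"{FEATURES[others[0]]}={ctx[0]},{FEATURES[others[1]]}={ctx[1]}",
                    "delta": delta,
                    "n_with": int(pos.sum()),
                    "n_without": int(neg.sum()),
                }
            )
    return pd.DataFrame(rows)


def correlation_r2(
    x: pd.Series, y: pd.Series, log: bool = True
) -> float:
    """Squared Pearson correlation, by default on log10(value + min positive).

    The pseudocount is the smallest positive value across both inputs.
    """
    shared = x.index.intersection(y.index)
    xv, yv = x.loc[shared].to_numpy(float), y.loc[shared].to_numpy(float)
    if log:
        pooled = np.r_[xv, yv]
        positive = pooled[pooled > 0]
        if positive.size == 0:
            raise ValueError("no positive values for log transform")
        pseudo = positive.min()
        xv, yv = np.log10(xv + pseudo), np.log10(yv + pseudo)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance input")
    r, _ = sps.pearsonr(xv, yv)
    return float(r**2)
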