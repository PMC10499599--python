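"""Association statistics: rank-based regression, partial Spearman correlation,
group tests, the two-stage host-marker screen, and Benjamini-Hochberg FDR.

The rank regression minimises Jaeckel's dispersion of the residuals under
Wilcoxon scores; inference uses the scale parameter tau estimated from the
residual density.  The partial Spearman correlation is the partial Pearson
correlation of average-rank-transformed variables, with a t-approximation
for the p-value (df = n - 2 - #covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "rank_regression",
    "partial_spearman",
    "bh_adjust",
    "kruskal_dunn",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "screen_host_markers",
]


@dataclass
class AssociationResult:
    target_id: str
    predictor_id: str
    coefficient: float
    standardized_coefficient: float
    p: float
    p_adj: float | None
    n_used: int
    covariates: tuple = ()


# ---------------------------------------------------------------------------
# multiple-testing correction


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# rank-based regression (Jaeckel dispersion, Wilcoxon scores)


def _wilcoxon_scores(n: int) -> np.ndarray:
    return np.sqrt(12.0) * (np.arange(1, n + 1) / (n + 1.0) - 0.5)


def _dispersion(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    e = y - X @ beta
    ranks = stats.rankdata(e, method="average")
    a = np.sqrt(12.0) * (ranks / (len(e) + 1.0) - 0.5)
    return float(np.sum(a * e))


def _tau_estimate(resid: np.ndarray, p: int) -> float:
    """tau = 1 / (sqrt(12) * integral f^2), with a leave-one-out Gaussian-kernel
    estimate of the residual density functional and a df correction."""
    n = len(resid)
    sd = np.std(resid, ddof=1)
    iqr = np.subtract(*np.percentile(resid, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = 0.9 * scale * n ** (-0.2)
    if h <= 0:
        return 0.0
    diffs = resid[:, None] - resid[None, :]
    K = np.exp(-0.5 * (diffs / h) ** 2) / (h * np.sqrt(2 * np.pi))
    np.fill_diagonal(K, 0.0)
    int_f2 = K.sum() / (n * (n - 1))
    tau = 1.0 / (np.sqrt(12.0) * int_f2)
    return tau * np.sqrt(n / max(n - p - 1, 1))


def rank_regression(y, X, feature_names=None):
    """Rank-based linear regression.

    Slopes minimise Jaeckel's rank dispersion with Wilcoxon scores; the
    intercept is the median residual.  Returns a DataFrame with columns
    ``coef``, ``se``, ``t``, ``p`` indexed by predictor name (intercept
    first); Wald p-values use the tau scale estimate with df = n - p - 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("rank_regression requires finite complete cases")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
    if rank < p + 1:
        raise ValueError("design matrix is rank deficient (collinear columns)")

    beta0, *_ = np.linalg.lstsq(X - X.mean(axis=0), y - y.mean(), rcond=None)
    res = optimize.minimize(
        _dispersion, beta0, args=(X, y), method="Powell",
        options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 10000},
    )
    # polish: Powell can stall on the piecewise-linear surface
    res2 = optimize.minimize(
        _dispersion, res.x, args=(X, y), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 40000},
    )
    beta = res2.x if res2.fun <= res.fun else res.x

    resid = y - X @ beta
    intercept = float(np.median(resid))
    resid_c = resid - intercept
    tau = _tau_estimate(resid_c, p)
    Xc = X - X.mean(axis=0)
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    se = tau * np.sqrt(np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    df = n - p - 1
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    out = pd.DataFrame(
        {
            "coef": np.concatenate([[intercept], beta]),
            "se": np.concatenate([[np.nan], se]),
            "t": np.concatenate([[np.nan], tvals]),
            "p": np.concatenate([[np.nan], pvals]),
        },
        index=["intercept"] + names,
    )
    out.attrs["dispersion"] = float(min(res.fun, res2.fun))
    out.attrs["tau"] = float(tau)
    out.attrs["n_used"] = int(n)
    return out


def rank_dispersion(beta, X, y) -> float:
    """Jaeckel's rank dispersion at a candidate slope vector (public for checks)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return _dispersion(np.atleast_1d(np.asarray(beta, dtype=float)), X, np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# partial Spearman correlation


def _rank_cols(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, M)


def partial_spearman(x, y, Z=None, method: str = "residual"):
    """Partial Spearman correlation of x and y given covariates Z.

    Average-rank transforms are applied to x, y and every column of Z; the
    partial Pearson correlation of the ranked data is computed either by
    residualising on the ranked covariates (``method='residual'``) or from
    the precision matrix (``method='precision'``); the two agree to
    numerical precision.  With no covariates this reduces exactly to the
    ordinary Spearman correlation.  Returns ``(rho, p)`` with p from the
    t-approximation at df = n - 2 - #covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if Z is None or (hasattr(Z, "shape") and np.size(Z) == 0):
        Z = np.empty((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 3:
        raise ValueError("insufficient data: need n > #covariates + 3")
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[mask], y[mask], Z[mask]
    n = len(x)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if k == 0:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        rZ = _rank_cols(Z)
        if method == "residual":
            Q = np.column_stack([np.ones(n), rZ])
            bx, *_ = np.linalg.lstsq(Q, rx, rcond=None)
            by, *_ = np.linalg.lstsq(Q, ry, rcond=None)
            ex, ey = rx - Q @ bx, ry - Q @ by
            rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
        elif method == "precision":
            R = np.corrcoef(np.column_stack([rx, ry, rZ]), rowvar=False)
            P = np.linalg.pinv(R)
            rho = float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
        else:
            raise ValueError(f"unknown method {method!r}")
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


# ---------------------------------------------------------------------------
# group tests


def kruskal_dunn(values, groups):
    """Tie-corrected Kruskal-Wallis test plus Dunn's pairwise z-tests (BH adjusted).

    Returns ``(overall_p, pairwise)`` where pairwise is a DataFrame with
    columns group1, group2, z, p, p_adj.  Groups with fewer than 2 members
    are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep_groups = []
    for g in pd.unique(groups):
        if np.sum(groups == g) >= 2:
            keep_groups.append(g)
        else:
            warnings.warn(f"group {g!r} has < 2 members; excluded", stacklevel=2)
    if len(keep_groups) < 2:
        raise ValueError("need at least two groups with >= 2 members")
    mask = np.isin(groups, keep_groups)
    values, groups = values[mask], groups[mask]

    samples = [values[groups == g] for g in keep_groups]
    overall = stats.kruskal(*samples)

    # Dunn's test on the pooled average ranks with tie correction
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    rows = []
    for i, gi in enumerate(keep_groups):
        for gj in keep_groups[i + 1:]:
            ri = ranks[groups == gi]
            rj = ranks[groups == gj]
            ni, nj = len(ri), len(rj)
            num = ri.mean() - rj.mean()
            den = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = num / den
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((gi, gj, z, p))
    pw = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    pw["p_adj"] = bh_adjust(pw["p"].to_numpy())
    return float(overall.pvalue), pw


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum p-value."""
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def fisher_exact(table, n_mc: int = 20000, seed: int = 0) -> float:
    """Fisher's exact test: hypergeometric enumeration for 2x2 tables,
    seeded Monte Carlo with fixed margins for larger tables."""
    T = np.asarray(table, dtype=int)
    if T.min() < 0:
        raise ValueError("table entries must be non-negative")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("empty row or column margin")
    if T.shape == (2, 2):
        return float(stats.fisher_exact(T)[1])
    # Monte Carlo over tables with the observed margins
    rng = np.random.default_rng(seed)
    row_m = T.sum(axis=1)
    col_m = T.sum(axis=0)
    logp_obs = _log_table_prob(T)
    hits = 0
    cols_expanded = np.repeat(np.arange(len(col_m)), col_m)
    for _ in range(n_mc):
        perm = rng.permutation(cols_expanded)
        sim = np.zeros_like(T)
        start = 0
        for i, m in enumerate(row_m):
            chunk = perm[start:start + m]
            for c in chunk:
                sim[i, c] += 1
            start += m
        if _log_table_prob(sim) <= logp_obs + 1e-12:
            hits += 1
    return float((hits + 1) / (n_mc + 1))


def _log_table_prob(T: np.ndarray) -> float:
    from scipy.special import gammaln

    n = T.sum()
    return float(
        gammaln(T.sum(axis=1) + 1).sum()
        + gammaln(T.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(T + 1).sum()
    )


# ---------------------------------------------------------------------------
# host-marker screen


def screen_host_markers(markers: pd.DataFrame, homa_ir, ir_labels, age, sex,
                        alpha: float = 0.05, gamma_link: str = "log") -> pd.DataFrame:
    """Two-stage marker screen against insulin resistance.

    Stage 1: per marker, gamma-family GLM of HOMA-IR on marker + age + sex;
    BH over all markers, keep p_adj < alpha.  Stage 2: logistic regression of
    IR (1) vs IS (0), intermediates excluded, on the stage-1 survivors with
    age + sex; BH again, keep p_adj < alpha.  Returns a DataFrame of the
    surviving markers with both stages' statistics.
    """
    homa_ir = np.asarray(homa_ir, dtype=float)
    if np.any(homa_ir[np.isfinite(homa_ir)] <= 0):
        raise ValueError("gamma GLM requires strictly positive HOMA-IR")
    ir_labels = np.asarray(ir_labels)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    link = sm.families.links.Log() if gamma_link == "log" else sm.families.links.InversePower()

    stage1 = []
    for m in markers.columns:
        x = markers[m].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(homa_ir) & np.isfinite(age) & np.isfinite(sex)
        X = np.column_stack([np.ones(mask.sum()), x[mask], age[mask], sex[mask]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"marker {m!r}: rank-deficient design (constant marker?)")
        fit = sm.GLM(homa_ir[mask], X, family=sm.families.Gamma(link=link)).fit()
        stage1.append((m, fit.params[1], fit.pvalues[1], int(mask.sum())))
    s1 = pd.DataFrame(stage1, columns=["marker", "coef_gamma", "p_gamma", "n_gamma"])
    s1["p_adj_gamma"] = bh_adjust(s1["p_gamma"].to_numpy())
    survivors = s1[s1["p_adj_gamma"] < alpha]

    rows = []
    binary = np.where(ir_labels == "IR", 1.0, np.where(ir_labels == "IS", 0.0, np.nan))
    for _, r in survivors.iterrows():
        m = r["marker"]
        x = markers[m].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(binary) & np.isfinite(age) & np.isfinite(sex)
        X = np.column_stack([np.ones(mask.sum()), x[mask], age[mask], sex[mask]])
        fit = sm.GLM(binary[mask], X, family=sm.families.Binomial()).fit()
        rows.append((m, r["coef_gamma"], r["p_gamma"], r["p_adj_gamma"],
                     fit.params[1], fit.pvalues[1], int(mask.sum())))
    s2 = pd.DataFrame(rows, columns=["marker", "coef_gamma", "p_gamma", "p_adj_gamma",
                                     "coef_logit", "p_logit", "n_logit"])
    if len(s2):
        s2["p_adj_logit"] = bh_adjust(s2["p_logit"].to_numpy())
        s2 = s2[s2["p_adj_logit"] < alpha].reset_index(drop=True)
    else:
        s2["p_adj_logit"] = pd.Series(dtype=float)
    return s2
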