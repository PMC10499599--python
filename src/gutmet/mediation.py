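"""Screened causal mediation: do plasma cytokines carry the in silico effect
of faecal carbohydrates on insulin-resistance markers?

The screen keeps (metabolite, cytokine, marker) triplets whose
metabolite-marker and cytokine-marker associations (each adjusted for age
and sex) are BH-significant within their screen family.  For each eligible
triplet two Gaussian linear models are fit:

    mediator model:  cytokine ~ metabolite + age + sex
    outcome model:   marker   ~ metabolite + age + sex + cytokine

The average causal mediation effect (ACME) is the product of the
metabolite->cytokine path (a) and the cytokine->marker path (b); the average
direct effect (ADE) is the metabolite coefficient of the outcome model; for
these linear models total = ACME + ADE exactly.  Uncertainty comes from a
nonparametric bootstrap: rows are resampled with replacement, both models
refit jointly, and percentile intervals / two-sided p-values are read off
the bootstrap distribution.  Exposure and mediator are scaled, so effects
are per standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .stats import bh_adjust

__all__ = [
    "MediationParams",
    "MediationResult",
    "screen_triplets",
    "mediate",
    "mediation_table",
]

#: below this |total effect| the proportion mediated is reported as undefined
_PROP_FLOOR = 1e-8


@dataclass(frozen=True)
class MediationParams:
    n_boot: int = 1000
    alpha_adj: float = 0.05
    covariates: tuple = ("age", "sex")
    markers: tuple = ("homa_ir", "bmi", "tg_mgdl", "hdl_mgdl")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 200:
            raise ValueError("n_boot must be >= 200")


@dataclass
class MediationResult:
    metabolite_id: str
    cytokine_id: str
    marker_id: str
    acme: float
    ade: float
    total: float
    prop_mediated: float  # NaN when |total| below the numeric floor
    acme_ci: tuple
    p_acme: float
    p_adj: float | None = None
    n_used: int = 0


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy import stats as sps

    n, p = X.shape
    coef = _ols(X, y)
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    return coef, 2.0 * sps.t.sf(np.abs(t), n - p)


def _scale(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def screen_triplets(carbohydrates: pd.DataFrame, cytokines: pd.DataFrame,
                    markers: pd.DataFrame, covariates: pd.DataFrame,
                    alpha_adj: float = 0.05) -> list[tuple]:
    """Eligible (metabolite, cytokine, marker) triplets.

    A triplet qualifies when both the metabolite-marker and the
    cytokine-marker linear association (adjusted for the covariates) pass
    BH at ``alpha_adj``; BH runs within each screen family (all
    metabolite x marker tests, and all cytokine x marker tests).
    Metabolite and cytokine values are scaled before testing.
    """

    def family(predictors: pd.DataFrame) -> pd.DataFrame:
        rows = []
        Zc = covariates.to_numpy(dtype=float)
        for pcol in predictors.columns:
            x = predictors[pcol].to_numpy(dtype=float)
            for mcol in markers.columns:
                y = markers[mcol].to_numpy(dtype=float)
                mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Zc), axis=1)
                X = np.column_stack([np.ones(mask.sum()), _scale(x[mask]), Zc[mask]])
                _, pv = _ols_pvalues(X, y[mask])
                rows.append((pcol, mcol, pv[1]))
        out = pd.DataFrame(rows, columns=["predictor", "marker", "p"])
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        return out

    met_scr = family(carbohydrates)
    cyt_scr = family(cytokines)
    met_ok = {(r.predictor, r.marker) for r in met_scr.itertuples() if r.p_adj < alpha_adj}
    cyt_ok = {(r.predictor, r.marker) for r in cyt_scr.itertuples() if r.p_adj < alpha_adj}
    triplets = []
    for met, marker in sorted(met_ok):
        for cyt in cytokines.columns:
            if (cyt, marker) in cyt_ok:
                triplets.append((met, cyt, marker))
    return triplets


def mediate(metabolite, cytokine, marker, covariates,
            params: MediationParams = MediationParams(),
            ids: tuple = ("metabolite", "cytokine", "marker")) -> MediationResult:
    """Fit the mediator and outcome models for one triplet with bootstrap inference.

    Inputs are 1-d arrays over the same samples; ``covariates`` is a 2-d
    array (or DataFrame).  Exposure and mediator are scaled internally.
    """
    x = np.asarray(metabolite, dtype=float)
    m = np.asarray(cytokine, dtype=float)
    y = np.asarray(marker, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    mask = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, m, y, Z = x[mask], m[mask], y[mask], Z[mask]
    n = len(x)
    if abs(np.corrcoef(x, m)[0, 1]) > 0.999:
        raise ValueError("exposure and mediator are numerically collinear")
    xs, ms = _scale(x), _scale(m)

    def fit(xv, mv, yv, Zv):
        Xm = np.column_stack([np.ones(len(xv)), xv, Zv])
        a = _ols(Xm, mv)[1]
        Xy = np.column_stack([np.ones(len(xv)), xv, Zv, mv])
        coefs = _ols(Xy, yv)
        c_prime, b = coefs[1], coefs[-1]
        return a * b, c_prime

    acme, ade = fit(xs, ms, y, Z)
    total = acme + ade
    prop = acme / total if abs(total) > _PROP_FLOOR else float("nan")

    rng = np.random.default_rng(params.seed)
    boot = np.empty(params.n_boot)
    for i in range(params.n_boot):
        idx = rng.integers(0, n, n)
        try:
            boot[i], _ = fit(xs[idx], ms[idx], y[idx], Z[idx])
        except np.linalg.LinAlgError:
            boot[i] = np.nan
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    frac = min(np.mean(boot <= 0), np.mean(boot >= 0))
    p_acme = float(min(1.0, 2.0 * max(frac, 1.0 / len(boot))))

    return MediationResult(
        metabolite_id=ids[0], cytokine_id=ids[1], marker_id=ids[2],
        acme=float(acme), ade=float(ade), total=float(total),
        prop_mediated=float(prop), acme_ci=(float(lo), float(hi)),
        p_acme=p_acme, n_used=n,
    )


def mediation_table(data: pd.DataFrame, triplets: list[tuple],
                    params: MediationParams = MediationParams()) -> pd.DataFrame:
    """Run ``mediate`` for every triplet and BH-adjust p_acme across the table.

    ``data`` holds all referenced columns plus the covariates named in
    ``params.covariates``.  Returns a DataFrame sorted as given, with a
    ``significant`` flag at ``alpha_adj``.
    """
    results = []
    for j, (met, cyt, marker) in enumerate(triplets):
        res = mediate(
            data[met], data[cyt], data[marker],
            data.loc[:, list(params.covariates)],
            MediationParams(n_boot=params.n_boot, alpha_adj=params.alpha_adj,
                            covariates=params.covariates, markers=params.markers,
                            seed=params.seed + j),
            ids=(met, cyt, marker),
        )
        results.append(res)
    out = pd.DataFrame(
        [
            (r.metabolite_id, r.cytokine_id, r.marker_id, r.acme, r.ade, r.total,
             r.prop_mediated, r.acme_ci[0], r.acme_ci[1], r.p_acme, r.n_used)
            for r in results
        ],
        columns=["metabolite", "cytokine", "marker", "acme", "ade", "total",
                 "prop_mediated", "acme_lo", "acme_hi", "p_acme", "n_used"],
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p_acme"].to_numpy())
        out["significant"] = out["p_adj"] < params.alpha_adj
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
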