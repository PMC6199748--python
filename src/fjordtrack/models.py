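"""Seasonal occupancy smooths and movement-metric mixed models.

Two model families:

* :func:`fit_occupancy` — penalized-spline logistic fit of a habitat
  indicator on the day-of-season index, one smooth per period, with an
  individual-level random intercept and within-individual AR1 residual
  correlation handled as variance components estimated from working
  residuals; pointwise 95% bands are widened by the implied design
  effect.
* :func:`fit_movement_model` — Gaussian feasible-GLS fit of log speed or
  turning angle on habitat x period with a per-animal random intercept
  and AR1 errors on the hourly chain (gaps longer than the step break
  the chain). Wald-type p-values.

These are deliberately not a re-implementation of any particular GAMM
package's numerics; the target is behavioural equivalence (curve shapes,
band separation, honest uncertainty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
import statsmodels.api as sm

from .errors import DegenerateFitError, InputError
from .habitat_metrics import HABITAT_CLASSES

__all__ = [
    "OccupancyFit",
    "fit_occupancy",
    "fit_movement_model",
    "summarize_metrics_by_class",
]


# ---------------------------------------------------------------------
# helpers shared by both model families
# ---------------------------------------------------------------------


def _segment_ids(df: pd.DataFrame, step: pd.Timedelta) -> np.ndarray:
    """Integer id per row; increments whenever the hourly chain breaks."""
    seg = np.zeros(len(df), dtype=int)
    counter = 0
    pos = 0
    for _, sub in df.groupby("animal_id", sort=False):
        t = pd.DatetimeIndex(sub["timestamp"])
        breaks = np.ones(len(sub), dtype=bool)
        breaks[1:] = (t[1:] - t[:-1]) != step
        counter += 1
        ids = counter + np.cumsum(breaks) - 1
        counter = ids[-1] + 1 if len(ids) else counter
        seg[pos : pos + len(sub)] = ids
        pos += len(sub)
    return seg


def _lag1_autocorr(resid: np.ndarray, seg: np.ndarray) -> tuple[float, int]:
    """Pooled lag-1 autocorrelation of residuals within contiguous segments."""
    same = seg[1:] == seg[:-1]
    a, b = resid[:-1][same], resid[1:][same]
    n_pairs = int(same.sum())
    denom = np.sum(resid**2)
    if n_pairs < 2 or denom <= 0:
        return 0.0, n_pairs
    rho = float(np.sum(a * b) / denom * len(resid) / max(n_pairs, 1))
    return float(np.clip(rho, -0.98, 0.98)), n_pairs


def _random_intercept_var(resid: np.ndarray, animals: np.ndarray, deff_ar1: float) -> float:
    """Moment estimate of the between-animal variance of residual means."""
    df = pd.DataFrame({"r": resid, "a": animals})
    g = df.groupby("a")["r"]
    means, sizes = g.mean().to_numpy(), g.size().to_numpy()
    if len(means) < 2:
        return 0.0
    var_within = float(np.var(resid)) if np.var(resid) > 0 else 0.0
    expected = var_within * deff_ar1 * float(np.mean(1.0 / sizes))
    return max(0.0, float(np.var(means, ddof=1)) - expected)


# ---------------------------------------------------------------------
# Occupancy smooths
# ---------------------------------------------------------------------


@dataclass
class OccupancyFit:
    """Per-period seasonal occupancy smooth for one habitat class."""

    habitat: str
    curves: dict  # period -> DataFrame(day_index, fit, lo95, hi95), probability scale
    rho: float
    rho_se: float
    sigma2_b: float
    deff: float
    alpha: dict  # period -> penalty weight used

    def band_overlap(self, periods: tuple[str, str] | None = None) -> np.ndarray:
        """Boolean per grid point: do the two periods' bands overlap?"""
        keys = periods or tuple(self.curves)
        a, b = self.curves[keys[0]], self.curves[keys[1]]
        grid = np.intersect1d(a["day_index"], b["day_index"])
        aa = a.set_index("day_index").loc[grid]
        bb = b.set_index("day_index").loc[grid]
        return ~((aa["hi95"].to_numpy() < bb["lo95"].to_numpy()) | (bb["hi95"].to_numpy() < aa["lo95"].to_numpy()))


def fit_occupancy(
    series: pd.DataFrame,
    habitat: str,
    df_spline: int = 10,
    day_grid: np.ndarray | None = None,
    random_intercept: bool = True,
    ar1: bool = True,
    alpha: float | None = None,
) -> OccupancyFit:
    """Penalized logistic smooth of one habitat indicator on day index.

    ``series`` is :func:`fjordtrack.habitat_metrics.occupancy_series`
    output and must carry ``occ_<habitat>``, ``day_index``, ``period``,
    ``animal_id`` and ``timestamp``. One smooth is fitted per period;
    the AR1 coefficient and the random-intercept variance are estimated
    from working residuals and inflate the pointwise bands via a Kish
    design effect. Set ``random_intercept=False`` / ``ar1=False`` to
    constrain either component to zero (plain penalized GAM).
    """
    col = f"occ_{habitat}"
    if col not in series.columns:
        raise InputError(f"series lacks column {col}; run occupancy_series first")
    if series["animal_id"].nunique() < 2:
        raise InputError("fit_occupancy needs at least 2 animals")
    periods = sorted(series["period"].unique())
    y_all = series[col].to_numpy()
    if y_all.min() == y_all.max():
        raise DegenerateFitError(f"habitat {habitat!r}: indicator is constant ({y_all[0]})")

    curves: dict = {}
    alphas: dict = {}
    resid_parts, seg_parts, animal_parts = [], [], []
    step = pd.Timedelta(hours=1)
    for period in periods:
        sub = series[series["period"] == period].sort_values(["animal_id", "timestamp"])
        y = sub[col].to_numpy().astype(float)
        if y.min() == y.max():
            raise DegenerateFitError(f"habitat {habitat!r}: indicator constant in period {period!r}")
        x = sub["day_index"].to_numpy().astype(float)
        bs = BSplines(x[:, None], df=[df_spline], degree=[3], include_intercept=False)
        exog = np.ones((len(y), 1))
        if alpha is None:
            pen = _select_alpha(y, exog, bs)
        else:
            pen = float(alpha)
        model = GLMGam(y, exog=exog, smoother=bs, alpha=[pen], family=sm.families.Binomial())
        res = model.fit()
        alphas[period] = pen

        grid = day_grid if day_grid is not None else np.arange(x.min(), x.max() + 1)
        grid = np.asarray(grid, dtype=float)
        basis = bs.transform(grid[:, None])
        design = np.column_stack([np.ones(len(grid)), basis])
        eta = design @ res.params
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", design, cov, design), 0.0))
        curves[period] = pd.DataFrame({"day_index": grid, "eta": eta, "eta_se": se})

        mu = res.fittedvalues
        w = np.maximum(mu * (1 - mu), 1e-8)
        pearson = (y - mu) / np.sqrt(w)
        resid_parts.append(pearson)
        seg_parts.append(_segment_ids(sub, step))
        animal_parts.append(sub["animal_id"].to_numpy())

    resid = np.concatenate(resid_parts)
    segs = _relabel_segments(seg_parts)
    animals = np.concatenate(animal_parts)
    rho, n_pairs = _lag1_autocorr(resid, segs) if ar1 else (0.0, 0)
    rho_se = 1.0 / np.sqrt(max(n_pairs, 1))
    deff_ar1 = (1.0 + rho) / (1.0 - rho) if ar1 else 1.0
    sigma2_b = _random_intercept_var(resid, animals, deff_ar1) if random_intercept else 0.0
    m_bar = len(resid) / series["animal_id"].nunique()
    deff = deff_ar1 + sigma2_b * m_bar
    infl = np.sqrt(deff)

    z = stats.norm.ppf(0.975)
    for period, cur in curves.items():
        lo = _expit(cur["eta"] - z * infl * cur["eta_se"])
        hi = _expit(cur["eta"] + z * infl * cur["eta_se"])
        curves[period] = pd.DataFrame(
            {"day_index": cur["day_index"], "fit": _expit(cur["eta"]), "lo95": lo, "hi95": hi}
        )
    return OccupancyFit(
        habitat=habitat, curves=curves, rho=rho, rho_se=rho_se, sigma2_b=sigma2_b, deff=deff, alpha=alphas
    )


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _relabel_segments(parts: list[np.ndarray]) -> np.ndarray:
    out = []
    offset = 0
    for p in parts:
        out.append(p + offset)
        offset += (p.max() + 1) if len(p) else 0
    return np.concatenate(out)


def _select_alpha(y, exog, bs, grid=(1e0, 1e1, 1e2, 1e3, 1e4, 1e5)) -> float:
    """Pick the spline penalty by BIC over a coarse grid."""
    best, best_alpha = np.inf, grid[0]
    for a in grid:
        try:
            res = GLMGam(y, exog=exog, smoother=bs, alpha=[a], family=sm.families.Binomial()).fit()
            bic = res.bic_llf if np.isfinite(res.bic_llf) else np.inf
        except Exception:
            continue
        if bic < best:
            best, best_alpha = bic, a
    return float(best_alpha)


# ---------------------------------------------------------------------
# Movement mixed model (feasible GLS)
# ---------------------------------------------------------------------


def _movement_design(df: pd.DataFrame, period_labels: list[str]) -> tuple[np.ndarray, list[str]]:
    ref_habitat = HABITAT_CLASSES[0]
    other_habitats = [h for h in HABITAT_CLASSES if h != ref_habitat]
    second = period_labels[1]
    habitat = df["habitat"].to_numpy()
    period = df["period"].to_numpy()
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for h in other_habitats:
        cols.append((habitat == h).astype(float))
        names.append(f"habitat{h}")
    cols.append((period == second).astype(float))
    names.append(f"period{second}")
    for h in other_habitats:
        cols.append(((habitat == h) & (period == second)).astype(float))
        names.append(f"period{second}: habitat{h}")
    return np.column_stack(cols), names


def fit_movement_model(
    metric: str,
    classified: pd.DataFrame,
    step: pd.Timedelta = pd.Timedelta(hours=1),
) -> pd.DataFrame:
    """Gaussian mixed model of a movement metric on habitat x period.

    ``metric`` is ``"log_speed"`` or ``"turn"``. Fixed effects are
    habitat (reference: Glacier-Fronts), period (reference: the earlier
    label) and their interaction; a per-animal random intercept and AR1
    errors within the hourly chain are estimated by moments from OLS
    residuals and absorbed through one feasible-GLS step. Returns a
    coefficient table (term, estimate, std_error, p_value) with the
    estimated variance components in ``DataFrame.attrs``.
    """
    if metric == "log_speed":
        if "speed" not in classified.columns:
            raise InputError("classified tracks lack a 'speed' column")
        vals = np.log(classified["speed"].to_numpy())
    elif metric == "turn":
        if "turn" not in classified.columns:
            raise InputError("classified tracks lack a 'turn' column")
        vals = classified["turn"].to_numpy()
    else:
        raise InputError(f"metric must be 'log_speed' or 'turn', got {metric!r}")

    df = classified.copy()
    df["_y"] = vals
    df = df[np.isfinite(df["_y"])]
    df = df.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)
    period_labels = sorted(df["period"].unique())
    if len(period_labels) != 2:
        raise InputError(f"need exactly 2 periods, got {period_labels}")
    cells = df.groupby(["period", "habitat"]).size()
    missing = [
        (p, h)
        for p in period_labels
        for h in HABITAT_CLASSES
        if (p, h) not in cells.index
    ]
    if missing:
        raise DegenerateFitError(f"empty habitat x period cells: {missing}")

    X, names = _movement_design(df, period_labels)
    y = df["_y"].to_numpy()
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    seg = _segment_ids(df, step)
    rho, _ = _lag1_autocorr(resid, seg)
    deff_ar1 = (1.0 + rho) / (1.0 - rho)
    sigma2_b = _random_intercept_var(resid, df["animal_id"].to_numpy(), deff_ar1)
    sigma2_e = max(float(np.var(resid)) - sigma2_b, 1e-12)
    lam = sigma2_b / sigma2_e

    # Prais-Winsten whitening of the AR1 part, per contiguous segment,
    # then a rank-one Woodbury correction for the random intercept.
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    rss = 0.0
    n_total = 0
    corrections = []  # (w_a, Xu, yu) accumulated for the residual quadratic form
    for _, sub_idx in df.groupby("animal_id", sort=False).indices.items():
        idx = np.sort(sub_idx)
        Xa, ya, sa = X[idx], y[idx], seg[idx]
        Xw = _pw_whiten(Xa, sa, rho)
        yw = _pw_whiten(ya[:, None], sa, rho)[:, 0]
        uw = _pw_whiten(np.ones((len(idx), 1)), sa, rho)[:, 0]
        w_a = lam / (1.0 + lam * float(uw @ uw)) if lam > 0 else 0.0
        Xu = Xw.T @ uw
        yu = float(yw @ uw)
        A += Xw.T @ Xw - w_a * np.outer(Xu, Xu)
        b += Xw.T @ yw - w_a * Xu * yu
        corrections.append((w_a, Xw, yw, uw))
        n_total += len(idx)

    beta = np.linalg.solve(A, b)
    for w_a, Xw, yw, uw in corrections:
        rw = yw - Xw @ beta
        rss += float(rw @ rw) - w_a * float(rw @ uw) ** 2
    dof = max(n_total - p, 1)
    sigma2_hat = max(rss / dof, 0.0)
    cov = sigma2_hat * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    table = pd.DataFrame(
        {"term": names, "estimate": beta, "std_error": se, "p_value": pvals}
    )
    table.attrs["rho"] = rho
    table.attrs["sigma2_b"] = sigma2_b
    table.attrs["sigma2_e"] = sigma2_e
    table.attrs["n_obs"] = n_total
    return table


def _pw_whiten(M: np.ndarray, seg: np.ndarray, rho: float) -> np.ndarray:
    """Prais-Winsten AR1 whitening applied column-wise within segments."""
    out = M.astype(float).copy()
    if rho == 0.0:
        return out
    scale = np.sqrt(max(1.0 - rho**2, 1e-12))
    same = np.zeros(len(M), dtype=bool)
    same[1:] = seg[1:] == seg[:-1]
    out[same] = (M[same] - rho * M[np.flatnonzero(same) - 1]) / scale
    return out


# ---------------------------------------------------------------------
# Descriptive summaries with bootstrap CIs
# ---------------------------------------------------------------------


def summarize_metrics_by_class(
    classified: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 500,
    metrics: tuple = ("speed", "turn"),
) -> pd.DataFrame:
    """Mean ± SD of speed and turn per habitat x period with bootstrap CIs.

    The nonparametric bootstrap resamples animals with replacement, then
    each sampled animal's locations with replacement; CIs are percentile
    95% intervals of the cell mean. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    group_cols = ["period", "habitat"] if "period" in classified.columns else ["habitat"]
    for keys, cell in classified.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for metric in metrics:
            vals = cell[metric].to_numpy()
            ok = np.isfinite(vals)
            v = vals[ok]
            row = dict(zip(group_cols, keys))
            row["metric"] = metric
            row["n"] = int(len(v))
            if len(v) == 0:
                row.update({"mean": np.nan, "sd": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
                rows.append(row)
                continue
            row["mean"] = float(np.mean(v))
            row["sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            groups = [g[metric].to_numpy() for _, g in cell[ok].groupby("animal_id", sort=True)]
            groups = [g[np.isfinite(g)] for g in groups]
            groups = [g for g in groups if len(g)]
            boots = np.empty(n_boot)
            for i in range(n_boot):
                picked = rng.integers(0, len(groups), len(groups))
                sample = np.concatenate(
                    [groups[j][rng.integers(0, len(groups[j]), len(groups[j]))] for j in picked]
                )
                boots[i] = sample.mean()
            row["ci_lo"] = float(np.quantile(boots, 0.025))
            row["ci_hi"] = float(np.quantile(boots, 0.975))
            rows.append(row)
    return pd.DataFrame(rows)
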