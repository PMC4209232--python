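"""Hospital profiling by direct standardisation, funnel plots and a
random-intercept sensitivity model.

The standardisation model is a logistic regression with *no global
intercept*, one indicator per hospital, and all adjustment covariates
centred at their cohort means. Each hospital's indicator coefficient is then
the log-odds of the outcome for that hospital's patients *at the cohort-mean
case mix*; back-transforming gives an adjusted proportion

    adjusted_j = expit(estimate_j) * K,      K = events / sum_j p_j n_j,

where the single-pass correction coefficient K rescales the inverse-logit
proportions ``p_j`` so that adjusted expected events sum exactly to the
observed event count (the defining conservation identity, which the test
suite checks to 1e-8 relative).

Funnel plots place each hospital at (volume n_j, adjusted proportion) with
control limits around the overall rate; the default limits use the normal
approximation on the proportion scale, with an exact-binomial option.
Limits are treated as closed: a point exactly on a limit is inside.

The sensitivity model replaces the fixed hospital indicators with a Gaussian
random intercept, fitted by Gauss–Hermite-quadrature maximum likelihood, and
reports shrunken per-hospital estimates and the between-hospital standard
deviation on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, roots_hermitenorm

from . import glm
from .config import ProfilingConfig


def center_covariates(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract the cohort mean from every covariate column (continuous
    covariates and category indicators alike). Idempotent up to float error;
    the returned mean vector allows exact reconstruction."""
    means = X.mean(axis=0)
    return X - means, means


def back_transform(estimate: np.ndarray | float, k: float) -> np.ndarray | float:
    """Adjusted proportion = inverse-logit(estimate) * k.

    Values above 1 are possible for large k; they are reported, not clipped
    (the caller flags them).
    """
    if k <= 0:
        raise ValueError("correction coefficient k must be positive")
    return expit(estimate) * k


def correction_k(p: np.ndarray, n: np.ndarray, total_events: float) -> float:
    """Single-pass correction coefficient K = events / sum(p_j * n_j)."""
    p = np.asarray(p, float)
    n = np.asarray(n, float)
    if p.shape != n.shape:
        raise ValueError("p and n must have equal length")
    denom = float(np.sum(p * n))
    if denom <= 0 or total_events <= 0:
        raise ValueError("K undefined: zero events or zero expected events")
    return float(total_events) / denom


@dataclass
class StandardisationResult:
    """Per-hospital directly standardised outcome proportions."""

    table: pd.DataFrame          # hospital_id, n, observed_events, estimate,
    #                              p_uncorrected, adjusted_proportion, flagged
    k: float
    total_events: int
    covariate_means: pd.Series
    overall_rate: float
    excluded: pd.DataFrame       # hospitals below the volume threshold

    def conservation_error(self) -> float:
        """Relative error of sum(adjusted_j * n_j) against observed events."""
        s = float((self.table["adjusted_proportion"] * self.table["n"]).sum())
        return abs(s - self.total_events) / self.total_events


def fit_hospital_model(X_centred: pd.DataFrame, hospital: pd.Series,
                       y: np.ndarray, ridge: float = 1e-4,
                       ) -> tuple[pd.Series, pd.Series]:
    """No-intercept logistic fit with one indicator per hospital plus centred
    adjustment covariates; returns per-hospital log-odds estimates.

    Hospitals with zero or all events have unbounded maximum-likelihood
    indicators; their indicator coefficients (only) receive a small ridge
    penalty and are flagged.
    """
    hosp_ids = pd.Index(sorted(hospital.unique()))
    h_idx = hosp_ids.get_indexer(hospital)
    m = len(hosp_ids)
    n = len(y)
    H = np.zeros((n, m))
    H[np.arange(n), h_idx] = 1.0
    cov_mat = X_centred.to_numpy(float) if X_centred.shape[1] else np.empty((n, 0))
    if cov_mat.shape[1]:
        # a covariate constant across episodes centres to a zero column and
        # carries no information; drop it so the fit stays full rank
        keep = np.abs(cov_mat).max(axis=0) > 1e-12
        cov_mat = cov_mat[:, keep]
    M = np.hstack([H, cov_mat])

    events = pd.Series(y).groupby(h_idx).sum().reindex(range(m), fill_value=0)
    sizes = pd.Series(1, index=range(n)).groupby(h_idx).sum().reindex(range(m), fill_value=0)
    degenerate = (events == 0) | (events == sizes)
    pen = np.zeros(M.shape[1])
    pen[np.where(degenerate)[0]] = ridge

    fit = glm.fit_irls(M, np.asarray(y, float), ridge=pen)
    if not fit.converged:
        raise RuntimeError("hospital indicator model did not converge")
    estimates = pd.Series(fit.beta[:m], index=hosp_ids, name="estimate")
    flagged = pd.Series(degenerate.to_numpy(), index=hosp_ids, name="flagged")
    return estimates, flagged


def standardise(cohort: pd.DataFrame, covariates: list[str],
                config: ProfilingConfig | None = None) -> StandardisationResult:
    """Directly standardised per-hospital outcome proportions.

    Composes covariate centring, the no-intercept hospital-indicator fit,
    the inverse-logit back-transform and the single-pass K correction.
    Hospitals with fewer than ``min_volume`` episodes are excluded from the
    model and listed separately.
    """
    cfg = config or ProfilingConfig()
    sizes = cohort.groupby("hospital_id").size()
    small = sizes[sizes < cfg.min_volume]
    excluded = pd.DataFrame({
        "hospital_id": small.index,
        "n": small.to_numpy(),
        "reason": f"volume below {cfg.min_volume}",
    })
    data = cohort[~cohort["hospital_id"].isin(small.index)].reset_index(drop=True)
    if data.empty:
        raise ValueError("no hospital meets the volume threshold")

    Xc, means = center_covariates(data[covariates]) if covariates else (
        data[[]], pd.Series(dtype=float))
    y = data["outcome"].to_numpy(float)
    estimates, flagged = fit_hospital_model(Xc, data["hospital_id"], y,
                                            ridge=cfg.ridge)

    grp = data.groupby("hospital_id")["outcome"]
    n_j = grp.size().reindex(estimates.index)
    obs = grp.sum().reindex(estimates.index).astype(int)
    total_events = int(y.sum())

    p_unc = expit(estimates.to_numpy())
    k = correction_k(p_unc, n_j.to_numpy(), total_events)
    adjusted = p_unc * k

    table = pd.DataFrame({
        "hospital_id": estimates.index,
        "n": n_j.to_numpy(),
        "observed_events": obs.to_numpy(),
        "observed_rate": obs.to_numpy() / n_j.to_numpy(),
        "estimate": estimates.to_numpy(),
        "p_uncorrected": p_unc,
        "adjusted_proportion": adjusted,
        "flagged": flagged.to_numpy(),
    }).reset_index(drop=True)
    if (adjusted > 1).any():
        import logging
        logging.getLogger(__name__).warning(
            "%d adjusted proportions exceed 1 (large K); reported unclipped",
            int((adjusted > 1).sum()))
    return StandardisationResult(
        table=table, k=k, total_events=total_events, covariate_means=means,
        overall_rate=total_events / len(data), excluded=excluded)


# --------------------------------------------------------------------------
# funnel plots


def funnel_limits(target: float, volumes: np.ndarray, level: float,
                  method: str = "normal") -> tuple[np.ndarray, np.ndarray]:
    """Two-sided control limits around a target proportion.

    ``normal``: target ± z * sqrt(target(1-target)/n), clipped to [0, 1];
    ``binomial``: exact binomial quantiles at the same tail probabilities.
    """
    if not (0 < target < 1):
        raise ValueError("target must lie strictly in (0,1)")
    volumes = np.asarray(volumes, float)
    alpha = (1.0 - level) / 2.0
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha)
        half = z * np.sqrt(target * (1.0 - target) / volumes)
        return np.clip(target - half, 0, 1), np.clip(target + half, 0, 1)
    if method == "binomial":
        lo = stats.binom.ppf(alpha, volumes, target) / volumes
        hi = stats.binom.ppf(1.0 - alpha, volumes, target) / volumes
        return lo, hi
    raise ValueError(f"unknown limit method {method!r}")


@dataclass
class FunnelChart:
    """Funnel-plot geometry plus per-hospital classification."""

    target: float
    levels: tuple[float, ...]
    method: str
    points: pd.DataFrame          # hospital_id, n, value, classification, direction


def classify_hospitals(result: StandardisationResult,
                       config: ProfilingConfig | None = None,
                       target: float | None = None) -> FunnelChart:
    """Label each hospital inside / outside_95 / outside_998 relative to the
    funnel limits at its own volume. Limits are closed: a value exactly on a
    limit is inside; classification reports the most extreme level crossed,
    with direction high/low."""
    cfg = config or ProfilingConfig()
    tgt = result.overall_rate if target is None else target
    levels = tuple(sorted(cfg.funnel_levels))
    pts = result.table[["hospital_id", "n", "adjusted_proportion"]].rename(
        columns={"adjusted_proportion": "value"}).copy()
    classification = np.array(["inside"] * len(pts), dtype=object)
    direction = np.array([""] * len(pts), dtype=object)
    for level in levels:                      # widest label wins (iterate upward)
        lo, hi = funnel_limits(tgt, pts["n"].to_numpy(), level, cfg.limit_method)
        above = pts["value"].to_numpy() > hi
        below = pts["value"].to_numpy() < lo
        label = f"outside_{str(level).replace('0.', '')}"
        classification[above | below] = label
        direction[above] = "high"
        direction[below] = "low"
    pts["classification"] = classification
    pts["direction"] = direction
    return FunnelChart(target=tgt, levels=levels, method=cfg.limit_method,
                       points=pts)


def funnel_plot(charts: dict[str, FunnelChart], path=None, title: str = ""):
    """Draw one funnel plot, overlaying the profiles of several models.

    ``charts`` maps a model label to its chart; limits are drawn for the
    first chart's target. Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = next(iter(charts.values()))
    fig, ax = plt.subplots(figsize=(7, 5))
    n_max = max(int(c.points["n"].max()) for c in charts.values())
    grid = np.linspace(max(2, first.points["n"].min() * 0.8), n_max * 1.05, 300)
    styles = {0.95: "--", 0.998: ":"}
    for level in first.levels:
        lo, hi = funnel_limits(first.target, grid, level, first.method)
        ls = styles.get(level, "-.")
        ax.plot(grid, lo, ls, color="grey", lw=1,
                label=f"{level:.1%} limits".rstrip("0").rstrip("."))
        ax.plot(grid, hi, ls, color="grey", lw=1)
    ax.axhline(first.target, color="black", lw=1, label="target")
    markers = ["o", "s", "^", "d"]
    for (label, chart), mk in zip(charts.items(), markers):
        ax.scatter(chart.points["n"], chart.points["value"], s=22, marker=mk,
                   alpha=0.75, label=label)
    ax.set_xlabel("hospital volume (episodes)")
    ax.set_ylabel("adjusted proportion")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


# --------------------------------------------------------------------------
# random-intercept sensitivity model


@dataclass
class MultilevelResult:
    """Random-intercept logistic fit."""

    sd: float                     # between-hospital sd (log-odds scale)
    intercept: float
    coefficients: pd.Series
    hospital_effects: pd.Series   # posterior-mode (shrunken) u_h
    shrunken_logodds: pd.Series   # intercept + u_h at mean covariates
    converged: bool
    loglik: float


def multilevel_sensitivity(cohort: pd.DataFrame, covariates: list[str],
                           n_quad: int = 25) -> MultilevelResult:
    """Random-intercept logistic regression by Gauss–Hermite quadrature ML.

    The hospital-specific intercept is integrated out with ``n_quad``
    Hermite nodes; (beta, log sd) are maximised with BFGS. Shrunken
    per-hospital effects are the posterior modes of u_h at the ML estimates.
    On optimizer failure the fixed-effect fallback (sd = 0) is returned with
    ``converged = False``.
    """
    hosp_ids = pd.Index(sorted(cohort["hospital_id"].unique()))
    if len(hosp_ids) < 2:
        raise ValueError("at least two hospitals required")
    h_idx = hosp_ids.get_indexer(cohort["hospital_id"])
    y = cohort["outcome"].to_numpy(float)
    Xc, means = center_covariates(cohort[covariates]) if covariates else (
        cohort[[]], pd.Series(dtype=float))
    X = np.hstack([np.ones((len(y), 1)), Xc.to_numpy(float)])
    m = len(hosp_ids)
    p = X.shape[1]

    nodes, wts = roots_hermitenorm(n_quad)
    log_w = np.log(wts / np.sqrt(2 * np.pi))

    def nll(params: np.ndarray) -> float:
        beta, log_sd = params[:-1], params[-1]
        sd = np.exp(log_sd)
        eta = X @ beta
        E = eta[:, None] + sd * nodes[None, :]
        contrib = np.where(y[:, None] == 1.0,
                           -np.logaddexp(0.0, -E), -np.logaddexp(0.0, E))
        S = np.zeros((m, n_quad))
        np.add.at(S, h_idx, contrib)
        return -float(logsumexp(S + log_w[None, :], axis=1).sum())

    start_fit = glm.fit_irls(X, y)
    x0 = np.concatenate([start_fit.beta, [np.log(0.2)]])
    res = minimize(nll, x0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 200})
    converged = bool(res.success) or res.status == 2  # precision-loss is fine
    if not np.isfinite(res.fun):
        converged = False
    beta = res.x[:p] if converged else start_fit.beta
    sd = float(np.exp(res.x[-1])) if converged else 0.0

    # posterior modes of u_h given the ML parameters (1-d Newton per hospital)
    eta = X @ beta
    u = np.zeros(m)
    if sd > 0:
        for _ in range(50):
            mu = expit(eta + u[h_idx])
            g = np.zeros(m)
            np.add.at(g, h_idx, y - mu)
            g -= u / sd**2
            h = np.zeros(m)
            np.add.at(h, h_idx, mu * (1 - mu))
            h += 1.0 / sd**2
            step = g / h
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break

    names = ["intercept"] + list(covariates)
    return MultilevelResult(
        sd=sd,
        intercept=float(beta[0]),
        coefficients=pd.Series(beta, index=names),
        hospital_effects=pd.Series(u, index=hosp_ids),
        shrunken_logodds=pd.Series(beta[0] + u, index=hosp_ids),
        converged=converged,
        loglik=-float(res.fun) if converged else start_fit.loglik,
    )


def rank_agreement(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
                   value_col: str = "value") -> tuple[float, float]:
    """Spearman rank correlation of two hospital profiles plus the fraction
    of hospitals with identical outlier classification."""
    a = profile_a.set_index("hospital_id")
    b = profile_b.set_index("hospital_id")
    if set(a.index) != set(b.index):
        raise ValueError("profiles cover different hospital sets")
    b = b.reindex(a.index)
    rho = float(stats.spearmanr(a[value_col], b[value_col]).statistic)
    if "classification" in a.columns and "classification" in b.columns:
        concord = float((a["classification"] == b["classification"]).mean())
    else:
        concord = np.nan
    return rho, concord
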