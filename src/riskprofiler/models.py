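"""Risk-adjustment models: logistic fits, bootstrap stepwise selection and
discrimination.

Two nested candidate sets are considered per outcome: the discharge-data
model (demographics + comorbidity flags) and the full model that adds
clinical categories and 3-month drug exposures. Age and gender are forced
into every model a priori. Candidate predictors are screened by a bootstrap
stepwise procedure: bidirectional stepwise selection (score-test entry,
Wald-test stay, both at 0.05 by default) is run on ``n_bootstrap`` resamples
drawn with replacement, and a candidate is retained when it is selected as
significant (p <= alpha) in at least ``retain_fraction`` of the usable
replicates. Categorical clinical variables enter as indicator blocks with
the highest-frequency level as reference, and a block is selected or dropped
as a whole.

Discrimination is the c-statistic (probability a random event outranks a
random non-event, ties counted half), computed by an O(n log n) midrank
method that equals brute-force pair counting exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import glm
from .config import SelectionConfig

#: indicator columns per categorical clinical block (reference level first in
#: the documented tables: SBP > 100 mmHg; INR 0.9-1.2)
CLINICAL_BLOCKS = {
    "sbp": ("sbp_le100", "sbp_missing"),
    "inr": ("inr_out_of_range", "inr_missing"),
}

FORCED_DEFAULT = ("age", "gender_female")


class FitFailure(RuntimeError):
    """A model fit failed to converge (or separated) on the full data."""


@dataclass
class FittedModel:
    """A fitted logistic risk model on a named design."""

    columns: list[str]
    coefficients: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov: np.ndarray
    converged: bool
    n: int
    loglik: float
    c: float | None = None
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack([np.ones(len(X))]
                            + [X[c].to_numpy(float) for c in self.columns])
        return glm._expit(Z @ np.concatenate(
            [[self.coefficients["intercept"]],
             self.coefficients[self.columns].to_numpy()]))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "se": self.se,
            "odds_ratio": self.odds_ratios,
            "p": self.pvalues,
        })


def fit_logistic(X: pd.DataFrame, y: np.ndarray | pd.Series,
                 add_intercept: bool = True) -> FittedModel:
    """Maximum-likelihood logistic fit with Wald standard errors.

    Raises :class:`FitFailure` on non-convergence/separation; inside
    resampling loops use :func:`_fit_raw`, which flags instead of raising.
    """
    fit, cols = _fit_raw(X, np.asarray(y, float), add_intercept)
    if not fit.converged:
        raise FitFailure("logistic fit did not converge (possible separation)")
    names = (["intercept"] if add_intercept else []) + cols
    return FittedModel(
        columns=cols,
        coefficients=pd.Series(fit.beta, index=names),
        se=pd.Series(fit.se, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        cov=fit.cov,
        converged=True,
        n=len(X),
        loglik=fit.loglik,
    )


def _fit_raw(X: pd.DataFrame, y: np.ndarray,
             add_intercept: bool = True) -> tuple[glm.GlmFit, list[str]]:
    cols = list(X.columns)
    mats = [X.to_numpy(float)]
    if add_intercept:
        mats.insert(0, np.ones((len(X), 1)))
    M = np.hstack(mats)
    zero = (M == 0).all(axis=0)
    if zero.any():
        raise ValueError("design matrix has constant-zero columns: "
                         f"{[c for c, z in zip(['intercept'] * add_intercept + cols, zero) if z]}")
    if M.shape[0] <= M.shape[1]:
        raise ValueError("more coefficients than observations")
    return glm.fit_irls(M, y), cols


def c_statistic(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance statistic: (concordant + 0.5 * tied) / (n_pos * n_neg).

    Computed via midranks (Mann–Whitney identity), which agrees exactly with
    brute-force enumeration of all positive-negative pairs.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("c-statistic undefined: both outcome classes required")
    r = rankdata(scores)
    rank_sum = float(r[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


# --------------------------------------------------------------------------
# stepwise machinery


def _group_matrix(X: pd.DataFrame, groups: dict[str, tuple[str, ...]],
                  selected: list[str], forced: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = ["__intercept__"] + list(forced)
    for g in selected:
        cols.extend(groups[g])
    M = np.column_stack(
        [np.ones(len(X))] + [X[c].to_numpy(float) for c in cols[1:]])
    return M, cols


def stepwise_select(X: pd.DataFrame, y: np.ndarray,
                    candidates: dict[str, tuple[str, ...]],
                    forced: tuple[str, ...] = FORCED_DEFAULT,
                    alpha_entry: float = 0.05, alpha_stay: float = 0.05,
                    ) -> tuple[list[str], dict[str, float], bool]:
    """Bidirectional stepwise selection over candidate groups.

    Starts from the forced-only model; repeatedly adds the candidate group
    with the smallest score-test p-value <= ``alpha_entry`` (ties broken by
    group name), then removes any non-forced group whose Wald p-value exceeds
    ``alpha_stay``. Deterministic given the input. Returns the selected
    groups, their final-model Wald p-values, and a convergence flag.
    """
    y = np.asarray(y, float)
    selected: list[str] = []
    seen: set[frozenset] = set()
    ok = True
    for _ in range(4 * len(candidates) + 4):
        M, cols = _group_matrix(X, candidates, selected, forced)
        fit = glm.fit_irls(M, y)
        if not fit.converged:
            return selected, {}, False
        # entry: best score-test p among remaining candidates
        best_name, best_p = None, np.inf
        for name in sorted(set(candidates) - set(selected)):
            Z = np.column_stack([X[c].to_numpy(float) for c in candidates[name]])
            _, p = glm.score_test(fit, Z)
            if p < best_p - 1e-15:
                best_name, best_p = name, p
        changed = False
        if best_name is not None and best_p <= alpha_entry:
            selected.append(best_name)
            selected.sort()
            changed = True
            M, cols = _group_matrix(X, candidates, selected, forced)
            fit = glm.fit_irls(M, y)
            if not fit.converged:
                return selected, {}, False
        # backward: drop the worst non-forced group while p > alpha_stay
        while selected:
            worst, worst_p = None, -np.inf
            for name in selected:
                idx = np.array([cols.index(c) for c in candidates[name]])
                _, p = glm.wald_block_test(fit, idx)
                if p > worst_p + 1e-15:
                    worst, worst_p = name, p
            if worst is None or worst_p <= alpha_stay:
                break
            selected.remove(worst)
            changed = True
            M, cols = _group_matrix(X, candidates, selected, forced)
            fit = glm.fit_irls(M, y)
            if not fit.converged:
                return selected, {}, False
        state = frozenset(selected)
        if not changed or state in seen:
            break
        seen.add(state)

    pvals = {}
    for name in selected:
        idx = np.array([cols.index(c) for c in candidates[name]])
        _, p = glm.wald_block_test(fit, idx)
        pvals[name] = p
    return selected, pvals, ok


@dataclass
class SelectionResult:
    """Selection frequencies across bootstrap replicates."""

    frequencies: pd.Series
    retained: list[str]
    n_converged: int
    n_bootstrap: int
    config: SelectionConfig


def bootstrap_stepwise(X: pd.DataFrame, y: np.ndarray,
                       candidates: dict[str, tuple[str, ...]],
                       config: SelectionConfig | None = None,
                       ) -> SelectionResult:
    """Bootstrap the stepwise procedure and retain stable predictors.

    Each replicate resamples ``n`` rows with replacement and reruns
    :func:`stepwise_select`; a candidate's frequency is the fraction of
    usable (converged) replicates in which it ended in the final model with
    p <= alpha. Retention: frequency >= ``retain_fraction`` (or, if
    ``min_count`` is set, count >= min_count). Forced covariates are always
    in the model and are not assigned a frequency.
    """
    cfg = config or SelectionConfig()
    if len(X) == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(cfg.seed)
    y = np.asarray(y, float)
    n = len(X)
    counts = {name: 0 for name in candidates}
    n_converged = 0
    keep_cols = list(dict.fromkeys(
        [c for cols in candidates.values() for c in cols] + list(cfg.forced)))
    Xv = X[keep_cols]
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, n)
        Xb = Xv.iloc[idx].reset_index(drop=True)
        yb = y[idx]
        try:
            sel, pvals, ok = stepwise_select(
                Xb, yb, candidates, cfg.forced, cfg.alpha_entry, cfg.alpha_stay)
        except ValueError:
            ok = False
        if not ok:
            continue
        n_converged += 1
        for name in sel:
            if pvals.get(name, 1.0) <= cfg.alpha:
                counts[name] += 1
    if n_converged < 0.5 * cfg.n_bootstrap:
        raise FitFailure(
            f"only {n_converged}/{cfg.n_bootstrap} bootstrap replicates "
            "converged; data too unstable for selection")
    freq = pd.Series({k: v / n_converged for k, v in counts.items()}).sort_index()
    if cfg.min_count is not None:
        retained = sorted(k for k, v in counts.items() if v >= cfg.min_count)
    else:
        retained = sorted(k for k in freq.index if freq[k] >= cfg.retain_fraction)
    return SelectionResult(freq, retained, n_converged, cfg.n_bootstrap, cfg)


def fit_final_model(X: pd.DataFrame, y: np.ndarray,
                    retained: list[str],
                    candidates: dict[str, tuple[str, ...]],
                    forced: tuple[str, ...] = FORCED_DEFAULT) -> FittedModel:
    """Fit the model with forced covariates plus the retained groups, and
    attach the apparent (in-sample) c-statistic."""
    cols = list(forced) + [c for g in retained for c in candidates[g]]
    model = fit_logistic(X[cols], y)
    model.groups = {g: candidates[g] for g in retained}
    model.c = c_statistic(model.predict(X), np.asarray(y))
    return model


@dataclass
class ModelPair:
    """The two risk-adjustment models for one outcome."""

    selection_a: SelectionResult
    selection_b: SelectionResult
    model_a: FittedModel
    model_b: FittedModel

    @property
    def delta_c(self) -> float:
        return self.model_b.c - self.model_a.c


def build_model_pair(X: pd.DataFrame, y: np.ndarray,
                     candidates_a: dict[str, tuple[str, ...]],
                     candidates_b: dict[str, tuple[str, ...]],
                     config: SelectionConfig | None = None) -> ModelPair:
    """Run bootstrap stepwise independently on the nested candidate sets
    (discharge-data set A, full set B ⊇ A), fit both final models on the full
    cohort, and compare apparent c-statistics."""
    missing = set(candidates_a) - set(candidates_b)
    if missing:
        raise ValueError(f"candidate set A must be a subset of B; extra: {missing}")
    cfg = config or SelectionConfig()
    sel_a = bootstrap_stepwise(X, y, candidates_a, cfg)
    sel_b = bootstrap_stepwise(X, y, candidates_b, cfg)
    model_a = fit_final_model(X, y, sel_a.retained, candidates_a, cfg.forced)
    model_b = fit_final_model(X, y, sel_b.retained, candidates_b, cfg.forced)
    return ModelPair(sel_a, sel_b, model_a, model_b)


# --------------------------------------------------------------------------
# candidate sets and report


def candidate_sets(cohort: pd.DataFrame, cohort_kind: str,
                   ) -> tuple[dict[str, tuple[str, ...]], dict[str, tuple[str, ...]]]:
    """Build the (discharge-only, full) candidate group dictionaries from the
    columns present in a cohort table."""
    skip = {"episode_id", "patient_id", "hospital_id", "outcome", "age",
            "gender", "gender_female", "sbp_cat", "inr_cat"}
    clinical_cols = {c for cols in CLINICAL_BLOCKS.values() for c in cols}
    from .synthetic import DRUG_CLASSES
    discharge = {}
    extra = {}
    for col in cohort.columns:
        if col in skip or col in clinical_cols:
            continue
        if cohort[col].dtype == object:
            continue
        if cohort[col].sum() == 0:       # never observed: not a candidate
            continue
        if col in DRUG_CLASSES:
            extra[col] = (col,)
        else:
            discharge[col] = (col,)
    block = "sbp" if cohort_kind == "ami" else "inr"
    cols = tuple(c for c in CLINICAL_BLOCKS[block]
                 if c in cohort.columns and cohort[c].sum() > 0)
    if cols:
        extra[block] = cols
    full = discharge | extra
    return discharge, full


def model_report(pair: ModelPair, X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Tabular report mirroring the published model tables: one row per
    covariate with n, crude OR, and adjusted OR + p per model, plus a final
    c-statistic row."""
    y = np.asarray(y, float)
    rows = []
    all_cols = list(dict.fromkeys(
        list(pair.model_a.columns) + list(pair.model_b.columns)))
    for col in all_cols:
        x = X[col].to_numpy(float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            n_col = int(x.sum())
            crude = fit_logistic(X[[col]], y).odds_ratios[col]
        else:
            n_col = len(x)
            crude = fit_logistic(X[[col]], y).odds_ratios[col]
        row = {"covariate": col, "n": n_col, "crude_or": round(float(crude), 2)}
        for tag, model in (("discharge", pair.model_a), ("full", pair.model_b)):
            if col in model.columns:
                row[f"adjusted_or_{tag}"] = round(float(model.odds_ratios[col]), 2)
                row[f"p_{tag}"] = round(float(model.pvalues[col]), 3)
            else:
                row[f"adjusted_or_{tag}"] = np.nan
                row[f"p_{tag}"] = np.nan
        rows.append(row)
    rows.append({"covariate": "c_statistic", "n": len(X), "crude_or": np.nan,
                 "adjusted_or_discharge": round(pair.model_a.c, 3),
                 "p_discharge": np.nan,
                 "adjusted_or_full": round(pair.model_b.c, 3),
                 "p_full": np.nan})
    return pd.DataFrame(rows)
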