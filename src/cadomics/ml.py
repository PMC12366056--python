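"""Bootstrapped cross-method consensus feature selection and CAD prediction.

The selection procedure repeats B stratified 80:20 resplits.  In each
iteration a LASSO-penalized logistic regression (penalty by internal 5-fold
CV, 1-SE rule) is fitted on the training split; its non-zero coefficient set
S_L of size k fixes the per-iteration budget.  A random forest contributes
its top-k features by impurity importance and a linear SVM its top-k by
absolute primal weight.  Cumulative selection counts across iterations and
methods rank the features; the top 16 feed the prediction models (RF, SVM,
LASSO-logistic, XGBoost with the 5×3×5 = 75-combination grid over eta,
max_depth and min_child_weight), evaluated by holdout or 10-fold CV with
AUC, accuracy, sensitivity, specificity, AUC-PR, Brier score and calibration
slope.  Robustness experiments rerun the evaluation under 1:1 case-control
subsampling, matched sampling (age/sex, optionally statin) and
statin × metabolite interaction features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .io import check_aligned, log

#: Hyperparameter grid for XGBoost, 75 combinations.
XGB_GRID = {
    "eta": (0.1, 0.3, 0.5, 0.7, 0.9),
    "max_depth": (6, 12, 29),
    "min_child_weight": (1, 2, 4, 8, 10),
}


def xgb_grid_combinations() -> list[dict]:
    keys = list(XGB_GRID)
    return [dict(zip(keys, combo)) for combo in itertools.product(*XGB_GRID.values())]


# ---------------------------------------------------------------- containers


@dataclass
class FeatureTable:
    """Model-ready design matrix and binary response."""

    X: pd.DataFrame
    y: pd.Series
    metabolite_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        check_aligned(self.X.index, self.y.index)
        if self.X.isna().any().any():
            raise ValueError("feature table may not contain missing values")
        if not self.X.columns.is_unique:
            raise ValueError("feature names must be unique")
        if set(self.y.unique()) - {0, 1}:
            raise ValueError("response must be binary 0/1")


@dataclass
class FeatureRanking:
    """Cumulative selection counts across bootstrap iterations and methods."""

    counts: pd.DataFrame  # per feature: lasso, rf, svm, total, rank
    k_per_iteration: list[int]
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return self.counts

    @property
    def total_selections(self) -> int:
        return int(self.counts[["lasso", "rf", "svm"]].to_numpy().sum())


@dataclass
class ModelEvaluation:
    scheme: str
    model: str
    per_fold: pd.DataFrame
    metrics: dict[str, float]
    seed: int
    best_params: dict | None = None
    grid_table: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.per_fold


# ---------------------------------------------------------------- assembly


def assemble_features(
    cohort: pd.DataFrame,
    metabolites: pd.DataFrame,
    haplotype: pd.Series | None = None,
    snp_encodings: pd.DataFrame | None = None,
    task: str = "cad_vs_rest",
    clinical: tuple[str, ...] = ("age", "bmi"),
    medications: bool = True,
) -> FeatureTable:
    """Assemble the trans-omics design matrix for a prediction task.

    ``task`` "cad_vs_rest" labels CAD = 1 against control + high-risk;
    "highrisk_vs_cad" restricts to those two groups with CAD = 1.  The
    haplotype enters as two indicators (hap2, hap3) against the hap1 baseline.
    """
    check_aligned(cohort.index, metabolites.index)
    if task == "cad_vs_rest":
        keep = cohort.index
    elif task == "highrisk_vs_cad":
        keep = cohort.index[cohort["group"].isin(["high-risk", "CAD"])]
    else:
        raise ValueError(f"unknown task {task!r}")
    sub = cohort.loc[keep]
    y = (sub["group"] == "CAD").astype(int).rename("cad")

    blocks = [metabolites.loc[keep]]
    clin = sub[list(clinical)].astype(float)
    clin["sex_male"] = (sub["sex"] == "male").astype(float)
    blocks.append(clin)
    if medications:
        meds = [c for c in ("statin", "fibrate", "ccb", "beta_blocker", "arb", "diuretics")
                if c in sub.columns]
        blocks.append(sub[meds].astype(float))
    if haplotype is not None:
        h = haplotype.loc[keep]
        blocks.append(
            pd.DataFrame({"hap2": (h == 2).astype(float), "hap3": (h == 3).astype(float)})
        )
    if snp_encodings is not None:
        blocks.append(snp_encodings.loc[keep].astype(float))
    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        raise ValueError("assembled features contain missing values")
    return FeatureTable(X, y, metabolite_features=list(metabolites.columns))


def interaction_features(
    t: FeatureTable, flag: str = "statin", targets: list[str] | None = None
) -> FeatureTable:
    """Add ``flag`` × metabolite product columns, originals retained."""
    if flag not in t.X.columns:
        raise ValueError(f"flag column {flag!r} absent")
    targets = targets if targets is not None else t.metabolite_features
    X = t.X.copy()
    for met in targets:
        X[f"{flag}_x_{met}"] = X[flag] * X[met]
    return FeatureTable(X, t.y, metabolite_features=t.metabolite_features)


# ---------------------------------------------------------------- selection


def _lasso_one_se(X: np.ndarray, y: np.ndarray, seed: int,
                  c_grid=np.logspace(-2.0, 1.0, 7)) -> np.ndarray:
    """L1 logistic with penalty chosen by 5-fold CV and the 1-SE rule.

    Returns the non-zero coefficient mask of the refit at the chosen penalty.
    """
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    scores = np.zeros((len(c_grid), 5))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        for i, C in enumerate(c_grid):
            m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                   random_state=seed, max_iter=200)
            m.fit(X[tr], y[tr])
            s = m.decision_function(X[va])
            scores[i, f] = roc_auc_score(y[va], s) if len(np.unique(y[va])) == 2 else 0.5
    mean, se = scores.mean(axis=1), scores.std(axis=1, ddof=1) / np.sqrt(5)
    best = int(np.argmax(mean))
    # smallest C (strongest penalty) within one SE of the best mean score
    ok = np.flatnonzero(mean >= mean[best] - se[best])
    chosen = c_grid[ok[0]]
    m = LogisticRegression(l1_ratio=1.0, C=chosen, solver="liblinear",
                           random_state=seed, max_iter=200)
    m.fit(X, y)
    return np.abs(m.coef_[0]) > 1e-10


def consensus_select(
    t: FeatureTable,
    B: int = 100,
    split: float = 0.8,
    seed: int = 0,
    rf_estimators: int = 100,
) -> FeatureRanking:
    """B bootstrapped resplits; per iteration LASSO fixes k, RF and SVM match it."""
    if B < 1:
        raise ValueError("B must be at least 1")
    if t.X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    features = t.X.columns
    counts = pd.DataFrame(0, index=features, columns=["lasso", "rf", "svm"])
    k_list: list[int] = []
    Xall, yall = t.X.to_numpy(dtype=float), t.y.to_numpy()
    rng = np.random.default_rng(seed)
    for b in range(B):
        it_seed = int(rng.integers(0, 2**31 - 1))
        Xtr, _, ytr, _ = train_test_split(
            Xall, yall, train_size=split, stratify=yall, random_state=it_seed
        )
        scaler = StandardScaler().fit(Xtr)
        Xs = scaler.transform(Xtr)
        lasso_mask = _lasso_one_se(Xs, ytr, it_seed)
        k = int(lasso_mask.sum())
        k_list.append(k)
        if k == 0:
            log.info("consensus_select iteration %d selected no features", b)
            continue
        counts.loc[features[lasso_mask], "lasso"] += 1
        rf = RandomForestClassifier(n_estimators=rf_estimators, random_state=it_seed)
        rf.fit(Xtr, ytr)
        top_rf = np.argsort(rf.feature_importances_)[::-1][:k]
        counts.loc[features[top_rf], "rf"] += 1
        svm = LinearSVC(C=1.0, random_state=it_seed, max_iter=5000)
        svm.fit(Xs, ytr)
        top_svm = np.argsort(np.abs(svm.coef_[0]))[::-1][:k]
        counts.loc[features[top_svm], "svm"] += 1
    counts["total"] = counts[["lasso", "rf", "svm"]].sum(axis=1)
    # deterministic ranking: total desc, lasso desc, then lexical name
    ordered = counts.assign(name=counts.index).sort_values(
        ["total", "lasso", "name"], ascending=[False, False, True], kind="stable"
    )
    counts = ordered.drop(columns="name")
    counts["rank"] = np.arange(1, len(counts) + 1)
    return FeatureRanking(counts, k_list, B)


def top_k_features(r: FeatureRanking, k: int = 16) -> list[str]:
    """The k top-ranked features (ties already broken deterministically)."""
    if k > len(r.counts):
        raise ValueError(f"k={k} exceeds the {len(r.counts)} ranked features")
    return r.counts.index[:k].tolist()


# ---------------------------------------------------------------- metrics


def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann–Whitney rank statistic (tie-aware)."""
    y = np.asarray(y)
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_trapezoid(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    y = np.asarray(y, dtype=float)
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(1 - ys)[distinct]
    tpr = np.r_[0.0, tp / tp[-1]]
    fpr = np.r_[0.0, fp / fp[-1]]
    return float(np.trapezoid(tpr, fpr))


def calibration_slope(y: np.ndarray, p: np.ndarray) -> float:
    """Coefficient of a logistic refit of outcomes on predicted log-odds."""
    lp = logit(np.clip(p, 1e-6, 1 - 1e-6)).reshape(-1, 1)
    m = LogisticRegression(C=np.inf, max_iter=1000).fit(lp, y)
    return float(m.coef_[0, 0])


def _metrics(y: np.ndarray, p: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {
        "auc": roc_auc_score(y, p),
        "accuracy": (tp + tn) / len(y),
        "sensitivity": sens,
        "specificity": spec,
        "auc_pr": average_precision_score(y, p),
        "brier": float(np.mean((p - y) ** 2)),
        "calibration_slope": calibration_slope(y, p),
    }


# ---------------------------------------------------------------- training


def _make_model(model: str, seed: int, params: dict | None = None):
    params = params or {}
    if model == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed, **params)
    if model == "svm":
        return SVC(kernel="linear", probability=True, random_state=seed, **params)
    if model == "lasso":
        return LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                                  random_state=seed, max_iter=500, **params)
    if model == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100, random_state=seed, eval_metric="logloss",
            learning_rate=params.get("eta", 0.3),
            max_depth=params.get("max_depth", 6),
            min_child_weight=params.get("min_child_weight", 1),
        )
    raise ValueError(f"unknown model {model!r}")


def _fit_predict(model: str, seed: int, params, Xtr, ytr, Xte) -> np.ndarray:
    scale = model in ("svm", "lasso")
    if scale:
        sc = StandardScaler().fit(Xtr)
        Xtr, Xte = sc.transform(Xtr), sc.transform(Xte)
    m = _make_model(model, seed, params)
    m.fit(Xtr, ytr)
    return m.predict_proba(Xte)[:, 1]


def train_and_evaluate(
    t: FeatureTable,
    features: list[str],
    scheme: str = "holdout",
    model: str = "rf",
    hyper_grid: list[dict] | None = None,
    seed: int = 0,
) -> ModelEvaluation:
    """Train a model on the chosen features and evaluate it.

    ``scheme`` is "holdout" (stratified 80:20) or "cv10" (stratified 10-fold).
    For XGBoost a ``hyper_grid`` (default the 75-combination grid) is searched
    by validation AUC on an inner stratified split of the training data.
    """
    if not features:
        raise ValueError("empty feature list")
    missing = [f for f in features if f not in t.X.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing[:5]}")
    X = t.X[features].to_numpy(dtype=float)
    y = t.y.to_numpy()

    best_params, grid_table = None, None
    if model == "xgboost":
        grid = hyper_grid if hyper_grid is not None else xgb_grid_combinations()
        Xg, Xv, yg, yv = train_test_split(X, y, train_size=0.8, stratify=y,
                                          random_state=seed)
        rows = []
        for params in grid:
            p = _fit_predict(model, seed, params, Xg, yg, Xv)
            rows.append({**params, "val_auc": roc_auc_score(yv, p)})
        grid_table = pd.DataFrame(rows)
        best_params = grid[int(grid_table["val_auc"].idxmax())]

    folds = []
    if scheme == "holdout":
        Xtr, Xte, ytr, yte = train_test_split(X, y, train_size=0.8, stratify=y,
                                              random_state=seed)
        p = _fit_predict(model, seed, best_params, Xtr, ytr, Xte)
        folds.append(_metrics(yte, p))
    elif scheme == "cv10":
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        for tr, te in skf.split(X, y):
            p = _fit_predict(model, seed, best_params, X[tr], y[tr], X[te])
            folds.append(_metrics(y[te], p))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    per_fold = pd.DataFrame(folds)
    metrics = per_fold.mean().to_dict()
    log.info("train_and_evaluate model=%s scheme=%s auc=%.3f", model, scheme,
             metrics["auc"])
    return ModelEvaluation(scheme, model, per_fold, metrics, seed,
                           best_params=best_params, grid_table=grid_table)


# ---------------------------------------------------------------- stepwise OR


def backward_stepwise_or(
    t: FeatureTable, features: list[str], criterion: str = "bic"
) -> pd.DataFrame:
    """Backward elimination on a logistic model; adjusted ORs with 95% CIs.

    Elimination drops the feature whose removal most improves the information
    criterion (BIC by default; "aic" available) until no removal helps.
    Returns one row per retained feature: odds_ratio, ci_low, ci_high, p,
    separation flag (CIs suppressed when quasi-separation is detected).
    """
    import statsmodels.api as sm

    if criterion not in ("bic", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    empty = pd.DataFrame(columns=["odds_ratio", "ci_low", "ci_high", "p", "separation"])
    if not features:
        return empty
    X = sm.add_constant(t.X[list(features)].astype(float))
    y = t.y.astype(int)
    current = list(features)

    def fit(cols):
        return sm.Logit(y, X[["const"] + cols]).fit(disp=0, maxiter=200)

    def ic(res):
        return res.bic if criterion == "bic" else res.aic

    res = fit(current)
    while current:
        best_ic, best_drop = ic(res), None
        for f in current:
            cand = fit([c for c in current if c != f])
            if ic(cand) < best_ic:
                best_ic, best_drop = ic(cand), f
        if best_drop is None:
            break
        current.remove(best_drop)
        res = fit(current)
    if not current:
        return empty
    params = res.params.drop("const")
    se = res.bse.drop("const")
    separation = (np.abs(params) > 15) | (se > 50)
    out = pd.DataFrame(
        {
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - 1.96 * se),
            "ci_high": np.exp(params + 1.96 * se),
            "p": res.pvalues.drop("const"),
            "separation": separation,
        }
    )
    out.loc[separation, ["ci_low", "ci_high"]] = np.nan
    return out


# ---------------------------------------------------------------- robustness


def _match_controls(
    sub: pd.DataFrame, y: pd.Series, covars: list[str], exact: list[str],
    caliper: float, seed: int
) -> pd.Index:
    """Greedy 1:1 nearest-neighbour matching of controls to cases.

    Continuous covariates are standardized; ``exact`` columns must agree; the
    age caliper applies on the raw scale.  Cases with no admissible control
    are dropped (with a warning), mirroring MatchIt's default; only an empty
    matched set is an error.
    """
    rng = np.random.default_rng(seed)
    cases = y.index[y == 1]
    ctrls = y.index[y == 0]
    z = (sub[covars] - sub[covars].mean()) / sub[covars].std(ddof=0)
    available = set(ctrls)
    matched_cases, chosen = [], []
    for case in rng.permutation(cases):
        pool = [c for c in available
                if all(sub.loc[c, e] == sub.loc[case, e] for e in exact)
                and abs(sub.loc[c, "age"] - sub.loc[case, "age"]) <= caliper]
        if not pool:
            continue
        d = ((z.loc[pool] - z.loc[case]) ** 2).sum(axis=1)
        best = d.idxmin()
        available.remove(best)
        matched_cases.append(case)
        chosen.append(best)
    if not matched_cases:
        raise ValueError("insufficient matchable controls")
    dropped = len(cases) - len(matched_cases)
    if dropped:
        log.warning("matching dropped %d of %d cases with no admissible control",
                    dropped, len(cases))
    return pd.Index(matched_cases + chosen)


def balance_experiments(
    t: FeatureTable,
    features: list[str],
    mode: str = "subsample_1to1",
    model: str = "rf",
    seed: int = 0,
    caliper: float = 5.0,
) -> tuple[ModelEvaluation, pd.Index]:
    """Rebalance the training data and re-evaluate on the untouched validation set.

    ``mode``: "subsample_1to1" draws controls without replacement to equal the
    case count; "match_age_sex" / "match_age_sex_statin" pair each case with
    its nearest control (standardized age, exact sex / sex+statin, age caliper
    5 years).  Returns the evaluation and the training subjects used.
    """
    idx_tr, idx_te = train_test_split(
        t.X.index, train_size=0.8, stratify=t.y, random_state=seed
    )
    ytr = t.y.loc[idx_tr]
    if mode == "subsample_1to1":
        rng = np.random.default_rng(seed)
        cases = ytr.index[ytr == 1]
        ctrls = ytr.index[ytr == 0]
        if len(ctrls) < len(cases):
            raise ValueError("insufficient controls for 1:1 subsampling")
        keep = pd.Index(list(cases) + list(rng.choice(ctrls, len(cases), replace=False)))
    elif mode in ("match_age_sex", "match_age_sex_statin"):
        exact = ["sex_male"] + (["statin"] if mode.endswith("statin") else [])
        for col in ["age"] + exact:
            if col not in t.X.columns:
                raise ValueError(f"matching needs column {col!r}")
        keep = _match_controls(t.X.loc[idx_tr], ytr, ["age"], exact, caliper, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    Xtr = t.X.loc[keep, features].to_numpy(dtype=float)
    Xte = t.X.loc[idx_te, features].to_numpy(dtype=float)
    p = _fit_predict(model, seed, None, Xtr, t.y.loc[keep].to_numpy(), Xte)
    per_fold = pd.DataFrame([_metrics(t.y.loc[idx_te].to_numpy(), p)])
    ev = ModelEvaluation(mode, model, per_fold, per_fold.iloc[0].to_dict(), seed)
    return ev, keep


# ---------------------------------------------------------------- calibration


@dataclass
class CalibrationReport:
    slope: float
    brier: float
    curve: pd.DataFrame
    method: str = "none"
    slope_after: float | None = None
    brier_after: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.curve


def calibration_report(
    p: np.ndarray,
    y: np.ndarray,
    bins: int = 10,
    recalibrate: str = "none",
    seed: int = 0,
) -> CalibrationReport:
    """Reliability curve over equal-frequency bins, calibration slope, Brier.

    With ``recalibrate`` "platt" or "isotonic" the recalibration map is fitted
    on a held-out half of the data and the after-metrics reported on the other
    half.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class labels")
    edges = np.quantile(p, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_id = np.digitize(p, edges[1:-1])
    curve = pd.DataFrame(
        {
            "mean_predicted": [p[bin_id == b].mean() if (bin_id == b).any() else np.nan
                               for b in range(bins)],
            "observed_rate": [y[bin_id == b].mean() if (bin_id == b).any() else np.nan
                              for b in range(bins)],
            "n": [(bin_id == b).sum() for b in range(bins)],
        }
    )
    report = CalibrationReport(
        slope=calibration_slope(y, p), brier=float(np.mean((p - y) ** 2)), curve=curve
    )
    if recalibrate == "none":
        return report
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(p))
    fit_idx, eval_idx = order[: len(p) // 2], order[len(p) // 2:]
    if recalibrate == "platt":
        lp = logit(np.clip(p, 1e-6, 1 - 1e-6))
        m = LogisticRegression(C=np.inf, max_iter=1000)
        m.fit(lp[fit_idx].reshape(-1, 1), y[fit_idx])
        p_new = m.predict_proba(lp[eval_idx].reshape(-1, 1))[:, 1]
    elif recalibrate == "isotonic":
        iso = IsotonicRegression(out_of_bounds="clip", y_min=0.0, y_max=1.0)
        iso.fit(p[fit_idx], y[fit_idx])
        p_new = iso.predict(p[eval_idx])
    else:
        raise ValueError(f"unknown recalibration {recalibrate!r}")
    report.method = recalibrate
    y_eval = y[eval_idx]
    report.slope_after = (
        calibration_slope(y_eval, p_new) if len(np.unique(y_eval)) == 2 else np.nan
    )
    report.brier_after = float(np.mean((p_new - y_eval) ** 2))
    return report
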