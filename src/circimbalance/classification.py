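"""Case/control classification from RNA features.

Evaluates feature sets (gene expression, BSJ counts, circular-to-linear
ratios, the direction-concordance score, and gene+BSJ combinations) as
classifiers of disease status. Regularized (elastic-net) logistic
regression models are tuned and evaluated under nested stratified
cross-validation: inner folds select hyperparameters, outer folds
provide held-out predictions, and gene preselection (nominal DE p <
0.05) is recomputed inside each training fold so no information leaks
from held-out samples. AUCs carry DeLong 95% confidence intervals, and
models refit on the full training cohort transfer to an independent
cohort with frozen coefficients.

The concordance score is deliberately model-free: each BSJ in a sample
scores 1 when its deviation from the training-control mean lies in the
training-cohort case-vs-control direction, and the per-sample sum is
used directly as a classification score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from circimbalance.normalization_de import build_design, nb_wald

CASE_LABEL = "PD"

L1_RATIOS = (0.1, 0.5, 1.0)
C_GRID = tuple(np.logspace(-2, 1, 4))


# ---------------------------------------------------------------------------
# AUC machinery


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    var: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.auc) and not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("confidence interval must contain the AUC")


def _binary_labels(labels: pd.Series | np.ndarray, case_label: str = CASE_LABEL) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == case_label).astype(int)
    return arr.astype(int)


def auc_midrank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the rank statistic with midrank tie handling.

    Cases are the positive class; the orientation is never flipped, so
    a feature lower in cases scores below 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    m = int(y.sum())
    n = int((1 - y).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return (ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n)


def per_feature_auc(
    features: pd.DataFrame, labels: pd.Series, case_label: str = CASE_LABEL
) -> pd.Series:
    """AUC of each feature (row) of a features x samples matrix."""
    labels = labels.reindex(features.columns)
    y = _binary_labels(labels, case_label)
    m = int(y.sum())
    n = int(y.size - m)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    values = features.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    aucs = (ranks[:, y == 1].sum(axis=1) - m * (m + 1) / 2.0) / (m * n)
    return pd.Series(aucs, index=features.index, name="auc")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    x = scores[y == 1]
    w = scores[y == 0]
    # psi(x_i, w_j): 1 if x > w, 0.5 if equal, 0 otherwise
    psi = (x[:, None] > w[None, :]).astype(float) + 0.5 * (x[:, None] == w[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = psi.mean()
    return auc, v10, v01


def delong_ci(
    scores, labels, confidence: float = 0.95, case_label: str = CASE_LABEL
) -> RocResult:
    """AUC with a DeLong structural-components confidence interval.

    The variance is var(V10)/m + var(V01)/n with V10/V01 the per-case
    and per-control structural components; the normal-theory interval
    is clipped to [0, 1]. Degenerate intervals (variance 0) collapse
    onto the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels, case_label)
    m = int(y.sum())
    n = int(y.size - m)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs at least 2 samples per class")
    auc, v10, v01 = _delong_components(scores, y)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_cases=m,
        n_controls=n,
        var=float(var),
    )


def roc_curve_table(scores, labels, case_label: str = CASE_LABEL) -> pd.DataFrame:
    """Threshold / sensitivity / specificity table for a score vector."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels, case_label)
    order = np.argsort(-scores, kind="mergesort")
    thresholds = scores[order]
    tp = np.cumsum(y[order])
    fp = np.cumsum(1 - y[order])
    sens = tp / max(int(y.sum()), 1)
    spec = 1.0 - fp / max(int((1 - y).sum()), 1)
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})


# ---------------------------------------------------------------------------
# Direction-concordance score


@dataclass
class ConcordanceModel:
    """Per-BSJ control means and case-vs-control directions from training."""

    features: list[str]
    control_means: pd.Series
    directions: pd.Series  # +1 / -1

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "control_means": self.control_means.to_dict(),
            "directions": {k: int(v) for k, v in self.directions.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConcordanceModel":
        features = list(d["features"])
        return cls(
            features=features,
            control_means=pd.Series(d["control_means"]).reindex(features),
            directions=pd.Series(d["directions"]).reindex(features).astype(float),
        )


def fit_concordance(
    train_expr: pd.DataFrame,
    train_labels: pd.Series,
    de_log2fc: pd.Series,
    case_label: str = CASE_LABEL,
) -> ConcordanceModel:
    """Learn control means and fold-change directions on the training cohort.

    ``train_expr`` is features x samples (transformed scale);
    ``de_log2fc`` are training-cohort log2 fold changes per BSJ. BSJs
    with a fold change of exactly 0 (or missing) carry no direction and
    are excluded with a warning.
    """
    labels = train_labels.reindex(train_expr.columns)
    controls = train_expr.loc[:, labels != case_label]
    if controls.shape[1] < 2:
        raise ValueError("need at least 2 training controls")
    de_log2fc = de_log2fc.reindex(train_expr.index)
    usable = de_log2fc.notna() & (de_log2fc != 0.0)
    dropped = int((~usable).sum())
    if dropped:
        warnings.warn(f"{dropped} BSJ(s) without a direction (log2FC 0 or missing) excluded")
    features = train_expr.index[usable].tolist()
    return ConcordanceModel(
        features=features,
        control_means=controls.loc[features].mean(axis=1),
        directions=np.sign(de_log2fc.loc[features]),
    )


def concordance_score(model: ConcordanceModel, sample_expr) -> "pd.Series | int":
    """Per-sample count of BSJs deviating in the modelled direction.

    A BSJ scores 1 iff the sign of (sample value - training control
    mean) equals the training direction; a deviation of exactly zero
    never agrees. Accepts a per-feature Series (one sample; returns an
    int) or a features x samples DataFrame (returns a per-sample Series).
    """
    single = isinstance(sample_expr, pd.Series)
    frame = sample_expr.to_frame() if single else sample_expr
    missing = [f for f in model.features if f not in frame.index]
    if missing:
        raise ValueError(f"sample is missing {len(missing)} model feature(s), e.g. {missing[0]!r}")
    dev = frame.loc[model.features].sub(model.control_means.loc[model.features], axis=0)
    agree = np.sign(dev).eq(model.directions.loc[model.features], axis=0) & (dev != 0)
    totals = agree.sum(axis=0)
    return int(totals.iloc[0]) if single else totals


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass
class FeatureSet:
    """One named candidate predictor set.

    ``X`` holds transformed feature values (features x samples). For
    sets that preselect features by nominal differential expression
    (genes), ``preselect_counts`` carries raw counts and
    ``size_factors`` the gene-derived factors; the screen is recomputed
    inside each training fold. ``kind="concordance"`` bypasses model
    fitting: the per-sample concordance sum is the score, with per-fold
    directions from a group-only NB fit on ``counts``.
    """

    name: str
    X: pd.DataFrame
    kind: str = "model"  # model | concordance
    preselect_counts: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("model", "concordance"):
            raise ValueError(f"unknown feature set kind {self.kind!r}")
        if self.kind == "concordance" and self.counts is None:
            raise ValueError("concordance feature sets need raw counts for per-fold directions")


@dataclass
class CvResult:
    name: str
    roc: RocResult
    predictions: pd.Series
    fold_of: pd.Series
    chosen_params: list[dict] = field(default_factory=list)
    n_features_per_fold: list[int] = field(default_factory=list)


def _nominal_de_features(
    counts: pd.DataFrame,
    labels: pd.Series,
    size_factors: pd.Series | None,
    p_cut: float = 0.05,
) -> pd.Index:
    samples = pd.DataFrame({"group": labels})
    design = build_design(samples, covariates=(), group_col="group")
    sf = (
        size_factors.reindex(counts.columns)
        if size_factors is not None
        else pd.Series(1.0, index=counts.columns)
    )
    res = nb_wald(counts, design, sf)
    return res.index[(res["p"] < p_cut).fillna(False)]


def _de_directions(
    counts: pd.DataFrame, labels: pd.Series, size_factors: pd.Series | None
) -> pd.Series:
    samples = pd.DataFrame({"group": labels})
    design = build_design(samples, covariates=(), group_col="group")
    sf = (
        size_factors.reindex(counts.columns)
        if size_factors is not None
        else pd.Series(1.0, index=counts.columns)
    )
    res = nb_wald(counts, design, sf)
    return res["log2FC"].where(res["p"].notna())


def _apply_preselect(feature_index: pd.Index, screened_index: pd.Index, selected: pd.Index) -> pd.Index:
    """Restrict screened features to the selected ones; features outside
    the screen (e.g. junctions in a gene+BSJ set) are always kept."""
    keep = feature_index.difference(screened_index).union(
        selected.intersection(feature_index)
    )
    kept = feature_index[feature_index.isin(keep)]
    # an empty screen would leave nothing to fit: fall back to the full set
    return kept if len(kept) else feature_index


def _standardize(train: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _fit_logistic(Xtr, ytr, l1_ratio, C, seed):
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=l1_ratio,
        C=C,
        max_iter=3000,
        tol=1e-3,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xtr, ytr)
    return clf


def _inner_select(X, y, inner_folds, seed):
    """Pick (l1_ratio, C) maximizing mean inner-fold AUC."""
    n_splits = min(inner_folds, int(y.sum()), int((1 - y).sum()))
    if n_splits < 2:
        raise ValueError("inner folds would lose a class; too few samples")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for l1_ratio in L1_RATIOS:
        for C in C_GRID:
            aucs = []
            for tr, te in splits:
                mean, sd = _standardize(X[tr])
                clf = _fit_logistic((X[tr] - mean) / sd, y[tr], l1_ratio, C, seed)
                scores = clf.decision_function((X[te] - mean) / sd)
                if y[te].min() == y[te].max():
                    continue
                aucs.append(auc_midrank(scores, y[te]))
            mean_auc = float(np.mean(aucs)) if aucs else 0.5
            if best is None or mean_auc > best[0]:
                best = (mean_auc, l1_ratio, C)
    return {"l1_ratio": best[1], "C": best[2], "inner_auc": best[0]}


def nested_cv(
    feature_sets: Sequence[FeatureSet],
    labels: pd.Series,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    case_label: str = CASE_LABEL,
) -> dict[str, CvResult]:
    """Nested stratified cross-validation over named feature sets.

    Outer folds are stratified by label; preselection, direction
    estimation and hyperparameter tuning all happen strictly inside
    each outer training fold. Held-out outer predictions are pooled
    into one ROC (with DeLong interval) per feature set. Identical
    seeds give identical fold assignments and results.
    """
    sample_index = labels.index
    y = _binary_labels(labels, case_label)
    if min(int(y.sum()), int(y.size - y.sum())) < outer_folds:
        raise ValueError("a class has fewer samples than outer folds; cannot stratify")
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(y.size), y))

    results: dict[str, CvResult] = {}
    preselect_cache: dict[tuple, pd.Index] = {}
    for fs in feature_sets:
        X_all = fs.X.reindex(columns=sample_index)
        preds = np.full(y.size, np.nan)
        fold_of = np.full(y.size, -1)
        chosen: list[dict] = []
        n_feats: list[int] = []
        for fold, (tr, te) in enumerate(splits):
            tr_samples = sample_index[tr]
            te_samples = sample_index[te]
            fold_of[te] = fold
            if fs.kind == "concordance":
                lfc = _de_directions(
                    fs.counts[tr_samples], labels.loc[tr_samples], fs.size_factors
                )
                model = fit_concordance(
                    X_all[tr_samples], labels.loc[tr_samples], lfc, case_label
                )
                preds[te] = concordance_score(model, X_all[te_samples]).to_numpy()
                chosen.append({})
                n_feats.append(len(model.features))
            else:
                feats = X_all.index
                if fs.preselect_counts is not None:
                    key = (id(fs.preselect_counts), fold)
                    if key not in preselect_cache:
                        preselect_cache[key] = _nominal_de_features(
                            fs.preselect_counts[tr_samples],
                            labels.loc[tr_samples],
                            fs.size_factors,
                        )
                    feats = _apply_preselect(
                        X_all.index, fs.preselect_counts.index, preselect_cache[key]
                    )
                Xtr = X_all.loc[feats, tr_samples].to_numpy().T
                Xte = X_all.loc[feats, te_samples].to_numpy().T
                params = _inner_select(Xtr, y[tr], inner_folds, seed + fold)
                mean, sd = _standardize(Xtr)
                clf = _fit_logistic(
                    (Xtr - mean) / sd, y[tr], params["l1_ratio"], params["C"], seed + fold
                )
                preds[te] = clf.decision_function((Xte - mean) / sd)
                chosen.append(params)
                n_feats.append(len(feats))
        roc = delong_ci(preds, y)
        results[fs.name] = CvResult(
            name=fs.name,
            roc=roc,
            predictions=pd.Series(preds, index=sample_index),
            fold_of=pd.Series(fold_of, index=sample_index),
            chosen_params=chosen,
            n_features_per_fold=n_feats,
        )
    return results


# ---------------------------------------------------------------------------
# Final models and cross-cohort transfer


@dataclass
class FittedModel:
    """A frozen classifier: preprocessing plus coefficients (or a
    concordance model), ready to apply to an independent cohort."""

    name: str
    kind: str
    features: list[str]
    control_means: pd.Series  # imputation values for absent features
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None
    coef: np.ndarray | None = None
    intercept: float = 0.0
    params: dict = field(default_factory=dict)
    concordance: ConcordanceModel | None = None

    def score(self, X: pd.DataFrame) -> pd.Series:
        """Score a features x samples matrix with frozen parameters."""
        if self.kind == "concordance":
            return concordance_score(self.concordance, X)
        Z = (X.loc[self.features].to_numpy().T - self.scaler_mean) / self.scaler_sd
        return pd.Series(Z @ self.coef + self.intercept, index=X.columns)

    def to_json(self) -> str:
        d = {
            "name": self.name,
            "kind": self.kind,
            "features": self.features,
            "control_means": self.control_means.to_dict(),
            "params": self.params,
            "intercept": self.intercept,
        }
        if self.kind == "model":
            d["scaler_mean"] = self.scaler_mean.tolist()
            d["scaler_sd"] = self.scaler_sd.tolist()
            d["coef"] = self.coef.tolist()
        else:
            d["concordance"] = self.concordance.to_dict()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        features = list(d["features"])
        model = cls(
            name=d["name"],
            kind=d["kind"],
            features=features,
            control_means=pd.Series(d["control_means"]).reindex(features),
            params=d.get("params", {}),
            intercept=float(d.get("intercept", 0.0)),
        )
        if d["kind"] == "model":
            model.scaler_mean = np.asarray(d["scaler_mean"], dtype=float)
            model.scaler_sd = np.asarray(d["scaler_sd"], dtype=float)
            model.coef = np.asarray(d["coef"], dtype=float)
        else:
            model.concordance = ConcordanceModel.from_dict(d["concordance"])
        return model


def fit_final(
    fs: FeatureSet,
    labels: pd.Series,
    inner_folds: int = 10,
    seed: int = 0,
    case_label: str = CASE_LABEL,
) -> FittedModel:
    """Refit on the full training cohort at cross-validated hyperparameters."""
    X_all = fs.X.reindex(columns=labels.index)
    y = _binary_labels(labels, case_label)
    controls = X_all.loc[:, y == 0]

    if fs.kind == "concordance":
        lfc = _de_directions(fs.counts, labels, fs.size_factors)
        cm = fit_concordance(X_all, labels, lfc, case_label)
        return FittedModel(
            name=fs.name,
            kind="concordance",
            features=cm.features,
            control_means=controls.loc[cm.features].mean(axis=1),
            concordance=cm,
        )

    feats = X_all.index
    if fs.preselect_counts is not None:
        selected = _nominal_de_features(fs.preselect_counts, labels, fs.size_factors)
        feats = _apply_preselect(X_all.index, fs.preselect_counts.index, selected)
    Xtr = X_all.loc[feats].to_numpy().T
    params = _inner_select(Xtr, y, inner_folds, seed)
    mean, sd = _standardize(Xtr)
    clf = _fit_logistic((Xtr - mean) / sd, y, params["l1_ratio"], params["C"], seed)
    return FittedModel(
        name=fs.name,
        kind="model",
        features=list(feats),
        control_means=controls.loc[feats].mean(axis=1),
        scaler_mean=mean,
        scaler_sd=sd,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        params=params,
    )


def transfer(
    model: FittedModel,
    features_b: pd.DataFrame,
    labels_b: pd.Series,
    case_label: str = CASE_LABEL,
) -> tuple[RocResult, int]:
    """Apply a frozen model to an independent cohort.

    Features absent from cohort B are imputed at the training control
    mean; the number imputed is returned alongside the ROC result.
    """
    present = [f for f in model.features if f in features_b.index]
    if not present:
        raise ValueError("no model feature is present in the transfer cohort")
    n_imputed = len(model.features) - len(present)
    X = features_b.reindex(model.features)
    if n_imputed:
        fill = model.control_means.reindex(model.features)
        X = X.apply(lambda col: col.fillna(fill), axis=0)
    scores = model.score(X[labels_b.index])
    return delong_ci(scores.to_numpy(), labels_b.reindex(scores.index), case_label=case_label), n_imputed
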