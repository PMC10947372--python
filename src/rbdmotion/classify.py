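"""Cross-validated ridge-logistic classification of iRBD from movement features.

The experiment mirrors standard clinical ML practice for small tabular
cohorts: for a chosen movement-duration bin, the 3D rate and 3D ratio of a
set of body regions are the predictors of iRBD status.  Seven predictor
configurations are examined — each single region (head HE, hands HAs,
upper body UB, lower body LB; 2 features each), head+hands+upper body,
head+hands+lower body (6 features each) and all four regions (8 features).

Model fitting is wrapped in a repeated, stratified 10-fold cross-validation
(10 runs with different fold seeds).  Inside every training fold each
feature is rescaled by the fold's own 5th and 95th percentiles (no
leakage); a logistic regression with an L2 (ridge) penalty on the weights
(intercept unpenalised) is fitted by damped Newton iteration on the exact
penalised log-likelihood.  Out-of-fold probabilities are pooled per run and
summarised as accuracy, F1, sensitivity, specificity, PPV and NPV,
reported as mean +/- SD across the 10 runs.

Usage follows the statsmodels Model/Results idiom::

    model = MovementClassifier.from_dataframe(cohort, duration_bin="short")
    res = model.fit(seed=42)
    print(res.summary())
    res.subgroup_metrics(["SRBD"])          # iRBD vs SRBD test performance
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ROI_SETS",
    "standard_configs",
    "ClassifierConfig",
    "CVPlan",
    "PercentileNormalizer",
    "fit_ridge_logistic",
    "compute_metrics",
    "MovementClassifier",
    "CVResult",
    "ConvergenceError",
]

#: the seven predictor configurations, keyed by a display name
ROI_SETS: dict[str, tuple[str, ...]] = {
    "HE": ("HE",),
    "HAs": ("HAs",),
    "UB": ("UB",),
    "LB": ("LB",),
    "HE+HAs+UB": ("HE", "HAs", "UB"),
    "HE+HAs+LB": ("HE", "HAs", "LB"),
    "HE+HAs+UB+LB": ("HE", "HAs", "UB", "LB"),
}

METRIC_NAMES = ("accuracy", "f1", "sensitivity", "specificity", "ppv", "npv")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier: a duration bin, a region set and the ridge penalty."""

    duration_bin: str = "short"
    roi_set: tuple[str, ...] = ("HE", "HAs", "UB", "LB")
    ridge_lambda: float = 0.01
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if tuple(self.roi_set) not in ROI_SETS.values():
            raise ValueError(
                f"roi_set {self.roi_set} is not one of the seven supported configurations"
            )
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must lie in (0, 1)")

    @property
    def feature_columns(self) -> list[str]:
        """Predictor columns: 3D rate and 3D ratio per region in the set."""
        return [
            f"{roi}_{self.duration_bin}_{feat}"
            for roi in self.roi_set
            for feat in ("rate", "ratio")
        ]

    @property
    def name(self) -> str:
        return "+".join(self.roi_set)


def standard_configs(duration_bin: str = "short", ridge_lambda: float = 0.01) -> list[ClassifierConfig]:
    """The seven classifier configurations for one duration bin."""
    return [
        ClassifierConfig(duration_bin, rois, ridge_lambda) for rois in ROI_SETS.values()
    ]


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan with one fold seed per run."""

    n_runs: int = 10
    n_folds: int = 10
    stratified: bool = True
    base_seed: int = 0

    @property
    def run_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.base_seed)
        return [int(s) % (2**31) for s in ss.generate_state(self.n_runs)]


class PercentileNormalizer:
    """Linear rescaling by the training 5th and 95th percentiles.

    ``x -> (x - p5) / (p95 - p5)`` per feature, fitted on training folds
    only; the training p5 maps to 0 and p95 to 1.  Values outside the
    training range are *not* clipped.
    """

    def __init__(self, low: float = 5.0, high: float = 95.0) -> None:
        self.low, self.high = low, high
        self.p_low: np.ndarray | None = None
        self.p_high: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "PercentileNormalizer":
        X = np.asarray(X, dtype=float)
        self.p_low = np.percentile(X, self.low, axis=0)
        self.p_high = np.percentile(X, self.high, axis=0)
        degenerate = np.flatnonzero(self.p_high == self.p_low)
        if degenerate.size:
            raise ValueError(
                f"constant training feature(s) at column index {degenerate.tolist()}: "
                "percentile normalization is undefined"
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.p_low is None:
            raise RuntimeError("normalizer is not fitted")
        return (np.asarray(X, dtype=float) - self.p_low) / (self.p_high - self.p_low)


def _nll_grad_hess(beta: np.ndarray, X1: np.ndarray, y: np.ndarray, lam: float):
    """Penalised mean negative log-likelihood with gradient and Hessian.

    ``beta`` stacks the weights and the (unpenalised) intercept last;
    ``X1`` carries an appended column of ones.
    """
    n = X1.shape[0]
    z = X1 @ beta
    # stable log(1 + exp(-s z)) with s = +/-1
    s = 2.0 * y - 1.0
    nll = np.mean(np.logaddexp(0.0, -s * z))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    w_pen = beta.copy()
    w_pen[-1] = 0.0
    loss = nll + 0.5 * lam * w_pen @ w_pen
    grad = X1.T @ (p - y) / n + lam * w_pen
    W = p * (1.0 - p)
    hess = (X1 * W[:, None]).T @ X1 / n
    hess[np.diag_indices_from(hess)] += lam
    hess[-1, -1] -= lam  # intercept unpenalised
    return loss, grad, hess


def fit_ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, float]:
    """Fit logistic regression minimising mean NLL + (lambda/2)*||w||^2.

    The intercept is unpenalised.  Damped Newton iteration, deterministic
    given the inputs; converged when the gradient 2-norm drops below
    ``tol``.  Returns ``(weights, intercept)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one sample of each class")
    n, p = X.shape
    X1 = np.hstack([X, np.ones((n, 1))])
    beta = np.zeros(p + 1)
    loss, grad, hess = _nll_grad_hess(beta, X1, y, ridge_lambda)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            return beta[:-1].copy(), float(beta[-1])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        t = 1.0
        for _ in range(50):
            cand = beta - t * step
            new_loss, new_grad, new_hess = _nll_grad_hess(cand, X1, y, ridge_lambda)
            if new_loss <= loss + 1e-12:
                beta, loss, grad, hess = cand, new_loss, new_grad, new_hess
                break
            t *= 0.5
        else:  # pragma: no cover - only reachable on numerical stall
            break
    if np.linalg.norm(grad) >= tol:
        raise ConvergenceError(
            f"Newton iteration did not converge: |grad| = {np.linalg.norm(grad):.3e}"
        )
    return beta[:-1].copy(), float(beta[-1])


def predict_proba(X: np.ndarray, weights: np.ndarray, intercept: float) -> np.ndarray:
    z = np.asarray(X, dtype=float) @ weights + intercept
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def compute_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Confusion-matrix metrics for the positive (iRBD) class.

    Ratios with a zero denominator are recorded as NaN and later excluded
    from aggregation.  F1 is the harmonic mean of PPV and sensitivity.
    """
    y_true = np.asarray(y_true).astype(bool)
    pred = np.asarray(y_prob) >= threshold
    tp = int(np.sum(pred & y_true))
    tn = int(np.sum(~pred & ~y_true))
    fp = int(np.sum(pred & ~y_true))
    fn = int(np.sum(~pred & y_true))
    n = tp + tn + fp + fn

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return {
        "accuracy": ratio(tp + tn, n),
        "f1": f1,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and metric aggregates of one experiment.

    ``predictions`` has one row per subject per run (columns ``run, fold,
    subject_id, prob, pred, label``); ``per_run`` and ``per_fold`` carry the
    six metrics per pooled run and per individual fold.
    """

    config: ClassifierConfig
    plan: CVPlan
    predictions: pd.DataFrame
    per_run: pd.DataFrame
    per_fold: pd.DataFrame
    groups: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def aggregate(self, level: str = "run") -> pd.DataFrame:
        """Mean +/- SD of each metric across runs (or across the 100 folds).

        NaN metric values (undefined ratios) are excluded with a warning.
        """
        table = self.per_run if level == "run" else self.per_fold
        rows = {}
        for m in METRIC_NAMES:
            vals = table[m].to_numpy(dtype=float)
            n_nan = int(np.isnan(vals).sum())
            if n_nan:
                warnings.warn(
                    f"{n_nan} undefined value(s) of '{m}' excluded from aggregation",
                    stacklevel=2,
                )
            ok = vals[~np.isnan(vals)]
            rows[m] = {
                "mean": float(ok.mean()) if ok.size else float("nan"),
                "sd": float(ok.std(ddof=1)) if ok.size > 1 else float("nan"),
                "n_undefined": n_nan,
            }
        return pd.DataFrame(rows).T

    def subgroup_metrics(self, subgroup: list[str] | tuple[str, ...]) -> pd.DataFrame:
        """Test performance for iRBD vs one comparison subgroup.

        The cross-validated models are *not* retrained: per run, the pooled
        out-of-fold predictions are restricted to iRBD subjects plus the
        requested subgroup(s) and the metrics recomputed, then aggregated
        as mean +/- SD across runs.
        """
        if self.groups is None:
            raise ValueError("subgroup metrics need per-subject group labels")
        subgroup = list(subgroup)
        if not subgroup:
            raise ValueError("empty subgroup")
        keep_groups = set(subgroup) | {self.metadata.get("positive_group", "iRBD")}
        keep_ids = set(self.groups[self.groups.isin(keep_groups)].index.astype(str))
        if not set(self.groups[self.groups.isin(subgroup)].index.astype(str)):
            raise ValueError(f"no subjects in subgroup {subgroup}")
        sel = self.predictions[self.predictions["subject_id"].isin(keep_ids)]
        rows = []
        for run, g in sel.groupby("run"):
            m = compute_metrics(
                g["label"].to_numpy(), g["prob"].to_numpy(), self.config.decision_threshold
            )
            rows.append({"run": run, **m})
        per_run = pd.DataFrame(rows)
        out = {}
        for m in METRIC_NAMES:
            vals = per_run[m].to_numpy(dtype=float)
            ok = vals[~np.isnan(vals)]
            out[m] = {
                "mean": float(ok.mean()) if ok.size else float("nan"),
                "sd": float(ok.std(ddof=1)) if ok.size > 1 else float("nan"),
            }
        return pd.DataFrame(out).T

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "Cross-validated movement classification (iRBD vs rest)",
            "=" * 56,
            f"predictors : {', '.join(self.config.feature_columns)}",
            f"duration   : {self.config.duration_bin}   regions: {self.config.name}",
            f"ridge lambda = {self.config.ridge_lambda:g}, "
            f"threshold = {self.config.decision_threshold:g}",
            f"CV         : {self.plan.n_runs} runs x {self.plan.n_folds} folds "
            f"(stratified={self.plan.stratified}, base_seed={self.plan.base_seed})",
            f"subjects   : {self.predictions['subject_id'].nunique()} "
            f"({int(self.predictions[self.predictions['run'] == self.predictions['run'].min()]['label'].sum())} positive)",
            "-" * 56,
            f"{'metric':<13}{'mean':>9}{'sd':>9}",
        ]
        for m in METRIC_NAMES:
            lines.append(f"{m:<13}{agg.loc[m, 'mean']:>9.3f}{agg.loc[m, 'sd']:>9.3f}")
        lines.append("=" * 56)
        return "\n".join(lines)


class MovementClassifier:
    """Model object for the iRBD vs no-RBD classification experiment.

    Parameters
    ----------
    features : DataFrame
        Wide per-subject feature table (``{roi}_{bin}_{rate|ratio}``
        columns), indexed by subject id.
    groups : Series
        Diagnostic group per subject, aligned with ``features``.
    config : ClassifierConfig
        Duration bin, region set and ridge penalty.
    positive_group : str
        The group treated as the positive class (default ``"iRBD"``).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        groups: pd.Series,
        config: ClassifierConfig | None = None,
        positive_group: str = "iRBD",
    ) -> None:
        self.config = config or ClassifierConfig()
        missing = set(self.config.feature_columns) - set(features.columns)
        if missing:
            raise ValueError(f"feature table lacks columns: {sorted(missing)}")
        self.features = features
        self.groups = groups.reindex(features.index)
        if self.groups.isna().any():
            raise ValueError("groups must cover every subject in the feature table")
        self.positive_group = positive_group
        self.y = (self.groups == positive_group).to_numpy()
        if self.y.sum() in (0, len(self.y)):
            raise ValueError("need both a positive and a negative class")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str = "group",
        config: ClassifierConfig | None = None,
        **kwargs,
    ) -> "MovementClassifier":
        """Build from a single table carrying features plus a group column."""
        groups = df[group_col]
        features = df.drop(columns=[group_col])
        return cls(features, groups, config=config, **kwargs)

    @classmethod
    def from_csv(
        cls,
        features_path: str,
        labels_path: str,
        config: ClassifierConfig | None = None,
        **kwargs,
    ) -> "MovementClassifier":
        features = pd.read_csv(features_path, index_col="subject_id")
        labels = pd.read_csv(labels_path, index_col="subject_id")
        features.index = features.index.astype(str)
        labels.index = labels.index.astype(str)
        if "group" in features.columns:
            features = features.drop(columns=["group"])
        return cls(features, labels["group"], config=config, **kwargs)

    def fit(
        self, n_runs: int = 10, n_folds: int = 10, seed: int = 0, stratified: bool = True
    ) -> CVResult:
        """Run the repeated stratified cross-validation experiment."""
        plan = CVPlan(n_runs=n_runs, n_folds=n_folds, stratified=stratified, base_seed=seed)
        cols = self.config.feature_columns
        X_all = self.features[cols].to_numpy(dtype=float)
        y_all = self.y.astype(float)
        ids = self.features.index.astype(str).to_numpy()

        pred_rows = []
        fold_rows = []
        run_rows = []
        for run, run_seed in enumerate(plan.run_seeds):
            if plan.stratified:
                splitter = StratifiedKFold(
                    n_splits=plan.n_folds, shuffle=True, random_state=run_seed
                )
                split_iter = splitter.split(X_all, y_all)
            else:
                from sklearn.model_selection import KFold

                split_iter = KFold(
                    n_splits=plan.n_folds, shuffle=True, random_state=run_seed
                ).split(X_all)
            run_probs = np.empty(len(y_all))
            for fold, (tr, te) in enumerate(split_iter):
                if len(np.unique(y_all[tr])) < 2:
                    raise ValueError(
                        f"run {run} fold {fold}: training fold lacks a class; re-stratify"
                    )
                norm = PercentileNormalizer().fit(X_all[tr])
                w, b = fit_ridge_logistic(
                    norm.transform(X_all[tr]), y_all[tr], self.config.ridge_lambda
                )
                probs = predict_proba(norm.transform(X_all[te]), w, b)
                run_probs[te] = probs
                fold_rows.append(
                    {
                        "run": run,
                        "fold": fold,
                        **compute_metrics(y_all[te], probs, self.config.decision_threshold),
                    }
                )
                for i, p in zip(te, probs):
                    pred_rows.append(
                        {
                            "run": run,
                            "fold": fold,
                            "subject_id": ids[i],
                            "prob": p,
                            "pred": bool(p >= self.config.decision_threshold),
                            "label": bool(y_all[i]),
                        }
                    )
            run_rows.append(
                {
                    "run": run,
                    **compute_metrics(y_all, run_probs, self.config.decision_threshold),
                }
            )
        return CVResult(
            config=self.config,
            plan=plan,
            predictions=pd.DataFrame(pred_rows),
            per_run=pd.DataFrame(run_rows),
            per_fold=pd.DataFrame(fold_rows),
            groups=self.groups.copy(),
            metadata={
                "positive_group": self.positive_group,
                "run_seeds": plan.run_seeds,
                "ridge_lambda": self.config.ridge_lambda,
                "decision_threshold": self.config.decision_threshold,
                "normalization": "train 5th-95th percentile",
            },
        )
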