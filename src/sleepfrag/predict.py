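"""Predicting stress susceptibility from pre-stress sleep architecture.

Pipeline: assemble a per-animal table of sleep features averaged over the
12-h light and dark phases of a pre-stress baseline recording; rank
features by their two-group ANOVA F statistic against the phenotype
label; prune multicollinearity by iteratively removing the feature with
the largest variance inflation factor (VIF) until all retained VIFs fall
at or below a threshold (default 35); then score an L2-penalized logistic
regression by repeated stratified 75/25 train/test splits, tracing
accuracy as the top-ranked features are added one at a time.

The selection and classification steps are exposed as scikit-learn
estimators (:class:`FRankSelector`, :class:`VIFPruner`,
:class:`SusceptibilityClassifier`) so they compose with sklearn pipelines
and model selection; the module-level functions are thin wrappers over
them.

With cohorts of ~15 animals a single 75/25 split is dominated by split
noise, so the default protocol repeats the split (``n_repeats=200``) and
reports the mean accuracy with its dispersion; ``n_repeats=1`` reproduces
a literal single-split protocol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .architecture import (
    bout_metrics,
    count_transitions,
    interbout_interval,
    latency,
    percent_time,
)
from .hypnogram import (
    TRANSITION_PAIRS,
    Hypnogram,
    VigilanceState,
    dark_window,
    light_window,
)
from .phenotype import PhenotypeLabel

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SCHEMA",
    "TOP10_FEATURES",
    "build_feature_table",
    "FRankSelector",
    "VIFPruner",
    "SusceptibilityClassifier",
    "ClassifierResult",
    "f_rank",
    "vif_prune",
    "cross_validated_accuracy",
    "accuracy_vs_k",
    "pca_projection",
]

_STATE_KEY = {
    VigilanceState.WAKE: "wake",
    VigilanceState.NREM: "nrem",
    VigilanceState.REM: "rem",
}
_METRICS = ("percent", "bouts", "dur", "latency", "ibi")


def _schema() -> tuple[str, ...]:
    cols: list[str] = []
    for phase in ("light", "dark"):
        for state in _STATE_KEY.values():
            cols.extend(f"{state}_{m}_{phase}" for m in _METRICS)
        for a, b in TRANSITION_PAIRS:
            cols.append(f"{_STATE_KEY[a]}_{_STATE_KEY[b]}_transitions_{phase}")
    return tuple(cols)


#: Canonical feature columns: (state x {percent time, bout count, mean bout
#: duration, latency, inter-bout interval} + the four reported transition
#: pairs) x {light, dark}.
FEATURE_SCHEMA: tuple[str, ...] = _schema()

#: The ten features most predictive of susceptibility in chronic-social-
#: defeat cohorts, in the canonical column naming.
TOP10_FEATURES: tuple[str, ...] = (
    "nrem_rem_transitions_dark",
    "rem_wake_transitions_dark",
    "nrem_bouts_dark",
    "wake_ibi_light",
    "nrem_wake_transitions_dark",
    "wake_nrem_transitions_dark",
    "nrem_dur_light",
    "wake_nrem_transitions_light",
    "nrem_bouts_light",
    "nrem_ibi_dark",
)


def _animal_features(hyp: Hypnogram) -> dict[str, float]:
    feats: dict[str, float] = {}
    for phase, win_fn in (("light", light_window), ("dark", dark_window)):
        win = win_fn(hyp)  # raises if the phase is not recorded
        for state, key in _STATE_KEY.items():
            feats[f"{key}_percent_{phase}"] = percent_time(hyp, state, win)
            n, dur = bout_metrics(hyp, state, win)
            feats[f"{key}_bouts_{phase}"] = float(n)
            feats[f"{key}_dur_{phase}"] = dur
            feats[f"{key}_latency_{phase}"] = latency(hyp, state, win.start_zt_h)
            feats[f"{key}_ibi_{phase}"] = interbout_interval(hyp, state, win)
        for a, b in TRANSITION_PAIRS:
            feats[f"{_STATE_KEY[a]}_{_STATE_KEY[b]}_transitions_{phase}"] = float(
                count_transitions(hyp, a, b, win)
            )
    return feats


def build_feature_table(
    hypnograms: Mapping[str, Hypnogram],
    labels: Mapping[str, PhenotypeLabel | str],
    missing: str = "impute",
) -> pd.DataFrame:
    """Per-animal pre-stress sleep feature table with phenotype labels.

    Parameters
    ----------
    hypnograms : mapping animal id -> baseline Hypnogram
        Each recording must cover both a light and a dark phase; animals
        missing a phase are dropped with a warning.
    labels : mapping animal id -> phenotype
        EXCLUDED animals are dropped.
    missing : "impute" or "drop"
        Undefined metric values (e.g. inter-bout interval with a single
        bout) are imputed with the column median, or the animal's row is
        dropped.

    Returns
    -------
    DataFrame indexed by animal (sorted), columns ``FEATURE_SCHEMA`` in
    fixed order plus a trailing ``phenotype`` column.
    """
    if missing not in ("impute", "drop"):
        raise ValueError("missing must be 'impute' or 'drop'")
    rows = {}
    for animal in sorted(hypnograms):
        label = PhenotypeLabel(labels[animal])
        if label is PhenotypeLabel.EXCLUDED:
            logger.info("dropping EXCLUDED animal %s", animal)
            continue
        try:
            feats = _animal_features(hypnograms[animal])
        except ValueError as err:
            logger.warning("dropping animal %s: %s", animal, err)
            continue
        feats["phenotype"] = label.value
        rows[animal] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "animal"
    table = table[[*FEATURE_SCHEMA, "phenotype"]]
    feat = table[list(FEATURE_SCHEMA)]
    if feat.isna().any().any():
        if missing == "drop":
            bad = feat.index[feat.isna().any(axis=1)]
            logger.warning("dropping animals with undefined features: %s",
                           list(bad))
            table = table.drop(index=bad)
        else:
            for col in FEATURE_SCHEMA:
                if table[col].isna().any():
                    med = table[col].median()
                    logger.warning("imputing %d missing %s with median %g",
                                   int(table[col].isna().sum()), col, med)
                    table[col] = table[col].fillna(med)
    return table


# ---------------------------------------------------------------------------
# Univariate F ranking
# ---------------------------------------------------------------------------

def _feature_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class FRankSelector(TransformerMixin, BaseEstimator):
    """Rank features by two-group ANOVA F statistic; keep the top ``k``.

    F = (between-group SS / 1) / (within-group SS / (n - 2)) for two
    groups. A feature constant across all animals scores 0; a feature with
    zero within-group variance but distinct group means scores +inf and
    outranks every finite value. Ties are broken lexically by feature name
    so the ranking is deterministic.

    Attributes
    ----------
    scores_ : pd.Series
        F statistic per feature (input order).
    ranking_ : list of str
        Feature names in descending F order.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y):
        Xf = _feature_frame(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2 or counts.min() < 2:
            raise ValueError("F ranking needs two classes with >= 2 animals each")
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # constant features are legitimate inputs here; they score F = 0
            warnings.filterwarnings("ignore", message="Features .* are constant")
            F, _ = f_classif(Xf.to_numpy(dtype=float), y)
        F = np.where(np.isnan(F), 0.0, F)  # 0/0: feature constant everywhere
        self.scores_ = pd.Series(F, index=Xf.columns, name="F")
        order = sorted(Xf.columns, key=lambda c: (-self.scores_[c], c))
        self.ranking_ = order
        self.n_features_in_ = Xf.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        Xf = _feature_frame(X)
        keep = self.ranking_[: self.k]
        return Xf[keep]

    def report(self) -> pd.DataFrame:
        """Per-feature F statistic and rank (1 = strongest)."""
        check_is_fitted(self, "ranking_")
        rank = {c: i + 1 for i, c in enumerate(self.ranking_)}
        return pd.DataFrame(
            {"F": self.scores_, "rank": [rank[c] for c in self.scores_.index]}
        ).sort_values("rank")


def f_rank(table: pd.DataFrame, labels=None, k: int = 10) -> pd.DataFrame:
    """Top-``k`` features by F statistic, as a DataFrame with columns
    ``F`` and ``rank``. ``table`` may carry a ``phenotype`` column or
    labels may be passed separately."""
    X, y = _split_xy(table, labels)
    sel = FRankSelector(k=k).fit(X, y)
    return sel.report().head(k)


def _split_xy(table: pd.DataFrame, labels=None):
    if labels is None:
        if "phenotype" not in table.columns:
            raise ValueError("table lacks a phenotype column and no labels given")
        return table.drop(columns="phenotype"), table["phenotype"].to_numpy()
    return table, np.asarray(labels)


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------

def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) from an intercept-included
    least-squares regression of column j on the remaining columns.

    Rank-deficient designs use the pseudo-inverse solution; R^2 at (or
    numerically indistinguishable from) 1 reports +inf.
    """
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(X.shape[0]), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("inf")  # constant column: perfectly fit by intercept
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


class VIFPruner(TransformerMixin, BaseEstimator):
    """Iteratively drop the feature with the largest variance inflation
    factor until all retained VIFs are <= ``threshold``.

    At every step the VIF of each retained feature is recomputed against
    the other retained features; the arg-max is removed (lexical
    tie-break). A lone surviving feature has VIF 1 by definition.

    Attributes
    ----------
    retained_ : list of str
        Features surviving the pruning, in input order.
    trace_ : pd.DataFrame
        One row per elimination: ``feature``, ``vif``, ``iteration``.
    vifs_ : pd.Series
        Final VIF of every retained feature.
    """

    def __init__(self, threshold: float = 35.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        Xf = _feature_frame(X)
        if Xf.shape[1] < 1:
            raise ValueError("VIF pruning needs at least one feature")
        retained = list(Xf.columns)
        trace: list[dict] = []
        iteration = 0
        while True:
            M = Xf[retained].to_numpy(dtype=float)
            if len(retained) == 1:
                vifs = pd.Series([1.0], index=retained)
            else:
                vifs = pd.Series(
                    [_vif_one(M, j) for j in range(len(retained))], index=retained
                )
            if vifs.max() <= self.threshold:
                break
            if len(retained) == 1:
                raise ValueError(
                    f"VIF threshold {self.threshold} eliminates every feature"
                )
            candidates = sorted(c for c in retained if vifs[c] == vifs.max())
            drop = candidates[0]
            iteration += 1
            trace.append(
                {"feature": drop, "vif": float(vifs[drop]), "iteration": iteration}
            )
            retained.remove(drop)
        self.retained_ = retained
        self.vifs_ = vifs
        self.trace_ = pd.DataFrame(trace, columns=["feature", "vif", "iteration"])
        self.n_features_in_ = Xf.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        return _feature_frame(X)[self.retained_]


def vif_prune(
    table: pd.DataFrame,
    features: Sequence[str] | None = None,
    threshold: float = 35.0,
) -> tuple[list[str], pd.DataFrame]:
    """Prune ``features`` (default: all non-label columns) by VIF.

    Returns ``(retained feature list, elimination trace)``.
    """
    X = table[list(features)] if features is not None else _split_xy(table)[0]
    pruner = VIFPruner(threshold=threshold).fit(X)
    return pruner.retained_, pruner.trace_


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class SusceptibilityClassifier(ClassifierMixin, BaseEstimator):
    """L2-penalized logistic regression on per-split standardized features.

    Features are standardized with the training data's mean and standard
    deviation only (the scaler is part of the estimator, so test data is
    transformed, never re-fit). The ridge penalty (fixed strength
    ``C = 1.0`` by default, intercept unpenalized) keeps the fit bounded
    under perfect separation at small n.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 1000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        Xf = _feature_frame(X)
        self.scaler_ = StandardScaler().fit(Xf.to_numpy(dtype=float))
        # ridge (L2) penalty, sklearn's default; intercept unpenalized
        self.model_ = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=self.max_iter
        ).fit(self.scaler_.transform(Xf.to_numpy(dtype=float)), np.asarray(y))
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        self.n_features_in_ = Xf.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        Xf = _feature_frame(X)
        return self.model_.predict(self.scaler_.transform(Xf.to_numpy(dtype=float)))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        Xf = _feature_frame(X)
        return self.model_.predict_proba(
            self.scaler_.transform(Xf.to_numpy(dtype=float))
        )


@dataclass
class ClassifierResult:
    """Repeated-split evaluation summary."""

    accuracies: np.ndarray  # one per split, in [0, 1]
    coefs: list[np.ndarray]  # fitted coefficient vector per split
    features: list[str]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def cross_validated_accuracy(
    table: pd.DataFrame,
    features: Sequence[str],
    labels=None,
    n_repeats: int = 200,
    test_fraction: float = 0.25,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierResult:
    """Mean accuracy over repeated stratified train/test splits.

    Each repeat draws a stratified random 75/25 (by default) split,
    standardizes with training statistics only, fits the penalized
    logistic model and scores the held-out fraction. Bit-for-bit
    reproducible given (table, features, seed, n_repeats). A degenerate
    split whose test fold misses a class is redrawn (logged); stratified
    splitting makes this rare.
    """
    if labels is None:
        _, y = _split_xy(table)
    else:
        y = np.asarray(labels)
    X = table[list(features)]
    if np.unique(y).size != 2:
        raise ValueError("need exactly two phenotype classes")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_repeats)
    coefs: list[np.ndarray] = []
    base = SusceptibilityClassifier(C=C)
    for r in range(n_repeats):
        while True:
            split_seed = int(rng.integers(0, 2**31 - 1))
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, test_size=test_fraction, stratify=y, random_state=split_seed
            )
            if np.unique(yte).size == 2 and np.unique(ytr).size == 2:
                break
            logger.info("redrawing split %d: a fold missed a class", r)
        model = clone(base).fit(Xtr, ytr)
        accs[r] = float(np.mean(model.predict(Xte) == yte))
        coefs.append(model.coef_.ravel().copy())
    return ClassifierResult(accuracies=accs, coefs=coefs, features=list(features))


def accuracy_vs_k(
    table: pd.DataFrame,
    ranked_features: Sequence[str],
    labels=None,
    k_max: int | None = None,
    n_repeats: int = 200,
    test_fraction: float = 0.25,
    seed: int = 0,
    C: float = 1.0,
) -> pd.Series:
    """Mean cross-validated accuracy using the top 1..k_max ranked
    features, added in rank order (the accuracy-vs-feature-count curve)."""
    if not ranked_features:
        raise ValueError("ranked feature list is empty")
    k_max = len(ranked_features) if k_max is None else min(k_max, len(ranked_features))
    out = {}
    for k in range(1, k_max + 1):
        res = cross_validated_accuracy(
            table,
            list(ranked_features[:k]),
            labels=labels,
            n_repeats=n_repeats,
            test_fraction=test_fraction,
            seed=seed,
            C=C,
        )
        out[k] = res.mean_accuracy
    return pd.Series(out, name="mean_accuracy").rename_axis("k")


def pca_projection(
    table: pd.DataFrame,
    features: Sequence[str],
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project animals onto the leading principal axes of the
    standardized feature submatrix.

    Zero-variance features are dropped with a warning. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    Returns ``(coordinates, explained variance ratios)``.
    """
    if len(features) < 1:
        raise ValueError("PCA needs at least one feature")
    X = table[list(features)].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        logger.warning("dropping zero-variance features: %s", dropped)
        X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no feature with nonzero variance")
    Z = StandardScaler().fit_transform(X)
    n_components = min(n_components, Z.shape[1], Z.shape[0])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(Z)
    for i in range(n_components):
        load = pca.components_[i]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, i] *= -1.0
    frame = pd.DataFrame(
        coords,
        index=table.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_
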