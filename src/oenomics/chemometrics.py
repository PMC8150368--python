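"""Chemometrics engine: scaling, PCA, Kennard-Stone, OPLS-DA, VIP, validation.

The discrimination model is OPLS-DA in the Trygg-Wold orthogonal-signal-
correction NIPALS form: a single predictive latent variable for a two-class
response (encoded 0/1) plus ``n_orthogonal`` components that capture
structured variation uncorrelated with class.  Markers are the variables
with VIP > 1; the V-plot couples the predictive loading p1 with VIP, and the
sign of p1 maps a marker to the class it is more expressed in.

Model validation follows standard chemometric practice: leave-one-seventh-
out cross-validated Q²Y, a permutation test of R²Y/Q²Y, an external test set
chosen by the Kennard-Stone algorithm, RMSEE/RMSEP on the encoded response
and ROC AUC of the continuous predictions.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

__all__ = [
    "FeatureMatrix",
    "OplsdaModel",
    "ColumnScaler",
    "normalize_to_is",
    "scale_matrix",
    "rank_scaling_methods",
    "run_pca",
    "kennard_stone_split",
    "fit_oplsda",
    "compute_vip",
    "cross_validate_q2",
    "select_n_orthogonal",
    "predict_class_maxdist",
    "permutation_test",
    "roc_auc",
    "select_markers",
    "vplot_table",
    "iqr_variable_filter",
    "drop_confounded_variables",
    "univariate_screen",
]

SCALING_METHODS = ("none", "center", "auto", "pareto", "range")


@dataclass
class FeatureMatrix:
    """Samples × variables table of IS-normalized abundances with metadata.

    ``classes`` holds the two-level class factor per sample (NaN for QC
    injections); ``vintage`` and ``qc`` are optional per-sample annotations.
    """

    values: pd.DataFrame
    classes: pd.Series
    vintage: pd.Series | None = None
    qc: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values; impute first")
        self.classes = self.classes.reindex(self.values.index)
        if self.vintage is not None:
            self.vintage = self.vintage.reindex(self.values.index)
        if self.qc is None:
            self.qc = pd.Series(False, index=self.values.index)
        else:
            self.qc = self.qc.reindex(self.values.index).fillna(False).astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.values.columns)

    def non_qc(self) -> "FeatureMatrix":
        keep = ~self.qc
        return self.subset(self.values.index[keep])

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.loc[list(sample_ids)],
            self.classes.loc[list(sample_ids)],
            None if self.vintage is None else self.vintage.loc[list(sample_ids)],
            self.qc.loc[list(sample_ids)],
        )

    def with_values(self, values: pd.DataFrame) -> "FeatureMatrix":
        return FeatureMatrix(values, self.classes, self.vintage, self.qc)


def normalize_to_is(
    raw_areas: pd.DataFrame,
    is_areas: pd.Series,
    classes: pd.Series | None = None,
    vintage: pd.Series | None = None,
    qc: pd.Series | None = None,
) -> FeatureMatrix:
    """Divide each sample's peak areas by that sample's internal-standard area.

    Samples with a missing or non-positive IS area are excluded with a
    warning (their drift correction is undefined).
    """
    is_areas = is_areas.reindex(raw_areas.index)
    bad = is_areas.isna() | (is_areas <= 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} sample(s) with missing IS area: "
            f"{list(raw_areas.index[bad])}",
            stacklevel=2,
        )
    kept = raw_areas.loc[~bad]
    values = kept.div(is_areas.loc[~bad], axis=0)
    if classes is None:
        classes = pd.Series(pd.NA, index=values.index, dtype=object)
    return FeatureMatrix(values, classes, vintage, qc)


class ColumnScaler:
    """Column-wise scaling with stored training parameters.

    Methods: ``none``, ``center`` (mean-centering), ``auto`` ((x−mean)/sd),
    ``pareto`` ((x−mean)/√sd) and ``range`` ((x−min)/(max−min)).  Columns
    whose scale parameter is degenerate (zero variance, or zero range for
    ``range``) are dropped with a warning.  Standard deviations use ddof=1.
    """

    def __init__(self, method: str = "pareto") -> None:
        if method not in SCALING_METHODS:
            raise ValueError(f"unknown scaling method {method!r}")
        self.method = method
        self.columns_: pd.Index | None = None
        self.center_: pd.Series | None = None
        self.scale_: pd.Series | None = None

    def fit(self, values: pd.DataFrame) -> "ColumnScaler":
        sd = values.std(ddof=1)
        if self.method in ("auto", "pareto", "center", "none"):
            degenerate = sd == 0 if self.method in ("auto", "pareto") else sd < 0
        else:  # range
            degenerate = (values.max() - values.min()) == 0
        if degenerate.any():
            warnings.warn(
                f"dropping {int(degenerate.sum())} zero-variance column(s): "
                f"{list(values.columns[degenerate])[:5]}...",
                stacklevel=2,
            )
        cols = values.columns[~degenerate]
        kept = values[cols]
        if self.method == "none":
            center, scale = kept.mean() * 0.0, pd.Series(1.0, index=cols)
        elif self.method == "center":
            center, scale = kept.mean(), pd.Series(1.0, index=cols)
        elif self.method == "auto":
            center, scale = kept.mean(), kept.std(ddof=1)
        elif self.method == "pareto":
            center, scale = kept.mean(), np.sqrt(kept.std(ddof=1))
        else:  # range
            center, scale = kept.min(), kept.max() - kept.min()
        self.columns_, self.center_, self.scale_ = cols, center, scale
        return self

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise ValueError("scaler not fitted")
        return (values[self.columns_] - self.center_) / self.scale_

    def fit_transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return self.fit(values).transform(values)


def scale_matrix(m: FeatureMatrix, method: str = "pareto") -> FeatureMatrix:
    """Column-scale a feature matrix (see :class:`ColumnScaler`)."""
    return m.with_values(ColumnScaler(method).fit_transform(m.values))


def run_pca(
    m: FeatureMatrix | pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA with internal mean-centering.

    Returns (scores, loadings, explained-variance fractions); components are
    ordered by decreasing variance and loadings are orthonormal.  Used to
    check that pooled-QC injections cluster centrally before any supervised
    modeling.
    """
    values = m.values if isinstance(m, FeatureMatrix) else m
    rank = int(np.linalg.matrix_rank(values - values.mean()))
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds matrix rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=values.index, columns=comp_names),
        pd.DataFrame(pca.components_.T, index=values.columns, columns=comp_names),
        pca.explained_variance_ratio_,
    )


def kennard_stone_split(
    m: FeatureMatrix | pd.DataFrame, train_fraction: float = 0.8
) -> tuple[list, list]:
    """Kennard-Stone max-min training-set selection on Euclidean distances.

    The first two picks are the maximally distant sample pair; each further
    pick maximizes its minimum distance to the already-selected set.  The
    training-set size is round-half-up(fraction × n) — 46 samples at 0.8
    give the 37/9 split.  Ties break toward the lowest sample index, so the
    selected *set* is invariant to sample order.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    values = m.values if isinstance(m, FeatureMatrix) else m
    index = list(values.index)
    x = values.to_numpy(dtype=float)
    n = len(index)
    if n < 2:
        raise ValueError("need at least 2 samples")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)

    # stable order: sort rows lexicographically by index label so ties in
    # distance resolve identically under any input permutation
    order = sorted(range(n), key=lambda i: str(index[i]))
    x = x[order]
    labels = [index[i] for i in order]

    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    i0, j0 = np.unravel_index(np.argmax(dist), dist.shape)
    if n_train == 1:
        selected = [min(i0, j0)]
        min_dist = dist[selected[0]].copy()
    else:
        selected = [min(i0, j0), max(i0, j0)]
        min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_train:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    selected_set = set(selected)
    train = [labels[i] for i in sorted(selected_set)]
    test = [labels[i] for i in range(n) if i not in selected_set]
    # restore original ordering of the input index
    pos = {lab: k for k, lab in enumerate(index)}
    return sorted(train, key=pos.get), sorted(test, key=pos.get)


def _encode_classes(y: Sequence) -> tuple[np.ndarray, dict]:
    labels = pd.Series(list(y))
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA requires exactly two classes, got {classes}")
    encoding = {classes[0]: 0.0, classes[1]: 1.0}
    return labels.map(encoding).to_numpy(dtype=float), encoding


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA state (one predictive + k orthogonal components)."""

    variable_ids: list[str]
    class_encoding: dict
    majority_class: object
    x_mean: np.ndarray
    y_mean: float
    w: np.ndarray  # predictive weights (unit norm)
    p: np.ndarray  # predictive loading p1
    c: float  # inner regression coefficient
    t: np.ndarray  # training predictive scores t1
    w_ortho: np.ndarray  # variables × k
    p_ortho: np.ndarray
    t_ortho: np.ndarray  # samples × k
    vip: pd.Series = field(repr=False, default=None)
    pcorr1: pd.Series = field(repr=False, default=None)
    r2x: float = np.nan
    r2y: float = np.nan
    rmsee: float = np.nan
    q2y: float = np.nan
    rmsep: float = np.nan

    @property
    def n_orthogonal(self) -> int:
        return self.w_ortho.shape[1]

    def _prepare(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [v for v in self.variable_ids if v not in X.columns]
            if missing:
                raise ValueError(f"missing variables in new data: {missing[:5]}")
            X = X[self.variable_ids].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.variable_ids):
            raise ValueError("column mismatch vs training variables")
        return X - self.x_mean

    def predict_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Continuous predicted response (encoded-class units)."""
        xc = self._prepare(X)
        for k in range(self.n_orthogonal):
            t_o = xc @ self.w_ortho[:, k]
            xc = xc - np.outer(t_o, self.p_ortho[:, k])
        return self.y_mean + self.c * (xc @ self.w)


def fit_oplsda(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    n_orthogonal: int = 1,
) -> OplsdaModel:
    """Fit OPLS-DA by orthogonal-signal-correction NIPALS (Trygg-Wold).

    ``X`` must already be column-scaled (e.g. Pareto); mean-centering of X
    and of the 0/1-encoded response happens internally.  With
    ``n_orthogonal=0`` the predictive component coincides with
    single-component PLS1.
    """
    if isinstance(X, pd.DataFrame):
        variable_ids = list(X.columns)
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        variable_ids = [f"v{j}" for j in range(x.shape[1])]
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    y_enc, encoding = _encode_classes(y)
    if len(y_enc) != x.shape[0]:
        raise ValueError("X and y length mismatch")
    counts = pd.Series(list(y)).value_counts()
    majority = sorted(counts.index[counts == counts.max()])[0]

    x_mean = x.mean(axis=0)
    xc0 = x - x_mean
    y_mean = float(y_enc.mean())
    yc = y_enc - y_mean
    rank = int(np.linalg.matrix_rank(xc0))
    if n_orthogonal >= rank:
        raise ValueError(f"n_orthogonal={n_orthogonal} too large for matrix rank {rank}")

    w = xc0.T @ yc
    norm_w = np.linalg.norm(w)
    if norm_w == 0:
        raise ValueError("response uncorrelated with every variable; cannot fit")
    w = w / norm_w

    xc = xc0.copy()
    n_vars = x.shape[1]
    w_ortho = np.zeros((n_vars, 0))
    p_ortho = np.zeros((n_vars, 0))
    t_ortho = np.zeros((x.shape[0], 0))
    ss_x_explained = 0.0
    for _ in range(n_orthogonal):
        t = xc @ w
        p = xc.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm_wo = np.linalg.norm(wo)
        if norm_wo < 1e-12:
            raise ValueError("no orthogonal variation left to extract")
        wo = wo / norm_wo
        to = xc @ wo
        po = xc.T @ to / (to @ to)
        xc = xc - np.outer(to, po)
        ss_x_explained += float((to @ to) * (po @ po))
        w_ortho = np.column_stack([w_ortho, wo])
        p_ortho = np.column_stack([p_ortho, po])
        t_ortho = np.column_stack([t_ortho, to])

    t = xc @ w
    p = xc.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    ss_x_explained += float((t @ t) * (p @ p))

    y_hat = y_mean + c * t
    residual = y_enc - y_hat
    ss_y = float(yc @ yc)
    r2y = 1.0 - float(residual @ residual) / ss_y
    r2x = ss_x_explained / float((xc0**2).sum())
    rmsee = float(np.sqrt(np.mean(residual**2)))

    with np.errstate(invalid="ignore"):
        pcorr = np.array(
            [stats.pearsonr(t, xc0[:, j])[0] if xc0[:, j].std() > 0 else 0.0
             for j in range(n_vars)]
        )
    model = OplsdaModel(
        variable_ids=variable_ids,
        class_encoding=encoding,
        majority_class=majority,
        x_mean=x_mean,
        y_mean=y_mean,
        w=w,
        p=p,
        c=c,
        t=t,
        w_ortho=w_ortho,
        p_ortho=p_ortho,
        t_ortho=t_ortho,
        pcorr1=pd.Series(pcorr, index=variable_ids, name="pcorr1"),
        r2x=r2x,
        r2y=r2y,
        rmsee=rmsee,
    )
    model.vip = compute_vip(model)
    return model


def compute_vip(model: OplsdaModel) -> pd.Series:
    """Variable Importance in Projection for the predictive component.

    With a single predictive component, VIP_j = √m · |w_j| / ‖w‖, so VIP is
    proportional to |w1| and the mean of squared VIP equals 1 by
    construction — the structure that makes the VIP/|p1| ratio constant
    across variables in a fitted model.
    """
    w = model.w
    m = len(w)
    vip = np.sqrt(m) * np.abs(w) / np.linalg.norm(w)
    return pd.Series(vip, index=model.variable_ids, name="vip")


def _stratified_folds(y: Sequence, folds: int, seed: int) -> np.ndarray:
    """Round-robin fold assignment after class-wise shuffling (deterministic)."""
    y = pd.Series(list(y))
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    offset = 0
    for cls in sorted(y.unique()):
        idx = np.flatnonzero(y.to_numpy() == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            assignment[i] = (k + offset) % folds
        offset += len(idx)
    return assignment


def cross_validate_q2(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    n_orthogonal: int = 1,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Leave-one-``folds``-th-out cross-validated Q²Y = 1 − PRESS/TSS."""
    x = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = list(y)
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    y_enc, _ = _encode_classes(y)
    assignment = _stratified_folds(y, folds, seed)
    press = 0.0
    for fold in range(folds):
        test = assignment == fold
        if not test.any():
            continue
        train = ~test
        if len(set(np.array(y, dtype=object)[train])) < 2:
            raise ValueError("cross-validation fold left a single-class training set")
        model = fit_oplsda(x[train], [y[i] for i in np.flatnonzero(train)], n_orthogonal)
        y_hat = model.predict_scores(x[test])
        press += float(((y_enc[test] - y_hat) ** 2).sum())
    tss = float(((y_enc - y_enc.mean()) ** 2).sum())
    return 1.0 - press / tss


def select_n_orthogonal(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    max_orthogonal: int = 5,
    folds: int = 7,
    seed: int = 0,
    min_improvement: float = 0.01,
) -> int:
    """Choose the orthogonal-component count at the first maximum of Q²Y.

    Components are added while cross-validated Q²Y improves by more than
    ``min_improvement``; the rule favors model simplicity.
    """
    best_n = 0
    best_q2 = cross_validate_q2(X, y, 0, folds=folds, seed=seed)
    for n in range(1, max_orthogonal + 1):
        try:
            q2 = cross_validate_q2(X, y, n, folds=folds, seed=seed)
        except ValueError:
            break
        if q2 > best_q2 + min_improvement:
            best_n, best_q2 = n, q2
        else:
            break
    return best_n


def predict_class_maxdist(
    model: OplsdaModel,
    X_new: pd.DataFrame | np.ndarray,
    y_true: Sequence | None = None,
) -> tuple[list, float | None, float | None]:
    """Max-dist classification: assign the class whose encoded value is nearest.

    With 0/1 encoding the decision threshold is 0.5; an exact tie goes to
    the majority training class.  Returns (labels, RMSEP, accuracy); RMSEP
    and accuracy are None without ``y_true``.
    """
    scores = model.predict_scores(X_new)
    decode = {v: k for k, v in model.class_encoding.items()}
    labels = []
    for s in scores:
        if s == 0.5:
            labels.append(model.majority_class)
        else:
            labels.append(decode[0.0] if s < 0.5 else decode[1.0])
    rmsep = accuracy = None
    if y_true is not None:
        y_enc = np.array([model.class_encoding[c] for c in y_true], dtype=float)
        rmsep = float(np.sqrt(np.mean((y_enc - scores) ** 2)))
        accuracy = float(np.mean([a == b for a, b in zip(labels, y_true)]))
    return labels, rmsep, accuracy


def permutation_test(
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    n_orthogonal: int = 1,
    n_perm: int = 20,
    seed: int = 0,
    folds: int = 7,
) -> dict:
    """Permutation test of R²Y and Q²Y under random class relabeling.

    The class vector is shuffled ``n_perm`` times and the full model
    (including cross-validation) is refit per permutation.  For a real class
    structure, every permuted Q²Y should fall below the actual one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = list(y)
    actual_model = fit_oplsda(X, y, n_orthogonal)
    actual_q2 = cross_validate_q2(X, y, n_orthogonal, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    permuted = []
    for _ in range(n_perm):
        y_perm = [y[i] for i in rng.permutation(len(y))]
        model_p = fit_oplsda(X, y_perm, n_orthogonal)
        q2_p = cross_validate_q2(X, y_perm, n_orthogonal, folds=folds, seed=seed)
        permuted.append((model_p.r2y, q2_p))
    return {
        "actual": (actual_model.r2y, actual_q2),
        "permuted": permuted,
    }


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve of continuous scores against two-class labels.

    Equivalent to the normalized Mann-Whitney U statistic; the positive
    class is the one encoded 1 (second in sorted label order).
    """
    y_enc, _ = _encode_classes(labels)
    if len(set(y_enc)) < 2:
        raise ValueError("ROC AUC undefined with a single class")
    return float(roc_auc_score(y_enc, np.asarray(scores, dtype=float)))


def select_markers(model: OplsdaModel, vip_threshold: float = 1.0) -> pd.DataFrame:
    """Marker table: variables with VIP strictly above the threshold.

    Columns: p1, pcorr1, vip and the associated class (sign of p1 maps a
    variable to the class it is more expressed in); sorted by VIP
    descending.
    """
    decode = {v: k for k, v in model.class_encoding.items()}
    table = pd.DataFrame(
        {
            "p1": pd.Series(model.p, index=model.variable_ids),
            "pcorr1": model.pcorr1,
            "vip": model.vip,
        }
    )
    sign = model.c if model.c != 0 else 1.0
    table["class"] = np.where(table["p1"] * sign > 0, decode[1.0], decode[0.0])
    markers = table[table["vip"] > vip_threshold].sort_values("vip", ascending=False)
    markers.index.name = "variable"
    return markers


def vplot_table(model: OplsdaModel) -> pd.DataFrame:
    """V-plot coordinates: p1 (abscissa) against VIP (ordinate), plus pcorr1."""
    return pd.DataFrame(
        {
            "p1": pd.Series(model.p, index=model.variable_ids),
            "vip": model.vip,
            "pcorr1": model.pcorr1,
        }
    ).rename_axis("variable")


def iqr_variable_filter(m: FeatureMatrix, drop_fraction: float = 0.25) -> FeatureMatrix:
    """Drop the ``drop_fraction`` of variables with the smallest interquartile range.

    Ties at the cut are kept, so the retained count may exceed the nominal
    target.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    iqr = m.values.quantile(0.75) - m.values.quantile(0.25)
    n_drop = int(np.floor(drop_fraction * len(iqr)))
    if n_drop == 0:
        return m
    cutoff = np.sort(iqr.to_numpy())[n_drop]
    keep = m.values.columns[iqr.to_numpy() >= cutoff]
    return m.with_values(m.values[keep])


def drop_confounded_variables(m: FeatureMatrix, removal: Sequence[str]) -> FeatureMatrix:
    """Remove named variables (organic acids, fermentation/defense metabolites).

    Unknown names are skipped with a warning.
    """
    removal = list(removal)
    unknown = [name for name in removal if name not in m.values.columns]
    if unknown:
        warnings.warn(f"removal list names not in matrix, skipped: {unknown}", stacklevel=2)
    keep = [c for c in m.values.columns if c not in set(removal)]
    return m.with_values(m.values[keep])


def univariate_screen(
    m: FeatureMatrix, alpha: float = 0.05, parametric_when_valid: bool = True
) -> pd.DataFrame:
    """Per-variable two-class comparison with assumption checks.

    Normality (Shapiro, per class) and homoscedasticity (Levene) are
    evaluated first; the comparison uses Student's t only when both hold
    (and ``parametric_when_valid``), otherwise the Wilcoxon-Mann-Whitney
    test.  p-values are Bonferroni-adjusted over the variables actually
    tested; constant variables are flagged untestable.
    """
    sub = m.non_qc()
    labels = sub.classes.dropna()
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("univariate screen requires exactly two classes")
    a_ids = labels.index[labels == classes[0]]
    b_ids = labels.index[labels == classes[1]]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("need at least 3 samples per class")

    rows = []
    for var in sub.values.columns:
        xa = sub.values.loc[a_ids, var].to_numpy(dtype=float)
        xb = sub.values.loc[b_ids, var].to_numpy(dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            rows.append((var, np.nan, np.nan, np.nan, "untestable", np.nan))
            continue
        sh_a = stats.shapiro(xa).pvalue if np.ptp(xa) > 0 else np.nan
        sh_b = stats.shapiro(xb).pvalue if np.ptp(xb) > 0 else np.nan
        lev = stats.levene(xa, xb).pvalue
        normal = (
            np.isfinite(sh_a) and np.isfinite(sh_b)
            and sh_a > alpha and sh_b > alpha and lev > alpha
        )
        if normal and parametric_when_valid:
            test, p = "t", stats.ttest_ind(xa, xb).pvalue
        else:
            test, p = "wilcoxon", stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        rows.append((var, sh_a, sh_b, lev, test, float(p)))

    out = pd.DataFrame(
        rows, columns=["variable", "shapiro_p_a", "shapiro_p_b", "levene_p", "test", "p"]
    ).set_index("variable")
    tested = out["test"] != "untestable"
    n_tested = int(tested.sum())
    out["p_adj"] = np.where(tested, np.minimum(1.0, out["p"] * n_tested), np.nan)
    out["significant"] = (out["p_adj"] < alpha).fillna(False)
    return out


def rank_scaling_methods(
    m: FeatureMatrix,
    methods: Sequence[str] = SCALING_METHODS,
    train_fraction: float = 0.8,
    n_orthogonal: int = 1,
    folds: int = 7,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Rank candidate scaling methods by classification-model performance.

    For each method the full pipeline is evaluated (scale, Kennard-Stone
    split, OPLS-DA fit, cross-validated Q²Y, external accuracy and RMSEP);
    the composite score is the mean of min-max-normalized {Q²Y, accuracy,
    1 − RMSEP} across the candidates, reported in [0, 1].  A degenerate
    metric (identical across methods) contributes 0.5 to every candidate.
    """
    if len(methods) < 2:
        raise ValueError("need at least two candidate methods")
    sub = m.non_qc()
    metrics: dict[str, tuple[float, float, float]] = {}
    for method in methods:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaled_all = scale_matrix(sub, method)
                train_ids, test_ids = kennard_stone_split(scaled_all, train_fraction)
                scaler = ColumnScaler(method).fit(sub.values.loc[train_ids])
                x_train = scaler.transform(sub.values.loc[train_ids])
                x_test = scaler.transform(sub.values.loc[test_ids])
                y_train = sub.classes.loc[train_ids]
                y_test = sub.classes.loc[test_ids]
                model = fit_oplsda(x_train, y_train, n_orthogonal)
                q2 = cross_validate_q2(x_train, y_train, n_orthogonal, folds, seed)
                _, rmsep, accuracy = predict_class_maxdist(model, x_test, y_test)
            metrics[method] = (q2, accuracy, 1.0 - rmsep)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"scaling method {method!r} failed: {exc}", stacklevel=2)
            metrics[method] = (np.nan, np.nan, np.nan)

    arr = np.array([metrics[meth] for meth in methods], dtype=float)
    normalized = np.full_like(arr, 0.5)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        finite = np.isfinite(col)
        if finite.sum() >= 2 and np.ptp(col[finite]) > 1e-12:
            lo, hi = np.nanmin(col), np.nanmax(col)
            normalized[finite, j] = (col[finite] - lo) / (hi - lo)
        normalized[~finite, j] = 0.0
    scores = normalized.mean(axis=1)
    ranking = sorted(zip(methods, scores.tolist()), key=lambda kv: (-kv[1], kv[0]))
    return [(meth, float(score)) for meth, score in ranking]
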