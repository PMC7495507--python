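"""Diagnostic classification from multiscale-entropy profiles.

The architecture treats every (subject, region) 60-dim entropy profile
(20 scale factors x spectral/amplitude/phase) as one unsupervised
sample: a bank of sparse autoencoders — identical except for their
random initialisation — is trained on the training-fold samples, and the
concatenated hidden activations form a feature pool.  Features restricted
to the temporal regions are ranked by Fisher's score on the training
subjects, the top-k enter a linear soft-margin SVM over subjects, and
(k, C) are chosen per outer fold by validation AUC inside a repeated
stratified five-fold double cross-validation (train:validation:test
3:1:1).  Two reference architectures — the plain SVM and Fisher-score
selection + SVM — share the same fold assignments for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

__all__ = [
    "SAEParams",
    "CVConfig",
    "ClassificationReport",
    "SparseAutoencoder",
    "train_sae",
    "build_feature_pool",
    "fisher_score",
    "select_features",
    "train_linear_svm",
    "roc_auc",
    "double_cv",
    "ARCHITECTURES",
]

logger = logging.getLogger(__name__)

ARCHITECTURES = ("svm", "fs_svm", "sae_fs_svm")


@dataclass
class SAEParams:
    """Sparse-autoencoder bank parameters.

    Each autoencoder has one hidden layer of ``n_hidden`` units and is
    trained to minimise mean-squared reconstruction error plus
    ``l1_coeff`` times the mean absolute hidden activation (activation-
    level L1 sparsity).  ``n_autoencoders`` members differing only by
    initialisation seed form the pool.
    """

    n_autoencoders: int = 300
    n_hidden: int = 70
    l1_coeff: float = 1e-3
    epochs: int = 200
    learning_rate: float = 0.01
    activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_autoencoders < 1 or self.n_hidden < 1:
            raise ValueError("counts must be >= 1")
        if self.l1_coeff < 0:
            raise ValueError("l1_coeff must be >= 0")
        if self.activation not in ("sigmoid", "linear"):
            raise ValueError("activation must be 'sigmoid' or 'linear'")


@dataclass
class CVConfig:
    """Repeated five-fold double cross-validation configuration."""

    n_folds: int = 5
    n_repeats: int = 300
    k_range: tuple[int, int] = (100, 10000)
    c_range: tuple[float, float] = (1e-3, 1.0)
    search_budget: int = 30
    seed: int = 0
    sae: SAEParams = field(default_factory=SAEParams)

    def __post_init__(self) -> None:
        if self.n_folds < 3:
            raise ValueError("need >= 3 folds for a 3:1:1 split")
        if self.k_range[0] > self.k_range[1] or self.k_range[0] < 1:
            raise ValueError("invalid k_range")
        if not (0 < self.c_range[0] <= self.c_range[1]):
            raise ValueError("invalid c_range")


@dataclass
class ClassificationReport:
    """Per-(repeat, fold) test metrics with mean +/- SD summaries."""

    architecture: str
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: np.ndarray

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            vals = getattr(self, name)
            vals = vals[np.isfinite(vals)]
            out[name] = {"mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0}
        return out

    def to_dict(self) -> dict:
        return {"architecture": self.architecture,
                "summary": self.summary(),
                "per_fold": {name: np.asarray(getattr(self, name)).tolist()
                             for name in ("accuracy", "sensitivity",
                                          "specificity", "auc")}}


class SparseAutoencoder:
    """Single-hidden-layer autoencoder with L1 activation sparsity.

    Trained by full-batch Adam on mean-squared reconstruction loss;
    deterministic given the seed.
    """

    def __init__(self, n_hidden: int, l1_coeff: float = 1e-3,
                 epochs: int = 200, learning_rate: float = 0.01,
                 activation: str = "sigmoid", seed: int = 0) -> None:
        self.n_hidden = n_hidden
        self.l1_coeff = l1_coeff
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.activation = activation
        self.seed = seed
        self.w1: np.ndarray | None = None

    def _act(self, a: np.ndarray) -> np.ndarray:
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-a))
        return a

    def fit(self, X: np.ndarray) -> "SparseAutoencoder":
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite inputs")
        if X.shape[0] < 10:
            raise ValueError("need >= 10 samples")
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        h = self.n_hidden
        w1 = rng.normal(0, 1 / np.sqrt(d), (d, h))
        b1 = np.zeros(h)
        w2 = rng.normal(0, 1 / np.sqrt(h), (h, d))
        b2 = np.zeros(d)

        params = [w1, b1, w2, b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        for t in range(1, self.epochs + 1):
            pre = X @ w1 + b1
            H = self._act(pre)
            Xhat = H @ w2 + b2
            err = Xhat - X                      # (n, d)
            # d(mse)/dXhat = 2 err / (n d); d(l1)/dH = sign(H)/(n h)
            g_out = 2.0 * err / (n * d)
            g_w2 = H.T @ g_out
            g_b2 = g_out.sum(axis=0)
            g_h = g_out @ w2.T + self.l1_coeff * np.sign(H) / (n * h)
            if self.activation == "sigmoid":
                g_pre = g_h * H * (1.0 - H)
            else:
                g_pre = g_h
            g_w1 = X.T @ g_pre
            g_b1 = g_pre.sum(axis=0)
            grads = [g_w1, g_b1, g_w2, g_b2]
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1 ** t)
                vhat = v[i] / (1 - beta2 ** t)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

        self.w1, self.b1, self.w2, self.b2 = params
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        if self.w1 is None:
            raise RuntimeError("autoencoder not fitted")
        return self._act(np.asarray(X, dtype=float) @ self.w1 + self.b1)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.encode(X) @ self.w2 + self.b2


def train_sae(X: np.ndarray, params: SAEParams,
              seed: int | None = None) -> SparseAutoencoder:
    """Fit one sparse autoencoder on standardized (subject, region) samples."""
    sae = SparseAutoencoder(
        n_hidden=params.n_hidden, l1_coeff=params.l1_coeff,
        epochs=params.epochs, learning_rate=params.learning_rate,
        activation=params.activation,
        seed=params.seed if seed is None else seed)
    return sae.fit(X)


def build_feature_pool(features: np.ndarray, params: SAEParams,
                       train_subjects: np.ndarray | None = None
                       ) -> tuple[np.ndarray, list[SparseAutoencoder]]:
    """Activations of an SAE bank for every (subject, region) sample.

    ``features`` is (n_subjects, n_regions, n_features), already imputed
    and standardized on training statistics.  The SAEs are fit on the
    ``train_subjects`` rows only (all subjects if None) but encode
    everyone.  Returns (n_subjects, n_regions,
    n_autoencoders * n_hidden) plus the fitted bank; feature provenance
    is positional (SAE i owns the contiguous block i*n_hidden ...).
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 3:
        raise ValueError("features must be (subjects, regions, features)")
    n_subj, n_reg, n_feat = F.shape
    flat = F.reshape(n_subj * n_reg, n_feat)
    if train_subjects is None:
        fit_rows = flat
    else:
        fit_rows = F[np.asarray(train_subjects)].reshape(-1, n_feat)
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(params.n_autoencoders)]
    bank = [train_sae(fit_rows, params, seed=s) for s in seeds]
    pool = np.concatenate([sae.encode(flat) for sae in bank], axis=1)
    return pool.reshape(n_subj, n_reg, -1), bank


def fisher_score(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher's discriminant score per feature column.

    ``(mu_0 - mu_1)^2 / (s2_0 + s2_1)`` with sample variances.  Features
    constant within both classes score 0 when the class means agree
    (uninformative) and +inf when they differ (a perfect separator).
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    a = X[y == classes[0]]
    b = X[y == classes[1]]
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)
    score = np.zeros_like(num)
    ok = den > 0
    score[ok] = num[ok] / den[ok]
    perfect = (~ok) & (num > 0)
    score[perfect] = np.inf
    constant = (~ok) & (num == 0)
    if constant.any():
        logger.warning("fisher_score: %d constant features scored 0",
                       int(constant.sum()))
    return score


def select_features(pool: np.ndarray, labels: np.ndarray, k: int,
                    region_subset, train_subjects: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Top-k (region, feature) pairs in ``region_subset`` by Fisher score.

    Scores are computed across the training subjects; ties break toward
    the lower flattened (region-major) index.  Returns
    ``(selector, scores)`` where ``selector`` is an (k, 2) array of
    (region, feature) index pairs; apply with
    ``pool[:, selector[:, 0], selector[:, 1]]``.
    """
    P = np.asarray(pool, dtype=float)
    y = np.asarray(labels)
    regions = np.asarray(list(region_subset), dtype=int)
    sub = P[:, regions, :]                      # (subj, r_sub, F)
    n_subj, n_reg, n_feat = sub.shape
    flat = sub.reshape(n_subj, n_reg * n_feat)
    rows = flat if train_subjects is None else flat[np.asarray(train_subjects)]
    ytr = y if train_subjects is None else y[np.asarray(train_subjects)]
    scores = fisher_score(rows, ytr)
    avail = scores.size
    if k > avail:
        logger.warning("select_features: k=%d capped to %d", k, avail)
        k = avail
    # stable sort on -score keeps lower index first among ties
    order = np.argsort(-scores, kind="stable")[:k]
    selector = np.column_stack([regions[order // n_feat], order % n_feat])
    return selector, scores[order]


def apply_selector(pool: np.ndarray, selector: np.ndarray) -> np.ndarray:
    """Per-subject vectors of the selected (region, feature) pairs."""
    return np.asarray(pool)[:, selector[:, 0], selector[:, 1]]


def train_linear_svm(X: np.ndarray, labels: np.ndarray, C: float) -> LinearSVC:
    """Linear soft-margin SVM (features pre-standardized on training stats)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input")
    clf = LinearSVC(C=C, dual=True, max_iter=20000, random_state=0)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def roc_auc(decision_values: np.ndarray, labels: np.ndarray,
            positive: object = 1) -> float:
    """P(score_pos > score_neg) with ties counted 1/2 (Mann-Whitney)."""
    s = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels) == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    from scipy.stats import rankdata
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# double cross-validation


def stratified_folds(labels: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Fold index per subject, dealing each class round-robin after a shuffle."""
    y = np.asarray(labels)
    fold = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def _standardize(train_rows: np.ndarray):
    mu = train_rows.mean(axis=0)
    sd = train_rows.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return lambda X: (X - mu) / sd


def _impute_train_mean(F: np.ndarray, train_subjects: np.ndarray) -> np.ndarray:
    """Replace undefined cells by the training-fold mean of that cell."""
    out = F.copy()
    tr = F[train_subjects]
    cell_mean = np.nanmean(tr, axis=0)          # (regions, features)
    cell_mean = np.nan_to_num(cell_mean, nan=0.0)
    nan_mask = ~np.isfinite(out)
    if nan_mask.any():
        fill = np.broadcast_to(cell_mean, out.shape)
        out[nan_mask] = fill[nan_mask]
    return out


def fit_outer_fold(features: np.ndarray, labels01: np.ndarray,
                   train_idx: np.ndarray, val_idx: np.ndarray,
                   temporal_regions, architecture: str, config: CVConfig,
                   rng: np.random.Generator) -> dict:
    """Fit one outer fold: SAE bank, selection and SVM on the training
    subjects only, hyperparameters chosen by validation AUC.

    Returns a bundle with a ``predict(features) -> (decisions, labels01
    predictions)`` closure so callers can score arbitrary subjects; the
    fitted state never saw any subject outside ``train_idx`` (validation
    subjects enter only through the hyperparameter choice).
    """
    F = _impute_train_mean(np.asarray(features, dtype=float), train_idx)
    n_subj, n_reg, n_feat = F.shape
    flat = F.reshape(n_subj * n_reg, n_feat)
    train_rows = F[train_idx].reshape(-1, n_feat)
    scale_rows = _standardize(train_rows)
    Fs = scale_rows(flat).reshape(n_subj, n_reg, n_feat)
    temporal = np.asarray(list(temporal_regions), dtype=int)

    if architecture == "sae_fs_svm":
        sae_params = SAEParams(
            n_autoencoders=config.sae.n_autoencoders,
            n_hidden=config.sae.n_hidden, l1_coeff=config.sae.l1_coeff,
            epochs=config.sae.epochs, learning_rate=config.sae.learning_rate,
            activation=config.sae.activation,
            seed=int(rng.integers(2 ** 31)))
        pool, _ = build_feature_pool(Fs, sae_params, train_subjects=train_idx)
    else:
        pool = Fs

    def candidate_ks() -> np.ndarray:
        lo, hi = config.k_range
        avail = len(temporal) * pool.shape[2]
        hi = min(hi, avail)
        lo = min(lo, hi)
        return rng.integers(lo, hi + 1, size=config.search_budget)

    def candidate_cs() -> np.ndarray:
        lo, hi = config.c_range
        return np.exp(rng.uniform(np.log(lo), np.log(hi),
                                  size=config.search_budget))

    def build(k: int | None, C: float):
        if architecture == "svm":
            X = pool[:, temporal, :].reshape(n_subj, -1)
            selector = None
        else:
            selector, _ = select_features(pool, labels01, int(k), temporal,
                                          train_subjects=train_idx)
            X = apply_selector(pool, selector)
        scale_subj = _standardize(X[train_idx])
        Xs = scale_subj(X)
        clf = train_linear_svm(Xs[train_idx], labels01[train_idx], C)
        return {"selector": selector, "X": Xs, "clf": clf}

    cs = candidate_cs()
    ks = candidate_ks() if architecture != "svm" else [None] * config.search_budget
    best, best_auc, best_hp = None, -np.inf, None
    searchable = val_idx.size > 0 and len(np.unique(labels01[val_idx])) == 2
    for k, C in zip(ks, cs):
        if not searchable:
            break
        model = build(k, float(C))
        dec = model["clf"].decision_function(model["X"][val_idx])
        try:
            auc = roc_auc(dec, labels01[val_idx], positive=1)
        except ValueError:
            auc = np.nan
        if np.isfinite(auc) and auc > best_auc:
            best, best_auc, best_hp = model, auc, (None if k is None else int(k),
                                                   float(C))
    if best is None:        # e.g. single-class validation fold
        best = build(ks[0], float(cs[0]))
        best_hp = (None if ks[0] is None else int(ks[0]), float(cs[0]))

    def predict(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dec = best["clf"].decision_function(best["X"][idx])
        pred = best["clf"].predict(best["X"][idx])
        return dec, pred

    return {"predict": predict, "hyperparams": best_hp,
            "val_auc": best_auc, "model": best}


def _test_metrics(dec, pred, truth) -> tuple[float, float, float, float]:
    acc = float(np.mean(pred == truth))
    pos = truth == 1
    neg = truth == 0
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else np.nan
    spec = float(np.mean(pred[neg] == 0)) if neg.any() else np.nan
    try:
        auc = roc_auc(dec, truth, positive=1)
    except ValueError:
        auc = np.nan
    return acc, sens, spec, auc


def double_cv(features: np.ndarray, labels, temporal_regions,
              config: CVConfig | None = None,
              architecture: str = "sae_fs_svm",
              fold_assignments: np.ndarray | None = None
              ) -> ClassificationReport:
    """Repeated stratified five-fold double CV of one architecture.

    ``features`` is (n_subjects, n_regions, 60); ``labels`` are 'HC'/'AD'
    strings or 0/1 with AD = positive = 1.  Per repeat, subjects are
    stratified into ``n_folds`` folds; each fold serves once as the test
    set with the next fold as validation (3:1:1).  ``fold_assignments``
    (n_repeats, n_subjects), normally derived from the seed alone, lets
    compared architectures share groupings.
    """
    if config is None:
        config = CVConfig()
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        labels01 = (y == "AD").astype(int)
    else:
        labels01 = y.astype(int)
    if min((labels01 == 1).sum(), (labels01 == 0).sum()) < 3:
        raise ValueError("need >= 3 subjects per group")
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")

    rng = np.random.default_rng(config.seed)
    n_subj = labels01.size
    if fold_assignments is None:
        fold_assignments = np.stack([
            stratified_folds(labels01, config.n_folds, rng)
            for _ in range(config.n_repeats)])

    metrics = {name: [] for name in ("accuracy", "sensitivity",
                                     "specificity", "auc")}
    for rep in range(config.n_repeats):
        folds = fold_assignments[rep]
        for test_fold in range(config.n_folds):
            val_fold = (test_fold + 1) % config.n_folds
            test_idx = np.nonzero(folds == test_fold)[0]
            val_idx = np.nonzero(folds == val_fold)[0]
            train_idx = np.nonzero((folds != test_fold)
                                   & (folds != val_fold))[0]
            if test_idx.size == 0 or len(np.unique(labels01[train_idx])) < 2:
                logger.warning("empty test fold or single-class training "
                               "fold; skipped")
                continue
            bundle = fit_outer_fold(features, labels01, train_idx, val_idx,
                                    temporal_regions, architecture, config,
                                    rng)
            dec, pred = bundle["predict"](test_idx)
            acc, sens, spec, auc = _test_metrics(dec, pred, labels01[test_idx])
            for name, val in zip(metrics, (acc, sens, spec, auc)):
                metrics[name].append(val)

    return ClassificationReport(
        architecture=architecture,
        accuracy=np.array(metrics["accuracy"]),
        sensitivity=np.array(metrics["sensitivity"]),
        specificity=np.array(metrics["specificity"]),
        auc=np.array(metrics["auc"]))
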