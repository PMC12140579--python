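"""Cross-validated phenotype prediction from connectivity features.

One prediction round: split subjects into k folds; per training fold run a
PEB analysis (optionally followed by BMR) on the training subjects only and
mask parameters whose covariate effect has PP above threshold; extract the
masked subject-level posterior means as features; train a LASSO- or
ridge-regularized linear model (penalty chosen by inner 5-fold CV on the
training fold); predict the held-out fold.  Accuracy per repetition is the
Pearson correlation between predicted and empirical scores averaged across
the round's testing folds (for LOOCV, where folds are singletons, the pooled
correlation over all subjects); the pooled-correlation variant is recorded
alongside for every scheme.  Label-shuffled permutations of the whole round
give the null distribution.

The per-fold-averaged convention is primary because pooling predictions
carries a systematic negative bias of order -1/sqrt(fold size) under the
null (fold-specific training means anticorrelate with held-out targets),
which at desk-scale cohort sizes swamps chance-level accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold

from .errors import AlignmentError, ConfigurationError, DegenerateTargetError
from .peb import EdgeMask, bmr_mask, build_design_matrix, fit_peb, pp_mask

_SOURCE_TO_WHICH = {"I-EC": "A", "M-EC": "B", "combined": "AB"}


@dataclass
class PredictionConfig:
    cv_scheme: str = "kfold"  # "kfold" | "loocv"
    k: int = 5
    n_repetitions: int = 100
    n_permutations: int = 500
    regressor: str = "lasso"  # "lasso" | "ridge"
    feature_source: str = "M-EC"  # I-EC | M-EC | combined | FC-full | FC-residual
    pp_threshold: float = 0.95
    use_bmr: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_scheme not in ("kfold", "loocv"):
            raise ConfigurationError(f"unknown cv_scheme {self.cv_scheme!r}")
        if self.cv_scheme == "loocv" and self.n_repetitions != 1:
            raise ConfigurationError("LOOCV admits exactly one repetition")
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")
        if self.regressor not in ("lasso", "ridge"):
            raise ConfigurationError(f"unknown regressor {self.regressor!r}")
        if not (0 < self.pp_threshold < 1):
            raise ConfigurationError("pp_threshold must lie in (0,1)")


@dataclass
class PredictionResult:
    r_per_repetition: np.ndarray  # fold-averaged Pearson r (pooled for LOOCV)
    mean_r: float
    predictions: pd.DataFrame  # subject, repetition, predicted, empirical
    masks_per_loop: list[EdgeMask]
    r_pooled_per_repetition: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)
    null_distribution: np.ndarray | None = None
    p_value: float | None = None
    p_per_repetition: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "r_per_repetition": self.r_per_repetition.tolist(),
            "r_pooled_per_repetition": (
                None
                if self.r_pooled_per_repetition is None
                else self.r_pooled_per_repetition.tolist()
            ),
            "mean_r": self.mean_r,
            "notes": self.notes,
            "p_value": self.p_value,
            "null_distribution": (
                None if self.null_distribution is None else self.null_distribution.tolist()
            ),
            "p_per_repetition": (
                None if self.p_per_repetition is None else self.p_per_repetition.tolist()
            ),
            "mask_sizes": [m.n_selected for m in self.masks_per_loop],
        }


def make_cv_splits(n_subjects: int, cfg: PredictionConfig):
    """Per-repetition lists of (train, test) index arrays (seeded, disjoint)."""
    if cfg.cv_scheme == "loocv":
        idx = np.arange(n_subjects)
        return [[(np.delete(idx, i), np.array([i])) for i in range(n_subjects)]]
    if cfg.k > n_subjects:
        raise ConfigurationError(f"k={cfg.k} exceeds n_subjects={n_subjects}")
    seeds = np.random.SeedSequence([cfg.seed, 0xC5]).generate_state(cfg.n_repetitions)
    out = []
    for rep in range(cfg.n_repetitions):
        kf = KFold(n_splits=cfg.k, shuffle=True, random_state=int(seeds[rep]) % (2**32))
        out.append([(tr, te) for tr, te in kf.split(np.arange(n_subjects))])
    return out


def select_features(
    posteriors,
    train_scores: np.ndarray,
    cfg: PredictionConfig,
    covariate_name: str = "target",
) -> EdgeMask:
    """Training-set-only PEB (or PEB+BMR) feature mask on the covariate column."""
    which = _SOURCE_TO_WHICH.get(cfg.feature_source)
    if which is None:
        raise ConfigurationError(
            f"feature_source {cfg.feature_source!r} is not an EC source"
        )
    X = build_design_matrix(np.asarray(train_scores, dtype=float), covariate_name)

    def one(which_one: str) -> EdgeMask:
        peb = fit_peb(posteriors, X, which=which_one)
        if cfg.use_bmr:
            return bmr_mask(peb, column="covariate", threshold=cfg.pp_threshold)
        return pp_mask(peb, column="covariate", threshold=cfg.pp_threshold)

    if which == "AB":  # combined: separate fits per matrix, concatenated
        masks = [one("A"), one("B")]
        mask = EdgeMask(
            values=np.concatenate([m.values for m in masks]),
            param_indices=np.concatenate([m.param_indices for m in masks]),
            names=masks[0].names + masks[1].names,
            matrix_kind="AB",
            design_column="covariate",
            provenance={"method": "PEB" if not cfg.use_bmr else "BMR", "combined": True},
        )
    else:
        mask = one(which)
    if mask.n_selected == 0:
        # fallback: keep every fold scorable with the single strongest edge
        peb = fit_peb(posteriors, X, which="B" if which == "AB" else which)
        j = int(np.argmax(peb.pp[:, 1]))
        values = np.zeros(len(mask.names), dtype=bool)
        # map the fallback edge into the (possibly concatenated) mask layout
        pos = np.flatnonzero(mask.param_indices == peb.param_indices[j])
        values[pos[0] if pos.size else 0] = True
        mask = EdgeMask(
            values=values,
            param_indices=mask.param_indices,
            names=mask.names,
            matrix_kind=mask.matrix_kind,
            design_column="covariate",
            provenance=dict(mask.provenance, fallback="highest-PP edge"),
        )
    return mask


def extract_features(posteriors, mask: EdgeMask) -> np.ndarray:
    """Subject posterior means at the masked indices (subjects x edges)."""
    if mask.n_selected == 0:
        raise ConfigurationError("cannot extract features from an empty mask")
    idx = mask.selected_global_indices()
    p = posteriors[0].vec.p
    if np.any(idx >= p):
        raise AlignmentError("mask indices exceed the parameter vectorization")
    return np.stack([post.mean[idx] for post in posteriors])


def _alpha_grid(X: np.ndarray, y: np.ndarray, regressor: str, n_alphas: int = 30):
    n = X.shape[0]
    if regressor == "lasso":
        amax = max(np.max(np.abs(X.T @ (y - y.mean()))) / n, 1e-6)
        return np.logspace(np.log10(amax * 1e-4), np.log10(amax * 1.1), n_alphas)
    return np.logspace(-4, 4, n_alphas)


def _make_model(regressor: str, alpha: float):
    if regressor == "lasso":
        if alpha <= 0:
            return LinearRegression()
        return Lasso(alpha=alpha, max_iter=20000, tol=1e-8)
    if alpha <= 0:
        return LinearRegression()
    return Ridge(alpha=alpha)


def fit_predict_regularized(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    regressor: str = "lasso",
    seed: int = 0,
    alpha_override: float | None = None,
):
    """Standardize by training statistics, pick the penalty by inner 5-fold
    CV over a log grid, and predict the test rows.

    Returns ``(predictions, fitted model, chosen alpha)``.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.shape[0] < 2 or X_train.shape[1] < 1:
        raise ConfigurationError("need >= 2 training subjects and >= 1 feature")
    if np.std(y_train) == 0:
        raise DegenerateTargetError("constant training target")

    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd

    if alpha_override is not None:
        alpha = float(alpha_override)
    else:
        grid = _alpha_grid(Xtr, y_train, regressor)
        n_splits = min(5, X_train.shape[0])
        if n_splits < 2:
            alpha = float(grid[len(grid) // 2])
        else:
            kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**32))
            errs = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                for tr, va in kf.split(Xtr):
                    if np.std(y_train[tr]) == 0:
                        continue
                    fold_err = np.empty(len(grid))
                    for gi, a in enumerate(grid):
                        model = _make_model(regressor, a)
                        model.fit(Xtr[tr], y_train[tr])
                        fold_err[gi] = float(
                            np.mean((model.predict(Xtr[va]) - y_train[va]) ** 2)
                        )
                    errs.append(fold_err)
            E = np.stack(errs) if errs else np.zeros((1, len(grid)))
            mean_err = E.mean(axis=0)
            best = int(np.argmin(mean_err))
            if regressor == "lasso" and E.shape[0] > 1:
                # one-standard-error rule: the sparsest model whose CV error is
                # within one SE of the minimum
                se = E[:, best].std(ddof=1) / np.sqrt(E.shape[0])
                ok = np.flatnonzero(mean_err <= mean_err[best] + se)
                best = int(ok.max())  # grid is ascending in alpha
            alpha = float(grid[best])
    model = _make_model(regressor, alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xtr, y_train)
    return model.predict(Xte), model, alpha


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return np.nan
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        return np.nan
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def run_cv_engine(selector, extractor, targets: np.ndarray, cfg: PredictionConfig):
    """Generic CV engine shared by the EC and FC prediction arms.

    ``selector(train_idx, train_targets) -> EdgeMask``;
    ``extractor(mask) -> (n_subjects, n_features)`` for all subjects.
    """
    targets = np.asarray(targets, dtype=float)
    n = targets.shape[0]
    splits = make_cv_splits(n, cfg)
    rows = []
    r_per_rep = np.full(cfg.n_repetitions, np.nan)
    r_pooled = np.full(cfg.n_repetitions, np.nan)
    masks: list[EdgeMask] = []
    notes: list[str] = []
    for rep, folds in enumerate(splits):
        preds = np.full(n, np.nan)
        fold_rs: list[float] = []
        for fold_i, (train, test) in enumerate(folds):
            try:
                mask = selector(train, targets[train])
                masks.append(mask)
                if "fallback" in mask.provenance:
                    notes.append(f"rep {rep} fold {fold_i}: empty-mask fallback engaged")
                Xall = extractor(mask)
                if np.any(np.std(Xall[train], axis=0) == 0):
                    notes.append(f"rep {rep} fold {fold_i}: zero-variance feature column")
                yhat, _, _ = fit_predict_regularized(
                    Xall[train],
                    targets[train],
                    Xall[test],
                    regressor=cfg.regressor,
                    seed=cfg.seed + 7919 * rep + fold_i,
                )
                preds[test] = yhat
                if test.shape[0] >= 3:
                    r_fold = _pearson(yhat, targets[test])
                    if np.isnan(r_fold):
                        notes.append(
                            f"rep {rep} fold {fold_i}: constant predictions; fold r set to 0"
                        )
                        r_fold = 0.0
                    fold_rs.append(r_fold)
            except (ConfigurationError, DegenerateTargetError) as exc:
                notes.append(f"rep {rep} fold {fold_i}: skipped ({exc})")
        ok = np.isfinite(preds)
        if ok.sum() >= 3:
            rp = _pearson(preds[ok], targets[ok])
            if np.isnan(rp):
                notes.append(f"rep {rep}: degenerate (constant) pooled predictions; r set to 0")
                rp = 0.0
        else:
            notes.append(f"rep {rep}: fewer than 3 pooled predictions; repetition flagged")
            rp = np.nan
        r_pooled[rep] = rp
        # primary accuracy: fold-averaged correlation; LOOCV folds are
        # singletons, so the pooled correlation is the only defined choice
        r_per_rep[rep] = float(np.mean(fold_rs)) if fold_rs else rp
        for s in range(n):
            if np.isfinite(preds[s]):
                rows.append((s, rep, preds[s], targets[s]))
    preds_df = pd.DataFrame(rows, columns=["subject", "repetition", "predicted", "empirical"])
    valid = np.isfinite(r_per_rep)
    mean_r = float(np.mean(r_per_rep[valid])) if valid.any() else np.nan
    return PredictionResult(
        r_per_repetition=r_per_rep,
        mean_r=mean_r,
        predictions=preds_df,
        masks_per_loop=masks,
        r_pooled_per_repetition=r_pooled,
        notes=notes,
    )


def run_prediction(
    posteriors,
    targets,
    cfg: PredictionConfig,
    covariate_name: str = "target",
) -> PredictionResult:
    """The full EC-based workflow (selection inside each training fold)."""
    targets = np.asarray(targets, dtype=float)
    if len(posteriors) != targets.shape[0]:
        raise AlignmentError(
            f"{len(posteriors)} posteriors vs {targets.shape[0]} targets"
        )

    def selector(train_idx, train_targets):
        return select_features(
            [posteriors[i] for i in train_idx], train_targets, cfg, covariate_name
        )

    def extractor(mask):
        return extract_features(posteriors, mask)

    return run_cv_engine(selector, extractor, targets, cfg)


def permutation_test(
    posteriors,
    targets,
    cfg: PredictionConfig,
    observed: PredictionResult | None = None,
    runner=None,
) -> PredictionResult:
    """Label-shuffled permutation null for the prediction accuracy.

    Each iteration shuffles the targets once and runs one full CV round
    (feature selection included).  The add-one p-value compares the observed
    mean accuracy against the null; per-repetition exceedance p-values are
    reported alongside.
    """
    if cfg.n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    if runner is None:
        runner = run_prediction
    targets = np.asarray(targets, dtype=float)
    if observed is None:
        observed = runner(posteriors, targets, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E]))
    null = np.empty(cfg.n_permutations)
    base = dict(
        cv_scheme=cfg.cv_scheme,
        k=cfg.k,
        n_repetitions=1,
        n_permutations=1,
        regressor=cfg.regressor,
        feature_source=cfg.feature_source,
        pp_threshold=cfg.pp_threshold,
        use_bmr=cfg.use_bmr,
    )
    for it in range(cfg.n_permutations):
        shuffled = rng.permutation(targets)
        one = PredictionConfig(**base, seed=cfg.seed + 104729 + it)
        null[it] = runner(posteriors, shuffled, one).r_per_repetition[0]
    null = null[np.isfinite(null)]
    m = null.shape[0]
    p_value = float((1 + np.sum(null >= observed.mean_r)) / (1 + m))
    p_reps = np.array(
        [
            (1 + np.sum(null >= r)) / (1 + m) if np.isfinite(r) else np.nan
            for r in observed.r_per_repetition
        ]
    )
    observed.null_distribution = null
    observed.p_value = p_value
    observed.p_per_repetition = p_reps
    return observed


def cohens_d(dist1, dist2) -> float:
    """Standardized mean difference with the pooled (n-1) standard deviation."""
    a = np.asarray(dist1, dtype=float)
    b = np.asarray(dist2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each distribution needs at least 2 values")
    s2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if s2 == 0:
        if np.mean(a) == np.mean(b):
            return 0.0
        raise DegenerateTargetError("zero pooled variance with unequal means")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(s2))


@dataclass
class FeatureFrequency:
    frequency: dict  # global parameter index -> selection frequency
    names: dict  # global parameter index -> name
    high_frequency: list  # indices with frequency >= threshold (inclusive)
    mean_mask_size: float
    threshold: float


def feature_frequency(masks_per_loop: list[EdgeMask], threshold: float = 0.80) -> FeatureFrequency:
    """Per-edge selection frequency across CV training loops."""
    if not masks_per_loop:
        raise ConfigurationError("need at least one mask")
    counts: dict[int, int] = {}
    names: dict[int, str] = {}
    for mask in masks_per_loop:
        for idx, name, val in zip(mask.param_indices, mask.names, mask.values):
            idx = int(idx)
            names.setdefault(idx, name)
            if val:
                counts[idx] = counts.get(idx, 0) + 1
    n_loops = len(masks_per_loop)
    freq = {idx: counts.get(idx, 0) / n_loops for idx in names}
    high = sorted(idx for idx, f in freq.items() if f >= threshold)
    mean_size = float(np.mean([m.n_selected for m in masks_per_loop]))
    return FeatureFrequency(
        frequency=freq,
        names=names,
        high_frequency=high,
        mean_mask_size=mean_size,
        threshold=threshold,
    )
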