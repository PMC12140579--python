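"""Parametric empirical Bayes over subject posteriors + Bayesian model reduction.

Second level: subject-level posterior means m_i over a chosen parameter subset
follow ``m_i = x_i0 b_mean + x_i1 b_cov + eps_i`` with a two-column design
matrix (ones; mean-centered covariate), known first-level covariances S_i, and
between-subject covariance ``exp(gamma) * diag(prior variances)`` whose scalar
log-magnitude gamma is estimated by empirical Bayes.  Everything downstream
(posterior probabilities, model search) runs on the analytic Gaussian reduced
log evidence, so "switching a parameter off" means shrinking its prior
variance to (effectively) zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dcm.invert import DCMPosterior
from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateDesignError,
    NumericalError,
)

_REDUCED_VAR = 1e-8  # prior variance standing in for "switched off"


@dataclass
class DesignMatrix:
    """Two-column second-level design: group mean + mean-centered covariate."""

    X: np.ndarray  # (n_subjects, 2)
    covariate_name: str

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


def build_design_matrix(scores, covariate_name: str = "covariate") -> DesignMatrix:
    """Ones column plus the covariate centered within the provided sample."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.shape[0] < 2:
        raise ConfigurationError("need a 1-D covariate over at least 2 subjects")
    if not np.all(np.isfinite(scores)):
        raise ConfigurationError(f"covariate {covariate_name!r} contains non-finite values")
    centered = scores - scores.mean()
    if np.allclose(centered, 0.0):
        raise DegenerateDesignError(f"covariate {covariate_name!r} is constant")
    X = np.column_stack([np.ones_like(scores), centered])
    return DesignMatrix(X=X, covariate_name=covariate_name)


@dataclass
class EdgeMask:
    """Boolean selection over a vectorized parameter subset, with provenance."""

    values: np.ndarray  # bool, (p,)
    param_indices: np.ndarray  # global indices into the full vectorization
    names: list[str]
    matrix_kind: str  # "A" | "B" | "AB" | "FC"
    design_column: str  # "mean" | "covariate"
    provenance: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.values))

    def selected_global_indices(self) -> np.ndarray:
        return self.param_indices[self.values]

    def selected_names(self) -> list[str]:
        return [n for n, v in zip(self.names, self.values) if v]


@dataclass
class PEBResult:
    """Group-level effects per design column with per-parameter PP."""

    effect_means: np.ndarray  # (p, 2)
    effect_cov: np.ndarray  # (2p, 2p), ordering: [mean block; covariate block]
    pp: np.ndarray  # (p, 2)
    gamma: float  # log between-subject variance scale
    free_energy: float
    param_indices: np.ndarray
    names: list[str]
    which: str
    covariate_name: str
    prior_variance: np.ndarray  # (2p,)

    @property
    def n_params(self) -> int:
        return self.effect_means.shape[0]


_COLUMNS = {"mean": 0, "covariate": 1}


def _select_first_level(posteriors: list[DCMPosterior], which: str):
    vec = posteriors[0].vec
    names0 = vec.names
    for post in posteriors[1:]:
        if post.vec.p != vec.p or post.vec.names != names0:
            raise AlignmentError("posteriors do not share a parameter vectorization")
    sel = np.flatnonzero(vec.mask_for(which))
    M = np.stack([post.mean[sel] for post in posteriors])
    S = [post.cov[np.ix_(sel, sel)] for post in posteriors]
    v1 = np.maximum(posteriors[0].priors.variance[sel], 1e-8)
    names = [names0[k] for k in sel]
    return sel, M, S, v1, names


def _evidence_at_gamma(gamma, M, S_list, v1, X, prior_var_b):
    """Log evidence (and posterior over stacked effects) for fixed gamma."""
    n_sub, p = M.shape
    Gamma = np.exp(gamma) * np.diag(v1)
    Pb0 = 1.0 / prior_var_b
    Pb = np.diag(np.concatenate([Pb0[:p], Pb0[p:]]))
    h = np.zeros(2 * p)
    ld_sum = 0.0
    quad = 0.0
    same_cov = all(S is S_list[0] or np.array_equal(S, S_list[0]) for S in S_list[1:])
    W0 = None
    for i in range(n_sub):
        if same_cov and W0 is not None:
            W, ld = W0
        else:
            Si = S_list[i] + Gamma
            sign, ld = np.linalg.slogdet(Si)
            if sign <= 0:
                raise NumericalError("indefinite first-level covariance in PEB")
            W = np.linalg.inv(Si)
            if same_cov:
                W0 = (W, ld)
        ld_sum += ld
        x0, x1 = X[i]
        Wm = W @ M[i]
        quad += float(M[i] @ Wm)
        h[:p] += x0 * Wm
        h[p:] += x1 * Wm
        Pb[:p, :p] += x0 * x0 * W
        Pb[:p, p:] += x0 * x1 * W
        Pb[p:, :p] += x0 * x1 * W
        Pb[p:, p:] += x1 * x1 * W
    Pb = 0.5 * (Pb + Pb.T)
    sign, ld_Pb = np.linalg.slogdet(Pb)
    if sign <= 0:
        raise NumericalError("indefinite second-level precision in PEB")
    Sb = np.linalg.inv(Pb)
    b = Sb @ h
    lnZ = (
        -0.5 * (n_sub * p * np.log(2 * np.pi) + ld_sum + quad)
        - 0.5 * float(np.sum(np.log(prior_var_b)))
        - 0.5 * ld_Pb
        + 0.5 * float(h @ b)
    )
    return lnZ, b, Sb


def fit_peb(
    posteriors: list[DCMPosterior],
    X: DesignMatrix,
    which: str = "B",
    gamma_hyper: tuple[float, float] = (np.log(1.0 / 16.0), 4.0),
) -> PEBResult:
    """Bayesian random-effects GLM on subject posterior means.

    First-level posterior covariances enter as known uncertainty — no
    per-subject refitting.  ``which`` selects the parameter subset: "A"
    (intrinsic), "B" (modulatory) or "AB".
    """
    if len(posteriors) != X.n_subjects:
        raise AlignmentError(
            f"{len(posteriors)} posteriors but design has {X.n_subjects} rows"
        )
    sel, M, S_list, v1, names = _select_first_level(posteriors, which)
    p = M.shape[1]
    prior_var_b = np.concatenate([v1, v1])  # same shrinkage per design column

    g0, gv = gamma_hyper

    def objective(gamma):
        lnZ, _, _ = _evidence_at_gamma(gamma, M, S_list, v1, X.X, prior_var_b)
        return lnZ - 0.5 * (gamma - g0) ** 2 / gv

    grid = np.linspace(-9.0, 2.0, 10)
    vals = [objective(g) for g in grid]
    g_best = grid[int(np.argmax(vals))]
    lo, hi = g_best - 1.3, g_best + 1.3
    for _ in range(12):  # golden-section refinement
        m1 = lo + 0.382 * (hi - lo)
        m2 = lo + 0.618 * (hi - lo)
        if objective(m1) >= objective(m2):
            hi = m2
        else:
            lo = m1
    gamma = 0.5 * (lo + hi)
    lnZ, b, Sb = _evidence_at_gamma(gamma, M, S_list, v1, X.X, prior_var_b)
    F = lnZ - 0.5 * (gamma - g0) ** 2 / gv

    pp = np.empty((p, 2))
    var_b = np.diag(Sb)
    for col in range(2):
        off = col * p
        for j in range(p):
            jj = off + j
            pp[j, col] = _pp_single(b[jj], var_b[jj], prior_var_b[jj])

    return PEBResult(
        effect_means=np.column_stack([b[:p], b[p:]]),
        effect_cov=Sb,
        pp=pp,
        gamma=float(gamma),
        free_energy=float(F),
        param_indices=sel,
        names=names,
        which=which,
        covariate_name=X.covariate_name,
        prior_variance=prior_var_b,
    )


def pp_mask(
    peb: PEBResult,
    column: str = "covariate",
    threshold: float = 0.95,
    which: str | None = None,
) -> EdgeMask:
    """Mask of parameters with PP strictly above ``threshold`` on a column."""
    if not (0 < threshold < 1):
        raise ConfigurationError(f"threshold must lie in (0,1), got {threshold}")
    if column not in _COLUMNS:
        raise ConfigurationError(f"column must be 'mean' or 'covariate', got {column!r}")
    col = _COLUMNS[column]
    values = peb.pp[:, col] > threshold
    return EdgeMask(
        values=values,
        param_indices=peb.param_indices,
        names=peb.names,
        matrix_kind=which or peb.which,
        design_column=column,
        provenance={
            "method": "PEB",
            "threshold": threshold,
            "covariate": peb.covariate_name,
        },
    )


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------


def _as_cov(x, p: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        return np.eye(p) * float(x)
    if x.ndim == 1:
        return np.diag(x)
    return x


def reduce_posterior(
    post_mean,
    post_cov,
    prior_mean,
    prior_cov,
    red_mean,
    red_cov,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Analytic evidence change and posterior for a reduced prior.

    Returns ``(dF, reduced posterior mean, reduced posterior cov)`` where
    ``dF`` is the change in log evidence incurred by replacing the prior
    ``N(prior_mean, prior_cov)`` with ``N(red_mean, red_cov)`` given the full
    posterior ``N(post_mean, post_cov)``.
    """
    mu = np.atleast_1d(np.asarray(post_mean, dtype=float))
    p = mu.shape[0]
    mu0 = np.broadcast_to(np.atleast_1d(np.asarray(prior_mean, dtype=float)), (p,))
    mur = np.broadcast_to(np.atleast_1d(np.asarray(red_mean, dtype=float)), (p,))
    S = _as_cov(post_cov, p)
    S0 = _as_cov(prior_cov, p)
    Sr = _as_cov(red_cov, p)

    P = np.linalg.inv(S)
    P0 = np.linalg.inv(S0)
    Pr = np.linalg.inv(Sr)
    Pp = P + Pr - P0
    sign, ld_Pp = np.linalg.slogdet(Pp)
    if sign <= 0:
        raise NumericalError("reduced posterior precision is not positive definite")
    mup = np.linalg.solve(Pp, P @ mu + Pr @ mur - P0 @ mu0)
    ld = (
        np.linalg.slogdet(P)[1]
        + np.linalg.slogdet(Pr)[1]
        - np.linalg.slogdet(P0)[1]
        - ld_Pp
    )
    quad = (
        float(mup @ (Pp @ mup))
        - float(mu @ (P @ mu))
        - float(mur @ (Pr @ mur))
        + float(mu0 @ (P0 @ mu0))
    )
    dF = 0.5 * ld + 0.5 * quad
    Sp = np.linalg.inv(Pp)
    return float(dF), mup, 0.5 * (Sp + Sp.T)


def reduced_log_evidence(
    post_mean, post_cov, prior_mean, prior_cov, red_mean, red_cov
) -> float:
    """Evidence change only (see :func:`reduce_posterior`)."""
    return reduce_posterior(post_mean, post_cov, prior_mean, prior_cov, red_mean, red_cov)[0]


def _pp_single(mu_j: float, var_j: float, prior_var_j: float) -> float:
    """PP that one parameter is 'on': sigmoid of the evidence lost by pruning.

    Rank-one closed form of :func:`reduced_log_evidence` for shrinking a
    single prior variance to ``_REDUCED_VAR`` (prior/reduced means zero).
    """
    delta = 1.0 / _REDUCED_VAR - 1.0 / prior_var_j
    denom = 1.0 + delta * var_j
    dF = 0.5 * (np.log1p(delta * prior_var_j) - np.log(denom)) - 0.5 * delta * mu_j**2 / denom
    # dF large-negative => pruning catastrophic => PP -> 1
    if dF > 500:
        return 0.0
    return float(1.0 / (1.0 + np.exp(dF)))


@dataclass
class BMRResult:
    """Outcome of a reduced-model search over a searchable parameter set."""

    searchable: np.ndarray  # indices into the searched vector
    winner_on: np.ndarray  # bool over searchable: retained in the best model
    winner_dF: float  # evidence of best model relative to the full model
    bma_pp: np.ndarray  # Bayesian-model-averaged P(on) over searchable
    n_models: int
    strategy: str
    winner_mean: np.ndarray
    winner_cov: np.ndarray


def _subset_reduction(mu, S, prior_var, off_idx):
    """Evidence change for switching off a set of parameters (means zero)."""
    red_var = prior_var.copy()
    red_var[off_idx] = _REDUCED_VAR
    return reduce_posterior(mu, S, np.zeros_like(mu), prior_var, np.zeros_like(mu), red_var)


def bmr_search(
    target: PEBResult | DCMPosterior,
    strategy: str = "auto",
    column: str = "covariate",
    max_exhaustive_params: int = 16,
) -> BMRResult:
    """Search reduced models that switch off subsets of parameters.

    For a :class:`PEBResult` the search runs over the requested design
    column's effects; for a first-level posterior over all free parameters.
    Exhaustive enumeration when the searchable count allows it, otherwise
    greedy pruning of the smallest effects iterated to evidence convergence.
    Per-parameter PP comes from Bayesian model averaging over the evaluated
    family.
    """
    if isinstance(target, PEBResult):
        p = target.n_params
        mu = np.concatenate([target.effect_means[:, 0], target.effect_means[:, 1]])
        S = target.effect_cov
        prior_var = target.prior_variance.copy()
        off = _COLUMNS[column] * p
        searchable = np.arange(off, off + p)
    else:
        mu = target.mean
        S = target.cov
        prior_var = np.maximum(target.priors.variance, 1e-8)
        searchable = np.arange(mu.shape[0])

    k = searchable.shape[0]
    if strategy == "auto":
        strategy = "exhaustive" if k <= max_exhaustive_params else "greedy"
    if strategy == "exhaustive" and k > max_exhaustive_params:
        raise ConfigurationError(
            f"exhaustive search over {k} parameters exceeds the cap "
            f"({max_exhaustive_params}); use greedy"
        )

    models: list[tuple[frozenset, float]] = []
    if strategy == "exhaustive":
        for code in range(2**k):
            off_local = frozenset(i for i in range(k) if code >> i & 1)
            off_idx = searchable[list(off_local)] if off_local else np.array([], dtype=int)
            dF, _, _ = _subset_reduction(mu, S, prior_var, off_idx)
            models.append((off_local, dF))
    elif strategy == "greedy":
        order = np.argsort(np.abs(mu[searchable]), kind="stable")
        off_set: set[int] = set()
        best_dF = 0.0
        models.append((frozenset(), 0.0))
        for _ in range(4):
            changed = False
            for j in order:
                j = int(j)
                if j in off_set:
                    continue
                cand = off_set | {j}
                dF, _, _ = _subset_reduction(mu, S, prior_var, searchable[sorted(cand)])
                models.append((frozenset(cand), dF))
                if dF > best_dF:
                    off_set = cand
                    best_dF = dF
                    changed = True
            if not changed:
                break
    else:
        raise ConfigurationError(f"unknown strategy {strategy!r}")

    dFs = np.array([m[1] for m in models])
    i_win = int(np.argmax(dFs))
    off_win, dF_win = models[i_win]
    w = np.exp(dFs - dFs.max())
    w /= w.sum()
    bma_pp = np.zeros(k)
    for (off_local, _), wi in zip(models, w):
        on = np.ones(k, dtype=bool)
        on[list(off_local)] = False
        bma_pp += wi * on

    off_idx = searchable[sorted(off_win)] if off_win else np.array([], dtype=int)
    _, mu_win, S_win = _subset_reduction(mu, S, prior_var, off_idx)
    on_win = np.ones(k, dtype=bool)
    on_win[list(off_win)] = False
    return BMRResult(
        searchable=searchable,
        winner_on=on_win,
        winner_dF=float(dF_win),
        bma_pp=bma_pp,
        n_models=len(models),
        strategy=strategy,
        winner_mean=mu_win,
        winner_cov=S_win,
    )


def bmr_mask(
    peb: PEBResult,
    column: str = "covariate",
    threshold: float = 0.95,
    max_exhaustive_params: int = 16,
) -> EdgeMask:
    """BMA-PP mask after a reduced-model search on a PEB design column."""
    res = bmr_search(peb, column=column, max_exhaustive_params=max_exhaustive_params)
    values = res.bma_pp > threshold
    return EdgeMask(
        values=values,
        param_indices=peb.param_indices,
        names=peb.names,
        matrix_kind=peb.which,
        design_column=column,
        provenance={
            "method": "BMR",
            "strategy": res.strategy,
            "threshold": threshold,
            "n_models": res.n_models,
            "covariate": peb.covariate_name,
        },
    )
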