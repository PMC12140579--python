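"""Forward model: bilinear neural dynamics and balloon-model hemodynamics.

Neural states evolve as ``dz/dt = (A + sum_k u_k(t) B_k) z + C u(t)`` with
piecewise-constant binary inputs; because u is constant within each microtime
cell the neural propagation is computed exactly with matrix exponentials (one
augmented exponential per distinct input pattern).  The observation is the
four-state balloon model with f, v, q integrated in log space (positivity by
construction) on the same grid and sampled at scan times.

Matrix orientation (everywhere in this package): ``A[i, j]`` is the coupling
FROM node j TO node i, i.e. rows are targets so that ``dz = A z`` reads
conventionally.  Tab-separated exports transpose to row=source ("From") /
column=target ("To"); see ``ecpredict.io``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from ..errors import AlignmentError, ConfigurationError, InstabilityError, NumericalError
from ..paradigm import StimulusEncoding

#: Baseline magnitude of self-connections: A_ii = -SELF_SCALE * exp(a_i).
SELF_SCALE = 0.5

try:  # pragma: no cover - exercised implicitly when numba is installed
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class HemodynamicParams:
    """Balloon-model constants (canonical values, shared across nodes)."""

    kappa: float = 0.64  # vasodilatory signal decay (1/s)
    gamma: float = 0.32  # flow-dependent feedback (1/s)
    tau: float = 2.0  # venous transit time (s)
    alpha: float = 0.32  # vessel stiffness exponent
    E0: float = 0.4  # resting oxygen extraction fraction
    V0: float = 0.04  # resting venous volume fraction

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma, self.tau, self.V0) <= 0:
            raise ConfigurationError("hemodynamic rate/time constants must be positive")
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must lie in (0,1), got {self.alpha}")
        if not (0 < self.E0 < 1):
            raise ConfigurationError(f"E0 must lie in (0,1), got {self.E0}")


@dataclass
class DCMParams:
    """Coupling matrices of one subject's generative model.

    ``A`` (n x n, Hz) intrinsic coupling; ``B`` (n_inputs x n x n, Hz)
    input-specific additive modulation (all-zero slab for non-modulatory
    inputs); ``C`` (n x n_inputs) driving gains.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise AlignmentError(f"A must be square, got {self.A.shape}")
        if self.B.ndim == 2:
            self.B = self.B[None, :, :]
        if self.B.shape[1:] != (n, n):
            raise AlignmentError(f"B slabs must be {n}x{n}, got {self.B.shape}")
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        if self.C.shape[0] != n:
            raise AlignmentError(f"C must have {n} rows, got {self.C.shape}")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]


DEFAULT_NODE_LABELS = (
    "AMCC",
    "L_IPS",
    "R_IPS",
    "L_PMC",
    "R_PMC",
    "L_DLPFC",
    "R_DLPFC",
    "L_AI",
    "R_AI",
)


@dataclass
class ParamVectorization:
    """Canonical flattening of the free (A, B, C) parameters.

    Free parameters, in order: A off-diagonal entries (row-major), A
    self-connections on a log scale (``A_ii = -SELF_SCALE * exp(a_i)``), all
    entries of each modulatory B slab (row-major, diagonal included), and C
    gains of the driving input restricted to ``driving_nodes``.
    """

    n_nodes: int
    node_labels: tuple[str, ...] = ()
    n_inputs: int = 2
    mod_inputs: tuple[int, ...] = (1,)
    driving_input: int = 0
    driving_nodes: tuple[int, ...] = ()
    _index: list[tuple] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.n_nodes
        if not self.node_labels:
            if n == len(DEFAULT_NODE_LABELS):
                self.node_labels = DEFAULT_NODE_LABELS
            else:
                self.node_labels = tuple(f"n{i}" for i in range(n))
        if len(self.node_labels) != n:
            raise AlignmentError("node_labels length must match n_nodes")
        if not self.driving_nodes:
            # default: bilateral IPS when using the canonical 9-ROI network
            if self.node_labels == DEFAULT_NODE_LABELS:
                self.driving_nodes = (1, 2)
            else:
                self.driving_nodes = tuple(range(n))
        idx: list[tuple] = []
        for i in range(n):
            for j in range(n):
                if i != j:
                    idx.append(("A", i, j))
        for i in range(n):
            idx.append(("Aself", i, i))
        for k in self.mod_inputs:
            for i in range(n):
                for j in range(n):
                    idx.append(("B", k, i, j))
        for i in self.driving_nodes:
            idx.append(("C", i, self.driving_input))
        self._index = idx

    @property
    def p(self) -> int:
        return len(self._index)

    @property
    def names(self) -> list[str]:
        lab = self.node_labels
        out = []
        for spec in self._index:
            if spec[0] == "A":
                out.append(f"A:{lab[spec[2]]}->{lab[spec[1]]}")
            elif spec[0] == "Aself":
                out.append(f"Aself:{lab[spec[1]]}")
            elif spec[0] == "B":
                out.append(f"B{spec[1]}:{lab[spec[3]]}->{lab[spec[2]]}")
            else:
                out.append(f"C:u{spec[2]}->{lab[spec[1]]}")
        return out

    def kinds(self) -> np.ndarray:
        return np.array([spec[0] for spec in self._index])

    def mask_for(self, which: str) -> np.ndarray:
        """Boolean mask over the vector for 'A' (I-EC), 'B' (M-EC) or 'AB'."""
        kinds = self.kinds()
        if which == "A":
            return (kinds == "A") | (kinds == "Aself")
        if which == "B":
            return kinds == "B"
        if which in ("AB", "A|B", "combined"):
            return (kinds == "A") | (kinds == "Aself") | (kinds == "B")
        raise ConfigurationError(f"unknown parameter subset {which!r}")

    def to_matrices(self, theta: np.ndarray) -> DCMParams:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.p,):
            raise AlignmentError(f"theta must have shape ({self.p},), got {theta.shape}")
        n = self.n_nodes
        A = np.zeros((n, n))
        B = np.zeros((self.n_inputs, n, n))
        C = np.zeros((n, self.n_inputs))
        for value, spec in zip(theta, self._index):
            if spec[0] == "A":
                A[spec[1], spec[2]] = value
            elif spec[0] == "Aself":
                A[spec[1], spec[1]] = -SELF_SCALE * np.exp(value)
            elif spec[0] == "B":
                B[spec[1], spec[2], spec[3]] = value
            else:
                C[spec[1], spec[2]] = value
        return DCMParams(A=A, B=B, C=C, node_labels=self.node_labels)

    def from_matrices(self, params: DCMParams) -> np.ndarray:
        theta = np.zeros(self.p)
        for k, spec in enumerate(self._index):
            if spec[0] == "A":
                theta[k] = params.A[spec[1], spec[2]]
            elif spec[0] == "Aself":
                aii = params.A[spec[1], spec[1]]
                if aii >= 0:
                    raise ConfigurationError(
                        f"self-connection of node {spec[1]} must be negative, got {aii}"
                    )
                theta[k] = np.log(-aii / SELF_SCALE)
            elif spec[0] == "B":
                theta[k] = params.B[spec[1], spec[2], spec[3]]
            else:
                theta[k] = params.C[spec[1], spec[2]]
        return theta

    def native_values(self, theta: np.ndarray) -> np.ndarray:
        """Vector with self-connections mapped back to Hz (for comparisons)."""
        out = np.array(theta, dtype=float)
        kinds = self.kinds()
        sel = kinds == "Aself"
        out[sel] = -SELF_SCALE * np.exp(out[sel])
        return out


def stability_check(A: np.ndarray) -> tuple[bool, complex]:
    """Return (all eigenvalue real parts < 0, leading eigenvalue)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise AlignmentError(f"A must be square, got {A.shape}")
    eig = np.linalg.eigvals(A)
    lead = eig[np.argmax(eig.real)]
    return bool(np.all(eig.real < 0)), lead


# ---------------------------------------------------------------------------
# neural integration
# ---------------------------------------------------------------------------


def _input_patterns(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique input rows and the per-timepoint pattern index."""
    patterns, pat_idx = np.unique(u, axis=0, return_inverse=True)
    return patterns, pat_idx.astype(np.int64)


def _propagators(
    params: DCMParams, patterns: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-step propagators per input pattern.

    Returns E (P, n, n) and d (P, n) with ``z_next = E z + d`` for a cell
    where the input row equals the pattern.  Uses the augmented-matrix
    exponential so singular effective coupling needs no special casing.
    """
    n = params.n_nodes
    P = patterns.shape[0]
    E = np.empty((P, n, n))
    d = np.empty((P, n))
    aug = np.zeros((n + 1, n + 1))
    for p in range(P):
        u = patterns[p]
        M = params.A + np.tensordot(u, params.B, axes=(0, 0))
        aug[:n, :n] = M
        aug[:n, n] = params.C @ u
        Phi = expm(aug * dt)
        E[p] = Phi[:n, :n]
        d[p] = Phi[:n, n]
    return E, d


def integrate_neural(
    params: DCMParams,
    enc: StimulusEncoding,
    z0: np.ndarray | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Integrate the bilinear neural ODE on the (sub-divided) microtime grid.

    ``dt`` must subdivide the encoding grid (default: the encoding grid
    itself).  Returns z at grid times 0, dt, ..., including both endpoints
    (shape ``(S+1, n)``).
    """
    n = params.n_nodes
    if z0 is None:
        z0 = np.zeros(n)
    z0 = np.asarray(z0, dtype=float)
    if not np.all(np.isfinite(z0)):
        raise NumericalError("z0 must be finite")
    subdiv = 1 if dt is None else int(round(enc.dt / dt))
    if dt is not None and abs(subdiv * dt - enc.dt) > 1e-9 * enc.dt:
        raise ConfigurationError(f"dt={dt} does not subdivide the encoding grid ({enc.dt})")
    dtf = enc.dt / subdiv
    patterns, pat = _input_patterns(enc.u)
    E, d = _propagators(params, patterns, dtf)

    S = enc.n_timepoints * subdiv
    out = np.empty((S + 1, n))
    out[0] = z0
    z = z0.copy()
    guard = 1e6
    for s in range(S):
        p = pat[s // subdiv]
        z = E[p] @ z + d[p]
        out[s + 1] = z
        if s % 256 == 0 and np.max(np.abs(z)) > guard:
            stable, lead = stability_check(params.A)
            raise InstabilityError(
                f"neural states diverged at t={s * dtf:.2f}s "
                f"(leading eigenvalue of A: {lead:.4f})"
            )
    if not np.all(np.isfinite(out)):
        stable, lead = stability_check(params.A)
        raise InstabilityError(f"non-finite neural states (leading eigenvalue of A: {lead:.4f})")
    return out


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------


def _bold_readout(v: np.ndarray, q: np.ndarray, hemo: HemodynamicParams) -> np.ndarray:
    k1 = 7.0 * hemo.E0
    k2 = 2.0
    k3 = 2.0 * hemo.E0 - 0.2
    return 100.0 * hemo.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def _balloon_deriv(state: np.ndarray, z: np.ndarray, hemo: HemodynamicParams) -> np.ndarray:
    """Derivatives of (s, ln f, ln v, ln q); log states keep f, v, q > 0."""
    s, lf, lv, lq = state
    f = np.exp(lf)
    v = np.exp(lv)
    q = np.exp(lq)
    fv = v ** (1.0 / hemo.alpha)
    Ef = 1.0 - (1.0 - hemo.E0) ** (1.0 / f)
    return np.stack(
        [
            z - hemo.kappa * s - hemo.gamma * (f - 1.0),
            s / f,
            (f - fv) / (hemo.tau * v),
            (f * Ef / hemo.E0 - fv * q / v) / (hemo.tau * q),
        ]
    )


def hemodynamic_forward(
    z: np.ndarray, hemo: HemodynamicParams, dt: float
) -> np.ndarray:
    """Balloon-model BOLD (percent deviation from baseline) along z(t).

    ``z`` is a trajectory on a grid of step ``dt`` (shape ``(S+1, n)``);
    the output has the same shape.  RK4 with linear interpolation of z
    between grid points.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if not np.all(np.isfinite(z)):
        raise NumericalError("neural trajectory contains non-finite values")
    S1, n = z.shape
    state = np.zeros((4, n))  # (s, ln f, ln v, ln q) — all zero at rest
    out = np.empty((S1, n))
    out[0] = _bold_readout(np.exp(state[2]), np.exp(state[3]), hemo)
    for s in range(S1 - 1):
        za, zb = z[s], z[s + 1]
        zm = 0.5 * (za + zb)
        k1 = _balloon_deriv(state, za, hemo)
        k2 = _balloon_deriv(state + 0.5 * dt * k1, zm, hemo)
        k3 = _balloon_deriv(state + 0.5 * dt * k2, zm, hemo)
        k4 = _balloon_deriv(state + dt * k3, zb, hemo)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)) or np.any(np.abs(state[1:]) > 20):
            raise NumericalError(f"nonphysical hemodynamic state at t={(s + 1) * dt:.2f}s")
        out[s + 1] = _bold_readout(np.exp(state[2]), np.exp(state[3]), hemo)
    return out


# ---------------------------------------------------------------------------
# batched composition (used for finite-difference Jacobians)
# ---------------------------------------------------------------------------


def _forward_loop_numpy(E, d, pat, subdiv, stride, n_scans, dtf, hemo_c, out):
    """Reference batched loop: neural expm stepping + RK4 balloon.

    E: (K, P, n, n); d: (K, P, n); pat: (S_enc,) pattern per encoding cell;
    out: (K, n_scans, n).
    """
    kappa, gamma, tau, alpha, E0, V0 = hemo_c
    K, P, n, _ = E.shape
    S = pat.shape[0] * subdiv
    z = np.zeros((K, n))
    s_ = np.zeros((K, n))
    lf = np.zeros((K, n))  # ln f, ln v, ln q: positivity by construction
    lv = np.zeros((K, n))
    lq = np.zeros((K, n))
    k1c = 7.0 * E0
    k3c = 2.0 * E0 - 0.2

    def readout(lvv, lqq):
        vv = np.exp(lvv)
        qq = np.exp(lqq)
        return 100.0 * V0 * (k1c * (1.0 - qq) + 2.0 * (1.0 - qq / vv) + k3c * (1.0 - vv))

    def deriv(s0, lf0, lv0, lq0, zz):
        f0 = np.exp(lf0)
        v0 = np.exp(lv0)
        q0 = np.exp(lq0)
        fv = v0 ** (1.0 / alpha)
        Ef = 1.0 - (1.0 - E0) ** (1.0 / f0)
        return (
            zz - kappa * s0 - gamma * (f0 - 1.0),
            s0 / f0,
            (f0 - fv) / (tau * v0),
            (f0 * Ef / E0 - fv * q0 / v0) / (tau * q0),
        )

    out[:, 0, :] = readout(lv, lq)
    rec = 1
    for step in range(S):
        p = pat[step // subdiv]
        zn = np.einsum("kij,kj->ki", E[:, p], z) + d[:, p]
        # Heun step (z interpolation already caps global accuracy at O(dt^2))
        a1, b1, c1, d1 = deriv(s_, lf, lv, lq, z)
        a2, b2, c2, d2 = deriv(
            s_ + dtf * a1, lf + dtf * b1, lv + dtf * c1, lq + dtf * d1, zn
        )
        s_ = s_ + 0.5 * dtf * (a1 + a2)
        lf = lf + 0.5 * dtf * (b1 + b2)
        lv = lv + 0.5 * dtf * (c1 + c2)
        lq = lq + 0.5 * dtf * (d1 + d2)
        z = zn
        bad = (
            (np.abs(z) > 50.0).any(axis=1)
            | (np.abs(lf) > 6.0).any(axis=1)
            | (np.abs(s_) > 50.0).any(axis=1)
            | ~np.isfinite(lf).all(axis=1)
        )
        if bad.any():  # mark diverged rows, freeze their states
            out[bad] = np.nan
            z[bad] = 0.0
            s_[bad] = 0.0
            lf[bad] = 0.0
            lv[bad] = 0.0
            lq[bad] = 0.0
        if (step + 1) % stride == 0 and rec < n_scans:
            live = ~np.isnan(out[:, 0, 0])
            out[live, rec, :] = readout(lv, lq)[live]
            rec += 1
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True, error_model="numpy")  # pragma: no cover - compiled
    def _forward_loop_numba(E, d, pat, subdiv, stride, n_scans, dtf, hemo_c, out):
        kappa, gamma, tau, alpha, E0, V0 = (
            hemo_c[0],
            hemo_c[1],
            hemo_c[2],
            hemo_c[3],
            hemo_c[4],
            hemo_c[5],
        )
        K = E.shape[0]
        n = E.shape[2]
        S = pat.shape[0] * subdiv
        k1c = 7.0 * E0
        k3c = 2.0 * E0 - 0.2
        ooa = 1.0 / alpha
        lme = np.log(1.0 - E0)
        for k in range(K):
            z = np.zeros(n)
            zn = np.zeros(n)
            s_ = np.zeros(n)
            lf = np.zeros(n)  # log hemodynamic states
            lv = np.zeros(n)
            lq = np.zeros(n)
            for i in range(n):
                out[k, 0, i] = 0.0
            rec = 1
            diverged = False
            for step in range(S):
                p = pat[step // subdiv]
                for i in range(n):
                    acc = d[k, p, i]
                    for j in range(n):
                        acc += E[k, p, i, j] * z[j]
                    zn[i] = acc
                for i in range(n):
                    zi = z[i]
                    ze = zn[i]
                    s0, lf0, lv0, lq0 = s_[i], lf[i], lv[i], lq[i]
                    # Heun stages (inlined balloon derivatives, log states)
                    f0 = np.exp(lf0)
                    v0 = np.exp(lv0)
                    q0 = np.exp(lq0)
                    fv = np.exp(ooa * lv0)
                    Ef = 1.0 - np.exp(lme / f0)
                    a1 = zi - kappa * s0 - gamma * (f0 - 1.0)
                    b1 = s0 / f0
                    c1 = (f0 - fv) / (tau * v0)
                    d1 = (f0 * Ef / E0 - fv * q0 / v0) / (tau * q0)
                    s1 = s0 + dtf * a1
                    lf1 = lf0 + dtf * b1
                    lv1 = lv0 + dtf * c1
                    lq1 = lq0 + dtf * d1
                    f1 = np.exp(lf1)
                    v1 = np.exp(lv1)
                    q1 = np.exp(lq1)
                    fv = np.exp(ooa * lv1)
                    Ef = 1.0 - np.exp(lme / f1)
                    a2 = ze - kappa * s1 - gamma * (f1 - 1.0)
                    b2 = s1 / f1
                    c2 = (f1 - fv) / (tau * v1)
                    d2 = (f1 * Ef / E0 - fv * q1 / v1) / (tau * q1)
                    s_[i] = s0 + 0.5 * dtf * (a1 + a2)
                    lf[i] = lf0 + 0.5 * dtf * (b1 + b2)
                    lv[i] = lv0 + 0.5 * dtf * (c1 + c2)
                    lq[i] = lq0 + 0.5 * dtf * (d1 + d2)
                    z[i] = zn[i]
                    if abs(z[i]) > 50.0 or abs(lf[i]) > 6.0 or abs(s_[i]) > 50.0:
                        diverged = True
                if diverged:
                    break
                if (step + 1) % stride == 0 and rec < n_scans:
                    for i in range(n):
                        vv = np.exp(lv[i])
                        qq = np.exp(lq[i])
                        out[k, rec, i] = 100.0 * V0 * (
                            k1c * (1.0 - qq) + 2.0 * (1.0 - qq / vv) + k3c * (1.0 - vv)
                        )
                    rec += 1
            if diverged:
                for t in range(n_scans):
                    for i in range(n):
                        out[k, t, i] = np.nan
        return out


def predict_bold_batch(
    thetas: np.ndarray,
    vec: ParamVectorization,
    enc: StimulusEncoding,
    hemo: HemodynamicParams,
    tr: float,
    n_scans: int | None = None,
    subdiv: int = 1,
    use_numba: bool | None = None,
) -> np.ndarray:
    """Model-predicted BOLD at scan times for a batch of parameter vectors.

    Returns ``(K, n_scans, n_nodes)``.  Scan k samples time ``k * tr``;
    ``tr`` must be an integer multiple of the encoding step.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    K = thetas.shape[0]
    dtf = enc.dt / subdiv
    stride = int(round(tr / dtf))
    if abs(stride * dtf - tr) > 1e-9 * tr:
        raise ConfigurationError(f"TR={tr} is not a multiple of the integration step {dtf}")
    S = enc.n_timepoints * subdiv
    max_scans = S // stride + 1
    if n_scans is None:
        n_scans = max_scans
    if n_scans > max_scans:
        raise ConfigurationError(f"n_scans={n_scans} exceeds encoding coverage ({max_scans})")

    patterns, pat = _input_patterns(enc.u)
    P = patterns.shape[0]
    n = vec.n_nodes
    E = np.empty((K, P, n, n))
    d = np.empty((K, P, n))
    for k in range(K):
        E[k], d[k] = _propagators(vec.to_matrices(thetas[k]), patterns, dtf)

    out = np.empty((K, n_scans, n))
    hemo_c = np.array([hemo.kappa, hemo.gamma, hemo.tau, hemo.alpha, hemo.E0, hemo.V0])
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba and _HAVE_NUMBA:
        _forward_loop_numba(E, d, pat, subdiv, stride, n_scans, dtf, hemo_c, out)
    else:
        _forward_loop_numpy(E, d, pat, subdiv, stride, n_scans, dtf, hemo_c, out)
    if not np.all(np.isfinite(out)):
        raise NumericalError("non-finite BOLD prediction (unstable parameters?)")
    return out


def predict_bold(
    params: DCMParams | np.ndarray,
    hemo: HemodynamicParams,
    enc: StimulusEncoding,
    tr: float,
    vec: ParamVectorization | None = None,
    n_scans: int | None = None,
    subdiv: int = 1,
) -> np.ndarray:
    """Noise-free BOLD prediction at scan times for one subject (T x n)."""
    if isinstance(params, DCMParams):
        if vec is None:
            vec = ParamVectorization(
                n_nodes=params.n_nodes,
                node_labels=params.node_labels or (),
                n_inputs=params.n_inputs,
            )
        theta = vec.from_matrices(params)
    else:
        if vec is None:
            raise ConfigurationError("a ParamVectorization is required with a raw theta vector")
        theta = np.asarray(params, dtype=float)
    y = predict_bold_batch(theta[None, :], vec, enc, hemo, tr, n_scans=n_scans, subdiv=subdiv)
    return y[0]


def explained_variance(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Fraction of variance explained, averaged over nodes, floored at 0."""
    from ..errors import DegenerateDataError

    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    if y.shape != y_hat.shape:
        raise AlignmentError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    var = np.var(y, axis=0)
    if np.any(var <= 0):
        bad = int(np.argmin(var))
        raise DegenerateDataError(f"node {bad} has zero variance")
    ev = 1.0 - np.var(y - y_hat, axis=0) / var
    return float(max(np.mean(ev), 0.0))
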