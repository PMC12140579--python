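"""Functional-connectivity comparison arm.

Full task-evoked FC is the pairwise Pearson correlation of the ROI series;
task-residual FC correlates the residuals after regressing out the task
timing (HRF-convolved driving/modulatory regressors plus an intercept, or raw
boxcars on request).  Feature selection follows the CPM recipe — the top 10%
most positively and top 10% most negatively target-correlated edges, merged —
but the masked edges enter the regularized regression as separate features
rather than being summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateDesignError, DegenerateNodeError
from .io import ROITimeSeries
from .paradigm import StimulusEncoding
from .peb import EdgeMask
from .predict import PredictionConfig, PredictionResult, run_cv_engine


@dataclass
class FCMatrix:
    """Symmetric Pearson-correlation matrix with a fixed edge ordering."""

    matrix: np.ndarray
    kind: str  # "full" | "residual"
    subject_id: str | None = None
    node_labels: tuple[str, ...] | None = None

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper triangle (i < j), row-major — the canonical edge ordering."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.matrix[iu]

    def edge_names(self) -> list[str]:
        labels = self.node_labels or tuple(f"n{i}" for i in range(self.n_nodes))
        iu = np.triu_indices(self.n_nodes, k=1)
        return [f"FC:{labels[i]}~{labels[j]}" for i, j in zip(*iu)]


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def _check_series(data: np.ndarray, labels) -> None:
    if data.shape[0] < 3:
        raise ConfigurationError("need at least 3 time points for correlation")
    spread = np.ptp(data, axis=0)
    if np.any(spread == 0):
        bad = int(np.argmin(spread))
        name = labels[bad] if labels else str(bad)
        raise DegenerateNodeError(f"node {name} has a constant time series")


def compute_fc(ts: ROITimeSeries) -> FCMatrix:
    """Full task-evoked FC: pairwise correlation of the raw ROI series."""
    _check_series(ts.data, ts.node_labels)
    r = np.corrcoef(ts.data, rowvar=False)
    return FCMatrix(matrix=r, kind="full", subject_id=ts.subject_id, node_labels=ts.node_labels)


def canonical_hrf(dt: float, length: float = 32.0) -> np.ndarray:
    """Double-gamma HRF sampled at dt (peak ~5 s, undershoot ratio 1/6)."""
    t = np.arange(0.0, length, dt)
    peak = stats.gamma.pdf(t, 6.0)
    under = stats.gamma.pdf(t, 16.0)
    h = peak - under / 6.0
    return h / np.sum(h)


def task_regressors(
    enc: StimulusEncoding,
    tr: float,
    n_scans: int,
    raw_boxcar: bool = False,
) -> np.ndarray:
    """Task timing at scan resolution: HRF-convolved inputs (or raw boxcars)."""
    stride = int(round(tr / enc.dt))
    if abs(stride * enc.dt - tr) > 1e-9 * tr:
        raise ConfigurationError(f"TR={tr} is not a multiple of the microtime step {enc.dt}")
    cols = []
    for k in range(enc.u.shape[1]):
        u = enc.u[:, k]
        if raw_boxcar:
            x = u
        else:
            x = np.convolve(u, canonical_hrf(enc.dt))[: enc.n_timepoints]
        samples = x[::stride][:n_scans]
        if samples.shape[0] < n_scans:
            samples = np.pad(samples, (0, n_scans - samples.shape[0]))
        cols.append(samples)
    return np.column_stack(cols)


def task_residual_fc(
    ts: ROITimeSeries,
    enc: StimulusEncoding,
    raw_boxcar: bool = False,
) -> FCMatrix:
    """FC of the OLS residuals after regressing out task timing + intercept."""
    _check_series(ts.data, ts.node_labels)
    R = task_regressors(enc, ts.tr, ts.n_scans, raw_boxcar=raw_boxcar)
    keep = np.std(R, axis=0) > 0
    design = np.column_stack([np.ones(ts.n_scans), R[:, keep]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDesignError("task regressors are rank deficient")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    sd = np.std(resid, axis=0)
    if np.any(sd == 0):
        bad = int(np.argmin(sd))
        raise DegenerateNodeError(
            f"node {ts.node_labels[bad]} has zero residual variance"
        )
    r = np.corrcoef(resid, rowvar=False)
    return FCMatrix(
        matrix=r, kind="residual", subject_id=ts.subject_id, node_labels=ts.node_labels
    )


def fc_edge_table(fcs: list[FCMatrix]) -> tuple[np.ndarray, list[str]]:
    """Stack per-subject edge vectors into (n_subjects, n_edges)."""
    if not fcs:
        raise ConfigurationError("empty FC list")
    return np.stack([fc.edge_vector() for fc in fcs]), fcs[0].edge_names()


def cpm_select(
    edge_features: np.ndarray,
    train_targets: np.ndarray,
    top_frac: float = 0.10,
    edge_names: list[str] | None = None,
) -> EdgeMask:
    """Merged mask of the most positively and most negatively correlated edges.

    ``ceil(top_frac * E)`` edges from each tail of the signed train
    correlation ranking (ties broken by edge index), then unioned.
    """
    Xe = np.asarray(edge_features, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    E = Xe.shape[1]
    if E == 0:
        raise ConfigurationError("no FC edges to select from")
    sd = np.std(Xe, axis=0)
    yc = y - y.mean()
    denom = sd * np.std(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xe - Xe.mean(axis=0)).T @ yc / (Xe.shape[0] * denom)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    n_sel = int(np.ceil(top_frac * E))
    order_pos = np.lexsort((np.arange(E), -corr))
    order_neg = np.lexsort((np.arange(E), corr))
    values = np.zeros(E, dtype=bool)
    values[order_pos[:n_sel]] = True
    values[order_neg[:n_sel]] = True
    names = edge_names or [f"edge{e}" for e in range(E)]
    return EdgeMask(
        values=values,
        param_indices=np.arange(E),
        names=names,
        matrix_kind="FC",
        design_column="covariate",
        provenance={"method": "CPM", "top_frac": top_frac, "n_per_tail": n_sel},
    )


def run_fc_prediction(
    series_or_edges,
    targets,
    cfg: PredictionConfig,
    enc: StimulusEncoding | None = None,
    top_frac: float = 0.10,
) -> PredictionResult:
    """FC-based prediction through the same CV/regression machinery.

    ``series_or_edges`` is either a list of :class:`ROITimeSeries` (FC kind
    chosen by ``cfg.feature_source``: "FC-full" or "FC-residual", the latter
    requiring ``enc``) or a precomputed (n_subjects, n_edges) table.
    """
    if isinstance(series_or_edges, np.ndarray):
        edges = series_or_edges
        names = [f"edge{e}" for e in range(edges.shape[1])]
    else:
        if cfg.feature_source == "FC-residual":
            if enc is None:
                raise ConfigurationError("task-residual FC requires the stimulus encoding")
            fcs = [task_residual_fc(ts, enc) for ts in series_or_edges]
        else:
            fcs = [compute_fc(ts) for ts in series_or_edges]
        edges, names = fc_edge_table(fcs)

    def selector(train_idx, train_targets):
        return cpm_select(edges[train_idx], train_targets, top_frac=top_frac, edge_names=names)

    def extractor(mask):
        return edges[:, mask.values]

    return run_cv_engine(selector, extractor, targets, cfg)
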