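"""Synthetic subject cohorts with ground-truth coupling matrices.

Stand-in for the (non-shareable) empirical cohort: each subject's intrinsic
matrix A covaries linearly with an age-like score on a fixed set of edges,
and the task-modulation matrix B covaries with an RT-like score on a disjoint
edge set — the planted dissociation the downstream prediction analysis is
expected to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dcm.forward import (
    SELF_SCALE,
    DCMParams,
    HemodynamicParams,
    ParamVectorization,
    predict_bold,
    stability_check,
)
from .dcm.invert import DCMPosterior, default_priors
from .errors import ConfigurationError, FormatError
from .io import ROITimeSeries, read_timeseries, write_timeseries
from .paradigm import StimulusEncoding

#: Edge tuples are (target, source) — the in-memory matrix convention.
Edge = tuple[int, int]


def _default_edges(n_nodes: int, count: int, exclude: set[Edge], seed: int) -> list[Edge]:
    rng = np.random.default_rng(seed)
    candidates = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    rng.shuffle(candidates)
    out = []
    for e in candidates:
        if e not in exclude:
            out.append(e)
        if len(out) == count:
            break
    return out


@dataclass
class CohortSpec:
    """Knobs of the synthetic cohort generator (all defaults desk-scale)."""

    node_labels: tuple[str, ...] = (
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
    driving_nodes: tuple[int, ...] | None = None  # default: bilateral IPS / all
    n_effect_edges: int = 4
    beta_B: float = 1.2  # Hz per second of rt_like (sd 0.08 -> B range ~ +/-0.2)
    beta_A: float = 0.006  # Hz per year of age_like (sd ~19 -> A range ~ +/-0.23)
    group_offdiag_A: float = 0.15
    group_B: float = 0.25
    c_gain: float = 0.35
    param_noise_sd: float = 0.03
    self_log_sd: float = 0.1
    rt_mean: float = 0.55
    rt_sd: float = 0.08
    age_range: tuple[float, float] = (18.0, 85.0)
    max_retries: int = 50
    effect_edges_A: list[Edge] | None = None
    effect_edges_B: list[Edge] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass
class CohortTruth:
    """Ground-truth generative parameters for a synthetic cohort."""

    n_subjects: int
    node_labels: tuple[str, ...]
    params: list[DCMParams]
    scores: pd.DataFrame  # columns: subject_id, rt_like, age_like
    group_mean_A: np.ndarray
    group_mean_B: np.ndarray
    beta_A: np.ndarray
    beta_B: np.ndarray
    effect_edges_A: list[Edge]
    effect_edges_B: list[Edge]
    noise_sd_params: float
    seed: int
    driving_nodes: tuple[int, ...] = ()

    def vectorization(self) -> ParamVectorization:
        return ParamVectorization(
            n_nodes=len(self.node_labels),
            node_labels=self.node_labels,
            driving_nodes=self.driving_nodes,
        )

    def subject_ids(self) -> list[str]:
        return list(self.scores["subject_id"])

    def to_json(self) -> str:
        doc = {
            "n_subjects": self.n_subjects,
            "node_labels": list(self.node_labels),
            "group_mean_A": self.group_mean_A.tolist(),
            "group_mean_B": self.group_mean_B.tolist(),
            "beta_A": self.beta_A.tolist(),
            "beta_B": self.beta_B.tolist(),
            "effect_edges_A": [list(e) for e in self.effect_edges_A],
            "effect_edges_B": [list(e) for e in self.effect_edges_B],
            "noise_sd_params": self.noise_sd_params,
            "seed": self.seed,
            "driving_nodes": list(self.driving_nodes),
            "subjects": [
                {"A": p.A.tolist(), "B": p.B.tolist(), "C": p.C.tolist()}
                for p in self.params
            ],
            "scores": self.scores.to_dict(orient="list"),
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        doc = json.loads(text)
        labels = tuple(doc["node_labels"])
        params = [
            DCMParams(
                A=np.array(s["A"]),
                B=np.array(s["B"]),
                C=np.array(s["C"]),
                node_labels=labels,
            )
            for s in doc["subjects"]
        ]
        return cls(
            n_subjects=doc["n_subjects"],
            node_labels=labels,
            params=params,
            scores=pd.DataFrame(doc["scores"])[["subject_id", "rt_like", "age_like"]],
            group_mean_A=np.array(doc["group_mean_A"]),
            group_mean_B=np.array(doc["group_mean_B"]),
            beta_A=np.array(doc["beta_A"]),
            beta_B=np.array(doc["beta_B"]),
            effect_edges_A=[tuple(e) for e in doc["effect_edges_A"]],
            effect_edges_B=[tuple(e) for e in doc["effect_edges_B"]],
            noise_sd_params=doc["noise_sd_params"],
            seed=doc["seed"],
            driving_nodes=tuple(doc["driving_nodes"]),
        )


def _group_matrices(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = spec.n_nodes
    A = np.zeros((n, n))
    np.fill_diagonal(A, -SELF_SCALE)
    # sparse plausible baseline couplings on a deterministic edge set
    for i, j in _default_edges(n, max(n // 2, 2), set(), seed=77):
        A[i, j] = spec.group_offdiag_A * (1 if (i + j) % 2 else -1) * 0.8
    B = np.zeros((n, n))
    for i, j in _default_edges(n, max(n // 2, 2), set(), seed=78):
        B[i, j] = spec.group_B
    C = np.zeros(n)
    driving = spec.driving_nodes
    if driving is None:
        labels = spec.node_labels
        driving = tuple(
            k for k, lab in enumerate(labels) if "IPS" in lab
        ) or tuple(range(n))
    C[list(driving)] = spec.c_gain
    return A, B, C


def sample_cohort_truth(
    n_subjects: int, spec: CohortSpec | None = None, seed: int = 0
) -> CohortTruth:
    """Draw a cohort of stable subject-level (A, B, C) matrices and scores.

    Subject matrices are ``group_mean + beta * centered(score) + noise`` with
    the age-like score planted in A and the RT-like score planted in B on
    disjoint edge sets.  Unstable draws are replaced (bounded retries).
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    spec = spec or CohortSpec()
    n = spec.n_nodes
    rng = np.random.default_rng(seed)

    edges_B = spec.effect_edges_B or _default_edges(n, spec.n_effect_edges, set(), seed=101)
    edges_A = spec.effect_edges_A or _default_edges(
        n, spec.n_effect_edges, set(edges_B), seed=202
    )
    for i, j in edges_A + edges_B:
        if i == j:
            raise ConfigurationError("effect edges may not be self-connections")

    gA, gB, gC = _group_matrices(spec)
    beta_A = np.zeros((n, n))
    for i, j in edges_A:
        beta_A[i, j] = spec.beta_A
    beta_B = np.zeros((n, n))
    for i, j in edges_B:
        beta_B[i, j] = spec.beta_B

    # subject scores
    rt = rng.normal(spec.rt_mean, spec.rt_sd, size=n_subjects)
    rt = np.clip(rt, 0.15, 1.5)
    age = rng.uniform(*spec.age_range, size=n_subjects)
    rt_c = rt - rt.mean()
    age_c = age - age.mean()

    offdiag = ~np.eye(n, dtype=bool)
    driving = tuple(int(k) for k in np.flatnonzero(gC))
    params: list[DCMParams] = []
    for s in range(n_subjects):
        ok = False
        for _ in range(spec.max_retries):
            A = gA + beta_A * age_c[s]
            A[offdiag] += rng.normal(0, spec.param_noise_sd, size=int(offdiag.sum()))
            np.fill_diagonal(A, -SELF_SCALE * np.exp(rng.normal(0, spec.self_log_sd, size=n)))
            B = gB + beta_B * rt_c[s]
            B[offdiag] += rng.normal(0, spec.param_noise_sd, size=int(offdiag.sum()))
            np.fill_diagonal(B, 0.0)
            stable_A, _ = stability_check(A)
            stable_AB, _ = stability_check(A + B)
            if stable_A and stable_AB:
                ok = True
                break
        if not ok:
            raise ConfigurationError(
                f"could not draw a stable subject after {spec.max_retries} retries; "
                "reduce effect sizes or parameter noise"
            )
        C = np.zeros((n, 2))
        C[:, 0] = gC
        Bfull = np.zeros((2, n, n))
        Bfull[1] = B
        params.append(
            DCMParams(A=A, B=Bfull, C=C, node_labels=spec.node_labels)
        )

    scores = pd.DataFrame(
        {
            "subject_id": [f"sub-{s:03d}" for s in range(n_subjects)],
            "rt_like": rt,
            "age_like": age,
        }
    )
    return CohortTruth(
        n_subjects=n_subjects,
        node_labels=spec.node_labels,
        params=params,
        scores=scores,
        group_mean_A=gA,
        group_mean_B=gB,
        beta_A=beta_A,
        beta_B=beta_B,
        effect_edges_A=list(edges_A),
        effect_edges_B=list(edges_B),
        noise_sd_params=spec.param_noise_sd,
        seed=seed,
        driving_nodes=driving,
    )


def simulate_subject_bold(
    truth_i: DCMParams,
    enc: StimulusEncoding,
    hemo: HemodynamicParams,
    tr: float,
    noise_sd: float,
    seed: int,
    subject_id: str | None = None,
    n_scans: int | None = None,
) -> ROITimeSeries:
    """Forward-simulate one subject: neural ODE -> balloon BOLD + white noise."""
    stable, lead = stability_check(truth_i.A)
    if not stable:
        from .errors import InstabilityError

        raise InstabilityError(f"unstable A (leading eigenvalue {lead:.4f})")
    clean = predict_bold(truth_i, hemo, enc, tr, n_scans=n_scans)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    labels = truth_i.node_labels or tuple(f"n{i}" for i in range(truth_i.n_nodes))
    return ROITimeSeries(data=noisy, tr=tr, node_labels=labels, subject_id=subject_id)


def simulate_cohort(
    truth: CohortTruth,
    enc: StimulusEncoding,
    hemo: HemodynamicParams | None = None,
    tr: float = 2.03,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[ROITimeSeries]:
    """Simulate BOLD for every subject (per-subject seed substreams)."""
    hemo = hemo or HemodynamicParams()
    child_seeds = np.random.SeedSequence(seed).spawn(truth.n_subjects)
    out = []
    for s, (p, ss) in enumerate(zip(truth.params, child_seeds)):
        out.append(
            simulate_subject_bold(
                p,
                enc,
                hemo,
                tr,
                noise_sd,
                seed=ss,  # spawned substream; accepted by default_rng
                subject_id=truth.scores["subject_id"].iloc[s],
            )
        )
    return out


def noise_sd_for_snr(
    truth: CohortTruth,
    enc: StimulusEncoding,
    hemo: HemodynamicParams | None = None,
    tr: float = 2.03,
    snr: float = 10.0,
    n_probe: int = 3,
) -> float:
    """Observation-noise sd giving the requested signal-sd/noise-sd ratio.

    Probes the first few subjects' noise-free BOLD to estimate the cohort's
    signal scale.
    """
    if snr <= 0:
        raise ConfigurationError("snr must be positive")
    hemo = hemo or HemodynamicParams()
    sds = [
        float(np.std(predict_bold(p, hemo, enc, tr)))
        for p in truth.params[: max(1, n_probe)]
    ]
    return float(np.mean(sds)) / snr


def pseudo_posteriors(
    truth: CohortTruth,
    post_sd: float = 0.02,
    seed: int = 0,
    vec: ParamVectorization | None = None,
) -> list[DCMPosterior]:
    """Posterior stand-ins: true parameters + Gaussian jitter, diagonal cov.

    Used to exercise the group-level (PEB) and prediction machinery without
    paying for first-level inversions.
    """
    vec = vec or truth.vectorization()
    rng = np.random.default_rng(seed)
    priors = default_priors(vec)
    cov = np.eye(vec.p) * post_sd**2
    out = []
    for s, p in enumerate(truth.params):
        mean = vec.from_matrices(p) + rng.normal(0, post_sd, size=vec.p)
        out.append(
            DCMPosterior(
                mean=mean,
                cov=cov.copy(),
                free_energy=0.0,
                explained_variance=1.0,
                priors=priors,
                vec=vec,
                converged=True,
                trace=[0.0],
                subject_id=truth.scores["subject_id"].iloc[s],
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort round-trip
# ---------------------------------------------------------------------------


def write_cohort(
    directory: str | Path,
    truth: CohortTruth,
    series: list[ROITimeSeries],
    tr: float,
    meta: dict | None = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.scores.to_csv(directory / "scores.csv", index=False)
    (directory / "truth.json").write_text(truth.to_json())
    doc = dict(meta or {})
    doc.update(
        {
            "tr": tr,
            "n_subjects": len(series),
            "node_labels": list(truth.node_labels),
        }
    )
    (directory / "meta.json").write_text(json.dumps(doc, sort_keys=True, indent=1))
    for ts in series:
        write_timeseries(ts, directory / f"{ts.subject_id}_ts.tsv")


def read_cohort(directory: str | Path) -> tuple[CohortTruth, list[ROITimeSeries], dict]:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json sidecar in {directory}")
    meta = json.loads(meta_path.read_text())
    if "tr" not in meta:
        raise FormatError(f"{meta_path} lacks a 'tr' entry")
    truth = CohortTruth.from_json((directory / "truth.json").read_text())
    series = [
        read_timeseries(directory / f"{sid}_ts.tsv") for sid in truth.subject_ids()
    ]
    return truth, series, meta
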