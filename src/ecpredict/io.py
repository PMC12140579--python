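"""File formats, run configuration, and the run manifest.

Plain-text dialects used throughout:

* ROI time series — tab-delimited, one header row of node labels, T rows of
  floats (12 significant digits); TR and subject metadata live in a JSON
  sidecar next to the file (same stem, ``.json`` extension).
* Task timing — FSL 3-column EV files: ``onset<TAB>duration<TAB>amplitude``.
* Connectivity matrices — tab-delimited with node-label headers, written
  row = source ("From"), column = target ("To"); note the in-memory
  convention is the transpose (rows are targets).
* Configuration — JSON (YAML accepted and normalized); unknown keys are
  rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FormatError

FLOAT_FMT = "%.12g"


@dataclass
class ROITimeSeries:
    """One subject's ROI BOLD table sampled at ``tr`` seconds."""

    data: np.ndarray  # (T, n_nodes)
    tr: float
    node_labels: tuple[str, ...]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"time series must be 2-D, got shape {self.data.shape}")
        if len(self.node_labels) != self.data.shape[1]:
            raise FormatError(
                f"{len(self.node_labels)} labels for {self.data.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("time series contains non-finite entries")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(ts.node_labels) + "\n")
        for row in ts.data:
            fh.write("\t".join(FLOAT_FMT % v for v in row) + "\n")
    sidecar = {
        "tr": ts.tr,
        "subject_id": ts.subject_id,
        "node_labels": list(ts.node_labels),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def read_timeseries(path: str | Path) -> ROITimeSeries:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such time-series file: {path}")
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing TR sidecar for {path} (expected {sc_path})")
    sidecar = json.loads(sc_path.read_text())
    if "tr" not in sidecar or sidecar["tr"] is None:
        raise FormatError(f"sidecar {sc_path} lacks a 'tr' entry")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(header):
                raise FormatError(f"{path}:{ln}: expected {len(header)} columns, got {len(parts)}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return ROITimeSeries(
        data=np.array(rows, dtype=float),
        tr=float(sidecar["tr"]),
        node_labels=tuple(header),
        subject_id=sidecar.get("subject_id"),
    )


def write_ev3(events, path: str | Path) -> None:
    """Write (onset, duration, amplitude) rows as an FSL 3-column EV file."""
    with open(path, "w") as fh:
        for onset, duration, amplitude in events:
            fh.write(
                "\t".join(FLOAT_FMT % v for v in (onset, duration, amplitude)) + "\n"
            )


def read_ev3(path: str | Path) -> list[tuple[float, float, float]]:
    path = Path(path)
    events: list[tuple[float, float, float]] = []
    prev_onset = -np.inf
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            try:
                onset, duration, amplitude = (float(v) for v in parts)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            if duration < 0:
                raise FormatError(f"{path}:{ln}: negative duration {duration}")
            if onset < prev_onset:
                raise FormatError(f"{path}:{ln}: onsets not monotone ({onset} < {prev_onset})")
            prev_onset = onset
            events.append((onset, duration, amplitude))
    return events


def write_matrix_tsv(matrix: np.ndarray, labels, path: str | Path) -> None:
    """Export a coupling matrix as row=From / column=To (transposes storage)."""
    matrix = np.asarray(matrix, dtype=float)
    out = matrix.T  # storage is row=To; the text dialect is row=From
    with open(path, "w") as fh:
        fh.write("From\\To\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, out):
            fh.write(lab + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header) + 1:
                raise FormatError(f"{path}:{ln}: ragged row")
            rows.append([float(v) for v in parts[1:]])
    return np.array(rows).T, tuple(header)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

CONFIG_SCHEMA_VERSION = 1

_CONFIG_DEFAULTS: dict = {
    "schema_version": CONFIG_SCHEMA_VERSION,
    "seed": 1,
    "log_level": "INFO",
    "design_kind": "event",
    "tr": 2.03,
    "paradigm": {
        "n_blocks": 24,
        "trials_per_block": [13, 16],
        "trial_duration": 0.2,
        "isi_range": [2.0, 4.5],
        "rest_range": [15.0, 19.0],
        "instruction_lead": 2.0,
    },
    "cohort": {
        "n_subjects": 60,
        "noise_sd": 0.05,
        "param_noise_sd": 0.03,
    },
    "dcm": {
        "max_iter": 64,
        "tol": 1e-4,
        "subdiv": 1,
        "ev_exclusion": 0.10,
        "a_offdiag_var": 1.0 / 64.0,
        "a_self_var": 1.0 / 256.0,
        "b_var": 1.0 / 16.0,
        "c_var": 1.0,
    },
    "peb": {
        "pp_threshold": 0.95,
        "use_bmr": False,
        "max_exhaustive_params": 16,
    },
    "predict": {
        "cv_scheme": "kfold",
        "k": 5,
        "n_repetitions": 100,
        "n_permutations": 500,
        "regressor": "lasso",
        "feature_source": "M-EC",
    },
    "paths": {
        "cohort_dir": None,
        "posterior_dir": None,
        "out_dir": None,
    },
}


@dataclass
class RunConfig:
    """Validated run configuration (defaults filled, unknown keys rejected)."""

    values: dict

    def __getitem__(self, key):
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True).encode()
        ).hexdigest()[:16]


def _merge_validate(defaults: dict, given: dict, prefix: str = "") -> dict:
    out = {}
    unknown = set(given) - set(defaults)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigurationError(f"unknown configuration key: {prefix}{key}")
    for key, default in defaults.items():
        if key in given:
            value = given[key]
            if isinstance(default, dict) and value is not None:
                if not isinstance(value, dict):
                    raise ConfigurationError(f"{prefix}{key} must be a mapping")
                out[key] = _merge_validate(default, value, prefix=f"{prefix}{key}.")
            else:
                out[key] = value
        else:
            out[key] = json.loads(json.dumps(default))  # deep copy
    return out


def make_config(overrides: dict | None = None) -> RunConfig:
    return RunConfig(values=_merge_validate(_CONFIG_DEFAULTS, overrides or {}))


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a JSON or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: config must be a JSON object")
    return make_config(doc)


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    timings: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)  # [{"subject": ..., "reason": ...}]
    warnings: list = field(default_factory=list)
    timestamp: str | None = None

    def exclude(self, subject: str, reason: str) -> None:
        self.exclusions.append({"subject": subject, "reason": reason})

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def write(self, path: str | Path) -> None:
        doc = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "timings": self.timings,
            "exclusions": self.exclusions,
            "warnings": self.warnings,
            "timestamp": self.timestamp,
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))
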