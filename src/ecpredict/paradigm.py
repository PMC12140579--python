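"""Spatial stimulus-response-compatibility (SRC) task designs and their encoding.

The task alternates Pro (spatially compatible) and Anti (incompatible) blocks
of brief lateralized stimuli.  This module generates seeded designs, encodes
them as binary model-input functions on a microtime grid (event-related or
block-based dialect), and computes the behavioral target (mean Anti-condition
reaction time after trial filtering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateSubjectError, ResolutionError

PRO = "Pro"
ANTI = "Anti"

#: Reaction-time filter bounds (seconds).  Strict inequalities: a trial is
#: invalid iff rt < RT_MIN or rt > RT_MAX, so the boundary values are retained.
RT_MIN = 0.150
RT_MAX = 1.500

DEFAULT_PROTOCOL = dict(
    n_blocks=24,
    trials_per_block=(13, 16),
    trial_duration=0.2,
    isi_range=(2.0, 4.5),
    rest_range=(15.0, 19.0),
    instruction_lead=2.0,
)


@dataclass(frozen=True)
class Trial:
    onset: float
    duration: float
    side: str  # "left" | "right"
    condition: str  # PRO | ANTI


@dataclass(frozen=True)
class Block:
    condition: str
    instruction_onset: float
    block_onset: float
    block_duration: float


@dataclass
class Paradigm:
    """A realized task design: ordered blocks, trials, and total run length."""

    blocks: list[Block]
    trials: list[Trial]
    total_duration: float

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def condition_counts(self) -> dict[str, int]:
        out = {PRO: 0, ANTI: 0}
        for b in self.blocks:
            out[b.condition] += 1
        return out

    def anti_trial_mask(self) -> np.ndarray:
        return np.array([t.condition == ANTI for t in self.trials], dtype=bool)

    def to_json(self) -> str:
        doc = {
            "blocks": [
                {
                    "condition": b.condition,
                    "instruction_onset": b.instruction_onset,
                    "block_onset": b.block_onset,
                    "block_duration": b.block_duration,
                }
                for b in self.blocks
            ],
            "trials": [
                {
                    "onset": t.onset,
                    "duration": t.duration,
                    "side": t.side,
                    "condition": t.condition,
                }
                for t in self.trials
            ],
            "total_duration": self.total_duration,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Paradigm":
        doc = json.loads(text)
        blocks = [Block(**b) for b in doc["blocks"]]
        trials = [Trial(**t) for t in doc["trials"]]
        return cls(blocks=blocks, trials=trials, total_duration=doc["total_duration"])


@dataclass
class StimulusEncoding:
    """Binary input functions u(t) on a microtime grid.

    Column 0 drives the network with every stimulus event; column 1 marks the
    Anti condition (the modulatory input).  Entries are 0/1 — the inputs are
    deliberately not mean-centered, so the intrinsic matrix A refers to the
    task-off baseline.
    """

    dt: float
    u: np.ndarray  # (n_timepoints, n_inputs), values in {0, 1}
    design_kind: str  # "event" | "block"
    input_labels: tuple[str, ...] = ("driving", "modulatory")

    @property
    def n_timepoints(self) -> int:
        return self.u.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt

    @property
    def duration(self) -> float:
        return self.n_timepoints * self.dt


@dataclass
class TrialResponses:
    """Per-trial reaction times aligned with ``Paradigm.trials``."""

    rt: np.ndarray
    valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        # invalid iff rt < 150 ms or rt > 1500 ms (strict; boundaries kept)
        self.valid = ~((self.rt < RT_MIN) | (self.rt > RT_MAX))


def generate_paradigm(seed: int, overrides: dict | None = None) -> Paradigm:
    """Generate a seeded SRC design.

    Defaults follow the protocol: 24 blocks (12 Pro / 12 Anti, shuffled),
    13-16 trials per block, 0.2-s stimuli with 2-4.5-s jittered onsets,
    15-19-s rests, and a 2-s instruction preceding each block.

    Parameters
    ----------
    seed:
        Seed for all jitter and shuffling; identical seeds yield identical
        designs.
    overrides:
        Optional protocol overrides (``n_blocks`` must stay even so conditions
        balance).
    """
    proto = dict(DEFAULT_PROTOCOL)
    if overrides:
        unknown = set(overrides) - set(proto)
        if unknown:
            raise ConfigurationError(f"unknown protocol overrides: {sorted(unknown)}")
        proto.update(overrides)

    n_blocks = int(proto["n_blocks"])
    lo, hi = (int(v) for v in proto["trials_per_block"])
    if n_blocks <= 0 or n_blocks % 2 != 0:
        raise ConfigurationError(f"n_blocks must be positive and even, got {n_blocks}")
    if lo > hi or lo <= 0:
        raise ConfigurationError(f"empty trials_per_block range ({lo}, {hi})")
    isi_lo, isi_hi = (float(v) for v in proto["isi_range"])
    rest_lo, rest_hi = (float(v) for v in proto["rest_range"])
    if isi_lo > isi_hi or isi_lo <= proto["trial_duration"]:
        raise ConfigurationError(f"invalid isi_range ({isi_lo}, {isi_hi})")
    if rest_lo > rest_hi or rest_lo < 0:
        raise ConfigurationError(f"invalid rest_range ({rest_lo}, {rest_hi})")

    rng = np.random.default_rng(seed)
    conditions = np.array([PRO, ANTI] * (n_blocks // 2))
    rng.shuffle(conditions)

    trial_duration = float(proto["trial_duration"])
    lead = float(proto["instruction_lead"])

    blocks: list[Block] = []
    trials: list[Trial] = []
    t = float(rng.uniform(rest_lo, rest_hi))  # initial rest before first block
    for cond in conditions:
        instruction_onset = t
        block_onset = instruction_onset + lead
        n_trials = int(rng.integers(lo, hi + 1))
        onset = block_onset
        block_trials = []
        for _ in range(n_trials):
            side = "left" if rng.uniform() < 0.5 else "right"
            block_trials.append(Trial(onset, trial_duration, side, str(cond)))
            onset += float(rng.uniform(isi_lo, isi_hi))
        block_end = block_trials[-1].onset + trial_duration
        blocks.append(Block(str(cond), instruction_onset, block_onset, block_end - block_onset))
        trials.extend(block_trials)
        t = block_end + float(rng.uniform(rest_lo, rest_hi))

    return Paradigm(blocks=blocks, trials=trials, total_duration=t)


def encode_inputs(p: Paradigm, design_kind: str, dt: float) -> StimulusEncoding:
    """Encode a paradigm as binary driving/modulatory inputs on a dt grid.

    Event dialect: the driving column is 1 on every trial window
    [onset, onset + 0.2 s); the modulatory column is 1 on Anti-trial windows
    only.  Block dialect: boxcars span each block's onset and full duration.
    """
    if design_kind not in ("event", "block"):
        raise ConfigurationError(f"design_kind must be 'event' or 'block', got {design_kind!r}")
    if dt <= 0:
        raise ResolutionError(f"dt must be positive, got {dt}")
    max_dt = min((t.duration for t in p.trials), default=0.2)
    if dt > max_dt + 1e-12:
        raise ResolutionError(f"dt={dt} cannot resolve {max_dt}-s stimuli (need dt <= {max_dt})")

    n_t = int(np.ceil(p.total_duration / dt))
    u = np.zeros((n_t, 2))

    def paint(col: int, onset: float, duration: float) -> None:
        i0 = int(np.ceil(onset / dt - 1e-9))
        i1 = int(np.ceil((onset + duration) / dt - 1e-9))
        u[max(i0, 0):min(i1, n_t), col] = 1.0

    if design_kind == "event":
        for t in p.trials:
            paint(0, t.onset, t.duration)
            if t.condition == ANTI:
                paint(1, t.onset, t.duration)
    else:
        for b in p.blocks:
            paint(0, b.block_onset, b.block_duration)
            if b.condition == ANTI:
                paint(1, b.block_onset, b.block_duration)

    return StimulusEncoding(dt=dt, u=u, design_kind=design_kind)


def behavioral_target(tr: TrialResponses, p: Paradigm) -> float:
    """Mean reaction time over valid Anti-condition trials (seconds)."""
    if len(tr.rt) != len(p.trials):
        raise ConfigurationError(
            f"responses ({len(tr.rt)}) not aligned with trials ({len(p.trials)})"
        )
    mask = p.anti_trial_mask() & tr.valid
    if not mask.any():
        raise DegenerateSubjectError("no valid Anti-condition trials")
    return float(np.mean(tr.rt[mask]))


def decode_boxcar_onsets(column: np.ndarray, dt: float) -> np.ndarray:
    """Recover boxcar onset times from a binary input column (test helper)."""
    col = (np.asarray(column) > 0.5).astype(int)
    rising = np.flatnonzero(np.diff(np.concatenate(([0], col))) == 1)
    return rising * dt


def events_from_encoding_column(
    p: Paradigm, column: int, design_kind: str
) -> list[tuple[float, float, float]]:
    """FSL-style (onset, duration, amplitude) rows for one input column."""
    rows: list[tuple[float, float, float]] = []
    if design_kind == "event":
        for t in p.trials:
            if column == 0 or t.condition == ANTI:
                rows.append((t.onset, t.duration, 1.0))
    else:
        for b in p.blocks:
            if column == 0 or b.condition == ANTI:
                rows.append((b.block_onset, b.block_duration, 1.0))
    return rows
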