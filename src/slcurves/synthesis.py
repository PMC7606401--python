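"""Synthetic ASRT sessions with known ground-truth learning parameters.

The alternating serial reaction time (ASRT) task hides a deterministic
four-position sequence inside apparent noise: after a handful of warm-up
trials, pattern trials (fixed cyclic sequence, e.g. 3-2-4-1) strictly
alternate with uniformly random trials.  The generator reproduces that
structure, simulates per-trial reaction times whose Random-Low minus
Random-High gap grows along a participant-specific exponential learning
curve, and draws neuropsychological test scores with configurable rank
correlation to the ground-truth curve parameters via a Gaussian copula.

All randomness flows from one master seed split into named substreams so
each stage is independently reproducible.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .triplets import EX, PH, RH, RL, label_trials

logger = logging.getLogger(__name__)

POSITIONS = (1, 2, 3, 4)
#: the 24 pattern permutations used for counterbalancing
ALL_PATTERNS: tuple[tuple[int, ...], ...] = tuple(itertools.permutations(POSITIONS))

ROLE_WARMUP, ROLE_PATTERN, ROLE_RANDOM = "warmup", "pattern", "random"


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# session design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionDesign:
    """Layout and timing of one ASRT session.

    Defaults follow the standard administration: 36 blocks of 85 trials,
    five random warm-up trials then ten repetitions of the eight-trial
    alternating unit; 500 ms stimulus, 120 ms inter-trial interval, 200 ms
    lead-in of empty circles at block start.
    """

    n_blocks: int = 36
    trials_per_block: int = 85
    n_warmup: int = 5
    unit_repeats: int = 10
    stimulus_ms: float = 500.0
    iti_ms: float = 120.0
    lead_in_ms: float = 200.0
    pattern: tuple[int, int, int, int] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_warmup + 8 * self.unit_repeats != self.trials_per_block:
            raise ValueError(
                "design invariant violated: n_warmup + 8*unit_repeats must equal trials_per_block"
            )
        if sorted(self.pattern) != list(POSITIONS):
            raise ValueError(f"pattern must visit each position once, got {self.pattern!r}")

    def next_pos(self, a: int) -> int:
        """Pattern successor of position ``a``."""
        i = self.pattern.index(a)
        return self.pattern[(i + 1) % 4]


def block_duration_ms(design: SessionDesign) -> float:
    """Duration of one block: lead-in plus per-trial stimulus + ITI."""
    return design.lead_in_ms + design.trials_per_block * (design.stimulus_ms + design.iti_ms)


def session_duration_ms(design: SessionDesign) -> float:
    """Task time for the full session, excluding rest periods."""
    return design.n_blocks * block_duration_ms(design)


def make_pattern_permutation(seed: int, participant_index: int) -> tuple[int, ...]:
    """Counterbalanced pattern assignment.

    A seed-shuffled ordering of the 24 permutations is assigned cyclically,
    so any 24 consecutive participant indices cover every permutation once.
    """
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    rng = substream_rng(seed, "pattern-assignment")
    order = rng.permutation(len(ALL_PATTERNS))
    return ALL_PATTERNS[order[participant_index % len(ALL_PATTERNS)]]


def generate_session(
    design: SessionDesign, seed: int, participant_id: str = "p000"
) -> pd.DataFrame:
    """Generate the target sequence of one session (no responses yet).

    Warm-up and random targets are i.i.d. uniform over the four positions;
    pattern targets follow the cyclic pattern, the cycle continuing across
    unit repeats within a block and restarting at the pattern's first
    element each block.
    """
    rng = substream_rng(seed, f"sequence:{participant_id}")
    tpb, nw = design.trials_per_block, design.n_warmup
    n_pattern = (tpb - nw + 1) // 2
    n_random = tpb - nw - n_pattern
    pattern_cycle = np.asarray(design.pattern)[np.arange(n_pattern) % 4]

    blocks, trials, roles, targets = [], [], [], []
    for b in range(1, design.n_blocks + 1):
        t = np.empty(tpb, dtype=np.int64)
        r = np.empty(tpb, dtype=object)
        t[:nw] = rng.integers(1, 5, nw)
        r[:nw] = ROLE_WARMUP
        t[nw::2] = pattern_cycle
        r[nw::2] = ROLE_PATTERN
        t[nw + 1 :: 2] = rng.integers(1, 5, n_random)
        r[nw + 1 :: 2] = ROLE_RANDOM
        blocks.append(np.full(tpb, b))
        trials.append(np.arange(1, tpb + 1))
        roles.append(r)
        targets.append(t)

    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "block": np.concatenate(blocks),
            "trial": np.concatenate(trials),
            "role": np.concatenate(roles),
            "target_pos": np.concatenate(targets),
        }
    )


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

#: per-condition accuracy defaults (overall ~92%)
DEFAULT_P_CORRECT: Mapping[str, float] = {PH: 0.927, RH: 0.929, RL: 0.902, EX: 0.92}


@dataclass(frozen=True)
class ParticipantGroundTruth:
    """Generative parameters of one simulated participant.

    The Random-Low RT penalty grows as ``gap(b) = A_true * (1 - exp(-(b -
    x0_true)/tau_true))`` over blocks b; every trial adds Gaussian noise and
    an optional linear practice speed-up common to all conditions.
    """

    A_true: float = 13.25
    x0_true: float = -0.39
    tau_true: float = 10.28
    base_rt_ms: float = 285.0
    practice_slope_ms: float = 0.0
    noise_sd_ms: float = 5.0
    p_correct: float | Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_P_CORRECT))

    def __post_init__(self) -> None:
        if self.tau_true <= 0:
            raise ValueError("tau_true must be > 0")
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be >= 0")
        p = self.p_correct
        vals = p.values() if isinstance(p, Mapping) else [p]
        if not all(0 < v <= 1 for v in vals):
            raise ValueError("p_correct must lie in (0, 1]")

    def gap(self, block: np.ndarray | float) -> np.ndarray | float:
        """Expected Random-Low minus Random-High RT difference at a block."""
        return self.A_true * (1.0 - np.exp(-(np.asarray(block, dtype=float) - self.x0_true) / self.tau_true))


def simulate_responses(
    labeled: pd.DataFrame,
    truth: ParticipantGroundTruth,
    seed: int,
    rt_floor_ms: float = 100.0,
    stream: str = "responses",
) -> pd.DataFrame:
    """Simulate responses and RTs for a condition-labeled trial table.

    Requires a ``condition`` column (run :func:`slcurves.triplets.label_trials`
    first).  Errors get a response drawn uniformly from the three non-target
    positions; RTs are truncated below at ``rt_floor_ms``.
    """
    if "condition" not in labeled.columns:
        raise ValueError("trials must carry a 'condition' column; label them first")
    df = labeled.copy()
    n = len(df)
    rng_rt = substream_rng(seed, f"rt:{stream}")
    rng_acc = substream_rng(seed, f"accuracy:{stream}")

    block = df["block"].to_numpy(dtype=float)
    rt = (
        truth.base_rt_ms
        - truth.practice_slope_ms * (block - 1.0)
        + np.asarray(truth.gap(block)) * (df["condition"] == RL).to_numpy()
        + rng_rt.normal(0.0, truth.noise_sd_ms, n)
    )
    df["rt_ms"] = np.maximum(rt, rt_floor_ms)

    if isinstance(truth.p_correct, Mapping):
        p = df["condition"].map(truth.p_correct).fillna(truth.p_correct.get(EX, 0.92)).to_numpy()
    else:
        p = np.full(n, float(truth.p_correct))
    correct = rng_acc.random(n) < p
    target = df["target_pos"].to_numpy()
    offset = rng_acc.integers(1, 4, n)  # uniform over the three wrong positions
    wrong = ((target - 1 + offset) % 4) + 1
    df["response_pos"] = np.where(correct, target, wrong)
    df["correct"] = correct
    return df


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Population distributions for a simulated cohort.

    Curve parameters are drawn i.i.d. Gaussian around the group-level values
    and clipped to their admissible ranges (tau to [1, 50]).
    """

    n_participants: int = 40
    A_mean: float = 13.25
    A_sd: float = 4.0
    x0_mean: float = -0.39
    x0_sd: float = 0.5
    tau_mean: float = 10.28
    tau_sd: float = 3.0
    base_rt_mean_ms: float = 285.0
    base_rt_sd_ms: float = 6.0
    practice_slope_ms: float = 1.0
    noise_sd_ms: float = 5.0


def draw_ground_truths(spec: CohortSpec, seed: int) -> list[ParticipantGroundTruth]:
    rng = substream_rng(seed, "ground-truth")
    truths = []
    for _ in range(spec.n_participants):
        truths.append(
            ParticipantGroundTruth(
                A_true=float(rng.normal(spec.A_mean, spec.A_sd)),
                x0_true=float(rng.normal(spec.x0_mean, spec.x0_sd)),
                tau_true=float(np.clip(rng.normal(spec.tau_mean, spec.tau_sd), 1.0, 50.0)),
                base_rt_ms=float(rng.normal(spec.base_rt_mean_ms, spec.base_rt_sd_ms)),
                practice_slope_ms=spec.practice_slope_ms,
                noise_sd_ms=spec.noise_sd_ms,
            )
        )
    return truths


def simulate_cohort(
    design: SessionDesign,
    spec: CohortSpec,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[int, ...]]]:
    """Simulate a full cohort: labeled trials with responses, truths, patterns.

    Returns ``(trials, truths, patterns)`` where ``trials`` carries one row
    per presented stimulus (condition-labeled, with responses), ``truths``
    one row of generative parameters per participant, and ``patterns`` maps
    participant id to its counterbalanced pattern permutation.
    """
    truths = draw_ground_truths(spec, seed)
    frames, rows, patterns = [], [], {}
    for i, truth in enumerate(truths):
        pid = f"p{i:03d}"
        pattern = make_pattern_permutation(seed, i)
        patterns[pid] = pattern
        d = replace(design, pattern=pattern)
        targets = generate_session(d, seed, participant_id=pid)
        labeled = label_trials(targets, pattern)
        frames.append(simulate_responses(labeled, truth, seed, stream=pid))
        rows.append(
            {
                "participant_id": pid,
                "A_true": truth.A_true,
                "x0_true": truth.x0_true,
                "tau_true": truth.tau_true,
                "base_rt_ms": truth.base_rt_ms,
                "practice_slope_ms": truth.practice_slope_ms,
                "noise_sd_ms": truth.noise_sd_ms,
            }
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(rows), patterns


# ---------------------------------------------------------------------------
# neuropsychological scores
# ---------------------------------------------------------------------------

#: Table-6 column order of the ten executive-function tests
NEUROPSYCH_TESTS = (
    "Category", "Letter", "CST(F)", "CST(B)", "CBT(F)",
    "CBT(B)", "WCST", "Stroop", "ANT", "GNG",
)

#: default copula targets: (curve parameter, Kendall tau) per test
DEFAULT_NEUROPSYCH_TARGETS: Mapping[str, tuple[str, float]] = {
    "Category": ("A", -0.038),
    "Letter": ("tau", 0.024),
    "CST(F)": ("tau", -0.066),
    "CST(B)": ("A", 0.076),
    "CBT(F)": ("A", 0.268),
    "CBT(B)": ("tau", -0.133),
    "WCST": ("tau", 0.244),
    "Stroop": ("A", -0.087),
    "ANT": ("A", 0.259),
    "GNG": ("A", -0.040),
}

#: plausible raw-score location/scale per test (affects presentation only;
#: rank correlations are invariant to this affine map)
_SCORE_SCALE: Mapping[str, tuple[float, float]] = {
    "Category": (20.0, 5.0), "Letter": (14.0, 4.0), "CST(F)": (5.5, 1.2),
    "CST(B)": (4.5, 1.2), "CBT(F)": (6.0, 1.2), "CBT(B)": (5.5, 1.2),
    "WCST": (4.5, 1.5), "Stroop": (10.0, 8.0), "ANT": (60.0, 25.0),
    "GNG": (0.9, 0.07),
}


def generate_neuropsych_scores(
    params: pd.DataFrame,
    targets: Mapping[str, tuple[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw test scores with requested Kendall correlation to A or tau.

    Gaussian-copula construction: the designated parameter's values are
    mapped to normal scores z via their ranks, and each test's latent score
    is ``rho*z + sqrt(1-rho^2)*eps`` with ``rho = sin(pi*kendall/2)``, so
    the latent pair has the requested Kendall correlation in expectation
    (``tau = (2/pi) * arcsin(rho)`` for bivariate Gaussians).

    Parameters
    ----------
    params
        One row per participant with columns ``participant_id`` and the
        curve parameters named in ``targets`` (``A``, ``tau``; the
        ground-truth columns ``A_true``/``tau_true`` are accepted too).
    targets
        ``{test: (parameter, kendall_tau)}``; defaults to the package's
        study-condition targets.
    """
    targets = dict(DEFAULT_NEUROPSYCH_TARGETS) if targets is None else dict(targets)
    n = len(params)
    out = pd.DataFrame({"participant_id": params["participant_id"].to_numpy()})
    zcache: dict[str, np.ndarray] = {}
    for test, (param, kt) in targets.items():
        if not -1.0 <= kt <= 1.0:
            raise ValueError(f"target correlation for {test} out of [-1, 1]: {kt}")
        col = param if param in params.columns else f"{param}_true"
        if col not in params.columns:
            raise KeyError(f"parameter column {param!r} not found in params")
        if param not in zcache:
            ranks = rankdata(params[col].to_numpy(), method="average")
            zcache[param] = norm.ppf(ranks / (n + 1))
        z = zcache[param]
        rho = np.sin(np.pi * kt / 2.0)
        rng = substream_rng(seed, f"neuropsych:{test}")
        eps = rng.standard_normal(n)
        latent = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        loc, scale = _SCORE_SCALE.get(test, (0.0, 1.0))
        out[test] = loc + scale * latent
    return out
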