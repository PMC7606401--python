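"""Triplet classification and statistical-learning (SL) scores for ASRT sessions.

Every trial is the terminal element of the triplet formed with its two
in-block predecessors.  By the alternation of pattern (P) and random (R)
trials a triplet's roles are either P-R-P (pattern type) or R-P-R (random
type).  Its probability is decided by the *third* trial: high if the third
position is the pattern successor of the first, low otherwise.  The three
observable conditions are therefore Pattern-High (``PH``), Random-High
(``RH``) and Random-Low (``RL``); warm-up trials and trials without two
in-block predecessors are excluded (``EX``).

The per-block SL score is the absolute difference between the Random-Low
and Random-High mean reaction times of correct trials, optionally
normalized by the block's overall mean RT and/or rescaled back to
milliseconds with the participant's grand-mean RT.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical condition codes used throughout the package
PH, RH, RL, EX = "PH", "RH", "RL", "EX"
CONDITIONS = (PH, RH, RL)

#: SL-score scale modes
SL_MODES = ("raw", "normalized", "rescaled")


def _successor_map(pattern: Sequence[int]) -> dict[int, int]:
    if sorted(pattern) != [1, 2, 3, 4]:
        raise ValueError(f"pattern must be a permutation of (1,2,3,4), got {pattern!r}")
    return {pattern[i]: pattern[(i + 1) % 4] for i in range(4)}


class TripletSpace(NamedTuple):
    """All 64 position identities (a, x, b), split by probability."""

    high_identities: frozenset[tuple[int, int, int]]
    low_identities: frozenset[tuple[int, int, int]]


def enumerate_triplet_space(pattern: Sequence[int]) -> TripletSpace:
    """Enumerate the 64 triplet identities under one pattern permutation.

    An identity (a, x, b) is high-probability iff ``b`` is the pattern
    successor of ``a``.  Every valid pattern yields 16 high and 48 low
    identities.
    """
    nxt = _successor_map(pattern)
    high, low = set(), set()
    for a in range(1, 5):
        for x in range(1, 5):
            for b in range(1, 5):
                (high if b == nxt[a] else low).add((a, x, b))
    return TripletSpace(frozenset(high), frozenset(low))


def _check_ordered(trials: pd.DataFrame) -> None:
    key = trials[["participant_id", "block", "trial"]]
    if not key.equals(key.sort_values(["participant_id", "block", "trial"], kind="stable").reset_index(drop=True)):
        raise ValueError("trials must be ordered by (participant_id, block, trial)")


def label_trials(trials: pd.DataFrame, pattern: Sequence[int]) -> pd.DataFrame:
    """Assign each trial the condition of the triplet it terminates.

    Parameters
    ----------
    trials
        Ordered trial table with columns ``participant_id, block, trial,
        role, target_pos`` (one pattern permutation for all rows).
    pattern
        The session's cyclic pattern permutation.

    Returns
    -------
    Copy of ``trials`` with columns ``a, x, b`` (triplet identity; ``<NA>``
    where undefined) and ``condition`` in {PH, RH, RL, EX}.  A trial is EX
    if any triplet member is a warm-up trial or lies outside the block.
    """
    _check_ordered(trials.reset_index(drop=True))
    nxt = _successor_map(pattern)
    df = trials.copy()
    g = df.groupby(["participant_id", "block"], sort=False)
    a = g["target_pos"].shift(2)
    x = g["target_pos"].shift(1)
    role_a = g["role"].shift(2)
    role_x = g["role"].shift(1)

    classifiable = (
        a.notna()
        & (role_a != "warmup")
        & (role_x != "warmup")
        & (df["role"] != "warmup")
    )
    high = df["target_pos"] == a.map(nxt)
    is_pattern = df["role"] == "pattern"

    condition = np.select(
        [
            classifiable & is_pattern & high,
            classifiable & ~is_pattern & high,
            classifiable & ~is_pattern & ~high,
        ],
        [PH, RH, RL],
        default=EX,  # includes the (pattern, low) cell, impossible for well-formed input
    )
    df["a"] = a.astype("Int64")
    df["x"] = x.astype("Int64")
    df["b"] = df["target_pos"]
    df["condition"] = condition
    return df


def label_cohort(trials: pd.DataFrame, patterns: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    """Label a multi-participant trial table, one pattern per participant."""
    parts = []
    for pid, sub in trials.groupby("participant_id", sort=False):
        if pid not in patterns:
            raise KeyError(f"no pattern for participant {pid!r}")
        parts.append(label_trials(sub.reset_index(drop=True), patterns[pid]))
    return pd.concat(parts, ignore_index=True)


def summarize_blocks(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per participant x block x condition summaries.

    Mean RT uses correct trials only; accuracy uses all non-excluded trials
    of the condition.  A cell with zero correct trials gets a missing mean
    (flagged via log, never a crash).
    """
    d = labeled[labeled["condition"].isin(CONDITIONS)].copy()
    d["rt_correct"] = d["rt_ms"].where(d["correct"].astype(bool))
    out = (
        d.groupby(["participant_id", "block", "condition"], sort=True)
        .agg(
            mean_rt_ms=("rt_correct", "mean"),
            n_trials=("rt_ms", "size"),
            n_correct=("correct", "sum"),
        )
        .reset_index()
    )
    out["accuracy"] = out["n_correct"] / out["n_trials"]
    missing = out["mean_rt_ms"].isna()
    if missing.any():
        for _, row in out[missing].iterrows():
            logger.warning(
                "no correct trials for participant=%s block=%s condition=%s; mean RT missing",
                row["participant_id"], row["block"], row["condition"],
            )
    return out


def _weighted_block_means(summaries: pd.DataFrame) -> pd.Series:
    """Overall mean RT of correct trials per (participant, block), all conditions."""
    s = summaries.dropna(subset=["mean_rt_ms"])
    num = (s["mean_rt_ms"] * s["n_correct"]).groupby([s["participant_id"], s["block"]]).sum()
    den = s.groupby(["participant_id", "block"])["n_correct"].sum()
    return num / den


def compute_sl_scores(summaries: pd.DataFrame, mode: str = "rescaled") -> pd.DataFrame:
    """Per-block SL scores for each participant.

    raw
        ``|mean_rt(RL) - mean_rt(RH)|`` in ms.
    normalized
        raw divided by the block's overall mean RT (correct trials, all
        conditions) — dimensionless.
    rescaled
        normalized multiplied by the participant's grand-mean RT, restoring
        an ms-comparable scale while removing block-level speed differences.

    Returns a tidy frame with columns ``participant_id, block, raw,
    normalized, rescaled, sl_score`` where ``sl_score`` is the column picked
    by ``mode``.
    """
    if mode not in SL_MODES:
        raise ValueError(f"mode must be one of {SL_MODES}, got {mode!r}")
    wide = summaries.pivot_table(
        index=["participant_id", "block"], columns="condition", values="mean_rt_ms"
    )
    for cond in (RH, RL):
        if cond not in wide.columns:
            wide[cond] = np.nan
    raw = (wide[RL] - wide[RH]).abs()
    block_mean = _weighted_block_means(summaries).reindex(raw.index)
    normalized = raw / block_mean

    # participant grand-mean RT over all blocks (correct trials, all conditions)
    s = summaries.dropna(subset=["mean_rt_ms"])
    num = (s["mean_rt_ms"] * s["n_correct"]).groupby(s["participant_id"]).sum()
    den = s.groupby("participant_id")["n_correct"].sum()
    grand = (num / den).reindex(raw.index.get_level_values(0)).to_numpy()
    rescaled = normalized * grand

    out = pd.DataFrame(
        {"raw": raw, "normalized": normalized, "rescaled": rescaled}
    ).reset_index()
    n_missing = int(out["raw"].isna().sum())
    if n_missing:
        logger.warning("%d participant-blocks have a missing SL score (missing condition mean)", n_missing)
    out["sl_score"] = out[mode]
    return out


def group_sl_series(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-block mean SL score over participants (missing scores skipped)."""
    g = scores.groupby("block", sort=True)["sl_score"].mean().reset_index()
    return g


def condition_proportions(labeled: pd.DataFrame) -> pd.Series:
    """Fraction of classified (non-EX) trials in each condition."""
    d = labeled[labeled["condition"].isin(CONDITIONS)]
    return d["condition"].value_counts(normalize=True).reindex(list(CONDITIONS)).fillna(0.0)
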