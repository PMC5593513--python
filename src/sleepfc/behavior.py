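"""Scoring of key-press logs into speed, accuracy and variability measures.

Speed is the mean inter-key-press interval for correct responses only;
accuracy is the percentage of incorrect presses per block (a sequence-level
variant is also provided); variability is the sample SD of the retained
inter-press intervals.  The overnight gain contrasts the mean speed of the
last three training blocks (S1) with the first three retest blocks (S2);
positive gains mean faster performance after sleep.

Correctness of MSL presses against the cyclic 5-item sequence uses a
deterministic resynchronization rule: an expected pointer walks the cyclic
sequence; a matching press is correct and advances it; a mismatch is
incorrect and re-anchors the pointer just past the nearest forward position
holding the pressed key (within one cycle), else leaves it in place.

For the CTL task each response is a simultaneous 4-key chord; the onset of
the first of the four presses is the response time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SEQUENCE",
    "UndefinedSpeedError",
    "score_correctness",
    "block_speed",
    "block_accuracy",
    "block_sequence_accuracy",
    "block_variability",
    "behavior_table",
    "overnight_gain",
]

DEFAULT_SEQUENCE = (4, 1, 3, 2, 4)


class UndefinedSpeedError(ValueError):
    """Raised when a block has too few correct presses to define a speed."""


def _condition_of(log: pd.DataFrame) -> str:
    conds = log["condition"].unique()
    if len(conds) != 1:
        raise ValueError(f"log mixes conditions {sorted(conds)}")
    return conds[0]


def score_correctness(
    log: pd.DataFrame, sequence: tuple[int, ...] = DEFAULT_SEQUENCE
) -> pd.Series:
    """Flag each MSL press as correct against the cyclic sequence.

    The pointer-based resynchronization rule is applied independently within
    each block (the sequence restarts at every block onset).
    """
    if _condition_of(log) != "MSL":
        raise ValueError("correctness scoring applies to MSL logs only")
    keys = log["key"].to_numpy()
    if not np.isin(keys, [1, 2, 3, 4]).all():
        bad = sorted(set(keys) - {1, 2, 3, 4})
        raise ValueError(f"unknown key ids: {bad}")
    seq = tuple(sequence)
    L = len(seq)
    flags = np.zeros(len(log), dtype=bool)
    for _, idx in log.groupby(["session", "block"], sort=False).indices.items():
        p = 0
        for row in idx:
            k = keys[row]
            if k == seq[p]:
                flags[row] = True
                p = (p + 1) % L
            else:
                # re-anchor at the nearest forward occurrence of the pressed key
                for j in range(1, L + 1):
                    q = (p + j) % L
                    if seq[q] == k:
                        p = (q + 1) % L
                        break
    return pd.Series(flags, index=log.index, name="correct")


def _block_intervals(
    block: pd.DataFrame, sequence: tuple[int, ...] = DEFAULT_SEQUENCE
) -> np.ndarray:
    """Inter-response intervals retained for speed/variability.

    MSL: intervals between consecutive presses where both are correct
    (intervals spanning an incorrect press are discarded).  CTL: intervals
    between consecutive chord onsets (earliest of the four finger presses).
    """
    cond = _condition_of(block)
    if cond == "CTL":
        onsets = block.groupby("chord", sort=True)["time"].min().to_numpy()
        onsets = np.sort(onsets)
        return np.diff(onsets)
    correct = score_correctness(block, sequence).to_numpy()
    times = block["time"].to_numpy()
    keep = correct[:-1] & correct[1:]
    return np.diff(times)[keep]


def block_speed(
    block: pd.DataFrame, sequence: tuple[int, ...] = DEFAULT_SEQUENCE
) -> float:
    """Mean inter-key-press interval (s) for correct responses in one block."""
    iv = _block_intervals(block, sequence)
    if iv.size < 1:
        raise UndefinedSpeedError(
            "fewer than two correct presses; block speed undefined"
        )
    return float(np.mean(iv))


def block_accuracy(
    block: pd.DataFrame, sequence: tuple[int, ...] = DEFAULT_SEQUENCE
) -> float:
    """Percentage of incorrect key presses in one MSL block."""
    if len(block) == 0:
        raise ValueError("empty block")
    correct = score_correctness(block, sequence).to_numpy()
    return 100.0 * float((~correct).sum()) / len(block)


def block_sequence_accuracy(
    block: pd.DataFrame, sequence: tuple[int, ...] = DEFAULT_SEQUENCE
) -> float:
    """Percentage of fully correct sequences among complete 5-press groups."""
    if len(block) == 0:
        raise ValueError("empty block")
    correct = score_correctness(block, sequence).to_numpy()
    L = len(sequence)
    n_seq = len(correct) // L
    if n_seq == 0:
        raise ValueError("block shorter than one sequence")
    groups = correct[: n_seq * L].reshape(n_seq, L)
    return 100.0 * float(groups.all(axis=1).sum()) / n_seq


def block_variability(
    block: pd.DataFrame, sequence: tuple[int, ...] = DEFAULT_SEQUENCE
) -> float:
    """Sample SD (s) of the retained inter-press intervals in one block."""
    iv = _block_intervals(block, sequence)
    if iv.size < 2:
        raise ValueError("need at least three presses to define variability")
    return float(np.std(iv, ddof=1))


def behavior_table(
    log: pd.DataFrame, sequence: tuple[int, ...] = DEFAULT_SEQUENCE
) -> pd.DataFrame:
    """Per-block speed / accuracy / variability for one or more subjects.

    Accuracy (percent incorrect presses) is reported for MSL blocks; it is
    0.0 for CTL chords, which have no wrong-key notion.
    """
    group_cols = [c for c in ("subject", "condition", "session", "block") if c in log]
    rows = []
    for key, block in log.groupby(group_cols, sort=True):
        rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        cond = _condition_of(block)
        rec["speed"] = block_speed(block, sequence)
        rec["accuracy"] = block_accuracy(block, sequence) if cond == "MSL" else 0.0
        rec["variability"] = block_variability(block, sequence)
        rows.append(rec)
    return pd.DataFrame(rows)


def overnight_gain(
    table: pd.DataFrame,
    subject: str | None = None,
    condition: str = "MSL",
    n_edge_blocks: int = 3,
    n_blocks: int = 14,
) -> tuple[float, float]:
    """Overnight gain in speed: mean(last S1 blocks) - mean(first S2 blocks).

    Returns ``(gain_s, gain_pct)`` where the percentage is relative to the
    end-of-training speed.  Positive values mean faster (shorter intervals)
    after sleep.
    """
    t = table
    if subject is not None:
        t = t[t["subject"] == subject]
    t = t[t["condition"] == condition] if "condition" in t else t
    s1_blocks = list(range(n_blocks - n_edge_blocks + 1, n_blocks + 1))
    s2_blocks = list(range(1, n_edge_blocks + 1))
    s1 = t[(t["session"] == "S1") & (t["block"].isin(s1_blocks))]
    s2 = t[(t["session"] == "S2") & (t["block"].isin(s2_blocks))]
    missing = [("S1", b) for b in s1_blocks if b not in set(s1["block"])]
    missing += [("S2", b) for b in s2_blocks if b not in set(s2["block"])]
    if missing:
        raise ValueError(f"missing blocks for overnight gain: {missing}")
    end_s1 = float(s1["speed"].mean())
    start_s2 = float(s2["speed"].mean())
    gain = end_s1 - start_s2
    return gain, 100.0 * gain / end_s1
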