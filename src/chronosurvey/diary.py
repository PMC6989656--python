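"""Time-use diary parsing: sleep-bout extraction and diary mid-sleep.

The diary is a grid of 48 half-hour slots covering the 24 h window from
06:00 of the reported day to 06:00 of the next morning.  Slot ``i`` covers
the half-open interval ``[06:00 + 0.5*i, 06:00 + 0.5*(i+1))``.  Respondents
may mark several activities per slot; only the sleep flag matters here, and
the adult and youth diary versions reduce to the same boolean grid.

The main sleep bout is the longest maximal run of consecutive sleep slots
(ties broken by earliest start).  A bout touching either edge of the window
(slot 0 or slot 47) is *censored*: the true onset or offset fell outside the
diary window, so no mid-sleep can be reported for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .instruments import centre, wrap_clock

__all__ = [
    "DIARY_START_H",
    "N_SLOTS",
    "SleepBout",
    "main_sleep_bout",
    "diary_midsleep",
    "score_diary_frame",
]

DIARY_START_H = 6.0
SLOT_H = 0.5
N_SLOTS = 48

# Exclusion reason codes used by score_diary_frame.
NO_SLEEP = "NO_SLEEP"
CENSORED = "CENSORED"
NOT_TYPICAL = "NOT_TYPICAL"
BAD_GRID = "BAD_GRID"


@dataclass(frozen=True)
class SleepBout:
    """A contiguous sleep episode extracted from a diary grid.

    ``onset``/``offset`` are clock hours in [0, 24) at the slot boundaries;
    ``duration`` is in hours.  ``censored`` marks bouts truncated by the
    diary window, for which no mid-sleep is reported.
    """

    onset: float
    offset: float
    duration: float
    censored: bool


def _slot_runs(slots: np.ndarray):
    """Yield (start, stop) index pairs of maximal runs of True values."""
    padded = np.concatenate(([False], slots, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def main_sleep_bout(slots: Sequence[bool]) -> Optional[SleepBout]:
    """Extract the main sleep bout from 48 half-hour sleep flags.

    Returns the longest maximal run of consecutive sleep slots (earliest
    start wins ties), or ``None`` when no slot is marked.  The bout is
    censored when it includes slot 0 or slot 47, i.e. when sleep was
    truncated by the 06:00 -> 06:00 diary window.
    """
    arr = np.asarray(slots, dtype=bool)
    if arr.shape != (N_SLOTS,):
        raise ValueError(f"diary grid must have exactly {N_SLOTS} slots, got {arr.shape}")
    runs = _slot_runs(arr)
    if not runs:
        return None
    # max() is stable over ties, so the earliest start wins.
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    onset = wrap_clock(DIARY_START_H + SLOT_H * start)
    offset = wrap_clock(DIARY_START_H + SLOT_H * stop)
    duration = SLOT_H * (stop - start)
    censored = start == 0 or stop == N_SLOTS
    return SleepBout(onset, offset, duration, censored)


def diary_midsleep(bout: SleepBout) -> float:
    """Mid-sleep of an uncensored bout, in hours centred on midnight."""
    if bout.censored:
        raise ValueError("mid-sleep is undefined for a censored sleep bout")
    return centre(bout.onset + bout.duration / 2.0)


def score_diary_frame(diary: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a diary table to per-subject mid-sleep values.

    Parameters
    ----------
    diary : DataFrame
        One row per diary with columns ``subject_id``, ``is_typical_day``,
        ``is_free_day``, ``version`` and slot flags ``s00`` .. ``s47``
        (0/1).

    Returns
    -------
    scores, exclusions : DataFrame
        ``scores`` has columns ``subject_id``, ``midsleep`` (hours centred
        on midnight), ``day_type`` (``"free"`` -> MSF, ``"work"`` -> MSW),
        ``onset``, ``offset``, ``duration``.  ``exclusions`` lists every
        dropped row with a ``reason`` code; the two row counts always add
        up to the input row count.
    """
    slot_cols = [f"s{i:02d}" for i in range(N_SLOTS)]
    missing = [c for c in ["subject_id", "is_typical_day", "is_free_day"] + slot_cols
               if c not in diary.columns]
    if missing:
        raise ValueError(f"diary table missing columns: {missing}")

    scores, excluded = [], []
    slot_matrix = diary[slot_cols].to_numpy()
    for pos, (_, row) in enumerate(diary.iterrows()):
        sid = row["subject_id"]
        if not bool(row["is_typical_day"]):
            excluded.append((sid, NOT_TYPICAL))
            continue
        bout = main_sleep_bout(slot_matrix[pos].astype(bool))
        if bout is None:
            excluded.append((sid, NO_SLEEP))
            continue
        if bout.censored:
            excluded.append((sid, CENSORED))
            continue
        scores.append(
            {
                "subject_id": sid,
                "midsleep": diary_midsleep(bout),
                "day_type": "free" if bool(row["is_free_day"]) else "work",
                "onset": bout.onset,
                "offset": bout.offset,
                "duration": bout.duration,
            }
        )
    scores_df = pd.DataFrame(
        scores, columns=["subject_id", "midsleep", "day_type", "onset", "offset", "duration"]
    )
    excl_df = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    assert len(scores_df) + len(excl_df) == len(diary)
    return scores_df, excl_df
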