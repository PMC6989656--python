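"""Clock-time arithmetic and questionnaire instruments.

Two chronotype instruments are scored here:

* the sleep-timing questionnaire (MCTQ-style items for work and free days),
  yielding the mid-sleep phases MSW/MSF and the sleep-debt-corrected MSFsc;
* the self-assessed best-alertness interval, yielding its midpoint BAmid.

Clock times are plain floats in **hours since midnight**, wrapped modulo 24.
Mid-sleep phases are expressed in **hours centred on midnight**, i.e. mapped
to the half-open interval [-12, 12) so that 03:07:30 becomes 3.125 and 23:00
becomes -1.0.  All intervals are half-open: a slot or interval includes its
start and excludes its end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "wrap_clock",
    "centre",
    "uncentre",
    "parse_hhmm",
    "format_hhmm",
    "sleep_onset",
    "bamid",
    "MctqRecord",
    "MctqScores",
    "score_mctq",
    "mctq_eligible",
]

#: Plausibility bounds on a single sleep episode, hours.  Durations at or
#: outside these bounds are rejected as data errors.
DURATION_BOUNDS = (0.0, 16.0)

#: Sleep latencies this long are treated as reporting errors.
MAX_LATENCY_H = 6.0


def wrap_clock(hours):
    """Wrap an hour value onto the clock face [0, 24)."""
    return np.asarray(hours, dtype=float) % 24.0 if np.ndim(hours) else float(hours) % 24.0


def centre(clock_hours):
    """Map clock hours [0, 24) to hours centred on midnight [-12, 12).

    The inverse of :func:`uncentre`; e.g. ``centre(23.0) == -1.0`` and
    ``centre(3.125) == 3.125``.
    """
    h = np.asarray(clock_hours, dtype=float)
    out = (h + 12.0) % 24.0 - 12.0
    return out if h.ndim else float(out)


def uncentre(centred_hours):
    """Map hours centred on midnight [-12, 12) back to clock hours [0, 24)."""
    h = np.asarray(centred_hours, dtype=float)
    out = h % 24.0
    return out if h.ndim else float(out)


def parse_hhmm(text: str) -> float:
    """Parse a 24-hour ``HH:MM`` string into hours since midnight.

    Raises :class:`ValueError` for malformed strings or out-of-range fields
    (hour 24 is not a valid clock reading; midnight is ``00:00``).
    """
    parts = str(text).strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"not an HH:MM time: {text!r}")
    hh, mm = int(parts[0]), int(parts[1])
    if not (0 <= hh <= 23 and 0 <= mm <= 59):
        raise ValueError(f"clock time out of range: {text!r}")
    return hh + mm / 60.0


def format_hhmm(hours: float) -> str:
    """Render hours-since-midnight as ``HH:MM`` (rounded to the minute)."""
    total = int(round(wrap_clock(hours) * 60.0)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


def sleep_onset(prep: float, latency: float) -> float:
    """Sleep onset from time of preparing to sleep plus sleep latency.

    Parameters are clock hours and a latency duration in hours; the result
    wraps past midnight.  Latencies outside [0, 6) hours are rejected.
    """
    if not 0.0 <= latency < MAX_LATENCY_H:
        raise ValueError(f"sleep latency must be in [0, {MAX_LATENCY_H}) h, got {latency}")
    return wrap_clock(prep + latency)


def bamid(start: float, end: float) -> float:
    """Midpoint of a best-alertness interval, as clock hours in [0, 24).

    The midpoint is taken along the forward arc from ``start`` to ``end`` so
    that intervals crossing midnight are handled naturally: (22, 2) -> 0.0.
    A zero-length interval returns its endpoint.
    """
    length = (end - start) % 24.0
    return wrap_clock(start + length / 2.0)


@dataclass(frozen=True)
class MctqRecord:
    """Raw sleep-timing questionnaire answers for one respondent.

    Attributes
    ----------
    workdays_per_week : int
        Number of workdays per week (WD), 0-7.
    work_sleep_prep, free_sleep_prep : float
        Clock hour of getting ready to fall asleep on work / free days.
    work_latency, free_latency : float
        Sleep latency in hours (>= 0).
    work_sleep_end, free_sleep_end : float
        Clock hour of sleep end (SEw / SEf).
    alarm_free : bool
        True if the respondent needs an alarm clock on free days.
    wakes_before_alarm_work : bool
        True if the respondent regularly wakes without or before the alarm
        on work days.
    """

    workdays_per_week: int
    work_sleep_prep: float
    work_latency: float
    work_sleep_end: float
    free_sleep_prep: float
    free_latency: float
    free_sleep_end: float
    alarm_free: bool = False
    wakes_before_alarm_work: bool = False

    def __post_init__(self):
        if not 0 <= self.workdays_per_week <= 7:
            raise ValueError(f"workdays_per_week must be 0-7, got {self.workdays_per_week}")


@dataclass(frozen=True)
class MctqScores:
    """Derived sleep-timing quantities for one respondent.

    Durations are in hours; mid-sleep phases in hours centred on midnight.
    ``social_jetlag`` (|MSF - MSW|, circular) is carried as a convenience
    column only.
    """

    sleep_onset_work: float
    sleep_onset_free: float
    sd_work: float
    sd_free: float
    sd_week: float
    msw: float
    msf: float
    msfsc: float
    social_jetlag: float


def _check_duration(label: str, value: float) -> None:
    lo, hi = DURATION_BOUNDS
    if not lo < value < hi:
        raise ValueError(f"{label} = {value:.3f} h outside plausible range ({lo}, {hi})")


def score_mctq(rec: MctqRecord) -> MctqScores:
    """Score a sleep-timing record to mid-sleep phases.

    SDx = (SEx - SOx) mod 24 for work/free days; MSF and MSW are the
    mid-points of the free- and work-day sleep episodes, centred on
    midnight.  The weekly average sleep duration is
    ``SDweek = (WD * SDw + (7 - WD) * SDf) / 7``, and the sleep-debt
    corrected chronotype is::

        MSFsc = MSF - (SDf - SDweek) / 2   if SDf > SDw
        MSFsc = MSF                        otherwise

    i.e. free-day mid-sleep is pulled earlier by half the sleep extension
    attributable to workday sleep restriction.
    """
    so_w = sleep_onset(rec.work_sleep_prep, rec.work_latency)
    so_f = sleep_onset(rec.free_sleep_prep, rec.free_latency)
    sd_w = (rec.work_sleep_end - so_w) % 24.0
    sd_f = (rec.free_sleep_end - so_f) % 24.0
    _check_duration("work sleep duration", sd_w)
    _check_duration("free sleep duration", sd_f)

    wd = rec.workdays_per_week
    sd_week = (wd * sd_w + (7 - wd) * sd_f) / 7.0
    msw = centre(so_w + sd_w / 2.0)
    msf = centre(so_f + sd_f / 2.0)
    msfsc = msf - (sd_f - sd_week) / 2.0 if sd_f > sd_w else msf
    sjl = abs(centre(msf - msw))
    return MctqScores(so_w, so_f, sd_w, sd_f, sd_week, msw, msf, msfsc, sjl)


def mctq_eligible(rec: MctqRecord) -> bool:
    """Whether the sleep-debt corrected chronotype is interpretable.

    MSFsc assumes free-day sleep is unconstrained: it is reported only for
    respondents who either do not need an alarm on free days, or regularly
    wake without/before their alarm on work days.
    """
    return (not rec.alarm_free) or rec.wakes_before_alarm_work
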