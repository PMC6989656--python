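"""I/O, validation and the end-to-end survey pipeline.

Stage order mirrors the analysis design: simulate (optional) -> score the
questionnaire and alertness instruments -> extract diary mid-sleeps ->
normalize for age/sex -> categorize extreme deciles -> run the association
battery.  Every stage reports row counts in/out and quarantines invalid
rows with reason codes instead of silently dropping them; a
:class:`RunManifest` ties the whole run together for reproducibility.

CSV dialect: UTF-8, comma separated, mandatory header row, times as 24-hour
``HH:MM``, booleans as 0/1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import diary as diary_mod
from .associations import AssociationBattery
from .instruments import MctqRecord, bamid, mctq_eligible, parse_hhmm, score_mctq
from .normalization import DEFAULT_CURVES, ChronotypeDecayModel, categorize_deciles, msfsasc
from .synthetic import GeneratorConfig, SyntheticSurvey, generate

__all__ = [
    "SCHEMAS",
    "read_validate",
    "score_bundle",
    "score_mctq_table",
    "score_alertness_table",
    "build_subject_table",
    "run_pipeline",
    "RunManifest",
]

log = logging.getLogger("chronosurvey")

# reason codes
MISSING = "MISSING"
TYPE_ERROR = "TYPE"
CLOCK_RANGE = "CLOCK_RANGE"
DURATION_RANGE = "DURATION_RANGE"
BOOL_RANGE = "BOOL_RANGE"
VALUE_RANGE = "VALUE_RANGE"

#: Column kind -> (parser, reason code).  Parsers raise ValueError on bad input.


def _parse_bool01(v):
    iv = int(v)
    if iv not in (0, 1):
        raise ValueError(f"not 0/1: {v!r}")
    return iv


def _parse_latency_min(v):
    fv = float(v)
    if not 0 <= fv < 360:
        raise ValueError(f"latency minutes out of range: {v!r}")
    return fv


def _parse_pos_float(v):
    fv = float(v)
    if not np.isfinite(fv) or fv <= 0:
        raise ValueError(f"not a positive number: {v!r}")
    return fv


_KINDS = {
    "hhmm": (parse_hhmm, CLOCK_RANGE),
    "latency_min": (_parse_latency_min, DURATION_RANGE),
    "bool01": (_parse_bool01, BOOL_RANGE),
    "int": (int, TYPE_ERROR),
    "float": (float, TYPE_ERROR),
    "pos_float": (_parse_pos_float, VALUE_RANGE),
    "str": (str, TYPE_ERROR),
}

SCHEMAS: Mapping[str, Mapping[str, str]] = {
    "mctq": {
        "subject_id": "int",
        "wd": "int",
        "work_prep_hhmm": "hhmm",
        "work_latency_min": "latency_min",
        "work_end_hhmm": "hhmm",
        "free_prep_hhmm": "hhmm",
        "free_latency_min": "latency_min",
        "free_end_hhmm": "hhmm",
        "alarm_free": "bool01",
        "wakes_before_alarm_work": "bool01",
    },
    "alertness": {
        "subject_id": "int",
        "best_start_hhmm": "hhmm",
        "best_end_hhmm": "hhmm",
    },
    "demographics": {
        "subject_id": "int",
        "age": "float",
        "sex": "str",
        "latitude": "float",
        "longitude": "float",
        "settlement_size": "pos_float",
    },
    "biomarkers": {
        "subject_id": "int",
        "hdl": "pos_float",
        "ldl": "pos_float",
    },
}


def read_validate(path, schema: Mapping[str, str]):
    """Read a CSV and validate it against a column schema.

    Returns ``(table, issues)``: ``table`` holds the typed valid rows (time
    columns parsed to float hours), ``issues`` quarantines every invalid
    row with ``row`` (0-based input position), ``column`` and ``reason``
    code.  Missing mandatory columns raise immediately.
    """
    raw = pd.read_csv(path, dtype=object)
    missing_cols = [c for c in schema if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory columns {missing_cols}")

    parsed: dict[str, list] = {c: [] for c in raw.columns}
    issues = []
    keep = []
    for pos, row in enumerate(raw.itertuples(index=False)):
        row = dict(zip(raw.columns, row))
        row_ok = True
        converted = {}
        for col, kind in schema.items():
            value = row[col]
            if pd.isna(value) or (isinstance(value, str) and not value.strip()):
                issues.append({"row": pos, "column": col, "reason": MISSING})
                row_ok = False
                continue
            parser, code = _KINDS[kind]
            try:
                converted[col] = parser(value)
            except (ValueError, TypeError):
                issues.append({"row": pos, "column": col, "reason": code})
                row_ok = False
        if row_ok:
            keep.append(pos)
            for col in raw.columns:
                parsed[col].append(converted.get(col, row[col]))
    table = pd.DataFrame({c: parsed[c] for c in raw.columns})
    issues_df = pd.DataFrame(issues, columns=["row", "column", "reason"])
    return table, issues_df


def score_mctq_table(mctq: pd.DataFrame):
    """Score a parsed questionnaire table to per-subject mid-sleep phases.

    Returns ``(scores, exclusions)``.  ``msfsc`` is reported only for
    eligible respondents (free sleepers); ineligible rows keep their MSF/
    MSW but carry ``eligible = 0`` and a null ``msfsc``.  Rows violating
    duration plausibility are quarantined with reason ``DURATION_RANGE``.
    """
    rows, excluded = [], []
    for row in mctq.itertuples(index=False):
        rec = MctqRecord(
            workdays_per_week=int(row.wd),
            work_sleep_prep=float(row.work_prep_hhmm),
            work_latency=float(row.work_latency_min) / 60.0,
            work_sleep_end=float(row.work_end_hhmm),
            free_sleep_prep=float(row.free_prep_hhmm),
            free_latency=float(row.free_latency_min) / 60.0,
            free_sleep_end=float(row.free_end_hhmm),
            alarm_free=bool(row.alarm_free),
            wakes_before_alarm_work=bool(row.wakes_before_alarm_work),
        )
        try:
            scores = score_mctq(rec)
        except ValueError:
            excluded.append({"subject_id": row.subject_id, "reason": DURATION_RANGE})
            continue
        eligible = mctq_eligible(rec)
        rows.append({
            "subject_id": row.subject_id,
            "msw": scores.msw,
            "msf": scores.msf,
            "msfsc": scores.msfsc if eligible else np.nan,
            "sd_work": scores.sd_work,
            "sd_free": scores.sd_free,
            "social_jetlag": scores.social_jetlag,
            "eligible": int(eligible),
        })
    return (
        pd.DataFrame(rows, columns=["subject_id", "msw", "msf", "msfsc", "sd_work",
                                    "sd_free", "social_jetlag", "eligible"]),
        pd.DataFrame(excluded, columns=["subject_id", "reason"]),
    )


def score_alertness_table(alertness: pd.DataFrame) -> pd.DataFrame:
    """Compute the best-alertness midpoint for every interval record."""
    vals = [
        bamid(float(row.best_start_hhmm), float(row.best_end_hhmm))
        for row in alertness.itertuples(index=False)
    ]
    return pd.DataFrame({"subject_id": alertness["subject_id"].to_numpy(), "bamid": vals})


def score_bundle(survey: SyntheticSurvey) -> dict:
    """Score a synthetic bundle in memory through the standard readers.

    Parses the HH:MM columns exactly as the CSV readers would and runs the
    questionnaire, alertness and diary scorers.  Returns a dict with keys
    ``scores``, ``alertness_scores``, ``diary_scores``, ``mctq_exclusions``,
    ``diary_exclusions``.
    """
    mctq = survey.mctq.copy()
    for col in ("work_prep_hhmm", "work_end_hhmm", "free_prep_hhmm", "free_end_hhmm"):
        mctq[col] = mctq[col].map(parse_hhmm)
    alert = survey.alertness.copy()
    for col in ("best_start_hhmm", "best_end_hhmm"):
        alert[col] = alert[col].map(parse_hhmm)
    scores, mctq_excl = score_mctq_table(mctq)
    alert_scores = score_alertness_table(alert)
    diary_scores, diary_excl = diary_mod.score_diary_frame(survey.diary)
    return {
        "scores": scores,
        "alertness_scores": alert_scores,
        "diary_scores": diary_scores,
        "mctq_exclusions": mctq_excl,
        "diary_exclusions": diary_excl,
    }


def build_subject_table(scores: pd.DataFrame, alertness_scores: pd.DataFrame,
                        demographics: pd.DataFrame,
                        biomarkers: Optional[pd.DataFrame] = None,
                        curves=None, reference: str = "pooled") -> pd.DataFrame:
    """Merge instrument scores with demographics into the analysis table.

    Adds the age/sex-normalized chronotype ``msfsasc`` (for eligible adults
    with known sex) and the extreme-decile ``category``.
    """
    curves = DEFAULT_CURVES if curves is None else curves
    table = demographics.merge(scores, on="subject_id", how="left")
    table = table.merge(alertness_scores, on="subject_id", how="left")
    if biomarkers is not None and len(biomarkers):
        table = table.merge(biomarkers, on="subject_id", how="left")
    else:
        table["hdl"] = np.nan
        table["ldl"] = np.nan

    ok = (
        table["msfsc"].notna()
        & table["age"].notna()
        & table["sex"].isin(list(curves))
        & (table["age"] >= 18)
    )
    table["msfsasc"] = np.nan
    if ok.any():
        table.loc[ok, "msfsasc"] = msfsasc(
            table.loc[ok, "msfsc"].to_numpy(dtype=float),
            table.loc[ok, "age"].to_numpy(dtype=float),
            table.loc[ok, "sex"].to_numpy(),
            curves=curves, reference=reference,
        )
    table["category"] = None
    valid = table["msfsasc"].notna()
    if valid.sum() >= 10:
        table.loc[valid, "category"] = categorize_deciles(
            table.loc[valid, "msfsasc"].to_numpy(dtype=float)
        )
    return table


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    config_hash: str
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @staticmethod
    def digest(path) -> str:
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        return h.hexdigest()


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "chronosurvey": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(config: GeneratorConfig, outdir, seed: Optional[int] = None,
                 fit_decay: bool = False) -> RunManifest:
    """Simulate, score, normalize, categorize and analyze in one run.

    Writes the raw bundle under ``outdir/data``, stage outputs under
    ``outdir``, and ``manifest.json``.  Deterministic for fixed
    ``(config, seed)``.
    """
    outdir = Path(outdir)
    datadir = outdir / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed

    survey = generate(config, seed=seed)
    paths = survey.write(datadir)

    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(seed=int(seed), config_hash=cfg_hash, versions=_versions())
    manifest.input_digests = {name: RunManifest.digest(p) for name, p in paths.items()}

    mctq, mctq_issues = read_validate(paths["mctq"], SCHEMAS["mctq"])
    alertness, alert_issues = read_validate(paths["alertness"], SCHEMAS["alertness"])
    demo, demo_issues = read_validate(paths["demographics"], SCHEMAS["demographics"])
    bio, bio_issues = read_validate(paths["biomarkers"], SCHEMAS["biomarkers"])

    scores, score_excl = score_mctq_table(mctq)
    alert_scores = score_alertness_table(alertness)
    diary_scores, diary_excl = diary_mod.score_diary_frame(pd.read_csv(paths["diary"]))

    curves = config.decay_curves
    if fit_decay:
        merged = scores.merge(demo[["subject_id", "age", "sex"]], on="subject_id")
        merged = merged.dropna(subset=["msfsc", "age"])
        curves = {}
        for sex in ("men", "women"):
            sub = merged[merged["sex"] == sex]
            res = ChronotypeDecayModel(sub["age"], sub["msfsc"], sex=sex).fit()
            curves[sex] = res.curve

    table = build_subject_table(scores, alert_scores, demo, bio, curves=curves)
    battery = AssociationBattery(table).run()

    scores.to_csv(outdir / "scores.csv", index=False)
    alert_scores.to_csv(outdir / "alertness_scores.csv", index=False)
    diary_scores.to_csv(outdir / "diary_scores.csv", index=False)
    table.to_csv(outdir / "subjects.csv", index=False)
    battery.to_frame().to_csv(outdir / "battery.csv", index=False)

    manifest.stage_counts = {
        "mctq_in": int(len(mctq)) + int(mctq_issues["row"].nunique() if len(mctq_issues) else 0),
        "mctq_scored": int(len(scores)),
        "mctq_eligible": int(scores["eligible"].sum()),
        "alertness_scored": int(len(alert_scores)),
        "diary_in": int(len(diary_scores) + len(diary_excl)),
        "diary_scored": int(len(diary_scores)),
        "subjects": int(len(table)),
        "battery_analyses": int(len(battery.to_frame())),
    }
    manifest.exclusions = {
        "mctq_validation": {
            r: int(c) for r, c in mctq_issues["reason"].value_counts().items()
        } if len(mctq_issues) else {},
        "mctq_scoring": {
            r: int(c) for r, c in score_excl["reason"].value_counts().items()
        } if len(score_excl) else {},
        "diary": {
            r: int(c) for r, c in diary_excl["reason"].value_counts().items()
        } if len(diary_excl) else {},
        "validation_other": int(len(alert_issues) + len(demo_issues) + len(bio_issues)),
    }
    manifest.to_json(outdir / "manifest.json")
    return manifest
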