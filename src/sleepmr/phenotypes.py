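"""Deterministic phenotype and outcome derivation rules.

Turns questionnaire responses into the binary sleep-trait variables
(insomnia symptoms, short/long sleep, morning chronotype) used as MR
exposures, and diagnosis/death records into incident-versus-prevalent
myocardial-infarction status with follow-up time.

Every classifier is a pure, total function on its declared response
vocabulary; anything outside it raises rather than guessing.  Responses
that the study design treats as uninformative map to ``MISSING``.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from typing import Iterable

DAYS_PER_YEAR = 365.25

# ICD-9 prefix 410 and ICD-10 prefixes I21/I22 identify acute myocardial
# infarction in hospital and cause-of-death records.
AMI_ICD_PREFIXES = ("410", "I21", "I22")


class TriState(enum.Enum):
    YES = "yes"
    NO = "no"
    MISSING = "missing"


def _norm(text: str) -> str:
    """Normalize curly quotes/apostrophes and case for matching."""
    return (
        text.strip()
        .replace("‘", "'")
        .replace("’", "'")
        .replace("“", '"')
        .replace("”", '"')
        .lower()
    )


_INSOMNIA_UKBB = {
    "never/rarely": TriState.NO,
    "sometimes": TriState.NO,
    "usually": TriState.YES,
    "prefer not to answer": TriState.MISSING,
}


def classify_insomnia_ukbb(response: str) -> TriState:
    """UK-Biobank-style single question on trouble falling/staying asleep.

    "Usually" is insomnia symptoms; "Never/rarely" or "Sometimes" is not;
    "Prefer not to answer" is missing.
    """
    key = _norm(response)
    if key not in _INSOMNIA_UKBB:
        raise ValueError(f"unknown insomnia response {response!r}")
    return _INSOMNIA_UKBB[key]


_HUNT_POSITIVE = {"often", "almost every night"}
_HUNT_NEGATIVE = {"never", "sometimes"}


def classify_insomnia_hunt2(
    q_fall_asleep: str | None, q_wake_early: str | None
) -> TriState:
    """Two-question (difficulty falling asleep / waking too early) rule.

    "Often" or "Almost every night" on either question means insomnia
    symptoms, even if the other question is unanswered.  A single
    "Never"/"Sometimes" answer with the other question unanswered is
    excluded (missing) to avoid misclassification; both answered without
    a positive response is no; both unanswered is missing.
    """
    answers = []
    for ans in (q_fall_asleep, q_wake_early):
        if ans is None:
            answers.append(None)
            continue
        key = _norm(ans)
        if key not in _HUNT_POSITIVE | _HUNT_NEGATIVE:
            raise ValueError(f"unknown insomnia response {ans!r}")
        answers.append(key)
    if any(a in _HUNT_POSITIVE for a in answers if a is not None):
        return TriState.YES
    n_answered = sum(a is not None for a in answers)
    if n_answered == 2:
        return TriState.NO
    return TriState.MISSING


@dataclass(frozen=True)
class SleepDurationVars:
    duration: int | None
    short: TriState
    long: TriState


def derive_sleep_duration_vars(hours: int) -> SleepDurationVars:
    """Sleep-duration variable plus short/long binary contrasts.

    Responses below 3 or above 18 hours are implausible and excluded.
    Short sleep contrasts <=6 h against the 7-8 h reference; long sleep
    contrasts >=9 h against the same reference.  A short sleeper is not
    part of the long-sleep contrast and vice versa, hence MISSING there.
    """
    if isinstance(hours, bool) or not isinstance(hours, (int,)):
        raise ValueError(f"sleep duration must be an integer, got {hours!r}")
    if hours < 3 or hours > 18:
        return SleepDurationVars(None, TriState.MISSING, TriState.MISSING)
    if hours <= 6:
        return SleepDurationVars(hours, TriState.YES, TriState.MISSING)
    if hours >= 9:
        return SleepDurationVars(hours, TriState.MISSING, TriState.YES)
    return SleepDurationVars(hours, TriState.NO, TriState.NO)


_CHRONOTYPE = {
    "definitely a 'morning' person": TriState.YES,
    "more a 'morning' than 'evening' person": TriState.YES,
    "more an 'evening' than a 'morning' person": TriState.NO,
    "definitely an 'evening' person": TriState.NO,
    "do not know": TriState.MISSING,
    "prefer not to answer": TriState.MISSING,
}


def classify_chronotype_ukbb(response: str) -> TriState:
    """Morning (yes) versus evening (no) chronotype from self-report."""
    key = _norm(response)
    if key not in _CHRONOTYPE:
        raise ValueError(f"unknown chronotype response {response!r}")
    return _CHRONOTYPE[key]


# ---------------------------------------------------------------------------
# outcome derivation


@dataclass(frozen=True)
class DiagnosisRecord:
    sample_id: str
    code: str
    date: _dt.date
    source: str = "hospital"  # or "death"

    def __post_init__(self):
        if not self.code or not str(self.code).strip():
            raise ValueError("empty diagnosis code")
        if not isinstance(self.date, _dt.date):
            raise ValueError("date must be a datetime.date")


def normalize_icd(code: str) -> str:
    """Uppercase and strip dots: 'I21.4' -> 'I214'."""
    cleaned = str(code).strip().upper().replace(".", "")
    if not cleaned or not cleaned[0].isalnum():
        raise ValueError(f"malformed ICD code {code!r}")
    return cleaned


def is_ami_code(code: str) -> bool:
    return normalize_icd(code).startswith(AMI_ICD_PREFIXES)


@dataclass(frozen=True)
class FollowupResult:
    status: str  # "prevalent" | "incident" | "censored"
    time: float  # years from enrolment
    event: int


def derive_followup(
    enrolment_date: _dt.date,
    diagnoses: Iterable[DiagnosisRecord],
    death_date: _dt.date | None = None,
    death_cause_code: str | None = None,
    end_of_followup_date: _dt.date | None = None,
) -> FollowupResult:
    """Incident/prevalent/censored status and follow-up time for one person.

    The earliest AMI-matching hospital or death record decides: on or
    before enrolment it makes the person a prevalent case (analysis
    exclusion); after enrolment it is the incident event.  Otherwise the
    person is censored at the earlier of death and the administrative
    end of follow-up.
    """
    if end_of_followup_date is None:
        raise ValueError("end_of_followup_date is required")

    ami_dates = [d.date for d in diagnoses if is_ami_code(d.code)]
    if death_date is not None and death_cause_code is not None:
        if is_ami_code(death_cause_code):
            ami_dates.append(death_date)

    if ami_dates:
        first_ami = min(ami_dates)
        if first_ami <= enrolment_date:  # tie on enrolment day: prevalent
            return FollowupResult("prevalent", 0.0, 0)
        t = (first_ami - enrolment_date).days / DAYS_PER_YEAR
        return FollowupResult("incident", t, 1)

    end = end_of_followup_date
    if death_date is not None and death_date < end:
        end = death_date
    t = (end - enrolment_date).days / DAYS_PER_YEAR
    if t <= 0:
        raise ValueError("censoring date not after enrolment")
    return FollowupResult("censored", t, 0)


@dataclass(frozen=True)
class ParticipantFlow:
    """Cohort accounting after the prevalent-case exclusion.

    ``incident = ever_diagnosed - prevalent`` and the analysis set is
    the genotyped cohort minus prevalent cases; the incidence is
    incident cases as a percentage of the analysis set.
    """

    total: int
    ever_diagnosed: int
    prevalent: int

    @property
    def incident(self) -> int:
        return self.ever_diagnosed - self.prevalent

    @property
    def analysis_n(self) -> int:
        return self.total - self.prevalent

    @property
    def incidence_pct(self) -> float:
        return 100.0 * self.incident / self.analysis_n

    def __post_init__(self):
        if not 0 <= self.prevalent <= self.ever_diagnosed <= self.total:
            raise ValueError("inconsistent participant-flow counts")


def derive_followup_table(
    pheno: "pd.DataFrame",
    diagnoses: "pd.DataFrame",
    end_of_followup_date: _dt.date,
) -> "pd.DataFrame":
    """Vectorized wrapper: per-sample follow-up from long-format records.

    ``pheno`` needs sample_id and enrolment_date columns (ISO dates);
    optional death_date / death_cause_code.  ``diagnoses`` is long
    format with sample_id, code, date, source.
    """
    import pandas as pd

    diag_by_sample: dict[str, list[DiagnosisRecord]] = {}
    for r in diagnoses.itertuples():
        diag_by_sample.setdefault(str(r.sample_id), []).append(
            DiagnosisRecord(
                sample_id=str(r.sample_id),
                code=str(r.code),
                date=_parse_date(r.date),
                source=getattr(r, "source", "hospital"),
            )
        )
    rows = []
    for r in pheno.itertuples():
        res = derive_followup(
            enrolment_date=_parse_date(r.enrolment_date),
            diagnoses=diag_by_sample.get(str(r.sample_id), []),
            death_date=_parse_date(getattr(r, "death_date", None)),
            death_cause_code=_opt_str(getattr(r, "death_cause_code", None)),
            end_of_followup_date=end_of_followup_date,
        )
        rows.append(
            {
                "sample_id": r.sample_id,
                "status": res.status,
                "time": res.time,
                "event": res.event,
                "prevalent": int(res.status == "prevalent"),
            }
        )
    return pd.DataFrame(rows)


def _parse_date(value) -> _dt.date | None:
    if value is None:
        return None
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        if value != value:  # NaN
            return None
    except TypeError:
        pass
    return _dt.date.fromisoformat(str(value))


def _opt_str(value) -> str | None:
    if value is None:
        return None
    try:
        if value != value:
            return None
    except TypeError:
        pass
    s = str(value).strip()
    return s or None
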