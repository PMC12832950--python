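"""Per-trial summary effects: records, log-scale conversion, analysis sets.

The analysis-scale datum for trial-level surrogacy is the pair of log
hazard ratios (surrogate endpoint, true endpoint) with their standard
errors.  Standard errors are recovered from published 95% confidence
intervals via the normal approximation on the log scale,
``se = (ln(ucl) - ln(lcl)) / (2 * z)``, using the exact normal quantile
rather than the rounded 1.96.

The module also bundles, as a packaged fixture, the summary-effect table
for the eleven first-line mCRPC randomized trials that jointly reported
radiographic progression-free survival (rPFS) and overall survival (OS),
together with the named analysis sets used throughout the package
(primary = proportional-hazards-compliant trials; sensitivity sets that
re-include the PH violator or additionally drop outlying trials).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "TrialRecord",
    "EffectPair",
    "AnalysisSet",
    "DEFAULT_OUTLIER_IDS",
    "read_trial_table",
    "write_trial_table",
    "to_effect",
    "to_effects",
    "fixture_table",
    "build_analysis_set",
]

#: trials excluded from the second sensitivity set on top of PH violators
DEFAULT_OUTLIER_IDS = ("NCT02294461", "ERA 223")


@dataclass(frozen=True)
class TrialRecord:
    """Summary treatment effects of one randomized comparison.

    Hazard ratios are intervention vs comparator; ``ci_*`` are the
    published two-sided confidence limits at ``level``.  ``ph_ok_*``
    indicate whether the proportional-hazards assumption held for the
    endpoint; a violation on either endpoint excludes the trial from the
    primary analysis set.
    """

    trial_id: str
    n_patients: int
    hr_surrogate: float
    ci_surrogate: tuple[float, float]
    hr_true: float
    ci_true: tuple[float, float]
    ph_ok_surrogate: bool = True
    ph_ok_true: bool = True
    level: float = 0.95
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"{self.trial_id}: confidence level must be in (0, 1)")
        if self.n_patients <= 0:
            raise ValueError(f"{self.trial_id}: n_patients must be positive")
        for name, hr, (lo, hi) in (
            ("surrogate", self.hr_surrogate, self.ci_surrogate),
            ("true", self.hr_true, self.ci_true),
        ):
            if min(hr, lo, hi) <= 0.0:
                raise ValueError(
                    f"{self.trial_id}: {name} endpoint has non-positive HR or bound"
                )
            if not lo < hr < hi:
                raise ValueError(
                    f"{self.trial_id}: {name} endpoint point estimate outside CI "
                    f"({hr} not in ({lo}, {hi}))"
                )

    @property
    def ph_ok(self) -> bool:
        """True when the PH assumption held for both endpoints."""
        return self.ph_ok_surrogate and self.ph_ok_true


@dataclass(frozen=True)
class EffectPair:
    """Log-scale effects of one trial: y = ln(HR), with standard errors."""

    trial_id: str
    y1: float  # log HR, surrogate endpoint (rPFS)
    se1: float
    y2: float  # log HR, true endpoint (OS)
    se2: float

    def __post_init__(self) -> None:
        if self.se1 <= 0 or self.se2 <= 0:
            raise ValueError(f"{self.trial_id}: standard errors must be positive")


@dataclass(frozen=True)
class AnalysisSet:
    """A named, ordered selection of trials with exclusion bookkeeping."""

    name: str
    included_ids: tuple[str, ...]
    exclusion_reasons: dict[str, str] = field(default_factory=dict)

    def select(self, records: list[TrialRecord]) -> list[TrialRecord]:
        by_id = {r.trial_id: r for r in records}
        return [by_id[tid] for tid in self.included_ids]


def to_effect(record: TrialRecord) -> EffectPair:
    """Convert one record to log-scale effects with CI-derived SEs.

    ``se = (ln(ucl) - ln(lcl)) / (2 * z)`` with ``z`` the exact standard
    normal quantile at the record's confidence level (1.959964 at 0.95).
    """
    z = stats.norm.ppf(0.5 + record.level / 2.0)

    def one(hr: float, ci: tuple[float, float], name: str) -> tuple[float, float]:
        lo, hi = ci
        if hi == lo:
            raise ValueError(f"{record.trial_id}: degenerate CI for {name} endpoint")
        return math.log(hr), (math.log(hi) - math.log(lo)) / (2.0 * z)

    y1, se1 = one(record.hr_surrogate, record.ci_surrogate, "surrogate")
    y2, se2 = one(record.hr_true, record.ci_true, "true")
    return EffectPair(record.trial_id, y1, se1, y2, se2)


def to_effects(records: list[TrialRecord]) -> list[EffectPair]:
    return [to_effect(r) for r in records]


_CSV_COLUMNS = [
    "trial_id",
    "n_patients",
    "hr_rpfs",
    "lcl_rpfs",
    "ucl_rpfs",
    "hr_os",
    "lcl_os",
    "ucl_os",
    "ph_rpfs",
    "ph_os",
    "notes",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "ph_ok": True, "ph_violation": False, "yes": True, "no": False}


def read_trial_table(path, level: float = 0.95) -> list[TrialRecord]:
    """Read a per-trial summary CSV into validated records, order preserved.

    The CSV is comma-separated UTF-8 with a header; required columns are
    ``trial_id, n_patients, hr_rpfs, lcl_rpfs, ucl_rpfs, hr_os, lcl_os,
    ucl_os``; ``ph_rpfs``/``ph_os`` (true/false) and ``notes`` are
    optional.  Validation errors name the offending row and field.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_rows(fh, level)


def _read_rows(fh, level: float) -> list[TrialRecord]:
    reader = csv.DictReader(fh)
    required = set(_CSV_COLUMNS[:8])
    header = set(reader.fieldnames or [])
    missing = required - header
    if missing:
        raise ValueError(f"trial table missing column(s): {sorted(missing)}")
    records = []
    for i, row in enumerate(reader, start=2):
        try:
            rec = TrialRecord(
                trial_id=row["trial_id"].strip(),
                n_patients=int(row["n_patients"]),
                hr_surrogate=float(row["hr_rpfs"]),
                ci_surrogate=(float(row["lcl_rpfs"]), float(row["ucl_rpfs"])),
                hr_true=float(row["hr_os"]),
                ci_true=(float(row["lcl_os"]), float(row["ucl_os"])),
                ph_ok_surrogate=_BOOL[(row.get("ph_rpfs") or "true").strip().lower()],
                ph_ok_true=_BOOL[(row.get("ph_os") or "true").strip().lower()],
                level=level,
                notes=(row.get("notes") or "").strip(),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"trial table row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_trial_table(records: list[TrialRecord], path=None) -> str:
    """Serialize records to the CSV dialect ``read_trial_table`` accepts."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(_CSV_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.trial_id,
                r.n_patients,
                r.hr_surrogate,
                *r.ci_surrogate,
                r.hr_true,
                *r.ci_true,
                str(r.ph_ok_surrogate).lower(),
                str(r.ph_ok_true).lower(),
                r.notes,
            ]
        )
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


# Summary efficacy table of the eleven first-line, ARPi-naive mCRPC phase 3
# trials jointly reporting rPFS and OS (intervention vs comparator hazard
# ratios with 95% CIs; n = total randomized in the analyzed comparison).
# KEYNOTE-641 uses the no-prior-abiraterone subgroup (245 + 242 patients).
# PEACEIII failed the proportional-hazards assumption for OS.
_FIXTURE_ROWS = [
    # id, n, hr_rpfs, lcl, ucl, hr_os, lcl, ucl, ph_rpfs, ph_os, notes
    ("ACIS", 982, 0.70, 0.60, 0.83, 0.95, 0.81, 1.11, True, True,
     "apalutamide + abiraterone vs abiraterone"),
    ("Alliance A031201", 1311, 0.86, 0.76, 0.97, 0.89, 0.78, 1.01, True, True,
     "enzalutamide + abiraterone vs enzalutamide"),
    ("COU-AA-302", 1088, 0.52, 0.45, 0.61, 0.81, 0.70, 0.93, True, True,
     "abiraterone vs placebo"),
    ("PEACEIII", 446, 0.69, 0.54, 0.87, 0.69, 0.52, 0.90, True, False,
     "radium-223 + enzalutamide vs enzalutamide; PH violated for OS"),
    ("ERA 223", 806, 1.152, 0.960, 1.383, 1.195, 0.950, 1.505, True, True,
     "radium-223 + abiraterone vs abiraterone"),
    ("IPATential150", 1101, 0.84, 0.71, 0.99, 0.90, 0.76, 1.07, True, True,
     "ipatasertib + abiraterone vs abiraterone"),
    ("KEYNOTE-641", 487, 1.14, 0.89, 1.44, 1.02, 0.80, 1.31, True, True,
     "pembrolizumab + enzalutamide vs enzalutamide; no-prior-abiraterone subgroup"),
    ("NCT02294461", 388, 0.31, 0.20, 0.46, 0.33, 0.16, 0.67, True, True,
     "enzalutamide vs placebo (Asia)"),
    ("PREVAIL", 1717, 0.32, 0.28, 0.37, 0.73, 0.63, 0.85, True, True,
     "enzalutamide vs placebo"),
    ("PROpel", 796, 0.68, 0.57, 0.81, 0.81, 0.67, 1.00, True, True,
     "olaparib + abiraterone vs abiraterone"),
    ("TALAPRO-2", 805, 0.667, 0.551, 0.807, 0.796, 0.661, 0.958, True, True,
     "talazoparib + enzalutamide vs enzalutamide"),
]


def fixture_table(level: float = 0.95) -> list[TrialRecord]:
    """The packaged 11-trial first-line mCRPC rPFS/OS summary table."""
    return [
        TrialRecord(
            trial_id=tid,
            n_patients=n,
            hr_surrogate=h1,
            ci_surrogate=(l1, u1),
            hr_true=h2,
            ci_true=(l2, u2),
            ph_ok_surrogate=p1,
            ph_ok_true=p2,
            level=level,
            notes=notes,
        )
        for tid, n, h1, l1, u1, h2, l2, u2, p1, p2, notes in _FIXTURE_ROWS
    ]


def build_analysis_set(
    records: list[TrialRecord],
    name: str,
    outlier_ids: tuple[str, ...] = DEFAULT_OUTLIER_IDS,
) -> AnalysisSet:
    """Resolve a named analysis set over the supplied records.

    primary
        trials satisfying the PH assumption on both endpoints
    sensitivity_1
        all trials, PH violations re-included
    sensitivity_2
        sensitivity_1 minus PH violators minus ``outlier_ids``
    """
    ids = [r.trial_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial_id in records")
    if name == "primary":
        reasons = {r.trial_id: "ph_violation" for r in records if not r.ph_ok}
    elif name == "sensitivity_1":
        reasons = {}
    elif name == "sensitivity_2":
        reasons = {r.trial_id: "ph_violation" for r in records if not r.ph_ok}
        for tid in outlier_ids:
            if tid in ids:
                reasons.setdefault(tid, "outlier")
    else:
        raise ValueError(
            f"unknown analysis set {name!r}; expected primary, sensitivity_1 "
            "or sensitivity_2"
        )
    included = tuple(r.trial_id for r in records if r.trial_id not in reasons)
    return AnalysisSet(name=name, included_ids=included, exclusion_reasons=reasons)
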