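"""Staff radiation-exposure bookkeeping for CLI procedures.

Per-procedure personal doses (electronic dosimeter readings) are
extrapolated to the number of procedures a staff member can perform
within an annual dose limit. The default limit of 1 mSv is the public
annual effective-dose limit; classified radiation workers may use 6 or
20 mSv instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DomainError

DEFAULT_ANNUAL_LIMIT_MSV = 1.0

ROLES = ("scrub_nurse", "surgeon", "anaesthetist", "periphery_nurse",
         "researcher", "other")

#: Per-procedure doses reported for the clinical cohort [mSv].
CLINICAL_DOSES_MSV = {
    "scrub_nurse": 0.016,
    "surgeon": 0.005,
    "anaesthetist": 0.001,
    "periphery_nurse": 0.002,
    "researcher": 0.001,
}


@dataclass(frozen=True)
class DoseRecord:
    role: str
    dose_per_procedure_msv: float
    annual_limit_msv: float = DEFAULT_ANNUAL_LIMIT_MSV

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DomainError(f"role must be one of {ROLES}")
        if self.dose_per_procedure_msv < 0:
            raise DomainError("dose must be non-negative")
        if self.annual_limit_msv <= 0:
            raise DomainError("annual limit must be positive")


def max_procedures(record: DoseRecord) -> float:
    """Procedures per year within the limit: floor(limit / dose).

    Returns ``math.inf`` for a zero dose (no measurable exposure).
    """
    if record.dose_per_procedure_msv == 0:
        return math.inf
    return float(math.floor(record.annual_limit_msv / record.dose_per_procedure_msv))


def cohort_dose_report(records: list[DoseRecord]) -> pd.DataFrame:
    """Per-role dose table sorted by descending dose.

    Flags any role for which a single procedure already exceeds the
    annual limit.
    """
    if not records:
        raise DomainError("cohort_dose_report needs at least one record")
    rows = []
    for rec in records:
        rows.append({
            "role": rec.role,
            "dose_per_procedure_msv": rec.dose_per_procedure_msv,
            "annual_limit_msv": rec.annual_limit_msv,
            "max_procedures": max_procedures(rec),
            "over_limit": rec.dose_per_procedure_msv > rec.annual_limit_msv,
        })
    return (pd.DataFrame(rows)
            .sort_values("dose_per_procedure_msv", ascending=False)
            .reset_index(drop=True))


def clinical_dose_records(annual_limit_msv: float = DEFAULT_ANNUAL_LIMIT_MSV
                          ) -> list[DoseRecord]:
    """The five monitored roles of the clinical cohort as DoseRecords."""
    return [DoseRecord(role=r, dose_per_procedure_msv=d,
                       annual_limit_msv=annual_limit_msv)
            for r, d in CLINICAL_DOSES_MSV.items()]


def load_dose_csv(path: str | Path,
                  annual_limit_msv: float = DEFAULT_ANNUAL_LIMIT_MSV
                  ) -> list[DoseRecord]:
    """Read dose records from a CSV with columns role, dose_msv[, limit_msv]."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        limit = float(row["limit_msv"]) if "limit_msv" in df.columns else annual_limit_msv
        records.append(DoseRecord(role=str(row["role"]),
                                  dose_per_procedure_msv=float(row["dose_msv"]),
                                  annual_limit_msv=limit))
    return records
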