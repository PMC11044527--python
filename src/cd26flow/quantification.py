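"""Per-sample quantification of CD26+ LSCs.

Three headline quantities per sample:

* ``pct_cd26_of_cd45`` — CD26+ LSC events as a percentage of CD45+ events
  (the headline percentage; the denominator is CD45+ events, not all
  acquired events).
* ``pct_cd26_of_lsc`` — CD26+ events as a percentage of the CD34+/CD38-
  (LSC) compartment.
* ``abs_cd26_per_ul`` — absolute circulating CD26+ LSC concentration,
  ``WBC/uL x pct_cd26_of_cd45 / 100``, in cells per microliter.

Empty denominators yield NaN with a flag, never a silent zero: a failed
gate must not fabricate a negative finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import ConsistencyError, PairingError, ParameterError

__all__ = ["SampleRecord", "LSCQuant", "pct_of", "absolute_cd26_count", "quantify"]

UNDEFINED = float("nan")


@dataclass
class SampleRecord:
    """Clinical metadata for one acquisition."""

    sample_id: str
    group: str = "CML"  # "CML" | "control"
    phase: str = "not-applicable"  # "chronic" | "blast-crisis" | "not-applicable"
    sokal: str = "not-applicable"  # "low" | "intermediate" | "high" | "not-applicable"
    timepoint: str = "diagnosis"  # "diagnosis" | "followup-6mo"
    wbc_per_ul: float = 0.0  # white-cell concentration, cells/uL
    patient_id: str = ""  # links diagnosis and follow-up rows

    def __post_init__(self) -> None:
        if not self.patient_id:
            self.patient_id = self.sample_id


@dataclass
class LSCQuant:
    """The three headline quantities for one sample (NaN = undefined)."""

    sample_id: str
    pct_cd26_of_cd45: float = UNDEFINED
    pct_cd26_of_lsc: float = UNDEFINED
    abs_cd26_per_ul: float = UNDEFINED
    flags: list[str] = field(default_factory=list)

    @property
    def cd26_evaluable(self) -> bool:
        return "cd26_unavailable" not in self.flags

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "pct_cd26_of_cd45": self.pct_cd26_of_cd45,
            "pct_cd26_of_lsc": self.pct_cd26_of_lsc,
            "abs_cd26_per_ul": self.abs_cd26_per_ul,
            "flags": ";".join(self.flags),
        }


def pct_of(numerator_count: int, denominator_count: int) -> float:
    """``100 * numerator / denominator``; NaN for an empty denominator.

    Raises :class:`ConsistencyError` if the numerator exceeds the
    denominator — that would violate gate nesting upstream.
    """
    if numerator_count < 0 or denominator_count < 0:
        raise ParameterError("event counts must be nonnegative")
    if denominator_count == 0:
        return UNDEFINED  # undefined, never a silent zero
    if numerator_count > denominator_count:
        raise ConsistencyError(
            f"numerator {numerator_count} exceeds denominator {denominator_count}"
        )
    return 100.0 * numerator_count / denominator_count


def absolute_cd26_count(wbc_per_ul: float, pct_cd26_of_cd45: float) -> float:
    """Absolute CD26+ LSC concentration: ``WBC/uL x pct / 100`` (cells/uL)."""
    if not wbc_per_ul > 0:
        raise ParameterError("wbc_per_ul must be positive")
    if math.isnan(pct_cd26_of_cd45):
        return UNDEFINED
    if not 0 <= pct_cd26_of_cd45 <= 100:
        raise ParameterError("percentage must lie in [0, 100]")
    return wbc_per_ul * pct_cd26_of_cd45 / 100.0


def quantify(report, record: SampleRecord) -> LSCQuant:
    """Assemble an :class:`LSCQuant` from a gating report and a clinical record.

    ``report`` is a :class:`~cd26flow.gating.GatingReport`.  Flags propagate
    from gating; when the CD26 calibration failed the CD26 quantities are
    NaN and the result is flagged ``cd26_unavailable``.
    """
    if report.sample_id and record.sample_id and report.sample_id != record.sample_id:
        raise PairingError(
            f"report sample {report.sample_id!r} != record sample {record.sample_id!r}"
        )
    flags = list(report.flags)
    q = LSCQuant(sample_id=record.sample_id, flags=flags)
    if not report.cd26_available:
        if "cd26_unavailable" not in flags:
            flags.append("cd26_unavailable")
        return q

    counts = report.counts
    n_cd45 = counts["CD45pos"]
    n_lsc = counts["LSC"]
    n_pos = counts["LSC_CD26pos"]

    q.pct_cd26_of_cd45 = pct_of(n_pos, n_cd45)
    if math.isnan(q.pct_cd26_of_cd45):
        flags.append("empty_cd45_denominator")
    q.pct_cd26_of_lsc = pct_of(n_pos, n_lsc)
    if math.isnan(q.pct_cd26_of_lsc):
        flags.append("empty_lsc_denominator")
    if record.wbc_per_ul > 0 and not math.isnan(q.pct_cd26_of_cd45):
        q.abs_cd26_per_ul = absolute_cd26_count(record.wbc_per_ul, q.pct_cd26_of_cd45)
    elif not record.wbc_per_ul > 0:
        flags.append("missing_wbc")
    return q
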