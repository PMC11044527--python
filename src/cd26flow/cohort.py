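"""Cohort orchestration: per-sample gating + quantification, study-level analysis.

Runs the gating pipeline and quantification across a cohort, then
reproduces the study's analysis layout: median/range summary blocks at
diagnosis and follow-up, Kruskal-Wallis across Sokal risk groups,
Mann-Whitney between WBC strata (boundary at 150 x10^3/uL, the low stratum
inclusive), Spearman correlation of the absolute CD26+ LSC count with WBC,
the paired diagnosis/follow-up Wilcoxon signed-rank test on both absolute
counts and percentages, and a detection summary (CML samples with >= 1
CD26+ LSC event vs controls).

Samples whose CD26 calibration failed are excluded from CD26 statistics
and reported in a separate not-evaluable count.  Follow-up analyses are
restricted to chronic-phase pairs (only chronic-phase patients are
followed), paired on patient identity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CD26FlowError, ParameterError
from .fcs_io import PanelConfig, read_fcs
from .gating import GatingConfig, run_gating_pipeline
from .nonparam import (
    StatResult,
    kruskal_wallis,
    mann_whitney,
    spearman,
    summarize,
    wilcoxon_signed_rank,
)
from .quantification import SampleRecord, quantify
from .transforms import TransformConfig

__all__ = [
    "WBC_STRATUM_BOUNDARY",
    "CohortTable",
    "AnalysisReport",
    "build_cohort",
    "cohort_from_samples",
    "analyze_cohort",
    "detection_summary",
]

logger = logging.getLogger("cd26flow")

#: WBC stratification boundary, cells/uL (low stratum is <= the boundary).
WBC_STRATUM_BOUNDARY = 150_000.0

_COLUMNS = [
    "sample_id",
    "patient_id",
    "group",
    "phase",
    "sokal",
    "timepoint",
    "wbc_per_ul",
    "wbc_stratum",
    "pct_cd26_of_cd45",
    "pct_cd26_of_lsc",
    "abs_cd26_per_ul",
    "n_lsc_cd26pos",
    "cd26_evaluable",
    "failed",
    "flags",
]


@dataclass
class CohortTable:
    """Per-sample quantification rows for a cohort (one row per acquisition)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for tp, sub in self.df.groupby("timepoint"):
            if sub["sample_id"].duplicated().any():
                raise ParameterError(f"duplicate sample_ids at timepoint {tp}")
        fu = self.df[self.df["timepoint"] == "followup-6mo"]
        dx_patients = set(
            self.df.loc[self.df["timepoint"] == "diagnosis", "patient_id"]
        )
        orphans = set(fu["patient_id"]) - dx_patients
        if orphans:
            raise ParameterError(
                f"follow-up rows without a diagnosis partner: {sorted(orphans)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def rows(self, **filters) -> pd.DataFrame:
        out = self.df
        for col, val in filters.items():
            out = out[out[col] == val]
        return out

    def complete_pairs(self) -> pd.DataFrame:
        """Diagnosis/follow-up pairs of chronic-phase patients, CD26-evaluable
        at both timepoints."""
        ok = self.df[~self.df["failed"] & self.df["cd26_evaluable"]]
        dx = ok[(ok["timepoint"] == "diagnosis") & (ok["group"] == "CML")]
        fu = ok[(ok["timepoint"] == "followup-6mo") & (ok["phase"] == "chronic")]
        merged = dx.merge(fu, on="patient_id", suffixes=("_dx", "_fu"))
        return merged[merged["phase_dx"] == "chronic"]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _row_from_quant(record: SampleRecord, quant, n_pos, failed=False, error="") -> dict:
    flags = list(quant.flags) if quant is not None else []
    if error:
        flags.append(f"failed:{error}")
    return {
        "sample_id": record.sample_id,
        "patient_id": record.patient_id,
        "group": record.group,
        "phase": record.phase,
        "sokal": record.sokal,
        "timepoint": record.timepoint,
        "wbc_per_ul": record.wbc_per_ul,
        "wbc_stratum": "low" if record.wbc_per_ul <= WBC_STRATUM_BOUNDARY else "high",
        "pct_cd26_of_cd45": quant.pct_cd26_of_cd45 if quant else float("nan"),
        "pct_cd26_of_lsc": quant.pct_cd26_of_lsc if quant else float("nan"),
        "abs_cd26_per_ul": quant.abs_cd26_per_ul if quant else float("nan"),
        "n_lsc_cd26pos": n_pos,
        "cd26_evaluable": bool(quant.cd26_evaluable) if quant else False,
        "failed": failed,
        "flags": ";".join(flags),
    }


def cohort_from_samples(
    samples,
    panel: PanelConfig | None = None,
    gcfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> CohortTable:
    """Gate + quantify in-memory (EventMatrix, SampleRecord) pairs.

    ``samples`` is an iterable of ``(EventMatrix, SampleRecord)`` or of
    simulator :class:`~cd26flow.synthetic.CohortSample` tuples.
    """
    rows = []
    for item in samples:
        em, record = (item.em, item.record) if hasattr(item, "record") else item
        try:
            report = run_gating_pipeline(em, panel, gcfg, tcfg)
            quant = quantify(report, record)
            n_pos = report.counts.get("LSC_CD26pos", 0) if report.cd26_available else 0
            rows.append(_row_from_quant(record, quant, n_pos))
        except CD26FlowError as exc:
            logger.warning("sample %s failed: %s", record.sample_id, exc)
            rows.append(_row_from_quant(record, None, 0, failed=True, error=str(exc)))
        logger.info("processed sample %s", record.sample_id)
    if not rows:
        raise ParameterError("empty cohort")
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if df["failed"].all():
        raise CD26FlowError("no sample in the cohort processed successfully")
    return CohortTable(df.sort_values("sample_id", kind="stable").reset_index(drop=True))


def build_cohort(
    manifest: list[tuple[str, SampleRecord]] | str | Path,
    panel: PanelConfig | None = None,
    gcfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> CohortTable:
    """Run the per-sample pipeline over FCS files listed in a manifest.

    ``manifest`` is either a list of ``(fcs_path, SampleRecord)`` or the
    path of a manifest CSV with columns path, sample_id, [patient_id,]
    group, phase, sokal, timepoint, wbc_per_ul.  Per-sample failures are
    recorded without aborting the cohort.
    """
    if isinstance(manifest, (str, Path)):
        mdf = pd.read_csv(manifest)
        entries = [
            (
                row["path"],
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    patient_id=str(row.get("patient_id", "") or row["sample_id"]),
                    group=str(row["group"]),
                    phase=str(row.get("phase", "not-applicable")),
                    sokal=str(row.get("sokal", "not-applicable")),
                    timepoint=str(row.get("timepoint", "diagnosis")),
                    wbc_per_ul=float(row["wbc_per_ul"]),
                ),
            )
            for _, row in mdf.iterrows()
        ]
    else:
        entries = list(manifest)
    if not entries:
        raise ParameterError("manifest is empty")

    loaded = []
    failed_rows = []
    for path, record in entries:
        try:
            em = read_fcs(path)
            em.sample_id = record.sample_id
            loaded.append((em, record))
        except (OSError, CD26FlowError) as exc:
            logger.warning("could not read %s: %s", path, exc)
            failed_rows.append(
                _row_from_quant(record, None, 0, failed=True, error=str(exc))
            )
    if not loaded and not failed_rows:
        raise ParameterError("manifest is empty")
    table = None
    if loaded:
        table = cohort_from_samples(loaded, panel, gcfg, tcfg)
    if failed_rows:
        extra = pd.DataFrame(failed_rows, columns=_COLUMNS)
        df = pd.concat([table.df, extra] if table is not None else [extra])
        df = df.sort_values("sample_id", kind="stable").reset_index(drop=True)
        if table is None and df["failed"].all():
            raise CD26FlowError("no sample in the cohort processed successfully")
        table = CohortTable(df)
    return table


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Study-level analysis: summary blocks, rank tests, detection summary."""

    summaries: dict[str, dict] = field(default_factory=dict)
    stats: dict[str, StatResult] = field(default_factory=dict)
    not_computable: dict[str, str] = field(default_factory=dict)
    detection: dict[str, int] = field(default_factory=dict)
    n_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries,
            "stats": {k: v.to_row() for k, v in sorted(self.stats.items())},
            "not_computable": self.not_computable,
            "detection": self.detection,
            "n_pairs": self.n_pairs,
        }

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(self.to_dict(), sort_keys=True, indent=1, default=_default)

    def summary(self) -> str:
        lines = ["Cohort analysis"]
        for name, block in self.summaries.items():
            lines.append(f"[{name}]")
            for k, v in block.items():
                lines.append(f"  {k}: {v:.6g}" if isinstance(v, float) else f"  {k}: {v}")
        for name, st in sorted(self.stats.items()):
            lines.append(f"{name}: {st.summary()}")
        for name, why in self.not_computable.items():
            lines.append(f"{name}: not computable ({why})")
        lines.append(f"detection: {self.detection}")
        return "\n".join(lines)


def _finite(series: pd.Series) -> np.ndarray:
    v = series.to_numpy(dtype=float)
    return v[np.isfinite(v)]


def _summary_block(sub: pd.DataFrame, with_lsc_pct: bool = True) -> dict:
    block: dict = {"n": int(len(sub))}
    for col, label in [
        ("pct_cd26_of_cd45", "pct_cd26_of_cd45"),
        ("pct_cd26_of_lsc", "pct_cd26_of_lsc"),
        ("abs_cd26_per_ul", "abs_cd26_per_ul"),
    ]:
        if col == "pct_cd26_of_lsc" and not with_lsc_pct:
            continue
        v = _finite(sub[col])
        if v.size:
            s = summarize(v)
            block[f"median_{label}"] = s["median"]
            block[f"min_{label}"] = s["min"]
            block[f"max_{label}"] = s["max"]
    return block


def detection_summary(table: CohortTable) -> dict[str, int]:
    """Counts of CML and control samples carrying >= 1 CD26+ LSC event.

    Samples whose CD26 calibration failed (or that failed outright) are
    reported separately as not evaluable.
    """
    df = table.df
    ok = df[~df["failed"] & df["cd26_evaluable"]]
    cml = ok[ok["group"] == "CML"]
    ctl = ok[ok["group"] == "control"]
    bad = df[df["failed"] | ~df["cd26_evaluable"]]
    return {
        "n_cml": int(len(cml)),
        "n_cml_cd26_positive": int((cml["n_lsc_cd26pos"] >= 1).sum()),
        "n_controls": int(len(ctl)),
        "n_controls_cd26_positive": int((ctl["n_lsc_cd26pos"] >= 1).sum()),
        "n_not_evaluable": int(len(bad)),
    }


def analyze_cohort(table: CohortTable) -> AnalysisReport:
    """Produce the full analysis report for a cohort table.

    Comparisons with an empty stratum are emitted under ``not_computable``
    with a reason, never as a fabricated statistic.
    """
    df = table.df
    ok = df[~df["failed"] & df["cd26_evaluable"]]
    dx = ok[
        (ok["group"] == "CML") & (ok["timepoint"] == "diagnosis")
    ]
    fu = ok[(ok["group"] == "CML") & (ok["timepoint"] == "followup-6mo")]

    report = AnalysisReport()
    report.detection = detection_summary(table)

    if len(dx) == 0:
        report.not_computable["diagnosis_block"] = "no evaluable CML diagnosis rows"
        return report
    report.summaries["diagnosis"] = _summary_block(dx)
    if len(fu):
        report.summaries["followup"] = _summary_block(fu)

    # Sokal risk: Kruskal-Wallis on absolute CD26+ LSC counts at diagnosis
    sokal_groups = []
    sokal_labels = []
    for level in ("low", "intermediate", "high"):
        v = _finite(dx.loc[dx["sokal"] == level, "abs_cd26_per_ul"])
        if v.size:
            sokal_groups.append(v)
            sokal_labels.append(level)
    if len(sokal_groups) >= 2:
        st = kruskal_wallis(sokal_groups)
        st.mean_ranks = dict(zip(sokal_labels, st.mean_ranks.values()))
        st.n_per_group = dict(zip(sokal_labels, st.n_per_group.values()))
        report.stats["sokal_kruskal_wallis_abs"] = st
    else:
        report.not_computable["sokal_kruskal_wallis_abs"] = "fewer than 2 Sokal strata"

    # WBC stratum: Mann-Whitney on absolute counts and on percentages
    low = dx[dx["wbc_stratum"] == "low"]
    high = dx[dx["wbc_stratum"] == "high"]
    for col, key in [
        ("abs_cd26_per_ul", "wbc_stratum_mann_whitney_abs"),
        ("pct_cd26_of_cd45", "wbc_stratum_mann_whitney_pct"),
    ]:
        a, b = _finite(high[col]), _finite(low[col])
        if a.size and b.size:
            st = mann_whitney(a, b)
            st.mean_ranks = {"wbc_high": st.mean_ranks["a"], "wbc_low": st.mean_ranks["b"]}
            st.n_per_group = {"wbc_high": a.size, "wbc_low": b.size}
            report.stats[key] = st
        else:
            report.not_computable[key] = "an empty WBC stratum"

    # Spearman: absolute CD26+ LSC count vs WBC at diagnosis
    both = dx[np.isfinite(dx["abs_cd26_per_ul"]) & np.isfinite(dx["wbc_per_ul"])]
    if len(both) >= 3:
        report.stats["spearman_abs_vs_wbc"] = spearman(
            both["abs_cd26_per_ul"].to_numpy(), both["wbc_per_ul"].to_numpy()
        )
    else:
        report.not_computable["spearman_abs_vs_wbc"] = "fewer than 3 evaluable rows"

    # Paired diagnosis vs follow-up Wilcoxon (chronic-phase complete pairs)
    pairs = table.complete_pairs()
    report.n_pairs = int(len(pairs))
    for col, key in [
        ("abs_cd26_per_ul", "paired_wilcoxon_abs"),
        ("pct_cd26_of_cd45", "paired_wilcoxon_pct"),
    ]:
        sub = pairs[
            np.isfinite(pairs[f"{col}_dx"]) & np.isfinite(pairs[f"{col}_fu"])
        ]
        if len(sub) >= 1:
            report.stats[key] = wilcoxon_signed_rank(
                sub[f"{col}_dx"].to_numpy(), sub[f"{col}_fu"].to_numpy()
            )
        else:
            report.not_computable[key] = "no complete diagnosis/follow-up pairs"
    return report
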