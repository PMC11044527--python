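"""Synthetic flow-cytometry acquisitions with known ground truth.

Emulates the study conditions of a CML CD26+ LSC assay so every downstream
stage is testable without patient data: 100,000-event peripheral-blood
acquisitions containing debris, lymphocytes (with a CD3+ subset whose CD26
expression is bimodal — the internal control for the CD26 cutoff),
monocytes, granulocytes, CD34+/CD38+ progenitors and a CD34+/CD38- stem
compartment whose CD26+ fraction is tunable.

The intensity model is deliberately simple: per-population normals on the
arcsinh display scale (linear for scatter, with an FSC/SSC correlation),
mapped back to raw instrument units through the inverse transform.  Mode
separations are >= 3 pooled SDs wherever a trough gate must find a valley,
so every generated sample admits the gating topology by construction.

Cohort generation draws per-sample parameters from the reported study
ranges: WBC log-uniform over 42.6-828.3 x10^3/uL at diagnosis, %CD26 of
CD45+ log-uniform over 0.001-1.77 at diagnosis and 0.001-0.2 at six-month
follow-up (log-uniform because reported medians sit far below range
midpoints, indicating strong right skew).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError
from .fcs_io import ChannelMeta, EventMatrix, write_fcs
from .quantification import SampleRecord
from .transforms import SCATTER_MARKERS, TransformConfig, inverse_asinh_scale

__all__ = [
    "POPULATIONS",
    "PopulationSpec",
    "SampleSimConfig",
    "SimGroundTruth",
    "default_populations",
    "simulate_sample",
    "simulate_cohort",
    "write_cohort",
    "CohortSample",
]

MARKERS = ("FSC", "SSC", "CD45", "CD34", "CD38", "CD26", "CD3")

#: Population labels, in emission order.
POPULATIONS = (
    "debris",
    "lymphocyte_other",
    "lymphocyte_cd3pos_cd26neg",
    "lymphocyte_cd3pos_cd26pos",
    "monocyte",
    "granulocyte",
    "progenitor_cd34pos_cd38pos",
    "lsc_cd34pos_cd38neg_cd26neg",
    "lsc_cd34pos_cd38neg_cd26pos",
)

CD26POS_LSC = "lsc_cd34pos_cd38neg_cd26pos"
CD26NEG_LSC = "lsc_cd34pos_cd38neg_cd26neg"
LSC_POPULATIONS = (CD26NEG_LSC, CD26POS_LSC)
CD34POS_POPULATIONS = ("progenitor_cd34pos_cd38pos",) + LSC_POPULATIONS


@dataclass
class PopulationSpec:
    """One cell population: its event fraction and intensity model.

    ``location``/``spread`` are per-marker mean and SD on the gating scale
    (arcsinh units for fluorescence, linear units for scatter).
    ``scatter_corr`` is the FSC/SSC correlation.
    """

    name: str
    fraction: float
    location: dict[str, float]
    spread: dict[str, float]
    scatter_corr: float = 0.3

    def __post_init__(self) -> None:
        for m in MARKERS:
            if m not in self.location or m not in self.spread:
                raise ConfigurationError(f"population {self.name} missing marker {m}")
        if not 0 <= self.fraction <= 1:
            raise ConfigurationError(f"population {self.name} fraction out of [0,1]")


@dataclass
class SampleSimConfig:
    """Parameters for one simulated acquisition.

    Defaults follow the study conditions: 100,000 acquired events, the
    reported median WBC (278 x10^3/uL), and the reported median CD26
    percentages (0.02% of CD45+ events; 5.04% of the CD34+/CD38-
    compartment).
    """

    n_events: int = 100_000
    wbc_per_ul: float = 278_000.0
    group: str = "CML-diagnosis"  # "CML-diagnosis" | "CML-followup" | "control"
    target_pct_cd26_of_cd45: float = 0.02
    target_pct_cd26_of_lsc: float = 5.04
    seed: int = 0
    #: below this expected CD26+ LSC event count the count is pinned
    #: deterministically instead of drawn multinomially
    pin_threshold: int = 5
    #: deterministic lower bound on the pinned CD26+ LSC event count
    min_cd26pos_events: int = 0
    transform: TransformConfig = field(default_factory=TransformConfig)

    def __post_init__(self) -> None:
        if self.group not in ("CML-diagnosis", "CML-followup", "control"):
            raise ParameterError(f"unknown group {self.group!r}")
        if self.group == "control":
            self.target_pct_cd26_of_cd45 = 0.0
        if not 0 <= self.target_pct_cd26_of_cd45 <= 100:
            raise ParameterError("target_pct_cd26_of_cd45 must lie in [0, 100]")
        if not 0 < self.target_pct_cd26_of_lsc <= 100:
            raise ParameterError("target_pct_cd26_of_lsc must lie in (0, 100]")
        if self.n_events < 1:
            raise ParameterError("n_events must be >= 1")
        if not self.wbc_per_ul > 0:
            raise ParameterError("wbc_per_ul must be positive")


@dataclass
class SimGroundTruth:
    """Per-event population labels and the realized (not target) fractions."""

    labels: np.ndarray  # integer codes into POPULATIONS
    counts: dict[str, int]
    pct_cd26_of_cd45: float
    pct_cd26_of_lsc: float
    abs_cd26_per_ul: float

    @property
    def n_events(self) -> int:
        return int(self.labels.size)

    def label_names(self) -> np.ndarray:
        return np.asarray(POPULATIONS, dtype=object)[self.labels]

    def mask(self, *names: str) -> np.ndarray:
        codes = [POPULATIONS.index(n) for n in names]
        return np.isin(self.labels, codes)


# ---------------------------------------------------------------------------
# Population template
# ---------------------------------------------------------------------------

# (FSC, SSC on linear scatter units; fluorescence on arcsinh scale.)
_LOC = {
    "debris": dict(FSC=100, SSC=80, CD45=0.2, CD34=0.2, CD38=0.2, CD26=0.2, CD3=0.2),
    "lymphocyte_other": dict(FSC=420, SSC=140, CD45=5.2, CD34=0.2, CD38=2.0, CD26=0.2, CD3=0.2),
    "lymphocyte_cd3pos_cd26neg": dict(FSC=420, SSC=140, CD45=5.2, CD34=0.2, CD38=2.0, CD26=0.2, CD3=4.0),
    "lymphocyte_cd3pos_cd26pos": dict(FSC=420, SSC=140, CD45=5.2, CD34=0.2, CD38=2.0, CD26=2.8, CD3=4.0),
    "monocyte": dict(FSC=480, SSC=300, CD45=5.0, CD34=0.2, CD38=3.5, CD26=0.2, CD3=0.2),
    "granulocyte": dict(FSC=500, SSC=700, CD45=4.8, CD34=0.2, CD38=2.5, CD26=0.2, CD3=0.2),
    "progenitor_cd34pos_cd38pos": dict(FSC=460, SSC=200, CD45=4.6, CD34=4.0, CD38=4.0, CD26=0.2, CD3=0.2),
    CD26NEG_LSC: dict(FSC=460, SSC=200, CD45=4.6, CD34=4.0, CD38=0.6, CD26=0.2, CD3=0.2),
    CD26POS_LSC: dict(FSC=460, SSC=200, CD45=4.6, CD34=4.0, CD38=0.6, CD26=2.8, CD3=0.2),
}

_SPREAD = {
    "debris": dict(FSC=50, SSC=40, CD45=0.25, CD34=0.25, CD38=0.25, CD26=0.25, CD3=0.25),
    "lymphocyte_other": dict(FSC=70, SSC=40, CD45=0.30, CD34=0.25, CD38=0.40, CD26=0.25, CD3=0.25),
    "lymphocyte_cd3pos_cd26neg": dict(FSC=70, SSC=40, CD45=0.30, CD34=0.25, CD38=0.40, CD26=0.25, CD3=0.30),
    "lymphocyte_cd3pos_cd26pos": dict(FSC=70, SSC=40, CD45=0.30, CD34=0.25, CD38=0.40, CD26=0.30, CD3=0.30),
    "monocyte": dict(FSC=70, SSC=60, CD45=0.35, CD34=0.25, CD38=0.35, CD26=0.25, CD3=0.25),
    "granulocyte": dict(FSC=80, SSC=120, CD45=0.40, CD34=0.25, CD38=0.45, CD26=0.25, CD3=0.25),
    "progenitor_cd34pos_cd38pos": dict(FSC=70, SSC=50, CD45=0.35, CD34=0.30, CD38=0.30, CD26=0.25, CD3=0.25),
    CD26NEG_LSC: dict(FSC=70, SSC=50, CD45=0.35, CD34=0.30, CD38=0.30, CD26=0.25, CD3=0.25),
    CD26POS_LSC: dict(FSC=70, SSC=50, CD45=0.35, CD34=0.30, CD38=0.30, CD26=0.30, CD3=0.25),
}

# Base event fractions before the LSC compartment is sized from the targets;
# the granulocyte fraction absorbs the LSC allocation so CD45+ events stay
# at a fixed 95% of the acquisition.
_BASE_FRACTIONS = {
    "debris": 0.05,
    "lymphocyte_other": 0.075,
    "lymphocyte_cd3pos_cd26neg": 0.070,
    "lymphocyte_cd3pos_cd26pos": 0.085,
    "monocyte": 0.05,
    "granulocyte": 0.65,  # minus the LSC compartment
    "progenitor_cd34pos_cd38pos": 0.02,
}

#: CD45+ fraction of all events (everything except debris).
CD45_FRACTION = 1.0 - _BASE_FRACTIONS["debris"]

#: CD26- HSC compartment carried by control (and zero-target CML) samples.
_BASE_HSC_FRACTION = 0.002

_MIN_GRANULOCYTE_FRACTION = 0.05


def default_populations(cfg: SampleSimConfig) -> list[PopulationSpec]:
    """Build the population template whose expected %CD26-of-CD45 equals the target.

    The CD26+ LSC event fraction is ``target/100 x CD45+ fraction``; the full
    CD34+/CD38- compartment is sized so the expected CD26+ share of it equals
    ``target_pct_cd26_of_lsc``.  Jointly infeasible targets (an implied LSC
    compartment crowding out the granulocytes) raise
    :class:`ConfigurationError`.
    """
    t45 = cfg.target_pct_cd26_of_cd45
    tlsc = cfg.target_pct_cd26_of_lsc
    f_cd26pos = (t45 / 100.0) * CD45_FRACTION
    if f_cd26pos > 0:
        f_lsc_total = f_cd26pos * 100.0 / tlsc
    else:
        f_lsc_total = _BASE_HSC_FRACTION
    f_cd26neg = f_lsc_total - f_cd26pos
    granulocyte = _BASE_FRACTIONS["granulocyte"] - f_lsc_total
    if granulocyte < _MIN_GRANULOCYTE_FRACTION or f_cd26neg < 0:
        raise ConfigurationError(
            f"targets infeasible: implied CD34+/CD38- compartment "
            f"{f_lsc_total:.4f} of all events"
        )
    fractions = dict(_BASE_FRACTIONS)
    fractions["granulocyte"] = granulocyte
    fractions[CD26NEG_LSC] = f_cd26neg
    fractions[CD26POS_LSC] = f_cd26pos
    specs = [
        PopulationSpec(name=n, fraction=fractions[n], location=_LOC[n], spread=_SPREAD[n])
        for n in POPULATIONS
    ]
    total = sum(s.fraction for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"population fractions sum to {total!r}")
    return specs


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------


def _default_channels() -> list[ChannelMeta]:
    # scatter channels carry no stain label -> exercised via short-name match
    return [
        ChannelMeta(1, "FSC-A", "", 1_048_576),
        ChannelMeta(2, "SSC-A", "", 1_048_576),
        ChannelMeta(3, "FL10", "CD45 KrO", 1_048_576),
        ChannelMeta(4, "FL6", "CD34 PC7", 1_048_576),
        ChannelMeta(5, "FL9", "CD38 APC750", 1_048_576),
        ChannelMeta(6, "FL2", "CD26 PE", 1_048_576),
        ChannelMeta(7, "FL4", "CD3 PB", 1_048_576),
    ]


def _draw_counts(cfg: SampleSimConfig, specs: list[PopulationSpec], rng) -> np.ndarray:
    fr = np.array([s.fraction for s in specs])
    n = cfg.n_events
    pos_idx = POPULATIONS.index(CD26POS_LSC)
    expected_pos = n * fr[pos_idx]
    pin = fr[pos_idx] > 0 and (
        expected_pos < cfg.pin_threshold or cfg.min_cd26pos_events > 0
    )
    if pin:
        k = max(int(round(expected_pos)), cfg.min_cd26pos_events)
        k = min(k, n)
        rest = fr.copy()
        rest[pos_idx] = 0.0
        rest = rest / rest.sum()
        counts = rng.multinomial(n - k, rest)
        counts[pos_idx] = k
        return counts
    return rng.multinomial(n, fr)


def simulate_sample(
    cfg: SampleSimConfig, rng: np.random.Generator | None = None
) -> tuple[EventMatrix, SimGroundTruth]:
    """Simulate one acquisition; identical seed + config give identical output."""
    specs = default_populations(cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    counts = _draw_counts(cfg, specs, rng)

    labels = np.repeat(np.arange(len(POPULATIONS)), counts)
    scaled = np.empty((cfg.n_events, len(MARKERS)), dtype=np.float64)
    start = 0
    for code, (spec, k) in enumerate(zip(specs, counts)):
        if k == 0:
            continue
        sl = slice(start, start + k)
        # correlated scatter pair
        rho = spec.scatter_corr
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=k, method="cholesky")
        for a, m in enumerate(("FSC", "SSC")):
            scaled[sl, MARKERS.index(m)] = spec.location[m] + spec.spread[m] * z[:, a]
        for m in MARKERS:
            if m in SCATTER_MARKERS:
                continue
            j = MARKERS.index(m)
            scaled[sl, j] = rng.normal(spec.location[m], spec.spread[m], size=k)
        start += k

    perm = rng.permutation(cfg.n_events)
    labels = labels[perm]
    scaled = scaled[perm]

    raw = scaled.copy()
    for j, m in enumerate(MARKERS):
        if m not in SCATTER_MARKERS or not cfg.transform.scatter_passthrough:
            raw[:, j] = inverse_asinh_scale(scaled[:, j], cfg.transform.cofactor)

    em = EventMatrix(data=raw, channels=_default_channels(), sample_id=f"sim-{cfg.seed}")

    count_map = {n: int(c) for n, c in zip(POPULATIONS, counts)}
    n_cd45 = cfg.n_events - count_map["debris"]
    n_lsc = count_map[CD26NEG_LSC] + count_map[CD26POS_LSC]
    n_pos = count_map[CD26POS_LSC]
    pct45 = 100.0 * n_pos / n_cd45 if n_cd45 else float("nan")
    pctlsc = 100.0 * n_pos / n_lsc if n_lsc else float("nan")
    truth = SimGroundTruth(
        labels=labels,
        counts=count_map,
        pct_cd26_of_cd45=pct45,
        pct_cd26_of_lsc=pctlsc,
        abs_cd26_per_ul=cfg.wbc_per_ul * pct45 / 100.0 if n_cd45 else float("nan"),
    )
    return em, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


class CohortSample(NamedTuple):
    em: EventMatrix
    truth: SimGroundTruth
    record: SampleRecord


def _log_uniform(rng, lo: float, hi: float, size=None):
    if hi < lo:
        raise ParameterError("log-uniform range inverted")
    if hi == lo:
        return lo if size is None else np.full(size, lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _categorical_counts(n: int, proportions: dict[str, float]) -> list[str]:
    # largest-remainder apportionment keeps the composition deterministic
    items = list(proportions.items())
    raw = [n * p for _, p in items]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainders first
    for i in range(rem):
        base[order[i]] += 1
    out: list[str] = []
    for (name, _), k in zip(items, base):
        out.extend([name] * k)
    return out

# Study-composition proportions: Sokal high/intermediate/low 8/31/4 of 43,
# phase chronic/blast-crisis 39/4 of 43.
_SOKAL_PROPORTIONS = {"high": 8 / 43, "intermediate": 31 / 43, "low": 4 / 43}
_PHASE_PROPORTIONS = {"chronic": 39 / 43, "blast-crisis": 4 / 43}

# Reported parameter ranges.
WBC_DIAGNOSIS_RANGE = (42_600.0, 828_300.0)  # cells/uL
WBC_FOLLOWUP_RANGE = (4_000.0, 11_000.0)  # normal-count range, cells/uL
PCT_CD26_DIAGNOSIS_RANGE = (0.001, 1.77)  # % of CD45+ events
PCT_CD26_FOLLOWUP_RANGE = (0.001, 0.2)
PCT_CD26_OF_LSC_RANGE = (0.05, 55.94)  # % of the CD34+/CD38- compartment


def _draw_pct_of_lsc(rng, t45: float) -> float:
    # keep the implied LSC compartment feasible: tlsc >= 4 x t45 caps the
    # CD34+/CD38- compartment at ~24% of events
    lo = max(PCT_CD26_OF_LSC_RANGE[0], 4.0 * t45)
    hi = PCT_CD26_OF_LSC_RANGE[1]
    return float(_log_uniform(rng, min(lo, hi), hi))


def simulate_cohort(
    n_cml: int,
    n_controls: int,
    n_followup_pairs: int,
    seed: int = 0,
    n_events: int = 100_000,
    fraction_reduced: float = 1.0,
    min_cd26pos_events_diagnosis: int = 5,
) -> list[CohortSample]:
    """Simulate a full study cohort with per-sample ground truth.

    Diagnosis samples draw WBC and %CD26-of-CD45 log-uniformly over the
    reported ranges; follow-up partners reuse the patient identity with
    %CD26 redrawn over the follow-up range and, for ``fraction_reduced`` of
    pairs (default all), constrained not to exceed the diagnosis value.
    Controls carry no CD26+ LSC population.  All randomness flows from one
    seed through per-sample spawned streams.
    """
    if n_cml < 0 or n_controls < 0 or n_followup_pairs < 0:
        raise ParameterError("cohort counts must be nonnegative")
    if n_followup_pairs > n_cml:
        raise ParameterError("n_followup_pairs cannot exceed n_cml")
    if not 0 <= fraction_reduced <= 1:
        raise ParameterError("fraction_reduced must lie in [0, 1]")

    master = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    sokal = _categorical_counts(n_cml, _SOKAL_PROPORTIONS)
    phase = _categorical_counts(n_cml, _PHASE_PROPORTIONS)
    assign_rng.shuffle(sokal)
    assign_rng.shuffle(phase)
    chronic_idx = [i for i, ph in enumerate(phase) if ph == "chronic"]
    if n_followup_pairs > len(chronic_idx):
        raise ParameterError(
            f"only {len(chronic_idx)} chronic-phase patients for "
            f"{n_followup_pairs} follow-up pairs"
        )
    followup_set = set(chronic_idx[:n_followup_pairs])
    reduced = assign_rng.random(n_cml) < fraction_reduced

    streams = master.spawn(n_cml + n_controls + n_followup_pairs + 1)[1:]
    samples: list[CohortSample] = []
    si = 0
    dx_t45 = {}
    for i in range(n_cml):
        rng = np.random.default_rng(streams[si]); si += 1
        t45 = float(_log_uniform(rng, *PCT_CD26_DIAGNOSIS_RANGE))
        dx_t45[i] = t45
        cfg = SampleSimConfig(
            n_events=n_events,
            wbc_per_ul=float(_log_uniform(rng, *WBC_DIAGNOSIS_RANGE)),
            group="CML-diagnosis",
            target_pct_cd26_of_cd45=t45,
            target_pct_cd26_of_lsc=_draw_pct_of_lsc(rng, t45),
            seed=seed,
            min_cd26pos_events=min_cd26pos_events_diagnosis,
        )
        em, truth = simulate_sample(cfg, rng=rng)
        rec = SampleRecord(
            sample_id=f"P{i + 1:03d}-dx",
            patient_id=f"P{i + 1:03d}",
            group="CML",
            phase=phase[i],
            sokal=sokal[i],
            timepoint="diagnosis",
            wbc_per_ul=cfg.wbc_per_ul,
        )
        em.sample_id = rec.sample_id
        samples.append(CohortSample(em, truth, rec))

    for j in range(n_controls):
        rng = np.random.default_rng(streams[si]); si += 1
        cfg = SampleSimConfig(
            n_events=n_events,
            wbc_per_ul=float(_log_uniform(rng, 8_000.0, 60_000.0)),
            group="control",
            seed=seed,
        )
        em, truth = simulate_sample(cfg, rng=rng)
        rec = SampleRecord(
            sample_id=f"C{j + 1:03d}",
            group="control",
            timepoint="diagnosis",
            wbc_per_ul=cfg.wbc_per_ul,
        )
        em.sample_id = rec.sample_id
        samples.append(CohortSample(em, truth, rec))

    for i in sorted(followup_set):
        rng = np.random.default_rng(streams[si]); si += 1
        hi = PCT_CD26_FOLLOWUP_RANGE[1]
        if reduced[i]:
            hi = min(hi, dx_t45[i])
        t45 = float(_log_uniform(rng, min(PCT_CD26_FOLLOWUP_RANGE[0], hi), hi))
        cfg = SampleSimConfig(
            n_events=n_events,
            wbc_per_ul=float(_log_uniform(rng, *WBC_FOLLOWUP_RANGE)),
            group="CML-followup",
            target_pct_cd26_of_cd45=t45,
            target_pct_cd26_of_lsc=_draw_pct_of_lsc(rng, t45),
            seed=seed,
        )
        em, truth = simulate_sample(cfg, rng=rng)
        rec = SampleRecord(
            sample_id=f"P{i + 1:03d}-fu",
            patient_id=f"P{i + 1:03d}",
            group="CML",
            phase="chronic",
            sokal=sokal[i],
            timepoint="followup-6mo",
            wbc_per_ul=cfg.wbc_per_ul,
        )
        em.sample_id = rec.sample_id
        samples.append(CohortSample(em, truth, rec))
    return samples


def write_cohort(samples: list[CohortSample], outdir: str | Path) -> Path:
    """Write a simulated cohort to disk: FCS files, ground-truth and manifest CSVs.

    Returns the manifest path.  Manifest columns: path, sample_id,
    patient_id, group, phase, sokal, timepoint, wbc_per_ul.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for em, truth, rec in samples:
        fcs_path = outdir / f"{rec.sample_id}.fcs"
        write_fcs(em, fcs_path)
        rows.append(
            {
                "path": str(fcs_path),
                "sample_id": rec.sample_id,
                "patient_id": rec.patient_id,
                "group": rec.group,
                "phase": rec.phase,
                "sokal": rec.sokal,
                "timepoint": rec.timepoint,
                "wbc_per_ul": rec.wbc_per_ul,
            }
        )
        truth_rows.append(
            {
                "sample_id": rec.sample_id,
                **{f"n_{k}": v for k, v in truth.counts.items()},
                "true_pct_cd26_of_cd45": truth.pct_cd26_of_cd45,
                "true_pct_cd26_of_lsc": truth.pct_cd26_of_lsc,
                "true_abs_cd26_per_ul": truth.abs_cd26_per_ul,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    return manifest
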