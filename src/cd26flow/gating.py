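"""Automated sequential gating down to CD26+ leukemic stem cells.

The hierarchy mirrors the assay's manual strategy, replaced by
density-driven 1-D threshold gates so the pipeline is deterministic and
testable:

    all events
      -> debris_free        (FSC above the debris/cell density trough)
        -> CD45pos          (CD45 above the CD45 trough)
          -> CD34pos        (CD34 above the trough, rare-positive aware)
            -> CD38pos / LSC  (CD38 split; the CD38-low child is the
                               CD34+/CD38- stem compartment)
              -> LSC_CD26pos / LSC_CD26neg

The CD26 positivity cutoff is not taken from the LSC events themselves but
calibrated on CD3+ lymphocytes — an internal control whose CD26 expression
is bimodal — as the density trough between their CD26- and CD26+ modes.

Thresholds come from :func:`density_trough`: a Gaussian-kernel density
estimate (Silverman bandwidth, 512-point grid spanning the 0.1-99.9
percentile range) whose two most prominent modes bracket the returned
minimum.  Unimodal distributions fall back to gate-specific quantile or
robust-sigma thresholds and set a warning flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .exceptions import CalibrationError, ConsistencyError, InsufficientEventsError
from .fcs_io import EventMatrix, PanelConfig, resolve_panel
from .transforms import TransformConfig, scale_marker

__all__ = [
    "GatingConfig",
    "GateResult",
    "TroughResult",
    "GatingReport",
    "GatingModel",
    "density_trough",
    "gate_debris_free",
    "gate_cd45",
    "gate_cd34",
    "split_cd38",
    "cd26_cutoff_from_lymphocytes",
    "classify_cd26",
    "run_gating_pipeline",
]


@dataclass
class GatingConfig:
    """Tunables of the density-threshold gates.

    kde_bandwidth_rule
        Bandwidth selection rule; only ``"silverman"`` is implemented.
    grid_size
        KDE evaluation grid (defines the threshold resolution).
    kde_exact_max_n
        Up to this many events the KDE is the exact Gaussian sum on the
        grid; above it a linear-binned convolution approximation is used
        (indistinguishable at trough-location scale, much faster at 1e5
        events).
    min_events_for_kde
        Below this an operation raises :class:`InsufficientEventsError`.
    min_lsc_events_warn
        LSC gates smaller than this are flagged (not suppressed — reported
        percentages go down to 0.001%, i.e. single-digit event counts).
    mode_prominence_frac / mode_min_separation_frac
        A KDE local maximum counts as a mode only if its prominence is at
        least this fraction of the peak density and it is separated from a
        larger mode by this fraction of the grid range; filters sampling
        wiggles that would masquerade as modes.
    rare_sigma
        The CD34 rare-positive fallback threshold is
        ``mode + rare_sigma x robust SD``.
    manual_overrides
        Fixed per-gate thresholds (scaled axis) taking precedence over
        density estimation; keys: debris_free, CD45pos, CD34pos, CD38,
        CD26, SSC_low, CD3pos.
    """

    kde_bandwidth_rule: str = "silverman"
    grid_size: int = 512
    kde_exact_max_n: int = 10_000
    min_events_for_kde: int = 50
    min_lsc_events_warn: int = 20
    mode_prominence_frac: float = 0.05
    mode_min_separation_frac: float = 0.05
    rare_sigma: float = 5.0
    manual_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_events_for_kde < 10:
            raise ValueError("min_events_for_kde must be >= 10")
        if self.kde_bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {self.kde_bandwidth_rule!r}")


@dataclass
class TroughResult:
    """Outcome of one density-trough threshold estimation."""

    threshold: float
    unimodal: bool
    grid: np.ndarray | None = None
    density: np.ndarray | None = None
    mode_locations: tuple[float, ...] = ()
    flags: list[str] = field(default_factory=list)

    @property
    def grid_step(self) -> float:
        if self.grid is None or len(self.grid) < 2:
            return float("nan")
        return float(self.grid[1] - self.grid[0])

    def __float__(self) -> float:
        return float(self.threshold)


@dataclass
class GateResult:
    """Per-event membership for one node of the gating hierarchy."""

    name: str
    parent: str | None
    member: np.ndarray  # boolean, length = n_events
    threshold: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.member))


def _silverman_bw(x: np.ndarray) -> float:
    n = x.size
    sd = float(np.std(x))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = (q75 - q25) / 1.34
    scale = min(sd, iqr) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def _kde_on_grid(x: np.ndarray, grid: np.ndarray, bw: float, exact: bool) -> np.ndarray:
    n = x.size
    if exact:
        # direct Gaussian sum, O(n * grid)
        z = (grid[None, :] - x[:, None]) / bw
        return np.exp(-0.5 * z * z).sum(axis=0) / (n * bw * np.sqrt(2 * np.pi))
    # linear-binned approximation: histogram + Gaussian convolution
    step = grid[1] - grid[0]
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])
    counts, _ = np.histogram(np.clip(x, grid[0], grid[-1]), bins=edges)
    smooth = gaussian_filter1d(counts.astype(np.float64), sigma=bw / step, mode="constant")
    return smooth / (n * step)


def density_trough(
    values: np.ndarray,
    cfg: GatingConfig | None = None,
    fallback_quantile: float = 0.5,
) -> TroughResult:
    """Place a threshold at the density minimum between the two main modes.

    Fits a Gaussian-kernel density estimate (Silverman bandwidth) on a
    512-point grid over the 0.1-99.9 percentile range, finds the two
    highest modes surviving the prominence/separation filter, and returns
    the lowest-intensity grid point attaining the minimum density strictly
    between them.  If the density is unimodal, returns the
    ``fallback_quantile`` of the data and flags the result.

    Raises :class:`InsufficientEventsError` below ``min_events_for_kde``.
    """
    cfg = cfg or GatingConfig()
    x = np.asarray(values, dtype=np.float64)
    if x.size < cfg.min_events_for_kde:
        raise InsufficientEventsError(
            f"{x.size} events < min_events_for_kde={cfg.min_events_for_kde}"
        )
    lo, hi = np.percentile(x, [0.1, 99.9])
    bw = _silverman_bw(x)
    if not (hi > lo) or not (bw > 0):
        thr = float(np.quantile(x, fallback_quantile))
        return TroughResult(thr, unimodal=True, flags=["degenerate_distribution"])
    grid = np.linspace(lo, hi, cfg.grid_size)
    dens = _kde_on_grid(x, grid, bw, exact=x.size <= cfg.kde_exact_max_n)

    padded = np.concatenate([[0.0], dens, [0.0]])  # let boundary modes count
    dmax = float(dens.max())
    distance = max(1, int(round(cfg.mode_min_separation_frac * cfg.grid_size)))
    peaks, _ = find_peaks(
        padded, prominence=cfg.mode_prominence_frac * dmax, distance=distance
    )
    peaks = peaks - 1  # undo padding
    if len(peaks) < 2:
        thr = float(np.quantile(x, fallback_quantile))
        return TroughResult(
            thr, unimodal=True, grid=grid, density=dens, flags=["unimodal_fallback"]
        )
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    between = dens[left + 1 : right]
    # ties resolved toward the lowest intensity (np.argmin returns the first)
    thr_idx = left + 1 + int(np.argmin(between))
    return TroughResult(
        threshold=float(grid[thr_idx]),
        unimodal=False,
        grid=grid,
        density=dens,
        mode_locations=(float(grid[left]), float(grid[right])),
    )


def _rare_positive_threshold(x: np.ndarray, cfg: GatingConfig) -> float:
    """Upper bound of the negative mode: KDE mode + rare_sigma x robust SD.

    Yields ~zero positives when no rare population exists, while a genuine
    rare-positive population several SDs above the bulk is fully retained.
    """
    med = float(np.median(x))
    mad_sigma = 1.4826 * float(np.median(np.abs(x - med)))
    lo, hi = np.percentile(x, [0.1, 99.9])
    if hi > lo and mad_sigma > 0:
        grid = np.linspace(lo, hi, cfg.grid_size)
        bw = _silverman_bw(x)
        dens = _kde_on_grid(x, grid, bw, exact=x.size <= cfg.kde_exact_max_n)
        mode = float(grid[int(np.argmax(dens))])
    else:
        mode = med
    if mad_sigma == 0:
        return float(np.quantile(x, 0.999))
    return mode + cfg.rare_sigma * mad_sigma


# ---------------------------------------------------------------------------
# Gate operations
# ---------------------------------------------------------------------------


def _scaled(em: EventMatrix, panel: Mapping[str, int], tcfg: TransformConfig, marker: str):
    return scale_marker(em.column(panel[marker]), marker, tcfg)


def _threshold_gate(
    name: str,
    parent: GateResult | None,
    values: np.ndarray,
    cfg: GatingConfig,
    fallback_quantile: float,
    n_total: int,
) -> GateResult:
    mask = parent.member if parent is not None else np.ones(n_total, dtype=bool)
    flags: list[str] = []
    if name in cfg.manual_overrides:
        thr = float(cfg.manual_overrides[name])
        flags.append("manual_override")
    else:
        tr = density_trough(values[mask], cfg, fallback_quantile=fallback_quantile)
        thr = tr.threshold
        flags.extend(tr.flags)
    member = np.zeros(n_total, dtype=bool)
    member[mask] = values[mask] > thr
    return GateResult(
        name=name,
        parent=parent.name if parent is not None else None,
        member=member,
        threshold=thr,
        flags=flags,
    )


def gate_debris_free(
    em: EventMatrix,
    panel: Mapping[str, int] | None = None,
    cfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> GateResult:
    """Remove debris: keep events with FSC above the debris/cell trough."""
    cfg, tcfg = cfg or GatingConfig(), tcfg or TransformConfig()
    panel = panel or resolve_panel(em)
    fsc = _scaled(em, panel, tcfg, "FSC")
    # unimodal fallback: 1st percentile, so a debris-less sample is retained
    return _threshold_gate("debris_free", None, fsc, cfg, 0.01, em.n_events)


def gate_cd45(
    em: EventMatrix,
    parent: GateResult,
    panel: Mapping[str, int] | None = None,
    cfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> GateResult:
    """CD45+ selection inside the debris-free population."""
    cfg, tcfg = cfg or GatingConfig(), tcfg or TransformConfig()
    panel = panel or resolve_panel(em)
    cd45 = _scaled(em, panel, tcfg, "CD45")
    return _threshold_gate("CD45pos", parent, cd45, cfg, 0.01, em.n_events)


def gate_cd34(
    em: EventMatrix,
    parent: GateResult,
    panel: Mapping[str, int] | None = None,
    cfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> GateResult:
    """CD34+ selection inside CD45+; CD34+ events are typically a small minority.

    When the CD34 density is effectively unimodal (the rare-positive
    regime), the threshold falls back to the upper bound of the negative
    mode (``mode + rare_sigma x robust SD``) so that an absent CD34+
    population yields a zero count while a genuinely present rare
    population is fully retained.
    """
    cfg, tcfg = cfg or GatingConfig(), tcfg or TransformConfig()
    panel = panel or resolve_panel(em)
    cd34 = _scaled(em, panel, tcfg, "CD34")
    mask = parent.member
    flags: list[str] = []
    if "CD34pos" in cfg.manual_overrides:
        thr = float(cfg.manual_overrides["CD34pos"])
        flags.append("manual_override")
    else:
        vals = cd34[mask]
        if vals.size < cfg.min_events_for_kde:
            raise InsufficientEventsError(
                f"{vals.size} events in {parent.name} < {cfg.min_events_for_kde}"
            )
        tr = density_trough(vals, cfg, fallback_quantile=0.999)
        if tr.unimodal:
            thr = _rare_positive_threshold(vals, cfg)
            flags.append("rare_positive_fallback")
        else:
            thr = tr.threshold
    member = np.zeros(em.n_events, dtype=bool)
    member[mask] = cd34[mask] > thr
    return GateResult("CD34pos", parent.name, member, threshold=thr, flags=flags)


def split_cd38(
    em: EventMatrix,
    parent: GateResult,
    panel: Mapping[str, int] | None = None,
    cfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> tuple[GateResult, GateResult]:
    """Partition CD34+ by CD38 into progenitors (CD38+) and the LSC compartment.

    The below-threshold child is the CD34+/CD38- stem ("LSC") compartment.
    An insufficient parent yields two empty, flagged children.
    """
    cfg, tcfg = cfg or GatingConfig(), tcfg or TransformConfig()
    panel = panel or resolve_panel(em)
    cd38 = _scaled(em, panel, tcfg, "CD38")
    mask = parent.member
    n = em.n_events
    flags: list[str] = []
    if "CD38" in cfg.manual_overrides:
        thr = float(cfg.manual_overrides["CD38"])
        flags.append("manual_override")
    elif np.count_nonzero(mask) < cfg.min_events_for_kde:
        empty = np.zeros(n, dtype=bool)
        fl = ["insufficient_events"]
        return (
            GateResult("CD38pos", parent.name, empty.copy(), None, list(fl)),
            GateResult("LSC", parent.name, empty.copy(), None, list(fl)),
        )
    else:
        tr = density_trough(cd38[mask], cfg, fallback_quantile=0.5)
        thr = tr.threshold
        flags.extend(tr.flags)
    pos = np.zeros(n, dtype=bool)
    pos[mask] = cd38[mask] > thr
    lsc = mask & ~pos
    lsc_res = GateResult("LSC", parent.name, lsc, threshold=thr, flags=list(flags))
    if lsc_res.count < cfg.min_lsc_events_warn:
        lsc_res.flags.append("low_lsc_events")
    return GateResult("CD38pos", parent.name, pos, threshold=thr, flags=list(flags)), lsc_res


def cd26_cutoff_from_lymphocytes(
    em: EventMatrix,
    debris_free: GateResult,
    cd45pos: GateResult | None = None,
    panel: Mapping[str, int] | None = None,
    cfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> tuple[TroughResult, GateResult]:
    """Calibrate the sample's CD26 cutoff on CD3+ lymphocytes.

    CD3+ lymphocytes (CD45+, SSC-low, CD3 above its trough) carry a bimodal
    CD26 distribution; the trough between their CD26- and CD26+ modes is
    the single CD26 positivity cutoff applied to the LSC compartment.  If
    the lymphocyte CD26 density is unimodal the 99.9th percentile is used
    (the lymphocytes then bound negativity from above) and the cutoff is
    flagged low-confidence.

    Returns the cutoff and the CD3+ lymphocyte gate; raises
    :class:`CalibrationError` when too few CD3+ lymphocytes exist.
    """
    cfg, tcfg = cfg or GatingConfig(), tcfg or TransformConfig()
    panel = panel or resolve_panel(em)
    n = em.n_events
    if cd45pos is None:
        cd45pos = gate_cd45(em, debris_free, panel, cfg, tcfg)

    ssc = _scaled(em, panel, tcfg, "SSC")
    mask = cd45pos.member
    if np.count_nonzero(mask) < cfg.min_events_for_kde:
        raise CalibrationError("too few CD45+ events to locate lymphocytes")
    if "SSC_low" in cfg.manual_overrides:
        ssc_thr = float(cfg.manual_overrides["SSC_low"])
    else:
        tr = density_trough(ssc[mask], cfg, fallback_quantile=0.5)
        ssc_thr = tr.threshold
    low_ssc = mask & (ssc <= ssc_thr)

    cd3 = _scaled(em, panel, tcfg, "CD3")
    if np.count_nonzero(low_ssc) < cfg.min_events_for_kde:
        raise CalibrationError("too few SSC-low CD45+ events to locate CD3+ lymphocytes")
    if "CD3pos" in cfg.manual_overrides:
        cd3_thr = float(cfg.manual_overrides["CD3pos"])
    else:
        tr = density_trough(cd3[low_ssc], cfg, fallback_quantile=0.999)
        cd3_thr = tr.threshold
    cd3_mask = low_ssc & (cd3 > cd3_thr)
    lymph_gate = GateResult(
        "CD3pos_lymphocytes", cd45pos.name, cd3_mask, threshold=cd3_thr
    )
    if lymph_gate.count < cfg.min_events_for_kde:
        raise CalibrationError(
            f"only {lymph_gate.count} CD3+ lymphocytes; CD26 cutoff not calibrated"
        )

    cd26 = _scaled(em, panel, tcfg, "CD26")
    if "CD26" in cfg.manual_overrides:
        cutoff = TroughResult(
            float(cfg.manual_overrides["CD26"]), unimodal=False, flags=["manual_override"]
        )
    else:
        cutoff = density_trough(cd26[cd3_mask], cfg, fallback_quantile=0.999)
        if cutoff.unimodal:
            cutoff.flags.append("cd26_cutoff_low_confidence")
    return cutoff, lymph_gate


def classify_cd26(
    em: EventMatrix,
    lsc: GateResult,
    cutoff: float | TroughResult,
    panel: Mapping[str, int] | None = None,
    cfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> tuple[GateResult, GateResult]:
    """Partition the LSC gate into CD26+ and CD26- by the calibrated cutoff."""
    cfg, tcfg = cfg or GatingConfig(), tcfg or TransformConfig()
    panel = panel or resolve_panel(em)
    thr = float(cutoff)
    if not np.isfinite(thr):
        raise CalibrationError("CD26 cutoff is not finite")
    cd26 = _scaled(em, panel, tcfg, "CD26")
    flags = list(cutoff.flags) if isinstance(cutoff, TroughResult) else []
    pos = lsc.member & (cd26 > thr)
    neg = lsc.member & ~pos
    return (
        GateResult("LSC_CD26pos", lsc.name, pos, threshold=thr, flags=list(flags)),
        GateResult("LSC_CD26neg", lsc.name, neg, threshold=thr, flags=list(flags)),
    )


# ---------------------------------------------------------------------------
# Pipeline / report
# ---------------------------------------------------------------------------

_HIERARCHY = [
    ("debris_free", None),
    ("CD45pos", "debris_free"),
    ("CD34pos", "CD45pos"),
    ("CD38pos", "CD34pos"),
    ("LSC", "CD34pos"),
    ("LSC_CD26pos", "LSC"),
    ("LSC_CD26neg", "LSC"),
]


@dataclass
class GatingReport:
    """Results of the full gating pipeline for one sample."""

    sample_id: str
    gates: dict[str, GateResult]
    thresholds: dict[str, float]
    flags: list[str]
    cd26_available: bool

    @property
    def counts(self) -> dict[str, int]:
        out = {"total": int(next(iter(self.gates.values())).member.size)}
        for name, g in self.gates.items():
            out[name] = g.count
        return out

    def check_nesting(self) -> None:
        """Raise :class:`ConsistencyError` if any child escapes its parent."""
        for child, parent in _HIERARCHY:
            if child not in self.gates or parent is None or parent not in self.gates:
                continue
            if np.any(self.gates[child].member & ~self.gates[parent].member):
                raise ConsistencyError(f"{child} not nested in {parent}")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cd26_available": self.cd26_available,
            "counts": self.counts,
            "thresholds": {k: round(v, 9) for k, v in self.thresholds.items()},
            "flags": sorted(self.flags),
            "gates": {
                name: {"parent": g.parent, "count": g.count, "flags": sorted(g.flags)}
                for name, g in self.gates.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def summary(self) -> str:
        lines = [f"Gating report for sample {self.sample_id or '<unnamed>'}"]
        lines.append(f"{'gate':<22}{'parent':<14}{'count':>9}  threshold  flags")
        counts = self.counts
        lines.append(f"{'(all events)':<22}{'':<14}{counts['total']:>9}")
        for name, parent in _HIERARCHY + [("CD3pos_lymphocytes", "CD45pos")]:
            if name not in self.gates:
                continue
            g = self.gates[name]
            thr = f"{g.threshold:9.4f}" if g.threshold is not None else "        -"
            lines.append(
                f"{name:<22}{g.parent or 'root':<14}{g.count:>9}  {thr}  "
                f"{','.join(g.flags)}"
            )
        if not self.cd26_available:
            lines.append("CD26 quantities unavailable: calibration failed")
        return "\n".join(lines)


def run_gating_pipeline(
    em: EventMatrix,
    panel: PanelConfig | Mapping[str, int] | None = None,
    cfg: GatingConfig | None = None,
    tcfg: TransformConfig | None = None,
) -> GatingReport:
    """Execute the full sequential gating strategy on one acquisition.

    Order: debris removal -> CD45 -> CD34 -> CD38 split, with the CD3
    lymphocyte CD26-cutoff calibration and CD26 classification of the LSC
    compartment.  Deterministic given (events, panel, config).  A failed
    CD26 calibration yields a report with ``cd26_available=False`` (never a
    silent zero).
    """
    cfg, tcfg = cfg or GatingConfig(), tcfg or TransformConfig()
    if isinstance(panel, PanelConfig):
        mapping = resolve_panel(em, panel)
    elif panel is None:
        mapping = resolve_panel(em)
    else:
        mapping = dict(panel)

    debris_free = gate_debris_free(em, mapping, cfg, tcfg)
    cd45 = gate_cd45(em, debris_free, mapping, cfg, tcfg)
    cd34 = gate_cd34(em, cd45, mapping, cfg, tcfg)
    cd38pos, lsc = split_cd38(em, cd34, mapping, cfg, tcfg)

    gates = {
        "debris_free": debris_free,
        "CD45pos": cd45,
        "CD34pos": cd34,
        "CD38pos": cd38pos,
        "LSC": lsc,
    }
    flags: list[str] = []
    for g in gates.values():
        flags.extend(f"{g.name}:{f}" for f in g.flags)

    cd26_available = True
    try:
        cutoff, lymph = cd26_cutoff_from_lymphocytes(
            em, debris_free, cd45, mapping, cfg, tcfg
        )
        gates["CD3pos_lymphocytes"] = lymph
        pos, neg = classify_cd26(em, lsc, cutoff, mapping, cfg, tcfg)
        gates["LSC_CD26pos"] = pos
        gates["LSC_CD26neg"] = neg
        flags.extend(f"CD26:{f}" for f in cutoff.flags)
    except CalibrationError as exc:
        cd26_available = False
        flags.append(f"cd26_unavailable:{exc}")

    thresholds = {
        name: g.threshold for name, g in gates.items() if g.threshold is not None
    }
    report = GatingReport(
        sample_id=em.sample_id,
        gates=gates,
        thresholds=thresholds,
        flags=flags,
        cd26_available=cd26_available,
    )
    report.check_nesting()
    return report


class GatingModel:
    """Model-style wrapper: built from one acquisition, ``fit()`` estimates
    every gate threshold and returns the :class:`GatingReport` results object.
    """

    def __init__(
        self,
        em: EventMatrix,
        panel: PanelConfig | Mapping[str, int] | None = None,
        config: GatingConfig | None = None,
        transform: TransformConfig | None = None,
    ) -> None:
        self.em = em
        self.panel = panel
        self.config = config or GatingConfig()
        self.transform = transform or TransformConfig()

    def fit(self) -> GatingReport:
        return run_gating_pipeline(self.em, self.panel, self.config, self.transform)
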