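"""Density-trough thresholds and the sequential gating pipeline.

Trough placements are checked against two independent oracles: the
analytic minimum of the true mixture density (fine-grid minimization) and
a brute-force direct-sum KDE recomputation on the same grid.
"""

import numpy as np
import pytest

from cd26flow import (
    CalibrationError,
    GatingConfig,
    GatingModel,
    InsufficientEventsError,
    SampleSimConfig,
    TransformConfig,
    cd26_cutoff_from_lymphocytes,
    classify_cd26,
    density_trough,
    gate_cd34,
    gate_cd45,
    gate_debris_free,
    run_gating_pipeline,
    simulate_sample,
    split_cd38,
)
from cd26flow.fcs_io import resolve_panel
from cd26flow.gating import _silverman_bw
from cd26flow.synthetic import CD26POS_LSC, CD34POS_POPULATIONS, LSC_POPULATIONS

from conftest import make_em


def _mixture(rng, n, locs, sds, weights):
    ks = rng.multinomial(n, weights)
    parts = [rng.normal(l, s, size=k) for l, s, k in zip(locs, sds, ks)]
    return np.concatenate(parts)


def _true_density_argmin(locs, sds, weights, lo, hi):
    """Independent fine-grid minimization of the analytic mixture density."""
    from scipy.stats import norm

    xs = np.linspace(lo, hi, 20001)
    dens = sum(w * norm.pdf(xs, l, s) for l, s, w in zip(locs, sds, weights))
    return xs[np.argmin(dens)]


class TestDensityTrough:
    def test_equal_mixture_matches_analytic_minimum(self):
        locs, sds, weights = (-1.0, 2.0), (1.0, 1.0), (0.5, 0.5)
        rng = np.random.default_rng(42)
        x = _mixture(rng, 10_000, locs, sds, weights)
        res = density_trough(x)
        assert not res.unimodal
        truth = _true_density_argmin(locs, sds, weights, -1.0, 2.0)
        assert truth == pytest.approx(0.5, abs=1e-3)  # symmetric mixture
        assert abs(res.threshold - truth) <= 0.15

    def test_threshold_matches_bruteforce_kde_minimization(self):
        """The returned threshold is the argmin of an independently
        recomputed direct-sum KDE on the same grid, between the two modes."""
        from scipy.stats import norm

        rng = np.random.default_rng(9)
        x = _mixture(rng, 8_000, (-1.0, 2.0), (1.0, 1.0), (0.5, 0.5))
        cfg = GatingConfig()
        res = density_trough(x, cfg)
        grid = res.grid
        dens = norm.pdf((grid[None, :] - x[:, None]) / _silverman_bw(x)).sum(
            axis=0
        ) / (x.size * _silverman_bw(x))
        np.testing.assert_allclose(dens, res.density, rtol=1e-9)
        left, right = res.mode_locations
        between = (grid > left) & (grid < right)
        oracle_thr = grid[between][np.argmin(dens[between])]
        step = res.grid_step
        assert abs(res.threshold - oracle_thr) <= step + 1e-12

    def test_unbalanced_mixture_between_modes(self):
        """A 5% component at +2 (unit SDs) is a shoulder, not a separate
        local max of the true density; whichever route is taken, the
        threshold lands strictly between the component locations."""
        rng = np.random.default_rng(3)
        x = _mixture(rng, 10_000, (-1.0, 2.0), (1.0, 1.0), (0.95, 0.05))
        res = density_trough(x, GatingConfig(mode_prominence_frac=0.01))
        assert -1.0 < res.threshold < 2.0

    def test_unimodal_fallback(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 5000)
        res = density_trough(x, fallback_quantile=0.9)
        assert res.unimodal
        assert "unimodal_fallback" in res.flags or "degenerate_distribution" in res.flags
        assert res.threshold == pytest.approx(np.quantile(x, 0.9))

    def test_insufficient_events(self):
        with pytest.raises(InsufficientEventsError):
            density_trough(np.arange(10.0))

    def test_binned_path_agrees_with_exact(self):
        """The fast binned KDE used above 10k events places the trough
        within a grid step of the exact-sum KDE."""
        rng = np.random.default_rng(17)
        x = _mixture(rng, 9_000, (-1.0, 2.0), (1.0, 1.0), (0.5, 0.5))
        exact = density_trough(x, GatingConfig(kde_exact_max_n=100_000))
        binned = density_trough(x, GatingConfig(kde_exact_max_n=10))
        assert abs(exact.threshold - binned.threshold) <= 2 * exact.grid_step


class TestStageGates:
    def test_debris_gate_separation(self, default_sample):
        em, truth = default_sample
        g = gate_debris_free(em)
        is_debris = truth.mask("debris")
        excluded = ~g.member
        assert excluded[is_debris].mean() >= 0.99  # debris excluded
        assert g.member[~is_debris].mean() >= 0.99  # cells retained

    def test_debris_free_all_cells_fallback(self):
        rng = np.random.default_rng(0)
        em = make_em(FSC=rng.normal(500, 60, 20_000), CD3=np.zeros(20_000))
        g = gate_debris_free(em)
        assert "unimodal_fallback" in g.flags
        assert g.count >= 0.985 * 20_000

    def test_cd45_capture(self, default_sample, default_report):
        """The CD45 gate keeps >= 99% of the true CD45-expressing events it
        sees (its parent, the debris-free population)."""
        em, truth = default_sample
        g = default_report.gates["CD45pos"]
        parent = default_report.gates["debris_free"]
        seen = ~truth.mask("debris") & parent.member
        assert g.member[seen].mean() >= 0.99

    def test_cd45_insufficient_parent(self, default_sample):
        em, _ = default_sample
        parent = gate_debris_free(em)
        parent.member = parent.member.copy()
        keep = np.flatnonzero(parent.member)[:30]
        parent.member[:] = False
        parent.member[keep] = True
        with pytest.raises(InsufficientEventsError):
            gate_cd45(em, parent)

    def test_manual_override_used_verbatim(self, default_sample):
        em, _ = default_sample
        cfg = GatingConfig(manual_overrides={"CD45pos": 2.5})
        parent = gate_debris_free(em, cfg=cfg)
        g = gate_cd45(em, parent, cfg=cfg)
        assert g.threshold == 2.5
        assert "manual_override" in g.flags

    def test_cd34_recovery_rare_regime(self, default_sample, default_report):
        """CD34+ events are a ~2% minority of CD45+; recovered count within
        +/-10% of ground truth."""
        em, truth = default_sample
        g = default_report.gates["CD34pos"]
        n_true = int(truth.mask(*CD34POS_POPULATIONS).sum())
        assert abs(g.count - n_true) <= 0.10 * n_true

    def test_cd34_recovery_abundant_regime(self):
        em, truth = simulate_sample(
            SampleSimConfig(seed=23, target_pct_cd26_of_cd45=1.0, n_events=50_000)
        )
        rep = run_gating_pipeline(em)
        n_true = int(truth.mask(*CD34POS_POPULATIONS).sum())
        assert abs(rep.counts["CD34pos"] - n_true) <= 0.10 * n_true

    def test_cd34_zero_positive_population(self):
        """No CD34+ population at all: rare-positive fallback yields a zero
        count and a flag."""
        rng = np.random.default_rng(5)
        n = 30_000
        em = make_em(
            FSC=rng.normal(500, 60, n),
            CD45=np.sinh(rng.normal(5.0, 0.3, n)) * 150,
            CD34=np.sinh(rng.normal(0.2, 0.25, n)) * 150,
        )
        parent = gate_debris_free(em)
        g = gate_cd34(em, parent)
        assert "rare_positive_fallback" in g.flags
        assert g.count == 0

    def test_cd38_split_partition_and_accuracy(self, default_sample, default_report):
        em, truth = default_sample
        pos, lsc = default_report.gates["CD38pos"], default_report.gates["LSC"]
        parent = default_report.gates["CD34pos"]
        assert pos.count + lsc.count == parent.count
        assert not np.any(pos.member & lsc.member)
        # misclassification against ground truth <= 1% of the CD34+ gate
        truth_lsc = truth.mask(*LSC_POPULATIONS)
        mis = np.sum(lsc.member & parent.member & ~truth_lsc) + np.sum(
            pos.member & truth_lsc
        )
        assert mis <= 0.01 * max(parent.count, 1)

    def test_cd38_split_insufficient_parent(self, default_sample):
        em, _ = default_sample
        parent = gate_debris_free(em)
        tiny = parent.member.copy()
        tiny[np.flatnonzero(tiny)[10:]] = False
        parent.member = tiny
        pos, lsc = split_cd38(em, parent)
        assert pos.count == 0 and lsc.count == 0
        assert "insufficient_events" in pos.flags


class TestCD26Calibration:
    def test_cutoff_near_analytic_trough(self, default_sample):
        em, _ = default_sample
        debris_free = gate_debris_free(em)
        cutoff, lymph = cd26_cutoff_from_lymphocytes(em, debris_free)
        # CD3+ lymphocyte CD26 mixture: modes 0.2 / 2.8, SDs 0.25 / 0.30,
        # weights 0.070 / 0.085 of events
        w = 0.070 + 0.085
        truth = _true_density_argmin(
            (0.2, 2.8), (0.25, 0.30), (0.070 / w, 0.085 / w), 0.2, 2.8
        )
        assert abs(cutoff.threshold - truth) <= 0.15
        assert lymph.count > 10_000

    def test_cutoff_invariant_under_raw_rescaling(self, default_sample):
        """Rescaling the raw axes and the cofactor together preserves the
        scaled-axis geometry, hence the cutoff."""
        em, _ = default_sample
        c = 4.0
        em2 = make_em(
            **{
                m: em.column(i) * (c if m not in ("FSC", "SSC") else 1.0)
                for m, i in resolve_panel(em).items()
            }
        )
        t1, t2 = TransformConfig(), TransformConfig(cofactor=150.0 * c)
        cut1, _ = cd26_cutoff_from_lymphocytes(em, gate_debris_free(em, tcfg=t1), tcfg=t1)
        cut2, _ = cd26_cutoff_from_lymphocytes(em2, gate_debris_free(em2, tcfg=t2), tcfg=t2)
        assert cut1.threshold == pytest.approx(cut2.threshold, abs=cut1.grid_step)

    def test_unimodal_lymphocyte_cd26_flags_low_confidence(self):
        rng = np.random.default_rng(8)
        n = 40_000
        em = make_em(
            FSC=rng.normal(450, 60, n),
            SSC=rng.normal(150, 40, n),
            CD45=np.sinh(rng.normal(5.2, 0.3, n)) * 150,
            CD3=np.sinh(np.concatenate([
                rng.normal(0.2, 0.25, n // 2), rng.normal(4.0, 0.3, n - n // 2)
            ])) * 150,
            CD26=np.sinh(rng.normal(0.2, 0.25, n)) * 150,  # all CD26-negative
        )
        cutoff, _ = cd26_cutoff_from_lymphocytes(em, gate_debris_free(em))
        assert cutoff.unimodal
        assert "cd26_cutoff_low_confidence" in cutoff.flags

    def test_too_few_cd3_lymphocytes_raises(self):
        rng = np.random.default_rng(2)
        n = 20_000
        em = make_em(
            FSC=rng.normal(450, 60, n),
            SSC=rng.normal(150, 40, n),
            CD45=np.sinh(rng.normal(5.2, 0.3, n)) * 150,
            CD3=np.sinh(rng.normal(0.2, 0.25, n)) * 150,  # no CD3+ subset
            CD26=np.sinh(rng.normal(0.2, 0.25, n)) * 150,
        )
        with pytest.raises(CalibrationError):
            cd26_cutoff_from_lymphocytes(em, gate_debris_free(em))

    def test_classify_cd26_partition_and_pinned_recovery(self):
        em, truth = simulate_sample(
            SampleSimConfig(seed=31, target_pct_cd26_of_cd45=0.001, min_cd26pos_events=5)
        )
        rep = run_gating_pipeline(em)
        assert truth.counts[CD26POS_LSC] == 5
        assert rep.counts["LSC_CD26pos"] == 5
        assert rep.counts["LSC_CD26pos"] + rep.counts["LSC_CD26neg"] == rep.counts["LSC"]

    def test_classify_cd26_empty_lsc(self, default_sample):
        em, _ = default_sample
        lsc = gate_debris_free(em)
        lsc.member = np.zeros(em.n_events, dtype=bool)
        lsc.name = "LSC"
        pos, neg = classify_cd26(em, lsc, 1.5)
        assert pos.count == 0 and neg.count == 0


class TestPipeline:
    def test_deterministic_report(self, default_sample, default_report):
        em, _ = default_sample
        again = run_gating_pipeline(em)
        assert again.to_json() == default_report.to_json()

    def test_nesting_invariant(self, default_report):
        default_report.check_nesting()  # raises on violation
        g = default_report.gates
        assert g["LSC_CD26pos"].count <= g["LSC"].count <= g["CD34pos"].count
        assert g["CD34pos"].count <= g["CD45pos"].count <= g["debris_free"].count

    def test_partition_conservation(self, default_report):
        c = default_report.counts
        assert c["CD38pos"] + c["LSC"] == c["CD34pos"]
        assert c["LSC_CD26pos"] + c["LSC_CD26neg"] == c["LSC"]

    def test_control_sample_no_cd26_positivity(self, control_report):
        assert control_report.cd26_available
        assert control_report.counts["LSC_CD26pos"] == 0

    def test_recovery_at_default_target(self, default_sample, default_report):
        """At the reported median 0.02% the pipeline estimate lands within 3
        binomial SEs of the target."""
        em, truth = default_sample
        c = default_report.counts
        est = 100 * c["LSC_CD26pos"] / c["CD45pos"]
        p = 0.02 / 100
        se = 100 * np.sqrt(p * (1 - p) / c["CD45pos"])
        assert abs(est - 0.02) <= 3 * se

    def test_membership_invariant_under_joint_rescaling(self, default_sample):
        em, _ = default_sample
        c = 2.5
        panel = resolve_panel(em)
        em2 = make_em(
            **{
                m: em.column(i) * (c if m not in ("FSC", "SSC") else 1.0)
                for m, i in panel.items()
            }
        )
        r1 = run_gating_pipeline(em, tcfg=TransformConfig())
        r2 = run_gating_pipeline(em2, tcfg=TransformConfig(cofactor=150.0 * c))
        for name in ("debris_free", "CD45pos", "CD34pos", "LSC", "LSC_CD26pos"):
            assert r1.counts[name] == r2.counts[name]

    def test_model_results_wrapper(self, default_sample):
        em, _ = default_sample
        report = GatingModel(em).fit()
        assert report.counts == run_gating_pipeline(em).counts
        text = report.summary()
        assert "LSC_CD26pos" in text and "debris_free" in text
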