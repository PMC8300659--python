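"""Generator contracts: determinism, exact noiseless identities, noise scaling."""

import dataclasses

import numpy as np
import pytest

from vimcys.alkylation import estimate_kobs, traces_to_frame
from vimcys.densitometry import lane_ratio, percent_inhibition
from vimcys.simulate import (
    AssayConstants,
    C328S_KINETICS,
    GelCondition,
    GelDesign,
    IonSpec,
    KineticsPreset,
    WT_KINETICS,
    figure6a_design,
    make_competition_curves,
    make_gel_table,
    make_kinetics_plate,
    make_structure_fixture,
    nearby_arrangement,
    true_kobs,
)
from vimcys.competition import BindingModel


def make_preset(**kw):
    base = dict(variant="wt", pka_values=(7.0,), limiting_rates=(0.04,),
                baseline_rate=0.002, noise_sd=0.0, ph_jitter_sd=0.0,
                replicates=1, background_wells=0)
    base.update(kw)
    return KineticsPreset(**base)


class TestKineticsGenerator:
    def test_zero_rate_trace_is_exactly_flat(self):
        preset = make_preset(pka_values=(), limiting_rates=(), baseline_rate=0.0,
                             ph_grid=(7.0,))
        (trace,) = make_kinetics_plate(preset)
        assert np.all(trace.fluorescence == preset.f0)

    def test_true_kobs_limits_and_midpoint(self):
        p = make_preset()
        assert true_kobs(p, -50.0) == pytest.approx(p.baseline_rate, abs=1e-12)
        assert true_kobs(p, 50.0) == pytest.approx(
            p.baseline_rate + sum(p.limiting_rates), abs=1e-12)
        # at pH == pKa the site contributes exactly half its limiting rate
        assert true_kobs(p, 7.0) == pytest.approx(
            p.baseline_rate + p.limiting_rates[0] / 2.0, rel=1e-14)

    def test_true_kobs_nondecreasing_in_ph(self):
        ph = np.linspace(1, 13, 200)
        k = [true_kobs(WT_KINETICS, x) for x in ph]
        assert np.all(np.diff(k) >= 0)

    def test_early_slope_matches_rate_law_oracle(self):
        """Noiseless single site at its pKa: the ln(F/F0) early slope must
        equal the OLS slope of the closed-form logistic evaluated
        independently, whose underlying rate is baseline + k_lim/2."""
        p = make_preset(ph_grid=(7.0,))
        (trace,) = make_kinetics_plate(p)
        k = p.baseline_rate + p.limiting_rates[0] / 2.0
        # independent evaluation of the generator's curve family
        t = np.asarray(p.times)
        F = p.f0 * p.fmax * np.exp(k * t) / (p.fmax + p.f0 * (np.exp(k * t) - 1))
        assert np.allclose(trace.fluorescence, F, rtol=1e-12)
        est = estimate_kobs(trace, f0=p.f0, top=p.fmax)
        y = np.log(F[: est.window[1]] / p.f0)
        x = t[: est.window[1]]
        slope_oracle = np.polyfit(x, y, 1)[0]
        assert est.slope == pytest.approx(slope_oracle, rel=1e-9)
        # and the early-phase slope approximates the true rate from below
        # (logistic curvature biases it low by <25% inside the window)
        assert 0.75 * k < est.slope <= k

    def test_same_seed_byte_identical(self):
        a = traces_to_frame(make_kinetics_plate(WT_KINETICS, seed=5)).to_csv()
        b = traces_to_frame(make_kinetics_plate(WT_KINETICS, seed=5)).to_csv()
        assert a == b
        c = traces_to_frame(make_kinetics_plate(WT_KINETICS, seed=6)).to_csv()
        assert a != c

    def test_background_wells_flat_at_f0(self):
        preset = dataclasses.replace(WT_KINETICS, noise_sd=0.0, ph_jitter_sd=0.0)
        traces = make_kinetics_plate(preset, seed=0)
        for tr in traces:
            if tr.role == "background":
                assert np.all(tr.fluorescence == preset.f0)

    def test_non_finite_parameter_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="baseline_rate"):
            make_preset(baseline_rate=float("nan"))
        with pytest.raises(ValueError, match="pka_values"):
            make_preset(pka_values=(float("inf"),), limiting_rates=(0.01,))

    def test_wt_and_mutant_preset_shapes(self):
        assert len(WT_KINETICS.pka_values) == 2
        assert len(C328S_KINETICS.pka_values) == 0


class TestGelGenerator:
    def row(self, **kw):
        base = dict(variant="wt", agent="DBB", agent_conc=24.0, pre_salt="none",
                    salt_conc=0.0, true_inhibition=0.0, baseline_ratio=1.0,
                    replicates=3, ratio_kind="oligomer")
        base.update(kw)
        return GelCondition(**base)

    def test_zero_noise_ratio_exact(self):
        design = GelDesign(rows=(self.row(baseline_ratio=1.3),), noise_cv=0.0)
        lanes = make_gel_table(design)
        for ln in lanes:
            assert lane_ratio(ln, "oligomer") == pytest.approx(1.3, rel=1e-12)

    def test_full_inhibition_gives_zero_signal_band(self):
        design = GelDesign(rows=(self.row(true_inhibition=1.0),), noise_cv=0.0)
        for ln in make_gel_table(design):
            assert ln.bands["oligomer"] == 0.0

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            GelDesign(rows=(self.row(),), noise_cv=-0.1)

    def test_determinism(self):
        d = figure6a_design(seed=3)
        a = make_gel_table(d)
        b = make_gel_table(d)
        assert all(x.bands == y.bands for x, y in zip(a, b))

    @pytest.mark.parametrize("agent,target,mc_sd", [
        ("DBB", 76.0, 1.68), ("TMEA", 56.0, 3.09),
    ])
    def test_figure6a_recovery_within_mc_tolerance(self, agent, target, mc_sd):
        """Percent-inhibition estimates stay within 4 sampling SDs of the
        encoded fractions (SDs frozen from a 10^4-draw Monte-Carlo of the
        lognormal noise model at CV 0.06, n=3)."""
        for seed in range(5):
            lanes = make_gel_table(figure6a_design(seed=seed))
            treated = [l for l in lanes if l.agent == agent and l.pre_salt == "ZnCl2"]
            control = [l for l in lanes if l.agent == agent and l.pre_salt == "none"]
            res = percent_inhibition(treated, control)
            assert abs(res.percent_inhibition - target) < 4 * mc_sd

    def test_estimator_sd_scales_as_inverse_sqrt_replicates(self):
        """Doubling replicates x4 (3 -> 12) should halve the estimator SD
        (Monte-Carlo oracle ratio 2.06)."""
        def sd_at(reps):
            vals = []
            for seed in range(40):
                design = figure6a_design(replicates=reps, seed=seed)
                lanes = make_gel_table(design)
                treated = [l for l in lanes if l.agent == "DBB" and l.pre_salt == "ZnCl2"]
                control = [l for l in lanes if l.agent == "DBB" and l.pre_salt == "none"]
                vals.append(percent_inhibition(treated, control).percent_inhibition)
            return np.std(vals)

        ratio = sd_at(3) / sd_at(12)
        assert 1.4 < ratio < 2.9


class TestCompetitionGenerator:
    def test_zero_zinc_baseline_for_both_curves(self):
        model = BindingModel(kd_protein_um=0.5, n_sites=2.0)
        assay = make_competition_curves(AssayConstants(), model,
                                        zn_totals=[0.0, 1.0, 2.0, 3.0, 4.0],
                                        noise_sd=0.0)
        at_zero = assay.points[assay.points["zn_total_um"] == 0.0]
        assert np.allclose(at_zero["a620"], model.abs_baseline)

    def test_noncompeting_protein_limit(self):
        """With vanishing affinity the protein curve equals the free curve."""
        model = BindingModel(kd_protein_um=1e9, n_sites=2.0)
        assay = make_competition_curves(AssayConstants(), model, noise_sd=0.0)
        free = assay.curve(False)["a620"].to_numpy()
        prot = assay.curve(True)["a620"].to_numpy()
        assert np.allclose(free, prot, atol=1e-6)

    def test_negative_zn_totals_rejected(self):
        with pytest.raises(ValueError):
            make_competition_curves(AssayConstants(),
                                    BindingModel(), zn_totals=[-1.0])


class TestStructureFixture:
    def test_nearby_and_distant_exact_sg_separation(self):
        from vimcys.geometry import cys_sg_distances

        near = make_structure_fixture(nearby_arrangement())
        (pair,) = cys_sg_distances(near, 0, inter_chain_only=True)
        assert pair.distance == pytest.approx(4.0, abs=1e-9)
        from vimcys.simulate import distant_arrangement
        far = make_structure_fixture(distant_arrangement())
        (pair,) = cys_sg_distances(far, 0, inter_chain_only=True)
        assert pair.distance == pytest.approx(22.0, abs=1e-9)

    def test_pinned_zinc_sits_at_coordination_distance_every_frame(self):
        arr = nearby_arrangement(n_frames=6, frame_jitter_sd=0.3,
                                 ions=(IonSpec(mode="pinned"),), seed=11)
        m = make_structure_fixture(arr)
        for f in range(m.n_frames):
            atoms = m.frame(f)
            sg = atoms[(atoms.chain_id == "A") & (atoms.atom_name == "SG")]
            zn = atoms[atoms.element == "ZN"]
            d = np.linalg.norm(sg.coord[0] - zn.coord[0])
            assert d == pytest.approx(2.5, abs=1e-5)

    def test_walk_ions_stay_far(self):
        arr = nearby_arrangement(
            n_frames=10, ions=(IonSpec(mode="walk"),), seed=2)
        m = make_structure_fixture(arr)
        far_frames = 0
        for f in range(m.n_frames):
            atoms = m.frame(f)
            ion = atoms[atoms.hetero]
            prot = atoms[~atoms.hetero]
            dmin = np.min(np.linalg.norm(prot.coord - ion.coord[0], axis=1))
            far_frames += dmin > 9.0  # 3x the default 3 A contact cutoff
        assert far_frames >= 2  # >=20% of frames

    def test_determinism_and_frame_validation(self):
        arr = nearby_arrangement(n_frames=3, frame_jitter_sd=0.5, seed=9)
        a = make_structure_fixture(arr)
        b = make_structure_fixture(arr)
        assert np.array_equal(a.stack.coord, b.stack.coord)
        with pytest.raises(ValueError):
            nearby_arrangement(n_frames=0)


def test_assay_constants_consistency():
    c = AssayConstants()
    assert c.probe_ratio == pytest.approx(4.0)
    with pytest.raises(ValueError):
        AssayConstants(zincon_conc=-1.0)
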