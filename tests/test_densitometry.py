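"""Band-ratio quantification, protection statistics, spacer trend."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vimcys.densitometry import (LaneRecord, ProtectionResult,
                                 compare_conditions, frame_to_lanes,
                                 lanes_to_frame, modification_ratio,
                                 oligomer_ratio, percent_inhibition,
                                 protection_vs_spacer)
from vimcys.registry import (Crosslinker, DEFAULT_REGISTRY, registry_from_json,
                             registry_to_json, validate_registry)


def lane(bands, agent="DBB", pre_salt="none", salt_conc=0.0, rep=1):
    return LaneRecord(lane_id=f"L{rep}", variant="wt", agent=agent,
                      agent_conc=24.0, pre_salt=pre_salt, salt_conc=salt_conc,
                      replicate=rep, bands=bands)


class TestRatios:
    def test_modification_ratio(self):
        assert modification_ratio(lane({"biotin": 200.0, "vimentin": 100.0})) == 2.0
        assert modification_ratio(lane({"biotin": 0.0, "vimentin": 50.0})) == 0.0

    def test_oligomer_ratio(self):
        assert oligomer_ratio(lane({"oligomer": 50.0, "monomer": 100.0})) == 0.5
        assert oligomer_ratio(lane({"oligomer": 0.0, "monomer": 10.0})) == 0.0

    def test_zero_reference_band_error_names_lane(self):
        with pytest.raises(ValueError, match="L1"):
            modification_ratio(lane({"biotin": 1.0, "vimentin": 0.0}))
        with pytest.raises(ValueError, match="L1"):
            oligomer_ratio(lane({"oligomer": 1.0, "monomer": 0.0}))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            lane({"monomer": -5.0})


class TestPercentInhibition:
    def groups(self, treated_vals, control_vals):
        treated = [lane({"oligomer": v, "monomer": 100.0}, pre_salt="ZnCl2",
                        salt_conc=500.0, rep=i) for i, v in enumerate(treated_vals)]
        control = [lane({"oligomer": v, "monomer": 100.0}, rep=i)
                   for i, v in enumerate(control_vals)]
        return treated, control

    def test_equal_groups_zero_inhibition(self):
        res = percent_inhibition(*self.groups([50, 60, 55], [50, 60, 55]))
        assert res.percent_inhibition == pytest.approx(0.0, abs=1e-12)

    def test_fully_blocked_hundred_percent(self):
        res = percent_inhibition(*self.groups([0, 0, 0], [50, 60, 55]))
        assert res.percent_inhibition == pytest.approx(100.0)

    def test_enhancement_reported_negative_unclipped(self):
        res = percent_inhibition(*self.groups([80, 90, 85], [40, 45, 42]))
        assert res.percent_inhibition < -80.0

    def test_invariant_formula(self):
        res = percent_inhibition(*self.groups([20, 25, 30], [50, 60, 55]))
        assert res.percent_inhibition == pytest.approx(
            (1 - res.ratio_treated / res.ratio_control) * 100.0, rel=1e-12)

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        t, c = self.groups([20, 25, 30], [50, 60, 55])
        base = percent_inhibition(t, c).percent_inhibition
        t2 = [lane({k: v * scale for k, v in ln.bands.items()},
                   pre_salt="ZnCl2", rep=i) for i, ln in enumerate(t)]
        c2 = [lane({k: v * scale for k, v in ln.bands.items()}, rep=i)
              for i, ln in enumerate(c)]
        assert percent_inhibition(t2, c2).percent_inhibition == \
            pytest.approx(base, rel=1e-9)

    def test_mixed_agents_rejected(self):
        t, c = self.groups([20, 25], [50, 60])
        c[0].agent = "TMEA"
        with pytest.raises(ValueError):
            percent_inhibition(t, c)


class TestCompareConditions:
    def test_identical_groups_p_one(self):
        p, _ = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_paired_identical_zero_effect(self):
        p, test = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert p == 1.0 and test == "paired t-test"

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1.0, 2.0])

    def test_power_against_strong_protection(self):
        """76% true inhibition, CV 0.1, 3v3 lanes: the t-test rejects at
        alpha=0.05 in at least 80% of 100 seeds (Monte-Carlo power oracle
        gives ~1.0)."""
        from vimcys.simulate import GelCondition, GelDesign, make_gel_table
        from vimcys.densitometry import percent_inhibition as pi

        rows = (
            GelCondition("wt", "DBB", 24.0, "none", 0.0, 0.0, 1.0, 3, "oligomer"),
            GelCondition("wt", "DBB", 24.0, "ZnCl2", 500.0, 0.76, 1.0, 3, "oligomer"),
        )
        rejections = 0
        for seed in range(100):
            lanes = make_gel_table(GelDesign(rows=rows, noise_cv=0.1), seed=seed)
            treated = [l for l in lanes if l.pre_salt == "ZnCl2"]
            control = [l for l in lanes if l.pre_salt == "none"]
            rejections += pi(treated, control).p_value < 0.05
        assert rejections >= 80


class TestSpacerTrend:
    def _res(self, agent, inhibition):
        return ProtectionResult(agent=agent, salt="ZnCl2", salt_conc=500.0,
                                ratio_control=1.0, ratio_treated=1.0,
                                percent_inhibition=inhibition, p_value=0.01,
                                test="unpaired t-test", n=3)

    def test_printed_values_give_perfect_inverse_trend(self):
        # the three reported protection magnitudes vs spacer arms
        results = [self._res("DBB", 76.0), self._res("TMEA", 56.0),
                   self._res("BMH", 0.0)]
        out = protection_vs_spacer(results)
        assert out["rho"] == pytest.approx(-1.0)
        assert out["trend"] == "inverse"
        assert out["pairs"][0] == (4.88, 76.0)

    def test_all_equal_is_flat_without_error(self):
        results = [self._res(a, 10.0) for a in ("DBB", "TMEA", "BMH")]
        out = protection_vs_spacer(results)
        assert out["trend"] == "flat"
        assert np.isnan(out["rho"])

    def test_order_invariance(self):
        results = [self._res("DBB", 76.0), self._res("TMEA", 56.0),
                   self._res("BMH", 10.0)]
        a = protection_vs_spacer(results)
        b = protection_vs_spacer(list(reversed(results)))
        assert a == b

    def test_duplicates_rejected(self):
        results = [self._res("DBB", 76.0), self._res("DBB", 50.0),
                   self._res("BMH", 0.0)]
        with pytest.raises(ValueError):
            protection_vs_spacer(results)


class TestDirectionalPresets:
    def test_dst_amine_control_shows_no_protection(self):
        """Amine-reactive DST: inhibition indistinguishable from zero
        (mean within 2 SEM across 50 seeds)."""
        from vimcys.simulate import figure6a_design, make_gel_table

        vals = []
        for seed in range(50):
            lanes = make_gel_table(figure6a_design(seed=seed))
            t = [l for l in lanes if l.agent == "DST" and l.pre_salt == "ZnCl2"]
            c = [l for l in lanes if l.agent == "DST" and l.pre_salt == "none"]
            vals.append(percent_inhibition(t, c).percent_inhibition)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 2 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_magnesium_enhances_dbb_crosslinking(self):
        from vimcys.simulate import make_gel_table, mg_dbb_design

        vals = []
        for seed in range(20):
            lanes = make_gel_table(mg_dbb_design(seed=seed))
            t = [l for l in lanes if l.agent == "DBB" and l.pre_salt == "MgCl2"]
            c = [l for l in lanes if l.agent == "DBB" and l.pre_salt == "none"]
            vals.append(percent_inhibition(t, c).percent_inhibition)
        assert np.mean(vals) < -15.0  # enhancement, not protection

    def test_magnesium_no_protection_of_alkylation(self):
        from vimcys.simulate import make_gel_table, mg_dbb_design

        vals = []
        for seed in range(50):
            lanes = make_gel_table(mg_dbb_design(seed=seed))
            t = [l for l in lanes if l.agent == "IacB" and l.pre_salt == "MgCl2"]
            c = [l for l in lanes if l.agent == "IacB" and l.pre_salt == "none"]
            vals.append(percent_inhibition(t, c, ratio_kind="modification")
                        .percent_inhibition)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 2 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_zinc_dose_series_monotone_protection(self):
        from vimcys.simulate import figure2d_design, make_gel_table
        from vimcys.densitometry import lane_ratio

        lanes = make_gel_table(figure2d_design(seed=1))
        means = []
        for conc in sorted({l.salt_conc for l in lanes}):
            grp = [l for l in lanes if l.salt_conc == conc]
            means.append(np.mean([lane_ratio(l, "modification") for l in grp]))
        assert all(b < a * 1.05 for a, b in zip(means, means[1:]))


class TestRegistryAndIO:
    def test_registry_spacer_arms(self):
        by_name = {x.name: x for x in DEFAULT_REGISTRY}
        assert by_name["DBB"].spacer_arm == 4.88
        assert by_name["TMEA"].arms == 3
        assert by_name["DST"].chemistry == "amine"

    def test_registry_json_round_trip(self, tmp_path):
        path = tmp_path / "xlinkers.json"
        registry_to_json(DEFAULT_REGISTRY, path)
        back = registry_from_json(path)
        assert back == list(DEFAULT_REGISTRY)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            validate_registry([Crosslinker("DBB", "thiol", 4.88)] * 2)

    def test_unknown_chemistry_rejected(self):
        with pytest.raises(ValueError):
            Crosslinker("X", "carboxyl", 5.0)

    def test_gel_csv_round_trip(self):
        from vimcys.simulate import figure6a_design, make_gel_table

        lanes = make_gel_table(figure6a_design(seed=0))
        back = frame_to_lanes(lanes_to_frame(lanes))
        assert len(back) == len(lanes)
        assert back[0].bands == pytest.approx(lanes[0].bands)
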