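"""Species mass arithmetic, ladder inference, peak assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sodims.species import (
    LadderError,
    SpeciesDefinition,
    assign_peaks,
    infer_charge_and_mass,
    neutral_mass,
    theoretical_mz,
)


def _species(name="s", n=1, m=15588.5, ncu=0, nzn=0, k=2):
    return SpeciesDefinition(
        name=name, oligomer_order=n, apo_monomer_mass=m, n_cu=ncu, n_zn=nzn,
        proton_displacement_per_metal=k,
    )


class TestNeutralMass:
    def test_zero_metals_is_apo_mass(self):
        assert neutral_mass(_species(m=12345.6)) == 12345.6

    def test_dimer_is_twice_monomer(self):
        mono = neutral_mass(_species(ncu=1, nzn=1))
        dim = neutral_mass(_species(n=2, ncu=2, nzn=2))
        assert dim == pytest.approx(2 * mono, rel=1e-14)

    def test_holo_monomer_arithmetic_oracle(self):
        # 10,000 + (63.546 - 2*1.00728) + (65.38 - 2*1.00728), frozen
        m = neutral_mass(_species(m=10000.0, ncu=1, nzn=1, k=2))
        assert m == pytest.approx(10124.89688, abs=1e-9)

    def test_mass_ordering_apo_single_holo(self):
        apo = neutral_mass(_species())
        cu = neutral_mass(_species(ncu=1))
        zn = neutral_mass(_species(nzn=1))
        holo = neutral_mass(_species(ncu=1, nzn=1))
        assert apo < cu < zn < holo

    def test_metal_overload_rejected(self):
        with pytest.raises(ValueError, match="metals"):
            _species(ncu=2, nzn=1)


class TestTheoreticalMz:
    def test_printed_dimer_and_monomer_values(self):
        # printed main-text peaks: 10+ dimer at 3,144; 6+ monomer at 2,620
        assert round(theoretical_mz(31426.9, 10)) == 3144
        assert round(theoretical_mz(15714.9, 6)) == 2620

    def test_singly_charged(self):
        assert theoretical_mz(1000.0, 1) == pytest.approx(1001.00728)

    def test_strictly_decreasing_in_charge(self):
        m = neutral_mass(_species(n=2, ncu=2, nzn=2))
        mzs = [theoretical_mz(m, z) for z in range(1, 31)]
        assert np.all(np.diff(mzs) < 0)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            theoretical_mz(1000.0, 0)


class TestChargeLadder:
    def test_printed_dimer_pair(self):
        charges, mass = infer_charge_and_mass([2858.0, 2620.0])
        assert charges == [11, 12]
        assert mass == pytest.approx(31427.4, abs=1.0)

    def test_printed_monomer_pair(self):
        charges, mass = infer_charge_and_mass([2246.0, 1965.0])
        assert charges == [7, 8]
        assert mass == pytest.approx(15715.0, abs=2.0)

    def test_single_peak_underdetermined(self):
        with pytest.raises(LadderError, match="underdetermined"):
            infer_charge_and_mass([2620.0])

    def test_inconsistent_ladder_reports_spread(self):
        with pytest.raises(LadderError, match="spread"):
            infer_charge_and_mass([2858.0, 2620.0, 2300.0])

    @given(mass=st.floats(5000.0, 80000.0), z0=st.integers(1, 28),
           n=st.integers(2, 6))
    @settings(deadline=None, max_examples=60)
    def test_exact_on_noiseless_ladders(self, mass, z0, n):
        zs = list(range(z0, min(z0 + n, 31)))
        mzs = [theoretical_mz(mass, z) for z in zs]
        charges, m_est = infer_charge_and_mass(mzs)
        assert charges == zs
        assert m_est == pytest.approx(mass, abs=0.01)


class TestAssignPeaks:
    @pytest.fixture()
    def hyp_list(self, hypotheses):
        return list(hypotheses.values())

    def test_coincident_dimer_monomer_at_2620(self, hyp_list):
        mz = theoretical_mz(neutral_mass(
            next(h for h in hyp_list if h.name == "holo-dimer")), 12)
        out = assign_peaks([(mz, 100.0)], hyp_list, z_range=(5, 16))
        names = {(a.species, a.charge) for a in out}
        assert names == {("holo-dimer", 12), ("holo-monomer", 6)}
        assert all("mz_coincident" in a.ambiguity_flags for a in out)

    def test_single_metal_peak_metal_ambiguous(self, hyp_list):
        cu = next(h for h in hyp_list if h.name == "single-metal-monomer-cu")
        mz = theoretical_mz(neutral_mass(cu), 7)
        out = assign_peaks([(mz, 50.0)], hyp_list, z_range=(6, 16),
                           mass_resolution_da=4.0)
        assert [a.species for a in out] == ["single-metal-monomer-cu"]
        assert "metal_identity_ambiguous" in out[0].ambiguity_flags

    def test_metal_flag_requires_coarse_resolution(self, hyp_list):
        # Cu-only vs Zn-only differ by ~1.83 Da: resolvable at 1 Da resolution
        cu = next(h for h in hyp_list if h.name == "single-metal-monomer-cu")
        mz = theoretical_mz(neutral_mass(cu), 7)
        out = assign_peaks([(mz, 50.0)], hyp_list, z_range=(6, 16),
                           mass_resolution_da=1.0)
        assert out[0].ambiguity_flags == set()

    def test_far_peak_unassigned(self, hyp_list):
        assert assign_peaks([(1234.5, 10.0)], hyp_list, z_range=(6, 16)) == []

    def test_empty_hypotheses_rejected(self):
        with pytest.raises(ValueError):
            assign_peaks([(1000.0, 1.0)], [])


class TestHypothesesIO:
    def test_json_roundtrip(self, hypotheses):
        from sodims.species import hypotheses_from_json, hypotheses_to_json

        hyp_list = list(hypotheses.values())
        back = hypotheses_from_json(hypotheses_to_json(hyp_list))
        assert back == hyp_list


class TestResolveCoincidence:
    def _native_frame_and_calib(self, presets, truth, fitted_calibration):
        from sodims.synthetic import synth_protein_frame

        frame, tt = synth_protein_frame(presets["native"], truth, seed=0)
        return frame, tt, fitted_calibration

    def test_native_2620_split_between_dimer_and_monomer(
        self, presets, truth, fitted_calibration, hypotheses
    ):
        from sodims.species import resolve_mz_coincidence

        frame, tt, calib = self._native_frame_and_calib(
            presets, truth, fitted_calibration
        )
        hyp_list = list(hypotheses.values())
        mz = theoretical_mz(neutral_mass(hypotheses["holo-dimer"]), 12)
        assignments = assign_peaks([(mz, 100.0)], hyp_list, z_range=(5, 16))
        priors = {"holo-dimer": 2693.5, "holo-monomer": 1610.0}
        survivors, attribution = resolve_mz_coincidence(
            assignments, frame, calib, hyp_list, priors
        )
        assert {(a.species, a.charge) for a in survivors} == {
            ("holo-dimer", 12), ("holo-monomer", 6)
        }
        # each ATD component attributed to the species whose truth time matches
        truth_times = {
            (r.species, r.charge): r.arrival_time_ms
            for r in tt.itertuples()
            if (r.species, r.charge) in {("holo-dimer", 12), ("holo-monomer", 6)}
        }
        for comp, key in attribution:
            assert comp.apex_time == pytest.approx(truth_times[key], abs=0.05)

    def test_swapped_priors_swap_attribution(
        self, presets, truth, fitted_calibration, hypotheses
    ):
        from sodims.species import resolve_mz_coincidence

        frame, _, calib = self._native_frame_and_calib(
            presets, truth, fitted_calibration
        )
        hyp_list = list(hypotheses.values())
        mz = theoretical_mz(neutral_mass(hypotheses["holo-dimer"]), 12)
        assignments = assign_peaks([(mz, 100.0)], hyp_list, z_range=(5, 16))
        # deliberately swapped expectations: the mapping must swap too
        swapped = {"holo-dimer": 1610.0 * 2.0, "holo-monomer": 2693.5 / 2.0}
        straight = {"holo-dimer": 2693.5, "holo-monomer": 1610.0}
        _, att1 = resolve_mz_coincidence(
            assignments, frame, calib, hyp_list, straight
        )
        _, att2 = resolve_mz_coincidence(
            assignments, frame, calib, hyp_list, swapped
        )
        m1 = {round(c.apex_time, 3): k[0] for c, k in att1}
        m2 = {round(c.apex_time, 3): k[0] for c, k in att2}
        assert m1.keys() == m2.keys()
        assert all(m1[t] != m2[t] for t in m1)

    def test_lone_component_single_survivor(
        self, presets, truth, fitted_calibration, hypotheses
    ):
        from sodims.species import resolve_mz_coincidence
        from sodims.synthetic import synth_protein_frame

        frame, _ = synth_protein_frame(presets["native"], truth, seed=0)
        hyp_list = list(hypotheses.values())
        # the 10+ dimer peak: monomer 5+ would coincide but has no component
        mz = theoretical_mz(neutral_mass(hypotheses["holo-dimer"]), 10)
        assignments = assign_peaks([(mz, 100.0)], hyp_list, z_range=(5, 16))
        assert {(a.species, a.charge) for a in assignments} == {
            ("holo-dimer", 10), ("holo-monomer", 5)
        }
        with pytest.warns(UserWarning, match="no ATD component"):
            survivors, _ = resolve_mz_coincidence(
                assignments, frame, fitted_calibration, hyp_list,
                {"holo-dimer": 2693.5, "holo-monomer": 1610.0},
            )
        assert [(a.species, a.charge) for a in survivors] == [("holo-dimer", 10)]
        assert survivors[0].ambiguity_flags == set()

    def test_requires_calibration(self, hypotheses):
        from sodims.species import resolve_mz_coincidence

        with pytest.raises(ValueError, match="calibration"):
            resolve_mz_coincidence([], None, None, list(hypotheses.values()), {})
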