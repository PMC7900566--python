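"""The forward simulator: drift relation, frame construction, presets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sodims.frames import refine_apex
from sodims.species import neutral_mass, theoretical_mz
from sodims.synthetic import (
    ChargeStateSpec,
    ConditionSpec,
    ConformerSpec,
    InstrumentTruth,
    SpeciesMix,
    condition_presets,
    default_hypotheses,
    forward_arrival_time,
    synth_calibrant_frame,
    synth_protein_frame,
)


class TestForwardArrivalTime:
    def test_zero_ccs_gives_dead_time(self, truth):
        assert forward_arrival_time(0.0, 15000.0, 7, truth) == truth.t_fix

    def test_hand_evaluated_formula_value(self):
        # frozen value of (0.15/10)*sqrt(31426.9/31454.9134)*2693.5 + 0.5,
        # computed independently by direct arithmetic
        truth = InstrumentTruth(beta=0.15, t_fix=0.5, gas_mass=28.0134)
        t = forward_arrival_time(2693.5, 31426.9, 10, truth)
        assert t == pytest.approx(40.8845049814464, rel=1e-12)

    def test_doubling_ccs_doubles_reduced_time(self, truth):
        t1 = forward_arrival_time(1200.0, 20000.0, 9, truth)
        t2 = forward_arrival_time(2400.0, 20000.0, 9, truth)
        assert t2 - truth.t_fix == pytest.approx(2 * (t1 - truth.t_fix), rel=1e-12)

    @given(
        ccs=st.floats(100.0, 5000.0),
        mass=st.floats(500.0, 60000.0),
        z=st.integers(1, 25),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_ccs_and_charge(self, ccs, mass, z):
        truth = InstrumentTruth()
        t = forward_arrival_time(ccs, mass, z, truth)
        assert forward_arrival_time(ccs * 1.01, mass, z, truth) > t
        assert forward_arrival_time(ccs, mass, z + 1, truth) < t

    def test_invalid_inputs_raise(self, truth):
        with pytest.raises(ValueError):
            forward_arrival_time(1000.0, -5.0, 10, truth)
        with pytest.raises(ValueError):
            forward_arrival_time(1000.0, 15000.0, 0, truth)


class TestCalibrantFrame:
    def test_apexes_at_forward_positions(self, truth, reference_calibrants):
        cals = [(c.mz, c.charge, c.reference_ccs) for c in reference_calibrants]
        frame, tt = synth_calibrant_frame(truth, cals, seed=0)
        for row in tt.itertuples():
            sel = np.abs(frame.mz_axis - row.mz) <= 3.0
            trace = frame.intensity[:, sel].sum(axis=1)
            apex_bin = frame.drift_axis[np.argmax(trace)]
            assert abs(apex_bin - row.arrival_time_ms) <= truth.drift_step

    def test_same_seed_bit_identical(self, truth):
        cals = [(622.0, 1, 203.0), (1222.0, 1, 282.0)]
        f1, _ = synth_calibrant_frame(truth, cals, noise_sd=0.05, seed=42)
        f2, _ = synth_calibrant_frame(truth, cals, noise_sd=0.05, seed=42)
        assert np.array_equal(f1.intensity, f2.intensity)

    def test_empty_calibrant_list_rejected(self, truth):
        with pytest.raises(ValueError):
            synth_calibrant_frame(truth, [], seed=0)


class TestProteinFrame:
    def test_truth_table_times_match_forward_model(self, presets, truth, hypotheses):
        _, tt = synth_protein_frame(presets["harsh"], truth, seed=0)
        for row in tt.itertuples():
            mass = neutral_mass(hypotheses[row.species])
            expected = forward_arrival_time(row.ccs, mass, row.charge, truth)
            assert row.arrival_time_ms == expected  # exact, same code path

    def test_single_conformer_preset_has_one_peak(self, truth, hypotheses):
        cond = ConditionSpec(
            name="minimal",
            mixes=[
                SpeciesMix(
                    hypotheses["holo-monomer"],
                    [ChargeStateSpec(7, 1.0, [ConformerSpec(1653.0, 1.0)])],
                )
            ],
        )
        frame, tt = synth_protein_frame(cond, truth, seed=0)
        assert len(tt) == 1
        # exactly one connected intensity blob: apex at the truth position
        i, j = np.unravel_index(np.argmax(frame.intensity), frame.intensity.shape)
        t_apex, _ = refine_apex(frame.drift_axis, frame.intensity[:, j], int(i))
        assert t_apex == pytest.approx(tt.arrival_time_ms[0], abs=1e-6)
        mz_apex, _ = refine_apex(frame.mz_axis, frame.intensity[i, :], int(j))
        assert mz_apex == pytest.approx(tt.mz[0], abs=1e-6)

    def test_total_intensity_conserved_noiseless(self, truth, hypotheses):
        # no valley fill so the configured-peak-integral accounting is exact
        cond = ConditionSpec(
            name="cons",
            mixes=[
                SpeciesMix(
                    hypotheses["holo-monomer"],
                    [
                        ChargeStateSpec(7, 0.6, [ConformerSpec(1653.0, 1.0)]),
                        ChargeStateSpec(
                            8, 0.4, [ConformerSpec(1700.0, 0.5), ConformerSpec(2160.0, 0.5)]
                        ),
                    ],
                )
            ],
            total_intensity=5.0e3,
        )
        frame, _ = synth_protein_frame(cond, truth, seed=0)
        assert frame.intensity.sum() == pytest.approx(5.0e3, rel=1e-3)

    def test_increasing_ccs_increases_arrival_time(self, truth, hypotheses):
        def one(ccs):
            cond = ConditionSpec(
                name="m",
                mixes=[
                    SpeciesMix(
                        hypotheses["apo-monomer"],
                        [ChargeStateSpec(9, 1.0, [ConformerSpec(ccs, 1.0)])],
                    )
                ],
            )
            _, tt = synth_protein_frame(cond, truth, seed=0)
            return tt.arrival_time_ms[0]

        times = [one(c) for c in (1700.0, 2100.0, 2500.0, 3000.0)]
        assert np.all(np.diff(times) > 0)

    def test_determinism_with_noise(self, presets, truth):
        presets["native"].noise_sd = 0.02
        try:
            f1, t1 = synth_protein_frame(presets["native"], truth, seed=7)
            f2, t2 = synth_protein_frame(presets["native"], truth, seed=7)
        finally:
            presets["native"].noise_sd = 0.0
        assert np.array_equal(f1.intensity, f2.intensity)
        assert t1.equals(t2)


class TestPresets:
    def test_three_presets_in_harshness_order(self):
        names = [c.name for c in condition_presets()]
        assert names == ["native", "intermediate", "harsh"]

    def test_native_species_content(self, presets):
        zs = {
            mix.species.name: sorted(cs.charge for cs in mix.charge_states)
            for mix in presets["native"].mixes
        }
        assert zs == {"holo-dimer": [10, 11, 12], "holo-monomer": [6, 7, 8]}

    def test_intermediate_contains_single_metal_monomer(self, presets):
        forms = {mix.species.form for mix in presets["intermediate"].mixes}
        assert "single-metal monomer" in forms

    def test_harsh_apo_charge_range_7_through_16(self, presets):
        apo = next(
            m for m in presets["harsh"].mixes if m.species.name == "apo-monomer"
        )
        assert sorted(cs.charge for cs in apo.charge_states) == list(range(7, 17))

    def test_harsh_11plus_dimer_has_three_conformers(self, presets):
        dimer = next(
            m for m in presets["harsh"].mixes if m.species.name == "holo-dimer"
        )
        cs11 = next(cs for cs in dimer.charge_states if cs.charge == 11)
        ccs = sorted(c.ccs for c in cs11.conformers)
        assert ccs == [2735.0, 3237.0, 3556.0]

    def test_mz_coincidence_configured_in_native_and_intermediate(
        self, presets, hypotheses
    ):
        for cond in ("native", "intermediate"):
            mzs = {}
            for mix in presets[cond].mixes:
                mass = neutral_mass(mix.species)
                for cs in mix.charge_states:
                    mzs[(mix.species.name, cs.charge)] = theoretical_mz(mass, cs.charge)
            assert mzs[("holo-dimer", 12)] == pytest.approx(
                mzs[("holo-monomer", 6)], abs=0.05
            )

    def test_preset_reported_ccs_fixtures(self, presets):
        def ccs_of(cond, species, z):
            mix = next(m for m in presets[cond].mixes if m.species.name == species)
            cs = next(c for c in mix.charge_states if c.charge == z)
            return sorted(conf.ccs for conf in cs.conformers)

        assert ccs_of("native", "holo-dimer", 10) == [2693.5]
        assert ccs_of("harsh", "apo-monomer", 16) == [3608.0]
        assert ccs_of("harsh", "holo-monomer", 7) == [1656.0, 2105.0]

    def test_out_of_range_conformer_rejected(self, truth, hypotheses):
        cond = ConditionSpec(
            name="bad",
            mixes=[
                SpeciesMix(
                    hypotheses["apo-monomer"],
                    [ChargeStateSpec(5, 1.0, [ConformerSpec(6000.0, 1.0)])],
                )
            ],
        )
        with pytest.raises(ValueError, match="drift-time range"):
            synth_protein_frame(cond, truth, seed=0)


class TestSpecValidation:
    def test_invalid_instrument_truth(self):
        with pytest.raises(ValueError):
            InstrumentTruth(beta=-0.1)
        with pytest.raises(ValueError):
            InstrumentTruth(drift_time_range=(50.0, 10.0))

    def test_invalid_valley_fill(self):
        with pytest.raises(ValueError):
            ChargeStateSpec(7, 1.0, [ConformerSpec(1700.0, 1.0)], valley_fill=1.0)

    def test_zero_charge_state_species(self, hypotheses):
        with pytest.raises(ValueError):
            SpeciesMix(hypotheses["holo-monomer"], [])
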