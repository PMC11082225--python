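"""Normalization and dependency metrics: oracles and flag policies."""

import numpy as np
import pytest

from bh3flow import (TubeRecord, ValidationError, build_profile,
                     call_dependencies, cytc_loss, delta_priming,
                     dependency_metrics, extended_dbp)
from bh3flow.gating import GatingResult
from bh3flow.priming import PrimingProfile


def _gres(mfi):
    return GatingResult(counts={"input": 1, "target": 1}, mfi=mfi,
                        qc_flags=[], retained_index={})


def _tube(sample, reagent, conc, rep, role="none", mfi=1000.0):
    rec = TubeRecord(path="<memory>", sample_id=sample, reagent=reagent,
                     concentration_uM=conc, replicate=rep, control_role=role)
    return (rec, _gres(mfi))


def make_profile(losses, sample_id="S1", controls=(5000.0, 200.0)):
    return PrimingProfile(
        sample_id=sample_id,
        losses={k: float(v) for k, v in losses.items()},
        replicate_losses={k: [float(v)] for k, v in losses.items()},
        control_mfis=controls,
    )


class TestCytcLoss:
    def test_sample_at_retention_control_is_zero(self):
        assert float(cytc_loss(5000, 200, 5000)) == 0.0

    def test_sample_at_release_control_is_hundred(self):
        assert float(cytc_loss(200, 200, 5000)) == 100.0

    def test_linear_interpolation_oracle(self):
        # (5000 - 2600) / (5000 - 200) = 0.5
        assert float(cytc_loss(2600, 200, 5000)) == pytest.approx(50.0)

    def test_out_of_range_value_flagged_not_clamped(self):
        loss = cytc_loss(100, 200, 5000)
        assert float(loss) == pytest.approx(102.0833333)
        assert loss.out_of_range
        assert not cytc_loss(2600, 200, 5000).out_of_range

    def test_degenerate_controls_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            cytc_loss(1000, 300, 300)

    def test_as_printed_is_retention_complement(self):
        # the literal printed ratio equals 100 - loss under the stated
        # control semantics
        for mfi in (200, 1000, 2600, 5000):
            assert float(cytc_loss(mfi, 200, 5000, as_printed=True)) \
                == pytest.approx(100 - float(cytc_loss(mfi, 200, 5000)))

    def test_monotone_decreasing_in_sample_mfi(self):
        samples = np.linspace(200, 5000, 25)
        losses = [float(cytc_loss(m, 200, 5000)) for m in samples]
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestBuildProfile:
    def test_identical_duplicates_equal_single_tube(self):
        tubes = [
            _tube("S", "PUMA2A", 10, 1, "PUMA2A", 5000),
            _tube("S", "PUMA2A", 10, 2, "PUMA2A", 5000),
            _tube("S", "alamethicin", 25, 1, "alamethicin", 200),
            _tube("S", "alamethicin", 25, 2, "alamethicin", 200),
            _tube("S", "BIM", 10, 1, mfi=2600),
            _tube("S", "BIM", 10, 2, mfi=2600),
        ]
        prof = build_profile(tubes)
        assert prof.loss("BIM", 10) == pytest.approx(50.0)
        assert prof.control_mfis == (5000.0, 200.0)

    def test_replicate_losses_averaged_and_retained(self):
        # losses 40 and 60 -> condition loss 50, spread 20
        mfi40 = 5000 - 0.40 * 4800
        mfi60 = 5000 - 0.60 * 4800
        tubes = [
            _tube("S", "PUMA2A", 10, 1, "PUMA2A", 5000),
            _tube("S", "alamethicin", 25, 1, "alamethicin", 200),
            _tube("S", "BIM", 10, 1, mfi=mfi40),
            _tube("S", "BIM", 10, 2, mfi=mfi60),
        ]
        prof = build_profile(tubes)
        assert prof.loss("BIM", 10) == pytest.approx(50.0)
        reps = prof.replicate_losses[("BIM", 10.0)]
        assert max(reps) - min(reps) == pytest.approx(20.0)

    def test_control_self_consistency(self):
        # evaluating the normalization on the controls' own mean MFIs gives
        # exactly 0 and 100
        tubes = [
            _tube("S", "PUMA2A", 10, 1, "PUMA2A", 5100),
            _tube("S", "PUMA2A", 10, 2, "PUMA2A", 4900),
            _tube("S", "alamethicin", 25, 1, "alamethicin", 210),
            _tube("S", "alamethicin", 25, 2, "alamethicin", 190),
            _tube("S", "BIM", 10, 1, mfi=2600),
        ]
        prof = build_profile(tubes)
        puma, alam = prof.control_mfis
        assert float(cytc_loss(puma, alam, puma)) == 0.0
        assert float(cytc_loss(alam, alam, puma)) == 100.0

    def test_missing_alamethicin_names_sample(self):
        tubes = [
            _tube("SAMPLE_X", "PUMA2A", 10, 1, "PUMA2A", 5000),
            _tube("SAMPLE_X", "BIM", 10, 1, mfi=2600),
        ]
        with pytest.raises(ValidationError, match="SAMPLE_X"):
            build_profile(tubes)


class TestDependencyMetrics:
    def test_bad_minus_hrk(self):
        prof = make_profile({("BAD", 10.0): 90.0, ("HRK", 10.0): 17.2,
                             ("MS-1", 10.0): 12.0, ("FS-1", 10.0): 8.0})
        panel = dependency_metrics(prof)
        assert panel.bcl2_dep == pytest.approx(72.8)
        assert panel.mcl1_dep == pytest.approx(12.0)
        assert panel.bclxl_dep == pytest.approx(17.2)
        assert panel.bfl1_dep == pytest.approx(8.0)

    def test_equal_bad_hrk_zero_dependence(self):
        prof = make_profile({("BAD", 10.0): 40.0, ("HRK", 10.0): 40.0})
        assert dependency_metrics(prof).bcl2_dep == 0.0

    def test_negative_bcl2_raw_with_flag(self):
        prof = make_profile({("BAD", 10.0): 10.0, ("HRK", 10.0): 40.0})
        panel = dependency_metrics(prof)
        assert panel.bcl2_dep == pytest.approx(-30.0)
        assert "negative_bcl2_dep" in panel.flags

    def test_missing_reagent_undefined_not_zero(self):
        prof = make_profile({("BAD", 10.0): 50.0, ("HRK", 10.0): 10.0})
        panel = dependency_metrics(prof)
        assert panel.mcl1_dep is None
        assert panel.bfl1_dep is None
        assert panel.bcl2_dep == pytest.approx(40.0)

    def test_decomposition_identity(self):
        # bcl2_dep + bclxl_dep == loss(BAD) by construction
        rng = np.random.default_rng(0)
        for _ in range(20):
            bad, hrk = rng.uniform(0, 100, 2)
            prof = make_profile({("BAD", 10.0): bad, ("HRK", 10.0): hrk})
            panel = dependency_metrics(prof)
            assert panel.bcl2_dep + panel.bclxl_dep == pytest.approx(bad)


class TestCalls:
    def test_all_zero_no_dependency(self):
        prof = make_profile({("BAD", 10.0): 0.0, ("HRK", 10.0): 0.0,
                             ("MS-1", 10.0): 0.0, ("FS-1", 10.0): 0.0})
        calls = call_dependencies(dependency_metrics(prof))
        assert calls["no_clear_dependency"] is True
        assert not any(v is True for k, v in calls.items()
                       if k != "no_clear_dependency")

    def test_strong_mcl1_called(self):
        prof = make_profile({("MS-1", 10.0): 90.8})
        calls = call_dependencies(dependency_metrics(prof), threshold=20)
        assert calls["MCL-1"] is True

    def test_tie_at_threshold_is_dependent(self):
        prof = make_profile({("MS-1", 10.0): 20.0})
        calls = call_dependencies(dependency_metrics(prof), threshold=20)
        assert calls["MCL-1"] is True

    def test_threshold_bounds(self):
        prof = make_profile({("MS-1", 10.0): 20.0})
        panel = dependency_metrics(prof)
        with pytest.raises(ValidationError):
            call_dependencies(panel, threshold=0.0)


class TestDeltaPriming:
    def test_identical_profiles_zero_delta(self):
        prof = make_profile({("BIM", 0.05): 20.0})
        res = delta_priming(prof, prof, "BIM")
        assert res.delta == 0.0
        assert res.qc == []

    def test_drug_minus_vehicle(self):
        drug = make_profile({("BIM", 0.05): 65.0})
        dmso = make_profile({("BIM", 0.05): 20.0})
        res = delta_priming(drug, dmso, "BIM")
        assert res.delta == pytest.approx(45.0)
        assert res.basal_loss == pytest.approx(20.0)
        assert res.qc == []

    def test_basal_window_flag(self):
        drug = make_profile({("BIM", 0.05): 30.0})
        dmso = make_profile({("BIM", 0.05): 5.0})
        res = delta_priming(drug, dmso, "BIM")
        assert "basal_outside_window" in res.qc

    def test_probe_missing_raises(self):
        drug = make_profile({("BIM", 0.05): 30.0})
        dmso = make_profile({("PUMA", 10.0): 5.0})
        with pytest.raises(KeyError):
            delta_priming(drug, dmso, "BIM")


class TestExtendedDBP:
    def test_identical_states_all_zero(self):
        prof = make_profile({("BAD", 1.0): 25.0, ("HRK", 1.0): 10.0,
                             ("MS-1", 1.0): 12.0, ("FS-1", 1.0): 8.0})
        deltas = extended_dbp(prof, prof, 1.0)
        assert all(v == 0.0 for v in deltas.values())

    def test_mcl1_delta(self):
        dmso = make_profile({("MS-1", 1.0): 12.0})
        treated = make_profile({("MS-1", 1.0): 50.0})
        deltas = extended_dbp(treated, dmso, 1.0)
        assert deltas["MCL-1"] == pytest.approx(38.0)

    def test_partial_panel_undefined_but_others_computed(self):
        dmso = make_profile({("MS-1", 1.0): 12.0, ("FS-1", 1.0): 8.0})
        treated = make_profile({("MS-1", 1.0): 50.0})   # FS-1 missing at t
        deltas = extended_dbp(treated, dmso, 1.0)
        assert deltas["BFL-1"] is None
        assert deltas["MCL-1"] == pytest.approx(38.0)

    def test_timepoint_mapping(self):
        dmso = make_profile({("MS-1", 1.0): 12.0})
        t3 = make_profile({("MS-1", 1.0): 30.0})
        t6 = make_profile({("MS-1", 1.0): 50.0})
        out = extended_dbp({"3h": t3, "6h": t6}, dmso, 1.0)
        assert out["3h"]["MCL-1"] == pytest.approx(18.0)
        assert out["6h"]["MCL-1"] == pytest.approx(38.0)
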