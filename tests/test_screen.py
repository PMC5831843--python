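"""Melt-curve Tm extraction, kinetics, stability filtering, structure shell."""

import math
import random

import numpy as np
import pytest

from ggshuffle.screen import (
    CalibrationResult,
    DdgRecord,
    MeltCurve,
    NoTransition,
    Residue,
    StructureModel,
    UninformativeCalibration,
    catalytic_efficiency,
    concentration_from_calibration,
    ddg_filter,
    delta_tm,
    enumerate_candidates,
    extract_tm,
    fit_michaelis_menten,
    rate_from_absorbance,
)
from ggshuffle.seqcore import MutationSpec
from ggshuffle.synthdata import simulate_melt_curve, simulate_mm_data


class TestExtractTm:
    @pytest.mark.parametrize("method", ["derivative", "sigmoid"])
    def test_noiseless_midpoint_recovered(self, method):
        curve = simulate_melt_curve(tm=50.0, noise_sd=0.0)
        result = extract_tm(curve, method=method)
        assert result.tm_app == pytest.approx(50.0, abs=0.5)
        assert result.method == method

    def test_affine_rescaling_invariance(self):
        curve = simulate_melt_curve(tm=55.0, noise_sd=0.005, seed=3)
        base = extract_tm(curve).tm_app
        for a, b in [(3.0, 100.0), (0.01, -5.0)]:
            scaled = MeltCurve(
                curve.temperatures, a * curve.fluorescence + b, "scaled"
            )
            assert extract_tm(scaled).tm_app == pytest.approx(base, abs=1e-9)

    def test_flat_curve_has_no_transition(self):
        curve = simulate_melt_curve(
            amplitude=0.0, pre_baseline=(100.0, 0.0), post_baseline_slope=0.0,
            noise_sd=0.0,
        )
        with pytest.raises(NoTransition):
            extract_tm(curve)

    def test_methods_agree_across_noisy_replicates(self):
        agree = 0
        reps = 100
        for seed in range(reps):
            curve = simulate_melt_curve(tm=48.5, noise_sd=0.01, seed=seed)
            t_d = extract_tm(curve, method="derivative").tm_app
            t_s = extract_tm(curve, method="sigmoid").tm_app
            agree += abs(t_d - t_s) <= 1.0
        assert agree / reps >= 0.95

    def test_tm_within_measured_range(self):
        curve = simulate_melt_curve(tm=48.5, noise_sd=0.01, seed=1)
        tm = extract_tm(curve).tm_app
        assert curve.temperatures[0] <= tm <= curve.temperatures[-1]


class TestDeltaTm:
    @pytest.mark.parametrize(
        "tm,ref,expected", [(60.5, 48.5, 12.0), (48.5, 48.5, 0.0), (54.5, 48.5, 6.0)]
    )
    def test_examples_on_instrument_grid(self, tm, ref, expected):
        assert delta_tm(tm, ref) == expected

    def test_rounds_to_half_degree(self):
        assert delta_tm(50.2, 48.5) == 1.5

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            delta_tm(float("nan"), 48.5)


class TestCalibration:
    def test_exact_line(self):
        points = [(1, 2.0), (2, 4.0), (3, 6.0), (4, 8.0)]
        result = concentration_from_calibration(points, 10.0)
        assert result.concentration == pytest.approx(5.0)
        assert result.extrapolated  # signal 10 beyond the calibrated range

    def test_interpolation_not_flagged(self):
        points = [(1, 2.0), (2, 4.0), (3, 6.0), (4, 8.0)]
        assert not concentration_from_calibration(points, 5.0).extrapolated

    def test_zero_slope_uninformative(self):
        with pytest.raises(UninformativeCalibration):
            concentration_from_calibration([(1, 3.0), (2, 3.0), (3, 3.0)], 3.0)

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(10)
        true_conc = 7.0
        slope, intercept, sd = 1.8, 0.4, 0.15
        hits = 0
        reps = 50
        for _ in range(reps):
            x = np.linspace(1, 10, 8)
            y = intercept + slope * x + rng.normal(0, sd, x.size)
            signal = intercept + slope * true_conc + rng.normal(0, sd)
            res = concentration_from_calibration(list(zip(x, y)), signal)
            hits += abs(res.concentration - true_conc) <= 2 * max(
                res.standard_error, sd / slope
            )
        assert hits / reps >= 0.8


class TestRateConversion:
    def test_printed_extinction_coefficient(self):
        out = rate_from_absorbance(0.026)
        assert out["mM_per_min"] == pytest.approx(0.001)
        assert out["uM_per_s"] == pytest.approx(1.0 / 60)

    def test_zero_slope(self):
        assert rate_from_absorbance(0.0)["mM_per_min"] == 0.0

    def test_dimensional_oracle_on_random_slopes(self):
        rng = random.Random(2)
        for _ in range(20):
            slope = rng.uniform(0, 0.5)
            eps = rng.uniform(5, 50)
            path = rng.uniform(0.2, 1.0)
            out = rate_from_absorbance(slope, path, eps)
            # independent recomputation in SI-ish steps
            rate_m_per_min = slope / (eps * 1000 * path)  # M min^-1
            assert out["mM_per_min"] == pytest.approx(rate_m_per_min * 1000)
            assert out["uM_per_s"] == pytest.approx(rate_m_per_min * 1e6 / 60)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rate_from_absorbance(-0.1)
        with pytest.raises(ValueError):
            rate_from_absorbance(0.1, path_cm=0)


class TestMichaelisMenten:
    def test_printed_parameters_reported_efficiency(self):
        assert catalytic_efficiency(11.8, 0.63) == 18.7
        assert catalytic_efficiency(13.7, 1.52) == 9.01

    def test_noiseless_recovery_is_exact(self):
        data = simulate_mm_data(kcat=13.7, km=1.52, noise_pct=0.0)
        fit = fit_michaelis_menten(data)
        assert fit.kcat == pytest.approx(13.7, rel=1e-6)
        assert fit.km == pytest.approx(1.52, rel=1e-6)
        assert fit.converged and not fit.flags

    def test_noisy_replicates_have_small_median_bias(self):
        kcat_err, km_err = [], []
        for seed in range(100):
            data = simulate_mm_data(
                kcat=11.8, km=0.63, noise_pct=5.0, seed=seed
            )
            fit = fit_michaelis_menten(data)
            kcat_err.append((fit.kcat - 11.8) / 11.8)
            km_err.append((fit.km - 0.63) / 0.63)
        assert abs(float(np.median(kcat_err))) < 0.05
        assert abs(float(np.median(km_err))) < 0.05

    def test_km_outside_span_flagged(self):
        data = [(s, 10.0 * s / (50.0 + s)) for s in (0.1, 0.2, 0.4, 0.8, 1.6)]
        fit = fit_michaelis_menten(data)
        assert any("span" in f for f in fit.flags)

    def test_needs_five_levels(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([(1.0, 1.0)] * 4)


def _rec(label, *vals):
    wt, pos, mut = label[0], int(label[1:-1]), label[-1]
    return DdgRecord(MutationSpec(pos, wt, mut), tuple(vals))


class TestDdgFilter:
    def test_boundary_kept_values_above_discarded(self):
        records = [_rec("A5G", -6.0), _rec("I7V", -1.0), _rec("K9E", -5.0)]
        keep, counts = ddg_filter(records, threshold=-5.0)
        assert [r.mutation.label for r in keep] == ["A5G", "K9E"]
        assert counts["retained"] == 2 and counts["discarded"] == 1

    def test_all_stabilizing_all_retained(self):
        records = [_rec("A5G", -10.0), _rec("I7V", -10.0)]
        keep, _ = ddg_filter(records)
        assert len(keep) == 2

    def test_combine_rules(self):
        records = [_rec("A5G", -6.0, -1.0)]
        assert len(ddg_filter(records, combine_rule="any")[0]) == 1
        assert len(ddg_filter(records, combine_rule="all")[0]) == 0
        assert len(ddg_filter(records, combine_rule="mean")[0]) == 0  # mean -3.5

    def test_empty_input(self):
        keep, counts = ddg_filter([])
        assert keep == [] and counts["input"] == 0

    def test_matches_bruteforce_and_is_monotone_in_threshold(self):
        rng = random.Random(4)
        records = [
            _rec(f"A{i + 1}G", rng.uniform(-12, 4)) for i in range(40)
        ]
        prev = len(records) + 1
        for thr in (0.0, -2.5, -5.0, -7.5, -10.0):
            keep, _ = ddg_filter(records, threshold=thr)
            brute = [r for r in records if r.ddg_fold[0] <= thr]
            assert keep == brute
            assert len(keep) <= prev
            prev = len(keep)


def _toy_structure():
    # ligand at the origin; residues at 3, 4 and 8 angstroms
    res = [
        Residue("A", 1, "G", ((9.0, 0.0, 0.0), (3.0, 0.0, 0.0))),
        Residue("A", 2, "A", ((4.0, 0.0, 0.0),)),
        Residue("A", 3, "L", ((8.0, 0.0, 0.0),)),
    ]
    return StructureModel(res, {"FAD": ((0.0, 0.0, 0.0),)})


class TestEnumerateCandidates:
    def test_hand_computed_shell(self):
        count, retained = enumerate_candidates(_toy_structure(), cutoff=5.0)
        # only the 8-angstrom residue stays: 1 * 19 candidates
        assert count == 19 and [r.number for r in retained] == [3]
        count2, retained2 = enumerate_candidates(_toy_structure(), cutoff=3.5)
        assert count2 == 2 * 19 and [r.number for r in retained2] == [2, 3]

    def test_zero_cutoff_retains_everything(self):
        count, retained = enumerate_candidates(_toy_structure(), cutoff=0.0)
        assert count == 3 * 19 and len(retained) == 3

    def test_monotone_in_cutoff(self):
        counts = [
            enumerate_candidates(_toy_structure(), cutoff=c)[0]
            for c in (0.0, 2.0, 3.5, 5.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_ca_convention_uses_first_atom(self):
        # residue 1's closest heavy atom sits at 3 A, but its first-listed
        # atom is at 9 A: the Calpha-only convention keeps it
        _, retained = enumerate_candidates(
            _toy_structure(), cutoff=3.5, distance_convention="ca"
        )
        assert [r.number for r in retained] == [1, 2, 3]

    def test_missing_het_group(self):
        with pytest.raises(KeyError):
            enumerate_candidates(_toy_structure(), het_name="NAD")

    def test_parse_synthetic_pdb(self, tmp_path):
        # synthetic miniature structure, not a deposited entry
        pdb = "\n".join(
            [
                "ATOM      1  CA  GLY A   1       3.000   0.000   0.000  1.00  0.00           C",
                "ATOM      2  CA  ALA A   2       4.000   0.000   0.000  1.00  0.00           C",
                "ATOM      3  CA  LEU A   3       8.000   0.000   0.000  1.00  0.00           C",
                "HETATM    4  N1  FAD A 501       0.000   0.000   0.000  1.00  0.00           N",
                "END",
            ]
        )
        path = tmp_path / "synthetic_toy.pdb"
        path.write_text(pdb)
        model = StructureModel.from_pdb(path)
        assert len(model.residues) == 3 and "FAD" in model.het_groups
        count, _ = enumerate_candidates(model, cutoff=5.0)
        assert count == 19
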