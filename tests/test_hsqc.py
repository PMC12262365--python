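"""HSQC titrations: CSPs, significance flagging, region maps, KD fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnatriage.hsqc import (
    DEFAULT_REGION_MAP,
    CSPTable,
    FastExchangeFitter,
    IntermediateExchangeFitter,
    Peak2D,
    build_peaklist,
    compute_csp,
    csp_table,
    fit_fast,
    fit_intermediate,
    flag_significant,
    fraction_bound,
    load_region_map,
    map_to_regions,
    read_peaklist,
    write_peaklist,
)
from rnatriage.simulate import ResidueParams, simulate_hsqc_titration


def peak(pos=40, base="A", corr="C2-H2", d_h=7.5, d_c=141.0, vol=1e6, status="ok"):
    return Peak2D(position=pos, base=base, correlation=corr, d_h=d_h, d_c=d_c,
                  volume=vol, intensity=vol, status=status)


class TestComputeCsp:
    def test_no_movement_gives_zero(self):
        assert compute_csp(peak(), peak()) == 0.0

    def test_collapses_to_proton_distance(self):
        assert compute_csp(peak(), peak(d_h=7.53)) == pytest.approx(0.03)

    def test_weighted_pythagorean_example(self):
        # sqrt(0.03^2 + 0.14*0.20^2) = 0.080623 under the literal weighting
        got = compute_csp(peak(), peak(d_h=7.53, d_c=141.20))
        assert got == pytest.approx(np.sqrt(0.0009 + 0.14 * 0.04), abs=1e-9)
        assert got == pytest.approx(0.0806, abs=1e-4)

    def test_scaled_convention_differs(self):
        free, bound = peak(), peak(d_h=7.53, d_c=141.20)
        literal = compute_csp(free, bound, convention="literal")
        scaled = compute_csp(free, bound, convention="scaled")
        assert scaled == pytest.approx(np.sqrt(0.0009 + (0.14 * 0.2) ** 2), abs=1e-9)
        assert scaled < literal

    def test_mismatched_peaks_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_csp(peak(pos=40), peak(pos=41))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        dh=st.floats(-1, 1, allow_nan=False),
        dc=st.floats(-5, 5, allow_nan=False),
        c=st.floats(0.1, 10, allow_nan=False),
    )
    def test_sign_flip_and_scale_covariance(self, dh, dc, c):
        free = peak()
        plus = compute_csp(free, peak(d_h=7.5 + dh, d_c=141.0 + dc))
        minus = compute_csp(free, peak(d_h=7.5 - dh, d_c=141.0 - dc))
        scaled = compute_csp(free, peak(d_h=7.5 + c * dh, d_c=141.0 + c * dc))
        assert plus >= 0.0
        assert plus == pytest.approx(minus, rel=1e-9, abs=1e-12)
        assert scaled == pytest.approx(c * plus, rel=1e-6, abs=1e-12)


class TestFlagSignificant:
    def make_table(self, csps, statuses=None):
        import pandas as pd

        statuses = statuses or ["ok"] * len(csps)
        df = pd.DataFrame(
            {
                "position": range(20, 20 + len(csps)),
                "base": ["A"] * len(csps),
                "correlation": ["C2-H2"] * len(csps),
                "csp_ppm": csps,
                "status": statuses,
                "significant": False,
            }
        )
        return CSPTable(table=df)

    def test_uniform_vector_flags_nothing(self):
        out = flag_significant(self.make_table([0.05] * 6))
        assert not out.table["significant"].any()

    def test_outlier_above_mean_plus_sd_flagged(self):
        out = flag_significant(self.make_table([0.01] * 8 + [0.20]))
        flagged = out.table[out.table["significant"]]
        assert list(flagged["position"]) == [28]
        assert out.threshold_used < 0.20

    def test_requires_three_quantifiable(self):
        with pytest.raises(ValueError, match="3 quantifiable"):
            flag_significant(self.make_table([0.1, 0.2]))

    def test_overlapped_peaks_excluded_from_statistics(self):
        base = [0.01] * 8 + [0.20]
        plain = flag_significant(self.make_table(base))
        padded = flag_significant(
            self.make_table(base + [9.9, 9.9], statuses=["ok"] * 9 + ["overlapped"] * 2)
        )
        assert plain.threshold_used == pytest.approx(padded.threshold_used)
        assert not padded.table.loc[padded.table["status"] == "overlapped", "significant"].any()

    def test_order_invariant(self):
        csps = [0.01, 0.30, 0.02, 0.015, 0.012]
        a = flag_significant(self.make_table(csps))
        b = flag_significant(self.make_table(csps[::-1]))
        assert set(a.table.loc[a.table["significant"], "csp_ppm"]) == set(
            b.table.loc[b.table["significant"], "csp_ppm"]
        )


class TestRegions:
    def test_default_map_covers_construct_once(self):
        assert sorted(DEFAULT_REGION_MAP) == list(range(20, 53))

    def test_no_flags_empty_summary(self):
        s = map_to_regions([])
        assert s.counts == {} and s.dominant == []

    def test_junction_and_dicing_site_dominate(self):
        # the perturbed residues A40/A41 (junction) and C42/C43 (dicing bulge)
        s = map_to_regions([(40, "A"), (41, "A"), (42, "C"), (43, "C")])
        assert set(s.dominant) == {"junction", "dicing-site bulge"}
        assert s.residues["junction"] == ["A40", "A41"]

    def test_stem_flag_counts_under_stem_only(self):
        s = map_to_regions([(21, "G")])
        assert s.counts == {"stem": 1}

    def test_unmapped_residue_named_in_error(self):
        with pytest.raises(KeyError, match="A99"):
            map_to_regions([(99, "A")])

    def test_region_map_file_roundtrip(self, tmp_path):
        path = tmp_path / "regions.txt"
        path.write_text(
            "\n".join(f"{p}={r}" for p, r in DEFAULT_REGION_MAP.items())
        )
        assert load_region_map(path) == DEFAULT_REGION_MAP


class TestFractionBound:
    @pytest.mark.parametrize("vx,vref,b", [(1e6, 1e6, 0.0), (0.0, 1e6, 1.0), (4e5, 1e6, 0.6)])
    def test_arithmetic(self, vx, vref, b):
        assert fraction_bound(vx, vref) == pytest.approx(b)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fraction_bound(1.0, 0.0)

    def test_overshoot_clipped_and_roundtrip(self):
        assert fraction_bound(1.2e6, 1e6) == 0.0
        for b in (0.1, 0.5, 0.9):
            assert fraction_bound((1 - b) * 1e6, 1e6) == pytest.approx(b)


CONCS = [0, 5, 10, 20, 40, 80, 160, 320]


class TestIntermediateFit:
    def test_noiseless_exact_recovery(self, two_residues):
        series = simulate_hsqc_titration("intermediate", two_residues, kd_uM=29.10,
                                         concs=CONCS)
        fit = fit_intermediate(series, [(40, "C2-H2"), (42, "C6-H6")])
        assert fit.kd_uM == pytest.approx(29.10, rel=1e-6)
        assert fit.bmax == pytest.approx(1.0, rel=1e-6)
        assert fit.ns == pytest.approx(0.0, abs=1e-9)
        assert fit.converged

    def test_nonspecific_slope_recovered(self, two_residues):
        # concentrations kept low enough that total occupancy stays below 1
        series = simulate_hsqc_titration("intermediate", two_residues, kd_uM=29.10,
                                         concs=[0, 5, 10, 20, 40, 80], ns_per_uM=0.001)
        fit = fit_intermediate(series, [(40, "C2-H2")])
        assert fit.ns == pytest.approx(0.001, rel=1e-3)
        # the excess slope of the fitted curve beyond the plateau equals NS
        est = IntermediateExchangeFitter().fit(
            [0, 5, 10, 20, 40, 80],
            [fraction_bound(series.peak_lists[i][(40, "C2-H2")].volume, 1.0e6)
             for i in range(6)],
        )
        big = 1.0e6
        assert (est.predict(big + 1) - est.predict(big)) == pytest.approx(
            est.ns_, rel=1e-3
        )

    def test_recovery_bias_shrinks_with_noise(self, two_residues):
        errs = []
        for noise in (0.08, 0.02, 0.005):
            kds = []
            for seed in range(40):
                s = simulate_hsqc_titration("intermediate", two_residues, kd_uM=29.10,
                                            concs=CONCS, noise_sigma=noise, seed=seed)
                kds.append(fit_intermediate(s, [(40, "C2-H2")]).kd_uM)
            errs.append(abs(np.median(kds) - 29.10) / 29.10)
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.01

    def test_too_few_points_rejected(self, two_residues):
        series = simulate_hsqc_titration("intermediate", two_residues, kd_uM=29.10,
                                         concs=[0, 10, 50])
        with pytest.raises(ValueError):
            fit_intermediate(series, [(40, "C2-H2")])

    def test_unknown_residue_rejected(self, two_residues):
        series = simulate_hsqc_titration("intermediate", two_residues, kd_uM=29.10,
                                         concs=CONCS)
        with pytest.raises(KeyError):
            fit_intermediate(series, [(99, "C2-H2")])

    def test_string_residue_specs_accepted(self, two_residues):
        series = simulate_hsqc_titration("intermediate", two_residues, kd_uM=29.10,
                                         concs=CONCS)
        fit = fit_intermediate(series, ["A40/C2-H2", "C42/C6-H6"])
        assert fit.kd_uM == pytest.approx(29.10, rel=1e-6)


class TestFastFit:
    def test_noiseless_exact_recovery(self):
        rp = [ResidueParams(40, "A", "C2-H2", 7.5, 141.0, delta_h=0.08, delta_c=0.5)]
        series = simulate_hsqc_titration("fast", rp, kd_uM=50.0,
                                         concs=[0, 10, 25, 50, 100, 200, 500, 1000])
        fit = fit_fast(series, [(40, "C2-H2")])
        assert fit.kd_uM == pytest.approx(50.0, rel=1e-6)
        assert fit.saturated

    def test_half_bmax_at_kd(self):
        f = FastExchangeFitter().fit(
            np.array([0, 10, 25, 50, 100, 400]),
            0.2 * np.array([0, 10, 25, 50, 100, 400]) / (50.0 + np.array([0, 10, 25, 50, 100, 400])),
        )
        assert f.predict(f.kd_) == pytest.approx(f.bmax_ / 2, rel=1e-9)

    def test_unsaturated_series_reports_lower_bound(self):
        # sampling only up to KD/5 never approaches the plateau
        rp = [ResidueParams(40, "A", "C2-H2", 7.5, 141.0, delta_h=0.08, delta_c=0.5)]
        series = simulate_hsqc_titration("fast", rp, kd_uM=5000.0,
                                         concs=[0, 100, 250, 500, 1000])
        fit = fit_fast(series, [(40, "C2-H2")])
        assert not fit.saturated
        assert fit.kd_display == "> 1000"

    def test_fixed_point_on_own_curve(self):
        x = np.array([0, 5, 10, 25, 50, 100, 250], float)
        est = FastExchangeFitter().fit(x, 0.1 * x / (30.0 + x))
        refit = FastExchangeFitter().fit(x, est.predict(x))
        assert refit.kd_ == pytest.approx(est.kd_, rel=1e-6)


class TestPeakListIO:
    def test_csv_roundtrip(self, tmp_path):
        pl = build_peaklist([peak(), peak(pos=42, base="C", corr="C6-H6", d_h=7.6)])
        path = tmp_path / "peaks.csv"
        write_peaklist(path, pl)
        back = read_peaklist(path)
        assert back.keys() == pl.keys()
        assert back[(40, "C2-H2")].d_h == pytest.approx(7.5)

    def test_sparky_style_accepted(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text("A40 C2-H2 7.50 141.00 1.0e6 5.0e5 ok\nC42 C6-H6 7.62 139.40 8e5 4e5\n")
        pl = read_peaklist(path)
        assert (40, "C2-H2") in pl and (42, "C6-H6") in pl
        assert pl[(42, "C6-H6")].status == "ok"

    def test_duplicate_peak_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_peaklist([peak(), peak()])
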