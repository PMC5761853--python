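import numpy as np
import pytest

import mvlattice as mv
from mvlattice.lattice import (DegenerateBasisError, SpectralPeak,
                               first_order_peak_snr, first_order_peaks,
                               fit_lattice)


def make_peak(kx, ky, mag=100.0):
    return SpectralPeak(kx=kx, ky=ky, magnitude=mag, halfwidth=1e-4)


def hexagonal_reciprocal(a, rot_deg=0.0):
    """Forward-generate the reciprocal basis of a hexagonal lattice."""
    t = np.deg2rad(60.0)
    A = np.array([[a, 0.0], [a * np.cos(t), a * np.sin(t)]])
    r = np.deg2rad(rot_deg)
    R = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
    A = A @ R.T
    B = np.linalg.inv(A.T)  # rows b1, b2 with a_i . b_j = delta_ij
    return B


class TestPowerSpectrum:
    def test_cosine_grating_peak_pair(self):
        n, px = 256, 7.0
        lam = 170.0
        xx = np.arange(n) * px
        z = 10.0 * np.cos(2 * np.pi * xx / lam)[None, :].repeat(n, axis=0)
        spec = mv.power_spectrum(mv.HeightMap(z, px))
        r, c = np.unravel_index(np.argmax(spec.magnitude), spec.magnitude.shape)
        assert spec.freq_row[r] == pytest.approx(0.0, abs=spec.bin_width / 2)
        assert abs(spec.freq_col[c]) == pytest.approx(1 / lam, abs=spec.bin_width)

    def test_hermitian_symmetry_of_magnitude(self, small_map):
        spec = mv.power_spectrum(small_map)
        m = spec.magnitude
        # even grid: bin 0 is unpaired, the rest mirror through DC
        flipped = m[1:, 1:][::-1, ::-1]
        np.testing.assert_allclose(m[1:, 1:], flipped, rtol=1e-8, atol=1e-8)

    def test_hexagonal_six_first_order_peaks_at_60deg(self):
        spec0 = mv.LatticeSpec("hexagonal", a=169.0, rotation_deg=23.0)
        hm, _ = mv.generate_field(spec0, seed=5)
        spec = mv.power_spectrum(mv.preprocess(hm))
        peaks = mv.find_lattice_peaks(spec)
        ring = first_order_peaks(peaks)
        assert len(ring) == 3  # three centro-symmetric pairs
        radii = [p.radius for p in ring]
        assert np.ptp(radii) / np.mean(radii) < 0.06
        angles = sorted(np.degrees(np.arctan2(p.ky, p.kx)) % 180 for p in ring)
        gaps = np.diff(angles + [angles[0] + 180])
        np.testing.assert_allclose(gaps, 60.0, atol=4.0)

    def test_nonsquare_input_cropped_with_warning(self, rng):
        hm = mv.HeightMap(rng.normal(0.0, 1.0, (48, 64)), 7.0)
        with pytest.warns(UserWarning, match="centred square crop"):
            spec = mv.power_spectrum(hm)
        assert spec.magnitude.shape == (48, 48)


class TestFindLatticePeaks:
    def test_grating_frequency_subpixel(self):
        n, px = 357, 7.0
        lam = 170.0
        xx = np.arange(n) * px
        z = 10.0 * np.cos(2 * np.pi * xx / lam)[None, :].repeat(n, axis=0)
        spec = mv.power_spectrum(mv.HeightMap(z, px))
        peaks = mv.find_lattice_peaks(spec)
        assert peaks
        best = peaks[0]
        assert best.radius == pytest.approx(1 / lam, abs=0.1 * spec.bin_width)

    def test_white_noise_yields_no_peaks(self, rng):
        hm = mv.HeightMap(rng.normal(0.0, 5.0, (256, 256)), 7.0)
        spec = mv.power_spectrum(hm)
        assert mv.find_lattice_peaks(spec) == []

    def test_dc_exclusion_enforced(self, small_map):
        spec = mv.power_spectrum(small_map)
        with pytest.raises(ValueError):
            mv.find_lattice_peaks(spec, annulus=(0.0, 0.01))

    def test_profile_line_mode_selects_along_segment(self):
        spec0 = mv.LatticeSpec("hexagonal", a=169.0, rotation_deg=0.0)
        hm, _ = mv.generate_field(spec0, seed=5)
        spec = mv.power_spectrum(mv.preprocess(hm))
        all_peaks = first_order_peaks(mv.find_lattice_peaks(spec))
        target = max(all_peaks, key=lambda p: p.magnitude)
        line = (target.k * 0.5, target.k * 1.5)
        kept = mv.find_lattice_peaks(spec, profile_line=line)
        assert kept
        assert all(
            min(np.linalg.norm(p.k - target.k), np.linalg.norm(p.k + target.k))
            <= 2 * spec.bin_width
            for p in kept
        )


class TestReciprocalToReal:
    def test_square_lattice_inversion(self):
        a = 150.0
        p1 = make_peak(1 / a, 0.0)
        p2 = make_peak(0.0, 1 / a)
        a1, a2 = mv.reciprocal_to_real(p1, p2)
        assert np.linalg.norm(a1) == pytest.approx(a)
        assert np.linalg.norm(a2) == pytest.approx(a)
        assert a1 @ a2 == pytest.approx(0.0, abs=1e-9)

    def test_hexagonal_forward_inverse_roundtrip(self):
        B = hexagonal_reciprocal(169.0, rot_deg=31.0)
        a1, a2 = mv.reciprocal_to_real(make_peak(*B[0]), make_peak(*B[1]))
        assert np.linalg.norm(a1) == pytest.approx(169.0, rel=1e-9)
        assert np.linalg.norm(a2) == pytest.approx(169.0, rel=1e-9)
        cosang = a1 @ a2 / (169.0**2)
        assert np.degrees(np.arccos(cosang)) == pytest.approx(60.0, abs=1e-6)

    def test_collinear_peaks_rejected(self):
        p1 = make_peak(0.006, 0.001)
        p2 = make_peak(0.0120, 0.0020)
        with pytest.raises(DegenerateBasisError):
            mv.reciprocal_to_real(p1, p2)


class TestClassifyBravais:
    @pytest.mark.parametrize(
        "l1,l2,theta,expected",
        [
            (169.0, 169.0, 60.0, "hexagonal"),
            (185.0, 185.0, 75.0, "rhombic"),
            (185.0, 185.0, 80.0, "rhombic"),
            (150.0, 150.0, 90.0, "square"),
            (100.0, 150.0, 90.0, "rectangular"),
            (100.0, 150.0, 70.0, "oblique"),
        ],
    )
    def test_truth_table(self, l1, l2, theta, expected):
        t = np.deg2rad(theta)
        a1 = np.array([l1, 0.0])
        a2 = np.array([l2 * np.cos(t), l2 * np.sin(t)])
        fit = mv.classify_bravais(a1, a2)
        assert fit.bravais_class == expected

    def test_equal_length_classes_report_mean_constant(self):
        a1 = np.array([169.0, 0.0])
        t = np.deg2rad(60.0)
        a2 = 171.0 * np.array([np.cos(t), np.sin(t)])
        fit = mv.classify_bravais(a1, a2)
        assert fit.lattice_constant_nm == pytest.approx(170.0)

    def test_invariant_to_swap_and_sign(self):
        t = np.deg2rad(80.0)
        a1 = np.array([185.0, 0.0])
        a2 = 185.0 * np.array([np.cos(t), np.sin(t)])
        ref = mv.classify_bravais(a1, a2)
        for b1, b2 in [(a2, a1), (-a1, a2), (a1, -a2), (-a2, -a1)]:
            fit = mv.classify_bravais(b1, b2)
            assert fit.bravais_class == ref.bravais_class
            assert fit.lattice_constant_nm == pytest.approx(
                ref.lattice_constant_nm
            )
            assert fit.theta_deg == pytest.approx(ref.theta_deg)

    def test_any_two_of_three_hexagonal_pairs_equivalent(self):
        """The three first-order pairs define the same lattice."""
        B = hexagonal_reciprocal(169.0, rot_deg=11.0)
        b3 = -(B[0] + B[1])  # the third first-order direction
        candidates = [B[0], B[1], b3]
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                a1, a2 = mv.reciprocal_to_real(
                    make_peak(*candidates[i]), make_peak(*candidates[j])
                )
                fit = mv.classify_bravais(a1, a2)
                assert fit.bravais_class == "hexagonal"
                assert fit.lattice_constant_nm == pytest.approx(169.0, rel=1e-6)


class TestFitLattice:
    def test_noiseless_recovery_within_one_bin(self):
        spec0 = mv.LatticeSpec("hexagonal", a=169.0, jitter_nm=0.0,
                               rotation_deg=40.0)
        hm, _ = mv.generate_field(spec0, seed=3, artifacts=None)
        fit = fit_lattice(hm)
        assert fit.bravais_class == "hexagonal"
        # one frequency bin at 2.5 um field is < 4% of the constant
        assert abs(fit.lattice_constant_nm - 169.0) / 169.0 < 0.04

    def test_rotation_equivariance_0_vs_90(self, hex_field):
        """Scanning the same area at 90 deg leaves class and constant."""
        hm, _ = hex_field
        fit0 = mv.LatticeModel(hm).fit()
        rotated = hm.with_heights(np.rot90(hm.heights).copy())
        fit90 = mv.LatticeModel(rotated).fit()
        assert fit0.bravais_class == fit90.bravais_class == "hexagonal"
        assert fit90.lattice_constant_nm == pytest.approx(
            fit0.lattice_constant_nm, rel=0.02
        )

    def test_featureless_field_class_none(self, rng):
        hm = mv.HeightMap(rng.normal(0.0, 2.0, (256, 256)), 7.0)
        fit = fit_lattice(hm)
        assert fit.bravais_class == "none"
        assert np.isnan(fit.lattice_constant_nm)

    def test_snr_degrades_from_fine_to_coarse_sampling(self):
        """Coarse sampling weakens the first-order peaks.

        The spectral contrast of the lattice drops when the same
        surface is sampled coarsely; detectability at 7 nm/px is far
        above the peak threshold.
        """
        spec0 = mv.LatticeSpec("hexagonal", a=169.0, rotation_deg=17.0)
        snrs = {}
        for px in (7.0, 18.0, 22.0):
            vals = []
            for s in (1, 2):
                gt = mv.generate_positions(spec0, (2500.0, 2500.0), seed=s)
                hm = mv.render_surface(gt.positions_nm, mv.MicrovillusShape(),
                                       px, (2500.0, 2500.0))
                hm = mv.tip_dilate(hm, mv.TipSpec())
                hm = mv.add_artifacts(hm, mv.ScanArtifactSpec(), seed=s + 7)
                vals.append(first_order_peak_snr(mv.preprocess(hm)))
            snrs[px] = np.mean(vals)
        assert snrs[7.0] > 10.0  # comfortably detectable at high res
        assert snrs[18.0] < snrs[7.0]
        assert snrs[22.0] < snrs[7.0]


class TestNeighborLinks:
    @staticmethod
    def _fit_for(spec):
        basis = spec.basis
        return mv.classify_bravais(basis[0], basis[1])

    def test_ideal_hexagonal_interior_coordination_six(self):
        spec = mv.LatticeSpec("hexagonal", a=169.0, jitter_nm=0.0,
                              rotation_deg=0.0)
        gt = mv.generate_positions(spec, (2500.0, 2500.0), seed=1)
        graph = mv.neighbor_links(gt.positions_nm, self._fit_for(spec),
                                  field_nm=(2500.0, 2500.0))
        counts = graph.interior_link_counts
        assert len(counts) > 100
        assert np.all(counts == 6)

    def test_ideal_rhombic_interior_coordination_four(self):
        spec = mv.LatticeSpec("rhombic", a=185.0, theta_deg=75.0,
                              jitter_nm=0.0, rotation_deg=0.0)
        gt = mv.generate_positions(spec, (2500.0, 2500.0), seed=1)
        graph = mv.neighbor_links(gt.positions_nm, self._fit_for(spec),
                                  field_nm=(2500.0, 2500.0))
        counts = graph.interior_link_counts
        assert len(counts) > 100
        assert np.all(counts == 4)

    def test_jittered_hexagonal_modal_six_max_six(self, hex_field):
        hm, gt = hex_field
        res = mv.LatticeModel(hm).fit()
        graph = res.neighbor_links(gt.positions_nm)
        counts = graph.interior_link_counts
        values, freq = np.unique(counts, return_counts=True)
        assert values[np.argmax(freq)] == 6  # modal coordination
        assert counts.max() <= 6

    def test_unclassified_lattice_rejected(self):
        fit = mv.LatticeFit(a1=np.zeros(2), a2=np.zeros(2),
                            bravais_class="none",
                            lattice_constant_nm=float("nan"),
                            lattice_constant_sd_nm=float("nan"),
                            theta_deg=float("nan"))
        with pytest.raises(ValueError):
            mv.neighbor_links(np.zeros((5, 2)), fit)


class TestLatticeModelInterface:
    def test_summary_contains_estimates(self, hex_field):
        hm, _ = hex_field
        res = mv.LatticeModel(hm).fit()
        text = res.summary()
        assert "hexagonal" in text
        assert "lattice constant" in text
        assert f"{res.lattice_constant_nm:8.1f}" in text

    def test_results_expose_uncertainty(self, hex_field):
        hm, _ = hex_field
        res = mv.LatticeModel(hm).fit()
        assert res.lattice_constant_sd_nm > 0
        assert 0 < res.theta_deg <= 90
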