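import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from isletfish.spots import (
    assign_spots,
    deconvolve_counts,
    detect_spots,
    estimate_unit_intensity,
    log_response_cube,
    tukey_filter,
)
from isletfish.types import LabelMask, UnitIntensity


def render_spot(shape, y, x, sigma, amplitude):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2))


def brute_force_log_peaks(img, sigmas, threshold):
    """Naive triple-loop local-maxima search in the LoG response cube
    (strictly greater than all 26 neighbors)."""
    cube = np.stack(
        [-(s**2) * ndi.gaussian_laplace(np.asarray(img, dtype=float), s) for s in sigmas]
    )
    K, H, W = cube.shape
    peaks = []
    cand = np.argwhere(cube > threshold)
    for k, r, c in cand:
        v = cube[k, r, c]
        is_max = True
        for dk in (-1, 0, 1):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dk == dr == dc == 0:
                        continue
                    kk, rr, cc = k + dk, r + dr, c + dc
                    if 0 <= kk < K and 0 <= rr < H and 0 <= cc < W and cube[kk, rr, cc] >= v:
                        is_max = False
                        break
                if not is_max:
                    break
            if not is_max:
                break
        if is_max:
            peaks.append((int(k), int(r), int(c)))
    return peaks


class TestDetectSpots:
    def test_all_zero_channel(self):
        out = detect_spots(np.zeros((32, 32)), 1.0, 2.0, 0.1)
        assert len(out) == 0

    def test_single_spot_position_scale_and_oracle(self):
        sigma_true = 1.5
        img = render_spot((48, 48), 24.0, 20.0, sigma_true, 100.0)
        sigmas = np.linspace(1.0, 2.5, 7)
        out = detect_spots(img, 1.0, 2.5, 5.0, n_scales=7)
        assert len(out) == 1
        f = out.iloc[0]
        assert abs(f["y"] - 24.0) < 1.0 and abs(f["x"] - 20.0) < 1.0
        assert abs(f["scale"] - sigma_true) / sigma_true < 0.25
        # oracle: argmax of the directly convolved LoG response
        cube = log_response_cube(img, sigmas)
        k, r, c = np.unravel_index(np.argmax(cube), cube.shape)
        assert (r, c) == (24, 20)
        assert abs(f["scale"] - sigmas[k]) <= (sigmas[1] - sigmas[0])

    def test_two_spots_15px_apart(self):
        img = render_spot((64, 64), 30.0, 20.0, 1.5, 100.0)
        img += render_spot((64, 64), 30.0, 35.0, 1.5, 100.0)
        out = detect_spots(img, 1.0, 2.5, 5.0)
        assert len(out) == 2

    def test_half_pixel_center_detected_once(self):
        # an exactly tied response plateau must yield one focus, not zero
        img = render_spot((48, 48), 24.0, 24.5, 1.2, 100.0)
        out = detect_spots(img, 0.9, 2.0, 5.0)
        assert len(out) == 1
        assert abs(out.iloc[0]["x"] - 24.5) < 1.0

    def test_intensity_near_total_integral(self):
        sigma = 1.2
        amp = 150.0
        img = render_spot((48, 48), 20.0, 25.0, sigma, amp)
        out = detect_spots(img, 0.9, 2.0, 5.0, aperture_radius_scales=2.5)
        total = 2 * np.pi * sigma**2 * amp
        assert out.iloc[0]["intensity"] == pytest.approx(total, rel=0.05)

    def test_matches_brute_force_oracle_on_noisy_field(self, rng):
        img = np.zeros((96, 96))
        positions = [(15, 20), (40, 70), (60, 30), (80, 80), (25, 55)]
        for y, x in positions:
            img += render_spot((96, 96), y, x, 1.4, 120.0)
        img += rng.normal(0, 3.0, img.shape)
        sigmas = np.linspace(1.0, 2.2, 5)
        out = detect_spots(img, 1.0, 2.2, 20.0, n_scales=5)
        oracle = brute_force_log_peaks(img, sigmas, 20.0)
        assert len(out) == len(oracle) == len(positions)
        oracle_pos = sorted((r, c) for _, r, c in oracle)
        got_pos = sorted(
            (int(round(y)), int(round(x))) for y, x in zip(out["y"], out["x"])
        )
        for (r1, c1), (r2, c2) in zip(oracle_pos, got_pos):
            assert abs(r1 - r2) <= 1 and abs(c1 - c2) <= 1

    def test_determinism(self, rng):
        img = render_spot((48, 48), 20.0, 20.0, 1.3, 90.0) + rng.normal(0, 2, (48, 48))
        img = np.clip(img, 0, None)
        out1 = detect_spots(img, 1.0, 2.0, 10.0)
        out2 = detect_spots(img, 1.0, 2.0, 10.0)
        pd.testing.assert_frame_equal(out1, out2)

    def test_nonfinite_rejected(self):
        img = np.zeros((8, 8))
        img[2, 2] = np.inf
        with pytest.raises(ValueError):
            detect_spots(img, 1.0, 2.0, 0.5)


class TestEstimateUnitIntensity:
    def test_worked_example(self):
        foci = pd.DataFrame({"intensity": [98.0, 99.0, 100.0, 101.0, 102.0, 305.0]})
        unit = estimate_unit_intensity(foci, bin_width=10.0, gene="G")
        assert unit.modal_bin == (100.0, 110.0)
        assert unit.I1 == pytest.approx(101.0)
        assert unit.n_support == 3

    def test_all_identical(self):
        foci = pd.DataFrame({"intensity": [50.0] * 7})
        unit = estimate_unit_intensity(foci, bin_width=10.0)
        assert unit.I1 == pytest.approx(50.0)

    def test_tie_goes_to_lower_bin(self):
        foci = pd.DataFrame({"intensity": [10.0, 11.0, 30.0, 31.0]})
        unit = estimate_unit_intensity(foci, bin_width=10.0)
        assert unit.modal_bin == (10.0, 20.0)

    def test_outliers_excluded(self):
        foci = pd.DataFrame(
            {"intensity": [100.0, 101.0, 5000.0, 5001.0, 5002.0],
             "outlier": [False, False, True, True, True]}
        )
        unit = estimate_unit_intensity(foci, bin_width=10.0)
        assert unit.I1 == pytest.approx(100.5)

    def test_no_foci_raises(self):
        with pytest.raises(ValueError):
            estimate_unit_intensity(pd.DataFrame({"intensity": []}), bin_width=10.0)

    def test_exhaustive_bin_enumeration_oracle(self, rng):
        intensities = rng.uniform(1, 500, 200)
        foci = pd.DataFrame({"intensity": intensities})
        bw = 25.0
        unit = estimate_unit_intensity(foci, bin_width=bw)
        # oracle: enumerate every bin, count half-open membership
        best_bin, best_count = None, -1
        for b in range(int(np.ceil(intensities.max() / bw)) + 1):
            count = int(((intensities >= b * bw) & (intensities < (b + 1) * bw)).sum())
            if count > best_count:
                best_bin, best_count = b, count
        members = intensities[
            (intensities >= best_bin * bw) & (intensities < (best_bin + 1) * bw)
        ]
        assert unit.modal_bin == (best_bin * bw, (best_bin + 1) * bw)
        assert unit.I1 == pytest.approx(np.median(members))
        assert unit.n_support == best_count


def quantile_oracle(x, q):
    """Linear-interpolation quantile between order statistics."""
    xs = sorted(x)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    frac = h - lo
    if lo + 1 < len(xs):
        return xs[lo] + frac * (xs[lo + 1] - xs[lo])
    return xs[lo]


class TestTukeyFilter:
    def test_worked_example(self):
        foci = pd.DataFrame({"intensity": [1.0, 2.0, 3.0, 4.0, 100.0]})
        out = tukey_filter(foci, k=1.5)
        assert quantile_oracle([1, 2, 3, 4, 100], 0.25) == 2.0
        assert quantile_oracle([1, 2, 3, 4, 100], 0.75) == 4.0
        assert list(out["outlier"]) == [False, False, False, False, True]

    def test_all_equal_none_flagged(self):
        out = tukey_filter(pd.DataFrame({"intensity": [5.0] * 6}), k=1.5)
        assert not out["outlier"].any()

    def test_no_upper_tail_no_flags(self):
        out = tukey_filter(pd.DataFrame({"intensity": [10.0, 11.0, 12.0, 13.0]}), k=1.5)
        assert not out["outlier"].any()

    def test_lower_fence_not_applied(self):
        out = tukey_filter(pd.DataFrame({"intensity": [0.001, 50.0, 51.0, 52.0, 53.0]}), k=1.5)
        assert not out.iloc[0]["outlier"]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tukey_filter(pd.DataFrame({"intensity": []}), k=1.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=40),
           st.floats(min_value=0.5, max_value=5.0))
    def test_matches_quantile_oracle(self, values, k):
        foci = pd.DataFrame({"intensity": values})
        out = tukey_filter(foci, k=k)
        q1 = quantile_oracle(values, 0.25)
        q3 = quantile_oracle(values, 0.75)
        fence = q3 + k * (q3 - q1)
        expected = [v > fence for v in values]
        assert list(out["outlier"]) == expected


class TestDeconvolveCounts:
    def _unit(self, i1=100.0):
        return UnitIntensity(gene="G", I1=i1, modal_bin=(i1 - 10, i1 + 10), n_support=5)

    def test_rounding(self):
        foci = pd.DataFrame({"intensity": [310.0], "outlier": [False]})
        out = deconvolve_counts(foci, self._unit(), clamp_min=1)
        assert out["mrna_count"].iloc[0] == 3

    def test_clamp(self):
        foci = pd.DataFrame({"intensity": [40.0], "outlier": [False]})
        out = deconvolve_counts(foci, self._unit(), clamp_min=1)
        assert out["mrna_count"].iloc[0] == 1

    def test_round_half_to_even(self):
        foci = pd.DataFrame({"intensity": [250.0, 350.0], "outlier": [False, False]})
        out = deconvolve_counts(foci, self._unit(), clamp_min=1)
        assert list(out["mrna_count"]) == [2, 4]

    def test_outlier_gets_zero(self):
        foci = pd.DataFrame({"intensity": [500.0], "outlier": [True]})
        out = deconvolve_counts(foci, self._unit(), clamp_min=1)
        assert out["mrna_count"].iloc[0] == 0

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=2, max_size=20))
    def test_monotone_in_intensity(self, values):
        foci = pd.DataFrame({"intensity": values, "outlier": [False] * len(values)})
        out = deconvolve_counts(foci, self._unit(), clamp_min=1)
        order = np.argsort(values, kind="stable")
        counts = out["mrna_count"].to_numpy()[order]
        assert (np.diff(counts) >= 0).all()


class TestAssignSpots:
    def _masks(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        nuclei[4:8, 4:8] = 1
        cells = np.zeros((20, 20), dtype=np.int32)
        cells[2:12, 2:12] = 1
        return LabelMask(labels=cells, kind="cell"), LabelMask(labels=nuclei, kind="nucleus")

    def test_nuclear(self):
        cells, nuclei = self._masks()
        foci = pd.DataFrame({"x": [5.2], "y": [5.4], "intensity": [10.0]})
        out = assign_spots(foci, cells, nuclei)
        assert out["cell_id"].iloc[0] == 1
        assert out["compartment"].iloc[0] == "nuclear"

    def test_cytoplasmic(self):
        cells, nuclei = self._masks()
        foci = pd.DataFrame({"x": [10.0], "y": [10.0], "intensity": [10.0]})
        out = assign_spots(foci, cells, nuclei)
        assert out["compartment"].iloc[0] == "cytoplasmic"

    def test_background_unassigned(self):
        cells, nuclei = self._masks()
        foci = pd.DataFrame({"x": [17.0], "y": [17.0], "intensity": [10.0]})
        out = assign_spots(foci, cells, nuclei)
        assert out["cell_id"].iloc[0] == 0
        assert out["compartment"].iloc[0] == "unassigned"

    def test_out_of_bounds(self):
        cells, nuclei = self._masks()
        foci = pd.DataFrame({"x": [25.0], "y": [5.0], "intensity": [10.0]})
        with pytest.raises(ValueError, match="bounds"):
            assign_spots(foci, cells, nuclei)

    def test_shape_mismatch(self):
        cells, _ = self._masks()
        nuclei = LabelMask(labels=np.zeros((10, 10), dtype=np.int32))
        with pytest.raises(ValueError, match="shape"):
            assign_spots(pd.DataFrame({"x": [1.0], "y": [1.0]}), cells, nuclei)

    def test_empty(self):
        cells, nuclei = self._masks()
        out = assign_spots(pd.DataFrame({"x": [], "y": []}), cells, nuclei)
        assert len(out) == 0
        assert "cell_id" in out.columns


def test_recovery_on_small_field(small_field_run):
    """Per-focus multiplicity and conservation on the small synthetic run."""
    result, gt = small_field_run
    foci = result.foci
    retained = foci[(~foci["outlier"]) & (foci["cell_id"] > 0)]
    # conservation: nuclear + cytoplasmic partition retained foci
    assert set(retained["compartment"]) <= {"nuclear", "cytoplasmic"}
    # the simulated autofluorescent blob is flagged
    assert foci["outlier"].sum() >= gt.spots["is_outlier"].sum()
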