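"""Rapoport's rule tests: fits, band rules, brute-force oracle equivalence."""

import numpy as np
import pytest
from scipy import stats

import elevdiv.rapoport as rp
from elevdiv.occurrence_io import ElevationBandSpec, SpeciesRange


def make_range(species_id, lo, hi, n_records=2, n_sites=2):
    return SpeciesRange(
        species_id=species_id,
        min_elev_m=lo,
        max_elev_m=hi,
        range_size_m=hi - lo,
        midpoint_m=(lo + hi) / 2,
        n_records=n_records,
        n_sites=n_sites,
    )


BANDS = ElevationBandSpec(origin_m=900, width_m=200, n_bands=7)


class TestFitLinear:
    def test_perfect_line(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [2 * v + 1 for v in x]
        fit = rp.fit_linear(x, y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-6

    def test_three_point_hand_values(self):
        fit = rp.fit_linear([1, 2, 3], [1, 2, 2])
        assert fit.slope == pytest.approx(0.5)
        assert fit.pearson_r == pytest.approx(np.sqrt(3) / 2, abs=1e-4)
        assert fit.r_squared == pytest.approx(fit.pearson_r**2)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rp.fit_linear([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rp.fit_linear([1, 2], [1, 2])

    def test_constant_y_gives_flat_fit(self):
        fit = rp.fit_linear([1, 2, 3], [5, 5, 5])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_null_pearson_small_and_p_uniform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        fit = rp.fit_linear(x, y)
        assert abs(fit.pearson_r) < 0.1
        pvals = []
        for _ in range(200):
            xa, ya = rng.normal(size=50), rng.normal(size=50)
            pvals.append(rp.fit_linear(xa, ya).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFitQuadratic:
    def test_exact_parabola_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = -2 * x**2 + 3 * x + 1
        fit = rp.fit_quadratic(x, y)
        assert fit.coefficients == pytest.approx((-2.0, 3.0, 1.0))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value == 0.0

    def test_nesting_beats_linear(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 20)
        y = 2 * x + rng.normal(size=20)
        assert rp.fit_quadratic(x, y).r_squared >= rp.fit_linear(x, y).r_squared

    def test_symmetric_unimodal_toy(self):
        fit = rp.fit_quadratic([1, 2, 3, 4, 5], [0, 3, 4, 3, 0])
        assert fit.coefficients[0] < 0
        assert fit.vertex_x == pytest.approx(3.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rp.fit_quadratic([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            rp.fit_quadratic([1, 1, 2, 2], [1, 2, 3, 4])


class TestStevens:
    def test_hand_enumerated_band_means(self):
        ranges = [
            make_range("A", 900, 1100),
            make_range("B", 1000, 1400),
            make_range("C", 1600, 2200),
        ]
        res = rp.stevens_method(ranges, BANDS)
        by_band = dict(zip(res.band_indices, zip(res.y, res.species_counts)))
        assert by_band[0] == (pytest.approx(300.0), 2)  # [900,1100): A, B
        assert by_band[3] == (pytest.approx(600.0), 1)  # [1500,1700): C

    def test_identical_ranges_give_flat_profile(self):
        ranges = [make_range(f"s{i}", 1000 + i, 1400 + i) for i in range(6)]
        res = rp.stevens_method(ranges, BANDS)
        assert res.fit.slope == pytest.approx(0.0, abs=1e-9)
        assert all(y == pytest.approx(400.0) for y in res.y)

    def test_single_band_occupied_rejected(self):
        ranges = [make_range(f"s{i}", 905, 910 + i) for i in range(5)]
        with pytest.raises(ValueError, match="occupied"):
            rp.stevens_method(ranges, BANDS)


class TestPagel:
    def test_upper_limit_band_assignment(self):
        # upper limit 1100 falls in [1100, 1300), nowhere else
        res = rp.pagel_method(
            [make_range("A", 900, 1100), make_range("B", 1000, 1700),
             make_range("C", 1600, 2200)],
            BANDS,
        )
        assert res.band_indices == [1, 4, 6]
        assert res.species_counts == [1, 1, 1]

    def test_partition_property(self, study_ranges):
        res = rp.pagel_method(study_ranges, BANDS)
        assert sum(res.species_counts) == len(study_ranges)


class TestRohde:
    def test_midpoint_band_assignment(self):
        ranges = [
            make_range("A", 900, 1100),   # midpoint 1000 -> band 0
            make_range("B", 1100, 1300),  # midpoint 1200 -> band 1
            make_range("C", 1700, 2100),  # midpoint 1900 -> band 5
        ]
        res = rp.rohde_midpoint_method(ranges, BANDS)
        assert res.band_indices == [0, 1, 5]
        assert res.quadratic_fit is None  # only 3 occupied bands

    def test_partition_property(self, study_ranges):
        res = rp.rohde_midpoint_method(study_ranges, BANDS)
        assert sum(res.species_counts) == len(study_ranges)

    def test_single_band_occupied_rejected(self):
        ranges = [make_range(f"s{i}", 1000, 1040 + i) for i in range(5)]
        with pytest.raises(ValueError):
            rp.rohde_midpoint_method(ranges, BANDS)


class TestCrossSpecies:
    def test_collinear_points(self):
        ranges = [
            make_range("A", 900, 1100),
            make_range("B", 1300, 1700),
            make_range("C", 1700, 2300),
        ]
        res = rp.cross_species_method(ranges)
        assert res.fit.slope == pytest.approx(0.4)
        assert res.fit.r_squared == pytest.approx(1.0)

    def test_constant_range_sizes(self):
        ranges = [make_range(f"s{i}", 900 + 100 * i, 1300 + 100 * i) for i in range(5)]
        res = rp.cross_species_method(ranges)
        assert res.fit.slope == 0.0
        assert res.fit.r_squared == 0.0

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            rp.cross_species_method([make_range("A", 900, 1100)])


@pytest.fixture(scope="module")
def study_ranges():
    """Representative species ranges from a seeded synthetic community."""
    from elevdiv.occurrence_io import species_ranges
    from elevdiv.synthetic import simulate_community, study_params

    _, _, records = simulate_community(study_params(seed=2024))
    return species_ranges(records)


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_method(ranges, bands, method):
    """Direct-loop reference for the three banded methods and cross-species."""
    if method == "cross_species":
        return (
            [r.midpoint_m for r in ranges],
            [r.range_size_m for r in ranges],
            [1] * len(ranges),
        )
    edges = [bands.origin_m + i * bands.width_m for i in range(bands.n_bands + 1)]
    xs, ys, cs = [], [], []
    for i in range(bands.n_bands):
        lo, hi = edges[i], edges[i + 1]
        last = i == bands.n_bands - 1
        members = []
        for r in ranges:
            if method == "stevens":
                upper_ok = r.min_elev_m <= hi if last else r.min_elev_m < hi
                inside = upper_ok and r.max_elev_m >= lo
            else:
                point = r.max_elev_m if method == "pagel" else r.midpoint_m
                if point < bands.origin_m:
                    inside = i == 0
                elif last:
                    inside = lo <= point <= hi
                else:
                    inside = lo <= point < hi
            if inside:
                members.append(r.range_size_m)
        if members:
            xs.append((lo + hi) / 2)
            ys.append(sum(members) / len(members))
            cs.append(len(members))
    return xs, ys, cs


@pytest.mark.parametrize("method", rp.METHODS)
def test_methods_match_brute_force(method):
    """All four methods agree exactly with direct-loop re-implementations on
    small random assemblages."""
    rng = np.random.default_rng(99)
    dispatch = {
        "stevens": rp.stevens_method,
        "pagel": rp.pagel_method,
        "rohde_midpoint": rp.rohde_midpoint_method,
        "cross_species": lambda rr, b: rp.cross_species_method(rr),
    }
    checked = 0
    for _ in range(30):
        n_sp = rng.integers(3, 11)
        ranges = []
        for i in range(n_sp):
            lo = rng.uniform(880, 2100)
            hi = lo + rng.uniform(0, 2300 - lo)
            ranges.append(make_range(f"s{i}", lo, hi))
        bx, by, bcounts = brute_force_method(ranges, BANDS, method)
        try:
            res = dispatch[method](ranges, BANDS)
        except ValueError:
            assert len(bx) < 3 or (
                method == "cross_species" and len(ranges) < 3
            ) or np.ptp(bx) == 0
            continue
        checked += 1
        assert res.x == pytest.approx(bx)
        assert res.y == pytest.approx(by)
        assert res.species_counts == bcounts
    assert checked >= 15


def test_stevens_count_at_least_partition_count(study_ranges):
    stevens = rp.stevens_method(study_ranges, BANDS)
    pagel = rp.pagel_method(study_ranges, BANDS)
    assert sum(stevens.species_counts) >= sum(pagel.species_counts)


class TestEquivariance:
    def test_cross_species_slope_invariant_under_shift_and_scale(self, study_ranges):
        base = rp.cross_species_method(study_ranges).fit.slope

        shifted = [
            make_range(r.species_id, r.min_elev_m + 500, r.max_elev_m + 500)
            for r in study_ranges
        ]
        assert rp.cross_species_method(shifted).fit.slope == pytest.approx(base)

        scaled = [
            make_range(r.species_id, r.min_elev_m * 2, r.max_elev_m * 2)
            for r in study_ranges
        ]
        assert rp.cross_species_method(scaled).fit.slope == pytest.approx(base)

    def test_banded_slopes_invariant_under_joint_shift(self, study_ranges):
        shift = 700.0
        shifted_ranges = [
            make_range(r.species_id, r.min_elev_m + shift, r.max_elev_m + shift)
            for r in study_ranges
        ]
        shifted_bands = ElevationBandSpec(
            origin_m=BANDS.origin_m + shift, width_m=BANDS.width_m, n_bands=BANDS.n_bands
        )
        for fn in (rp.stevens_method, rp.pagel_method, rp.rohde_midpoint_method):
            a = fn(study_ranges, BANDS)
            b = fn(shifted_ranges, shifted_bands)
            assert b.fit.slope == pytest.approx(a.fit.slope)
            assert b.y == pytest.approx(a.y)


class TestVerdict:
    def test_positive_requires_significance(self):
        rng = np.random.default_rng(3)
        ranges = []
        for i in range(40):
            lo = rng.uniform(900, 1200)
            hi = lo + 200 + 0.8 * (lo - 900) + rng.uniform(0, 50)
            ranges.append(make_range(f"s{i}", lo, min(hi, 2300)))
        res = rp.cross_species_method(ranges)
        assert res.fit.slope > 0
        assert res.supports_rapoport == "positive"

    def test_inconclusive_on_noise(self):
        rng = np.random.default_rng(4)
        ranges = [
            make_range(f"s{i}", lo := rng.uniform(900, 1800), lo + rng.uniform(50, 400))
            for i in range(10)
        ]
        res = rp.cross_species_method(ranges, alpha=1e-12)
        assert res.supports_rapoport == "inconclusive"

    def test_unknown_method_rejected(self, study_ranges):
        with pytest.raises(ValueError, match="unknown"):
            rp.run_all_methods(study_ranges, methods=("stevens", "bogus"))
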