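"""Feature extractors vs analytic values and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from xeromics.features import (
    DEFAULT_PRIORITY,
    MOMENT_ORDERS,
    FeatureTable,
    concordance_probability,
    dose_gradients,
    dose_moments,
    dvh_features,
    kendall_tau,
    morphological_features,
    redundancy_filter,
    shape_features,
    subvolume_mean_doses,
)
from xeromics.grids import DoseGrid, GridError, OrganMask

from conftest import ball_mask


def grid_of(values, spacing=(1.0, 1.0, 1.0)):
    return DoseGrid(np.asarray(values, dtype=float), spacing)


def mask_of(values, spacing=(1.0, 1.0, 1.0)):
    return OrganMask(np.asarray(values, dtype=bool), spacing)


def gaussian_blob(shape=(20, 20, 20), sigma=8.0, spacing=(1.0, 1.0, 1.0)):
    g = DoseGrid(np.zeros(shape), spacing)
    x, y, z = g.coordinate_grids()
    c = [(n - 1) * s / 2 for n, s in zip(shape, spacing)]
    vals = 30.0 * np.exp(
        -((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) / (2 * sigma**2)
    )
    return DoseGrid(vals, spacing)


# ---------------------------------------------------------------------------
# oracles: direct double-loop summation over voxels


def oracle_moments(dose: DoseGrid, mask: OrganMask) -> dict:
    total = xs = ys = zs = 0.0
    vox = np.argwhere(mask.values)
    for i, j, k in vox:
        d = dose.values[i, j, k]
        total += d
        xs += d * i * dose.spacing[0]
        ys += d * j * dose.spacing[1]
        zs += d * k * dose.spacing[2]
    cx, cy, cz = xs / total, ys / total, zs / total
    out = {}
    for p, q, r in MOMENT_ORDERS:
        mu = 0.0
        for i, j, k in vox:
            mu += (
                dose.values[i, j, k]
                * (i * dose.spacing[0] - cx) ** p
                * (j * dose.spacing[1] - cy) ** q
                * (k * dose.spacing[2] - cz) ** r
            )
        out[(p, q, r)] = mu / total ** (1 + (p + q + r) / 3)
    return out


def oracle_kendall(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                tx += 1
                ty += 1
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestShapeFeatures:
    def test_cube_volume(self):
        m = mask_of(np.ones((10, 10, 10)))
        assert shape_features(m).volume == pytest.approx(1000.0)

    def test_ball_sphericity_and_eccentricity(self):
        geo = DoseGrid(np.zeros((45, 45, 45)), (1, 1, 1))
        m = ball_mask(geo, (22, 22, 22), 20)
        sf = shape_features(m)
        assert 0.95 <= sf.sphericity <= 1.05
        assert sf.eccentricity < 0.05

    def test_ellipsoid_principal_variances(self):
        geo = DoseGrid(np.zeros((45, 25, 25)), (1, 1, 1))
        x, y, z = geo.coordinate_grids()
        inside = ((x - 22) / 20) ** 2 + ((y - 12) / 10) ** 2 + ((z - 12) / 10) ** 2 <= 1
        sf = shape_features(OrganMask(inside, geo.spacing, geo.origin))
        assert sf.lambda1 / sf.lambda2 == pytest.approx(4.0, rel=0.05)
        assert sf.lambda1 >= sf.lambda2 >= sf.lambda3

    def test_single_voxel_rejected(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 1
        with pytest.raises(GridError):
            shape_features(mask_of(vals))


class TestDVH:
    def test_constant_dose_degenerate(self):
        dose = grid_of(np.full((4, 4, 4), 20.0))
        f = dvh_features(dose, mask_of(np.ones((4, 4, 4))))
        assert f.mean == 20.0
        assert f.spread == 0.0
        assert f.vx[10] == 1.0
        assert f.vx[25] == 0.0
        assert f.entropy == 0.0
        assert f.uniformity == 1.0
        # percentiles of a constant all equal the constant
        assert f.dx[2] == f.dx[50] == f.dx[98] == 20.0

    def test_two_point_distribution(self):
        vals = np.zeros((4, 4, 4))
        vals[:2] = 10.0
        vals[2:] = 30.0
        f = dvh_features(grid_of(vals), mask_of(np.ones((4, 4, 4))))
        assert f.mean == 20.0
        assert f.vx[20] == 0.5
        assert f.entropy == pytest.approx(1.0)
        assert f.uniformity == pytest.approx(0.5)

    def test_monotonicity_on_random_field(self, rng):
        dose = grid_of(rng.uniform(0, 60, (8, 8, 8)))
        f = dvh_features(dose, mask_of(np.ones((8, 8, 8))))
        dx_order = [f.dx[x] for x in (2, 10, 20, 30, 40, 50, 60, 70, 80, 90, 98)]
        assert all(a >= b for a, b in zip(dx_order, dx_order[1:]))
        vx_order = [f.vx[x] for x in (10, 15, 20, 25, 30, 35, 40, 45)]
        assert all(a >= b for a, b in zip(vx_order, vx_order[1:]))
        assert 0 <= f.uniformity <= 1
        assert f.spread >= 0

    def test_oracle_equivalence_random_field(self, rng):
        """Mean/spread/skewness/Dx/Vx against direct summation formulas."""
        vals = rng.uniform(0, 50, (6, 6, 6))
        inside = rng.uniform(size=(6, 6, 6)) < 0.7
        inside[0, 0, :2] = True
        f = dvh_features(grid_of(vals), mask_of(inside))
        d = vals[inside]
        assert f.mean == pytest.approx(d.mean())
        assert f.spread == pytest.approx(d.std())
        if d.std() > 0:
            sk = ((d - d.mean()) ** 3).mean() / d.std() ** 3
            assert f.skewness == pytest.approx(sk)
        assert f.vx[20] == pytest.approx((d >= 20).mean())
        assert f.dx[10] == pytest.approx(np.percentile(d, 90))


class TestSubvolumes:
    def test_uniform_dose(self):
        dose = grid_of(np.full((9, 9, 9), 7.0))
        s = subvolume_mean_doses(dose, mask_of(np.ones((9, 9, 9))))
        assert len(s) == 9
        assert all(v == pytest.approx(7.0) for v in s.values())

    def test_linear_ramp_ordering(self):
        geo = DoseGrid(np.zeros((9, 9, 9)), (1, 1, 1))
        x, _, _ = geo.coordinate_grids()
        dose = DoseGrid(1.0 + 2.0 * x, geo.spacing)
        s = subvolume_mean_doses(dose, mask_of(np.ones((9, 9, 9))))
        assert s["sx1"] < s["sx2"] < s["sx3"]
        assert s["sy1"] == pytest.approx(s["sy2"]) == pytest.approx(s["sy3"])

    def test_flip_maps_x_slabs(self, rng):
        vals = rng.uniform(0, 30, (9, 9, 9))
        dose = grid_of(vals)
        mask = mask_of(np.ones((9, 9, 9)))
        s = subvolume_mean_doses(dose, mask)
        sf = subvolume_mean_doses(dose.flip_sagittal(), mask)
        assert sf["sx1"] == pytest.approx(s["sx3"])
        assert sf["sx3"] == pytest.approx(s["sx1"])
        for key in ("sy1", "sy2", "sy3", "sz1", "sz2", "sz3"):
            assert sf[key] == pytest.approx(s[key])

    def test_thin_axis_rejected(self):
        m = np.zeros((9, 9, 9))
        m[:, :, 4:6] = 1
        with pytest.raises(GridError, match="'z'"):
            subvolume_mean_doses(grid_of(np.ones((9, 9, 9))), mask_of(m))


class TestGradients:
    def test_exact_affine_recovery(self):
        geo = DoseGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        x, _, _ = geo.coordinate_grids()
        dose = DoseGrid(5.0 + 1.5 * x, geo.spacing)
        g = dose_gradients(dose, mask_of(np.ones((10, 10, 10))))
        assert g == pytest.approx((1.5, 0.0, 0.0), abs=1e-9)

    def test_constant_dose(self):
        g = dose_gradients(grid_of(np.full((5, 5, 5), 9.0)), mask_of(np.ones((5, 5, 5))))
        assert g == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_flip_negates_x_only(self, rng):
        vals = rng.uniform(0, 30, (8, 8, 8))
        dose = grid_of(vals)
        mask = mask_of(np.ones((8, 8, 8)))
        gx, gy, gz = dose_gradients(dose, mask)
        fx, fy, fz = dose_gradients(dose.flip_sagittal(), mask)
        assert fx == pytest.approx(-gx)
        assert fy == pytest.approx(gy)
        assert fz == pytest.approx(gz)

    def test_planar_mask_rejected(self):
        m = np.zeros((5, 5, 5))
        m[:, :, 2] = 1
        with pytest.raises(GridError):
            dose_gradients(grid_of(np.ones((5, 5, 5))), mask_of(m))

    def test_least_squares_oracle(self, rng):
        vals = rng.uniform(0, 40, (7, 7, 7))
        inside = rng.uniform(size=(7, 7, 7)) < 0.6
        inside[[0, -1], [0, -1], [0, -1]] = True
        mask = mask_of(inside)
        g = dose_gradients(grid_of(vals), mask)
        coords = np.argwhere(inside).astype(float)
        X = np.column_stack([np.ones(len(coords)), coords])
        beta = np.linalg.lstsq(X, vals[inside], rcond=None)[0]
        assert g == pytest.approx(tuple(beta[1:]), abs=1e-8)


class TestMoments:
    def test_symmetric_distribution_zero_skewness(self):
        blob = gaussian_blob((15, 15, 15), sigma=4.0)
        mask = mask_of(np.ones((15, 15, 15)))
        eta = dose_moments(blob, mask)
        assert eta.eta(3, 0, 0) == pytest.approx(0.0, abs=1e-10)

    def test_translation_invariance(self, rng):
        vals = rng.uniform(0, 20, (8, 8, 8))
        inside = rng.uniform(size=(8, 8, 8)) < 0.7
        inside[0, 0, 0] = True
        a = dose_moments(DoseGrid(vals, (1, 1, 1), (0, 0, 0)), OrganMask(inside, (1, 1, 1), (0, 0, 0)))
        b = dose_moments(
            DoseGrid(vals, (1, 1, 1), (10.0, -7.0, 3.0)),
            OrganMask(inside, (1, 1, 1), (10.0, -7.0, 3.0)),
        )
        for o in MOMENT_ORDERS:
            assert a[o] == pytest.approx(b[o], abs=1e-12)

    def test_isotropic_blob_and_oracle(self):
        blob = gaussian_blob((20, 20, 20), sigma=8.0)
        mask = mask_of(np.ones((20, 20, 20)))
        eta = dose_moments(blob, mask)
        assert eta.eta(2, 0, 0) == pytest.approx(eta.eta(0, 2, 0), rel=0.02)
        assert eta.eta(0, 2, 0) == pytest.approx(eta.eta(0, 0, 2), rel=0.02)
        oracle = oracle_moments(blob, mask)
        for o in MOMENT_ORDERS:
            assert eta[o] == pytest.approx(oracle[o], abs=1e-12)

    def test_second_order_diagonal_nonnegative(self, rng):
        vals = rng.uniform(0, 25, (10, 10, 10))
        eta = dose_moments(grid_of(vals), mask_of(np.ones((10, 10, 10))))
        for o in ((2, 0, 0), (0, 2, 0), (0, 0, 2)):
            assert eta[o] >= 0

    def test_zero_total_dose_rejected(self):
        with pytest.raises(GridError):
            dose_moments(grid_of(np.zeros((4, 4, 4))), mask_of(np.ones((4, 4, 4))))


class TestMorphological:
    def test_symmetric_contra_skewness_zero(self):
        blob = gaussian_blob((15, 15, 15), sigma=5.0)
        mask = mask_of(np.ones((15, 15, 15)))
        m = morphological_features(blob, mask, mask)
        assert m["eta300_contra"] == pytest.approx(0.0, abs=1e-10)
        # x-mirror-symmetric dose: eta110 vanishes, so the product term does
        assert m["eta110_product"] == pytest.approx(0.0, abs=1e-12)

    def test_oracle_on_random_field(self, rng):
        vals = rng.uniform(0, 30, (20, 20, 20))
        dose = grid_of(vals)
        mi = np.zeros((20, 20, 20), bool)
        mi[2:9, 4:16, 4:16] = True
        mc = np.zeros((20, 20, 20), bool)
        mc[11:18, 4:16, 4:16] = True
        m = morphological_features(dose, mask_of(mi), mask_of(mc))
        oi = oracle_moments(dose, mask_of(mi))
        oc = oracle_moments(dose, mask_of(mc))
        assert m["eta111_ipsi"] == pytest.approx(oi[(1, 1, 1)], abs=1e-12)
        assert m["eta002_contra"] == pytest.approx(oc[(0, 0, 2)], abs=1e-12)
        assert m["eta300_contra"] == pytest.approx(oc[(3, 0, 0)], abs=1e-12)
        assert m["eta110_product"] == pytest.approx(oi[(1, 1, 0)] * oc[(1, 1, 0)], abs=1e-12)


class TestKendall:
    def test_perfect_agreement(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3]) == 1.0

    def test_perfect_disagreement(self):
        assert kendall_tau([1, 2, 3], [3, 2, 1]) == -1.0

    def test_brute_force_oracle_with_ties(self, rng):
        for _ in range(5):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert kendall_tau(x, y) == pytest.approx(oracle_kendall(x, y))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestConcordance:
    @pytest.mark.parametrize(
        "tau,expected", [(0.5, 0.75), (1.0, 1.0), (0.0, 0.5), (-1.0, 0.0)]
    )
    def test_values(self, tau, expected):
        assert concordance_probability(tau) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            concordance_probability(1.5)


class TestRedundancyFilter:
    def _table(self, cols: dict) -> FeatureTable:
        return FeatureTable(pd.DataFrame(cols))

    def test_identical_columns_one_dropped(self, rng):
        v = rng.uniform(5000, 30000, 40)
        t = self._table(
            {
                "volume_ipsi": v,
                "volume_contra": v * 1.1,
                "compactness_ipsi": v * 2,
                "compactness_contra": v * 2.2,
            }
        )
        reduced, log = redundancy_filter(t)
        assert "compactness_ipsi" not in reduced.data.columns
        assert "volume_ipsi" in reduced.data.columns
        assert log.iloc[0]["kept"] == "volume"
        assert log.iloc[0]["dropped"] == "compactness"

    def test_independent_columns_untouched(self, rng):
        t = self._table(
            {
                "volume_ipsi": rng.normal(size=200),
                "volume_contra": rng.normal(size=200),
                "spread_ipsi": rng.normal(size=200),
                "spread_contra": rng.normal(size=200),
            }
        )
        reduced, log = redundancy_filter(t)
        assert len(log) == 0
        assert list(reduced.data.columns) == list(t.data.columns)

    def test_correlation_in_one_gland_only_is_kept(self, rng):
        shared = rng.normal(size=100)
        t = self._table(
            {
                "mean_ipsi": shared,
                "mean_contra": rng.normal(size=100),
                "d50_ipsi": shared + 0.01 * rng.normal(size=100),
                "d50_contra": rng.normal(size=100),
            }
        )
        reduced, log = redundancy_filter(t)
        assert len(log) == 0  # correlated in the ipsi gland only

    def test_mean_kept_over_d50(self, rng):
        base_i = rng.normal(size=80)
        base_c = rng.normal(size=80)
        t = self._table(
            {
                "mean_ipsi": base_i,
                "mean_contra": base_c,
                "d50_ipsi": base_i + 0.05 * rng.normal(size=80),
                "d50_contra": base_c + 0.05 * rng.normal(size=80),
            }
        )
        reduced, log = redundancy_filter(t)
        assert "mean_ipsi" in reduced.data.columns
        assert "d50_ipsi" not in reduced.data.columns
        assert log.iloc[0]["kept"] == "mean"

    def test_missing_priority_raises(self, rng):
        v = rng.normal(size=50)
        t = self._table({"odd_ipsi": v, "odd_contra": v, "mean_ipsi": v, "mean_contra": v})
        with pytest.raises(KeyError):
            redundancy_filter(t, priority=DEFAULT_PRIORITY)


class TestFeatureTable:
    def test_long_export_and_csv_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(
            {"age": rng.uniform(30, 80, 5), "volume_ipsi": rng.uniform(5e3, 3e4, 5)},
            index=[f"P{i}" for i in range(5)],
        )
        t = FeatureTable(df)
        long = t.to_long()
        assert set(long.columns) == {"patient_id", "side", "group", "feature", "value"}
        assert len(long) == 10
        path = tmp_path / "ft.csv"
        t.write_csv(path)
        back = FeatureTable.read_csv(path)
        pd.testing.assert_frame_equal(back.data, t.data)

    def test_relabeling_symmetry(self, demo_cohort):
        """Mirroring a patient (geometry and labels together) leaves the
        lateralized ipsi/contra features unchanged."""
        import dataclasses

        from xeromics.features import extract_patient_features
        from xeromics.grids import lateralize

        p = demo_cohort.patients[0]
        a = lateralize(p.dose, p.left_mask, p.right_mask)
        mirrored_left = dataclasses.replace(p.right_mask.flip_sagittal(), laterality="left")
        mirrored_right = dataclasses.replace(p.left_mask.flip_sagittal(), laterality="right")
        b = lateralize(p.dose.flip_sagittal(), mirrored_left, mirrored_right)
        assert a.flipped != b.flipped  # exactly one orientation needs the flip
        fa = extract_patient_features(a, p.age, p.sex)
        fb = extract_patient_features(b, p.age, p.sex)
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], rel=1e-6), k
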