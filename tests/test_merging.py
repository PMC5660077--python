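import gemmi
import numpy as np
import pandas as pd
import pytest

from sfx2c import symmetry
from sfx2c.geometry import BeamColour, Orientation, UnitCell
from sfx2c.indexing import IndexingSolution
from sfx2c.merging import (
    MergedDataset,
    ReflectionObservation,
    cc_ano,
    cc_half,
    completeness,
    disc_pixel_count,
    i_over_sigma,
    integrate,
    merge,
    multiplicity,
    r_split,
    resolution_shells,
    shell_table,
    split_half_datasets,
)


def make_solution(predicted, colour=None, cell=None):
    cell = cell or UnitCell(78.3, 78.3, 39.1, lattice_type="tetragonal",
                            space_group="P43212")
    return IndexingSolution(
        orientation=Orientation(np.eye(3) * 0.01), cell=cell,
        colour=colour or BeamColour.from_energy(9.0),
        n_peaks_indexed=len(predicted), n_peaks_total=len(predicted),
        rms_residual_px=0.0, matched_hkl=np.empty((0, 3)),
        matched_peak_index=np.empty(0, dtype=int), predicted=predicted,
    )


def obs_table(rows):
    return pd.DataFrame(rows, columns=["h", "k", "l", "intensity", "sigma",
                                       "image_id", "colour"])


class TestIntegrate:
    def test_uniform_image_integrates_to_zero(self):
        img = np.full((100, 100), 37.0)
        sol = make_solution([((1, 2, 3), 50.0, 50.0)])
        obs = integrate(img, sol)
        assert len(obs) == 1
        assert obs.intensity.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_isolated_spot_recovers_injected_sum(self):
        img = np.zeros((100, 100))
        total = 5000.0
        yy, xx = np.mgrid[0:100, 0:100]
        sigma = 1.0
        img += total / (2 * np.pi * sigma ** 2) * np.exp(
            -((xx - 50.0) ** 2 + (yy - 50.0) ** 2) / (2 * sigma ** 2))
        obs = integrate(img, make_solution([((1, 2, 3), 50.0, 50.0)]))
        assert obs.intensity.iloc[0] == pytest.approx(total, rel=5e-3)

    def test_disc_pixel_count_matches_lattice_enumeration(self):
        for radius in (2.0, 6.0, 8.0):
            count = 0
            r_int = int(np.ceil(radius))
            for dx in range(-r_int, r_int + 1):
                for dy in range(-r_int, r_int + 1):
                    count += dx * dx + dy * dy <= radius * radius
            assert disc_pixel_count(radius) == count

    def test_off_panel_annulus_skipped(self):
        img = np.zeros((50, 50))
        sol = make_solution([((1, 0, 0), 3.0, 3.0), ((0, 1, 0), 25.0, 25.0)])
        obs = integrate(img, sol)
        assert len(obs) == 1  # only the interior spot

    def test_radii_ordering_enforced(self):
        with pytest.raises(ValueError):
            integrate(np.zeros((50, 50)), make_solution([]), radii=(6, 8, 7))


class TestMerge:
    def test_identical_observations(self, cell):
        rows = [(1, 2, 3, 5.0, 1.0, i, "9keV") for i in range(4)]
        merged = merge(obs_table(rows), cell)
        assert len(merged) == 1
        row = merged.table.iloc[0]
        assert row.intensity == 5.0
        assert row.sigma == 0.0
        assert row.n_obs == 4

    def test_two_observations_average(self, cell):
        merged = merge(obs_table([(1, 2, 3, 1.0, 1.0, 0, "9keV"),
                                  (1, 2, 3, 3.0, 1.0, 1, "9keV")]), cell)
        assert merged.table.iloc[0].intensity == pytest.approx(2.0)

    def test_symmetry_equivalents_share_a_key(self, cell):
        h = np.array([3, 1, 2])
        r = symmetry.rotations("P43212")[4]
        merged = merge(obs_table([
            (*h, 10.0, 1.0, 0, "9keV"),
            (*(h @ r), 20.0, 1.0, 1, "9keV"),
        ]), cell)
        assert len(merged) == 1
        assert merged.table.iloc[0].intensity == pytest.approx(15.0)

    def test_friedel_mates_not_merged(self, cell):
        merged = merge(obs_table([(3, 1, 2, 10.0, 1.0, 0, "9keV"),
                                  (-3, -1, -2, 20.0, 1.0, 1, "9keV")]), cell)
        assert len(merged) == 2

    def test_permutation_invariant(self, cell):
        rng = np.random.default_rng(0)
        rows = [(int(h), int(k), int(l), float(v), 1.0, int(i), "9keV")
                for (h, k, l), v, i in zip(
                    rng.integers(1, 6, (30, 3)), rng.random(30) * 100,
                    rng.integers(0, 10, 30))]
        m1 = merge(obs_table(rows), cell).table
        m2 = merge(obs_table(rows[::-1]), cell).table
        pd.testing.assert_frame_equal(m1.reset_index(drop=True),
                                      m2.reset_index(drop=True))

    def test_observation_dataclass_validation(self):
        with pytest.raises(ValueError):
            ReflectionObservation((1, 2, 3), 5.0, 0.0, 0, "9keV")


class TestHalfSetStatistics:
    def _halves(self, cell, noise=0.0, seed=0, n_refl=60, n_img=8):
        rng = np.random.default_rng(seed)
        hkl = symmetry.unique_reflections(cell, 8.0, "P43212")[:n_refl]
        truth = rng.random(len(hkl)) * 100 + 10
        rows = []
        for i in range(n_img):
            for (h, k, l), v in zip(hkl, truth):
                rows.append((h, k, l, v + noise * rng.normal(), 1.0, i, "9keV"))
        return split_half_datasets(obs_table(rows), cell)

    def test_identical_halves(self, cell):
        even, odd = self._halves(cell, noise=0.0)
        assert r_split(even, odd) == pytest.approx(0.0, abs=1e-12)
        assert cc_half(even, odd) == pytest.approx(1.0)

    def test_hand_example(self, cell):
        even = merge(obs_table([(1, 2, 3, 2.0, 1.0, 0, "9keV")]), cell)
        odd = merge(obs_table([(1, 2, 3, 1.0, 1.0, 1, "9keV")]), cell)
        assert r_split(even, odd) == pytest.approx(1.0 / (np.sqrt(2) * 1.5),
                                                   abs=1e-4)
        assert r_split(even, odd) == pytest.approx(0.4714, abs=1e-4)

    def test_scale_invariance(self, cell):
        even, odd = self._halves(cell, noise=5.0, seed=3)
        base = r_split(even, odd)
        even2 = MergedDataset(even.table.assign(
            intensity=even.table.intensity * 7.3), cell, "P43212")
        odd2 = MergedDataset(odd.table.assign(
            intensity=odd.table.intensity * 7.3), cell, "P43212")
        assert r_split(even2, odd2) == pytest.approx(base, rel=1e-12)

    def test_cc_ano_sign_flip(self, cell, sf_set):
        # build observations from simulated Friedel amplitudes with noise
        rng = np.random.default_rng(5)
        acent = ~sf_set.centric
        hkl = sf_set.hkl[acent][:200]
        fp = np.abs(sf_set.f_plus["9keV"])[acent][:200]
        fm = np.abs(sf_set.f_minus["9keV"])[acent][:200]
        rows = []
        for i in range(4):
            for (h, k, l), p, m in zip(hkl, fp, fm):
                rows.append((h, k, l, p ** 2 + rng.normal(), 1.0, i, "9keV"))
                rows.append((-h, -k, -l, m ** 2 + rng.normal(), 1.0, i, "9keV"))
        even, odd = split_half_datasets(obs_table(rows), cell)
        assert cc_ano(even, odd) > 0.9
        # flip the anomalous differences of one half
        pairs = odd.table.copy()
        mates = symmetry.canonical_hkl(-pairs[["h", "k", "l"]].to_numpy(),
                                       "P43212")
        flipped = odd.table.copy()
        key = {tuple(r): i for i, r in
               enumerate(flipped[["h", "k", "l"]].to_numpy())}
        inten = flipped["intensity"].to_numpy().copy()
        for i, m in enumerate(mates):
            j = key.get(tuple(m))
            if j is not None:
                inten[i] = odd.table["intensity"].to_numpy()[j]
        flipped["intensity"] = inten
        assert cc_ano(even, MergedDataset(flipped, cell, "P43212")) \
            == pytest.approx(-cc_ano(even, odd), rel=1e-9)

    def test_independent_noise_decorrelates(self, cell):
        hits = 0
        n_trials = 20
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            a, b = rng.normal(size=(2, 1000))
            cc = np.corrcoef(a, b)[0, 1]
            hits += abs(cc) < 0.1
        assert hits >= 18


class TestCompletenessAndFriends:
    def test_fully_enumerated_sphere_is_complete(self, cell):
        d_min = 8.0
        hkl = symmetry.unique_reflections(cell, d_min, "P43212")
        rows = [(h, k, l, 1.0, 1.0, 0, "9keV") for h, k, l in hkl]
        merged = merge(obs_table(rows), cell)
        assert completeness(merged, d_min) == pytest.approx(100.0)

    def test_half_the_reflections_give_half_completeness(self, cell):
        d_min = 8.0
        hkl = symmetry.unique_reflections(cell, d_min, "P43212")
        rows = [(h, k, l, 1.0, 1.0, 0, "9keV") for h, k, l in hkl[::2]]
        merged = merge(obs_table(rows), cell)
        expected = 100.0 * len(hkl[::2]) / len(hkl)
        assert completeness(merged, d_min) == pytest.approx(expected, abs=0.5)

    def test_possible_count_matches_gemmi_oracle(self, cell):
        d_min = 6.0
        ours = len(symmetry.unique_reflections(cell, d_min, "P43212"))
        sg = gemmi.SpaceGroup("P 43 21 2")
        gv = sg.operations()
        rots = [np.array(op.rot) // op.DEN for op in gv.sym_ops]
        seen = set()
        hmax = 14
        for h in range(-hmax, hmax + 1):
            for k in range(-hmax, hmax + 1):
                for l in range(-hmax, hmax + 1):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if cell.d_spacing((h, k, l)) < d_min:
                        continue
                    if gv.is_systematically_absent([h, k, l]):
                        continue
                    seen.add(max(tuple(np.array([h, k, l]) @ r) for r in rots))
        assert ours == len(seen)

    def test_multiplicity_and_i_over_sigma(self, cell):
        rows = [(1, 2, 3, 10.0, 1.0, i, "9keV") for i in range(4)]
        rows += [(2, 3, 1, 8.0, 1.0, 0, "9keV")]
        merged = merge(obs_table(rows), cell)
        assert multiplicity(merged) == pytest.approx((4 + 1) / 2)
        assert np.isfinite(i_over_sigma(merged)) or len(
            merged.table[merged.table.sigma > 0]) == 0


class TestPipelineClosure:
    def test_noise_free_chain_recovers_injected_intensities(
            self, cell, geom, colours):
        """simulate -> find peaks -> index -> integrate returns the
        injected spot intensities (spots isolated enough not to overlap a
        neighbour's integration disc)."""
        from sfx2c.indexing import two_colour_pipeline
        from sfx2c.simulate import SimConfig, simulate_two_colour_image
        cfg = SimConfig(seed=44, noise="none", colour_ratio_fixed=1.0,
                        d_min=4.5)
        img, truth = simulate_two_colour_image(cell, geom, colours, cfg)
        s0, s1, report = two_colour_pipeline(img, cell, colours, geom)
        assert report["category"] == "both"
        errs = []
        for ci, sol in enumerate((s0, s1)):
            obs = integrate(img, sol, image_id=0)
            injected = {(r.h, r.k, r.l): r.intensity
                        for r in truth.peak_table[
                            truth.peak_table.colour == ci].itertuples()}
            for r in obs.itertuples():
                true_i = injected.get((r.h, r.k, r.l))
                if true_i and true_i > 500:
                    errs.append(abs(r.intensity - true_i) / true_i)
        errs = np.asarray(errs)
        assert len(errs) > 100
        assert np.median(errs) < 0.005
        assert (errs < 0.02).mean() >= 0.85


class TestShellTable:
    def test_shells_partition_and_noise_free_split_is_perfect(self, cell):
        rng = np.random.default_rng(7)
        hkl = symmetry.unique_reflections(cell, 4.0, "P43212")
        sel = rng.choice(len(hkl), 400, replace=False)
        rows = []
        for i in range(6):
            for h, k, l in hkl[sel]:
                rows.append((h, k, l, float(10 + (h * h + k + l) % 50), 1.0,
                             i, "9keV"))
        table = shell_table(obs_table(rows), cell, n_shells=5)
        shells = table[table.shell >= 0]
        # edges partition the resolution range
        assert np.all(shells.d_max.to_numpy()[1:]
                      == pytest.approx(shells.d_min.to_numpy()[:-1]))
        overall = table[table.shell == -1].iloc[0]
        assert overall.r_split == pytest.approx(0.0, abs=1e-12)
        assert overall.cc_half == pytest.approx(1.0)
        assert overall.multiplicity == pytest.approx(6.0)

    def test_equal_volume_shells(self):
        d = np.array([10.0, 8.0, 5.0, 4.0, 3.0, 2.5, 2.0])
        edges = resolution_shells(d, 4)
        inv3 = 1.0 / edges ** 3
        steps = np.diff(inv3)
        assert np.allclose(steps, steps[0])
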