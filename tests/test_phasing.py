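import numpy as np
import pandas as pd
import pytest

from conftest import circular_error_deg
from sfx2c import symmetry
from sfx2c.geometry import BeamColour, UnitCell
from sfx2c.merging import merge
from sfx2c.phasing import (
    anomalous_difference,
    compare_sad_mad,
    figure_of_merit,
    invert_sites,
    mad_phase_distribution,
    mean_cosine_difference,
    mean_phase_error,
    patterson_site_search,
    sad_phase_distribution,
)
from sfx2c.simulate import (
    AnomalousScatterer,
    GD_SITES,
    HeavySite,
    make_pseudo_protein,
    simulate_structure_factors,
)


def df_table(sf, label="9keV"):
    acent = ~sf.centric
    fp, fm = sf.amplitudes(label)
    return pd.DataFrame({
        "h": sf.hkl[acent, 0], "k": sf.hkl[acent, 1], "l": sf.hkl[acent, 2],
        "d": sf.d[acent], "colour": label, "dF": (fp - fm)[acent],
    })


@pytest.fixture(scope="module")
def found_sites(sf_set, cell):
    """Error-free two-site search, shared across assertions."""
    return patterson_site_search(df_table(sf_set), cell, "P43212",
                                 n_sites_max=4)


class TestAnomalousDifference:
    def test_equal_mates_give_zero(self, cell):
        rows = pd.DataFrame([(3, 1, 2, 25.0, 1.0, 0, "9keV"),
                             (-3, -1, -2, 25.0, 1.0, 0, "9keV")],
                            columns=["h", "k", "l", "intensity", "sigma",
                                     "image_id", "colour"])
        out = anomalous_difference(merge(rows, cell))
        assert len(out) == 1
        assert out.dF.iloc[0] == pytest.approx(0.0)

    def test_friedel_symmetric_data_gives_zero_everywhere(
            self, cell, protein, colours):
        sc = AnomalousScatterer(corrections=((9.0, 0.0, 0.0), (7.0, 0.0, 0.0)))
        sf = simulate_structure_factors(cell, GD_SITES, sc, protein, colours, 4.0)
        t = df_table(sf)
        assert np.abs(t.dF).max() < 1e-9

    def test_swapping_mates_flips_the_sign(self, cell):
        rows = pd.DataFrame([(3, 1, 2, 36.0, 1.0, 0, "9keV"),
                             (-3, -1, -2, 16.0, 1.0, 0, "9keV")],
                            columns=["h", "k", "l", "intensity", "sigma",
                                     "image_id", "colour"])
        swapped = rows.copy()
        swapped["intensity"] = rows["intensity"].to_numpy()[::-1]
        a = anomalous_difference(merge(rows, cell)).dF.iloc[0]
        b = anomalous_difference(merge(swapped, cell)).dF.iloc[0]
        assert a == pytest.approx(2.0) and b == pytest.approx(-2.0)

    def test_negative_intensities_clamped_and_flagged(self, cell):
        rows = pd.DataFrame([(3, 1, 2, -5.0, 1.0, 0, "9keV"),
                             (-3, -1, -2, 9.0, 1.0, 0, "9keV")],
                            columns=["h", "k", "l", "intensity", "sigma",
                                     "image_id", "colour"])
        out = anomalous_difference(merge(rows, cell), clamp_flag=True)
        assert out.dF.iloc[0] == pytest.approx(-3.0)
        assert bool(out.clamped.iloc[0])


class TestPattersonSiteSearch:
    def test_zero_differences_give_no_sites(self, sf_set, cell):
        t = df_table(sf_set)
        t["dF"] = 0.0
        assert patterson_site_search(t, cell, "P43212") == []

    def test_too_few_differences_rejected(self, sf_set, cell):
        with pytest.raises(ValueError):
            patterson_site_search(df_table(sf_set).head(50), cell, "P43212")

    def test_two_sites_recovered_within_half_angstrom(self, found_sites, cell):
        assert len(found_sites) == 2
        for truth in GD_SITES:
            assert any(symmetry.sites_equivalent(s.xyz, truth.xyz, cell,
                                                 "P43212", tol=0.5)
                       for s in found_sites)

    def test_single_site_recovered(self, cell, scatterer, protein, colours):
        sf = simulate_structure_factors(cell, GD_SITES[:1], scatterer,
                                        protein, colours, 3.0)
        sites = patterson_site_search(df_table(sf), cell, "P43212",
                                      n_sites_max=4)
        assert len(sites) == 1
        assert symmetry.sites_equivalent(sites[0].xyz, GD_SITES[0].xyz, cell,
                                         "P43212", tol=0.5)

    def test_occupancy_ratio_from_peak_heights(self, cell, scatterer,
                                               protein, colours):
        truth = (GD_SITES[0], HeavySite(GD_SITES[1].xyz, occupancy=0.5,
                                        b_iso=12.0))
        sf = simulate_structure_factors(cell, truth, scatterer, protein,
                                        colours, 3.0)
        sites = patterson_site_search(df_table(sf), cell, "P43212",
                                      n_sites_max=2, rel_cutoff=0.08)
        assert len(sites) == 2
        occs = sorted(s.occupancy for s in sites)
        assert occs[0] / occs[1] == pytest.approx(0.5, rel=0.2)


def strong_signal_subset(sf, n=300):
    """Reflections with a healthy anomalous signal relative to |F|."""
    from sfx2c.simulate import heavy_partial_structure_factors
    acent = ~sf.centric
    hkl, d = sf.hkl[acent], sf.d[acent]
    high = max(sf.colours, key=lambda c: c.photon_energy)
    sc = AnomalousScatterer()
    hp, _ = heavy_partial_structure_factors(hkl, d, GD_SITES, sc, high,
                                            "P43212", include_f0=False)
    fp = np.abs(sf.f_plus[high.label][acent])
    order = np.argsort(np.abs(hp) / fp)[::-1][:n]
    return acent, order


class TestSadDistribution:
    def test_error_free_acentric_bimodal_with_mode_at_truth(
            self, sf_set, cell, scatterer, colours):
        acent, order = strong_signal_subset(sf_set)
        hkl = sf_set.hkl[acent][order]
        d = sf_set.d[acent][order]
        truth = sf_set.true_phase[acent][order]
        fp, fm = sf_set.amplitudes("9keV")
        high = colours[1]
        est = sad_phase_distribution(fp[acent][order], fm[acent][order],
                                     hkl, d, GD_SITES, scatterer, high, cell)
        n_modes, at_truth = [], []
        for i in range(len(hkl)):
            p = est.prob[i]
            modes = np.flatnonzero((p > np.roll(p, 1)) & (p >= np.roll(p, -1))
                                   & (p > 0.005 * p.max()))
            n_modes.append(len(modes))
            at_truth.append(bool(len(modes)) and np.min(np.abs(
                (modes - truth[i] + 180) % 360 - 180)) < 5)
        # two Harker intersections per reflection, except where the circles
        # meet tangentially and the modes coalesce
        assert 1.7 <= np.mean(n_modes) <= 2.0
        assert (np.array(n_modes) == 2).mean() > 0.75
        assert np.mean(at_truth) > 0.9
        assert np.all(est.fom <= 1.0 + 1e-12)
        assert np.median(est.fom) < 0.999  # bimodality caps the FOM

    def test_centric_reflections_restricted_to_allowed_phases(
            self, sf_set, cell, scatterer, colours):
        cen = sf_set.centric
        hkl = sf_set.hkl[cen][:50]
        d = sf_set.d[cen][:50]
        fp, fm = sf_set.amplitudes("9keV")
        est = sad_phase_distribution(fp[cen][:50], fm[cen][:50], hkl, d,
                                     GD_SITES, scatterer, colours[1], cell,
                                     centric=np.ones(len(hkl), dtype=bool))
        for i in range(len(hkl)):
            allowed = symmetry.centric_phase(hkl[i], "P43212")
            support = np.flatnonzero(est.prob[i] > 0)
            for s in support:
                assert min(abs((s - allowed) % 360), abs((s - allowed) % 360 - 180),
                           abs((s - allowed) % 360 - 360)) < 1.5

    def test_infinite_error_gives_uniform_distribution(
            self, sf_set, cell, scatterer, colours):
        acent = ~sf_set.centric
        hkl = sf_set.hkl[acent][:20]
        d = sf_set.d[acent][:20]
        fp, fm = sf_set.amplitudes("9keV")
        est = sad_phase_distribution(fp[acent][:20], fm[acent][:20], hkl, d,
                                     GD_SITES, scatterer, colours[1], cell,
                                     sigma_e=1e9)
        assert np.allclose(est.prob, 1.0 / 360.0, atol=1e-6)
        assert np.all(est.fom < 1e-3)


class TestMadDistribution:
    def test_error_free_unimodal_at_truth_for_strong_signal(
            self, sf_set, cell, scatterer, colours):
        acent, order = strong_signal_subset(sf_set, n=200)
        hkl = sf_set.hkl[acent][order]
        d = sf_set.d[acent][order]
        truth = sf_set.true_phase[acent][order]
        obs = {lab: (np.abs(sf_set.f_plus[lab])[acent][order],
                     np.abs(sf_set.f_minus[lab])[acent][order])
               for lab in sf_set.f_plus}
        est = mad_phase_distribution(obs, hkl, d, GD_SITES, scatterer,
                                     colours, cell)
        err = circular_error_deg(est.best_phase, truth)
        assert np.median(est.fom) > 0.99
        assert np.median(err) < 1.0

    def test_uninformative_second_colour_reduces_to_sad(
            self, sf_set, cell, colours):
        # a colour with f' = f'' = 0 contributes a circle through every
        # trial phase: its likelihood is flat and the product equals SAD
        acent = ~sf_set.centric
        sel = slice(0, 150)
        hkl = sf_set.hkl[acent][sel]
        d = sf_set.d[acent][sel]
        fp, fm = sf_set.amplitudes("9keV")
        fp, fm = fp[acent][sel], fm[acent][sel]
        sc0 = AnomalousScatterer(corrections=((9.0, -4.0, 11.7),
                                              (7.0, 0.0, 0.0)))
        sad = sad_phase_distribution(fp, fm, hkl, d, GD_SITES, sc0,
                                     colours[1], cell)
        obs = {"9keV": (fp, fm), "7keV": (fp, fm)}
        mad = mad_phase_distribution(obs, hkl, d, GD_SITES, sc0, colours, cell)
        assert np.allclose(mad.prob, sad.prob, atol=1e-6)


class TestFigureOfMerit:
    def test_limit_cases(self):
        delta = np.zeros(360)
        delta[123] = 1.0
        assert figure_of_merit(delta) == pytest.approx(1.0)
        assert figure_of_merit(np.full(360, 1 / 360)) == pytest.approx(0.0, abs=1e-12)
        antipodal = np.zeros(360)
        antipodal[[10, 190]] = 0.5
        assert figure_of_merit(antipodal) == pytest.approx(0.0, abs=1e-12)


class TestMeanCosineDifference:
    def test_identical_and_antiphase(self):
        phases = np.array([10.0, 100.0, 250.0])
        assert mean_cosine_difference(phases, phases) == 0.0
        assert mean_cosine_difference(np.zeros(5), np.full(5, 180.0)) \
            == pytest.approx(2.0)

    def test_independent_uniform_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 360, (2, 200_000))
        observed = mean_cosine_difference(a, b)
        oracle = np.abs(np.cos(rng.uniform(0, 2 * np.pi, 10 ** 6))
                        - np.cos(rng.uniform(0, 2 * np.pi, 10 ** 6))).mean()
        assert observed == pytest.approx(oracle, abs=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_cosine_difference([0.0], [0.0, 1.0])


class TestEnantiomorphSymmetry:
    def test_inversion_with_mate_swap_conjugates_distributions_in_p1(self):
        """Inverting a structure through the origin conjugates its structure
        factors and exchanges the Friedel mates; accordingly, running the
        engine with the inverted substructure *and* swapped |F+|/|F-| roles
        mirrors the phase distribution exactly: P'(phi) = P(-phi).
        (P1: no translation parts to complicate the bookkeeping.)"""
        cell = UnitCell(30.0, 25.0, 20.0, space_group="P1")
        sites = [HeavySite((0.23, 0.61, 0.4))]
        sc = AnomalousScatterer()
        protein = make_pseudo_protein(40, seed=2)
        colours = (BeamColour.from_energy(7.0), BeamColour.from_energy(9.0))
        sf = simulate_structure_factors(cell, sites, sc, protein, colours,
                                        4.0, space_group="P1")
        acent = ~sf.centric
        hkl = sf.hkl[acent][:100]
        d = sf.d[acent][:100]
        fp, fm = sf.amplitudes("9keV")
        # a fixed, moderate lack-of-closure width keeps the distributions
        # smooth so the comparison is not dominated by exponent blow-up of
        # float rounding on near-delta spikes
        base = sad_phase_distribution(fp[acent][:100], fm[acent][:100], hkl,
                                      d, sites, sc, colours[1], cell,
                                      space_group="P1", sigma_e=5.0)
        inv = sad_phase_distribution(fm[acent][:100], fp[acent][:100], hkl,
                                     d, invert_sites(sites), sc, colours[1],
                                     cell, space_group="P1", sigma_e=5.0)
        mirrored = base.prob[:, (-np.arange(360)) % 360]
        assert np.allclose(inv.prob, mirrored, atol=1e-7)


class TestCompareSadMad:
    def test_noise_free_mad_beats_sad(self, sf_set, scatterer):
        rep = compare_sad_mad(sf_set, scatterer, noise_frac=0.0, n_images=1,
                              seed=0)
        assert rep.n_sites_found == 2
        assert rep.mean_phase_error_mad < rep.mean_phase_error_sad
        assert rep.median_fom_mad >= rep.median_fom_sad

    def test_fewer_images_degrade_both_foms(self, sf_set, scatterer):
        rich = compare_sad_mad(sf_set, scatterer, noise_frac=0.2,
                               n_images=200, seed=1)
        poor = compare_sad_mad(sf_set, scatterer, noise_frac=0.2,
                               n_images=4, seed=1)
        assert poor.median_fom_mad < rich.median_fom_mad
        assert poor.median_fom_sad <= rich.median_fom_sad + 0.02

    def test_deterministic_given_seed(self, sf_set, scatterer):
        r1 = compare_sad_mad(sf_set, scatterer, seed=5)
        r2 = compare_sad_mad(sf_set, scatterer, seed=5)
        assert r1.summary_lines() == r2.summary_lines()
        pd.testing.assert_frame_equal(r1.fom_by_shell, r2.fom_by_shell)

    def test_phase_error_helper(self):
        assert mean_phase_error([10.0], [350.0]) == pytest.approx(20.0)
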