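"""Torus density estimation, remodeling free energy and Ramachandran regions."""

import math

import numpy as np
import pytest

from chapfold.dihedrals import (BoundReference, DihedralSampleSet,
                                EnergyProfile, VonMisesBasin, delta_g,
                                estimate_density, generate_dihedral_samples,
                                ramachandran_classify, ubiquitin_demo_basins,
                                ubiquitin_demo_reference)

_DEG = math.pi / 180.0


def _circ_mean_deg(a):
    a = np.asarray(a) * _DEG
    return math.degrees(math.atan2(np.sin(a).mean(), np.cos(a).mean()))


class TestEstimateDensity:
    def test_uniform_samples_give_flat_density(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(-180, 180, size=(60_000, 2))
        dens = estimate_density(s, bin_width_deg=20.0)
        grid = np.linspace(-170, 170, 12)
        vals = np.array([dens(p, q) for p in grid for q in grid])
        # within counting noise of the flat value everywhere
        assert np.allclose(vals, 1 / 360.0 ** 2, rtol=0.35)
        assert vals.mean() == pytest.approx(1 / 360.0 ** 2, rel=0.02)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        s = np.degrees(rng.vonmises(0.5, 5.0, size=(5_000, 2)))
        dens = estimate_density(s, bin_width_deg=5.0)
        centers = np.arange(-177.5, 180, 5.0)
        total = sum(dens(p, q) for p in centers for q in centers) * 25.0
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_wraparound_mode_at_the_seam(self):
        """Samples split across +/-179 degrees are one mode at the seam,
        denser there than at the antipode."""
        rng = np.random.default_rng(2)
        phi = np.where(rng.random(2_000) < 0.5, 179.0, -179.0)
        phi += rng.normal(0, 0.2, 2_000)
        s = np.column_stack([phi, phi])
        for method in ("histogram", "kde"):
            dens = estimate_density(s, method=method, bin_width_deg=5.0)
            assert dens(180.0, 180.0) > 100 * dens(0.0, 0.0)

    def test_von_mises_log_density_matches_closed_form(self):
        mu_phi, mu_psi, kap = -65.0, 120.0, 8.0
        rng = np.random.default_rng(3)
        n = 200_000
        s = np.column_stack([np.degrees(rng.vonmises(mu_phi * _DEG, kap, n)),
                             np.degrees(rng.vonmises(mu_psi * _DEG, kap, n))])
        basin = VonMisesBasin(mu_phi, mu_psi, kap, kap, lambda f: 1.0)
        analytic = basin.log_density(mu_phi, mu_psi)
        for method in ("histogram", "kde"):
            dens = estimate_density(s, method=method, bin_width_deg=3.0,
                                    kde_kappa=400.0)
            assert float(np.log(dens(mu_phi, mu_psi))) == pytest.approx(
                analytic, abs=0.1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            estimate_density(np.zeros((50, 2)))

    def test_zero_support_without_regularization_instructs(self):
        rng = np.random.default_rng(4)
        s = np.degrees(rng.vonmises(0.0, 50.0, size=(500, 2)))
        dens = estimate_density(s, pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount|regulariz"):
            dens(180.0, 180.0)


# basin centres on 5-degree bin centres, so the histogram oracle comparison
# is free of bin-edge bias; the far basin is (30, 20) degrees off the
# reference
NEAR = VonMisesBasin(-77.5, 32.5, 12.0, 12.0, lambda f: 1.0)
FAR = VonMisesBasin(-107.5, 52.5, 12.0, 12.0, lambda f: 1.0)


def _two_force_set(shift_force=300.0, seed=5):
    """One residue whose basin sits on the reference at 100 pN and moves
    (30, 20) degrees away at ``shift_force``."""
    basins = {"LYS48": [
        VonMisesBasin(NEAR.mu_phi_deg, NEAR.mu_psi_deg, 12.0, 12.0,
                      lambda f: 1.0 if f < 200 else 0.0),
        VonMisesBasin(FAR.mu_phi_deg, FAR.mu_psi_deg, 12.0, 12.0,
                      lambda f: 0.0 if f < 200 else 1.0),
    ]}
    return generate_dihedral_samples(basins, [100.0, shift_force],
                                     n_per_replicate=60_000, replicates=3,
                                     seed=seed)


class TestDeltaG:
    def test_delta_like_distribution_at_reference_is_minimum(self):
        basins = {"LYS48": [VonMisesBasin(-80.0, 30.0, 200.0, 200.0,
                                          lambda f: 1.0)]}
        # sharper concentration at 150 pN than elsewhere: cheapest there
        basins150 = {"LYS48": [VonMisesBasin(-80.0, 30.0, 2.0, 2.0,
                                             lambda f: 1.0)]}
        s_lo = generate_dihedral_samples(basins150, [50.0], seed=0)
        s_mid = generate_dihedral_samples(basins, [150.0], seed=1)
        s_hi = generate_dihedral_samples(basins150, [300.0], seed=2)
        import pandas as pd
        allsamples = DihedralSampleSet(pd.concat(
            [s_lo.df, s_mid.df, s_hi.df], ignore_index=True))
        ref = BoundReference({"LYS48": (-80.0, 30.0)})
        prof = delta_g(allsamples, ref)
        assert prof.normalized
        assert prof.min_force_pn == 150.0
        assert prof.dg_mean_kbt.min() == 0.0

    def test_two_force_shift_matches_analytic_log_density_difference(self):
        """Moving the basin (30, 20) degrees off the reference raises dG by
        the analytic von Mises log-density difference, within 0.1 k_BT."""
        samples = _two_force_set()
        ref = BoundReference({"LYS48": (-77.5, 32.5)})
        prof = delta_g(samples, ref, normalize=False, bin_width_deg=5.0)
        analytic = (-FAR.log_density(-77.5, 32.5)) - (-NEAR.log_density(-77.5, 32.5))
        observed = prof.dg_mean_kbt[1] - prof.dg_mean_kbt[0]
        assert observed == pytest.approx(analytic, abs=0.1)

    def test_normalization_preserves_differences_and_zeroes_minimum(self):
        samples = _two_force_set()
        ref = BoundReference({"LYS48": (-77.5, 32.5)})
        raw = delta_g(samples, ref, normalize=False)
        norm = raw.normalize()
        assert norm.dg_mean_kbt.min() == 0.0
        assert np.allclose(np.diff(norm.dg_mean_kbt), np.diff(raw.dg_mean_kbt))
        assert np.allclose(norm.dg_sd_kbt, raw.dg_sd_kbt)

    def test_demo_scenario_gives_u_shaped_profile(self):
        """Consensus-fragment emulation: outer residues leave their
        low-force basins and the central beta couple only populates its
        bound values at high force, so dG(F) dips at intermediate force."""
        forces = [50.0, 100.0, 150.0, 200.0, 300.0]
        samples = generate_dihedral_samples(ubiquitin_demo_basins(), forces,
                                            n_per_replicate=4_000, seed=7)
        prof = delta_g(samples, ubiquitin_demo_reference())
        i_min = int(np.argmin(prof.dg_mean_kbt))
        assert 0 < i_min < len(forces) - 1          # interior minimum
        assert prof.dg_mean_kbt[0] > 0.5 and prof.dg_mean_kbt[-1] > 0.5

    def test_missing_reference_residue_rejected(self):
        samples = _two_force_set()
        with pytest.raises(ValueError, match="absent"):
            delta_g(samples, BoundReference({"GLN49": (0.0, 0.0)}))


class TestGenerator:
    def test_single_component_circular_mean_within_two_degrees(self):
        basins = {"LYS48": [VonMisesBasin(-70.0, 140.0, 6.0, 6.0,
                                          lambda f: 1.0)]}
        s = generate_dihedral_samples(basins, [100.0], n_per_replicate=10_000,
                                      replicates=1, seed=11)
        arr = s.samples("LYS48", 100.0, 0)
        assert abs(_circ_mean_deg(arr[:, 0]) - (-70.0)) < 2.0
        assert abs(_circ_mean_deg(arr[:, 1]) - 140.0) < 2.0

    def test_zero_concentration_component_is_uniform(self):
        basins = {"LYS48": [VonMisesBasin(0.0, 0.0, 0.0, 0.0, lambda f: 1.0)]}
        s = generate_dihedral_samples(basins, [100.0], n_per_replicate=20_000,
                                      replicates=1, seed=12)
        arr = s.samples("LYS48", 100.0, 0)
        # all four quadrants roughly equally occupied
        q = np.histogram(arr[:, 0], bins=4, range=(-180, 180))[0] / 20_000
        assert np.allclose(q, 0.25, atol=0.02)

    def test_seed_determinism_and_tsv_round_trip(self, tmp_path):
        basins = ubiquitin_demo_basins()
        a = generate_dihedral_samples(basins, [100.0], 500, 2, seed=3)
        b = generate_dihedral_samples(basins, [100.0], 500, 2, seed=3)
        assert a.df.equals(b.df)
        p = tmp_path / "dihedrals.tsv"
        a.to_tsv(p)
        back = DihedralSampleSet.from_tsv(p)
        assert np.allclose(back.df.phi_deg, a.df.phi_deg)

    def test_unnormalizable_weights_rejected(self):
        basins = {"LYS48": [VonMisesBasin(0, 0, 1, 1, lambda f: 0.0)]}
        with pytest.raises(ValueError, match="normalizable"):
            generate_dihedral_samples(basins, [100.0], 200, 1, seed=0)


class TestRamachandran:
    CANONICAL = [
        ((-120.0, 130.0), "beta/PPII"),   # beta sheet
        ((-75.0, 150.0), "beta/PPII"),    # polyproline II
        ((-60.0, -45.0), "alphaR"),       # right-handed helix
        ((-63.0, -42.0), "alphaR"),
        ((60.0, 45.0), "alphaL"),         # left-handed helix
        ((120.0, -120.0), "other"),
        ((-150.0, 0.0), "alphaR"),
    ]

    @pytest.mark.parametrize("angles,expected", CANONICAL)
    def test_canonical_angles_classified(self, angles, expected):
        assert ramachandran_classify(*angles) == expected

    def test_replicate_sd_shrinks_with_sample_size(self):
        ref = BoundReference({"LYS48": (-80.0, 30.0)})
        basins = {"LYS48": [VonMisesBasin(-80.0, 30.0, 6.0, 6.0,
                                          lambda f: 1.0)]}
        sds = []
        for n in (500, 8_000):
            s = generate_dihedral_samples(basins, [100.0], n, 5, seed=9)
            prof = delta_g(s, ref, normalize=False)
            sds.append(prof.dg_sd_kbt[0])
        assert sds[1] < sds[0]
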