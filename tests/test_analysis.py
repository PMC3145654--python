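import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camdyn import analysis, fixtures, structure
from camdyn.analysis import (
    BASIN_M1,
    BASIN_M2,
    BasinDefinition,
    ContactDefinitions,
    HelixAnnotation,
    WHAMConvergenceError,
    asphericity,
    basin_population,
    cd_basis,
    contact_covariance,
    contact_probability_matrix,
    contact_states,
    ef_hand_angle,
    free_energy_surface,
    helicity,
    overlap_chi,
    radius_of_gyration,
    synthesize_cd_spectrum,
    wham,
)


class TestShapeParameters:
    def test_rg_of_two_unit_masses_two_angstrom_apart(self):
        assert radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == 1.0

    def test_rg_rotation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, (15, 3))
        theta = 0.7
        R = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        assert radius_of_gyration(x @ R.T) == pytest.approx(radius_of_gyration(x))

    def test_asphericity_of_tetrahedron_is_zero(self):
        tet = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        assert asphericity(tet) == pytest.approx(0.0, abs=1e-12)

    def test_asphericity_of_collinear_beads_is_one(self):
        rod = np.stack([np.arange(8.0), np.zeros(8), np.zeros(8)], axis=1)
        assert asphericity(rod) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_asphericity_bounded(self, seed):
        x = np.random.default_rng(seed).normal(0, 5, (12, 3))
        assert 0.0 <= asphericity(x) <= 1.0


class TestOverlapChi:
    def test_reference_against_itself_is_zero(self):
        ref = np.random.default_rng(0).normal(0, 5, (20, 3))
        assert overlap_chi(ref, ref) == 0.0

    def test_fully_displaced_is_one(self):
        ref = np.random.default_rng(0).normal(0, 5, (20, 3))
        assert overlap_chi(ref * 4 + 100.0, ref) == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 5, (20, 3))
        frame = ref + rng.normal(0, 1.5, ref.shape)
        got = overlap_chi(frame, ref, tolerance=2.0)
        hits = total = 0
        for i in range(20):
            for j in range(i + 2, 20):
                total += 1
                d = np.linalg.norm(frame[i] - frame[j])
                dref = np.linalg.norm(ref[i] - ref[j])
                hits += abs(d - dref) >= 2.0
        assert got == pytest.approx(hits / total)

    def test_mismatched_bead_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_chi(np.zeros((5, 3)), np.zeros((6, 3)))


class TestHelicity:
    def test_ideal_helix_is_fully_helical(self, helix_topology):
        ca = helix_topology.positions[helix_topology.ca_indices()]
        assert helicity(ca) == 1.0

    def test_extended_chain_has_no_helicity(self):
        rs = fixtures.make_extended_chain(12)
        top = structure.coarse_grain(rs)
        ca = top.positions[top.ca_indices()]
        assert helicity(ca) == 0.0

    def test_helix_coil_helix_matches_per_residue_oracle(self):
        ca = fixtures.make_helix_coil_helix(12, 7, 12)
        got = helicity(ca)
        # independent per-residue evaluation of the same assignment rule
        count = total = 0
        for i in range(1, len(ca) - 4):
            total += 1
            phi = math.degrees(
                structure.dihedral_angle(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
            )
            formed = 30.0 <= phi <= 80.0 and np.linalg.norm(ca[i] - ca[i + 4]) < 6.5
            count += formed
        assert got == pytest.approx(count / total)
        assert 0.0 < got < 1.0


class TestEFHandAngle:
    def test_antiparallel_helices(self):
        h = fixtures._helix_coords(8)[0]
        assert ef_hand_angle(h, h[::-1]) == pytest.approx(180.0, abs=1e-6)

    def test_perpendicular_and_requested_angles(self):
        for requested in (60.0, 90.0, 135.0):
            fx = fixtures.make_mini_efhand(requested)
            top = structure.coarse_grain(fx.record_set)
            ca = top.positions[top.ca_indices()]
            (s1, e1), (s2, e2) = fx.helix_residues
            got = ef_hand_angle(ca[s1 - 1 : e1], ca[s2 - 1 : e2])
            assert got == pytest.approx(requested, abs=2.0)

    def test_zero_length_vector_rejected(self):
        flat = np.zeros((8, 3))
        with pytest.raises(ValueError):
            ef_hand_angle(flat, flat)

    def test_annotation_ranges_must_not_overlap(self):
        with pytest.raises(ValueError):
            HelixAnnotation({"A": (1, 10), "B": (5, 20)})

    def test_annotation_from_helix_records(self, helix_record_set):
        ann = HelixAnnotation.from_helix_records(helix_record_set.helices)
        assert ann.ranges["A"] == (1, 12)


@pytest.fixture(scope="module")
def defs(helix_record_set):
    top = structure.build_native_contacts(
        helix_record_set, structure.coarse_grain(helix_record_set), cutoff=6.5
    )
    return top, ContactDefinitions.from_topology(top)


class TestContactStatistics:
    def test_reference_forms_all_native_no_nonnative(self, defs):
        top, d = defs
        q = contact_states(top.positions, d)
        n = len(d.native_pairs)
        assert np.all(q[:n] == 1)
        # nonnative 8 A cutoff may catch nothing on a compact helix beyond
        # the native set only if distances exceed it; verify against geometry
        x = top.positions
        dist = np.linalg.norm(
            x[d.nonnative_pairs[:, 0]] - x[d.nonnative_pairs[:, 1]], axis=1
        )
        assert np.array_equal(q[n:], (dist < 8.0).astype(int))

    def test_stretched_chain_forms_nothing(self, defs):
        top, d = defs
        q = contact_states(top.positions * 10.0, d)
        assert np.all(q == 0)

    def test_probabilities_reproduce_bernoulli_means(self, defs):
        _, d = defs
        rng = np.random.default_rng(0)
        p_true = np.linspace(0.1, 0.9, d.n_contacts)
        q = (rng.random((4000, d.n_contacts)) < p_true).astype(float)
        mats = contact_probability_matrix(q, d)
        assert np.abs(mats.probabilities - p_true).max() < 0.05
        assert np.all((mats.probabilities >= 0) & (mats.probabilities <= 1))

    def test_single_reference_frame_gives_unit_upper_triangle(self, defs):
        top, d = defs
        q = contact_states(top.positions, d)[None, :].astype(float)
        mats = contact_probability_matrix(q, d)
        for idx, (ra, rb) in enumerate(d.native_residues):
            lo, hi = min(ra, rb), max(ra, rb)
            assert mats.residue_matrix[lo, hi] == 1.0

    def test_covariance_of_identical_and_complementary_streams(self):
        rng = np.random.default_rng(1)
        q0 = rng.integers(0, 2, 5000).astype(float)
        q = np.stack([q0, q0, 1.0 - q0], axis=1)
        cov = contact_covariance(q)
        assert cov[0, 1] == pytest.approx(1.0)
        assert cov[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cov), 1.0)

    def test_independent_streams_nearly_uncorrelated(self):
        rng = np.random.default_rng(2)
        q = rng.integers(0, 2, (10_000, 4)).astype(float)
        cov = contact_covariance(q)
        off = cov[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_constant_contacts_flagged_undefined(self):
        q = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        cov = contact_covariance(q)
        assert np.isnan(cov[0, 0]) and np.isnan(cov[0, 1])

    def test_covariance_symmetric_and_near_psd(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 2, (2000, 1)).astype(float)
        noise = (rng.random((2000, 5)) < 0.3).astype(float)
        q = np.clip(base + noise, 0, 1)
        cov = contact_covariance(q)
        assert np.allclose(cov, cov.T, equal_nan=True)
        evals = np.linalg.eigvalsh(np.nan_to_num(cov))
        assert evals.min() > -1e-8

    def test_cpi_table_format(self, defs):
        top, d = defs
        q = contact_states(top.positions, d)[None, :].astype(float)
        table = contact_probability_matrix(q, d).to_cpi_table()
        lines = table.strip().splitlines()
        assert lines[0].startswith("# cpi")
        assert len(lines) == 1 + d.n_contacts


@pytest.fixture(scope="module")
def harmonic_samples():
    # exact Boltzmann samples of independent harmonic wells: E ~ Gamma
    n_particles, k = 5, 1.0
    temps = (1.0, 1.4)
    rng = np.random.default_rng(42)
    series = []
    for t in temps:
        x = rng.normal(0, math.sqrt(t / k), size=(4000, n_particles, 3))
        series.append(0.5 * k * (x**2).sum(axis=(1, 2)))
    return n_particles, temps, series


class TestWHAM:
    def test_single_temperature_reduces_to_plain_average(self):
        rng = np.random.default_rng(0)
        e = rng.normal(10.0, 2.0, 500)
        res = wham([e], [1.2])
        w = res.weights(1.2)
        assert np.allclose(w, 1.0 / len(e))
        assert res.expectation(e, 1.2) == pytest.approx(e.mean())

    def test_reweighted_energy_matches_equipartition(self, harmonic_samples):
        n, temps, series = harmonic_samples
        res = wham(series, temps)
        pooled = np.concatenate(series)
        for t in (1.0, 1.2, 1.4):
            got = res.expectation(pooled, t)
            expect = 1.5 * n * t
            sd = math.sqrt(1.5 * n) * t  # sd of a 3n/2-shape gamma
            se = 3 * sd / math.sqrt(len(series[0]) / 2)
            assert abs(got - expect) < max(se, 0.2)

    def test_free_energy_offsets_match_partition_ratios(self, harmonic_samples):
        n, temps, series = harmonic_samples
        res = wham(series, temps)
        analytic = -1.5 * n * math.log(temps[1] / temps[0])
        assert res.free_energies[1] == pytest.approx(analytic, abs=0.1)

    def test_disjoint_histograms_raise_with_diagnostic(self):
        with pytest.raises(WHAMConvergenceError, match="overlap"):
            wham([np.linspace(0, 1, 50), np.linspace(100, 101, 50)], [1.0, 1.1])


class TestSurfaceAndBasins:
    def test_surface_minimum_zero_and_empty_bins_flagged(self):
        rng = np.random.default_rng(0)
        chi = np.clip(rng.normal(0.2, 0.05, 2000), 0, 1)
        delta = np.clip(rng.normal(0.29, 0.02, 2000), 0, 1)
        surf = free_energy_surface(chi, delta, temperature=1.15)
        assert np.nanmin(surf.free_energy) == 0.0
        assert np.isnan(surf.free_energy[surf.counts == 0]).all()
        assert surf.counts.sum() == 2000

    def test_all_frames_inside_basin(self):
        chi = np.full(100, 0.2)
        delta = np.full(100, 0.29)
        assert basin_population(chi, delta, BASIN_M1) == 1.0

    def test_disjoint_basins_partition_probability(self):
        rng = np.random.default_rng(1)
        chi = rng.uniform(0, 1, 5000)
        delta = rng.uniform(0, 1, 5000)
        p1 = basin_population(chi, delta, BASIN_M1)
        p2 = basin_population(chi, delta, BASIN_M2)
        rest = BasinDefinition("rest", (0.0, 1.0), (0.0, 1.0))
        assert basin_population(chi, delta, rest) == 1.0
        assert p1 + p2 <= 1.0

    def test_two_cluster_split_recovered(self):
        rng = np.random.default_rng(2)
        n1, n2 = 7000, 3000
        chi = np.concatenate([
            rng.uniform(0.12, 0.28, n1), rng.uniform(0.31, 0.39, n2),
        ])
        delta = np.concatenate([
            rng.uniform(0.282, 0.298, n1), rng.uniform(0.05, 0.14, n2),
        ])
        assert basin_population(chi, delta, BASIN_M1) == pytest.approx(0.7, abs=0.02)
        assert basin_population(chi, delta, BASIN_M2) == pytest.approx(0.3, abs=0.02)

    def test_weighted_population(self):
        chi = np.array([0.2, 0.35])
        delta = np.array([0.29, 0.10])
        w = np.array([0.25, 0.75])
        assert basin_population(chi, delta, BASIN_M2, weights=w) == 0.75

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            basin_population(np.array([]), np.array([]), BASIN_M1)


class TestCDSpectrum:
    def test_pure_helix_returns_helix_basis(self):
        wl, theta = synthesize_cd_spectrum(1.0, 0.0)
        assert np.array_equal(theta, cd_basis(wl)["helix"])

    def test_linearity_in_fractions(self):
        _, a = synthesize_cd_spectrum(0.8, 0.1)
        _, b = synthesize_cd_spectrum(0.2, 0.5)
        _, mix = synthesize_cd_spectrum(0.5, 0.3)
        assert np.allclose(mix, 0.5 * a + 0.5 * b)

    def test_more_helix_deepens_the_222nm_band(self):
        wl = analysis.DEFAULT_WAVELENGTHS
        i222 = int(np.where(wl == 222.0)[0][0])
        values = [
            synthesize_cd_spectrum(f, 0.0)[1][i222] for f in (0.1, 0.4, 0.7, 1.0)
        ]
        assert np.all(np.diff(values) < 0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            synthesize_cd_spectrum(0.8, 0.4)
        with pytest.raises(ValueError):
            synthesize_cd_spectrum(-0.1, 0.0)
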