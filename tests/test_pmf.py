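"""Umbrella bias, WHAM unbiasing, well geometry, escape times, clusters."""

import numpy as np
import pytest

from memdpd import (SimulationState, UmbrellaWindow, binding_energy,
                    detect_clusters, inplane_com_distance, mfpt,
                    mfpt_quadrature, umbrella_bias_force, wham)
from memdpd.fixtures import biased_samples_from_known_pmf, double_well
from memdpd.pmf import PMFResult, bootstrap_well_depth


def _two_body_state(xa, xb, box=20.0):
    pos = np.array([[*xa, 10.0], [*xb, 10.0]])
    return SimulationState(
        positions=pos, velocities=np.zeros((2, 3)),
        species=np.zeros(2, dtype=int), molecule_id=np.array([0, 1]),
        box=np.array([box, box, box]))


class TestUmbrellaBias:
    def test_zero_force_at_window_center(self):
        st = _two_body_state((5.0, 5.0), (8.0, 5.0))
        f = umbrella_bias_force(st, np.array([0]), np.array([1]),
                                r_center=3.0, k_u=50.0)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_harmonic_restoring_force_antisymmetric_in_plane(self):
        delta = 0.2
        st = _two_body_state((5.0, 5.0), (8.2, 5.0))
        f = umbrella_bias_force(st, np.array([0]), np.array([1]),
                                r_center=3.0, k_u=50.0)
        # pulls the pair back together with magnitude k*delta
        assert f[1, 0] == pytest.approx(-50.0 * delta)
        np.testing.assert_allclose(f[0], -f[1], atol=1e-12)
        np.testing.assert_allclose(f[:, 2], 0.0)   # strictly in-plane

    def test_distance_uses_minimum_image(self):
        st = _two_body_state((1.0, 5.0), (19.0, 5.0))
        r, e = inplane_com_distance(st, np.array([0]), np.array([1]))
        assert r == pytest.approx(2.0)

    def test_adjacent_window_histograms_overlap(self):
        """Neighboring biased distributions share support (coverage)."""
        wins = biased_samples_from_known_pmf(
            double_well, centers=[1.0, 1.25, 1.5], k_u=50.0,
            n_samples=2000, seed=5)
        for a, b in zip(wins, wins[1:]):
            assert a.samples.max() > b.samples.min()


class TestWham:
    def test_single_unbiased_window_is_log_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(2.0, 0.3, 20000)
        win = UmbrellaWindow(center=2.0, k_u=0.0, samples=samples)
        res = wham([win], bin_width=0.05, jacobian=False,
                   plateau_fraction=0.05)
        ok = res.counts > 200
        hist_w = -np.log(res.counts[ok] / res.counts.sum())
        # equal up to the gauge constant
        diff = res.W[ok] - hist_w
        assert np.nanstd(diff) < 1e-9

    def test_window_reordering_leaves_pmf_unchanged(self):
        wins = biased_samples_from_known_pmf(
            double_well, centers=np.arange(0.6, 3.0, 0.3), n_samples=1500,
            seed=8)
        res1 = wham(wins, bin_width=0.05)
        res2 = wham(wins[::-1], bin_width=0.05)
        np.testing.assert_allclose(res1.W, res2.W, equal_nan=True,
                                   atol=1e-8)

    def test_splitting_a_window_in_half_is_invariant(self):
        wins = biased_samples_from_known_pmf(
            double_well, centers=np.arange(0.6, 3.0, 0.3), n_samples=2000,
            seed=9)
        w0 = wins[3]
        half = w0.samples.size // 2
        split = wins[:3] + [
            UmbrellaWindow(w0.center, w0.k_u, w0.samples[:half]),
            UmbrellaWindow(w0.center, w0.k_u, w0.samples[half:]),
        ] + wins[4:]
        res1 = wham(wins, bin_width=0.05)
        res2 = wham(split, bin_width=0.05)
        np.testing.assert_allclose(res1.W, res2.W, equal_nan=True, atol=1e-6)

    def test_gap_between_windows_is_reported(self):
        rng = np.random.default_rng(1)
        wins = [
            UmbrellaWindow(1.0, 50.0, rng.normal(1.0, 0.1, 500)),
            UmbrellaWindow(3.0, 50.0, rng.normal(3.0, 0.1, 500)),
        ]
        with pytest.raises(ValueError, match="gap"):
            wham(wins, bin_width=0.05)

    def test_known_double_well_recovered(self):
        wins = biased_samples_from_known_pmf(
            double_well, centers=np.arange(0.6, 3.61, 0.25),
            n_samples=4000, seed=42)
        res = wham(wins, bin_width=0.05, jacobian=False)
        ok = res.counts > 50
        shift = double_well(
            res.r[ok & (res.r >= res.zero_level_range[0])]).mean()
        rms = np.sqrt(np.nanmean(
            (res.W[ok] - (double_well(res.r[ok]) - shift)) ** 2))
        assert rms < 0.1


def _pmf_from_arrays(r, w):
    ok = np.isfinite(w)
    return PMFResult(r=r, W=w, W_no_jacobian=w.copy(),
                     uncertainty=np.zeros_like(w),
                     counts=np.where(ok, 1000, 0),
                     zero_level_range=(r[-5], r[-1]))


class TestBindingEnergy:
    def test_flat_pmf_has_no_binding(self):
        r = np.linspace(0.2, 5.0, 100)
        de, rmin, width = binding_energy(_pmf_from_arrays(r, np.zeros(100)))
        assert de == 0.0 and width == 0.0

    def test_square_well_depth_and_width(self):
        r = np.linspace(0.0, 6.0, 1201)
        w = np.where((r >= 1.0) & (r <= 2.2), -5.0, 0.0)
        de, rmin, width = binding_energy(_pmf_from_arrays(r, w))
        assert de == pytest.approx(5.0)
        assert 1.0 <= rmin <= 2.2
        assert width == pytest.approx(1.2, abs=0.02)

    def test_depth_within_bootstrap_spread_of_truth(self):
        wins = biased_samples_from_known_pmf(
            double_well, centers=np.arange(0.6, 3.61, 0.25),
            n_samples=1500, seed=17)
        res = wham(wins, bin_width=0.05, jacobian=False)
        de, _, _ = binding_energy(res)
        boots = bootstrap_well_depth(wins, n_boot=50, seed=1,
                                     bin_width=0.05, jacobian=False)
        true_depth = -double_well(np.linspace(0.5, 3.5, 500)).min()
        assert abs(de - true_depth) < 4 * max(boots.std(), 0.02)

    def test_shift_invariance_of_depth_and_escape_time(self):
        r = np.linspace(0.2, 5.0, 500)
        w = double_well(r)
        w -= w[-50:].mean()
        p1 = _pmf_from_arrays(r, w)
        p2 = _pmf_from_arrays(r, w + 3.0)
        de1, _, _ = binding_energy(p1)
        # depth is defined against the plateau: recompute p2's zero level
        de2, _, _ = binding_energy(_pmf_from_arrays(r, (w + 3.0) - 3.0))
        assert de1 == pytest.approx(de2)
        t1 = mfpt(p1, D=0.1).tau
        # tau depends only on W differences inside the integrand
        t2 = mfpt_quadrature(r, w + 3.0, 0.1, a=r[np.argmin(w)],
                             b=mfpt(p1, D=0.1).b, r_reflect=r[0])
        # the double integral of exp(+W)exp(-W) cancels any constant
        assert t2 == pytest.approx(t1, rel=1e-9)


class TestMFPT:
    def test_flat_potential_closed_form(self):
        r = np.linspace(0.0, 3.0, 50)
        tau = mfpt_quadrature(r, np.zeros(50), D=0.2, a=0.0, b=3.0)
        assert tau == pytest.approx(3.0 ** 2 / (2 * 0.2), rel=1e-3)

    def test_sharp_square_well_closed_form(self):
        # constant-depth well with absorbing edge: tau = w^2 / 2D
        # (the constant cancels between the two exponentials)
        r = np.linspace(0.0, 1.5, 600)
        w = np.full(600, -4.0)
        tau = mfpt_quadrature(r, w, D=0.1, a=0.0, b=1.5)
        assert tau == pytest.approx(1.5 ** 2 / (2 * 0.1), rel=1e-3)

    def test_width_scaling_is_quadratic(self):
        """Dilating the well by 2 multiplies the escape time by 4."""
        for scale in (1.0, 2.0):
            pass
        r = np.linspace(0.0, 4.0, 800)
        w = -3.0 * np.exp(-0.5 * ((r - 1.0) / 0.3) ** 2)
        t1 = mfpt_quadrature(r, w, 0.1, a=1.0, b=3.5, r_reflect=0.0)
        r2 = 2 * r
        w2 = -3.0 * np.exp(-0.5 * ((r2 - 2.0) / 0.6) ** 2)
        t2 = mfpt_quadrature(r2, w2, 0.1, a=2.0, b=7.0, r_reflect=0.0)
        assert t2 / t1 == pytest.approx(4.0, rel=1e-3)

    def test_pmf_without_zero_crossing_raises(self):
        r = np.linspace(0.2, 3.0, 100)
        w = -np.ones(100)    # never returns to zero
        with pytest.raises(ValueError, match="zero level"):
            mfpt(_pmf_from_arrays(r, w), D=0.1)

    def test_positive_diffusion_required(self):
        r = np.linspace(0.0, 2.0, 50)
        with pytest.raises(ValueError):
            mfpt_quadrature(r, np.zeros(50), D=0.0, a=0.0, b=2.0)


class TestClusters:
    def _frames(self, coords_per_frame, box=20.0):
        """Each protein is a single bead; coords is {label: (x,y,z)}."""
        frames = []
        labels = sorted(coords_per_frame[0])
        for coords in coords_per_frame:
            pos = np.array([coords[l] for l in labels], dtype=float)
            frames.append(SimulationState(
                positions=pos, velocities=np.zeros_like(pos),
                species=np.zeros(len(labels), dtype=int),
                molecule_id=np.arange(len(labels)),
                box=np.array([box] * 3)))
        beads = {l: np.array([k]) for k, l in enumerate(labels)}
        return frames, beads

    def test_separated_proteins_stay_singletons(self):
        frames, beads = self._frames(
            [{0: (2, 2, 2), 1: (10, 10, 10)}] * 30)
        ts = detect_clusters(frames, beads, cutoff=1.0)
        assert all(part == (frozenset({0}), frozenset({1}))
                   for part in ts.frames)
        assert frozenset({0, 1}) not in ts.lifetimes

    def test_dimer_interval_lifetime(self):
        apart = {0: (2.0, 2.0, 2.0), 1: (8.0, 8.0, 8.0)}
        close = {0: (2.0, 2.0, 2.0), 1: (2.5, 2.0, 2.0)}
        seq = [apart] * 10 + [close] * 100 + [apart] * 10
        frames, beads = self._frames(seq)
        ts = detect_clusters(frames, beads, cutoff=1.0)
        assert ts.lifetimes[frozenset({0, 1})] == 100

    def test_cross_boundary_contact_detected(self):
        frames, beads = self._frames([{0: (0.2, 5, 5), 1: (19.9, 5, 5)}])
        ts = detect_clusters(frames, beads, cutoff=1.0)
        assert ts.frames[0] == (frozenset({0, 1}),)

    def test_components_match_networkx_on_random_configurations(self):
        import networkx as nx
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            coords = {i: tuple(rng.uniform(0, 6, 3)) for i in range(n)}
            frames, beads = self._frames([coords], box=6.0)
            ts = detect_clusters(frames, beads, cutoff=1.2)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            pos = np.array([coords[i] for i in range(n)])
            d = pos[:, None] - pos[None, :]
            d -= 6.0 * np.round(d / 6.0)
            dist = np.sqrt((d ** 2).sum(-1))
            for i in range(n):
                for j in range(i + 1, n):
                    if dist[i, j] < 1.2:
                        g.add_edge(i, j)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert set(ts.frames[0]) == expected

    def test_needs_two_proteins(self):
        frames, beads = self._frames([{0: (1, 1, 1)}] * 2)
        with pytest.raises(ValueError):
            detect_clusters(frames, {0: beads[0]})
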