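"""Phase computation, PS detection against brute-force winding, density
conservation, and hotspot segmentation."""

import numpy as np
import pytest

from valab import phase_mapping as pm
from valab import monodomain_sim as ms


class TestComputePhase:
    def test_sinusoid_unwrapped_slope(self):
        t = np.arange(0, 2000, 5.0)
        v = 20 * np.sin(2 * np.pi * t / 250.0)
        phase, valid = pm.compute_phase(v[:, None])
        assert valid[0]
        slope = np.diff(np.unwrap(phase[:, 0])).mean() / 5.0
        assert abs(slope - 2 * np.pi / 250.0) / (2 * np.pi / 250.0) < 0.01

    def test_cosine_phase_zero_at_maxima(self):
        t = np.arange(0, 2000, 5.0)
        v = np.cos(2 * np.pi * t / 200.0)
        phase, _ = pm.compute_phase(v[:, None])
        peaks = np.where(np.isclose(np.mod(t, 200.0), 0.0))[0][1:-1]
        assert np.max(np.abs(phase[peaks, 0])) < 0.1

    def test_half_period_shift_gives_pi_offset(self):
        t = np.arange(0, 2000, 5.0)
        a = np.sin(2 * np.pi * t / 200.0)
        b = np.sin(2 * np.pi * (t - 100.0) / 200.0)
        phase, _ = pm.compute_phase(np.stack([a, b], axis=1))
        interior = slice(20, -20)
        d = np.angle(np.exp(1j * (phase[interior, 0] - phase[interior, 1])))
        assert np.allclose(np.abs(d), np.pi, atol=0.05)

    def test_flat_trace_marked_invalid(self):
        v = np.zeros((100, 2))
        v[:, 0] = 20 * np.sin(np.arange(100))
        _, valid = pm.compute_phase(v)
        assert valid[0] and not valid[1]


def _brute_force_charges(phase, surface):
    """Independent per-element loop integral of wrapped phase differences."""
    out = {}
    for e, tri in enumerate(surface.triangles):
        total = 0.0
        for a, b in ((0, 1), (1, 2), (2, 0)):
            d = phase[tri[b]] - phase[tri[a]]
            while d > np.pi:
                d -= 2 * np.pi
            while d <= -np.pi:
                d += 2 * np.pi
            total += d
        q = int(round(total / (2 * np.pi)))
        if q != 0:
            out[e] = q
    return out


class TestDetectPs:
    def test_analytic_spiral_single_ps(self):
        patch = ms.make_strip(length=20, width=20, edge_length=1.0)
        x = patch.vertices[:, 0] - 10.2
        y = patch.vertices[:, 1] - 10.5
        phase = np.arctan2(y, x)
        hits = pm.detect_ps(phase, patch)
        assert len(hits) == 1
        e, q = hits[0]
        assert q == 1
        bary = patch.vertices[patch.triangles[e]].mean(axis=0)
        assert np.linalg.norm(bary[:2] - [10.2, 10.5]) < 2.0

    def test_mirrored_spiral_negative_charge(self):
        patch = ms.make_strip(length=20, width=20, edge_length=1.0)
        x = patch.vertices[:, 0] - 10.2
        y = patch.vertices[:, 1] - 10.5
        hits = pm.detect_ps(np.arctan2(-y, x), patch)
        assert len(hits) == 1 and hits[0][1] == -1

    def test_uniform_phase_no_ps(self):
        patch = ms.make_strip(length=10, width=10, edge_length=1.0)
        assert pm.detect_ps(np.full(len(patch.vertices), 0.7), patch) == []

    def test_matches_brute_force_on_random_fields(self):
        """Detector equals the brute-force topological-charge oracle on
        patches below 500 elements."""
        patch = ms.make_strip(length=15, width=7, edge_length=1.0)
        assert len(patch.triangles) <= 500
        rng = np.random.default_rng(6)
        for _ in range(5):
            phase = rng.uniform(-np.pi, np.pi, len(patch.vertices))
            got = dict(pm.detect_ps(phase, patch))
            assert got == _brute_force_charges(phase, patch)

    def test_net_charge_matches_boundary_circulation(self):
        """Sum of interior charges equals the wrapped-phase winding of the
        patch boundary (charge conservation on a disk)."""
        patch = ms.make_strip(length=15, width=7, edge_length=1.0)
        x = patch.vertices[:, 0] - 7.3
        y = patch.vertices[:, 1] - 3.4
        phase = np.arctan2(y, x) + 0.3 * np.sin(x)
        net = sum(q for _, q in pm.detect_ps(phase, patch))
        loop = patch.boundary_loops[0]
        d = np.angle(np.exp(1j * np.diff(phase[np.r_[loop, loop[0]]])))
        winding = int(round(d.sum() / (2 * np.pi)))
        assert net == winding


class TestPsDensity:
    def _tracks(self, surface, elements, frames=40):
        events = np.array([(f, e, 1) for f in range(frames) for e in elements],
                          dtype=int)
        return pm.PSTrackSet(events=events, window_ms=frames * 5.0, dt_output=5.0)

    def test_single_stationary_ps_peaks_at_site(self, surface):
        tracks = self._tracks(surface, [500])
        dens = pm.ps_density(tracks, surface)
        peak = np.argmax(dens)
        bary = surface.vertices[surface.triangles[500]].mean(axis=0)
        assert np.linalg.norm(surface.vertices[peak] - bary) < 6.0

    def test_density_integral_conserves_event_count(self, surface):
        tracks = self._tracks(surface, [500, 1300], frames=25)
        dens = pm.ps_density(tracks, surface)
        va_cm2 = surface.vertex_areas() / 100.0
        integral = float((dens * va_cm2).sum()) * (tracks.window_ms / 1000.0)
        assert abs(integral - len(tracks)) / len(tracks) < 0.01

    def test_two_equal_sources_equal_peaks(self):
        patch = ms.make_strip(length=40, width=10, edge_length=1.0)
        bary = patch.vertices[patch.triangles].mean(axis=1)
        e1 = int(np.argmin(np.linalg.norm(bary - [10, 5, 0], axis=1)))
        e2 = int(np.argmin(np.linalg.norm(bary - [30, 5, 0], axis=1)))
        tracks = self._tracks(patch, [e1, e2])
        dens = pm.ps_density(tracks, patch)
        p1 = dens[np.argmin(np.linalg.norm(patch.vertices - [10, 5, 0], axis=1))]
        p2 = dens[np.argmin(np.linalg.norm(patch.vertices - [30, 5, 0], axis=1))]
        assert abs(p1 - p2) / max(p1, p2) < 0.05

    def test_empty_tracks_zero_map(self, surface):
        tracks = pm.PSTrackSet(events=np.zeros((0, 3), dtype=int),
                               window_ms=100.0, dt_output=5.0)
        assert not pm.ps_density(tracks, surface).any()

    def test_frame_order_permutation_invariant(self, surface):
        ev = np.array([(f, e, 1) for f, e in [(0, 10), (1, 700), (2, 10), (3, 50)]])
        a = pm.ps_density(pm.PSTrackSet(ev, 100.0, 5.0), surface)
        b = pm.ps_density(pm.PSTrackSet(ev[::-1], 100.0, 5.0), surface)
        assert np.allclose(a, b)


class TestHotspots:
    def test_all_zero_density_no_hotspots(self, surface):
        hs = pm.find_hotspots(np.zeros(len(surface.vertices)), surface)
        assert len(hs.regions) == 0

    def test_planted_bump_recovered(self, surface):
        d = surface.geodesic_distance([800])
        dens = np.exp(-0.5 * (d / 5.0) ** 2)
        hs = pm.find_hotspots(dens, surface)
        assert len(hs.regions) == 1
        assert 800 in hs.regions[0]

    def test_area_monotone_shrinkage_in_k_sd(self, surface):
        rng = np.random.default_rng(8)
        d = surface.geodesic_distance([800])
        dens = np.exp(-0.5 * (d / 8.0) ** 2) + 0.05 * rng.random(len(d))
        areas = [pm.find_hotspots(dens, surface, k_sd=k).total_area_cm2
                 for k in (0.5, 1.0, 2.0, 4.0)]
        assert areas[0] >= areas[1] >= areas[2] >= areas[3]
        big = pm.find_hotspots(dens, surface, k_sd=50.0)
        assert big.total_area_cm2 == 0.0

    def test_matches_flood_fill_oracle(self, surface):
        rng = np.random.default_rng(9)
        dens = rng.random(len(surface.vertices)) ** 3
        hs = pm.find_hotspots(dens, surface)
        mask = dens > hs.threshold
        edges = surface.edges()
        neigh = {}
        for a, b in edges:
            if mask[a] and mask[b]:
                neigh.setdefault(a, set()).add(b)
                neigh.setdefault(b, set()).add(a)
        seen, brute = set(), set()
        for v in np.where(mask)[0]:
            if v in seen:
                continue
            stack, comp = [v], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(neigh.get(x, ()))
            seen |= comp
            brute.add(frozenset(int(i) for i in comp))
        assert {frozenset(int(i) for i in r) for r in hs.regions} == brute
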