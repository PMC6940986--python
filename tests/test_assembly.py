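import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import saxshybrid as sx
from saxshybrid.assembly import build_assembly_model, sasa, _canonicalize
from saxshybrid.coordinates import bead_model, concat_models


def _c2_dimer(n=60, seed=0, jitter=0.0):
    """Two chains related by an exact 180-degree rotation about a known axis."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-15, 15, (n, 3)) + np.array([20.0, 0.0, 0.0])
    b = a.copy()
    b[:, 0] *= -1
    b[:, 1] *= -1
    if jitter:
        a = a + rng.normal(0, jitter, a.shape)
        b = b + rng.normal(0, jitter, b.shape)
    return concat_models([bead_model(a, "A"), bead_model(b, "B")])


def _coarse_config():
    cfg = sx.Config()
    cfg["assembly"].update({"phi_step": 15.0, "t_step": 2.0, "euler_step": 90.0,
                            "radial_step": 10.0, "radial_max": 30.0,
                            "max_candidates": 150})
    return cfg


class TestDetectC2Axis:
    def test_exact_dimer(self):
        ax = sx.detect_c2_axis(_c2_dimer())
        assert ax.rotation_angle_found == pytest.approx(180.0, abs=0.1)
        assert abs(ax.direction[2]) == pytest.approx(1.0, abs=1e-6)

    def test_jittered_dimer_axis_within_two_degrees(self):
        ax = sx.detect_c2_axis(_c2_dimer(seed=2, jitter=0.5))
        tilt = np.degrees(np.arccos(min(abs(ax.direction[2]), 1.0)))
        assert tilt < 2.0
        assert ax.rotation_angle_found == pytest.approx(180.0, abs=2.0)

    def test_translated_duplicate_is_not_c2(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-10, 10, (40, 3))
        m = concat_models([bead_model(a, "A"),
                           bead_model(a + [30.0, 0, 0], "B")])
        with pytest.raises(ValueError, match="not a C2 dimer"):
            sx.detect_c2_axis(m)

    def test_insufficient_overlap_rejected(self):
        m = _c2_dimer(n=10)
        with pytest.raises(ValueError, match="matched residues"):
            sx.detect_c2_axis(m)

    def test_generated_dimer_is_exactly_c2(self):
        model = sx.generate_structure(sx.ToyStructureSpec())
        ax = sx.detect_c2_axis(model, ("A", "B"))
        assert ax.rotation_angle_found == pytest.approx(180.0, abs=1e-6)


class TestEnumerateAssemblies:
    def test_ground_truth_recovery(self, search_q):
        truth = sx.generate_structure(sx.ToyStructureSpec(phi_deg=40.0))
        ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
        ds = sx.simulate_curve(truth, search_q, sx.NoiseSpec(0.01, 0.001, seed=5))
        cands = sx.enumerate_assemblies(ref.select_chains("AB"),
                                        ref.select_chains("CD"), ds.noisy)
        best = cands[0]
        dphi = min(abs(best.phi - 40.0), abs(180.0 - best.phi - 40.0))
        assert dphi <= 5.0 + 1e-6                 # one phi grid step
        assert best.t_axial == pytest.approx(36.0, abs=1.0 + 1e-6)
        assert best.chi2 < 2.0

    def test_gated_survivors_cluster_at_truth(self, search_q):
        truth = sx.generate_structure(sx.ToyStructureSpec(phi_deg=40.0))
        ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
        ds = sx.simulate_curve(truth, search_q, sx.NoiseSpec(0.01, 0.001, seed=5))
        cands = sx.enumerate_assemblies(ref.select_chains("AB"),
                                        ref.select_chains("CD"), ds.noisy)
        survivors = [c for c in cands if c.clash_count == 0 and c.chi2 < 2.0]
        assert survivors
        for c in survivors:
            dphi = min(abs(c.phi - 40.0), abs(180.0 - c.phi - 40.0))
            assert dphi <= 25.0 + 1e-6            # the verified basin width
            assert abs(c.t_axial - 36.0) <= 3.0 + 1e-6

    def test_overlapping_bodies_flagged_and_excluded(self, search_q):
        ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
        ds = sx.simulate_curve(ref, search_q, sx.NoiseSpec(0.01, 0.001, seed=3))
        cands = sx.enumerate_assemblies(ref.select_chains("AB"),
                                        ref.select_chains("CD"), ds.noisy)
        clashing = [c for c in cands if c.clash_count > 0]
        assert clashing
        assert all(not np.isfinite(c.chi2) for c in clashing)

    def test_emitted_assembly_is_exactly_c2(self):
        ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
        up = _canonicalize(ref.select_chains("AB"))
        lo = _canonicalize(ref.select_chains("CD"))
        m = build_assembly_model(up, lo, 40.0, 36.0)
        for a_chain, b_chain in [("A", "B"), ("C'", "D'")]:
            A = m.select_chains([a_chain]).xyz
            B = m.select_chains([b_chain]).xyz
            flipped = A.copy()
            flipped[:, :2] *= -1.0
            assert np.abs(flipped - B).max() < 1e-6

    def test_chi2_ranking_invariant_to_rigid_motion(self, search_q):
        truth = sx.generate_structure(sx.ToyStructureSpec(phi_deg=40.0))
        ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
        ds = sx.simulate_curve(truth, search_q, sx.NoiseSpec(0.01, 0.001, seed=5))
        R = Rotation.random(random_state=8).as_matrix()
        moved_bat = ref.select_chains("AB").rotated(R).translated([11.0, -4.0, 7.0])
        moved_cnmp = ref.select_chains("CD").rotated(R).translated([11.0, -4.0, 7.0])
        a = sx.enumerate_assemblies(ref.select_chains("AB"),
                                    ref.select_chains("CD"), ds.noisy)
        b = sx.enumerate_assemblies(moved_bat, moved_cnmp, ds.noisy)
        assert b[0].chi2 == pytest.approx(a[0].chi2, rel=1e-3)
        assert abs(b[0].t_axial - a[0].t_axial) <= 1.0 + 1e-6


class TestScenarioSearch:
    def test_scenario_one_wins_on_scenario_one_truth(self, search_q):
        cfg = _coarse_config()
        truth = sx.generate_structure(sx.ToyStructureSpec(phi_deg=40.0))
        ds = sx.simulate_curve(truth, search_q, sx.NoiseSpec(0.01, 0.001, seed=11))
        ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
        bat, cnmp = ref.select_chains("AB"), ref.select_chains("CD")
        mono = ref.select_chains("C")
        mono_bat = ref.select_chains("A")
        bests = {}
        for scen, inputs in [(1, (bat, cnmp)), (2, (bat, mono)), (3, (mono_bat, cnmp))]:
            res = sx.scenario_search(sx.ScenarioSpec(scenario=scen, chi2_gate=1e9),
                                     *inputs, ds.noisy, config=cfg, seed=scen + 10)
            finite = [c.chi2 for c in res.candidates if np.isfinite(c.chi2)]
            bests[scen] = min(finite) if finite else np.inf
        assert bests[1] <= bests[2]
        assert bests[1] <= bests[3]

    def test_two_phi_minima_reported_as_rotamer_pair(self, search_q, tmp_path):
        # equal mixture of phi = 30 and phi = 90 targets -> bimodal landscape
        m1 = sx.generate_structure(sx.ToyStructureSpec(phi_deg=30.0))
        m2 = sx.generate_structure(sx.ToyStructureSpec(phi_deg=90.0))
        I = 0.5 * (sx.debye_intensity(m1, search_q).I
                   + sx.debye_intensity(m2, search_q).I)
        sig = 0.01 * I + 0.001 * I[0]
        data = sx.ScatteringCurve(search_q, I, sig)
        ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
        res = sx.scenario_search(sx.ScenarioSpec(scenario=1, chi2_gate=1e9),
                                 ref.select_chains("AB"), ref.select_chains("CD"),
                                 data)
        # the mixture's landscape carries two equivalent minima 60 degrees
        # apart (verified chi2 profile); both must be reported
        assert len(res.rotamer_pair) == 2
        phis = sorted(c.phi for c in res.rotamer_pair)
        assert phis[1] - phis[0] >= 10.0          # distinct minima
        chi2s = [c.chi2 for c in res.rotamer_pair]
        assert abs(chi2s[0] - chi2s[1]) < 0.2     # chi2-degenerate pair
        assert phis[0] == pytest.approx(60.0, abs=5.0)
        assert phis[1] == pytest.approx(120.0, abs=5.0)


class TestInterfaceArea:
    def test_distant_bodies_bury_nothing(self):
        a = bead_model(np.zeros((1, 3)), "A")
        b = bead_model(np.full((1, 3), 100.0), "B")
        m = concat_models([a, b])
        assert sx.interface_area(m, ["A"], ["B"]) == 0.0

    def test_two_touching_spheres_match_cap_integration(self):
        # single-bead bodies radius 3.5+1.4; buried area of each sphere is a
        # spherical cap, computed here by dense numeric integration
        d = 6.0
        m = concat_models([bead_model(np.zeros((1, 3)), "A"),
                           bead_model(np.array([[d, 0.0, 0.0]]), "B")])
        got = sx.interface_area(m, ["A"], ["B"])
        R = 3.5 + 1.4
        n = 200000
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5 ** 0.5) * i
        pts = R * np.column_stack([np.sin(phi) * np.cos(theta),
                                   np.sin(phi) * np.sin(theta), np.cos(phi)])
        buried_frac = (np.linalg.norm(pts - [d, 0, 0], axis=1) < R).mean()
        expect = buried_frac * 4 * np.pi * R ** 2     # one cap == PISA half-sum
        assert got == pytest.approx(expect, rel=0.02)

    def test_overlapping_groups_rejected(self):
        m = _c2_dimer()
        with pytest.raises(ValueError):
            sx.interface_area(m, ["A"], ["A"])


class TestComplementarity:
    def test_zero_contact_scores_zero(self):
        m = concat_models([bead_model(np.zeros((1, 3)), "A"),
                           bead_model(np.full((1, 3), 100.0), "B")])
        assert sx.complementarity_score(m, ["A"], ["B"]) == 0.0

    def test_larger_clean_interface_ranks_first(self):
        rng = np.random.default_rng(3)
        slab = rng.uniform(-10, 10, (40, 3)) * [1, 1, 0.2]
        near = concat_models([bead_model(slab, "A"),
                              bead_model(slab + [0, 0, 8.0], "B")])
        far = concat_models([bead_model(slab, "A"),
                             bead_model(slab + [0, 0, 14.0], "B")])
        assert (sx.complementarity_score(near, ["A"], ["B"])
                > sx.complementarity_score(far, ["A"], ["B"]))

    def test_near_clashes_penalized(self):
        a = bead_model(np.zeros((1, 3)), "A")
        b = bead_model(np.array([[3.2, 0.0, 0.0]]), "B")   # in the 3.0-3.5 band
        m = concat_models([a, b])
        area = sx.interface_area(m, ["A"], ["B"])
        score = sx.complementarity_score(m, ["A"], ["B"])
        assert score == pytest.approx(area - 50.0)
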