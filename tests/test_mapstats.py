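"""Contact-map statistics against brute-force and fixed-point oracles."""

import numpy as np
import pandas as pd
import pytest

from chromodyn.mapstats import (
    AnchorAnnotation,
    ContactMap,
    LoopTable,
    apa_pileup,
    classify_anchors,
    classify_loop_compartments,
    classify_loops,
    compartment_call,
    contact_map_from_trajectory,
    contact_scaling,
    expected_by_distance,
    ice_balance,
    local_background_matrix,
    loop_strength,
    sim_window_strength,
)
from chromodyn.polymer import MonomerTyping, Trajectory3D
from chromodyn.synth import gen_synthetic_map


def _decay_map(n=300, seed=0, **kw):
    cmap, _ = gen_synthetic_map(n_bins=n, noise="none", seed=seed, **kw)
    return cmap


class TestContactMapFromTrajectory:
    def test_three_coincident_monomers_bin1(self):
        typing = MonomerTyping(np.zeros(3, dtype=np.int8))
        traj = Trajectory3D(np.zeros((1, 3, 3)), np.array([1]), typing)
        cmap = contact_map_from_trajectory(traj, bin_monomers=1)
        off = cmap.matrix[~np.eye(3, dtype=bool)]
        assert np.all(off == 1)

    def test_line_with_wide_spacing_only_self_contacts(self):
        typing = MonomerTyping(np.zeros(6, dtype=np.int8))
        coords = np.zeros((1, 6, 3))
        coords[0, :, 0] = np.arange(6) * 5.0
        traj = Trajectory3D(coords, np.array([1]), typing)
        cmap = contact_map_from_trajectory(traj, contact_radius=4.0, bin_monomers=1)
        assert np.array_equal(cmap.matrix, np.eye(6))

    def test_matches_brute_force_on_random_walk(self):
        rng = np.random.default_rng(12)
        n = 50
        coords = np.cumsum(rng.standard_normal((n, 3)), axis=0)[None]
        typing = MonomerTyping(np.zeros(n, dtype=np.int8))
        traj = Trajectory3D(coords, np.array([1]), typing)
        cmap = contact_map_from_trajectory(traj, contact_radius=4.0, bin_monomers=1)
        d = np.linalg.norm(coords[0][:, None] - coords[0][None], axis=2)
        brute = (d <= 4.0).astype(float)
        assert np.array_equal(cmap.matrix, brute)

    def test_binning_must_give_at_least_two_bins(self):
        typing = MonomerTyping(np.zeros(4, dtype=np.int8))
        traj = Trajectory3D(np.zeros((1, 4, 3)), np.array([1]), typing)
        with pytest.raises(ValueError):
            contact_map_from_trajectory(traj, bin_monomers=4)


class TestIceBalance:
    def test_symmetric_2x2_already_balanced(self):
        cmap = ContactMap(np.array([[2.0, 1.0], [1.0, 2.0]]), 500)
        out = ice_balance(cmap)
        rs = out.balanced().sum(axis=1)
        assert rs[0] == pytest.approx(rs[1], abs=1e-10)
        assert out.weights[0] == pytest.approx(out.weights[1], abs=1e-10)

    def test_matches_independent_fixed_point_iteration(self):
        """Balanced row sums equalize and weights agree with a naive
        fixed-point iteration written independently."""
        m = np.array([[4.0, 1.0], [1.0, 1.0]])
        out = ice_balance(ContactMap(m, 500))
        rs = out.balanced().sum(axis=1)
        assert np.max(np.abs(rs / rs.mean() - 1)) < 1e-8
        w = np.ones(2)
        for _ in range(10_000):
            s = (m * np.outer(w, w)).sum(axis=1)
            w = w / np.sqrt(s / s.mean())
        ratio = out.weights / w
        assert ratio[0] == pytest.approx(ratio[1], rel=1e-6)  # same up to scale

    def test_zero_row_is_masked(self):
        m = np.array([[1.0, 0.0, 2.0], [0.0, 0.0, 0.0], [2.0, 0.0, 1.0]])
        out = ice_balance(ContactMap(m, 500))
        assert np.isnan(out.weights[1])
        assert np.isfinite(out.weights[[0, 2]]).all()

    def test_random_map_row_sums_equalize(self):
        cmap, _ = gen_synthetic_map(n_bins=60, seed=8)
        out = ice_balance(cmap)
        rs = np.nansum(out.balanced(), axis=1)
        good = rs[rs > 0]
        assert np.max(np.abs(good / good.mean() - 1)) < 1e-7


class TestContactScaling:
    def test_recovers_planted_power_law_slope(self):
        cmap, _ = gen_synthetic_map(n_bins=300, base_count=2000, decay_exponent=-1.0, seed=2)
        ps = contact_scaling(cmap)
        sel = (ps.s_bp > 5 * 500) & (ps.s_bp < 150 * 500)
        assert np.nanmean(ps.dlogp_dlogs[sel]) == pytest.approx(-1.0, abs=0.05)

    def test_single_separation_derivative_undefined(self):
        cmap = ContactMap(np.array([[1.0, 2.0], [2.0, 1.0]]), 500)
        ps = contact_scaling(cmap)
        assert ps["dlogp_dlogs"].isna().all()

    def test_too_small_map_raises(self):
        with pytest.raises(ValueError):
            contact_scaling(ContactMap(np.array([[1.0]]), 500))


class TestLocalBackground:
    def test_pure_decay_background_equals_window_and_bg_sub_zero(self):
        cmap = _decay_map()
        bg = local_background_matrix(cmap, (100, 200), use_balanced=False)
        window = cmap.matrix[90:111, 190:211]
        assert np.allclose(bg, window, atol=1e-10)
        c = ContactMap(cmap.matrix, 500)
        assert loop_strength(c, (100, 200), "bg_subtracted") == pytest.approx(0.0, abs=1e-9)

    def test_uniform_map_background_is_constant(self):
        cmap = ContactMap(np.full((100, 100), 7.0), 500)
        bg = local_background_matrix(cmap, (20, 70), use_balanced=False)
        assert np.allclose(bg, 7.0)

    def test_matches_brute_force_enumeration(self):
        """Each background cell equals the brute-force average over all
        same-separation cells within the flank."""
        cmap, _ = gen_synthetic_map(
            n_bins=200, seed=5, loops=[{"i": 60, "j": 140, "excess": 30.0}]
        )
        i0, j0, hw, flank = 60, 140, 10, 200_000 // 500
        bg = local_background_matrix(cmap, (i0, j0), use_balanced=False, flank_bins=flank)
        mat = cmap.matrix
        n = mat.shape[0]
        for a in (-10, -3, 0, 4, 10):
            for b in (-10, -2, 0, 5, 10):
                u0, v0 = i0 + a, j0 + b
                s = v0 - u0
                vals = [
                    mat[u, u + s]
                    for u in range(max(u0 - flank, 0), min(u0 + flank, n - 1 - s) + 1)
                ]
                assert bg[a + hw, b + hw] == pytest.approx(np.mean(vals), rel=1e-12)

    def test_loop_too_close_to_diagonal_raises(self):
        cmap = _decay_map(100)
        with pytest.raises(ValueError, match="within"):
            local_background_matrix(cmap, (40, 55), use_balanced=False)


class TestLoopStrength:
    def test_planted_uniform_excess_recovered(self):
        """A uniform excess e over the full 21x21 window gives
        bg_subtracted ~ 441 e (minus the small leak of the excess into its own
        local background) and obs_over_exp = 1 + e / mean-background."""
        n, i0, j0, e = 300, 100, 200, 5.0
        seps = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        base = 200.0 * (1.0 + seps) ** -1.0
        mat = base.copy()
        mat[i0 - 10 : i0 + 11, j0 - 10 : j0 + 11] += e
        mat[j0 - 10 : j0 + 11, i0 - 10 : i0 + 11] += e
        cmap = ContactMap(mat, 500)
        bgs = loop_strength(cmap, (i0, j0), "bg_subtracted")
        # leak: each background diagonal average picks up 21*e/(#cells in flank)
        assert 0.85 * 441 * e < bgs <= 441 * e
        oe = loop_strength(cmap, (i0, j0), "obs_over_exp")
        bg = local_background_matrix(cmap, (i0, j0), use_balanced=False)
        assert oe == pytest.approx(np.sum(base[i0 - 10 : i0 + 11, j0 - 10 : j0 + 11] + e) / np.sum(bg), rel=1e-12)
        assert oe > 1.5

    def test_null_map_scores(self):
        cmap, _ = gen_synthetic_map(n_bins=300, base_count=500, seed=3)
        bgs = loop_strength(cmap, (100, 200), "bg_subtracted")
        oe = loop_strength(cmap, (100, 200), "obs_over_exp")
        assert abs(bgs) < 3 * np.sqrt(441 * cmap.matrix[100, 200])
        assert oe == pytest.approx(1.0, abs=0.1)

    def test_total_minus_bg_subtracted_identity(self):
        cmap, _ = gen_synthetic_map(n_bins=300, seed=4, loops=[{"i": 100, "j": 200, "excess": 40.0}])
        tot = loop_strength(cmap, (100, 200), "total")
        bgs = loop_strength(cmap, (100, 200), "bg_subtracted")
        bg = local_background_matrix(cmap, (100, 200), use_balanced=False)
        assert tot - bgs == pytest.approx(np.sum(bg), rel=1e-10)

    def test_invariant_under_added_distance_decay_field(self):
        """Adding any pure distance-decay field leaves bg_subtracted
        unchanged: the defining property of the local background."""
        cmap, _ = gen_synthetic_map(n_bins=300, seed=6, loops=[{"i": 120, "j": 210, "excess": 25.0}])
        base = loop_strength(cmap, (120, 210), "bg_subtracted")
        seps = np.abs(np.subtract.outer(np.arange(300), np.arange(300)))
        field = 50.0 * (1.0 + seps) ** -0.5
        shifted = ContactMap(cmap.matrix + field, 500)
        assert loop_strength(shifted, (120, 210), "bg_subtracted") == pytest.approx(base, abs=1e-6)

    def test_translation_equivariance(self):
        """Shifting the whole map shifts loop scores with it."""
        n, shift = 260, 17
        seps = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        rng = np.random.default_rng(9)
        noise = rng.poisson(100.0 * (1.0 + seps) ** -0.8).astype(float)
        noise = np.triu(noise) + np.triu(noise, 1).T
        noise[80 - 10 : 80 + 11, 180 - 10 : 180 + 11] += 8.0
        noise[180 - 10 : 180 + 11, 80 - 10 : 80 + 11] += 8.0
        cmap = ContactMap(noise, 500)
        moved = ContactMap(np.roll(np.roll(noise, shift, 0), shift, 1), 500)
        a = loop_strength(cmap, (80, 180), "total")
        b = loop_strength(moved, (80 + shift, 180 + shift), "total")
        assert a == pytest.approx(b, rel=1e-12)

    def test_planted_loops_recovered_at_high_snr(self):
        """>= 95% of planted loops with excess >= 3x background noise SD have
        positive background-subtracted strength (20 replicates)."""
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            positions = [(60 + 10 * k, 160 + 9 * k) for k in range(5)]
            # noise SD of the 441-cell windowed background score
            loops = [{"i": i, "j": j, "excess": 3.0 * np.sqrt(441 * 200.0 / (1 + j - i))}
                     for i, j in positions]
            cmap, _ = gen_synthetic_map(n_bins=300, seed=seed, loops=loops)
            for i, j in positions:
                total += 1
                if loop_strength(cmap, (i, j), "bg_subtracted") > 0:
                    hits += 1
        assert hits / total >= 0.95


class TestSimWindowStrength:
    def test_uniform_map(self):
        cmap = ContactMap(np.full((100, 100), 3.0), 2000)
        assert sim_window_strength(cmap, (20, 60)) == pytest.approx(3.0)
        assert sim_window_strength(cmap, (20, 60), relative=True) == pytest.approx(1.0)

    def test_single_hot_cell(self):
        mat = np.full((100, 100), 2.0)
        mat[30, 70] = mat[70, 30] = 20.0
        cmap = ContactMap(mat, 2000)
        assert sim_window_strength(cmap, (30, 70)) == pytest.approx((20 + 8 * 2) / 9)

    def test_matches_brute_force(self):
        cmap, _ = gen_synthetic_map(n_bins=100, resolution=2000, seed=13)
        i0, j0 = 25, 75
        score = sim_window_strength(cmap, (i0, j0))
        brute = cmap.matrix[i0 - 1 : i0 + 2, j0 - 1 : j0 + 2].mean()
        assert score == pytest.approx(brute, rel=1e-12)
        rel = sim_window_strength(cmap, (i0, j0), relative=True)
        exp = expected_by_distance(cmap.matrix)
        seps = [abs((j0 + b) - (i0 + a)) for a in (-1, 0, 1) for b in (-1, 0, 1)]
        assert rel == pytest.approx(brute / np.mean([exp[s] for s in seps]), rel=1e-12)

    def test_out_of_bounds_raises(self):
        cmap = ContactMap(np.ones((20, 20)), 2000)
        with pytest.raises(ValueError):
            sim_window_strength(cmap, (0, 10))


class TestApaPileup:
    def test_identical_planted_loops_center_is_maximum(self):
        loops = [{"i": 60 + 30 * k, "j": 160 + 30 * k, "excess": 60.0} for k in range(4)]
        cmap, _ = gen_synthetic_map(n_bins=300, seed=21, loops=loops)
        out = apa_pileup(cmap, [(lp["i"], lp["j"]) for lp in loops], use_balanced=False)
        stack = out["stack"]
        hw = stack.shape[0] // 2
        assert stack[hw, hw] == stack.max()
        assert out["n_used"] == 4

    def test_pure_decay_pileup_is_flat_near_one(self):
        cmap = _decay_map()
        out = apa_pileup(cmap, [(70, 170), (100, 220), (60, 200)], use_balanced=False)
        assert np.allclose(out["stack"], 1.0, atol=0.02)

    def test_planted_mean_enrichment_recovered(self):
        rng = np.random.default_rng(3)
        pos = [(int(i), int(i) + int(g)) for i, g in zip(
            rng.integers(40, 120, 20), rng.integers(60, 140, 20))]
        loops = [{"i": i, "j": j, "excess": 40.0} for i, j in pos]
        cmap, _ = gen_synthetic_map(n_bins=300, seed=3, base_count=400, loops=loops)
        out = apa_pileup(cmap, pos, use_balanced=False)
        hw = out["stack"].shape[0] // 2
        # center enrichment ~ 1 + excess/background, averaged over loops
        seps = [j - i for i, j in pos]
        expected_center = np.mean([1 + 40.0 / (400.0 * (1 + s) ** -1.0) for s in seps])
        assert out["stack"][hw, hw] == pytest.approx(expected_center, rel=0.25)

    def test_truncated_windows_skipped_and_all_skipped_raises(self):
        cmap = _decay_map(100)
        with pytest.raises(ValueError):
            apa_pileup(cmap, [(2, 30)], window_bp=24_000, use_balanced=False)


# ----------------------------------------------------------------------------
# anchors / loops


def _annotation():
    tss = pd.DataFrame({"chrom": ["chrS"], "start": [50_000], "end": [50_001], "name": ["g1"]})
    h3k4me1 = pd.DataFrame({"chrom": ["chrS", "chrS"], "start": [80_000, 120_000], "end": [80_400, 120_400]})
    h3k27ac = pd.DataFrame({"chrom": ["chrS"], "start": [80_100, ], "end": [80_500]})
    ctcf = pd.DataFrame({"chrom": ["chrS", "chrS"], "start": [50_100, 140_000], "end": [50_500, 140_400], "strand": ["+", "-"]})
    rad21 = pd.DataFrame({"chrom": ["chrS", "chrS"], "start": [50_100, 140_000], "end": [50_500, 140_400]})
    return AnchorAnnotation(tss, h3k4me1, h3k27ac, ctcf, rad21)


class TestClassifyAnchors:
    def test_hierarchy_promoter_over_ctcf_and_exclusive_drop(self):
        ann = _annotation()
        anchors = pd.DataFrame({"chrom": ["chrS"], "start": [49_900], "end": [50_200]})
        assert classify_anchors(anchors, ann, "inclusive").iloc[0] == "promoter"
        assert classify_anchors(anchors, ann, "exclusive").iloc[0] == "dropped"

    def test_h3k4me1_without_h3k27ac_is_not_enhancer(self):
        ann = _annotation()
        anchors = pd.DataFrame({"chrom": ["chrS"], "start": [119_900], "end": [120_300]})
        assert classify_anchors(anchors, ann, "inclusive").iloc[0] == "other"

    def test_enhancer_requires_both_marks(self):
        ann = _annotation()
        anchors = pd.DataFrame({"chrom": ["chrS"], "start": [80_050], "end": [80_300]})
        assert classify_anchors(anchors, ann, "inclusive").iloc[0] == "enhancer"

    def test_pure_ctcf_site(self):
        ann = _annotation()
        anchors = pd.DataFrame({"chrom": ["chrS"], "start": [139_900], "end": [140_200]})
        assert classify_anchors(anchors, ann, "inclusive").iloc[0] == "ctcf"

    def test_malformed_interval_raises(self):
        ann = _annotation()
        anchors = pd.DataFrame({"chrom": ["chrS"], "start": [500], "end": [400]})
        with pytest.raises(ValueError, match="malformed"):
            classify_anchors(anchors, ann)

    def test_matches_brute_force_interval_oracle(self, annotation_fixture):
        """Random anchors against generated annotation: classes equal a
        brute-force overlap oracle applying the same hierarchy."""
        ann, _ = annotation_fixture
        rng = np.random.default_rng(17)
        starts = rng.integers(0, 1_990_000, 50)
        anchors = pd.DataFrame({"chrom": "chrS", "start": starts, "end": starts + 500})
        got = classify_anchors(anchors, ann, "inclusive")
        proms, enhs, ctcfs = ann.promoters(), ann.enhancers(), ann.ctcf_rad21()

        def brute(lo, hi):
            def hit(df):
                return any((row.start < hi) and (row.end > lo) for row in df.itertuples())
            if hit(proms):
                return "promoter"
            if hit(enhs):
                return "enhancer"
            if hit(ctcfs):
                return "ctcf"
            return "other"

        expect = [brute(s - 1000, e + 1000) for s, e in zip(anchors.start, anchors.end)]
        assert list(got) == expect


def test_loop_table_canonicalizes_anchor_order_and_classifies():
    ann = _annotation()
    df = pd.DataFrame(
        {
            "chrom1": ["chrS"], "start1": [139_900], "end1": [140_200],
            "chrom2": ["chrS"], "start2": [49_900], "end2": [50_200],
        }
    )
    table = LoopTable(df.copy())
    assert table.loops.loc[0, "start1"] == 49_900
    out = classify_loops(table, ann, "inclusive")
    assert out.loops.loc[0, "loop_class"] == "E/P-CTCF"
    out_ex = classify_loops(LoopTable(df.copy()), ann, "exclusive")
    assert len(out_ex) == 0  # promoter anchor also CTCF -> dropped


# ----------------------------------------------------------------------------
# compartments


class TestCompartments:
    def _checkerboard(self, n=80, amp=0.6, seed=2):
        labels = np.where((np.arange(n) // 20) % 2 == 0, 1, -1)
        cmap, _ = gen_synthetic_map(
            n_bins=n, base_count=800, compartment_blocks=labels,
            compartment_amplitude=amp, seed=seed,
        )
        return cmap, labels

    def test_planted_checkerboard_recovered_exactly(self):
        cmap, labels = self._checkerboard()
        call = compartment_call(cmap, labels.astype(float))
        assert np.array_equal(call["labels"], labels)
        assert call["reliable"]

    def test_orientation_flip_swaps_labels(self):
        cmap, labels = self._checkerboard()
        a = compartment_call(cmap, labels.astype(float))
        b = compartment_call(cmap, -labels.astype(float))
        assert np.array_equal(a["labels"], -b["labels"])

    def test_uniform_map_flagged_unreliable(self):
        cmap = ContactMap(np.full((40, 40), 5.0), 2000)
        call = compartment_call(cmap, np.arange(40, dtype=float))
        assert not call["reliable"]

    def test_all_zero_map_raises(self):
        with pytest.raises(ValueError):
            compartment_call(ContactMap(np.zeros((10, 10)), 2000), np.arange(10.0))

    def test_transitions_at_block_boundaries(self):
        cmap, labels = self._checkerboard()
        call = compartment_call(cmap, labels.astype(float))
        assert set(call["transitions"]) == {20, 40, 60}


class TestLoopCompartments:
    def test_construction_counts_recovered(self):
        labels = np.array([1, 1, -1, -1, 1, 0])
        loops = [(0, 1), (0, 4), (2, 3), (1, 2), (0, 5)]
        out = classify_loop_compartments(loops, labels)
        assert out["counts"] == {"intra-A": 2, "intra-B": 1, "inter": 1, "unassigned": 1}
        assert out["fractions"]["intra-A"] == pytest.approx(0.5)

    def test_empty_loop_list(self):
        out = classify_loop_compartments([], np.array([1, -1]))
        assert sum(out["counts"].values()) == 0
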