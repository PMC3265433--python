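import itertools

import numpy as np
import pytest

from spinealign.body_bed_model import (
    GRAVITY_M_PER_S2, PRESETS, SEGMENT_NAMES, BodyBedError,
    BodySegmentProfile, MattressArrangement, UncoveredSegmentError,
    build_body, classify_body_shape, optimize_zones, solve_equilibrium,
)
from spinealign.config import ConfigError
from spinealign.spine_geometry import LUMBAR, VERTEBRAE, compute_p8


def toy_body(masses, half_widths, extents=None):
    """Six-segment body with explicit parameters and evenly spread markers."""
    masses = np.asarray(masses, dtype=float)
    if extents is None:
        extents = np.full(6, 300.0)
    extents = np.asarray(extents, dtype=float)
    b = np.concatenate([[0.0], np.cumsum(extents)])
    # C7 at shoulder start, L5 a third into the pelvis
    x_c7, x_l5 = b[1], b[3] + extents[3] / 3.0
    from spinealign.spine_geometry import VERTEBRAL_LEVEL
    span = x_l5 - x_c7
    vx = {v: x_c7 + VERTEBRAL_LEVEL[v] / 17.0 * span for v in VERTEBRAE}
    return BodySegmentProfile(masses, extents, np.asarray(half_widths, float), vx)


class TestClassifyBodyShape:
    @pytest.mark.parametrize("ratio,label", [
        (1.59, "triangular"), (1.52, "triangular"),
        (1.33, "square"), (1.28, "square"),
        (1.45, "square"),  # strictly above 1.45 is triangular
    ])
    def test_ratio_thresholds(self, ratio, label):
        assert classify_body_shape(ratio) == label

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(BodyBedError):
            classify_body_shape(0.0)

    def test_presets_carry_expected_anthropometry(self):
        expected = {"HTM": (181, 103, 1.59, "triangular"),
                    "HSM": (183, 93, 1.33, "square"),
                    "LTM": (182, 74, 1.52, "triangular"),
                    "LSM": (184, 76, 1.28, "square")}
        for name, (h, w, r, shape) in expected.items():
            p = PRESETS[name]
            assert (p.height_cm, p.weight_kg, p.shoulder_pelvis_ratio) == (h, w, r)
            assert p.shape == shape


class TestBuildBody:
    @pytest.mark.parametrize("name", list(PRESETS))
    def test_width_ratio_realized_exactly(self, name):
        body = build_body(name)
        i_sh, i_pe = SEGMENT_NAMES.index("shoulder"), SEGMENT_NAMES.index("pelvis")
        ratio = body.half_widths_mm[i_sh] / body.half_widths_mm[i_pe]
        assert ratio == pytest.approx(PRESETS[name].shoulder_pelvis_ratio,
                                      abs=1e-9)

    @pytest.mark.parametrize("name", list(PRESETS))
    def test_mass_and_length_conserved(self, name):
        body = build_body(name)
        assert body.total_mass_kg == pytest.approx(PRESETS[name].weight_kg)
        assert body.length_mm == pytest.approx(PRESETS[name].height_cm * 10)

    def test_mass_scales_linearly_with_weight(self):
        from spinealign.body_bed_model import AnthropometricPreset
        a = build_body(AnthropometricPreset("X", 180.0, 80.0, 1.5))
        b = build_body(AnthropometricPreset("Y", 180.0, 160.0, 1.5))
        assert np.allclose(b.masses_kg, 2.0 * a.masses_kg)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            build_body("HTM", {"mass_fractions": {
                s: 0.2 for s in SEGMENT_NAMES}})

    def test_vertebrae_ordered_within_trunk(self):
        body = build_body("HSM")
        xs = [body.vertebra_x_mm[v] for v in VERTEBRAE]
        assert all(a < b for a, b in zip(xs, xs[1:]))  # C7 ... L5 caudally
        b = body.boundaries_mm
        assert xs[0] == pytest.approx(b[1])         # C7 at shoulder start
        assert b[3] < xs[-1] < b[4]                  # L5 inside the pelvis


class TestSolveEquilibrium:
    def test_independent_sag_balance(self):
        # two loaded segments: 60 kg on K = 6 N/mm, 30 kg on K = 3 N/mm
        # both sag 60*9.81/6 = 30*9.81/3 = 98.1 mm
        masses = [1e-6, 60.0, 1e-6, 30.0, 1e-6, 1e-6]
        body = toy_body(masses, np.full(6, 150.0))
        # zone per segment: 300 mm extent -> 3 blocks; per-block stiffness
        # 2 and 1 give segment totals 6 and 3
        bed = MattressArrangement(
            (1, 2, 3, 4, 5, 6), np.full(6, 300.0),
            np.array([1.0, 2.0, 1.0, 1.0, 1.0, 1.0]))
        eq = solve_equilibrium(body, bed, coupling=0.0)
        assert eq.sag_mm[1] == pytest.approx(98.1, abs=1e-9)
        assert eq.sag_mm[3] == pytest.approx(98.1, abs=1e-9)

    def test_balanced_load_gives_straight_spine(self):
        # mass proportional to support stiffness everywhere -> equal sag,
        # equal half-widths -> flat spine
        body = toy_body(np.full(6, 20.0), np.full(6, 160.0))
        bed = MattressArrangement.tiling(body, [4.0] * 6)
        eq = solve_equilibrium(body, bed, coupling=0.0)
        assert np.ptp(eq.sag_mm) < 1e-12
        assert eq.dev_deg == pytest.approx(0.0, abs=1e-9)

    def test_global_force_balance(self, rng):
        # without saturation, sum K_i s_i = total weight * g
        for _ in range(5):
            masses = rng.uniform(5.0, 40.0, 6)
            widths = rng.uniform(100.0, 220.0, 6)
            body = toy_body(masses, widths)
            bed = MattressArrangement.tiling(body, rng.uniform(2.0, 30.0, 6))
            eq = solve_equilibrium(body, bed, coupling=0.0)
            from spinealign.body_bed_model import _segment_stiffness
            K = _segment_stiffness(body, bed)
            total = float((K * eq.sag_mm).sum())
            weight = float(masses.sum() * GRAVITY_M_PER_S2)
            assert total == pytest.approx(weight, rel=1e-6)

    def test_force_balance_holds_with_coupling(self, rng):
        # bending redistributes load between segments but cannot create
        # force, provided no contact or saturation bound is active
        masses = rng.uniform(15.0, 25.0, 6)
        body = toy_body(masses, rng.uniform(150.0, 170.0, 6))
        bed = MattressArrangement.tiling(body, rng.uniform(6.0, 10.0, 6))
        eq = solve_equilibrium(body, bed, coupling=3.0)
        assert eq.sag_mm.min() > 0 and eq.sag_mm.max() < bed.max_sag_mm
        from spinealign.body_bed_model import _segment_stiffness
        K = _segment_stiffness(body, bed)
        assert float((K * eq.sag_mm).sum()) == pytest.approx(
            float(masses.sum() * GRAVITY_M_PER_S2), rel=1e-6)

    def test_sag_saturates_at_80pct_block_height(self):
        body = toy_body([1e-6, 500.0, 1e-6, 1e-6, 1e-6, 1e-6],
                        np.full(6, 200.0))
        bed = MattressArrangement.tiling(body, [1.0] * 6)
        eq = solve_equilibrium(body, bed, coupling=0.0)
        assert eq.sag_mm[1] == pytest.approx(0.8 * 200.0)

    def test_rigid_limit_reproduces_contour(self):
        # stiffness -> 1e6 N/mm: sag < 0.01 mm, spine follows the body
        # contour, so the narrow waist is the lowest vertebral region
        for name in PRESETS:
            body = build_body(name)
            bed = MattressArrangement.tiling(body, [1e6] * 6)
            eq = solve_equilibrium(body, bed, coupling=0.0)
            assert eq.sag_mm.max() < 0.01
            lowest = min(eq.spine_heights_mm, key=eq.spine_heights_mm.get)
            assert lowest in LUMBAR

    def test_monotonicity_softening_zone_increases_sag(self):
        body = build_body("HTM")
        base = MattressArrangement.tiling(body, [10.0] * 6)
        eq0 = solve_equilibrium(body, base, coupling=0.0)
        for z in range(6):
            k = base.stiffness_n_per_mm.copy()
            k[z] = 5.0
            softer = MattressArrangement.tiling(body, k)
            eq1 = solve_equilibrium(body, softer, coupling=0.0)
            assert (eq1.sag_mm >= eq0.sag_mm - 1e-12).all()

    def test_uncovered_body_rejected(self):
        body = build_body("HTM")
        short_bed = MattressArrangement(
            (1, 2), np.array([300.0, 300.0]), np.array([5.0, 5.0]))
        with pytest.raises(UncoveredSegmentError):
            solve_equilibrium(body, short_bed)

    @pytest.mark.parametrize("name", list(PRESETS))
    def test_soft_bed_c7_above_pelvis(self, name):
        body = build_body(name)
        soft = MattressArrangement.tiling(body, [2.0] * 6)
        for coupling in (0.0, 2.0):
            eq = solve_equilibrium(body, soft, coupling=coupling)
            assert eq.spine_heights_mm["C7"] > eq.spine_heights_mm["L5"]


class TestOptimizeZones:
    @pytest.mark.parametrize("name", list(PRESETS))
    def test_soft_firm_custom_ordering(self, name):
        body = build_body(name)
        coupling = 2.0
        soft = solve_equilibrium(
            body, MattressArrangement.tiling(body, [2.0] * 6), coupling)
        firm = solve_equilibrium(
            body, MattressArrangement.tiling(body, [100.0] * 6), coupling)
        custom = optimize_zones(body, coupling=coupling)
        assert soft.dev_deg > firm.dev_deg > custom.dev_deg

    def test_two_zone_toy_matches_grid_oracle(self):
        # equal half-widths, unequal loads: straightness requires equal
        # sag, i.e. zone stiffness proportional to zone load
        masses = [10.0, 30.0, 30.0, 15.0, 15.0, 10.0]
        body = toy_body(masses, np.full(6, 150.0))
        result = optimize_zones(body, bounds=(1.0, 8.0), coupling=0.0,
                                n_zones=2)
        k_opt = result.arrangement.stiffness_n_per_mm
        assert result.dev_deg < 0.05

        grid = np.arange(1.0, 8.0 + 0.05, 0.05)
        best, best_dev = None, np.inf
        for k1, k2 in itertools.product(grid, grid):
            bed = MattressArrangement.tiling(body, [k1, k2])
            dev = solve_equilibrium(body, bed, coupling=0.0).dev_deg
            if dev < best_dev:
                best, best_dev = (k1, k2), dev
        assert k_opt[0] / k_opt[1] == pytest.approx(best[0] / best[1],
                                                    rel=0.02)

    def test_straight_configuration_is_fixed_point(self):
        body = toy_body(np.full(6, 20.0), np.full(6, 160.0))
        bed = MattressArrangement.tiling(body, [4.0] * 6)
        assert solve_equilibrium(body, bed).dev_deg == pytest.approx(0.0,
                                                                     abs=1e-9)
        result = optimize_zones(body, bounds=(1.0, 20.0), coupling=0.0,
                                bed=bed)
        assert result.no_improvement
        assert result.dev_deg == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(result.arrangement.stiffness_n_per_mm,
                              bed.stiffness_n_per_mm)

    @pytest.mark.parametrize("name", ["HTM", "LTM"])
    def test_triangular_presets_get_soft_shoulder_zones(self, name):
        body = build_body(name)
        result = optimize_zones(body, coupling=2.0)
        norm = result.table.normalized_pct
        assert max(norm[0], norm[1]) < min(norm[2], norm[3])

    def test_heavy_spread_at_least_light_spread(self):
        spreads = {}
        for name in PRESETS:
            result = optimize_zones(build_body(name), coupling=2.0)
            norm = result.table.normalized_pct
            spreads[name] = norm.max() - norm.min()
        assert min(spreads["HTM"], spreads["HSM"]) >= max(
            spreads["LTM"], spreads["LSM"])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(BodyBedError):
            optimize_zones(build_body("HTM"), bounds=(5.0, 2.0))
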