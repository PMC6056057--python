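"""COBRA band normalisation, pattern deconvolution and in-silico digestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from line1meth.cobra import (
    AmpliconModel,
    BandIntensityRecord,
    insilico_digest,
    normalize_bands,
    overall_methylation,
    pattern_percentages,
    quantify,
    compare_groups,
    synthetic_amplicon,
)
from line1meth.simulate import PatternCounts, simulate_gel_lane, simulate_gel_study

from conftest import random_counts


def lane(i160=0.0, i98=0.0, i80=0.0, i62=0.0):
    return BandIntensityRecord("s", "g", i160, i98, i80, i62)


class TestNormalizeBands:
    def test_single_160_band(self):
        b = normalize_bands(lane(i160=100))
        assert b.A == pytest.approx(100 / 160)
        assert b.B == b.C == b.D == 0

    def test_scale_invariance_raw_units(self):
        b1 = normalize_bands(lane(i160=100))
        b2 = normalize_bands(lane(i160=200))
        assert b1 == b2

    def test_equal_counts_lane_recovers_1_1_3_2_molar_ratio(self):
        b = normalize_bands(lane(25.72, 15.76, 38.59, 19.94))
        ratios = np.array([b.A, b.B, b.C, b.D]) / b.A
        assert ratios == pytest.approx([1, 1, 3, 2], abs=1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            lane()


class TestOverallMethylation:
    @pytest.mark.parametrize(
        "bands, expected",
        [
            (dict(i80=50.0), 100.0),          # fully methylated limit
            (dict(i160=50.0), 50.0),          # uncut lane: (0+A)/(2A)
        ],
    )
    def test_limits(self, bands, expected):
        assert overall_methylation(normalize_bands(lane(**bands))) == pytest.approx(expected)

    def test_molar_hand_case(self):
        # molar A=25,B=25,C=75,D=50 -> (75+25)/(75+50+25+50) = 50%
        from line1meth.cobra import NormalizedBands

        b = NormalizedBands(A=25, B=25, C=75, D=50)
        assert overall_methylation(b) == pytest.approx(50.0)


class TestPatternPercentages:
    def test_only_160_band_is_pure_mu(self):
        p = pattern_percentages(normalize_bands(lane(i160=100)))
        assert (p.pct_mu, p.pct_mm, p.pct_um, p.pct_uu) == pytest.approx((100, 0, 0, 0))

    def test_only_80_band_is_pure_mm(self):
        p = pattern_percentages(normalize_bands(lane(i80=100)))
        assert p.pct_mm == pytest.approx(100)
        assert p.pct_m == pytest.approx(100)

    def test_equal_counts_lane_gives_four_25s(self):
        p = pattern_percentages(normalize_bands(lane(25.72, 15.76, 38.59, 19.94)))
        assert (p.pct_mm, p.pct_mu, p.pct_um, p.pct_uu) == pytest.approx(
            (25, 25, 25, 25), abs=0.02
        )

    def test_only_98_band_is_infeasible(self):
        # a lone 98-bp band implies n_uu = B molecules but a 62-bp amount of
        # zero, impossible under the two-site model: T = B/2, raw um = -200,
        # uu = +200, mm = +100, and the four still sum to 100
        p = pattern_percentages(normalize_bands(lane(i98=100)), "propagate")
        assert not p.feasible
        assert p.pct_um == pytest.approx(-200)
        assert p.pct_uu == pytest.approx(200)
        assert p.pct_mm == pytest.approx(100)
        assert p.pct_mm + p.pct_mu + p.pct_um + p.pct_uu == pytest.approx(100)

    def test_clamp_renormalises_infeasible_lane(self):
        p = pattern_percentages(normalize_bands(lane(i98=100)), "clamp")
        assert p.clamped and not p.feasible
        assert p.pct_mm + p.pct_mu + p.pct_um + p.pct_uu == pytest.approx(100)
        assert min(p.pct_mm, p.pct_mu, p.pct_um, p.pct_uu) >= 0

    def test_sum_and_identity_on_random_feasible_lanes(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            rec = simulate_gel_lane(random_counts(rng))
            p = pattern_percentages(normalize_bands(rec))
            assert p.feasible
            total = p.pct_mm + p.pct_mu + p.pct_um + p.pct_uu
            assert total == pytest.approx(100, abs=1e-9)
            assert p.pct_m == pytest.approx(
                p.pct_mm + (p.pct_mu + p.pct_um) / 2, abs=1e-9
            )

    @given(
        st.tuples(*[st.floats(0, 1000) for _ in range(4)]).filter(
            lambda t: sum(t) > 1e-6
        ),
        st.floats(0.1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_property(self, intensities, scale):
        r1 = lane(*intensities)
        r2 = lane(*(i * scale for i in intensities))
        p1 = pattern_percentages(normalize_bands(r1))
        p2 = pattern_percentages(normalize_bands(r2))
        assert p1.pct_m == pytest.approx(p2.pct_m, rel=1e-9)
        assert p1.pct_mm == pytest.approx(p2.pct_mm, rel=1e-9, abs=1e-9)


class TestRoundTrip:
    def test_generator_roundtrip_exact_at_zero_noise(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            counts = random_counts(rng)
            rec = simulate_gel_lane(counts, noise_sd=0.0)
            p = pattern_percentages(normalize_bands(rec))
            want = counts.proportions()
            assert p.pct_mm == pytest.approx(want["mm"], abs=1e-9)
            assert p.pct_mu == pytest.approx(want["mu"], abs=1e-9)
            assert p.pct_um == pytest.approx(want["um"], abs=1e-9)
            assert p.pct_uu == pytest.approx(want["uu"], abs=1e-9)

    def test_molecule_conservation_identity(self):
        # B + (D-B) + A + (C-D+B)/2 equals the molecule total for any counts
        rng = np.random.default_rng(11)
        for _ in range(100):
            counts = random_counts(rng)
            A = counts.n_mu
            B = counts.n_uu
            C = 2 * counts.n_mm + counts.n_um
            D = counts.n_um + counts.n_uu
            assert B + (D - B) + A + (C - D + B) / 2 == pytest.approx(counts.total)


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        bands = simulate_gel_study({"A": (35, 5), "CTRL": (35, 5)}, between_sd=0,
                                   noise_sd=0, seed=1)
        profiles = quantify(bands)
        profiles["pct_m"] = 35.0  # copied values
        out = compare_groups(profiles, "CTRL")
        assert out.loc[0, "t"] == 0
        assert out.loc[0, "p"] == 1

    def test_planted_shift_detected(self):
        bands = simulate_gel_study(
            {"L": (30, 10), "CTRL": (36, 10)}, between_sd=1.0, noise_sd=0.005, seed=5
        )
        out = compare_groups(quantify(bands), "CTRL")
        row = out[out["group"] == "L"].iloc[0]
        assert row["mean_case"] < row["mean_control"]
        assert row["p_adj"] < 0.05

    def test_small_group_skipped(self):
        bands = simulate_gel_study({"L": (30, 1), "M": (35, 4), "CTRL": (36, 4)},
                                   seed=3)
        out = compare_groups(quantify(bands), "CTRL")
        assert set(out["group"]) == {"M"}


class TestInsilicoDigest:
    @pytest.mark.parametrize(
        "state, fragments",
        [
            ("mu", [160]),
            ("mm", [80, 80]),
            ("uu", [62, 98]),
            ("um", [18, 62, 80]),
        ],
    )
    def test_pattern_signatures(self, state, fragments):
        assert insilico_digest(synthetic_amplicon(), state) == fragments

    @pytest.mark.parametrize("state", ["mm", "mu", "um", "uu"])
    def test_fragments_sum_to_amplicon_length(self, state):
        model = synthetic_amplicon()
        assert sum(insilico_digest(model, state)) == len(model.sequence)

    def test_primer_mismatch_rejected(self):
        with pytest.raises(ValueError, match="primers do not match"):
            AmpliconModel.from_reference("ACGT" * 50, "TTTTTTTTTT", "AAAAAAAAAA")

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="state"):
            insilico_digest(synthetic_amplicon(), "xx")
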