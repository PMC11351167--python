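import numpy as np
import pytest

from matsplice.alignment import AlignmentParams, pairwise_align
from matsplice.protscale import (
    ScaleTable,
    compare_profiles,
    load_scale,
    window_weights,
    windowed_profile,
)

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng, n):
    return "".join(rng.choice(AAS, n))


class TestWeights:
    def test_uniform_window(self):
        w = window_weights(5, edge_weight=1.0)
        assert w.weights == pytest.approx((0.2,) * 5)

    def test_zero_edge_rejected(self):
        with pytest.raises(ValueError):
            window_weights(3, edge_weight=0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            window_weights(10)

    def test_linear_interpolation(self):
        w = window_weights(5, edge_weight=0.5)
        rel = np.array([0.5, 0.75, 1.0, 0.75, 0.5])
        assert np.asarray(w.weights) == pytest.approx(rel / rel.sum())

    def test_window_one(self):
        assert window_weights(1).weights == (1.0,)


class TestScales:
    @pytest.mark.parametrize("name", ["helix", "sheet", "turn", "coil",
                                      "chou_fasman_helix"])
    def test_bundled_scales_complete(self, name):
        scale = load_scale(name)
        assert len(scale.values) == 20
        assert scale.provenance

    def test_unknown_scale(self):
        with pytest.raises(KeyError):
            load_scale("nope")

    def test_scale_file_round_trip(self, tmp_path):
        scale = load_scale("helix")
        path = tmp_path / "scale.txt"
        path.write_text("\n".join(
            f"{aa} {v}" for aa, v in scale.values.items()
        ))
        again = ScaleTable.from_file(path)
        assert again.values == scale.values


class TestProfiles:
    def test_homopolymer_constant(self):
        scale = load_scale("helix")
        prof = windowed_profile("A" * 60, scale, window_weights(21))
        assert set(round(s, 9) for s in prof.scores) == {
            round(scale.values["A"], 9)
        }

    def test_window_one_equals_raw_values(self):
        scale = load_scale("sheet")
        seq = "ACDEFGHIKLMNPQRSTVWY"
        prof = windowed_profile(seq, scale, window_weights(1))
        assert list(prof.scores) == pytest.approx(
            [scale.values[aa] for aa in seq]
        )
        assert prof.positions == tuple(range(1, 21))

    def test_uniform_window_is_moving_average(self, rng):
        scale = load_scale("turn")
        for _ in range(100):
            seq = random_protein(rng, 100)
            prof = windowed_profile(seq, scale, window_weights(21, 1.0))
            vals = [scale.values[aa] for aa in seq]
            for pos, score in zip(prof.positions, prof.scores):
                window = vals[pos - 11: pos + 10]
                assert score == pytest.approx(float(np.mean(window)))

    def test_weighted_window_brute_force(self, rng):
        scale = load_scale("helix")
        weights = window_weights(9, edge_weight=0.4)
        seq = random_protein(rng, 50)
        prof = windowed_profile(seq, scale, weights)
        vals = [scale.values[aa] for aa in seq]
        for pos, score in zip(prof.positions, prof.scores):
            expected = sum(
                w * vals[pos - 5 + i] for i, w in enumerate(weights.weights)
            )
            assert score == pytest.approx(expected)

    def test_position_span(self):
        prof = windowed_profile("A" * 100, load_scale("coil"),
                                window_weights(21))
        assert prof.positions[0] == 11 and prof.positions[-1] == 90

    def test_shift_equivariance(self, rng):
        scale = load_scale("helix")
        seq = random_protein(rng, 80)
        prefix = random_protein(rng, 7)
        p1 = windowed_profile(seq, scale, window_weights(9))
        p2 = windowed_profile(prefix + seq, scale, window_weights(9))
        shifted = dict(zip(p2.positions, p2.scores))
        for pos, score in zip(p1.positions, p1.scores):
            if pos + 7 in shifted and pos > 4 + 7:
                assert shifted[pos + 7] == pytest.approx(score)

    def test_scores_bounded_by_scale(self, rng):
        scale = load_scale("sheet")
        lo, hi = min(scale.values.values()), max(scale.values.values())
        for _ in range(20):
            prof = windowed_profile(random_protein(rng, 60), scale,
                                    window_weights(21, 0.3))
            assert all(lo - 1e-9 <= s <= hi + 1e-9 for s in prof.scores)

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            windowed_profile("MKV", load_scale("helix"), window_weights(21))


class TestDivergence:
    def test_self_comparison(self, rng):
        scale = load_scale("helix")
        seq = random_protein(rng, 120)
        prof = windowed_profile(seq, scale, window_weights(21))
        mapping = pairwise_align(seq, seq, AlignmentParams.protein())
        div = compare_profiles(prof, prof, mapping)
        assert div.correlation == pytest.approx(1.0)
        assert div.max_abs_difference == 0.0
        assert div.divergent_runs == ()

    def test_negated_profile_anticorrelates(self, rng):
        from matsplice.protscale import ScaleProfile

        scale = load_scale("helix")
        seq = random_protein(rng, 120)
        prof = windowed_profile(seq, scale, window_weights(21))
        mean = float(np.mean(prof.scores))
        negated = ScaleProfile(
            protein_id=prof.protein_id, scale=prof.scale,
            positions=prof.positions,
            scores=tuple(2 * mean - s for s in prof.scores),
        )
        mapping = pairwise_align(seq, seq, AlignmentParams.protein())
        div = compare_profiles(prof, negated, mapping)
        assert div.correlation == pytest.approx(-1.0)

    def test_planted_deletion_flagged_near_locus(self, rng):
        scale = load_scale("helix")
        seq = random_protein(rng, 200)
        lo = 90
        mutant = seq[:lo] + seq[lo + 18:]
        ref_prof = windowed_profile(seq, scale, window_weights(21))
        mut_prof = windowed_profile(mutant, scale, window_weights(21))
        mapping = pairwise_align(seq, mutant, AlignmentParams.protein())
        div = compare_profiles(ref_prof, mut_prof, mapping)
        assert any(
            run[0] <= lo + 18 + 21 and run[1] >= lo - 21
            for run in div.divergent_runs
        )

    def test_disjoint_profiles_rejected(self, rng):
        from matsplice.protscale import ScaleProfile

        scale = load_scale("helix")
        seq = random_protein(rng, 60)
        prof = windowed_profile(seq, scale, window_weights(21))
        far = ScaleProfile(protein_id="x", scale=prof.scale,
                           positions=(1000, 1001), scores=(0.0, 0.0))
        mapping = pairwise_align(seq, seq, AlignmentParams.protein())
        with pytest.raises(ValueError):
            compare_profiles(prof, far, mapping)
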