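import math

import numpy as np
import pytest

from mitorepeats import MitoGenome, Repeat, RepeatSet, ScanParams, find_repeats
from mitorepeats.scoring import (
    ScoreParams,
    fit_power_exponent,
    positional_scores,
    profile,
    repeat_score,
    score_vs_deletion_table,
    spacer_stratified_scores,
    subsample_to_reference_length,
)

from mitorepeats.synthetic import PlantSpec, plant_repeat

from conftest import make_genome, revcomp, rotate


def _repeat(i, l, spacer=10, kind="DR", a1=1):
    a2 = a1 + l + spacer
    return Repeat(kind=kind, arm1_start=a1, arm1_end=a1 + l - 1,
                  arm2_start=a2, arm2_end=a2 + l - 1,
                  length=l, matches=i, mismatches=l - i, spacer=spacer)


def _repeat_set(reps, L=2000, accession="X"):
    return RepeatSet(accession=accession, kind=reps[0].kind if reps else "DR",
                     params=ScanParams(), genome_length=L, repeats=list(reps))


class TestRepeatScore:
    @pytest.mark.parametrize("i,l,expected,tol", [
        (17, 18, 0.0702, 5e-4),          # the mouse inversion-1 repeat
        (25, 25, 1.0, 1e-12),            # normalization point
        (12, 12, 0.48 ** 6, 1e-12),      # (144/300)^6 by hand
        (2, 2, 2.62144e-7, 1e-12),       # (4/50)^6 = 0.08^6 by hand
    ])
    def test_known_values(self, i, l, expected, tol):
        assert repeat_score(i, l) == pytest.approx(expected, abs=tol)

    def test_monotone_in_matches_and_length(self):
        for l in (10, 18, 25):
            scores = [repeat_score(i, l) for i in range(1, l + 1)]
            assert all(b > a for a, b in zip(scores, scores[1:]))
        for i in (5, 10):
            scores = [repeat_score(i, l) for l in range(i, 30)]
            assert all(b < a for a, b in zip(scores, scores[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            repeat_score(0, 5)
        with pytest.raises(ValueError):
            repeat_score(6, 5)


class TestProfile:
    def test_empty_set_scores_zero(self):
        p = profile(_repeat_set([]))
        assert p.total == 0.0 and p.total_excl_dloop == 0.0

    def test_single_repeat_total(self):
        p = profile(_repeat_set([_repeat(17, 18)]))
        assert p.total == pytest.approx(0.0702, abs=5e-4)
        assert p.by_length == {18: p.total}
        assert p.by_matches == {17: p.total}

    def test_additivity(self):
        r1, r2 = _repeat(10, 12, a1=1), _repeat(15, 15, a1=200)
        pa = profile(_repeat_set([r1]))
        pb = profile(_repeat_set([r2]))
        pu = profile(_repeat_set([r1, r2]))
        assert pu.total == pytest.approx(pa.total + pb.total)

    def test_mismatched_accessions_rejected(self):
        with pytest.raises(ValueError, match="different genomes"):
            profile(_repeat_set([_repeat(5, 5)], accession="A"),
                    _repeat_set([_repeat(5, 5)], accession="B"))

    def test_totals_invariant_under_rotation_and_revcomp(self):
        g = make_genome(150, seed=77)
        base = profile(find_repeats(g, "IR", ScanParams())).total
        rot = MitoGenome(sequence=rotate(g.sequence, 31), accession="R")
        rc = MitoGenome(sequence=revcomp(g.sequence), accession="C")
        assert profile(find_repeats(rot, "IR", ScanParams())).total == pytest.approx(base)
        assert profile(find_repeats(rc, "IR", ScanParams())).total == pytest.approx(base)


class TestSubsampling:
    def test_reference_class_always_kept(self):
        reps = [_repeat(12, 12, a1=1 + 40 * k) for k in range(50)]
        out = subsample_to_reference_length(_repeat_set(reps), seed=1)
        assert len(out) == 50

    def test_above_reference_clamped(self):
        reps = [_repeat(13, 13, a1=1 + 40 * k) for k in range(50)]
        out = subsample_to_reference_length(_repeat_set(reps), seed=2)
        assert len(out) == 50

    def test_binomial_keep_rate(self):
        # i=10 -> keep probability 3^-2 = 1/9
        reps = [_repeat(10, 10, a1=1 + 25 * k) for k in range(9000)]
        out = subsample_to_reference_length(_repeat_set(reps, L=300000), seed=1)
        expected = 9000 / 9
        sigma = math.sqrt(9000 * (1 / 9) * (8 / 9))
        assert abs(len(out) - expected) < 3 * sigma

    def test_deterministic_under_seed(self):
        reps = [_repeat(11, 11, a1=1 + 30 * k) for k in range(100)]
        a = subsample_to_reference_length(_repeat_set(reps, L=5000), seed=9)
        b = subsample_to_reference_length(_repeat_set(reps, L=5000), seed=9)
        assert a.coordinate_keys() == b.coordinate_keys()


class TestSpacerStrata:
    def test_single_bin(self):
        out = spacer_stratified_scores(_repeat_set([_repeat(10, 10, spacer=100)]), [0, 1000])
        assert out[(0, 1000)] == pytest.approx(repeat_score(10, 10))

    def test_bins_conserve_total(self):
        reps = [_repeat(10, 10, spacer=s, a1=1 + 30 * k) for k, s in enumerate((5, 50, 500))]
        rs = _repeat_set(reps)
        out = spacer_stratified_scores(rs, [0, 10, 100, 1000])
        assert sum(out.values()) == pytest.approx(profile(rs).total)

    def test_circular_spacer_is_short_side(self):
        g = make_genome(1000, seed=55, accession="CIRC")
        g2, truth = plant_repeat(
            g, PlantSpec(kind="DR", length=5, arm1_start=10, arm2_start=990, seed=1))
        # short way round: from arm2 end (994) across the origin to arm1 start (10)
        assert truth.spacer == 15

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            spacer_stratified_scores(_repeat_set([_repeat(5, 5)]), [10, 5])


class TestPositionalScores:
    def test_rebasing_and_half_weight_split(self, toy_genome):
        # tRNA-Phe starts at 71; a repeat with both arm midpoints inside one window
        rep = _repeat(10, 10, kind="DR", a1=71, spacer=5)
        out = positional_scores(_repeat_set([rep], L=120), toy_genome, window=60)
        assert out == {1: pytest.approx(repeat_score(10, 10))}

    def test_arms_in_different_windows_split_half(self, toy_genome):
        rep = Repeat(kind="DR", arm1_start=71, arm1_end=74, arm2_start=20, arm2_end=23,
                     length=4, matches=4, mismatches=0, spacer=42)
        out = positional_scores(_repeat_set([rep], L=120), toy_genome, window=30)
        sc = repeat_score(4, 4)
        assert out[1] == pytest.approx(sc / 2)  # arm at the origin feature
        assert sum(out.values()) == pytest.approx(sc)

    def test_identity_when_origin_at_one(self, toy_genome):
        feats = list(toy_genome.features)
        feats[1] = feats[1].__class__(kind="tRNA", start=1, end=30, name="tRNA-Phe")
        g = MitoGenome(sequence=toy_genome.sequence, accession="T", features=feats)
        rep = _repeat(6, 6, kind="DR", a1=3, spacer=4)
        out = positional_scores(_repeat_set([rep], L=120), g, window=40)
        assert list(out) == [1]

    def test_missing_origin_feature(self, toy_genome):
        with pytest.raises(ValueError, match="not found"):
            positional_scores(_repeat_set([_repeat(5, 5)], L=120), toy_genome,
                              origin_feature="tRNA-Leu")


class TestPowerFit:
    def test_exact_recovery_noise_free(self):
        l = np.arange(6, 31)
        rates = 3.5 * l.astype(float) ** 6
        fit = fit_power_exponent(l, rates)
        assert fit.exponent == pytest.approx(6.0, abs=1e-9)
        assert fit.scale == pytest.approx(3.5, rel=1e-9)

    def test_exact_recovery_any_weights(self):
        l = np.arange(6, 31)
        rates = 0.2 * l.astype(float) ** 6
        rng = np.random.default_rng(4)
        fit = fit_power_exponent(l, rates, weights=rng.uniform(0.1, 5, l.size))
        assert fit.exponent == pytest.approx(6.0, abs=1e-9)

    def test_two_point_weights_give_two_point_slope(self):
        l = np.array([5.0, 10.0, 20.0, 40.0])
        rates = np.array([1.0, 70.0, 900.0, 100000.0])
        w = np.array([1.0, 0.0, 0.0, 1.0])
        fit = fit_power_exponent(l, rates, weights=w)
        expected = (math.log(rates[3]) - math.log(rates[0])) / (math.log(l[3]) - math.log(l[0]))
        assert fit.exponent == pytest.approx(expected, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_power_exponent([1, 2], [1, 64])


class TestScoreVsDeletions:
    def test_identical_vectors_r_one(self):
        scores = {2: 1.0, 5: 3.0, 9: 7.0}
        df, r, p = score_vs_deletion_table(scores, {2: 1, 5: 3, 9: 7})
        assert r == pytest.approx(1.0)

    def test_anti_ordered_r_minus_one(self):
        df, r, p = score_vs_deletion_table({2: 1.0, 5: 2.0, 9: 3.0}, {2: 30, 5: 20, 9: 10})
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson_on_four_points(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 5.0]
        # independent hand computation from the definition
        mx, my = sum(x) / 4, sum(y) / 4
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        expected = sxy / math.sqrt(sxx * syy)
        df, r, p = score_vs_deletion_table(
            {l: v for l, v in zip((2, 3, 4, 5), x)},
            {l: v for l, v in zip((2, 3, 4, 5), y)})
        assert r == pytest.approx(expected, abs=1e-12)

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError, match="overlap"):
            score_vs_deletion_table({2: 1.0}, {9: 4})
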