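"""Contamination filtering, block PDIs, feedback correlations and Mantel tests."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import greenhouse_frame, random_distance_matrix
from rhizospec.genotyping import DistanceMatrix
from rhizospec.greenhouse import (
    GreenhouseError,
    block_pdi,
    effect_pdi,
    feedback_correlations,
    filter_contaminated,
    fitness_effect,
    fold_increase,
    genotype_means,
    mantel,
    phenotype_difference_matrix,
    response_pdi,
)


class TestFilterContaminated:
    def test_nodulated_control_excluded(self):
        df = greenhouse_frame()
        df.loc[
            (df.treatment == "CONTROL") & (df.block == 1), "nodule_count"
        ] = [3, 0]
        kept, report = filter_contaminated(df)
        assert report.n_excluded == 1
        assert report.n_controls == 4
        assert not (
            (kept.treatment == "CONTROL") & (kept.nodule_count > 0)
        ).any()

    def test_clean_control_retained(self):
        df = greenhouse_frame()
        kept, report = filter_contaminated(df)
        assert report.n_excluded == 0
        assert (kept.treatment == "CONTROL").sum() == 4

    def test_treatment_records_never_excluded(self):
        df = greenhouse_frame()
        df.loc[df.treatment == "T1", "nodule_count"] = 50
        kept, _ = filter_contaminated(df)
        assert (kept.treatment == "T1").sum() == 2

    def test_block_with_all_controls_nodulated_errors(self):
        df = greenhouse_frame()
        df.loc[
            (df.treatment == "CONTROL") & (df.block == 2), "nodule_count"
        ] = 1
        with pytest.raises(GreenhouseError, match="block"):
            filter_contaminated(df)


class TestFitnessEffect:
    @pytest.mark.parametrize(
        "w,wc,expected",
        [(0.1, 0.1, 0.0), (0.2, 0.1, 0.5), (0.05, 0.1, -1.0)],
    )
    def test_hand_values(self, w, wc, expected):
        assert fitness_effect(w, wc) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "w,wc,expected", [(0.1, 0.1, 0.0), (0.3, 0.1, 2.0)]
    )
    def test_fold_increase_hand_values(self, w, wc, expected):
        assert fold_increase(w, wc) == pytest.approx(expected)

    def test_sign_agreement(self, rng):
        for _ in range(100):
            w, wc = rng.uniform(0.01, 1.0, size=2)
            assert np.sign(fitness_effect(w, wc)) == np.sign(
                fold_increase(w, wc)
            )

    def test_fitness_effect_bounded_above_by_one(self, rng):
        for _ in range(100):
            w, wc = rng.uniform(0.01, 1.0, size=2)
            assert fitness_effect(w, wc) < 1.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            fitness_effect(0.0, 0.1)


class TestBlockPDI:
    def test_identical_values_zero(self):
        assert block_pdi([2.0, 2.0, 2.0]) == 0.0

    def test_hand_example(self):
        assert block_pdi([3, 1, 0]) == pytest.approx(2.5)

    def test_scale_equivariant(self, rng):
        v = rng.normal(size=10)
        c = 3.7
        assert block_pdi(c * v) == pytest.approx(c * block_pdi(v))

    def test_translation_sensitive_numerator_invariant(self, rng):
        # shifting all values leaves the paired differences unchanged
        v = rng.normal(size=8)
        assert block_pdi(v + 5.0) == pytest.approx(block_pdi(v))


class TestResponsePDI:
    def test_all_strains_equal_control_gives_zero(self):
        df = greenhouse_frame(control_weight=0.1)
        res = response_pdi(df, "HA")
        assert res.mean == pytest.approx(0.0)
        assert res.values.tolist() == [0.0, 0.0]

    def test_single_doubling_strain_recovers_effect(self):
        """One strain doubles weight, the rest sit at control level:
        per-block PDI equals that strain's fitness effect p = 0.5."""
        weights = {}
        for b in (1, 2):
            weights[("HA", "T1", b)] = 0.2
            weights[("HA", "T2", b)] = 0.1
            weights[("HA", "T3", b)] = 0.1
        df = greenhouse_frame(strain_weights=weights, control_weight=0.1)
        res = response_pdi(df, "HA")
        assert res.mean == pytest.approx(0.5)
        assert res.n_strains_by_block == {1: 3, 2: 3}

    def test_missing_control_block_errors(self):
        df = greenhouse_frame()
        df = df[~((df.treatment == "CONTROL") & (df.block == 2))]
        with pytest.raises(GreenhouseError):
            response_pdi(df, "HA")

    def test_explicit_denominator(self):
        weights = {("HA", s, b): (0.2 if s == "T1" else 0.1)
                   for s in ("T1", "T2", "T3") for b in (1, 2)}
        df = greenhouse_frame(strain_weights=weights)
        res = response_pdi(df, "HA", denominator=30)
        assert res.mean == pytest.approx(0.5 * 2 / 30)


class TestEffectPDI:
    def test_equal_trait_values_zero(self):
        df = greenhouse_frame(nodule_counts={
            ("HA", s, b): 8 for s in ("T1", "T2", "T3") for b in (1, 2)
        })
        res = effect_pdi(df, "HA", "nodule_count")
        assert res.mean == pytest.approx(0.0)

    def test_ln_scale_hand_oracle(self):
        """One strain with e^2-fold more nodules: ln-scale PDI equals the
        direct paired-difference evaluation of the constructed vector."""
        counts = {}
        for b in (1, 2):
            counts[("HA", "T1", b)] = round(8 * np.exp(2))
            counts[("HA", "T2", b)] = 8
            counts[("HA", "T3", b)] = 8
        df = greenhouse_frame(nodule_counts=counts)
        res = effect_pdi(df, "HA", "nodule_count", transform="ln")
        expected = oracles.pdi_bruteforce(
            [np.log(round(8 * np.exp(2))), np.log(8), np.log(8)]
        )
        assert res.mean == pytest.approx(expected)

    def test_sqrt_transform_for_area(self):
        areas = {("HA", s, b): (0.16 if s == "T1" else 0.04)
                 for s in ("T1", "T2", "T3") for b in (1, 2)}
        df = greenhouse_frame(total_areas=areas)
        res = effect_pdi(df, "HA", "total_nodule_area")
        assert res.mean == pytest.approx(oracles.pdi_bruteforce([0.4, 0.2, 0.2]))

    def test_zero_counts_fall_back_to_log1p(self):
        counts = {("HA", s, b): (0 if s == "T3" else 8)
                  for s in ("T1", "T2", "T3") for b in (1, 2)}
        df = greenhouse_frame(nodule_counts=counts)
        with pytest.warns(UserWarning, match="ln"):
            res = effect_pdi(df, "HA", "nodule_count")
        assert res.mean == pytest.approx(
            oracles.pdi_bruteforce([np.log(9), np.log(9), np.log(1)])
        )


class TestGenotypeMeans:
    def test_replicate_mean_and_se(self):
        weights = {("HA", "T1", 1): 2.0, ("HA", "T1", 2): 4.0}
        for s in ("T2", "T3"):
            weights[("HA", s, 1)] = 1.0
            weights[("HA", s, 2)] = 1.0
        df = greenhouse_frame(strain_weights=weights)
        means = genotype_means(df)
        row = means[(means.host_species == "HA") & (means.strain == "T1")]
        assert row.shoot_weight_mean.item() == pytest.approx(3.0)
        assert row.shoot_weight_se.item() == pytest.approx(1.0)

    def test_single_replicate_has_no_se(self):
        df = greenhouse_frame(blocks=(1,))
        means = genotype_means(df)
        assert means.shoot_weight_se.isna().all()

    def test_mean_nodule_area_is_per_plant_ratio(self):
        df = greenhouse_frame(
            nodule_counts={("HA", s, b): (4 if b == 1 else 8)
                           for s in ("T1", "T2", "T3") for b in (1, 2)},
            total_areas={("HA", s, b): 0.8 for s in ("T1", "T2", "T3")
                         for b in (1, 2)},
        )
        means = genotype_means(df)
        # per-plant ratios 0.2 and 0.1, averaged -> 0.15 (not 1.6/12)
        assert means.mean_nodule_area_mean.iloc[0] == pytest.approx(0.15)

    def test_controls_never_contribute(self):
        df = greenhouse_frame()
        means = genotype_means(df)
        assert "CONTROL" not in set(means.strain)


class TestFeedbackCorrelations:
    def _means(self, x, y):
        return pd.DataFrame(
            {
                "host_species": "HA",
                "strain": [f"T{i}" for i in range(len(x))],
                "shoot_weight_mean": y,
                "nodule_count_mean": x,
                "total_nodule_area_mean": x,
                "mean_nodule_area_mean": x,
            }
        )

    def test_perfect_positive(self):
        res = feedback_correlations(self._means([1, 2, 3], [1, 2, 3]), "HA")
        assert all(c.r == pytest.approx(1.0) for c in res)

    def test_perfect_negative(self):
        res = feedback_correlations(self._means([1, 2, 3], [6, 4, 2]), "HA")
        assert all(c.r == pytest.approx(-1.0) for c in res)

    def test_zero_variance_undefined(self):
        res = feedback_correlations(self._means([1, 1, 1], [1, 2, 3]), "HA")
        assert all(c.r is None for c in res)

    def test_ln_transform_map(self):
        res = feedback_correlations(
            self._means([1, 10, 100], [0, 1, 2]),
            "HA",
            transform_map={"nodule_count": "ln"},
        )
        by = {c.x: c for c in res}
        assert by["nodule_count"].r == pytest.approx(1.0)
        assert by["total_nodule_area"].r < 1.0


class TestPhenotypeDifferenceMatrix:
    def _means(self, values, strains=None):
        strains = strains or [f"T{i}" for i in range(len(values))]
        return pd.DataFrame(
            {
                "host_species": "HA",
                "strain": strains,
                "shoot_weight_mean": values,
            }
        )

    def test_identical_means_zero_matrix(self):
        m = phenotype_difference_matrix(self._means([2, 2, 2]), "shoot_weight", "HA")
        assert (m.values == 0).all()

    def test_absolute_differences(self):
        m = phenotype_difference_matrix(self._means([1, 4, 2]), "shoot_weight", "HA")
        assert m.values[0, 1] == pytest.approx(3.0)

    def test_exclusions_dropped(self):
        m = phenotype_difference_matrix(
            self._means([1, 2, 3, 4], ["T1", "T11", "T12", "T30"]),
            "shoot_weight",
            "HA",
            exclude=("T11",),
        )
        assert "T11" not in m.labels


class TestMantel:
    def test_matrix_vs_itself(self, rng):
        dm = random_distance_matrix(rng, 6)
        res = mantel(dm, dm, perms=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_exact_enumeration_n4(self, rng):
        """All 24 joint permutations vs the sampled permutation p."""
        x = random_distance_matrix(rng, 4, length=200)
        y = random_distance_matrix(rng, 4, length=200)
        exact = oracles.mantel_exact_p(x.values, y.values)
        res = mantel(x, y, perms=5000, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.04)

    def test_invariant_under_joint_relabeling(self, rng):
        x = random_distance_matrix(rng, 7)
        y = random_distance_matrix(rng, 7)
        perm = rng.permutation(7)
        xp = DistanceMatrix(
            [x.labels[i] for i in perm], x.values[np.ix_(perm, perm)]
        )
        yp = DistanceMatrix(
            [y.labels[i] for i in perm], y.values[np.ix_(perm, perm)]
        )
        a = mantel(x, y, perms=199, seed=5)
        b = mantel(xp, yp, perms=199, seed=5)
        assert a.r == pytest.approx(b.r)

    def test_permutation_distribution_centred_on_zero(self, rng):
        x = random_distance_matrix(rng, 8)
        y = random_distance_matrix(rng, 8)
        rs = []
        for _ in range(200):
            perm = rng.permutation(8)
            rs.append(
                oracles.mantel_r_bruteforce(
                    x.values, y.values[np.ix_(perm, perm)]
                )
            )
        assert abs(np.mean(rs)) < 0.1

    def test_agrees_with_skbio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        x = random_distance_matrix(rng, 8)
        y = random_distance_matrix(rng, 8)
        ours = mantel(x, y, perms=999, seed=2)
        r_ref, p_ref, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(x.values, x.labels),
            skbio_distance.DistanceMatrix(y.values, y.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert ours.r == pytest.approx(float(r_ref))
        assert ours.p_value == pytest.approx(float(p_ref), abs=0.05)

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c", "d"]
        const = DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            mantel(const, const, perms=9, seed=0)

    def test_mismatched_labels_rejected(self, rng):
        x = random_distance_matrix(rng, 4)
        y = DistanceMatrix(["q1", "q2", "q3", "q4"], x.values)
        with pytest.raises(ValueError, match="share labels"):
            mantel(x, y, perms=9, seed=0)
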