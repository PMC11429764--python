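"""Evaluation statistics: pattern matrices, Hamming clustering, activation
frequencies, expression correlation, and phenotype network scores."""

import itertools

import numpy as np
import pandas as pd
import pytest

from boolmerge import (
    Attractor,
    CohortRecord,
    LogicalModel,
    MutationProfile,
    NodeSpec,
    PhenotypeScoreConfig,
    activation_frequency,
    cohort_correlation,
    correlate,
    find_attractors,
    hamming_cluster,
    network_score,
    parse_rule,
    pattern_matrix,
)
from boolmerge.errors import DegenerateVarianceError
from boolmerge.evaluation import _masked_hamming

from conftest import random_closed_model


def model_of(name: str, rules: dict[str, str]) -> LogicalModel:
    return LogicalModel(
        name, [NodeSpec(sym, parse_rule(text)) for sym, text in rules.items()]
    )


def fp(states, label="", basin=None):
    kind = "FIXED_POINT" if len(states) == 1 else "CYCLIC"
    return Attractor(kind=kind, states=tuple(states), basin_fraction=basin, label=label)


class TestPatternMatrix:
    two_gene = model_of("ab", {"A": "A", "B": "B"})

    def test_fixed_point_contributes_its_state(self):
        pm = pattern_matrix([(self.two_gene, [fp([(1, 0)], "X1")])])
        assert pm.values.loc["X1"].tolist() == [1.0, 0.0]

    def test_gene_absent_from_a_model_is_missing(self):
        other = model_of("c", {"C": "C"})
        pm = pattern_matrix([
            (self.two_gene, [fp([(1, 0)], "X1")]),
            (other, [fp([(1,)], "Y1")]),
        ])
        assert np.isnan(pm.values.loc["X1", "C"])
        assert np.isnan(pm.values.loc["Y1", "A"])
        assert pm.values.loc["Y1", "C"] == 1.0

    def test_cyclic_majority_with_tie_flagged_as_zero(self):
        three_gene = model_of("abc", {"A": "A", "B": "B", "C": "C"})
        # A: 2/4 tie -> 0 flagged; B: 3/4 majority ON; C: 1/4 majority OFF
        cycle = fp([(0, 1, 0), (1, 1, 1), (0, 1, 1), (1, 0, 0)], "C1")
        pm = pattern_matrix([(three_gene, [cycle])])
        assert pm.values.loc["C1", "A"] == 0.0
        assert pm.values.loc["C1", "B"] == 1.0
        assert pm.values.loc["C1", "C"] == 0.0
        assert pm.ties.loc["C1", "A"]
        assert not pm.ties.loc["C1", "B"]
        assert pm.ties.loc["C1", "C"]


class TestHammingCluster:
    def test_distance_counts_differing_cells(self):
        rows = pd.DataFrame([[1, 1, 0], [1, 0, 0]], index=["r1", "r2"])
        assert _masked_hamming(rows.to_numpy(float))[0, 1] == pytest.approx(1 / 3)

    def test_identical_rows_cluster_together(self):
        rows = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]], index=["r1", "r2", "r3"], dtype=float
        )
        labels, _ = hamming_cluster(rows, k=2)
        assert labels["r1"] == labels["r2"] != labels["r3"]

    def test_missing_cells_excluded_from_distance(self):
        rows = pd.DataFrame([[1, np.nan, 0], [1, 1, 0]], index=["r1", "r2"])
        assert _masked_hamming(rows.to_numpy(float))[0, 1] == 0.0

    def test_no_shared_positions_is_an_error(self):
        rows = pd.DataFrame([[1, np.nan], [np.nan, 1]], index=["r1", "r2"])
        with pytest.raises(ValueError, match="no non-missing"):
            hamming_cluster(rows, k=2)

    def test_single_row_cannot_be_clustered(self):
        with pytest.raises(ValueError, match="at least two"):
            hamming_cluster(pd.DataFrame([[1, 0]], index=["r1"]), k=1)

    @pytest.mark.parametrize("seed", range(10))
    def test_distance_is_a_metric_on_complete_rows(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 2, size=(6, 8)).astype(float)
        d = _masked_hamming(rows)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestActivationFrequency:
    attractors = [fp([(1, 0)], "a", basin=0.75), fp([(1, 1)], "b", basin=0.25)]

    def test_uniform_states_pools_all_states(self):
        prof = activation_frequency(self.attractors, ["A", "B"], "UNIFORM_STATES")
        assert prof["A"] == 1.0
        assert prof["B"] == 0.5

    def test_basin_weighting_uses_basin_fractions(self):
        prof = activation_frequency(self.attractors, ["A", "B"], "BASIN")
        assert prof["A"] == 1.0
        assert prof["B"] == 0.25

    def test_single_fixed_point_reproduces_its_bits(self):
        prof = activation_frequency([fp([(0, 1)])], ["A", "B"])
        assert (prof["A"], prof["B"]) == (0.0, 1.0)

    def test_basin_weighting_without_basins_is_an_error(self):
        with pytest.raises(ValueError, match="basin"):
            activation_frequency([fp([(1, 0)])], ["A", "B"], "BASIN")

    def test_weightings_agree_for_equal_basins_and_sizes(self):
        a = [fp([(1, 0)], basin=0.5), fp([(0, 1)], basin=0.5)]
        u = activation_frequency(a, ["A", "B"], "UNIFORM_STATES").frequencies
        b = activation_frequency(a, ["A", "B"], "BASIN").frequencies
        assert np.allclose(u, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_frequencies_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(40 + seed)
        model = random_closed_model(rng, n=6)
        found = find_attractors(model, "SYNC")
        for weighting in ("UNIFORM_STATES", "BASIN"):
            prof = activation_frequency(found, model.symbols, weighting)
            assert ((prof.frequencies >= 0) & (prof.frequencies <= 1)).all()


class TestCorrelate:
    def profile(self, values):
        from boolmerge.evaluation import ActivationProfile

        return ActivationProfile(
            frequencies=pd.Series(values), weighting="UNIFORM_STATES"
        )

    def test_perfect_agreement(self):
        prof = self.profile({"A": 0.0, "B": 0.5, "C": 1.0})
        r, n, excluded = correlate(prof, {"A": 0.0, "B": 0.5, "C": 1.0})
        assert r == pytest.approx(1.0)
        assert n == 3 and excluded == []

    def test_perfect_anticorrelation(self):
        prof = self.profile({"A": 0.0, "B": 0.5, "C": 1.0})
        r, _, _ = correlate(prof, {"A": 1.0, "B": 0.5, "C": 0.0})
        assert r == pytest.approx(-1.0)

    def test_constant_predictions_degenerate(self):
        prof = self.profile({"A": 0.5, "B": 0.5, "C": 0.5})
        with pytest.raises(DegenerateVarianceError):
            correlate(prof, {"A": 0.1, "B": 0.5, "C": 0.9})

    def test_genes_absent_from_either_side_are_excluded_and_reported(self):
        prof = self.profile({"A": 0.0, "B": 0.5, "C": 1.0, "D": 0.2})
        r, n, excluded = correlate(prof, {"A": 0.0, "B": 0.5, "C": 1.0, "E": 0.7})
        assert n == 3
        assert set(excluded) == {"D", "E"}

    def test_fewer_than_three_common_genes_is_an_error(self):
        prof = self.profile({"A": 0.0, "B": 1.0})
        with pytest.raises(ValueError, match="at least 3"):
            correlate(prof, {"A": 0.0, "B": 1.0})

    def test_spearman_flag(self):
        prof = self.profile({"A": 0.0, "B": 0.1, "C": 1.0})
        r, _, _ = correlate(prof, {"A": 0.2, "B": 0.3, "C": 0.4}, method="spearman")
        assert r == pytest.approx(1.0)  # monotone agreement


class TestNetworkScore:
    # B copies A; clamping A drives B's activation frequency to the clamp.
    chain = model_of("chain", {"A": "A", "B": "A"})

    def test_clamp_forcing_phenotype_on_scores_one(self):
        config = PhenotypeScoreConfig.from_dict({"B": 1.0})
        score = network_score(
            self.chain, MutationProfile.from_dict({"A": 1}), config
        )
        assert score == pytest.approx(1.0)

    def test_opposing_weights_cancel(self):
        model = model_of("m", {"P": "1", "Q": "1"})
        config = PhenotypeScoreConfig.from_dict({"P": 1.0, "Q": -1.0})
        assert network_score(model, MutationProfile(()), config) == pytest.approx(0.0)

    def test_empty_profile_scores_wild_type(self):
        config = PhenotypeScoreConfig.from_dict({"B": 1.0})
        wild = network_score(self.chain, MutationProfile(()), config)
        # wild-type fixed points (0,0) and (1,1): mean activation of B = 0.5
        assert wild == pytest.approx(0.5)

    def test_unknown_phenotype_node_rejected(self):
        config = PhenotypeScoreConfig.from_dict({"Z": 1.0})
        with pytest.raises(KeyError, match="Z"):
            network_score(self.chain, MutationProfile(()), config)

    def test_invariant_to_node_order_and_zero_weight_padding(self):
        m1 = model_of("m1", {"A": "A", "B": "A", "C": "!A"})
        m2 = LogicalModel("m2", [m1.nodes[2], m1.nodes[0], m1.nodes[1]])
        profile = MutationProfile.from_dict({"A": 1})
        c1 = PhenotypeScoreConfig.from_dict({"B": 1.0})
        c2 = PhenotypeScoreConfig.from_dict({"B": 1.0, "C": 0.0})
        scores = {
            network_score(m, profile, c)
            for m in (m1, m2) for c in (c1, c2)
        }
        assert len(scores) == 1


class TestCohortCorrelation:
    model = model_of("m", {"A": "A", "B": "A", "C": "B"})
    config = PhenotypeScoreConfig.from_dict({"C": 1.0})

    def cohort(self, specs):
        return [
            CohortRecord(f"P{i}", MutationProfile.from_dict(clamps), value)
            for i, (clamps, value) in enumerate(specs)
        ]

    def test_scores_matching_clinical_values_give_r_one(self):
        # ground truth: clamp A=1 -> C freq 1; A=0 -> 0; wild-type -> 0.5
        cohort = self.cohort([
            ({"A": 1}, 100.0),
            ({"A": 0}, 0.0),
            ({}, 50.0),
        ])
        r, table = cohort_correlation(self.model, cohort, self.config)
        assert r == pytest.approx(1.0)
        assert len(table) == 3

    def test_identical_profiles_are_pooled_with_mean_clinical_value(self):
        cohort = self.cohort([
            ({"A": 1}, 90.0),
            ({"A": 1}, 110.0),
            ({"A": 0}, 0.0),
            ({}, 50.0),
        ])
        r, table = cohort_correlation(self.model, cohort, self.config)
        pooled = table.set_index("profile")
        assert pooled.loc["A=1", "n_patients"] == 2
        assert pooled.loc["A=1", "clinical_value"] == pytest.approx(100.0)
        assert r == pytest.approx(1.0)

    def test_fewer_than_three_profiles_is_an_error(self):
        cohort = self.cohort([({"A": 1}, 1.0), ({"A": 1}, 2.0)])
        with pytest.raises(ValueError, match="3 distinct"):
            cohort_correlation(self.model, cohort, self.config)

    def test_weighting_by_group_size_moves_r(self):
        cohort = self.cohort([
            ({"A": 1}, 80.0),
            ({"A": 1}, 80.0),
            ({"A": 1}, 80.0),
            ({"A": 0}, 30.0),
            ({}, 20.0),
        ])
        plain, _ = cohort_correlation(self.model, cohort, self.config)
        weighted, _ = cohort_correlation(
            self.model, cohort, self.config, weight_by_size=True
        )
        assert plain != pytest.approx(weighted)

    def test_shuffled_clinical_values_decorrelate_on_average(self):
        """Permutation oracle: |r| under label shuffling is small on average."""
        rng = np.random.default_rng(123)
        model = model_of("m", {"A": "A", "B": "A", "C": "B", "D": "C"})
        config = PhenotypeScoreConfig.from_dict({"D": 1.0})
        profiles = [{"A": 1}, {"A": 0}, {"B": 1}, {"C": 0}, {}, {"D": 1}]
        base_values = [90.0, 10.0, 70.0, 30.0, 50.0, 95.0]
        rs = []
        for _ in range(200):
            shuffled = rng.permutation(base_values)
            cohort = self.cohort(list(zip(profiles, shuffled)))
            try:
                r, _ = cohort_correlation(model, cohort, config)
            except DegenerateVarianceError:
                continue
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15
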