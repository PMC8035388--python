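"""Fold construction, spec enumeration, MSD/NMSD scoring, and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from workloadcv import (
    ModelSpec,
    enumerate_specs,
    make_folds,
    normalize_msd,
    rank_and_stability,
    run_cv,
    zstandardize_within_participant,
)
from workloadcv.crossval import CVResult


class TestFolds:
    def test_39_participants_split_8x4_plus_7(self):
        plan = make_folds([f"p{i}" for i in range(39)], k=5, seed=1)
        assert sorted(plan.sizes(), reverse=True) == [8, 8, 8, 8, 7]

    def test_46_participants_split_10_plus_9x4(self):
        plan = make_folds([f"p{i}" for i in range(46)], k=5, seed=1)
        assert sorted(plan.sizes(), reverse=True) == [10, 9, 9, 9, 9]

    def test_folds_partition_participants(self):
        people = [f"p{i}" for i in range(23)]
        plan = make_folds(people, k=5, seed=3)
        members = [set(plan.members(f)) for f in range(5)]
        assert set().union(*members) == set(people)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not members[i] & members[j]

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5, seed=0)

    def test_same_seed_same_assignment(self):
        people = [f"p{i}" for i in range(17)]
        assert make_folds(people, seed=5) == make_folds(people, seed=5)


class TestEnumerateSpecs:
    def test_five_events_give_36_specs(self):
        specs = enumerate_specs(["a", "b", "c", "d", "e"])
        assert len(specs) == 36

    def test_six_refined_give_68_specs(self):
        specs = enumerate_specs(list("abcdef"))
        assert len(specs) == 68

    def test_no_optional_gives_only_baselines(self):
        specs = enumerate_specs([])
        # the empty event combination coincides with the difficulty+block
        # baseline; the four baselines remain distinct entries
        assert set(specs) == {
            "(events:none)",
            "baseline:difficulty+block",
            "baseline:block",
            "baseline:difficulty",
            "baseline:intercept",
        }

    def test_always_terms_present_in_event_specs(self):
        specs = enumerate_specs(["a"])
        for sid, spec in specs.items():
            if not sid.startswith("baseline:"):
                assert {"difficulty", "block"} <= set(spec.fixed_terms)


def _noise_free_table(rng_seed=0, n_participants=6, n_trials=40):
    """log RT is an exact linear function of block: predictable to ~0 MSD."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for i in range(n_participants):
        for j in range(n_trials):
            block = j % 5 + 1
            rows.append(
                {
                    "participant_id": f"p{i:02d}",
                    "day": 1,
                    "block": block,
                    "difficulty": [3, 5, 7][j % 3],
                    "prompt_t": float(j),
                    "rt_ms": float(np.exp(6.0 + 0.01 * block + 1e-7 * rng.normal())),
                    "omission": 0,
                }
            )
    return pd.DataFrame(rows)


class TestRunCV:
    def test_near_perfect_predictions_give_near_zero_msd(self):
        table = _noise_free_table()
        specs = {"block-only": ModelSpec("log_rt", "linear", ("block",))}
        plan = make_folds(table["participant_id"].unique(), k=3, seed=0)
        result = run_cv(table, specs, plan, response="log_rt", family="lmm")
        assert (result.cells["msd"] < 1e-10).all()

    def test_cell_count_is_folds_times_specs(self, tiny_table):
        day1 = tiny_table[tiny_table["day"] == 1]
        specs = enumerate_specs(["HHO_3s", "FAR_3s"])  # 4 + 4 = 8 specs
        plan = make_folds(day1["participant_id"].unique(), k=3, seed=2)
        result = run_cv(day1, specs, plan)
        assert len(result.cells) == 3 * len(specs)
        assert result.cells["msd"].notna().all()

    def test_intercept_only_msd_at_least_test_variance(self, tiny_table):
        day1 = tiny_table[tiny_table["day"] == 1]
        specs = {"baseline:intercept": ModelSpec("log_rt", "linear", ())}
        plan = make_folds(day1["participant_id"].unique(), k=3, seed=2)
        result = run_cv(day1, specs, plan)
        responded = day1[day1["omission"] == 0]
        logrt = np.log(responded["rt_ms"].to_numpy(dtype=float))
        fold_of = responded["participant_id"].map(plan.assignment)
        for _, cell in result.cells.iterrows():
            test_y = logrt[(fold_of != cell["fold"]).to_numpy()]
            assert cell["msd"] >= np.var(test_y) - 1e-12

    def test_train_and_test_participants_disjoint(self, tiny_table):
        # fixed-effects-only prediction cannot leak identity; verify the
        # fold bookkeeping explicitly
        day1 = tiny_table[tiny_table["day"] == 1]
        plan = make_folds(day1["participant_id"].unique(), k=3, seed=4)
        for fold in range(plan.k):
            train = set(plan.members(fold))
            test = set(day1["participant_id"]) - train
            assert not train & test

    def test_omission_family_scores_probabilities(self, tiny_table):
        day1 = tiny_table[tiny_table["day"] == 1]
        specs = {"base": ModelSpec("omission", "binomial", ("difficulty",))}
        plan = make_folds(day1["participant_id"].unique(), k=3, seed=2)
        result = run_cv(day1, specs, plan, response="omission", family="glmm")
        assert ((result.cells["msd"] >= 0) & (result.cells["msd"] <= 1)).all()


class TestNormalize:
    def _result(self, cells):
        return CVResult(
            cells=pd.DataFrame(cells), specs={}, response="log_rt", family="lmm"
        )

    def test_two_cells_centre_on_grand_mean(self):
        res = normalize_msd(
            self._result(
                [
                    {"fold": 0, "spec_id": "a", "msd": 0.5},
                    {"fold": 0, "spec_id": "b", "msd": 0.7},
                ]
            )
        )
        assert res.cells["nmsd"].tolist() == pytest.approx([-0.1, 0.1])

    def test_equal_msd_gives_zero_nmsd(self):
        res = normalize_msd(
            self._result(
                [{"fold": f, "spec_id": "a", "msd": 0.3} for f in range(5)]
            )
        )
        assert res.cells["nmsd"].tolist() == pytest.approx([0.0] * 5)

    def test_ordering_invariant_between_msd_and_nmsd(self, tiny_table):
        day1 = tiny_table[tiny_table["day"] == 1]
        specs = enumerate_specs(["HHO_3s"])
        plan = make_folds(day1["participant_id"].unique(), k=3, seed=0)
        result = run_cv(day1, specs, plan)
        by_msd = result.spec_means("msd")
        by_nmsd = result.spec_means("nmsd")
        rho = stats.spearmanr(
            by_msd.rank(), by_nmsd.loc[by_msd.index].rank()
        ).statistic
        assert rho == pytest.approx(1.0)

    def test_per_fold_centering_zeroes_fold_means(self):
        res = normalize_msd(
            self._result(
                [
                    {"fold": 0, "spec_id": "a", "msd": 0.5},
                    {"fold": 0, "spec_id": "b", "msd": 0.7},
                    {"fold": 1, "spec_id": "a", "msd": 1.5},
                    {"fold": 1, "spec_id": "b", "msd": 1.7},
                ]
            ),
            centering="per_fold",
        )
        fold_means = res.cells.groupby("fold")["nmsd"].mean()
        assert fold_means.to_numpy() == pytest.approx([0.0, 0.0])


class TestRanking:
    def test_single_spec_ranks_first(self, tiny_table):
        day1 = tiny_table[tiny_table["day"] == 1]
        specs = {"only": ModelSpec("log_rt", "linear", ("difficulty", "block"))}
        plan = make_folds(day1["participant_id"].unique(), k=3, seed=1)
        summary = rank_and_stability(run_cv(day1, specs, plan))
        assert summary["ranking"]["rank"].tolist() == [1]
        assert summary["discordant_folds"] == []

    def test_inclusion_frequency_bounds(self, tiny_table):
        day1 = tiny_table[tiny_table["day"] == 1]
        specs = enumerate_specs(["WeightFuel_z", "nHHO3s_z"])
        plan = make_folds(day1["participant_id"].unique(), k=3, seed=1)
        summary = rank_and_stability(run_cv(day1, specs, plan), top_frac=0.5)
        for freq in summary["inclusion"]["overall"].values():
            assert 0.0 <= freq <= 1.0


def test_standardization_has_no_cross_participant_leakage(tiny_table):
    """Within-participant z-scores are identical computed before or after a
    participant subset is taken, so fold splitting cannot leak statistics."""
    col = tiny_table["WeightFuel"]
    keys = [tiny_table["participant_id"], tiny_table["day"]]
    full = zstandardize_within_participant(col, keys)
    subset_ids = sorted(tiny_table["participant_id"].unique())[:3]
    mask = tiny_table["participant_id"].isin(subset_ids)
    sub = zstandardize_within_participant(
        col[mask], [k[mask] for k in keys]
    )
    assert np.allclose(full[mask].to_numpy(), sub.to_numpy())
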