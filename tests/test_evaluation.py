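"""Agreement/consistency statistics, the breakdown matrix, and the
experiment runners."""

import numpy as np
import pytest

import molprobe as mp
from molprobe.evaluation import consistency_histograms


def _record(i, value=0.0):
    return mp.MoleculeRecord(f"m{i}", "CCO", {"homo": value}, frozenset(), {})


TASK = mp.ClassificationTask("homo", 3, (-6.0, -4.0))


class TestAccuracy:
    def test_perfect(self):
        assert mp.accuracy([0, 1, 2], [0, 1, 2]) == 1.0

    def test_all_erroneous(self):
        assert mp.accuracy([mp.ERRONEOUS] * 3, [0, 1, 2]) == 0.0

    def test_two_of_three(self):
        assert mp.accuracy([0, 1, 0], [0, 1, 2]) == pytest.approx(2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mp.accuracy([0], [0, 1])


class TestCorrectlyPredictedFilter:
    def test_oracle_backend_is_identity(self, stub_backend_factory):
        records = [_record(0, -7.0), _record(1, -5.0), _record(2, -3.0)]
        mapping = {"CCO": "0"}  # truth for record 0 only

        class Oracle:
            metadata = {}
            def fit(self, pairs): return self
            def complete(self, prompt):  # all records share the same smiles here
                return "0"

        kept = mp.correctly_predicted_filter(records, Oracle(), TASK)
        assert [r.id for r in kept] == ["m0"]

    def test_always_wrong_backend_empty(self, stub_backend_factory):
        records = [_record(0, -7.0)]
        kept = mp.correctly_predicted_filter(
            records, stub_backend_factory(default="2"), TASK
        )
        assert kept == []

    def test_kept_fraction_equals_accuracy(self, nitro_records, nitro_task):
        backend = mp.NGramBackend(seed=0).fit(
            mp.build_prompt_pairs(nitro_records[:500], nitro_task)
        )
        test = nitro_records[500:700]
        truths = [mp.assign_class(r.properties["homo"], nitro_task) for r in test]
        preds = [mp.parse_completion(backend.complete(r.smiles), 3) for r in test]
        kept = mp.correctly_predicted_filter(test, backend, nitro_task)
        assert len(kept) / len(test) == pytest.approx(mp.accuracy(preds, truths))


def _variants(n):
    return [
        mp.AblationVariant("m0", "atom", (i,), None, f"variant{i}", "<missing>")
        for i in range(n)
    ]


class TestAgreementAnalysis:
    def test_all_agree(self, stub_backend_factory):
        backend = stub_backend_factory(default="1")
        res = mp.agreement_analysis(backend, _record(0, -5.0), _variants(4), TASK)
        assert res.n_tests == 4 and res.n_agree == 4
        assert res.agreement_rate == 1.0

    def test_one_of_three(self, stub_backend_factory):
        backend = stub_backend_factory(
            mapping={"CCO": "1", "variant0": "1", "variant1": "2", "variant2": "0"},
        )
        res = mp.agreement_analysis(backend, _record(0), _variants(3), TASK)
        assert (res.n_tests, res.n_agree) == (3, 1)
        assert res.agreement_rate == pytest.approx(1 / 3)

    def test_erroneous_counts_as_disagreement(self, stub_backend_factory):
        backend = stub_backend_factory(
            mapping={"CCO": "1", "variant0": "gibberish", "variant1": "1"},
        )
        res = mp.agreement_analysis(backend, _record(0), _variants(2), TASK)
        assert res.n_agree == 1

    def test_zero_variants_skipped(self, stub_backend_factory):
        assert mp.agreement_analysis(stub_backend_factory(), _record(0), [], TASK) is None


class TestBreakdownMatrix:
    def test_worked_example_three_tests_one_agree(self):
        matrix = mp.breakdown_matrix([mp.AgreementResult("m0", 3, 1)])
        assert matrix.cell("1-10", "(30%, 40%]") == 1
        assert matrix.total == 1

    def test_full_agreement_row(self):
        results = [mp.AgreementResult(f"m{i}", i + 1, i + 1) for i in range(5)]
        matrix = mp.breakdown_matrix(results)
        assert matrix.table.loc["100%"].sum() == 5

    def test_zero_and_hundred_rows_are_exact(self):
        results = [
            mp.AgreementResult("a", 10, 0),
            mp.AgreementResult("b", 10, 10),
            mp.AgreementResult("c", 10, 9),   # 90% -> (80%, 90%]
            mp.AgreementResult("d", 20, 19),  # 95% -> (90%, 100%)
        ]
        matrix = mp.breakdown_matrix(results)
        assert matrix.cell("1-10", "0%") == 1
        assert matrix.cell("1-10", "100%") == 1
        assert matrix.cell("1-10", "(80%, 90%]") == 1
        assert matrix.cell("11-20", "(90%, 100%)") == 1

    def test_open_ended_last_column(self):
        matrix = mp.breakdown_matrix([mp.AgreementResult("big", 200, 100)])
        assert matrix.cell(">60", "(40%, 50%]") == 1

    def test_conservation_on_random_results(self):
        rng = np.random.default_rng(0)
        results = []
        for i in range(500):
            n = int(rng.integers(1, 80))
            results.append(mp.AgreementResult(f"m{i}", n, int(rng.integers(0, n + 1))))
        assert mp.breakdown_matrix(results).total == 500


class TestConsistency:
    def test_all_match(self, stub_backend_factory):
        res = mp.consistency_analysis(
            stub_backend_factory(default="1"),
            _record(0, -5.0),
            TASK,
            variants=[f"v{i}" for i in range(10)],
        )
        assert res.level == 10 and res.n_erroneous == 0 and res.n_mismatch == 0

    def test_partition_identity(self, stub_backend_factory):
        mapping = {"CCO": "1"}
        mapping.update({f"v{i}": "1" for i in range(4)})      # match
        mapping.update({f"v{i}": "0" for i in range(4, 7)})   # valid mismatch
        mapping.update({f"v{i}": "??" for i in range(7, 10)}) # erroneous
        res = mp.consistency_analysis(
            stub_backend_factory(mapping=mapping),
            _record(0),
            TASK,
            variants=[f"v{i}" for i in range(10)],
        )
        assert (res.level, res.n_mismatch, res.n_erroneous) == (4, 3, 3)
        assert res.level + res.n_mismatch + res.n_erroneous == res.n_tests == 10

    def test_histograms_conserve_molecule_count(self):
        rng = np.random.default_rng(1)
        results = []
        for i in range(300):
            level = int(rng.integers(0, 11))
            err = int(rng.integers(0, 11 - level))
            results.append(mp.ConsistencyResult(f"m{i}", level, err))
        levels, errs = consistency_histograms(results)
        assert levels.sum() == 300
        assert errs.sum() == 300

    def test_run_consistency_skips_unenumerable(self, stub_backend_factory):
        records = [
            mp.MoleculeRecord("tiny", "C", {"homo": -5.0}, frozenset(), {}),
            mp.MoleculeRecord("ok", "c1ccc2ccccc2c1O", {"homo": -5.0}, frozenset(), {}),
        ]
        results, skipped = mp.run_consistency_analysis(
            stub_backend_factory(default="1"), records, TASK, seed=0
        )
        assert skipped == 1
        assert [r.molecule_id for r in results] == ["ok"]


class TestLearningCurve:
    def test_accuracy_rises_with_training_fraction(self, nitro_records, nitro_task):
        table = mp.run_learning_curve(
            nitro_records,
            nitro_task,
            lambda s: mp.NGramBackend(seed=s),
            fractions=[0.02, 0.5],
            seeds=[0, 1, 2],
        )
        assert list(table["fraction"]) == [0.02, 0.5]
        assert table["mean_accuracy"].iloc[1] >= table["mean_accuracy"].iloc[0]

    def test_deterministic(self, nitro_records, nitro_task):
        kwargs = dict(fractions=[0.1], seeds=[4])
        a = mp.run_learning_curve(
            nitro_records, nitro_task, lambda s: mp.NGramBackend(seed=s), **kwargs
        )
        b = mp.run_learning_curve(
            nitro_records, nitro_task, lambda s: mp.NGramBackend(seed=s), **kwargs
        )
        assert a.equals(b)


class TestAugmentationExperiment:
    def test_order_invariant_backend_ties(self, nitro_records, nitro_task, stub_backend_factory):
        """A backend whose output ignores token order entirely must show
        identical consistency in both arms."""
        report = mp.run_augmentation_experiment(
            nitro_records[:100],
            nitro_task,
            lambda s: stub_backend_factory(default="1"),
            seed=0,
        )
        assert report.mean_level_canonical == report.mean_level_augmented == 10.0

    def test_histograms_conserve_and_arms_align(self, nitro_records, nitro_task):
        report = mp.run_augmentation_experiment(
            nitro_records[:150],
            nitro_task,
            lambda s: mp.NGramBackend(n_range=(2, 3), seed=s),
            seed=1,
        )
        n = len(report.canonical_results)
        assert n == len(report.augmented_results) > 0
        lev_c, lev_a = report.level_histograms()
        err_c, err_a = report.erroneous_histograms()
        assert lev_c.sum() == lev_a.sum() == n
        assert err_c.sum() == err_a.sum() == n
        # both arms were evaluated on the same molecules
        assert [r.molecule_id for r in report.canonical_results] == [
            r.molecule_id for r in report.augmented_results
        ]
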