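import numpy as np
import pandas as pd
import pytest

import farmclock as fc
from farmclock.clock_model import lambda_path, transformed_ages, _resolve_life_histories

from conftest import small_species_specs
from test_preprocess import tiny_dataset


@pytest.fixture(scope="module")
def goat_small():
    """Single-species dataset small enough for repeated fits."""
    config = fc.GeneratorConfig(
        species_specs=(
            fc.SpeciesSpec(fc.builtin_life_history("goat"), n_samples=60,
                           age_range_days=(14.0, 3135.0)),
        ),
        n_probes=400, n_causal=20, n_shared_causal=0, n_sex_probes=6, seed=21,
    )
    return fc.generate(config)


@pytest.fixture(scope="module")
def goat_clock(goat_small):
    dataset, _ = goat_small
    return fc.fit_clock(dataset, 1, seed=4)


def overdetermined_instance(seed=0, n=50, p=5):
    rng = np.random.default_rng(seed)
    beta = rng.uniform(0.1, 0.9, size=(n, p))
    coef = rng.normal(0, 0.5, size=p)
    lh = fc.builtin_life_history("goat")
    tf = fc.AgeTransform(1, lh)
    # choose ages so the response is exactly linear in the probes
    y = beta @ coef + 7.0
    ages = np.clip(tf.inverse_transform(y), 1.0, None)
    ids = [f"s{i}" for i in range(n)]
    frame = pd.DataFrame(beta, index=pd.Index(ids, name="sample_id"),
                         columns=[f"cg{j:02d}" for j in range(p)])
    sheet = pd.DataFrame(
        {"species": "goat", "sex": "female", "age_days": ages, "batch": "chip1"},
        index=frame.index,
    )
    return fc.MethylationDataset(frame, sheet)


class TestFitLimits:
    def test_lambda_zero_limit_matches_least_squares(self):
        ds = overdetermined_instance()
        clock = fc.fit_clock(ds, 1, seed=0, lambda_grid=np.array([1e-10]))
        X = np.column_stack([np.ones(ds.n_samples), ds.beta.to_numpy()])
        y = transformed_ages(ds, 1, _resolve_life_histories(ds, None))
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert clock.intercept == pytest.approx(ols[0], abs=1e-4)
        fitted = np.array([clock.coefficients.get(p, 0.0) for p in ds.probe_ids])
        assert fitted == pytest.approx(ols[1:], abs=1e-4)

    def test_huge_lambda_gives_empty_clock(self):
        ds = overdetermined_instance()
        clock = fc.fit_clock(ds, 1, seed=0, lambda_grid=np.array([1e6]))
        assert clock.coefficients == {}
        y = transformed_ages(ds, 1, _resolve_life_histories(ds, None))
        assert clock.intercept == pytest.approx(y.mean())

    def test_zero_variance_response_rejected(self):
        ds = tiny_dataset(np.random.default_rng(0).uniform(0.2, 0.8, (12, 5)),
                          ["goat"] * 12, ages=[500.0] * 12)
        with pytest.raises(ValueError, match="zero variance"):
            fc.fit_clock(ds, 1, n_folds=3, seed=0)

    def test_fewer_samples_than_folds_rejected(self):
        ds = overdetermined_instance(n=8)
        with pytest.raises(ValueError, match="n_folds"):
            fc.fit_clock(ds, 1, n_folds=10, seed=0)

    def test_pooled_clock1_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="clock 2 or 3"):
            fc.fit_clock(small_dataset, 1, seed=0)


class TestFitRecovery:
    def test_selected_sites_cover_causal_set(self, goat_small):
        dataset, truth = goat_small
        clock = fc.fit_clock(dataset, 1, seed=4)
        causal = set(truth.causal_probes["goat"])
        selected = set(clock.coefficients)
        assert len(selected & causal) >= len(causal) * 0.5
        assert len(selected) <= 200

    def test_in_sample_fit_is_strong(self, goat_small, goat_clock):
        dataset, _ = goat_small
        pred = fc.predict_transformed(goat_clock, dataset)
        y = transformed_ages(dataset, 1, _resolve_life_histories(dataset, None))
        assert np.corrcoef(pred, y)[0, 1] >= 0.97

    def test_seed_determinism(self, goat_small):
        dataset, _ = goat_small
        c1 = fc.fit_clock(dataset, 2, seed=11)
        c2 = fc.fit_clock(dataset, 2, seed=11)
        assert c1.lambda_selected == c2.lambda_selected
        assert c1.coefficients == c2.coefficients
        assert c1.intercept == c2.intercept

    def test_penalized_objective_beats_zero_vector(self, goat_small, goat_clock):
        dataset, _ = goat_small
        X = dataset.beta.to_numpy()
        y = transformed_ages(dataset, 1, _resolve_life_histories(dataset, None))
        n = len(y)
        # objective on the standardized scale the solver works on
        mean, sd = X.mean(0), X.std(0)
        sd[sd == 0] = 1.0
        Xs = (X - mean) / sd
        coef_std = np.array(
            [goat_clock.coefficients.get(p, 0.0) for p in dataset.probe_ids]
        ) * sd
        yc = y - y.mean()

        def objective(b):
            resid = yc - Xs @ b
            lam, a = goat_clock.lambda_selected, goat_clock.alpha
            return (resid @ resid) / (2 * n) + lam * (
                a * np.abs(b).sum() + (1 - a) / 2 * (b @ b)
            )

        assert objective(coef_std) <= objective(np.zeros_like(coef_std)) + 1e-12

    def test_prediction_equivariant_under_row_permutation(self, goat_small, goat_clock):
        dataset, _ = goat_small
        pred = fc.predict_age(goat_clock, dataset)
        perm = np.random.default_rng(5).permutation(dataset.n_samples)
        shuffled = dataset.subset_samples(dataset.sample_ids[perm])
        pred_shuffled = fc.predict_age(goat_clock, shuffled)
        assert np.allclose(pred_shuffled.to_numpy(), pred.to_numpy()[perm])

    def test_sparsity_grows_as_lambda_shrinks(self, goat_small):
        """The active set is empty at lambda_max and, descending the path,
        grows in the overwhelming majority of steps (coordinate descent can
        drop the odd coefficient as correlated sites trade places)."""
        dataset, _ = goat_small
        lambdas, coefs = lambda_path(dataset, 1)
        assert np.all(np.diff(lambdas) < 0)
        counts = (coefs != 0).sum(axis=0)
        assert counts[0] == 0
        assert counts[-1] == counts.max() > 0
        assert np.mean(np.diff(counts) >= 0) >= 0.9


class TestPredict:
    def test_constant_clock_predicts_asm(self, goat_small):
        dataset, _ = goat_small
        lh = fc.builtin_life_history("goat")
        tf = fc.AgeTransform(3, lh)
        clock = fc.FittedClock(
            clock_number=3, life_histories={"goat": lh},
            intercept=tf.transform(lh.asm_days), coefficients={},
            alpha=0.5, lambda_selected=1.0,
        )
        pred = fc.predict_age(clock, dataset)
        assert np.allclose(pred, lh.asm_days)

    def test_back_transform_uses_species_constants(self, small_dataset):
        # same linear predictor, different species -> different DNAm ages
        lhs = {"goat": fc.builtin_life_history("goat"),
               "sheep": fc.builtin_life_history("sheep")}
        probe = small_dataset.probe_ids[0]
        clock = fc.FittedClock(
            clock_number=2, life_histories=lhs, intercept=-0.5,
            coefficients={str(probe): 0.3}, alpha=0.5, lambda_selected=1.0,
        )
        beta = pd.DataFrame(
            [[0.5] * small_dataset.n_probes] * 2,
            index=pd.Index(["a", "b"], name="sample_id"),
            columns=small_dataset.probe_ids,
        )
        sheet = pd.DataFrame(
            {"species": ["goat", "sheep"], "sex": "female",
             "age_days": [100.0, 100.0], "batch": "chip1"},
            index=beta.index,
        )
        ds = fc.MethylationDataset(beta, sheet)
        t = fc.predict_transformed(clock, ds)
        assert t.iloc[0] == t.iloc[1]
        ages = fc.predict_age(clock, ds)
        assert ages.iloc[0] != ages.iloc[1]

    def test_missing_probe_error_and_impute(self, goat_small, goat_clock):
        dataset, _ = goat_small
        probe = next(iter(goat_clock.coefficients))
        stripped = fc.MethylationDataset(
            dataset.beta.drop(columns=[probe]), dataset.samples.copy()
        )
        with pytest.raises(ValueError, match="absent"):
            fc.predict_transformed(goat_clock, stripped)
        pred = fc.predict_transformed(goat_clock, stripped, missing="impute")
        assert np.all(np.isfinite(pred))


class TestSummary:
    def test_empty_clock(self, goat_small):
        dataset, _ = goat_small
        lh = fc.builtin_life_history("goat")
        clock = fc.FittedClock(1, {"goat": lh}, 5.0, {}, 0.5, 1.0)
        summary = fc.summarize_clock(clock, dataset)
        assert (summary.n_sites, summary.n_positive, summary.n_negative) == (0, 0, 0)

    def test_all_positive_construction(self):
        config = fc.GeneratorConfig(
            species_specs=(
                fc.SpeciesSpec(fc.builtin_life_history("goat"), n_samples=40,
                               age_range_days=(14.0, 3135.0)),
            ),
            n_probes=200, n_causal=10, n_shared_causal=0, n_sex_probes=4,
            frac_positive=1.0, seed=13,
        )
        dataset, truth = generate_and_check(config)
        # a clock made of exactly the all-positive causal sites
        lh = fc.builtin_life_history("goat")
        clock = fc.FittedClock(
            1, {"goat": lh}, 0.0,
            {p: 0.1 for p in truth.causal_probes["goat"]}, 0.5, 1.0,
        )
        summary = fc.summarize_clock(clock, dataset)
        assert summary.n_negative == 0
        assert summary.n_sites == len(truth.causal_probes["goat"])

    def test_counts_partition_sites(self, goat_small, goat_clock):
        dataset, _ = goat_small
        summary = fc.summarize_clock(goat_clock, dataset)
        assert summary.n_positive + summary.n_negative == summary.n_sites
        assert summary.n_sites == goat_clock.n_sites


def generate_and_check(config):
    dataset, truth = fc.generate(config)
    assert dataset.is_complete()
    return dataset, truth


class TestOverlap:
    def make_clock(self, probes, species="goat"):
        lh = fc.builtin_life_history(species)
        return fc.FittedClock(
            2, {species: lh}, 0.0, {p: 0.1 for p in probes}, 0.5, 1.0
        )

    def test_identical_clocks_fully_overlap(self):
        clocks = {"a": self.make_clock(["cg1", "cg2"]), "b": self.make_clock(["cg1", "cg2"])}
        regions = fc.cpg_overlap(clocks)
        assert regions == {frozenset({"a", "b"}): ["cg1", "cg2"]}
        assert fc.shared_in_all(clocks) == ["cg1", "cg2"]

    def test_disjoint_clocks(self):
        clocks = {"a": self.make_clock(["cg1"]), "b": self.make_clock(["cg2"])}
        regions = fc.cpg_overlap(clocks)
        assert regions[frozenset({"a"})] == ["cg1"]
        assert regions[frozenset({"b"})] == ["cg2"]
        assert frozenset({"a", "b"}) not in regions
        assert fc.shared_in_all(clocks) == []

    def test_single_clock_rejected(self):
        with pytest.raises(ValueError):
            fc.cpg_overlap({"a": self.make_clock(["cg1"])})


class TestClockFile:
    def test_write_read_identical_predictions(self, tmp_path, goat_small, goat_clock):
        dataset, _ = goat_small
        path = tmp_path / "clock.csv"
        fc.write_clock(goat_clock, path)
        back = fc.read_clock(path)
        assert back.coefficients == goat_clock.coefficients
        assert back.intercept == goat_clock.intercept
        assert back.lambda_selected == goat_clock.lambda_selected
        assert back.life_histories == goat_clock.life_histories
        p1 = fc.predict_age(goat_clock, dataset)
        p2 = fc.predict_age(back, dataset)
        assert (p1.to_numpy() == p2.to_numpy()).all()
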