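import numpy as np
import pytest

from farmclock import (
    GeneratorConfig,
    MethylationDataset,
    SpeciesSpec,
    builtin_life_history,
    generate,
)


def small_species_specs(n_samples=24):
    """Two species, herd-like age ranges, small n for fast unit tests."""
    return (
        SpeciesSpec(builtin_life_history("goat"), n_samples=n_samples,
                    age_range_days=(14.0, 3135.0)),
        SpeciesSpec(builtin_life_history("sheep"), n_samples=n_samples,
                    age_range_days=(16.0, 2585.0)),
    )


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        species_specs=small_species_specs(),
        n_probes=300,
        n_causal=20,
        n_shared_causal=4,
        n_sex_probes=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_data):
    return small_data[0]


@pytest.fixture(scope="session")
def small_truth(small_data):
    return small_data[1]


@pytest.fixture(scope="session")
def default_data():
    """The default study-scale dataset: 4 species x 96 samples, 3000 probes."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def goat_dataset(default_data):
    dataset, _ = default_data
    return dataset.subset_samples(dataset.samples.index[dataset.species == "goat"])


def permute_ages(dataset: MethylationDataset, seed: int) -> MethylationDataset:
    """Break the age-methylation link by permuting ages against beta rows."""
    rng = np.random.default_rng(seed)
    sheet = dataset.samples.copy()
    sheet["age_days"] = sheet["age_days"].to_numpy()[rng.permutation(len(sheet))]
    return MethylationDataset(dataset.beta.copy(), sheet)
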