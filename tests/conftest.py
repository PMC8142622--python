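import pytest

from vinculo.preprocess import clean_registry, deduplicate
from vinculo.records import CleanRecord
from vinculo.synthetic import CorruptionConfig, derive_linked_registry, generate_population


def make_clean(record_id, full_name="", sex="", mother_name="", birth_date=None,
               municipality_code=None, nis=None):
    """Shorthand CleanRecord builder for fixtures."""
    return CleanRecord(
        record_id=record_id,
        full_name=full_name,
        sex=sex,
        mother_name=mother_name,
        birth_date=birth_date,
        municipality_code=municipality_code,
        nis=nis,
    )


@pytest.fixture(scope="session")
def zero_noise_pair():
    """Two cleaned registries with 50% overlap and zero corruption."""
    base = generate_population(200, seed=11, id_prefix="L")
    derived, gold = derive_linked_registry(base, 0.5, CorruptionConfig.none(seed=12))
    left, _ = deduplicate(clean_registry(base))
    right, _ = deduplicate(clean_registry(derived))
    return left, right, gold


@pytest.fixture(scope="session")
def noisy_pair():
    """Cleaned registries under the moderate-corruption benchmark profile."""
    base = generate_population(300, seed=21, id_prefix="L")
    derived, gold = derive_linked_registry(base, 0.5, CorruptionConfig.benchmark(seed=22))
    left, _ = deduplicate(clean_registry(base))
    right, _ = deduplicate(clean_registry(derived))
    return left, right, gold
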