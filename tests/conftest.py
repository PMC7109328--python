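import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abcident.seq_io import CANONICAL_ALPHABET, Label, ProteinRecord
from abcident.synthetic import SyntheticSpec, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_record(rng: np.random.Generator, length: int, rid: str,
                  label: Label = Label.UNLABELED) -> ProteinRecord:
    letters = rng.choice(list(CANONICAL_ALPHABET), size=length)
    return ProteinRecord(rid, "".join(letters), label)


@pytest.fixture(scope="session")
def random_records() -> list[ProteinRecord]:
    """200 uniform-alphabet records with lengths spanning 2..400."""
    rng = np.random.default_rng(20240917)
    lengths = rng.integers(2, 401, size=200)
    return [random_record(rng, int(L), f"R{i:03d}") for i, L in enumerate(lengths)]


@pytest.fixture(scope="session")
def separable_pool():
    """Strongly composition-biased two-class pool (delta = 0.3, n = 100/100)."""
    return generate_dataset(
        SyntheticSpec(n_positive=100, n_negative=100, length_range=(50, 200),
                      delta=0.3, seed=11)
    )


@pytest.fixture(scope="session")
def separable_matrix(separable_pool):
    from abcident.features import encode_dataset

    return encode_dataset(separable_pool.positives + separable_pool.negatives)
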