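import numpy as np
import pytest

from mirlog.anatomy import MatureArm, MirnaHairpin
from mirlog.features import SCORE_COLUMNS
from mirlog.simulate import SimConfig, gen_labeled_dataset


def model_xy(df):
    """Split a labeled score frame into the model matrix and label vector."""
    X = np.column_stack(
        [df[list(SCORE_COLUMNS)].to_numpy(dtype=float), df["autosomal"].to_numpy(dtype=float)]
    )
    return X, df["label"].to_numpy(dtype=int)


def _random_rna(rng, n):
    return "".join(rng.choice(["A", "C", "G", "U"], size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_mature_hairpin(rng):
    """70 nt plus-strand hairpin with matures at offsets 10-31 and 40-61."""
    return MirnaHairpin(
        id="syn-mir-a",
        chrom="chr1",
        strand="+",
        start=1000,
        end=1069,
        sequence=_random_rna(rng, 70),
        matures=[MatureArm("syn-miR-a-5p", 10, 22), MatureArm("syn-miR-a-3p", 40, 22)],
    )


@pytest.fixture
def single_mature_hairpin(rng):
    """80 nt plus-strand hairpin with one mature at offsets 5-26."""
    return MirnaHairpin(
        id="syn-mir-b",
        chrom="chr2",
        strand="+",
        start=5000,
        end=5079,
        sequence=_random_rna(rng, 80),
        matures=[MatureArm("syn-miR-b-5p", 5, 22)],
    )


@pytest.fixture(scope="session")
def separable_xy():
    """Dataset-1-shaped labeled data (24 deleterious / 219 neutral), d' = 6."""
    df = gen_labeled_dataset(SimConfig(seed=11, class_separation=6.0))
    return model_xy(df)
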