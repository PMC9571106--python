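import numpy as np
import pandas as pd
import pytest

from litterlab import (
    calibrate_cell_means, generate_feature_matrix, generate_litterbags,
)
from litterlab.core_io import FORESTS, SPECIES


@pytest.fixture(scope="session")
def calibrated_table():
    return calibrate_cell_means()


@pytest.fixture(scope="session")
def default_litterbags():
    return generate_litterbags(seed=11)


@pytest.fixture(scope="session")
def metabo_fixture():
    """Seeded default feature matrix with planted ground truth."""
    return generate_feature_matrix(seed=7)


def random_d_slice(rng: np.random.Generator, low=20.0, high=80.0) -> pd.DataFrame:
    """A random 3 x 3 species-by-forest decomposition table."""
    return pd.DataFrame(rng.uniform(low, high, size=(3, 3)),
                        index=list(SPECIES), columns=list(FORESTS))


def adh_literal(d: pd.DataFrame) -> dict[str, float]:
    """Independent transcription of the ADH definitions, term by term.

    Kept deliberately naive (explicit species/forest labels, no shared
    helpers) so it can serve as an oracle for the vectorised path.
    """
    qi, qp, ph = SPECIES
    fi, fp, fh = FORESTS
    hdd = {
        qi: (d.at[qi, fi] - d.at[qp, fi]) + (d.at[qi, fi] - d.at[ph, fi]),
        qp: (d.at[qp, fp] - d.at[qi, fp]) + (d.at[qp, fp] - d.at[ph, fp]),
        ph: (d.at[ph, fh] - d.at[qi, fh]) + (d.at[ph, fh] - d.at[qp, fh]),
    }
    add = {
        qi: (d.at[qi, fp] - d.at[qp, fp]) + (d.at[qi, fh] - d.at[ph, fh]),
        qp: (d.at[qp, fi] - d.at[qi, fi]) + (d.at[qp, fh] - d.at[ph, fh]),
        ph: (d.at[ph, fi] - d.at[qi, fi]) + (d.at[ph, fp] - d.at[qp, fp]),
    }
    h = (hdd[qi] + hdd[qp] + hdd[ph]) / 2.0
    return {s: hdd[s] - add[s] - h for s in (qi, qp, ph)}
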