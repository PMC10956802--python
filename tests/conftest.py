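import numpy as np
import pandas as pd
import pytest

from mirparc.core import compute_grid, select_interactions
from mirparc.io_matrices import ExpressionMatrix
from mirparc.preprocess import preprocess
from mirparc.synth import generate_dataset, generate_genome_fixture, make_spec


def make_matrix(values, features=None, samples=None, layer="mrna"):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), layer=layer
    )


@pytest.fixture(scope="session")
def planted_run():
    """One full pipeline run on the standard planted-repression dataset."""
    spec = make_spec(rng_seed=1)
    M, P, MI, truth = generate_dataset(spec)
    ds = preprocess(M, P, MI)
    grid = compute_grid(ds)
    table = select_interactions(grid)
    return {"spec": spec, "truth": truth, "ds": ds, "grid": grid, "table": table}


# implants cover every region on both strands; gene order alternates strand
IMPLANT_PLAN = [
    ("GENEA", "ACGUACG", "5putr"),
    ("GENEB", "CCAUGGA", "5putr"),
    ("GENEC", "GAUUACA", "cds"),
    ("GENED", "UGCAUGC", "cds"),
    ("GENEE", "AAGGCCU", "3putr"),
    ("GENEF", "CUCUAGA", "3putr"),
    ("GENEG", "GGAUCCA", "intron"),
    ("GENEH", "UUACGAA", "intron"),
    ("GENEI", "CAGUCAG", "shorter_exon"),
    ("GENEJ", "AGUCAGU", "shorter_exon"),
]


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    out = tmp_path_factory.mktemp("genome")
    return generate_genome_fixture(IMPLANT_PLAN, out, rng_seed=5)
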