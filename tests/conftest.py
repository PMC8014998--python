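import pytest

from ntails.models import TailsAnalysis
from ntails.proteins import FeatureAnnotation, ProteinDB, ProteinRecord
from ntails.simulate import (SyntheticConfig, generate_protein_db,
                             generate_tails_experiment,
                             generate_trap_experiment)

PROT1_SEQ = "MLSRRAFSTASDEKLVRAGKWTEYFDNARG"


@pytest.fixture
def prot1():
    return ProteinRecord("PROT1", PROT1_SEQ, True,
                         [FeatureAnnotation("MTS", 1, 10, "annotated")])


@pytest.fixture
def prot1_db(prot1):
    return ProteinDB([prot1])


@pytest.fixture(scope="session")
def tails_default():
    """Default synthetic TAILS study at a fixed seed, analysed end to end."""
    cfg = SyntheticConfig(seed=1)
    db, db_truth = generate_protein_db(cfg)
    dataset = generate_tails_experiment(cfg, db, db_truth)
    results = TailsAnalysis(dataset.evidence, db, dataset.protein_lfq).fit()
    return cfg, db, dataset, results


@pytest.fixture(scope="session")
def trap_default():
    cfg = SyntheticConfig(seed=7)
    matrix, truth = generate_trap_experiment(cfg)
    return cfg, matrix, truth
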