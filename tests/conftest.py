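import warnings

import numpy as np
import pytest

import meddecode as md

warnings.filterwarnings("ignore", message="n_volumes")


@pytest.fixture(scope="session")
def parcellation90():
    return md.load_parcellation()


@pytest.fixture(scope="session")
def edges90(parcellation90):
    return md.build_edge_table(parcellation90)


@pytest.fixture(scope="session")
def default_study(parcellation90):
    """Default two-group study (planted effects, seed 1), preprocessed."""
    study = md.generate_study(parcellation90, md.SimulationConfig(seed=1))
    md.preprocess_study(study)
    return study


@pytest.fixture(scope="session")
def expert_dataset(default_study):
    return md.assemble_dataset(default_study, "expert")


@pytest.fixture(scope="session")
def novice_dataset(default_study):
    return md.assemble_dataset(default_study, "novice")


@pytest.fixture(scope="session")
def expert_cv(expert_dataset):
    return md.run_cv(expert_dataset, md.CVConfig(n_repetitions=200, seed=1))


@pytest.fixture(scope="session")
def novice_cv(novice_dataset):
    return md.run_cv(novice_dataset, md.CVConfig(n_repetitions=200, seed=1))


@pytest.fixture
def toy3():
    """3-ROI toy: A/net1/left, B/net1/right, C/net2/left."""
    return md.parcellation_from_lists(
        ["A", "B", "C"], ["net1", "net1", "net2"], ["L", "R", "L"])


def make_tiny_dataset(n_subjects=8, n_edges=6, separation=0.0, seed=0,
                      samples_per_condition=2):
    """Hand-built DecodingDataset: Gaussian features, optional class shift on
    edge 0, one subject-specific offset shared across that subject's samples."""
    parc = md.toy_parcellation(4, 2)
    edge_table = md.build_edge_table(parc)
    assert edge_table.n_edges == n_edges
    rng = np.random.default_rng(seed)
    X, y, subj = [], [], []
    for s in range(n_subjects):
        offset = rng.normal(0, 0.3, size=n_edges)
        for cond in ("FA", "OM"):
            for _ in range(samples_per_condition):
                row = rng.normal(0, 1.0, size=n_edges) + offset
                if cond == "FA":
                    row[0] += separation
                else:
                    row[0] -= separation
                X.append(row)
                y.append(cond)
                subj.append(f"s{s:02d}")
    ages = {f"s{s:02d}": 30.0 + s for s in range(n_subjects)}
    return md.DecodingDataset(X=np.array(X), y=np.array(y),
                              subject=np.array(subj), group="expert",
                              edge_table=edge_table, ages=ages)
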