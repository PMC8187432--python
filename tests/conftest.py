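import numpy as np
import pytest

import mogonet as mg


@pytest.fixture(scope="session")
def trio_small():
    """A small complementary-trio dataset plus planted truth (shared, read-only)."""
    return mg.generate_complementary_trio(
        n=120, c=3, seed=7, n_features=40, n_informative=6
    )


@pytest.fixture(scope="session")
def quick_cfg():
    """A fast training configuration for unit tests."""
    return mg.RunConfig(
        k=3, gcn_hidden=[16], pretrain_epochs=40, joint_epochs=60, seed=7
    )


def split_dataset(data, test_fraction=0.3, seed=0):
    from sklearn.model_selection import StratifiedShuffleSplit

    ids = np.array(data.sample_ids)
    sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    tr_idx, te_idx = next(sss.split(ids, data.labels.labels))
    return data.subset(list(ids[tr_idx])), data.subset(list(ids[te_idx]))


@pytest.fixture(scope="session")
def trio_model(trio_small, quick_cfg):
    """A trained model with its train/test split (shared across tests)."""
    data, truth = trio_small
    train, test = split_dataset(data, seed=7)
    model = mg.fit(train, quick_cfg)
    return model, train, test, truth
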