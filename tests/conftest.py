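import numpy as np
import pytest

from biodrop import (BioDropClassifier, SimConfig, TrainConfig, apply_scaler,
                     fit_scaler, simulate_cohort, split_train_test, train_model)
from biodrop.nn import MaskedDualNet


SMALL_SIM = dict(n_samples=240, n_snps=30, n_tfs=10, n_genes=12,
                 density_eqtl=0.15, density_grn=0.3, n_causal_genes=2,
                 n_causal_snps=6)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick planted cohort small enough for repeated training in tests."""
    return simulate_cohort(SimConfig(seed=7, **SMALL_SIM))


@pytest.fixture(scope="session")
def small_scaled(small_cohort):
    c = small_cohort
    y = c["labels"]
    ids = c["genotypes"].sample_ids
    tr_ids, _ = split_train_test(ids, y, ratio=0.8, seed=7)
    tr = np.isin(ids, tr_ids)
    sa = fit_scaler(c["genotypes"].values[tr])
    sb = fit_scaler(c["expression"].values[tr])
    return {"Xa": apply_scaler(c["genotypes"].values, sa),
            "Xb": apply_scaler(c["expression"].values, sb),
            "y": y, "train": tr, "mask_a": c["mask_a"], "mask_b": c["mask_b"],
            "truth": c["truth"]}


@pytest.fixture(scope="session")
def quick_config():
    return TrainConfig(seed=3, max_epochs=40, patience=8)


@pytest.fixture(scope="session")
def trained_small(small_scaled, quick_config):
    d = small_scaled
    tr = d["train"]
    est, _ = train_model(d["Xa"][tr], d["Xb"][tr], d["y"][tr],
                         (d["mask_a"], d["mask_b"]), quick_config)
    return est


def make_tiny_net(seed=0, activation="relu", hidden=(3,), dropout=0.0,
                  la=4, nb=3, p=3, n_classes=2, density=0.7):
    rng = np.random.default_rng(seed)
    ma = (rng.random((la, p)) < density).astype(float)
    mb = (rng.random((nb, p)) < density).astype(float)
    ma[0, :] = 1.0  # guarantee some connectivity
    mb[0, :] = 1.0
    return MaskedDualNet(ma, mb, hidden_sizes=hidden, n_classes=n_classes,
                         dropout_rate=dropout, activation=activation,
                         rng=np.random.default_rng(seed + 1))
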