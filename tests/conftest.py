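import numpy as np
import pytest

from pcppn import (AugmentationSpec, EmbeddingTrainConfig, NetworkConfig,
                   SynthSpec, TrainingConfig, augment, balance_by_oversampling,
                   cluster_per_class, extract_embeddings, fit,
                   generate_imageset, make_pseudo_labels, preprocess,
                   train_embedding_backbone)

SEED = 1


@pytest.fixture(scope="session")
def fixture_data():
    """Planted 2-class / 2-sub-mode image set, confound off, with truth table."""
    spec = SynthSpec(q=2, K_true=2, n_per_mode=25, side=64, seed=SEED)
    ds, truth = generate_imageset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def split_sets(fixture_data):
    """Preprocessed train (folds != 0) and test (fold 0) splits."""
    ds, _ = fixture_data
    train = preprocess(ds.subset(ds.fold != 0), 64)
    test = preprocess(ds.subset(ds.fold == 0), 64)
    return train, test


@pytest.fixture(scope="session")
def blackbox(split_sets):
    train, _ = split_sets
    return train_embedding_backbone(train, EmbeddingTrainConfig(epochs=5, seed=SEED))


@pytest.fixture(scope="session")
def pseudo_labeled_train(split_sets, blackbox):
    """Train split with K=2 pseudo-labels, balanced and once-augmented."""
    train, _ = split_sets
    feats = extract_embeddings(blackbox, train)
    clusters = cluster_per_class(feats, train.labels, 2, seed=SEED)
    pseudo, pmap = make_pseudo_labels(train.labels, clusters, 2)
    labeled = train.with_pseudo_labels(pseudo)
    target = int(np.bincount(labeled.pseudo_labels).max())
    balanced = balance_by_oversampling(labeled, target, key="pseudo_label", seed=SEED)
    return augment(balanced, AugmentationSpec(multiplier=1, seed=SEED)), pmap


@pytest.fixture(scope="session")
def trained_model(pseudo_labeled_train, split_sets):
    """Fully trained part-prototype model (3 cycles of joint/push/head)."""
    train, pmap = pseudo_labeled_train
    _, test = split_sets
    net_cfg = NetworkConfig(backbone="tiny", input_side=64, D=32,
                            M_per_class=10, C=pmap.n_pseudo)
    tr_cfg = TrainingConfig(seed=SEED)
    model, history = fit(train, test, net_cfg, tr_cfg, pseudo_map=pmap)
    return model, history


@pytest.fixture()
def tiny_net():
    """Untrained small network on a 4x4 feature grid (64px input)."""
    from pcppn import PCPPNet, PseudoLabelMap
    cfg = NetworkConfig(backbone="tiny", input_side=64, D=8, M_per_class=2, C=4)
    return PCPPNet(cfg, pseudo_map=PseudoLabelMap(q=2, K=2), seed=SEED)
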