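"""Run configuration and the end-to-end pipeline.

The pipeline follows the method's order: preprocess -> train black-box
embedder -> per-class K-means -> pseudo-relabel -> balance/augment ->
three-stage part-prototype training -> remap & evaluate (-> explain/probe).
One master seed fans out to named sub-seeds so each stochastic component
can be perturbed independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import imageset_io as iio
from .imageset_io import AugmentationSpec, LabeledImageSet
from .inference_eval import evaluate
from .interpretability import confounding_probe, explain_prototype, overlay_figure
from .protonet_core import NetworkConfig, PCPPNet
from .pseudo_class import (EmbeddingTrainConfig, cluster_per_class,
                           extract_embeddings, make_pseudo_labels,
                           train_embedding_backbone)
from .synthetic_fixtures import SynthSpec, generate_imageset
from .training import TrainingConfig, fit


def derive_seed(master: int, name: str) -> int:
    """Stable named sub-seed in [0, 2^31) derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs. Unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "pcppn_run"
    manifest: str | None = None          # if None, synth generates the data
    image_root: str | None = None
    synth: SynthSpec = field(default_factory=SynthSpec)
    test_fold: int = 0
    side: int = 64                       # preprocessing side length
    K: int = 2                           # clusters (pseudo-classes) per class
    balance_target: int = 0              # 0 -> max group size
    use_augmentation: bool = True
    augmentation: AugmentationSpec = field(default_factory=lambda: AugmentationSpec(multiplier=1))
    embed: EmbeddingTrainConfig = field(default_factory=EmbeddingTrainConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    run_explain: bool = False
    run_probe: bool = False

    _NESTED = {"synth": SynthSpec, "augmentation": AugmentationSpec,
               "embed": EmbeddingTrainConfig, "network": NetworkConfig,
               "training": TrainingConfig}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for key, sub_cls in cls._NESTED.items():
            if key in d:
                sub = d.pop(key)
                try:
                    kwargs[key] = sub_cls(**sub)
                except TypeError as exc:
                    raise ValueError(f"bad {key!r} section: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        # round-trip through JSON so tuples become lists (YAML-safe)
        return json.loads(json.dumps(dataclasses.asdict(self)))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _split(ds: LabeledImageSet, test_fold: int):
    return ds.subset(ds.fold != test_fold), ds.subset(ds.fold == test_fold)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and write artifacts under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    # -- data -------------------------------------------------------------
    truth = None
    if cfg.manifest is not None:
        root = cfg.image_root or str(Path(cfg.manifest).parent)
        ds = iio.load_manifest(cfg.manifest, root)
    else:
        spec = dataclasses.replace(cfg.synth, seed=derive_seed(cfg.seed, "synth"))
        ds, truth = generate_imageset(spec)
        truth.to_csv(out / "ground_truth.csv", index=False)
    train_raw, test_raw = _split(ds, cfg.test_fold)
    train = iio.preprocess(train_raw, cfg.side)
    test = iio.preprocess(test_raw, cfg.side)
    summary["n_train"], summary["n_test"] = train.n, test.n

    # -- black-box embedding + per-class clustering ------------------------
    embed_cfg = dataclasses.replace(cfg.embed, seed=derive_seed(cfg.seed, "embed"))
    embed_train = train
    if cfg.use_augmentation:
        aug = dataclasses.replace(cfg.augmentation,
                                  seed=derive_seed(cfg.seed, "embed-aug"))
        embed_train = iio.augment(train, aug)
    blackbox = train_embedding_backbone(embed_train, embed_cfg)
    feats = extract_embeddings(blackbox, train)
    clusters = cluster_per_class(feats, train.labels, cfg.K,
                                 seed=derive_seed(cfg.seed, "kmeans"))
    pseudo, pmap = make_pseudo_labels(train.labels, clusters, cfg.K)
    train = train.with_pseudo_labels(pseudo)
    pmap.save(out / "pseudo_map.json")

    # -- balance / augment over pseudo-classes -----------------------------
    counts = np.bincount(train.pseudo_labels, minlength=pmap.n_pseudo)
    target = cfg.balance_target or int(counts.max())
    train = iio.balance_by_oversampling(train, target, key="pseudo_label",
                                        seed=derive_seed(cfg.seed, "balance"))
    if cfg.use_augmentation:
        aug = dataclasses.replace(cfg.augmentation,
                                  seed=derive_seed(cfg.seed, "augment"))
        train = iio.augment(train, aug)

    # -- part-prototype training -------------------------------------------
    net_cfg = dataclasses.replace(cfg.network, C=pmap.n_pseudo, input_side=cfg.side)
    train_cfg = dataclasses.replace(cfg.training, seed=derive_seed(cfg.seed, "fit"))
    model, history = fit(train, test, net_cfg, train_cfg, pseudo_map=pmap)
    model.save(out / "model.ckpt")
    summary["history"] = {"joint_loss": history["joint_loss"],
                          "val_accuracy": history["val_accuracy"]}

    # -- evaluation ---------------------------------------------------------
    report = evaluate(test, model, fold=cfg.test_fold)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    summary["report"] = report.to_dict()

    # -- interpretability ----------------------------------------------------
    if cfg.run_explain:
        expl_dir = out / "explanations"
        expl_dir.mkdir(exist_ok=True)
        records = []
        for j in range(model.bank.M):
            expl = explain_prototype(model, train, j)
            idx = train.ids.index(expl.source_image_id)
            overlay_figure(expl, iio.denormalize(train.images[idx]),
                           expl_dir / f"prototype_{j}.png")
            records.append({"prototype": j, "source": expl.source_image_id,
                            "box": list(expl.box),
                            "max_similarity": expl.max_similarity})
        (expl_dir / "explanations.json").write_text(json.dumps(records, indent=1))
    if cfg.run_probe:
        if truth is None:
            raise ValueError("the confounding probe needs fixture ground truth")
        probe = confounding_probe(model, train, truth)
        probe_out = {k: v for k, v in probe.items() if k != "iou_per_prototype"}
        (out / "probe.json").write_text(json.dumps(probe_out, indent=1))
        summary["probe"] = probe_out

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
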