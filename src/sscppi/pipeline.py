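"""End-to-end orchestration: encode pair lists, run training experiments,
and sweep the channel x kernel-scale ablation grid."""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dataset import (
    DatasetSplit,
    InteractionPair,
    ProteinRecord,
    assemble_negatives,
    make_splits,
)
from .encoding import EncodingConfig, encode_interaction
from .metrics import MetricsReport, compute_metrics
from .model import (
    CHANNEL_VARIANTS,
    KERNEL_SCALE_GROUPS,
    ModelConfig,
    TrainedClassifier,
    build_cnn_2d,
    predict,
    train,
)

__all__ = [
    "encode_pairs",
    "build_labeled_dataset",
    "run_training_experiment",
    "run_ablation_grid",
]


def encode_pairs(
    pairs: Sequence[InteractionPair],
    records: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    config: EncodingConfig = EncodingConfig(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Encode a pair list into a stacked tensor array and its label vector.

    Returns ``(tensors, labels)`` with tensors of shape
    (n_pairs, grid_side, grid_side, n_channels), float32.
    """
    by_id = (
        dict(records)
        if isinstance(records, Mapping)
        else {r.id: r for r in records}
    )
    n = len(pairs)
    out = np.zeros(
        (n, config.grid_side, config.grid_side, config.n_channels), dtype=np.float32
    )
    labels = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(pairs):
        for pid in (p.id_a, p.id_b):
            if pid not in by_id:
                raise KeyError(f"pair references unknown protein {pid!r}")
        t = encode_interaction(
            by_id[p.id_a].sequence,
            by_id[p.id_b].sequence,
            config,
            pair_ids=(p.id_a, p.id_b),
        )
        out[i] = t.values
        labels[i] = p.label
    return out, labels


def build_labeled_dataset(
    records: Sequence[ProteinRecord],
    positives: Sequence[InteractionPair],
    seed: int = 0,
    negative_mix: Optional[Mapping[str, float]] = None,
    test_fraction: float = 0.20,
    k: int = 5,
) -> Tuple[DatasetSplit, List[ProteinRecord]]:
    """Balance positives with assembled negatives and split 80/20 + k folds.

    Returns the split and the full record list including synthesized
    edited-negative variants.
    """
    negatives, variants = assemble_negatives(
        positives, records, total=len(positives), mix=negative_mix, seed=seed
    )
    split = make_splits(
        list(positives) + negatives, test_fraction=test_fraction, k=k, seed=seed
    )
    return split, list(records) + variants


def run_training_experiment(
    records: Sequence[ProteinRecord],
    split: DatasetSplit,
    encoding_config: EncodingConfig = EncodingConfig(),
    model_config: Optional[ModelConfig] = None,
    epochs: Optional[int] = None,
    augment_swap: bool = True,
    verbose: bool = False,
) -> Tuple[TrainedClassifier, MetricsReport]:
    """Encode a split, train the 2D CNN on its training set and report
    held-out test metrics.

    ``augment_swap`` additionally trains on the (b, a) orientation of every
    training pair: interaction databases record both orientations as
    distinct entries, and the context channel makes the two tensors carry
    different features, so the swap is a natural data augmentation.  The
    test set is never augmented.
    """
    if model_config is None:
        model_config = ModelConfig(
            input_channels=encoding_config.n_channels,
            grid_side=encoding_config.grid_side,
        )
    if model_config.input_channels != encoding_config.n_channels:
        model_config = replace(
            model_config, input_channels=encoding_config.n_channels
        )
    train_pairs = list(split.train)
    if augment_swap:
        train_pairs += [
            InteractionPair(p.id_b, p.id_a, p.label, p.provenance)
            for p in split.train
        ]
    x_train, y_train = encode_pairs(train_pairs, records, encoding_config)
    x_test, y_test = encode_pairs(split.test, records, encoding_config)
    clf = build_cnn_2d(model_config)
    train(clf, x_train, y_train, epochs=epochs, validation=(x_test, y_test), verbose=verbose)
    scores = predict(clf, x_test)
    return clf, compute_metrics(y_test, scores)


def run_ablation_grid(
    records: Sequence[ProteinRecord],
    split: DatasetSplit,
    channel_variants: Sequence[Tuple[str, ...]] = CHANNEL_VARIANTS,
    kernel_groups: Sequence[str] = tuple(KERNEL_SCALE_GROUPS),
    base_encoding: EncodingConfig = EncodingConfig(),
    base_model: Optional[ModelConfig] = None,
    epochs: Optional[int] = None,
    verbose: bool = False,
) -> Dict[Tuple[str, str], MetricsReport]:
    """Train/evaluate every (channel variant, kernel group) combination.

    Mirrors the published two experiment grids: channel ablations
    [S1], [S1,S2], [S1,C], [S1,S2,C] and kernel-scale groups 32/64 ...
    256/512.  Returns a report per cell keyed by
    ("+"-joined channels, kernel group).
    """
    if base_model is None:
        base_model = ModelConfig()
    results: Dict[Tuple[str, str], MetricsReport] = {}
    for channels in channel_variants:
        enc = EncodingConfig(
            max_len=base_encoding.max_len,
            min_len=base_encoding.min_len,
            grid_side=base_encoding.grid_side,
            channels=tuple(channels),
            nonstandard_policy=base_encoding.nonstandard_policy,
            alphabet=base_encoding.alphabet,
        )
        for group in kernel_groups:
            cfg = replace(
                base_model,
                kernel_scale_group=group,
                input_channels=enc.n_channels,
                grid_side=enc.grid_side,
            )
            _, report = run_training_experiment(
                records, split, enc, cfg, epochs=epochs, verbose=verbose
            )
            results[("+".join(enc.channels), group)] = report
    return results
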