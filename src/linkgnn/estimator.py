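"""Scikit-learn style estimators wrapping the subgraph classifier.

:class:`SubgraphGNNClassifier` is the core fit/predict object: its samples
are labeled enclosing subgraphs.  :class:`BipartiteLinkPredictor` layers the
extraction pipeline on top, so it can be fit directly on an association
matrix and score arbitrary candidate pairs.  Both follow the scikit-learn
estimator contract (``get_params``/``set_params``, fitted attributes with a
trailing underscore, ``clone``-ability), so they compose with sklearn model
selection utilities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .data import AssociationMatrix, PairSample, sample_negative_pairs
from .model import ModelConfig, TrainedModel
from .subgraph import LabeledSubgraph, LabelEncoding, batch_extract

__all__ = ["SubgraphGNNClassifier", "BipartiteLinkPredictor"]


class SubgraphGNNClassifier(ClassifierMixin, BaseEstimator):
    """Graph classifier over labeled enclosing subgraphs.

    Aggregates the configured propagation operators in every graph
    convolution layer, concatenates all layer outputs per node, sort-pools
    to a fixed-size tensor and reads out with a small 1-D convolutional
    network trained under the negative log-likelihood loss.

    Parameters mirror :class:`~linkgnn.model.ModelConfig` plus the
    optimization settings; ``pooling_k`` may be a fraction in (0, 1)
    resolved as that quantile of the training subgraph sizes.
    """

    def __init__(
        self,
        propagators: tuple[str, ...] = nn.ALL_PROPAGATORS,
        conv_dims: tuple[int, ...] = (32, 32, 1),
        pooling_k: int | float | None = 0.6,
        conv1_channels: int = 16,
        conv2_channels: int = 32,
        conv2_kernel: int = 5,
        dense_units: int = 128,
        activation: str = "tanh",
        epochs: int = 50,
        batch_size: int = 50,
        learning_rate: float = 1e-4,
        seed: int = 0,
        dtype: str = "float32",
    ):
        self.propagators = propagators
        self.conv_dims = conv_dims
        self.pooling_k = pooling_k
        self.conv1_channels = conv1_channels
        self.conv2_channels = conv2_channels
        self.conv2_kernel = conv2_kernel
        self.dense_units = dense_units
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.dtype = dtype

    @classmethod
    def from_config(cls, config: ModelConfig, spec) -> "SubgraphGNNClassifier":
        return cls(
            propagators=config.propagators,
            conv_dims=config.conv_dims,
            pooling_k=config.pooling_k,
            conv1_channels=config.conv1_channels,
            conv2_channels=config.conv2_channels,
            conv2_kernel=config.conv2_kernel,
            dense_units=config.dense_units,
            activation=config.activation,
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            learning_rate=spec.learning_rate,
            seed=spec.seed,
        )

    def _config(self) -> ModelConfig:
        return ModelConfig(
            propagators=tuple(self.propagators),
            conv_dims=tuple(self.conv_dims),
            pooling_k=self.pooling_k,
            conv1_channels=self.conv1_channels,
            conv2_channels=self.conv2_channels,
            conv2_kernel=self.conv2_kernel,
            dense_units=self.dense_units,
            activation=self.activation,
            seed=self.seed,
        )

    def fit(self, X: Sequence[LabeledSubgraph], y=None):
        """Train on a list of labeled subgraphs.

        ``y`` defaults to each subgraph's stored ``true_label``.
        """
        X = list(X)
        if y is None:
            y = np.array([g.true_label for g in X], dtype=np.int64)
        else:
            y = np.asarray(y, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(np.unique(y)) < 2:
            raise ValueError("training set needs both classes")
        widths = {g.features.shape[1] for g in X}
        if len(widths) != 1:
            raise ValueError("inconsistent feature widths across subgraphs")
        config = self._config()
        rng = np.random.default_rng(self.seed)
        # honor an explicit y that may differ from the stored labels
        relabeled = [
            g if g.true_label == int(lab) else _with_label(g, int(lab))
            for g, lab in zip(X, y)
        ]
        k = nn.resolve_pooling_k(config, [g.n_nodes for g in relabeled])
        dtype = np.dtype(self.dtype)
        batches = nn.make_batches(
            relabeled, self.batch_size, prop_names=config.propagators, rng=rng,
            dtype=dtype,
        )
        params, history = nn.train_network(
            batches,
            config,
            k=k,
            feature_width=widths.pop(),
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            seed=self.seed,
            dtype=dtype,
        )
        self.model_ = TrainedModel(
            config=config,
            parameters=params,
            resolved_k=k,
            feature_width=relabeled[0].features.shape[1],
        )
        self.resolved_k_ = k
        self.feature_width_ = self.model_.feature_width
        self.loss_history_ = history
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: Sequence[LabeledSubgraph]) -> np.ndarray:
        self._check_fitted()
        X = list(X)
        if not X:
            return np.zeros((0, 2))
        batches = nn.make_batches(
            X, batch_size=64, prop_names=self.model_.config.propagators
        )
        out = []
        for b in batches:
            logp, _ = nn.net_forward(
                self.model_.parameters, self.model_.config, b, self.resolved_k_
            )
            out.append(np.exp(logp))
        return np.concatenate(out)

    def predict(self, X: Sequence[LabeledSubgraph]) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")


def _with_label(g: LabeledSubgraph, label: int) -> LabeledSubgraph:
    return LabeledSubgraph(
        adj=g.adj, sides=g.sides, global_indices=g.global_indices,
        labels=g.labels, features=g.features, h=g.h, true_label=label,
    )


class BipartiteLinkPredictor(BaseEstimator):
    """End-to-end link predictor over a bipartite association matrix.

    ``fit`` takes the association matrix itself: positives are its recorded
    associations, negatives an equal number of uniformly sampled zero
    entries (or pass explicit ``pairs``).  Scoring extracts each candidate
    pair's h-hop enclosing subgraph — with the pair's own edge masked — and
    classifies it.
    """

    def __init__(
        self,
        h: int = 2,
        label_cap: int = 50,
        distance_scope: str = "subgraph",
        classifier: SubgraphGNNClassifier | None = None,
        seed: int = 0,
    ):
        self.h = h
        self.label_cap = label_cap
        self.distance_scope = distance_scope
        self.classifier = classifier
        self.seed = seed

    def fit(self, Y: AssociationMatrix, pairs: Sequence[PairSample] | None = None):
        if pairs is None:
            pos = Y.positive_pairs()
            neg = sample_negative_pairs(Y, len(pos), seed=self.seed)
            pairs = pos + neg
        encoding = LabelEncoding(cap=self.label_cap)
        subs = batch_extract(Y, list(pairs), self.h, encoding,
                             distance_scope=self.distance_scope)
        clf = self.classifier if self.classifier is not None else SubgraphGNNClassifier(seed=self.seed)
        from sklearn.base import clone

        self.classifier_ = clone(clf)
        self.classifier_.fit(subs)
        self.encoding_ = encoding
        self.train_matrix_ = Y
        return self

    def score_pairs(
        self, pairs: Sequence[tuple[int, int]], Y: AssociationMatrix | None = None
    ) -> np.ndarray:
        """Association probability for each (row, col) pair."""
        self._check_fitted()
        from .evaluate import predict_pairs

        mat = Y if Y is not None else self.train_matrix_
        return predict_pairs(self.classifier_.model_, mat, list(pairs), self.h)

    def rank_candidates(self, target: str, Y: AssociationMatrix | None = None):
        """Ranked unobserved side-A partners of one side-B entity."""
        self._check_fitted()
        from .evaluate import rank_candidates

        mat = Y if Y is not None else self.train_matrix_
        return rank_candidates(self.classifier_.model_, mat, target, self.h)

    def _check_fitted(self) -> None:
        if not hasattr(self, "classifier_"):
            raise RuntimeError("estimator is not fitted")
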