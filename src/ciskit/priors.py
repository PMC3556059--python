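"""Positional priors: construction, discriminative conversion, trainable
priors generators, and merit evaluation.

A positional prior assigns every sequence position a value in [0, 1]
expressing belief that the position lies inside a functional binding
site.  Any numeric evidence track (conservation, DNase signal, ...) can
be rescaled into a prior; several priors can be combined by weighted
sums (:func:`ciskit.ops.combine_tracks`); and a *priors generator* — a
small per-position classifier — can be trained on sequences with known
binding sites to map arbitrary feature combinations to a prior, then
applied to any new sequence annotated with the same features.

The merit of a prior is measured by how well it separates binding-site
positions from background positions, summarized as ROC / AUC.
"""

from __future__ import annotations

import json
import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .core import (CiskitError, Collection, NumericTrack, RegionTrack,
                   SequenceSet)
from .ops import regions_to_numeric, sliding_window

logger = logging.getLogger("ciskit")

DEFAULT_WINDOWS = (1, 11, 101)  # point, local and broad context means


class PriorsTrack(NumericTrack):
    """A numeric track constrained to values in [0, 1]."""

    def __init__(self, sequences, data):
        super().__init__(sequences, data)
        for name, v in self.data.items():
            if np.any(v < 0) or np.any(v > 1):
                raise CiskitError(f"prior values outside [0,1] in sequence {name!r}")


def normalize_priors(track: NumericTrack) -> PriorsTrack:
    """Min-max rescale a numeric track to [0, 1] jointly over all
    sequences; a constant track maps to all 0.5 (with a warning)."""
    allv = np.concatenate([track[n] for n in track.names])
    mn, mx = float(allv.min()), float(allv.max())
    if mx == mn:
        logger.warning("normalize_priors: constant track; mapping to 0.5")
        return PriorsTrack(track.sequences,
                           {n: np.full_like(track[n], 0.5) for n in track.names})
    return PriorsTrack(track.sequences,
                       {n: (track[n] - mn) / (mx - mn) for n in track.names})


def discriminative_prior(priors: PriorsTrack, control_mean: float) -> PriorsTrack:
    """Convert a prior into a discriminative prior that contrasts each
    position against a background expectation q:

        d = p (1 - q) / (p (1 - q) + q (1 - p))

    The map fixes 0 and 1, sends p = q to 0.5, and preserves order for
    any q in (0, 1).  ``control_mean`` is typically the mean prior over
    a control sequence set (see :func:`control_mean`).
    """
    q = float(control_mean)
    if not (0.0 < q < 1.0):
        raise CiskitError("control mean must lie strictly inside (0, 1)")
    out = {}
    for name in priors.names:
        p = priors[name]
        out[name] = p * (1 - q) / (p * (1 - q) + q * (1 - p))
    return PriorsTrack(priors.sequences, out)


def control_mean(priors: NumericTrack,
                 control: Optional[Collection] = None) -> float:
    names = list(control) if control is not None else priors.names
    return float(np.mean(np.concatenate([priors[n] for n in names])))


# ------------------------------------------------------------- the generator

def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class _Network:
    """One feed-forward member network with its own input scaling."""

    def __init__(self, norm_lo, norm_hi, weights, biases):
        self.norm_lo = np.asarray(norm_lo, dtype=float)
        self.norm_hi = np.asarray(norm_hi, dtype=float)
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]

    def predict(self, X: np.ndarray) -> np.ndarray:
        span = self.norm_hi - self.norm_lo
        span = np.where(span == 0, 1.0, span)
        a = (X - self.norm_lo) / span
        for W, b in zip(self.weights, self.biases):
            a = _logistic(a @ W + b)
        return a[:, 0]

    def to_dict(self) -> dict:
        return {"norm_lo": self.norm_lo.tolist(),
                "norm_hi": self.norm_hi.tolist(),
                "weights": [w.tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases]}

    @classmethod
    def from_dict(cls, d: dict) -> "_Network":
        return cls(np.array(d["norm_lo"]), np.array(d["norm_hi"]),
                   [np.array(w) for w in d["weights"]],
                   [np.array(b) for b in d["biases"]])


class PriorsGenerator:
    """A trained per-position classifier mapping feature-track values to
    a binding-site prior in [0, 1].

    The feature vector of a position is the centered windowed mean of
    each input feature at each configured window size.  The classifier
    is a small bagged ensemble of feed-forward networks (one hidden
    layer of logistic units each); every member was trained on its own
    seeded negative subsample and min-max input scaling, and the prior
    is the mean of the member probabilities.  Weights are stored as
    explicit matrices, so applying a reloaded generator is bit-identical
    to applying the original.
    """

    def __init__(self, feature_names: List[str], windows: Sequence[int],
                 networks: List[_Network], metadata: Optional[dict] = None):
        self.feature_names = list(feature_names)
        self.windows = list(windows)
        self.networks = list(networks)
        self.metadata = metadata or {}

    # feature construction -------------------------------------------------
    def _feature_matrix(self, features: Mapping[str, NumericTrack],
                        seq_name: str) -> np.ndarray:
        cols = []
        for fname in self.feature_names:
            if fname not in features:
                raise CiskitError(f"required feature {fname!r} is missing")
            track = features[fname]
            for w in self.windows:
                smoothed = track if w == 1 else sliding_window(track, "mean", w)
                cols.append(smoothed[seq_name])
        return np.column_stack(cols)

    def apply(self, features: Mapping[str, NumericTrack]) -> PriorsTrack:
        """Generate a priors track for any sequences carrying the
        features this generator was trained on."""
        for fname in self.feature_names:
            if fname not in features:
                raise CiskitError(f"required feature {fname!r} is missing")
        base = features[self.feature_names[0]]
        out = {}
        for name in base.names:
            X = self._feature_matrix(features, name)
            out[name] = np.mean([net.predict(X) for net in self.networks], axis=0)
        return PriorsTrack(base.sequences, out)

    # serialization --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "feature_names": self.feature_names,
            "windows": self.windows,
            "networks": [net.to_dict() for net in self.networks],
            "metadata": self.metadata,
        })

    @classmethod
    def from_json(cls, text: str) -> "PriorsGenerator":
        d = json.loads(text)
        return cls(d["feature_names"], d["windows"],
                   [_Network.from_dict(n) for n in d["networks"]],
                   d.get("metadata"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PriorsGenerator":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train_priors_generator(features: Mapping[str, NumericTrack],
                           target: RegionTrack,
                           seed: int,
                           training_sequences: Optional[Iterable[str]] = None,
                           windows: Sequence[int] = DEFAULT_WINDOWS,
                           negative_ratio: float = 1.0,
                           hidden_units: int = 8,
                           max_iter: int = 500,
                           tol: float = 1e-4,
                           n_members: int = 3,
                           alpha: float = 1e-3) -> PriorsGenerator:
    """Train a priors generator on sequences with a known answer track.

    Every position of every training sequence becomes an example: its
    feature vector is the windowed means of each feature, its label is 1
    iff the position lies inside a target region.  Each of the
    ``n_members`` ensemble members subsamples its own negatives to
    ``negative_ratio`` negatives per positive (default 1:1, seeded) and
    trains a single-hidden-layer network of ``hidden_units`` logistic
    units (L2 penalty ``alpha``) to convergence tolerance ``tol`` or
    ``max_iter`` epochs; the generator output averages the members,
    which tames the variance of any single subsample and fit.

    This one call covers the wizard steps: select target, select input
    features, build the training set, train, and (via ``save``) store.
    """
    from sklearn.neural_network import MLPClassifier

    if seed is None:
        raise CiskitError("training requires a seed")
    feature_names = list(features)
    if not feature_names:
        raise CiskitError("need at least one input feature")
    base = features[feature_names[0]]
    names = list(training_sequences) if training_sequences is not None else base.names

    proto = PriorsGenerator(feature_names, windows, [])
    coverage = regions_to_numeric(target, "coverage")
    X_parts, y_parts = [], []
    for name in names:
        X_parts.append(proto._feature_matrix(features, name))
        y_parts.append((coverage[name] > 0).astype(int))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if pos_idx.size == 0:
        raise CiskitError("target track has no positive positions on the training set")

    networks = []
    for member in range(max(1, n_members)):
        member_seed = (int(seed) * 100 + member) % (2 ** 31)
        rng = np.random.default_rng(member_seed)
        n_neg = min(neg_idx.size, int(round(pos_idx.size * negative_ratio)))
        keep_neg = rng.choice(neg_idx, size=n_neg, replace=False)
        idx = np.sort(np.concatenate([pos_idx, keep_neg]))
        Xs, ys = X[idx], y[idx]
        lo, hi = Xs.min(axis=0), Xs.max(axis=0)
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        clf = MLPClassifier(hidden_layer_sizes=(hidden_units,),
                            activation="logistic", solver="lbfgs",
                            max_iter=max_iter, tol=tol, alpha=alpha,
                            random_state=member_seed)
        clf.fit((Xs - lo) / span, ys)
        networks.append(_Network(lo, hi, [np.asarray(w) for w in clf.coefs_],
                                 [np.asarray(b) for b in clf.intercepts_]))

    n_train = int(pos_idx.size * (1 + negative_ratio))
    return PriorsGenerator(
        feature_names, list(windows), networks,
        metadata={"seed": int(seed), "n_members": len(networks),
                  "n_examples_per_member": n_train,
                  "positive_fraction": float(1 / (1 + negative_ratio)),
                  "windows": list(windows)})


def apply_priors_generator(pg: PriorsGenerator,
                           features: Mapping[str, NumericTrack]) -> PriorsTrack:
    return pg.apply(features)


# --------------------------------------------------------------- evaluation

def evaluate_priors(priors: NumericTrack, answer: RegionTrack) -> Dict[str, object]:
    """Merit of a prior (or any numeric track) against an answer track.

    Every position is labeled positive iff inside an answer region; AUC
    is the Mann-Whitney rank statistic with midrank tie correction, and
    ROC points are reported at every distinct score threshold.
    """
    coverage = regions_to_numeric(answer, "coverage")
    scores = np.concatenate([priors[n] for n in priors.names])
    labels = np.concatenate([(coverage[n] > 0).astype(int) for n in priors.names])
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise CiskitError("evaluation needs both positive and negative positions")
    ranks = rankdata(scores)  # midranks for ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    distinct = np.flatnonzero(np.diff(sorted_scores, append=np.nan) != 0)
    roc = [(0.0, 0.0)] + [(fp[i] / n_neg, tp[i] / n_pos) for i in distinct]
    return {"auc": float(auc), "roc_points": roc,
            "n_pos": n_pos, "n_neg": n_neg}
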