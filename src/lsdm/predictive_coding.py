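"""Two-layer bidirectional predictive-coding model with symmetric weights.

A perceptual layer ``P`` (one unit per color and per shape feature) exchanges
signals with a conceptual layer ``C`` (one unit per stored color-shape
concept) through a binary weight matrix ``W`` (features x concepts; each
concept binds exactly one color and one shape).  The conceptual layer predicts
perceptual activity as ``W C``; the perceptual layer transmits the residual
(prediction error) ``R_t = P_t - W C_t`` upward, and both layers relax with
rate ``alpha`` in discrete time:

    R_t     = P_t - W C_t
    P_{t+1} = P_t + alpha (I - P_t)
    C_{t+1} = C_t + alpha W^T R_t

For a complete concept as input the residual decays toward zero; for an
incomplete input (e.g. a colorless color-associated shape) the residual in the
missing feature channel stays elevated, since no stored concept can fully
explain the input.  The dynamics are linear, so trajectories superpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PCModel", "build_from_concepts", "step", "simulate"]


@dataclass
class PCModel:
    """Weights, update rate, and current (P, C) state of the two-layer network."""

    W: np.ndarray  # (n_features, n_concepts), binary
    alpha: float = 0.2
    feature_names: list[str] = field(default_factory=list)
    concept_names: list[str] = field(default_factory=list)
    P: np.ndarray = None
    C: np.ndarray = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not np.isin(self.W, (0.0, 1.0)).all():
            raise ValueError("W entries must be binary")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.P is None:
            self.P = np.zeros(self.W.shape[0])
        if self.C is None:
            self.C = np.zeros(self.W.shape[1])

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_concepts(self) -> int:
        return self.W.shape[1]

    def reset(self) -> None:
        self.P = np.zeros(self.n_features)
        self.C = np.zeros(self.n_concepts)

    def input_vector(self, *features: str) -> np.ndarray:
        """Input with the named feature units set to 1."""
        vec = np.zeros(self.n_features)
        for f in features:
            vec[self.feature_names.index(f)] = 1.0
        return vec

    def concept_input(self, concept: str) -> np.ndarray:
        """Complete-concept input: the concept's color and shape units active."""
        return self.W[:, self.concept_names.index(concept)].copy()


def build_from_concepts(
    colors: list[str], shapes: list[str], concepts: list[tuple[str, str]], alpha: float = 0.2
) -> PCModel:
    """Construct the network from named features and (color, shape) concepts.

    With 2 colors, 3 shapes and 3 concepts the perceptual layer is 5-dimensional
    and W is 5x3; every concept column has exactly two active entries (its color
    and its shape).  Duplicate concepts are allowed (the model flags them) but
    a concept naming an unknown feature is an error.
    """
    features = list(colors) + list(shapes)
    w = np.zeros((len(features), len(concepts)))
    names = []
    seen = set()
    duplicates = []
    for ci, (color, shape) in enumerate(concepts):
        if color not in colors:
            raise ValueError(f"concept {ci} references unknown color {color!r}")
        if shape not in shapes:
            raise ValueError(f"concept {ci} references unknown shape {shape!r}")
        w[features.index(color), ci] = 1.0
        w[features.index(shape), ci] = 1.0
        key = (color, shape)
        if key in seen:
            duplicates.append(key)
        seen.add(key)
        names.append(f"{color}-{shape}")
    model = PCModel(W=w, alpha=alpha, feature_names=features, concept_names=names)
    model.duplicate_concepts = duplicates
    return model


def step(model: PCModel, I: np.ndarray) -> np.ndarray:
    """One synchronous update of (P, C); returns the residual ``R_t``.

    The residual is computed from the pre-update states, then both layers are
    updated simultaneously.
    """
    I = np.asarray(I, dtype=float)
    if I.shape != (model.n_features,):
        raise ValueError(f"input must have {model.n_features} features, got {I.shape}")
    r = model.P - model.W @ model.C
    p_new = model.P + model.alpha * (I - model.P)
    c_new = model.C + model.alpha * (model.W.T @ r)
    model.P, model.C = p_new, c_new
    return r


def simulate(model: PCModel, I: np.ndarray, n_steps: int, reset: bool = True) -> dict:
    """Iterate the dynamics for ``n_steps``; returns the full state history.

    Returns ``{"P": (n_steps+1, n_feat), "C": (n_steps+1, n_conc),
    "R": (n_steps, n_feat)}`` where row ``t`` of ``R`` is the residual emitted
    at step ``t``.  Deterministic.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if reset:
        model.reset()
    P = [model.P.copy()]
    C = [model.C.copy()]
    R = []
    for _ in range(n_steps):
        R.append(step(model, I))
        P.append(model.P.copy())
        C.append(model.C.copy())
    return {"P": np.array(P), "C": np.array(C), "R": np.array(R)}
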