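"""Partial-credit model family and its mixture extensions.

The partial credit model (PCM) and the generalized partial credit model
(GPCM) are adjacent-category logit models for ordered polytomous items.  An
item *i* with categories ``0..m_i`` is described by ``m_i`` threshold
parameters ``tau_is`` — the latent-trait locations where the characteristic
curves of adjacent categories intersect — and, in the GPCM, a positive
discrimination ``delta_i`` controlling how sharply response probabilities
change along the trait.

The mixture variants assume G latent subpopulations, each with its own
threshold set, latent-trait variance and mixing weight:

* ``mPCM``    — mixture PCM, all discriminations fixed at 1;
* ``rmGPCM``  — restricted mixture GPCM, item discriminations shared
  across classes;
* ``mGPCM``   — full mixture GPCM, class-specific item discriminations.

Class-specific latent traits are normal with mean 0 (an identification
constraint) and free variance.  The latent trait is integrated out by
Gauss–Hermite quadrature rescaled per class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateItemError,
    InvalidParameterError,
)

MISSING = -1
"""Integer marker for a missing response inside a ``ResponseMatrix``."""

VARIANTS = ("pcm", "mpcm", "gpcm", "rmgpcm", "mgpcm")

#: Probability floor applied before taking logs; floored evaluations are
#: counted so callers can report how often the guard fired.
PROB_FLOOR = 1e-300

_floor_warnings = {"count": 0}


def floor_warning_count() -> int:
    """Number of times a pattern probability was floored at ``PROB_FLOOR``."""
    return _floor_warnings["count"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ResponseMatrix:
    """n x I matrix of ordinal responses in categories ``0..m_i``.

    ``values`` uses ``MISSING`` (-1) for absent entries.  Every person must
    have at least one observed response and every observed entry must lie
    within its item's category range.
    """

    values: np.ndarray
    item_labels: list[str]
    category_counts: np.ndarray  # m_i + 1 categories per item

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        self.category_counts = np.asarray(self.category_counts, dtype=int)
        if self.values.ndim != 2:
            raise DataError("response values must be a 2-D matrix")
        n, n_items = self.values.shape
        if n < 1 or n_items < 1:
            raise DataError("need at least one person and one item")
        if len(self.item_labels) != n_items:
            raise DataError("item_labels length does not match matrix width")
        if len(self.category_counts) != n_items:
            raise DataError("category_counts length does not match matrix width")
        if np.any(self.category_counts < 2):
            raise DegenerateItemError("every item needs at least 2 categories")
        observed = self.values != MISSING
        if np.any(~observed.any(axis=1)):
            bad = int(np.flatnonzero(~observed.any(axis=1))[0])
            raise DataError(f"person {bad} has no observed responses")
        too_low = observed & (self.values < 0)
        too_high = observed & (self.values >= self.category_counts[None, :])
        if np.any(too_low | too_high):
            v, i = np.argwhere(too_low | too_high)[0]
            raise DataError(
                f"category {self.values[v, i]} out of range for item "
                f"'{self.item_labels[i]}' (person row {v})"
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_rate(self) -> float:
        return float(np.mean(self.values == MISSING))


@dataclass
class ModelSpec:
    """Which member of the model family to fit and at what resolution."""

    variant: str
    n_classes: int
    category_counts: np.ndarray
    quadrature_nodes: int = 21

    def __post_init__(self):
        self.variant = self.variant.lower()
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant '{self.variant}'; expected one of {VARIANTS}"
            )
        self.category_counts = np.asarray(self.category_counts, dtype=int)
        if np.any(self.category_counts < 2):
            raise DegenerateItemError("every item needs at least 2 categories")
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        if self.variant in ("pcm", "gpcm") and self.n_classes != 1:
            raise ConfigurationError(f"{self.variant} implies a single class")
        if self.quadrature_nodes < 5:
            raise ConfigurationError("quadrature_nodes must be >= 5")

    @property
    def n_items(self) -> int:
        return len(self.category_counts)

    @property
    def has_item_discriminations(self) -> bool:
        return self.variant in ("gpcm", "rmgpcm", "mgpcm")

    @property
    def has_class_discriminations(self) -> bool:
        return self.variant == "mgpcm"


@dataclass
class ParameterSet:
    """Class-specific thresholds, discriminations, mixing weights, variances.

    Shapes: ``thresholds`` is (G, I, max m_i) with entries beyond an item's
    ``m_i`` ignored (NaN-padded); ``discriminations`` is (G, I) — variants
    that tie or fix slopes simply store the expanded values; ``mixing`` is
    (G,) summing to 1; ``variances`` is (G,).  Class means are fixed at 0.
    """

    thresholds: np.ndarray
    discriminations: np.ndarray
    mixing: np.ndarray
    variances: np.ndarray
    category_counts: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.discriminations = np.asarray(self.discriminations, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.category_counts = np.asarray(self.category_counts, dtype=int)
        G, I = self.discriminations.shape
        if self.thresholds.shape[:2] != (G, I):
            raise InvalidParameterError("thresholds/discriminations shape mismatch")
        if self.mixing.shape != (G,) or self.variances.shape != (G,):
            raise InvalidParameterError("mixing/variances must have one entry per class")
        if abs(self.mixing.sum() - 1.0) > 1e-8:
            raise InvalidParameterError("mixing proportions must sum to 1")
        if G > 1 and np.any((self.mixing <= 0) | (self.mixing >= 1)):
            raise InvalidParameterError("mixing proportions must lie strictly in (0, 1)")
        if np.any(self.discriminations <= 0):
            raise InvalidParameterError("discriminations must be positive")
        if np.any(self.variances <= 0):
            raise InvalidParameterError("latent variances must be positive")
        for i, m in enumerate(self.category_counts - 1):
            if np.any(~np.isfinite(self.thresholds[:, i, :m])):
                raise InvalidParameterError(f"non-finite threshold for item {i}")

    @property
    def n_classes(self) -> int:
        return self.discriminations.shape[0]

    @property
    def n_items(self) -> int:
        return self.discriminations.shape[1]

    def reorder_classes(self, order) -> "ParameterSet":
        order = np.asarray(order, dtype=int)
        return ParameterSet(
            thresholds=self.thresholds[order],
            discriminations=self.discriminations[order],
            mixing=self.mixing[order],
            variances=self.variances[order],
            category_counts=self.category_counts,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        G, I = self.discriminations.shape
        thr = [
            [list(self.thresholds[g, i, : self.category_counts[i] - 1]) for i in range(I)]
            for g in range(G)
        ]
        return {
            "n_classes": G,
            "category_counts": self.category_counts.tolist(),
            "thresholds": thr,
            "discriminations": self.discriminations.tolist(),
            "mixing": self.mixing.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        counts = np.asarray(d["category_counts"], dtype=int)
        G = d["n_classes"]
        I = len(counts)
        m_max = int(counts.max()) - 1
        thr = np.full((G, I, m_max), np.nan)
        for g in range(G):
            for i in range(I):
                vals = d["thresholds"][g][i]
                thr[g, i, : len(vals)] = vals
        return cls(
            thresholds=thr,
            discriminations=np.asarray(d["discriminations"], dtype=float),
            mixing=np.asarray(d["mixing"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
            category_counts=counts,
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class QuadratureGrid:
    """Gauss–Hermite nodes/weights on the standard-normal scale.

    ``nodes`` are z-values; ``weights`` are the corresponding N(0, 1)
    quadrature weights, normalized to sum to 1.  Class-specific latent
    distributions N(0, sigma_g^2) are handled by rescaling the nodes by
    sigma_g at evaluation time.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.nodes.size == 0:
            raise ConfigurationError("quadrature grid is empty")
        if np.any(np.diff(self.nodes) <= 0):
            raise ConfigurationError("quadrature nodes must be strictly increasing")
        if np.any(self.weights < 0):
            raise ConfigurationError("quadrature weights must be non-negative")
        self.weights = self.weights / self.weights.sum()

    @classmethod
    def gauss_hermite(cls, n_nodes: int) -> "QuadratureGrid":
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        return cls(nodes=x * np.sqrt(2.0), weights=w / np.sqrt(np.pi))

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


# ---------------------------------------------------------------------------
# Probability computations
# ---------------------------------------------------------------------------


def category_probabilities(theta, thresholds, discrimination):
    """Response-category probabilities of one (G)PCM item.

    Parameters
    ----------
    theta : float or array
        Latent-trait value(s).
    thresholds : array of length m
        Adjacent-category intersection locations ``tau_1..tau_m`` (need not
        be ordered).
    discrimination : float
        Positive slope parameter.

    Returns
    -------
    array of shape ``theta.shape + (m + 1,)`` with rows summing to 1.  The
    category-0 term of the cumulative logit sum is identically 0, making
    category 0 the reference.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size < 1:
        raise DegenerateItemError("an item needs at least one threshold (m >= 1)")
    if not discrimination > 0:
        raise InvalidParameterError("discrimination must be positive")
    theta = np.asarray(theta, dtype=float)
    # cumulative logit numerators: 0, d(t - tau_1), d(t - tau_1) + d(t - tau_2), ...
    steps = discrimination * (theta[..., None] - thresholds)
    cum = np.concatenate(
        [np.zeros(theta.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1
    )
    cum -= cum.max(axis=-1, keepdims=True)  # log-sum-exp guard
    p = np.exp(cum)
    return p / p.sum(axis=-1, keepdims=True)


def log_probability_table(params: ParameterSet, grid: QuadratureGrid) -> np.ndarray:
    """Log category probabilities at every (class, node, item, category).

    Returns an array of shape (G, Q, I, C_max) with ``-inf`` padding for
    categories beyond an item's range.  Node q in class g is evaluated at
    ``theta = sigma_g * z_q``.
    """
    G, I = params.discriminations.shape
    Q = grid.n_nodes
    c_max = int(params.category_counts.max())
    table = np.full((G, Q, I, c_max), -np.inf)
    sigma = np.sqrt(params.variances)
    theta = sigma[:, None] * grid.nodes[None, :]  # (G, Q)
    for i in range(I):
        m = int(params.category_counts[i]) - 1
        tau = params.thresholds[:, i, :m]  # (G, m)
        delta = params.discriminations[:, i]  # (G,)
        steps = delta[:, None, None] * (theta[:, :, None] - tau[:, None, :])
        cum = np.concatenate([np.zeros((G, Q, 1)), np.cumsum(steps, axis=-1)], axis=-1)
        table[:, :, i, : m + 1] = cum - logsumexp(cum, axis=-1, keepdims=True)
    return table


def pattern_log_likelihoods(
    values: np.ndarray, params: ParameterSet, grid: QuadratureGrid
) -> np.ndarray:
    """Log P(pattern_v | class g, theta at node q) for all v, g, q.

    Missing entries contribute a factor of 1 (ignorable missingness).
    Returns shape (n, G, Q).
    """
    table = log_probability_table(params, grid)  # (G, Q, I, C)
    n, I = values.shape
    G, Q = table.shape[:2]
    out = np.zeros((n, G, Q))
    for i in range(I):
        x = values[:, i]
        obs = x != MISSING
        if not obs.any():
            continue
        contrib = table[:, :, i, x[obs]]  # (G, Q, n_obs)
        out[obs] += np.moveaxis(contrib, -1, 0)
    return out


def class_conditional_pattern_probability(
    pattern, class_index: int, params: ParameterSet, theta: float
) -> float:
    """Probability of one response pattern given class and trait value.

    The pattern is a length-I vector with ``MISSING`` allowed; missing items
    contribute a factor of 1 (so an all-missing pattern has probability 1).
    """
    pattern = np.asarray(pattern, dtype=int)
    if class_index >= params.n_classes:
        raise ConfigurationError("class_index out of range")
    prob = 1.0
    for i, x in enumerate(pattern):
        if x == MISSING:
            continue
        m = int(params.category_counts[i]) - 1
        if x < 0 or x > m:
            raise DataError(f"category {x} out of range for item {i}")
        p = category_probabilities(
            theta,
            params.thresholds[class_index, i, :m],
            params.discriminations[class_index, i],
        )
        prob *= float(p[..., x])
    return prob


def marginal_pattern_probability(
    pattern, params: ParameterSet, grid: QuadratureGrid
) -> float:
    """Mixture-marginal pattern probability with the trait integrated out."""
    pattern = np.asarray(pattern, dtype=int).reshape(1, -1)
    ll = pattern_log_likelihoods(pattern, params, grid)  # (1, G, Q)
    log_w = np.log(grid.weights)[None, None, :]
    log_pi = np.log(params.mixing)[None, :, None]
    return float(np.exp(logsumexp(ll + log_w + log_pi, axis=(1, 2))[0]))


def person_log_marginals(
    values: np.ndarray, params: ParameterSet, grid: QuadratureGrid
) -> np.ndarray:
    """Per-person log marginal probability, floored at ``PROB_FLOOR``."""
    ll = pattern_log_likelihoods(values, params, grid)
    joint = ll + np.log(grid.weights)[None, None, :] + np.log(params.mixing)[None, :, None]
    out = logsumexp(joint, axis=(1, 2))
    floor = np.log(PROB_FLOOR)
    n_floored = int(np.sum(out < floor))
    if n_floored:
        _floor_warnings["count"] += n_floored
        warnings.warn(
            f"{n_floored} pattern probabilities floored at {PROB_FLOOR:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.maximum(out, floor)
    return out


def log_likelihood(
    data: ResponseMatrix, params: ParameterSet, grid: QuadratureGrid, weights=None
) -> float:
    """Marginal log-likelihood of the data (sum over persons)."""
    if weights is None:
        return float(person_log_marginals(data.values, params, grid).sum())
    return float(weights @ person_log_marginals(data.values, params, grid))


def count_free_parameters(spec: ModelSpec) -> int:
    """Free parameters under the package's identification scheme.

    Per class: all ``m_i`` thresholds are free and one latent variance is
    free (class means are fixed at 0).  Mixing weights contribute G - 1.
    Discriminations: none for PCM/mPCM (all fixed at 1); I - 1 for
    GPCM/rmGPCM (item 1 fixed at 1, shared across classes); I*G - 1 for
    mGPCM (item 1 in class 1 is the overall reference).
    """
    G = spec.n_classes
    n_thresholds = int(np.sum(spec.category_counts - 1)) * G
    n_variances = G
    n_mixing = G - 1
    if spec.variant in ("pcm", "mpcm"):
        n_disc = 0
    elif spec.variant in ("gpcm", "rmgpcm"):
        n_disc = spec.n_items - 1
    else:  # mgpcm
        n_disc = spec.n_items * G - 1
    return n_thresholds + n_variances + n_mixing + n_disc
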