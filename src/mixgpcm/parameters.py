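"""Parameter containers for the restrictive mixed generalized partial credit model.

The model (rmGPCM) is a finite mixture of generalized partial credit models
(GPCMs) in which each latent class g carries its own step thresholds
``tau[i, s]`` and its own latent-trait standard deviation ``sigma_g`` (traits
are normal with mean zero within class), while the item discriminations
``delta_i`` are shared across classes.  Identification constraints: the first
discrimination is fixed at 1, the zeroth step threshold of every item is fixed
at 0 (and therefore never stored), and the class weights live on the simplex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RatingScale",
    "ClassParams",
    "ModelParameters",
    "ResponseMatrix",
    "QuadratureGrid",
    "parameter_count",
]

MISSING = -1  # internal sentinel for absent responses


@dataclass(frozen=True)
class RatingScale:
    """An ordered rating scale with categories coded 0..m (m+1 categories)."""

    n_categories: int

    def __post_init__(self) -> None:
        if int(self.n_categories) != self.n_categories or self.n_categories < 2:
            raise ValueError("a rating scale needs at least 2 integer categories")
        object.__setattr__(self, "n_categories", int(self.n_categories))

    @property
    def m(self) -> int:
        """Highest category code (number of step thresholds per item)."""
        return self.n_categories - 1

    @property
    def categories(self) -> np.ndarray:
        return np.arange(self.n_categories)


@dataclass
class ClassParams:
    """Class-specific parameters: threshold matrix (I x m) and trait SD.

    ``thresholds[i, s-1]`` holds tau_{i,s} for steps s = 1..m; the fixed
    tau_{i,0} = 0 is implicit and never stored.
    """

    thresholds: np.ndarray
    trait_sd: float

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite")
        self.trait_sd = float(self.trait_sd)
        if not (self.trait_sd > 0 and np.isfinite(self.trait_sd)):
            raise ValueError("trait_sd must be positive and finite")

    @property
    def n_items(self) -> int:
        return self.thresholds.shape[0]

    @property
    def m(self) -> int:
        return self.thresholds.shape[1]


@dataclass
class ModelParameters:
    """Full rmGPCM parameter set.

    Attributes
    ----------
    scale : RatingScale
    classes : list of ClassParams, one per latent class
    weights : class mixing proportions pi_g on the simplex
    discriminations : item slopes delta_i, delta_1 = 1, all positive
    """

    scale: RatingScale
    classes: list[ClassParams]
    weights: np.ndarray
    discriminations: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.discriminations = np.asarray(self.discriminations, dtype=float)
        if len(self.classes) != len(self.weights):
            raise ValueError("one weight per class required")
        if abs(self.weights.sum() - 1.0) > 1e-12 or np.any(self.weights < 0):
            raise ValueError("class weights must lie on the simplex (sum 1)")
        if np.any(self.discriminations <= 0):
            raise ValueError("discriminations must be positive")
        if self.discriminations[0] != 1.0:
            raise ValueError("the first discrimination is fixed at 1 for identification")
        m = self.scale.m
        n_items = len(self.discriminations)
        for cp in self.classes:
            if cp.m != m or cp.n_items != n_items:
                raise ValueError("all classes must share the item count and scale length")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_items(self) -> int:
        return len(self.discriminations)

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.n_classes, self.n_items, self.scale.m)

    @property
    def threshold_array(self) -> np.ndarray:
        """Thresholds stacked as a (G, I, m) array."""
        return np.stack([cp.thresholds for cp in self.classes])

    @property
    def trait_sds(self) -> np.ndarray:
        return np.array([cp.trait_sd for cp in self.classes])

    # ------------------------------------------------------------------
    # serialization (JSON-compatible schema)
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_categories": self.scale.n_categories,
            "weights": self.weights.tolist(),
            "discriminations": self.discriminations.tolist(),
            "classes": [
                {"thresholds": cp.thresholds.tolist(), "trait_sd": cp.trait_sd}
                for cp in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            scale=RatingScale(d["n_categories"]),
            classes=[
                ClassParams(np.asarray(c["thresholds"], float), c["trait_sd"])
                for c in d["classes"]
            ],
            weights=np.asarray(d["weights"], float),
            discriminations=np.asarray(d["discriminations"], float),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def relabel(self, order: Sequence[int]) -> "ModelParameters":
        """Return a copy with classes permuted into ``order``."""
        order = list(order)
        return ModelParameters(
            scale=self.scale,
            classes=[self.classes[g] for g in order],
            weights=self.weights[order],
            discriminations=self.discriminations.copy(),
        )


def parameter_count(n_classes: int, n_items: int, m: int) -> int:
    """Number of free parameters of an rmGPCM.

    Per class: I*m free thresholds (step 0 fixed) and one trait variance;
    shared: I-1 free discriminations (first fixed at 1); G-1 free weights.
    """
    if n_classes < 1 or n_items < 1 or m < 1:
        raise ValueError("n_classes, n_items and m must all be positive")
    return n_items * m * n_classes + (n_items - 1) + n_classes + (n_classes - 1)


class ResponseMatrix:
    """Person x item integer response matrix with a missing-value sentinel.

    Internally missing entries are stored as ``-1``; valid responses are
    integers in ``{0, ..., m}``.
    """

    def __init__(self, data, scale: RatingScale, item_names: Sequence[str] | None = None):
        arr = np.asarray(data)
        if arr.ndim != 2:
            raise ValueError("response data must be two-dimensional (persons x items)")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(arr, dtype=float)
            nan_mask = np.isnan(flt)
            flt = np.where(nan_mask, MISSING, flt)
            if not np.allclose(flt, np.round(flt)):
                raise ValueError("responses must be integers")
            arr = np.round(flt).astype(int)
        else:
            arr = arr.astype(int, copy=True)
        bad = (arr != MISSING) & ((arr < 0) | (arr > scale.m))
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"response code {arr[r, c]} at row {r}, column {c} is outside 0..{scale.m}"
            )
        self.values = arr
        self.scale = scale
        self.item_names = (
            list(item_names)
            if item_names is not None
            else [f"item{i + 1}" for i in range(arr.shape[1])]
        )
        if len(self.item_names) != arr.shape[1]:
            raise ValueError("one item name per column required")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.item_names)
        return df.mask(df == MISSING)

    @classmethod
    def from_dataframe(cls, df, scale: RatingScale) -> "ResponseMatrix":
        vals = df.to_numpy(dtype=float)
        return cls(vals, scale, item_names=list(df.columns))


@dataclass
class QuadratureGrid:
    """Fixed quadrature rule for integrals over a standard-normal trait.

    Nodes are on the standard-normal scale; for class g the trait values are
    ``sigma_g * nodes``.  Weights are normalized to sum to one.
    """

    nodes: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")
        self.weights = self.weights / self.weights.sum()

    @classmethod
    def gauss_hermite(cls, n_nodes: int = 49) -> "QuadratureGrid":
        """Gauss-Hermite rule transformed to standard-normal expectation."""
        x, w = np.polynomial.hermite.hermgauss(int(n_nodes))
        return cls(nodes=x * np.sqrt(2.0), weights=w / np.sqrt(np.pi))
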