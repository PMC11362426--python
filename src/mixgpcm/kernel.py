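"""Closed-form quantities of the mixed generalized partial credit model.

The class-conditional GPCM assigns category x in {0, ..., m} of item i the
probability

    P(x | theta, g) = exp( sum_{s=0}^{x} delta_i (theta - tau_{i s g}) )
                      / sum_{c=0}^{m} exp( sum_{s=0}^{c} delta_i (theta - tau_{i s g}) )

with tau_{i 0 g} = 0.  Writing T_x = sum_{s<=x} tau_{i s g}, the log-numerator
is delta_i ((x+1) theta - T_x), a line in theta with slope (x+1) delta_i.
All normalizations use log-sum-exp so that |delta * theta| up to several
hundred stays finite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .parameters import ClassParams, ModelParameters, QuadratureGrid

__all__ = [
    "category_probabilities",
    "log_category_probabilities",
    "mixture_response_probability",
    "modal_category_map",
    "modal_categories",
    "expected_category_frequencies",
]


def _check_finite(name, value):
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite")


def cumulative_thresholds(thresholds: np.ndarray) -> np.ndarray:
    """T_x = sum_{s=1}^{x} tau_s for x = 0..m (T_0 = 0), along the last axis."""
    thresholds = np.asarray(thresholds, dtype=float)
    zeros = np.zeros(thresholds.shape[:-1] + (1,))
    return np.concatenate([zeros, np.cumsum(thresholds, axis=-1)], axis=-1)


def log_category_probabilities(theta, thresholds, discrimination):
    """Log category probabilities of one item under a single-class GPCM.

    Parameters
    ----------
    theta : scalar or array of trait values
    thresholds : (m,) step thresholds tau_1..tau_m of the item
    discrimination : positive item slope

    Returns array of shape ``theta.shape + (m+1,)``.
    """
    theta = np.asarray(theta, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    _check_finite("theta", theta)
    _check_finite("thresholds", thresholds)
    if not (discrimination > 0 and np.isfinite(discrimination)):
        raise ValueError("discrimination must be positive and finite")
    T = cumulative_thresholds(thresholds)  # (m+1,)
    x = np.arange(thresholds.shape[-1] + 1)
    a = discrimination * ((x + 1.0) * theta[..., None] - T)
    return a - logsumexp(a, axis=-1, keepdims=True)


def category_probabilities(theta, item_index, class_params: ClassParams, discrimination):
    """Category response probabilities P(x | theta) for one item in one class."""
    logp = log_category_probabilities(
        theta, class_params.thresholds[item_index], discrimination
    )
    return np.exp(logp)


def mixture_response_probability(theta_by_class, item_index, model: ModelParameters):
    """Mixture category probabilities sum_g pi_g P(x | theta_g, g) for one item.

    ``theta_by_class`` supplies one trait value per latent class (a person's
    position may differ across class-specific trait scales).
    """
    theta_by_class = np.asarray(theta_by_class, dtype=float)
    if theta_by_class.shape != (model.n_classes,):
        raise ValueError(
            f"theta_by_class must have length G={model.n_classes}, got {theta_by_class.shape}"
        )
    out = np.zeros(model.scale.n_categories)
    for g, cp in enumerate(model.classes):
        out += model.weights[g] * category_probabilities(
            theta_by_class[g], item_index, cp, model.discriminations[item_index]
        )
    return out


def log_prob_table(model: ModelParameters, grid: QuadratureGrid) -> np.ndarray:
    """Log P(x | theta_q, g) for all classes, nodes, items, categories.

    Returns an array of shape (G, Q, I, m+1) where theta for class g at node q
    is ``sigma_g * nodes[q]`` (nodes on the standard-normal scale).
    """
    tau = model.threshold_array  # (G, I, m)
    T = cumulative_thresholds(tau)  # (G, I, m+1)
    delta = model.discriminations  # (I,)
    theta = model.trait_sds[:, None] * grid.nodes[None, :]  # (G, Q)
    x1 = np.arange(model.scale.n_categories) + 1.0  # (m+1,)
    a = delta[None, None, :, None] * (
        x1[None, None, None, :] * theta[:, :, None, None] - T[:, None, :, :]
    )
    return a - logsumexp(a, axis=-1, keepdims=True)


# ----------------------------------------------------------------------
# Modal-category structure
# ----------------------------------------------------------------------

def modal_categories(thresholds) -> np.ndarray:
    """Categories of one item with a nonempty modal region on the real line.

    The log-numerators are lines in theta with strictly increasing slopes, so
    category c is modal on some interval iff the point (c, T_c) is a vertex of
    the lower convex hull of the cumulative thresholds {(c, T_c)}.  The
    extreme categories 0 and m are always modal.
    """
    T = cumulative_thresholds(np.asarray(thresholds, dtype=float))
    m = T.shape[-1] - 1
    scale = 1.0 + float(np.max(np.abs(T)))
    tol = 1e-10 * scale  # collinear-within-rounding points are not vertices
    # incremental lower convex hull over points (c, T_c)
    hull = [0]
    for c in range(1, m + 1):
        while len(hull) >= 2:
            c1, c2 = hull[-2], hull[-1]
            # drop c2 if it lies on or above the segment c1 -> c
            if (T[c2] - T[c1]) * (c - c2) >= (T[c] - T[c2]) * (c2 - c1) - tol:
                hull.pop()
            else:
                break
        hull.append(c)
    return np.asarray(hull)


def modal_category_map(model: ModelParameters, class_index: int, item_index: int, theta_grid):
    """Modal (highest-probability) category along a trait grid.

    Ties are broken toward the lower category code.  Returns an array of
    ``(theta, category)`` pairs with shape (len(grid), 2).
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("theta_grid must be non-empty")
    if np.any(np.diff(theta_grid) <= 0):
        raise ValueError("theta_grid must be strictly increasing")
    logp = log_category_probabilities(
        theta_grid,
        model.classes[class_index].thresholds[item_index],
        model.discriminations[item_index],
    )
    cats = np.argmax(logp, axis=-1)  # argmax returns the first (lowest) maximizer
    return np.column_stack([theta_grid, cats.astype(float)])


def default_theta_grid(model: ModelParameters, n_points: int = 1001) -> np.ndarray:
    half = 4.0 * float(np.max(model.trait_sds))
    return np.linspace(-half, half, n_points)


def expected_category_frequencies(
    model: ModelParameters, grid: QuadratureGrid | None = None
) -> np.ndarray:
    """Model-implied marginal category distribution per class and item.

    Integrates P(x | theta, g) over the class trait distribution N(0, sigma_g^2)
    by Gauss-Hermite quadrature.  Returns an array (G, I, m+1); each (g, i)
    row sums to one.
    """
    if grid is None:
        grid = QuadratureGrid.gauss_hermite(49)
    logp = log_prob_table(model, grid)  # (G, Q, I, K)
    return np.einsum("q,gqik->gik", grid.weights, np.exp(logp))
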