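"""Marginal maximum-likelihood estimation of the mixed GPCM.

``MixedGPCM`` is the model class (statsmodels-style): it is constructed from a
response matrix plus a class count, and ``fit()`` returns a
``MixedGPCMResults`` object carrying the estimates, posteriors, diagnostics
and a ``summary()`` table.

Estimation is EM over the latent class and the latent trait jointly.  The
trait integral within class g uses a fixed Gauss-Hermite rule on the
standard-normal scale with theta = sigma_g * node, so the class variance
enters the item-response kernel and the node weights stay fixed.  The E-step
collapses persons into unique response patterns; the M-step maximizes the
expected complete-data log-likelihood with L-BFGS (analytic gradients) over
thresholds, log-discriminations and log-trait-SDs, warm-started at the
current parameters so the observed-data likelihood never decreases.  Class
weights are updated in closed form.  Missing responses are dropped from the
within-person item product (missing at random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .kernel import cumulative_thresholds, log_prob_table
from .parameters import (
    MISSING,
    ClassParams,
    ModelParameters,
    QuadratureGrid,
    RatingScale,
    ResponseMatrix,
    parameter_count,
)

__all__ = ["EstimationOptions", "MixedGPCM", "MixedGPCMResults", "fit_rmgpcm"]


@dataclass(frozen=True)
class EstimationOptions:
    """Tuning knobs of the EM estimator.

    ``n_starts`` random initializations are each run for ``burnin_iterations``
    EM steps; the best is continued to convergence (relative log-likelihood
    change below ``rel_tolerance`` or ``max_em_iterations`` total steps).
    """

    n_quadrature_nodes: int = 49
    max_em_iterations: int = 1000
    rel_tolerance: float = 1e-8
    n_starts: int = 20
    burnin_iterations: int = 40
    mstep_maxiter: int = 25
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_quadrature_nodes",
            "max_em_iterations",
            "n_starts",
            "burnin_iterations",
            "mstep_maxiter",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not self.rel_tolerance > 0:
            raise ValueError("rel_tolerance must be positive")


# ----------------------------------------------------------------------
# internal pattern representation
# ----------------------------------------------------------------------

class _PatternData:
    """Unique response patterns with person counts and an inverse index."""

    def __init__(self, data: ResponseMatrix):
        X = data.values
        self.n_persons, self.n_items = X.shape
        self.patterns, self.inverse, self.counts = np.unique(
            X, axis=0, return_inverse=True, return_counts=True
        )
        self.counts = self.counts.astype(float)
        self.miss = self.patterns == MISSING
        self.safe = np.where(self.miss, 0, self.patterns)
        self.item_index = np.arange(self.n_items)


def _pattern_loglik(pd_: _PatternData, logp: np.ndarray) -> np.ndarray:
    """log prod_i P(x_pi | node, class) for each unique pattern: (P, G, Q)."""
    lpt = np.transpose(logp, (2, 3, 0, 1))  # (I, K, G, Q)
    contrib = lpt[pd_.item_index[None, :], pd_.safe]  # (P, I, G, Q)
    contrib = np.where(pd_.miss[:, :, None, None], 0.0, contrib)
    return contrib.sum(axis=1)  # (P, G, Q)


# ----------------------------------------------------------------------
# model class
# ----------------------------------------------------------------------

class MixedGPCM:
    """Restrictive mixed generalized partial credit model.

    Parameters
    ----------
    data : ResponseMatrix or array-like or DataFrame
        Person x item integer responses coded 0..m (NaN = missing).
    n_classes : int
        Number of latent classes G.
    scale : RatingScale, optional
        Inferred from the data maximum when omitted.
    """

    def __init__(self, data, n_classes: int, scale: RatingScale | None = None):
        if not isinstance(data, ResponseMatrix):
            if isinstance(data, pd.DataFrame):
                if scale is None:
                    scale = RatingScale(int(np.nanmax(data.to_numpy(float))) + 1)
                data = ResponseMatrix.from_dataframe(data, scale)
            else:
                arr = np.asarray(data)
                if scale is None:
                    scale = RatingScale(int(np.nanmax(np.asarray(arr, float))) + 1)
                data = ResponseMatrix(arr, scale)
        self.data = data
        self.scale = data.scale
        self.n_classes = int(n_classes)
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if data.n_persons < self.n_classes:
            raise ValueError("need at least as many persons as classes")
        self._check_identifiable()
        self._pat = _PatternData(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_classes: int, scale: RatingScale | None = None):
        return cls(df, n_classes=n_classes, scale=scale)

    def _check_identifiable(self) -> None:
        X = self.data.values
        for i in range(self.data.n_items):
            col = X[:, i]
            observed = np.unique(col[col != MISSING])
            if observed.size < 2:
                raise ValueError(
                    f"item {self.data.item_names[i]!r} shows fewer than two observed "
                    "categories; its thresholds are not identifiable"
                )

    # ------------------------------------------------------------------
    # likelihood machinery
    # ------------------------------------------------------------------
    def _estep(self, params: ModelParameters, grid: QuadratureGrid):
        """Return (loglik, R) with R the (P, G, Q) posterior over (class, node)."""
        logp = log_prob_table(params, grid)
        ll_pgq = _pattern_loglik(self._pat, logp)  # (P, G, Q)
        with np.errstate(divide="ignore"):
            joint = (
                ll_pgq
                + np.log(params.weights)[None, :, None]
                + np.log(grid.weights)[None, None, :]
            )
        ll_p = logsumexp(joint, axis=(1, 2))  # (P,)
        R = np.exp(joint - ll_p[:, None, None])
        return float(np.dot(self._pat.counts, ll_p)), R

    def loglike(self, params: ModelParameters, grid: QuadratureGrid | None = None) -> float:
        """Marginal log-likelihood of ``params`` on the model's data."""
        if grid is None:
            grid = QuadratureGrid.gauss_hermite(49)
        return self._estep(params, grid)[0]

    def _expected_counts(self, R: np.ndarray) -> np.ndarray:
        """W[g,q,i,c] = expected number of (class g, node q) responses in category c."""
        K = self.scale.n_categories
        P, I = self._pat.patterns.shape
        onehot = np.zeros((P, I, K))
        rows, cols = np.nonzero(~self._pat.miss)
        onehot[rows, cols, self._pat.patterns[rows, cols]] = 1.0
        Rw = R * self._pat.counts[:, None, None]
        return np.einsum("pgq,pik->gqik", Rw, onehot)

    # ------------------------------------------------------------------
    # M-step: maximize sum W * logP over (tau, log delta, log sigma)
    # ------------------------------------------------------------------
    def _mstep(self, params: ModelParameters, W: np.ndarray, grid: QuadratureGrid,
               maxiter: int) -> ModelParameters:
        G, I, m = params.n_classes, params.n_items, params.scale.m
        K = m + 1
        u = grid.nodes
        x1 = np.arange(K) + 1.0

        def unpack(vec):
            tau = vec[: G * I * m].reshape(G, I, m)
            logdelta = vec[G * I * m : G * I * m + (I - 1)]
            logsigma = vec[G * I * m + (I - 1) :]
            delta = np.concatenate([[1.0], np.exp(logdelta)])
            sigma = np.exp(logsigma)
            return tau, delta, sigma

        def neg_q_and_grad(vec):
            tau, delta, sigma = unpack(vec)
            T = cumulative_thresholds(tau)  # (G, I, K)
            theta = sigma[:, None] * u[None, :]  # (G, Q)
            a = delta[None, None, :, None] * (
                x1[None, None, None, :] * theta[:, :, None, None] - T[:, None, :, :]
            )
            logp = a - logsumexp(a, axis=-1, keepdims=True)
            q_val = float(np.sum(W * logp))
            # multinomial score wrt the linear predictor a
            n_gqi = W.sum(axis=-1)  # (G, Q, I)
            D = W - n_gqi[..., None] * np.exp(logp)  # (G, Q, I, K)
            # d a_{c} / d tau_s = -delta_i for s <= c  -> reverse cumulative sum
            rev = np.cumsum(D[..., ::-1], axis=-1)[..., ::-1]  # (G,Q,I,K): sum_{c>=s}
            g_tau = -delta[None, None, :, None] * rev[..., 1:]  # steps 1..m
            g_tau = g_tau.sum(axis=1)  # (G, I, m)
            # d a_c / d delta_i = a_c / delta_i
            g_delta = np.einsum("gqik,gqik->i", D, a) / delta
            g_logdelta = g_delta[1:] * delta[1:]
            # d a_c / d sigma_g = delta_i (c+1) u_q
            g_sigma = np.einsum(
                "gqik,i,k,q->g", D, delta, x1, u
            )
            g_logsigma = g_sigma * sigma
            grad = np.concatenate([g_tau.ravel(), g_logdelta, g_logsigma])
            return -q_val, -grad

        x0 = np.concatenate(
            [
                params.threshold_array.ravel(),
                np.log(params.discriminations[1:]),
                np.log(params.trait_sds),
            ]
        )
        res = minimize(
            neg_q_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        xbest = res.x if res.fun <= neg_q_and_grad(x0)[0] else x0
        tau, delta, sigma = unpack(xbest)
        return ModelParameters(
            scale=params.scale,
            classes=[ClassParams(tau[g], sigma[g]) for g in range(G)],
            weights=params.weights.copy(),
            discriminations=delta,
        )

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------
    def _initial_params(self, rng: np.random.Generator) -> ModelParameters:
        m = self.scale.m
        I = self.data.n_items
        G = self.n_classes
        X = self.data.values.astype(float)
        X[X == MISSING] = np.nan
        base = np.zeros((I, m))
        for i in range(I):
            col = X[:, i]
            col = col[np.isfinite(col)]
            # spread thresholds by observed quantile structure of the item
            mean_shift = -(np.mean(col) / m - 0.5) * 2.0
            base[i] = np.linspace(-1.5, 1.5, m) + mean_shift
        classes = []
        for _ in range(G):
            jitter = rng.normal(0.0, 0.25, size=(I, m))
            classes.append(ClassParams(base + jitter, trait_sd=1.0))
        return ModelParameters(
            scale=self.scale,
            classes=classes,
            weights=np.full(G, 1.0 / G),
            discriminations=np.ones(I),
        )

    # ------------------------------------------------------------------
    # EM driver
    # ------------------------------------------------------------------
    def _em(self, params: ModelParameters, grid: QuadratureGrid,
            options: EstimationOptions, max_iter: int):
        ll_prev = -np.inf
        ll = -np.inf
        n_iter = 0
        converged = False
        N_eff = self._pat.counts.sum()
        for n_iter in range(1, max_iter + 1):
            ll, R = self._estep(params, grid)
            if n_iter > 1:
                rel = abs(ll - ll_prev) / (abs(ll_prev) + 1.0)
                if rel < options.rel_tolerance:
                    converged = True
                    break
            ll_prev = ll
            pi = np.einsum("p,pgq->g", self._pat.counts, R) / N_eff
            pi = np.clip(pi, 1e-12, None)
            pi /= pi.sum()
            W = self._expected_counts(R)
            params = self._mstep(params, W, grid, options.mstep_maxiter)
            params = replace_weights(params, pi)
        return params, ll, n_iter, converged

    def fit(self, options: EstimationOptions | None = None,
            start_params: ModelParameters | None = None) -> "MixedGPCMResults":
        """Fit by EM from multiple random starts; return the best solution.

        With ``start_params`` given, a single EM run starts there (used for
        bootstrap refits and warm restarts).
        """
        options = options or EstimationOptions()
        grid = QuadratureGrid.gauss_hermite(options.n_quadrature_nodes)
        rng = np.random.default_rng(options.seed)
        if start_params is not None:
            params, ll, n_iter, converged = self._em(
                start_params, grid, options, options.max_em_iterations
            )
            best_start = 0
        else:
            candidates = []
            for s in range(options.n_starts):
                p0 = self._initial_params(rng)
                burn = min(options.burnin_iterations, options.max_em_iterations)
                p1, ll1, it1, conv1 = self._em(p0, grid, options, burn)
                candidates.append((ll1, s, p1, it1, conv1))
            ll1, best_start, p1, it1, conv1 = max(candidates, key=lambda t: t[0])
            remaining = options.max_em_iterations - it1
            if conv1 or remaining <= 0:
                params, ll, n_iter, converged = p1, ll1, it1, conv1
            else:
                params, ll, it2, converged = self._em(p1, grid, options, remaining)
                n_iter = it1 + it2
        # canonical order: decreasing class weight
        order = np.argsort(-params.weights, kind="stable")
        params = params.relabel(order)
        _, R = self._estep(params, grid)
        posterior = R.sum(axis=2)[self._pat.inverse]  # (N, G)
        return MixedGPCMResults(
            model=self,
            params=params,
            log_likelihood=ll,
            posterior=posterior,
            n_iterations=n_iter,
            converged=converged,
            start_index=int(best_start),
            options=options,
            grid=grid,
        )


def replace_weights(params: ModelParameters, weights: np.ndarray) -> ModelParameters:
    return ModelParameters(
        scale=params.scale,
        classes=params.classes,
        weights=weights,
        discriminations=params.discriminations,
    )


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

class MixedGPCMResults:
    """Converged (or best-found) rmGPCM estimate with posteriors and scores."""

    def __init__(self, model: MixedGPCM, params: ModelParameters, log_likelihood: float,
                 posterior: np.ndarray, n_iterations: int, converged: bool,
                 start_index: int, options: EstimationOptions, grid: QuadratureGrid):
        self.model = model
        self.params = params
        self.log_likelihood = float(log_likelihood)
        self.posterior = posterior
        self.n_iterations = int(n_iterations)
        self.converged = bool(converged)
        self.start_index = start_index
        self.options = options
        self.grid = grid

    # statsmodels-flavoured aliases
    @property
    def llf(self) -> float:
        return self.log_likelihood

    @property
    def n_parameters(self) -> int:
        return self.params.n_parameters

    @property
    def n_persons(self) -> int:
        return self.model.data.n_persons

    @property
    def class_sizes(self) -> np.ndarray:
        """Estimated mixing proportions pi_g (canonical decreasing order)."""
        return self.params.weights

    def modal_assignment(self) -> np.ndarray:
        """Hard class assignment by posterior argmax (ties to lower index)."""
        return np.argmax(self.posterior, axis=1)

    def assignment_summary(self) -> pd.DataFrame:
        """Per class: estimated size, modal share, mean winning posterior."""
        G = self.params.n_classes
        hard = self.modal_assignment()
        rows = []
        for g in range(G):
            members = hard == g
            mean_post = float(self.posterior[members, g].mean()) if members.any() else np.nan
            rows.append(
                {
                    "class": g + 1,
                    "estimated_size": float(self.params.weights[g]),
                    "modal_share": float(members.mean()),
                    "mean_assignment_probability": mean_post,
                }
            )
        return pd.DataFrame(rows).set_index("class")

    def eap_scores(self) -> pd.DataFrame:
        """EAP trait scores and posterior variances per person.

        The posterior over (class, node) mixes the class-specific trait scales
        theta = sigma_g * node; the variance includes the between-class spread
        of the class-conditional means.  Persons with no observed responses
        get NaN.
        """
        _, R = self.model._estep(self.params, self.grid)
        theta = self.params.trait_sds[:, None] * self.grid.nodes[None, :]  # (G, Q)
        e1 = np.einsum("pgq,gq->p", R, theta)
        e2 = np.einsum("pgq,gq->p", R, theta**2)
        eap = e1[self.model._pat.inverse]
        var = (e2 - e1**2)[self.model._pat.inverse]
        all_missing = self.model._pat.miss.all(axis=1)[self.model._pat.inverse]
        eap = np.where(all_missing, np.nan, eap)
        var = np.where(all_missing, np.nan, np.maximum(var, 0.0))
        return pd.DataFrame({"eap": eap, "posterior_variance": var})

    def model_based_reliability(self) -> float:
        """Single reliability coefficient of the trait scores.

        Total variance decomposes into the variance of the person-level EAP
        scores (signal, including between-class dispersion) plus the average
        posterior variance (noise); reliability is the signal share.
        """
        if self.n_persons < 2:
            raise ValueError("reliability needs at least two persons")
        scores = self.eap_scores().dropna()
        signal = float(scores["eap"].var(ddof=0))
        noise = float(scores["posterior_variance"].mean())
        return signal / (signal + noise)

    def summary(self) -> str:
        lines = [
            "Mixed GPCM results",
            "==================",
            f"classes: {self.params.n_classes}   items: {self.params.n_items}   "
            f"categories: {self.params.scale.n_categories}",
            f"persons: {self.n_persons}   parameters: {self.n_parameters}",
            f"log-likelihood: {self.log_likelihood:.2f}   "
            f"converged: {self.converged} ({self.n_iterations} EM iterations)",
            "",
            str(self.assignment_summary().round(3)),
            "",
            "discriminations: "
            + np.array2string(self.params.discriminations, precision=3),
            "trait SDs:       " + np.array2string(self.params.trait_sds, precision=3),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "start_index": self.start_index,
            "seed": self.options.seed,
            "options": {
                "n_quadrature_nodes": self.options.n_quadrature_nodes,
                "max_em_iterations": self.options.max_em_iterations,
                "rel_tolerance": self.options.rel_tolerance,
                "n_starts": self.options.n_starts,
            },
        }


def posterior_class_probabilities(params: ModelParameters, data: ResponseMatrix,
                                  grid: QuadratureGrid | None = None) -> np.ndarray:
    """Bayes posterior P(class g | responses) for every person (N x G).

    Persons with no observed responses get the prior weights (with a warning).
    """
    if grid is None:
        grid = QuadratureGrid.gauss_hermite(49)
    model = object.__new__(MixedGPCM)
    model.data = data
    model.scale = data.scale
    model.n_classes = params.n_classes
    model._pat = _PatternData(data)
    _, R = model._estep(params, grid)
    post = R.sum(axis=2)[model._pat.inverse]
    all_missing = model._pat.miss.all(axis=1)[model._pat.inverse]
    if all_missing.any():
        warnings.warn("persons with no observed responses receive the prior weights")
        post[all_missing] = params.weights
    return post


def fit_rmgpcm(data: ResponseMatrix, n_classes: int,
               options: EstimationOptions | None = None) -> MixedGPCMResults:
    """Convenience wrapper: construct a MixedGPCM and fit it."""
    return MixedGPCM(data, n_classes=n_classes).fit(options=options)
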