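"""Information criteria, best-model selection and parametric-bootstrap fit.

Model comparison across class counts uses the sample-size-adjusted BIC,
saBIC = -2 LL + p * ln((N + 2) / 24), which behaves well for one-dimensional
polytomous mixture IRT models; the candidate with the lowest saBIC wins.
Absolute fit uses Pearson and Cressie-Read (lambda = 2/3) statistics over
observed response patterns, calibrated by a parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.special import logsumexp

from .model import EstimationOptions, MixedGPCM, MixedGPCMResults, _PatternData, _pattern_loglik
from .kernel import log_prob_table
from .parameters import ModelParameters, QuadratureGrid, ResponseMatrix

__all__ = [
    "FitStatistics",
    "information_criteria",
    "select_best_model",
    "pattern_chi_square",
    "bootstrap_gof",
]

_PROB_FLOOR = 1e-300


@dataclass
class FitStatistics:
    """Fit summary of one candidate model (one row of a selection table)."""

    n_classes: int
    ll: float
    n_parameters: int
    n_persons: int
    saBIC: float = field(init=False)
    BIC: float = field(init=False)
    AIC: float = field(init=False)
    pearson_p: float | None = None
    pearson_se: float | None = None
    cressie_read_p: float | None = None
    cressie_read_se: float | None = None
    n_bootstrap: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        self.saBIC = -2.0 * self.ll + self.n_parameters * np.log((self.n_persons + 2) / 24.0)
        self.BIC = -2.0 * self.ll + self.n_parameters * np.log(self.n_persons)
        self.AIC = -2.0 * self.ll + 2.0 * self.n_parameters


def information_criteria(ll: float, n_parameters: int, n_persons: int,
                         n_classes: int = 0) -> FitStatistics:
    """saBIC, BIC and AIC from a log-likelihood and parameter count."""
    return FitStatistics(n_classes=n_classes, ll=ll, n_parameters=n_parameters,
                         n_persons=n_persons)


def select_best_model(fits: list[FitStatistics]) -> int:
    """Index of the candidate with the lowest saBIC (ties: fewest classes)."""
    if not fits:
        raise ValueError("no candidate models supplied")
    order = sorted(range(len(fits)), key=lambda k: (fits[k].saBIC, fits[k].n_classes))
    return order[0]


# ----------------------------------------------------------------------
# pattern-level goodness of fit
# ----------------------------------------------------------------------

def _pattern_probabilities(params: ModelParameters, pat: _PatternData,
                           grid: QuadratureGrid) -> np.ndarray:
    logp = log_prob_table(params, grid)
    ll_pgq = _pattern_loglik(pat, logp)
    joint = (
        ll_pgq
        + np.log(params.weights)[None, :, None]
        + np.log(grid.weights)[None, None, :]
    )
    return np.exp(logsumexp(joint, axis=(1, 2)))


def pattern_chi_square(params: ModelParameters, data: ResponseMatrix,
                       grid: QuadratureGrid | None = None,
                       cressie_read_lambda: float = 2.0 / 3.0):
    """Pearson and Cressie-Read statistics over observed response patterns.

    Pearson sums (O - E)^2 / E over the distinct observed patterns plus one
    aggregate cell for the total expected mass of unobserved patterns (whose
    observed count is zero, contributing N * residual mass).  The power
    divergence with index ``cressie_read_lambda`` runs over observed patterns
    only.  Expected probabilities below 1e-300 are floored (and counted) so
    the statistics stay finite.
    """
    if grid is None:
        grid = QuadratureGrid.gauss_hermite(49)
    pat = _PatternData(data)
    probs = _pattern_probabilities(params, pat, grid)
    n_floored = int(np.sum(probs < _PROB_FLOOR))
    probs = np.maximum(probs, _PROB_FLOOR)
    N = pat.counts.sum()
    O = pat.counts
    E = N * probs
    residual_mass = max(0.0, 1.0 - probs.sum())
    pearson = float(np.sum((O - E) ** 2 / E) + N * residual_mass)
    lam = cressie_read_lambda
    if abs(lam) < 1e-12:
        cr = float(2.0 * np.sum(O * np.log(O / E)))
    else:
        cr = float(2.0 / (lam * (lam + 1.0)) * np.sum(O * ((O / E) ** lam - 1.0)))
    return pearson, cr, {"n_floored_patterns": n_floored, "residual_mass": residual_mass}


def _simulate_from(params: ModelParameters, n_persons: int, rng: np.random.Generator) -> np.ndarray:
    """Draw complete response data from an rmGPCM (internal, array output)."""
    G = params.n_classes
    cls = rng.choice(G, size=n_persons, p=params.weights)
    theta = rng.standard_normal(n_persons) * params.trait_sds[cls]
    from .kernel import log_category_probabilities

    X = np.empty((n_persons, params.n_items), dtype=int)
    K = params.scale.n_categories
    u = rng.random((n_persons, params.n_items))
    for g in range(G):
        sel = cls == g
        if not sel.any():
            continue
        for i in range(params.n_items):
            p = np.exp(
                log_category_probabilities(
                    theta[sel], params.classes[g].thresholds[i], params.discriminations[i]
                )
            )
            cdf = np.cumsum(p, axis=-1)
            X[sel, i] = np.minimum((u[sel, i][:, None] > cdf).sum(axis=-1), K - 1)
    return X


def bootstrap_gof(results: MixedGPCMResults, n_bootstrap: int = 200, seed: int = 0,
                  refit_max_iterations: int = 100, multi_start: bool = False):
    """Parametric-bootstrap p-values for the pattern chi-square statistics.

    Simulates ``n_bootstrap`` datasets of the original size from the fitted
    model, refits each (by default a single EM run started at the generating
    values with capped iterations; ``multi_start=True`` uses the full
    multi-start protocol), and recomputes both statistics.  p-values use the
    add-one rule p = (1 + #{boot >= observed}) / (B + 1); the standard error
    is sqrt(p (1 - p) / B).  Replicates whose refit raises are dropped and
    counted.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    params = results.params
    data = results.model.data
    grid = results.grid
    obs_pearson, obs_cr, _ = pattern_chi_square(params, data, grid)
    refit_opts = dc_replace(
        results.options,
        max_em_iterations=refit_max_iterations,
    )
    boot_pearson = []
    boot_cr = []
    n_failed = 0
    for _ in range(n_bootstrap):
        Xb = _simulate_from(params, data.n_persons, rng)
        bdata = ResponseMatrix(Xb, data.scale)
        try:
            bmodel = MixedGPCM(bdata, n_classes=params.n_classes, scale=data.scale)
            if multi_start:
                bres = bmodel.fit(options=refit_opts)
            else:
                bres = bmodel.fit(options=refit_opts, start_params=params)
            bp, bc, _ = pattern_chi_square(bres.params, bdata, grid)
        except ValueError:
            n_failed += 1
            continue
        boot_pearson.append(bp)
        boot_cr.append(bc)
    B = len(boot_pearson)
    if B == 0:
        raise RuntimeError("all bootstrap refits failed")
    p_pearson = (1 + np.sum(np.asarray(boot_pearson) >= obs_pearson)) / (B + 1)
    p_cr = (1 + np.sum(np.asarray(boot_cr) >= obs_cr)) / (B + 1)
    return {
        "pearson_stat": obs_pearson,
        "cressie_read_stat": obs_cr,
        "pearson_p": float(p_pearson),
        "pearson_se": float(np.sqrt(p_pearson * (1 - p_pearson) / B)),
        "cressie_read_p": float(p_cr),
        "cressie_read_se": float(np.sqrt(p_cr * (1 - p_cr) / B)),
        "n_bootstrap": B,
        "n_failed": n_failed,
    }
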