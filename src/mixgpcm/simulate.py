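"""Synthetic rating-scale data with planted response styles.

Generates everything the analysis pipeline consumes: mixture GPCM response
matrices with known class memberships and trait values, paired-condition
data with class switching, auxiliary screening columns, and external
criterion variables with target Spearman correlations.

Class templates encode the three prototypical response styles seen in
rating-scale data: ORS (ordinary — ordered, roughly equidistant thresholds,
every category has its own latent segment), ERS (extreme — thresholds
compressed near the centre so the two extreme categories dominate), and RRS
(range — a disordered pattern that leaves one or two upper categories
covering the whole reasonable trait range), plus shifted "extended" variants
eERS and eRRS.  Default mixing weights follow the class shares typically
reported for such mixtures (roughly 55 / 26 / 19% for ORS / ERS / RRS), and a
downward threshold shift (-0.8 by default) mimics the left-skewed category
frequencies of well-being items while keeping within-class traits normal.
All template constants live in this module so tests cite a single source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .parameters import ClassParams, ModelParameters, RatingScale, ResponseMatrix

__all__ = [
    "SyntheticDesign",
    "SimulatedDataset",
    "style_template_parameters",
    "simulate_responses",
    "simulate_paired_conditions",
    "simulate_external_criteria",
    "default_design",
    "STYLE_NAMES",
    "DEFAULT_WEIGHTS",
    "DEFAULT_TRAIT_SDS",
    "DEFAULT_THRESHOLD_SHIFT",
    "default_discriminations",
]

STYLE_NAMES = ("ORS", "ERS", "RRS", "eERS", "eRRS")

# default 3-class preset: ORS / ERS / RRS shares and trait SDs
DEFAULT_WEIGHTS = np.array([0.55, 0.26, 0.19])
DEFAULT_TRAIT_SDS = {"ORS": 1.0, "ERS": 1.1, "RRS": 0.5, "eERS": 1.0, "eRRS": 0.5}
DEFAULT_THRESHOLD_SHIFT = -0.8


def default_discriminations(n_items: int) -> np.ndarray:
    """Fixed item-slope pattern, first slope 1, rest cycling through 0.8-1.4."""
    cycle = np.array([1.0, 1.2, 0.9, 1.1, 1.3, 0.8, 1.4, 1.0])
    return np.concatenate([[1.0], np.resize(cycle, n_items)[1:].clip(0.8, 1.4)])[:n_items]


def _thresholds_from_modal_plan(modal_cats, boundaries, m, spread=2.0) -> np.ndarray:
    """Build a threshold vector whose modal sequence matches a plan.

    ``modal_cats`` is the increasing sequence of categories that should be
    modal, ``boundaries`` the trait values where the modal category hands over
    to the next.  Steps between consecutive modal categories share the
    boundary as their mean; blocks spanning skipped categories get strictly
    decreasing values (mean preserved), which disorders them and empties the
    skipped categories' modal regions.
    """
    modal_cats = list(modal_cats)
    boundaries = list(boundaries)
    if modal_cats[0] != 0 or modal_cats[-1] != m:
        raise ValueError("modal plan must start at category 0 and end at m")
    if len(boundaries) != len(modal_cats) - 1:
        raise ValueError("need one boundary per modal transition")
    tau = np.empty(m)
    for (c_prev, c_next), b in zip(zip(modal_cats[:-1], modal_cats[1:]), boundaries):
        L = c_next - c_prev
        offsets = (np.arange(L)[::-1] - (L - 1) / 2.0) * spread
        tau[c_prev:c_next] = b + offsets
    return tau


def style_template_parameters(style_name: str, m: int, n_items: int,
                              shift: float = 0.0,
                              jitter_sd: float = 0.0,
                              rng: np.random.Generator | None = None) -> ClassParams:
    """Deterministic threshold template of a named response style.

    ORS: ordered equidistant thresholds across [-1.8, 1.8] (inside the
         central 95% range of a unit-SD trait).
    ERS: ordered thresholds compressed into [-0.3, 0.3]; the extreme
         categories dominate the latent continuum.
    RRS: disordered plan leaving the upper non-extreme categories (the
         penultimate category for short scales) modal over the whole central
         range.
    eERS / eRRS: extended variants (extremes plus near-extreme categories
         dominant; range pattern including the top category).
    ``shift`` is added to every threshold (negative values induce the
    left-skewed category use typical of well-being items); optional normal
    jitter with SD ``jitter_sd`` individualizes items.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if style_name not in STYLE_NAMES:
        raise ValueError(f"unknown style {style_name!r}; expected one of {STYLE_NAMES}")
    if m == 1:
        base = np.array([0.0])
    elif style_name == "ORS":
        # equidistant inside the central 95% trait range so every category,
        # extremes included, owns a latent segment there
        base = np.linspace(-1.8, 1.8, m)
    elif style_name == "ERS":
        base = np.linspace(-0.3, 0.3, m)
    elif style_name == "eERS":
        # extremes dominant but near-extreme categories keep moderate segments
        if m < 3:
            base = np.linspace(-0.9, 1.0, m)
        else:
            base = _thresholds_from_modal_plan(
                [0, 1, m - 1, m], [-0.9, -0.45, 1.0], m, spread=1.0
            )
    elif style_name in ("RRS", "eRRS"):
        # the dominant upper categories take over below the central range of
        # the sigma = 0.5 trait distribution; the strictly decreasing lower
        # block disorders and empties categories up to the dominant one while
        # keeping every category's expected frequency workable.  eRRS pulls
        # the top boundary inside the central range so the extreme category
        # joins the dominant set.
        ers_top = style_name == "eRRS"
        if m < 3:
            base = np.array([0.0]) if m == 1 else np.linspace(-0.5, 0.5, m)
        elif m == 3:
            base = np.array([-0.5, -2.3, 0.4 if ers_top else 1.9])
        elif m == 5:
            base = np.array([-0.5, -1.4, -2.3, 0.2, 0.45 if ers_top else 1.9])
        elif m == 10:
            if ers_top:
                base = np.array(
                    [0.3, -0.3, -0.9, -1.5, -2.1, -2.7, -3.3, -3.9, 0.0, 0.5]
                )
            else:
                base = np.array(
                    [0.1, -0.7, -1.5, -2.3, -3.1, -3.9, -4.7, -0.2, 0.5, 1.9]
                )
        else:
            block = -1.4 + 0.6 * ((m - 2) / 2.0 - np.arange(m - 1))
            base = np.append(block, 0.45 if ers_top else 1.9)
    sd = DEFAULT_TRAIT_SDS[style_name]
    thresholds = np.tile(base + shift, (n_items, 1)).astype(float)
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        thresholds = thresholds + rng.normal(0.0, jitter_sd, size=thresholds.shape)
    return ClassParams(thresholds=thresholds, trait_sd=sd)


@dataclass
class SyntheticDesign:
    """Specification of a synthetic mixture rating-scale dataset."""

    n_persons: int = 2500
    n_categories: int = 4
    n_items: int = 8
    class_templates: tuple = ("ORS", "ERS", "RRS")
    weights: np.ndarray = None  # type: ignore[assignment]
    discriminations: np.ndarray = None  # type: ignore[assignment]
    threshold_shift: float = DEFAULT_THRESHOLD_SHIFT
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.weights is None:
            self.weights = (
                DEFAULT_WEIGHTS.copy()
                if len(self.class_templates) == 3
                else np.full(len(self.class_templates), 1.0 / len(self.class_templates))
            )
        self.weights = np.asarray(self.weights, float)
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("weights must lie on the simplex")
        if len(self.weights) != len(self.class_templates):
            raise ValueError("one weight per class template")
        if self.discriminations is None:
            self.discriminations = default_discriminations(self.n_items)
        self.discriminations = np.asarray(self.discriminations, float)

    def to_model_parameters(self) -> ModelParameters:
        scale = RatingScale(self.n_categories)
        rng = np.random.default_rng(self.seed + 1)
        classes = []
        for tpl in self.class_templates:
            if isinstance(tpl, ClassParams):
                classes.append(tpl)
            else:
                classes.append(
                    style_template_parameters(
                        tpl, scale.m, self.n_items,
                        shift=self.threshold_shift,
                        jitter_sd=self.jitter_sd, rng=rng,
                    )
                )
        return ModelParameters(
            scale=scale,
            classes=classes,
            weights=self.weights,
            discriminations=self.discriminations,
        )


@dataclass
class SimulatedDataset:
    """Responses plus the generating ground truth."""

    responses: ResponseMatrix
    true_class: np.ndarray
    true_theta: np.ndarray
    design: SyntheticDesign
    paired_responses: ResponseMatrix | None = None
    paired_class: np.ndarray | None = None
    criteria: pd.DataFrame | None = None


def _draw_responses(params: ModelParameters, cls: np.ndarray, theta: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    from .kernel import log_category_probabilities

    n = len(cls)
    X = np.empty((n, params.n_items), dtype=int)
    K = params.scale.n_categories
    u = rng.random((n, params.n_items))
    for g in range(params.n_classes):
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


def simulate_responses(design: SyntheticDesign) -> SimulatedDataset:
    """Draw a dataset from the mixture: class ~ pi, theta ~ N(0, sigma_g^2),
    responses item-wise from the class-conditional GPCM.  Reproducible from
    ``design.seed``."""
    params = design.to_model_parameters()
    rng = np.random.default_rng(design.seed)
    cls = rng.choice(params.n_classes, size=design.n_persons, p=params.weights)
    theta = rng.standard_normal(design.n_persons) * params.trait_sds[cls]
    X = _draw_responses(params, cls, theta, rng)
    return SimulatedDataset(
        responses=ResponseMatrix(X, params.scale),
        true_class=cls,
        true_theta=theta,
        design=design,
    )


def simulate_paired_conditions(design_given: SyntheticDesign,
                               design_chosen: SyntheticDesign,
                               switch_matrix, n_persons: int, seed: int = 0) -> SimulatedDataset:
    """Paired-condition data with class-membership switching.

    The first-condition class is drawn from ``design_given.weights``; the
    second-condition class from the corresponding row of ``switch_matrix``
    (rows on the simplex).  Traits are redrawn per condition on the relevant
    class scale.  The ground-truth 2x2 table of ORS membership (class 0 =
    first template) is derivable from ``true_class`` / ``paired_class``.
    """
    switch = np.asarray(switch_matrix, float)
    G1 = len(design_given.class_templates)
    G2 = len(design_chosen.class_templates)
    if switch.shape != (G1, G2):
        raise ValueError(f"switch_matrix must be {G1}x{G2}")
    if not np.allclose(switch.sum(axis=1), 1.0) or np.any(switch < 0):
        raise ValueError("switch_matrix rows must lie on the simplex")
    rng = np.random.default_rng(seed)
    pg = design_given.to_model_parameters()
    pc = design_chosen.to_model_parameters()
    cls1 = rng.choice(G1, size=n_persons, p=design_given.weights)
    cls2 = np.array([rng.choice(G2, p=switch[c]) for c in cls1])
    theta1 = rng.standard_normal(n_persons) * pg.trait_sds[cls1]
    theta2 = rng.standard_normal(n_persons) * pc.trait_sds[cls2]
    X1 = _draw_responses(pg, cls1, theta1, rng)
    X2 = _draw_responses(pc, cls2, theta2, rng)
    return SimulatedDataset(
        responses=ResponseMatrix(X1, pg.scale),
        true_class=cls1,
        true_theta=theta1,
        design=design_given,
        paired_responses=ResponseMatrix(X2, pc.scale),
        paired_class=cls2,
    )


def simulate_external_criteria(true_theta, target_rho, seed: int = 0,
                               names=None) -> pd.DataFrame:
    """Criterion variables with target Spearman correlations to the trait.

    Gaussian-copula construction: the trait values are rank-transformed to
    normal scores z; each criterion is r z + sqrt(1 - r^2) eps with the
    Pearson coefficient r = 2 sin(pi rho_S / 6) that yields the requested
    Spearman value in population.  Margins are standard normal.
    """
    theta = np.asarray(true_theta, float)
    target_rho = np.atleast_1d(np.asarray(target_rho, float))
    if np.any(np.abs(target_rho) >= 1):
        raise ValueError("target Spearman correlations must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    n = len(theta)
    ranks = pd.Series(theta).rank(method="average").to_numpy()
    z = norm.ppf((ranks - 0.5) / n)
    cols = {}
    if names is None:
        names = [f"criterion{j + 1}" for j in range(len(target_rho))]
    for name, rho in zip(names, target_rho):
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        eps = rng.standard_normal(n)
        cols[name] = r * z + np.sqrt(1.0 - r**2) * eps
    return pd.DataFrame(cols)


def simulate_screening_columns(n_persons: int, n_careless: int = 0, seed: int = 0,
                               n_task_items: int = 10):
    """Auxiliary screening inputs: IMC failures, log response times, task
    responses — with ``n_careless`` planted invariant responders (first rows)."""
    rng = np.random.default_rng(seed)
    imc_fails = rng.binomial(1, 0.05, size=n_persons)
    log_rt = rng.normal(6.0, 0.4, size=n_persons)
    task = rng.integers(0, 4, size=(n_persons, n_task_items))
    for p in range(min(n_careless, n_persons)):
        run = n_task_items // 2 + 1
        start = rng.integers(0, n_task_items - run + 1)
        task[p, start : start + run] = task[p, start]
    return imc_fails, log_rt, task


def default_design(n_persons: int = 2500, n_categories: int = 4, seed: int = 0) -> SyntheticDesign:
    """The default 3-class ORS/ERS/RRS study preset."""
    return SyntheticDesign(n_persons=n_persons, n_categories=n_categories, seed=seed)
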