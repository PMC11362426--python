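"""Threshold-order diagnostics and response-style characterization.

In adjacent-category models, ordered thresholds (tau_{i,s-1} < tau_{i,s})
mean each category owns a segment of the latent continuum; a disordered
threshold signals an avoided category.  Classes are characterized by which
categories are modal across the central part of the class trait distribution,
how much of that range the extreme categories cover, and the disorder rate —
and heuristic style labels (ORS / ERS / RRS and extended variants) are
attached with the numeric evidence that triggered them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kernel import log_category_probabilities
from .parameters import ModelParameters

__all__ = [
    "ThresholdDiagnostics",
    "StyleProfile",
    "StyleRules",
    "disordered_threshold_counts",
    "style_metrics",
    "assign_style_labels",
]


@dataclass
class ThresholdDiagnostics:
    """Disordered-threshold counts per class and item, plus scale percentages."""

    per_item_counts: np.ndarray  # (G, I)
    scale_percentages: np.ndarray  # (G,)

    def to_dataframe(self) -> pd.DataFrame:
        G, I = self.per_item_counts.shape
        df = pd.DataFrame(
            self.per_item_counts,
            index=[f"class{g + 1}" for g in range(G)],
            columns=[f"item{i + 1}" for i in range(I)],
        )
        df["scale_percentage"] = self.scale_percentages
        return df


def disordered_threshold_counts(
    model: ModelParameters, longest_run_counting: bool = False
) -> ThresholdDiagnostics:
    """Count disordered thresholds per item and class.

    Default counting: threshold s (s >= 2) is disordered when
    tau_{i,s} < tau_{i,s-1} (the violation is charged to the right member of
    the adjacent pair).  The scale percentage divides the class total by the
    I * m thresholds of the scale.  ``longest_run_counting=True`` instead
    counts, per item, m minus the longest strictly increasing subsequence of
    the threshold sequence (an alternative convention for runs of violations).
    """
    tau = model.threshold_array  # (G, I, m)
    G, I, m = tau.shape
    if longest_run_counting:
        counts = np.zeros((G, I), dtype=int)
        for g in range(G):
            for i in range(I):
                counts[g, i] = m - _longest_increasing_subsequence(tau[g, i])
    else:
        counts = (np.diff(tau, axis=-1) < 0).sum(axis=-1).astype(int)
    pct = 100.0 * counts.sum(axis=1) / (I * m)
    return ThresholdDiagnostics(per_item_counts=counts, scale_percentages=pct)


def _longest_increasing_subsequence(x: np.ndarray) -> int:
    best = []
    for v in x:
        lo, hi = 0, len(best)
        while lo < hi:
            mid = (lo + hi) // 2
            if best[mid] < v:
                lo = mid + 1
            else:
                hi = mid
        if lo == len(best):
            best.append(v)
        else:
            best[lo] = v
    return len(best)


@dataclass
class StyleProfile:
    """Numeric response-style evidence for one latent class."""

    class_index: int
    modal_sets: list[np.ndarray]  # per item: categories modal in the central range
    mean_modal_count: float
    extreme_coverage: float  # fraction of central range where category 0 or m is modal
    top_extreme_coverage: float
    bottom_extreme_coverage: float
    near_extreme_coverage: float  # categories 1 and m-1
    upper_nonextreme_coverage: float  # categories in (m/2, m)
    disorder_percentage: float
    m: int
    label: str | None = None
    triggered_rule: str | None = None


def style_metrics(model: ModelParameters, class_index: int,
                  theta_coverage: float = 0.95, n_grid: int = 2001) -> StyleProfile:
    """Modal-category structure of one class over its central trait range.

    The central range is the symmetric ``theta_coverage`` interval of
    N(0, sigma_g^2).  Coverage shares are averaged over items and measure the
    fraction of the range where the named categories are modal.
    """
    G = model.n_classes
    if not 0 <= class_index < G:
        raise ValueError("invalid class index")
    cp = model.classes[class_index]
    m = model.scale.m
    half = norm.ppf(0.5 + theta_coverage / 2.0) * cp.trait_sd
    grid = np.linspace(-half, half, n_grid)
    modal_sets = []
    counts = np.zeros(model.scale.n_categories)
    for i in range(model.n_items):
        logp = log_category_probabilities(grid, cp.thresholds[i], model.discriminations[i])
        cats = np.argmax(logp, axis=-1)
        modal_sets.append(np.unique(cats))
        counts += np.bincount(cats, minlength=model.scale.n_categories)
    shares = counts / (n_grid * model.n_items)
    upper = np.arange(m // 2 + 1, m)  # non-extreme upper categories
    disorder = disordered_threshold_counts(model).scale_percentages[class_index]
    return StyleProfile(
        class_index=class_index,
        modal_sets=modal_sets,
        mean_modal_count=float(np.mean([s.size for s in modal_sets])),
        extreme_coverage=float(shares[0] + shares[m]),
        top_extreme_coverage=float(shares[m]),
        bottom_extreme_coverage=float(shares[0]),
        near_extreme_coverage=float(shares[1] + shares[m - 1]) if m >= 2 else 0.0,
        upper_nonextreme_coverage=float(shares[upper].sum()) if upper.size else 0.0,
        disorder_percentage=float(disorder),
        m=m,
    )


@dataclass(frozen=True)
class StyleRules:
    """Cutoffs of the heuristic style labels (all exposed, all documented).

    Rules are evaluated in a fixed order (eERS, ERS, ORS, RRS, eRRS) and the
    first match wins; a profile matching none is labelled "other".  The label
    never replaces the numeric evidence, which stays on the profile.
    """

    ers_extreme_coverage: float = 0.60
    eers_extreme_coverage: float = 0.50
    eers_near_extreme_coverage: float = 0.20
    ors_max_disorder_pct: float = 25.0
    rrs_max_modal_count: float = 3.0
    rrs_upper_coverage: float = 0.50
    rrs_max_extreme_coverage: float = 0.20
    errs_extreme_range: tuple = (0.20, 0.50)


def _label_one(p: StyleProfile, r: StyleRules) -> tuple[str, str]:
    if (
        p.extreme_coverage >= r.eers_extreme_coverage
        and p.near_extreme_coverage >= r.eers_near_extreme_coverage
    ):
        return "eERS", (
            f"extreme_coverage={p.extreme_coverage:.2f}>={r.eers_extreme_coverage} and "
            f"near_extreme_coverage={p.near_extreme_coverage:.2f}>={r.eers_near_extreme_coverage}"
        )
    if p.extreme_coverage >= r.ers_extreme_coverage:
        return "ERS", f"extreme_coverage={p.extreme_coverage:.2f}>={r.ers_extreme_coverage}"
    if p.disorder_percentage <= r.ors_max_disorder_pct and p.mean_modal_count >= p.m:
        return "ORS", (
            f"disorder%={p.disorder_percentage:.1f}<={r.ors_max_disorder_pct} and "
            f"mean_modal_count={p.mean_modal_count:.1f}>=m={p.m}"
        )
    if (
        p.mean_modal_count <= r.rrs_max_modal_count
        and p.upper_nonextreme_coverage >= r.rrs_upper_coverage
        and p.extreme_coverage <= r.rrs_max_extreme_coverage
    ):
        return "RRS", (
            f"mean_modal_count={p.mean_modal_count:.1f}<={r.rrs_max_modal_count}, "
            f"upper_nonextreme_coverage={p.upper_nonextreme_coverage:.2f}"
            f">={r.rrs_upper_coverage}, extreme_coverage={p.extreme_coverage:.2f}"
        )
    lo, hi = r.errs_extreme_range
    if (
        p.mean_modal_count <= r.rrs_max_modal_count
        and p.upper_nonextreme_coverage >= r.rrs_upper_coverage
        and lo < p.extreme_coverage < hi
    ):
        return "eRRS", (
            f"RRS shape with extreme_coverage={p.extreme_coverage:.2f} in ({lo}, {hi})"
        )
    return "other", "no rule matched; see numeric evidence"


def assign_style_labels(profiles: list[StyleProfile],
                        rules: StyleRules | None = None) -> list[StyleProfile]:
    """Attach heuristic style labels to class profiles (first matching rule)."""
    rules = rules or StyleRules()
    for p in profiles:
        p.label, p.triggered_rule = _label_one(p, rules)
    return profiles


def profile_classes(model: ModelParameters, theta_coverage: float = 0.95,
                    rules: StyleRules | None = None) -> list[StyleProfile]:
    """Style profiles with labels for every class of a model."""
    profiles = [style_metrics(model, g, theta_coverage) for g in range(model.n_classes)]
    return assign_style_labels(profiles, rules)
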