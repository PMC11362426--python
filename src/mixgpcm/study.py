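"""Downstream study statistics: screening, paired proportions, correlations,
reliability.

Covers the analysis steps that surround the mixture model in a rating-scale
study: careless-responder screening, the McNemar test and population odds
ratio for paired ordinary-response-style membership across two administration
conditions, Spearman criterion correlations and their comparison between
independent groups (Spearman -> Pearson -> Fisher z), Bonferroni control,
and McDonald's omega with a bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedStyleTable",
    "CorrelationComparison",
    "ScreeningReport",
    "screen_careless",
    "mcnemar_test",
    "population_odds_ratio",
    "spearman_correlations",
    "compare_independent_correlations",
    "bonferroni_alpha",
    "mcdonalds_omega",
    "run_study",
]


@dataclass(frozen=True)
class PairedStyleTable:
    """2x2 concordant/discordant counts of ORS membership across conditions.

    Rows index the given condition (ORS yes / no), columns the self-chosen
    condition.  ``n12`` counts switchers from non-ORS (given) to ORS
    (self-chosen) following the switch-proportion convention pi_12; ``n21``
    the reverse.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self):
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @classmethod
    def from_memberships(cls, ors_given, ors_chosen) -> "PairedStyleTable":
        g = np.asarray(ors_given, bool)
        c = np.asarray(ors_chosen, bool)
        if g.shape != c.shape:
            raise ValueError("membership vectors must align")
        return cls(
            n11=int(np.sum(g & c)),
            n12=int(np.sum(~g & c)),
            n21=int(np.sum(g & ~c)),
            n22=int(np.sum(~g & ~c)),
        )


def mcnemar_test(table: PairedStyleTable):
    """McNemar chi-square for paired binary outcomes, without continuity
    correction; returns (chi_square, df, p_two_sided, p_one_sided).

    The one-sided p halves the two-sided value when the discordance runs in
    the hypothesized direction (n12 > n21), else it is its complement.
    """
    d = table.n12 + table.n21
    if d == 0:
        warnings.warn("no discordant pairs; McNemar statistic undefined, returning 0")
        return 0.0, 1, 1.0, 1.0
    chi2 = (table.n12 - table.n21) ** 2 / d
    p_two = float(stats.chi2.sf(chi2, df=1))
    p_one = p_two / 2.0 if table.n12 > table.n21 else 1.0 - p_two / 2.0
    return float(chi2), 1, p_two, p_one


def population_odds_ratio(table: PairedStyleTable) -> float:
    """OR_pop = pi_12 / pi_21 = n12 / n21, the relative odds of switching
    into versus out of ordinary response behavior."""
    if table.n21 == 0:
        warnings.warn("n21 = 0; population odds ratio is infinite")
        return float("inf")
    return table.n12 / table.n21


def bonferroni_alpha(alpha_family: float, k: int) -> float:
    """Per-comparison significance level alpha_family / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha_family / k


# ----------------------------------------------------------------------
# correlations
# ----------------------------------------------------------------------

def spearman_correlations(scores, externals: pd.DataFrame) -> pd.Series:
    """Spearman rank correlations (average ranks for ties, pairwise-complete)
    between one score vector and each criterion column."""
    scores = np.asarray(scores, float)
    out = {}
    for col in externals.columns:
        y = np.asarray(externals[col], float)
        ok = np.isfinite(scores) & np.isfinite(y)
        if ok.sum() < 4:
            raise ValueError(f"fewer than 4 complete pairs for criterion {col!r}")
        if np.unique(scores[ok]).size < 2 or np.unique(y[ok]).size < 2:
            out[col] = np.nan  # undefined for constant input
            continue
        out[col] = float(stats.spearmanr(scores[ok], y[ok]).statistic)
    return pd.Series(out, name="spearman_rho")


@dataclass(frozen=True)
class CorrelationComparison:
    rho1: float
    rho2: float
    n1: int
    n2: int
    z_statistic: float
    p_value: float
    alpha_corrected: float | None = None


def compare_independent_correlations(rho1: float, n1: int, rho2: float, n2: int,
                                     alpha_corrected: float | None = None,
                                     fieller_adjustment: bool = False) -> CorrelationComparison:
    """Compare two independent Spearman correlations.

    Each rho is first converted to the Pearson scale via r = 2 sin(pi rho / 6)
    and then Fisher-z transformed; the test statistic is
    Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) with a two-sided normal p-value.
    ``fieller_adjustment`` inflates each variance by 1.06 (Fieller's factor
    for rank correlations); off by default.
    """
    for n in (n1, n2):
        if n < 4:
            raise ValueError("group sizes must be at least 4")
    for rho in (rho1, rho2):
        if abs(rho) >= 1:
            raise ValueError("correlations of magnitude 1 cannot be z-transformed")
    infl = 1.06 if fieller_adjustment else 1.0
    z1 = np.arctanh(2.0 * np.sin(np.pi * rho1 / 6.0))
    z2 = np.arctanh(2.0 * np.sin(np.pi * rho2 / 6.0))
    se = np.sqrt(infl / (n1 - 3) + infl / (n2 - 3))
    Z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(Z))
    return CorrelationComparison(rho1, rho2, n1, n2, float(Z), float(p), alpha_corrected)


# ----------------------------------------------------------------------
# screening
# ----------------------------------------------------------------------

@dataclass
class ScreeningReport:
    flags: pd.DataFrame  # columns imc_fail, fast_rt, invariant_runs, retained
    thresholds: dict

    @property
    def retained(self) -> np.ndarray:
        return self.flags["retained"].to_numpy()


def _longest_run(row: np.ndarray) -> int:
    best = run = 1
    for a, b in zip(row[:-1], row[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def screen_careless(imc_fails=None, log_rt=None, task_responses=None,
                    imc_threshold: int = 2, rt_sd_multiplier: float = 3.0,
                    invariant_fraction: float = 0.5) -> ScreeningReport:
    """Flag careless responders by three rules.

    (1) at least ``imc_threshold`` failed instructional manipulation checks;
    (2) log response time strictly below mean - 3 SD of the supplied log-RT
        vector (the cutoff is computed from the data themselves; a person at
        exactly the cutoff is retained);
    (3) an invariant (constant) run covering at least half of the successive
        task items.
    Missing inputs skip the corresponding rule with a warning.  A person is
    retained iff no flag is set.
    """
    lengths = [len(v) for v in (imc_fails, log_rt) if v is not None]
    if task_responses is not None:
        lengths.append(np.asarray(task_responses).shape[0])
    if not lengths:
        raise ValueError("at least one screening input is required")
    if len(set(lengths)) > 1:
        raise ValueError("screening inputs must align by person")
    n = lengths[0]
    flags = pd.DataFrame(index=range(n))
    thresholds = {
        "imc_threshold": imc_threshold,
        "rt_sd_multiplier": rt_sd_multiplier,
        "invariant_fraction": invariant_fraction,
    }
    if imc_fails is not None:
        flags["imc_fail"] = np.asarray(imc_fails) >= imc_threshold
    else:
        warnings.warn("no manipulation-check data; IMC rule skipped")
        flags["imc_fail"] = False
    if log_rt is not None:
        log_rt = np.asarray(log_rt, float)
        cutoff = log_rt.mean() - rt_sd_multiplier * log_rt.std(ddof=1)
        thresholds["rt_cutoff"] = float(cutoff)
        flags["fast_rt"] = log_rt < cutoff  # strict: exactly at the cutoff passes
    else:
        warnings.warn("no response-time data; RT rule skipped")
        flags["fast_rt"] = False
    if task_responses is not None:
        task = np.asarray(task_responses)
        need = int(np.ceil(task.shape[1] * invariant_fraction))
        runs = np.array([_longest_run(row) for row in task])
        flags["invariant_runs"] = runs >= max(need, 2)
    else:
        warnings.warn("no task responses; invariance rule skipped")
        flags["invariant_runs"] = False
    flags["retained"] = ~(flags["imc_fail"] | flags["fast_rt"] | flags["invariant_runs"])
    return ScreeningReport(flags=flags, thresholds=thresholds)


# ----------------------------------------------------------------------
# McDonald's omega
# ----------------------------------------------------------------------

def _omega_point(data: np.ndarray) -> float:
    """Omega from a one-factor ML fit to the item correlations, rescaled to
    the raw-score covariance metric; loadings are sign-aligned (equivalent to
    reverse-coding) before summing."""
    from statsmodels.multivariate.factor import Factor

    corr = np.corrcoef(data, rowvar=False)
    sds = data.std(axis=0, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = Factor(corr=corr, n_factor=1, method="ml").fit()
    load_std = np.abs(fit.loadings[:, 0])
    lam = load_std * sds
    psi = np.clip(1.0 - load_std**2, 0.0, None) * sds**2
    s = lam.sum()
    return float(s**2 / (s**2 + psi.sum()))


def mcdonalds_omega(responses, n_bootstrap: int = 1000, seed: int = 0,
                    ci_level: float = 0.95):
    """McDonald's omega of a scale with a percentile-bootstrap CI.

    Fits a one-factor model to the item covariance structure; omega is
    (sum lambda)^2 / ((sum lambda)^2 + sum psi).  The CI resamples persons.
    Returns (omega, (lower, upper)).
    """
    data = np.asarray(
        responses.values if hasattr(responses, "values") else responses, float
    )
    if data.shape[1] < 3:
        raise ValueError("omega needs at least 3 items")
    if data.shape[0] < 10:
        raise ValueError("too few persons for a stable factor fit")
    try:
        omega = _omega_point(data)
    except Exception as exc:  # non-convergent factor fit
        raise RuntimeError(f"one-factor fit failed: {exc}") from exc
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, data.shape[0], size=data.shape[0])
        try:
            boots.append(_omega_point(data[idx]))
        except Exception:
            continue
    if boots:
        lo, hi = np.quantile(boots, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    else:
        lo = hi = np.nan
    return omega, (float(lo), float(hi))


# ----------------------------------------------------------------------
# full-study orchestration
# ----------------------------------------------------------------------

def run_study(config: dict) -> dict:
    """Run the full analysis sequence on a synthetic paired design.

    Stages: screening (if auxiliary data requested) -> per-condition mixture
    fits over a class range -> saBIC selection -> bootstrap GoF -> threshold
    diagnostics and style labels -> paired ORS McNemar + odds ratio ->
    criterion correlations with Bonferroni-corrected comparison -> omega and
    model-based reliability.  Each stage failure is recorded in the report
    without discarding earlier results.  Deterministic given ``config['seed']``.
    """
    from . import diagnostics as diag
    from .model import MixedGPCM, EstimationOptions
    from .selection import FitStatistics, bootstrap_gof, select_best_model
    from .simulate import (
        SyntheticDesign,
        simulate_external_criteria,
        simulate_paired_conditions,
        simulate_screening_columns,
    )

    seed = int(config.get("seed", 0))
    n_persons = int(config.get("n_persons", 600))
    n_categories = int(config.get("n_categories", 4))
    class_range = list(config.get("class_range", [1, 2, 3]))
    est = config.get("estimation", {})
    options = EstimationOptions(
        n_quadrature_nodes=int(est.get("n_quadrature_nodes", 21)),
        max_em_iterations=int(est.get("max_em_iterations", 300)),
        n_starts=int(est.get("n_starts", 3)),
        burnin_iterations=int(est.get("burnin_iterations", 25)),
        seed=seed,
    )
    report: dict = {"seed": seed, "config": config, "stages": {}}

    def stage(name, fn):
        try:
            report[name] = fn()
            report["stages"][name] = "ok"
        except Exception as exc:  # keep earlier results
            report["stages"][name] = f"failed: {exc}"

    design_given = SyntheticDesign(
        n_persons=n_persons, n_categories=n_categories, seed=seed
    )
    design_chosen = SyntheticDesign(
        n_persons=n_persons, n_categories=n_categories, seed=seed + 1
    )
    switch = np.asarray(
        config.get(
            "switch_matrix",
            [[0.85, 0.10, 0.05], [0.35, 0.60, 0.05], [0.30, 0.05, 0.65]],
        ),
        float,
    )
    sim = simulate_paired_conditions(design_given, design_chosen, switch, n_persons, seed)

    if config.get("screening", True):
        def _screening():
            imc, rt, task = simulate_screening_columns(n_persons, n_careless=0, seed=seed)
            rep = screen_careless(imc_fails=imc, log_rt=rt, task_responses=task)
            return {
                "n_retained": int(rep.retained.sum()),
                "thresholds": rep.thresholds,
            }
        stage("screening", _screening)

    fits = {}

    def _fit_condition(name, responses):
        stats_rows = []
        results = {}
        for G in class_range:
            res = MixedGPCM(responses, n_classes=G).fit(options=options)
            results[G] = res
            stats_rows.append(
                FitStatistics(
                    n_classes=G,
                    ll=res.log_likelihood,
                    n_parameters=res.n_parameters,
                    n_persons=responses.n_persons,
                )
            )
        best = select_best_model(stats_rows)
        fits[name] = results[class_range[best]]
        return {
            "table": [
                {
                    "n_classes": s.n_classes,
                    "n_parameters": s.n_parameters,
                    "ll": s.ll,
                    "saBIC": s.saBIC,
                }
                for s in stats_rows
            ],
            "selected_classes": class_range[best],
        }

    stage("fit_given", lambda: _fit_condition("given", sim.responses))
    stage("fit_chosen", lambda: _fit_condition("chosen", sim.paired_responses))

    if config.get("bootstrap_gof", False) and "given" in fits:
        stage(
            "gof_given",
            lambda: bootstrap_gof(
                fits["given"],
                n_bootstrap=int(config.get("n_bootstrap", 50)),
                seed=seed,
                refit_max_iterations=30,
            ),
        )

    def _diagnostics():
        out = {}
        for name, res in fits.items():
            table = diag.disordered_threshold_counts(res.params)
            profiles = diag.profile_classes(res.params)
            out[name] = {
                "disordered_counts": table.per_item_counts.tolist(),
                "scale_percentages": table.scale_percentages.tolist(),
                "labels": [p.label for p in profiles],
                "rules": [p.triggered_rule for p in profiles],
            }
        return out

    stage("diagnostics", _diagnostics)

    def _paired():
        if not {"given", "chosen"} <= fits.keys():
            raise RuntimeError("both condition fits required")
        labels_g = [p.label for p in diag.profile_classes(fits["given"].params)]
        labels_c = [p.label for p in diag.profile_classes(fits["chosen"].params)]
        ors_g = np.isin(fits["given"].modal_assignment(),
                        [i for i, l in enumerate(labels_g) if l == "ORS"])
        ors_c = np.isin(fits["chosen"].modal_assignment(),
                        [i for i, l in enumerate(labels_c) if l == "ORS"])
        table = PairedStyleTable.from_memberships(ors_g, ors_c)
        chi2, df, p2, p1 = mcnemar_test(table)
        return {
            "table": [table.n11, table.n12, table.n21, table.n22],
            "ors_share_given": float(np.mean(ors_g)),
            "ors_share_chosen": float(np.mean(ors_c)),
            "chi_square": chi2,
            "p_two_sided": p2,
            "p_one_sided": p1,
            "odds_ratio": population_odds_ratio(table),
            "alpha_corrected": bonferroni_alpha(0.05, 3),
        }

    stage("paired_ors", _paired)

    def _validity():
        target = config.get("criterion_rho", [0.4, -0.3])
        crit = simulate_external_criteria(sim.true_theta, target, seed=seed + 2)
        rows = {}
        for name, res in fits.items():
            scores = res.eap_scores()["eap"].to_numpy()
            rows[name] = spearman_correlations(scores, crit).to_dict()
        comparison = None
        if len(rows) == 2:
            (na, ra), (nb, rb) = rows.items()
            first = list(crit.columns)[0]
            comp = compare_independent_correlations(
                ra[first], n_persons, rb[first], n_persons,
                alpha_corrected=bonferroni_alpha(0.05, len(crit.columns)),
            )
            comparison = {"z": comp.z_statistic, "p": comp.p_value,
                          "alpha_corrected": comp.alpha_corrected}
        return {"correlations": rows, "comparison": comparison}

    stage("criterion_validity", _validity)

    def _reliability():
        out = {}
        for name, res in fits.items():
            omega, ci = mcdonalds_omega(
                res.model.data.values, n_bootstrap=int(config.get("omega_bootstrap", 50)),
                seed=seed,
            )
            out[name] = {
                "omega": omega,
                "omega_ci": ci,
                "model_based_reliability": res.model_based_reliability(),
            }
        return out

    stage("reliability", _reliability)
    return report
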