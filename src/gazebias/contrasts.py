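"""Estimated marginal means and odds-ratio contrasts for the orienting model.

EMMs are the model-implied logit-scale means of the four cohort-by-
condition cells with the random intercept at its zero mean; they are
back-transformed to probabilities by applying the inverse logit to the
point estimate and to the CI endpoints (endpoint transformation keeps the
asymmetry of the interval on the probability scale).  A population-
averaged variant that integrates the probability over the random-intercept
distribution is available via ``population_averaged=True`` and is labeled
distinctly in the output.

Pairwise contrasts compare aggressive vs non-aggressive within each
cohort on the log-odds scale; the exponentiated difference is the odds
ratio.  Multiplicity adjustment over the contrast family: 'none'
(default), 'bonferroni', 'holm' or 'tukey' (studentized range over the
four cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import DataError
from .mixed_models import DesignSpec, MixedModelFit

ADJUSTMENTS = ("none", "bonferroni", "holm", "tukey")

#: design vectors of the four cohort x condition cells under treatment
#: coding with reference (adolescent, aggressive)
CELL_DESIGN = {
    ("adolescent", "aggressive"): np.array([1.0, 0.0, 0.0, 0.0]),
    ("adolescent", "non_aggressive"): np.array([1.0, 1.0, 0.0, 0.0]),
    ("child", "aggressive"): np.array([1.0, 0.0, 1.0, 0.0]),
    ("child", "non_aggressive"): np.array([1.0, 1.0, 1.0, 1.0]),
}


@dataclass
class EMMCell:
    """One cohort x condition estimated marginal mean."""

    cohort: str
    condition: str
    eta: float
    se: float
    ci_logit: tuple[float, float]
    prob: float
    prob_ci: tuple[float, float]


@dataclass
class ContrastResult:
    """One pairwise contrast expressed as an odds ratio."""

    label: str
    log_or: float
    or_value: float
    se: float
    z: float
    p_raw: float
    p_adj: float
    adjustment: str


def back_transform(eta: float, ci: tuple[float, float]) -> tuple[float, tuple[float, float]]:
    """Inverse-logit of a logit-scale estimate and its interval endpoints."""
    lo, hi = ci
    return float(expit(eta)), (float(expit(lo)), float(expit(hi)))


def _check_fit(fit: MixedModelFit) -> None:
    if not np.all(np.isfinite(fit.vcov)):
        raise DataError("rank-deficient or undefined fixed-effect covariance")


def emm_grid(
    fit: MixedModelFit,
    spec: DesignSpec | None = None,
    conf_level: float = 0.95,
    population_averaged: bool = False,
    n_quad: int = 51,
) -> list[EMMCell]:
    """EMMs of the four design cells, back-transformed to probabilities.

    With ``population_averaged=True`` the reported probability is
    E[logit^-1(eta + b)] over b ~ N(0, sigma_b^2) (Gauss-Hermite), i.e. the
    marginal probability in the population rather than for an average
    subject; the logit-scale columns are unchanged.
    """
    _check_fit(fit)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    cells: list[EMMCell] = []
    sigma_b = np.sqrt(max(fit.sigma_b2, 0.0))
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    for (cohort, condition), c in CELL_DESIGN.items():
        eta = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.vcov @ c))
        ci = (eta - z * se, eta + z * se)
        if population_averaged and sigma_b > 0:
            pav = lambda m: float(
                np.sum(weights * expit(m + np.sqrt(2.0) * sigma_b * nodes))
                / np.sqrt(np.pi)
            )
            prob, prob_ci = pav(eta), (pav(ci[0]), pav(ci[1]))
        else:
            prob, prob_ci = back_transform(eta, ci)
        cells.append(
            EMMCell(
                cohort=cohort,
                condition=condition,
                eta=eta,
                se=se,
                ci_logit=(float(ci[0]), float(ci[1])),
                prob=prob,
                prob_ci=prob_ci,
            )
        )
    return cells


def emm_frame(cells: list[EMMCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cohort": [c.cohort for c in cells],
            "condition": [c.condition for c in cells],
            "eta": [c.eta for c in cells],
            "se": [c.se for c in cells],
            "ci_low": [c.ci_logit[0] for c in cells],
            "ci_high": [c.ci_logit[1] for c in cells],
            "prob": [c.prob for c in cells],
            "prob_lo": [c.prob_ci[0] for c in cells],
            "prob_hi": [c.prob_ci[1] for c in cells],
        }
    )


def _adjust(p_raw: np.ndarray, z: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if method == "none":
        return p_raw.copy()
    if method == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(running, 1.0)
        return adj
    if method == "tukey":
        # studentized range over the k=4 cells, asymptotic (normal) version
        k = len(CELL_DESIGN)
        q = np.abs(z) * np.sqrt(2.0)
        return stats.studentized_range.sf(q, k, np.inf)
    raise ValueError(f"unknown adjustment method {method!r}; use one of {ADJUSTMENTS}")


def pairwise_contrasts(
    fit: MixedModelFit,
    adjustment: str = "none",
    direction: str = "aggressive_vs_non_aggressive",
) -> list[ContrastResult]:
    """Aggressive vs non-aggressive log-odds contrast within each cohort.

    ``direction`` fixes the sign convention; reversing it inverts every
    odds ratio and negates the z statistics.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment method {adjustment!r}; use one of {ADJUSTMENTS}")
    _check_fit(fit)
    sign = 1.0
    a, b = "aggressive", "non_aggressive"
    if direction == "non_aggressive_vs_aggressive":
        sign = -1.0
        a, b = b, a
    elif direction != "aggressive_vs_non_aggressive":
        raise ValueError("unknown contrast direction")

    rows = []
    for cohort in ("adolescent", "child"):
        c = sign * (
            CELL_DESIGN[(cohort, "aggressive")] - CELL_DESIGN[(cohort, "non_aggressive")]
        )
        log_or = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.vcov @ c))
        z = log_or / se
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        rows.append((f"{a} vs {b} | {cohort}", log_or, se, z, p_raw))

    p_raw_arr = np.array([r[4] for r in rows])
    z_arr = np.array([r[3] for r in rows])
    p_adj = np.maximum(_adjust(p_raw_arr, z_arr, adjustment), p_raw_arr)
    return [
        ContrastResult(
            label=label,
            log_or=log_or,
            or_value=float(np.exp(log_or)),
            se=se,
            z=z,
            p_raw=p,
            p_adj=float(pa),
            adjustment=adjustment,
        )
        for (label, log_or, se, z, p), pa in zip(rows, p_adj)
    ]


def contrast_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "log_or": [r.log_or for r in results],
            "or": [r.or_value for r in results],
            "se": [r.se for r in results],
            "z": [r.z for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "method": [r.adjustment for r in results],
        }
    )
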