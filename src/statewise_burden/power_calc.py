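"""Analytic case-control power for single-variant association.

Model: a bi-allelic risk allele at frequency ``raf`` acting multiplicatively
on the odds scale — genotype odds are ``odds0 * OR^g`` under HWE — with the
baseline odds ``odds0`` solved so the population prevalence equals K.
Cases follow the genotype distribution conditional on disease; controls are
population-based (unscreened), so their genotype distribution is the
population's.  Power for the 1-df allele-dosage (Cochran-Armitage trend)
chi-square is computed from its non-centrality at the expected case/control
genotype counts:

    power = P( chi2_1(ncp) > q_{1 - alpha} )

and the minimal detectable OR is found by bisection of power = target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .burden_tests import BONFERRONI_TABLE

__all__ = [
    "PowerSpec",
    "disease_model_frequencies",
    "power_cc",
    "or_for_power",
    "bonferroni_constants",
]


@dataclass
class PowerSpec:
    raf: float  # risk allele frequency
    or_per_allele: float  # odds ratio per risk allele
    prevalence: float
    n_case: int
    n_control: int
    alpha: float = 5e-9

    def validate(self) -> None:
        if not 0 < self.raf < 1:
            raise ValueError("raf must be in (0,1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.or_per_allele <= 0:
            raise ValueError("odds ratio must be positive")


def disease_model_frequencies(spec: PowerSpec, scale: str = "risk"):
    """Expected genotype frequencies in cases and controls.

    Returns ``(case_freqs, control_freqs, baseline_odds)`` over genotypes
    g = 0,1,2 risk alleles.  ``scale='risk'`` (default) multiplies genotype
    *penetrances*, ``f_g = f_0 . OR^g``, the Genetic Power Calculator
    convention for a multiplicative model; under it the case risk-allele
    frequency is exactly ``p.OR / (1 - p + p.OR)``.  ``scale='odds'``
    multiplies genotype odds instead, ``odds_g = odds_0 . OR^g``, which
    saturates for highly penetrant genotypes.  In both cases the baseline
    is solved by log-space bisection (tolerance 1e-12 relative) so the
    implied population prevalence equals K; control frequencies are the
    population HWE frequencies (population-based, unscreened controls).
    """
    spec.validate()
    p = spec.raf
    pop = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    orv = spec.or_per_allele ** np.arange(3)

    if scale == "risk":
        def penetrance(base):
            return np.minimum(base * orv, 1.0)
    elif scale == "odds":
        def penetrance(base):
            return base * orv / (1 + base * orv)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    def prevalence_at(base):
        return float(pop @ penetrance(base))

    lo, hi = 1e-15, 1e15 if scale == "odds" else 1.0
    if not prevalence_at(lo) <= spec.prevalence <= prevalence_at(hi):
        raise ValueError("no baseline risk yields the requested prevalence")
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisect in log space
        if prevalence_at(mid) < spec.prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * hi:
            break
    base = np.sqrt(lo * hi)
    pen = penetrance(base)
    if scale == "risk" and np.any(base * orv > 1):
        raise ValueError("penetrance exceeds 1 under the risk-scale model")
    case = pop * pen
    case = case / case.sum()
    f0 = pen[0]
    baseline_odds = f0 / (1 - f0)
    return case, pop.copy(), float(baseline_odds)


def _trend_ncp(case_f, ctrl_f, n_case, n_control):
    """Cochran-Armitage trend chi-square evaluated at expected counts."""
    x = np.arange(3, dtype=float)
    r = n_case * case_f
    n = n_case * case_f + n_control * ctrl_f
    N = n_case + n_control
    R = n_case
    num = N * (N * (x @ r) - R * (x @ n)) ** 2
    den = R * (N - R) * (N * (x**2 @ n) - (x @ n) ** 2)
    return float(num / den) if den > 0 else 0.0


def _allelic_ncp(case_f, ctrl_f, n_case, n_control):
    """1-df chi-square of the 2x2 allele-count table at expected counts."""
    p_case = case_f[1] / 2 + case_f[2]
    p_ctrl = ctrl_f[1] / 2 + ctrl_f[2]
    m_case, m_ctrl = 2 * n_case, 2 * n_control
    p_bar = (m_case * p_case + m_ctrl * p_ctrl) / (m_case + m_ctrl)
    if p_bar <= 0 or p_bar >= 1:
        return 0.0
    return float(
        (p_case - p_ctrl) ** 2 / (p_bar * (1 - p_bar) * (1 / m_case + 1 / m_ctrl))
    )


def power_cc(spec: PowerSpec, mode: str = "trend", scale: str = "risk") -> float:
    """Power of the 1-df case-control test at significance level alpha.

    ``mode='trend'`` (default) uses the genotype trend-test non-centrality;
    ``mode='allelic'`` uses the 2x2 allele-count chi-square as a
    sensitivity alternative.  ``scale`` selects the disease-model
    parameterisation (see ``disease_model_frequencies``).
    """
    case_f, ctrl_f, _ = disease_model_frequencies(spec, scale=scale)
    if mode == "trend":
        ncp = _trend_ncp(case_f, ctrl_f, spec.n_case, spec.n_control)
    elif mode == "allelic":
        ncp = _allelic_ncp(case_f, ctrl_f, spec.n_case, spec.n_control)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    crit = stats.chi2.ppf(1 - spec.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(spec.alpha)


def or_for_power(
    spec: PowerSpec, target: float = 0.80, mode: str = "trend", scale: str = "risk"
) -> float:
    """Smallest OR > 1 reaching the target power (bisection, tol 1e-6)."""
    if not 0 < target < 1:
        raise ValueError("target power must be in (0,1)")

    def f(or_value):
        try:
            return power_cc(replace(spec, or_per_allele=or_value), mode=mode, scale=scale) - target
        except ValueError:
            # risk-scale penetrance saturates at extreme ORs; power is past
            # the target well before that point
            return 1.0 - target

    lo, hi = 1.0 + 1e-9, 100.0
    if f(hi) < 0:
        raise ValueError("target power unreachable for OR <= 100")
    return float(brentq(f, lo, hi, xtol=1e-6))


def bonferroni_constants() -> dict:
    """The audited table of multiple-testing constants used in the study."""
    return dict(BONFERRONI_TABLE)
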