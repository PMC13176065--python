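"""Disproportionality statistics and consensus signal classification.

Four algorithms, each comparing a drug-event pair's reporting frequency to the
background of all other reports:

* **ROR** — reporting odds ratio ad/(bc) with a Wald 95% CI on the log scale.
* **PRR** — proportional reporting ratio [a/(a+b)]/[c/(c+d)] flagged together
  with the Pearson chi-square of the 2x2 table.
* **BCPNN IC** — information component, the log2 ratio of the joint reporting
  probability to the product of its margins, under the standard closed-form
  Bayesian posterior approximation (Dirichlet/Beta conjugate priors).
* **MGPS EBGM** — multi-item gamma-Poisson shrinker: an empirical-Bayes
  two-component gamma mixture prior on the relative reporting ratio
  lambda = a/E, fitted across all pairs of a run by marginal maximum
  likelihood; EBGM is the posterior geometric mean of lambda, EB05 its
  posterior 5th percentile.

A term is a *consensus signal* when all four criteria fire: ROR lower CI > 1;
PRR >= 2 with chi2 >= 4; IC - 2 SD > 0; EB05 > 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable

NAN = float("nan")


# ---------------------------------------------------------------------------
# Frequentist statistics
# ---------------------------------------------------------------------------

def ror_stats(t: ContingencyTable, z: float = 1.96) -> Tuple[float, float, float]:
    """Reporting odds ratio with Wald CI: exp(ln ROR -/+ z*sqrt(sum 1/cell)).

    Any zero cell makes the statistic undefined (returned as NaN); no Haldane
    correction is applied.
    """
    if t.has_zero_cell():
        return (NAN, NAN, NAN)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    half = z * se
    return (ror, ror * math.exp(-half), ror * math.exp(half))


def prr_chi2(t: ContingencyTable, yates: bool = False) -> Tuple[float, float]:
    """PRR and the 2x2 Pearson chi-square (no continuity correction by default)."""
    ab, cd, ac, bd = t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d
    if ab == 0 or cd == 0 or ac == 0 or t.c == 0:
        return (NAN, NAN)
    prr = (t.a / ab) / (t.c / cd)
    if bd == 0:
        return (prr, NAN)
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(0.0, diff - t.n / 2)
    chi2 = t.n * diff * diff / (ab * cd * ac * bd)
    return (prr, chi2)


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BcpnnPriors:
    """Conjugate prior constants of the closed-form BCPNN posterior.

    Defaults are the standard choice: symmetric Beta(1, 1) margins
    (alpha = beta = 2 prior totals) and a joint-cell prior gamma11 = 1 with
    gamma calibrated so the prior IC is centred at zero.
    """

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def gamma(self, t: ContingencyTable) -> float:
        """Joint-cell prior total, calibrated to the table's margins."""
        return (
            self.gamma11
            * (t.n + self.alpha)
            * (t.n + self.beta)
            / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1))
        )


def bcpnn_ic(
    t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()
) -> Tuple[float, float, float]:
    """Posterior expectation, variance and lower bound of the IC in bits.

    Returns ``(ic, ic_var, ic025)`` with ``ic025 = ic - 2*sqrt(ic_var)``,
    the "IC - 2 SD" signal quantity.
    """
    if t.n == 0:
        raise ValueError("empty table")
    a, n = t.a, t.n
    ab, ac = t.a + t.b, t.a + t.c
    al, be, al1, be1, g11 = (
        priors.alpha,
        priors.beta,
        priors.alpha1,
        priors.beta1,
        priors.gamma11,
    )
    g = priors.gamma(t)
    ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + g) * (ab + al1) * (ac + be1))
    )
    ic_var = (1 / math.log(2)) ** 2 * (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - ab + al - al1) / ((ab + al1) * (1 + n + al))
        + (n - ac + be - be1) / ((ac + be1) * (1 + n + be))
    )
    return (ic, ic_var, ic - 2.0 * math.sqrt(ic_var))


# ---------------------------------------------------------------------------
# MGPS: empirical-Bayes gamma-Poisson shrinkage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgpsHyperparams:
    """Five-parameter two-component gamma mixture prior on lambda = a/E."""

    alpha1_g: float
    beta1_g: float
    alpha2_g: float
    beta2_g: float
    p_mix: float

    def __post_init__(self) -> None:
        if min(self.alpha1_g, self.beta1_g, self.alpha2_g, self.beta2_g) <= 0:
            raise ValueError("gamma shapes/rates must be positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha1_g, self.beta1_g, self.alpha2_g, self.beta2_g, self.p_mix]
        )


#: DuMouchel's conventional optimizer start: component means 2 and 0.5, p = 1/3.
MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class MgpsConvergenceError(RuntimeError):
    def __init__(self, message: str, best: Sequence[float], grad_norm: float):
        super().__init__(f"{message} (best iterate {best}, |grad| {grad_norm:.3g})")
        self.best = tuple(best)
        self.grad_norm = grad_norm


def _mixture_logpmf(a, e, theta: np.ndarray) -> np.ndarray:
    """log marginal pmf of counts under the gamma-mixture Poisson model.

    Marginalising Poisson(lambda*E) over a Gamma(shape, rate) prior gives a
    negative binomial with n=shape and p = rate/(rate + E).
    """
    a1, b1, a2, b2, p = theta
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    return np.logaddexp(np.log(p) + lp1, np.log1p(-p) + lp2)


def mgps_fit(
    tables: Iterable[ContingencyTable],
    start: Sequence[float] = MGPS_START,
    gtol: float = 1e-6,
) -> MgpsHyperparams:
    """Fit the five mixture hyperparameters by marginal maximum likelihood.

    Bounded quasi-Newton (L-BFGS-B) on the summed negative log marginal
    likelihood over all (a, E) pairs; deterministic given the data (the fit
    is invariant to table order).
    """
    pairs = sorted((t.a, t.expected) for t in tables if t.expected > 0)
    if not pairs:
        raise ValueError("no tables with positive expected count")
    a = np.array([p[0] for p in pairs], dtype=float)
    e = np.array([p[1] for p in pairs], dtype=float)

    # optimize in log space for shapes/rates and logit space for the weight:
    # the surface is badly conditioned on the natural scale (e.g. near-null
    # databases push the shapes to very large values)
    def unpack(x: np.ndarray) -> np.ndarray:
        theta = np.empty(5)
        theta[:4] = np.exp(x[:4])
        theta[4] = 1.0 / (1.0 + math.exp(-x[4]))
        return theta

    def nll(x: np.ndarray) -> float:
        val = -float(np.sum(_mixture_logpmf(a, e, unpack(x))))
        return val if np.isfinite(val) else 1e12

    log_cap = math.log(1e6)
    bounds = [(-log_cap, log_cap)] * 4 + [(-13.8, 13.8)]
    # a stalled line search from one start is retried from perturbed starts
    # before giving up; the fixed start list keeps the fit deterministic
    starts = [
        np.asarray(start, dtype=float),
        np.array([1.0, 1.0, 1.0, 1.0, 0.5]),
        np.array([0.5, 0.25, 4.0, 2.0, 0.2]),
    ]
    res = None
    for s0 in starts:
        x0 = np.concatenate([np.log(s0[:4]), [math.log(s0[4] / (1 - s0[4]))]])
        cand = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol},
        )
        # L-BFGS-B sometimes stops on ftol with a perfectly usable optimum;
        # only a genuinely failed line search / abnormal exit is retried.
        abnormal = not cand.success and "ABNORMAL" in str(cand.message).upper()
        if res is None or cand.fun < res.fun:
            res = cand
        if not abnormal:
            res = cand if cand.fun <= res.fun else res
            break
    else:
        if "ABNORMAL" in str(res.message).upper():
            grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else NAN
            raise MgpsConvergenceError(str(res.message), unpack(res.x), grad_norm)
    a1, b1, a2, b2, p = unpack(res.x)
    return MgpsHyperparams(a1, b1, a2, b2, p)


def _posterior_mixture(t: ContingencyTable, theta: MgpsHyperparams):
    """Posterior over lambda: gamma mixture with updated shapes/rates and
    weights proportional to prior weight x marginal negative-binomial mass."""
    a, e = t.a, t.expected
    lw1 = math.log(theta.p_mix) + stats.nbinom.logpmf(
        a, theta.alpha1_g, theta.beta1_g / (theta.beta1_g + e)
    )
    lw2 = math.log1p(-theta.p_mix) + stats.nbinom.logpmf(
        a, theta.alpha2_g, theta.beta2_g / (theta.beta2_g + e)
    )
    m = max(lw1, lw2)
    w1 = math.exp(lw1 - m)
    w2 = math.exp(lw2 - m)
    q1 = w1 / (w1 + w2)
    shapes = (theta.alpha1_g + a, theta.alpha2_g + a)
    rates = (theta.beta1_g + e, theta.beta2_g + e)
    return q1, shapes, rates


def mgps_score(t: ContingencyTable, theta: MgpsHyperparams) -> Tuple[float, float]:
    """EBGM (posterior geometric mean of lambda) and EB05 (posterior 5th pct).

    EBGM = exp(sum_j Q_j [psi(shape_j) - ln rate_j]); EB05 solves
    mixture-CDF(lambda) = 0.05 by bracketed root search (relative tol 1e-8).
    Undefined (NaN) when E = 0.
    """
    if t.expected <= 0:
        return (NAN, NAN)
    q1, shapes, rates = _posterior_mixture(t, theta)
    mean_log = q1 * (special.digamma(shapes[0]) - math.log(rates[0])) + (1 - q1) * (
        special.digamma(shapes[1]) - math.log(rates[1])
    )
    ebgm = math.exp(mean_log)

    def cdf(lam: float) -> float:
        return q1 * stats.gamma.cdf(lam, shapes[0], scale=1 / rates[0]) + (
            1 - q1
        ) * stats.gamma.cdf(lam, shapes[1], scale=1 / rates[1])

    hi = max(shapes[0] / rates[0], shapes[1] / rates[1]) + 1.0
    while cdf(hi) < 0.05:
        hi *= 2.0
    lo = min(1e-12, hi * 1e-12)
    eb05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, rtol=1e-8)
    return (ebgm, eb05)


def simplified_ebgm(t: ContingencyTable, z: float = 1.96) -> Tuple[float, float]:
    """Simplified EBGM family used by many spontaneous-report studies.

    EBGM is the naive relative reporting ratio a/E = aN/((a+b)(a+c)) and EB05
    a log-normal-style lower bound sharing the ROR's Wald standard error.
    """
    e = t.expected
    if e <= 0:
        return (NAN, NAN)
    ebgm = t.a / e
    if t.has_zero_cell():
        return (ebgm, NAN)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ebgm, ebgm * math.exp(-z * se))


# ---------------------------------------------------------------------------
# Classification and overlap
# ---------------------------------------------------------------------------

ALGORITHMS = ("ROR", "PRR", "BCPNN", "EBGM")


@dataclass
class SignalStats:
    """All disproportionality quantities and per-algorithm flags for one term."""

    term: str
    level: str
    a: int
    ror: float = NAN
    ror_lo: float = NAN
    ror_hi: float = NAN
    prr: float = NAN
    chi2: float = NAN
    ic: float = NAN
    ic_var: float = NAN
    ic025: float = NAN
    expected: float = NAN
    ebgm: float = NAN
    eb05: float = NAN
    eligible: bool = True
    undefined: Tuple[str, ...] = ()
    flags: Dict[str, bool] = field(default_factory=dict)
    consensus: bool = False


def classify(s: SignalStats, min_a: int = 3) -> SignalStats:
    """Apply the four positive-signal criteria.

    ROR: lower 95% CI bound strictly > 1. PRR: PRR >= 2 together with
    chi2 >= 4 (both non-strict). BCPNN: IC - 2 SD strictly > 0.
    EBGM: EB05 strictly > 2. Terms with a < min_a are ineligible and get
    all-false flags. NaN statistics never fire.
    """
    if s.a < min_a:
        s.eligible = False
        s.flags = {alg: False for alg in ALGORITHMS}
        s.consensus = False
        return s
    s.eligible = True
    s.flags = {
        "ROR": bool(s.ror_lo > 1.0),
        "PRR": bool(s.prr >= 2.0 and s.chi2 >= 4.0),
        "BCPNN": bool(s.ic025 > 0.0),
        "EBGM": bool(s.eb05 > 2.0),
    }
    s.consensus = all(s.flags.values())
    return s


def score_tables(
    tables: Mapping[str, ContingencyTable],
    level: str = "PT",
    min_a: int = 3,
    z: float = 1.96,
    yates: bool = False,
    priors: BcpnnPriors = BcpnnPriors(),
    mgps_mode: str = "empirical_bayes",
    theta: Optional[MgpsHyperparams] = None,
) -> List[SignalStats]:
    """Score every table of a run with all four algorithms.

    With ``mgps_mode="empirical_bayes"`` (default) the gamma-mixture prior is
    fitted across this run's eligible tables unless ``theta`` is supplied;
    ``mgps_mode="simplified"`` uses the relative-reporting-ratio variant.
    Returns one SignalStats per term, ineligible terms included with all-false
    flags.
    """
    if mgps_mode not in ("empirical_bayes", "simplified"):
        raise ValueError(f"unknown mgps_mode {mgps_mode!r}")
    results: List[SignalStats] = []
    if mgps_mode == "empirical_bayes" and theta is None:
        fit_tables = [t for t in tables.values() if t.a >= min_a and t.expected > 0]
        theta = mgps_fit(fit_tables) if fit_tables else None
    for term, t in tables.items():
        s = SignalStats(term=term, level=level, a=t.a, expected=t.expected)
        undefined = []
        s.ror, s.ror_lo, s.ror_hi = ror_stats(t, z=z)
        if math.isnan(s.ror):
            undefined.append("ror")
        s.prr, s.chi2 = prr_chi2(t, yates=yates)
        if math.isnan(s.prr) or math.isnan(s.chi2):
            undefined.append("prr")
        if t.n > 0:
            s.ic, s.ic_var, s.ic025 = bcpnn_ic(t, priors=priors)
        else:
            undefined.append("bcpnn")
        if mgps_mode == "simplified":
            s.ebgm, s.eb05 = simplified_ebgm(t, z=z)
        elif theta is not None:
            s.ebgm, s.eb05 = mgps_score(t, theta)
        if math.isnan(s.ebgm) or math.isnan(s.eb05):
            undefined.append("ebgm")
        s.undefined = tuple(undefined)
        results.append(classify(s, min_a=min_a))
    return results


def overlap_counts(stats: Iterable[SignalStats]) -> Dict[str, int]:
    """Per-algorithm positive counts and every pairwise/3-way/4-way
    intersection, plus the consensus count. Keys join algorithm names with
    ``&`` (e.g. ``"ROR&PRR"``)."""
    flagged = {alg: set() for alg in ALGORITHMS}
    consensus = 0
    for s in stats:
        for alg in ALGORITHMS:
            if s.flags.get(alg, False):
                flagged[alg].add(s.term)
        if s.consensus:
            consensus += 1
    out: Dict[str, int] = {alg: len(flagged[alg]) for alg in ALGORITHMS}
    for k in (2, 3, 4):
        for combo in itertools.combinations(ALGORITHMS, k):
            common = set.intersection(*(flagged[alg] for alg in combo))
            out["&".join(combo)] = len(common)
    out["consensus"] = consensus
    return out
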