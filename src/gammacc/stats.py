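"""Matched case-control construction and inferential machinery.

Cases are compared with the average of their age (+-1 year) and
gender-matched healthy controls. Group tests are non-parametric
(Kruskal-Wallis on medians, chi-square approximation with df = k-1);
uncertainty on medians comes from bootstrap resampling (10,000 iterations
by default). Directional evidence is quantified with a JZS paired-t Bayes
factor: the effect size receives a Cauchy prior with scale 1, truncated to
a half-line (and renormalized) for one-tailed tests. Severity dependence
is modelled as ordinary least squares:

    dPower = b0 + b_CDR * CDR + b_AGE * AGE + b_GENDER * GENDER + eps

with gender coded 0 = male, 1 = female. No multiple-comparison correction
is applied by default; Bonferroni/FDR adjustment is available as a helper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import integrate, stats as sps

from .synth import SubjectProfile

__all__ = [
    "MatchedSet",
    "BootstrapResult",
    "KWResult",
    "BFResult",
    "RegressionResult",
    "match_controls",
    "bootstrap_median",
    "kruskal_wallis",
    "bayes_factor_paired_t",
    "fit_linear_model",
    "adjust_pvalues",
]

#: Interpretive bands for BF10: <1 favors the null, 1-3 anecdotal,
#: 3-10 substantial, >10 strong evidence for the alternative.
BF_BANDS = ((1.0, "null"), (3.0, "anecdotal"), (10.0, "substantial"), (np.inf, "strong"))


class MatchingError(ValueError):
    """No age/gender-matched control exists for a case."""


@dataclass
class MatchedSet:
    case_id: str
    control_ids: List[str]
    matched_on: str = "age+-1y, gender"
    averaged_control_spectra: Optional[Tuple[np.ndarray, np.ndarray]] = None


@dataclass
class BootstrapResult:
    median: float
    sd_of_median: float
    n_iter: int


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    tie_corrected: bool = True


@dataclass
class BFResult:
    bf10: float
    tail: str
    prior_scale: float
    n: int

    @property
    def interpretation(self) -> str:
        for hi, label in BF_BANDS:
            if self.bf10 < hi:
                return label
        return "strong"


@dataclass
class RegressionResult:
    params: Dict[str, float]
    t: Dict[str, float]
    p: Dict[str, float]
    resid_var: float
    n: int


def match_controls(
    case: SubjectProfile,
    pool: Sequence[SubjectProfile],
    limit_n: Optional[int] = None,
    ordering_key=None,
) -> MatchedSet:
    """All healthy controls matched on age (+-1 year) and gender.

    With ``limit_n`` set, only the first N matches under ``ordering_key``
    (default: absolute age distance, then id) are retained. Raises
    :class:`MatchingError` when no control qualifies — such a case is
    dropped from analysis rather than matched loosely.
    """
    if not pool:
        raise MatchingError("empty control pool")
    matches = [
        p for p in pool
        if p.group == "healthy" and p.gender == case.gender and abs(p.age - case.age) <= 1
    ]
    if not matches:
        raise MatchingError(f"no age/gender-matched control for case {case.id}")
    key = ordering_key or (lambda p: (abs(p.age - case.age), p.id))
    matches = sorted(matches, key=key)
    if limit_n is not None:
        if limit_n < 1:
            raise ValueError("limit_n must be >= 1")
        matches = matches[:limit_n]
    return MatchedSet(case_id=case.id, control_ids=[p.id for p in matches])


def bootstrap_median(
    values: Sequence[float], n_iter: int = 10000, rng: Optional[np.random.Generator] = None
) -> BootstrapResult:
    """Median of the data and the SD of bootstrap medians (seeded)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = rng or np.random.default_rng()
    idx = rng.integers(0, v.size, size=(n_iter, v.size))
    boots = np.median(v[idx], axis=1)
    return BootstrapResult(median=float(np.median(v)), sd_of_median=float(np.std(boots)),
                           n_iter=n_iter)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k-1)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return KWResult(H=0.0, df=len(groups) - 1, p=1.0)
    H, p = sps.kruskal(*arrays)
    return KWResult(H=float(H), df=len(groups) - 1, p=float(p))


def _jzs_bf10(t: float, n: int, tail: str, prior_scale: float) -> float:
    """JZS Bayes factor for a one-sample t (paired differences).

    Marginal likelihood under H1 integrates the noncentral-t density over a
    Cauchy(0, r) effect-size prior via the substitution delta = r*tan(u),
    which maps the real line onto (-pi/2, pi/2). One-tailed variants
    truncate the prior to a half-line and renormalize (doubling the
    half-line integral).
    """
    nu = n - 1
    null_like = sps.t.pdf(t, nu)

    def integrand(u: float) -> float:
        delta = prior_scale * np.tan(u)
        return sps.nct.pdf(t, nu, delta * np.sqrt(n)) / np.pi

    if tail == "two":
        lo, hi, norm = -np.pi / 2, np.pi / 2, 1.0
    elif tail == "right":
        lo, hi, norm = 0.0, np.pi / 2, 2.0
    elif tail == "left":
        lo, hi, norm = -np.pi / 2, 0.0, 2.0
    else:
        raise ValueError("tail must be 'two', 'right' or 'left'")
    alt_like, _ = integrate.quad(integrand, lo, hi, limit=200)
    return float(norm * alt_like / null_like)


def bayes_factor_paired_t(
    x: Sequence[float], y: Sequence[float], tail: str = "two", prior_scale: float = 1.0
) -> BFResult:
    """JZS Bayes factor for paired data, on differences d = x - y.

    ``tail='right'`` quantifies evidence for mean(x) > mean(y) (used for
    the control-minus-case gamma contrast), ``'left'`` the reverse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; t statistic undefined")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    return BFResult(bf10=_jzs_bf10(t, d.size, tail, prior_scale), tail=tail,
                    prior_scale=prior_scale, n=int(d.size))


def fit_linear_model(
    delta_power: Sequence[float],
    cdr: Sequence[float],
    age: Sequence[float],
    gender: Sequence[int],
) -> RegressionResult:
    """OLS of band power change on CDR, age and gender (0=male, 1=female)."""
    y = np.asarray(delta_power, dtype=float)
    g = np.asarray(gender, dtype=float)
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("gender must be coded 0 (male) / 1 (female)")
    X = np.column_stack([np.asarray(cdr, float), np.asarray(age, float), g])
    if y.size <= 4:
        raise ValueError("need more than 4 observations")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, Xc).fit()
    names = ["beta0", "beta_cdr", "beta_age", "beta_gender"]
    return RegressionResult(
        params=dict(zip(names, map(float, fit.params))),
        t=dict(zip(names, map(float, fit.tvalues))),
        p=dict(zip(names, map(float, fit.pvalues))),
        resid_var=float(fit.mse_resid),
        n=int(y.size),
    )


def adjust_pvalues(pvals: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Optional multiple-comparison adjustment (off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    method = {"bonferroni": "bonferroni", "fdr": "fdr_bh"}[method]
    return multipletests(np.asarray(pvals, float), method=method)[1]
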