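"""Significance and control machinery around the decoding engine.

Permutation testing reruns the *entire* cross-validation chain (fold-wise
feature selection included) on label-shuffled data; Bonferroni correction,
Mann-Whitney group comparison, a Bayesian correlated t-test against a null
classifier, bootstrap subject subsampling, and age-confound regression
complete the statistical toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .connectivity import DecodingDataset
from .decoding import CVConfig, CVResult, run_cv
from .util import ConfigurationError, ValidationError, log, rng_stream


@dataclass
class PermutationResult:
    observed: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int
    scheme: str
    correction: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value outside [0, 1]")


@dataclass
class GroupComparison:
    U: float
    p_value: float
    n1: int
    n2: int
    alternative: str


@dataclass
class BayesianComparison:
    p_greater: float               # posterior P(mean difference > 0)
    rho: float
    mean_diff: float
    rope: tuple[float, float] | None = None
    p_rope: float | None = None    # posterior mass inside the ROPE
    p_less: float | None = None
    degenerate: bool = False


@dataclass
class BootstrapResult:
    accuracies: np.ndarray
    n_boot: int

    def percentile_of(self, x: float) -> float:
        """100 * fraction of bootstrap means <= x."""
        return float(100.0 * (self.accuracies <= x).mean())


def shuffle_labels(dataset: DecodingDataset, rng: np.random.Generator,
                   scheme: Literal["within_subject", "global"]) -> np.ndarray:
    y = dataset.y.copy()
    if scheme == "global":
        rng.shuffle(y)
    elif scheme == "within_subject":
        for s in dataset.subjects:
            idx = np.nonzero(dataset.subject == s)[0]
            y[idx] = y[idx[rng.permutation(idx.size)]]
    else:
        raise ConfigurationError(f"unknown permutation scheme {scheme!r}")
    return y


def permutation_test(dataset: DecodingDataset, cv_config: CVConfig,
                     n_perm: int = 200,
                     scheme: Literal["within_subject", "global"] = "within_subject",
                     correction: Literal["add_one", "ratio"] = "add_one",
                     seed: int | None = None,
                     observed: float | None = None) -> PermutationResult:
    """Permutation test of the mean CV accuracy.

    Labels are shuffled (by default within each subject, preserving the
    per-subject class balance) and the whole run_cv chain is repeated to
    build the null.  The default p-value is the add-one Monte-Carlo estimate
    (#{null >= observed} + 1) / (n_perm + 1); ``correction="ratio"`` gives
    the plain #{null >= observed} / n_perm convention instead.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if seed is None:
        seed = cv_config.seed
    if observed is None:
        observed = run_cv(dataset, cv_config).mean_accuracy
    null = np.empty(n_perm)
    for p in range(n_perm):
        rng = rng_stream(seed, "permutation", p)
        y_perm = shuffle_labels(dataset, rng, scheme)
        perm_ds = replace(dataset, y=y_perm)
        null[p] = run_cv(perm_ds, cv_config).mean_accuracy
    count = int((null >= observed).sum())
    if correction == "add_one":
        p_value = (count + 1) / (n_perm + 1)
    elif correction == "ratio":
        p_value = count / n_perm
    else:
        raise ConfigurationError(f"unknown correction {correction!r}")
    return PermutationResult(observed=float(observed), null_accuracies=null,
                             p_value=float(p_value), n_perm=n_perm,
                             scheme=scheme, correction=correction)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m*p); m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ConfigurationError("family size m must cover all tests")
    return np.minimum(1.0, m * p)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float],
                 alternative: str = "two-sided") -> GroupComparison:
    """Rank-sum U test (midrank ties); exact for small tie-free samples.

    The returned U is the statistic of ``sample_a`` (number of (a, b) pairs
    with a > b, ties counted 1/2), so U + U' = n1*n2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return GroupComparison(U=float(res.statistic), p_value=float(res.pvalue),
                           n1=a.size, n2=b.size, alternative=alternative)


def bayesian_correlated_ttest(acc_folds: Sequence[float],
                              comparator: float | Sequence[float] = 0.5,
                              rho: float = 0.25,
                              rope: tuple[float, float] | None = None,
                              ) -> BayesianComparison:
    """Bayesian correlated t-test of cross-validated accuracies.

    Fold accuracies from overlapping training sets are positively correlated;
    the posterior of the mean difference is a Student-t with the variance
    inflated by the Nadeau-Bengio factor (1/n + rho/(1-rho)), where rho
    defaults to the test fraction (0.25).  Returns P(diff > 0) and, when a
    region of practical equivalence is given, the three posterior masses.
    """
    if not 0 <= rho < 1:
        raise ConfigurationError("rho must lie in [0, 1)")
    d = np.asarray(acc_folds, dtype=float) - np.asarray(comparator, dtype=float)
    n = d.size
    if n < 2:
        raise ValidationError("need at least 2 folds")
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    if var == 0.0:
        if mean == 0.0:
            return BayesianComparison(p_greater=0.5, rho=rho, mean_diff=0.0,
                                      degenerate=True)
        return BayesianComparison(p_greater=1.0 if mean > 0 else 0.0,
                                  rho=rho, mean_diff=mean, degenerate=True)
    scale = np.sqrt(var * (1.0 / n + rho / (1.0 - rho)))
    post = stats.t(df=n - 1, loc=mean, scale=scale)
    out = BayesianComparison(p_greater=float(post.sf(0.0)), rho=rho,
                             mean_diff=mean)
    if rope is not None:
        lo, hi = rope
        out.rope = (lo, hi)
        out.p_less = float(post.cdf(lo))
        out.p_rope = float(post.cdf(hi) - post.cdf(lo))
        out.p_greater = float(post.sf(hi))
    return out


def bootstrap_subsample(dataset: DecodingDataset, target_n_subjects: int,
                        cv_config: CVConfig, n_boot: int = 100,
                        seed: int | None = None) -> BootstrapResult:
    """Subsample subjects without replacement and rerun the full CV.

    Used to check whether a larger group's accuracy survives shrinking it to
    the smaller group's size (e.g. expert n=12 resampled to 10).
    """
    subjects = np.array(dataset.subjects)
    if target_n_subjects >= subjects.size:
        raise ConfigurationError(
            f"target_n_subjects must be < {subjects.size}")
    if seed is None:
        seed = cv_config.seed
    accs = np.empty(n_boot)
    for i in range(n_boot):
        rng = rng_stream(seed, "bootstrap", i)
        keep = set(rng.choice(subjects, size=target_n_subjects, replace=False))
        mask = np.array([str(s) in keep for s in dataset.subject])
        sub = replace(dataset, X=dataset.X[mask], y=dataset.y[mask],
                      subject=dataset.subject[mask])
        accs[i] = run_cv(sub, cv_config).mean_accuracy
    return BootstrapResult(accuracies=accs, n_boot=n_boot)


def regress_out_age(dataset: DecodingDataset) -> DecodingDataset:
    """Replace every feature by its residual on [intercept, age].

    Fit over all samples of the group (dataset-level cleanup, as a control
    analysis; the train/test leakage this implies is a documented caveat of
    the procedure being replicated, not corrected here).
    """
    ages = dataset.sample_ages()
    if np.ptp(ages) == 0:
        log.warning("regress_out_age: constant age vector; identity transform")
        return dataset
    design = np.column_stack([np.ones(ages.size), ages])
    beta, *_ = np.linalg.lstsq(design, dataset.X, rcond=None)
    resid = dataset.X - design @ beta
    return replace(dataset, X=resid)
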