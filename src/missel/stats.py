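"""Selection tests against the neutral null model.

Two test families compare observed mutations with the trinucleotide-spectrum
null:

* an exact two-tailed binomial test for Boolean features (interface
  membership, calcium-site membership, destabilising yes/no), using the
  minimum-likelihood two-sided convention: the p-value sums the
  probabilities of all outcomes no more likely than the observed count;
* a two-tailed Monte Carlo test for continuous scores (∆∆G, distance to a
  binding partner): samples of the observed size are drawn from the null,
  a summary statistic (median by default) is computed per sample, and the
  two tails of the observed statistic are counted with a +1 pseudo-count, so
  the smallest reportable p is 2/(n_draws+1).

The ∆∆G CDF shift used for gene-level classification transforms each score
to its mid-distribution CDF value under the null, F(x) = P(X<x) + P(X=x)/2,
whose null mean is exactly 1/2; the shift is the mean observed F minus the
null mean and is bounded in [-0.5, 0.5]. Positive shifts indicate selection
for destabilising mutations (fitness-suppressor pattern), negative shifts
selection against them.

Recurrent mutations are treated as independent originations under the null
(each clone counts as one draw); pass ``count_weighted=False`` upstream for
unique-site analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .catalogue import ObservedMutationSet, SnvCatalogue
from .errors import (
    DegenerateFeatureError,
    EmptyObservationError,
)

__all__ = [
    "SelectionTestResult",
    "CdfShiftResult",
    "binom_minlike_pvalue",
    "binomial_feature_test",
    "expected_count_ci",
    "monte_carlo_test",
    "cdf_transform",
    "weighted_median",
    "cdf_shift",
    "aggregate_gene_shift",
    "correlate_shift_dnds",
]

# Relative tolerance when comparing pmf values for the minimum-likelihood
# two-sided test: outcomes whose probability is within this relative margin
# of the observed outcome's count as ties (guards against float noise in
# exactly symmetric cases such as p0 = 1/2).
_PMF_TIE_RTOL = 1e-10


@dataclass
class SelectionTestResult:
    """Outcome of one feature-selection test against the neutral null."""

    feature: str
    test: str  # "binomial" | "monte_carlo"
    n: int
    expected_summary: float
    observed_summary: float
    p_two_tailed: float
    ci95: tuple[float, float]
    excluded_features: tuple[str, ...] = ()
    n_draws: int | None = None
    seed: int | None = None
    statistic: str | None = None
    n_unscored_dropped: int = 0
    underpowered: bool = False

    def __post_init__(self):
        if not 0 < self.p_two_tailed <= 1:
            raise ValueError(f"p-value {self.p_two_tailed} outside (0, 1]")
        if self.ci95[0] > self.ci95[1]:
            raise ValueError(f"inverted confidence interval {self.ci95}")

    def to_dict(self) -> dict:
        d = {
            "feature": self.feature,
            "test": self.test,
            "n": self.n,
            "expected": self.expected_summary,
            "observed": self.observed_summary,
            "p": self.p_two_tailed,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "exclusions": ";".join(self.excluded_features),
            "underpowered": self.underpowered,
        }
        if self.test == "monte_carlo":
            d.update(n_draws=self.n_draws, seed=self.seed, statistic=self.statistic)
        return d


@dataclass
class CdfShiftResult:
    """Mean shift of observed vs null mid-CDF values of a score.

    ``shift`` lies in [-0.5, 0.5]: 0.5 means every observed mutation sits at
    the maximum score possible in the region (in the vanishing-null-mass
    limit), -0.5 the minimum, 0 means the observed and null CDF-value means
    coincide.
    """

    shift: float
    n: int
    gene_id: str = ""
    per_structure_shifts: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        # 1e-12 slack absorbs float summation noise at the extremes
        if not -0.5 - 1e-12 <= self.shift <= 0.5 + 1e-12:
            raise ValueError(f"CDF shift {self.shift} outside [-0.5, 0.5]")
        self.shift = float(min(0.5, max(-0.5, self.shift)))


# --------------------------------------------------------------------------
# Binomial test

def binom_minlike_pvalue(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p by the minimum-likelihood method.

    Sums Binomial(n, p0) probabilities of every outcome whose probability
    does not exceed that of the observed count ``k`` (with a tiny relative
    tie tolerance). Never returns 0: the observed outcome itself is always
    included.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0 < p0 < 1:
        raise DegenerateFeatureError(f"degenerate null proportion p0={p0}")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[k] * (1.0 + _PMF_TIE_RTOL)].sum())
    if p == 0.0:  # extreme tail underflow: floor at the outcome's own mass
        p = float(np.exp(sps.binom.logpmf(k, n, p0)))
    return min(1.0, max(p, float(np.finfo(float).tiny)))


def expected_count_ci(
    n: int, p0: float, level: float = 0.95
) -> tuple[int, int]:
    """Equal-tailed quantile interval of Binomial(n, p0) for the expected count."""
    if not 0 <= p0 <= 1:
        raise ValueError(f"p0={p0} outside [0, 1]")
    if p0 == 0:
        return (0, 0)
    if p0 == 1:
        return (n, n)
    alpha = 1.0 - level
    lo = int(sps.binom.ppf(alpha / 2, n, p0))
    hi = int(sps.binom.ppf(1 - alpha / 2, n, p0))
    return (lo, hi)


def _restrict_scored(
    catalogue: SnvCatalogue, observed: ObservedMutationSet, column: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Drop entries whose score is missing from both null and observed.

    Returns (values, renormalised probs, counts, observed count dropped).
    """
    values = catalogue.entries[column].to_numpy()
    probs = catalogue.prob.astype(float)
    counts = observed.counts
    if values.dtype == bool:
        return values, probs, counts, 0
    values = values.astype(float)
    scored = np.isfinite(values)
    dropped = int(counts[~scored].sum())
    if not scored.all():
        mass = probs[scored].sum()
        if mass <= 0:
            raise DegenerateFeatureError(f"no null mass on scored entries of {column}")
        probs = probs[scored] / mass
        values = values[scored]
        counts = counts[scored]
    return values, probs, counts, dropped


def binomial_feature_test(
    observed: ObservedMutationSet,
    null: SnvCatalogue,
    feature: str,
) -> SelectionTestResult:
    """Two-tailed binomial test of a Boolean feature's observed proportion.

    The null proportion p0 is the summed neutral probability of
    feature-positive entries; the observed count k is the recurrence-weighted
    number of observed mutations on feature-positive entries, tested against
    Binomial(n, p0).
    """
    mask = null.eval_predicate(feature)
    probs = null.prob
    counts = observed.counts
    n = int(counts.sum())
    if n == 0:
        raise EmptyObservationError("no observed mutations to test")
    p0 = float(probs[mask].sum())
    if p0 <= 0.0 or p0 >= 1.0:
        raise DegenerateFeatureError(
            f"feature {feature!r} has degenerate null proportion p0={p0}"
        )
    k = int(counts[mask].sum())
    return SelectionTestResult(
        feature=feature,
        test="binomial",
        n=n,
        expected_summary=p0,
        observed_summary=k / n,
        p_two_tailed=binom_minlike_pvalue(k, n, p0),
        ci95=expected_count_ci(n, p0),
        excluded_features=null.exclusions,
    )


# --------------------------------------------------------------------------
# Monte Carlo test

def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of a discrete distribution: smallest value whose CDF >= 1/2,
    averaged with the next distinct value when the CDF hits 1/2 exactly."""
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    cum = np.cumsum(w) / total
    i = int(np.searchsorted(cum, 0.5))
    if np.isclose(cum[i], 0.5) and i + 1 < len(v):
        return float((v[i] + v[i + 1]) / 2)
    return float(v[i])


_CHUNK_CELLS = 5_000_000  # draws x n kept below this per block


def monte_carlo_test(
    observed: ObservedMutationSet,
    null: SnvCatalogue,
    score: str,
    statistic: str = "median",
    n_draws: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> SelectionTestResult:
    """Two-tailed Monte Carlo test of a continuous score.

    Draws ``n_draws`` samples of the observed size (with replacement,
    probabilities = null probabilities; recurrent mutations count as
    independent draws), computes the chosen statistic per sample, and reports

        p = min(1, 2 * (min tail count + 1) / (n_draws + 1)).

    ``statistic`` is ``"median"`` (sample median, reported in score units) or
    ``"mean_cdf"`` (mean of mid-CDF-transformed scores, robust to outliers).
    A seed (or Generator) is mandatory so runs are reproducible.
    """
    if seed is None:
        raise ValueError("monte_carlo_test requires an explicit seed")
    if statistic not in ("median", "mean_cdf"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)

    values, probs, counts, dropped = _restrict_scored(null, observed, score)
    n = int(counts.sum())
    if n == 0:
        raise EmptyObservationError("no (scored) observed mutations to test")

    if statistic == "mean_cdf":
        values = cdf_transform(values, probs)

    if np.ptp(values) == 0:
        warnings.warn(
            f"score {score!r} is constant on the included entries; p = 1",
            stacklevel=2,
        )
        v0 = float(values[0])
        return SelectionTestResult(
            feature=score, test="monte_carlo", n=n,
            expected_summary=v0, observed_summary=v0, p_two_tailed=1.0,
            ci95=(v0, v0), excluded_features=null.exclusions,
            n_draws=n_draws, seed=seed if isinstance(seed, int) else None,
            statistic=statistic, n_unscored_dropped=dropped,
        )

    obs_values = np.repeat(values, counts)
    if statistic == "median":
        observed_stat = float(np.median(obs_values))
        expected_stat = weighted_median(values, probs)
    else:
        observed_stat = float(np.mean(obs_values))
        expected_stat = 0.5

    n_ge = 0
    n_le = 0
    collected = []
    rows_per_chunk = max(1, _CHUNK_CELLS // max(n, 1))
    remaining = n_draws
    while remaining > 0:
        m = min(rows_per_chunk, remaining)
        sample = rng.choice(values, size=(m, n), replace=True, p=probs)
        stats_chunk = (
            np.median(sample, axis=1) if statistic == "median"
            else sample.mean(axis=1)
        )
        n_ge += int((stats_chunk >= observed_stat).sum())
        n_le += int((stats_chunk <= observed_stat).sum())
        collected.append(stats_chunk)
        remaining -= m
    sim_stats = np.concatenate(collected)

    p = min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (n_draws + 1))
    ci = tuple(np.quantile(sim_stats, [0.025, 0.975]))
    return SelectionTestResult(
        feature=score,
        test="monte_carlo",
        n=n,
        expected_summary=expected_stat,
        observed_summary=observed_stat,
        p_two_tailed=p,
        ci95=(float(ci[0]), float(ci[1])),
        excluded_features=null.exclusions,
        n_draws=n_draws,
        seed=seed if isinstance(seed, int) else None,
        statistic=statistic,
        n_unscored_dropped=dropped,
    )


# --------------------------------------------------------------------------
# CDF shift

def cdf_transform(values: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Mid-distribution CDF values under the probability-weighted null.

    F(x) = P(X < x) + P(X = x) / 2, computed with exact ties on the score
    values; guarantees E_null[F(X)] = 1/2.
    """
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)
    uniq, inverse = np.unique(values, return_inverse=True)
    p_at = np.bincount(inverse, weights=probs, minlength=len(uniq))
    cum = np.cumsum(p_at)
    f_uniq = cum - 0.5 * p_at  # P(X < x) + P(X = x)/2
    total = cum[-1]
    if not np.isclose(total, 1.0, atol=1e-9):
        f_uniq = f_uniq / total
    return f_uniq[inverse]


def cdf_shift(
    observed: ObservedMutationSet | np.ndarray,
    null: SnvCatalogue,
    score: str = "ddg",
    gene_id: str = "",
) -> CdfShiftResult:
    """Mean observed mid-CDF value minus the null mean (which is 1/2).

    ``observed`` may be an :class:`ObservedMutationSet` or a bare weight
    array aligned with the catalogue entries (weights need not be integral,
    so the null can be replayed against itself exactly). Entries without a
    finite score are dropped from both sides, renormalising the null.
    """
    if isinstance(observed, ObservedMutationSet):
        obs = observed
    else:
        w = np.asarray(observed, dtype=float)
        obs = None
    if obs is not None:
        values, probs, weights, _ = _restrict_scored(null, obs, score)
        weights = weights.astype(float)
        n = int(obs.counts.sum())
    else:
        values = null.entries[score].to_numpy(dtype=float)
        probs = null.prob.astype(float)
        weights = w
        scored = np.isfinite(values)
        if not scored.all():
            mass = probs[scored].sum()
            probs = probs[scored] / mass
            values, weights = values[scored], weights[scored]
        n = int(round(weights.sum()))
    wsum = weights.sum()
    if wsum <= 0:
        raise EmptyObservationError("no scored observed weight for CDF shift")

    f = cdf_transform(values, probs)
    observed_mean = float(np.dot(weights, f) / wsum)
    null_mean = float(np.dot(probs, f))
    shift = observed_mean - null_mean
    return CdfShiftResult(shift=shift, n=max(n, 0), gene_id=gene_id)


def aggregate_gene_shift(
    per_structure: Sequence[CdfShiftResult], gene_id: str | None = None
) -> CdfShiftResult:
    """Unweighted mean of per-structure CDF shifts for one gene."""
    if not per_structure:
        raise EmptyObservationError("no per-structure shifts to aggregate")
    genes = {r.gene_id for r in per_structure if r.gene_id}
    if gene_id is None:
        gene_id = genes.pop() if len(genes) == 1 else ""
    shifts = tuple(r.shift for r in per_structure)
    return CdfShiftResult(
        shift=float(np.mean(shifts)),
        n=int(np.mean([r.n for r in per_structure])),
        gene_id=gene_id,
        per_structure_shifts=shifts,
    )


def correlate_shift_dnds(
    gene_shifts: Mapping[str, float] | Mapping[str, CdfShiftResult],
    dnds: Mapping[str, float],
) -> tuple[float, float, int]:
    """Pearson correlation of per-gene CDF shift vs log truncating dN/dS.

    Genes lacking either value, or with non-positive dN/dS (no logarithm),
    are excluded with a warning. Returns (r, two-tailed p, n genes).
    """
    xs, ys = [], []
    for gene, s in gene_shifts.items():
        if gene not in dnds:
            continue
        d = float(dnds[gene])
        if d <= 0:
            warnings.warn(
                f"gene {gene}: non-positive truncating dN/dS ({d}); excluded",
                stacklevel=2,
            )
            continue
        shift = s.shift if isinstance(s, CdfShiftResult) else float(s)
        xs.append(shift)
        ys.append(np.log(d))
    if len(xs) < 3:
        raise ValueError(f"need >=3 genes with both values, have {len(xs)}")
    r, p = sps.pearsonr(xs, ys)
    return float(r), float(p), len(xs)
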