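"""Permutation significance testing for differential correlation edges.

Phenotype labels are shuffled uniformly at random; each shuffle defines one
permuted dataset shared by all metabolite pairs, on which the full
differential statistic is recomputed with the original group sizes.  The
two-sided empirical p-value for a pair uses the add-one estimator

    p = (b + 1) / (B + 1),

where b counts permuted |r_diff| >= observed |r_diff| (ties count as
exceedances, conservatively) over B permutations.  p can never be zero and
its floor is 1/(B+1).  No multiple-testing correction is applied beyond the
fixed significance threshold; edge selection uses permutation p-values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .diffcorr import all_pairs, diffstat_matrix
from .phenotype import classify
from .preprocessing import preprocess

logger = logging.getLogger(__name__)


@dataclass
class PermutationConfig:
    """Settings for the label-shuffling test.

    ``alpha`` is the edge-selection threshold (0.01 primary, 0.05
    exploratory); the test itself is two-sided on |r_diff|.
    """

    n_permutations: int = 1000
    seed: int | None = None
    alpha: float = 0.01
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness != "two-sided":
            raise ValueError("only the two-sided test is supported")


@dataclass
class PermutationResult:
    """Edge table augmented with exceedance counts and permutation p-values."""

    edges: pd.DataFrame
    n_permutations: int
    seed: int | None

    def significant(self, alpha: float) -> pd.DataFrame:
        return self.edges[self.edges["p_perm"] < alpha].reset_index(drop=True)


def permutation_pvalues(
    x: np.ndarray,
    case_mask: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low-level engine: add-one permutation p-values for every pair.

    Returns ``(p, exceed, obs_stat)`` where ``p`` and ``exceed`` are m x m
    (NaN / meaningless where the observed pair is unusable) and ``obs_stat``
    is the observed differential-statistic matrix.  A non-finite permuted
    statistic counts as an exceedance for that pair (conservative) and is
    logged.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    obs_stat = diffstat_matrix(x, case_mask)[0]
    obs_abs = np.abs(obs_stat)
    exceed = np.zeros_like(obs_abs)
    n_nonfinite = 0
    for _ in range(n_permutations):
        perm = rng.permutation(case_mask)
        stat = diffstat_matrix(x, perm)[0]
        bad = ~np.isfinite(stat)
        if bad.any():
            n_nonfinite += int(np.count_nonzero(np.triu(bad, k=1)))
        exceed += np.where(bad, 1.0, np.abs(stat) >= obs_abs)
    if n_nonfinite:
        logger.warning(
            "%d non-finite permuted statistics treated as exceedances", n_nonfinite
        )
    p = (exceed + 1.0) / (n_permutations + 1.0)
    p[~np.isfinite(obs_abs)] = np.nan
    return p, exceed, obs_stat


def permutation_test(matrix, labels, outcome: str, config: PermutationConfig) -> PermutationResult:
    """Fill the edge table's ``p_perm`` column by label-shuffling.

    The same seed with the same inputs reproduces the p-values exactly.
    """
    from .diffcorr import _select_samples  # shared sample alignment

    edges = all_pairs(matrix, labels, outcome)
    x, case_mask, mets = _select_samples(matrix, labels, outcome)
    rng = np.random.default_rng(config.seed)
    p, exceed, _ = permutation_pvalues(x, case_mask, config.n_permutations, rng)
    pos = {m: k for k, m in enumerate(mets)}
    ii = edges["metabolite_i"].map(pos).to_numpy()
    jj = edges["metabolite_j"].map(pos).to_numpy()
    edges = edges.copy()
    edges["p_perm"] = p[ii, jj]
    edges["exceedances"] = exceed[ii, jj].astype(int)
    return PermutationResult(
        edges=edges, n_permutations=config.n_permutations, seed=config.seed
    )


def type1_calibration(
    spec,
    config: PermutationConfig,
    n_replicates: int = 20,
    alphas: tuple[float, ...] = (0.01, 0.05),
) -> pd.DataFrame:
    """Empirical type-I error of the permutation test on null cohorts.

    Generates ``n_replicates`` synthetic cohorts from ``spec`` (which must
    plant no differential edges), runs the full QC + permutation pipeline on
    each, and reports, per significance level, the fraction of metabolite
    pairs declared significant together with binomial 99% bounds around the
    nominal level.
    """
    from .simulate import generate_cohort  # deferred: avoids import cycle

    if getattr(spec, "planted_edges", None):
        raise ValueError("type-I calibration requires a spec with no planted edges")
    master = np.random.default_rng(config.seed)
    n_reject = {a: 0 for a in alphas}
    n_pairs = 0
    for _ in range(n_replicates):
        cohort_seed = int(master.integers(0, 2**31 - 1))
        perm_seed = int(master.integers(0, 2**31 - 1))
        cohort = generate_cohort(replace(spec, seed=cohort_seed))
        matrix, _ = preprocess(cohort.concentrations)
        labels = classify(cohort.outcomes)
        result = permutation_test(
            matrix, labels, "pain", replace(config, seed=perm_seed)
        )
        pvals = result.edges["p_perm"].to_numpy()
        n_pairs += len(pvals)
        for a in alphas:
            n_reject[a] += int((pvals < a).sum())
    rows = []
    z99 = stats.norm.ppf(0.995)
    for a in alphas:
        frac = n_reject[a] / n_pairs
        half = z99 * np.sqrt(a * (1 - a) / n_pairs)
        rows.append(
            {
                "alpha": a,
                "n_pairs": n_pairs,
                "n_reject": n_reject[a],
                "rejection_fraction": frac,
                "lower99": a - half,
                "upper99": a + half,
                "within_bounds": bool(a - half <= frac <= a + half),
            }
        )
    return pd.DataFrame(rows)
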