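"""Fisher z-based differential correlation statistic for two-group data.

For every metabolite pair (i, j) the Pearson correlation is computed
separately in the case group (non-responders) and the control group
(responders), each correlation is variance-stabilised with Fisher's
z-transform, z = arctanh(r), and the difference is standardised by the
combined Fisher variance, which accounts for unequal group sizes:

    r_diff(i, j) = (z_case - z_control) / sqrt(1/(n_case - 3) + 1/(n_control - 3))

Under the null of equal population correlations, r_diff is approximately
standard normal.  Correlations use pairwise-complete observations, and the
per-pair complete-observation counts (not the global group sizes) feed the
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: clamp applied to |r| before arctanh so collinear pairs stay finite
R_CLAMP = 1.0 - 1e-12

#: minimum complete observations per pair and group (Fisher variance needs n > 3)
MIN_PAIR_N = 4

EDGE_COLUMNS = [
    "metabolite_i",
    "metabolite_j",
    "r_case",
    "r_control",
    "z_case",
    "z_control",
    "n_case",
    "n_control",
    "r_diff",
    "p_normal",
    "p_perm",
    "sign",
]


def fisher_z(r):
    """Fisher z-transform, z = (1/2) ln((1+r)/(1-r)) = arctanh(r).

    Accepts scalars or arrays with |r| <= 1; values numerically at +-1 are
    clamped to keep the transform finite.  Non-finite input raises.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("fisher_z requires finite input")
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(arr, -R_CLAMP, R_CLAMP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def differential_statistic(r_case, r_control, n_case, n_control):
    """Standardised difference of Fisher z values between the two groups.

    Antisymmetric under swapping the groups; zero iff the correlations are
    equal.  Requires n > 3 in both groups.
    """
    n_case = np.asarray(n_case, dtype=float)
    n_control = np.asarray(n_control, dtype=float)
    if np.any(n_case <= 3) or np.any(n_control <= 3):
        raise ValueError("group sizes must exceed 3 (Fisher variance 1/(n-3))")
    num = fisher_z(r_case) - fisher_z(r_control)
    denom = np.sqrt(1.0 / (n_case - 3.0) + 1.0 / (n_control - 3.0))
    return num / denom


def pairwise_pearson(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix over pairwise-complete observations.

    Parameters
    ----------
    x : ndarray, samples x variables, NaN marking unavailable cells.

    Returns
    -------
    r : ndarray (m, m)
        Correlations; NaN where a pair has fewer than ``MIN_PAIR_N`` complete
        observations or zero variance on the complete subset.
    n : ndarray (m, m)
        Complete-observation counts per pair.
    """
    x = np.asarray(x, dtype=float)
    n_samples, m = x.shape
    finite = np.isfinite(x)
    if finite.all():
        n = np.full((m, m), n_samples, dtype=np.int64)
        xc = x - x.mean(axis=0)
        ss = np.einsum("ij,ij->j", xc, xc)
        denom = np.sqrt(np.outer(ss, ss))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc.T @ xc) / denom
        if n_samples < MIN_PAIR_N:
            r[:] = np.nan
    else:
        mask = finite.astype(float)
        x0 = np.where(finite, x, 0.0)
        n = (mask.T @ mask).astype(np.int64)
        sx = x0.T @ mask  # (i, j): sum of x_i over rows complete for (i, j)
        sxx = (x0 * x0).T @ mask
        sxy = x0.T @ x0
        nf = n.astype(float)
        cov = nf * sxy - sx * sx.T
        var_i = nf * sxx - sx**2
        var_j = var_i.T
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(var_i * var_j)
        r[(n < MIN_PAIR_N) | (var_i <= 0) | (var_j <= 0)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r, n


def diffstat_matrix(
    x: np.ndarray, case_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs differential statistic for one labelling of the samples.

    Returns ``(stat, r_case, r_control, n_case, n_control)`` as m x m arrays;
    ``stat`` is NaN for unusable pairs (pairwise n < 4 or zero variance).
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    r_case, n_case = pairwise_pearson(x[case_mask])
    r_ctrl, n_ctrl = pairwise_pearson(x[~case_mask])
    usable = (
        (n_case >= MIN_PAIR_N)
        & (n_ctrl >= MIN_PAIR_N)
        & np.isfinite(r_case)
        & np.isfinite(r_ctrl)
    )
    stat = np.full(r_case.shape, np.nan)
    if usable.any():
        z_case = np.arctanh(np.clip(r_case[usable], -R_CLAMP, R_CLAMP))
        z_ctrl = np.arctanh(np.clip(r_ctrl[usable], -R_CLAMP, R_CLAMP))
        denom = np.sqrt(
            1.0 / (n_case[usable] - 3.0) + 1.0 / (n_ctrl[usable] - 3.0)
        )
        stat[usable] = (z_case - z_ctrl) / denom
    return stat, r_case, r_ctrl, n_case, n_ctrl


@dataclass
class GroupCorrelation:
    """Per-group Pearson correlation matrix with per-pair complete counts."""

    group: str  # "case" | "control"
    r: pd.DataFrame
    n_pairwise: pd.DataFrame
    n_group: int


def _select_samples(matrix, labels, outcome: str):
    """Align a normalized matrix with responder labels; return X and case mask."""
    assignments = labels.group_assignments(outcome)
    ids = assignments.index.intersection(matrix.sample_ids)
    if len(ids) == 0:
        raise ValueError("no overlap between matrix samples and analyzable labels")
    assignments = assignments.loc[ids]
    x = matrix.values.loc[ids].to_numpy(dtype=float)
    case_mask = (assignments == "case").to_numpy()
    n_case, n_control = int(case_mask.sum()), int((~case_mask).sum())
    if n_case < MIN_PAIR_N or n_control < MIN_PAIR_N:
        raise ValueError(
            f"each group needs at least {MIN_PAIR_N} samples "
            f"(got case={n_case}, control={n_control})"
        )
    return x, case_mask, list(matrix.metabolite_ids)


def group_correlations(matrix, labels, outcome: str) -> tuple[GroupCorrelation, GroupCorrelation]:
    """Pairwise-complete Pearson correlations in the case and control groups."""
    if matrix.stage != "normalized":
        raise ValueError("group_correlations expects a normalized matrix")
    x, case_mask, mets = _select_samples(matrix, labels, outcome)
    out = []
    for name, mask in (("case", case_mask), ("control", ~case_mask)):
        r, n = pairwise_pearson(x[mask])
        if np.isnan(r[np.triu_indices_from(r, k=1)]).any():
            logger.warning(
                "%s group: some metabolite pairs are unusable "
                "(pairwise n < %d or zero variance)", name, MIN_PAIR_N,
            )
        out.append(
            GroupCorrelation(
                group=name,
                r=pd.DataFrame(r, index=mets, columns=mets),
                n_pairwise=pd.DataFrame(n, index=mets, columns=mets),
                n_group=int(mask.sum()),
            )
        )
    return out[0], out[1]


def edge_sign(r_diff: float) -> str:
    if r_diff > 0:
        return "positive"
    if r_diff < 0:
        return "negative"
    return "zero"


def all_pairs(matrix, labels, outcome: str) -> pd.DataFrame:
    """Differential-correlation edge table over all usable metabolite pairs.

    One row per unordered pair, ordered lexicographically by metabolite id;
    unusable pairs (pairwise n < 4 in either group, or zero variance) are
    dropped and logged.  ``p_perm`` is NaN until permutation testing fills it;
    ``p_normal`` is the two-sided standard-normal approximation, provided for
    diagnostics only.
    """
    if matrix.stage != "normalized":
        raise ValueError("all_pairs expects a normalized matrix")
    x, case_mask, mets = _select_samples(matrix, labels, outcome)
    stat, r_case, r_ctrl, n_case, n_ctrl = diffstat_matrix(x, case_mask)
    order = np.argsort(np.asarray(mets, dtype=object))
    rows = []
    dropped = 0
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            if not np.isfinite(stat[i, j]):
                dropped += 1
                continue
            rd = float(stat[i, j])
            rows.append(
                {
                    "metabolite_i": mets[i],
                    "metabolite_j": mets[j],
                    "r_case": float(r_case[i, j]),
                    "r_control": float(r_ctrl[i, j]),
                    "z_case": float(fisher_z(r_case[i, j])),
                    "z_control": float(fisher_z(r_ctrl[i, j])),
                    "n_case": int(n_case[i, j]),
                    "n_control": int(n_ctrl[i, j]),
                    "r_diff": rd,
                    "p_normal": float(2.0 * stats.norm.sf(abs(rd))),
                    "p_perm": np.nan,
                    "sign": edge_sign(rd),
                }
            )
    if dropped:
        logger.warning("dropped %d unusable metabolite pairs", dropped)
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)
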