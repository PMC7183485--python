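"""Synthetic two-group metabolomics cohorts with planted correlation structure.

The generator emulates a plasma metabolomics study of total-joint-replacement
outcome: two groups of unequal size (by default 67 non-responders vs 378
responders), a Biocrates-style panel (186 measured metabolites of which 55
are heavily censored below the limit of detection and fail QC, leaving 131),
log-normal concentrations, sporadic missing values, injected extreme
outliers, and WOMAC pain / function scores consistent with the group labels.

Within each group, log-concentrations are drawn from a multivariate normal
whose correlation matrix is a uniform background plus planted per-group
entries, then exponentiated; planted correlation targets are therefore exact
on the natural-log scale, which is the scale the analysis pipeline works on
after its log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotype import OutcomeRecord
from .preprocessing import BELOW_LOD, MISSING, OBSERVED, ConcentrationMatrix


@dataclass
class WomacParams:
    """Means/SDs for baseline and change scores per subscale and group.

    Baselines are shared between groups; change-score distributions differ so
    that cases (non-responders) fall strictly below the MCID and controls at
    or above it, for both subscales.  Scores are integers clipped to the
    subscale ranges (pain 0-20, function 0-68).
    """

    baseline_pain_mean: float = 12.0
    baseline_pain_sd: float = 3.0
    baseline_function_mean: float = 45.0
    baseline_function_sd: float = 10.0
    case_pain_change_mean: float = 3.0
    case_pain_change_sd: float = 2.0
    control_pain_change_mean: float = 10.0
    control_pain_change_sd: float = 2.0
    case_function_change_mean: float = 10.0
    case_function_change_sd: float = 6.0
    control_function_change_mean: float = 32.0
    control_function_change_sd: float = 6.0
    mcid_pain: int = 7
    mcid_function: int = 22
    tkr_fraction: float = 0.724


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    ``planted_edges`` is a list of ``(i, j, r_case, r_control)`` tuples with
    metabolite indices on the *retained* (non-LOD-designated) part of the
    panel; the last ``n_lod_metabolites`` columns are the ones subjected to
    heavy LOD censoring.
    """

    n_case: int = 67
    n_control: int = 378
    n_metabolites: int = 186
    planted_edges: tuple = ()
    background_r: float = 0.2
    lod_fraction: float = 0.15
    n_lod_metabolites: int = 55
    missing_fraction: float = 0.02
    outlier_fraction: float = 0.005
    seed: int = 0
    womac_params: WomacParams = field(default_factory=WomacParams)

    def __post_init__(self) -> None:
        if self.n_case < 4 or self.n_control < 4:
            raise ValueError("each group needs at least 4 samples (Fisher variance)")
        for frac, name in (
            (self.lod_fraction, "lod_fraction"),
            (self.missing_fraction, "missing_fraction"),
            (self.outlier_fraction, "outlier_fraction"),
        ):
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.background_r < 1.0:
            raise ValueError("background_r must lie in [0, 1)")
        if not 0 <= self.n_lod_metabolites <= self.n_metabolites:
            raise ValueError("n_lod_metabolites out of range")
        for i, j, rc, rr in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i}, {j}) is a self-pair")
            if max(abs(rc), abs(rr)) > 0.99:
                raise ValueError(f"planted |r| must be <= 0.99 (edge {i}-{j})")
            if not (0 <= i < self.n_metabolites and 0 <= j < self.n_metabolites):
                raise ValueError(f"planted edge ({i}, {j}) outside the panel")


@dataclass
class SyntheticCohort:
    """Generated cohort plus ground truth for validation."""

    concentrations: ConcentrationMatrix  # raw scale, masked cells NaN
    labels: pd.Series  # "case" / "control" per sample
    outcomes: list  # OutcomeRecord per sample
    truth: dict  # planted edges (by metabolite id), censoring/outlier masks


def _group_correlation_matrix(spec: SyntheticCohortSpec, group: str) -> np.ndarray:
    m = spec.n_metabolites
    corr = np.full((m, m), spec.background_r)
    np.fill_diagonal(corr, 1.0)
    col = 2 if group == "case" else 3
    for edge in spec.planted_edges:
        i, j = edge[0], edge[1]
        corr[i, j] = corr[j, i] = edge[col]
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        pairs = [(e[0], e[1]) for e in spec.planted_edges]
        raise ValueError(
            f"target correlation matrix for the {group} group is not positive "
            f"definite; check planted edges {pairs}"
        ) from None
    return corr


def _metabolite_ids(m: int) -> list[str]:
    return [f"M{k:03d}" for k in range(m)]


def _draw_womac(rng: np.random.Generator, params: WomacParams, is_case: bool,
                sample_id: str, joint: str) -> OutcomeRecord:
    bp = int(np.clip(round(rng.normal(params.baseline_pain_mean, params.baseline_pain_sd)),
                     params.mcid_pain, 20))
    bf = int(np.clip(round(rng.normal(params.baseline_function_mean, params.baseline_function_sd)),
                     params.mcid_function, 68))
    if is_case:
        cp = int(np.clip(round(rng.normal(params.case_pain_change_mean,
                                          params.case_pain_change_sd)),
                         0, params.mcid_pain - 1))
        cf = int(np.clip(round(rng.normal(params.case_function_change_mean,
                                          params.case_function_change_sd)),
                         0, params.mcid_function - 1))
    else:
        cp = int(np.clip(round(rng.normal(params.control_pain_change_mean,
                                          params.control_pain_change_sd)),
                         params.mcid_pain, bp))
        cf = int(np.clip(round(rng.normal(params.control_function_change_mean,
                                          params.control_function_change_sd)),
                         params.mcid_function, bf))
    return OutcomeRecord(
        sample_id=sample_id,
        baseline_pain=bp,
        followup_pain=int(np.clip(bp - cp, 0, 20)),
        baseline_function=bf,
        followup_function=int(np.clip(bf - cf, 0, 68)),
        joint=joint,
        primary_oa=True,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw one synthetic cohort; bit-identical for a fixed seed.

    Per group, log-scale values are multivariate normal with the requested
    correlation structure, scaled by per-metabolite location/scale parameters
    and exponentiated to a strictly positive raw scale.  Outliers (|z| drawn
    uniformly in [4, 6] on the log scale) are injected first, then LOD
    censoring (the lowest ``lod_fraction`` quantile of each designated
    metabolite) and sporadic missingness are applied; each manipulated cell
    is recorded in the truth masks.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_metabolites
    n = spec.n_case + spec.n_control
    mets = _metabolite_ids(m)
    sample_ids = [f"S{k:04d}" for k in range(n)]
    is_case = np.zeros(n, dtype=bool)
    is_case[: spec.n_case] = True

    mu = rng.normal(3.0, 1.0, size=m)  # per-metabolite log-scale location
    sd = rng.uniform(0.2, 0.8, size=m)  # per-metabolite log-scale spread

    blocks = []
    for group, n_g in (("case", spec.n_case), ("control", spec.n_control)):
        corr = _group_correlation_matrix(spec, group)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n_g, m)) @ chol.T
        blocks.append(z)
    logvals = np.vstack(blocks) * sd + mu

    # inject extreme deviates on the log scale (|z| in [4, 6] from the
    # empirical column mean/SD) so the downstream +-3 SD rule must catch them
    outlier_mask = np.zeros((n, m), dtype=bool)
    if spec.outlier_fraction > 0:
        cells = rng.random((n, m)) < spec.outlier_fraction
        if cells.any():
            col_mean = logvals.mean(axis=0)
            col_sd = logvals.std(axis=0, ddof=1)
            rows, cols = np.nonzero(cells)
            signs = rng.choice([-1.0, 1.0], size=len(rows))
            mags = rng.uniform(4.0, 6.0, size=len(rows))
            logvals[rows, cols] = col_mean[cols] + signs * mags * col_sd[cols]
            outlier_mask[rows, cols] = True

    raw = np.exp(logvals)

    # LOD censoring: the lowest lod_fraction of each designated metabolite
    # falls below the detection floor (last n_lod_metabolites columns)
    lod_mask = np.zeros((n, m), dtype=bool)
    if spec.n_lod_metabolites > 0 and spec.lod_fraction > 0:
        k_censor = int(round(spec.lod_fraction * n))
        for col in range(m - spec.n_lod_metabolites, m):
            order = np.argsort(raw[:, col], kind="stable")
            lod_mask[order[:k_censor], col] = True

    missing_mask = np.zeros((n, m), dtype=bool)
    if spec.missing_fraction > 0:
        missing_mask = (
            (rng.random((n, m)) < spec.missing_fraction) & ~lod_mask & ~outlier_mask
        )

    values = raw.copy()
    values[lod_mask | missing_mask] = np.nan
    prov = np.full((n, m), OBSERVED, dtype=np.int8)
    prov[missing_mask] = MISSING
    prov[lod_mask] = BELOW_LOD

    values_df = pd.DataFrame(values, index=sample_ids, columns=mets)
    prov_df = pd.DataFrame(prov, index=sample_ids, columns=mets)
    concentrations = ConcentrationMatrix(values_df, prov_df, "raw")

    params = spec.womac_params
    joints = np.where(rng.random(n) < params.tkr_fraction, "TKR", "THR")
    outcomes = [
        _draw_womac(rng, params, bool(is_case[k]), sample_ids[k], str(joints[k]))
        for k in range(n)
    ]
    labels = pd.Series(
        np.where(is_case, "case", "control"), index=sample_ids, name="group"
    )
    truth = {
        "planted_edges": [
            (mets[i], mets[j], rc, rr) for i, j, rc, rr in spec.planted_edges
        ],
        "outlier_mask": pd.DataFrame(outlier_mask, index=sample_ids, columns=mets),
        "lod_mask": pd.DataFrame(lod_mask, index=sample_ids, columns=mets),
        "missing_mask": pd.DataFrame(missing_mask, index=sample_ids, columns=mets),
    }
    return SyntheticCohort(
        concentrations=concentrations, labels=labels, outcomes=outcomes, truth=truth
    )
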