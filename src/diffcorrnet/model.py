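"""Model/Results facade over the differential correlation pipeline.

`DifferentialCorrelationModel` holds normalized metabolite data and a binary
group assignment; `fit` runs the permutation test and returns a
`DifferentialCorrelationResults` carrying the per-pair estimates
(correlations, Fisher z values, the standardized difference r_diff), their
permutation p-values, and helpers to threshold them into a signed network
and print a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network as _network
from .diffcorr import MIN_PAIR_N, EDGE_COLUMNS, diffstat_matrix, fisher_z, edge_sign
from .permutation import PermutationConfig, permutation_pvalues

__all__ = ["DifferentialCorrelationModel", "DifferentialCorrelationResults"]


class DifferentialCorrelationModel:
    """Two-group differential correlation model.

    Parameters
    ----------
    data : pandas.DataFrame
        Normalized samples x metabolites table (NaN = masked cell).
    groups : array-like or pandas.Series
        Group membership per sample; entries equal to ``case`` form the case
        group (by convention the non-responders), all others the controls.
    case : hashable
        The value in ``groups`` identifying the case group.
    """

    def __init__(self, data: pd.DataFrame, groups, case="case"):
        data = pd.DataFrame(data)
        groups = pd.Series(np.asarray(groups), index=data.index)
        case_mask = (groups == case).to_numpy()
        n_case, n_control = int(case_mask.sum()), int((~case_mask).sum())
        if n_case < MIN_PAIR_N or n_control < MIN_PAIR_N:
            raise ValueError(
                f"each group needs at least {MIN_PAIR_N} samples "
                f"(got case={n_case}, control={n_control})"
            )
        self.data = data
        self.case_mask = case_mask
        self.n_case = n_case
        self.n_control = n_control

    @classmethod
    def from_cohort(cls, matrix, labels, outcome: str) -> "DifferentialCorrelationModel":
        """Build from a normalized ConcentrationMatrix and ResponderLabels."""
        assignments = labels.group_assignments(outcome)
        ids = assignments.index.intersection(matrix.sample_ids)
        return cls(matrix.values.loc[ids], assignments.loc[ids], case="case")

    def fit(
        self, n_permutations: int = 1000, seed: int | None = None
    ) -> "DifferentialCorrelationResults":
        """Run the label-shuffling permutation test over all metabolite pairs."""
        config = PermutationConfig(n_permutations=n_permutations, seed=seed)
        x = self.data.to_numpy(dtype=float)
        rng = np.random.default_rng(config.seed)
        p, exceed, _ = permutation_pvalues(
            x, self.case_mask, config.n_permutations, rng
        )
        stat, r_case, r_ctrl, n_case, n_ctrl = diffstat_matrix(x, self.case_mask)
        mets = list(self.data.columns)
        order = np.argsort(np.asarray(mets, dtype=object))
        from scipy import stats as _st

        rows = []
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                i, j = order[a], order[b]
                if not np.isfinite(stat[i, j]):
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
                        "p_normal": float(2.0 * _st.norm.sf(abs(rd))),
                        "p_perm": float(p[i, j]),
                        "sign": edge_sign(rd),
                    }
                )
        edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return DifferentialCorrelationResults(
            edges=edges,
            n_case=self.n_case,
            n_control=self.n_control,
            n_permutations=n_permutations,
            seed=seed,
        )


@dataclass
class DifferentialCorrelationResults:
    """Fitted differential correlation estimates with permutation p-values."""

    edges: pd.DataFrame
    n_case: int
    n_control: int
    n_permutations: int
    seed: int | None

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        """Edges with permutation p strictly below alpha."""
        return self.edges[self.edges["p_perm"] < alpha].reset_index(drop=True)

    def network(self, alpha: float = 0.01) -> _network.DifferentialNetwork:
        """Signed network over the significant edges."""
        return _network.build_network(self.edges, alpha)

    def summary(self, alpha: float = 0.01) -> str:
        """Plain-text summary: fit info plus the significant edge table."""
        sig = self.significant(alpha).sort_values("p_perm", kind="stable")
        net = self.network(alpha)
        lines = [
            "Differential Correlation Results",
            "=" * 64,
            f"Samples:            {self.n_case} case / {self.n_control} control",
            f"Metabolite pairs:   {len(self.edges)}",
            f"Permutations:       {self.n_permutations} (seed={self.seed})",
            f"Threshold:          p < {alpha:g} (two-sided, add-one estimator)",
            f"Significant edges:  {len(sig)}",
            f"Network:            {net.n_nodes} metabolites, "
            f"components {net.component_sizes}",
            "No multiple-testing correction is applied beyond this threshold.",
            "-" * 64,
        ]
        if len(sig):
            cols = ["metabolite_i", "metabolite_j", "r_case", "r_control",
                    "r_diff", "p_perm", "sign"]
            lines.append(sig[cols].to_string(index=False, float_format="%.4f"))
        else:
            lines.append("(no significant edges)")
        return "\n".join(lines)
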