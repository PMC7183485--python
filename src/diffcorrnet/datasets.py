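"""Curated synthetic example data for demonstrations and structural tests.

Two kinds of objects live here, both constructed in code (no data files):

* Signed edge tables with the component structure characteristic of
  differential correlation networks in total-joint-replacement outcome
  studies: a *pain* network of 12 metabolites (an 8-node central component
  plus two separate pairs, hub proline with degree 3) and a *function*
  network of 23 metabolites (a 14-node central component, a 3-node network
  and three separate pairs, hub PC aa C36:8 with degree 5), sharing five
  metabolites.  The exact pairings are synthetic; only the summary topology
  (component sizes, hub degrees, node classes, overlap) is meaningful.

* A synthetic outcome cohort whose exclusion bookkeeping mirrors a typical
  enrolment funnel: 704 enrolled, 188 missing WOMAC entirely, 48 with
  non-primary osteoarthritis, 7 below both MCID baselines, leaving 461
  analyzable (445 with complete pain scores, 455 with complete function
  scores, 439 with known joint type).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffcorr import EDGE_COLUMNS, differential_statistic, edge_sign, fisher_z
from .network import DifferentialNetwork, build_network
from .phenotype import OutcomeRecord

_R_POS = (0.6, 0.1)  # (r_case, r_control) giving a positive differential edge
_R_NEG = (0.1, 0.6)

# (metabolite_i, metabolite_j, sign) -- pain network: 8-node core + two pairs
_PAIN_EDGES = [
    ("Proline", "Glutamine", "+"),
    ("Proline", "Isoleucine", "+"),
    ("Proline", "C2", "+"),
    ("Glutamine", "PC aa C38:6", "-"),
    ("Isoleucine", "PC aa C38:0", "+"),
    ("Taurine", "PC aa C38:0", "-"),
    ("Taurine", "PC aa C40:6", "-"),
    ("C14:2", "PC ae C40:6", "+"),
    ("Valine", "PC aa C36:4", "+"),
]

# function network: 14-node core + 3-node network + three pairs
_FUNCTION_EDGES = [
    ("PC aa C36:8", "Glutamine", "+"),
    ("PC aa C36:8", "Isoleucine", "+"),
    ("PC aa C36:8", "Threonine", "+"),
    ("PC aa C36:8", "C0", "+"),
    ("PC aa C36:8", "PC aa C32:1", "+"),
    ("Glutamine", "PC aa C38:0", "-"),
    ("Glutamine", "PC aa C38:6", "-"),
    ("Glutamine", "PC aa C40:6", "+"),
    ("PC aa C38:0", "lysoPC a C18:2", "-"),
    ("lysoPC a C18:2", "PC ae C36:3", "-"),
    ("PC aa C38:6", "PC aa C34:2", "+"),
    ("PC aa C40:6", "PC ae C38:2", "+"),
    ("C0", "PC aa C40:2", "+"),
    ("Serine", "PC ae C40:5", "+"),
    ("PC ae C40:5", "PC aa C38:4", "+"),
    ("Leucine", "PC aa C36:2", "+"),
    ("Glycine", "PC ae C42:3", "+"),
    ("Tryptophan", "PC aa C30:0", "+"),
]

# edges present in the table but not significant at either threshold,
# exercising the p < alpha filter
_FILLER_EDGES = [("Alanine", "Histidine", "+"), ("Lysine", "Methionine", "-")]


def _edge_table(edges, n_case: int, n_control: int, p_sig: float = 0.002) -> pd.DataFrame:
    rows = []
    for mi, mj, s in edges:
        r_case, r_control = _R_POS if s == "+" else _R_NEG
        rd = float(differential_statistic(r_case, r_control, n_case, n_control))
        rows.append(
            {
                "metabolite_i": mi,
                "metabolite_j": mj,
                "r_case": r_case,
                "r_control": r_control,
                "z_case": fisher_z(r_case),
                "z_control": fisher_z(r_control),
                "n_case": n_case,
                "n_control": n_control,
                "r_diff": rd,
                "p_normal": np.nan,
                "p_perm": p_sig,
                "sign": edge_sign(rd),
            }
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def pain_example_edges() -> pd.DataFrame:
    """Synthetic edge table for the 12-metabolite pain non-responder network."""
    table = _edge_table(_PAIN_EDGES, n_case=67, n_control=378)
    filler = _edge_table(_FILLER_EDGES, n_case=67, n_control=378, p_sig=0.3)
    return pd.concat([table, filler], ignore_index=True)


def function_example_edges() -> pd.DataFrame:
    """Synthetic edge table for the 23-metabolite function non-responder network."""
    table = _edge_table(_FUNCTION_EDGES, n_case=73, n_control=382)
    filler = _edge_table(_FILLER_EDGES, n_case=73, n_control=382, p_sig=0.3)
    return pd.concat([table, filler], ignore_index=True)


def example_networks(alpha: float = 0.01) -> tuple[DifferentialNetwork, DifferentialNetwork]:
    """Build the pain and function example networks at the given threshold."""
    return (
        build_network(pain_example_edges(), alpha),
        build_network(function_example_edges(), alpha),
    )


def synthetic_outcome_cohort(
    n_total: int = 704,
    n_missing_womac: int = 188,
    n_non_primary: int = 48,
    n_baseline_floor: int = 7,
    n_pain_missing: int = 16,
    n_function_missing: int = 6,
    n_pain_nonresponders: int = 67,
    n_function_nonresponders: int = 73,
    n_unknown_joint: int = 22,
    n_tkr: int = 318,
) -> list[OutcomeRecord]:
    """Deterministic outcome records realising a given enrolment funnel.

    The defaults produce 704 records of which 461 are analyzable (445 for
    pain, 455 for function), with 67 pain and 73 function non-responders and
    a 318/121 TKR/THR split among the 439 patients with known joint type.
    """
    n_analyzable = n_total - n_missing_womac - n_non_primary - n_baseline_floor
    if n_analyzable <= 0:
        raise ValueError("exclusions exceed the total cohort size")
    if n_pain_missing + n_function_missing > n_analyzable:
        raise ValueError("per-outcome missingness exceeds the analyzable cohort")
    n_known_joint = n_analyzable - n_unknown_joint
    if not 0 <= n_tkr <= n_known_joint:
        raise ValueError("TKR count exceeds patients with known joint type")

    records: list[OutcomeRecord] = []
    k = 0

    def next_id() -> str:
        nonlocal k
        k += 1
        return f"P{k:04d}"

    for _ in range(n_missing_womac):
        records.append(OutcomeRecord(sample_id=next_id()))
    for _ in range(n_non_primary):
        records.append(
            OutcomeRecord(next_id(), 15, 5, 50, 20, primary_oa=False)
        )
    for _ in range(n_baseline_floor):
        records.append(OutcomeRecord(next_id(), 5, 0, 20, 0))

    pain_seen = func_seen = 0
    for idx in range(n_analyzable):
        pain_missing = idx < n_pain_missing
        func_missing = n_pain_missing <= idx < n_pain_missing + n_function_missing
        joint = "unknown" if idx >= n_analyzable - n_unknown_joint else (
            "TKR" if idx < n_tkr else "THR"
        )
        if pain_missing:
            bp, fp = 15, None
        else:
            non_resp = pain_seen < n_pain_nonresponders
            pain_seen += 1
            bp, fp = (15, 10) if non_resp else (15, 5)  # change 5 vs 10
        if func_missing:
            bf, ff = 50, None
        else:
            non_resp = func_seen < n_function_nonresponders
            func_seen += 1
            bf, ff = (50, 35) if non_resp else (50, 20)  # change 15 vs 30
        records.append(OutcomeRecord(next_id(), bp, fp, bf, ff, joint=joint))
    return records
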