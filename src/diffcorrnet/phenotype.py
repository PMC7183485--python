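"""Responder / non-responder classification from WOMAC outcome scores.

Patients undergoing total joint replacement (TJR) report pain (0-20) and
function (0-68) on the WOMAC index before and after surgery, 0 meaning no
symptoms.  Improvement is measured as the pre-to-post change score
(baseline - follow-up, positive = improvement).  A patient is a
*non-responder* for an outcome when the change score falls below the minimal
clinically important difference (MCID): 7 points for pain, 22 for function.

Cohort exclusions are applied in a fixed precedence order before
classification: (1) WOMAC data missing for both subscales, (2) non-primary
osteoarthritis, (3) baseline scores below both MCIDs simultaneously (such
patients cannot achieve either MCID).  A patient with one complete subscale
remains analyzable for that outcome only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

OUTCOMES = ("pain", "function")

RESPONDER = "responder"
NON_RESPONDER = "non-responder"
EXCLUDED = "excluded"

REASON_MISSING = "missing_womac"
REASON_NON_PRIMARY = "non_primary_oa"
REASON_BASELINE_FLOOR = "baseline_below_mcid"

_RANGES = {"pain": (0, 20), "function": (0, 68)}


@dataclass
class OutcomeRecord:
    """One patient's WOMAC scores and surgical joint.

    Missing scores are ``None``.  ``joint`` is ``"TKR"``, ``"THR"`` or
    ``"unknown"``.
    """

    sample_id: str
    baseline_pain: int | None = None
    followup_pain: int | None = None
    baseline_function: int | None = None
    followup_function: int | None = None
    joint: str = "unknown"
    primary_oa: bool = True

    def __post_init__(self) -> None:
        for outcome in OUTCOMES:
            lo, hi = _RANGES[outcome]
            for when in ("baseline", "followup"):
                score = getattr(self, f"{when}_{outcome}")
                if score is not None and not lo <= score <= hi:
                    raise ValueError(
                        f"record {self.sample_id!r}: {when} {outcome} score "
                        f"{score} outside [{lo}, {hi}]"
                    )

    def complete(self, outcome: str) -> bool:
        return (
            getattr(self, f"baseline_{outcome}") is not None
            and getattr(self, f"followup_{outcome}") is not None
        )

    def change(self, outcome: str) -> int:
        return getattr(self, f"baseline_{outcome}") - getattr(self, f"followup_{outcome}")


@dataclass
class ResponderLabels:
    """Per-sample, per-outcome labels with exclusion reasons.

    ``frame`` is indexed by sample id with columns ``pain``, ``pain_reason``,
    ``function``, ``function_reason``.  Labels are ``responder``,
    ``non-responder`` or ``excluded``; reasons are empty strings for
    non-excluded samples.
    """

    frame: pd.DataFrame

    def analyzable(self, outcome: str) -> pd.Index:
        """Sample ids classified (not excluded) for the given outcome."""
        lab = self.frame[outcome]
        return self.frame.index[lab != EXCLUDED]

    def analyzable_overall(self) -> pd.Index:
        """Samples analyzable for at least one outcome."""
        keep = (self.frame["pain"] != EXCLUDED) | (self.frame["function"] != EXCLUDED)
        return self.frame.index[keep]

    def group_assignments(self, outcome: str) -> pd.Series:
        """Map analyzable samples to 'case' (non-responder) / 'control' (responder)."""
        lab = self.frame.loc[self.analyzable(outcome), outcome]
        return lab.map({NON_RESPONDER: "case", RESPONDER: "control"})


def classify(
    records: list[OutcomeRecord], mcid_pain: int = 7, mcid_function: int = 22
) -> ResponderLabels:
    """Classify each record as responder / non-responder / excluded per outcome.

    Non-responder iff change score (baseline - followup) < MCID, strictly;
    a change exactly at the MCID is a responder.
    """
    if mcid_pain <= 0 or mcid_function <= 0:
        raise ValueError("MCID thresholds must be positive")
    mcid = {"pain": mcid_pain, "function": mcid_function}
    rows = {}
    for rec in records:
        if rec.sample_id in rows:
            raise ValueError(f"duplicate sample id {rec.sample_id!r}")
        row = {}
        pain_ok, func_ok = rec.complete("pain"), rec.complete("function")
        floor = (
            rec.baseline_pain is not None
            and rec.baseline_function is not None
            and rec.baseline_pain < mcid_pain
            and rec.baseline_function < mcid_function
        )
        if not pain_ok and not func_ok:
            reason = REASON_MISSING
        elif not rec.primary_oa:
            reason = REASON_NON_PRIMARY
        elif floor:
            reason = REASON_BASELINE_FLOOR
        else:
            reason = None
        for outcome, ok in (("pain", pain_ok), ("function", func_ok)):
            if reason is not None:
                row[outcome] = EXCLUDED
                row[f"{outcome}_reason"] = reason
            elif not ok:
                row[outcome] = EXCLUDED
                row[f"{outcome}_reason"] = REASON_MISSING
            else:
                label = NON_RESPONDER if rec.change(outcome) < mcid[outcome] else RESPONDER
                row[outcome] = label
                row[f"{outcome}_reason"] = ""
        rows[rec.sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return ResponderLabels(frame)


def percent(numerator: int, denominator: int) -> float:
    """Percentage to one decimal place, rounding half away from zero."""
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cohort_summary(
    labels: ResponderLabels, records: list[OutcomeRecord]
) -> dict:
    """Per-outcome analyzable counts, non-responder rates, and joint-type mix."""
    overall = labels.analyzable_overall()
    if len(overall) == 0:
        raise ValueError("no analyzable patients")
    summary: dict = {"analyzable_overall": int(len(overall))}
    for outcome in OUTCOMES:
        ids = labels.analyzable(outcome)
        n = len(ids)
        n_non = int((labels.frame.loc[ids, outcome] == NON_RESPONDER).sum())
        summary[outcome] = {
            "analyzable": n,
            "non_responders": n_non,
            "non_responder_pct": percent(n_non, n) if n else float("nan"),
        }
    joint = {rec.sample_id: rec.joint for rec in records}
    known = [s for s in overall if joint.get(s) in ("TKR", "THR")]
    n_known = len(known)
    n_tkr = sum(1 for s in known if joint[s] == "TKR")
    summary["joint"] = {
        "known": n_known,
        "TKR": n_tkr,
        "THR": n_known - n_tkr,
        "TKR_pct": percent(n_tkr, n_known) if n_known else float("nan"),
        "THR_pct": percent(n_known - n_tkr, n_known) if n_known else float("nan"),
    }
    return summary
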