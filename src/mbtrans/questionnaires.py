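"""Scoring for the PedsQL 4.0 HRQoL inventory and the WHO-5 well-being index.

PedsQL: 23 items on a 0 (Never) to 4 (Almost always) scale in four domains
(physical 8, emotional 5, social 5, school 5). Items are reverse-transformed
to 0-100 via ``(4 - raw) * 25`` so higher means better quality of life.
Missing items within a domain are replaced by the mean of that domain's
answered transformed items, provided at least half the domain was answered;
otherwise every score involving that domain is missing. Physical functioning
is the physical-domain mean, psychosocial functioning the mean over the 15
emotional+social+school items, and the total score the mean over all 23.

WHO-5: 5 items on 0 (At no time) to 5 (All of the time); the item sum times
4 gives a 0-100 score. All five items must be answered.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

PEDSQL_DOMAINS = {"physical": 8, "emotional": 5, "social": 5, "school": 5}
PEDSQL_COLUMNS = (
    [f"pedsql_p{i}" for i in range(1, 9)]
    + [f"pedsql_e{i}" for i in range(1, 6)]
    + [f"pedsql_s{i}" for i in range(1, 6)]
    + [f"pedsql_sc{i}" for i in range(1, 6)]
)
WHO5_COLUMNS = [f"who5_{i}" for i in range(1, 6)]

__all__ = [
    "PEDSQL_COLUMNS",
    "WHO5_COLUMNS",
    "score_pedsql",
    "score_who5",
    "score_table",
]


def _domain_scores(items: list, min_answered_frac: float = 0.5):
    """Transformed item values for one domain with domain-mean imputation.

    Returns a list of 0-100 item scores of the domain's full length, or None
    if fewer than ``min_answered_frac`` of the items were answered.
    """
    vals = []
    for v in items:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            vals.append(None)
        else:
            v = float(v)
            if not (0 <= v <= 4):
                raise ValueError(f"PedsQL response out of range: {v}")
            vals.append((4.0 - v) * 25.0)
    answered = [v for v in vals if v is not None]
    if len(answered) < min_answered_frac * len(vals):
        return None
    mean = sum(answered) / len(answered)
    return [mean if v is None else v for v in vals]


def score_pedsql(
    physical, emotional, social, school
) -> dict[str, float]:
    """Score one PedsQL response; returns physical, psychosocial, total (0-100).

    Each argument is the list of raw item responses for that domain (None or
    NaN for missing). A score is NaN when any domain it uses had fewer than
    half its items answered.
    """
    for name, items in (
        ("physical", physical),
        ("emotional", emotional),
        ("social", social),
        ("school", school),
    ):
        if len(items) != PEDSQL_DOMAINS[name]:
            raise ValueError(f"{name} domain expects {PEDSQL_DOMAINS[name]} items")
    doms = {
        "physical": _domain_scores(physical),
        "emotional": _domain_scores(emotional),
        "social": _domain_scores(social),
        "school": _domain_scores(school),
    }
    phys = float(np.mean(doms["physical"])) if doms["physical"] is not None else float("nan")
    psych_items = [doms[d] for d in ("emotional", "social", "school")]
    if any(d is None for d in psych_items):
        psych = float("nan")
    else:
        flat = [v for d in psych_items for v in d]
        psych = float(np.mean(flat))
    if doms["physical"] is None or any(d is None for d in psych_items):
        total = float("nan")
    else:
        allv = [v for d in doms.values() for v in d]
        total = float(np.mean(allv))
    return {"physical": phys, "psychosocial": psych, "total": total}


def score_who5(items) -> float:
    """WHO-5 score: four times the item sum; NaN unless all 5 answered."""
    if len(items) != 5:
        raise ValueError("WHO-5 expects 5 items")
    vals = []
    for v in items:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return float("nan")
        v = float(v)
        if not (0 <= v <= 5):
            raise ValueError(f"WHO-5 response out of range: {v}")
        vals.append(v)
    return 4.0 * sum(vals)


def score_table(items_df: pd.DataFrame) -> pd.DataFrame:
    """Score a table of item responses into HRQoL and well-being columns.

    Recognises the PedsQL columns (pedsql_p1..p8, e1..e5, s1..s5, sc1..sc5)
    and/or WHO-5 columns (who5_1..who5_5); missing responses are NaN. Output
    has hrqol_total, hrqol_physical, hrqol_psychosocial and/or wellbeing.
    """
    out = pd.DataFrame(index=items_df.index)
    if all(c in items_df for c in PEDSQL_COLUMNS):
        res = []
        for _, row in items_df[PEDSQL_COLUMNS].iterrows():
            r = row.to_numpy(dtype=float)
            scores = score_pedsql(
                list(r[0:8]), list(r[8:13]), list(r[13:18]), list(r[18:23])
            )
            res.append(scores)
        out["hrqol_total"] = [s["total"] for s in res]
        out["hrqol_physical"] = [s["physical"] for s in res]
        out["hrqol_psychosocial"] = [s["psychosocial"] for s in res]
    if all(c in items_df for c in WHO5_COLUMNS):
        out["wellbeing"] = [
            score_who5(list(row))
            for row in items_df[WHO5_COLUMNS].to_numpy(dtype=float)
        ]
    if "participant_id" in items_df:
        out.insert(0, "participant_id", items_df["participant_id"].values)
    return out
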