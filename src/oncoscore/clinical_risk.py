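"""Rule-based clinical risk classification and reclassification
cross-tabulation.

Clinical risk follows the MINDACT criteria (a modified Adjuvant! Online
rule table on grade, tumor size, and nodal status): node-negative cases
are low risk with grade 1 tumors <= 3 cm, grade 2 tumors <= 2 cm, or
grade 3 tumors <= 1 cm; node-positive cases are low risk only with
grade 1 tumors <= 2 cm. Size boundaries are inclusive. Every complete
case not matching a low-risk row is high risk; any missing field makes
the case unclassifiable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._common import DataError

__all__ = ["mindact_risk", "mindact_risk_table", "reclassification_table"]

logger = logging.getLogger(__name__)

# (nodal_status, grade) -> maximum size in cm still classified low risk
_LOW_RISK_MAX_SIZE = {
    ("negative", 1): 3.0,
    ("negative", 2): 2.0,
    ("negative", 3): 1.0,
    ("positive", 1): 2.0,
}


def mindact_risk(grade, tumor_size_cm, nodal_status) -> str:
    """Classify one case as 'low', 'high', or 'unclassifiable'."""
    if grade is None or tumor_size_cm is None or nodal_status is None:
        return "unclassifiable"
    try:
        if np.isnan(float(grade)) or np.isnan(float(tumor_size_cm)):
            return "unclassifiable"
    except (TypeError, ValueError):
        return "unclassifiable"
    if isinstance(nodal_status, float) and np.isnan(nodal_status):
        return "unclassifiable"
    grade = int(grade)
    size = float(tumor_size_cm)
    if grade not in (1, 2, 3):
        raise DataError(f"grade must be 1, 2 or 3, got {grade}")
    if nodal_status not in ("negative", "positive"):
        raise DataError(f"nodal_status must be 'negative' or 'positive', "
                        f"got {nodal_status!r}")
    if size <= 0:
        raise DataError(f"tumor size must be positive, got {size}")
    max_size = _LOW_RISK_MAX_SIZE.get((nodal_status, grade))
    if max_size is not None and size <= max_size:
        return "low"
    return "high"


def mindact_risk_table(patients: pd.DataFrame) -> pd.Series:
    """Vectorized rule application over a patients table."""
    out = [mindact_risk(g, s, n) for g, s, n in
           zip(patients["grade"], patients["tumor_size_cm"],
               patients["nodal_status"])]
    return pd.Series(out, index=patients.index, name="clinical_risk")


def reclassification_table(clinical_risk, ai_category,
                           strata=None) -> pd.DataFrame:
    """Stratified (clinical risk x surrogate risk) cross-tabulation.

    Unclassifiable clinical rows are excluded with a logged count. Row
    proportions normalize within each (stratum, clinical_risk) row, so
    they read as "share of clinically low/high patients reclassified to
    each surrogate category".
    """
    clinical_risk = pd.Series(np.asarray(clinical_risk, dtype=object),
                              name="clinical_risk")
    ai_category = pd.Series(np.asarray(ai_category, dtype=object),
                            name="ai_risk")
    if len(clinical_risk) != len(ai_category):
        raise DataError("clinical_risk and ai_category must have equal length")
    if strata is None:
        strata = pd.Series(["all"] * len(clinical_risk), name="stratum")
    else:
        strata = pd.Series(np.asarray(strata, dtype=object), name="stratum")
        if len(strata) != len(clinical_risk):
            raise DataError("strata must align with the risk vectors")
    df = pd.concat([strata, clinical_risk, ai_category], axis=1)
    n_excluded = int((df["clinical_risk"] == "unclassifiable").sum())
    if n_excluded:
        logger.info("excluding %d unclassifiable case(s) from the "
                    "reclassification table", n_excluded)
    df = df[df["clinical_risk"] != "unclassifiable"]
    counts = (df.groupby(["stratum", "clinical_risk", "ai_risk"], sort=True)
              .size().rename("count").reset_index())
    row_totals = counts.groupby(["stratum", "clinical_risk"])["count"].transform("sum")
    counts["row_proportion"] = counts["count"] / row_totals
    return counts
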