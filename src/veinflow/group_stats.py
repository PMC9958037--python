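"""Group comparisons of QFlow parameters between reflux and control limbs.

For each venous segment (EIV, FV, PV, GSV) and each of the six parameters
SV, FFV, ASV, MF, SD, MV an unpaired two-tailed Student's t test (pooled
variance, df = n_a + n_b - 2) compares the reflux-patient limbs against the
healthy-control limbs.  Significance tiers follow the usual convention:
* p < 0.05, ** p < 0.01, *** p < 0.001, otherwise ns.  BFV and RF are not
compared (RF can be undefined, and both are redundant with FFV/ASV given
SV).  No multiple-testing correction is applied; the 24 comparisons are
reported raw and the output notes this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: parameters compared per segment
COMPARE_PARAMS = ["sv", "ffv", "asv", "mf", "sd", "mv"]
SEGMENTS = ["EIV", "FV", "PV", "GSV"]

MULTIPLICITY_NOTE = ("p values are reported raw, without multiple-testing "
                     "correction, across all segment/parameter comparisons")


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    tier: str


def student_t_test(a, b, welch: bool = False) -> TTestResult:
    """Unpaired two-tailed t test of two samples.

    Classic pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Two constant samples with equal means give
    t = 0, p = 1; with unequal means the test is rejected as degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        df = float(a.size + b.size - 2)
        if a[0] == b[0]:
            return TTestResult(0.0, df, 1.0, "ns")
        raise ValueError("zero pooled variance with unequal means: "
                         "t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), float(res.df), p,
                       significance_tier(p))


def compare_segments(qflow: pd.DataFrame, labels,
                     welch: bool = False) -> pd.DataFrame:
    """One t-test row per (segment, parameter); 4 x 6 = 24 rows.

    ``labels`` maps subject_id -> 1 (reflux limb) / 0 (control limb).  Rows
    where a segment lacks one group (or a group has < 2 values) are flagged
    ``skipped`` instead of producing a spurious statistic.  Undefined (NaN)
    parameter values never enter a test.
    """
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["subject_id"], labels["label"]))
    lab = qflow["subject_id"].map(dict(labels))
    rows = []
    for seg in SEGMENTS:
        sub = qflow[qflow["setpoint"] == seg]
        for param in COMPARE_PARAMS:
            vals = sub[param].to_numpy(dtype=float)
            grp = lab[sub.index].to_numpy()
            ok = np.isfinite(vals) & ~pd.isna(grp)
            a = vals[ok & (grp == 1)]
            b = vals[ok & (grp == 0)]
            row = {"segment": seg, "parameter": param,
                   "n_reflux": int(a.size), "n_control": int(b.size)}
            if a.size < 2 or b.size < 2:
                row.update(t=np.nan, df=np.nan, p=np.nan, tier="skipped")
            else:
                res = student_t_test(a, b, welch=welch)
                row.update(t=res.t_statistic, df=res.degrees_of_freedom,
                           p=res.p_value, tier=res.tier)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["note"] = MULTIPLICITY_NOTE
    return df
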