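"""Build the six-dimensional classifier input from a QFlow parameter table.

Per subject the feature vector is

    [SV_GSV, FFV_GSV, ASV_GSV, MF_GSV, SD_GSV/SD_PV, MF_GSV/MF_PV]

i.e. the four GSV parameters that separate refluxing from normal limbs plus
two unitless GSV/PV ratios.  The second ratio can optionally be taken over
MV instead of MF (``ratio="mv"``).  The desired classifier output is 1 for a
reflux-patient limb and 0 for a healthy-control limb.

Because the features mix mL, mL/s and unitless ratios into one Euclidean
distance inside the Gaussian hidden units, standardization (zero mean, unit
dispersion per component, learned on the training table) is applied by
default before training; see :class:`Standardizer`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fixed order of the six classifier inputs (default MF-based second ratio)
FEATURE_COLUMNS = ["sv_gsv", "ffv_gsv", "asv_gsv", "mf_gsv",
                   "sd_gsv_pv", "mf_gsv_pv"]


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    reason: str


def _labels_to_map(labels) -> dict[str, int]:
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["subject_id"], labels["label"]))
    labels = {k: int(v) for k, v in dict(labels).items()}
    bad = {v for v in labels.values() if v not in (0, 1)}
    if bad:
        raise ValueError(f"labels must be binary 0/1, got {sorted(bad)}")
    return labels


def build_features(qflow: pd.DataFrame, labels,
                   ratio: str = "mf") -> tuple[pd.DataFrame, list[Exclusion]]:
    """Assemble one feature row per subject from the QFlow table.

    ``labels`` maps subject_id -> {0, 1} (or is a DataFrame with subject_id
    and label columns).  Subjects missing a GSV or PV row, with a zero ratio
    denominator, or with non-finite features are excluded with a logged
    reason rather than poisoning the training table.
    """
    if ratio not in ("mf", "mv"):
        raise ValueError("ratio must be 'mf' or 'mv'")
    label_map = _labels_to_map(labels)
    cols = list(FEATURE_COLUMNS)
    cols[5] = f"{ratio}_gsv_pv"

    rows, exclusions = [], []
    by_subject = {sid: g.set_index("setpoint")
                  for sid, g in qflow.groupby("subject_id")}
    for sid in by_subject:
        if sid not in label_map:
            exclusions.append(Exclusion(sid, "no label"))
            continue
        g = by_subject[sid]
        missing = {"GSV", "PV"} - set(g.index)
        if missing:
            exclusions.append(Exclusion(sid, f"missing setpoint {sorted(missing)}"))
            continue
        gsv, pv = g.loc["GSV"], g.loc["PV"]
        if pv["sd"] == 0 or pv[ratio] == 0:
            exclusions.append(Exclusion(sid, "zero PV ratio denominator"))
            continue
        x = [gsv["sv"], gsv["ffv"], gsv["asv"], gsv["mf"],
             gsv["sd"] / pv["sd"], gsv[ratio] / pv[ratio]]
        if not np.all(np.isfinite(x)):
            exclusions.append(Exclusion(sid, "non-finite feature value"))
            continue
        rows.append({"subject_id": sid, **dict(zip(cols, x)),
                     "label": label_map[sid]})
    for exc in exclusions:
        logger.warning("excluding subject %s: %s", exc.subject_id, exc.reason)
    df = pd.DataFrame(rows, columns=["subject_id", *cols, "label"])
    return df, exclusions


def feature_matrix(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into the (n, 6) input matrix and 0/1 targets."""
    cols = [c for c in features.columns if c not in ("subject_id", "label")]
    if len(cols) != 6:
        raise ValueError(f"expected 6 feature columns, found {cols}")
    return features[cols].to_numpy(dtype=float), \
        features["label"].to_numpy(dtype=int)


@dataclass(frozen=True)
class Standardizer:
    """Affine per-component transform to zero mean and unit dispersion."""

    center: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.center

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d) -> "Standardizer":
        return cls(center=np.asarray(d["center"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float))


def fit_standardizer(X: np.ndarray) -> Standardizer:
    """Learn componentwise center (mean) and scale (population SD)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D table with at least 2 rows")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    dead = np.flatnonzero(scale == 0)
    if dead.size:
        raise ValueError(f"zero-dispersion feature component(s) {dead.tolist()}: "
                         "cannot standardize")
    return Standardizer(center=center, scale=scale)
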