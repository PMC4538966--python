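"""Arousal/valence affective-state mapping.

The two-dimensional (Lang) affective space is spanned by emotional valence
and physiological arousal; quadrants name affective states (positive
valence + low arousal = relaxed, negative valence + high arousal =
distressed). Each physiological index loads on one dimension with a known
direction: heart rate, skin conductance and EEG beta rise with arousal;
corrugator EMG and frontal alpha asymmetry fall as valence rises (under the
activation-is-low-alpha convention); pupil dilation tracks emotional
intensity; slow alpha falls as sustained attention rises; and the LF/HF
balance rises — with NN50 and RMSSD falling — under negative affect.

Scores are equal-weight averages of within-cohort z-scores, so they are
invariant to any affine rescaling of a raw index across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DegenerateError, InsufficientDataError

#: Loadings of each z-scored index on each affective dimension.
DIMENSION_LOADINGS = {
    "arousal": {"heart_rate": 1.0, "skin_conductance": 1.0, "beta": 1.0},
    "valence": {"emg_corrugator": -1.0, "alpha_asymmetry": -1.0},
    "intensity": {"pupil_dilation": 1.0},
    "attention": {"slow_alpha": -1.0},
    "negative_affect": {"lf_hf": 1.0, "nn50": -1.0, "rmssd": -1.0},
}


class Quadrant(str, Enum):
    POSITIVE_LOW = "POSITIVE_LOW"     # relaxed
    POSITIVE_HIGH = "POSITIVE_HIGH"
    NEGATIVE_LOW = "NEGATIVE_LOW"
    NEGATIVE_HIGH = "NEGATIVE_HIGH"   # distressed
    NEUTRAL = "NEUTRAL"


@dataclass
class AffectiveState:
    """Per-subject scores (z-units) plus the Lang-quadrant label."""

    arousal: float
    valence: float
    intensity: float
    attention: float
    negative_affect: float
    quadrant: Quadrant


def classify_quadrant(valence: float, arousal: float,
                      epsilon: float = 1e-9) -> Quadrant:
    """Quadrant from the signs of valence and arousal; near-zero is NEUTRAL."""
    if not (np.isfinite(valence) and np.isfinite(arousal)):
        raise ValueError("valence and arousal must be finite")
    if abs(valence) < epsilon or abs(arousal) < epsilon:
        return Quadrant.NEUTRAL
    if valence > 0:
        return Quadrant.POSITIVE_HIGH if arousal > 0 else Quadrant.POSITIVE_LOW
    return Quadrant.NEGATIVE_HIGH if arousal > 0 else Quadrant.NEGATIVE_LOW


def _zscore_cohort(features: pd.DataFrame) -> pd.DataFrame:
    cols = sorted({name for loads in DIMENSION_LOADINGS.values()
                   for name in loads})
    if len(features) < 2:
        raise InsufficientDataError("z-scaling needs >= 2 included subjects")
    z = pd.DataFrame(index=features.index)
    for col in cols:
        x = features[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateError(f"zero cohort variance for '{col}'")
        z[col] = (x - x.mean()) / sd
    return z


def compute_scores(features: pd.DataFrame) -> pd.DataFrame:
    """Affective scores for every included subject of a cohort.

    ``features`` is the extraction output (one row per subject, the ten
    index columns; an optional ``excluded`` flag drops subjects from both
    the z-scaling pool and the output). Returns one row per subject with
    the five dimension scores and the quadrant label.
    """
    if "excluded" in features.columns:
        features = features.loc[~features["excluded"].astype(bool)]
    z = _zscore_cohort(features)
    out = pd.DataFrame(index=features.index)
    for key in ("subject_id", "condition", "role"):
        if key in features.columns:
            out[key] = features[key]
    for dim, loads in DIMENSION_LOADINGS.items():
        out[dim] = sum(sign * z[name] for name, sign in loads.items()) / len(loads)
    out["quadrant"] = [classify_quadrant(v, a).value
                       for v, a in zip(out["valence"], out["arousal"])]
    return out


def subject_state(scores_row: pd.Series) -> AffectiveState:
    """Wrap one row of :func:`compute_scores` output as an AffectiveState."""
    return AffectiveState(
        arousal=float(scores_row["arousal"]),
        valence=float(scores_row["valence"]),
        intensity=float(scores_row["intensity"]),
        attention=float(scores_row["attention"]),
        negative_affect=float(scores_row["negative_affect"]),
        quadrant=Quadrant(scores_row["quadrant"]),
    )


def group_states(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean scores per condition, with the quadrant of the group mean."""
    dims = list(DIMENSION_LOADINGS)
    agg = scores.groupby("condition")[dims].mean()
    agg["quadrant"] = [classify_quadrant(row["valence"], row["arousal"]).value
                       for _, row in agg.iterrows()]
    return agg
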