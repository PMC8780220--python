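"""Classifier feature schema for registrations.

Thirteen per-registration features describe a registration and its
movement context within the same tag: the previous/current/next zones, the
strongest RSS, the tracking-station identity, the previous/current/next
stay durations, the runner-up zone and its RSS, whether three or more
zones were heard in the decoding window, and whether the neighbouring
registrations' runner-up zone equals the current zone (a strong signature
of a stationary hen flip-flopping between two markers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: the 13 feature columns, in schema order
FEATURE_COLUMNS = [
    "previous_zone",
    "zone",
    "next_zone",
    "rss",
    "tracking_system_id",
    "previous_duration",
    "duration",
    "next_duration",
    "zone2",
    "rss_zone2",
    "zone3exist",
    "next2zone_eq_zone",
    "previous2zone_eq_zone",
]

#: category used for previous/next fields at the edges of a tag's record
NONE_CATEGORY = "NONE"

CATEGORICAL_FEATURES = [
    "previous_zone",
    "zone",
    "next_zone",
    "tracking_system_id",
    "zone2",
]


def build_features(regs: pd.DataFrame) -> pd.DataFrame:
    """Build the 13-column feature table, one row per registration.

    Previous/next fields are computed within tag; boundary registrations
    get the ``NONE`` category (and NaN durations).  The returned frame is
    index-aligned with ``regs``.
    """
    if regs.empty:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    out = pd.DataFrame(index=regs.index)
    g = regs.groupby("tag_id", sort=False)
    zone2 = regs["zone2"].where(regs["zone2"].notna(), NONE_CATEGORY)

    out["previous_zone"] = g["zone"].shift(1).fillna(NONE_CATEGORY)
    out["zone"] = regs["zone"]
    out["next_zone"] = g["zone"].shift(-1).fillna(NONE_CATEGORY)
    out["rss"] = regs["rss"]
    out["tracking_system_id"] = regs["station_id"]
    out["previous_duration"] = g["duration"].shift(1)
    out["duration"] = regs["duration"]
    out["next_duration"] = g["duration"].shift(-1)
    out["zone2"] = zone2
    out["rss_zone2"] = regs["rss2"]
    out["zone3exist"] = regs["zone3exist"].astype(int)

    zone2_by_tag = zone2.groupby(regs["tag_id"], sort=False)
    next2 = zone2_by_tag.shift(-1)
    prev2 = zone2_by_tag.shift(1)
    out["next2zone_eq_zone"] = (next2 == regs["zone"]).astype(int)
    out["previous2zone_eq_zone"] = (prev2 == regs["zone"]).astype(int)
    out["next2zone_eq_zone"] = out["next2zone_eq_zone"].where(next2.notna(), 0)
    out["previous2zone_eq_zone"] = out["previous2zone_eq_zone"].where(
        prev2.notna(), 0
    )
    assert list(out.columns) == FEATURE_COLUMNS
    return out


def encode_features(features: pd.DataFrame, categories: dict | None = None):
    """Encode the feature table numerically for a tree learner.

    Categorical columns become integer codes over a fixed category list
    (so train/apply encodings agree); numeric columns pass through with
    NaN preserved.  Returns ``(X, categorical_mask, categories)``.
    """
    from .zones import ZONES

    zone_cats = [z.value for z in ZONES] + [NONE_CATEGORY]
    if categories is None:
        categories = {
            col: (
                zone_cats
                if col != "tracking_system_id"
                else sorted(features[col].astype(str).unique())
            )
            for col in CATEGORICAL_FEATURES
        }
    X = features.copy()
    for col in CATEGORICAL_FEATURES:
        codes = pd.Categorical(
            X[col].astype(str), categories=categories[col]
        ).codes.astype(np.float64)
        codes[codes < 0] = np.nan  # unseen category
        X[col] = codes
    mask = np.array([c in CATEGORICAL_FEATURES for c in FEATURE_COLUMNS])
    return X[FEATURE_COLUMNS].astype(float), mask, categories
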