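"""Label registrations against ground truth: CR/FR, subtypes, missed moves.

A registration is a correct registration (CR) when the registered zone is
the animal's true zone at the registration time, and a false registration
(FR) otherwise.  Among CRs, the first registration falling inside a true
stay is *transitional* (it reports the actual zone change); later CRs in
the same stay are *corrected* (the system re-confirming the zone after an
error).  A true zone change with no registration at all inside its stay is
a *missed transition* and is emitted as its own row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LABEL_COLUMNS = [
    "tag_id",
    "pen_id",
    "zone",
    "t_start",
    "duration",
    "label",
    "subtype",
    "missed",
    "true_zone",
]


class LabelingGapError(ValueError):
    """A registration falls outside the ground-truth coverage."""


def label_registrations(regs: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Label each registration CR/FR (with CR subtype) and append one
    ``missed = 1`` row per true transition that produced no registration.

    ``truth`` must cover every registration's ``t_start``; a gap raises
    :class:`LabelingGapError` naming the tag and time.
    """
    rows: list[pd.DataFrame] = []
    reg_groups = (
        {k: v for k, v in regs.groupby("tag_id", sort=False)}
        if not regs.empty
        else {}
    )
    for tag_id, tag_truth in truth.groupby("tag_id", sort=False):
        tag_truth = tag_truth.sort_values("t_start")
        starts = tag_truth["t_start"].to_numpy(float)
        ends = tag_truth["t_end"].to_numpy(float)
        true_zones = tag_truth["zone"].to_numpy(object)

        tag_regs = reg_groups.pop(tag_id, None)
        if tag_regs is not None and not tag_regs.empty:
            t = tag_regs["t_start"].to_numpy(float)
            stay_idx = np.searchsorted(starts, t, side="right") - 1
            bad = (stay_idx < 0) | (t >= ends[np.clip(stay_idx, 0, None)])
            if bad.any():
                k = int(np.argmax(bad))
                raise LabelingGapError(
                    f"registration of tag {tag_id} at t={t[k]:.1f}s outside "
                    "ground-truth coverage"
                )
            true_zone = true_zones[stay_idx]
            is_cr = tag_regs["zone"].to_numpy(object) == true_zone
            # first registration inside each true stay
            first_in_stay = np.zeros(len(t), dtype=bool)
            _, first_pos = np.unique(stay_idx, return_index=True)
            first_in_stay[first_pos] = True
            labeled = tag_regs.copy()
            labeled["label"] = np.where(is_cr, "CR", "FR")
            labeled["subtype"] = np.where(
                is_cr & first_in_stay,
                "transitional",
                np.where(is_cr, "corrected", None),
            )
            labeled["missed"] = 0
            labeled["true_zone"] = true_zone
            rows.append(labeled[LABEL_COLUMNS + ["station_id"]])
            covered = set(np.unique(stay_idx).tolist())
        else:
            covered = set()

        # entry into the first stay is not a transition by convention
        missed_idx = [
            i for i in range(1, len(starts)) if i not in covered
        ]
        if missed_idx:
            pen = tag_truth["pen_id"].iloc[0]
            rows.append(
                pd.DataFrame(
                    {
                        "tag_id": tag_id,
                        "pen_id": pen,
                        "zone": None,
                        "t_start": starts[missed_idx],
                        "duration": np.nan,
                        "label": None,
                        "subtype": None,
                        "missed": 1,
                        "true_zone": true_zones[missed_idx],
                        "station_id": None,
                    }
                )
            )
    if reg_groups:
        tag_id = next(iter(reg_groups))
        raise LabelingGapError(f"no ground truth for tag {tag_id}")
    if not rows:
        return pd.DataFrame(columns=LABEL_COLUMNS + ["station_id"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["tag_id", "t_start"], kind="stable").reset_index(
        drop=True
    )
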