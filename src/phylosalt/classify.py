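"""Salinity-preference classification from reciprocal-transplant presence patterns.

A taxon's preference is a pure function of its presence in the four
origin-host treatments FF, FS, SF, SS:

* ``none``  — present in both controls (FF and SS): native to both salinities.
* ``fresh`` — present in the freshwater controls (FF), present in saltwater-
  origin soil transplanted to freshwater (SF), absent from the saltwater
  controls (SS).
* ``salt``  — mirrored: present in SS and FS, absent from FF.
* ``unclassified`` — any other pattern (e.g. present only in a transplant).

This deliberately conservative membership-based rule does not call taxa that
are merely enriched or depleted between salinities; the raw 4-bit pattern is
emitted with every label so alternative rules can be re-derived downstream.
"""

from __future__ import annotations

import pandas as pd

from ._util import PREFERENCES, TREATMENTS, log_stage
from .prep import PresenceMatrix


def classify_pattern(ff: bool, fs: bool, sf: bool, ss: bool) -> str:
    """Label one presence pattern over (FF, FS, SF, SS)."""
    if ff and ss:
        return "none"
    if ff and sf and not ss:
        return "fresh"
    if ss and fs and not ff:
        return "salt"
    return "unclassified"


def classify_preference(presence: PresenceMatrix) -> pd.DataFrame:
    """Assign every taxon a salinity preference from its presence pattern.

    Returns a DataFrame indexed by taxon_id with the four 0/1 treatment
    columns and a ``preference`` column in
    {fresh, salt, none, unclassified}.
    """
    missing = [t for t in TREATMENTS if t not in presence.treatment_ids]
    if missing:
        raise ValueError(f"presence matrix missing treatment(s): {missing}")
    pat = presence.presence[list(TREATMENTS)]
    labels = [
        classify_pattern(*row)
        for row in pat.itertuples(index=False)
    ]
    out = pat.astype(int).copy()
    out["preference"] = pd.Categorical(labels, categories=list(PREFERENCES))
    log_stage("classify_preference", taxa=len(out),
              **out["preference"].value_counts().to_dict())
    return out


def tabulate_preferences(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per preference label (all four labels reported).

    Counts sum to the number of taxa; fractions sum to 1.
    """
    counts = (assignments["preference"].value_counts()
              .reindex(PREFERENCES, fill_value=0))
    total = int(counts.sum())
    out = pd.DataFrame({"count": counts.astype(int)})
    out["fraction"] = out["count"] / total if total else 0.0
    out.index.name = "preference"
    return out
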