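"""Rare-taxon filtering, rarefaction, and replicate-majority presence calls.

The presence/absence collapse implements the replicate-majority rule: a
taxon is "present" in a treatment when it is detected in strictly more than
half of that treatment's replicates (3 of 5 in the reference design); ties
under even replicate counts resolve to absent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._util import TREATMENTS, derive_rng, log_stage, logger
from .io import SampleMetadata, TaxonCountTable


class PresenceMatrix:
    """Boolean presence of taxa across treatments, with replicate support.

    Attributes
    ----------
    presence : DataFrame (taxa x treatments, bool)
    detected : DataFrame (taxa x treatments, int) — replicates detected in
    replicates : Series (treatments, int) — replicate count per treatment
    """

    def __init__(self, presence: pd.DataFrame, detected: pd.DataFrame,
                 replicates: pd.Series):
        if not presence.index.equals(detected.index):
            raise ValueError("presence/support taxon indices differ")
        if list(presence.columns) != list(detected.columns):
            raise ValueError("presence/support treatment columns differ")
        if ((detected.to_numpy() > replicates.loc[detected.columns].to_numpy())
                .any()):
            raise ValueError("support numerator exceeds replicate count")
        expected = detected.gt(replicates.loc[detected.columns] / 2.0, axis=1)
        if not expected.equals(presence.astype(bool)):
            raise ValueError("presence does not match strict-majority support")
        self.presence = presence.astype(bool)
        self.detected = detected.astype(int)
        self.replicates = replicates.astype(int)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def treatment_ids(self) -> list[str]:
        return list(self.presence.columns)

    def write(self, path: str | Path, support_path: str | Path | None = None) -> None:
        self.presence.astype(int).to_csv(path, sep="\t")
        if support_path is not None:
            support = self.detected.astype(str) + "/" + pd.DataFrame(
                {c: [str(self.replicates[c])] * len(self.detected) for c in
                 self.detected.columns}, index=self.detected.index)
            support.to_csv(support_path, sep="\t")

    def __repr__(self) -> str:
        return (f"PresenceMatrix({len(self.taxon_ids)} taxa x "
                f"{self.treatment_ids})")


def filter_rare_taxa(
    table: TaxonCountTable, rare_fraction: float
) -> TaxonCountTable:
    """Drop taxa whose share of all reads is strictly below ``rare_fraction``.

    The inequality is strict: a taxon holding exactly the threshold fraction
    is retained. Taxon order is preserved. Removing every taxon is fatal.
    """
    if not 0.0 <= rare_fraction < 1.0:
        raise ValueError("rare_fraction must lie in [0, 1)")
    totals = table.taxon_totals
    grand = table.grand_total
    keep = totals >= rare_fraction * grand
    removed = totals.index[~keep].tolist()
    if keep.sum() == 0:
        raise ValueError("rare-taxon filter removed every taxon")
    if removed:
        logger.info("filter_rare_taxa removed %d taxa: %s",
                    len(removed), removed[:10])
    log_stage("filter_rare_taxa", rare_fraction=rare_fraction,
              taxa_in=len(totals), taxa_out=int(keep.sum()))
    if not removed:
        return table
    return TaxonCountTable(table.data.loc[keep])


def rarefy_counts(
    table: TaxonCountTable, depth: int, seed: int | None = None
) -> TaxonCountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Draws are multivariate hypergeometric per sample (classic rarefaction),
    so a sample whose total equals the depth is returned unchanged. Samples
    below the depth are an error, listed by ID.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.sample_totals
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        raise ValueError(f"samples below rarefaction depth {depth}: {shallow}")
    rng = derive_rng(seed, "rarefy")
    out = np.empty_like(table.counts)
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    log_stage("rarefy_counts", depth=depth, samples=len(table.sample_ids))
    return TaxonCountTable(pd.DataFrame(out, index=table.data.index,
                                        columns=table.data.columns))


def collapse_presence(
    table: TaxonCountTable,
    meta: SampleMetadata,
    min_count: int = 1,
) -> PresenceMatrix:
    """Collapse replicate samples into per-treatment presence/absence.

    Detection in one sample means count >= ``min_count`` (default 1; the
    study design states no per-sample detection floor). A taxon is present
    in a treatment iff detected in strictly more than half its replicates.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    absent_meta = sorted(set(table.sample_ids) - set(meta.sample_ids))
    if absent_meta:
        raise ValueError(f"samples missing from metadata: {absent_meta}")
    codes = meta.treatment_codes().reindex(table.sample_ids)
    detected_flags = table.data >= min_count
    detected = detected_flags.T.groupby(codes).sum().T
    replicates = codes.value_counts().sort_index()
    if (replicates < 1).any():
        raise ValueError("every treatment needs at least one replicate")
    order = [t for t in TREATMENTS if t in detected.columns] + [
        t for t in detected.columns if t not in TREATMENTS]
    detected = detected[order]
    presence = detected.gt(replicates.loc[order] / 2.0, axis=1)
    log_stage("collapse_presence", min_count=min_count,
              treatments=list(order), taxa=len(table.taxon_ids))
    return PresenceMatrix(presence, detected, replicates)


def shared_membership(presence: PresenceMatrix) -> pd.DataFrame:
    """Count taxa in every treatment-set intersection region (Venn table).

    Each taxon falls in exactly one of the 2^T membership regions, including
    the absent-everywhere bin; region counts therefore sum to the number of
    taxa. Regions are keyed by per-treatment 0/1 columns.
    """
    treatments = presence.treatment_ids
    if len(treatments) < 2:
        raise ValueError("shared membership needs at least two treatments")
    pat = presence.presence.astype(int)
    counts = pat.groupby(treatments).size()
    grid = pd.MultiIndex.from_product([[0, 1]] * len(treatments),
                                      names=treatments)
    counts = counts.reindex(grid, fill_value=0)
    out = counts.reset_index(name="n_taxa")
    out["region"] = [
        "|".join(f"{t}{'+' if row[t] else '-'}" for t in treatments)
        for _, row in out.iterrows()
    ]
    return out[["region", *treatments, "n_taxa"]]
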