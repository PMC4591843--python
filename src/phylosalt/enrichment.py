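"""Bootstrap enrichment of salinity preferences within taxonomic clades.

For each clade, the share of taxa in each preference category is compared
with the community-wide expectation (the category's share of all taxa in
the comparison universe). A percentile bootstrap CI — resampling the
clade's members with replacement, clade size preserved — decides the
verdict: *enriched* when the CI lies entirely above the expectation,
*depleted* when entirely below, otherwise *indistinguishable*. No
multiple-testing correction is applied across clades.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import derive_rng, log_stage, logger

CLASSIFIED = ("fresh", "salt", "none")

PROTEO_CLASSES = {
    "alphaproteobacteria", "betaproteobacteria", "gammaproteobacteria",
    "deltaproteobacteria", "epsilonproteobacteria", "zetaproteobacteria",
}


def bootstrap_share_ci(
    category_counts: np.ndarray,
    iters: int,
    ci_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Percentile bootstrap CIs for category shares of a finite sample.

    Resampling n items with replacement and tallying categories is
    distributionally identical to one multinomial(n, observed shares) draw,
    which is how the resamples are generated. Returns an array of
    (lower, upper) percentage bounds per category.
    """
    n = int(category_counts.sum())
    probs = category_counts / n
    draws = rng.multinomial(n, probs, size=iters)  # (iters, n_categories)
    pct = draws * (100.0 / n)
    lo = (1.0 - ci_level) / 2.0
    return np.quantile(pct, [lo, 1.0 - lo], axis=0).T


def clade_enrichment(
    assignments: pd.DataFrame,
    clade_map: pd.Series,
    bootstrap_iters: int = 6000,
    ci_level: float = 0.95,
    universe: str = "classified",
    min_clade_size: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per clade x preference: observed %, bootstrap CI, expected %, verdict.

    Parameters
    ----------
    assignments : DataFrame
        Output of :func:`phylosalt.classify.classify_preference`.
    clade_map : Series
        taxon_id -> clade label. Taxa without a mapping are reported and
        excluded.
    universe : {'classified', 'all'}
        The comparison universe for the expected percentages: the three
        named preference categories, or all four including unclassified.
    """
    if universe not in ("classified", "all"):
        raise ValueError("universe must be 'classified' or 'all'")
    categories = list(CLASSIFIED) + (["unclassified"] if universe == "all" else [])
    prefs = assignments["preference"].astype(str)
    in_universe = prefs.isin(categories)
    prefs = prefs[in_universe]

    unmapped = sorted(set(prefs.index) - set(clade_map.index))
    if unmapped:
        logger.warning("clade_enrichment: %d taxa without clade mapping "
                       "excluded: %s", len(unmapped), unmapped[:10])
        prefs = prefs.drop(unmapped)
    if prefs.empty:
        raise ValueError("no taxa left in the enrichment universe")

    clades = clade_map.reindex(prefs.index)
    universe_counts = prefs.value_counts().reindex(categories, fill_value=0)
    expected_pct = universe_counts / len(prefs) * 100.0

    rng = derive_rng(seed, "clade_enrichment")
    rows = []
    for clade, members in prefs.groupby(clades, sort=True):
        n = len(members)
        if n == 0:
            logger.warning("clade_enrichment: empty clade %r skipped", clade)
            continue
        counts = members.value_counts().reindex(categories, fill_value=0)
        ci = bootstrap_share_ci(counts.to_numpy(dtype=float),
                                bootstrap_iters, ci_level, rng)
        observed = counts / n * 100.0
        for i, cat in enumerate(categories):
            lo, hi = ci[i]
            exp = expected_pct[cat]
            if lo > exp:
                verdict = "enriched"
            elif hi < exp:
                verdict = "depleted"
            else:
                verdict = "indistinguishable"
            rows.append({
                "clade": clade, "n_taxa": n, "preference": cat,
                "observed_pct": observed[cat], "ci_lower": lo, "ci_upper": hi,
                "expected_pct": exp, "verdict": verdict,
                "iterations": bootstrap_iters,
                "low_confidence": n < min_clade_size,
            })
    log_stage("clade_enrichment", clades=len({r['clade'] for r in rows}),
              iters=bootstrap_iters, universe=universe)
    return pd.DataFrame(rows)


def preference_by_rank(
    assignments: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str = "phylum_with_proteobacterial_classes",
) -> pd.Series:
    """Map taxa to clades at a taxonomic rank from ranked lineage strings.

    Lineages are semicolon-delimited with optional Greengenes-style
    ``k__/p__/c__`` prefixes. Missing or empty lineages map to
    ``Unassigned``. With ``rank='phylum_with_proteobacterial_classes'``,
    Proteobacteria are resolved at class level (alpha-, beta-, gamma-,
    delta-proteobacteria reported separately).
    """
    ranks = {"phylum": 1, "class": 2}
    if rank not in ranks and rank != "phylum_with_proteobacterial_classes":
        raise ValueError(f"unknown rank {rank!r}")

    def level(parts: list[str], i: int) -> str:
        if i >= len(parts):
            return ""
        name = parts[i].strip()
        if "__" in name:
            name = name.split("__", 1)[1]
        return name.strip()

    out = {}
    lineages = taxonomy["lineage"] if "lineage" in taxonomy.columns else None
    for taxon in assignments.index:
        lineage = ""
        if lineages is not None and taxon in lineages.index:
            lineage = str(lineages.loc[taxon]) or ""
        parts = [p for p in lineage.split(";")] if lineage else []
        if rank in ranks:
            clade = level(parts, ranks[rank])
        else:
            phylum = level(parts, 1)
            if phylum.lower() == "proteobacteria":
                clade = level(parts, 2) or "Proteobacteria"
            else:
                clade = phylum
        out[taxon] = clade if clade else "Unassigned"
    return pd.Series(out, name="clade")
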