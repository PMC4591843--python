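"""Model-object facade over the pipeline: build once, ``fit()``, inspect results.

``TransplantExperiment`` holds the aligned inputs and configuration;
``fit()`` runs filtering, presence collapsing, preference classification,
phylogenetic-signal testing, optional clade enrichment and
composition-function coupling, returning a ``TransplantResults`` with the
estimates, their uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from ._util import log_stage
from .classify import classify_preference, tabulate_preferences
from .config import AnalysisConfig
from .coupling import MantelResult, gower_distance, mantel_test, weighted_unifrac
from .enrichment import clade_enrichment, preference_by_rank
from .io import (SampleMetadata, TaxonCountTable, align_inputs,
                 read_count_table, read_function_table, read_metadata,
                 read_taxonomy, read_tree)
from .phylo import NullModelSpec, signal_report
from .prep import (PresenceMatrix, collapse_presence, filter_rare_taxa,
                   rarefy_counts, shared_membership)


class TransplantExperiment:
    """A reciprocal-transplant community dataset ready for analysis.

    Parameters
    ----------
    counts : TaxonCountTable
        Taxa x samples read counts.
    tree : skbio.TreeNode
        Rooted phylogeny with branch lengths covering the table's taxa.
    metadata : SampleMetadata
        origin / host / replicate per sample (plus optional environmental
        variables).
    functions : DataFrame, optional
        Samples x functional variables (enzyme activities, gas rates) for
        the composition-function Mantel test.
    taxonomy : DataFrame, optional
        taxon_id -> ranked lineage, enabling clade enrichment.
    config : AnalysisConfig, optional
    """

    def __init__(
        self,
        counts: TaxonCountTable,
        tree: TreeNode,
        metadata: SampleMetadata,
        functions: pd.DataFrame | None = None,
        taxonomy: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.config = config or AnalysisConfig()
        self.counts, self.tree = align_inputs(counts, tree, metadata)
        self.metadata = metadata
        self.functions = functions
        self.taxonomy = taxonomy

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        tree_path: str | Path,
        metadata_path: str | Path,
        functions_path: str | Path | None = None,
        taxonomy_path: str | Path | None = None,
        config: AnalysisConfig | None = None,
    ) -> "TransplantExperiment":
        return cls(
            read_count_table(counts_path),
            read_tree(tree_path),
            read_metadata(metadata_path),
            functions=(read_function_table(functions_path)
                       if functions_path else None),
            taxonomy=read_taxonomy(taxonomy_path) if taxonomy_path else None,
            config=config,
        )

    def fit(self, seed: int | None = None) -> "TransplantResults":
        """Run the full inference chain and return the results object."""
        cfg = self.config
        seed = cfg.random_seed if seed is None else seed

        filtered = filter_rare_taxa(self.counts, cfg.rare_fraction)
        filtered, tree = align_inputs(filtered, self.tree, self.metadata)

        rarefied = None
        if cfg.rarefaction_depth is not None:
            rarefied = rarefy_counts(filtered, cfg.rarefaction_depth, seed=seed)

        presence_source = rarefied if (cfg.presence_on_rarefied and
                                       rarefied is not None) else filtered
        presence = collapse_presence(presence_source, self.metadata,
                                     min_count=cfg.min_detection_count)
        venn = shared_membership(presence)
        assignments = classify_preference(presence)
        preference_table = tabulate_preferences(assignments)

        null = NullModelSpec(model=cfg.null_model, runs=cfg.null_runs,
                             seed=seed)
        signal = signal_report(tree, assignments, null=null,
                               include_root=cfg.include_root, alpha=cfg.alpha)

        enrichment = None
        if self.taxonomy is not None:
            clade_map = preference_by_rank(assignments, self.taxonomy)
            enrichment = clade_enrichment(
                assignments, clade_map,
                bootstrap_iters=cfg.bootstrap_iters, ci_level=cfg.ci_level,
                universe=cfg.enrichment_universe,
                min_clade_size=cfg.min_clade_size, seed=seed)

        diversity_table = rarefied if rarefied is not None else filtered
        unifrac = weighted_unifrac(diversity_table, tree,
                                   normalized=cfg.unifrac_normalized)
        mantel = None
        if self.functions is not None:
            gower = gower_distance(
                self.functions.loc[diversity_table.sample_ids])
            mantel = mantel_test(unifrac, gower,
                                 permutations=cfg.mantel_permutations,
                                 seed=seed)
        log_stage("fit", taxa=len(filtered.taxon_ids),
                  samples=len(filtered.sample_ids), seed=seed)
        return TransplantResults(
            model=self, filtered=filtered, rarefied=rarefied, tree=tree,
            presence=presence, venn=venn, assignments=assignments,
            preference_table=preference_table, signal=signal,
            enrichment=enrichment, unifrac=unifrac, mantel=mantel, seed=seed)


class TransplantResults:
    """Fitted results of a :class:`TransplantExperiment`."""

    def __init__(self, model, filtered, rarefied, tree, presence: PresenceMatrix,
                 venn, assignments, preference_table, signal, enrichment,
                 unifrac, mantel: MantelResult | None, seed):
        self.model = model
        self.filtered = filtered
        self.rarefied = rarefied
        self.tree = tree
        self.presence = presence
        self.venn = venn
        self.assignments = assignments
        self.preference_table = preference_table
        self.signal = signal
        self.enrichment = enrichment
        self.unifrac = unifrac
        self.mantel = mantel
        self.seed = seed

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline."""
        lines = ["Reciprocal-transplant salinity-preference analysis",
                 "=" * 50]
        lines.append(f"taxa: {len(self.filtered.taxon_ids)}   samples: "
                     f"{len(self.filtered.sample_ids)}   seed: {self.seed}")
        lines.append("")
        lines.append("Preference counts:")
        lines.append(self.preference_table.to_string())
        lines.append("")
        lines.append("Phylogenetic signal (SES-PD / NTI; negative SES-PD and "
                     "positive NTI = clustering):")
        cols = ["group", "metric", "size", "observed", "null_mean", "null_sd",
                "ses", "nti", "p_lower", "clustered"]
        lines.append(self.signal[cols].to_string(index=False,
                                                 float_format="%.3f"))
        if self.enrichment is not None:
            flagged = self.enrichment[
                self.enrichment["verdict"] != "indistinguishable"]
            lines.append("")
            lines.append(f"Clade enrichment: {len(flagged)} clade x preference "
                         "cells differ from the community expectation")
        if self.mantel is not None:
            lines.append("")
            lines.append(
                f"Composition-function coupling: Mantel r = "
                f"{self.mantel.r:.2f}, p = {self.mantel.p_value:.4f} "
                f"({self.mantel.permutations} permutations)")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write every result table to TSV/JSON in ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_count_table, write_tree
        write_count_table(self.filtered, out / "filtered_counts.tsv")
        if self.rarefied is not None:
            write_count_table(self.rarefied, out / "rarefied_counts.tsv")
        write_tree(self.tree, out / "pruned_tree.nwk")
        self.presence.write(out / "presence.tsv", out / "presence_support.tsv")
        self.venn.to_csv(out / "venn_regions.tsv", sep="\t", index=False)
        self.assignments.to_csv(out / "preferences.tsv", sep="\t")
        self.preference_table.to_csv(out / "preference_counts.tsv", sep="\t")
        self.signal.to_csv(out / "phylo_signal.tsv", sep="\t", index=False)
        if self.enrichment is not None:
            self.enrichment.to_csv(out / "clade_enrichment.tsv", sep="\t",
                                   index=False)
        self.unifrac.to_data_frame().to_csv(out / "weighted_unifrac.tsv",
                                            sep="\t")
        if self.mantel is not None:
            with open(out / "mantel.json", "w") as fh:
                json.dump({"r": self.mantel.r, "p_value": self.mantel.p_value,
                           "permutations": self.mantel.permutations,
                           "n": self.mantel.n, "method": self.mantel.method},
                          fh, indent=2)
                fh.write("\n")
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
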