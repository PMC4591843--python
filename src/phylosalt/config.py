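"""Analysis configuration shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable parameters of the salinity-preference pipeline.

    Parameters
    ----------
    rare_fraction : float
        Taxa whose share of the grand total of reads is strictly below this
        fraction are removed (default 0.005% = 5e-5).
    rarefaction_depth : int or None
        Common per-sample read depth for rarefaction; ``None`` disables
        rarefaction. Diversity analyses (UniFrac) use the rarefied table
        when a depth is set.
    min_detection_count : int
        Minimum read count for a taxon to be called detected in one sample.
    presence_on_rarefied : bool
        If True, the replicate-majority presence call uses the rarefied
        table; the default keeps full detection sensitivity by using the
        filtered, un-rarefied table.
    null_model : str
        Null model name for SES statistics; ``taxa_labels`` and
        ``pool_draw`` both reduce to uniform equal-size tip-set draws from
        the tip pool for a single tip set.
    null_runs : int
        Number of null randomizations for SES-PD / NTI (>= 99).
    alpha : float
        Significance level for reporting phylogenetic clustering.
    include_root : bool
        Whether Faith's PD includes the path from the spanning subtree to
        the tree root.
    bootstrap_iters : int
        Bootstrap iterations for clade-enrichment confidence intervals.
    ci_level : float
        Coverage of the percentile bootstrap CI.
    enrichment_universe : str
        ``classified`` compares clades against the fresh/salt/none universe;
        ``all`` also counts unclassified taxa.
    min_clade_size : int
        Clades smaller than this are reported but flagged low-confidence.
    unifrac_normalized : bool
        Use the normalized weighted UniFrac variant.
    mantel_permutations : int
        Permutations for the Mantel test (>= 99).
    random_seed : int
        Single integer seed; each randomized stage derives its own stream.
    """

    rare_fraction: float = 5e-5
    rarefaction_depth: int | None = None
    min_detection_count: int = 1
    presence_on_rarefied: bool = False
    null_model: str = "taxa_labels"
    null_runs: int = 999
    alpha: float = 0.05
    include_root: bool = True
    bootstrap_iters: int = 6000
    ci_level: float = 0.95
    enrichment_universe: str = "classified"
    min_clade_size: int = 10
    unifrac_normalized: bool = False
    mantel_permutations: int = 999
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rare_fraction < 1.0:
            raise ValueError("rare_fraction must lie in [0, 1)")
        if self.rarefaction_depth is not None and self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.null_runs < 99:
            raise ValueError("null_runs must be >= 99")
        if self.bootstrap_iters < 1000:
            raise ValueError("bootstrap_iters must be >= 1000")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.null_model not in ("taxa_labels", "pool_draw"):
            raise ValueError(f"unknown null model {self.null_model!r}")
        if self.enrichment_universe not in ("classified", "all"):
            raise ValueError("enrichment_universe must be 'classified' or 'all'")
        if self.mantel_permutations < 99:
            raise ValueError("mantel_permutations must be >= 99")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
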