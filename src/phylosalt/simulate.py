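"""Synthetic reciprocal-transplant communities with known salinity niches.

The generator emulates a 2 origins x 2 hosts x 5 replicates soil-transplant
design: a pure-birth (Yule) phylogeny, a heritable continuous salinity-niche
trait evolved by Brownian motion with Pagel's lambda branch rescaling,
thresholds turning the latent trait into discrete classes (fresh / salt /
generalist), class- and treatment-dependent detection probabilities with
residual-DNA carryover and host colonization in the transplant treatments,
lognormal relative abundances, and multinomial read sampling at a fixed
per-sample depth. Ground truth (latent trait, true class, occupancy
probabilities) is returned so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import TREATMENTS, derive_rng, log_stage
from .io import SampleMetadata, TaxonCountTable
from .phylo import TreeIndex

CLASSES = ("fresh", "generalist", "salt")

#: per-environment detection probability for each true niche class
DEFAULT_DETECTION_ENV = {
    ("fresh", "fresh"): 0.95,
    ("fresh", "salt"): 0.02,
    ("salt", "salt"): 0.95,
    ("salt", "fresh"): 0.02,
    ("generalist", "fresh"): 0.90,
    ("generalist", "salt"): 0.90,
}

#: standard functional-variable names (seven enzymes, two gases)
FUNCTION_VARS = ("BG", "CBH", "BX", "LAP", "AS", "POX", "PR", "CO2", "CH4")


@dataclasses.dataclass
class SimulationParams:
    """Parameters of the synthetic reciprocal-transplant experiment.

    Defaults are the study conditions the generator emulates: 200 taxa,
    four origin x host treatments with five replicates each (20 samples),
    21,398 reads per sample, full phylogenetic signal (lambda = 1), niche
    thresholds at the standard-normal tertiles, 0.9 residual-DNA carryover
    and 0.8 host-colonization efficiency in the transplant treatments.
    """

    n_taxa: int = 200
    birth_rate: float = 1.0
    trait_model: str = "brownian_threshold"  # or "independent"
    lam: float = 1.0  # Pagel's lambda in [0, 1]
    trait_sd: float = 1.0
    thresholds: tuple[float, float] = (-0.4307, 0.4307)  # N(0,1) tertiles
    detection_env: dict | None = None  # (class, environment) -> p
    detection_treatment: dict | None = None  # (class, treatment) -> p override
    carryover: float = 0.9
    colonization: float = 0.8
    replicates: int = 5
    depth: int = 21398
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    function_noise_sd: float = 0.25
    function_niche_weight: float = 0.5
    n_function_vars: int = len(FUNCTION_VARS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.thresholds[0] > self.thresholds[1]:
            raise ValueError("thresholds must be ordered")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for p in (self.carryover, self.colonization):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.trait_model not in ("brownian_threshold", "independent"):
            raise ValueError(f"unknown trait model {self.trait_model!r}")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(d["thresholds"])
        for key in ("detection_env", "detection_treatment"):
            if d[key] is not None:
                d[key] = {f"{k[0]}|{k[1]}": v for k, v in d[key].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")


def simulate_tree(
    n_taxa: int,
    seed: int | None = None,
    birth_rate: float = 1.0,
    normalize_depth: bool = True,
) -> TreeNode:
    """Pure-birth (Yule) tree with binary splits, optionally depth-scaled to 1.

    Waiting times between successive splits with k extant lineages are
    Exponential(k * birth_rate); a final Exponential(n * birth_rate) stem
    interval follows the last split, after which all tips are harvested
    (ultrametric by construction).
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = derive_rng(seed, "simulate_tree")
    root = TreeNode(length=0.0)
    t = 0.0
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        active.append((child, 0.0))
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    width = len(str(n_taxa))
    for j, (node, born) in enumerate(active):
        node.length = t - born
    for j, tip in enumerate(root.tips()):
        tip.name = f"t{j + 1:0{width}d}"
    if normalize_depth and t > 0:
        for node in root.traverse(include_self=False):
            node.length /= t
    log_stage("simulate_tree", n_taxa=n_taxa, depth=1.0 if normalize_depth else t)
    return root


def evolve_trait(
    tree: TreeNode,
    lam: float = 1.0,
    seed: int | None = None,
    sigma: float = 1.0,
) -> pd.Series:
    """Latent niche values at the tips: Brownian motion with Pagel's lambda.

    Tip covariance is lambda times the shared-path Brownian covariance off
    the diagonal, with variances (tip depths, times sigma^2) untouched:
    lambda = 0 gives independent draws, lambda = 1 the full tree covariance.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    rng = derive_rng(seed, "evolve_trait")
    index = TreeIndex(tree)
    names = index.tip_names
    depths = index.incidence.T.astype(float) @ index.edge_lengths
    dist = index.tip_distances
    shared = (depths[:, None] + depths[None, :] - dist) / 2.0
    cov = lam * shared
    np.fill_diagonal(cov, depths)
    cov = cov * sigma**2
    jitter = 1e-10 * max(float(np.max(depths)) * sigma**2, 1.0)
    chol = np.linalg.cholesky(cov + jitter * np.eye(len(names)))
    z = chol @ rng.standard_normal(len(names))
    return pd.Series(z, index=names, name="latent_trait")


def classify_latent(latent: pd.Series, thresholds: tuple[float, float]) -> pd.Series:
    """Deterministic class from the latent trait: fresh / generalist / salt."""
    lo, hi = thresholds
    cls = np.where(latent < lo, "fresh",
                   np.where(latent > hi, "salt", "generalist"))
    return pd.Series(cls, index=latent.index, name="true_class")


def treatment_detection_probs(
    detection_env: dict | None = None,
    carryover: float = 0.9,
    colonization: float = 0.8,
) -> pd.DataFrame:
    """Per-class detection probability in each origin-host treatment.

    Controls use the origin-environment probability directly. In a
    transplant, a taxon is detectable if it persisted from the origin
    community (tolerating the host, or lingering as residual DNA with
    probability ``carryover``) or colonized from the host environment with
    efficiency ``colonization``.
    """
    env = dict(DEFAULT_DETECTION_ENV)
    if detection_env:
        env.update(detection_env)
    envs = {"F": "fresh", "S": "salt"}
    rows = {}
    for cls in CLASSES:
        row = {}
        for trt in TREATMENTS:
            origin, host = envs[trt[0]], envs[trt[1]]
            d_o, d_h = env[(cls, origin)], env[(cls, host)]
            if origin == host:
                row[trt] = d_o
            else:
                persist = d_o * (carryover + (1.0 - carryover) * d_h)
                colonize = colonization * d_h
                row[trt] = 1.0 - (1.0 - persist) * (1.0 - colonize)
        rows[cls] = row
    return pd.DataFrame(rows).T[list(TREATMENTS)]


def simulate_experiment(
    params: SimulationParams,
    tree: TreeNode | None = None,
) -> tuple[TaxonCountTable, SampleMetadata, pd.DataFrame]:
    """Simulate the full reciprocal-transplant count table with ground truth.

    Returns (count table, metadata, ground truth). Ground truth holds the
    latent trait, true class, and the occupancy probability per treatment.
    Column sums of the count table equal ``params.depth`` exactly.
    """
    if tree is None:
        tree = simulate_tree(params.n_taxa, seed=params.seed,
                             birth_rate=params.birth_rate)
    names = [t.name for t in tree.tips()]
    if params.trait_model == "independent":
        latent = evolve_trait(tree, 0.0, seed=params.seed, sigma=params.trait_sd)
    else:
        latent = evolve_trait(tree, params.lam, seed=params.seed,
                              sigma=params.trait_sd)
    # classes are defined on the standardized latent scale
    index = TreeIndex(tree)
    mean_depth = float((index.incidence.T.astype(float)
                        @ index.edge_lengths).mean())
    latent_std = latent / (np.sqrt(mean_depth) * params.trait_sd)
    true_class = classify_latent(latent_std, params.thresholds)

    det = treatment_detection_probs(params.detection_env, params.carryover,
                                    params.colonization)
    if params.detection_treatment:
        for (cls, trt), p in params.detection_treatment.items():
            det.loc[cls, trt] = p
    probs = det.loc[true_class.to_numpy()].to_numpy()  # (n_taxa, 4)

    rng = derive_rng(params.seed, "simulate_experiment")
    n = len(names)
    counts = {}
    meta_rows = []
    envs = {"F": "fresh", "S": "salt"}
    for j, trt in enumerate(TREATMENTS):
        for rep in range(1, params.replicates + 1):
            sample = f"{trt}_{rep}"
            occupied = rng.random(n) < probs[:, j]
            weights = np.where(
                occupied,
                rng.lognormal(params.lognormal_mu, params.lognormal_sigma, n),
                0.0,
            )
            if weights.sum() == 0:  # pathological detection table
                weights[rng.integers(n)] = 1.0
            counts[sample] = rng.multinomial(params.depth,
                                             weights / weights.sum())
            meta_rows.append({"sample_id": sample, "origin": envs[trt[0]],
                              "host": envs[trt[1]], "replicate": rep})
    table = TaxonCountTable(pd.DataFrame(counts, index=names))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = pd.DataFrame({"latent_trait": latent, "true_class": true_class})
    for trt in TREATMENTS:
        truth[f"p_occupy_{trt}"] = det.loc[true_class.to_numpy(), trt].to_numpy()
    truth.index.name = "taxon_id"
    log_stage("simulate_experiment", n_taxa=n, samples=len(meta_rows),
              depth=params.depth, lam=params.lam)
    return table, meta, truth


def simulate_function_profiles(
    meta: SampleMetadata,
    composition: pd.DataFrame,
    noise_sd: float = 0.25,
    seed: int | None = None,
    n_vars: int = len(FUNCTION_VARS),
    tree: TreeNode | None = None,
    niche: pd.Series | None = None,
    niche_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-sample functional activities as linear images of composition.

    Each variable is a fixed linear functional of the sample's relative-
    abundance vector plus independent Gaussian noise, so the strength of
    the composition-function coupling is set by ``noise_sd`` (0 =
    deterministic coupling; large = decoupled). With a tree, each variable
    is the community-weighted mean of a per-taxon functional trait evolved
    by Brownian motion on that tree, mirroring phylogenetically conserved
    metabolic capabilities; between two samples the expected squared
    difference of such a variable is the branch-length-weighted sum of
    squared flow differences — the squared-difference analog of weighted
    UniFrac — so function tracks phylogenetic composition by construction.
    When the latent salinity-niche trait is supplied, each functional trait
    mixes it in with weight ``niche_weight`` (functional capabilities
    co-vary with the salinity niche). Without a tree, dense random
    loadings are used.

    ``composition`` is samples x taxa (rows sum to 1, e.g. the transpose of
    :meth:`TaxonCountTable.relative_abundance`). Noise is scaled by each
    variable's signal SD so ``noise_sd`` is a relative noise level.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = derive_rng(seed, "simulate_function_profiles")
    comp = composition.loc[meta.sample_ids]
    n_taxa = comp.shape[1]
    if tree is not None:
        index = TreeIndex(tree)
        order = index.tip_indices(comp.columns)
        depths = index.incidence.T.astype(float) @ index.edge_lengths
        shared = (depths[:, None] + depths[None, :] - index.tip_distances) / 2.0
        cov = shared.copy()
        np.fill_diagonal(cov, depths)
        jitter = 1e-10 * max(float(depths.max()), 1.0)
        chol = np.linalg.cholesky(cov + jitter * np.eye(index.n_tips))
        traits = chol @ rng.standard_normal((index.n_tips, n_vars))
        if niche is not None and niche_weight > 0:
            z = niche.reindex(index.tip_names).to_numpy()
            z = (z - z.mean()) / (z.std() or 1.0)
            a = float(np.clip(niche_weight, 0.0, 1.0))
            traits = a * z[:, None] + np.sqrt(1.0 - a**2) * traits
        loadings = traits[order]  # (taxa, vars), BM functional traits
    else:
        loadings = rng.standard_normal((n_taxa, n_vars)) * np.sqrt(n_taxa)
    signal = comp.to_numpy() @ loadings
    scale = signal.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    noise = rng.standard_normal(signal.shape) * (noise_sd * scale)
    names = list(FUNCTION_VARS[:n_vars])
    names += [f"f{i}" for i in range(len(names), n_vars)]
    out = pd.DataFrame(signal + noise, index=comp.index, columns=names)
    out.index.name = "sample_id"
    return out


def simulate_dataset(
    params: SimulationParams,
) -> dict:
    """One-call convenience: tree, counts, metadata, truth, function table."""
    tree = simulate_tree(params.n_taxa, seed=params.seed,
                         birth_rate=params.birth_rate)
    table, meta, truth = simulate_experiment(params, tree)
    composition = table.relative_abundance().T
    functions = simulate_function_profiles(
        meta, composition, noise_sd=params.function_noise_sd,
        seed=params.seed, n_vars=params.n_function_vars, tree=tree,
        niche=truth["latent_trait"],
        niche_weight=params.function_niche_weight)
    return {"tree": tree, "table": table, "metadata": meta,
            "truth": truth, "functions": functions, "params": params}
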