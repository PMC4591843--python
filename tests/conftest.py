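"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use a different computational route than the
package (explicit per-node subtree enumeration and full patristic matrices
via scikit-bio traversals) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import phylosalt as ps


# ---------------------------------------------------------------------------
# random structure factories
# ---------------------------------------------------------------------------

def random_tree(n_tips: int, seed: int, ultrametric: bool = False):
    """Random tree: Yule topology, optionally with iid uniform branch lengths."""
    tree = ps.simulate_tree(n_tips, seed=seed)
    if not ultrametric:
        rng = np.random.default_rng(seed + 10_000)
        for node in tree.traverse(include_self=False):
            node.length = float(rng.uniform(0.05, 2.0))
    return tree


def random_table(tree, n_samples: int, seed: int) -> ps.TaxonCountTable:
    rng = np.random.default_rng(seed + 20_000)
    taxa = [t.name for t in tree.tips()]
    counts = rng.integers(0, 60, size=(len(taxa), n_samples))
    counts[0] += 1  # guard against an all-zero sample
    return ps.TaxonCountTable(pd.DataFrame(
        counts, index=taxa, columns=[f"s{i}" for i in range(n_samples)]))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_faith_pd(tree, tips, include_root: bool) -> float:
    """Edge-set enumeration: walk every node, test its descendant tip set."""
    tips = set(tips)
    total = 0.0
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips(include_self=True)}
        inside = below & tips
        if include_root:
            keep = len(inside) > 0
        else:
            keep = 0 < len(inside) < len(tips)
        if keep:
            total += node.length or 0.0
    return total


def brute_mntd(tree, tips) -> float:
    """Nearest-neighbour mean from the full patristic matrix."""
    tips = list(tips)
    dm = tree.tip_tip_distances()
    nearest = []
    for a in tips:
        nearest.append(min(dm[a, b] for b in tips if b != a))
    return float(np.mean(nearest))


def brute_weighted_unifrac(tree, table: ps.TaxonCountTable,
                           normalized: bool) -> np.ndarray:
    """Branch enumeration: per branch, sum descendant read fractions directly."""
    rel = table.relative_abundance()
    samples = table.sample_ids
    n = len(samples)
    d = np.zeros((n, n))
    branches = []
    for node in tree.traverse(include_self=False):
        below = [t.name for t in node.tips(include_self=True)
                 if t.name in rel.index]
        branches.append((node.length or 0.0,
                         rel.loc[below].sum(axis=0).to_numpy()))
    for i in range(n):
        for j in range(i + 1, n):
            raw = sum(L * abs(p[i] - p[j]) for L, p in branches)
            if normalized:
                denom = sum(L * (p[i] + p[j]) for L, p in branches)
                val = raw / denom if denom > 0 else 0.0
            else:
                val = raw
            d[i, j] = d[j, i] = val
    return d


# ---------------------------------------------------------------------------
# small concrete fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def quartet_tree():
    return ps.parse_tree("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def toy_table():
    return ps.TaxonCountTable(pd.DataFrame(
        [[5, 0], [1, 2], [0, 7]],
        index=["A", "B", "C"], columns=["s1", "s2"]))


@pytest.fixture
def design_metadata():
    """The 2 origins x 2 hosts x 5 replicates design (20 samples)."""
    rows = []
    for origin in ("fresh", "salt"):
        for host in ("fresh", "salt"):
            code = origin[0].upper() + host[0].upper()
            for rep in range(1, 6):
                rows.append({"sample_id": f"{code}_{rep}", "origin": origin,
                             "host": host, "replicate": rep})
    return ps.SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick end-to-end synthetic dataset shared across tests."""
    params = ps.SimulationParams(n_taxa=60, depth=2000, seed=42)
    return ps.simulate_dataset(params)
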