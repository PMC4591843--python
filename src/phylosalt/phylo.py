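"""Faith's PD, MNTD, and their standardized effect sizes (SES-PD, NTI).

The null model draws equal-size tip sets uniformly from the tip pool (the
pruned tree's full tip set); for a single tip set the label-shuffling and
pool-draw nulls both reduce to this scheme. SES = (obs - null mean)/null SD;
NTI = -SES(MNTD). Negative SES-PD / positive NTI indicate phylogenetic
clustering. Rank p-values use the (r+1)/(runs+1) permutation convention, so
p is never 0 and its resolution is 1/(runs+1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._util import derive_rng, log_stage, logger


class TreeIndex:
    """Edge-indexed view of a rooted tree for fast repeated PD/MNTD.

    Precomputes, per non-root edge, its length and the set of tips below it
    (a boolean incidence matrix). Faith's PD of a tip set S is then

    * include_root: sum of lengths of edges with >=1 selected descendant;
    * otherwise: edges whose descendant count is in (0, |S|), i.e. edges
      separating two selected tips.

    The tip-tip patristic matrix is built lazily for MNTD.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        self.tip_names = [t.name for t in tree.tips()]
        if len(set(self.tip_names)) != len(self.tip_names):
            raise ValueError("tree tip labels are not unique")
        self.tip_pos = {n: i for i, n in enumerate(self.tip_names)}
        n_tips = len(self.tip_names)
        edges = []
        incidence = []
        for node in tree.postorder(include_self=False):
            mask = np.zeros(n_tips, dtype=bool)
            if node.is_tip():
                mask[self.tip_pos[node.name]] = True
            else:
                for child in node.children:
                    mask |= child._psalt_mask
            node._psalt_mask = mask
            edges.append(0.0 if node.length is None else float(node.length))
            incidence.append(mask)
        for node in tree.postorder(include_self=False):
            del node._psalt_mask
        self.edge_lengths = np.asarray(edges)
        self.incidence = np.asarray(incidence)  # (n_edges, n_tips)
        self.total_length = float(self.edge_lengths.sum())
        self._dist = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def tip_distances(self) -> np.ndarray:
        if self._dist is None:
            dm = self.tree.tip_tip_distances(endpoints=self.tip_names)
            self._dist = dm.filter(self.tip_names).data
        return self._dist

    def tip_indices(self, tips) -> np.ndarray:
        idx = []
        for t in tips:
            if t not in self.tip_pos:
                raise KeyError(f"unknown tip {t!r}")
            idx.append(self.tip_pos[t])
        return np.asarray(idx, dtype=np.intp)

    # -- vectorized metric kernels ---------------------------------------
    def pd_many(self, selections: np.ndarray, include_root: bool) -> np.ndarray:
        """Faith's PD for each row of a (k, n_tips) boolean selection matrix."""
        counts = selections.astype(np.float64) @ self.incidence.T.astype(np.float64)
        sizes = selections.sum(axis=1, keepdims=True)
        if include_root:
            used = counts > 0
        else:
            used = (counts > 0) & (counts < sizes)
        return used @ self.edge_lengths

    def mntd_many(self, index_sets: np.ndarray) -> np.ndarray:
        """MNTD for each row of a (k, m) matrix of tip indices."""
        d = self.tip_distances[index_sets[:, :, None], index_sets[:, None, :]]
        m = index_sets.shape[1]
        d[:, np.arange(m), np.arange(m)] = np.inf
        return d.min(axis=2).mean(axis=1)


def _as_index(tree: TreeNode | TreeIndex) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree)


def faith_pd(tree: TreeNode | TreeIndex, tips, include_root: bool = True) -> float:
    """Total branch length of the minimal subtree spanning ``tips``.

    With ``include_root`` (default) the path from the spanning subtree to
    the tree root is included, matching the classic picante-lineage
    convention; without it only edges separating selected tips count.
    For a single tip, include_root gives the tip-to-root path length and
    the rootless variant is 0.
    """
    index = _as_index(tree)
    idx = index.tip_indices(tips)
    if idx.size < 1:
        raise ValueError("faith_pd needs at least one tip")
    sel = np.zeros((1, index.n_tips), dtype=bool)
    sel[0, idx] = True
    return float(index.pd_many(sel, include_root)[0])


def mntd(tree: TreeNode | TreeIndex, tips) -> float:
    """Mean patristic distance from each tip to its nearest other tip in the set."""
    index = _as_index(tree)
    idx = index.tip_indices(tips)
    if idx.size < 2:
        raise ValueError("mntd needs at least two tips")
    return float(index.mntd_many(idx[None, :])[0])


@dataclasses.dataclass
class NullModelSpec:
    """Null-model configuration for SES statistics.

    ``taxa_labels`` and ``pool_draw`` are accepted as synonyms: for a single
    tip set both reduce to uniform equal-size draws from the tip pool.
    """

    model: str = "taxa_labels"
    runs: int = 999
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("taxa_labels", "pool_draw"):
            raise ValueError(f"unknown null model {self.model!r}")
        if self.runs < 99:
            raise ValueError("null runs must be >= 99")


@dataclasses.dataclass
class SesResult:
    """Observed metric, null moments, SES and rank p-values for one tip set."""

    group: str
    metric: str  # "PD" or "MNTD"
    size: int
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when the null SD is 0 (degenerate)
    p_lower: float
    p_upper: float
    runs: int
    note: str = ""

    @property
    def nti(self) -> float:
        """Nearest taxon index: -SES(MNTD). NaN for the PD metric."""
        return -self.ses if self.metric == "MNTD" else float("nan")


def ses_statistic(
    tree: TreeNode | TreeIndex,
    tips,
    metric: str = "PD",
    null: NullModelSpec | None = None,
    include_root: bool = True,
    group: str = "",
    _rng: np.random.Generator | None = None,
) -> SesResult:
    """Standardized effect size of PD or MNTD against equal-size random tip sets.

    A degenerate null (SD = 0, e.g. the tip set is the whole pool) yields
    ses = NaN with an explanatory note rather than a silent 0.
    """
    if metric not in ("PD", "MNTD"):
        raise ValueError(f"unknown metric {metric!r}")
    null = null or NullModelSpec()
    index = _as_index(tree)
    idx = index.tip_indices(tips)
    k = idx.size
    if k < 2:
        raise ValueError("ses_statistic needs at least two tips")
    rng = _rng if _rng is not None else derive_rng(null.seed, f"ses.{metric}")

    # null draws: `runs` uniform k-subsets of the pool (k smallest of a
    # random vector is a uniform k-subset), as row index sets
    u = rng.random((null.runs, index.n_tips))
    draw_idx = np.argpartition(u, k - 1, axis=1)[:, :k].astype(np.intp)

    if metric == "PD":
        sel = np.zeros((1, index.n_tips), dtype=bool)
        sel[0, idx] = True
        observed = float(index.pd_many(sel, include_root)[0])
        null_sel = np.zeros((null.runs, index.n_tips), dtype=bool)
        null_sel[np.repeat(np.arange(null.runs), k), draw_idx.ravel()] = True
        null_vals = index.pd_many(null_sel, include_root)
    else:
        observed = float(index.mntd_many(idx[None, :])[0])
        null_vals = index.mntd_many(draw_idx)

    null_mean = float(null_vals.mean())
    null_sd = float(null_vals.std(ddof=1))
    note = ""
    if null_sd == 0.0:
        ses = float("nan")
        note = "degenerate null distribution (SD = 0); SES undefined"
        logger.warning("ses_statistic(%s, %s): %s", group, metric, note)
    else:
        ses = (observed - null_mean) / null_sd
    p_lower = (int((null_vals <= observed).sum()) + 1) / (null.runs + 1)
    p_upper = (int((null_vals >= observed).sum()) + 1) / (null.runs + 1)
    return SesResult(group=group, metric=metric, size=k, observed=observed,
                     null_mean=null_mean, null_sd=null_sd, ses=ses,
                     p_lower=p_lower, p_upper=p_upper, runs=null.runs,
                     note=note)


def signal_report(
    tree: TreeNode | TreeIndex,
    assignments: pd.DataFrame,
    null: NullModelSpec | None = None,
    include_root: bool = True,
    alpha: float = 0.05,
    groups: tuple[str, ...] = ("fresh", "salt", "none"),
) -> pd.DataFrame:
    """SES-PD and NTI for each salinity-preference group.

    The tip pool is the whole tree (classified and unclassified taxa: the
    observed community). Groups with fewer than two members are skipped with
    a warning. Clustering is flagged when SES-PD < 0 (lower-tail rank p) or
    NTI > 0 (lower-tail rank p of MNTD) at level ``alpha``.
    """
    null = null or NullModelSpec()
    index = _as_index(tree)
    rng = derive_rng(null.seed, "signal_report")
    rows = []
    for g in groups:
        members = assignments.index[assignments["preference"] == g]
        members = [m for m in members if m in index.tip_pos]
        if len(members) < 2:
            logger.warning("signal_report: group %r has <2 tips; skipped", g)
            continue
        for metric in ("PD", "MNTD"):
            res = ses_statistic(index, members, metric=metric, null=null,
                                include_root=include_root, group=g, _rng=rng)
            clustered = bool(res.p_lower <= alpha
                             and not np.isnan(res.ses) and res.ses < 0)
            rows.append({
                "group": g, "metric": metric, "size": res.size,
                "observed": res.observed, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "ses": res.ses,
                "nti": res.nti, "p_lower": res.p_lower,
                "p_upper": res.p_upper, "runs": res.runs,
                "clustered": bool(clustered), "note": res.note,
            })
    log_stage("signal_report", groups=len(rows) // 2, runs=null.runs)
    return pd.DataFrame(rows)
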