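"""Greedy top-down extraction of SomaModules from correlation matrices.

Given an expression matrix restricted to the SOMAmers of one (translated)
parent gene set, the procedure is:

1. keep one sample per participant (the earliest visit), so repeat visits
   do not bias correlation estimates;
2. compute the full Pearson correlation matrix over the parent's SOMAmers;
3. build one hierarchical-clustering dendrogram on the distance d = 1 - r
   and cut it at every K from ``k_min`` to ``k_max`` clusters
   (K = 2..5 yields sum(K) = 14 raw candidates);
4. score each candidate cluster by its size n and its summary pairwise
   correlation r_bar (mean by default);
5. keep candidates with n >= n_min and r_bar >= r_min, rank by size then
   correlation, take the top cluster as the next child module;
6. delete that module's SOMAmers from the correlation matrix and iterate
   until no candidate passes or too few SOMAmers remain.

Children of one parent are pairwise disjoint by construction and named
``<parent prefix>.<child index>`` with indices starting at 1
(``R.144.1``, ``R.144.2``, ... under parent ``R.144.0``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .gmt import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """samples x SOMAmers matrix of log10(RFU) abundances with metadata.

    ``values`` has one row per sample and one column per SeqId; metadata
    arrays are aligned with rows. Missing values are rejected at
    construction: normalized SomaScan matrices are complete.
    """

    values: pd.DataFrame
    participant_ids: np.ndarray
    visit_dates: np.ndarray

    def __post_init__(self) -> None:
        self.participant_ids = np.asarray(self.participant_ids)
        self.visit_dates = np.asarray(self.visit_dates)
        n = len(self.values)
        if len(self.participant_ids) != n or len(self.visit_dates) != n:
            raise ValueError("metadata length does not match number of samples")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate SeqId column labels")
        if not self.values.index.is_unique:
            raise ValueError("duplicate sample ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def seqids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @classmethod
    def from_files(cls, matrix_path, meta_path) -> "ExpressionMatrix":
        """Load from headered delimited text.

        ``matrix_path``: rows = samples (first column sample_id), columns =
        SeqIds. ``meta_path``: columns sample_id, participant_id,
        visit_date (ISO-8601).
        """
        values = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
        meta = pd.read_csv(meta_path, sep=None, engine="python", dtype=str)
        meta = meta.set_index("sample_id").loc[values.index.astype(str)]
        return cls(values=values,
                   participant_ids=meta["participant_id"].to_numpy(),
                   visit_dates=meta["visit_date"].to_numpy())


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlations (and two-sided p-values) over SeqIds."""

    seqids: List[str]
    r: np.ndarray
    m: int
    p: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.seqids)
        if self.r.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")

    def subset(self, members: Sequence[str]) -> "CorrelationMatrix":
        idx = [self.seqids.index(m) for m in members]
        return CorrelationMatrix(seqids=list(members), r=self.r[np.ix_(idx, idx)],
                                 m=self.m, p=self.p[np.ix_(idx, idx)])

    def drop(self, members: Sequence[str]) -> "CorrelationMatrix":
        gone = set(members)
        keep = [s for s in self.seqids if s not in gone]
        return self.subset(keep)


@dataclass
class ClusterCandidate:
    """One cluster from a dendrogram cut, scored by size and r_bar."""

    members: List[str]
    n: int
    r_bar: float
    k_origin: int


@dataclass
class ExtractionParams:
    """Tunable knobs of the extraction procedure.

    Defaults: cut the dendrogram at K = 2..5, keep clusters with at least
    10 members and mean pairwise correlation at least 0.5, Ward linkage on
    d = 1 - r. Ward is the default because complete and average linkage
    tend to attach isolated background features to tight clusters at high
    merge heights, contaminating recovered modules; complete/average
    remain available via ``linkage_method``.
    """

    k_min: int = 2
    k_max: int = 5
    n_min: int = 10
    r_min: float = 0.5
    linkage_method: str = "ward"
    distance: str = "signed"        # "signed": d = 1 - r; "absolute": d = 1 - |r|
    statistic: str = "mean"         # summary of pairwise correlations: mean | median

    def __post_init__(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if not (-1.0 < self.r_min < 1.0):
            raise ValueError("r_min must lie in (-1, 1)")
        if self.distance not in ("signed", "absolute"):
            raise ValueError("distance must be 'signed' or 'absolute'")
        if self.statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")


@dataclass
class SomaModule:
    """An extracted child module: ``module_id = <prefix>.<parent>.<child>``."""

    module_id: str
    parent_id: str
    members: List[str]
    n: int
    r_bar: float

    def to_gene_set(self) -> GeneSet:
        return GeneSet(set_id=self.module_id, name=self.module_id,
                       description=f"child of {self.parent_id}", members=list(self.members))


def select_first_visits(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly one row per participant: the earliest visit.

    Date ties are broken by the lexicographically smallest sample id.
    """
    if pd.isna(mat.visit_dates).any():
        raise ValueError("missing visit date")
    order = pd.DataFrame({
        "participant": mat.participant_ids,
        "date": mat.visit_dates,
        "sample": mat.sample_ids.astype(str),
    })
    keep_pos = (
        order.sort_values(["date", "sample"], kind="mergesort")
        .groupby("participant", sort=False)
        .head(1)
        .index
    )
    mask = np.zeros(mat.n_samples, dtype=bool)
    mask[np.asarray(keep_pos)] = True
    return ExpressionMatrix(values=mat.values.iloc[mask],
                            participant_ids=mat.participant_ids[mask],
                            visit_dates=mat.visit_dates[mask])


def pairwise_correlations(mat: ExpressionMatrix,
                          members: Optional[Sequence[str]] = None) -> CorrelationMatrix:
    """Pearson correlations of all SOMAmer pairs over all samples.

    Two-sided p-values come from the t transform
    ``t = r * sqrt((m - 2) / (1 - r^2))`` on m - 2 degrees of freedom.
    Zero-variance columns are dropped with a warning (their correlation is
    undefined); fewer than 3 samples is an error.
    """
    if members is None:
        members = mat.seqids
    missing = [m for m in members if m not in mat.values.columns]
    if missing:
        raise KeyError(f"SeqIds not in expression matrix: {missing[:5]}")
    if mat.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = mat.values.loc[:, list(members)].to_numpy(dtype=float)
    sd = x.std(axis=0)
    ok = sd > 0
    if not ok.all():
        dropped = [m for m, good in zip(members, ok) if not good]
        logger.warning("dropping %d zero-variance columns: %s", len(dropped), dropped[:5])
        members = [m for m, good in zip(members, ok) if good]
        x = x[:, ok]
    m_samples = x.shape[0]
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = r * np.sqrt((m_samples - 2) / (1.0 - r * r))
    p = 2.0 * t_dist.sf(np.abs(tval), df=m_samples - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry
    return CorrelationMatrix(seqids=list(members), r=r, m=m_samples, p=p)


def _distance_condensed(corr: CorrelationMatrix, distance: str) -> np.ndarray:
    r = corr.r
    d = 1.0 - (np.abs(r) if distance == "absolute" else r)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return squareform(np.maximum(d, 0.0), checks=False)


def summary_correlation(members: Sequence[str], corr: CorrelationMatrix,
                        statistic: str = "mean") -> float:
    """Summary (mean or median) of the n(n-1)/2 pairwise correlations."""
    if len(members) < 2:
        raise ValueError("summary correlation needs >= 2 members")
    sub = corr.subset(list(members))
    iu = np.triu_indices(len(members), k=1)
    pairs = sub.r[iu]
    return float(np.median(pairs) if statistic == "median" else np.mean(pairs))


def candidate_clusters(corr: CorrelationMatrix,
                       params: ExtractionParams) -> List[ClusterCandidate]:
    """Cut one dendrogram at each K in [k_min, k_max] and emit every cluster.

    A single linkage tree is built from d = 1 - r; each cut partitions the
    SOMAmers into exactly K clusters. Identical member sets regenerated by
    nested cuts are deduplicated, keeping the first occurrence (smallest K).
    """
    labels = corr.seqids
    if len(labels) < params.k_max:
        raise ValueError(
            f"{len(labels)} labels < k_max={params.k_max}; lower k_max to cluster this matrix"
        )
    condensed = _distance_condensed(corr, params.distance)
    tree = linkage(condensed, method=params.linkage_method)
    seen: set = set()
    out: List[ClusterCandidate] = []
    for k in range(params.k_min, params.k_max + 1):
        assignment = fcluster(tree, t=k, criterion="maxclust")
        for cluster_label in np.unique(assignment):
            members = [labels[i] for i in np.flatnonzero(assignment == cluster_label)]
            key = frozenset(members)
            if key in seen:
                continue
            seen.add(key)
            r_bar = (summary_correlation(members, corr, params.statistic)
                     if len(members) >= 2 else float("nan"))
            out.append(ClusterCandidate(members=members, n=len(members),
                                        r_bar=r_bar, k_origin=k))
    return out


def count_raw_candidates(params: ExtractionParams) -> int:
    """Number of clusters considered before dedup: sum of K over the cuts."""
    return sum(range(params.k_min, params.k_max + 1))


def filter_and_rank(cands: Sequence[ClusterCandidate],
                    params: ExtractionParams) -> List[ClusterCandidate]:
    """Apply the n >= n_min and r_bar >= r_min gates, then rank.

    Ranking is by decreasing size first, decreasing summary correlation
    second; remaining ties are broken by the lexicographically smallest
    sorted member list so builds are deterministic.
    """
    passing = [c for c in cands
               if c.n >= params.n_min and np.isfinite(c.r_bar) and c.r_bar >= params.r_min]
    return sorted(passing, key=lambda c: (-c.n, -c.r_bar, sorted(c.members)))


def extract_somamodules(corr: CorrelationMatrix, parent_id: str,
                        params: ExtractionParams | None = None) -> List[SomaModule]:
    """Greedy iterative extraction of non-overlapping child modules.

    The top-ranked passing cluster becomes the next child; its SOMAmers are
    removed from the correlation matrix and the procedure repeats. The loop
    stops when no candidate passes the gates or when fewer than
    ``max(n_min, k_max)`` SOMAmers remain.
    """
    if params is None:
        params = ExtractionParams()
    if not parent_id.endswith(".0"):
        raise ValueError(f"parent_id {parent_id!r} should carry the '.0' suffix")
    stem = parent_id[: -len(".0")]
    modules: List[SomaModule] = []
    current = corr
    child_index = 1
    floor = max(params.n_min, params.k_max)
    while len(current.seqids) >= floor:
        ranked = filter_and_rank(candidate_clusters(current, params), params)
        if not ranked:
            break
        top = ranked[0]
        modules.append(SomaModule(
            module_id=f"{stem}.{child_index}",
            parent_id=parent_id,
            members=list(top.members),
            n=top.n,
            r_bar=top.r_bar,
        ))
        current = current.drop(top.members)
        child_index += 1
    return modules


def significant_links(corr: CorrelationMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Edge list of SOMAmer pairs with correlation p-value below ``alpha``.

    Columns: seqid_a, seqid_b, r, p — the network-export view of a parent's
    correlation structure (links colored by sign downstream).
    """
    iu = np.triu_indices(len(corr.seqids), k=1)
    mask = corr.p[iu] < alpha
    a = np.asarray(corr.seqids)[iu[0][mask]]
    b = np.asarray(corr.seqids)[iu[1][mask]]
    return pd.DataFrame({"seqid_a": a, "seqid_b": b,
                         "r": corr.r[iu][mask], "p": corr.p[iu][mask]})
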