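"""Self-contained preranked GSEA with the Kolmogorov running-sum statistic.

Given a ranked list of n identifiers with scores r_1 >= ... >= r_n and a
gene set G (restricted to the ranked universe), each position k gets a
step

    x_k = |r_k|^p / sum_{j in G} |r_j|^p     if identifier k is in G,
    x_k = -1 / (n - |G|)                     otherwise,

where p is the enrichment weight (p = 0 is the classic unweighted
statistic; p = 1, 1.5, 2 are the weighted variants). The running sum
E_m = sum_{k<=m} x_k starts at E_0 = 0 and returns to E_n = 0; the
Enrichment Score (ES) is the running sum's maximum departure from zero in
either direction, its sign indicating top- versus bottom-of-list
enrichment. Significance comes from gene-set permutations: random sets of
the same size drawn from the universe give a null ES distribution, a
sign-stratified Normalized Enrichment Score (NES = ES divided by the mean
|null ES| of the same sign) and a nominal permutation p-value with a +1
pseudocount.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gmt import GeneSet, GeneSetCollection, sanitize_seqid

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Identifiers ordered by non-increasing score; ties by identifier."""

    identifiers: List[str]
    scores: np.ndarray
    index: Dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.identifiers) != len(self.scores):
            raise ValueError("identifiers and scores differ in length")
        if len(set(self.identifiers)) != len(self.identifiers):
            raise ValueError("duplicate identifiers in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")
        self.index = {ident: k for k, ident in enumerate(self.identifiers)}

    @property
    def n(self) -> int:
        return len(self.identifiers)

    @classmethod
    def from_file(cls, path: str | Path, sanitize: bool = False) -> "RankedList":
        """Read a two-column .rnk file (identifier TAB score), '#' comments allowed."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["identifier", "score"], dtype={"identifier": str})
        ids = df["identifier"].tolist()
        if sanitize:
            ids = [sanitize_seqid(i) if "-" in i else i for i in ids]
        return build_ranked_list(dict(zip(ids, df["score"].astype(float))))


@dataclass
class GseaParams:
    """Enrichment weight, permutation count and root seed."""

    weight: float = 0.0
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class EnrichmentProfile:
    """Steps, running sums and the signed extremum for one set."""

    steps: np.ndarray
    running: np.ndarray          # E_0..E_n, with E_0 = 0
    es: float
    es_position: int             # m* with |E_{m*}| maximal (1-based)


@dataclass
class EnrichmentResult:
    set_id: str
    size: int
    es: float
    nes: Optional[float]
    nominal_p: Optional[float]

    @property
    def direction(self) -> int:
        return 1 if self.es >= 0 else -1


def build_ranked_list(scores: Dict[str, float]) -> RankedList:
    """Sort identifier->score pairs into a RankedList.

    Descending by score; equal scores ordered by identifier ascending, so
    the ranking is reproducible across platforms.
    """
    if not scores:
        raise ValueError("empty score table")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedList(identifiers=[k for k, _ in items],
                      scores=np.array([v for _, v in items], dtype=float))


def _member_positions(rl: RankedList, gs: GeneSet | Sequence[str]) -> np.ndarray:
    members = gs.members if isinstance(gs, GeneSet) else gs
    pos = sorted(rl.index[m] for m in members if m in rl.index)
    return np.asarray(pos, dtype=np.intp)


def _steps_from_positions(scores: np.ndarray, positions: np.ndarray,
                          weight: float) -> np.ndarray:
    n = len(scores)
    m = len(positions)
    if m == 0 or m >= n:
        raise ValueError(f"set size must satisfy 1 <= size < n (got {m}, n={n})")
    steps = np.full(n, -1.0 / (n - m))
    if weight == 0:
        steps[positions] = 1.0 / m
    else:
        # scalar libm pow + correctly rounded sum: bit-reproducible across
        # platforms and summation orders
        w = np.array([abs(float(s)) ** weight for s in scores[positions]])
        total = math.fsum(w)
        if total == 0:
            # all member scores exactly zero: continuous p->0 limit
            logger.warning("all member scores are zero at weight=%g; using uniform member weights", weight)
            steps[positions] = 1.0 / m
        else:
            steps[positions] = w / total
    return steps


def step_variable(rl: RankedList, gs: GeneSet | Sequence[str],
                  weight: float = 0.0) -> EnrichmentProfile:
    """Compute steps and the running enrichment profile for one set.

    Members outside the ranked universe are ignored. Raises if the
    restricted set is empty or spans the whole universe (the step
    denominators vanish).
    """
    positions = _member_positions(rl, gs)
    steps = _steps_from_positions(rl.scores, positions, weight)
    return _profile_from_steps(steps)


def running_sum(steps: np.ndarray) -> np.ndarray:
    """E_0..E_n: cumulative sum of the steps with a leading zero."""
    return np.concatenate([[0.0], np.cumsum(steps)])


def _profile_from_steps(steps: np.ndarray) -> EnrichmentProfile:
    running = running_sum(steps)
    inner = running[1:]
    m_star = int(np.argmax(np.abs(inner)))  # first maximum on ties
    return EnrichmentProfile(steps=steps, running=running,
                             es=float(inner[m_star]), es_position=m_star + 1)


def enrichment_score(profile: EnrichmentProfile) -> float:
    """Signed maximal departure of the running sum from zero."""
    return profile.es


def _set_rng(params: GseaParams, set_id: str) -> np.random.Generator:
    # stable per-set substream: adding a set never perturbs other sets' nulls
    return np.random.default_rng(
        np.random.SeedSequence([params.seed, zlib.crc32(set_id.encode("utf-8"))])
    )


def permutation_null(rl: RankedList, set_size: int, params: GseaParams,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Null ES distribution from gene-set permutations.

    Each permutation draws ``set_size`` identifiers uniformly without
    replacement from the universe and scores them with the same weight.
    Vectorized over permutations; reproducible given the seed.
    """
    n = rl.n
    if not (1 <= set_size < n):
        raise ValueError(f"set_size must satisfy 1 <= set_size < n (got {set_size}, n={n})")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    nperm = params.n_permutations
    # positions of the permuted set in the ranked list, one row per draw
    pos = np.argsort(rng.random((nperm, n)), axis=1)[:, :set_size]
    steps = np.full((nperm, n), -1.0 / (n - set_size))
    rows = np.repeat(np.arange(nperm), set_size)
    cols = pos.ravel()
    if params.weight == 0:
        steps[rows, cols] = 1.0 / set_size
    else:
        w = np.abs(rl.scores[pos]) ** params.weight
        totals = w.sum(axis=1, keepdims=True)
        uniform = totals == 0
        if uniform.any():
            w = np.where(uniform, 1.0, w)
            totals = np.where(uniform, float(set_size), totals)
        steps[rows, cols] = (w / totals).ravel()
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(nperm), idx]


def normalize_and_test(es: float, null: np.ndarray) -> Tuple[Optional[float], Optional[float]]:
    """Sign-stratified NES and nominal permutation p-value.

    NES divides the ES by the mean |null ES| over null draws of the same
    sign; the nominal p is the same-sign exceedance fraction with a +1
    pseudocount in numerator and denominator (so p is never exactly zero).
    If no null draw shares the observed sign both are reported undefined
    (``None``) rather than silently dropped.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    same_sign = null >= 0 if es >= 0 else null < 0
    stratum = null[same_sign]
    if stratum.size == 0:
        logger.warning("no same-sign null ES values; NES and p undefined")
        return None, None
    mean_abs = float(np.mean(np.abs(stratum)))
    nes = None if mean_abs == 0 else es / mean_abs
    n_exceed = int(np.sum(np.abs(stratum) >= abs(es)))
    p = (1 + n_exceed) / (1 + stratum.size)
    return nes, p


def gsea_preranked(rl: RankedList, gs: GeneSet, params: GseaParams) -> EnrichmentResult:
    """Run one set against one ranked list: ES, NES, nominal p."""
    positions = _member_positions(rl, gs)
    if len(positions) == 0:
        raise ValueError(f"set {gs.set_id!r} has no members in the ranked universe")
    profile = step_variable(rl, gs, params.weight)
    null = permutation_null(rl, len(positions), params, rng=_set_rng(params, gs.set_id))
    nes, p = normalize_and_test(profile.es, null)
    return EnrichmentResult(set_id=gs.set_id, size=len(positions),
                            es=profile.es, nes=nes, nominal_p=p)


def gsea_collection(rl: RankedList, coll: GeneSetCollection,
                    params: GseaParams | None = None) -> List[EnrichmentResult]:
    """Run every set in a collection; sets with no overlap are skipped.

    Sets are reduced to the ranked universe before sizing. Results are
    sorted by set_id. Per-set permutation substreams are derived from the
    root seed and the set_id, so results for one set are invariant to the
    presence of other sets.
    """
    if params is None:
        params = GseaParams()
    results: List[EnrichmentResult] = []
    for gs in coll:
        if len(_member_positions(rl, gs)) == 0:
            logger.warning("set %r: no members in ranked universe, skipped", gs.set_id)
            continue
        results.append(gsea_preranked(rl, gs, params))
    return sorted(results, key=lambda r: r.set_id)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"set_id": r.set_id, "size": r.size, "es": r.es, "nes": r.nes,
          "nominal_p": r.nominal_p, "direction": r.direction} for r in results]
    )
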