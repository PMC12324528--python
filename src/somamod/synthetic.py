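"""Seeded generators for synthetic expression matrices, annotations and
ranked statistics.

The expression generator emulates the correlation structure that module
extraction operates on: a Gaussian sample whose covariance plants blocks
of strongly intra-correlated features on a near-independent background,
optionally with negative block-versus-background cross-correlation (the
regime observed for real extracted modules, which contrast with their
background). Marginals are standard normal — extraction depends only on
the correlation structure, and log10-RFU abundances are approximately
continuous, so a Gaussian copula suffices.

The ranked-stat generator plants an enriched set in an otherwise uniform
p-value landscape: background features get p ~ Uniform(0,1) with random
signs, enriched features get their -log10 p inflated by a constant shift
with a consistent sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .extraction import ExpressionMatrix
from .gmt import GeneSet, GeneSetCollection
from .mapping import AliasTable, AnnotationTable
from .ranking import FeatureStat

PSD_TOL = -1e-8


@dataclass
class Block:
    """One planted block: size, within-block correlation, member signs.

    ``signs`` (optional, +/-1 per member) split a block into anti-correlated
    arms: the correlation between members i and j is s_i * s_j * r.
    """

    size: int
    within_correlation: float
    signs: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("block size must be >= 2")
        if not (-1.0 < self.within_correlation < 1.0):
            raise ValueError("within_correlation must lie in (-1, 1)")
        if self.signs is not None and len(self.signs) != self.size:
            raise ValueError("signs length must equal block size")


@dataclass
class BlockSpec:
    """Covariance blueprint for a planted-module expression matrix."""

    blocks: List[Block] = field(default_factory=list)
    n_background: int = 0
    n_samples: int = 100
    background_correlation: float = 0.0
    cross_block_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.n_features == 0:
            raise ValueError("spec describes no features")
        # fail fast on an impossible correlation structure
        evmin = float(np.linalg.eigvalsh(self.correlation_matrix()).min())
        if evmin < PSD_TOL:
            raise ValueError(f"implied correlation matrix is not PSD (min eigenvalue {evmin:.3g})")

    @property
    def n_features(self) -> int:
        return sum(b.size for b in self.blocks) + self.n_background

    def correlation_matrix(self) -> np.ndarray:
        """The population correlation matrix the generator samples from."""
        n = self.n_features
        c = np.full((n, n), self.cross_block_correlation)
        start_bg = sum(b.size for b in self.blocks)
        bg = slice(start_bg, n)
        c[bg, bg.start:] = self.background_correlation
        offset = 0
        for b in self.blocks:
            sl = slice(offset, offset + b.size)
            signs = np.asarray(b.signs if b.signs is not None else np.ones(b.size))
            c[sl, sl] = np.outer(signs, signs) * b.within_correlation
            offset += b.size
        np.fill_diagonal(c, 1.0)
        return c

    def seqids(self) -> List[str]:
        """Synthetic SeqIds in SomaScan style: block members then background."""
        out = []
        for bi, b in enumerate(self.blocks, start=1):
            out.extend(f"{1000 * bi + j}-{bi}" for j in range(b.size))
        out.extend(f"{9000 + j}-99" for j in range(self.n_background))
        return out


@dataclass
class PlantedTruth:
    """Ground-truth block memberships recorded alongside a simulated matrix."""

    block_members: List[List[str]]
    background: List[str]


def simulate_expression(spec: BlockSpec) -> Tuple[ExpressionMatrix, PlantedTruth]:
    """Draw a seeded Gaussian sample with the spec's block covariance."""
    rng = np.random.default_rng(spec.seed)
    corr = spec.correlation_matrix()
    evals, evecs = np.linalg.eigh(corr)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((spec.n_samples, spec.n_features))
    x = z @ root.T
    seqids = spec.seqids()
    sample_ids = [f"S{i:05d}" for i in range(spec.n_samples)]
    values = pd.DataFrame(x, index=sample_ids, columns=seqids)
    mat = ExpressionMatrix(
        values=values,
        participant_ids=np.array([f"P{i:05d}" for i in range(spec.n_samples)]),
        visit_dates=np.array(["2020-01-01"] * spec.n_samples),
    )
    offset = 0
    members: List[List[str]] = []
    for b in spec.blocks:
        members.append(seqids[offset:offset + b.size])
        offset += b.size
    truth = PlantedTruth(block_members=members, background=seqids[offset:])
    return mat, truth


def simulate_ranked_stats(universe: Sequence[str], enriched: Sequence[str],
                          shift: float, seed: int = 0) -> List[FeatureStat]:
    """Per-feature (sign, p) stats with a planted enriched subset.

    Background features get p ~ Uniform(0,1) with random +/-1 signs; the
    enriched subset gets its -log10 p inflated by ``shift`` (on the log10
    scale) and a consistent positive sign, so it concentrates at the top
    of the signed -log10(p) ranking.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    enriched_set = set(enriched)
    if not enriched_set <= set(universe):
        raise ValueError("enriched features must be a subset of the universe")
    rng = np.random.default_rng(seed)
    stats: List[FeatureStat] = []
    for ident in universe:
        p = float(rng.uniform(0.0, 1.0))
        if ident in enriched_set:
            p = 10.0 ** (np.log10(max(p, 1e-300)) - shift)
            sign = 1
        else:
            sign = 1 if rng.random() < 0.5 else -1
        stats.append(FeatureStat(identifier=ident, sign=sign, p_value=max(p, 1e-300)))
    return stats


def make_toy_annotation(n_genes: int = 30, seed: int = 0
                        ) -> Tuple[AnnotationTable, AliasTable, GeneSetCollection]:
    """A small consistent symbol<->SeqId world for end-to-end tests.

    Includes one gene targeted by two SOMAmers (the STAT3-style case) and
    one gene reachable only through an alias, plus a symbol-space
    collection of three sets drawn from the gene universe.
    """
    rng = np.random.default_rng(seed)
    symbols = [f"GENE{i}" for i in range(1, n_genes + 1)]
    pairs: List[Tuple[str, str]] = []
    counter = 1000
    for i, sym in enumerate(symbols):
        n_soma = 2 if i == 0 else 1   # GENE1 gets two SOMAmers
        for j in range(n_soma):
            pairs.append((f"{counter}-{j + 1}", sym))
            counter += 10
    ann = AnnotationTable(pairs=pairs)
    # GENE2 is listed in sets only under its legacy alias
    aliases = AliasTable.from_pairs([("OLDG2", "GENE2"), ("ALT5", "GENE5")])
    universe = list(symbols)
    universe[1] = "OLDG2"
    k = min(15, n_genes)
    set_a = universe[:k]
    set_b = universe[max(0, n_genes - k):]
    mid = list(rng.choice(universe, size=min(12, n_genes), replace=False))
    coll = GeneSetCollection(prefix="TOY", sets=[
        GeneSet(set_id="TOY_ALPHA", name="TOY_ALPHA", description="first toy set", members=set_a),
        GeneSet(set_id="TOY_BETA", name="TOY_BETA", description="last toy set", members=set_b),
        GeneSet(set_id="TOY_GAMMA", name="TOY_GAMMA", description="random toy set",
                members=sorted(set(mid))),
    ], id_space="symbol")
    return ann, aliases, coll


def jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    """|A n B| / |A u B| — used to score recovery of planted modules."""
    sa, sb = set(a), set(b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 1.0
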