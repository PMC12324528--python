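"""Parent/child correlation summaries and paired enrichment comparisons.

Two questions about extracted modules are answered here. First, how does
the correlation structure of a child module relate to its parent set:
mean pairwise correlation within the parent, within the child, and the
cross-correlation between child members and the parent-only remainder
(extraction tends to select clusters that contrast with — i.e. correlate
negatively with — their background). Second, do child modules enrich more
strongly than their parents on the same ranked list: paired Wilcoxon
signed-rank and paired t-tests on |ES| (or |NES|), plus the median paired
difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .extraction import CorrelationMatrix, SomaModule
from .gmt import GeneSet
from .gsea import EnrichmentResult

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX = 25  # exact null enumeration up to here, normal approx above


@dataclass
class ParentChildSummary:
    parent_id: str
    child_id: str
    mean_within_parent: float
    mean_within_child: float
    mean_cross: Optional[float]   # None when child == parent


@dataclass
class PairedComparison:
    label: str
    parent_values: np.ndarray
    child_values: np.ndarray
    wilcoxon_p: Optional[float]
    ttest_p: Optional[float]
    median_paired_difference: float


def _mean_pairwise(members: Sequence[str], corr: CorrelationMatrix) -> float:
    idx = [corr.seqids.index(m) for m in members]
    vals = [corr.r[i, j] for i, j in combinations(idx, 2)]
    return float(np.mean(vals))


def parent_child_summary(parent: GeneSet, child: SomaModule | GeneSet,
                         corr: CorrelationMatrix) -> ParentChildSummary:
    """Within-parent, within-child and cross mean correlations.

    The cross term averages correlations between child members and
    parent-only members (those not in the child); it is undefined when the
    child exhausts the parent.
    """
    child_members = list(child.members)
    parent_members = list(parent.members)
    if not set(child_members) <= set(parent_members):
        raise ValueError("child members must be a subset of the parent")
    child_id = child.module_id if isinstance(child, SomaModule) else child.set_id
    within_parent = _mean_pairwise(parent_members, corr)
    within_child = _mean_pairwise(child_members, corr)
    only_parent = [m for m in parent_members if m not in set(child_members)]
    if not only_parent:
        cross = None
    else:
        ci = [corr.seqids.index(m) for m in child_members]
        pi = [corr.seqids.index(m) for m in only_parent]
        cross = float(np.mean(corr.r[np.ix_(ci, pi)]))
    return ParentChildSummary(parent_id=parent.set_id, child_id=child_id,
                              mean_within_parent=within_parent,
                              mean_within_child=within_child,
                              mean_cross=cross)


def paired_enrichment_test(parents: Sequence[EnrichmentResult],
                           children: Sequence[EnrichmentResult],
                           value: str = "es",
                           label: str = "|ES|",
                           zero_method: str = "wilcox") -> PairedComparison:
    """Paired Wilcoxon signed-rank + paired t-test on absolute enrichment.

    ``parents`` and ``children`` must align pairwise (child i derived from
    parent i). The Wilcoxon test uses the exact null for up to 25 non-zero
    pairs and a continuity-corrected normal approximation above; zero
    differences are dropped by default (``zero_method='pratt'`` keeps
    them). Tests are two-sided. All-zero differences make both tests
    undefined (``None``).
    """
    if len(parents) != len(children):
        raise ValueError("parent and child result lists differ in length")
    if len(parents) < 2:
        raise ValueError("need at least 2 aligned pairs")
    for p_res, c_res in zip(parents, children):
        if not c_res.set_id.startswith(p_res.set_id.rsplit(".", 1)[0]):
            logger.warning("pair (%s, %s) ids do not share a stem", p_res.set_id, c_res.set_id)

    def pull(r: EnrichmentResult) -> float:
        v = getattr(r, value)
        if v is None:
            raise ValueError(f"{value} undefined for set {r.set_id}")
        return abs(v)

    pv = np.array([pull(r) for r in parents])
    cv = np.array([pull(r) for r in children])
    diff = cv - pv
    median_diff = float(np.median(diff))
    if np.all(diff == 0):
        logger.warning("all paired differences are zero; tests undefined")
        return PairedComparison(label=label, parent_values=pv, child_values=cv,
                                wilcoxon_p=None, ttest_p=None,
                                median_paired_difference=median_diff)
    n_nonzero = int(np.sum(diff != 0))
    method = "exact" if n_nonzero <= EXACT_WILCOXON_MAX else "approx"
    wilcoxon_p = float(stats.wilcoxon(cv, pv, zero_method=zero_method,
                                      correction=(method == "approx"),
                                      alternative="two-sided", method=method).pvalue)
    t_res = stats.ttest_rel(cv, pv)
    ttest_p = float(t_res.pvalue) if np.isfinite(t_res.pvalue) else None
    return PairedComparison(label=label, parent_values=pv, child_values=cv,
                            wilcoxon_p=wilcoxon_p, ttest_p=ttest_p,
                            median_paired_difference=median_diff)
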