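"""Signed -log10(p) rank metric for preranked GSEA.

Upstream differential models (e.g. empirical-Bayes moderated fits for
case/control contrasts, mixed-effects likelihood-ratio tests for
longitudinal outcomes) export, per SOMAmer, a direction of change and a
p-value. The rank score is

    r = sign * (-log10(p)),

so strongly significant up-regulated features rank at the top and
down-regulated ones at the bottom. Fitting those models is out of scope
here; this module consumes their tables. A minimal ordinary-least-squares
Wald option is provided for synthetic end-to-end runs only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .gsea import RankedList, build_ranked_list

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps scores finite when upstream tools underflow to 0


@dataclass
class FeatureStat:
    """Per-feature direction (+1/-1) and p-value."""

    identifier: str
    sign: int
    p_value: float

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.p_value > 1:
            raise ValueError(f"p-value {self.p_value} > 1")
        if self.p_value <= 0:
            logger.warning("p-value %g <= 0 for %s floored at %g",
                           self.p_value, self.identifier, P_FLOOR)
            self.p_value = P_FLOOR


def rank_score(stat: FeatureStat) -> float:
    """r = sign * (-log10(p)), with p floored at 1e-300."""
    p = max(stat.p_value, P_FLOOR)
    return stat.sign * (-math.log10(p))


def build_scores(stats: Sequence[FeatureStat]) -> RankedList:
    """Apply the rank metric to a table of feature stats and sort."""
    ids = [s.identifier for s in stats]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate identifiers in feature stats")
    return build_ranked_list({s.identifier: rank_score(s) for s in stats})


def read_feature_stats(path: str | Path) -> List[FeatureStat]:
    """Read a delimited table with columns identifier, sign, p_value.

    ``sign`` may be +/-1 or any signed effect (e.g. logFC); only its sign
    is used. Zero effects default to +1 with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for row in df.itertuples(index=False):
        ident, effect, p = str(row[0]), float(row[1]), float(row[2])
        if effect == 0:
            logger.warning("zero effect for %s; sign defaults to +1", ident)
        out.append(FeatureStat(identifier=ident, sign=1 if effect >= 0 else -1, p_value=p))
    return out


def ols_wald_stats(y: np.ndarray, x: pd.DataFrame) -> List[FeatureStat]:
    """Simple per-column OLS slope + Wald test, for synthetic pipelines only.

    Regresses ``y`` on each column of ``x`` separately and returns the
    slope sign with its two-sided p-value.
    """
    from scipy.stats import t as t_dist

    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 observations")
    yc = y - y.mean()
    out = []
    for col in x.columns:
        v = x[col].to_numpy(dtype=float)
        vc = v - v.mean()
        sxx = float(vc @ vc)
        if sxx == 0:
            out.append(FeatureStat(identifier=str(col), sign=1, p_value=1.0))
            continue
        beta = float(vc @ yc) / sxx
        resid = yc - beta * vc
        sigma2 = float(resid @ resid) / (n - 2)
        se = math.sqrt(sigma2 / sxx) if sigma2 > 0 else 0.0
        if se == 0:
            p = P_FLOOR
        else:
            p = float(2 * t_dist.sf(abs(beta / se), df=n - 2))
        out.append(FeatureStat(identifier=str(col), sign=1 if beta >= 0 else -1,
                               p_value=max(min(p, 1.0), P_FLOOR)))
    return out
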