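"""Over-representation analysis of gene lists against gene sets.

For a query of n genes from a universe of N, a set containing K universe
genes and overlapping the query in k, the enrichment p-value is the
upper-tail hypergeometric probability P(X ≥ k) — identical to a one-sided
Fisher's exact test on the 2×2 membership table. BH correction is applied
across sets.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats

from triohet.diffexpr import bh_adjust
from triohet.io_formats import GeneSets

logger = logging.getLogger(__name__)


def enrich(
    query: Iterable[str], sets: GeneSets, min_set_size: int = 3
) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``query`` against each set.

    Query genes outside the universe are dropped (with a logged count);
    sets smaller than ``min_set_size`` are skipped. Returns one row per
    tested set, sorted by adjusted p: set_id, k (overlap), n (query size),
    K (set size), N (universe size), p, padj.
    """
    if not sets.universe:
        raise ValueError("empty gene universe")
    q = set(query)
    if not q:
        raise ValueError("empty query gene list")
    outside = q - sets.universe
    if outside:
        logger.info("dropped %d query genes absent from the universe", len(outside))
        q &= sets.universe
    if not q:
        raise ValueError("no query genes remain inside the universe")

    N, n = len(sets.universe), len(q)
    rows = []
    for sid, members in sets.sets.items():
        K = len(members)
        if K < min_set_size:
            logger.debug("skipping set %s (size %d < %d)", sid, K, min_set_size)
            continue
        k = len(q & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_id": sid, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    if not rows:
        raise ValueError("no gene sets passed the minimum size filter")
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["padj", "p", "set_id"], kind="stable").reset_index(drop=True)
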