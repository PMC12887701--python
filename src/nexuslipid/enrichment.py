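"""Hypergeometric over-representation analysis with BH-FDR control.

Mirrors the MSigDB C5-style workflow: gene sets are pre-filtered to
5 <= size <= 2000 after intersection with the analytical background, the
one-sided upper-tail hypergeometric P is computed per set, and
Benjamini-Hochberg adjustment is applied across all tested sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import load_gmt  # noqa: F401  (re-exported: GMT is this module's input format)

log = logging.getLogger(__name__)

MIN_SET_SIZE = 5
MAX_SET_SIZE = 2000


@dataclass(frozen=True)
class GeneSet:
    name: str
    domain: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def filter_sets(collection, background: set[str],
                min_size: int = MIN_SET_SIZE, max_size: int = MAX_SET_SIZE):
    """Drop sets whose background-intersected size is outside [min, max]."""
    kept = []
    for s in collection:
        n = len(s.members & background)
        if min_size <= n <= max_size:
            kept.append(s)
    return kept


def default_background(collection) -> set[str]:
    """Union of all genes across the collection."""
    bg: set[str] = set()
    for s in collection:
        bg |= s.members
    return bg


def hypergeom_p(k: int, N: int, K: int, n: int) -> float:
    """One-sided upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query: set[str], collection, background: set[str] | None = None,
           fdr_thresh: float = 0.05, size_filter: bool = True) -> pd.DataFrame:
    """Over-representation of ``query`` against each set in ``collection``.

    Counts are all intersected with the background (default: union of the
    collection); query genes outside the background are dropped with a log
    message.  Returns one row per tested set with columns
    ``set_name domain N K n k p fdr significant``, sorted by p.
    """
    if background is None:
        background = default_background(collection)
    if size_filter:
        collection = filter_sets(collection, background)

    dropped = query - background
    if dropped:
        log.info("enrich: %d query gene(s) outside the background dropped", len(dropped))
    query_bg = query & background
    columns = ["set_name", "domain", "N", "K", "n", "k", "p", "fdr", "significant"]
    if not query_bg:
        warnings.warn("enrich: empty query after background intersection")
        return pd.DataFrame(columns=columns)
    if not collection:
        warnings.warn("enrich: no gene sets survive the size filter")
        return pd.DataFrame(columns=columns)

    N = len(background)
    n = len(query_bg)
    rows = []
    for s in collection:
        K = len(s.members & background)
        k = len(s.members & query_bg)
        rows.append({"set_name": s.name, "domain": s.domain,
                     "N": N, "K": K, "n": n, "k": k,
                     "p": hypergeom_p(k, N, K, n)})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_thresh
    return df.sort_values(["p", "set_name"]).reset_index(drop=True)[columns]
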