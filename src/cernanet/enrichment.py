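"""Over-representation analysis (ORA) against local GMT gene sets.

For a query gene list and a background universe, each term is scored
with the upper-tail hypergeometric probability of observing at least the
overlap seen, and with the enrichment ratio observed/expected =
``k / (n*K/N)`` — the ranking quantity.  BH FDR is computed across
terms.  Results are sorted by enrichment ratio descending, ties by
p-value ascending then term id.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .core_io import GeneSetCollection
from .diffexpr import adjust_bh

ENRICH_COLUMNS = ["term_id", "term_name", "k", "n", "K", "N",
                  "enrichment_ratio", "p_value", "fdr"]


def ora(query: set[str], collection: GeneSetCollection,
        background: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``background`` defaults to the union of all collection members; the
    query must be contained in it.  Term memberships are intersected with
    the background before testing.
    """
    if not query:
        raise ValueError("query gene set is empty")
    if len(collection) == 0:
        raise ValueError("gene set collection is empty")
    if background is None:
        background = collection.all_members | set(query)
    offenders = set(query) - set(background)
    if offenders:
        raise ValueError("query genes missing from background: "
                         f"{sorted(offenders)[:10]}")
    N = len(background)
    n = len(query)
    rows = []
    for term, (name, members) in collection.sets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        k = len(set(query) & in_bg)
        if K == 0:
            ratio, p = 0.0, 1.0
        else:
            expected = n * K / N
            ratio = k / expected
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term, name, k, n, K, N, ratio, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    out["fdr"] = adjust_bh(out["p_value"].tolist())
    out = out.sort_values(["enrichment_ratio", "p_value", "term_id"],
                          ascending=[False, True, True],
                          kind="stable").reset_index(drop=True)
    return out


def top_terms(rows: pd.DataFrame, top_k: int = 10,
              max_fdr: float = 1.0) -> pd.DataFrame:
    """First ``top_k`` terms with ``fdr <= max_fdr`` under the ORA ordering."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    return rows[rows["fdr"] <= max_fdr].head(top_k).reset_index(drop=True)
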