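"""Hypergeometric over-representation analysis on a flat annotation table.

For a DEP set of size n drawn from a universe of N detected proteins, a term
with K universe members and k DEP members gets the upper-tail p-value
P(X >= k) with X ~ Hypergeometric(N, K, n) — equivalent to a one-sided Fisher
exact test on the 2x2 membership table. P-values are adjusted across tested
terms with Benjamini–Hochberg. The universe is the set of proteins surviving
the preprocessing funnel at that endpoint, not the full proteome: a
detection-conditioned background avoids trivially enriching abundant plasma
proteins.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .io_tables import AnnotationSet

RESULT_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "q_value"]


def enrich(
    dep_ids,
    universe_ids,
    annotations: AnnotationSet,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Test each annotation term for over-representation in ``dep_ids``.

    Terms are intersected with the universe first; terms with fewer than
    ``min_term_size`` universe members are skipped. Returns one row per
    tested term, sorted by ascending p-value.
    """
    universe = frozenset(universe_ids)
    if not universe:
        raise ConfigurationError("empty universe")
    dep = frozenset(dep_ids)
    stray = dep - universe
    if stray:
        raise ConfigurationError(f"DEP ids outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(dep)
    rows = []
    for term, members in annotations.terms.items():
        in_universe = members & universe
        K = len(in_universe)
        if K < min_term_size:
            continue
        k = len(in_universe & dep)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": annotations.names.get(term, term),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(result):
        _, q, _, _ = multipletests(result["p_value"].to_numpy(), method="fdr_bh")
        result["q_value"] = q
        result = result.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        result["q_value"] = []
    return result
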