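"""Hypergeometric over-representation of metabolite sets.

The detected metabolome is the background universe; each set is intersected
with the background before testing. P values are the upper tail
P[X >= hits] with X ~ Hypergeometric(N, K, n); no multiplicity adjustment by
default, with an optional BH column.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust
from .errors import ValidationError
from .io import MetaboliteSetCollection


def hypergeometric_upper_tail(hits: int, N: int, K: int, n: int) -> float:
    """P[X >= hits] for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if K == 0 or n == 0 or hits <= 0:
        return 1.0
    return float(min(hypergeom.sf(hits - 1, N, K, n), 1.0))


def enrich(
    query: list[str],
    sets: MetaboliteSetCollection,
    background: list[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Test each metabolite set for over-representation in the query list.

    Returns a DataFrame sorted by P with columns set_name, description,
    set_size (within background), hits, expected, p_value and, when
    ``adjust`` is set, p_adjusted.
    """
    background_set = set(background)
    if len(background_set) != len(background):
        raise ValidationError("background contains duplicates")
    query_set = set(query)
    offenders = sorted(query_set - background_set)
    if offenders:
        raise ValidationError(f"query metabolites not in background: {offenders}")
    N = len(background_set)
    n = len(query_set)
    rows = []
    for name, (description, members) in sets:
        member_set = set(members) & background_set
        K = len(member_set)
        hits = len(member_set & query_set)
        rows.append(
            {
                "set_name": name,
                "description": description,
                "set_size": K,
                "hits": hits,
                "expected": n * K / N if N else 0.0,
                "p_value": hypergeometric_upper_tail(hits, N, K, n),
            }
        )
    result = pd.DataFrame(rows)
    if adjust and not result.empty:
        result["p_adjusted"] = bh_adjust(result["p_value"].to_numpy())
    return result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
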