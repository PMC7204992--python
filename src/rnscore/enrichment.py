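"""Over-representation analysis against user-supplied gene sets.

For a query of n_q genes drawn from a universe of N genes, a set with
K_set members in the universe, and an observed overlap of k genes, the
one-sided enrichment p-value is the hypergeometric upper tail
P(X ≥ k); p-values are Benjamini–Hochberg adjusted across all tested
sets. The universe conventionally defaults to the genes of the PPI
network under study (configurable by the caller).
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError
from .io import GeneSetCollection


def ora(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; the query is
    likewise restricted to the universe. Rows are sorted by (adj_p,
    set_id) and carry the overlap members for inspection.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise PipelineError("query is empty after intersection with the universe")
    N, n_q = len(universe), len(query)
    records = []
    for set_id, (desc, members) in sorted(sets.sets.items()):
        in_universe = members & universe
        if not in_universe:
            continue
        overlap = sorted(query & in_universe)
        k, K_set = len(overlap), len(in_universe)
        p = float(hypergeom.sf(k - 1, N, K_set, n_q))
        records.append(
            {
                "set_id": set_id,
                "description": desc,
                "overlap": k,
                "set_size": K_set,
                "query_size": n_q,
                "universe_size": N,
                "p_value": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    if not records:
        raise PipelineError("no gene set intersects the universe")
    out = pd.DataFrame.from_records(records).set_index("set_id")
    _, adj, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["adj_p"] = adj
    out["significant"] = out["adj_p"] < alpha
    return out.sort_values(by=["adj_p", "set_id"], kind="stable")
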