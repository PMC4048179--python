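"""Hypergeometric over-representation tests for modules.

One machinery serves both annotation (GO-style) enrichment — "term" = the
set of traits annotated to a category — and eQTL enrichment, where the
"term" is the set of genes associated with a SNP.  The p-value for a module
of size m with overlap t against a term of size K_t in a universe of N
traits is the upper hypergeometric tail P(T >= t); Benjamini-Hochberg
q-values are reported across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "enrich_hypergeom", "eqtl_term_map"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # term, overlap, term_size, module_size, universe_size, p, q
    universe_size: int
    module_size: int
    provenance: dict = field(default_factory=dict)

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table.q <= q_max]


def enrich_hypergeom(
    module: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Optional[Iterable[str]] = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment of ``module`` against each term.

    ``term_map`` maps trait -> terms.  The universe defaults to every trait
    carrying at least one annotation; the module must be a subset of it.
    """
    module = set(module)
    if not module:
        raise ValueError("module is empty")
    annotated = {t for t, terms in term_map.items() if terms}
    universe = set(universe) if universe is not None else annotated
    if not module <= universe:
        raise ValueError(f"module traits outside the universe: "
                         f"{sorted(module - universe)[:5]}")

    term_members: dict[str, set[str]] = {}
    for trait, terms in term_map.items():
        if trait in universe:
            for term in terms:
                term_members.setdefault(term, set()).add(trait)

    N = len(universe)
    m = len(module)
    rows = []
    for term, members in sorted(term_members.items()):
        K_t = len(members)
        t = len(module & members)
        p = float(hypergeom.sf(t - 1, N, K_t, m))  # P(T >= t)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append({"term": term, "overlap": t, "term_size": K_t,
                     "module_size": m, "universe_size": N, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    return EnrichmentResult(
        table=table,
        universe_size=N,
        module_size=m,
        provenance={"test": "hypergeometric_upper_tail", "correction": "benjamini_hochberg"},
    )


def eqtl_term_map(coeffs, snp_ids: Optional[Iterable[str]] = None) -> dict[str, set[str]]:
    """Build a trait -> {SNP} annotation map from a coefficient matrix, so the
    enrichment machinery can ask whether a module is enriched for the targets
    of a given SNP (eQTL enrichment)."""
    frame = coeffs.to_frame()
    if snp_ids is not None:
        keep = set(snp_ids)
        frame = frame[frame.row_id.isin(keep)]
    out: dict[str, set[str]] = {}
    for _, rec in frame.iterrows():
        out.setdefault(rec["col_id"], set()).add(rec["row_id"])
    return out
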