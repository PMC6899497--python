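"""Term enrichment of a gene list against a background.

DAVID-style functional annotation enrichment computed locally: for each
term with K background members of which k fall in the n-gene query list
(background size N), the upper-tail hypergeometric p-value
P(X >= k) and the more conservative EASE score — the same tail
probability with one success removed, P(X >= k-1) — are reported, with
Benjamini-Hochberg adjusted q-values across all tested terms. The
background is the set of genes actually quantified in the experiment,
not the genome.

Terms with no background members or no query members are excluded from
testing (their p-value is 1 by construction and including them would only
dilute the multiple-testing correction).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentError", "enrich", "bh_adjust", "read_term_map"]


class EnrichmentError(ValueError):
    """Invalid enrichment input."""


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(q, 1.0)


def read_term_map(path) -> pd.DataFrame:
    """Read a gene->term TSV with columns gene_id, term_id, term_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "term_id"} - set(df.columns)
    if missing:
        raise EnrichmentError(f"term map missing column(s): {sorted(missing)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df


def _term_sets(term_map, background: Set[str]) -> tuple[Dict[str, Set[str]], Dict[str, str]]:
    """Term -> background member set, plus term names; foreign genes dropped."""
    members: Dict[str, Set[str]] = {}
    names: Dict[str, str] = {}
    dropped: Set[str] = set()
    if isinstance(term_map, pd.DataFrame):
        rows = term_map.itertuples(index=False)
        for row in rows:
            gene, term = str(row.gene_id), str(row.term_id)
            names.setdefault(term, str(getattr(row, "term_name", term)))
            if gene not in background:
                dropped.add(gene)
                continue
            members.setdefault(term, set()).add(gene)
    else:  # mapping gene -> iterable of terms
        for gene, terms in term_map.items():
            if gene not in background:
                dropped.add(gene)
                continue
            for term in terms:
                names.setdefault(str(term), str(term))
                members.setdefault(str(term), set()).add(gene)
    if dropped:
        logger.warning(
            "%d gene(s) in the term map are not in the background; dropped", len(dropped)
        )
    return members, names


def enrich(
    gene_list: Iterable[str],
    background: Iterable[str],
    term_map: pd.DataFrame | Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric/EASE enrichment of ``gene_list`` within ``background``.

    Parameters
    ----------
    gene_list
        Query genes; must be a subset of the background.
    background
        The gene universe (typically all quantified genes).
    term_map
        DataFrame (gene_id, term_id, term_name) or mapping gene -> terms.
        Genes outside the background are dropped with a warning.
    alpha
        Significance level recorded with the result (used by callers to
        threshold ``q_bh``); must lie in (0, 1).

    Returns
    -------
    DataFrame with one row per tested term (k >= 1, K >= 1), columns
    term_id, term_name, k, n, K, N, p_hyper, p_ease, q_bh, sorted by
    p_ease ascending. ``p_hyper`` is the upper tail P(X >= k); ``p_ease``
    removes one overlapping gene (P(X >= k-1)), so p_ease >= p_hyper.
    """
    if not (0.0 < alpha < 1.0):
        raise EnrichmentError(f"alpha must be in (0, 1), got {alpha}")
    query = set(map(str, gene_list))
    bg = set(map(str, background))
    if not query or not bg:
        raise EnrichmentError("gene_list and background must be non-empty")
    offenders = sorted(query - bg)
    if offenders:
        raise EnrichmentError(
            f"{len(offenders)} query gene(s) absent from the background: "
            + ", ".join(offenders[:10])
        )

    members, names = _term_sets(term_map, bg)
    N, n = len(bg), len(query)
    rows = []
    for term, genes_with_term in members.items():
        K = len(genes_with_term)
        k = len(genes_with_term & query)
        if K == 0 or k == 0:
            continue
        p_hyper = float(hypergeom.sf(k - 1, N, K, n))
        p_ease = float(hypergeom.sf(k - 2, N, K, n))  # EASE: one success removed
        rows.append((term, names[term], k, n, K, N, min(p_hyper, 1.0), min(p_ease, 1.0)))

    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_hyper", "p_ease"]
    )
    if len(result):
        result["q_bh"] = bh_adjust(result["p_ease"].to_numpy())
        result = result.sort_values(
            ["p_ease", "p_hyper", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        result["q_bh"] = pd.Series(dtype=float)
    result.attrs["alpha"] = alpha
    return result
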