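"""Over-representation analysis (ORA) of a protein set against annotation terms.

Given a query set (e.g. the overexpressed proteins), a background universe
(the identified proteome) and a collection of annotation terms with member
lists, each term is tested with a one-sided Fisher exact test on the 2x2
table (in query & in term, in query & not in term, not in query & in term,
neither).  The one-sided "greater" alternative tests enrichment only, as
functional-annotation servers do.  Raw p-values are adjusted with the
Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "enrichment_pvalue",
    "fisher_enrichment",
    "bh_fdr",
    "filter_significant",
    "read_gmt",
    "write_gmt",
    "results_to_frame",
]


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term: identifier, free-text name, member identifiers."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.term_id}: annotation term has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query hits in term
    K: int  # background members of term
    n: int  # query size
    N: int  # background size
    p_value: float
    fdr: float = float("nan")


def enrichment_pvalue(k, K, n, N, ease: bool = False):
    """One-sided (greater) Fisher p for the 2x2 enrichment table.

    Equals the hypergeometric upper tail P(X >= k) with X ~ Hypergeom(N, K,
    n): the chance of drawing at least k term members in a query of size n
    from a background of N containing K members.  Vectorized over array
    inputs; with ``ease=True`` one hit is discounted (k-1, the DAVID EASE
    variant).  Returns a float for scalar input.
    """
    k = np.asarray(k)
    k_eff = np.maximum(k - 1, 0) if ease else k
    p = np.minimum(stats.hypergeom.sf(k_eff - 1, N, K, n), 1.0)
    return float(p) if p.ndim == 0 else p


def fisher_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    sets: Sequence[AnnotationSet],
    min_background_members: int = 2,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment p-value for every term, sorted by p.

    Terms with fewer than ``min_background_members`` members in the
    background are skipped as degenerate.  With ``ease=True`` the EASE-score
    variant is used: one query hit is discounted (k-1), a conservative
    penalty for small overlaps popularized by DAVID.  BH-adjusted values are
    filled in across the tested terms.
    """
    query_set = frozenset(query)
    bg = frozenset(background)
    if not bg:
        raise ValueError("background is empty")
    stray = sorted(query_set - bg)
    if stray:
        raise ValueError(f"query identifiers missing from background: {stray}")
    n, N = len(query_set), len(bg)
    results: list[EnrichmentResult] = []
    for s in sets:
        members = s.members & bg
        K = len(members)
        if K < min_background_members:
            continue
        k = len(members & query_set)
        p = enrichment_pvalue(k, K, n, N, ease=ease)
        results.append(EnrichmentResult(s.term_id, s.term_name, k, K, n, N, p))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if results:
        fdr = bh_fdr([r.p_value for r in results])
        results = [
            EnrichmentResult(r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p_value, q)
            for r, q in zip(results, fdr)
        ]
    logger.info("enrichment: %d/%d terms tested (query %d of %d)", len(results), len(sets), n, N)
    return results


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def filter_significant(
    results: Sequence[EnrichmentResult],
    alpha_p: float = 0.05,
    alpha_fdr: float = 0.05,
    mode: str = "fdr",
) -> list[EnrichmentResult]:
    """Keep terms passing the inclusive threshold on p (mode='p') or FDR."""
    if mode == "p":
        return [r for r in results if r.p_value <= alpha_p]
    if mode == "fdr":
        return [r for r in results if r.fdr <= alpha_fdr]
    raise ValueError(f"mode must be 'p' or 'fdr', got {mode!r}")


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """Read annotation sets from a GMT file (term, description, members...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line!r}")
        sets.append(AnnotationSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def write_gmt(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in results
        ],
        columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr"],
    )
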