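"""Over-representation statistics with Benjamini-Hochberg FDR control.

A gene set is tested against an annotation catalog (GO-style terms and/or
pathway gene sets, GMT-serializable) with the one-sided hypergeometric tail
test; adjusted p-values are computed by the BH step-up procedure, by default
within each annotation category separately (mirroring how annotation portals
report BP/CC/MF/KEGG blocks).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

__all__ = ["AnnotationCatalog", "hypergeom_p", "bh_adjust", "enrich"]

DEFAULT_CATEGORY = "GENESET"


@dataclass
class AnnotationCatalog:
    """Term -> gene-set catalog with optional per-term category labels.

    Categories default to a single pooled label; GO/pathway catalogs
    typically use BP, CC, MF and KEGG. Serializes to the tab-delimited GMT
    format (term, description, members...), where the description column
    carries the category.
    """

    terms: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    _KNOWN_CATEGORIES = ("BP", "CC", "MF", "KEGG", DEFAULT_CATEGORY)

    def __post_init__(self):
        self.terms = {str(t): frozenset(str(g).strip().upper() for g in gs)
                      for t, gs in self.terms.items()}
        self.categories = {str(t): str(c) for t, c in self.categories.items()}
        for t in self.terms:
            self.categories.setdefault(t, DEFAULT_CATEGORY)

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs
        return out

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in self.terms:
                genes = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\t{self.categories[term]}\t{genes}\n")

    @classmethod
    def from_gmt(cls, path) -> "AnnotationCatalog":
        terms: dict[str, frozenset[str]] = {}
        categories: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(
                        f"GMT line needs term, description and >= 1 gene: "
                        f"{line!r}")
                term, desc, genes = parts[0], parts[1], parts[2:]
                terms[term] = frozenset(genes)
                categories[term] = (desc if desc in cls._KNOWN_CATEGORIES
                                    else DEFAULT_CATEGORY)
        return cls(terms=terms, categories=categories)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    ``k`` query genes hit a term of size ``K`` in a query of size ``n``
    drawn from a background of ``N`` genes. Evaluated through the survival
    function (log-space internals), so deep tails stay accurate.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query: Iterable[str], catalog: AnnotationCatalog,
           background: Iterable[str] | None = None, alpha: float = 0.05,
           per_category: bool = True, ease: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set.

    One record per catalog term with at least one query hit; columns
    ``term, category, k, K, n, N, p, p_adj, significant``, sorted by
    adjusted p then term id. BH correction is applied within each category
    separately unless ``per_category=False`` pools all terms. The background
    defaults to the union of catalog genes; term genes outside the
    background are dropped with a warning. ``ease=True`` applies the
    conservative EASE variant (tail evaluated at k - 1).
    """
    query = {str(g).strip().upper() for g in query}
    if background is None:
        bg = catalog.genes()
    else:
        bg = {str(g).strip().upper() for g in background}
    if not query <= bg:
        raise ValidationError("query genes must be a subset of the background")
    N = len(bg)
    n = len(query)
    rows = []
    dropped = 0
    for term, genes in catalog.terms.items():
        inside = genes & bg
        dropped += len(genes) - len(inside)
        k = len(query & inside)
        if k == 0:
            continue
        K = len(inside)
        k_eff = k - 1 if ease else k
        rows.append({"term": term, "category": catalog.categories[term],
                     "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_p(k_eff, K, n, N)})
    if dropped:
        warnings.warn(f"{dropped} annotation gene(s) outside the background "
                      "were dropped", stacklevel=2)
    if not rows:
        return pd.DataFrame(columns=["term", "category", "k", "K", "n", "N",
                                     "p", "p_adj", "significant"])
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    if per_category:
        for cat, idx in df.groupby("category").groups.items():
            df.loc[idx, "p_adj"] = bh_adjust(df.loc[idx, "p"])
    else:
        df["p_adj"] = bh_adjust(df["p"])
    df["significant"] = df["p_adj"] < alpha
    df["gene_ratio"] = df["k"] / df["K"]
    return (df.sort_values(["p_adj", "term"], kind="stable")
            .reset_index(drop=True))
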