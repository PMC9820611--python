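"""GO-term over-representation of DEGs against a gene universe.

The default test is the central hypergeometric upper tail
P[X >= k] for k DEGs among K term members, n DEGs and N universe genes,
with BH correction across terms.  A Wallenius non-central mode accepts
per-gene sampling-bias weights (e.g. transcript length): each term's
odds ratio is the mean weight of its member genes over the mean weight
of non-members, and the tail is evaluated under the Wallenius
non-central hypergeometric distribution.  Equal weights reduce exactly
to the central test.

Annotation is taken as given flat gene -> term-set bins; no GO-DAG
ancestor propagation is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust

__all__ = ["AnnotationMap", "hypergeom_pvalue", "wallenius_pvalue", "enrich"]

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class AnnotationMap:
    """Flat gene -> GO-term-set map with optional human-readable term names."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.gene_terms = {
            g: set(ts) for g, ts in self.gene_terms.items() if ts
        }

    def add(self, gene_id: str, term_id: str) -> None:
        self.gene_terms.setdefault(gene_id, set()).add(term_id)

    def terms_for(self, gene_id: str) -> set[str]:
        return self.gene_terms.get(gene_id, set())

    def genes_for(self, term_id: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term_id in ts}

    @property
    def all_terms(self) -> set[str]:
        return {t for ts in self.gene_terms.values() for t in ts}

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        """Two-column TSV (gene_id, term_id); repeated rows for multiple terms."""
        amap = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
                amap.add(parts[0], parts[1])
        return amap


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Central hypergeometric upper tail P[X >= k].

    k: DEGs in the term; K: universe genes in the term; n: DEG count;
    N: universe size.
    """
    if not (0 <= k <= min(K, n) and k <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(require 0 <= k <= min(K, n) and K, n <= N)"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def wallenius_pvalue(k: int, K: int, n: int, N: int, odds: float) -> float:
    """Wallenius non-central hypergeometric upper tail P[X >= k] at the given odds."""
    if odds <= 0:
        raise ValueError("odds ratio must be positive")
    if not (0 <= k <= min(K, n) and k <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if K == 0 or n == 0:
        return 1.0 if k == 0 else 0.0
    return float(stats.nchypergeom_wallenius.sf(k - 1, N, K, n, odds))


def enrich(
    deg_ids: Iterable[str],
    universe_ids: Iterable[str],
    annotation: AnnotationMap | Mapping[str, set[str]],
    fdr_max: float = 0.05,
    mode: str = "central",
    bias_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Term-by-term over-representation with BH correction across terms.

    Returns one row per term with >= 1 universe gene, columns
    (term_id, term_name, k, K, n, N, p_value, fdr, enriched), sorted by
    p-value then term ID.  ``enriched`` is fdr < ``fdr_max``.
    """
    if mode not in ("central", "wallenius"):
        raise ValueError("mode must be 'central' or 'wallenius'")
    gene_terms = annotation.gene_terms if isinstance(annotation, AnnotationMap) else annotation
    term_names = annotation.term_names if isinstance(annotation, AnnotationMap) else {}

    universe = set(universe_ids)
    degs = set(deg_ids)
    stray = sorted(degs - universe)
    if stray:
        raise ValueError(f"DEGs absent from the universe: {stray}")
    if not universe:
        raise ValueError("empty universe")

    N, n = len(universe), len(degs)
    term_members: dict[str, set[str]] = {}
    for g in universe:
        for t in gene_terms.get(g, set()):
            term_members.setdefault(t, set()).add(g)
    if not term_members:
        raise ValueError("annotation covers no universe gene")

    if mode == "wallenius" and bias_weights is not None:
        w = {g: float(bias_weights.get(g, 1.0)) for g in universe}
        if any(v <= 0 for v in w.values()):
            raise ValueError("bias weights must be positive")
    else:
        w = None

    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & degs)
        if mode == "central" or w is None:
            p = hypergeom_pvalue(k, K, n, N)
        else:
            inside = np.mean([w[g] for g in members])
            outside_genes = universe - members
            outside = np.mean([w[g] for g in outside_genes]) if outside_genes else 1.0
            p = wallenius_pvalue(k, K, n, N, inside / outside)
        rows.append((term, term_names.get(term, term), k, K, n, N, p))

    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["enriched"] = table["fdr"] < fdr_max
    return table.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
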