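"""Three-layer hierarchical GRN inference by triple-gene partial correlation.

The algorithm screens gene pairs (x, y) that are strongly co-expressed
across the time-course samples (Pearson r_xy >= 0.8 at p < 0.001), then
asks, for every candidate transcription factor z, whether conditioning
on z destroys that co-expression:

    r_xy|z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

A triple passes when |r_xy|z| <= 0.3 — z statistically explains the
pair, and the pair's co-expression is attributed to co-regulation by z,
materialized as directed edges z->x and z->y.  Two passes assemble the
hierarchy: structural-gene pairs attributed to TFs define the middle
layer and its bottom-layer targets; pairs among middle-layer TFs
attributed to the remaining TFs define the top layer.

The model-fitting surface follows the statsmodels convention:
``HierarchicalGRNModel(expr, tf_ids, structural_ids).fit()`` returns a
:class:`GRNResults` carrying the network, the thresholds used, stage
counts, and a ``summary()``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .util import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "GRNParams",
    "TripleTestResult",
    "GRNEdge",
    "HierarchicalGRN",
    "GRNSummary",
    "pearson_with_p",
    "partial_correlation",
    "find_coexpressed_pairs",
    "attribute_pairs_to_regulators",
    "edges_from_triples",
    "assemble_three_layer_grn",
    "summarize_grn",
    "HierarchicalGRNModel",
    "GRNResults",
]

_DEGENERATE_TOL = 1.0 - 1e-12


# ----------------------------------------------------------------------
# parameters and result records
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GRNParams:
    """Thresholds of the pair screen and the regulator-attribution gate."""

    r_min: float = 0.8
    p_max: float = 0.001
    partial_max: float = 0.3
    use_absolute_r: bool = False

    def __post_init__(self):
        if not (0 < self.r_min <= 1):
            raise ValueError("r_min must be in (0, 1]")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")
        if not (0 <= self.partial_max < self.r_min):
            raise ValueError("partial_max must satisfy 0 <= partial_max < r_min")


@dataclass(frozen=True)
class TripleTestResult:
    """One (x, y, z) co-regulation test."""

    x: str
    y: str
    z: str
    r_xy: float
    p_xy: float
    r_xz: float
    r_yz: float
    r_xy_given_z: float
    passes: bool

    def __post_init__(self):
        if self.x == self.y or self.z in (self.x, self.y):
            raise ValueError("triple requires x != y and z not in {x, y}")


@dataclass(frozen=True)
class GRNEdge:
    """Directed regulator->target edge with its supporting triples."""

    source: str
    target: str
    layer_pair: str  # "1->2" or "2->3"
    triples: tuple[TripleTestResult, ...]

    @property
    def best_r_xy(self) -> float:
        return max(t.r_xy for t in self.triples)

    @property
    def best_partial(self) -> float:
        return min(abs(t.r_xy_given_z) for t in self.triples)


@dataclass(frozen=True)
class HierarchicalGRN:
    """Three disjoint layers plus directed edges restricted to layer k -> k+1."""

    layer1: frozenset[str]
    layer2: frozenset[str]
    layer3: frozenset[str]
    edges: tuple[GRNEdge, ...]
    two_layer_warning: bool = False
    dropped_tfs: frozenset[str] = frozenset()
    unregulated_layer2: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.layer1 & self.layer2 or self.layer1 & self.layer3 or self.layer2 & self.layer3:
            raise ValueError("layers must be pairwise disjoint")
        for e in self.edges:
            if not e.triples:
                raise ValueError(f"edge {e.source}->{e.target} has no supporting triples")
            for t in e.triples:
                if not t.passes:
                    raise ValueError(
                        f"edge {e.source}->{e.target} supported by a non-passing triple"
                    )
                if t.z != e.source:
                    raise ValueError(
                        f"edge {e.source}->{e.target} supported by a triple with z={t.z}"
                    )
            if e.layer_pair == "1->2":
                ok = e.source in self.layer1 and e.target in self.layer2
            elif e.layer_pair == "2->3":
                ok = e.source in self.layer2 and e.target in self.layer3
            else:
                raise ValueError(f"unknown layer pair {e.layer_pair!r}")
            if not ok:
                raise ValueError(
                    f"edge {e.source}->{e.target} endpoints disagree with "
                    f"layer pair {e.layer_pair}"
                )

    @property
    def edges_12(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges if e.layer_pair == "1->2"}

    @property
    def edges_23(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges if e.layer_pair == "2->3"}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        """Directed graph with per-node ``layer`` and per-edge correlation attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for layer_no, layer in ((1, self.layer1), (2, self.layer2), (3, self.layer3)):
            for node in sorted(layer):
                g.add_node(node, layer=layer_no)
        for e in sorted(self.edges, key=lambda e: (e.layer_pair, e.source, e.target)):
            g.add_edge(
                e.source, e.target,
                layer_pair=e.layer_pair,
                r_xy=float(e.best_r_xy),
                partial_r=float(e.best_partial),
                n_triples=len(e.triples),
            )
        return g


# ----------------------------------------------------------------------
# correlation primitives
# ----------------------------------------------------------------------
def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p-value from the t distribution.

    p is derived from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; |r| = 1 gives p = 0.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xv.size < 3:
        raise ValueError("need n >= 3 samples for a correlation p-value")
    if xv.std() == 0:
        raise ValueError("zero-variance input vector x")
    if yv.std() == 0:
        raise ValueError("zero-variance input vector y")
    res = stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy|z from the three pairwise r's.

    Symmetric in (r_xz, r_yz); clipped to [-1, 1] against floating-point
    overshoot.  Requires |r_xz| < 1 and |r_yz| < 1.
    """
    if abs(r_xz) >= 1 or abs(r_yz) >= 1:
        raise ValueError("degenerate conditioning variable (|r| = 1)")
    num = r_xy - r_xz * r_yz
    den = math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return float(min(1.0, max(-1.0, num / den)))


def _corr_matrix_with_p(values: np.ndarray, gene_ids: Sequence[str]):
    """Pairwise Pearson r and two-sided t-distribution p over matrix rows."""
    sds = values.std(axis=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance expression for genes: {[gene_ids[i] for i in zero]}"
        )
    n = values.shape[1]
    if n < 3:
        raise ValueError("need n >= 3 samples for correlation p-values")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return r, p


# ----------------------------------------------------------------------
# pair screening and regulator attribution
# ----------------------------------------------------------------------
def find_coexpressed_pairs(
    matrix: ExpressionMatrix,
    gene_set: Iterable[str],
    params: GRNParams = GRNParams(),
) -> list[tuple[str, str, float, float]]:
    """All unordered co-expressed pairs within ``gene_set``.

    A pair qualifies when r_xy >= r_min (|r_xy| >= r_min in absolute
    mode — both thresholds inclusive, within a 1e-12 floating-point
    tolerance so a correlation exactly at the cut is never dropped by a
    rounding artifact) and p_xy < p_max.  Each pair is reported once with
    x < y lexicographically.
    """
    genes = sorted(set(gene_set))
    if len(genes) < 2:
        raise ValueError("gene_set must contain at least two genes")
    values = matrix.submatrix(genes)
    r, p = _corr_matrix_with_p(values, genes)
    rr = np.abs(r) if params.use_absolute_r else r
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = (rr[iu, ju] >= params.r_min - 1e-12) & (p[iu, ju] < params.p_max)
    return [
        (genes[i], genes[j], float(r[i, j]), float(p[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    ]


def attribute_pairs_to_regulators(
    pairs: Sequence[tuple[str, str, float, float]],
    tf_ids: Iterable[str],
    matrix: ExpressionMatrix,
    params: GRNParams = GRNParams(),
) -> list[TripleTestResult]:
    """Test every (screened pair, candidate TF) combination.

    For each pair (x, y) and each z not in {x, y} the partial correlation
    r_xy|z is computed; the triple passes when |r_xy|z| <= partial_max.
    All combinations are returned (passing and failing); a pair may be
    explained by multiple TFs.  Degenerate conditioners (|r_xz| = 1) are
    skipped with a logged warning.
    """
    tfs = sorted(set(tf_ids))
    if not tfs or not pairs:
        return []
    pair_genes = sorted({g for x, y, _, _ in pairs for g in (x, y)})
    union = pair_genes + [z for z in tfs if z not in set(pair_genes)]
    idx = {g: i for i, g in enumerate(union)}
    values = matrix.submatrix(union)
    r, _ = _corr_matrix_with_p(values, union)

    results: list[TripleTestResult] = []
    n_degenerate = 0
    for x, y, r_xy, p_xy in pairs:
        xi, yi = idx[x], idx[y]
        for z in tfs:
            if z == x or z == y:
                continue
            zi = idx[z]
            r_xz, r_yz = float(r[xi, zi]), float(r[yi, zi])
            if abs(r_xz) >= _DEGENERATE_TOL or abs(r_yz) >= _DEGENERATE_TOL:
                n_degenerate += 1
                logger.warning(
                    "skipping degenerate conditioning TF %s for pair (%s, %s)", z, x, y
                )
                continue
            pc = partial_correlation(r_xy, r_xz, r_yz)
            results.append(
                TripleTestResult(
                    x=x, y=y, z=z,
                    r_xy=r_xy, p_xy=p_xy, r_xz=r_xz, r_yz=r_yz,
                    r_xy_given_z=pc,
                    passes=abs(pc) <= params.partial_max,
                )
            )
    if n_degenerate:
        logger.warning("%d degenerate triples skipped", n_degenerate)
    return results


def edges_from_triples(
    triples: Iterable[TripleTestResult],
) -> dict[tuple[str, str], list[TripleTestResult]]:
    """Materialize directed edges: each passing (x, y, z) yields z->x and z->y.

    Duplicate edges are merged, accumulating their supporting triples.
    """
    edges: dict[tuple[str, str], list[TripleTestResult]] = {}
    for t in triples:
        if not t.passes:
            raise ValueError(f"non-passing triple ({t.x}, {t.y}, {t.z}) in input")
        for target in (t.x, t.y):
            edges.setdefault((t.z, target), []).append(t)
    return edges


# ----------------------------------------------------------------------
# hierarchy assembly
# ----------------------------------------------------------------------
def assemble_three_layer_grn(
    matrix: ExpressionMatrix,
    tf_degs: Iterable[str],
    structural_degs: Iterable[str],
    params: GRNParams = GRNParams(),
) -> HierarchicalGRN:
    """Two-pass hierarchy construction.

    PASS A screens pairs among structural genes and attributes them to
    TFs; TFs acquiring >= 1 structural target form layer 2, their edges
    form 2->3, and structural genes with >= 1 incoming edge form layer 3.
    PASS B screens pairs among layer-2 TFs and attributes them to the
    remaining TFs; TFs acquiring >= 1 layer-2 target form layer 1.  TFs
    placed in neither layer are dropped (logged); layer-2 TFs without a
    layer-1 regulator are retained (logged).  When fewer than two TFs
    reach layer 2, PASS B is impossible and the result carries
    ``two_layer_warning=True``.
    """
    tf_set = set(tf_degs)
    struct_set = set(structural_degs)
    if not tf_set or not struct_set:
        raise ValueError("tf_degs and structural_degs must both be non-empty")
    if tf_set & struct_set:
        raise ValueError(f"TF and structural sets overlap: {sorted(tf_set & struct_set)}")

    # PASS A: structural pairs -> layer2 TFs and 2->3 edges
    pairs_a = (
        find_coexpressed_pairs(matrix, struct_set, params)
        if len(struct_set) >= 2 else []
    )
    triples_a = attribute_pairs_to_regulators(pairs_a, tf_set, matrix, params)
    passing_a = [t for t in triples_a if t.passes]
    edge_map_23 = edges_from_triples(passing_a)
    layer2 = {z for z, _ in edge_map_23}
    layer3 = {x for _, x in edge_map_23}
    logger.info(
        "PASS A: %d structural pairs, %d/%d passing triples, %d TFs -> layer2, "
        "%d structural genes -> layer3",
        len(pairs_a), len(passing_a), len(triples_a), len(layer2), len(layer3),
    )

    # PASS B: layer-2 pairs -> layer1 TFs and 1->2 edges
    edge_map_12: dict[tuple[str, str], list[TripleTestResult]] = {}
    two_layer_warning = False
    if len(layer2) < 2:
        two_layer_warning = True
        logger.warning(
            "PASS B impossible: only %d TF(s) reached layer 2; returning a "
            "two-layer network", len(layer2),
        )
    else:
        candidates = tf_set - layer2
        pairs_b = find_coexpressed_pairs(matrix, layer2, params)
        triples_b = attribute_pairs_to_regulators(pairs_b, candidates, matrix, params)
        passing_b = [t for t in triples_b if t.passes]
        edge_map_12 = edges_from_triples(passing_b)
        logger.info(
            "PASS B: %d layer-2 pairs, %d/%d passing triples, %d TFs -> layer1",
            len(pairs_b), len(passing_b), len(triples_b),
            len({z for z, _ in edge_map_12}),
        )
    layer1 = {z for z, _ in edge_map_12}

    dropped = tf_set - layer1 - layer2
    if dropped:
        logger.info("%d TFs placed in neither layer (dropped): %s",
                    len(dropped), sorted(dropped))
    orphan_l2 = layer2 - {t for _, t in edge_map_12}
    if not two_layer_warning and orphan_l2:
        logger.info("%d layer-2 TFs retained without a layer-1 regulator",
                    len(orphan_l2))

    edges = tuple(
        GRNEdge(source=s, target=t, layer_pair=pair, triples=tuple(tri))
        for pair, emap in (("1->2", edge_map_12), ("2->3", edge_map_23))
        for (s, t), tri in sorted(emap.items())
    )
    return HierarchicalGRN(
        layer1=frozenset(layer1),
        layer2=frozenset(layer2),
        layer3=frozenset(layer3),
        edges=edges,
        two_layer_warning=two_layer_warning,
        dropped_tfs=frozenset(dropped),
        unregulated_layer2=frozenset(orphan_l2),
    )


# ----------------------------------------------------------------------
# summary bookkeeping
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GRNSummary:
    """Layer sizes, per-layer-pair edge counts and GO composition of layer 3."""

    n_layer1: int
    n_layer2: int
    n_layer3: int
    n_edges_12: int
    n_edges_23: int
    total_edges: int
    go_composition: tuple[tuple[str, int, float], ...] = ()
    subset_terms: tuple[str, ...] = ()
    subset_count: int = 0
    subset_pct: float = float("nan")

    def to_dict(self) -> dict:
        subset_pct = None if math.isnan(self.subset_pct) else self.subset_pct
        return {
            "layer_sizes": [self.n_layer1, self.n_layer2, self.n_layer3],
            "edges_layer1_to_2": self.n_edges_12,
            "edges_layer2_to_3": self.n_edges_23,
            "total_edges": self.total_edges,
            "go_composition": [
                {"term": term, "count": count, "pct_of_layer3": pct}
                for term, count, pct in self.go_composition
            ],
            "subset_terms": list(self.subset_terms),
            "subset_count": self.subset_count,
            "subset_pct_of_layer3": subset_pct,
        }

    def to_text(self) -> str:
        lines = [
            "Hierarchical GRN summary",
            "------------------------",
            f"layer 1 (top TFs):        {self.n_layer1}",
            f"layer 2 (middle TFs):     {self.n_layer2}",
            f"layer 3 (structural):     {self.n_layer3}",
            f"edges layer1 -> layer2:   {self.n_edges_12}",
            f"edges layer2 -> layer3:   {self.n_edges_23}",
            f"total edges:              {self.total_edges}",
        ]
        if self.go_composition:
            lines.append("GO composition of layer 3:")
            for term, count, pct in self.go_composition:
                lines.append(f"  {term}: {count} ({pct}% of layer 3)")
        if self.subset_terms:
            lines.append(
                f"genes in subset {list(self.subset_terms)}: "
                f"{self.subset_count} ({self.subset_pct}% of layer 3)"
            )
        return "\n".join(lines)


def summarize_grn(
    grn: HierarchicalGRN,
    annotation: Mapping[str, set[str]] | None = None,
    go_terms: Sequence[str] | None = None,
    subset_terms: Sequence[str] | None = None,
) -> GRNSummary:
    """Bookkeeping over a built network.

    Per-GO-term counts and percentages cover layer-3 genes; percentages
    are of layer-3 size, rounded half-up to one decimal.  ``subset_terms``
    additionally reports the share of layer-3 genes annotated to *any*
    term of that subset.  An empty layer 3 yields NaN percentages.
    """
    n3 = len(grn.layer3)

    def pct(count: int) -> float:
        return round_half_up(100.0 * count / n3, 1) if n3 else float("nan")

    composition: list[tuple[str, int, float]] = []
    if annotation is not None:
        terms = list(go_terms) if go_terms is not None else sorted(
            {t for g in grn.layer3 for t in annotation.get(g, set())}
        )
        for term in terms:
            count = sum(1 for g in grn.layer3 if term in annotation.get(g, set()))
            composition.append((term, count, pct(count)))

    subset_count = 0
    subset_pct = float("nan")
    subset = tuple(subset_terms) if subset_terms else ()
    if subset and annotation is not None:
        sub = set(subset)
        subset_count = sum(
            1 for g in grn.layer3 if annotation.get(g, set()) & sub
        )
        subset_pct = pct(subset_count)

    n12, n23 = len(grn.edges_12), len(grn.edges_23)
    return GRNSummary(
        n_layer1=len(grn.layer1),
        n_layer2=len(grn.layer2),
        n_layer3=n3,
        n_edges_12=n12,
        n_edges_23=n23,
        total_edges=n12 + n23,
        go_composition=tuple(composition),
        subset_terms=subset,
        subset_count=subset_count,
        subset_pct=subset_pct,
    )


# ----------------------------------------------------------------------
# model / results surface
# ----------------------------------------------------------------------
class HierarchicalGRNModel:
    """Hierarchy-inference model over a time-course expression matrix.

    Parameters
    ----------
    expr
        Expression matrix (log2 values) containing every gene under test.
    tf_ids
        Candidate regulators (differentially expressed TFs).
    structural_ids
        Candidate bottom-layer genes (differentially expressed non-TFs).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        tf_ids: Iterable[str],
        structural_ids: Iterable[str],
    ):
        self.expr = expr
        self.tf_ids = sorted(set(tf_ids))
        self.structural_ids = sorted(set(structural_ids))
        if not self.tf_ids or not self.structural_ids:
            raise ValueError("tf_ids and structural_ids must both be non-empty")
        overlap = set(self.tf_ids) & set(self.structural_ids)
        if overlap:
            raise ValueError(f"TF and structural sets overlap: {sorted(overlap)}")
        missing = [g for g in self.tf_ids + self.structural_ids if g not in expr]
        if missing:
            raise ValueError(f"genes absent from expression matrix: {missing}")

    @classmethod
    def from_deg_table(
        cls,
        expr: ExpressionMatrix,
        deg_table: pd.DataFrame,
        tf_list: Iterable[str],
    ) -> "HierarchicalGRNModel":
        """Split the DEG union (genes significant at >= 1 time point) by TF membership."""
        from .deg import deg_union

        degs = deg_union(deg_table)
        tfs = set(tf_list)
        return cls(expr, degs & tfs, degs - tfs)

    def fit(
        self,
        r_min: float = 0.8,
        p_max: float = 0.001,
        partial_max: float = 0.3,
        use_absolute_r: bool = False,
        collapse_replicates: bool = False,
    ) -> "GRNResults":
        params = GRNParams(
            r_min=r_min, p_max=p_max, partial_max=partial_max,
            use_absolute_r=use_absolute_r,
        )
        matrix = self.expr.collapse_replicates() if collapse_replicates else self.expr
        network = assemble_three_layer_grn(
            matrix, self.tf_ids, self.structural_ids, params
        )
        return GRNResults(self, params, network)


class GRNResults:
    """Fit result: the inferred network plus the thresholds that produced it."""

    def __init__(self, model: HierarchicalGRNModel, params: GRNParams,
                 network: HierarchicalGRN):
        self.model = model
        self.params = params
        self.network = network

    def grn_summary(self, annotation=None, go_terms=None, subset_terms=None) -> GRNSummary:
        return summarize_grn(self.network, annotation, go_terms, subset_terms)

    def summary(self, annotation=None, go_terms=None, subset_terms=None) -> str:
        head = [
            "Hierarchical GRN inference",
            "==========================",
            f"samples: {self.model.expr.n_samples}   "
            f"candidate TFs: {len(self.model.tf_ids)}   "
            f"candidate structural genes: {len(self.model.structural_ids)}",
            f"thresholds: r_min={self.params.r_min}, p_max={self.params.p_max}, "
            f"partial_max={self.params.partial_max}, "
            f"absolute_r={self.params.use_absolute_r}",
        ]
        if self.network.two_layer_warning:
            head.append("WARNING: fewer than 2 layer-2 TFs; two-layer result only")
        body = self.grn_summary(annotation, go_terms, subset_terms).to_text()
        return "\n".join(head) + "\n\n" + body

    def score_against(self, planted) -> "RecoveryReport":  # noqa: F821
        from .simulate import score_recovery

        return score_recovery(planted, self.network)

    def to_networkx(self):
        return self.network.to_networkx()

    def write(self, path, fmt: str = "tsv") -> None:
        from .io import write_network

        write_network(self.network, fmt, path)
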