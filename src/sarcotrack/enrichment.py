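"""GO-term enrichment ratios and severity-annotated interaction networks.

The enrichment ratio of a GO term in a phenotypic class is the frequency
of the term among the class genes divided by its frequency in the entire
screened set:

    ratio = (k_class / n_class) / (K_universe / N_universe)

A ratio of 0 means the term is absent from the class; 1 means the class
mirrors the screened set; >1 means over-representation.  These are
descriptive ratios — no significance machinery is attached by default
(a hypergeometric p-value helper is available for the curious).

The interaction network is a multigraph of screened genes with edge kinds
``genetic``/``physical`` (self-loops allowed, duplicates collapsed per
endpoints-and-kind), node attributes for severity class, display colour
(Severe red, Intermediate orange, Weak blue) and functional group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "AnnotationSet",
    "SEVERITY_COLORS",
    "enrichment_ratio",
    "enrichment_table",
    "hypergeom_pvalue",
    "build_network",
    "export_graph",
    "import_graph",
]

SEVERITY_COLORS = {"Severe": "red", "Intermediate": "orange", "Weak": "blue"}
_DEFAULT_COLOR = "gray"

GRAPH_FORMATS = ("graphml", "tsv")


@dataclass(frozen=True)
class AnnotationSet:
    """Gene → GO-term annotations over a fixed screened universe.

    Genes with no annotation still belong to the universe (they were
    screened) and count in frequency denominators.
    """

    annotations: Mapping[str, frozenset[str]]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", tuple(self.universe))
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("universe contains duplicate genes")
        extra = set(self.annotations) - set(self.universe)
        if extra:
            raise ValueError(f"annotated genes outside the universe: {sorted(extra)[:5]}")

    def genes_with(self, term: str) -> set[str]:
        return {g for g, terms in self.annotations.items() if term in terms}


def enrichment_ratio(
    term: str, class_genes: Iterable[str], annotations: AnnotationSet
) -> float:
    """Class frequency of ``term`` over its universe frequency.

    Raises on an empty class, a class gene outside the universe, or a term
    absent from the whole universe (ratio undefined).
    """
    cls = set(class_genes)
    if not cls:
        raise ValueError("empty phenotypic class")
    if not cls <= set(annotations.universe):
        raise ValueError("class genes must be a subset of the universe")
    carriers = annotations.genes_with(term)
    if not carriers:
        raise ValueError(f"term {term!r} absent from the universe: ratio undefined")
    class_freq = len(cls & carriers) / len(cls)
    universe_freq = len(carriers) / len(annotations.universe)
    return class_freq / universe_freq


def enrichment_table(
    terms: Sequence[str],
    classes: Mapping[str, Iterable[str]],
    annotations: AnnotationSet,
) -> pd.DataFrame:
    """Term × class matrix of enrichment ratios.

    Undefined cells (term absent from the universe, or an empty class)
    carry NaN and a warning rather than aborting the whole table.
    """
    data: dict[str, list[float]] = {}
    for cls_name, genes in classes.items():
        col = []
        genes = list(genes)
        for term in terms:
            try:
                col.append(enrichment_ratio(term, genes, annotations))
            except ValueError as exc:
                warnings.warn(f"{term!r} × {cls_name!r}: {exc}", stacklevel=2)
                col.append(float("nan"))
        data[cls_name] = col
    return pd.DataFrame(data, index=list(terms))


def hypergeom_pvalue(
    term: str, class_genes: Iterable[str], annotations: AnnotationSet
) -> float:
    """Optional hypergeometric over-representation p-value for one cell."""
    from scipy import stats

    cls = set(class_genes)
    carriers = annotations.genes_with(term)
    k = len(cls & carriers)
    return float(
        stats.hypergeom.sf(k - 1, len(annotations.universe), len(carriers), len(cls))
    )


# ---------------------------------------------------------------------------
# interaction network


def build_network(
    severities: Mapping[str, str],
    edges: Iterable[tuple[str, str, str]],
    functional_groups: Mapping[str, str] | None = None,
) -> nx.MultiGraph:
    """Severity-annotated interaction multigraph.

    ``severities`` maps each screened gene to its phenotype class;
    ``edges`` are ``(gene, gene, kind)`` triples with kind ``genetic`` or
    ``physical``.  Edges touching unknown genes are dropped with a
    warning; duplicate edges collapse per (endpoints, kind); self-loops
    (a gene interacting with itself) are retained.
    """
    g = nx.MultiGraph()
    groups = functional_groups or {}
    for gene, severity in severities.items():
        g.add_node(
            gene,
            severity=severity,
            color=SEVERITY_COLORS.get(severity, _DEFAULT_COLOR),
            functional_group=groups.get(gene, ""),
        )
    for u, v, kind in edges:
        if u not in g or v not in g:
            warnings.warn(f"dropping edge ({u}, {v}, {kind}): unknown endpoint", stacklevel=2)
            continue
        key = (min(u, v), max(u, v), kind)
        g.add_edge(u, v, key=str(key), kind=kind)
    return g


def export_graph(graph: nx.MultiGraph, path: str, format: str = "graphml") -> None:
    """Serialise a network to GraphML or a TSV edge list.

    GraphML round-trips node and edge attributes; the TSV form is the bare
    ``gene<TAB>gene<TAB>kind`` edge list the pipeline also accepts as
    input.
    """
    if format not in GRAPH_FORMATS:
        raise ValueError(f"unknown format {format!r}; use one of {GRAPH_FORMATS}")
    if format == "graphml":
        nx.write_graphml(graph, path)
        return
    with open(path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('kind', '')}\n")


def import_graph(path: str, format: str = "graphml") -> nx.MultiGraph:
    """Read a network written by :func:`export_graph`."""
    if format not in GRAPH_FORMATS:
        raise ValueError(f"unknown format {format!r}; use one of {GRAPH_FORMATS}")
    if format == "graphml":
        return nx.MultiGraph(nx.read_graphml(path))
    g = nx.MultiGraph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v, kind = line.split("\t")
            key = (min(u, v), max(u, v), kind)
            g.add_edge(u, v, key=str(key), kind=kind)
    return g
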