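"""Per-miRNA GO-term enrichment and the overlap-coefficient term network.

Given a regulator→target table (filtered to experimentally validated or
high-confidence predictions) and a gene→GO-term annotation, each miRNA's
target set is tested for term enrichment with a right-tailed hypergeometric
(Fisher) test, optionally in the conservative EASE variant that decrements
the overlap cell by one.  Neuron/brain-related terms are selected by
keyword, pairwise overlap coefficients |A∩B| / min(|A|,|B|) of their target
sets are computed, and a term/miRNA graph is assembled: term-term edges
where the coefficient strictly exceeds 0.5, miRNA-term edges for each
retained enrichment.  The graph exports to SIF and GraphML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

CONFIDENCE_LEVELS = {"experimentally_validated", "high_confidence", "moderate"}
DEFAULT_CONFIDENCES = frozenset({"experimentally_validated", "high_confidence"})
BRAIN_KEYWORDS = ["neuro", "neuron", "brain", "synap", "axon", "dendrit", "glia"]


@dataclass(frozen=True)
class EnrichmentResult:
    mirna_id: str
    term_id: str
    term_name: str
    k: int  # overlap: targets annotated with the term
    n: int  # miRNA target-list size (within the universe)
    K: int  # term size (within the universe)
    N: int  # universe size
    p_fisher: float  # right-tailed hypergeometric P(X >= k)
    p_ease: float  # same tail with the overlap cell decremented


def filter_targets(
    table: pd.DataFrame,
    allowed: Iterable[str] = DEFAULT_CONFIDENCES,
) -> pd.DataFrame:
    """Keep records at the allowed confidence levels; deduplicate pairs.

    Expects columns ``mirna_id``, ``gene``, ``confidence`` (one of
    experimentally_validated / high_confidence / moderate).  Unknown
    confidence labels raise, listing the offenders.
    """
    allowed = set(allowed)
    seen = set(table["confidence"])
    unknown = sorted(seen - CONFIDENCE_LEVELS)
    if unknown:
        raise ValueError(f"unknown confidence label(s): {unknown}")
    kept = table[table["confidence"].isin(allowed)]
    return kept.drop_duplicates(subset=["mirna_id", "gene"]).reset_index(drop=True)


def _tail(k: int, N: int, K: int, n: int) -> float:
    """Right tail P(X >= k) of Hypergeom(N, K, n); k <= 0 gives 1."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    targets: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str] | None = None,
    p_cut: float = 0.05,
    term_names: Mapping[str, str] | None = None,
    mirna_id: str = "",
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment for one miRNA's target set.

    ``annotation`` maps term_id -> set of genes.  The universe defaults to
    the union of all annotated genes; terms with no gene in the universe are
    skipped with a warning, and only terms with k >= 1 and p_fisher < p_cut
    are returned.  The EASE score repeats the tail with k-1 successes
    against unchanged margins, so p_ease >= p_fisher always.
    """
    universe = set(universe) if universe is not None else set().union(*annotation.values(), set())
    targets = set(targets) & universe
    names = term_names or {}
    N, n = len(universe), len(targets)
    results = []
    for term_id, genes in annotation.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            warnings.warn(f"term {term_id} has no genes in the universe; skipped", stacklevel=2)
            continue
        k = len(targets & term_genes)
        if k < 1:
            continue
        p = _tail(k, N, K, n)
        if p < p_cut:
            results.append(
                EnrichmentResult(
                    mirna_id=mirna_id,
                    term_id=term_id,
                    term_name=names.get(term_id, term_id),
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    p_fisher=p,
                    p_ease=_tail(k - 1, N, K, n),
                )
            )
    results.sort(key=lambda r: (r.p_fisher, r.term_id))
    return results


def select_brain_terms(
    results: Sequence[EnrichmentResult],
    keywords: Sequence[str] = tuple(BRAIN_KEYWORDS),
) -> list[EnrichmentResult]:
    """Case-insensitive keyword filter on term names."""
    if not keywords:
        raise ValueError("keyword list must not be empty")
    lowered = [k.lower() for k in keywords]
    return [r for r in results if any(k in r.term_name.lower() for k in lowered)]


def overlap_coefficient(set_a: Iterable, set_b: Iterable) -> float:
    """|A∩B| / min(|A|, |B|); undefined (None, warned) for empty sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        warnings.warn("overlap coefficient undefined for an empty set", stacklevel=2)
        return None
    return len(a & b) / min(len(a), len(b))


def build_network(
    results: Sequence[EnrichmentResult],
    term_targets: Mapping[str, set[str]],
    mirna_directions: Mapping[str, str],
    oc_cut: float = 0.5,
    group_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Assemble the term/miRNA graph.

    Term nodes carry name, functional group (from the supplied term→group
    map) and size = number of predicted miRNA targets in the term; miRNA
    nodes carry their direction of change.  Term-term edges require an
    overlap coefficient strictly greater than ``oc_cut``; each retained
    enrichment contributes one miRNA-term edge.
    """
    group_map = group_map or {}
    g = nx.Graph()
    terms = sorted({r.term_id for r in results})
    for t in terms:
        if t not in term_targets:
            raise KeyError(f"no target set supplied for enriched term {t}")
        name = next(r.term_name for r in results if r.term_id == t)
        g.add_node(
            t,
            kind="term",
            name=name,
            group=group_map.get(t, ""),
            size=len(term_targets[t]),
        )
    for r in results:
        if r.mirna_id not in g:
            g.add_node(r.mirna_id, kind="mirna", direction=mirna_directions.get(r.mirna_id, ""))
        g.add_edge(r.mirna_id, r.term_id, relation="mirna_term", p=r.p_fisher)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1 :]:
            oc = overlap_coefficient(term_targets[t1], term_targets[t2])
            if oc is not None and oc > oc_cut:
                g.add_edge(t1, t2, relation="term_term", weight=oc)
    return g


def export_network(g: nx.Graph, sif_path, graphml_path) -> None:
    """Write the graph as SIF (canonically sorted) and GraphML.

    The SIF line format is ``source<TAB>relation<TAB>target`` with one edge
    per line; GraphML keeps all node and edge attributes, so reading it back
    reproduces the graph isomorphically.
    """
    lines = sorted(
        f"{min(u, v)}\t{d['relation']}\t{max(u, v)}" for u, v, d in g.edges(data=True)
    )
    try:
        with open(sif_path, "w") as fh:
            for node in sorted(n for n in g.nodes if g.degree(n) == 0):
                fh.write(f"{node}\n")
            fh.write("\n".join(lines) + ("\n" if lines else ""))
        nx.write_graphml(g, graphml_path)
    except OSError as exc:
        raise OSError(f"failed to export network near {sif_path!s} / {graphml_path!s}: {exc}") from exc


def import_graphml(graphml_path) -> nx.Graph:
    return nx.read_graphml(graphml_path)


def enrich_all(
    target_table: pd.DataFrame,
    annotation: Mapping[str, set[str]],
    universe: Iterable[str] | None = None,
    p_cut: float = 0.05,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Run per-miRNA enrichment over every miRNA in a filtered target table."""
    results: list[EnrichmentResult] = []
    for mirna_id, sub in target_table.groupby("mirna_id"):
        results += enrich_terms(
            sub["gene"], annotation, universe, p_cut, term_names, mirna_id=str(mirna_id)
        )
    return results
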