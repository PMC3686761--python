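"""GO-slim categorization and binomial overrepresentation testing.

Gene lists are mapped to high-level GO terms by climbing is_a edges of the
ontology (slim mapping), and candidate gene sets are tested for category
overrepresentation against a reference list with a one-sided binomial test:
under the null, each of the n_category reference genes in a category is a
candidate with probability q = |candidates| / |reference|, so

    p_raw = sum_{k = observed}^{n_category} C(n_category, k) q^k (1-q)^(n-k)

Bonferroni correction multiplies p_raw by the number of categories tested
(those with at least one annotated reference gene), capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GODag:
    """Gene Ontology DAG restricted to the relations the mapping traverses.

    `parents` maps each term to its direct is_a parents (part_of edges are
    included only when the DAG was loaded with include_part_of=True). The
    graph must be acyclic and every referenced parent must exist.
    """

    parents: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parents = {t: frozenset(ps) for t, ps in self.parents.items()}
        dangling = {
            p for ps in self.parents.values() for p in ps if p not in self.parents
        }
        if dangling:
            raise ValueError(f"parents referenced but not defined: {sorted(dangling)}")
        graph = nx.DiGraph(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        graph.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("GO graph contains a cycle")
        self._graph = graph
        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def _ancestors_uncached(self, term: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._graph, term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of `term`, excluding the term itself."""
        if term not in self.parents:
            raise KeyError(term)
        return self._ancestors(term)

    @classmethod
    def from_obo(cls, path: str, include_part_of: bool = False) -> "GODag":
        import obonet

        graph = obonet.read_obo(path)
        relations = {"is_a"} | ({"part_of"} if include_part_of else set())
        parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
        names = {
            t: data.get("name", "") for t, data in graph.nodes(data=True)
        }
        for child, parent, key in graph.edges(keys=True):
            if key in relations:
                parents[child].add(parent)
        return cls(parents={t: frozenset(ps) for t, ps in parents.items()}, names=names)

    @classmethod
    def flat(cls, terms, names: dict[str, str] | None = None) -> "GODag":
        """Parent-less DAG over `terms` (annotation terms used directly)."""
        return cls(parents={t: frozenset() for t in terms}, names=names or {})


def _gene_slim_terms(
    terms: set[str], dag: GODag, slim: set[str]
) -> set[str]:
    hits: set[str] = set()
    for t in terms:
        if t not in dag:
            logger.warning("annotation term %s not in DAG; skipped", t)
            continue
        if t in slim:
            hits.add(t)
        hits |= dag.ancestors(t) & slim
    return hits


def map_to_slim_counts(
    annotations: dict[str, set[str]], dag: GODag, slim: set[str]
) -> dict[str, int]:
    """Gene-hit count per slim term via ancestor closure.

    A gene hits a slim term when one of its annotated terms equals the slim
    term or has it among its is_a ancestors; each (gene, term) pair counts
    once regardless of how many annotation paths reach it.
    """
    unknown = slim - set(dag.parents)
    if unknown:
        raise ValueError(f"slim terms not in DAG: {sorted(unknown)}")
    counts = dict.fromkeys(sorted(slim), 0)
    for terms in annotations.values():
        for s in _gene_slim_terms(terms, dag, slim):
            counts[s] += 1
    return {s: c for s, c in counts.items() if c or s in slim}


def binomial_enrichment(
    psg: set[str],
    reference: set[str],
    annotations: dict[str, set[str]],
    dag: GODag,
    categories,
    *,
    alpha: float = 0.05,
    direction: str = "over",
) -> pd.DataFrame:
    """Binomial category enrichment of a candidate set against a reference.

    Unannotated genes stay in both denominators (whole-list fractions). A
    category with no annotated reference gene is excluded and does not count
    toward the Bonferroni factor m; m is recorded in ``result.attrs["m"]``.
    Rows are sorted by corrected p-value then category id. `direction` is
    "over" (default) or "under" for the opposite one-sided test.
    """
    psg, reference = set(psg), set(reference)
    stray = psg - reference
    if stray:
        raise ValueError(f"candidate genes not in reference: {sorted(stray)[:5]}")
    if not reference:
        raise ValueError("empty reference set")
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    q = len(psg) / len(reference)
    member_cache: dict[str, set[str]] = {}
    for gene in reference:
        terms = annotations.get(gene, set())
        closure = _gene_slim_terms(terms, dag, set(categories))
        for cat in closure:
            member_cache.setdefault(cat, set()).add(gene)
    rows = []
    for cat in categories:
        members = member_cache.get(cat, set())
        n_cat = len(members)
        if n_cat == 0:
            continue
        observed = len(members & psg)
        if direction == "over":
            p_raw = float(stats.binom.sf(observed - 1, n_cat, q))
        else:
            p_raw = float(stats.binom.cdf(observed, n_cat, q))
        rows.append(
            {
                "category": cat,
                "name": dag.names.get(cat, ""),
                "n_category": n_cat,
                "observed": observed,
                "expected": n_cat * q,
                "p_raw": min(p_raw, 1.0),
            }
        )
    m = len(rows)
    for row in rows:
        row["p_bonferroni"] = min(1.0, m * row["p_raw"])
        row["significant"] = row["p_bonferroni"] < alpha
    result = pd.DataFrame(
        rows,
        columns=[
            "category",
            "name",
            "n_category",
            "observed",
            "expected",
            "p_raw",
            "p_bonferroni",
            "significant",
        ],
    )
    if m:
        result = result.sort_values(
            ["p_bonferroni", "category"], kind="stable"
        ).reset_index(drop=True)
    result.attrs["m"] = m
    return result


def read_annotations(path: str) -> dict[str, set[str]]:
    """Read a gene -> GO TSV (gene id, semicolon- or tab-separated terms)."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0]
            terms = set()
            for fieldval in parts[1:]:
                terms.update(t for t in fieldval.split(";") if t)
            annotations.setdefault(gene, set()).update(terms)
    return annotations


def write_enrichment_table(result: pd.DataFrame, path: str) -> None:
    """TSV mirroring the enrichment table, with the Bonferroni m in a header."""
    with open(path, "w") as fh:
        fh.write(f"# categories_tested_m={result.attrs.get('m', len(result))}\n")
        result.to_csv(fh, sep="\t", index=False, float_format="%.6g")
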