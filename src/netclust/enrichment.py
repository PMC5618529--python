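"""GO over-representation analysis in the BiNGO style.

Given a study set of genes (a pasted list, a file, or the members of a
detected cluster), a GO ontology (full GO or a GOSlim, in OBO format) and a
gene→term annotation, the analysis propagates annotations upward through the
is_a / part_of hierarchy, and tests every term annotating at least one study
gene for over-representation against a reference set, with either the
hypergeometric or the binomial upper-tail test and Bonferroni /
Benjamini–Hochberg multiple-testing correction.

Counts follow the standard 2×2 notation: k study genes carry the term, the
study has n annotated genes, K reference genes carry the term, the reference
has N annotated genes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import obonet
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationMap",
    "EnrichParams",
    "EnrichmentRow",
    "load_obo",
    "read_gaf",
    "propagate",
    "hypergeom_p",
    "binom_p",
    "adjust",
    "enrich",
    "write_enrichment",
]

_PROPAGATING_RELATIONS = ("is_a", "part_of")


class OntologyDAG:
    """A GO-style term hierarchy: terms plus typed child→parent links.

    Only is_a and part_of links participate in annotation propagation; other
    relation types are ignored with a warning. The link structure must be
    acyclic.
    """

    def __init__(
        self,
        terms: Mapping[str, tuple[str, str]],
        links: Iterable[tuple[str, str, str]],
    ):
        """``terms`` maps term ID → (name, namespace); ``links`` are
        (child, parent, relation) triples."""
        self.terms: dict[str, tuple[str, str]] = {
            t: (str(name), str(ns)) for t, (name, ns) in terms.items()
        }
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        skipped = 0
        for child, parent, rel in links:
            if rel not in _PROPAGATING_RELATIONS:
                skipped += 1
                continue
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"link ({child}, {parent}) references an unknown term")
            g.add_edge(child, parent)
        if skipped:
            logger.warning("ignored %d link(s) of non-propagating relation types", skipped)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology links contain a cycle")
        self._g = g

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def name(self, term: str) -> str:
        return self.terms[term][0]

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a/part_of ancestors of a term (excluding itself)."""
        return frozenset(nx.descendants(self._g, term))

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._g.successors(term))


def load_obo(path: Union[str, os.PathLike]) -> OntologyDAG:
    """Load an OBO 1.2 ontology (full GO or GOSlim) into an OntologyDAG."""
    g = obonet.read_obo(os.fspath(path))
    terms = {
        t: (data.get("name", t), data.get("namespace", ""))
        for t, data in g.nodes(data=True)
    }
    links = [(child, parent, rel) for child, parent, rel in g.edges(keys=True)]
    return OntologyDAG(terms, links)


def read_gaf(
    path: Union[str, os.PathLike], *, gene_column: int = 1, term_column: int = 4
) -> dict[str, frozenset[str]]:
    """Read a GAF-style tab-delimited annotation file into gene → term sets.

    Comment lines starting with '!' are skipped. Column indices are 0-based
    and default to the GAF 2.x DB-Object-ID and GO-ID columns.
    """
    direct: dict[str, set[str]] = {}
    need = max(gene_column, term_column) + 1
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < need:
                continue
            gene = fields[gene_column].strip()
            term = fields[term_column].strip()
            if gene and term:
                direct.setdefault(gene, set()).add(term)
    return {g: frozenset(ts) for g, ts in direct.items()}


def propagate(
    dag: OntologyDAG, direct: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Close each gene's annotation upward over is_a/part_of ancestors.

    Terms absent from the ontology are dropped with a logged warning.
    """
    ancestor_cache: dict[str, frozenset[str]] = {}
    unknown: set[str] = set()
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag:
                unknown.add(t)
                continue
            closed.add(t)
            if t not in ancestor_cache:
                ancestor_cache[t] = dag.ancestors(t)
            closed.update(ancestor_cache[t])
        out[gene] = frozenset(closed)
    if unknown:
        logger.warning("dropped %d annotation term(s) not in the ontology", len(unknown))
    return out


@dataclass
class AnnotationMap:
    """Direct and upward-propagated gene → term annotations."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]

    @classmethod
    def build(cls, dag: OntologyDAG, direct: Mapping[str, Iterable[str]]) -> "AnnotationMap":
        d = {g: frozenset(ts) for g, ts in direct.items()}
        return cls(d, propagate(dag, d))


def _check_counts(k: int, n: int, K_ref: int, N_ref: int) -> None:
    if not (0 <= k <= n <= N_ref):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k} n={n} N={N_ref}")
    if not (0 <= K_ref <= N_ref):
        raise ValueError(f"need 0 <= K <= N, got K={K_ref} N={N_ref}")
    if k > K_ref:
        raise ValueError(f"k={k} exceeds K={K_ref}")


def hypergeom_p(k: int, n: int, K_ref: int, N_ref: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N_ref, K_ref, n)."""
    _check_counts(k, n, K_ref, N_ref)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N_ref, K_ref, n))


def binom_p(k: int, n: int, K_ref: int, N_ref: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Binomial(n, K_ref / N_ref)."""
    _check_counts(k, n, K_ref, N_ref)
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, K_ref / N_ref))


def adjust(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment: 'bonferroni', 'bh' (Benjamini–Hochberg
    step-up), or 'none'. Output order matches input order."""
    ps = list(p_values)
    if not ps:
        return []
    if any(not 0 < p <= 1 for p in ps):
        raise ValueError("p-values must be in (0, 1]")
    if method == "none":
        return ps
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown correction method {method!r}")
    return list(multipletests(ps, method=sm_method)[1])


_TESTS = {"hypergeometric": hypergeom_p, "binomial": binom_p}


@dataclass
class EnrichParams:
    """Over-representation settings: test, correction, significance level,
    optional custom reference gene set, and whether to keep all rows."""

    test: str = "hypergeometric"
    correction: str = "bh"
    alpha: float = 0.05
    reference: frozenset[str] | None = None
    all_rows: bool = False

    def __post_init__(self):
        if self.test not in _TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if self.correction not in ("bonferroni", "bh", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term: counts, raw and adjusted p, and the study genes."""

    term: str
    name: str
    k: int
    n: int
    K_ref: int
    N_ref: int
    p: float
    p_adj: float
    genes: tuple[str, ...]


def enrich(
    study: Iterable[str],
    dag: OntologyDAG,
    annotations: AnnotationMap,
    params: EnrichParams | None = None,
) -> list[EnrichmentRow]:
    """Test every term annotating ≥ 1 study gene for over-representation.

    Study genes missing from the annotated reference are dropped (logged).
    Rows with adjusted p ≤ alpha are returned sorted by raw p ascending
    (all rows when ``params.all_rows``).
    """
    params = params or EnrichParams()
    prop = annotations.propagated
    if params.reference is None:
        reference = set(prop)
    else:
        reference = set(params.reference) & set(prop)
    if not reference:
        raise ValueError("reference set contains no annotated genes")
    study_kept: list[str] = []
    seen: set[str] = set()
    dropped = 0
    for g in study:
        if g in seen:
            continue
        seen.add(g)
        if g in reference:
            study_kept.append(g)
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d study gene(s) absent from the annotated reference", dropped)
    if not study_kept:
        raise ValueError("no study gene is present in the annotated reference")

    n = len(study_kept)
    big_n = len(reference)
    term_genes: dict[str, list[str]] = {}
    for g in study_kept:
        for t in prop.get(g, ()):
            term_genes.setdefault(t, []).append(g)
    ref_counts: dict[str, int] = {}
    for g in reference:
        for t in prop.get(g, ()):
            ref_counts[t] = ref_counts.get(t, 0) + 1

    test = _TESTS[params.test]
    tested = sorted(term_genes)
    # clamp to the open-unit interval: scipy tail sums can underflow to 0
    raw = [
        min(max(test(len(term_genes[t]), n, ref_counts[t], big_n), 5e-324), 1.0)
        for t in tested
    ]
    adjusted = adjust(raw, params.correction)
    rows = [
        EnrichmentRow(
            term=t,
            name=dag.name(t) if t in dag else t,
            k=len(term_genes[t]),
            n=n,
            K_ref=ref_counts[t],
            N_ref=big_n,
            p=raw[i],
            p_adj=float(adjusted[i]),
            genes=tuple(sorted(term_genes[t])),
        )
        for i, t in enumerate(tested)
    ]
    if not params.all_rows:
        rows = [r for r in rows if r.p_adj <= params.alpha]
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def write_enrichment(rows: Sequence[EnrichmentRow], path: Union[str, os.PathLike]) -> None:
    """Write enrichment rows as a tab-delimited table."""
    header = "GO-ID\tname\tk\tn\tK\tN\tp\tp_adj\tgenes"
    lines = [header]
    for r in rows:
        lines.append(
            "\t".join(
                (
                    r.term,
                    r.name,
                    str(r.k),
                    str(r.n),
                    str(r.K_ref),
                    str(r.N_ref),
                    f"{r.p:.6e}",
                    f"{r.p_adj:.6e}",
                    ",".join(r.genes),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
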