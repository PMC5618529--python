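"""Synthetic PPI-like networks with planted complexes, and match statistics.

The generator realises each planted complex as a dense Erdős–Rényi block
(edge probability ``p_in``) over its member nodes, optionally sharing
``overlap_nodes`` members between consecutive complexes, and overlays a
sparse Erdős–Rényi background (``p_out``) across all node pairs. Edge
weights are either unit (deterministic networks) or drawn uniformly from
(0.5, 1) to emulate interaction-probability data for uncertain-graph
methods. Everything is driven by numpy's default PRNG (PCG64) under an
explicit seed, so fixtures are reproducible across platforms.

``match`` scores a clustering against the planted ground truth with the
Jaccard coefficient, the standard recovery measure in complex-detection
benchmarks. ``toy_ontology`` builds a small GO-like hierarchy with one
deliberately over-represented term for end-to-end enrichment checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .enrichment import AnnotationMap, OntologyDAG
from .graph_core import ClusteringResult, Network, UncertainNetwork

__all__ = [
    "PlantedNetworkSpec",
    "GroundTruth",
    "MatchReport",
    "generate",
    "match",
    "jaccard",
    "toy_ontology",
    "write_ground_truth",
    "read_ground_truth",
    "ontology_to_obo_text",
    "annotations_to_gaf_text",
]


@dataclass
class PlantedNetworkSpec:
    """Description of a planted-complex benchmark network.

    n_background: number of pure-background nodes added around the complexes.
    complex_sizes: sizes (≥ 3) of the planted dense blocks.
    p_in / p_out: intra-complex and background edge probabilities, p_in > p_out.
    overlap_nodes: members shared between consecutive complexes.
    weight_mode: "unit" for weight-1 edges, "uniform" for U(0.5, 1) edge
    probabilities (uncertain-graph fixtures).
    """

    n_background: int = 60
    complex_sizes: Sequence[int] = (8, 8, 8, 8, 8)
    p_in: float = 0.9
    p_out: float = 0.02
    overlap_nodes: int = 0
    weight_mode: str = "unit"
    seed: int = 0

    def __post_init__(self):
        if any(s < 3 for s in self.complex_sizes):
            raise ValueError("complex sizes must be >= 3")
        if not 0 < self.p_in <= 1 or not 0 <= self.p_out <= 1:
            raise ValueError("probabilities must lie in [0, 1] (p_in > 0)")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.overlap_nodes < 0:
            raise ValueError("overlap_nodes must be >= 0")
        if self.overlap_nodes and any(
            self.overlap_nodes >= s for s in self.complex_sizes
        ):
            raise ValueError("overlap_nodes must be smaller than every complex")
        if self.weight_mode not in ("unit", "uniform"):
            raise ValueError("weight_mode must be 'unit' or 'uniform'")


@dataclass
class GroundTruth:
    """The planted complexes: a list of member sets."""

    complexes: list[frozenset[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass
class MatchReport:
    """Recovery statistics of a clustering against planted complexes."""

    best_jaccard: list[float]
    n_recovered: int
    precision: float
    recall: float
    f_measure: float


def generate(spec: PlantedNetworkSpec) -> tuple[Network, GroundTruth]:
    """Generate a planted-complex network; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    complexes: list[list[str]] = []
    counter = 0
    prev_tail: list[str] = []
    for ci, size in enumerate(spec.complex_sizes):
        shared = prev_tail[: spec.overlap_nodes] if ci > 0 else []
        fresh = [f"c{counter + j:03d}" for j in range(size - len(shared))]
        counter += len(fresh)
        members = shared + fresh
        complexes.append(members)
        prev_tail = fresh[::-1]  # share the newest nodes with the next block
    background = [f"b{j:03d}" for j in range(spec.n_background)]
    all_nodes = sorted({n for c in complexes for n in c} | set(background))

    intra: set[tuple[str, str]] = set()
    for members in complexes:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = sorted((members[i], members[j]))
                intra.add((a, b))

    edges: list[tuple[str, str, float]] = []
    for i in range(len(all_nodes)):
        for j in range(i + 1, len(all_nodes)):
            pair = (all_nodes[i], all_nodes[j])
            p = spec.p_in if pair in intra else spec.p_out
            if rng.random() < p:
                edges.append((pair[0], pair[1], 1.0))
    if spec.weight_mode == "uniform":
        weights = rng.uniform(0.5, 1.0, size=len(edges))
        edges = [(u, v, float(w)) for (u, v, _), w in zip(edges, weights)]
        net: Network = UncertainNetwork(edges, nodes=all_nodes)
    else:
        net = Network(edges, nodes=all_nodes)
    truth = GroundTruth([frozenset(c) for c in complexes])
    return net, truth


def jaccard(a, b) -> float:
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def match(
    found: ClusteringResult | Sequence[frozenset[str]],
    truth: GroundTruth,
    jaccard_threshold: float = 0.5,
) -> MatchReport:
    """Score found clusters against planted complexes.

    A planted complex is recovered when some found cluster reaches the
    Jaccard threshold with it; precision is the fraction of found clusters
    matching some planted complex at the threshold, recall the fraction of
    planted complexes recovered, F their harmonic mean.
    """
    if not 0 < jaccard_threshold <= 1:
        raise ValueError("jaccard_threshold must be in (0, 1]")
    if not truth.complexes:
        raise ValueError("ground truth is empty")
    sets = found.member_sets() if isinstance(found, ClusteringResult) else list(found)
    best = [max((jaccard(t, f) for f in sets), default=0.0) for t in truth.complexes]
    recovered = sum(1 for b in best if b >= jaccard_threshold)
    recall = recovered / len(truth.complexes)
    if sets:
        matched_found = sum(
            1
            for f in sets
            if max(jaccard(t, f) for t in truth.complexes) >= jaccard_threshold
        )
        precision = matched_found / len(sets)
    else:
        precision = 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return MatchReport(best, recovered, precision, recall, f)


def write_ground_truth(truth: GroundTruth, path: Union[str, os.PathLike]) -> None:
    """One planted complex per line, comma-separated sorted member IDs."""
    lines = [",".join(sorted(c)) for c in truth.complexes]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ground_truth(path: Union[str, os.PathLike]) -> GroundTruth:
    complexes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            complexes.append(frozenset(line.strip().split(",")))
    return GroundTruth(complexes)


# -- enrichment fixture ---------------------------------------------------


def toy_ontology(seed: int = 0) -> tuple[OntologyDAG, AnnotationMap, list[str]]:
    """A small three-level ontology, ~1000 annotated genes, and a study set
    drawn from one deliberately over-represented leaf term.

    Returns (dag, annotations, study_genes). The planted term is the first
    leaf ("T:0200"); the first 30 genes are all annotated to it and the
    20-gene study set is sampled from them, so the planted term's study
    frequency k/n far exceeds its reference frequency K/N.
    """
    rng = np.random.default_rng(seed)
    root = "T:0000"
    mids = [f"T:01{i:02d}" for i in range(4)]
    leaves = [f"T:02{i:02d}" for i in range(16)]
    terms = {root: ("cellular process", "biological_process")}
    links: list[tuple[str, str, str]] = []
    for m in mids:
        terms[m] = (f"mid-level process {m}", "biological_process")
        links.append((m, root, "is_a"))
    for i, leaf in enumerate(leaves):
        terms[leaf] = (f"leaf process {leaf}", "biological_process")
        # mix is_a and part_of parentage across the mid level
        rel = "is_a" if i % 2 == 0 else "part_of"
        links.append((leaf, mids[i % 4], rel))
    dag = OntologyDAG(terms, links)

    planted = leaves[0]
    genes = [f"g{i:04d}" for i in range(1000)]
    direct: dict[str, set[str]] = {}
    other_leaves = leaves[1:]
    for i, g in enumerate(genes):
        n_terms = int(rng.integers(1, 4))
        picks = rng.choice(len(other_leaves), size=n_terms, replace=False)
        direct[g] = {other_leaves[int(j)] for j in picks}
        if i < 30:
            direct[g].add(planted)
    study_idx = rng.choice(30, size=20, replace=False)
    study = sorted(f"g{int(i):04d}" for i in study_idx)
    return dag, AnnotationMap.build(dag, direct), study


def ontology_to_obo_text(dag: OntologyDAG) -> str:
    """Serialise an OntologyDAG as minimal OBO 1.2 text."""
    blocks = ["format-version: 1.2"]
    for term in sorted(dag.terms):
        name, ns = dag.terms[term]
        lines = [f"[Term]", f"id: {term}", f"name: {name}"]
        if ns:
            lines.append(f"namespace: {ns}")
        for parent in sorted(dag.parents(term)):
            lines.append(f"is_a: {parent}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def annotations_to_gaf_text(annotations: AnnotationMap) -> str:
    """Serialise direct annotations as GAF-style rows (gene in column 2,
    term in column 5, 1-based)."""
    lines = ["!gaf-version: 2.1"]
    for gene in sorted(annotations.direct):
        for term in sorted(annotations.direct[gene]):
            lines.append("\t".join(("DB", gene, gene, "", term, "", "", "", "")))
    return "\n".join(lines) + "\n"
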