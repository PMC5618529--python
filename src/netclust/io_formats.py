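"""Readers and writers: edge lists, SIF, gene lists, and the cluster result file."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from .graph_core import Cluster, ClusteringResult, Network, UncertainNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "EdgeListDialect",
    "read_network",
    "read_sif",
    "write_clusters",
    "read_clusters",
    "read_gene_list",
    "parse_gene_list",
]


class ParseError(ValueError):
    """Malformed input file content, with a line number where possible."""


@dataclass
class EdgeListDialect:
    """How to interpret a delimited edge-list file.

    delimiter: field separator ("\\t" or ",").
    has_header: skip the first line.
    weight_column: 0-based column holding positive edge weights; None means
    the network is unweighted (all weights 1.0).
    """

    delimiter: str = "\t"
    has_header: bool = False
    weight_column: int | None = None


def _dialect_for(path: Path, dialect: EdgeListDialect | None) -> EdgeListDialect:
    if dialect is not None:
        return dialect
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    return EdgeListDialect(delimiter=delim)


def read_network(
    path: Union[str, os.PathLike],
    dialect: EdgeListDialect | None = None,
    *,
    uncertain: bool = False,
) -> Network:
    """Read a simple undirected network from a delimited edge-list file.

    Self-loops are dropped and duplicate edges collapsed keeping the maximum
    weight, each with a logged warning. Without a weight column every edge
    gets weight 1.0. With ``uncertain=True`` the result is an
    :class:`UncertainNetwork` and weights must lie in (0, 1].
    """
    p = Path(path)
    dia = _dialect_for(p, dialect)
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    n_loops = n_dups = 0
    with open(p, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if dia.has_header and lineno == 1:
                continue
            line = raw.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(dia.delimiter)]
            if len(fields) < 2:
                raise ParseError(f"{p.name}:{lineno}: expected >= 2 columns, got {len(fields)}")
            u, v = fields[0], fields[1]
            if not u or not v:
                raise ParseError(f"{p.name}:{lineno}: empty node identifier")
            w = 1.0
            if dia.weight_column is not None:
                if dia.weight_column >= len(fields):
                    raise ParseError(
                        f"{p.name}:{lineno}: weight column {dia.weight_column} missing"
                    )
                try:
                    w = float(fields[dia.weight_column])
                except ValueError:
                    raise ParseError(
                        f"{p.name}:{lineno}: bad weight {fields[dia.weight_column]!r}"
                    ) from None
                if not w > 0:
                    raise ValueError(f"{p.name}:{lineno}: non-positive weight {w}")
            nodes.update((u, v))
            if u == v:
                n_loops += 1
                continue
            key = (min(u, v), max(u, v))
            if key in edges:
                n_dups += 1
                edges[key] = max(edges[key], w)
            else:
                edges[key] = w
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", p.name, n_loops)
    if n_dups:
        logger.warning("%s: collapsed %d duplicate edge(s), keeping max weight", p.name, n_dups)
    cls = UncertainNetwork if uncertain else Network
    net = cls(((u, v, w) for (u, v), w in edges.items()), nodes=nodes)
    logger.info("%s: %d nodes, %d edges", p.name, net.number_of_nodes(), net.number_of_edges())
    return net


def read_sif(path: Union[str, os.PathLike]) -> Network:
    """Read a SIF file: ``source interaction target [target ...]``.

    The interaction type is ignored; a single-field row declares an isolated
    node. Edges are unweighted.
    """
    p = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_loops = 0
    with open(p, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) == 1:
                nodes.add(fields[0])
                continue
            if len(fields) == 2:
                raise ParseError(
                    f"{p.name}:{lineno}: SIF rows need 1 field or >= 3 fields, got 2"
                )
            src = fields[0]
            nodes.add(src)
            for tgt in fields[2:]:
                nodes.add(tgt)
                if tgt == src:
                    n_loops += 1
                    continue
                edges.add((min(src, tgt), max(src, tgt)))
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", p.name, n_loops)
    return Network(edges, nodes=nodes)


# -- cluster result file --------------------------------------------------
#
# Header block: one "# key = value" line per entry, the first being the
# algorithm name; body: one cluster per line with tab-delimited columns
# rank, size, density, score, modularity, comma-separated sorted members.

_FLOAT_FMT = "{:.6f}"


def _format_param(value) -> str:
    return repr(value) if isinstance(value, str) else str(value)


def _parse_param(text: str):
    text = text.strip()
    if len(text) >= 2 and text[0] == text[-1] and text[0] in "'\"":
        return text[1:-1]
    for conv in (int, float):
        try:
            return conv(text)
        except ValueError:
            continue
    return text


def write_clusters(result: ClusteringResult, path: Union[str, os.PathLike]) -> None:
    """Write a :class:`ClusteringResult` as a tab-delimited .txt file."""
    lines = [f"# algorithm = {result.algorithm}"]
    for key, value in result.parameters.items():
        lines.append(f"# {key} = {_format_param(value)}")
    for rank, c in enumerate(result.clusters, start=1):
        lines.append(
            "\t".join(
                (
                    str(rank),
                    str(c.size),
                    _FLOAT_FMT.format(c.density),
                    _FLOAT_FMT.format(c.score),
                    _FLOAT_FMT.format(c.modularity),
                    ",".join(c.sorted_members()),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_clusters(path: Union[str, os.PathLike]) -> ClusteringResult:
    """Read a cluster file written by :func:`write_clusters`."""
    p = Path(path)
    algorithm: str | None = None
    parameters: dict = {}
    clusters: list[Cluster] = []
    with open(p, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ParseError(f"{p.name}:{lineno}: malformed header line")
                key, _, value = body.partition("=")
                key = key.strip()
                if key == "algorithm":
                    algorithm = value.strip()
                else:
                    parameters[key] = _parse_param(value)
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{p.name}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                size = int(fields[1])
                dens, score, modularity = (float(fields[i]) for i in (2, 3, 4))
            except ValueError:
                raise ParseError(f"{p.name}:{lineno}: malformed numeric field") from None
            members = frozenset(m for m in fields[5].split(",") if m)
            if len(members) != size:
                raise ParseError(f"{p.name}:{lineno}: size {size} != |members| {len(members)}")
            clusters.append(Cluster(members, size, dens, score, modularity))
    if algorithm is None:
        raise ParseError(f"{p.name}: missing '# algorithm = ...' header")
    return ClusteringResult(algorithm, parameters, clusters)


def parse_gene_list(text: str) -> list[str]:
    """Parse a gene-list text block: one ID per line, trimmed, deduplicated
    preserving first appearance; blank lines ignored."""
    seen: dict[str, None] = {}
    for raw in text.splitlines():
        gid = raw.strip()
        if gid:
            seen.setdefault(gid)
    if not seen:
        raise ValueError("gene list is empty")
    return list(seen)


def read_gene_list(source: Union[str, os.PathLike]) -> list[str]:
    """Read gene IDs from a file path, or parse a pasted text block.

    A string containing a newline, or one that is not an existing path, is
    treated as a pasted text block (the "flexible mode" input).
    """
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        return parse_gene_list(Path(source).read_text(encoding="utf-8"))
    if isinstance(source, str):
        return parse_gene_list(source)
    raise TypeError(f"unsupported gene-list source {type(source).__name__}")
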