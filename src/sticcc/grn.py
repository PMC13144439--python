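"""Signed gene regulatory network (GRN) topologies.

A topology is the method's only prior knowledge: an ordered list of signed
regulator→target edges over named genes. Edge order is load-bearing — it
defines the index ``k`` of the regulator/target/sign vectors used by the
cross-cell correlation, so it is preserved exactly through I/O and
perturbation.

The on-disk dialect is the tab-separated ``Source\\tTarget\\tType`` table used
by the sRACIPE ecosystem, with ``Type`` 1 for activation and 2 for
inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "Edge",
    "GRNTopology",
    "TopologyParseError",
    "read_topology",
    "write_topology",
    "builtin_circuit",
    "perturb_topology",
    "CIRCUIT_NAMES",
]


class TopologyParseError(ValueError):
    """Raised when a topology file violates the Source/Target/Type dialect."""


@dataclass(frozen=True)
class Edge:
    """One signed regulatory interaction.

    Parameters
    ----------
    source, target
        Gene names (non-empty).
    sign
        ``+1`` for activation, ``-1`` for inhibition.
    """

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty gene names")
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")


@dataclass
class GRNTopology:
    """An ordered signed edge list over named genes.

    ``genes`` lists every node in first-appearance order; ``edges`` keeps the
    order in which edges were declared. Exact duplicate edges (same source,
    target and sign) are rejected; an activating and an inhibiting edge
    between the same pair may coexist, as some curated networks contain both.

    ``degenerate`` is set by :func:`perturb_topology` when fewer than two
    edges remain — the cross-cell correlation is undefined on such networks.
    """

    genes: list[str]
    edges: list[Edge]
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        known = set(self.genes)
        seen: set[tuple[str, str, int]] = set()
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e} references a gene not in the gene list")
            key = (e.source, e.target, e.sign)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @classmethod
    def from_edges(cls, edges: Iterable[Edge]) -> "GRNTopology":
        """Build a topology from edges; genes in first-appearance order."""
        edges = list(edges)
        genes: list[str] = []
        for e in edges:
            for g in (e.source, e.target):
                if g not in genes:
                    genes.append(g)
        return cls(genes=genes, edges=edges)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def edge_arrays(self) -> tuple[list[int], list[int], list[int]]:
        """Regulator index, target index and sign vectors, edge-order aligned."""
        idx = self.gene_index()
        src = [idx[e.source] for e in self.edges]
        tgt = [idx[e.target] for e in self.edges]
        sgn = [e.sign for e in self.edges]
        return src, tgt, sgn

    def in_edges(self, gene: str) -> list[int]:
        """Indices (edge order) of edges targeting ``gene``."""
        return [k for k, e in enumerate(self.edges) if e.target == gene]


def read_topology(path: str | Path) -> GRNTopology:
    """Read a Source/Target/Type TSV into a topology.

    ``Type`` 1 maps to activation (+1), 2 to inhibition (−1). Row order
    becomes edge order; genes are collected in first-appearance order.

    Raises
    ------
    TopologyParseError
        On a missing column, an unknown Type value (named with its row), or
        an empty edge list.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TopologyParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    try:
        i_src = header.index("Source")
        i_tgt = header.index("Target")
        i_typ = header.index("Type")
    except ValueError as exc:
        raise TopologyParseError(
            f"{path}: header must contain Source, Target and Type columns, got {header}"
        ) from exc
    edges: list[Edge] = []
    for row_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) < len(header):
            raise TopologyParseError(f"{path}: row {row_no} has too few columns")
        typ = parts[i_typ].strip()
        if typ == "1":
            sign = 1
        elif typ == "2":
            sign = -1
        else:
            raise TopologyParseError(
                f"{path}: row {row_no} has unknown Type {typ!r} (expected 1 or 2)"
            )
        edges.append(Edge(parts[i_src].strip(), parts[i_tgt].strip(), sign))
    if not edges:
        raise TopologyParseError(f"{path}: no edges found")
    return GRNTopology.from_edges(edges)


def write_topology(topology: GRNTopology, path: str | Path) -> None:
    """Write a topology as a Source/Target/Type TSV (read_topology dialect)."""
    if topology.n_edges == 0:
        raise ValueError("cannot write a topology with no edges")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Source\tTarget\tType\n")
        for e in topology.edges:
            typ = 1 if e.sign == 1 else 2
            fh.write(f"{e.source}\t{e.target}\t{typ}\n")


def write_edge_list(topology: GRNTopology, path: str | Path) -> None:
    """Write a plain ``source target sign`` edge list for generic graph tools."""
    with open(Path(path), "w") as fh:
        for e in topology.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.sign:+d}\n")


def _edges(*triples: tuple[str, str, int]) -> list[Edge]:
    return [Edge(s, t, sg) for s, t, sg in triples]


# Small benchmark circuits with well-understood dynamics. REP oscillates
# (limit cycle), CTS is multistable with two major (A/C-high, B/D-high) and
# two minor states, IFFL shows pulse adaptation of Z, TSREP couples a
# bistable toggle (A, C) with a negative feedback loop through B.
_CIRCUITS: dict[str, list[Edge]] = {
    "REP": _edges(("A", "B", -1), ("B", "C", -1), ("C", "A", -1)),
    "CTS": _edges(
        ("A", "B", -1),
        ("B", "A", -1),
        ("C", "D", -1),
        ("D", "C", -1),
        ("A", "C", 1),
        ("C", "A", 1),
        ("B", "D", 1),
        ("D", "B", 1),
    ),
    "IFFL": _edges(("I", "X", 1), ("X", "Y", 1), ("X", "Z", 1), ("Y", "Z", -1)),
    "TSREP": _edges(("A", "C", -1), ("C", "A", -1), ("A", "B", -1), ("B", "C", -1)),
}

CIRCUIT_NAMES = tuple(_CIRCUITS)


def builtin_circuit(name: str) -> GRNTopology:
    """Return one of the bundled benchmark circuits.

    ``REP``
        Repressilator: three genes inhibiting each other in a cycle.
    ``CTS``
        Coupled toggle switch: mutual inhibition A⊣B and C⊣D, coupled by
        activations A→C, C→A, B→D, D→B.
    ``IFFL``
        Incoherent feedforward loop: I→X, X→Y, X→Z, Y⊣Z.
    ``TSREP``
        Toggle switch (A, C) plus a third gene B closing a negative
        feedback loop: A⊣C, C⊣A, A⊣B, B⊣C.
    """
    key = name.upper().replace("/", "").replace("-", "")
    if key not in _CIRCUITS:
        raise KeyError(
            f"unknown circuit {name!r}; available: {', '.join(_CIRCUITS)}"
        )
    return GRNTopology.from_edges(_CIRCUITS[key])


def perturb_topology(
    topology: GRNTopology,
    remove_edges: Sequence[tuple[str, str]] | None = None,
    remove_node: str | None = None,
    direction: Literal["outgoing", "incoming", "both"] = "both",
    missing: Literal["strict", "ignore"] = "strict",
) -> GRNTopology:
    """Remove edges, or all edges touching a node, from a topology.

    The gene list is unchanged (the node stays, its edges go). Removing so
    much that fewer than two edges remain marks the result ``degenerate``:
    downstream correlation inference is undefined on it.

    Parameters
    ----------
    remove_edges
        ``(source, target)`` pairs; both signed variants of a pair are
        removed if present.
    remove_node, direction
        Remove the node's outgoing edges, incoming edges, or both.
    missing
        ``"strict"`` (default) raises if a requested edge is absent;
        ``"ignore"`` treats it as a no-op.
    """
    to_drop: set[int] = set()
    if remove_edges:
        present = {}
        for k, e in enumerate(topology.edges):
            present.setdefault((e.source, e.target), []).append(k)
        for pair in remove_edges:
            pair = tuple(pair)
            if pair in present:
                to_drop.update(present[pair])
            elif missing == "strict":
                raise KeyError(f"edge {pair[0]}->{pair[1]} not in topology")
    if remove_node is not None:
        if remove_node not in topology.genes:
            if missing == "strict":
                raise KeyError(f"node {remove_node!r} not in topology")
        for k, e in enumerate(topology.edges):
            if direction in ("outgoing", "both") and e.source == remove_node:
                to_drop.add(k)
            if direction in ("incoming", "both") and e.target == remove_node:
                to_drop.add(k)
    kept = [e for k, e in enumerate(topology.edges) if k not in to_drop]
    result = GRNTopology(genes=list(topology.genes), edges=kept)
    result.degenerate = len(kept) < 2
    return result
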