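"""Read and write networks, gene sets and labels; build the RWR transition matrix.

The reference protein–protein interaction network is an undirected simple
graph ``G = (V, E)`` held as a binary adjacency matrix ``A`` (edge weights
beyond a confidence threshold are discarded).  The random-walk transition
matrix ``W`` is the column-wise normalisation of ``A``: ``W[i, j] =
A[i, j] / sum_i A[i, j]``, with columns of isolated nodes left all-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GeneNetwork",
    "GeneSet",
    "LabelTable",
    "read_edge_list",
    "read_alias_map",
    "write_edge_list",
    "normalize_adjacency",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_labels",
    "write_labels",
    "ParseError",
]


class ParseError(ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (module members, aging or disease genes)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def jaccard(self, other: "GeneSet") -> float:
        union = self.genes | other.genes
        return len(self.genes & other.genes) / len(union)


class LabelTable(Mapping):
    """Binary disease labels: disease name -> True for age-related (ARD)."""

    _TRUE = {"1", "ard", "true", "yes"}
    _FALSE = {"0", "non-ard", "nonard", "false", "no"}

    def __init__(self, labels: Mapping[str, bool] | None = None):
        self._labels: dict[str, bool] = dict(labels or {})

    def __getitem__(self, disease: str) -> bool:
        return self._labels[disease]

    def __iter__(self):
        return iter(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def is_ard(self, disease: str) -> bool:
        return self._labels[disease]

    @classmethod
    def parse_label(cls, token: str) -> bool:
        low = token.strip().lower()
        if low in cls._TRUE:
            return True
        if low in cls._FALSE:
            return False
        raise ValueError(f"unknown label {token!r} (expected 1/0 or ARD/non-ARD)")


@dataclass
class GeneNetwork:
    """An undirected gene network with adjacency ``A`` and transition ``W``.

    ``nodes`` fixes the row/column order of both matrices.  ``adjacency`` is
    symmetric, binary and zero-diagonal; ``transition`` is column-stochastic
    except on isolated nodes, whose columns are all zero.
    """

    nodes: list[str]
    adjacency: sp.csr_matrix
    transition: sp.csc_matrix | None = None
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {g: i for i, g in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def map_genes(self, genes: Iterable[str]) -> list[str]:
        """Genes present in the network, in sorted order (deterministic)."""
        return sorted(g for g in set(genes) if g in self.index)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    def subnetwork(self, genes: Sequence[str]) -> "GeneNetwork":
        """Induced subgraph on ``genes`` (order preserved), with fresh ``W``."""
        idx = np.array([self.index[g] for g in genes], dtype=int)
        sub = self.adjacency[idx][:, idx].tocsr()
        net = GeneNetwork(list(genes), sub)
        return normalize_adjacency(net)

    def edges(self) -> Iterable[tuple[str, str]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        for i, j in zip(coo.row, coo.col):
            yield self.nodes[i], self.nodes[j]

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "GeneNetwork":
        pairs = {tuple(sorted(e)) for e in edges if e[0] != e[1]}
        nodes = sorted({g for e in pairs for g in e} | set(extra_nodes))
        index = {g: i for i, g in enumerate(nodes)}
        if pairs:
            rows, cols = zip(*((index[a], index[b]) for a, b in pairs))
            data = np.ones(len(pairs))
            a = sp.coo_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))
            a = (a + a.T).tocsr()
        else:
            a = sp.csr_matrix((len(nodes), len(nodes)))
        return cls(nodes, a)


def normalize_adjacency(net: GeneNetwork) -> GeneNetwork:
    """Populate ``net.transition`` with the column-normalised adjacency.

    W[i, j] = A[i, j] / colsum_j when the column sum is positive; isolated
    nodes keep an all-zero column, so W is merely sub-stochastic there.
    Replaces any stale transition matrix in place and returns ``net``.
    """
    a = net.adjacency.tocsc().astype(float)
    colsum = np.asarray(a.sum(axis=0)).ravel()
    scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    net.transition = (a @ sp.diags(scale)).tocsc()
    return net


def read_alias_map(path) -> dict[str, str]:
    """2-column TSV mapping raw identifiers (e.g. STRING proteins) to gene names."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(path, lineno, "expected 2 columns (alias, gene)")
            mapping[parts[0]] = parts[1]
    return mapping


def read_edge_list(
    path,
    dialect: str = "two_column",
    min_confidence: int | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> GeneNetwork:
    """Read an undirected PPI edge list into a :class:`GeneNetwork`.

    Parameters
    ----------
    dialect
        ``"two_column"`` — whitespace/tab separated pairs, optional third
        numeric score column; ``"string_tsv"`` — STRING detailed-links style
        with a header naming ``protein1``, ``protein2`` and
        ``combined_score``.
    min_confidence
        Drop edges whose score is strictly below this threshold.  Requires a
        score column.
    alias_map
        Optional identifier translation applied to both endpoints.

    Duplicate edges are collapsed, self-loops removed, and the adjacency is
    binary regardless of scores (weights only gate edge inclusion).
    """
    if dialect not in ("two_column", "string_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        lineno = 0
        cols: tuple[int, int, int | None] | None = None
        if dialect == "string_tsv":
            header = fh.readline()
            lineno += 1
            names = header.split()
            try:
                score_col = names.index("combined_score")
                cols = (names.index("protein1"), names.index("protein2"), score_col)
            except ValueError:
                raise ParseError(
                    path, 1, "string_tsv header must name protein1, protein2, combined_score"
                )
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if cols is not None:
                i1, i2, isc = cols
                if len(parts) <= max(i1, i2, isc):
                    raise ParseError(path, lineno, "too few columns")
                a, b, score_tok = parts[i1], parts[i2], parts[isc]
            else:
                if len(parts) < 2:
                    raise ParseError(path, lineno, "expected at least 2 columns")
                a, b = parts[0], parts[1]
                score_tok = parts[2] if len(parts) > 2 else None
            if min_confidence is not None:
                if score_tok is None:
                    raise ParseError(path, lineno, "min_confidence set but no score column")
                try:
                    score = float(score_tok)
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric score {score_tok!r}")
                if score < min_confidence:
                    continue
            if alias_map is not None:
                a = alias_map.get(a, a)
                b = alias_map.get(b, b)
            if a == b:
                continue
            edges.add((a, b) if a <= b else (b, a))
    if not edges:
        raise ValueError(f"{path}: no edges remain after filtering")
    return GeneNetwork.from_edges(edges)


def write_edge_list(net: GeneNetwork, path) -> None:
    """Write the network as a plain 2-column edge list (round-trips with
    ``read_edge_list(dialect='two_column')``)."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges()):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "GMT line needs name, description and >=1 gene")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ParseError(path, lineno, "GMT line has no genes")
            sets.append(GeneSet(parts[0], genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One gene per line (the anchor/aging list format)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g.split()[0])
    return GeneSet(name or Path(path).stem, genes)


def read_labels(path) -> LabelTable:
    """2-column TSV: disease <tab> label; labels 1/0 or ARD/non-ARD."""
    labels: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, lineno, "expected 2 tab-separated columns")
            disease, token = parts[0], parts[1]
            try:
                value = LabelTable.parse_label(token)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc))
            if disease in labels and labels[disease] != value:
                raise ParseError(path, lineno, f"conflicting labels for {disease!r}")
            labels[disease] = value
    return LabelTable(labels)


def write_labels(labels: LabelTable, path) -> None:
    with open(path, "w") as fh:
        for disease in sorted(labels):
            fh.write(f"{disease}\t{int(labels[disease])}\n")
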