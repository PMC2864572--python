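"""Domain types and I/O for integrated physical interaction networks.

The method operates on three kinds of objects:

* *physical layers* — named interaction networks (e.g. ``TRI`` for
  transcriptional regulation, ``PPI`` for protein binding, ``PhI`` for
  phosphorylation), each declared directed or undirected;
* a *cause--effect network* linking each perturbed gene (typically a
  deleted or overexpressed transcription factor) to the genes that are
  differentially expressed under that perturbation;
* optional *gene-set collections* (GMT) used as functional annotation
  for module enrichment.

Gene identifiers are case-sensitive opaque strings throughout; no alias
or ortholog resolution is attempted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("pathmotifs")

__all__ = [
    "PathType",
    "PhysicalLayer",
    "IntegratedNetwork",
    "CauseEffectNetwork",
    "GeneSetCollection",
    "ParseError",
    "read_layer",
    "write_layer",
    "read_cause_effect",
    "write_cause_effect",
    "read_gene_sets",
    "write_paths_sif",
]


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True, order=True)
class PathType:
    """An ordered sequence of 1-3 layer labels, e.g. ``PPI-TRI``.

    A path of this type traverses one edge of each listed layer in
    order, starting at a causative gene and ending at an effect gene.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.labels, tuple):
            object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 1:
            raise ValueError("a path type needs at least one layer label")
        if any(not lab or "-" in lab for lab in self.labels):
            raise ValueError(f"invalid layer labels in path type: {self.labels!r}")

    @property
    def name(self) -> str:
        return "-".join(self.labels)

    @classmethod
    def parse(cls, name: str) -> "PathType":
        return cls(tuple(name.split("-")))

    def __len__(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


class PhysicalLayer:
    """One named interaction layer.

    Directed layers store edges in their given orientation; undirected
    layers canonicalize each unordered pair to a single stored edge and
    answer membership queries in either orientation.  Self-loops are
    dropped on construction (the method's paths connect distinct genes).
    """

    def __init__(self, label: str, directed: bool, edges: Iterable[tuple[str, str]] = ()):
        if not label:
            raise ValueError("layer label must be non-empty")
        self.label = label
        self.directed = bool(directed)
        self._edges: set[tuple[str, str]] = set()
        self._succ: dict[str, tuple[str, ...]] | None = None
        n_self = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            self._edges.add(self._canon(a, b))
        if n_self:
            logger.info("layer %s: dropped %d self-loop edge(s)", label, n_self)

    def _canon(self, a: str, b: str) -> tuple[str, str]:
        if self.directed or a <= b:
            return (a, b)
        return (b, a)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._edges)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return self._canon(a, b) in self._edges

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError("self-loop edges are not allowed")
        self._edges.add(self._canon(a, b))
        self._succ = None

    def successors(self, node: str) -> tuple[str, ...]:
        """Nodes reachable from ``node`` along one edge of this layer.

        For undirected layers this is the full neighbourhood; for
        directed layers, out-neighbours only.  Sorted for determinism.
        """
        if self._succ is None:
            adj: dict[str, set[str]] = {}
            for a, b in self._edges:
                adj.setdefault(a, set()).add(b)
                if not self.directed:
                    adj.setdefault(b, set()).add(a)
            self._succ = {n: tuple(sorted(s)) for n, s in adj.items()}
        return self._succ.get(node, ())

    def __repr__(self) -> str:  # pragma: no cover
        kind = "directed" if self.directed else "undirected"
        return f"PhysicalLayer({self.label!r}, {kind}, {len(self)} edges)"


class IntegratedNetwork:
    """A set of physical layers sharing one gene-identifier space."""

    def __init__(self, layers: Iterable[PhysicalLayer]):
        self.layers: dict[str, PhysicalLayer] = {}
        for layer in layers:
            if layer.label in self.layers:
                raise ValueError(f"duplicate layer label {layer.label!r}")
            self.layers[layer.label] = layer

    @property
    def labels(self) -> list[str]:
        return list(self.layers)

    @property
    def node_universe(self) -> set[str]:
        out: set[str] = set()
        for layer in self.layers.values():
            out |= layer.nodes
        return out

    def layer(self, label: str) -> PhysicalLayer:
        try:
            return self.layers[label]
        except KeyError:
            raise KeyError(
                f"unknown layer label {label!r}; available: {sorted(self.layers)}"
            ) from None

    def validate_path_type(self, path_type: PathType) -> None:
        for lab in path_type.labels:
            self.layer(lab)

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(f"{l.label}:{len(l)}" for l in self.layers.values())
        return f"IntegratedNetwork({parts})"


class CauseEffectNetwork:
    """Per-cause sets of perturbed effect genes.

    ``causes`` preserves first-appearance order so that runs are
    reproducible regardless of set-iteration order.
    """

    def __init__(self, pairs: Mapping[str, Iterable[str]] | None = None,
                 causes: Sequence[str] | None = None):
        self.pairs: dict[str, set[str]] = {}
        self.causes: list[str] = []
        pairs = pairs or {}
        order = causes if causes is not None else list(pairs)
        n_self = 0
        for cause in order:
            effects = {e for e in pairs.get(cause, ())}
            if cause in effects:
                effects.discard(cause)
                n_self += 1
            if not effects:
                continue
            self.pairs[cause] = effects
            self.causes.append(cause)
        if n_self:
            logger.info("cause-effect network: dropped %d self-pair(s)", n_self)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.pairs.values())

    @property
    def effect_genes(self) -> set[str]:
        out: set[str] = set()
        for v in self.pairs.values():
            out |= v
        return out

    def iter_pairs(self) -> Iterator[tuple[str, str]]:
        for cause in self.causes:
            for effect in sorted(self.pairs[cause]):
                yield cause, effect

    def __repr__(self) -> str:  # pragma: no cover
        return f"CauseEffectNetwork({len(self.causes)} causes, {self.n_pairs} pairs)"


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe for enrichment."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            u: set[str] = set()
            for s in self.sets.values():
                u |= s
            self.universe = u
        else:
            for name, s in self.sets.items():
                if not s <= self.universe:
                    raise ValueError(f"gene set {name!r} is not a subset of the universe")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _iter_edge_lines(path: Path, fmt: str) -> Iterator[tuple[int, str, str, str | None]]:
    """Yield (lineno, source, target, relation) from a TSV or SIF file."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if fmt == "tsv":
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    raise ParseError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
                yield lineno, fields[0], fields[1], None
            elif fmt == "sif":
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) != 3 or not all(fields):
                    raise ParseError(f"{path}:{lineno}: expected 'source relation target'")
                yield lineno, fields[0], fields[2], fields[1]
            else:
                raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'sif')")


def read_layer(path: str | Path, label: str, directed: bool, format: str = "tsv") -> PhysicalLayer:
    """Read one physical layer from a 2+-column TSV or a SIF file.

    Extra TSV columns (scores, p-values) are ignored: any confidence
    thresholding is expected to have been applied upstream.  Duplicate
    edges are collapsed; self-loops are dropped with a logged count.
    """
    path = Path(path)
    raw_edges = [(a, b) for _, a, b, _ in _iter_edge_lines(path, format)]
    if not raw_edges:
        raise ParseError(f"{path}: no edges")
    layer = PhysicalLayer(label, directed, raw_edges)
    n_dup = len(raw_edges) - len(layer) - sum(1 for a, b in raw_edges if a == b)
    if n_dup > 0:
        logger.info("layer %s: collapsed %d duplicate edge(s)", label, n_dup)
    if len(layer) == 0:
        raise ParseError(f"{path}: no edges remain after dropping self-loops")
    return layer


def write_layer(layer: PhysicalLayer, path: str | Path) -> None:
    """Write a layer as a two-column TSV (sorted, LF endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in sorted(layer.edges):
            fh.write(f"{a}\t{b}\n")


def read_cause_effect(path: str | Path) -> CauseEffectNetwork:
    """Read a cause--effect network from a two-column TSV (cause, effect)."""
    path = Path(path)
    pairs: dict[str, set[str]] = {}
    order: list[str] = []
    for _, cause, effect, _ in _iter_edge_lines(path, "tsv"):
        if cause not in pairs:
            pairs[cause] = set()
            order.append(cause)
        pairs[cause].add(effect)
    ce = CauseEffectNetwork(pairs, causes=order)
    if ce.n_pairs == 0:
        raise ParseError(f"{path}: no pairs remain")
    return ce


def write_cause_effect(ce: CauseEffectNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for cause, effect in ce.iter_pairs():
            fh.write(f"{cause}\t{effect}\n")


def read_gene_sets(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: name, description, then member genes."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    if not sets:
        raise ParseError(f"{path}: empty gene-set file")
    return GeneSetCollection(sets, universe=universe or set())


def config_digest(text: str) -> str:
    """Short stable digest used to stamp output files."""
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:12]


def write_paths_sif(instances, out_prefix: str | Path, header: str | None = None,
                    module_ids: Mapping | None = None) -> dict[str, Path]:
    """Export path instances as a Cytoscape-compatible SIF bundle.

    Writes ``<prefix>.sif`` (one line per distinct traversed edge, the
    relation token being the layer label), ``<prefix>.edges.tsv``
    (membership of each edge in each path instance) and
    ``<prefix>.nodes.tsv`` (role of each node: cause, intermediate or
    effect; a node playing several roles gets one row per role).
    Line order is sorted so repeated runs are byte-identical.

    ``module_ids`` optionally maps an instance to a module identifier,
    added as an extra edge-attribute column.
    """
    instances = list(instances)
    if not instances:
        raise ValueError("no path instances to write")
    out_prefix = Path(out_prefix)
    sif_lines: set[str] = set()
    edge_rows: set[tuple[str, ...]] = set()
    node_rows: set[tuple[str, str]] = set()
    for inst in instances:
        inst_id = f"{inst.cause}|{inst.path_type.name}|{'|'.join(inst.intermediates())}|{inst.effect}"
        for label, a, b in inst.edges:
            sif_lines.add(f"{a}\t{label}\t{b}")
            row = [a, label, b, inst_id]
            if module_ids is not None:
                row.append(str(module_ids.get(inst, "")))
            edge_rows.add(tuple(row))
        node_rows.add((inst.cause, "cause"))
        node_rows.add((inst.effect, "effect"))
        for n in inst.intermediates():
            node_rows.add((n, "intermediate"))
    paths = {
        "sif": out_prefix.with_suffix(".sif"),
        "edges": Path(str(out_prefix) + ".edges.tsv"),
        "nodes": Path(str(out_prefix) + ".nodes.tsv"),
    }
    hdr = (header + "\n") if header else ""
    with open(paths["sif"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(hdr)
        fh.write("\n".join(sorted(sif_lines)) + "\n")
    with open(paths["edges"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(hdr)
        cols = ["source", "interaction", "target", "path_id"]
        if module_ids is not None:
            cols.append("module_id")
        fh.write("\t".join(cols) + "\n")
        for row in sorted(edge_rows):
            fh.write("\t".join(row) + "\n")
    with open(paths["nodes"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(hdr)
        fh.write("node\trole\n")
        for node, role in sorted(node_rows):
            fh.write(f"{node}\t{role}\n")
    return paths
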