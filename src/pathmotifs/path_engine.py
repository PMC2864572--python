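"""Enumeration and counting of typed path instances.

A *path instance* is a simple path (all nodes distinct) whose i-th edge
belongs to the i-th layer of a path type, traversed in the stored
orientation for directed layers and in either orientation for
undirected ones.  Simplicity is the central counting convention: it
rules out degenerate undirected back-tracking walks such as
cause-partner-cause, and implies the cause never reappears downstream
and the effect never appears as an intermediate.

Intermediate nodes are otherwise unconstrained — in particular they need
not be differentially expressed themselves, which is what lets the
method explain indirect perturbation effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .net_model import CauseEffectNetwork, IntegratedNetwork, PathType

__all__ = [
    "PathInstance",
    "all_path_types",
    "enumerate_instances",
    "path_counts",
    "reach",
    "count_instances",
    "connected_pairs",
    "filter_without_direct",
]


@dataclass(frozen=True)
class PathInstance:
    """One concrete cause -> ... -> effect walk realizing a path type."""

    cause: str
    effect: str
    path_type: PathType
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.path_type) + 1:
            raise ValueError("node sequence length must be path length + 1")
        if self.nodes[0] != self.cause or self.nodes[-1] != self.effect:
            raise ValueError("node sequence must start at cause and end at effect")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path instances are simple: nodes must be distinct")

    @property
    def edges(self) -> tuple[tuple[str, str, str], ...]:
        """(layer label, source, target) triples in traversal order."""
        return tuple(
            (lab, self.nodes[i], self.nodes[i + 1])
            for i, lab in enumerate(self.path_type.labels)
        )

    def intermediates(self) -> tuple[str, ...]:
        return self.nodes[1:-1]


def all_path_types(labels: Sequence[str], max_length: int = 3) -> list[PathType]:
    """All ordered layer-label sequences of length 1..max_length.

    Order is length-major, then lexicographic, so the list is stable
    across runs.  With 3 layers and max_length 3 there are
    3 + 9 + 27 = 39 types.
    """
    if not labels:
        raise ValueError("need at least one layer label")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    labs = sorted(set(labels))
    if len(labs) != len(labels):
        raise ValueError("layer labels must be unique")
    out: list[PathType] = []
    for k in range(1, max_length + 1):
        for combo in itertools.product(labs, repeat=k):
            out.append(PathType(combo))
    return out


def enumerate_instances(
    net: IntegratedNetwork, pair: tuple[str, str], path_type: PathType
) -> list[PathInstance]:
    """Every simple typed path from cause to effect, in sorted node order.

    Genes absent from the network simply yield no paths.  An unknown
    layer label in ``path_type`` is a configuration error.
    """
    net.validate_path_type(path_type)
    cause, effect = pair
    labels = path_type.labels
    out: list[PathInstance] = []
    if cause == effect:
        return out

    def _extend(prefix: list[str], depth: int) -> None:
        layer = net.layer(labels[depth])
        last = depth == len(labels) - 1
        for nxt in layer.successors(prefix[-1]):
            if last:
                if nxt == effect:
                    out.append(
                        PathInstance(cause, effect, path_type, tuple(prefix) + (effect,))
                    )
            else:
                if nxt == effect or nxt in prefix:
                    continue
                prefix.append(nxt)
                _extend(prefix, depth + 1)
                prefix.pop()

    # successors() is sorted, so the DFS emits instances in sorted node order
    if effect not in (cause,):
        _extend([cause], 0)
    return out


def path_counts(
    net: IntegratedNetwork, cause: str, path_type: PathType
) -> dict[str, int]:
    """Number of simple typed paths from ``cause`` to every terminal gene.

    The per-terminal tally is independent of which genes happen to be
    differentially expressed, which is what makes the perturbation null
    model cheap: a randomized effect set just re-weights this mapping.
    """
    net.validate_path_type(path_type)
    labels = path_type.labels
    counts: dict[str, int] = {}

    def _extend(prefix: list[str], depth: int) -> None:
        layer = net.layer(labels[depth])
        last = depth == len(labels) - 1
        for nxt in layer.successors(prefix[-1]):
            if last:
                if nxt not in prefix:
                    counts[nxt] = counts.get(nxt, 0) + 1
            else:
                if nxt in prefix:
                    continue
                prefix.append(nxt)
                _extend(prefix, depth + 1)
                prefix.pop()

    _extend([cause], 0)
    return counts


def reach(net: IntegratedNetwork, cause: str, path_type: PathType) -> set[str]:
    """Genes reachable from ``cause`` by at least one instance of the type."""
    return set(path_counts(net, cause, path_type))


def count_instances(
    net: IntegratedNetwork, ce: CauseEffectNetwork, path_type: PathType
) -> int:
    """Total number of path instances over all cause--effect pairs."""
    total = 0
    for cause in ce.causes:
        counts = path_counts(net, cause, path_type)
        total += sum(counts.get(e, 0) for e in ce.pairs[cause])
    return total


def connected_pairs(
    net: IntegratedNetwork, ce: CauseEffectNetwork, path_type: PathType
) -> set[tuple[str, str]]:
    """Cause--effect pairs joined by at least one instance of the type."""
    out: set[tuple[str, str]] = set()
    for cause in ce.causes:
        reached = reach(net, cause, path_type)
        out.update((cause, e) for e in ce.pairs[cause] & reached)
    return out


def filter_without_direct(
    instances: Iterable[PathInstance],
    direct_label: str,
    net: IntegratedNetwork,
    keep_direct: bool = False,
) -> list[PathInstance]:
    """Drop indirect instances whose endpoints also share a direct edge.

    Used as a control: it verifies that longer-path enrichment is not a
    shadow of plain direct-edge enrichment.  Length-1 instances of the
    direct layer itself are excluded from the indirect analysis unless
    ``keep_direct`` is set.
    """
    direct = net.layer(direct_label)
    if not direct.directed:
        raise ValueError(f"direct layer {direct_label!r} must be directed")
    out: list[PathInstance] = []
    for inst in instances:
        if inst.path_type.labels == (direct_label,):
            if keep_direct:
                out.append(inst)
            continue
        if not direct.has_edge(inst.cause, inst.effect):
            out.append(inst)
    return out
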