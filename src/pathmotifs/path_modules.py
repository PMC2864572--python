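"""Aggregation of path instances into modules and summary statistics.

The effect genes of one cause explained by the same path type through
the same intermediate nodes form a *path module*: the module key is
(cause, path type, ordered intermediates), and members differ only in
the terminal node.  Modules are the unit of functional interpretation —
e.g. a TF binding one partner that regulates a battery of pathway genes
shows up as a single module covering that battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy import stats

from .net_model import CauseEffectNetwork, GeneSetCollection, IntegratedNetwork, PathType
from .path_engine import PathInstance, connected_pairs

logger = logging.getLogger("pathmotifs")

__all__ = [
    "PathModule",
    "ModuleEnrichment",
    "extract_modules",
    "module_enrichment",
    "fraction_explained",
    "motif_abundance",
    "subset_causes",
]

#: modules smaller than this are listed but not tested functionally
DEFAULT_MIN_MODULE_SIZE = 3


@dataclass(frozen=True)
class PathModule:
    cause: str
    path_type: PathType
    intermediates: tuple[str, ...]
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a module needs at least one member")
        if self.cause in self.intermediates or set(self.intermediates) & self.members:
            raise ValueError("intermediates may contain neither the cause nor members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def key(self) -> str:
        inner = ",".join(self.intermediates) if self.intermediates else "-"
        return f"{self.cause}|{self.path_type.name}|{inner}"


@dataclass(frozen=True)
class ModuleEnrichment:
    module: PathModule
    set_name: str
    overlap: int
    set_size: int
    p_value: float


def extract_modules(instances: list[PathInstance]) -> list[PathModule]:
    """Group instances by (cause, path type, intermediates).

    Every instance lands in exactly one module; two instances from the
    same cause via different intermediates form different modules even
    when they reach the same effect.  Output order is deterministic
    (cause, type name, intermediates).
    """
    grouped: dict[tuple[str, PathType, tuple[str, ...]], set[str]] = {}
    for inst in instances:
        key = (inst.cause, inst.path_type, inst.intermediates())
        grouped.setdefault(key, set()).add(inst.effect)
    modules = [
        PathModule(cause, pt, inter, frozenset(members))
        for (cause, pt, inter), members in grouped.items()
    ]
    modules.sort(key=lambda m: (m.cause, m.path_type.name, m.intermediates))
    return modules


def module_enrichment(module: PathModule, sets: GeneSetCollection) -> list[ModuleEnrichment]:
    """Hypergeometric functional overrepresentation of one module.

    Members outside the annotation universe are dropped with a warning
    (they carry no annotation information).  Results are sorted by
    ascending p.
    """
    if not sets.universe:
        raise ValueError("gene-set universe is empty")
    members = module.members & sets.universe
    dropped = module.size - len(members)
    if dropped:
        logger.warning(
            "module %s: %d member(s) outside the annotation universe dropped",
            module.key, dropped,
        )
    m_total = len(sets.universe)
    results = []
    for name in sorted(sets.sets):
        gene_set = sets.sets[name]
        overlap = len(members & gene_set)
        p = float(stats.hypergeom.sf(overlap - 1, m_total, len(gene_set), len(members)))
        results.append(ModuleEnrichment(module, name, overlap, len(gene_set), p))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def fraction_explained(
    ce: CauseEffectNetwork,
    net: IntegratedNetwork,
    enriched_types: list[PathType],
) -> float:
    """Fraction of cause--effect pairs connected by >=1 enriched type.

    Pairs, not distinct genes: a gene perturbed under two causes is two
    separate perturbation events and counts twice.
    """
    if not enriched_types:
        raise ValueError("enriched_types must be non-empty")
    if ce.n_pairs == 0:
        raise ValueError("cause-effect network is empty")
    explained: set[tuple[str, str]] = set()
    for pt in enriched_types:
        explained |= connected_pairs(net, ce, pt)
    return len(explained) / ce.n_pairs


def motif_abundance(
    ce: CauseEffectNetwork,
    net: IntegratedNetwork,
    enriched_types: list[PathType],
    return_counts: bool = False,
):
    """Relative share of each enriched type among explained pairs.

    The tally is over (pair, type) assignments: a pair explained by k
    types contributes once to each of the k types, and the fractions
    sum to 1 whenever anything is explained.  With ``return_counts``
    the raw assignment tally is returned alongside, so alternative
    normalizations can be derived.
    """
    if not enriched_types:
        raise ValueError("enriched_types must be non-empty")
    counts = {pt: len(connected_pairs(net, ce, pt)) for pt in enriched_types}
    total = sum(counts.values())
    fractions = {
        pt: (c / total if total else 0.0) for pt, c in counts.items()
    }
    if return_counts:
        return fractions, counts
    return fractions


def subset_causes(ce: CauseEffectNetwork, keep: set[str]) -> CauseEffectNetwork:
    """Restrict to a subset of causes, e.g. known cell-cycle regulators,
    for condition-specific reanalysis."""
    if not keep:
        raise ValueError("keep must be non-empty")
    causes = [c for c in ce.causes if c in keep]
    if not causes:
        raise ValueError("no causes remain after subsetting")
    return CauseEffectNetwork({c: ce.pairs[c] for c in causes}, causes=causes)


def write_modules_tsv(modules: list[PathModule], path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write(header + "\n")
        fh.write("cause\tpath_type\tintermediates\tmembers\tsize\n")
        for m in modules:
            inter = ",".join(m.intermediates)
            members = ",".join(sorted(m.members))
            fh.write(f"{m.cause}\t{m.path_type.name}\t{inter}\t{members}\t{m.size}\n")


def write_module_enrichment_tsv(results: list[ModuleEnrichment], path,
                                header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write(header + "\n")
        fh.write("module\tset_name\toverlap\tset_size\tp_value\n")
        for r in results:
            fh.write(f"{r.module.key}\t{r.set_name}\t{r.overlap}\t{r.set_size}\t{r.p_value:.3g}\n")
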