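"""Synthetic integrated networks with planted path structure.

Every statistical claim the package makes is testable without external
data: the generator draws sparse Erdős–Rényi physical layers shaped
like a TRI/PPI/PhI stack (directed transcriptional and phosphorylation
layers, an undirected protein-interaction layer) and a cause--effect
network made of *planted* path-reachable targets plus uniform noise
targets.  Planted instances share one intermediate chain per cause, so
module extraction has non-trivial structure to recover.

The generator does not attempt to mimic real degree distributions
(no scale-free wiring); it provides exact ground truth, not realism of
topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .net_model import (
    CauseEffectNetwork,
    IntegratedNetwork,
    PathType,
    PhysicalLayer,
)
from .path_engine import PathInstance

__all__ = [
    "LayerSpec",
    "SyntheticSpec",
    "generate_integrated",
    "plant_paths",
    "simulate",
    "hub_example_fixture",
]


@dataclass(frozen=True)
class LayerSpec:
    directed: bool
    density: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("edge density must lie in [0, 1]")


def _default_layers() -> dict[str, LayerSpec]:
    return {
        "TRI": LayerSpec(directed=True, density=0.01),
        "PPI": LayerSpec(directed=False, density=0.01),
        "PhI": LayerSpec(directed=True, density=0.01),
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic data set.

    Defaults describe the standard planted-recovery experiment: 300
    genes, 10 perturbed causes, three sparse layers at density 0.01,
    8 planted PPI-TRI targets per cause sharing one intermediate, and
    20 uniform noise targets per cause.
    """

    n_genes: int = 300
    n_causes: int = 10
    layer_specs: dict[str, LayerSpec] = field(default_factory=_default_layers)
    planted_type: PathType = PathType(("PPI", "TRI"))
    n_planted_per_cause: int = 8
    noise_targets_per_cause: int = 20
    seed: int = 0
    add_direct_edges: bool = False

    def __post_init__(self) -> None:
        if self.n_causes > self.n_genes:
            raise ValueError("n_causes cannot exceed n_genes")
        if self.n_planted_per_cause < 0 or self.noise_targets_per_cause < 0:
            raise ValueError("per-cause target counts must be >= 0")
        if self.n_planted_per_cause and self.planted_type.labels[0] not in self.layer_specs:
            raise ValueError("planted_type uses a label missing from layer_specs")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "SyntheticSpec":
        """No planted structure: effect genes are pure uniform noise."""
        return cls(n_planted_per_cause=0, seed=seed, **kwargs)

    @classmethod
    def null_calibration(cls, seed: int = 0) -> "SyntheticSpec":
        """Null conditions sized for p-value calibration checks.

        Denser layers and more noise targets push observed path counts
        into the z-rule regime (expected PPI-TRI count ~ 11 per data
        set), where the reported p-value is continuous; with the sparse
        defaults most null counts fall below five, where the empirical
        fraction rule is discrete by construction and uniformity of p
        is not even the target behaviour.
        """
        layers = {
            "TRI": LayerSpec(directed=True, density=0.05),
            "PPI": LayerSpec(directed=False, density=0.05),
            "PhI": LayerSpec(directed=True, density=0.05),
        }
        return cls(
            n_genes=150,
            n_causes=10,
            layer_specs=layers,
            n_planted_per_cause=0,
            noise_targets_per_cause=30,
            seed=seed,
        )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_integrated(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> IntegratedNetwork:
    """Independent Erdős–Rényi draw for each layer at its density."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    genes = _gene_names(spec.n_genes)
    layers = []
    n = spec.n_genes
    for label in sorted(spec.layer_specs):
        lspec = spec.layer_specs[label]
        edges: list[tuple[str, str]] = []
        if lspec.directed:
            mask = rng.random((n, n)) < lspec.density
            np.fill_diagonal(mask, False)
            for i, j in zip(*np.nonzero(mask)):
                edges.append((genes[i], genes[j]))
        else:
            iu, ju = np.triu_indices(n, k=1)
            mask = rng.random(iu.size) < lspec.density
            for i, j in zip(iu[mask], ju[mask]):
                edges.append((genes[i], genes[j]))
        layers.append(PhysicalLayer(label, lspec.directed, edges))
    return IntegratedNetwork(layers)


def plant_paths(
    net: IntegratedNetwork,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[IntegratedNetwork, CauseEffectNetwork, list[PathInstance]]:
    """Wire planted path instances into ``net`` and build the
    cause--effect network.

    For each cause, one fresh intermediate chain is reserved and reused
    by all of that cause's planted instances (so each cause yields one
    module), and ``n_planted_per_cause`` fresh terminal genes are wired
    as effects; ``noise_targets_per_cause`` further effects are drawn
    uniformly from the remaining genes.  Planted intermediates never
    appear as noise targets (avoiding accidental direct shortcuts);
    other genes — including another cause's planted targets — stay
    eligible, so the noise marginal matches the randomization null's
    uniform draw.  Returns the mutated network, the cause--effect
    network, and the planted instances.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    genes = _gene_names(spec.n_genes)
    causes = genes[: spec.n_causes]
    length = len(spec.planted_type)
    per_cause = (length - 1) + spec.n_planted_per_cause
    n_reserved = per_cause * spec.n_causes if spec.n_planted_per_cause else 0
    if spec.n_causes + n_reserved > spec.n_genes:
        raise ValueError(
            f"not enough genes: {spec.n_genes} available, "
            f"{spec.n_causes} causes + {n_reserved} reserved needed"
        )
    reserved = genes[spec.n_genes - n_reserved:] if n_reserved else []
    pairs: dict[str, set[str]] = {}
    truth: list[PathInstance] = []
    all_intermediates: set[str] = set()
    blocks: dict[str, tuple[tuple[str, ...], list[str]]] = {}
    for ci, cause in enumerate(causes):
        if spec.n_planted_per_cause:
            block = reserved[ci * per_cause : (ci + 1) * per_cause]
            inters = tuple(block[: length - 1])
            targets = block[length - 1 :]
            blocks[cause] = (inters, targets)
            all_intermediates |= set(inters)
    noise_pool = [g for g in genes if g not in all_intermediates]
    for cause in causes:
        effects: set[str] = set()
        if spec.n_planted_per_cause:
            inters, targets = blocks[cause]
            chain = (cause,) + inters
            for i, lab in enumerate(spec.planted_type.labels[:-1]):
                net.layer(lab).add_edge(chain[i], chain[i + 1])
            last_lab = spec.planted_type.labels[-1]
            for t in targets:
                net.layer(last_lab).add_edge(chain[-1], t)
                truth.append(PathInstance(cause, t, spec.planted_type, chain + (t,)))
                if spec.add_direct_edges:
                    net.layer("TRI").add_edge(cause, t)
            effects |= set(targets)
        pool = [g for g in noise_pool if g != cause and g not in effects]
        k = min(spec.noise_targets_per_cause, len(pool))
        if k:
            drawn = rng.choice(len(pool), size=k, replace=False)
            effects |= {pool[i] for i in drawn}
        if effects:
            pairs[cause] = effects
    ce = CauseEffectNetwork(pairs, causes=[c for c in causes if c in pairs])
    return net, ce, truth


def simulate(
    spec: SyntheticSpec,
) -> tuple[IntegratedNetwork, CauseEffectNetwork, list[PathInstance]]:
    """Generate one full synthetic data set from a spec (one seed
    drives both the background draw and the planting)."""
    ss = np.random.SeedSequence(spec.seed)
    net_ss, plant_ss = ss.spawn(2)
    net = generate_integrated(spec, rng=np.random.default_rng(net_ss))
    return plant_paths(net, spec, rng=np.random.default_rng(plant_ss))


def hub_example_fixture() -> tuple[IntegratedNetwork, CauseEffectNetwork]:
    """A small frozen 20-node example: a directed transcriptional layer
    over five TF nodes, an undirected protein-interaction layer with one
    hub, and one perturbed cause with five effect genes.

    The edge list is this package's own construction (stored as
    packaged TSV data) and is frozen so counts on it can serve as
    regression values.
    """
    data = resources.files("pathmotifs").joinpath("data")

    def _edges(name: str) -> list[tuple[str, str]]:
        text = data.joinpath(name).read_text(encoding="utf-8")
        out = []
        for line in text.splitlines():
            if line.strip() and not line.startswith("#"):
                a, b = line.split("\t")[:2]
                out.append((a, b))
        return out

    tri = PhysicalLayer("TRI", True, _edges("hub_example_tri.tsv"))
    ppi = PhysicalLayer("PPI", False, _edges("hub_example_ppi.tsv"))
    net = IntegratedNetwork([tri, ppi])
    pairs: dict[str, set[str]] = {}
    order: list[str] = []
    for c, e in _edges("hub_example_ce.tsv"):
        if c not in pairs:
            pairs[c] = set()
            order.append(c)
        pairs[c].add(e)
    return net, CauseEffectNetwork(pairs, causes=order)
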