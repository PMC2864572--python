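"""Null models and significance tests for path-type enrichment.

Two complementary randomization schemes decide whether a path type is a
*motif*:

1. **Perturbation randomization** — the physical layers stay fixed and
   each cause's effect set is replaced by a uniform draw of the same
   size from the gene universe.  The observed statistic is the total
   number of path instances over all cause--effect pairs, compared to
   an ensemble (default 10,000) of randomized data sets.

2. **Network randomization** — the perturbational data stays fixed.
   For a given path type a directed *projection* network is built with
   an edge cause -> gene wherever at least one instance of the type
   links them; the projection is then rewired by degree-preserving
   double-edge swaps and the statistic is the overlap between
   projection edges and real cause--effect pairs.

Both are one-sided (enrichment only).  When the observed count is at
least five and the null spread is positive, significance comes from a
z statistic against the null mean and standard deviation; for smaller
counts the z approximation is unusable and the empirical fraction of
randomizations reaching the observed count is reported instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .net_model import CauseEffectNetwork, IntegratedNetwork, PathType
from .path_engine import path_counts, reach

logger = logging.getLogger("pathmotifs")

__all__ = [
    "EnrichmentResult",
    "randomize_cause_effect",
    "perturbation_enrichment",
    "perturbation_enrichment_many",
    "build_projection",
    "degree_preserving_randomize",
    "network_enrichment",
    "network_enrichment_many",
    "hypergeometric_reach_test",
    "per_cause_specificity",
    "write_enrichment_tsv",
]

#: below this observed count the z approximation is not trusted
Z_RULE_MIN_OBSERVED = 5


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one path type under one null model.

    ``rule`` records which p-value rule applied: ``"z"`` (normal upper
    tail of (observed - null_mean)/null_sd) or ``"empirical"`` (fraction
    of randomizations with a count >= observed; an observed fraction of
    zero is reported as 1/n_random, the resolution limit — the raw
    fraction is n_null_ge_observed / n_random).
    """

    path_type: PathType
    observed: int
    null_mean: float
    null_sd: float
    z: float | None
    p_value: float
    method: str
    n_random: int
    n_null_ge_observed: int
    rule: str

    @property
    def empirical_fraction(self) -> float:
        return self.n_null_ge_observed / self.n_random


def _result_from_null(
    path_type: PathType, observed: int, null_counts: np.ndarray, method: str
) -> EnrichmentResult:
    null_counts = np.asarray(null_counts, dtype=float)
    n_random = int(null_counts.size)
    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1)) if n_random > 1 else 0.0
    n_ge = int(np.count_nonzero(null_counts >= observed))
    if observed >= Z_RULE_MIN_OBSERVED and sd > 0:
        z = (observed - mean) / sd
        p = float(stats.norm.sf(z))
        rule = "z"
    else:
        # small counts, or a degenerate null spread: empirical fraction
        z = None
        p = max(n_ge / n_random, 1.0 / n_random)
        rule = "empirical"
    return EnrichmentResult(
        path_type=path_type,
        observed=int(observed),
        null_mean=mean,
        null_sd=sd,
        z=z,
        p_value=p,
        method=method,
        n_random=n_random,
        n_null_ge_observed=n_ge,
        rule=rule,
    )


# ---------------------------------------------------------------------------
# perturbation randomization
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def resolve_universe(
    net: IntegratedNetwork, ce: CauseEffectNetwork, universe_mode: str = "union"
) -> set[str]:
    """Gene universe over which randomized effect sets are drawn.

    ``union`` (the default) is network nodes plus all effect genes, so
    genes that were measured but are absent from every layer remain
    eligible to be drawn.
    """
    if universe_mode == "network_nodes":
        return net.node_universe
    if universe_mode == "effect_genes":
        return ce.effect_genes
    if universe_mode == "union":
        return net.node_universe | ce.effect_genes
    raise ValueError(f"unknown universe_mode {universe_mode!r}")


def randomize_cause_effect(
    ce: CauseEffectNetwork, universe: set[str], seed
) -> CauseEffectNetwork:
    """One randomized data set: same causes, same per-cause effect-set
    sizes, effects drawn uniformly without replacement from the
    universe minus the cause itself."""
    rng = _as_rng(seed)
    uni = sorted(universe)
    pairs: dict[str, set[str]] = {}
    for cause in ce.causes:
        pool = [g for g in uni if g != cause]
        k = len(ce.pairs[cause])
        if k > len(pool):
            raise ValueError(
                f"universe too small to randomize cause {cause!r}: "
                f"needs {k} genes, has {len(pool)}"
            )
        drawn = rng.choice(len(pool), size=k, replace=False)
        pairs[cause] = {pool[i] for i in drawn}
    return CauseEffectNetwork(pairs, causes=list(ce.causes))


def _null_sample_indices(
    rng: np.random.Generator, n_random: int, pool_size: int, k: int
) -> np.ndarray:
    """n_random independent samples of k indices without replacement."""
    keys = rng.random((n_random, pool_size))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def perturbation_enrichment_many(
    net: IntegratedNetwork,
    ce: CauseEffectNetwork,
    path_types: list[PathType],
    n_random: int = 10000,
    universe_mode: str = "union",
    seed=None,
) -> list[EnrichmentResult]:
    """Perturbation-randomization enrichment for several path types.

    One ensemble of randomized data sets is drawn and every path type
    is scored against the same ensemble, mirroring how a randomized
    data set is scored for each path in turn.  Because the per-terminal
    path tally from a cause does not depend on the effect sets, each
    randomization reduces to re-sampling which terminals count.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    for pt in path_types:
        net.validate_path_type(pt)
    universe = resolve_universe(net, ce, universe_mode)
    root = np.random.SeedSequence(seed if seed is not None else 0)
    streams = root.spawn(len(ce.causes))

    observed = np.zeros(len(path_types), dtype=np.int64)
    null = np.zeros((len(path_types), n_random), dtype=np.float64)
    for ci, cause in enumerate(ce.causes):
        pool = sorted(universe - {cause})
        effects = ce.pairs[cause]
        k = len(effects)
        if k > len(pool):
            raise ValueError(
                f"universe too small to randomize cause {cause!r}: "
                f"needs {k} genes, has {len(pool)}"
            )
        rng = np.random.default_rng(streams[ci])
        idx = _null_sample_indices(rng, n_random, len(pool), k)
        for ti, pt in enumerate(path_types):
            counts = path_counts(net, cause, pt)
            observed[ti] += sum(counts.get(e, 0) for e in effects)
            if counts:
                vec = np.array([counts.get(g, 0) for g in pool], dtype=np.float64)
                null[ti] += vec[idx].sum(axis=1)
    return [
        _result_from_null(pt, int(observed[ti]), null[ti], "perturbation_randomization")
        for ti, pt in enumerate(path_types)
    ]


def perturbation_enrichment(
    net: IntegratedNetwork,
    ce: CauseEffectNetwork,
    path_type: PathType,
    n_random: int = 10000,
    universe_mode: str = "union",
    seed=None,
) -> EnrichmentResult:
    """Perturbation-randomization enrichment for one path type."""
    return perturbation_enrichment_many(
        net, ce, [path_type], n_random=n_random, universe_mode=universe_mode, seed=seed
    )[0]


# ---------------------------------------------------------------------------
# network randomization
# ---------------------------------------------------------------------------

def build_projection(
    net: IntegratedNetwork, causes: list[str], path_type: PathType
) -> nx.DiGraph:
    """Directed pair network: cause -> g wherever >=1 instance exists."""
    if not causes:
        raise ValueError("causes must be non-empty")
    g = nx.DiGraph()
    g.add_nodes_from(causes)
    for cause in causes:
        for target in sorted(reach(net, cause, path_type)):
            g.add_edge(cause, target)
    return g


def _swap_chunk_python(src, dst, adj, proposals, n_needed):
    """Pure-python fallback for the swap kernel (same semantics)."""
    done = 0
    for k in range(proposals.shape[0]):
        if done >= n_needed:
            return done, k
        i, j = proposals[k, 0], proposals[k, 1]
        a, b = src[i], dst[i]
        c, d = src[j], dst[j]
        if b == d or a == c or a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[c, d] = False
        adj[a, d] = True
        adj[c, b] = True
        dst[i] = d
        dst[j] = b
        done += 1
    return done, proposals.shape[0]


try:  # optional compiled kernel; semantics identical to the fallback
    from numba import njit as _njit

    _swap_chunk = _njit(cache=True)(_swap_chunk_python)
except ImportError:  # pragma: no cover - depends on environment
    _swap_chunk = _swap_chunk_python


def _swap_arrays(
    src: np.ndarray,
    dst: np.ndarray,
    adj: np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> int:
    """In-place double-edge swaps (a->b, c->d => a->d, c->b).

    ``adj`` is the boolean adjacency matrix of the current edge set and
    is kept in sync.  Swaps creating duplicate edges or self-loops are
    rejected.  Returns the number of successful swaps; bails out after
    ``max_attempts`` proposals so frozen configurations (where every
    swap is rejected) still terminate.
    """
    n_edges = src.size
    if max_attempts is None:
        max_attempts = max(200 * n_swaps, 1000)
    done = 0
    attempts = 0
    while done < n_swaps and attempts < max_attempts:
        chunk = min(max(2 * (n_swaps - done), 64), max_attempts - attempts)
        proposals = rng.integers(0, n_edges, size=(chunk, 2))
        d, used = _swap_chunk(src, dst, adj, proposals, n_swaps - done)
        done += d
        attempts += used
    return done


def degree_preserving_randomize(
    pairs_net: nx.DiGraph, n_swaps: int | None = None, seed=None
) -> nx.DiGraph:
    """Rewire a directed pair network keeping every node's in- and
    out-degree fixed, via repeated double-edge swaps (default
    10 x |edges| successful swaps)."""
    edges = sorted(pairs_net.edges())
    if len(edges) < 2:
        logger.warning("degree_preserving_randomize: fewer than 2 edges; returning input")
        return pairs_net.copy()
    rng = _as_rng(seed)
    nodes = sorted(pairs_net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    src = np.array([index[a] for a, b in edges], dtype=np.int64)
    dst = np.array([index[b] for a, b in edges], dtype=np.int64)
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.bool_)
    adj[src, dst] = True
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    done = _swap_arrays(src, dst, adj, n_swaps, rng)
    if done < n_swaps:
        logger.warning(
            "degree_preserving_randomize: only %d of %d swaps achievable", done, n_swaps
        )
    out = nx.DiGraph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[a], nodes[b]) for a, b in zip(src.tolist(), dst.tolist()))
    return out


def network_enrichment_many(
    net: IntegratedNetwork,
    ce: CauseEffectNetwork,
    path_types: list[PathType],
    n_random: int = 10000,
    seed=None,
) -> list[EnrichmentResult]:
    """Network-randomization enrichment for several path types.

    The statistic is a pair count (an edge of the projection that is
    also a real cause--effect pair), because the rewiring operates on
    the projection, where multiplicity of instances is already
    collapsed.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    root = np.random.SeedSequence(seed if seed is not None else 0)
    streams = root.spawn(len(path_types))
    results: list[EnrichmentResult] = []
    for ti, pt in enumerate(path_types):
        proj = build_projection(net, list(ce.causes), pt)
        edges = sorted(proj.edges())
        pair_keys = {(c, e) for c in ce.causes for e in ce.pairs[c]}
        observed = sum(1 for e in edges if e in pair_keys)
        rng = np.random.default_rng(streams[ti])
        if len(edges) < 2:
            # nothing to rewire: the null is degenerate at the observed value
            null = np.full(n_random, float(observed))
            results.append(_result_from_null(pt, observed, null, "network_randomization"))
            continue
        nodes = sorted(proj.nodes() | {g for k in pair_keys for g in k})
        index = {n: i for i, n in enumerate(nodes)}
        n_nodes = len(nodes)
        src0 = np.array([index[a] for a, b in edges], dtype=np.int64)
        dst0 = np.array([index[b] for a, b in edges], dtype=np.int64)
        pair_codes = np.fromiter(
            sorted(index[c] * n_nodes + index[e] for c, e in pair_keys),
            dtype=np.int64,
            count=len(pair_keys),
        )
        n_swaps = 10 * len(edges)
        null = np.empty(n_random, dtype=np.float64)
        adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
        for r in range(n_random):
            src = src0.copy()
            dst = dst0.copy()
            adj[:] = False
            adj[src, dst] = True
            _swap_arrays(src, dst, adj, n_swaps, rng)
            codes = src * n_nodes + dst
            pos = np.searchsorted(pair_codes, codes)
            pos[pos == pair_codes.size] = 0
            null[r] = int(np.count_nonzero(pair_codes[pos] == codes))
        results.append(_result_from_null(pt, observed, null, "network_randomization"))
    return results


def network_enrichment(
    net: IntegratedNetwork,
    ce: CauseEffectNetwork,
    path_type: PathType,
    n_random: int = 10000,
    seed=None,
) -> EnrichmentResult:
    """Network-randomization enrichment for one path type."""
    return network_enrichment_many(net, ce, [path_type], n_random=n_random, seed=seed)[0]


# ---------------------------------------------------------------------------
# hypergeometric tests
# ---------------------------------------------------------------------------

def hypergeometric_reach_test(
    net: IntegratedNetwork,
    cause: str,
    effects: set[str],
    path_type: PathType,
    universe: set[str],
) -> float:
    """Upper-tail hypergeometric overlap between the genes reachable
    from ``cause`` by the path type and its perturbed effect set."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if cause in effects:
        raise ValueError("cause must not be one of its own effects")
    uni = universe - {cause}
    reached = reach(net, cause, path_type) & uni
    eff = effects & uni
    overlap = len(reached & eff)
    return float(stats.hypergeom.sf(overlap - 1, len(uni), len(reached), len(eff)))


def per_cause_specificity(
    net: IntegratedNetwork,
    ce: CauseEffectNetwork,
    path_types: list[PathType],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cause path specificity table.

    For every (cause, path type) pair, the hypergeometric reach test
    p-value and the number of that cause's effects explained by the
    type.  Rows are sorted by cause, then ascending p, so each cause's
    preferred paths head its block.
    """
    if universe is None:
        universe = net.node_universe | ce.effect_genes
    rows = []
    for cause in ce.causes:
        effects = ce.pairs[cause]
        for pt in path_types:
            reached = reach(net, cause, pt)
            p = hypergeometric_reach_test(net, cause, effects, pt, universe)
            rows.append(
                {
                    "cause": cause,
                    "path_type": pt.name,
                    "p_value": p,
                    "n_explained": len(reached & effects),
                }
            )
    df = pd.DataFrame(rows, columns=["cause", "path_type", "p_value", "n_explained"])
    return df.sort_values(["cause", "p_value"], kind="stable").reset_index(drop=True)


def write_enrichment_tsv(results: list[EnrichmentResult], path, header: str | None = None) -> None:
    """Enrichment table: one row per path type, p in 3-sig-digit
    scientific notation."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write(header + "\n")
        fh.write("path_type\tobserved\tnull_mean\tnull_sd\tz\tp_value\tmethod\tn_random\n")
        for r in results:
            z = "" if r.z is None or not math.isfinite(r.z) else f"{r.z:.4f}"
            fh.write(
                f"{r.path_type.name}\t{r.observed}\t{r.null_mean:.4f}\t{r.null_sd:.4f}\t"
                f"{z}\t{r.p_value:.3g}\t{r.method}\t{r.n_random}\n"
            )
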