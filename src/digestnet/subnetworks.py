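"""Methanogen-centered subnetwork extraction and guild enrichment.

Subnetworks are grown from hydrogenotrophic-methanogen seed nodes out to
two co-occurrence edges (primary + secondary neighbours); neighbourhoods
that share nodes are merged.  Whether a subnetwork is unusually rich in
syntrophs and methanogens is judged against random draws of equally many
nodes from the parent network — a permutation test whose closed-form twin
is the multivariate hypergeometric distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datatypes import ValidationError

__all__ = [
    "Subnetwork",
    "EnrichmentResult",
    "extract_subnetworks",
    "guild_enrichment",
    "guild_enrichment_exact",
]


@dataclass
class Subnetwork:
    id: int
    nodes: frozenset
    seeds: frozenset
    n_syntrophs: int
    n_methanogens: int

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class EnrichmentResult:
    subnetwork_id: int
    observed_syntrophs: int
    observed_methanogens: int
    probability: float  # empirical, raw (can be 0)
    n_perm: int
    seed: int
    mode: str
    exact_probability: float | None = None


def _guild(net: nx.Graph, node) -> str:
    return net.nodes[node].get("guild") or "other"


def extract_subnetworks(
    net: nx.Graph,
    seed_guild: str = "hydrogenotrophic_methanogen",
    max_hops: int = 2,
) -> list[Subnetwork]:
    """Neighbourhoods of radius ``max_hops`` around each seed-guild node.

    Overlapping neighbourhoods are merged into a single subnetwork (a
    large subnetwork can form from several smaller but contiguous ones).
    Subnetworks are numbered 1.. by descending size, ties by smallest
    member id; output is invariant to node insertion order.
    """
    seeds = sorted(n for n in net.nodes if _guild(net, n) == seed_guild)
    if not seeds:
        warnings.warn(f"no nodes with guild {seed_guild!r}; no subnetworks")
        return []
    neighbourhoods = []
    for seed in seeds:
        reach = nx.single_source_shortest_path_length(net, seed, cutoff=max_hops)
        neighbourhoods.append((seed, frozenset(reach)))
    # union-find merge of overlapping neighbourhoods
    parent = list(range(len(neighbourhoods)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(neighbourhoods)):
        for j in range(i + 1, len(neighbourhoods)):
            if neighbourhoods[i][1] & neighbourhoods[j][1]:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(neighbourhoods)):
        groups.setdefault(find(i), []).append(i)

    subs = []
    for members in groups.values():
        nodes = frozenset().union(*(neighbourhoods[i][1] for i in members))
        seed_set = frozenset(neighbourhoods[i][0] for i in members)
        guilds = [_guild(net, n) for n in nodes]
        subs.append(
            Subnetwork(
                id=0, nodes=nodes, seeds=seed_set,
                n_syntrophs=guilds.count("syntroph"),
                n_methanogens=guilds.count("hydrogenotrophic_methanogen"),
            )
        )
    subs.sort(key=lambda s: (-s.size, min(str(n) for n in s.nodes)))
    for rank, sub in enumerate(subs, start=1):
        sub.id = rank
    return subs


def _meets(i: int, j: int, s: int, m: int, mode: str) -> bool:
    if mode == "at_least":
        return i >= s and j >= m
    if mode == "exact_counts":
        return i == s and j == m
    raise ValueError(f"unknown mode {mode!r}")


def guild_enrichment(
    net: nx.Graph,
    subnet: Subnetwork,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "at_least",
    pseudocount: bool = False,
) -> EnrichmentResult:
    """Permutation probability of the subnetwork's guild composition.

    Draws ``subnet.size`` nodes uniformly without replacement from the
    parent network ``n_perm`` times and reports the fraction of draws whose
    syntroph and hydrogenotrophic-methanogen counts meet the observed
    counts under ``mode`` (jointly >= for ``at_least``, == for
    ``exact_counts``).  The closed-form multivariate hypergeometric value
    is attached for comparison.  ``pseudocount`` switches to the
    ``(r+1)/(B+1)`` convention for downstream inference.
    """
    nodes = list(net.nodes)
    k = subnet.size
    if k > len(nodes):
        raise ValidationError("subnetwork larger than its parent network")
    guilds = np.array([_guild(net, n) for n in nodes])
    is_syn = (guilds == "syntroph").astype(np.int64)
    is_met = (guilds == "hydrogenotrophic_methanogen").astype(np.int64)
    s, m = subnet.n_syntrophs, subnet.n_methanogens
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(len(nodes), size=k, replace=False)
        if _meets(int(is_syn[draw].sum()), int(is_met[draw].sum()), s, m, mode):
            hits += 1
    prob = (hits + 1) / (n_perm + 1) if pseudocount else hits / n_perm
    exact = guild_enrichment_exact(
        len(nodes), int(is_syn.sum()), int(is_met.sum()), k, s, m, mode
    )
    return EnrichmentResult(subnet.id, s, m, prob, n_perm, seed, mode, exact)


def guild_enrichment_exact(
    N: int, S: int, M: int, k: int, s: int, m: int, mode: str = "at_least"
) -> float:
    """Multivariate hypergeometric probability of the guild composition.

    ``P = sum over (i, j) meeting the mode criterion of
    C(S,i) C(M,j) C(N-S-M, k-i-j) / C(N,k)`` for a draw of ``k`` nodes from
    ``N`` containing ``S`` syntrophs and ``M`` methanogens.
    """
    if S < 0 or M < 0 or s < 0 or m < 0 or S + M > N or k > N:
        raise ValidationError("inconsistent counts")
    other = N - S - M
    denom = math.comb(N, k)
    total = 0
    for i in range(0, min(S, k) + 1):
        for j in range(0, min(M, k - i) + 1):
            rest = k - i - j
            if rest > other:
                continue
            if _meets(i, j, s, m, mode):
                total += math.comb(S, i) * math.comb(M, j) * math.comb(other, rest)
    return total / denom
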