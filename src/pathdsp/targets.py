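"""Drug target expansion for the DG-Net seed sets.

Each drug's primary targets are expanded with its curated off-target genes
and then with the first-order neighbours of that union in the PPI network.
Drugs without any target, or whose targets all miss the network, are
dropped and reported (mirroring the exclusion of drugs lacking usable
target information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["DrugGeneSets", "expand_targets"]


@dataclass
class DrugGeneSets:
    """Expanded per-drug gene sets with per-gene provenance.

    ``provenance[drug][gene]`` is one of ``primary``, ``off_target`` or
    ``neighbor`` (primary wins over off_target wins over neighbor when a
    gene qualifies for several).
    """

    sets: dict[str, set[str]]
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)  # drug -> reason

    def __getitem__(self, drug: str) -> set[str]:
        return self.sets[drug]

    def mean_size(self) -> float:
        return sum(len(s) for s in self.sets.values()) / max(len(self.sets), 1)


def expand_targets(
    primary: dict[str, set[str]],
    off_targets: dict[str, set[str]] | None,
    network: nx.Graph,
) -> DrugGeneSets:
    """Expand ``primary ∪ off_targets`` with first-order PPI neighbours.

    Target genes absent from the network are retained in the set (they
    simply contribute no neighbours). A drug is dropped when it has no
    targets at all or none of its targets maps to the network.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("PPI network is empty")
    off_targets = off_targets or {}
    sets: dict[str, set[str]] = {}
    provenance: dict[str, dict[str, str]] = {}
    dropped: dict[str, str] = {}
    for drug in dict.fromkeys([*primary, *off_targets]):
        prim = set(primary.get(drug, set()))
        off = set(off_targets.get(drug, set()))
        base = prim | off
        if not base:
            dropped[drug] = "no target information"
            continue
        mapped = [g for g in base if g in network]
        if not mapped:
            dropped[drug] = "no target on the PPI network"
            continue
        neighbors = set()
        for g in mapped:
            neighbors.update(network.neighbors(g))
        expanded = base | neighbors
        prov = {g: "neighbor" for g in expanded}
        prov.update({g: "off_target" for g in off})
        prov.update({g: "primary" for g in prim})
        sets[drug] = expanded
        provenance[drug] = prov
    if dropped:
        logger.warning("dropped %d drugs: %s", len(dropped), dropped)
    return DrugGeneSets(sets=sets, provenance=provenance, dropped=dropped)
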