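"""Overlapped-network assembly across the per-subset top networks.

Each subset's top network contributes the edges incident to the traits of
interest; the union of those edges (and their incident nodes) forms the
overlapped network.  Membership is direction-agnostic — parents and children
of a trait both count as direct links — while the orientations observed per
edge are kept as metadata.  An edge's multiplicity counts how many subset
networks contained it in either orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bn import DAGNetwork
from .errors import ValidationError

TRAITS_OF_INTEREST = (
    "clutch_size",
    "first_week_mortality",
    "rearing_abnormalities",
    "natural_death",
    "rearing_success",
)


def direct_neighbors(network: DAGNetwork, node: str) -> set[str]:
    """Parents and children of ``node`` (direction ignored for membership)."""
    if node not in network.nodes:
        raise ValidationError(f"node {node!r} not present in network")
    return network.parents(node) | network.children(node)


@dataclass
class OverlappedNetwork:
    """Union of trait-incident edges across networks with multiplicities."""

    phenotype_nodes: set[str]
    snp_nodes: set[str]
    multiplicity: dict[frozenset, int] = field(default_factory=dict)
    orientations: dict[frozenset, set[tuple[str, str]]] = field(
        default_factory=dict
    )
    traits_of_interest: tuple[str, ...] = TRAITS_OF_INTEREST

    @property
    def nodes(self) -> set[str]:
        return self.phenotype_nodes | self.snp_nodes

    def edge_pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.multiplicity)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for e in self.multiplicity:
            if node in e:
                (other,) = set(e) - {node} or {node}
                out.add(other)
        return out

    @property
    def trait_associations(self) -> dict[str, list[str]]:
        return {
            t: sorted(n for n in self.neighbors(t) if n in self.snp_nodes)
            for t in self.traits_of_interest
        }

    def to_dot(self) -> str:
        lines = ["graph overlapped {"]
        for n in sorted(self.phenotype_nodes):
            lines.append(f'  "{n}" [style=filled, fillcolor=grey];')
        for n in sorted(self.snp_nodes):
            lines.append(
                f'  "{n}" [shape=box, style=filled, fillcolor=yellow];'
            )
        for u, v in self.edge_pairs():
            m = self.multiplicity[frozenset((u, v))]
            lines.append(f'  "{u}" -- "{v}" [label="{m}"];')
        lines.append("}")
        return "\n".join(lines)


def build_overlapped(
    networks: list[DAGNetwork],
    traits_of_interest=TRAITS_OF_INTEREST,
    phenotype_vars=None,
) -> OverlappedNetwork:
    """Union over networks of all edges incident to a trait of interest.

    ``phenotype_vars`` defaults to the union of variables that appear in
    every input network (SNP panels differ per subset; phenotypes do not).
    """
    if not networks:
        raise ValidationError("cannot overlap an empty list of networks")
    for net in networks:
        for t in traits_of_interest:
            if t not in net.nodes:
                raise ValidationError(
                    f"trait of interest {t!r} missing from a network"
                )
    if phenotype_vars is None:
        phenotype_vars = set.intersection(*(set(n.nodes) for n in networks))
    phenotype_vars = set(phenotype_vars)
    multiplicity: dict[frozenset, int] = {}
    orientations: dict[frozenset, set[tuple[str, str]]] = {}
    nodes: set[str] = set(traits_of_interest)
    for net in networks:
        seen_here = set()
        for u, v in net.edges:
            if u not in traits_of_interest and v not in traits_of_interest:
                continue
            key = frozenset((u, v))
            orientations.setdefault(key, set()).add((u, v))
            if key not in seen_here:
                multiplicity[key] = multiplicity.get(key, 0) + 1
                seen_here.add(key)
            nodes.update((u, v))
    return OverlappedNetwork(
        phenotype_nodes={n for n in nodes if n in phenotype_vars},
        snp_nodes={n for n in nodes if n not in phenotype_vars},
        multiplicity=multiplicity,
        orientations=orientations,
        traits_of_interest=tuple(traits_of_interest),
    )


def summarize_associations(overlapped: OverlappedNetwork):
    """Per-trait linked-SNP counts plus the distinct total.

    SNPs linked to several traits count once in the total, mirroring the
    single-entry rule used during SNP selection.
    """
    assoc = overlapped.trait_associations
    rows = [
        {"trait": t, "n_linked_snps": len(snps), "snp_ids": snps}
        for t, snps in assoc.items()
    ]
    distinct = set()
    for snps in assoc.values():
        distinct.update(snps)
    return {"per_trait": rows, "total_distinct_snps": len(distinct)}
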