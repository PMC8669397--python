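"""Combinatorics of multi-site cysteine cross-linking.

Each engineered cysteine pair (site) reacts with the bifunctional thiol
cross-linker independently with efficiency p_i. Enumerating all 2^k
subsets of formed sites yields the expected distribution of covalent
species; connected components over the chain graph identify which chains
are covalently fused, and cycles of the multigraph identify covalently
circularized compartments (ring, clamp, frame). The same independence
model inverts observed precursor depletions to implied site efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import networkx as nx

from muklock.errors import DataError

#: compartment circles named by the exact set of sites closing them
DEFAULT_COMPARTMENTS: dict[frozenset, str] = {
    frozenset({"cap", "neck", "hinge"}): "ring",
    frozenset({"cap", "neck", "head"}): "clamp",
    frozenset({"head", "hinge"}): "frame",
}


@dataclass(frozen=True)
class Chain:
    chain_id: str
    type: str
    reporter: bool = False


@dataclass(frozen=True)
class CrosslinkSite:
    """A cysteine pair bridging two chain attachment points.

    ``endpoints`` is a pair of (chain_id, coordinate in [0, 1] along the
    chain); the two endpoints must differ in chain or coordinate.
    """

    name: str
    endpoints: tuple
    efficiency: float

    def __post_init__(self) -> None:
        (c1, x1), (c2, x2) = self.endpoints
        if c1 == c2 and x1 == x2:
            raise DataError(f"site {self.name}: endpoints coincide")
        for x in (x1, x2):
            if not 0.0 <= x <= 1.0:
                raise DataError(f"site {self.name}: coordinates must be in [0,1]")
        if not 0.0 <= self.efficiency <= 1.0:
            raise DataError(f"site {self.name}: efficiency must be in [0,1]")


@dataclass(frozen=True)
class ComplexTemplate:
    chains: tuple
    sites: tuple
    compartments: Mapping[frozenset, str] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENTS))

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise DataError("chain ids must be unique")
        reporter_types = {c.type for c in self.chains if c.reporter}
        if len(reporter_types) != 1:
            raise DataError("exactly one reporter chain type is required")
        known = set(ids)
        for s in self.sites:
            for cid, _ in s.endpoints:
                if cid not in known:
                    raise DataError(f"site {s.name} references unknown chain {cid}")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise DataError("site names must be unique")

    def site(self, name: str) -> CrosslinkSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class SpeciesOutcome:
    formed_sites: frozenset
    probability: float
    reporter_component: frozenset
    circles: frozenset


@dataclass(frozen=True)
class SpeciesDistribution:
    outcomes: tuple  # of SpeciesOutcome


def default_template(
    efficiencies: Mapping[str, float] | None = None,
) -> ComplexTemplate:
    """The shipped MukBEF template.

    Chains are the two MukB protomers (kappa and nu, the reporter type:
    detection is via the fluorescent tag on MukB) and the kleisin MukF.
    Sites: hinge (kappa-nu), cap (MukF-kappa), neck (MukF-nu) and head
    (kappa-nu at the engaged ATPase heads). MukE carries no cysteines in
    this scheme and is omitted. Default efficiencies are the observed
    single-site values: hinge 0.62, head 0.29; cap and neck default to
    0.5 and should be overridden with measured values.
    """
    p = {"hinge": 0.62, "cap": 0.5, "neck": 0.5, "head": 0.29}
    if efficiencies:
        p.update(efficiencies)
    chains = (
        Chain("MukB_kappa", "MukB", reporter=True),
        Chain("MukB_nu", "MukB", reporter=True),
        Chain("MukF", "MukF", reporter=False),
    )
    sites = (
        CrosslinkSite("hinge", (("MukB_kappa", 0.5), ("MukB_nu", 0.5)), p["hinge"]),
        CrosslinkSite("cap", (("MukF", 0.9), ("MukB_kappa", 0.1)), p["cap"]),
        CrosslinkSite("neck", (("MukF", 0.5), ("MukB_nu", 0.85)), p["neck"]),
        CrosslinkSite("head", (("MukB_kappa", 0.05), ("MukB_nu", 0.05)), p["head"]),
    )
    return ComplexTemplate(chains=chains, sites=sites)


def find_covalent_circles(
    template: ComplexTemplate,
    formed_sites: Iterable[str],
) -> set[str]:
    """Covalent circles closed by a set of formed sites.

    Chains are nodes and formed sites are edges of a multigraph; every
    simple cycle (edge subset that is connected with all incident vertices
    of degree two; a single intra-chain site counts as a one-edge loop) is
    reported. Cycles matching the template's compartment table are named
    (ring/clamp/frame); others are reported as the '+'-joined sorted site
    names.
    """
    formed = set(formed_sites)
    unknown = formed - {s.name for s in template.sites}
    if unknown:
        raise DataError(f"unknown sites: {sorted(unknown)}")
    edges = []
    for s in template.sites:
        if s.name in formed:
            (c1, _), (c2, _) = s.endpoints
            edges.append((s.name, c1, c2))

    circles: set[str] = set()
    for r in range(1, len(edges) + 1):
        for subset in combinations(edges, r):
            deg: dict[str, int] = {}
            for _, c1, c2 in subset:
                deg[c1] = deg.get(c1, 0) + 1
                deg[c2] = deg.get(c2, 0) + 1
            if any(d != 2 for d in deg.values()):
                continue
            g = nx.MultiGraph()
            for name, c1, c2 in subset:
                g.add_edge(c1, c2, key=name)
            if nx.number_connected_components(g) != 1:
                continue
            key = frozenset(name for name, _, _ in subset)
            circles.add(template.compartments.get(key, "+".join(sorted(key))))
    return circles


def enumerate_species(template: ComplexTemplate) -> SpeciesDistribution:
    """Expected distribution over all 2^k cross-linking outcomes.

    Site reactions are modelled as independent Bernoulli events with the
    declared efficiencies. Each outcome records the covalent component
    containing the (first) reporter chain and the covalent circles formed.
    """
    sites = template.sites
    if len(sites) > 20:
        raise DataError(
            "more than 20 sites: exhaustive enumeration is infeasible, "
            "use a sampling approach"
        )
    reporter_chain = next(c.chain_id for c in template.chains if c.reporter)
    outcomes = []
    for mask in product([False, True], repeat=len(sites)):
        prob = 1.0
        formed = []
        for site, on in zip(sites, mask):
            prob *= site.efficiency if on else (1.0 - site.efficiency)
            if on:
                formed.append(site.name)
        g = nx.Graph()
        g.add_nodes_from(c.chain_id for c in template.chains)
        for name in formed:
            (c1, _), (c2, _) = template.site(name).endpoints
            g.add_edge(c1, c2)
        component = frozenset(nx.node_connected_component(g, reporter_chain))
        circles = find_covalent_circles(template, formed) if formed else set()
        outcomes.append(SpeciesOutcome(
            formed_sites=frozenset(formed),
            probability=prob,
            reporter_component=component,
            circles=frozenset(circles),
        ))
    total = sum(o.probability for o in outcomes)
    if abs(total - 1.0) > 1e-12:
        raise AssertionError(f"outcome probabilities sum to {total}, not 1")
    return SpeciesDistribution(outcomes=tuple(outcomes))


def infer_site_efficiency(fraction_alone: float, fraction_combined: float) -> float:
    """Implied efficiency of a second site from precursor depletion.

    Under independence, adding a second cross-linkable site depletes a
    precursor species by the factor (1 - p2):
    p2 = 1 - fraction_combined / fraction_alone.
    """
    if not 0 < fraction_alone <= 1:
        raise DataError("fraction_alone must be in (0, 1]")
    if not 0 <= fraction_combined <= fraction_alone:
        raise DataError(
            "fraction_combined must be in [0, fraction_alone]: observed "
            "enrichment violates the independence model"
        )
    return 1.0 - fraction_combined / fraction_alone
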