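"""Microscopic-reversibility (detailed balance) diagnostics.

Around any closed cycle of reversible binding reactions the product of
equilibrium constants must equal one; otherwise the network supports a
perpetual flux at equilibrium.  The substrate-selective inhibitor scheme is
the delicate case: the compound binds the p38-MK2 complex tighter (K_I)
than free p38 (K_I/(1-f)), so the MK2 dissociation rate from
inhibitor-bound complexes must carry a compensating (1-f) factor.  This
module enumerates the binding cycles and reports the cycle products so that
a missing correction is caught mechanically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .network import NetworkModel

__all__ = ["CycleReport", "check_thermodynamic_cycles"]

#: all cycles in the generated networks are squares or their compositions;
#: length 8 bounds every elementary cycle that can appear.
MAX_CYCLE_LEN = 8


@dataclass
class CycleReport:
    """One closed binding cycle and its product of equilibrium constants."""

    species: tuple[str, ...]
    product: float
    consistent: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        arrow = " -> ".join(self.species)
        flag = "ok" if self.consistent else "VIOLATION"
        return f"<Cycle {arrow}: prod={self.product:.6g} [{flag}]>"


def _carrier(reaction, model: NetworkModel) -> str:
    """The reactant that carries the complex identity (enzyme-containing
    when possible)."""
    names = [n for n, _ in reaction.reactants]
    for n in names:
        if model.species[model.index(n)].composition.get("p38"):
            return n
    return names[0]


def check_thermodynamic_cycles(
    model: NetworkModel, rtol: float = 1e-10
) -> list[CycleReport]:
    """Enumerate closed cycles of reversible reactions and report
    ``prod(kf/kr)`` around each.

    Only composition-balanced cycles (net stoichiometric change zero) are
    thermodynamic cycles; unbalanced graph cycles are skipped.  A
    consistent network has every product equal to 1 within ``rtol``.
    """
    G = nx.Graph()
    edge_rxn: dict[frozenset, object] = {}
    for r in model.reactions:
        if not r.reversible or not r.kr or not r.kf:
            continue
        if len(r.reactants) == 2 and len(r.products) == 1:
            a, c = _carrier(r, model), r.products[0][0]
        elif len(r.reactants) == 1 and len(r.products) == 2:
            # written as dissociation; treat symmetrically
            a, c = r.reactants[0][0], _carrier_products(r, model)
        else:
            continue
        key = frozenset((a, c))
        if key in edge_rxn:  # parallel edge would hide a cycle; not produced
            raise NotImplementedError("parallel reversible reactions")
        G.add_edge(a, c)
        edge_rxn[key] = r

    reports: list[CycleReport] = []
    for cycle in nx.simple_cycles(G, length_bound=MAX_CYCLE_LEN):
        product = 1.0
        net: Counter = Counter()
        ok = True
        for u, v in zip(cycle, cycle[1:] + cycle[:1]):
            r = edge_rxn[frozenset((u, v))]
            complex_name = r.products[0][0]
            sign = +1 if v == complex_name else -1
            product *= (r.kf / r.kr) ** sign
            for n, nu in r.reactants:
                net[n] -= sign * nu
            for n, nu in r.products:
                net[n] += sign * nu
        if any(net.values()):
            continue  # not composition balanced -> not a thermodynamic cycle
        consistent = abs(product - 1.0) <= rtol
        reports.append(CycleReport(tuple(cycle), product, consistent))
    return reports


def _carrier_products(r, model):  # pragma: no cover - not produced by builder
    for n, _ in r.products:
        if model.species[model.index(n)].composition.get("p38"):
            return n
    return r.products[0][0]
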