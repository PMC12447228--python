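"""Structural-equation model specification.

A :class:`SemModel` couples a reflective measurement model (constructs and
their indicator blocks) with a structural model (a directed acyclic graph of
standardized paths between constructs).  It is the common specification
object consumed by the synthetic-data generator, the PLS estimator and the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import yaml

__all__ = ["SemModel", "ModelSpecError"]


class ModelSpecError(ValueError):
    """Raised for structurally invalid model specifications."""


@dataclass(frozen=True)
class SemModel:
    """Constructs, reflective indicator blocks and directed structural paths.

    Parameters
    ----------
    blocks
        Mapping construct name -> ordered list of indicator (column) names.
        Every construct is reflective (Mode A) and owns at least one
        indicator; an indicator belongs to exactly one block.
    paths
        Directed edges ``(source construct, target construct)``.  The edge
        set must form a DAG.
    """

    blocks: dict[str, list[str]]
    paths: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ModelSpecError("model needs at least one construct")
        seen: dict[str, str] = {}
        for construct, indicators in self.blocks.items():
            if not indicators:
                raise ModelSpecError(f"construct {construct!r} has no indicators")
            for ind in indicators:
                if ind in seen:
                    raise ModelSpecError(
                        f"indicator {ind!r} appears in blocks {seen[ind]!r} and {construct!r}"
                    )
                seen[ind] = construct
        object.__setattr__(self, "paths", tuple(tuple(e) for e in self.paths))
        for src, dst in self.paths:
            for c in (src, dst):
                if c not in self.blocks:
                    raise ModelSpecError(f"path endpoint {c!r} is not a construct")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ModelSpecError(f"structural model contains a cycle: {cycle}")

    # -- graph views -------------------------------------------------------

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.blocks)
        g.add_edges_from(self.paths)
        return g

    @property
    def constructs(self) -> list[str]:
        return list(self.blocks)

    @property
    def indicators(self) -> list[str]:
        """All indicator names in block order."""
        return [ind for block in self.blocks.values() for ind in block]

    def topological_order(self) -> list[str]:
        """Construct order with every predecessor before its successors.

        Ties are broken by declaration order so the result is deterministic.
        """
        order_index = {c: i for i, c in enumerate(self.blocks)}
        return list(
            nx.lexicographical_topological_sort(self.graph(), key=order_index.__getitem__)
        )

    def predecessors(self, construct: str) -> list[str]:
        return [s for s, t in self.paths if t == construct]

    def successors(self, construct: str) -> list[str]:
        return [t for s, t in self.paths if s == construct]

    @property
    def exogenous(self) -> list[str]:
        return [c for c in self.blocks if not self.predecessors(c)]

    @property
    def endogenous(self) -> list[str]:
        return [c for c in self.blocks if self.predecessors(c)]

    def block_of(self, indicator: str) -> str:
        for construct, inds in self.blocks.items():
            if indicator in inds:
                return construct
        raise KeyError(indicator)

    # -- editing -----------------------------------------------------------

    def drop_indicator(self, indicator: str) -> "SemModel":
        """Return a copy without ``indicator`` (its block must keep >=1)."""
        construct = self.block_of(indicator)
        if len(self.blocks[construct]) == 1:
            raise ModelSpecError(
                f"cannot drop {indicator!r}: it is the last indicator of {construct!r}"
            )
        blocks = {c: [i for i in inds if i != indicator] for c, inds in self.blocks.items()}
        return SemModel(blocks=blocks, paths=self.paths)

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_dict(cls, spec: dict) -> "SemModel":
        try:
            blocks = {str(c): [str(i) for i in inds] for c, inds in spec["blocks"].items()}
            paths = [(str(s), str(t)) for s, t in spec.get("paths", [])]
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelSpecError(f"malformed model spec: {exc}") from exc
        return cls(blocks=blocks, paths=tuple(paths))

    @classmethod
    def from_yaml(cls, path: str) -> "SemModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "blocks": {c: list(inds) for c, inds in self.blocks.items()},
            "paths": [list(e) for e in self.paths],
        }

    def to_dot(self) -> str:
        """GraphViz DOT rendering of the structural diagram."""
        lines = ["digraph sem {", "  rankdir=LR;"]
        for c in self.blocks:
            lines.append(f'  "{c}" [shape=ellipse];')
        for s, t in self.paths:
            lines.append(f'  "{s}" -> "{t}";')
        lines.append("}")
        return "\n".join(lines)
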