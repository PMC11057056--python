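"""Rooted species trees with branch lengths.

Thin tree container tailored to the likelihood engine: nodes are integer
ids in postorder, every non-root node carries a branch length in expected
substitutions per codon site.  Parsing and serialization delegate to
dendropy's newick support.

The default topology is the five-taxon chordate tree used throughout the
analysis: the coelacanth *Latimeria menadoensis* as outgroup, the chimaera
*Callorhinchus milii* next, then the catshark *Scyliorhinus retifer*, with
the little skate *Leucoraja erinacea* sister to the smalltooth sawfish
*Pristis pectinata*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

FIVE_TAXON_TAXA = (
    "L_menadoensis",
    "C_milii",
    "S_retifer",
    "L_erinacea",
    "P_pectinata",
)

#: Default branch lengths (expected substitutions per codon).  The source
#: phylogeny reports only divergence times — all splits are ancient (the
#: skate/sawfish split is roughly 270 My old, the coelacanth split over
#: 400 My) — so defaults reflect deep-divergence coding sequence: several
#: tenths of a substitution per codon on terminal branches, longest on the
#: oldest lineages.
FIVE_TAXON_NEWICK = (
    "(L_menadoensis:0.70,(C_milii:0.60,(S_retifer:0.50,"
    "(L_erinacea:0.40,P_pectinata:0.40):0.15):0.15):0.15);"
)


@dataclass
class TreeNode:
    id: int
    name: str | None
    length: float  # branch above this node; 0.0 for the root
    parent: int | None
    children: list[int] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted binary tree with named tips and non-negative branch lengths.

    ``nodes`` is indexed by node id and ordered so that every child precedes
    its parent (postorder); the root is last.
    """

    def __init__(self, nodes: list[TreeNode]):
        self.nodes = nodes
        self._validate()
        self.root = nodes[-1].id
        self.tip_ids = [n.id for n in nodes if n.is_tip]
        self.tip_names = [nodes[i].name for i in self.tip_ids]
        self._name_to_id = {nodes[i].name: i for i in self.tip_ids}

    def _validate(self) -> None:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if self.nodes[-1].parent is not None:
            raise ValueError("nodes must be in postorder with the root last")
        seen = set()
        for n in self.nodes:
            if n.parent is not None:
                if not (n.length >= 0.0) or not n.length < float("inf"):
                    raise ValueError(f"branch length of node {n.id} must be finite and >= 0")
                if n.parent in seen:
                    raise ValueError("child listed after its parent: not postorder")
            if n.children and len(n.children) != 2:
                raise ValueError("tree must be binary")
            seen.add(n.id)
        tips = [n.name for n in self.nodes if n.is_tip]
        if any(t is None for t in tips):
            raise ValueError("every tip must be named")
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")

    # -- construction --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        nodes: list[TreeNode] = []
        ids: dict[object, int] = {}
        for dnode in dt.postorder_node_iter():
            nid = len(nodes)
            ids[dnode] = nid
            name = dnode.taxon.label.replace(" ", "_") if dnode.taxon else (
                dnode.label if dnode.label else None
            )
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            nodes.append(TreeNode(id=nid, name=name, length=float(length), parent=None))
        for dnode in dt.postorder_node_iter():
            for child in dnode.child_nodes():
                nodes[ids[child]].parent = ids[dnode]
                nodes[ids[dnode]].children.append(ids[child])
        return cls(nodes)

    @classmethod
    def default_five_taxon(cls) -> "SpeciesTree":
        return cls.from_newick(FIVE_TAXON_NEWICK)

    # -- queries -------------------------------------------------------------

    def tip_id(self, name: str) -> int:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise KeyError(f"no tip named {name!r}") from None

    def branch_ids(self) -> list[int]:
        """Ids of all nodes that carry a branch (everything but the root)."""
        return [n.id for n in self.nodes if n.parent is not None]

    def branch_name(self, node_id: int) -> str:
        node = self.nodes[node_id]
        if node.name:
            return node.name
        tips = sorted(self.nodes[t].name for t in self._subtree_tips(node_id))
        return "mrca(" + ",".join(tips) + ")"

    def _subtree_tips(self, node_id: int) -> list[int]:
        out, stack = [], [node_id]
        while stack:
            n = self.nodes[stack.pop()]
            if n.is_tip:
                out.append(n.id)
            else:
                stack.extend(n.children)
        return out

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent is not None)

    def with_branch_lengths(self, lengths: dict[int, float]) -> "SpeciesTree":
        nodes = [
            TreeNode(n.id, n.name, lengths.get(n.id, n.length), n.parent, list(n.children))
            for n in self.nodes
        ]
        return SpeciesTree(nodes)

    # -- serialization -------------------------------------------------------

    def to_newick(self) -> str:
        def render(nid: int) -> str:
            n = self.nodes[nid]
            if n.is_tip:
                body = n.name
            else:
                body = "(" + ",".join(render(c) for c in n.children) + ")"
            if n.parent is None:
                return body
            return f"{body}:{n.length:.10g}"

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"SpeciesTree({self.to_newick()})"
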