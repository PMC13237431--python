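"""Gene-tree / species-tree reconciliation and topology tests.

Implements the standard parsimony LCA (lowest-common-ancestor) mapping:
each gene-tree leaf maps to its species; each internal gene node maps to
the species-tree LCA of its children's images; a node is a DUPLICATION iff
its image equals the image of at least one child.  Losses are counted per
gene-tree edge from the species-tree path depth between the parent and
child images, with the usual +1 adjustment below duplication nodes.

On top of this sit two analyses used to argue about duplicative history:

* ``compare_scenarios`` turns "one ancestral duplication vs several
  independent ones" into a computable duplication/loss cost comparison;
* ``species_clustering_test`` checks the gene-conversion expectation that
  a species' paralogs form a species-specific clade.

Trees are consumed and emitted as Newick via dendropy.  Leaf labels follow
the ``geneID|speciesID`` convention (configurable delimiter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy


class TreeError(ValueError):
    """Parse failures, unrooted/polytomous input, duplicate leaves."""


class MappingError(ValueError):
    """A gene-tree species that the species tree does not contain."""


DEFAULT_DELIMITER = "|"


@dataclass
class LabeledTree:
    """A rooted binary tree whose leaves carry (gene_id, species).

    For species trees, gene_id == species.  Wraps a dendropy tree; node
    identity for results is the frozenset of descendant gene_ids.
    """

    tree: dendropy.Tree
    gene_of_leaf: dict[int, str] = field(default_factory=dict)
    species_of_leaf: dict[int, str] = field(default_factory=dict)

    # -- construction ----------------------------------------------------

    @staticmethod
    def from_newick(
        text: str,
        delimiter: str = DEFAULT_DELIMITER,
        allow_polytomies: bool = False,
    ) -> "LabeledTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        tree.is_rooted = True
        poly = [
            nd for nd in tree.preorder_node_iter()
            if len(nd.child_nodes()) > 2
        ]
        if poly:
            if not allow_polytomies:
                raise TreeError(
                    f"tree contains {len(poly)} polytomies; pass "
                    "allow_polytomies=True to auto-resolve"
                )
            tree.resolve_polytomies()
        out = LabeledTree(tree=tree)
        seen = set()
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            if not label:
                raise TreeError("leaf without label")
            if delimiter in label:
                gene, species = label.split(delimiter, 1)
            else:
                gene = species = label
            if gene in seen:
                raise TreeError(f"duplicate leaf gene id {gene!r}")
            seen.add(gene)
            out.gene_of_leaf[id(leaf)] = gene
            out.species_of_leaf[id(leaf)] = species
        return out

    @staticmethod
    def read_newick(path: str | Path, **kwargs) -> "LabeledTree":
        return LabeledTree.from_newick(Path(path).read_text(), **kwargs)

    def write_newick(self, path: str | Path | None = None) -> str:
        text = self.tree.as_string(schema="newick", unquoted_underscores=True)
        text = text.strip()
        if not text.endswith(";"):
            text += ";"
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    # -- accessors -------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaves(self) -> list[dendropy.Node]:
        return list(self.tree.leaf_node_iter())

    def gene_ids(self) -> set[str]:
        return set(self.gene_of_leaf.values())

    def species(self) -> set[str]:
        return set(self.species_of_leaf.values())

    def clade_genes(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(
            self.gene_of_leaf[id(lf)] for lf in node.leaf_iter()
        )

    def postorder(self) -> list[dendropy.Node]:
        return list(self.tree.postorder_node_iter())


@dataclass(frozen=True)
class ReconciliationResult:
    """Event labels per internal gene-tree node plus loss count.

    Nodes are identified by the frozenset of gene ids below them.
    ``mapping`` sends each gene-tree node to the species-tree node it
    embeds into, identified by the frozenset of species below it.
    ``loss_branches`` lists the species-tree branches (by species leafset)
    on which a loss is inferred, with multiplicity.
    """

    node_events: Mapping[frozenset[str], str]  # "SPECIATION" | "DUPLICATION"
    mapping: Mapping[frozenset[str], frozenset[str]]
    n_duplications: int
    n_losses: int
    loss_branches: tuple[frozenset[str], ...]

    @property
    def duplication_clades(self) -> set[frozenset[str]]:
        return {
            clade for clade, ev in self.node_events.items() if ev == "DUPLICATION"
        }


def _species_index(
    species_tree: LabeledTree,
) -> tuple[dict[str, dendropy.Node], dict[int, int], dict[int, int | None]]:
    """Leaf lookup, node depth and parent maps for the species tree."""
    leaf_of_species: dict[str, dendropy.Node] = {}
    for lf in species_tree.leaves():
        leaf_of_species[species_tree.species_of_leaf[id(lf)]] = lf
    depth: dict[int, int] = {}
    parent: dict[int, int | None] = {}
    for nd in species_tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0
            parent[id(nd)] = None
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + 1
            parent[id(nd)] = id(nd.parent_node)
    return leaf_of_species, depth, parent


def lca_reconcile(
    gene_tree: LabeledTree, species_tree: LabeledTree
) -> ReconciliationResult:
    """Reconcile a rooted gene tree with a rooted species tree (LCA method).

    Losses on the edge from gene node u to child v: with d the number of
    species-tree edges from M(u) down to M(v), the edge implies d - 1
    losses if u is a speciation and d if u is a duplication (each species
    branch the lineage passes without speciating, plus the branch on which
    a duplicate copy went missing).
    """
    missing = gene_tree.species() - species_tree.species()
    if missing:
        raise MappingError(
            f"species absent from species tree: {sorted(missing)}"
        )
    leaf_of_species, depth, parent = _species_index(species_tree)
    node_by_id = {id(nd): nd for nd in species_tree.tree.preorder_node_iter()}

    # M: gene node -> species node (by python id)
    M: dict[int, dendropy.Node] = {}
    for node in gene_tree.postorder():
        if node.is_leaf():
            M[id(node)] = leaf_of_species[gene_tree.species_of_leaf[id(node)]]
        else:
            children = node.child_nodes()
            img = M[id(children[0])]
            for ch in children[1:]:
                img = _species_lca(img, M[id(ch)], depth, parent, node_by_id)
            M[id(node)] = img

    events: dict[frozenset[str], str] = {}
    mapping: dict[frozenset[str], frozenset[str]] = {}
    species_clade = {
        id(nd): frozenset(
            species_tree.species_of_leaf[id(lf)] for lf in nd.leaf_iter()
        )
        for nd in species_tree.tree.preorder_node_iter()
    }
    is_dup: dict[int, bool] = {}
    n_dup = 0
    for node in gene_tree.postorder():
        clade = gene_tree.clade_genes(node)
        mapping[clade] = species_clade[id(M[id(node)])]
        if node.is_leaf():
            continue
        dup = any(M[id(ch)] is M[id(node)] for ch in node.child_nodes())
        is_dup[id(node)] = dup
        events[clade] = "DUPLICATION" if dup else "SPECIATION"
        n_dup += dup

    # losses per gene-tree edge
    loss_branches: list[frozenset[str]] = []
    for node in gene_tree.postorder():
        if node.parent_node is None:
            continue
        u, v = node.parent_node, node
        d = depth[id(M[id(v)])] - depth[id(M[id(u)])]
        n_edge_losses = d - 1 + (1 if is_dup[id(u)] else 0)
        if n_edge_losses <= 0:
            continue
        # walk up from M(v); each passed species node contributes the
        # sibling branch (or, for the duplication case, the image branch)
        sp = id(M[id(v)])
        path = []
        while sp != id(M[id(u)]):
            path.append(sp)
            sp = parent[sp]  # type: ignore[assignment]
        # losses sit on the sibling branches of the path's upper nodes
        for sp_id in path[:-1] if not is_dup[id(u)] else path:
            par = parent[sp_id]
            for sib in node_by_id[par].child_nodes():  # type: ignore[index]
                if id(sib) != sp_id:
                    loss_branches.append(species_clade[id(sib)])
    return ReconciliationResult(
        node_events=events,
        mapping=mapping,
        n_duplications=n_dup,
        n_losses=len(loss_branches),
        loss_branches=tuple(loss_branches),
    )


def _species_lca(a, b, depth, parent, node_by_id):
    ia, ib = id(a), id(b)
    while depth[ia] > depth[ib]:
        ia = parent[ia]
    while depth[ib] > depth[ia]:
        ib = parent[ib]
    while ia != ib:
        ia = parent[ia]
        ib = parent[ib]
    return node_by_id[ia]


def count_losses(
    gene_tree: LabeledTree, species_tree: LabeledTree
) -> tuple[int, tuple[frozenset[str], ...]]:
    """Total inferred losses plus their species-branch locations."""
    recon = lca_reconcile(gene_tree, species_tree)
    return recon.n_losses, recon.loss_branches


def species_clustering_test(
    gene_tree: LabeledTree,
) -> tuple[dict[str, bool | None], float | None]:
    """Gene-conversion check: do each species' copies form a clade?

    Under gene conversion, paralogs homogenize within genomes and are
    expected to cluster by species.  For each species with >= 2 gene
    copies, reports True iff its copies are monophyletic; single-copy
    species report None (not applicable).  The overall fraction is over
    testable species only (None if there are none).
    """
    leaves_of_species: dict[str, set[int]] = {}
    for lf in gene_tree.leaves():
        sp = gene_tree.species_of_leaf[id(lf)]
        leaves_of_species.setdefault(sp, set()).add(id(lf))
    clades = {
        frozenset(id(lf) for lf in nd.leaf_iter())
        for nd in gene_tree.tree.preorder_node_iter()
    }
    result: dict[str, bool | None] = {}
    for sp, leaf_ids in sorted(leaves_of_species.items()):
        if len(leaf_ids) < 2:
            result[sp] = None
        else:
            result[sp] = frozenset(leaf_ids) in clades
    testable = [v for v in result.values() if v is not None]
    fraction = (sum(testable) / len(testable)) if testable else None
    return result, fraction


@dataclass(frozen=True)
class ScenarioComparison:
    """Duplication/loss tabulation of competing gene-tree scenarios."""

    table: tuple[tuple[str, int, int, float], ...]  # (name, n_dup, n_loss, cost)
    dup_cost: float
    loss_cost: float
    preferred: str
    tied: tuple[str, ...]  # all scenario names achieving the minimal cost

    def as_dict(self) -> dict:
        return {
            "dup_cost": self.dup_cost,
            "loss_cost": self.loss_cost,
            "preferred": self.preferred,
            "tied": list(self.tied),
            "scenarios": [
                {"name": n, "n_duplications": d, "n_losses": l, "cost": c}
                for n, d, l, c in self.table
            ],
        }


def compare_scenarios(
    scenarios: Mapping[str, LabeledTree],
    species_tree: LabeledTree,
    dup_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> ScenarioComparison:
    """Reconcile competing gene-tree topologies and rank them by cost.

    All scenarios must cover the same gene set.  cost = dup_cost * dups +
    loss_cost * losses.  Ties are reported explicitly; ``preferred`` is the
    first minimal-cost scenario in input order.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    gene_sets = {name: t.gene_ids() for name, t in scenarios.items()}
    first = next(iter(gene_sets.values()))
    for name, genes in gene_sets.items():
        if genes != first:
            raise ValueError(
                f"scenario {name!r} covers a different gene set "
                f"(difference: {sorted(genes ^ first)})"
            )
    rows = []
    for name, tree in scenarios.items():
        recon = lca_reconcile(tree, species_tree)
        cost = dup_cost * recon.n_duplications + loss_cost * recon.n_losses
        rows.append((name, recon.n_duplications, recon.n_losses, cost))
    best = min(r[3] for r in rows)
    tied = tuple(r[0] for r in rows if r[3] == best)
    return ScenarioComparison(
        table=tuple(rows),
        dup_cost=dup_cost,
        loss_cost=loss_cost,
        preferred=tied[0],
        tied=tied,
    )


def root_with_outgroup(tree: LabeledTree, outgroup_species: str) -> LabeledTree:
    """Reroot on the edge above the clade of the given species' leaves.

    Rooting is an explicit analysis choice; this helper never runs
    silently inside reconciliation.
    """
    leaves = [
        lf for lf in tree.leaves()
        if tree.species_of_leaf[id(lf)] == outgroup_species
    ]
    if not leaves:
        raise MappingError(f"no leaves of species {outgroup_species!r}")
    mrca = leaves[0] if len(leaves) == 1 else tree.tree.mrca(
        taxa=[lf.taxon for lf in leaves]
    )
    tree.tree.reroot_at_edge(mrca.edge, update_bipartitions=False)
    newick = tree.write_newick()
    return LabeledTree.from_newick(newick)
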