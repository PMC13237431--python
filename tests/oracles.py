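"""Independent reference implementations used to cross-check the package.

Each oracle deliberately takes a different computational route from the
implementation it checks:

* diagnostic discovery — a direct per-column scan of the definition;
* reconciliation — species mapping via ancestor-leafset containment and
  loss counting via explicit path enumeration;
* superposition RMSD — Horn's quaternion method (eigenvalue form), no
  rotation matrix ever constructed.
"""

from __future__ import annotations

import numpy as np

from hcarkit.align_io import Group, ReferenceAlignment, SeqRecord


# -- diagnostic discovery -------------------------------------------------


def brute_force_diagnostics(aln: ReferenceAlignment, strict: bool = True):
    """Scan every column against the diagnostic definition, one test each."""
    a_recs = [r.residues for r in aln.records_in(Group.GROUP_A)]
    b_recs = [r.residues for r in aln.records_in(Group.GROUP_B)]
    hits = []
    for col in range(aln.width):
        ref_pos = aln.col_to_ref[col]
        if ref_pos is None:
            continue
        col_a = {s[col] for s in a_recs}
        col_b = {s[col] for s in b_recs}
        if strict:
            ok = (
                len(col_a) == 1
                and len(col_b) == 1
                and col_a != col_b
                and not (col_a | col_b) & {"-", "X"}
            )
        else:
            col_a -= {"-", "X"}
            col_b -= {"-", "X"}
            ok = bool(col_a) and bool(col_b) and not (col_a & col_b)
        if ok:
            hits.append((ref_pos, frozenset(col_a), frozenset(col_b)))
    return hits


def random_alignment(rng: np.random.Generator, n_seqs=6, width=50,
                     alphabet="ACDG-X") -> ReferenceAlignment:
    """Small random gapped alignment with random group labels.

    The reference record (first) is kept gap-free so every column has a
    reference number only where the random reference allows; gaps are
    permitted in the reference too, exercising insertion columns.
    """
    groups = [Group.GROUP_A, Group.GROUP_B]
    records = []
    for i in range(n_seqs):
        chars = rng.choice(list(alphabet), size=width)
        if i == 0:
            # keep at least one non-gap so the reference frame exists
            if all(c == "-" for c in chars):
                chars[0] = "A"
        group = groups[i % 2] if i < 4 else groups[rng.integers(0, 2)]
        records.append(
            SeqRecord(id=f"s{i}", species=f"sp{i}", group=group,
                      residues="".join(chars))
        )
    return ReferenceAlignment.from_records(records, "s0")


# -- reconciliation -------------------------------------------------------


def oracle_reconcile(gene_tree, species_tree):
    """Ancestor-set reconciliation oracle.

    Mapping: the species-tree node with the *smallest leafset containing*
    the gene clade's species (found by scanning all species nodes).
    Duplication: image equals a child's image.  Losses: for every gene
    edge, enumerate the species nodes on the open path between the two
    images and add one more below a duplication parent.
    """
    sp_nodes = list(species_tree.tree.preorder_node_iter())
    sp_leafsets = {
        id(nd): frozenset(
            species_tree.species_of_leaf[id(lf)] for lf in nd.leaf_iter()
        )
        for nd in sp_nodes
    }
    sp_parent = {
        id(nd): (id(nd.parent_node) if nd.parent_node else None)
        for nd in sp_nodes
    }

    def map_node(gene_node):
        species = frozenset(
            gene_tree.species_of_leaf[id(lf)] for lf in gene_node.leaf_iter()
        )
        candidates = [
            nd for nd in sp_nodes if species <= sp_leafsets[id(nd)]
        ]
        return min(candidates, key=lambda nd: len(sp_leafsets[id(nd)]))

    M = {id(nd): map_node(nd) for nd in gene_tree.tree.preorder_node_iter()}
    n_dup = 0
    is_dup = {}
    for nd in gene_tree.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        dup = any(M[id(ch)] is M[id(nd)] for ch in nd.child_nodes())
        is_dup[id(nd)] = dup
        n_dup += dup
    n_loss = 0
    for nd in gene_tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        top, bottom = M[id(nd.parent_node)], M[id(nd)]
        path = []
        cursor = id(bottom)
        while cursor != id(top):
            path.append(cursor)
            cursor = sp_parent[cursor]
            if cursor is None:
                raise AssertionError("child image not below parent image")
        strictly_between = len(path) - 1 if path else 0
        n_loss += max(strictly_between, 0)
        if is_dup[id(nd.parent_node)] and path:
            n_loss += 1
    events = {}
    for nd in gene_tree.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        clade = frozenset(
            gene_tree.gene_of_leaf[id(lf)] for lf in nd.leaf_iter()
        )
        events[clade] = "DUPLICATION" if is_dup[id(nd)] else "SPECIATION"
    return n_dup, n_loss, events


def random_topology(rng: np.random.Generator, labels: list[str]) -> str:
    """Random rooted binary topology via sequential random attachment."""
    subtrees = list(labels)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b})")
    return subtrees[0] + ";"


def random_tree_pair(rng: np.random.Generator, max_leaves: int = 12):
    """Random species tree + random gene tree over those species."""
    n_species = int(rng.integers(2, 7))
    species = [f"S{i}" for i in range(n_species)]
    species_newick = random_topology(rng, species)
    n_genes = int(rng.integers(2, max_leaves + 1))
    gene_labels = [
        f"g{i}|{species[rng.integers(0, n_species)]}" for i in range(n_genes)
    ]
    gene_newick = random_topology(rng, gene_labels)
    return gene_newick, species_newick


# -- superposition --------------------------------------------------------


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = len(P)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Pc.T @ Qc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (Pc * Pc).sum() + (Qc * Qc).sum()
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / n))
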