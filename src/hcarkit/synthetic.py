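"""Synthetic gene-family and structure generators with machine-readable truth.

Everything downstream (diagnostic-site discovery, reconciliation, indel
detection, superposition, the paired RMSD test) can be exercised on data
whose true history is known exactly:

* :func:`simulate_family` evolves a protein family along a species tree
  with duplication events placed on named branches.  Background sites
  substitute with probability 1 - exp(-rate * branch_length) to a
  uniformly chosen different residue (a deliberately minimal model — no
  empirical exchangeability matrix, no rate heterogeneity); a designated
  set of D diagnostic sites is invariant except that a state-switching
  duplication flips one daughter lineage to a second global state set,
  after which both paralog groups stay internally invariant.  Indels and
  losses are *placed*, not evolved: the biology being emulated treats them
  as discrete lineage-specific features.
* :func:`simulate_hcar_like` is a preset emulating the qualitative
  primate HCAR2/HCAR3 history: three independent duplications (hominine
  ancestor, orangutan ancestor, gibbon ancestor), one nested duplication
  in the Hoolock lineage, one placed loss of the HCAR2-like gibbon copy
  in Hoolock, D = 12 diagnostic sites and a 24-residue insertion in a
  hominine subclade of the HCAR3-like group.
* :func:`simulate_coord_pairs` builds a self-avoiding Calpha chain and
  noisy, rigidly displaced copies for superposition and power testing.

A single :class:`numpy.random.Generator` seeded once drives every draw;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .align_io import Group, ReferenceAlignment, SeqRecord
from .indels import IndelFeature, IndelKind
from .reconcile import LabeledTree
from .structcompare import CoordSet, kabsch_superpose, write_ca_pdb

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    pass


BranchKey = frozenset


def _branch_key(spec: str | Iterable[str]) -> frozenset[str]:
    if isinstance(spec, str):
        return frozenset([spec])
    return frozenset(spec)


@dataclass(frozen=True)
class DuplicationEvent:
    """A duplication placed on the species-tree branch above ``branch``.

    ``branch`` names the clade below the branch (a leaf name or an
    iterable of species).  ``rel_position`` in (0, 1) places the event
    along the branch.  ``switches_states`` controls whether the derived
    daughter flips the diagnostic sites to the group-B states; a nested
    duplication *within* an already-derived lineage sets this False so
    both daughters stay in their parent's paralog group.
    ``target_lineage`` selects which gene lineage duplicates when several
    co-occur on the branch (None is valid only when exactly one does).
    """

    branch: frozenset[str]
    rel_position: float = 0.5
    switches_states: bool = True
    target_lineage: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch", _branch_key(self.branch))
        if not (0.0 < self.rel_position < 1.0):
            raise ConfigError("rel_position must be in (0, 1)")


@dataclass(frozen=True)
class IndelSpec:
    """A lineage-specific indel placed at emission time.

    Carried by records whose species is in ``clade`` and (if ``group`` is
    given) whose paralog group matches.  ``ref_anchor`` is the reference
    position after which an insertion sits / at which a deletion starts.
    """

    clade: frozenset[str]
    length: int
    kind: IndelKind = IndelKind.INSERTION
    group: str | None = None  # "A" | "B" | None = any
    ref_anchor: int | None = None  # default: near the C-terminus

    def __post_init__(self) -> None:
        object.__setattr__(self, "clade", _branch_key(self.clade))
        if self.length < 1:
            raise ConfigError("indel length must be >= 1")


@dataclass(frozen=True)
class CoordSpec:
    """Design of the paired structural-noise experiment.

    ``noise_sd_a``/``noise_sd_b`` are per-coordinate Gaussian sds in
    angstroms for the two comparison groups (defaults mirror a ~0.8 vs
    ~1.3 A contrast); ``n_residues`` defaults to a receptor-sized chain.
    """

    n_models: int = 6
    n_residues: int = 300
    noise_sd_a: float = 0.8
    noise_sd_b: float = 1.3

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ConfigError("n_residues must be >= 3")
        if self.n_models < 2:
            raise ConfigError("n_models must be >= 2")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    species_tree: str  # Newick with branch lengths (expected subst/site)
    duplication_events: tuple[DuplicationEvent, ...] = ()
    loss_probability: float = 0.0
    seq_length: int = 300
    n_diagnostic_sites: int = 12
    background_rate_scale: float = 1.0
    indel_specs: tuple[IndelSpec, ...] = ()
    forced_losses: tuple[tuple[frozenset[str], str], ...] = ()  # (branch, lineage)
    coord_spec: CoordSpec | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.loss_probability <= 1.0):
            raise ConfigError("loss_probability must be in [0, 1]")
        if self.n_diagnostic_sites > self.seq_length:
            raise ConfigError("n_diagnostic_sites exceeds seq_length")
        object.__setattr__(
            self,
            "forced_losses",
            tuple((_branch_key(b), lin) for b, lin in self.forced_losses),
        )


@dataclass
class GroundTruth:
    """Everything the generator knows about what it emitted."""

    seed: int
    true_gene_tree: str  # Newick
    true_duplication_branches: list[list[str]]  # species sets, one per event
    true_loss_branches: list[list[str]]
    true_diagnostic_positions: list[int]
    state_a: dict[int, str]
    state_b: dict[int, str]
    record_groups: dict[str, str]  # record id -> "A" | "B"
    true_indels: list[IndelFeature] = field(default_factory=list)
    true_transforms: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "true_gene_tree": self.true_gene_tree,
            "true_duplication_branches": [
                sorted(b) for b in self.true_duplication_branches
            ],
            "true_loss_branches": [sorted(b) for b in self.true_loss_branches],
            "true_diagnostic_positions": self.true_diagnostic_positions,
            "state_a": {str(k): v for k, v in self.state_a.items()},
            "state_b": {str(k): v for k, v in self.state_b.items()},
            "record_groups": self.record_groups,
            "true_indels": [
                {
                    "kind": f.kind.value,
                    "ref_anchor": f.ref_anchor,
                    "length": f.length,
                    "carriers": sorted(f.carriers),
                }
                for f in self.true_indels
            ],
            "true_transforms": self.true_transforms,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class FamilyDataset:
    """Output bundle of :func:`simulate_family`."""

    alignment: ReferenceAlignment
    gene_tree: LabeledTree
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .align_io import write_alignment, write_labels

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": outdir / "alignment.fasta",
            "labels": outdir / "labels.tsv",
            "gene_tree": outdir / "gene_tree.nwk",
            "species_tree": outdir / "species_tree.nwk",
            "truth": outdir / "truth.json",
        }
        write_alignment(self.alignment, paths["alignment"])
        write_labels(self.alignment, paths["labels"])
        paths["gene_tree"].write_text(self.truth.true_gene_tree + "\n")
        paths["species_tree"].write_text(self.config.species_tree.strip() + "\n")
        self.truth.to_json(paths["truth"])
        return paths


# -- gene-tree construction ----------------------------------------------


class _Lineage:
    __slots__ = ("label", "group", "seq", "pending")

    def __init__(self, label: str, group: str, seq: np.ndarray, pending: float):
        self.label = label
        self.group = group  # "A" | "B"
        self.seq = seq  # int8 indices into AMINO_ACIDS
        self.pending = pending  # branch length since last gene-tree node


def _substitute(
    seq: np.ndarray,
    length: float,
    rate_scale: float,
    diagnostic: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Background substitution along a branch; diagnostic sites are frozen."""
    seq = seq.copy()
    if length <= 0 or rate_scale <= 0:
        return seq
    p = 1.0 - np.exp(-rate_scale * length)
    hit = rng.random(len(seq)) < p
    hit &= ~diagnostic
    idx = np.nonzero(hit)[0]
    for i in idx:
        new = rng.integers(0, 19)
        if new >= seq[i]:
            new += 1  # uniform over the 19 other residues
        seq[i] = new
    return seq


def simulate_family(config: SimulationConfig) -> FamilyDataset:
    """Evolve a gene family along a species tree with placed duplications.

    Returns the gap-padded alignment, the true gene tree (Newick with
    ``gene|species`` leaf labels) and a :class:`GroundTruth` that
    validates against the emitted data.
    """
    rng = np.random.default_rng(config.seed)
    sp_tree = dendropy.Tree.get(
        data=config.species_tree, schema="newick", preserve_underscores=True
    )
    sp_tree.is_rooted = True

    clade_below: dict[int, frozenset[str]] = {}
    for nd in sp_tree.postorder_node_iter():
        if nd.is_leaf():
            clade_below[id(nd)] = frozenset([nd.taxon.label])
        else:
            clade_below[id(nd)] = frozenset().union(
                *(clade_below[id(c)] for c in nd.child_nodes())
            )
    known_branches = set(clade_below.values())
    events_by_branch: dict[frozenset[str], list[DuplicationEvent]] = {}
    for ev in config.duplication_events:
        if ev.branch not in known_branches:
            raise ConfigError(
                f"duplication branch {sorted(ev.branch)} not in species tree"
            )
        events_by_branch.setdefault(ev.branch, []).append(ev)
    for evs in events_by_branch.values():
        evs.sort(key=lambda e: e.rel_position)
    forced_by_branch: dict[frozenset[str], list[str]] = {}
    for branch, lineage in config.forced_losses:
        if branch not in known_branches:
            raise ConfigError(
                f"forced-loss branch {sorted(branch)} not in species tree"
            )
        forced_by_branch.setdefault(branch, []).append(lineage)

    L = config.seq_length
    D = config.n_diagnostic_sites
    diag_pos0 = np.sort(rng.choice(L, size=D, replace=False))  # 0-based
    diagnostic_mask = np.zeros(L, dtype=bool)
    diagnostic_mask[diag_pos0] = True
    root_seq = rng.integers(0, 20, size=L).astype(np.int8)
    state_a = {int(p): AMINO_ACIDS[root_seq[p]] for p in diag_pos0}
    state_b_arr = {}
    for p in diag_pos0:
        new = int(rng.integers(0, 19))
        if new >= root_seq[p]:
            new += 1
        state_b_arr[int(p)] = new
    state_b = {p: AMINO_ACIDS[v] for p, v in state_b_arr.items()}

    # The gene tree grows as newick substrings with branch lengths; a
    # trailing ":length" is always present, so suppressed unary nodes can
    # extend it in place.
    records: list[tuple[str, str, str, np.ndarray]] = []  # id, species, group, seq
    dup_branches: list[frozenset[str]] = []
    loss_branches: list[frozenset[str]] = []

    def _add_length(nwk: str, extra: float) -> str:
        head, _, tail = nwk.rpartition(":")
        return f"{head}:{float(tail) + extra:.6f}"

    def descend_edge(sp_node, entering: list[_Lineage]) -> dict[str, str | None]:
        """Walk one species-tree edge (and the subtree below it).

        ``entering`` are the gene lineages present at the top of the edge
        above ``sp_node``.  Returns, per entering lineage label, the newick
        subtree it resolves to below this point (None if every descendant
        was lost).  Duplication nodes created on this edge are joined here.
        """
        branch = clade_below[id(sp_node)]
        blen = sp_node.edge.length or 0.0
        is_root = sp_node.parent_node is None
        current = list(entering)
        # (parent_label, a_label, b_label, parent_pending), creation order
        edge_dups: list[tuple[str, str, str, float]] = []
        prev = 0.0
        for ev in ([] if is_root else events_by_branch.get(branch, [])):
            seg = (ev.rel_position - prev) * blen
            for lin in current:
                lin.seq = _substitute(
                    lin.seq, seg, config.background_rate_scale,
                    diagnostic_mask, rng,
                )
                lin.pending += seg
            prev = ev.rel_position
            if ev.target_lineage is None:
                if len(current) != 1:
                    raise ConfigError(
                        f"duplication on {sorted(branch)} is ambiguous: "
                        f"{len(current)} lineages present; set target_lineage"
                    )
                target = current[0]
            else:
                matches = [l for l in current if l.label == ev.target_lineage]
                if not matches:
                    raise ConfigError(
                        f"target lineage {ev.target_lineage!r} absent on "
                        f"branch {sorted(branch)}"
                    )
                target = matches[0]
            dup_branches.append(branch)
            d_a = _Lineage(target.label + "a", target.group,
                           target.seq.copy(), 0.0)
            d_b = _Lineage(target.label + "b", target.group,
                           target.seq.copy(), 0.0)
            if ev.switches_states:
                d_b.group = "B"
                for p, v in state_b_arr.items():
                    d_b.seq[p] = v
            edge_dups.append((target.label, d_a.label, d_b.label, target.pending))
            current[current.index(target) : current.index(target) + 1] = [d_a, d_b]
        seg = (1.0 - prev) * blen
        for lin in current:
            lin.seq = _substitute(
                lin.seq, seg, config.background_rate_scale,
                diagnostic_mask, rng,
            )
            lin.pending += seg
        # losses act at the bottom of the edge, never on the root stem
        arrived: list[_Lineage] = []
        if is_root:
            arrived = current
        else:
            forced = forced_by_branch.get(branch, [])
            for lin in current:
                if lin.label in forced:
                    loss_branches.append(branch)
                elif (
                    config.loss_probability > 0
                    and lin.label != "0"
                    and rng.random() < config.loss_probability
                ):
                    loss_branches.append(branch)
                else:
                    arrived.append(lin)

        # resolve the node below
        sub: dict[str, str | None] = {}
        if not arrived:
            pass
        elif sp_node.is_leaf():
            species = sp_node.taxon.label
            for lin in arrived:
                gene_id = f"{species}_{lin.label}"
                records.append((gene_id, species, lin.group, lin.seq.copy()))
                sub[lin.label] = f"{gene_id}|{species}:{lin.pending:.6f}"
        else:
            child_maps = []
            for ch in sp_node.child_nodes():
                copies = [
                    _Lineage(l.label, l.group, l.seq.copy(), 0.0)
                    for l in arrived
                ]
                child_maps.append(descend_edge(ch, copies))
            for lin in arrived:
                parts = [
                    m[lin.label] for m in child_maps if m.get(lin.label)
                ]
                if not parts:
                    sub[lin.label] = None
                elif len(parts) == 1:
                    # survives toward one side only: suppress the unary
                    # speciation node and extend the branch
                    sub[lin.label] = _add_length(parts[0], lin.pending)
                else:
                    sub[lin.label] = (
                        f"({','.join(parts)}):{lin.pending:.6f}"
                    )
        # join this edge's duplications bottom-up (latest first)
        for parent_label, a_label, b_label, parent_pending in reversed(edge_dups):
            sub_a = sub.pop(a_label, None)
            sub_b = sub.pop(b_label, None)
            if sub_a and sub_b:
                sub[parent_label] = (
                    f"({sub_a},{sub_b}):{parent_pending:.6f}"
                )
            elif sub_a or sub_b:
                sub[parent_label] = _add_length(sub_a or sub_b, parent_pending)
            else:
                sub[parent_label] = None
        return {lin.label: sub.get(lin.label) for lin in entering}

    root_lineage = _Lineage("0", "A", root_seq.copy(), 0.0)
    top = descend_edge(sp_tree.seed_node, [root_lineage])
    root_nwk = top.get("0")
    if root_nwk is None:
        raise ConfigError("all gene lineages were lost; nothing to emit")
    gene_newick = root_nwk.rsplit(":", 1)[0] + ";"

    # -- emit the alignment (gap padding for indels) ---------------------
    diag_positions_1based = [int(p) + 1 for p in diag_pos0]
    insertions = [s for s in config.indel_specs if s.kind is IndelKind.INSERTION]
    deletions = [s for s in config.indel_specs if s.kind is IndelKind.DELETION]

    def carriers_of(spec: IndelSpec) -> list[str]:
        out = []
        for rid, species, grp, _ in records:
            if species in spec.clade and (spec.group in (None, grp)):
                out.append(rid)
        if not out:
            raise ConfigError(
                f"indel clade {sorted(spec.clade)} has no carrier records"
            )
        return out

    ins_plan = []  # (anchor_pos_1based, length, carriers, residues)
    for spec in insertions:
        anchor = spec.ref_anchor if spec.ref_anchor is not None else L - 10
        if not (0 <= anchor <= L):
            raise ConfigError(f"insertion anchor {anchor} outside 0..{L}")
        residues = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=spec.length)
        )
        ins_plan.append((anchor, spec.length, carriers_of(spec), residues))
    ins_plan.sort(key=lambda t: t[0])
    del_plan = []
    for spec in deletions:
        anchor = spec.ref_anchor if spec.ref_anchor is not None else L - spec.length - 5
        if not (1 <= anchor and anchor + spec.length - 1 <= L):
            raise ConfigError("deletion outside the reference range")
        del_plan.append((anchor, spec.length, carriers_of(spec)))

    seq_records: list[SeqRecord] = []
    truth_indels: list[IndelFeature] = []
    for rid, species, grp, seq in records:
        chars = [AMINO_ACIDS[i] for i in seq]
        for anchor, length, carrier_ids, _ in del_plan:
            if rid in carrier_ids:
                for p in range(anchor, anchor + length):
                    chars[p - 1] = "-"
        # splice insertion columns from the right so offsets stay valid
        for anchor, length, carrier_ids, residues in sorted(
            ins_plan, key=lambda t: -t[0]
        ):
            block = list(residues) if rid in carrier_ids else ["-"] * length
            chars[anchor:anchor] = block
        group = {"A": Group.GROUP_A, "B": Group.GROUP_B}[grp]
        seq_records.append(
            SeqRecord(id=rid, species=species, group=group,
                      residues="".join(chars))
        )
    for anchor, length, carrier_ids, _ in ins_plan:
        truth_indels.append(
            IndelFeature(kind=IndelKind.INSERTION, ref_anchor=anchor,
                         length=length, carriers=frozenset(carrier_ids))
        )
    for anchor, length, carrier_ids in del_plan:
        truth_indels.append(
            IndelFeature(kind=IndelKind.DELETION, ref_anchor=anchor,
                         length=length, carriers=frozenset(carrier_ids))
        )

    reference_id = next(rid for rid, _, grp, _ in records if grp == "A")
    alignment = ReferenceAlignment.from_records(seq_records, reference_id)
    gene_tree = LabeledTree.from_newick(gene_newick)
    truth = GroundTruth(
        seed=config.seed,
        true_gene_tree=gene_newick,
        true_duplication_branches=[sorted(b) for b in dup_branches],
        true_loss_branches=[sorted(b) for b in loss_branches],
        true_diagnostic_positions=diag_positions_1based,
        state_a={p + 1: state_a[p] for p in state_a},
        state_b={p + 1: state_b[p] for p in state_b},
        record_groups={rid: grp for rid, _, grp, _ in records},
        true_indels=truth_indels,
    )
    return FamilyDataset(
        alignment=alignment, gene_tree=gene_tree, truth=truth, config=config
    )


# -- the HCAR-like preset ------------------------------------------------

PRIMATE_SPECIES_TREE = (
    "((((((((Homo_sapiens:0.01,(Pan_troglodytes:0.005,Pan_paniscus:0.005)"
    ":0.005):0.005,Gorilla_gorilla:0.015):0.01,(Pongo_abelii:0.01,"
    "Pongo_pygmaeus:0.01):0.015):0.005,(Hoolock_leuconedys:0.02,"
    "(Symphalangus_syndactylus:0.015,(Hylobates_agilis:0.01,"
    "Nomascus_leucogenys:0.01):0.005):0.005):0.01):0.02,"
    "(Macaca_fascicularis:0.02,Rhinopithecus_roxellana:0.02):0.02):0.02,"
    "Callithrix_jacchus:0.06):0.02,Carlito_syrichta:0.09):0.02,"
    "Lemur_catta:0.11);"
)

HOMININES = frozenset(
    ["Homo_sapiens", "Pan_troglodytes", "Pan_paniscus", "Gorilla_gorilla"]
)
PONGO = frozenset(["Pongo_abelii", "Pongo_pygmaeus"])
GIBBONS = frozenset(
    [
        "Hoolock_leuconedys",
        "Symphalangus_syndactylus",
        "Hylobates_agilis",
        "Nomascus_leucogenys",
    ]
)


def hcar_like_config(seed: int) -> SimulationConfig:
    """Preset emulating the primate HCAR2/HCAR3 duplicative history."""
    return SimulationConfig(
        seed=seed,
        species_tree=PRIMATE_SPECIES_TREE,
        duplication_events=(
            DuplicationEvent(branch=HOMININES, rel_position=0.5),
            DuplicationEvent(branch=PONGO, rel_position=0.5),
            DuplicationEvent(branch=GIBBONS, rel_position=0.4),
            # nested duplication of the derived (B) copy within Hoolock;
            # both daughters stay in group B
            DuplicationEvent(
                branch=frozenset(["Hoolock_leuconedys"]),
                rel_position=0.5,
                switches_states=False,
                target_lineage="0b",
            ),
        ),
        # the ancestral-like (A) gibbon copy was lost in Hoolock
        forced_losses=((frozenset(["Hoolock_leuconedys"]), "0a"),),
        loss_probability=0.0,
        seq_length=300,
        n_diagnostic_sites=12,
        background_rate_scale=1.0,
        indel_specs=(
            IndelSpec(
                clade=frozenset(
                    ["Homo_sapiens", "Pan_troglodytes", "Pan_paniscus"]
                ),
                length=24,
                kind=IndelKind.INSERTION,
                group="B",
                ref_anchor=280,
            ),
        ),
        coord_spec=CoordSpec(),
    )


def simulate_hcar_like(seed: int) -> FamilyDataset:
    """Full synthetic dataset with the HCAR-like history (see module doc)."""
    return simulate_family(hcar_like_config(seed))


def profile_labels(dataset: FamilyDataset) -> dict[str, tuple[str, Group]]:
    """Label table for classification on a simulated dataset.

    Every copy from a duplicated lineage keeps its true paralog group
    (the groups then span all independent duplications, so no background
    site can be group-fixed by chance); single-copy species are queries.
    """
    labels = {}
    single_copy = {
        sp
        for sp in {r.species for r in dataset.alignment.records}
        if sum(r.species == sp for r in dataset.alignment.records) == 1
    }
    for rec in dataset.alignment.records:
        if rec.species in single_copy:
            labels[rec.id] = (rec.species, Group.QUERY)
        else:
            labels[rec.id] = (rec.species, rec.group)
    return labels


# -- coordinate-set simulation -------------------------------------------


@dataclass
class CoordPairDataset:
    base: CoordSet
    models_a: list[CoordSet]
    models_b: list[CoordSet]
    truth: GroundTruth

    def rmsd_vectors(self) -> tuple[list[float], list[float]]:
        to_a = [kabsch_superpose(m, self.base).rmsd for m in self.models_a]
        to_b = [kabsch_superpose(m, self.base).rmsd for m in self.models_b]
        return to_a, to_b

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"base": outdir / "base.pdb"}
        write_ca_pdb(self.base, paths["base"])
        for m in self.models_a + self.models_b:
            p = outdir / f"{m.model_id}.pdb"
            write_ca_pdb(m, p)
            paths[m.model_id] = p
        self.truth.to_json(outdir / "truth.json")
        return paths


def _self_avoiding_walk(
    n: int, rng: np.random.Generator, step: float = 3.8, min_dist: float = 3.0
) -> np.ndarray:
    """Random Calpha-like chain: fixed step, no two points closer than
    ``min_dist``."""
    pts = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = pts[i - 1] + v
            d = np.linalg.norm(pts[:i] - cand, axis=1)
            if d.min() >= min_dist:
                pts[i] = cand
                break
        else:
            raise RuntimeError("self-avoiding walk got stuck")
    return pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def simulate_coord_pairs(
    coord_spec: CoordSpec, seed: int
) -> CoordPairDataset:
    """Base chain plus paired noisy, rigidly displaced copies.

    Model i contributes one group-A copy (noise ``noise_sd_a`` per
    coordinate) and one group-B copy (``noise_sd_b``), each under its own
    random rigid motion; after superposition onto the base the expected
    RMSD is approximately ``noise_sd * sqrt(3)`` (slightly below, because
    the fitted transform absorbs six degrees of freedom).
    """
    rng = np.random.default_rng(seed)
    base_pts = _self_avoiding_walk(coord_spec.n_residues, rng)
    numbers = tuple(range(1, coord_spec.n_residues + 1))
    base = CoordSet(model_id="base", residue_numbers=numbers, coords=base_pts)
    transforms = []

    def make(group: str, i: int, sd: float) -> CoordSet:
        noisy = base_pts + rng.normal(scale=sd, size=base_pts.shape)
        R = _random_rotation(rng)
        t = rng.uniform(-50, 50, size=3)
        moved = noisy @ R.T + t
        model_id = f"model_{group}{i}"
        transforms.append(
            {"model_id": model_id, "rotation": R.tolist(),
             "translation": t.tolist(), "noise_sd": sd}
        )
        return CoordSet(model_id=model_id, residue_numbers=numbers, coords=moved)

    models_a = [make("a", i, coord_spec.noise_sd_a)
                for i in range(coord_spec.n_models)]
    models_b = [make("b", i, coord_spec.noise_sd_b)
                for i in range(coord_spec.n_models)]
    truth = GroundTruth(
        seed=seed,
        true_gene_tree="",
        true_duplication_branches=[],
        true_loss_branches=[],
        true_diagnostic_positions=[],
        state_a={},
        state_b={},
        record_groups={},
        true_transforms=transforms,
    )
    return CoordPairDataset(base=base, models_a=models_a, models_b=models_b,
                            truth=truth)


# -- truth audit ---------------------------------------------------------


def validate_ground_truth(dataset: FamilyDataset) -> None:
    """Round-trip audit: the emitted truth must hold in the emitted files.

    Raises AssertionError on any inconsistency.
    """
    aln, truth = dataset.alignment, dataset.truth
    for rec in aln.records:
        grp = truth.record_groups[rec.id]
        states = truth.state_a if grp == "A" else truth.state_b
        for pos, expected in states.items():
            assert aln.residue_at(rec.id, pos) == expected, (
                f"{rec.id} at {pos}: expected {expected}"
            )
    tree = LabeledTree.from_newick(truth.true_gene_tree)
    assert tree.gene_ids() == {rec.id for rec in aln.records}
    for feat in truth.true_indels:
        for rid in feat.carriers:
            assert rid in aln
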