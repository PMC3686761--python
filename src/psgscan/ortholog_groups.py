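"""Ortholog-group selection and per-group species-tree synthesis.

The scan does not infer orthology; it consumes externally built groups of
single-copy 1:1 orthologs and applies a "non-exact" selection: every kept
group must contain a fixed set of required species, at least `min_species`
members overall, and all members must come from an allowed wider taxon
(e.g. mammals). Each kept group then gets its own species tree by pruning a
master topology down to the group's species.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import dendropy

from .codon_align import normalize_cds, read_fasta
from .trees import LabeledTree, prune_to_species

logger = logging.getLogger(__name__)


@dataclass
class OrthologGroup:
    """One candidate gene: per-species (protein, CDS) sequence pairs."""

    group_id: str
    members: dict[str, tuple[str, str]]  # species -> (protein, cds)

    @property
    def species(self) -> set[str]:
        return set(self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def check_sequences(self) -> None:
        """Enforce that every CDS is 3x its protein (terminal stop removed)."""
        for sp, (protein, cds) in self.members.items():
            nt = normalize_cds(cds)
            if len(nt) != 3 * len(protein.replace("-", "")):
                raise ValueError(
                    f"group {self.group_id}, species {sp!r}: CDS length "
                    f"{len(nt)} is not 3x protein length {len(protein.replace('-', ''))}"
                )


@dataclass
class GroupFilterSpec:
    """Constraints of the non-exact group search.

    required_species must all be present; unspecified members must come from
    allowed_taxon (None = unrestricted); a kept group needs at least
    min_species members inside the allowed taxon.
    """

    required_species: frozenset[str]
    min_species: int
    allowed_taxon: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.required_species = frozenset(self.required_species)
        if self.allowed_taxon is not None:
            self.allowed_taxon = frozenset(self.allowed_taxon)
            outside = self.required_species - self.allowed_taxon
            if outside:
                raise ValueError(
                    f"required species outside allowed taxon: {sorted(outside)}"
                )
        if self.min_species < max(1, len(self.required_species)):
            raise ValueError(
                "min_species must be >= max(1, number of required species)"
            )


def filter_groups(
    groups: list[OrthologGroup], spec: GroupFilterSpec
) -> list[OrthologGroup]:
    """Keep groups satisfying the non-exact search; drop out-of-taxon members.

    A group is kept iff it contains every required species and, after
    restricting to the allowed taxon, still has at least min_species members.
    Members outside the allowed taxon are removed from kept groups (each
    drop is logged). Input order is preserved; the operation is idempotent.
    """
    kept: list[OrthologGroup] = []
    for group in groups:
        if not spec.required_species <= group.species:
            continue
        if spec.allowed_taxon is None:
            allowed_members = dict(group.members)
        else:
            allowed_members = {
                sp: seqs
                for sp, seqs in group.members.items()
                if sp in spec.allowed_taxon
            }
            for sp in group.species - set(allowed_members):
                logger.info(
                    "group %s: dropping out-of-taxon species %s", group.group_id, sp
                )
        if len(allowed_members) < spec.min_species:
            continue
        kept.append(OrthologGroup(group.group_id, allowed_members))
    return kept


def prune_master_tree(
    master: dendropy.Tree | LabeledTree | str, species: set[str]
) -> LabeledTree:
    """Per-group species tree: master topology induced on the group's species.

    Unary nodes are suppressed and, when the master carries branch lengths,
    path lengths between retained leaves are preserved. The returned tree has
    no foreground flag yet; the scan labels it per hypothesis.
    """
    if isinstance(master, str):
        master = LabeledTree.from_newick(master)
    tree = master.tree if isinstance(master, LabeledTree) else master
    return LabeledTree(prune_to_species(tree, set(species)), foreground=None)


def group_size_histogram(groups: list[OrthologGroup]) -> dict[int, int]:
    """Number of groups at each species count (the group-size distribution)."""
    hist: dict[int, int] = {}
    for group in groups:
        hist[group.size] = hist.get(group.size, 0) + 1
    return dict(sorted(hist.items()))


def read_group_collection(
    membership_tsv: str, protein_fasta: str, cds_fasta: str
) -> list[OrthologGroup]:
    """Load groups from a flat membership table plus two FASTA files.

    The table has columns group_id, species, protein_id, cds_id (one row per
    group member); sequences are resolved from the FASTA files by id. Group
    order follows first appearance in the table.
    """
    proteins = read_fasta(protein_fasta)
    cds = read_fasta(cds_fasta)
    by_group: dict[str, dict[str, tuple[str, str]]] = {}
    with open(membership_tsv) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required_cols = {"group_id", "species", "protein_id", "cds_id"}
        if reader.fieldnames is None or not required_cols <= set(reader.fieldnames):
            raise ValueError(
                f"membership table must have columns {sorted(required_cols)}"
            )
        for row in reader:
            gid, sp = row["group_id"], row["species"]
            if row["protein_id"] not in proteins:
                raise ValueError(f"protein id {row['protein_id']!r} not in FASTA")
            if row["cds_id"] not in cds:
                raise ValueError(f"cds id {row['cds_id']!r} not in FASTA")
            members = by_group.setdefault(gid, {})
            if sp in members:
                raise ValueError(
                    f"group {gid}: duplicate species {sp!r} (groups must be "
                    "single-copy)"
                )
            members[sp] = (proteins[row["protein_id"]], cds[row["cds_id"]])
    return [OrthologGroup(gid, members) for gid, members in by_group.items()]


def write_group_collection(
    groups: list[OrthologGroup],
    membership_tsv: str,
    protein_fasta: str,
    cds_fasta: str,
) -> None:
    """Inverse of :func:`read_group_collection` (ids are group_id|species)."""
    with open(membership_tsv, "w") as mt, open(protein_fasta, "w") as pf, open(
        cds_fasta, "w"
    ) as cf:
        mt.write("group_id\tspecies\tprotein_id\tcds_id\n")
        for group in groups:
            for sp, (protein, cds_seq) in group.members.items():
                pid = f"{group.group_id}|{sp}|p"
                cid = f"{group.group_id}|{sp}|c"
                mt.write(f"{group.group_id}\t{sp}\t{pid}\t{cid}\n")
                pf.write(f">{pid}\n{protein}\n")
                cf.write(f">{cid}\n{cds_seq}\n")
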