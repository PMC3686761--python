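"""Synthetic data with known ground truth for every pipeline input.

Three generators: codon alignments evolved under the branch-site process
(the generative counterpart of the model fitted by :mod:`psgscan.branchsite`),
ortholog-group collections with controlled species composition, and GO-style
annotation tables with planted category enrichment. All generators are pure
functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branchsite import (
    BranchSiteParams,
    CodonFrequencies,
    _ReversibleExponentiator,
    _as_pi_array,
    build_rate_matrix,
    mixture_scale,
)
from .codon_align import CodonAlignment
from .codons import SENSE_CODONS, translate_codon
from .ortholog_groups import OrthologGroup
from .trees import ArrayTree, LabeledTree


@dataclass
class SimulationManifest:
    """Ground truth of one simulated alignment; replaying seed reproduces it."""

    seed: int
    params: BranchSiteParams
    n_sites: int
    site_classes: np.ndarray  # 0, 1, 2, 3 for classes 0, 1, 2a, 2b
    tree_newick: str

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"seed\t{self.seed}\n")
            fh.write(f"n_sites\t{self.n_sites}\n")
            p = self.params
            fh.write(
                f"params\tkappa={p.kappa};omega0={p.omega0};omega2={p.omega2};"
                f"p0={p.p0};p1={p.p1}\n"
            )
            fh.write(f"tree\t{self.tree_newick}\n")
            fh.write("site_classes\t" + ",".join(map(str, self.site_classes)) + "\n")


def simulate_codon_alignment(
    tree: LabeledTree,
    params: BranchSiteParams,
    pi,
    n_sites: int,
    seed: int,
) -> tuple[CodonAlignment, SimulationManifest]:
    """Evolve a codon alignment under branch-site model A along `tree`.

    Per site a latent class is drawn from (p0, p1, p2a, p2b), the root codon
    from pi, and each branch's child codon is sampled directly from the
    class- and branch-appropriate transition matrix P(t) (exact under the
    model; no event-by-event simulation). Branch lengths are interpreted on
    the same normalized scale the likelihood uses.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    pi_arr = _as_pi_array(pi)
    atree = ArrayTree.from_labeled(tree)
    if atree.foreground_node < 0:
        raise ValueError("tree has no foreground branch label")
    if not atree.has_lengths:
        raise ValueError("tree must carry branch lengths")
    rng = np.random.default_rng(seed)
    support = pi_arr > 0
    pi_s = pi_arr[support]
    codons = np.array(SENSE_CODONS)[support]
    scale = mixture_scale(params, pi_arr)
    ts = atree.lengths.copy()
    ts[atree.root] = 0.0

    omegas = {"w0": params.omega0, "one": 1.0, "w2": params.omega2}
    cum = {}
    for name, w in omegas.items():
        Q = build_rate_matrix(params.kappa, w, pi_arr)
        Qs = Q[np.ix_(support, support)]
        P = _ReversibleExponentiator(Qs, pi_s).matrices(ts / scale)
        P /= P.sum(axis=2, keepdims=True)
        cum[name] = np.cumsum(P, axis=2)
    bg_keys = ["w0", "one", "w0", "one"]
    fg_keys = ["w0", "one", "w2", "w2"]

    classes = rng.choice(4, size=n_sites, p=params.proportions)
    states = np.empty((atree.n_nodes, n_sites), dtype=np.intp)
    states[atree.root] = rng.choice(len(pi_s), size=n_sites, p=pi_s)
    for v in range(atree.n_nodes - 2, -1, -1):  # parents precede children
        parent_states = states[atree.parent[v]]
        child = np.empty(n_sites, dtype=np.intp)
        for c in range(4):
            mask = classes == c
            if not mask.any():
                continue
            key = fg_keys[c] if v == atree.foreground_node else bg_keys[c]
            rows = cum[key][v][parent_states[mask]]
            u = rng.random(mask.sum())
            child[mask] = (rows >= u[:, None]).argmax(axis=1)
        states[v] = child

    rows = {
        name: "".join(codons[states[v]]) for v, name in atree.leaf_names.items()
    }
    caln = CodonAlignment(rows)
    manifest = SimulationManifest(
        seed=seed,
        params=params,
        n_sites=n_sites,
        site_classes=classes,
        tree_newick=tree.to_newick(),
    )
    return caln, manifest


def group_from_alignment(group_id: str, caln: CodonAlignment) -> OrthologGroup:
    """Wrap a gap-free simulated codon alignment as an ortholog group.

    Proteins are the translations of the rows, so the group feeds straight
    into the scan's back-translation step.
    """
    members = {}
    for sp, row in caln.rows.items():
        codons = [row[i : i + 3] for i in range(0, len(row), 3)]
        if any(c == "---" for c in codons):
            raise ValueError("alignment with gaps cannot become a raw group")
        protein = "".join(translate_codon(c) for c in codons)
        members[sp] = (protein, row)
    return OrthologGroup(group_id=group_id, members=members)


def _draw_size(size_distribution, rng: np.random.Generator) -> int:
    if callable(size_distribution):
        return int(size_distribution(rng))
    if isinstance(size_distribution, int):
        return size_distribution
    if isinstance(size_distribution, dict):
        sizes = np.array(sorted(size_distribution))
        probs = np.array([size_distribution[s] for s in sizes], dtype=float)
        return int(rng.choice(sizes, p=probs / probs.sum()))
    return int(rng.choice(np.asarray(list(size_distribution))))


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def simulate_group_collection(
    species_pool: list[str],
    required_species: set[str],
    size_distribution,
    n_groups: int,
    seed: int,
    *,
    n_codons: int = 100,
    substitution_rate: float = 0.05,
) -> tuple[list[OrthologGroup], pd.DataFrame]:
    """Ortholog-group collection with the required species always present.

    Each group holds the required species plus a random draw from the rest of
    the pool, sized by `size_distribution` (an int, a sequence of sizes, a
    {size: weight} dict, or a callable of the RNG). Per group an ancestral
    CDS of `n_codons` sense codons is generated and each species receives a
    copy with random codon substitutions at `substitution_rate`; proteins are
    translations of the CDS, so every member back-translates cleanly and all
    rows share one length (a gap-free alignment).
    """
    required = sorted(required_species)
    missing = set(required) - set(species_pool)
    if missing:
        raise ValueError(f"required species not in pool: {sorted(missing)}")
    optional = sorted(set(species_pool) - set(required))
    rng = np.random.default_rng(seed)
    sense = np.array(SENSE_CODONS)
    groups: list[OrthologGroup] = []
    records = []
    for g in range(n_groups):
        size = _draw_size(size_distribution, rng)
        size = max(size, len(required))
        n_extra = min(size - len(required), len(optional))
        extra = list(rng.choice(optional, size=n_extra, replace=False))
        members_species = required + sorted(extra)
        ancestral = rng.integers(0, len(sense), size=n_codons)
        members = {}
        for sp in members_species:
            codon_idx = ancestral.copy()
            mut = rng.random(n_codons) < substitution_rate
            codon_idx[mut] = rng.integers(0, len(sense), size=int(mut.sum()))
            cds = "".join(sense[codon_idx])
            protein = "".join(translate_codon(c) for c in (sense[codon_idx]))
            members[sp] = (protein, cds)
        gid = f"OG{g:05d}"
        groups.append(OrthologGroup(group_id=gid, members=members))
        records.append(
            {
                "group_id": gid,
                "n_species": len(members_species),
                "species": ";".join(members_species),
            }
        )
    return groups, pd.DataFrame.from_records(
        records, columns=["group_id", "n_species", "species"]
    )


def simulate_annotations(
    genes,
    categories,
    baseline_rate: float,
    planted,
    psg_fraction: float,
    seed: int,
) -> tuple[dict[str, set[str]], set[str], pd.DataFrame]:
    """Annotation table and PSG set with planted category enrichment.

    Every gene is annotated to each category independently at
    `baseline_rate`. A gene's probability of being a PSG is `psg_fraction`,
    multiplied by the planted fold (capped at 1) when the gene carries a
    planted category. `planted` is a (category, fold) pair or a list of
    them; fold = 1 plants nothing. Returns (annotations, psg set, truth
    table with per-category fold and annotated-gene count).
    """
    if isinstance(genes, int):
        genes = [f"gene{i:05d}" for i in range(genes)]
    if isinstance(categories, int):
        categories = [f"GO:{7000000 + i}" for i in range(categories)]
    if planted and isinstance(planted[0], str):
        planted = [planted]
    folds = {cat: float(fold) for cat, fold in planted}
    for cat, fold in folds.items():
        if fold < 1:
            raise ValueError(f"fold must be >= 1, got {fold} for {cat}")
        if cat not in categories:
            raise ValueError(f"planted category {cat!r} not among categories")
    rng = np.random.default_rng(seed)
    annotations: dict[str, set[str]] = {}
    psg: set[str] = set()
    n_annotated = dict.fromkeys(categories, 0)
    for gene in genes:
        hits = {
            cat for cat in categories if rng.random() < baseline_rate
        }
        annotations[gene] = hits
        for cat in hits:
            n_annotated[cat] += 1
        fold = max((folds.get(cat, 1.0) for cat in hits), default=1.0)
        if rng.random() < min(1.0, psg_fraction * fold):
            psg.add(gene)
    truth = pd.DataFrame(
        {
            "category": list(categories),
            "fold": [folds.get(cat, 1.0) for cat in categories],
            "n_annotated": [n_annotated[cat] for cat in categories],
        }
    )
    return annotations, psg, truth
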