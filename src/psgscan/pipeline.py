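"""Genome-scan orchestration: filter, align, dual-foreground LRT, summary.

One scan = for every ortholog group, prune the master topology to the
group's species, estimate branch lengths once under the one-ratio model,
then for each foreground species fit the branch-site null and alternative
(three-start protocol) and record the LRT. Per-gene failures are flagged in
the result table, never abort the scan; every hypothesis is per-gene
independent, so row content does not depend on group order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branchsite import (
    BranchSiteLikelihood,
    branch_site_lrt,
    estimate_codon_frequencies_f3x4,
    fit_m0,
)
from .codon_align import ProteinAlignment, back_translate, validate_codon_alignment
from .ortholog_groups import OrthologGroup, group_size_histogram, prune_master_tree
from .trees import LabeledTree

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "group_id",
    "foreground",
    "n_species",
    "n_sites",
    "lnL_null",
    "lnL_alt",
    "lrt",
    "p_value",
    "significant",
    "omega2_hat",
    "best_start",
    "n_starts",
    "status",
]


def _blank_row(group: OrthologGroup, foreground: str, status: str) -> dict:
    return {
        "group_id": group.group_id,
        "foreground": foreground,
        "n_species": group.size,
        "n_sites": np.nan,
        "lnL_null": np.nan,
        "lnL_alt": np.nan,
        "lrt": np.nan,
        "p_value": np.nan,
        "significant": False,
        "omega2_hat": np.nan,
        "best_start": np.nan,
        "n_starts": 0,
        "status": status,
    }


def run_scan(
    groups: list[OrthologGroup],
    master,
    foregrounds: list[str],
    *,
    alpha: float = 0.05,
    omega2_starts: tuple[float, ...] = (0.5, 1.0, 2.0),
    null_distribution: str = "chi2",
) -> pd.DataFrame:
    """Run the dual-foreground branch-site scan over a group collection.

    `master` is the master species topology (newick string, dendropy tree or
    LabeledTree); `foregrounds` names one or two foreground species that must
    be present in every group (enforced upstream by the group filter). The
    pruned tree and its one-ratio branch lengths are shared between the
    foreground hypotheses of a gene; only the foreground flag differs.
    Returns one row per (group, foreground) in input order.
    """
    if not foregrounds:
        raise ValueError("at least one foreground species is required")
    rows = []
    for group in groups:
        rows.extend(
            _scan_group(
                group,
                master,
                foregrounds,
                alpha=alpha,
                omega2_starts=omega2_starts,
                null_distribution=null_distribution,
            )
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _scan_group(
    group, master, foregrounds, *, alpha, omega2_starts, null_distribution
) -> list[dict]:
    missing = [fg for fg in foregrounds if fg not in group.species]
    if missing:
        return [
            _blank_row(group, fg, f"skipped:foreground-absent:{m}")
            for fg, m in zip(foregrounds, [",".join(missing)] * len(foregrounds))
        ]
    if group.size < 3:
        return [
            _blank_row(group, fg, "skipped:fewer-than-3-species")
            for fg in foregrounds
        ]
    try:
        pruned = prune_master_tree(master, group.species)
    except ValueError as exc:
        logger.warning("group %s: %s", group.group_id, exc)
        return [_blank_row(group, fg, f"failed:prune:{exc}") for fg in foregrounds]
    try:
        proteins = {sp: p for sp, (p, _) in group.members.items()}
        aln = ProteinAlignment(proteins)
        caln = back_translate(aln, {sp: c for sp, (_, c) in group.members.items()})
    except ValueError as exc:
        logger.warning("group %s: alignment assembly failed: %s", group.group_id, exc)
        return [_blank_row(group, fg, f"failed:alignment:{exc}") for fg in foregrounds]
    report = validate_codon_alignment(caln)
    if not report.ok:
        first = report.violations[0]
        return [
            _blank_row(group, fg, f"failed:validation:{first}") for fg in foregrounds
        ]
    pi = estimate_codon_frequencies_f3x4(caln)

    # branch lengths estimated once per gene (one-ratio model), then shared
    base = LabeledTree(pruned.tree, foreground=None)
    engine0 = BranchSiteLikelihood(caln, base, pi)
    m0 = fit_m0(caln, base, pi=pi, engine=engine0)
    for i, node in enumerate(base.tree.postorder_node_iter()):
        node.edge.length = (
            None if np.isnan(m0.lengths[i]) else float(m0.lengths[i])
        )

    out = []
    for fg in foregrounds:
        try:
            labeled = base.with_foreground(fg)
            engine = BranchSiteLikelihood(caln, labeled, pi)
            result = branch_site_lrt(
                caln,
                labeled,
                pi=pi,
                omega2_starts=omega2_starts,
                alpha=alpha,
                null_distribution=null_distribution,
                engine=engine,
            )
        except Exception as exc:  # per-gene failures must not abort the scan
            logger.warning("group %s fg %s: %s", group.group_id, fg, exc)
            out.append(_blank_row(group, fg, f"failed:fit:{exc}"))
            continue
        lrt = result.lrt
        best = result.fit_alt.best
        out.append(
            {
                "group_id": group.group_id,
                "foreground": fg,
                "n_species": group.size,
                "n_sites": caln.n_sites,
                "lnL_null": lrt.lnL_null,
                "lnL_alt": lrt.lnL_alt,
                "lrt": lrt.statistic,
                "p_value": lrt.p_value,
                "significant": lrt.significant,
                "omega2_hat": best.params.omega2,
                "best_start": best.omega2_start,
                "n_starts": len(result.fit_alt.starts),
                "status": "ok",
            }
        )
    return out


def exclusive_psg_set(
    table: pd.DataFrame, foreground_a: str, foreground_b: str
) -> set[str]:
    """Genes significant for foreground_a but not for foreground_b."""
    present = set(table["foreground"])
    for fg in (foreground_a, foreground_b):
        if fg not in present:
            raise ValueError(f"foreground {fg!r} not present in results table")
    sig = {
        fg: set(
            table.loc[
                (table["foreground"] == fg) & table["significant"], "group_id"
            ]
        )
        for fg in (foreground_a, foreground_b)
    }
    return sig[foreground_a] - sig[foreground_b]


def summary_report(table: pd.DataFrame) -> dict:
    """Per-foreground tested/significant counts and one-decimal percentages.

    Percentages are 100 x significant / tested rounded to one decimal; the
    group-size histogram over the scanned groups is included.
    """
    if table.empty:
        raise ValueError("empty results table")
    report: dict = {"foregrounds": {}}
    for fg, sub in table.groupby("foreground", sort=False):
        ok = sub[sub["status"] == "ok"]
        tested = len(ok)
        significant = int(ok["significant"].sum())
        percent = round(100.0 * significant / tested, 1) if tested else 0.0
        report["foregrounds"][fg] = {
            "tested": tested,
            "significant": significant,
            "percent": percent,
            "skipped": int((sub["status"] != "ok").sum()),
        }
    per_group = table.drop_duplicates("group_id")
    hist: dict[int, int] = {}
    for n in per_group["n_species"]:
        hist[int(n)] = hist.get(int(n), 0) + 1
    report["group_size_histogram"] = dict(sorted(hist.items()))
    return report


@dataclass
class ScanConfig:
    """Flat configuration of one scan run (see cli for the YAML layout)."""

    membership: str
    protein_fasta: str
    cds_fasta: str
    master_tree: str
    required_species: list[str]
    min_species: int
    foregrounds: list[str]
    allowed_taxon: list[str] | None = None
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str) -> "ScanConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"bad scan config {path}: {exc}") from exc
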