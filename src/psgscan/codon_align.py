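"""Protein-guided codon alignment assembly (back-translation) and validation.

A multiple protein alignment plus the unaligned coding sequences it was
derived from determine a codon alignment exactly: every aligned residue is
replaced by its source codon and every gap by a codon gap ``---``. This is
the classical PAL2NAL construction, re-implemented here so the codon model
can consume alignments without external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .codons import CODON_INDEX, STOP_CODONS, translate_codon

GAP_CODON = "---"


@dataclass
class ProteinAlignment:
    """Aligned amino-acid rows keyed by species; all rows share one length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged protein alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return list(self.rows)


@dataclass
class CodonAlignment:
    """Gap-aware aligned codon rows keyed by species.

    Row length is 3 x the number of codon sites; each aligned triplet is
    either the gap codon ``---``, a sense codon, or a triplet containing
    IUPAC ambiguity codes (treated as missing data downstream).
    """

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged codon alignment: row lengths {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("codon alignment length is not a multiple of 3")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) // 3 if self.rows else 0

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def codon(self, species: str, site: int) -> str:
        return self.rows[species][3 * site : 3 * site + 3]

    def codons(self, species: str) -> list[str]:
        row = self.rows[species]
        return [row[i : i + 3] for i in range(0, len(row), 3)]


def normalize_cds(seq: str) -> str:
    """Uppercase, map RNA U to T, and strip one terminal stop codon if present."""
    seq = seq.upper().replace("U", "T")
    if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    return seq


def back_translate(
    aln: ProteinAlignment, cds: dict[str, str]
) -> CodonAlignment:
    """Thread each CDS onto its gapped protein row, yielding a codon alignment.

    For every species the CDS (terminal stop removed) must have length exactly
    3x the ungapped protein length, every codon must translate to the aligned
    residue, and no internal stop codon may occur. Gap residues become the
    gap codon; degapping any output row reproduces the input CDS.
    """
    out: dict[str, str] = {}
    for species, protein_row in aln.rows.items():
        if species not in cds:
            raise ValueError(f"no CDS provided for species {species!r}")
        nt = normalize_cds(cds[species])
        n_residues = sum(1 for ch in protein_row if ch != "-")
        if len(nt) != 3 * n_residues:
            raise ValueError(
                f"CDS/protein length mismatch for {species!r}: "
                f"expected {3 * n_residues} nt, observed {len(nt)}"
            )
        codons_out = []
        pos = 0
        for col, residue in enumerate(protein_row):
            if residue == "-":
                codons_out.append(GAP_CODON)
                continue
            codon = nt[pos : pos + 3]
            pos += 3
            if codon in STOP_CODONS:
                raise ValueError(
                    f"internal stop codon {codon} in {species!r} at "
                    f"alignment column {col}"
                )
            if codon in CODON_INDEX:
                aa = translate_codon(codon)
                if residue != "X" and aa != residue.upper():
                    raise ValueError(
                        f"codon/residue conflict for {species!r} at alignment "
                        f"column {col}: codon {codon} translates to {aa}, "
                        f"aligned residue is {residue}"
                    )
            codons_out.append(codon)
        out[species] = "".join(codons_out)
    return CodonAlignment(out)


@dataclass
class ValidationReport:
    """Per-species violations and ambiguity flags for a codon alignment."""

    violations: list[tuple[str, int, str]] = field(default_factory=list)
    ambiguous_columns: set[int] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_codon_alignment(caln: CodonAlignment) -> ValidationReport:
    """Report frame problems, internal stops and ambiguity codes.

    Ambiguity codes (N etc.) are not errors: the affected columns are flagged
    so the likelihood treats them as missing data. Internal stop codons and
    characters outside the IUPAC alphabet are violations.
    """
    report = ValidationReport()
    for species, row in caln.rows.items():
        if len(row) % 3:
            report.violations.append((species, -1, "row length not a multiple of 3"))
            continue
        for site in range(len(row) // 3):
            codon = row[3 * site : 3 * site + 3].upper().replace("U", "T")
            if codon == GAP_CODON:
                continue
            if codon in STOP_CODONS:
                report.violations.append((species, site, f"internal stop {codon}"))
            elif codon not in CODON_INDEX:
                if all(ch in "ACGTURYSWKMBDHVN-" for ch in codon):
                    report.ambiguous_columns.add(site)
                else:
                    report.violations.append(
                        (species, site, f"unrecognized codon {codon}")
                    )
    return report


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(rows: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in rows.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_phylip(caln: CodonAlignment, path: str) -> None:
    """Write a sequential PHYLIP file (relaxed names) for external tools."""
    rows = caln.rows
    length = 3 * caln.n_sites
    with open(path, "w") as fh:
        fh.write(f" {len(rows)} {length}\n")
        for name, seq in rows.items():
            fh.write(f"{name}  {seq}\n")
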