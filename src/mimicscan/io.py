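"""Readers and writers for the external formats the screen touches.

Formats: protein FASTA, GTDB-style taxonomy TSV, 12-column tabular alignment
hits (the classic ``outfmt 6`` dialect), and the two structure-prediction
confidence tables (peptide-MHC II scalars, TCR:pMHC docking runs).

Coordinate convention: the tabular alignment dialect is 1-based inclusive on
disk; everything in memory is 0-based half-open. Conversion happens exactly
once, on read/write here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mimicscan")

#: 20 canonical amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted residue alphabet: canonical plus the ambiguity letter X.
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)

#: Peptide-MHC II structural templates carried as metadata.
MHC_TEMPLATES = ("4p23", "6mng", "1muj")
#: TCR:pMHC II structural templates (one mouse TCR type each).
TCR_TEMPLATES = ("3c60", "3rdt", "3c5z", "6mnn")
#: Docking runs per (candidate, template).
RUNS_PER_TEMPLATE = 3

UNCLASSIFIED = "UNCLASSIFIED"

#: Column order of the 12-column tabular alignment dialect.
ALIGNMENT_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: FASTA id, sequence, and its source genome/contig."""

    id: str
    sequence: str
    source_genome: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)} "
                f"(alphabet is {ALPHABET})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonAssignment:
    """GTDB-style lineage for one genome or contig, with the phylum pre-parsed."""

    genome_id: str
    lineage: str
    phylum: str = field(default="")

    @staticmethod
    def from_lineage(genome_id: str, lineage: str) -> "TaxonAssignment":
        return TaxonAssignment(genome_id, lineage, parse_phylum(lineage))


@dataclass(frozen=True)
class AlignmentHitRow:
    """One row of the 12-column tabular alignment dialect.

    Coordinates are kept 0-based half-open in memory; `ingest_alignment_hits`
    and `write_alignment_hits` convert from/to the on-disk 1-based inclusive
    convention.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: evalue < 0")
        if self.s_start > self.s_end:
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: s_start > s_end after "
                "normalization"
            )


@dataclass(frozen=True)
class ConfidenceRecord:
    """Peptide-MHC II structure-prediction confidence scalars for one candidate.

    ``peptide_plddt`` is the per-residue confidence of the modelled peptide
    reduced to one scalar (mean over the 11-mer, see docs); ``inter_pae`` is
    the mean over peptide residues of the lowest inter-chain predicted aligned
    error against the MHC chains.
    """

    candidate_id: str
    mhc_template: str
    peptide_plddt: float
    inter_pae: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.peptide_plddt <= 100.0:
            raise ValueError(
                f"{self.candidate_id}: peptide_plddt {self.peptide_plddt} "
                "outside [0, 100]"
            )
        if self.inter_pae < 0:
            raise ValueError(f"{self.candidate_id}: inter_pae {self.inter_pae} < 0")


@dataclass(frozen=True)
class TcrDockRecord:
    """One TCR:pMHC II docking simulation (3 runs per candidate x template)."""

    candidate_id: str
    tcr_template: str
    run_index: int
    pae_tcr_pmhc: float
    peptide_plddt: float

    def __post_init__(self) -> None:
        if self.tcr_template not in TCR_TEMPLATES:
            raise ValueError(
                f"{self.candidate_id}: unknown tcr_template {self.tcr_template!r}; "
                f"expected one of {TCR_TEMPLATES}"
            )
        if self.run_index not in (1, 2, 3):
            raise ValueError(
                f"{self.candidate_id}: run_index {self.run_index} not in {{1,2,3}}"
            )
        if not 0.0 <= self.peptide_plddt <= 100.0:
            raise ValueError(
                f"{self.candidate_id}: peptide_plddt {self.peptide_plddt} "
                "outside [0, 100]"
            )
        if self.pae_tcr_pmhc < 0:
            raise ValueError(f"{self.candidate_id}: pae_tcr_pmhc < 0")


# ---------------------------------------------------------------------------
# FASTA


def _split_header(header: str) -> tuple[str, str]:
    """Return (record id, source genome) from a FASTA id token.

    The convention is ``genome|protein``; headers without a ``|`` yield an
    empty source genome (callers may join on an explicit mapping instead).
    """
    if "|" in header:
        genome, _, _ = header.partition("|")
        return header, genome
    return header, ""


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are upper-cased. In strict mode any residue outside the
    canonical-20-plus-X alphabet raises :class:`FormatError`; in lenient mode
    such residues are masked to ``X`` (and a count is logged).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    masked = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - _ALPHABET_SET
        if bad:
            if strict:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains invalid residues "
                    f"{sorted(bad)}"
                )
            seq = "".join(c if c in _ALPHABET_SET else "X" for c in seq)
            masked += 1
        rec_id, genome = _split_header(rec.id)
        records.append(ProteinRecord(rec_id, seq, genome))
    if masked:
        logger.warning("%s: masked non-canonical residues in %d records", path, masked)
    if not records:
        logger.warning("%s: empty FASTA, no records read", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as single-line-sequence FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Taxonomy


def parse_phylum(lineage: str) -> str:
    """Extract the phylum from a GTDB lineage string (``p__`` rank).

    Returns :data:`UNCLASSIFIED` when the rank is absent or empty.
    """
    for token in lineage.split(";"):
        token = token.strip()
        if token.startswith("p__"):
            name = token[3:].strip()
            return name if name else UNCLASSIFIED
    return UNCLASSIFIED


def read_taxonomy_table(path: str | Path) -> list[TaxonAssignment]:
    """Read a TSV with columns ``genome_id`` and ``lineage``.

    Every row yields a phylum label (possibly UNCLASSIFIED); duplicate genome
    ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"genome_id", "lineage"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate genome_id {dup.iloc[0]!r}")
    return [
        TaxonAssignment.from_lineage(row.genome_id, row.lineage)
        for row in df.itertuples()
    ]


def write_taxonomy_table(assignments: Iterable[TaxonAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [(a.genome_id, a.lineage, a.phylum) for a in assignments],
        columns=["genome_id", "lineage", "phylum"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tabular alignment hits


def ingest_alignment_hits(
    path: str | Path, evalue_threshold: float = 0.001
) -> list[AlignmentHitRow]:
    """Read 12-column tabular alignment hits, keeping rows with
    evalue <= threshold (boundary inclusive).

    Subject and query coordinates are converted from the dialect's 1-based
    inclusive convention to 0-based half-open.
    """
    path = Path(path)
    kept: list[AlignmentHitRow] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                row = AlignmentHitRow(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_len=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]) - 1,
                    q_end=int(parts[7]),
                    s_start=int(parts[8]) - 1,
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if row.evalue <= evalue_threshold:
                kept.append(row)
            else:
                dropped += 1
    logger.info(
        "%s: kept %d hits at evalue <= %g, dropped %d",
        path, len(kept), evalue_threshold, dropped,
    )
    return kept


def write_alignment_hits(rows: Iterable[AlignmentHitRow], path: str | Path) -> None:
    """Write hits in the 12-column dialect (coordinates back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id, r.subject_id, f"{r.pct_identity:.3f}",
                        r.aln_len, r.mismatches, r.gap_opens,
                        r.q_start + 1, r.q_end, r.s_start + 1, r.s_end,
                        f"{r.evalue:.3g}", f"{r.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Confidence score tables


def read_score_tables(
    path_mhc: str | Path, path_tcr: str | Path
) -> tuple[list[ConfidenceRecord], list[TcrDockRecord]]:
    """Read the peptide-MHC II confidence table and the TCR docking table.

    MHC table columns: candidate_id, mhc_template, peptide_plddt, inter_pae.
    TCR table columns: candidate_id, tcr_template, run_index, pae_tcr_pmhc,
    peptide_plddt. Record invariants (score ranges, template whitelist) are
    enforced on construction; (candidate, template) groups with a run count
    other than 3 are flagged with a warning but still returned.
    """
    mhc_df = pd.read_csv(path_mhc, sep="\t")
    required = {"candidate_id", "mhc_template", "peptide_plddt", "inter_pae"}
    if not required <= set(mhc_df.columns):
        raise FormatError(
            f"{path_mhc}: missing columns {sorted(required - set(mhc_df.columns))}"
        )
    mhc_records = [
        ConfidenceRecord(
            str(row.candidate_id), str(row.mhc_template),
            float(row.peptide_plddt), float(row.inter_pae),
        )
        for row in mhc_df.itertuples()
    ]

    tcr_df = pd.read_csv(path_tcr, sep="\t")
    required = {"candidate_id", "tcr_template", "run_index", "pae_tcr_pmhc",
                "peptide_plddt"}
    if not required <= set(tcr_df.columns):
        raise FormatError(
            f"{path_tcr}: missing columns {sorted(required - set(tcr_df.columns))}"
        )
    tcr_records = [
        TcrDockRecord(
            str(row.candidate_id), str(row.tcr_template), int(row.run_index),
            float(row.pae_tcr_pmhc), float(row.peptide_plddt),
        )
        for row in tcr_df.itertuples()
    ]
    counts = tcr_df.groupby(["candidate_id", "tcr_template"]).size()
    incomplete = counts[counts != RUNS_PER_TEMPLATE]
    if not incomplete.empty:
        logger.warning(
            "%s: %d (candidate, template) groups without exactly %d runs",
            path_tcr, len(incomplete), RUNS_PER_TEMPLATE,
        )
    return mhc_records, tcr_records


def write_score_tables(
    mhc_records: Sequence[ConfidenceRecord],
    tcr_records: Sequence[TcrDockRecord],
    path_mhc: str | Path,
    path_tcr: str | Path,
) -> None:
    pd.DataFrame(
        [(r.candidate_id, r.mhc_template, r.peptide_plddt, r.inter_pae)
         for r in mhc_records],
        columns=["candidate_id", "mhc_template", "peptide_plddt", "inter_pae"],
    ).to_csv(path_mhc, sep="\t", index=False)
    pd.DataFrame(
        [(r.candidate_id, r.tcr_template, r.run_index, r.pae_tcr_pmhc,
          r.peptide_plddt) for r in tcr_records],
        columns=["candidate_id", "tcr_template", "run_index", "pae_tcr_pmhc",
                 "peptide_plddt"],
    ).to_csv(path_tcr, sep="\t", index=False)
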