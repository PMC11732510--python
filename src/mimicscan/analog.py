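"""Local-alignment search of the query epitope against a protein collection.

This is the analog-search stage of the screen: a Smith-Waterman style local
alignment of the self-epitope against every subject protein, with
Karlin-Altschul e-values and an e-value cutoff (default 0.001). The alignment
itself is delegated to Biopython's ``PairwiseAligner``; the statistics are
computed here. The pipeline may bypass this stage and scan every protein
directly, since the footprint motif filter is the discriminating step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from mimicscan.io import ProteinRecord

logger = logging.getLogger("mimicscan")

#: Default Karlin-Altschul parameters for BLOSUM62 gapped alignment.
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267


@dataclass(frozen=True)
class EpitopeQuery:
    """A self-peptide with its annotated MHC-anchor / TCR-contact footprint.

    ``footprint`` maps 0-based offsets within the epitope to the required
    residue; ``mhc_anchor_offset`` marks the single MHC II anchor position
    (the p1-pocket residue), which the motif filter never relaxes.
    """

    name: str
    sequence: str
    footprint: Mapping[int, str]
    mhc_anchor_offset: int

    def __post_init__(self) -> None:
        offsets = sorted(self.footprint)
        if offsets != list(self.footprint):
            object.__setattr__(self, "footprint", dict(sorted(self.footprint.items())))
        if self.mhc_anchor_offset not in self.footprint:
            raise ValueError(
                f"epitope {self.name!r}: anchor offset {self.mhc_anchor_offset} "
                "not in footprint"
            )
        for off, res in self.footprint.items():
            if not 0 <= off < len(self.sequence):
                raise ValueError(
                    f"epitope {self.name!r}: footprint offset {off} outside sequence"
                )
            if self.sequence[off] != res:
                raise ValueError(
                    f"epitope {self.name!r}: residue at offset {off} is "
                    f"{self.sequence[off]!r}, footprint says {res!r}"
                )


#: Footprint of MOG 35-55 in 21-mer offsets: Y40 anchors the MHC II p1 pocket;
#: R41, F44, R46, V47 are the dominant TCR contacts.
MOG_FOOTPRINT = {5: "Y", 6: "R", 9: "F", 11: "R", 12: "V"}


def mouse_mog35_55() -> EpitopeQuery:
    """Mouse MOG 35-55 (the classic EAE-inducing epitope in C57BL/6J mice)."""
    return EpitopeQuery(
        "mouse_MOG_35-55", "MEVGWYRSPFSRVVHLYRNGK", MOG_FOOTPRINT, 5
    )


def human_mog35_55() -> EpitopeQuery:
    """Human MOG 35-55: differs from mouse at position 42 (S -> P).

    Position 42 is not part of the footprint, so both variants compile to the
    same motif set.
    """
    return EpitopeQuery(
        "human_MOG_35-55", "MEVGWYRPPFSRVVHLYRNGK", MOG_FOOTPRINT, 5
    )


BUILTIN_EPITOPES = {
    "mouse_mog35_55": mouse_mog35_55,
    "human_mog35_55": human_mog35_55,
}


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for the local-alignment search.

    Gap cost for a gap of length k is ``gap_open + k * gap_extend`` (the
    convention of the common protein-search tools).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    K: float = DEFAULT_K
    lam: float = DEFAULT_LAMBDA


@dataclass(frozen=True)
class AnalogHit:
    """Best local-alignment hit of the epitope in one subject protein."""

    subject_id: str
    subject_span: tuple[int, int]
    query_span: tuple[int, int]
    score: float
    bitscore: float
    evalue: float
    subject_subsequence: str
    source_genome: str = ""
    pct_identity: float = 0.0
    aln_len: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.subject_span[1] - self.subject_span[0] < 1:
            raise ValueError("empty subject span")
        if self.evalue < 0:
            raise ValueError("negative evalue")


def _alignment_stats(query: str, subject: str, q_blocks, s_blocks):
    """(identities, alignment length incl. gaps, mismatches, gap opens)."""
    identities = mismatches = aligned_cols = gap_opens = gap_cols = 0
    prev_q_end = prev_s_end = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            gap = (qs - prev_q_end) + (ss - prev_s_end)
            if gap:
                gap_opens += 1
                gap_cols += gap
        for qc, sc in zip(query[qs:qe], subject[ss:se]):
            if qc == sc:
                identities += 1
            else:
                mismatches += 1
        aligned_cols += qe - qs
        prev_q_end, prev_s_end = qe, se
    return identities, aligned_cols + gap_cols, mismatches, gap_opens


def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    try:
        matrix = substitution_matrices.load(params.matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {params.matrix!r}") from exc
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = matrix
    # PairwiseAligner charges open_gap_score on the first gap residue, so the
    # open+k*extend convention maps to open_gap = -(open + extend).
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Maximal local alignment score of query vs subject under affine gaps.

    Returns ``(score, query_span, subject_span)`` with 0-based half-open
    spans from the aligner's deterministic first optimal traceback. A score
    of 0 (no positive-scoring alignment) yields empty spans ``(0, 0)``.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    aligner = _make_aligner(params)
    score = float(aligner.score(query, subject))
    if score <= 0:
        return 0.0, (0, 0), (0, 0)
    aln = next(iter(aligner.align(query, subject)))
    q_blocks, s_blocks = aln.aligned
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return score, q_span, s_span


def evalue_from_score(
    score: float, m: int, n: int, K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA
) -> float:
    """Karlin-Altschul expected number of chance hits: ``K * m * n * exp(-lam * S)``.

    ``m`` is the query length, ``n`` the total database residue count.
    Strictly decreasing in the score.
    """
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return K * m * n * math.exp(-lam * score)


def bitscore_from_score(score: float, K: float = DEFAULT_K,
                        lam: float = DEFAULT_LAMBDA) -> float:
    """Normalised (bit) score: ``(lam*S - ln K) / ln 2``."""
    return (lam * score - math.log(K)) / math.log(2.0)


def search_analogs(
    query: EpitopeQuery,
    proteome: Sequence[ProteinRecord],
    evalue_threshold: float = 0.001,
    params: AlignmentParams = AlignmentParams(),
) -> list[AnalogHit]:
    """Align the epitope against every protein; keep the best hit per subject
    with evalue <= threshold (boundary inclusive).

    The database length ``n`` in the e-value is the total residue count of
    the proteome. Hits carry the aligned subject subsequence so the motif
    filter can rescan it (in practice the filter rescans the whole subject).
    """
    if not proteome:
        logger.warning("search_analogs: empty proteome, no hits")
        return []
    n_db = sum(len(p) for p in proteome)
    m = len(query.sequence)
    aligner = _make_aligner(params)
    hits: list[AnalogHit] = []
    for protein in proteome:
        score = float(aligner.score(query.sequence, protein.sequence))
        if score <= 0:
            continue
        evalue = evalue_from_score(score, m, n_db, params.K, params.lam)
        if evalue > evalue_threshold:
            continue
        aln = next(iter(aligner.align(query.sequence, protein.sequence)))
        q_blocks, s_blocks = aln.aligned
        q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
        s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
        identities, aln_len, mismatches, gap_opens = _alignment_stats(
            query.sequence, protein.sequence, q_blocks, s_blocks
        )
        hits.append(
            AnalogHit(
                subject_id=protein.id,
                subject_span=s_span,
                query_span=q_span,
                score=score,
                bitscore=bitscore_from_score(score, params.K, params.lam),
                evalue=evalue,
                subject_subsequence=protein.sequence[s_span[0]:s_span[1]],
                source_genome=protein.source_genome,
                pct_identity=100.0 * identities / aln_len if aln_len else 0.0,
                aln_len=aln_len,
                mismatches=mismatches,
                gap_opens=gap_opens,
            )
        )
    logger.info(
        "search_analogs: %d/%d subjects hit at evalue <= %g (db %d residues)",
        len(hits), len(proteome), evalue_threshold, n_db,
    )
    return hits


def hits_to_rows(query: EpitopeQuery, hits: Sequence[AnalogHit]):
    """Convert analog hits to 12-column tabular rows (core_io dialect)."""
    from mimicscan.io import AlignmentHitRow

    return [
        AlignmentHitRow(
            query_id=query.name,
            subject_id=h.subject_id,
            pct_identity=h.pct_identity,
            aln_len=h.aln_len,
            mismatches=h.mismatches,
            gap_opens=h.gap_opens,
            q_start=h.query_span[0],
            q_end=h.query_span[1],
            s_start=h.subject_span[0],
            s_end=h.subject_span[1],
            evalue=h.evalue,
            bitscore=h.bitscore,
        )
        for h in hits
    ]
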