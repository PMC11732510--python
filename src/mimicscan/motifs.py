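"""Footprint-motif filtering, ligand-window truncation and core enumeration.

The discriminating stage of the screen. The epitope's footprint (one MHC II
anchor plus four TCR contacts at fixed spacing) is compiled into five
degenerate 9-position motifs: the full pattern ``YR..F.RV.`` and the four
variants that each relax exactly one TCR contact (the MHC anchor is never
relaxed). Sequences are scanned at every offset; around each match a ~21-mer
ligand window is truncated with the anchor at window index 5 (emulating the
proteolytic fragment presented to MHC II); windows are deduplicated globally
by exact sequence; each window is chopped into stride-1 11-mers whose central
9-mers are the putative MHC II binding cores.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mimicscan.analog import EpitopeQuery
from mimicscan.io import ProteinRecord

logger = logging.getLogger("mimicscan")

MOTIF_LENGTH = 9
WINDOW_LENGTH = 21
ANCHOR_INDEX = 5
CORE_WINDOW = 11


@dataclass(frozen=True)
class FootprintMotif:
    """A fixed-spacing degenerate pattern over a 9-residue frame.

    ``required`` maps core offsets (0-based within the 9-mer frame) to exact
    residues; all other positions are wildcards. The display form uses ``.``
    for wildcards, e.g. ``YR..F.RV.``.
    """

    motif_id: str
    required: Mapping[int, str]
    length: int = MOTIF_LENGTH

    def __post_init__(self) -> None:
        if 0 not in self.required:
            raise ValueError(f"motif {self.motif_id!r}: anchor offset 0 not required")
        for off in self.required:
            if not 0 <= off < self.length:
                raise ValueError(f"motif {self.motif_id!r}: offset {off} out of frame")

    @property
    def pattern_string(self) -> str:
        return "".join(
            self.required.get(i, ".") for i in range(self.length)
        )

    def matches(self, window: str) -> bool:
        """Exact-residue test of a 9-mer against the required positions."""
        if len(window) != self.length:
            return False
        return all(window[off] == res for off, res in self.required.items())


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence: the 9-mer frame starting at ``start`` (the anchor)."""

    sequence_id: str
    motif_id: str
    start: int
    matched_9mer: str
    genome_id: str = ""


@dataclass
class LigandWindow:
    """A ~21-mer candidate ligand truncated around a motif match.

    ``anchor_index`` is the position of the motif anchor within the window
    (5 except when the match sits closer than 5 residues to the parent's
    N-terminus). ``sources`` accumulates (parent_id, parent_start, motif_id,
    genome_id) tuples after deduplication.
    """

    sequence: str
    parent_id: str
    parent_start: int
    motif_id: str
    anchor_index: int
    genome_id: str = ""
    ligand_id: str = ""
    sources: list[tuple[str, int, str, str]] = field(default_factory=list)
    multiplicity: int = 1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoreCandidate:
    """An 11-mer window with its central 9-mer binding core."""

    candidate_id: str
    window11: str
    core9: str
    ligand_ref: str
    start_in_ligand: int

    def __post_init__(self) -> None:
        if len(self.window11) != CORE_WINDOW:
            raise ValueError(f"{self.candidate_id}: window11 must be 11 residues")
        if self.core9 != self.window11[1:10]:
            raise ValueError(f"{self.candidate_id}: core9 is not the central 9-mer")


def build_motifs(epitope: EpitopeQuery) -> list[FootprintMotif]:
    """Compile the five footprint motifs from the epitope annotation.

    The footprint offsets are rebased so the MHC anchor sits at motif offset
    0. Returns the full motif first, then the four variants each relaxing one
    TCR-contact position (in footprint order). For MOG 35-55 this yields
    YR..F.RV., Y...F.RV., YR....RV., YR..F..V. and YR..F.R.. .
    """
    anchor = epitope.mhc_anchor_offset
    required_full = {
        off - anchor: res for off, res in epitope.footprint.items()
    }
    if any(off < 0 for off in required_full):
        raise ValueError("footprint extends upstream of the MHC anchor")
    if max(required_full) >= MOTIF_LENGTH:
        raise ValueError("footprint does not fit a 9-residue core frame")
    full = FootprintMotif(_pattern_of(required_full), required_full)
    motifs = [full]
    tcr_offsets = [off for off in sorted(required_full) if off != 0]
    for relax in tcr_offsets:
        req = {off: res for off, res in required_full.items() if off != relax}
        motifs.append(FootprintMotif(_pattern_of(req), req))
    return motifs


def _pattern_of(required: Mapping[int, str]) -> str:
    return "".join(required.get(i, ".") for i in range(MOTIF_LENGTH))


def parse_pattern(pattern: str) -> FootprintMotif:
    """Compile a literal bracketed/dotted pattern (e.g. ``YR..F.RV.``)."""
    pattern = pattern.strip().strip("[]")
    required = {
        i: c for i, c in enumerate(pattern) if c not in ".xX"
    }
    if len(pattern) != MOTIF_LENGTH:
        raise ValueError(
            f"pattern {pattern!r} must span {MOTIF_LENGTH} positions"
        )
    return FootprintMotif(_pattern_of(required), required)


def _compile_regex(motif: FootprintMotif) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all reported. Wildcards may be
    # any alphabet letter including X; required positions are exact residues,
    # so X can never satisfy them.
    body = "".join(
        re.escape(motif.required[i]) if i in motif.required else "."
        for i in range(motif.length)
    )
    return re.compile(f"(?=({body}))")


def scan_motifs(
    sequence: str,
    motifs: Sequence[FootprintMotif],
    sequence_id: str = "",
    genome_id: str = "",
) -> list[MotifMatch]:
    """All (offset, motif) occurrences of the motifs in one sequence.

    A 9-mer satisfying several motifs yields one match per motif (a full-motif
    site necessarily also satisfies all four relaxed variants). Matches are
    returned sorted by (start, motif order as given).
    """
    matches: list[MotifMatch] = []
    for motif in motifs:
        rx = _compile_regex(motif)
        for m in rx.finditer(sequence):
            matches.append(
                MotifMatch(
                    sequence_id=sequence_id,
                    motif_id=motif.motif_id,
                    start=m.start(),
                    matched_9mer=m.group(1),
                    genome_id=genome_id,
                )
            )
    motif_rank = {motif.motif_id: i for i, motif in enumerate(motifs)}
    matches.sort(key=lambda m: (m.start, motif_rank[m.motif_id]))
    return matches


def scan_proteins(
    proteins: Iterable[ProteinRecord], motifs: Sequence[FootprintMotif]
) -> list[MotifMatch]:
    """Scan a protein collection; genome ids are carried from the records."""
    out: list[MotifMatch] = []
    for p in proteins:
        out.extend(scan_motifs(p.sequence, motifs, p.id, p.source_genome))
    return out


def truncate_window(
    parent: ProteinRecord,
    match: MotifMatch,
    window_len: int = WINDOW_LENGTH,
    anchor_offset: int = ANCHOR_INDEX,
) -> LigandWindow:
    """Truncate the ~21-mer ligand window around a motif match.

    The window is ``parent[max(0, start - anchor_offset) :][:window_len]``:
    the anchor lands at window index 5 whenever the parent provides 5 upstream
    residues, and the window is clipped (shorter than 21) at the termini.
    """
    if not (0 <= match.start and match.start + MOTIF_LENGTH <= len(parent)):
        raise ValueError(
            f"match at {match.start} outside parent {parent.id!r}"
        )
    begin = max(0, match.start - anchor_offset)
    window = parent.sequence[begin:begin + window_len]
    return LigandWindow(
        sequence=window,
        parent_id=parent.id,
        parent_start=begin,
        motif_id=match.motif_id,
        anchor_index=match.start - begin,
        genome_id=match.genome_id or parent.source_genome,
    )


def dedup_ligands(windows: Sequence[LigandWindow]) -> list[LigandWindow]:
    """Collapse windows to one representative per distinct sequence.

    Deduplication is global (across genomes) on exact, case-sensitive string
    identity of the full window; the representative is the first window
    encountered in input order and accumulates the source list and
    multiplicity of its duplicates. Ligand ids are assigned sequentially.
    Idempotent: deduplicating the output is a no-op.
    """
    by_seq: dict[str, LigandWindow] = {}
    for w in windows:
        src = (w.parent_id, w.parent_start, w.motif_id, w.genome_id)
        rep = by_seq.get(w.sequence)
        if rep is None:
            rep = LigandWindow(
                sequence=w.sequence,
                parent_id=w.parent_id,
                parent_start=w.parent_start,
                motif_id=w.motif_id,
                anchor_index=w.anchor_index,
                genome_id=w.genome_id,
                sources=list(w.sources) or [src],
                multiplicity=0,
            )
            by_seq[w.sequence] = rep
        else:
            for s in (w.sources or [src]):
                if s not in rep.sources:
                    rep.sources.append(s)
        rep.multiplicity += w.multiplicity
    result = list(by_seq.values())
    for i, rep in enumerate(result):
        rep.ligand_id = f"lig_{i:05d}"
    return result


def enumerate_cores(ligand: LigandWindow) -> list[CoreCandidate]:
    """Chop a ligand into consecutive 11-mers with central 9-mer cores.

    A ligand of length L yields L-10 stride-1 windows; duplicate 11-mer
    strings within the ligand are collapsed (first occurrence kept). Windows
    containing the ambiguity letter X are excluded: motif and anchor positions
    are exact-residue tests, so an X-bearing core is uninterpretable.
    """
    L = len(ligand.sequence)
    if L < CORE_WINDOW:
        logger.warning(
            "ligand %s: length %d < %d, no core candidates",
            ligand.ligand_id or ligand.sequence, L, CORE_WINDOW,
        )
        return []
    seen: set[str] = set()
    out: list[CoreCandidate] = []
    for i in range(L - CORE_WINDOW + 1):
        win = ligand.sequence[i:i + CORE_WINDOW]
        if win in seen:
            continue
        seen.add(win)
        if "X" in win:
            logger.warning(
                "ligand %s: window at %d contains X, excluded",
                ligand.ligand_id or ligand.sequence, i,
            )
            continue
        out.append(
            CoreCandidate(
                candidate_id=f"{ligand.ligand_id or 'lig'}:{i:02d}",
                window11=win,
                core9=win[1:10],
                ligand_ref=ligand.ligand_id,
                start_in_ligand=i,
            )
        )
    return out
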