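"""Binder triage from structure-prediction confidence scalars.

A core candidate is called an MHC II binder when its peptide pLDDT is at
least 90 AND its mean inter-chain lowest PAE against the MHC chains is at
most 4.34 (both boundaries inclusive). For TCR docking, each (candidate,
TCR template) pair is simulated three times and the model with the lowest
TCR:pMHC PAE is kept; the chosen model is "confident" when its peptide
pLDDT is at least 70.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from mimicscan.io import ConfidenceRecord, TcrDockRecord, TCR_TEMPLATES

logger = logging.getLogger("mimicscan")


@dataclass(frozen=True)
class TriageThresholds:
    """Binder-classification and modelling-confidence cutoffs.

    plddt_min / inter_pae_max gate the binder call; confident_plddt_min is
    the lower bar for calling a docking model confidently modelled.
    """

    plddt_min: float = 90.0
    inter_pae_max: float = 4.34
    confident_plddt_min: float = 70.0

    def __post_init__(self) -> None:
        if not 0 <= self.confident_plddt_min <= self.plddt_min <= 100:
            raise ValueError(
                "need 0 <= confident_plddt_min <= plddt_min <= 100"
            )
        if self.inter_pae_max <= 0:
            raise ValueError("inter_pae_max must be positive")


@dataclass(frozen=True)
class BinderCall:
    candidate_id: str
    is_binder: bool
    peptide_plddt: float
    inter_pae: float


@dataclass(frozen=True)
class BestModel:
    """Lowest-PAE docking model among a template's three runs."""

    candidate_id: str
    tcr_template: str
    chosen_run: int
    pae_tcr_pmhc: float
    confident: bool


def classify_binder(
    record: ConfidenceRecord, thresholds: TriageThresholds = TriageThresholds()
) -> BinderCall:
    """Binder iff pLDDT >= plddt_min AND inter-PAE <= inter_pae_max
    (boundaries inclusive)."""
    is_binder = (
        record.peptide_plddt >= thresholds.plddt_min
        and record.inter_pae <= thresholds.inter_pae_max
    )
    return BinderCall(
        record.candidate_id, is_binder, record.peptide_plddt, record.inter_pae
    )


def classify_binders(
    records: Iterable[ConfidenceRecord],
    thresholds: TriageThresholds = TriageThresholds(),
) -> list[BinderCall]:
    return [classify_binder(r, thresholds) for r in records]


def select_best_model(
    runs: Sequence[TcrDockRecord],
    thresholds: TriageThresholds = TriageThresholds(),
    allow_incomplete: bool = False,
) -> BestModel:
    """Pick the lowest-PAE run of one (candidate, template) triple.

    Ties are broken by the lowest run index. With ``allow_incomplete`` a
    group of fewer than three runs is accepted with a warning; otherwise a
    group size other than three is an error.
    """
    if not runs:
        raise ValueError("no docking runs supplied")
    candidate_ids = {r.candidate_id for r in runs}
    templates = {r.tcr_template for r in runs}
    if len(candidate_ids) != 1 or len(templates) != 1:
        raise ValueError(
            "runs must share one candidate and one template; got "
            f"{candidate_ids} x {templates}"
        )
    if len(runs) != 3:
        if not allow_incomplete:
            raise ValueError(
                f"{runs[0].candidate_id}/{runs[0].tcr_template}: expected 3 "
                f"runs, got {len(runs)}"
            )
        logger.warning(
            "%s/%s: best-of-%d (incomplete run set)",
            runs[0].candidate_id, runs[0].tcr_template, len(runs),
        )
    chosen = min(runs, key=lambda r: (r.pae_tcr_pmhc, r.run_index))
    return BestModel(
        candidate_id=chosen.candidate_id,
        tcr_template=chosen.tcr_template,
        chosen_run=chosen.run_index,
        pae_tcr_pmhc=chosen.pae_tcr_pmhc,
        confident=chosen.peptide_plddt >= thresholds.confident_plddt_min,
    )


def select_best_models(
    records: Iterable[TcrDockRecord],
    thresholds: TriageThresholds = TriageThresholds(),
    allow_incomplete: bool = False,
) -> list[BestModel]:
    """Group docking runs by (candidate, template) and pick each best model."""
    groups: dict[tuple[str, str], list[TcrDockRecord]] = defaultdict(list)
    for r in records:
        groups[(r.candidate_id, r.tcr_template)].append(r)
    return [
        select_best_model(runs, thresholds, allow_incomplete)
        for _, runs in sorted(groups.items())
    ]


def modeled_fraction(
    binders: Sequence[BinderCall],
    best_models: Sequence[BestModel],
    templates: Sequence[str] = TCR_TEMPLATES,
) -> float:
    """Fraction of binders whose best model is confident for every template.

    Returns NaN (with a warning) when there are no binders. A binder missing
    a best model for some template counts as not fully modelled.
    """
    binder_ids = [b.candidate_id for b in binders if b.is_binder]
    if not binder_ids:
        logger.warning("modeled_fraction: zero binders, fraction undefined")
        return float("nan")
    confident: dict[str, set[str]] = defaultdict(set)
    for m in best_models:
        if m.confident:
            confident[m.candidate_id].add(m.tcr_template)
    wanted = set(templates)
    fully = sum(1 for cid in binder_ids if wanted <= confident[cid])
    return fully / len(binder_ids)


def reduce_inter_pae(pae_matrix: np.ndarray, peptide_len: int) -> float:
    """Convenience reducer: mean inter-chain lowest PAE from a full matrix.

    Convention: the peptide occupies the first ``peptide_len`` rows/columns
    of a square (peptide+MHC) PAE matrix. For each peptide residue the
    minimum PAE over all MHC residues is taken in both matrix directions;
    the result is the mean of those per-residue minima. Scalar TSVs remain
    the pipeline contract; this helper exists for users who hold raw
    matrices.
    """
    pae = np.asarray(pae_matrix, dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError("PAE matrix must be square")
    if not 0 < peptide_len < pae.shape[0]:
        raise ValueError("peptide_len must split the matrix into two chains")
    pep = slice(0, peptide_len)
    mhc = slice(peptide_len, pae.shape[0])
    lowest = np.minimum(pae[pep, mhc].min(axis=1), pae[mhc, pep].min(axis=0))
    return float(lowest.mean())
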