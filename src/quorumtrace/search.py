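"""Homolog retrieval against the QS reference database.

Every catalog gene is aligned against every reference protein; a gene is
retained if its best hit passes all three thresholds (identity >= 30%,
subject coverage >= 50%, e-value <= 1e-5 by default). A second,
annotation-based filter then discards genes whose functional annotation
does not mention the matched reference's conserved-domain keyword — the
surrogate for a conserved-domain / NR cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .align import AlignmentParams, AlignmentResult, align_pair, compute_evalue
from .reference import ReferenceDB, ReferenceQSProtein, Role


@dataclass(frozen=True)
class SearchThresholds:
    """Retrieval thresholds for accepting a catalog gene as a QS homolog."""

    min_identity: float = 0.30
    min_coverage: float = 0.50
    max_evalue: float = 1e-5
    #: which sequence the coverage filter applies to; the reference
    #: ("subject") guarantees the functional domain is spanned
    coverage_of: str = "subject"

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if not self.max_evalue > 0:
            raise ValueError("max_evalue must be positive")
        if self.coverage_of not in ("subject", "query"):
            raise ValueError("coverage_of must be 'subject' or 'query'")

    def passes(self, aln: AlignmentResult) -> bool:
        cov = aln.subject_coverage if self.coverage_of == "subject" else aln.query_coverage
        return (
            aln.identity >= self.min_identity
            and cov >= self.min_coverage
            and aln.evalue <= self.max_evalue
        )


@dataclass(frozen=True)
class QSHomolog:
    """An accepted catalog-to-reference match."""

    gene_id: str
    best_reference: ReferenceQSProtein
    alignment: AlignmentResult
    passed_annotation_filter: bool = True

    @property
    def signal(self) -> str:
        return self.best_reference.signal

    @property
    def role(self) -> Role:
        return self.best_reference.role


def search_homologs(
    catalog: Mapping[str, str],
    refdb: ReferenceDB,
    thresholds: SearchThresholds = SearchThresholds(),
    params: AlignmentParams = AlignmentParams(),
    db_residues: int | None = None,
) -> list[QSHomolog]:
    """Retrieve QS homologs from a gene catalog.

    ``catalog`` maps gene id to amino-acid sequence. Each gene is assigned
    at most one best reference: highest alignment score, ties broken by
    lower e-value then reference file order. ``db_residues`` (for the
    e-value) defaults to the total residue count of the catalog, mirroring
    search tools that treat the gene catalog as the database side.
    """
    if not catalog:
        return []
    if len(refdb) == 0:
        raise ValueError("reference database is empty")
    if db_residues is None:
        db_residues = sum(len(s) for s in catalog.values())

    homologs: list[QSHomolog] = []
    for gene_id, seq in catalog.items():
        best: tuple[float, int, int] | None = None  # (-score, evalue-rank key) packed below
        best_aln: AlignmentResult | None = None
        best_ref: ReferenceQSProtein | None = None
        for order, ref in enumerate(refdb):
            aln = align_pair(seq, ref.sequence, params, gene_id, ref.protein_id)
            evalue = compute_evalue(max(aln.score, 0), len(seq), db_residues, params)
            aln = replace(aln, evalue=evalue)
            if not thresholds.passes(aln):
                continue
            key = (-aln.score, aln.evalue, order)
            if best is None or key < best:
                best, best_aln, best_ref = key, aln, ref
        if best_aln is not None and best_ref is not None:
            homologs.append(QSHomolog(gene_id=gene_id, best_reference=best_ref, alignment=best_aln))
    return homologs


def filter_by_annotation(
    homologs: list[QSHomolog], annotations: Mapping[str, str]
) -> list[QSHomolog]:
    """Keep homologs whose annotation mentions the reference's domain keyword.

    Case-insensitive substring containment; a homolog without an annotation
    entry is a hard error naming the gene. Returned homologs have
    ``passed_annotation_filter=True``; discarded ones are dropped.
    """
    retained = []
    for h in homologs:
        if h.gene_id not in annotations:
            raise KeyError(f"gene {h.gene_id!r} has no annotation entry")
        ok = h.best_reference.domain_keyword.lower() in annotations[h.gene_id].lower()
        if ok:
            retained.append(replace(h, passed_annotation_filter=True))
    return retained


def homologs_to_frame(homologs: list[QSHomolog]) -> pd.DataFrame:
    """Tabular view of a homolog list (one row per accepted gene)."""
    rows = [
        {
            "gene_id": h.gene_id,
            "signal": h.signal,
            "role": h.role.value,
            "reference_id": h.best_reference.protein_id,
            "identity": h.alignment.identity,
            "coverage": h.alignment.subject_coverage,
            "evalue": h.alignment.evalue,
            "passed_annotation_filter": h.passed_annotation_filter,
        }
        for h in homologs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "signal", "role", "reference_id",
            "identity", "coverage", "evalue", "passed_annotation_filter",
        ],
    )


def write_homolog_table(homologs: list[QSHomolog], path: str | Path) -> None:
    homologs_to_frame(homologs).to_csv(path, sep="\t", index=False)
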