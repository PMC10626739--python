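"""Quorum-sensing reference protein database: data model and I/O.

A reference database holds experimentally characterized QS synthases,
receptors and peptide processors, each tagged with the signal molecule class
it belongs to (AI-2, AHL, AIP variants, DSF, ...). Homology search assigns
catalog genes to these references; completeness and network inference then
reason over the (signal, role) ontology defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 canonical amino acids plus the ambiguity code X
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Role(str, enum.Enum):
    """Functional role of a QS protein within its pathway.

    ``processor`` covers peptide maturation machinery (e.g. lantibiotic
    cyclases); for pathway-completeness purposes it counts as synthase-side,
    since it sits on the signal-production arm of the circuit.
    """

    SYNTHASE = "synthase"
    RECEPTOR = "receptor"
    PROCESSOR = "processor"

    @property
    def is_synthase_side(self) -> bool:
        return self in (Role.SYNTHASE, Role.PROCESSOR)


@dataclass(frozen=True)
class ReferenceQSProtein:
    """One entry of the QS reference database."""

    protein_id: str
    signal: str
    role: Role
    source_organism: str
    sequence: str
    domain_keyword: str
    step: Optional[int] = None  # multi-step synthases, e.g. Pfs (step 1)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.protein_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"reference {self.protein_id!r}: invalid residues {sorted(bad)}"
            )


@dataclass
class ReferenceDB:
    """A validated collection of reference QS proteins.

    Entries keep file order; ``signals`` is derived and kept consistent.
    """

    entries: list[ReferenceQSProtein] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.signal, e.role, e.protein_id)
            if key in seen:
                raise ValueError(f"duplicate reference entry {key}")
            seen.add(key)

    @property
    def signals(self) -> set[str]:
        return {e.signal for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, protein_id: str) -> ReferenceQSProtein:
        for e in self.entries:
            if e.protein_id == protein_id:
                return e
        raise KeyError(protein_id)


METADATA_COLUMNS = ["protein_id", "signal", "role", "step", "source_organism", "domain_keyword"]


def load_reference_db(fasta_path: str | Path, metadata_path: str | Path) -> ReferenceDB:
    """Load a reference DB from a protein FASTA plus a metadata TSV.

    The TSV must carry the columns ``protein_id, signal, role, step,
    source_organism, domain_keyword`` (step may be blank). Every FASTA id
    must have a metadata row; a missing row is a hard error naming the id.
    Entries are returned in FASTA file order.
    """
    fasta_path, metadata_path = Path(fasta_path), Path(metadata_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty or unreadable FASTA: {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns and c != "step"]
    if missing_cols:
        raise ValueError(f"metadata {metadata_path}: missing columns {missing_cols}")
    meta_by_id = {row["protein_id"]: row for _, row in meta.iterrows()}

    entries = []
    for rec in records:
        if rec.id not in meta_by_id:
            raise KeyError(f"FASTA id {rec.id!r} has no metadata row in {metadata_path}")
        row = meta_by_id[rec.id]
        step_raw = str(row.get("step", "") or "").strip()
        entries.append(
            ReferenceQSProtein(
                protein_id=rec.id,
                signal=row["signal"],
                role=Role(row["role"]),
                step=int(step_raw) if step_raw else None,
                source_organism=row["source_organism"],
                sequence=str(rec.seq).upper(),
                domain_keyword=row["domain_keyword"],
            )
        )
    return ReferenceDB(entries=entries)


def write_reference_db(db: ReferenceDB, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write a reference DB as FASTA + metadata TSV (inverse of loading)."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.protein_id, description="") for e in db.entries
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "protein_id": e.protein_id,
            "signal": e.signal,
            "role": e.role.value,
            "step": "" if e.step is None else e.step,
            "source_organism": e.source_organism,
            "domain_keyword": e.domain_keyword,
        }
        for e in db.entries
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def reference_entries(
    db: ReferenceDB, signal: str, role: Role | str
) -> list[ReferenceQSProtein]:
    """All entries matching both a signal and a role (empty list if none)."""
    role = Role(role)
    return [e for e in db.entries if e.signal == signal and e.role == role]
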