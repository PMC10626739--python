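"""Gene abundance normalization and community diversity.

Three normalization layers, mirroring standard metagenomic practice:

1. *relative* gene abundance — read counts divided by gene length, then by
   the per-sample sum of length-corrected counts, so each sample column
   sums to 1;
2. *per-cell* homolog abundance — summed relative abundance of all genes
   assigned to a (signal, role) homolog class, divided by the relative
   abundance of the single-copy housekeeping gene recA, interpreted as
   average gene copies per cell;
3. genus profiles — relative abundance aggregated over a gene-to-genus
   taxonomy, the substrate for succession and network analysis.

Shannon diversity (natural log) summarizes genus profiles per sample.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .search import QSHomolog

_SAMPLE_RE = re.compile(r"^d(\d+)_r(\d+)$")


def parse_sample_id(sample_id: str) -> tuple[int, int]:
    """Split a ``d{day}_r{replicate}`` sample id into (day, replicate)."""
    m = _SAMPLE_RE.match(sample_id)
    if not m:
        raise ValueError(f"sample id {sample_id!r} is not of the form d<day>_r<rep>")
    return int(m.group(1)), int(m.group(2))


class Normalization(str, enum.Enum):
    RELATIVE = "relative"
    PER_CELL = "per_cell"


@dataclass
class CountTable:
    """Per-sample read counts per gene, plus gene nucleotide lengths.

    ``counts`` is a gene x sample integer DataFrame whose columns are
    ``d{day}_r{rep}`` sample ids; ``lengths`` maps gene id to nucleotide
    length.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()[:5]
            raise ValueError(f"genes without a length: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        if (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        for c in self.counts.columns:
            parse_sample_id(c)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def days(self) -> list[int]:
        return sorted({parse_sample_id(c)[0] for c in self.counts.columns})

    @classmethod
    def from_tsv(cls, counts_path: str | Path, lengths_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts=counts, lengths=lengths)

    def to_tsv(self, counts_path: str | Path, lengths_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.lengths.rename("length_nt").to_csv(lengths_path, sep="\t", index_label="gene_id")


@dataclass
class NormalizedAbundance:
    """Entity x sample matrix of nonnegative reals with its normalization tag."""

    values: pd.DataFrame
    normalization: Normalization

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative abundances")
        if self.normalization is Normalization.RELATIVE:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = sums[~np.isclose(sums, 1.0, atol=1e-9)].index.tolist()[:5]
                raise ValueError(f"relative columns must sum to 1; offending samples: {bad}")


def relative_abundance(table: CountTable) -> NormalizedAbundance:
    """Length-normalized relative gene abundance.

    a_gs = (c_gs / L_g) / sum_g' (c_g's / L_g'). Errors on any sample with
    zero total reads, naming the sample.
    """
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    per_len = table.counts.div(table.lengths, axis=0)
    rel = per_len.div(per_len.sum(axis=0), axis=1)
    return NormalizedAbundance(values=rel, normalization=Normalization.RELATIVE)


def normalize_by_recA(
    homologs: Sequence[QSHomolog],
    rel: NormalizedAbundance,
    recA_gene_ids: Iterable[str],
) -> NormalizedAbundance:
    """Per-cell abundance of each (signal, role) homolog class.

    Sums the relative abundances of all genes assigned to a (signal, role)
    and divides by the community-wide summed relative abundance of recA
    genes — the single-copy proxy for cell number. Rows are indexed by
    ``"{signal}|{role}"``.
    """
    recA_ids = [g for g in recA_gene_ids if g in rel.values.index]
    if not recA_ids:
        raise ValueError("no recA genes present in the abundance table")
    denom = rel.values.loc[recA_ids].sum(axis=0)
    zero = denom[denom == 0].index.tolist()
    if zero:
        raise ValueError(f"recA abundance is zero in samples: {zero}")

    groups: dict[str, list[str]] = {}
    for h in homologs:
        groups.setdefault(f"{h.signal}|{h.role.value}", []).append(h.gene_id)
    rows = {}
    for key, gene_ids in sorted(groups.items()):
        present = [g for g in gene_ids if g in rel.values.index]
        rows[key] = rel.values.loc[present].sum(axis=0) / denom if present else denom * 0.0
    values = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=rel.values.columns)
    values = values.reindex(columns=rel.values.columns, fill_value=0.0)
    return NormalizedAbundance(values=values, normalization=Normalization.PER_CELL)


def genus_profile(rel: NormalizedAbundance, taxonomy: Mapping[str, str]) -> NormalizedAbundance:
    """Aggregate relative gene abundance to genus level.

    Genes without a taxonomy entry fall into ``"unclassified"``. Column
    sums are preserved (still 1).
    """
    if rel.normalization is not Normalization.RELATIVE:
        raise ValueError("genus_profile expects relative abundances")
    genera = pd.Series(
        [taxonomy.get(g, "unclassified") for g in rel.values.index], index=rel.values.index
    )
    agg = rel.values.groupby(genera).sum()
    agg = agg.sort_index()
    return NormalizedAbundance(values=agg, normalization=Normalization.RELATIVE)


def shannon_index(p: Sequence[float] | np.ndarray | pd.Series) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log).

    Input need not be normalized; it is renormalized to sum 1 and zero
    entries are skipped. An all-zero vector is an error.
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    q = arr / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def shannon_per_sample(profile: NormalizedAbundance) -> pd.Series:
    """Shannon index of every sample column of a genus profile."""
    return profile.values.apply(lambda col: shannon_index(col.values), axis=0)
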