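"""Assembly-phase scheme and pathway-level classification.

Oral-biofilm assembly proceeds through an adapting phase (AP, days 0-2,
subdivided AP1 day 0-1 and AP2 day 1-2), a growing phase (GP, days 2-5)
and a mature phase (MP, days 5-11). Day windows are half-open with the
terminal day inclusive, so every day of the series maps to exactly one
phase at either granularity.

A QS pathway (signal class) is *complete* when both a synthase-side and a
receptor homolog are detected; only complete pathways carry signal from
producers to responders and enter the cross-talk network. Pathways are
further labelled AP-/GP-/MP-specific from their per-cell abundance phase
means.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import NormalizedAbundance, parse_sample_id
from .search import QSHomolog


class Completeness(str, enum.Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    ABSENT = "absent"


#: coarse phases in assembly order
COARSE_PHASES = ("AP", "GP", "MP")


@dataclass(frozen=True)
class PhaseWindow:
    name: str
    start: int  # inclusive
    end: int    # exclusive, except the terminal window


@dataclass(frozen=True)
class PhaseScheme:
    """Ordered fine-grained phase windows plus the fine-to-coarse map."""

    windows: tuple[PhaseWindow, ...] = (
        PhaseWindow("AP1", 0, 1),
        PhaseWindow("AP2", 1, 2),
        PhaseWindow("GP", 2, 5),
        PhaseWindow("MP", 5, 11),
    )
    coarse_of: Mapping[str, str] = field(
        default_factory=lambda: {"AP1": "AP", "AP2": "AP", "GP": "GP", "MP": "MP"}
    )

    def __post_init__(self) -> None:
        for prev, cur in zip(self.windows, self.windows[1:]):
            if prev.end != cur.start:
                raise ValueError(
                    f"phase windows must be contiguous: {prev.name} ends at "
                    f"{prev.end}, {cur.name} starts at {cur.start}"
                )
        for w in self.windows:
            if w.end <= w.start:
                raise ValueError(f"empty phase window {w.name}")
            if w.name not in self.coarse_of:
                raise ValueError(f"window {w.name} missing from coarse_of map")

    @property
    def last_day(self) -> int:
        return self.windows[-1].end

    @property
    def coarse_order(self) -> list[str]:
        seen: list[str] = []
        for w in self.windows:
            c = self.coarse_of[w.name]
            if c not in seen:
                seen.append(c)
        return seen

    def phase_rank(self, coarse: str) -> int:
        return self.coarse_order.index(coarse)


def assign_phase(day: int, scheme: PhaseScheme = PhaseScheme(), granularity: str = "coarse") -> str:
    """Phase label for a day; half-open windows, terminal day inclusive."""
    if granularity not in ("fine", "coarse"):
        raise ValueError("granularity must be 'fine' or 'coarse'")
    first = scheme.windows[0].start
    if day < first or day > scheme.last_day:
        raise ValueError(f"day {day} outside [{first}, {scheme.last_day}]")
    for w in scheme.windows:
        if w.start <= day < w.end or (w is scheme.windows[-1] and day == w.end):
            return w.name if granularity == "fine" else scheme.coarse_of[w.name]
    raise AssertionError("unreachable: windows cover the full range")


def sample_phases(
    sample_ids: Sequence[str], scheme: PhaseScheme = PhaseScheme(), granularity: str = "coarse"
) -> pd.Series:
    """Phase label of every ``d{day}_r{rep}`` sample id."""
    return pd.Series(
        {s: assign_phase(parse_sample_id(s)[0], scheme, granularity) for s in sample_ids}
    )


def classify_completeness(
    homologs: Sequence[QSHomolog], signals: Sequence[str] | set[str]
) -> dict[str, Completeness]:
    """Pathway completeness per signal from detected homologs.

    Complete: both a synthase-side (synthase or processor) and a receptor
    homolog present. Incomplete: exactly one of the two sides. Absent: no
    homolog at all.
    """
    synth: set[str] = set()
    recep: set[str] = set()
    for h in homologs:
        (synth if h.role.is_synthase_side else recep).add(h.signal)
    out = {}
    for s in signals:
        has_syn, has_rec = s in synth, s in recep
        if has_syn and has_rec:
            out[s] = Completeness.COMPLETE
        elif has_syn or has_rec:
            out[s] = Completeness.INCOMPLETE
        else:
            out[s] = Completeness.ABSENT
    return out


def phase_means(
    series: pd.Series | pd.DataFrame, scheme: PhaseScheme = PhaseScheme()
) -> pd.DataFrame:
    """Mean abundance per coarse phase (columns) for each row entity.

    Accepts a sample-indexed Series (one entity) or an entity x sample
    DataFrame; samples are pooled over all (day, replicate) pairs of each
    phase.
    """
    df = series.to_frame().T if isinstance(series, pd.Series) else series
    phases = sample_phases(df.columns, scheme, "coarse")
    means = df.T.groupby(phases).mean().T
    return means.reindex(columns=scheme.coarse_order)


def classify_specificity(
    series: pd.Series,
    scheme: PhaseScheme = PhaseScheme(),
    ratio_threshold: float = 1.5,
    stability_threshold: float = 0.25,
) -> str:
    """Phase specificity of one pathway's per-cell abundance series.

    The pathway is X-specific if its largest coarse-phase mean exceeds the
    runner-up by ``ratio_threshold``. Failing that, a flat profile —
    relative range (max - min) / mean below ``stability_threshold`` — is
    called GP-specific, matching the observation that growth-phase
    pathways hold steady abundance throughout assembly. Anything else is
    left unclassified rather than forced into a bin.
    """
    if series.empty:
        raise ValueError("empty abundance series")
    means = phase_means(series, scheme).iloc[0]
    if means.isna().any():
        missing = means[means.isna()].index.tolist()
        raise ValueError(f"series has no samples in phases: {missing}")
    vals = means.values.astype(float)
    order = np.argsort(vals)[::-1]
    top, second = vals[order[0]], vals[order[1]]
    if second == 0 and top > 0:
        return f"{means.index[order[0]]}-specific"
    if second > 0 and top / second >= ratio_threshold:
        return f"{means.index[order[0]]}-specific"
    mean = vals.mean()
    if mean > 0 and (vals.max() - vals.min()) / mean < stability_threshold:
        return "GP-specific"
    return "unclassified"


@dataclass
class PathwayProfile:
    """Per-signal summary: completeness, phase means, specificity."""

    signal: str
    completeness: Completeness
    per_cell: pd.Series  # sample-indexed per-cell abundance (roles summed)
    phase_means: dict[str, float]
    specificity: str


def pathway_profiles(
    homologs: Sequence[QSHomolog],
    per_cell: NormalizedAbundance,
    signals: Sequence[str],
    scheme: PhaseScheme = PhaseScheme(),
    ratio_threshold: float = 1.5,
    stability_threshold: float = 0.25,
) -> list[PathwayProfile]:
    """Assemble the per-signal pathway report from pipeline intermediates."""
    completeness = classify_completeness(homologs, signals)
    profiles = []
    for signal in signals:
        rows = [r for r in per_cell.values.index if r.split("|")[0] == signal]
        series = (
            per_cell.values.loc[rows].sum(axis=0)
            if rows
            else pd.Series(0.0, index=per_cell.values.columns)
        )
        if series.sum() > 0:
            spec = classify_specificity(series, scheme, ratio_threshold, stability_threshold)
        else:
            spec = "unclassified"
        pm = phase_means(series, scheme).iloc[0]
        profiles.append(
            PathwayProfile(
                signal=signal,
                completeness=completeness[signal],
                per_cell=series,
                phase_means={k: float(v) for k, v in pm.items()},
                specificity=spec,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[PathwayProfile], scheme: PhaseScheme = PhaseScheme()) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"signal": p.signal, "completeness": p.completeness.value}
        for c in scheme.coarse_order:
            row[f"{c}_mean"] = p.phase_means.get(c, float("nan"))
        row["specificity"] = p.specificity
        rows.append(row)
    return pd.DataFrame(rows)


def top_genera(
    homologs: Sequence[QSHomolog],
    rel: NormalizedAbundance,
    taxonomy: Mapping[str, str],
    phase: str,
    reference: str | tuple[str, str],
    scheme: PhaseScheme = PhaseScheme(),
    k: int = 5,
) -> list[str]:
    """Top genera carrying a reference protein's homologs in one phase.

    ``reference`` is either a reference protein id or a (signal, role)
    pair; ``phase`` may be fine (AP1, AP2) or coarse (AP, GP, MP). Genera
    are ranked by the summed relative abundance of the matching homolog
    genes over the phase's samples; ties break alphabetically; zero-
    abundance genera are omitted.
    """
    if isinstance(reference, tuple):
        signal, role = reference
        genes = [h.gene_id for h in homologs if h.signal == signal and h.role.value == str(role)]
        if not any(h.signal == signal for h in homologs):
            raise KeyError(f"no homologs for signal {signal!r}")
    else:
        genes = [h.gene_id for h in homologs if h.best_reference.protein_id == reference]
        if not genes:
            raise KeyError(f"no homologs matched to reference {reference!r}")

    fine = {w.name for w in scheme.windows}
    granularity = "fine" if phase in fine else "coarse"
    if granularity == "coarse" and phase not in scheme.coarse_order:
        raise ValueError(f"unknown phase {phase!r}")
    phases = sample_phases(rel.values.columns, scheme, granularity)
    cols = phases[phases == phase].index
    if len(cols) == 0:
        raise ValueError(f"no samples fall in phase {phase!r}")

    sums: dict[str, float] = {}
    present = [g for g in genes if g in rel.values.index]
    for g in present:
        genus = taxonomy.get(g, "unclassified")
        sums[genus] = sums.get(genus, 0.0) + float(rel.values.loc[g, cols].sum())
    ranked = sorted(sums.items(), key=lambda kv: (-kv[1], kv[0]))
    return [genus for genus, total in ranked if total > 0][:k]
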