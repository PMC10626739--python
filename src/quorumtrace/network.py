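"""Directed longitudinal cross-talk network and interference prediction.

A *cross-talk* edge runs from a genus possessing a signal's synthase to a
genus possessing the cognate receptor. Orienting edges by the peak
assembly phase of the two genera distinguishes

* forward cross-talk — the receiver peaks in a later phase than the
  sender, so early colonizers hand the signal on to later arrivals;
* reverse cross-talk — the receiver peaks earlier, so late colonizers act
  back on established members (a brake on the former colonists);
* intra-phase talk — both peak in the same phase (including self-talk of
  a genus carrying both roles), excluded from interference propagation.

Genera carrying both roles across multiple complete signals act as QS
hubs relaying information through the succession. Blocking a signal then
has qualitatively predictable consequences: forward-edge receivers are
delayed or suppressed, while reverse-edge receivers lose their brake and
persist longer or grow higher.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .abundance import NormalizedAbundance
from .phases import Completeness, PhaseScheme, phase_means
from .search import QSHomolog


class Direction(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    INTRA = "intra"


class Effect(str, enum.Enum):
    DELAYED = "delayed_or_suppressed"
    PROLONGED = "prolonged_or_enhanced"
    NONE = "none"


@dataclass(frozen=True)
class CrosstalkEdge:
    signal: str
    source_genus: str
    target_genus: str
    direction: Direction
    source_peak_phase: str
    target_peak_phase: str

    @property
    def self_talk(self) -> bool:
        return self.source_genus == self.target_genus


@dataclass
class CrosstalkNetwork:
    edges: list[CrosstalkEdge] = field(default_factory=list)
    hubs: set[str] = field(default_factory=set)
    #: complete signals known to the network even when they carry no edges
    complete_signals: set[str] = field(default_factory=set)

    @property
    def signals(self) -> set[str]:
        return {e.signal for e in self.edges} | self.complete_signals

    @property
    def genera(self) -> set[str]:
        return {e.source_genus for e in self.edges} | {e.target_genus for e in self.edges}

    def edges_for(self, signal: str) -> list[CrosstalkEdge]:
        return [e for e in self.edges if e.signal == signal]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "signal": e.signal,
                    "source": e.source_genus,
                    "target": e.target_genus,
                    "direction": e.direction.value,
                    "source_peak": e.source_peak_phase,
                    "target_peak": e.target_peak_phase,
                }
                for e in self.edges
            ],
            columns=["signal", "source", "target", "direction", "source_peak", "target_peak"],
        )

    def to_graphml(self, path: str | Path) -> None:
        g = nx.MultiDiGraph()
        for genus in sorted(self.genera):
            g.add_node(genus, hub=genus in self.hubs)
        for e in self.edges:
            g.add_edge(
                e.source_genus, e.target_genus,
                signal=e.signal, direction=e.direction.value,
            )
        nx.write_graphml(g, path)


@dataclass
class InterferencePrediction:
    """Qualitative per-genus outcome of blocking one signal."""

    signal: str
    effects: dict[str, Effect]

    def genera_with(self, effect: Effect) -> set[str]:
        return {g for g, e in self.effects.items() if e is effect}


def genus_peak_phase(
    genus_prof: NormalizedAbundance, scheme: PhaseScheme = PhaseScheme()
) -> dict[str, str]:
    """Coarse phase of maximal mean relative abundance per genus.

    Ties resolve to the earliest phase in assembly order.
    """
    means = phase_means(genus_prof.values, scheme)
    if means.isna().any().any():
        raise ValueError("genus profile must cover every coarse phase")
    peaks = {}
    for genus, row in means.iterrows():
        best = max(scheme.coarse_order, key=lambda c: (row[c], -scheme.phase_rank(c)))
        peaks[genus] = best
    return peaks


def build_network(
    homologs: Sequence[QSHomolog],
    taxonomy: Mapping[str, str],
    completeness: Mapping[str, Completeness],
    peaks: Mapping[str, str],
    rel: NormalizedAbundance | None = None,
    genus_prof: NormalizedAbundance | None = None,
    min_genus_abundance: float = 0.01,
    scheme: PhaseScheme = PhaseScheme(),
    min_signals: int = 2,
) -> CrosstalkNetwork:
    """Construct the directed cross-talk network over complete signals.

    For each complete signal, one edge per (synthase genus, receptor genus)
    pair among genera whose mean relative abundance in their own peak phase
    reaches ``min_genus_abundance`` (no filter if no genus profile given).
    Edge order is deterministic: (signal, source, target).
    """
    qualifying: set[str] | None = None
    if genus_prof is not None:
        gm = phase_means(genus_prof.values, scheme)
        qualifying = {
            genus
            for genus, row in gm.iterrows()
            if genus in peaks and row[peaks[genus]] >= min_genus_abundance
        }

    per_signal: dict[str, tuple[set[str], set[str]]] = {}
    for h in homologs:
        if completeness.get(h.signal) is not Completeness.COMPLETE:
            continue
        genus = taxonomy.get(h.gene_id, "unclassified")
        if qualifying is not None and genus not in qualifying:
            continue
        if genus not in peaks:
            raise KeyError(f"no peak phase for genus {genus!r}")
        syn, rec = per_signal.setdefault(h.signal, (set(), set()))
        (syn if h.role.is_synthase_side else rec).add(genus)

    edges = []
    for signal in sorted(per_signal):
        syn, rec = per_signal[signal]
        for source in sorted(syn):
            for target in sorted(rec):
                r_src, r_tgt = scheme.phase_rank(peaks[source]), scheme.phase_rank(peaks[target])
                if r_tgt > r_src:
                    direction = Direction.FORWARD
                elif r_tgt < r_src:
                    direction = Direction.REVERSE
                else:
                    direction = Direction.INTRA
                edges.append(
                    CrosstalkEdge(
                        signal=signal,
                        source_genus=source,
                        target_genus=target,
                        direction=direction,
                        source_peak_phase=peaks[source],
                        target_peak_phase=peaks[target],
                    )
                )
    network = CrosstalkNetwork(
        edges=edges,
        complete_signals={
            s for s, c in completeness.items() if c is Completeness.COMPLETE
        },
    )
    network.hubs = identify_hubs(network, homologs, taxonomy, min_signals=min_signals)
    return network


def identify_hubs(
    network: CrosstalkNetwork,
    homologs: Sequence[QSHomolog],
    taxonomy: Mapping[str, str],
    min_signals: int = 2,
) -> set[str]:
    """QS hubs: genera with both roles and >= min_signals complete signals.

    A hub must carry at least one synthase-side and one receptor homolog
    (over any signals) and participate — as sender or receiver — in at
    least ``min_signals`` distinct signals of the network.
    """
    syn_genera: set[str] = set()
    rec_genera: set[str] = set()
    for h in homologs:
        genus = taxonomy.get(h.gene_id, "unclassified")
        (syn_genera if h.role.is_synthase_side else rec_genera).add(genus)

    signals_of: dict[str, set[str]] = {}
    for e in network.edges:
        signals_of.setdefault(e.source_genus, set()).add(e.signal)
        signals_of.setdefault(e.target_genus, set()).add(e.signal)

    return {
        genus
        for genus, sigs in signals_of.items()
        if len(sigs) >= min_signals and genus in syn_genera and genus in rec_genera
    }


def predict_interference(
    network: CrosstalkNetwork, signal: str, reverse_release_dominates: bool = False
) -> InterferencePrediction:
    """Qualitative per-genus outcome of blocking a signal's delivery.

    Forward-edge receivers no longer get the go signal: delayed or
    suppressed, and that delay propagates down forward chains. Reverse-edge
    receivers lose the brake imposed by later colonizers: prolonged or
    enhanced. A genus hit by both rules is resolved as delayed by default —
    losing its own go signal outweighs losing a later arrival's brake, and
    only genera that receive no forward edge (the initial colonizers) are
    released into prolonged growth. ``reverse_release_dominates=True``
    flips the resolution. Intra-phase edges do not propagate.
    """
    if signal not in network.signals:
        raise KeyError(f"unknown signal {signal!r}")
    edges = [e for e in network.edges_for(signal) if not e.self_talk]
    if not edges:  # known signal without cross-talk: nothing to perturb
        return InterferencePrediction(
            signal=signal, effects={g: Effect.NONE for g in sorted(network.genera)}
        )
    forward = [e for e in edges if e.direction is Direction.FORWARD]
    reverse = [e for e in edges if e.direction is Direction.REVERSE]

    delayed = {e.target_genus for e in forward}
    # propagate down forward chains: a delayed sender delays its receivers
    changed = True
    while changed:
        changed = False
        for e in forward:
            if e.source_genus in delayed and e.target_genus not in delayed:
                delayed.add(e.target_genus)
                changed = True
    prolonged = {e.target_genus for e in reverse}

    effects: dict[str, Effect] = {}
    for genus in sorted({g for e in edges for g in (e.source_genus, e.target_genus)}):
        in_d, in_p = genus in delayed, genus in prolonged
        if in_d and in_p:
            effects[genus] = Effect.PROLONGED if reverse_release_dominates else Effect.DELAYED
        elif in_p:
            effects[genus] = Effect.PROLONGED
        elif in_d:
            effects[genus] = Effect.DELAYED
        else:
            effects[genus] = Effect.NONE
    return InterferencePrediction(signal=signal, effects=effects)


def prediction_to_frame(pred: InterferencePrediction) -> pd.DataFrame:
    return pd.DataFrame(
        [{"signal": pred.signal, "genus": g, "effect": e.value} for g, e in sorted(pred.effects.items())],
        columns=["signal", "genus", "effect"],
    )
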