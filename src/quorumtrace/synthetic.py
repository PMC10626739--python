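"""Synthetic succession-structured communities with planted QS genes.

The generator emulates an 11-day in vitro oral-biofilm assembly with known
ground truth, so the whole inference chain — homolog search, recA
normalization, phase classification, network construction — can be
exercised and scored without any sequencing data:

* five-genus succession (Streptococcus-dominated adapting phase, a
  Veillonella/Megasphaera growing phase, a Prevotella/Fusobacterium mature
  phase) with eight replicate series per day;
* planted QS synthase/receptor genes mutated to a controlled percent
  identity against their reference proteins, plus residue-shuffled decoys
  (hardest null for a local aligner: same composition, no alignment);
* a recA gene in every genus at one copy per cell, anchoring per-cell
  normalization;
* per-sample read counts drawn multinomially with probability proportional
  to genus abundance x gene copy number x gene length, reproducing the
  count/length confound that length normalization must remove.

Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import CountTable
from .align import align_pair
from .fixtures import AA_ALPHABET, AA_FREQS, random_protein
from .network import CrosstalkNetwork, Effect, predict_interference
from .reference import ReferenceDB, Role, reference_entries

#: Gaussian bump center (day) and width per coarse phase, chosen so each
#: genus's expected abundance peaks inside its assigned phase
PHASE_CENTERS = {"AP": 1.0, "GP": 3.5, "MP": 8.0}
PHASE_WIDTHS = {"AP": 1.0, "GP": 1.3, "MP": 2.4}
BASELINE = 0.02

#: default succession, mirroring the oral-biofilm core genera
DEFAULT_GENERA = {
    "Streptococcus": "AP",
    "Veillonella": "GP",
    "Megasphaera": "GP",
    "Prevotella": "MP",
    "Fusobacterium": "MP",
}


@dataclass(frozen=True)
class PlantedGene:
    """One QS gene to plant: which genus gets it, at what identity."""

    genus: str
    signal: str
    role: str  # synthase / receptor / processor
    target_identity: float
    copies_per_cell: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.target_identity <= 1):
            raise ValueError("target_identity must be in (0, 1]")
        if self.copies_per_cell <= 0:
            raise ValueError("copies_per_cell must be positive")


@dataclass(frozen=True)
class GenusModifier:
    """Trajectory perturbation applied by signal-interference scenarios."""

    peak_shift: float = 0.0      # days; positive = delayed
    amplitude_scale: float = 1.0
    width_scale: float = 1.0


@dataclass
class CommunitySpec:
    """Full description of one synthetic community experiment."""

    genera: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GENERA))
    days: list[int] = field(default_factory=lambda: list(range(12)))
    replicates: int = 8
    total_reads_per_sample: int = 100_000
    decoys_per_genus: int = 5
    background_per_genus: int = 90
    planted: list[PlantedGene] = field(default_factory=list)
    trajectory_noise_sd: float = 0.05
    seed: int = 0
    modifiers: dict[str, GenusModifier] = field(default_factory=dict)
    #: set by simulate_interference: (signal, {genus: effect name})
    interference: Optional[tuple[str, dict[str, str]]] = None

    def __post_init__(self) -> None:
        if not self.genera:
            raise ValueError("genera list must not be empty")
        bad = {p for p in self.genera.values() if p not in PHASE_CENTERS}
        if bad:
            raise ValueError(f"unknown peak phases: {sorted(bad)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.trajectory_noise_sd < 0:
            raise ValueError("trajectory_noise_sd must be nonnegative")
        for p in self.planted:
            if p.genus not in self.genera:
                raise ValueError(f"planted gene in unknown genus {p.genus!r}")


@dataclass(frozen=True)
class TruthRecord:
    genus: str
    klass: str  # qs_true / qs_decoy / recA / background
    signal: Optional[str] = None
    role: Optional[str] = None
    realized_identity: Optional[float] = None
    copies_per_cell: float = 1.0


@dataclass
class SyntheticTruth:
    """Ground truth for every catalog gene, plus any applied interference."""

    genes: dict[str, TruthRecord] = field(default_factory=dict)
    applied_interference: Optional[tuple[str, dict[str, str]]] = None

    def gene_ids(self, klass: str) -> set[str]:
        return {g for g, r in self.genes.items() if r.klass == klass}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": {
                g: {
                    "genus": r.genus,
                    "class": r.klass,
                    "signal": r.signal,
                    "role": r.role,
                    "realized_identity": r.realized_identity,
                    "copies_per_cell": r.copies_per_cell,
                }
                for g, r in self.genes.items()
            },
            "applied_interference": (
                None
                if self.applied_interference is None
                else {
                    "signal": self.applied_interference[0],
                    "effects": self.applied_interference[1],
                }
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticDataset:
    """Everything generate_catalog produces, ready for the pipeline."""

    genes: dict[str, str]            # gene_id -> amino-acid sequence
    counts: CountTable
    taxonomy: dict[str, str]         # gene_id -> genus
    annotations: dict[str, str]      # gene_id -> free-text annotation
    truth: SyntheticTruth
    trajectories: pd.DataFrame       # genus x sample relative abundance

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = [SeqRecord(Seq(s), id=g, description="") for g, s in self.genes.items()]
        SeqIO.write(records, str(outdir / "catalog.faa"), "fasta")
        self.counts.to_tsv(outdir / "counts.tsv", outdir / "gene_lengths.tsv")
        pd.Series(self.taxonomy, name="genus").to_csv(
            outdir / "taxonomy.tsv", sep="\t", index_label="gene_id"
        )
        pd.Series(self.annotations, name="annotation").to_csv(
            outdir / "annotations.tsv", sep="\t", index_label="gene_id"
        )
        self.truth.to_json(outdir / "truth.json")


def _genus_curve(spec: CommunitySpec, genus: str, days: np.ndarray) -> np.ndarray:
    phase = spec.genera[genus]
    mod = spec.modifiers.get(genus, GenusModifier())
    center = PHASE_CENTERS[phase] + mod.peak_shift
    width = PHASE_WIDTHS[phase] * mod.width_scale
    return BASELINE + mod.amplitude_scale * np.exp(-((days - center) ** 2) / (2 * width**2))


def sample_trajectories(spec: CommunitySpec) -> pd.DataFrame:
    """Genus x sample relative-abundance table (columns ``d{day}_r{rep}``).

    Per-genus Gaussian bump over days centered in its peak phase plus a
    baseline, log-normal replicate noise, renormalized per sample. With
    ``trajectory_noise_sd == 0`` replicates of a day are identical.
    """
    genera = list(spec.genera)
    days = np.array(spec.days, dtype=float)
    rng = np.random.default_rng([spec.seed, 11])
    cols, data = [], []
    base = np.vstack([_genus_curve(spec, g, days) for g in genera])  # genus x day
    for di, day in enumerate(spec.days):
        for rep in range(1, spec.replicates + 1):
            noise = (
                np.exp(rng.normal(0.0, spec.trajectory_noise_sd, size=len(genera)))
                if spec.trajectory_noise_sd > 0
                else np.ones(len(genera))
            )
            col = base[:, di] * noise
            data.append(col / col.sum())
            cols.append(f"d{day}_r{rep}")
    return pd.DataFrame(np.array(data).T, index=genera, columns=cols)


def plant_homolog(reference_seq: str, target_identity: float, seed: int) -> tuple[str, float]:
    """Mutate a reference to a target percent identity; return (seq, realized).

    Substitutions at uniformly chosen positions, replacement residues drawn
    from natural background frequencies (never the original residue); no
    indels, so the mutant keeps the reference length. Realized identity is
    verified by a global alignment against the reference.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    if len(reference_seq) < 30:
        raise ValueError("reference must be at least 30 aa")
    if target_identity == 1.0:
        return reference_seq, 1.0
    rng = np.random.default_rng(seed)
    L = len(reference_seq)
    n_sub = int(round((1 - target_identity) * L))
    positions = rng.choice(L, size=n_sub, replace=False)
    seq = list(reference_seq)
    for pos in positions:
        choices = AA_ALPHABET[AA_ALPHABET != seq[pos]]
        freqs = AA_FREQS[AA_ALPHABET != seq[pos]]
        seq[pos] = rng.choice(choices, p=freqs / freqs.sum())
    mutant = "".join(seq)
    aln = align_pair(mutant, reference_seq, local=False)
    realized = aln.identity
    if target_identity >= 0.3 and abs(realized - target_identity) > 0.05:
        raise AssertionError(
            f"realized identity {realized:.3f} drifted from target {target_identity:.3f}"
        )
    return mutant, realized


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def generate_catalog(spec: CommunitySpec, refdb: ReferenceDB) -> SyntheticDataset:
    """Generate the full synthetic dataset for a community spec.

    Gene inventory per genus: one recA at 1 copy per cell, the planted QS
    genes, ``decoys_per_genus`` residue-shuffled reference decoys, and
    ``background_per_genus`` random background proteins. Read counts per
    sample are one multinomial draw of ``total_reads_per_sample`` over all
    genes with probability proportional to genus abundance x copy number x
    nucleotide length.
    """
    for p in spec.planted:
        if not reference_entries(refdb, p.signal, Role(p.role)):
            raise ValueError(f"no reference entry for planted ({p.signal!r}, {p.role!r})")

    rng = np.random.default_rng([spec.seed, 23])
    trajectories = sample_trajectories(spec)
    genes: dict[str, str] = {}
    taxonomy: dict[str, str] = {}
    annotations: dict[str, str] = {}
    truth = SyntheticTruth(applied_interference=spec.interference)
    copies: dict[str, float] = {}

    recA_base = random_protein(np.random.default_rng(97), 350)

    def add(gene_id, seq, genus, annotation, record, cpc):
        genes[gene_id] = seq
        taxonomy[gene_id] = genus
        annotations[gene_id] = annotation
        truth.genes[gene_id] = record
        copies[gene_id] = cpc

    planted_by_genus: dict[str, list[PlantedGene]] = {}
    for p in spec.planted:
        planted_by_genus.setdefault(p.genus, []).append(p)

    for genus in spec.genera:
        # recA: genus-specific variant of a shared backbone, 1 copy per cell
        recA_seq, _ = plant_homolog(recA_base, 0.95, int(rng.integers(2**31)))
        add(
            f"{genus}_recA", recA_seq, genus,
            "recA recombinase A, DNA recombination and repair",
            TruthRecord(genus=genus, klass="recA"), 1.0,
        )
        for i, p in enumerate(planted_by_genus.get(genus, [])):
            refs = reference_entries(refdb, p.signal, Role(p.role))
            ref = refs[int(rng.integers(len(refs)))]
            seq, realized = plant_homolog(
                ref.sequence, p.target_identity, int(rng.integers(2**31))
            )
            klass = "qs_true" if realized >= 0.30 else "qs_decoy"
            add(
                f"{genus}_{p.signal}_{p.role}_{i}", seq, genus,
                f"putative {ref.domain_keyword} family protein",
                TruthRecord(
                    genus=genus, klass=klass, signal=p.signal, role=p.role,
                    realized_identity=realized, copies_per_cell=p.copies_per_cell,
                ),
                p.copies_per_cell,
            )
        for i in range(spec.decoys_per_genus):
            ref = refdb.entries[int(rng.integers(len(refdb)))]
            add(
                f"{genus}_decoy_{i}", _shuffled(ref.sequence, rng), genus,
                "hypothetical protein, no conserved domain",
                TruthRecord(genus=genus, klass="qs_decoy"), 1.0,
            )
        for i in range(spec.background_per_genus):
            length = int(rng.integers(80, 301))
            add(
                f"{genus}_bg_{i}", random_protein(rng, length), genus,
                "hypothetical protein",
                TruthRecord(genus=genus, klass="background"), 1.0,
            )

    gene_ids = list(genes)
    lengths_nt = pd.Series({g: 3 * len(genes[g]) for g in gene_ids})
    copies_arr = np.array([copies[g] for g in gene_ids])
    length_arr = lengths_nt.loc[gene_ids].values.astype(float)
    genus_idx = [list(spec.genera).index(taxonomy[g]) for g in gene_ids]

    count_cols = {}
    for col in trajectories.columns:
        genus_ab = trajectories[col].values
        weights = genus_ab[genus_idx] * copies_arr * length_arr
        probs = weights / weights.sum()
        count_cols[col] = rng.multinomial(spec.total_reads_per_sample, probs)
    counts = pd.DataFrame(count_cols, index=gene_ids)
    table = CountTable(counts=counts, lengths=lengths_nt)

    return SyntheticDataset(
        genes=genes, counts=table, taxonomy=taxonomy,
        annotations=annotations, truth=truth, trajectories=trajectories,
    )


#: trajectory perturbations realizing each qualitative interference effect
EFFECT_MODIFIERS = {
    Effect.DELAYED: GenusModifier(peak_shift=1.0, amplitude_scale=0.6),
    Effect.PROLONGED: GenusModifier(peak_shift=0.0, amplitude_scale=1.4, width_scale=1.6),
}


def simulate_interference(
    spec: CommunitySpec, network: CrosstalkNetwork, signal: str
) -> CommunitySpec:
    """Community spec under blockage of one signal's delivery.

    Applies the qualitative network prediction to the trajectory model:
    forward-edge receivers are delayed (+1 day) and damped; reverse-edge
    receivers are prolonged and elevated. A signal with no edges leaves the
    spec unchanged. The applied effects are recorded so downstream truth
    carries them.
    """
    pred = predict_interference(network, signal)  # KeyError on unknown signal
    new = copy.deepcopy(spec)
    touched = False
    effects: dict[str, str] = {}
    for genus, effect in pred.effects.items():
        effects[genus] = effect.value
        if genus in new.genera and effect in EFFECT_MODIFIERS:
            new.modifiers[genus] = EFFECT_MODIFIERS[effect]
            touched = True
    if touched:
        new.interference = (signal, effects)
    return new


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """The default five-genus study spec with a planted AI-2 subnetwork.

    Planted genes realize the oral-biofilm cross-talk geometry: AI-2
    synthases in Streptococcus, Prevotella and Fusobacterium; AI-2
    receptors in all five genera (forward transmission from the adapting-
    phase colonizer to growing/mature-phase genera, reverse transmission
    from mature-phase genera back to Streptococcus). DSF and an Agr-type
    peptide provide the second complete signal needed for hub status.
    Identities span 0.5-0.9; one sub-threshold negative is planted below
    the 30% retrieval floor.
    """
    planted = [
        PlantedGene("Streptococcus", "AI-2", "synthase", 0.85, copies_per_cell=2.0),
        PlantedGene("Prevotella", "AI-2", "synthase", 0.80),
        PlantedGene("Fusobacterium", "AI-2", "synthase", 0.75),
        PlantedGene("Streptococcus", "AI-2", "receptor", 0.80),
        PlantedGene("Veillonella", "AI-2", "receptor", 0.70),
        PlantedGene("Megasphaera", "AI-2", "receptor", 0.65),
        PlantedGene("Prevotella", "AI-2", "receptor", 0.62),
        PlantedGene("Fusobacterium", "AI-2", "receptor", 0.60),
        PlantedGene("Streptococcus", "AIP_Agr-Fsr_Like", "synthase", 0.90),
        PlantedGene("Streptococcus", "AIP_Agr-Fsr_Like", "receptor", 0.85),
        PlantedGene("Veillonella", "DSF", "synthase", 0.70),
        PlantedGene("Veillonella", "DSF", "receptor", 0.68),
        PlantedGene("Megasphaera", "DSF", "synthase", 0.66),
        PlantedGene("Megasphaera", "DSF", "receptor", 0.64),
        PlantedGene("Prevotella", "DSF", "synthase", 0.62),
        PlantedGene("Prevotella", "DSF", "receptor", 0.60),
        PlantedGene("Fusobacterium", "DSF", "synthase", 0.58),
        PlantedGene("Fusobacterium", "DSF", "receptor", 0.56),
        # planted negatives: below the 30% identity retrieval floor
        PlantedGene("Streptococcus", "AI-2", "receptor", 0.20),
        PlantedGene("Prevotella", "DSF", "synthase", 0.20),
    ]
    return CommunitySpec(planted=planted, seed=seed)


def evaluate_search(truth: SyntheticTruth, homolog_gene_ids: set[str]) -> tuple[float, float]:
    """Precision and recall of retrieved gene ids against planted truth.

    Positives are genes of class ``qs_true``; everything else (decoys,
    sub-threshold plants, recA, background) counts as a negative.
    """
    positives = truth.gene_ids("qs_true")
    tp = len(homolog_gene_ids & positives)
    precision = tp / len(homolog_gene_ids) if homolog_gene_ids else 1.0
    recall = tp / len(positives) if positives else 1.0
    return precision, recall
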