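"""End-to-end orchestration: simulate/load -> search -> normalize -> profile
-> network -> predict, from a single config with full determinism.

The run report mirrors the retrieval funnel: catalog size, putative hits
passing the alignment thresholds, hits surviving the annotation filter,
pathway completeness counts, network composition and interference
predictions. Stage counts are monotone non-increasing along the filter
chain, which makes the report the primary debugging surface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import fixtures
from .abundance import (
    CountTable,
    genus_profile,
    normalize_by_recA,
    relative_abundance,
    shannon_per_sample,
)
from .align import AlignmentParams
from .network import (
    CrosstalkNetwork,
    build_network,
    genus_peak_phase,
    prediction_to_frame,
    predict_interference,
)
from .phases import Completeness, PhaseScheme, pathway_profiles, profiles_to_frame
from .reference import ReferenceDB, load_reference_db
from .search import (
    SearchThresholds,
    filter_by_annotation,
    search_homologs,
    write_homolog_table,
)
from .synthetic import CommunitySpec, default_community_spec, generate_catalog


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one input mode is active: either ``simulation`` (a community
    spec for the synthetic generator) or the four real-input paths
    (catalog FASTA, counts/lengths TSV, taxonomy TSV, annotation TSV).
    The reference DB defaults to the bundled fixture when no paths are
    given.
    """

    simulation: Optional[CommunitySpec] = None
    catalog_fasta: Optional[str] = None
    counts_tsv: Optional[str] = None
    lengths_tsv: Optional[str] = None
    taxonomy_tsv: Optional[str] = None
    annotations_tsv: Optional[str] = None
    refdb_fasta: Optional[str] = None
    refdb_metadata: Optional[str] = None
    thresholds: SearchThresholds = field(default_factory=SearchThresholds)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    scheme: PhaseScheme = field(default_factory=PhaseScheme)
    ratio_threshold: float = 1.5
    stability_threshold: float = 0.25
    min_genus_abundance: float = 0.01
    min_hub_signals: int = 2
    predict_signals: list[str] = field(default_factory=lambda: ["AI-2"])
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def default_synthetic(cls, seed: int = 0, outdir: Optional[str] = None) -> "PipelineConfig":
        return cls(simulation=default_community_spec(seed=seed), seed=seed, outdir=outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "simulation" in raw:
            sim = raw["simulation"]
            if sim == "default":
                kwargs["simulation"] = default_community_spec(seed=int(raw.get("seed", 0)))
            elif sim is not None:
                kwargs["simulation"] = CommunitySpec(**sim)
        if "thresholds" in raw:
            kwargs["thresholds"] = SearchThresholds(**raw["thresholds"])
        if "alignment" in raw:
            kwargs["alignment"] = AlignmentParams(**raw["alignment"])
        for key in (
            "catalog_fasta", "counts_tsv", "lengths_tsv", "taxonomy_tsv",
            "annotations_tsv", "refdb_fasta", "refdb_metadata",
            "ratio_threshold", "stability_threshold", "min_genus_abundance",
            "min_hub_signals", "predict_signals", "seed", "outdir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect configuration issues; empty list means the config is valid."""
    issues: list[str] = []
    real_paths = [config.catalog_fasta, config.counts_tsv, config.taxonomy_tsv, config.annotations_tsv]
    has_real = any(p is not None for p in real_paths)
    if config.simulation is not None and has_real:
        issues.append("exactly one of simulation spec and real input paths may be active")
    if config.simulation is None and not has_real:
        issues.append("no input: provide a simulation spec or real input paths")
    if config.simulation is None and has_real and not all(real_paths):
        issues.append("real-input mode needs catalog_fasta, counts_tsv, taxonomy_tsv and annotations_tsv")
    try:
        dataclasses.replace(config.thresholds)
    except ValueError as exc:
        issues.append(f"thresholds: {exc}")
    if not (0 < config.thresholds.min_identity <= 1):
        issues.append("min_identity must be in (0, 1]")
    try:
        dataclasses.replace(config.alignment)
    except ValueError as exc:
        issues.append(f"alignment: {exc}")
    try:
        dataclasses.replace(config.scheme)
    except ValueError as exc:
        issues.append(f"PhaseScheme: {exc}")
    if config.ratio_threshold < 1:
        issues.append("ratio_threshold must be >= 1")
    if config.stability_threshold < 0:
        issues.append("stability_threshold must be nonnegative")
    if config.min_genus_abundance < 0:
        issues.append("min_genus_abundance must be nonnegative")
    for path in real_paths + [config.refdb_fasta, config.refdb_metadata, config.lengths_tsv]:
        if path is not None and not Path(path).exists():
            issues.append(f"input file not found: {path}")
    return issues


@dataclass
class RunReport:
    """Stage-by-stage summary of one pipeline run."""

    n_genes: int
    n_putative_hits: int
    n_annotation_passing: int
    n_signals_detected: int
    completeness_counts: dict[str, int]
    complete_signals: list[str]
    pathway_table: pd.DataFrame
    edge_counts: dict[str, int]
    edges: list[dict]
    hubs: list[str]
    predictions: dict[str, dict[str, str]]
    shannon_by_sample: dict[str, float]
    config_fingerprint: str

    def funnel(self) -> list[int]:
        return [self.n_genes, self.n_putative_hits, self.n_annotation_passing]

    def to_json_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_putative_hits": self.n_putative_hits,
            "n_annotation_passing": self.n_annotation_passing,
            "n_signals_detected": self.n_signals_detected,
            "completeness_counts": self.completeness_counts,
            "complete_signals": self.complete_signals,
            "pathway_table": self.pathway_table.to_dict(orient="records"),
            "edge_counts": self.edge_counts,
            "edges": self.edges,
            "hubs": self.hubs,
            "predictions": self.predictions,
            "shannon_by_sample": self.shannon_by_sample,
            "config_fingerprint": self.config_fingerprint,
        }

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _load_refdb(config: PipelineConfig) -> ReferenceDB:
    if config.refdb_fasta and config.refdb_metadata:
        return load_reference_db(config.refdb_fasta, config.refdb_metadata)
    return fixtures.fixture_reference_db()


def _fingerprint_config(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full inference chain described by a config.

    Stages: input acquisition (simulation or files), homolog search,
    annotation filter, abundance normalization, pathway profiling,
    network construction, interference prediction. Outputs are written to
    ``config.outdir`` when set; a rerun with the same config and seed is
    bit-identical.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))

    refdb = _load_refdb(config)

    if config.simulation is not None:
        dataset = generate_catalog(config.simulation, refdb)
        genes = dataset.genes
        counts = dataset.counts
        taxonomy = dataset.taxonomy
        annotations = dataset.annotations
        recA_ids = dataset.truth.gene_ids("recA")
    else:
        from Bio import SeqIO

        genes = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(config.catalog_fasta, "fasta")
        }
        if not genes:
            raise ValueError(f"stage input: empty catalog {config.catalog_fasta}")
        counts = CountTable.from_tsv(config.counts_tsv, config.lengths_tsv or config.counts_tsv)
        taxonomy = (
            pd.read_csv(config.taxonomy_tsv, sep="\t", index_col=0).iloc[:, 0].to_dict()
        )
        annotations = (
            pd.read_csv(config.annotations_tsv, sep="\t", index_col=0).iloc[:, 0].to_dict()
        )
        recA_ids = {g for g, a in annotations.items() if "reca" in str(a).lower()}
        dataset = None

    putative = search_homologs(genes, refdb, config.thresholds, config.alignment)
    homologs = filter_by_annotation(putative, annotations)

    rel = relative_abundance(counts)
    gp = genus_profile(rel, taxonomy)
    shannon = shannon_per_sample(gp)

    signals = sorted(refdb.signals)
    if homologs and recA_ids:
        per_cell = normalize_by_recA(homologs, rel, recA_ids)
        profiles = pathway_profiles(
            homologs, per_cell, signals, config.scheme,
            config.ratio_threshold, config.stability_threshold,
        )
    else:
        from .abundance import Normalization, NormalizedAbundance

        per_cell = NormalizedAbundance(
            values=pd.DataFrame(columns=rel.values.columns), normalization=Normalization.PER_CELL
        )
        profiles = pathway_profiles(homologs, per_cell, signals, config.scheme)

    completeness = {p.signal: p.completeness for p in profiles}
    peaks = genus_peak_phase(gp, config.scheme)
    network = build_network(
        homologs, taxonomy, completeness, peaks,
        genus_prof=gp, min_genus_abundance=config.min_genus_abundance,
        scheme=config.scheme, min_signals=config.min_hub_signals,
    )

    predictions: dict[str, dict[str, str]] = {}
    for signal in config.predict_signals:
        if signal in network.signals:
            pred = predict_interference(network, signal)
            predictions[signal] = {g: e.value for g, e in pred.effects.items()}

    edge_counts = {"forward": 0, "reverse": 0, "intra": 0}
    for e in network.edges:
        edge_counts[e.direction.value] += 1

    comp_counts = {c.value: 0 for c in Completeness}
    for c in completeness.values():
        comp_counts[c.value] += 1

    detected = {p.signal for p in profiles if p.completeness is not Completeness.ABSENT}

    report = RunReport(
        n_genes=len(genes),
        n_putative_hits=len(putative),
        n_annotation_passing=len(homologs),
        n_signals_detected=len(detected),
        completeness_counts=comp_counts,
        complete_signals=sorted(
            s for s, c in completeness.items() if c is Completeness.COMPLETE
        ),
        pathway_table=profiles_to_frame(profiles, config.scheme),
        edge_counts=edge_counts,
        edges=network.to_frame().to_dict(orient="records"),
        hubs=sorted(network.hubs),
        predictions=predictions,
        shannon_by_sample={k: float(v) for k, v in shannon.items()},
        config_fingerprint=_fingerprint_config(config),
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if dataset is not None:
            dataset.write(outdir / "synthetic")
        write_homolog_table(homologs, outdir / "homologs.tsv")
        report.pathway_table.to_csv(outdir / "pathway_report.tsv", sep="\t", index=False)
        network.to_frame().to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        network.to_graphml(outdir / "network.graphml")
        pred_frames = [
            prediction_to_frame(predict_interference(network, s))
            for s in predictions
        ]
        if pred_frames:
            pd.concat(pred_frames).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report.to_json_dict(), indent=1, sort_keys=True, default=str)
        )
    return report
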