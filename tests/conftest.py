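"""Shared fixtures: the expensive default synthetic run is computed once
per session and reused across modules."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import quorumtrace as qt
from quorumtrace.fixtures import fixture_catalog, fixture_reference_db


@pytest.fixture(scope="session")
def refdb() -> qt.ReferenceDB:
    return fixture_reference_db()


@pytest.fixture(scope="session")
def default_spec() -> qt.CommunitySpec:
    return qt.default_community_spec(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_spec, refdb):
    return qt.generate_catalog(default_spec, refdb)


@dataclass
class SearchState:
    putative: list
    homologs: list


@pytest.fixture(scope="session")
def default_search(default_dataset, refdb) -> SearchState:
    putative = qt.search_homologs(default_dataset.genes, refdb)
    homologs = qt.filter_by_annotation(putative, default_dataset.annotations)
    return SearchState(putative=putative, homologs=homologs)


@dataclass
class PipelineState:
    rel: qt.NormalizedAbundance
    genus_prof: qt.NormalizedAbundance
    per_cell: qt.NormalizedAbundance
    completeness: dict
    peaks: dict
    network: qt.CrosstalkNetwork


@pytest.fixture(scope="session")
def default_state(default_dataset, default_search, refdb) -> PipelineState:
    ds = default_dataset
    rel = qt.relative_abundance(ds.counts)
    gp = qt.genus_profile(rel, ds.taxonomy)
    per_cell = qt.normalize_by_recA(
        default_search.homologs, rel, ds.truth.gene_ids("recA")
    )
    completeness = qt.classify_completeness(default_search.homologs, refdb.signals)
    peaks = qt.genus_peak_phase(gp)
    network = qt.build_network(
        default_search.homologs, ds.taxonomy, completeness, peaks, genus_prof=gp
    )
    return PipelineState(
        rel=rel, genus_prof=gp, per_cell=per_cell,
        completeness=completeness, peaks=peaks, network=network,
    )


@dataclass
class WorkedExample:
    genes: dict
    taxonomy: dict
    annotations: dict
    homologs: list
    completeness: dict


@pytest.fixture(scope="session")
def worked_example(refdb) -> WorkedExample:
    genes, taxonomy, annotations = fixture_catalog()
    putative = qt.search_homologs(genes, refdb)
    homologs = qt.filter_by_annotation(putative, annotations)
    completeness = qt.classify_completeness(homologs, refdb.signals)
    return WorkedExample(
        genes=genes, taxonomy=taxonomy, annotations=annotations,
        homologs=homologs, completeness=completeness,
    )
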