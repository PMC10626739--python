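"""Length normalization, recA per-cell scaling, genus aggregation, Shannon."""

import math

import numpy as np
import pandas as pd
import pytest

import quorumtrace as qt
from quorumtrace.abundance import (
    CountTable,
    Normalization,
    NormalizedAbundance,
    parse_sample_id,
    shannon_per_sample,
)
from quorumtrace.align import AlignmentResult
from quorumtrace.reference import ReferenceQSProtein, Role
from quorumtrace.search import QSHomolog


def make_homolog(gene_id: str, signal: str, role: str) -> QSHomolog:
    ref = ReferenceQSProtein(
        protein_id=f"ref_{signal}_{role}", signal=signal, role=Role(role),
        source_organism="synthetic", sequence="M" * 40, domain_keyword="kw",
    )
    aln = AlignmentResult(
        query_id=gene_id, subject_id=ref.protein_id, score=100, identity=0.9,
        subject_coverage=1.0, query_coverage=1.0, query_span=(0, 40),
        subject_span=(0, 40), evalue=1e-20,
    )
    return QSHomolog(gene_id=gene_id, best_reference=ref, alignment=aln)


def test_sample_id_parsing():
    assert parse_sample_id("d0_r1") == (0, 1)
    assert parse_sample_id("d11_r8") == (11, 8)
    with pytest.raises(ValueError):
        parse_sample_id("day0-rep1")


def test_single_gene_has_abundance_one():
    counts = pd.DataFrame({"d0_r1": [7], "d1_r1": [3]}, index=["g1"])
    t = CountTable(counts=counts, lengths=pd.Series({"g1": 300}))
    rel = qt.relative_abundance(t)
    assert (rel.values.loc["g1"] == 1.0).all()


def test_two_gene_closed_form():
    # counts (100, 100), lengths (1000, 500) -> abundances (1/3, 2/3)
    counts = pd.DataFrame({"d0_r1": [100, 100]}, index=["a", "b"])
    t = CountTable(counts=counts, lengths=pd.Series({"a": 1000, "b": 500}))
    rel = qt.relative_abundance(t)
    assert rel.values["d0_r1"].tolist() == pytest.approx([1 / 3, 2 / 3])


def test_relative_abundance_matches_naive_two_pass_loop():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(20)]
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(20, 6)),
        index=genes,
        columns=[f"d{d}_r{r}" for d in (0, 3, 7) for r in (1, 2)],
    )
    counts.iloc[0] += 1  # avoid an all-zero column by construction
    lengths = pd.Series(rng.integers(100, 2000, size=20), index=genes)
    rel = qt.relative_abundance(CountTable(counts=counts, lengths=lengths))
    for s in counts.columns:
        divided = {g: counts.loc[g, s] / lengths[g] for g in genes}
        total = sum(divided.values())
        for g in genes:
            assert rel.values.loc[g, s] == pytest.approx(divided[g] / total)


def test_relative_abundance_scale_invariance():
    counts = pd.DataFrame({"d0_r1": [10, 20, 30]}, index=list("abc"))
    lengths = pd.Series({"a": 100, "b": 200, "c": 400})
    rel1 = qt.relative_abundance(CountTable(counts=counts, lengths=lengths))
    rel2 = qt.relative_abundance(CountTable(counts=counts * 17, lengths=lengths))
    pd.testing.assert_frame_equal(rel1.values, rel2.values)


def test_zero_total_sample_error_names_sample():
    counts = pd.DataFrame({"d0_r1": [1], "d1_r1": [0]}, index=["g"])
    with pytest.raises(ValueError, match="d1_r1"):
        qt.relative_abundance(CountTable(counts=counts, lengths=pd.Series({"g": 100})))


def test_recA_normalization_unit_and_zero_cases():
    # homolog gene with rel abundance equal to total recA abundance -> 1.0
    counts = pd.DataFrame({"d0_r1": [100, 100, 200]}, index=["qs", "recA", "bg"])
    lengths = pd.Series({"qs": 300, "recA": 300, "bg": 300})
    rel = qt.relative_abundance(CountTable(counts=counts, lengths=lengths))
    hom = [make_homolog("qs", "AI-2", "synthase")]
    per_cell = qt.normalize_by_recA(hom, rel, {"recA"})
    assert per_cell.values.loc["AI-2|synthase", "d0_r1"] == pytest.approx(1.0)
    # no genes for a (signal, role) -> series of zeros
    per_cell2 = qt.normalize_by_recA(
        [make_homolog("missing_gene", "AHL", "receptor")], rel, {"recA"}
    )
    assert (per_cell2.values.loc["AHL|receptor"] == 0.0).all()


def test_recA_zero_abundance_is_error():
    counts = pd.DataFrame({"d0_r1": [100, 0]}, index=["qs", "recA"])
    lengths = pd.Series({"qs": 300, "recA": 300})
    rel = qt.relative_abundance(CountTable(counts=counts, lengths=lengths))
    with pytest.raises(ValueError, match="d0_r1"):
        qt.normalize_by_recA([make_homolog("qs", "AI-2", "synthase")], rel, {"recA"})


def test_genus_profile_conserves_column_sums_and_matches_brute_force():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(12)]
    counts = pd.DataFrame(
        rng.integers(1, 100, size=(12, 4)),
        index=genes, columns=["d0_r1", "d0_r2", "d5_r1", "d5_r2"],
    )
    lengths = pd.Series(rng.integers(100, 900, size=12), index=genes)
    taxonomy = {g: ["Strep", "Veill", "Prev"][i % 3] for i, g in enumerate(genes)}
    del taxonomy["g11"]  # unassigned gene falls into "unclassified"
    rel = qt.relative_abundance(CountTable(counts=counts, lengths=lengths))
    prof = qt.genus_profile(rel, taxonomy)
    assert prof.values.sum(axis=0).tolist() == pytest.approx([1.0] * 4, abs=1e-9)
    assert "unclassified" in prof.values.index
    for s in counts.columns:
        for genus in prof.values.index:
            brute = sum(
                rel.values.loc[g, s]
                for g in genes
                if taxonomy.get(g, "unclassified") == genus
            )
            assert prof.values.loc[genus, s] == pytest.approx(brute)


@pytest.mark.parametrize("k", [1, 2, 5, 11])
def test_shannon_equal_genera_is_ln_k(k):
    assert qt.shannon_index([1.0] * k) == pytest.approx(math.log(k))


def test_shannon_direct_value_and_errors():
    assert qt.shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397207708399179)
    # independent route: scipy entropy with natural log
    from scipy.stats import entropy

    p = [0.1, 0.2, 0.3, 0.4]
    assert qt.shannon_index(p) == pytest.approx(float(entropy(p)))
    assert qt.shannon_index([0.3, 0.0, 0.7]) == pytest.approx(qt.shannon_index([3, 0, 7]))
    with pytest.raises(ValueError):
        qt.shannon_index([0.0, 0.0])
    with pytest.raises(ValueError):
        qt.shannon_index([-0.1, 1.1])


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=1, max_size=30)
    )
    def test_shannon_bounds_and_permutation_invariance(p):
        if sum(p) == 0:
            with pytest.raises(ValueError):
                qt.shannon_index(p)
            return
        h = qt.shannon_index(p)
        assert -1e-9 <= h <= math.log(len(p)) + 1e-9
        assert qt.shannon_index(list(reversed(p))) == pytest.approx(h)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=20),
        st.integers(min_value=2, max_value=1000),
    )
    def test_relative_abundance_scale_invariance_property(counts_list, factor):
        if sum(counts_list) == 0:
            return
        genes = [f"g{i}" for i in range(len(counts_list))]
        lengths = pd.Series({g: 100 + 7 * i for i, g in enumerate(genes)})
        c1 = pd.DataFrame({"d0_r1": counts_list}, index=genes)
        rel1 = qt.relative_abundance(CountTable(counts=c1, lengths=lengths))
        rel2 = qt.relative_abundance(CountTable(counts=c1 * factor, lengths=lengths))
        pd.testing.assert_frame_equal(rel1.values, rel2.values)

except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_relative_columns_must_sum_to_one():
    bad = pd.DataFrame({"d0_r1": [0.5, 0.4]}, index=["a", "b"])
    with pytest.raises(ValueError, match="d0_r1"):
        NormalizedAbundance(values=bad, normalization=Normalization.RELATIVE)


def test_shannon_rises_with_evenness_in_default_run(default_state):
    """Succession diversification: late, more even samples are more diverse
    than the Streptococcus-dominated start."""
    sh = shannon_per_sample(default_state.genus_prof)
    day0 = sh[[c for c in sh.index if c.startswith("d0_")]].mean()
    day3 = sh[[c for c in sh.index if c.startswith("d3_")]].mean()
    assert day3 > day0
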