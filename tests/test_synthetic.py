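"""Synthetic community generator: trajectories, planting, counts, truth."""

import numpy as np
import pandas as pd
import pytest

import quorumtrace as qt
from quorumtrace.align import align_pair
from quorumtrace.synthetic import (
    CommunitySpec,
    PlantedGene,
    plant_homolog,
    sample_trajectories,
)


def small_spec(**kw) -> CommunitySpec:
    defaults = dict(
        genera={"Streptococcus": "AP", "Veillonella": "GP", "Prevotella": "MP"},
        replicates=2,
        total_reads_per_sample=20_000,
        decoys_per_genus=1,
        background_per_genus=3,
        trajectory_noise_sd=0.0,
        seed=3,
    )
    defaults.update(kw)
    return CommunitySpec(**defaults)


def test_trajectories_sum_to_one_and_peak_in_assigned_phase():
    traj = sample_trajectories(small_spec(trajectory_noise_sd=0.05))
    assert np.allclose(traj.sum(axis=0), 1.0, atol=1e-9)
    phases = pd.Series({c: qt.assign_phase(int(c[1:].split("_")[0])) for c in traj.columns})
    for genus, phase in [("Streptococcus", "AP"), ("Veillonella", "GP"), ("Prevotella", "MP")]:
        means = traj.loc[genus].groupby(phases).mean()
        assert means.idxmax() == phase
    # construction target from the succession: early colonizer higher in AP than MP
    strep = traj.loc["Streptococcus"]
    assert strep[phases == "AP"].mean() > strep[phases == "MP"].mean()


def test_zero_noise_replicates_identical_and_seed_determinism():
    spec = small_spec(trajectory_noise_sd=0.0)
    traj = sample_trajectories(spec)
    for day in spec.days:
        pd.testing.assert_series_equal(
            traj[f"d{day}_r1"], traj[f"d{day}_r2"], check_names=False
        )
    again = sample_trajectories(small_spec(trajectory_noise_sd=0.0))
    pd.testing.assert_frame_equal(traj, again)


def test_empty_genera_rejected():
    with pytest.raises(ValueError):
        CommunitySpec(genera={})


def test_plant_homolog_identity_control(refdb):
    ref = refdb.by_id("LuxS").sequence
    # identity case
    seq, realized = plant_homolog(ref, 1.0, seed=1)
    assert seq == ref and realized == 1.0
    # controlled divergence, realized verified by a global alignment oracle
    ref100 = refdb.by_id("AgrC").sequence[:100]
    seq60, realized60 = plant_homolog(ref100, 0.60, seed=2)
    assert len(seq60) == 100
    oracle = align_pair(seq60, ref100, local=False)
    assert 0.55 <= oracle.identity <= 0.65
    assert realized60 == pytest.approx(oracle.identity)
    # sub-threshold plant lands below the 30% retrieval floor
    _, realized20 = plant_homolog(ref, 0.20, seed=3)
    assert realized20 < 0.30
    with pytest.raises(ValueError):
        plant_homolog(ref, 0.0, seed=1)
    with pytest.raises(ValueError):
        plant_homolog(ref, 1.2, seed=1)
    with pytest.raises(ValueError):
        plant_homolog("M" * 10, 0.5, seed=1)


def test_catalog_bookkeeping_single_genus(refdb):
    spec = CommunitySpec(
        genera={"Streptococcus": "AP"},
        replicates=1,
        total_reads_per_sample=10_000,
        decoys_per_genus=5,
        background_per_genus=0,
        planted=[PlantedGene("Streptococcus", "AI-2", "synthase", 0.9)],
        trajectory_noise_sd=0.0,
        seed=4,
    )
    ds = qt.generate_catalog(spec, refdb)
    assert len(ds.truth.genes) == 7  # 1 planted + 1 recA + 5 decoys
    assert len(ds.truth.gene_ids("recA")) == 1
    assert len(ds.truth.gene_ids("qs_true")) == 1
    assert len(ds.truth.gene_ids("qs_decoy")) == 5
    # planted gene annotation carries the reference keyword; decoys do not
    planted_id = next(iter(ds.truth.gene_ids("qs_true")))
    record = ds.truth.genes[planted_id]
    assert record.realized_identity == pytest.approx(0.9, abs=0.05)
    assert "hypothetical" not in ds.annotations[planted_id]


def test_generate_catalog_deterministic(refdb):
    a = qt.generate_catalog(small_spec(), refdb)
    b = qt.generate_catalog(small_spec(), refdb)
    assert a.genes == b.genes
    pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
    assert a.taxonomy == b.taxonomy


def test_unknown_planted_genus_rejected():
    with pytest.raises(ValueError, match="Rothia"):
        small_spec(planted=[PlantedGene("Rothia", "AI-2", "synthase", 0.8)])


def test_unknown_planted_signal_rejected(refdb):
    spec = small_spec(planted=[PlantedGene("Streptococcus", "NoSignal", "synthase", 0.8)])
    with pytest.raises(ValueError, match="NoSignal"):
        qt.generate_catalog(spec, refdb)


def test_counts_reflect_copies_and_length(refdb):
    """Expected read share of each gene is proportional to genus abundance
    x copy number x length; checked on a noise-free single-genus spec."""
    spec = CommunitySpec(
        genera={"Streptococcus": "AP"},
        replicates=1,
        days=[0],
        total_reads_per_sample=200_000,
        decoys_per_genus=0,
        background_per_genus=2,
        planted=[PlantedGene("Streptococcus", "AI-2", "synthase", 0.9, copies_per_cell=3.0)],
        trajectory_noise_sd=0.0,
        seed=8,
    )
    ds = qt.generate_catalog(spec, refdb)
    lengths = ds.counts.lengths
    planted_id = next(iter(ds.truth.gene_ids("qs_true")))
    weights = {
        g: (3.0 if g == planted_id else 1.0) * lengths[g] for g in ds.genes
    }
    total = sum(weights.values())
    counts = ds.counts.counts["d0_r1"]
    n = spec.total_reads_per_sample
    for g in ds.genes:
        p = weights[g] / total
        se = (n * p * (1 - p)) ** 0.5
        assert abs(counts[g] - n * p) < 5 * se


def test_interference_scenario_shifts_and_damps(default_spec, default_state):
    base = sample_trajectories(default_spec)
    spec2 = qt.simulate_interference(default_spec, default_state.network, "AI-2")
    assert spec2.interference is not None
    signal, effects = spec2.interference
    assert signal == "AI-2"
    pred = qt.predict_interference(default_state.network, "AI-2")
    assert effects == {g: e.value for g, e in pred.effects.items()}

    perturbed = sample_trajectories(spec2)
    days = sorted({int(c[1:].split("_")[0]) for c in base.columns})

    def day_means(traj, genus):
        by_day = {}
        for c in traj.columns:
            d = int(c[1:].split("_")[0])
            by_day.setdefault(d, []).append(traj.loc[genus, c])
        return np.array([np.mean(by_day[d]) for d in days])

    # Veillonella peak shifted to a later day
    assert np.argmax(day_means(perturbed, "Veillonella")) > np.argmax(
        day_means(base, "Veillonella")
    )
    # Streptococcus trajectory elevated overall
    assert day_means(perturbed, "Streptococcus").mean() > day_means(base, "Streptococcus").mean()
    # Prevotella / Fusobacterium damped at their unperturbed peak day
    for genus in ("Prevotella", "Fusobacterium"):
        peak_day = int(np.argmax(day_means(base, genus)))
        assert day_means(perturbed, genus)[peak_day] < day_means(base, genus)[peak_day]


def test_interference_unknown_signal_and_no_edge_signal(default_spec, default_state):
    with pytest.raises(KeyError):
        qt.simulate_interference(default_spec, default_state.network, "NoSuchSignal")
    # a complete signal whose edges are all intra-genus leaves the spec unchanged
    net = qt.CrosstalkNetwork(edges=[], complete_signals={"Lantibiotics"})
    spec2 = qt.simulate_interference(default_spec, net, "Lantibiotics")
    assert spec2.modifiers == default_spec.modifiers
    assert spec2.interference is None


def test_dataset_files_round_trip(tmp_path, refdb):
    ds = qt.generate_catalog(small_spec(), refdb)
    ds.write(tmp_path)
    table = qt.CountTable.from_tsv(tmp_path / "counts.tsv", tmp_path / "gene_lengths.tsv")
    pd.testing.assert_frame_equal(table.counts, ds.counts.counts, check_names=False)
    tax = pd.read_csv(tmp_path / "taxonomy.tsv", sep="\t", index_col=0).iloc[:, 0].to_dict()
    assert tax == ds.taxonomy
    from Bio import SeqIO

    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / "catalog.faa"), "fasta")}
    assert seqs == ds.genes
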