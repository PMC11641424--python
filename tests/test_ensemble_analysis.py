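"""Ensemble characterization: reranking, profiles, states, clustering."""

import numpy as np
import pandas as pd
import pytest

from rass.backend import MockPredictor, PredictedConformer, PredictionRequest, Provenance
from rass.ensemble_analysis import (
    ConformerEnsemble,
    classify_states,
    cluster_ensemble,
    cluster_state_contingency,
    confident_fraction,
    distribution_summary,
    pairwise_rmsd_matrix,
    plddt_rmsd_scatter,
    rerank_by_confidence,
    rmsd_profile,
)
from rass.exceptions import DegenerateEnsembleError, InputError
from rass.structure_io import ReferencePair, StructureModel
from rass.synthetic import make_hinge_conformer

from conftest import basin_truth_labels
from oracles import threshold_cut_partition


def _conformer_with_plddt(plddt, n_res=40, jitter=0.0, seed=0, tag="c"):
    model = make_hinge_conformer(n_res, 0.0, tag)
    if jitter:
        rng = np.random.default_rng(seed)
        atoms = model.atoms.copy()
        atoms.coord = (atoms.coord + rng.normal(0, jitter, atoms.coord.shape)).astype(
            np.float32
        )
        model = StructureModel(id=tag, atoms=atoms, source="predicted")
    return PredictedConformer(
        structure=model,
        plddt=np.asarray(plddt, dtype=float),
        provenance=Provenance(0, 0, False, 0, seed),
    )


# ---------------------------------------------------------------------------
# Reranking
# ---------------------------------------------------------------------------

def test_rerank_keeps_uniformly_confident_conformer():
    ens = ConformerEnsemble([_conformer_with_plddt([90.0] * 40)])
    kept, fractions = rerank_by_confidence(ens)
    assert len(kept) == 1 and fractions[0] == 1.0


def test_rerank_removes_low_confidence_conformer():
    ens = ConformerEnsemble([_conformer_with_plddt([50.0] * 40)])
    kept, fractions = rerank_by_confidence(ens)
    assert len(kept) == 0 and fractions[0] == 0.0


def test_rerank_half_confident_fraction_below_threshold():
    # 20 residues at 90, 20 at 50 -> fraction 0.5 < 0.70 -> removed
    ens = ConformerEnsemble([_conformer_with_plddt([90.0] * 20 + [50.0] * 20)])
    kept, fractions = rerank_by_confidence(ens)
    assert fractions[0] == 0.5
    assert len(kept) == 0


def test_rerank_orders_by_fraction_then_mean():
    c1 = _conformer_with_plddt([90.0] * 30 + [50.0] * 10)  # fraction 0.75, mean 80
    c2 = _conformer_with_plddt([90.0] * 40)                # fraction 1.0, mean 90
    c3 = _conformer_with_plddt([86.0] * 30 + [50.0] * 10)  # fraction 0.75, mean 77
    kept, _ = rerank_by_confidence(ConformerEnsemble([c1, c2, c3]))
    assert [c.mean_plddt for c in kept.conformers] == sorted(
        [c.mean_plddt for c in kept.conformers], reverse=True
    )
    assert len(kept) == 3 and kept.conformers[0] is c2


def test_rerank_never_grows_and_threshold_zero_is_identity_set():
    rng = np.random.default_rng(11)
    conformers = [
        _conformer_with_plddt(rng.uniform(30, 100, size=40), seed=i) for i in range(12)
    ]
    ens = ConformerEnsemble(conformers)
    kept, _ = rerank_by_confidence(ens, plddt_threshold=85.0)
    assert len(kept) <= len(ens)
    kept0, fr0 = rerank_by_confidence(ens, plddt_threshold=0.0)
    assert np.all(fr0 == 1.0)
    assert {id(c) for c in kept0.conformers} == {id(c) for c in ens.conformers}


def test_rerank_empty_ensemble_warns():
    with pytest.warns(UserWarning, match="empty"):
        kept, fractions = rerank_by_confidence(ConformerEnsemble([]))
    assert len(kept) == 0 and fractions.size == 0


# ---------------------------------------------------------------------------
# RMSD profile
# ---------------------------------------------------------------------------

def test_profile_of_apo_copy(hinge_pair, hinge_reference_pair):
    apo, _, _ = hinge_pair
    copy = _conformer_with_plddt([90.0] * 60, n_res=60)
    ens = ConformerEnsemble([copy])
    # conformer geometry: exact hinge-open form == apo backbone
    profile, summary = rmsd_profile(ens, hinge_reference_pair, compute_tm=False)
    assert profile.loc[0, "rmsd_to_apo"] < 1e-6
    assert profile.loc[0, "rmsd_to_holo"] == pytest.approx(3.5, abs=1e-3)
    assert summary["n_conformers"] == 1


def test_profile_zero_noise_mixture_is_exactly_bimodal(hinge_pair, hinge_reference_pair):
    apo, holo, _ = hinge_pair
    mock = MockPredictor(apo, holo, weight_a=0.5, noise_scale=0.0, seed=3)
    conformers = mock.predict(PredictionRequest(sequence="", num_models=4, num_recycles=8))
    ens = ConformerEnsemble(conformers)
    profile, _ = rmsd_profile(ens, hinge_reference_pair, compute_tm=False)
    pair_rmsd = 3.5
    for _, row in profile.iterrows():
        if row["basin"] == "A":
            assert row["rmsd_to_apo"] < 1e-5
            assert row["rmsd_to_holo"] == pytest.approx(pair_rmsd, abs=1e-3)
        else:
            assert row["rmsd_to_holo"] < 1e-5
            assert row["rmsd_to_apo"] == pytest.approx(pair_rmsd, abs=1e-3)


def test_profile_summary_mean_consistency(two_basin_ensemble, hinge_reference_pair):
    profile, summary = rmsd_profile(
        two_basin_ensemble, hinge_reference_pair, compute_tm=False
    )
    assert summary["rmsd_to_apo"]["mean"] == pytest.approx(
        profile["rmsd_to_apo"].mean()
    )
    assert summary["rmsd_to_holo"]["mean"] == pytest.approx(
        profile["rmsd_to_holo"].mean()
    )
    q1, q3 = np.percentile(profile["rmsd_to_apo"], [25, 75])
    assert summary["rmsd_to_apo"]["q1"] == pytest.approx(q1)
    assert summary["rmsd_to_apo"]["q3"] == pytest.approx(q3)


def test_profile_empty_ensemble_rejected(hinge_reference_pair):
    with pytest.raises(InputError):
        rmsd_profile(ConformerEnsemble([]), hinge_reference_pair)


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------

def test_classify_margin_rule_on_crafted_profile():
    profile = pd.DataFrame(
        {
            "rmsd_to_apo": [0.1, 2.0, 3.8, 2.0, 1.4],
            "rmsd_to_holo": [3.6, 2.0, 0.2, 2.4, 2.0],
        }
    )
    out = classify_states(profile, margin=0.5)
    assert list(out["state"]) == ["apo", "intermediate", "holo", "intermediate", "apo"]


def test_classify_recovers_generating_basins(two_basin_ensemble, hinge_reference_pair):
    profile, _ = rmsd_profile(two_basin_ensemble, hinge_reference_pair, compute_tm=False)
    labeled = classify_states(profile)
    truth = basin_truth_labels(two_basin_ensemble)
    assert np.mean(labeled["state"].to_numpy() == truth) == 1.0


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _basin_ensemble(angles, n_per, noise, n_res=60, seed=0):
    rng = np.random.default_rng(seed)
    conformers = []
    for bi, angle in enumerate(angles):
        base = make_hinge_conformer(n_res, angle, f"basin{bi}")
        for j in range(n_per):
            atoms = base.atoms.copy()
            atoms.coord = (
                atoms.coord + rng.normal(0, noise, atoms.coord.shape)
            ).astype(np.float32)
            conformers.append(
                PredictedConformer(
                    structure=StructureModel(
                        id=f"b{bi}_{j}", atoms=atoms, source="predicted"
                    ),
                    plddt=np.full(n_res, 90.0),
                    provenance=Provenance(bi, j, False, 0, seed, basin=str(bi)),
                )
            )
    return ConformerEnsemble(conformers)


def test_two_basins_cluster_k2_matching_threshold_cut_oracle():
    ens = _basin_ensemble(angles=[0.0, 25.0], n_per=30, noise=0.2, seed=1)
    sol = cluster_ensemble(ens, k_range=range(2, 8))
    assert sol.k == 2
    d = pairwise_rmsd_matrix(ens)
    oracle = threshold_cut_partition(d, threshold=0.5 * d.max())
    assert len(np.unique(oracle)) == 2
    # identical partitions up to label permutation
    mapping = {}
    for a, b in zip(sol.labels, oracle):
        mapping.setdefault(a, b)
        assert mapping[a] == b


def test_three_basins_cluster_k3():
    ens = _basin_ensemble(angles=[0.0, 25.0, 50.0], n_per=15, noise=0.2, seed=2)
    sol = cluster_ensemble(ens, k_range=range(2, 8))
    assert sol.k == 3
    truth = np.array([c.provenance.basin for c in ens.conformers])
    for label in np.unique(sol.labels):
        assert len(np.unique(truth[sol.labels == label])) == 1


def test_degenerate_identical_conformers():
    ens = _basin_ensemble(angles=[0.0], n_per=5, noise=1e-8, seed=3)
    with pytest.raises(DegenerateEnsembleError, match="k=1"):
        cluster_ensemble(ens, k_range=range(2, 4))


def test_ensemble_too_small_for_k_range():
    ens = _basin_ensemble(angles=[0.0, 25.0], n_per=2, noise=0.2)
    with pytest.raises(InputError, match="k_range"):
        cluster_ensemble(ens, k_range=range(2, 11))


def test_cluster_labels_invariant_under_reordering():
    ens = _basin_ensemble(angles=[0.0, 25.0], n_per=10, noise=0.2, seed=4)
    sol = cluster_ensemble(ens, k_range=range(2, 5))
    order = np.random.default_rng(5).permutation(len(ens))
    shuffled = ConformerEnsemble([ens.conformers[i] for i in order])
    sol2 = cluster_ensemble(shuffled, k_range=range(2, 5))
    assert sol2.k == sol.k
    mapping = {}
    for i, j in enumerate(order):
        mapping.setdefault(sol2.labels[i], sol.labels[j])
        assert mapping[sol2.labels[i]] == sol.labels[j]


def test_silhouette_selection_ties_go_to_smaller_k():
    ens = _basin_ensemble(angles=[0.0, 25.0], n_per=8, noise=0.15, seed=6)
    sol = cluster_ensemble(ens, k_range=range(2, 6))
    best = max(s for s in sol.silhouette_by_k.values() if np.isfinite(s))
    ks_at_best = [k for k, s in sol.silhouette_by_k.items() if s == best]
    assert sol.k == min(ks_at_best)


# ---------------------------------------------------------------------------
# pLDDT vs RMSD scatter
# ---------------------------------------------------------------------------

def test_scatter_negative_correlation_for_decaying_confidence(hinge_reference_pair):
    # conformers at increasing displacement from the apo basin with
    # correspondingly decaying confidence (the mock's construction)
    rng = np.random.default_rng(8)
    conformers = []
    for i, scale in enumerate(np.linspace(0.05, 1.2, 12)):
        base = make_hinge_conformer(60, 0.0, f"n{i}")
        noise = rng.normal(0, scale, base.atoms.coord.shape)
        atoms = base.atoms.copy()
        atoms.coord = (atoms.coord + noise).astype(np.float32)
        ca_disp = np.linalg.norm(noise[atoms.atom_name == "CA"], axis=1)
        plddt = np.clip(100.0 * np.exp(-ca_disp / 2.0), 30.0, 100.0)
        conformers.append(
            PredictedConformer(
                structure=StructureModel(id=f"n{i}", atoms=atoms, source="predicted"),
                plddt=plddt,
                provenance=Provenance(0, i, False, 0, 0),
            )
        )
    ens = ConformerEnsemble(conformers)
    profile, _ = rmsd_profile(ens, hinge_reference_pair, compute_tm=False)
    table, corrs = plddt_rmsd_scatter(profile)
    assert corrs["rmsd_to_apo"]["defined"]
    assert corrs["rmsd_to_apo"]["spearman_rho"] < -0.8
    assert set(table.columns) == {"conformer", "mean_plddt", "rmsd_to_apo", "rmsd_to_holo"}


def test_scatter_constant_plddt_flagged_undefined():
    profile = pd.DataFrame(
        {
            "conformer": [0, 1, 2],
            "mean_plddt": [90.0, 90.0, 90.0],
            "rmsd_to_apo": [0.5, 1.0, 1.5],
            "rmsd_to_holo": [3.0, 2.5, 2.0],
        }
    )
    _, corrs = plddt_rmsd_scatter(profile)
    assert not corrs["rmsd_to_apo"]["defined"]
    assert np.isnan(corrs["rmsd_to_apo"]["spearman_rho"])


def test_scatter_single_conformer_undefined():
    profile = pd.DataFrame(
        {"conformer": [0], "mean_plddt": [90.0], "rmsd_to_apo": [0.5], "rmsd_to_holo": [3.0]}
    )
    _, corrs = plddt_rmsd_scatter(profile)
    assert not corrs["rmsd_to_apo"]["defined"] and not corrs["rmsd_to_holo"]["defined"]


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

def test_single_value_occupies_single_bin():
    out = distribution_summary(np.array([1.3]), kind="rmsd")
    counts = np.array(out["counts"])
    assert counts.sum() == 1
    (occupied,) = np.flatnonzero(counts)
    edges = np.array(out["bin_edges"])
    assert edges[occupied] <= 1.3 < edges[occupied + 1]
    assert out["kde_grid"] is None  # KDE undefined for one distinct value


def test_uniform_grid_gives_flat_histogram():
    # one value per 0.25-wide bin
    values = np.arange(0.125, 5.0, 0.25)
    out = distribution_summary(values, kind="rmsd", with_kde=False)
    assert set(out["counts"]) == {1}


def test_two_point_mass_kde_modes_near_masses():
    values = np.array([1.0] * 50 + [4.0] * 50) + np.random.default_rng(9).normal(
        0, 0.01, 100
    )
    out = distribution_summary(values, kind="rmsd")
    grid = np.array(out["kde_grid"])
    dens = np.array(out["kde_density"])
    step = grid[1] - grid[0]
    local_max = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    modes = grid[local_max[np.argsort(dens[local_max])[::-1][:2]]]
    assert min(abs(modes - 1.0)) <= max(step, 0.05)
    assert min(abs(modes - 4.0)) <= max(step, 0.05)


def test_distribution_fixed_grids():
    tm = distribution_summary(np.array([0.3, 0.9]), kind="tm", with_kde=False)
    assert tm["bin_edges"][0] == 0.0 and tm["bin_edges"][-1] == pytest.approx(1.0)
    assert tm["bin_width"] == 0.025
    pl = distribution_summary(np.array([55.0, 90.0]), kind="plddt", with_kde=False)
    assert pl["bin_edges"][-1] == pytest.approx(100.0)
    assert pl["bin_width"] == 2.5
    with pytest.raises(InputError):
        distribution_summary(np.array([]), kind="rmsd")
    with pytest.raises(InputError):
        distribution_summary(np.array([1.0]), kind="unknown")


# ---------------------------------------------------------------------------
# Contingency
# ---------------------------------------------------------------------------

def test_cluster_state_contingency_counts(two_basin_ensemble, hinge_reference_pair):
    profile, _ = rmsd_profile(two_basin_ensemble, hinge_reference_pair, compute_tm=False)
    profile = classify_states(profile)
    sol = cluster_ensemble(two_basin_ensemble, k_range=range(2, 6))
    tab = cluster_state_contingency(profile, sol)
    assert tab.to_numpy().sum() == len(two_basin_ensemble)
    # clean two-basin ensemble: each cluster maps to a single state
    assert (tab.to_numpy() > 0).sum() == 2
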