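"""Kinship construction, genotype PCA, Tracy-Widom tests, outliers, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from grasspred import (PopulationModel, TraitModel, assign_subpops,
                       correlate_trait_with_axes, detect_outliers,
                       estimate_blups, grm_vanraden, ibs_kinship,
                       pca_genotypes, simulate_structured_genotypes,
                       simulate_trait)
from grasspred.exceptions import DataError
from grasspred.structure import (read_kinship_tsv, tracy_widom_pvalue,
                                 write_kinship_tsv)

from conftest import make_table


# -- IBS kinship -----------------------------------------------------------

def test_ibs_hand_computations():
    dosage = np.array([
        [0, 1, 2],
        [2, 1, 0],   # (0+1+0)/3 vs row 0
        [0, 1, 2],   # duplicate of row 0
        [2, 2, 2],
        [0, 0, 0],
    ], dtype=float)
    k = ibs_kinship(make_table(dosage))
    assert k.values[0, 1] == pytest.approx(1 / 3)
    assert k.values[0, 2] == pytest.approx(1.0)
    assert k.values[3, 4] == pytest.approx(0.0)  # opposite homozygotes
    assert np.all(np.diag(k.values) == 1.0)
    assert k.values.min() >= 0 and k.values.max() <= 1


def test_ibs_respects_missingness_pairwise():
    nan = np.nan
    dosage = np.array([[0, 1, nan, 2],
                       [0, nan, 1, 0]], dtype=float)
    k = ibs_kinship(make_table(dosage))
    # joint loci are L1 and L4: (2-0)/2=1 and (2-2)/2=0 -> mean 1/2
    assert k.values[0, 1] == pytest.approx(0.5)


def test_ibs_no_joint_loci_errors():
    nan = np.nan
    dosage = np.array([[0, nan], [nan, 1]], dtype=float)
    with pytest.raises(DataError, match="share no observed loci"):
        ibs_kinship(make_table(dosage))


# -- VanRaden GRM ----------------------------------------------------------

def test_grm_single_locus_hand_value():
    dosage = np.array([[0.0], [2.0]])
    k = grm_vanraden(make_table(dosage))
    # p=0.5: Z=(-1,+1), denom=2*0.25=0.5 -> K12 = -2
    assert k.values[0, 1] == pytest.approx(-2.0)


def test_grm_diagonal_near_one_under_hwe():
    gt = simulate_structured_genotypes(
        PopulationModel(n_individuals=200, n_loci=5000, fst=0.0,
                        ld_strength=0.0, missing_rate=0.0, seed=31))
    k = grm_vanraden(gt)
    assert np.mean(np.diag(k.values)) == pytest.approx(1.0, abs=0.05)


def test_grm_elevated_within_subpopulation(panel):
    k = grm_vanraden(panel)
    labels = panel.metadata.set_index("genotype_id").loc[panel.ids, "subpop"]
    same = np.equal.outer(labels.to_numpy(), labels.to_numpy())
    off = ~np.eye(len(k.ids), dtype=bool)
    assert k.values[same & off].mean() > k.values[~same].mean()


def test_grm_monomorphic_only_errors():
    with pytest.raises(DataError, match="monomorphic"):
        grm_vanraden(make_table(np.zeros((5, 3))))


def test_ibs_and_grm_agree_in_ordering():
    # needs genuine relatedness variation to rank: under a pure-noise panel
    # both off-diagonal sets are ~constant and rank agreement is attenuated
    gt = simulate_structured_genotypes(
        PopulationModel(n_individuals=120, n_loci=4000, fst=0.05,
                        missing_rate=0.0, seed=11))
    ki = ibs_kinship(gt).values
    kg = grm_vanraden(gt).values
    tri = np.triu_indices_from(ki, k=1)
    rho = sps.spearmanr(ki[tri], kg[tri]).statistic
    assert rho > 0.9


# -- PCA -------------------------------------------------------------------

def test_pca_eigenvalues_sum_to_trace(panel):
    pca = pca_genotypes(panel, max_axes=panel.n_individuals)
    from grasspred.genotypes import impute_mean
    x = impute_mean(panel)
    p = x.mean(axis=0) / 2
    keep = (p > 0) & (p < 1) & (x.std(axis=0) > 0)
    z = (x[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    trace = np.trace(z @ z.T / keep.sum())
    assert np.sum(pca.eigenvalues) == pytest.approx(trace, rel=1e-8)


def test_pca_separates_differentiated_subpops():
    gt = simulate_structured_genotypes(
        PopulationModel(n_individuals=200, n_loci=10_000, fst=0.10,
                        missing_rate=0.0, seed=41))
    pca = pca_genotypes(gt, max_axes=5)
    assert pca.tw_pvalues[0] < 1e-4
    labels = gt.metadata["subpop"].to_numpy()
    pred = pca.scores[:, 0] > np.median(pca.scores[:, 0])
    agree = max(np.mean(pred == (labels == "P1")),
                np.mean(pred == (labels == "P2")))
    assert agree >= 0.95


def test_pca_score_ordering_invariant_to_duplication(panel):
    sub = panel.subset(individuals=panel.ids[:40],
                       loci=list(panel.loci["locus"][:300]))
    pca1 = pca_genotypes(sub, max_axes=1)
    doubled = make_table(np.vstack([sub.dosage, sub.dosage]))
    pca2 = pca_genotypes(doubled, max_axes=1)
    s1 = pca1.scores[:, 0]
    s2 = pca2.scores[:40, 0]
    assert abs(sps.spearmanr(s1, s2).statistic) > 0.999


def test_tracy_widom_tail_values():
    # published TW1 percentiles: 0.4501 (90th), 0.9793 (95th), 2.0234 (99th)
    assert tracy_widom_pvalue(0.4501) == pytest.approx(0.10, abs=0.01)
    assert tracy_widom_pvalue(0.9793) == pytest.approx(0.05, abs=0.005)
    assert tracy_widom_pvalue(2.0234) == pytest.approx(0.01, abs=0.002)


def test_tw_null_calibration_moderate():
    # unstructured data: leading axis should rarely be significant
    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        gt = simulate_structured_genotypes(
            PopulationModel(n_individuals=60, n_loci=400, fst=0.0,
                            ld_strength=0.0, missing_rate=0.0, seed=100 + seed))
        pca = pca_genotypes(gt, max_axes=1)
        hits += pca.tw_pvalues[0] < 0.05
    assert hits <= 5  # ~binomial(20, 0.05) upper tail


# -- outliers / clustering -------------------------------------------------

def test_no_outliers_in_clean_panel(panel):
    assert detect_outliers(panel, sd_threshold=6.0) == []


def test_planted_contaminated_individual_is_flagged(panel):
    rng = np.random.default_rng(5)
    dosage = panel.dosage.copy()
    # 30% of loci forced to the rare homozygote for one individual
    freqs = np.nanmean(dosage, axis=0) / 2
    rare = np.where(freqs < 0.5, 2.0, 0.0)
    loci = rng.choice(panel.n_loci, size=int(0.3 * panel.n_loci), replace=False)
    dosage[17, loci] = rare[loci]
    gt = make_table(dosage)
    assert "I18" in detect_outliers(gt, sd_threshold=6.0)


def test_planted_duplicate_is_not_flagged(panel):
    dosage = np.vstack([panel.dosage, panel.dosage[[3], :]])
    gt = make_table(dosage)
    dup_id = gt.ids[-1]
    assert dup_id not in detect_outliers(gt, sd_threshold=6.0)


def test_assign_subpops_recovers_truth_and_is_equivariant():
    gt = simulate_structured_genotypes(
        PopulationModel(n_individuals=150, n_loci=6000, fst=0.10,
                        missing_rate=0.0, seed=51))
    pca = pca_genotypes(gt, max_axes=5)
    labels = assign_subpops(pca, k=2, seed=0)
    truth = gt.metadata.set_index("genotype_id").loc[labels.index, "subpop"]
    agree = max((labels.to_numpy() == np.where(truth == "P1", "C1", "C2")).mean(),
                (labels.to_numpy() == np.where(truth == "P1", "C2", "C1")).mean())
    assert agree >= 0.95
    # permutation equivariance via centroid-canonical labels
    perm = np.random.default_rng(1).permutation(len(pca.ids))
    from grasspred.structure import PCAResult
    pca_perm = PCAResult(ids=[pca.ids[i] for i in perm],
                         eigenvalues=pca.eigenvalues,
                         scores=pca.scores[perm], loadings=pca.loadings,
                         tw_pvalues=pca.tw_pvalues,
                         pct_variance=pca.pct_variance)
    labels_perm = assign_subpops(pca_perm, k=2, seed=0)
    assert (labels_perm.loc[labels.index] == labels).all()


def test_assign_subpops_k1_single_label(panel):
    pca = pca_genotypes(panel, max_axes=2)
    assert set(assign_subpops(pca, k=1)) == {"C1"}


# -- trait-axis correlation ------------------------------------------------

def test_trait_equal_to_pc1_has_r_one(panel):
    pca = pca_genotypes(panel, max_axes=2)
    trait = pd.Series(pca.scores[:, 0], index=pca.ids)
    out = correlate_trait_with_axes(trait, pca, axes=(1,))
    assert out.loc[0, "r"] == pytest.approx(1.0)
    assert out.loc[0, "p"] < 1e-20


def test_structure_free_trait_mostly_uncorrelated(panel):
    pca = pca_genotypes(panel, max_axes=1)
    rng = np.random.default_rng(77)
    crit = 0.17 * np.sqrt(138 / len(pca.ids))  # |r| null quantile, n-adjusted
    hits = sum(
        abs(correlate_trait_with_axes(
            pd.Series(rng.normal(size=len(pca.ids)), index=pca.ids),
            pca, axes=(1,)).loc[0, "r"]) > crit
        for _ in range(60))
    assert hits <= 9  # ~5% expected, binomial slack


def test_kinship_tsv_round_trip(tmp_path, panel_kinship):
    path = tmp_path / "k.tsv"
    write_kinship_tsv(panel_kinship, path)
    back = read_kinship_tsv(path)
    assert back.method == "IBS"
    assert back.ids == panel_kinship.ids
    np.testing.assert_allclose(back.values, panel_kinship.values, atol=1e-12)
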