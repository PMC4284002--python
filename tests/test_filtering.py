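"""Locus statistics, filter profiles, LD and windowed pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from grasspred import (FilterProfile, LIBERAL, STRINGENT,
                       apply_filter_profile, ld_prune, ld_r2, locus_stats)
from grasspred.exceptions import (ConfigurationError, DataError,
                                  InvalidParameterError)
from grasspred.filtering import locus_stats_table

from conftest import make_table


@pytest.mark.parametrize("dosages,expect", [
    # Hardy-Weinberg case: p=0.5, Ho=0.5, He=0.5, F_IS=0
    ([0, 1, 1, 2], dict(maf=0.5, ho=0.5, he=0.5, fis=0.0)),
    # no heterozygotes: F_IS = 1
    ([0, 2, 0, 2], dict(maf=0.5, ho=0.0, he=0.5, fis=1.0)),
    # all heterozygous: F_IS = -1
    ([1, 1, 1, 1], dict(maf=0.5, ho=1.0, he=0.5, fis=-1.0)),
])
def test_locus_stats_hand_cases(dosages, expect):
    gt = make_table(np.asarray(dosages, dtype=float)[:, None])
    st = locus_stats(gt, "L1")
    for key, val in expect.items():
        assert getattr(st, key) == pytest.approx(val), key


def test_locus_stats_monomorphic_fis_undefined():
    gt = make_table(np.zeros((4, 1)))
    st = locus_stats(gt, "L1")
    assert st.he == 0.0 and np.isnan(st.fis)


def _five_locus_table():
    """Hand-designed 10-individual, 5-locus filtering fixture.

    L1 clean biallelic near HWE; L2 two minor-allele copies carried by one
    rare homozygote (F_IS = 1); L3 30% missing; L4 triallelic; L5 fully
    heterozygote-free (F_IS = 1) but common.
    """
    nan = np.nan
    cols = {
        "L1": [0, 1, 1, 2, 0, 1, 1, 2, 0, 1],
        "L2": [0, 0, 0, 0, 0, 0, 0, 0, 0, 2],
        "L3": [0, 1, 1, 2, 0, 1, 2, nan, nan, nan],
        "L4": [0, 1, 1, 2, 0, 1, 1, 2, 0, 1],
        "L5": [0, 2, 0, 2, 0, 2, 0, 2, 0, 2],
    }
    dosage = np.column_stack([cols[k] for k in cols])
    return make_table(dosage, n_alleles=[2, 2, 2, 3, 2])


def test_liberal_style_profile_hand_evaluated():
    gt = _five_locus_table()
    profile = FilterProfile(min_minor_allele_copies=3, max_missing_pct=20,
                            required_n_alleles=2)
    kept, report = apply_filter_profile(gt, profile)
    assert list(kept.loci["locus"]) == ["L1", "L5"]
    failed = report.set_index("locus")["failed_criterion"]
    assert failed["L2"] == "minor_alleles"
    assert failed["L3"] == "missing"
    assert failed["L4"] == "n_alleles"


def test_stringent_style_profile_hand_evaluated():
    gt = _five_locus_table()
    profile = FilterProfile(max_missing_pct=10, max_abs_fis=0.25,
                            required_n_alleles=2)
    kept, report = apply_filter_profile(gt, profile)
    assert list(kept.loci["locus"]) == ["L1"]
    failed = report.set_index("locus")["failed_criterion"]
    assert failed["L2"] == "fis" and failed["L5"] == "fis"


def test_empty_profile_is_identity_on_biallelic_table(panel):
    kept, report = apply_filter_profile(panel, FilterProfile())
    assert kept.n_loci == panel.n_loci
    assert report["passed"].all()


def test_filtering_is_idempotent(panel):
    once, _ = apply_filter_profile(panel, LIBERAL)
    twice, rep = apply_filter_profile(once, LIBERAL)
    assert twice.n_loci == once.n_loci
    assert rep["passed"].all()


def test_tightening_a_threshold_never_adds_survivors(panel):
    base, _ = apply_filter_profile(panel, LIBERAL)
    for tighter in (LIBERAL.with_(max_missing_pct=10),
                    LIBERAL.with_(min_minor_allele_copies=6),
                    LIBERAL.with_(min_ave_depth=20),
                    LIBERAL.with_(min_depth=10)):
        kept, _ = apply_filter_profile(panel, tighter)
        assert kept.n_loci <= base.n_loci


def test_het_read_masking_happens_before_missingness(panel):
    profile = FilterProfile(min_het_read_fraction=0.45, max_missing_pct=5)
    kept, _ = apply_filter_profile(panel, profile)
    # masked het calls inflate missingness, so this removes real loci
    loose, _ = apply_filter_profile(panel, FilterProfile(max_missing_pct=5))
    assert kept.n_loci < loose.n_loci
    assert not (kept.dosage[(kept.minor_read_fraction() < 0.45)
                            & (kept.dosage == 1)].size)


def test_profile_requiring_absent_annotation_errors():
    gt = _five_locus_table()  # no depth fields
    with pytest.raises(ConfigurationError, match="depth"):
        apply_filter_profile(gt, FilterProfile(min_depth=5))
    with pytest.raises(ConfigurationError, match="quality"):
        apply_filter_profile(gt, FilterProfile(min_qual=15))


# -- LD --------------------------------------------------------------------

def test_ld_r2_trivial_and_brute_force():
    g_a = np.array([0, 1, 2, 0], dtype=float)
    g_b = np.array([0, 1, 0, 2], dtype=float)
    gt = make_table(np.column_stack([g_a, g_a, 2 - g_a, g_b]))
    assert ld_r2(gt, "L1", "L2") == pytest.approx(1.0)
    assert ld_r2(gt, "L1", "L3") == pytest.approx(1.0)  # complement: r=-1
    expected = np.corrcoef(g_a, g_b)[0, 1] ** 2  # brute force on the 4 pairs
    assert ld_r2(gt, "L1", "L4") == pytest.approx(expected)


def test_ld_r2_zero_variance_is_nan_not_error():
    gt = make_table(np.column_stack([[1, 1, 1, 1], [0, 1, 2, 0]]).astype(float))
    assert np.isnan(ld_r2(gt, "L1", "L2"))


def test_ld_prune_hand_trace_duplicate_dropped():
    g = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=float)
    indep = np.array([0, 0, 1, 2, 2, 1, 0, 1], dtype=float)
    gt = make_table(np.column_stack([g, g, indep]))
    kept = ld_prune(gt, window=3, step=1, r2_threshold=0.2)
    assert kept == ["L1", "L3"]


def test_ld_prune_identity_when_all_below_threshold():
    rng = np.random.default_rng(3)
    dosage = rng.integers(0, 3, size=(200, 10)).astype(float)
    gt = make_table(dosage)
    r2 = max(ld_r2(gt, a, b) for a, b in
             itertools.combinations(gt.loci["locus"], 2))
    assert r2 < 0.2  # precondition of the scenario
    assert ld_prune(gt) == list(gt.loci["locus"])


def test_ld_prune_satisfies_window_constraint_brute_force(panel):
    sub = panel.subset(loci=list(panel.loci["locus"][:200]))
    window, step, thr = 20, 5, 0.2
    kept = ld_prune(sub, window=window, step=step, r2_threshold=thr)
    assert kept == sorted(kept, key=list(sub.loci["locus"]).index)
    # exhaustive oracle: no retained pair inside any window exceeds threshold
    pos = {l: i for i, l in enumerate(sub.loci["locus"])}
    kept_idx = [pos[l] for l in kept]
    for start in range(0, 200, step):
        inside = [i for i in kept_idx if start <= i < start + window]
        for a, b in itertools.combinations(inside, 2):
            r2 = ld_r2(sub, sub.loci["locus"][a], sub.loci["locus"][b])
            assert not (r2 > thr), (a, b, r2)


def test_ld_prune_parameter_validation(panel):
    with pytest.raises(InvalidParameterError):
        ld_prune(panel, window=1)
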