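"""Differential-expression screen, BH adjustment, clustering, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import graftflow as gf


# ----------------------------------------------------------------------
# BH adjustment
# ----------------------------------------------------------------------

def test_bh_step_up_hand_example():
    # sorted p*m/i = (.04, .04, .04, .04); monotone minimum from the top
    adjusted = gf.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adjusted, 0.04)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_is_monotone_and_dominates_raw_p(pvals):
    p = np.asarray(pvals)
    q = gf.benjamini_hochberg(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ----------------------------------------------------------------------
# Welch test + DE screen
# ----------------------------------------------------------------------

def _welch_brute(a, b):
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (ma - mb) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, 2 * stats.t.sf(abs(t), df)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=10_000))
def test_welch_statistic_matches_brute_force_formula(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, rng.integers(3, 8))
    b = rng.normal(0.5, 2, rng.integers(3, 8))
    t, p = gf.welch_t(a[None, :], b[None, :])
    tb, pb = _welch_brute(a, b)
    assert abs(t[0] - tb) < 1e-10 and abs(p[0] - pb) < 1e-10


def test_identical_groups_yield_fold_one_and_no_pass(matrix_builder):
    profiles = {f"g{i}": {("A", "rootstock"): [10.0 * (i + 1)] * 3,
                          ("B", "rootstock"): [10.0 * (i + 1)] * 3}
                for i in range(5)}
    expr = matrix_builder(profiles, n_rep=4)
    rec = gf.test_differential_expression(expr, "rootstock", "CA", ("A", "B"))
    assert np.allclose(rec["log2fc"], 0.0)  # fold change 1
    assert not rec["passed"].any()
    assert (rec["fdr"] >= rec["p"] - 1e-12).all()


def test_missing_group_raises_with_cell_name(matrix_builder):
    profiles = {"g0": {("A", "rootstock"): [1, 2, 3]}}
    expr = matrix_builder(profiles)
    with pytest.raises(ValueError, match="combination=B"):
        gf.test_differential_expression(expr, "rootstock", "CA", ("A", "B"))


def test_planted_deg_recovery_on_simulated_data(small_ds):
    truth = small_ds.truth
    records = gf.deg_screen(small_ds.expression)
    venn = gf.filter_and_partition(records[records["tissue"] == "rootstock"],
                                   records[records["tissue"] == "scion"])
    planted_rs = set(truth.loc[truth["deg_rootstock"], "gene_id"])
    found_rs = set(venn.rootstock_only) | set(venn.shared)
    assert len(found_rs & planted_rs) / len(planted_rs) >= 0.9
    null_genes = set(truth.loc[~truth["deg_rootstock"], "gene_id"])
    assert len(found_rs & null_genes) / len(null_genes) <= 0.02


# ----------------------------------------------------------------------
# Venn partition
# ----------------------------------------------------------------------

def _records(tissue, passing, failing=()):
    rows = [(g, tissue, "CA", 2.0, 1e-4, 1e-3, True) for g in passing]
    rows += [(g, tissue, "CA", 0.0, 0.9, 0.95, False) for g in failing]
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "stage", "log2fc", "p", "fdr", "passed"])


def test_partition_when_scion_subset_of_rootstock():
    venn = gf.filter_and_partition(_records("rootstock", "abcd"), _records("scion", "ab"))
    assert venn.scion_only == frozenset()
    assert venn.shared == frozenset("ab")
    assert venn.rootstock_only == frozenset("cd")


def test_partition_of_disjoint_sets_has_empty_shared():
    venn = gf.filter_and_partition(_records("rootstock", "ab"), _records("scion", "cd"))
    assert venn.shared == frozenset()
    assert venn.union == frozenset("abcd")


def test_partition_identities_on_simulated_data(small_ds):
    records = gf.deg_screen(small_ds.expression)
    venn = gf.filter_and_partition(records[records["tissue"] == "rootstock"],
                                   records[records["tissue"] == "scion"])
    rs = set(records.loc[(records["tissue"] == "rootstock") & records["passed"], "gene_id"])
    sc = set(records.loc[(records["tissue"] == "scion") & records["passed"], "gene_id"])
    assert venn.union == rs | sc
    assert venn.shared == frozenset(rs & sc)
    # planted shared DEGs (mobile + shared non-mobile) land in the shared set
    truth = small_ds.truth
    planted_shared = set(truth.loc[truth["deg_rootstock"] & truth["deg_scion"], "gene_id"])
    assert len(set(venn.shared) & planted_shared) / len(planted_shared) >= 0.9


# ----------------------------------------------------------------------
# k-means clustering of dynamics
# ----------------------------------------------------------------------

def _brute_min_wcss(points, k=2):
    best = np.inf
    for labels in itertools.product(range(k), repeat=len(points)):
        if len(set(labels)) < k:
            continue
        w = 0.0
        for c in range(k):
            pts = points[np.array(labels) == c]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return best


def _two_blob_matrix(builder, n_per_blob=3, jitter=0.04):
    profiles = {}
    for i in range(n_per_blob):
        profiles[f"up{i}"] = {("A", "rootstock"): [1, 5, 9], ("B", "rootstock"): [1, 5, 9]}
        profiles[f"down{i}"] = {("A", "rootstock"): [9, 5, 1], ("B", "rootstock"): [9, 5, 1]}
    return builder(profiles, n_rep=2, jitter=jitter, seed=4)


def test_two_separated_blobs_recovered_perfectly(matrix_builder):
    expr = _two_blob_matrix(matrix_builder)
    res = gf.cluster_dynamics(expr, list(expr.genes), k=2, seed=0)
    labels = res.assignments
    up = {labels[g] for g in labels.index if g.startswith("up")}
    down = {labels[g] for g in labels.index if g.startswith("down")}
    assert len(up) == 1 and len(down) == 1 and up != down


def test_single_cluster_wcss_equals_total_ss(matrix_builder):
    expr = _two_blob_matrix(matrix_builder)
    res = gf.cluster_dynamics(expr, list(expr.genes), k=1, seed=0)
    z = res.profiles.to_numpy()
    total_ss = ((z - z.mean(axis=0)) ** 2).sum()
    assert res.wcss == pytest.approx(total_ss)


def test_wcss_matches_exhaustive_partition_minimum(matrix_builder):
    expr = _two_blob_matrix(matrix_builder, n_per_blob=3, jitter=0.15)
    res = gf.cluster_dynamics(expr, list(expr.genes), k=2, seed=0)
    assert res.wcss == pytest.approx(_brute_min_wcss(res.profiles.to_numpy(), k=2), rel=1e-9)


def test_k_larger_than_distinct_profiles_raises(matrix_builder):
    profiles = {f"g{i}": {("A", "rootstock"): [1, 2, 3], ("B", "rootstock"): [1, 2, 3]}
                for i in range(4)}
    expr = matrix_builder(profiles)
    with pytest.raises(ValueError, match="distinct"):
        gf.cluster_dynamics(expr, list(expr.genes), k=2, seed=0)


# ----------------------------------------------------------------------
# concordance
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, r_expected",
    [([1, 2, 3, 4], [3, 5, 7, 9], 1.0),        # y = 2x + 1
     ([1, 2, 3], [1, 2, 4], 0.982),            # hand Pearson: cov 1.5, var 1 and 7/3
     ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0)],  # y = -x
)
def test_concordance_reference_values(x, y, r_expected):
    res = gf.concordance(x, y)
    assert res.r == pytest.approx(r_expected, abs=5e-4)
    assert res.r2 == pytest.approx(res.r**2)


def test_concordance_rejects_zero_variance():
    with pytest.raises(ValueError, match="variance"):
        gf.concordance([1, 1, 1], [1, 2, 3])


def test_qpcr_vs_rpkm_concordance_on_simulated_replicates(small_ds):
    # two noisy measurements of the same stage means should correlate strongly
    means = small_ds.expression.stage_means()
    rng = np.random.default_rng(0)
    genes = small_ds.truth["gene_id"].head(13)
    rpkm = np.log2(means.loc[genes, ("Gala-G202", "scion", "CA")] + 1)
    qpcr = rpkm * (1 + 0.05 * rng.standard_normal(len(genes)))
    res = gf.concordance(rpkm, qpcr)
    assert res.r2 > 0.8 and res.p < 1e-4


# ----------------------------------------------------------------------
# metabolites (raw-p rule)
# ----------------------------------------------------------------------

def _metabolite_frame(values_a, values_b):
    cols, rows = [], []
    for comb, vals in (("A", values_a), ("B", values_b)):
        for r, _ in enumerate(vals[0], start=1):
            cols.append(f"{comb}_rootstock_CA_R{r}")
            rows.append((comb, "rootstock", "CA", r))
    data = [list(a) + list(b) for a, b in zip(values_a, values_b)]
    values = pd.DataFrame(data, index=[f"m{i}" for i in range(len(values_a))], columns=cols)
    sheet = pd.DataFrame(rows, index=cols, columns=["combination", "tissue", "stage", "replicate"])
    sheet.index.name = "sample_id"
    return values, sheet


def test_identical_metabolite_groups_pass_nothing():
    values, sheet = _metabolite_frame([[10, 10, 11, 11]] * 3, [[10, 10, 11, 11]] * 3)
    pooled, _ = gf.filter_differential_metabolites(values, sheet, ("A", "B"))
    assert pooled["rootstock"] == set()


def test_planted_twofold_metabolite_passes():
    base = np.array([100.0, 102.0, 98.0, 101.0])
    values, sheet = _metabolite_frame([list(2 * base)], [list(base)])
    pooled, _ = gf.filter_differential_metabolites(values, sheet, ("A", "B"))
    assert pooled["rootstock"] == {"m0"}


def test_significant_but_small_fold_fails_gate():
    base = np.array([100.0, 101.0, 99.0, 100.5])
    values, sheet = _metabolite_frame([list(1.4 * base)], [list(base)])
    pooled, table = gf.filter_differential_metabolites(values, sheet, ("A", "B"))
    assert table["p"].iloc[0] <= 0.05  # highly significant ...
    assert pooled["rootstock"] == set()  # ... but below the fold-change gate
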