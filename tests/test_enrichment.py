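"""Gene/hotspot enrichment, Ser/Thr accounting, and BH FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from tosca.enrichment import (
    _two_group_test,
    bh_fdr,
    mutation_indicators,
    per_gene_case_control,
    ser_thr_accounting,
    subgroup_enrichment,
)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact enumeration: sum hypergeometric probabilities <= P(observed)."""
    n1, n2, m = a + b, c + d, a + c
    ks = np.arange(max(0, m - n2), min(n1, m) + 1)
    probs = hypergeom.pmf(ks, n1 + n2, n1, m)
    p_obs = hypergeom.pmf(a, n1 + n2, n1, m)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def test_bh_fdr_hand_computed():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([0.3]) == pytest.approx([0.3])
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    # shuffled input keeps positional correspondence
    p = [0.001, 0.5, 0.04, 0.2]
    q = bh_fdr(p)
    assert q[0] == pytest.approx(0.004) and q[1] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_fisher_fallback_matches_enumeration_oracle():
    """Zero-cell tables route to Fisher and match exact enumeration."""
    rng = np.random.default_rng(0)
    for _ in range(150):
        n1, n2 = rng.integers(1, 25, 2)
        a = int(rng.integers(0, n1 + 1))
        c = int(rng.integers(0, n2 + 1))
        if min(a, n1 - a, c, n2 - c) > 0:
            a = 0  # force the zero-cell path
        p, method = _two_group_test(a, int(n1), c, int(n2))
        assert method == "fisher"
        assert p == pytest.approx(fisher_two_sided_oracle(a, n1 - a, c, n2 - c),
                                  rel=1e-8)


def test_wald_primary_path_sensible():
    p, method = _two_group_test(30, 60, 10, 60)
    assert method == "logit_wald" and p < 0.01
    p_null, _ = _two_group_test(20, 60, 20, 60)
    assert p_null > 0.9


def _cohort_indicators(seed, n1=30, n2=20, genes=6, rate=0.3):
    rng = np.random.default_rng(seed)
    ind = pd.DataFrame(
        rng.random((n1 + n2, genes)) < rate,
        columns=[f"G{i}" for i in range(genes)],
    ).astype(int)
    labels = np.array([1] * n1 + [0] * n2)
    return ind, labels


def test_per_gene_results_structure_and_invariances():
    ind, labels = _cohort_indicators(3)
    lengths = {f"G{i}": 2.0 for i in range(6)}
    res = per_gene_case_control(ind, labels, lengths)
    assert (res["q"] >= res["p"] - 1e-12).all()
    assert res["p"].is_monotonic_increasing
    # swapping groups flips direction, keeps p
    res_sw = per_gene_case_control(ind, 1 - labels, lengths)
    merged = res.merge(res_sw, on="gene", suffixes=("_a", "_b"))
    assert np.allclose(merged["p_a"], merged["p_b"], rtol=1e-6)
    assert (merged["direction_a"] == -merged["direction_b"]).all()
    # sample reordering leaves results unchanged
    perm = np.random.default_rng(0).permutation(len(labels))
    res_perm = per_gene_case_control(ind.iloc[perm].reset_index(drop=True),
                                     labels[perm], lengths)
    merged = res.merge(res_perm, on="gene", suffixes=("_a", "_b"))
    assert np.allclose(merged["p_a"], merged["p_b"], rtol=1e-6)


def test_gene_length_adjustment_halves():
    ind, labels = _cohort_indicators(4)
    r1 = per_gene_case_control(ind, labels, {f"G{i}": 1.0 for i in range(6)})
    r2 = per_gene_case_control(ind, labels, {f"G{i}": 2.0 for i in range(6)})
    m = r1.merge(r2, on="gene", suffixes=("_1", "_2"))
    assert np.allclose(m["rate_group1_1"], 2 * m["rate_group1_2"])


def test_unmutated_gene_excluded_and_fractions():
    ind = pd.DataFrame({"G0": [1, 1, 0, 0, 0], "G1": [0, 0, 0, 0, 0]})
    res = per_gene_case_control(ind, [1, 1, 1, 0, 0])
    assert list(res["gene"]) == ["G0"]
    assert res.loc[0, "frac_group1"] == pytest.approx(2 / 3)
    assert res.loc[0, "frac_group2"] == 0.0


def _hotspot_variants(seed=0, n_pdwa=40, n_np=60, rate1=0.5, rate2=0.1):
    rng = np.random.default_rng(seed)
    samples = [f"p{i}" for i in range(n_pdwa)] + [f"n{i}" for i in range(n_np)]
    rows = []
    for i, s in enumerate(samples):
        rate = rate1 if i < n_pdwa else rate2
        if rng.random() < rate:
            rows.append({"sample": s, "gene": "PIK3CA",
                         "protein_change": "p.H1047R", "variant_class": "missense"})
        rows.append({"sample": s, "gene": "TTN", "protein_change": "p.A1B",
                     "variant_class": "missense"})
        rows.append({"sample": s, "gene": "TTN", "protein_change": "p.(=)",
                     "variant_class": "silent"})
    sub = pd.Series([True] * n_pdwa + [False] * n_np, index=samples)
    return pd.DataFrame(rows), sub


def test_subgroup_hotspot_enrichment():
    variants, sub = _hotspot_variants()
    res = subgroup_enrichment(variants, sub, level="hotspot")
    row = res[res["gene"] == "PIK3CA:p.H1047R"].iloc[0]
    assert row["p"] < 0.01 and row["direction"] == 1
    # silent records are excluded by default
    ind = mutation_indicators(variants, sub.index, level="gene")
    assert "TTN" in ind.columns and ind["TTN"].max() == 1
    ind_s = mutation_indicators(variants, sub.index, level="gene",
                                include_silent=True)
    assert ind_s["TTN"].sum() == ind["TTN"].sum()  # indicator, not count
    with pytest.raises(ValueError):
        subgroup_enrichment(variants, sub & False)


def test_min_vaf_secondary_analysis():
    variants, sub = _hotspot_variants()
    variants["vaf"] = 0.1
    variants.loc[variants["gene"] == "TTN", "vaf"] = 0.5
    ind = mutation_indicators(variants, sub.index, level="gene", min_vaf=0.25)
    assert "PIK3CA" not in ind.columns or ind["PIK3CA"].sum() == 0
    assert ind["TTN"].sum() == len(sub)


def test_subgroup_null_uniform_p():
    ps = []
    for s in range(40):
        variants, sub = _hotspot_variants(seed=s, rate1=0.3, rate2=0.3)
        res = subgroup_enrichment(variants, sub, level="hotspot")
        row = res[res["gene"] == "PIK3CA:p.H1047R"]
        if len(row):
            ps.append(row["p"].iloc[0])
    assert 0.3 < np.mean(ps) < 0.85
    assert np.mean(np.array(ps) < 0.05) < 0.2


def test_ser_thr_accounting_oracle():
    rng = np.random.default_rng(5)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    changes = [f"p.{aas[rng.integers(20)]}{rng.integers(1, 500)}{aas[rng.integers(20)]}"
               for _ in range(200)]
    changes = [c for c in changes if c[2] != c[-1]][:150]
    df = pd.DataFrame({"protein_change": changes,
                       "variant_class": "missense"})
    out = ser_thr_accounting(df)
    n = len(df)
    assert out.fractions["loss_S"] == sum(c[2] == "S" for c in changes[:n]) / n
    assert out.fractions["gain_T"] == sum(c[-1] == "T" for c in changes[:n]) / n
    # definitional cases
    one = pd.DataFrame({"protein_change": ["p.S100T"], "variant_class": ["missense"]})
    res = ser_thr_accounting(one)
    assert res.fractions["loss_S"] == 1.0 and res.fractions["gain_T"] == 1.0
    none = ser_thr_accounting(pd.DataFrame(
        {"protein_change": ["p.H1047R"], "variant_class": ["missense"]}))
    assert all(v == 0.0 for v in none.fractions.values())
    with pytest.raises(ValueError):
        ser_thr_accounting(pd.DataFrame(
            {"protein_change": ["p.H1047R"], "variant_class": ["nonsense"]}))
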