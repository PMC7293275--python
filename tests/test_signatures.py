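"""Catalog folding, NMF extraction, signature matching, exposure tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tosca.channels import CHANNELS, fold, unfold
from tosca.signatures import (
    associate_exposure,
    build_catalog,
    cosine_similarity_matrix,
    exposure_group_test,
    extract_signatures,
    match_signatures,
    read_reference,
    reference_signatures,
    select_rank,
    write_reference,
)
from tosca.simulate import default_signatures, simulate_catalogs


def _variant(sample, ref, alt, context, **kw):
    base = {"sample": sample, "chrom": "chr1", "pos": 1, "ref": ref, "alt": alt,
            "context": context}
    base.update(kw)
    return base


def test_fold_matches_brute_force_table():
    """All 192 strand-specific SNV contexts map onto the 96 channels."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seen = {}
    for ref, alt, f5, f3 in itertools.product("ACGT", repeat=4):
        if ref == alt:
            continue
        # independent expectation: complement purine-centered changes
        r, a, five, three = ref, alt, f5, f3
        if r in "AG":
            r, a = comp[r], comp[a]
            five, three = comp[f3], comp[f5]
        expected = f"{five}[{r}>{a}]{three}"
        got = fold(ref, alt, f5 + ref + f3)
        assert got == expected
        seen.setdefault(got, 0)
        seen[got] += 1
    assert set(seen) == set(CHANNELS)
    assert all(v == 2 for v in seen.values())  # two strands per channel


def test_fold_examples_and_errors():
    assert fold("C", "T", "ACA") == "A[C>T]A"
    assert fold("G", "A", "TGA") == "T[C>T]A"
    with pytest.raises(ValueError):
        fold("C", "T", "AAT")  # middle base mismatch
    with pytest.raises(ValueError):
        fold("CA", "T", "ACA")
    ref, alt, ctx = unfold("T[T>G]C")
    assert (ref, alt, ctx) == ("T", "G", "TTC")


def test_build_catalog_counts_and_skips():
    rows = [
        _variant("s1", "C", "T", "ACA"),
        _variant("s1", "G", "A", "TGA"),        # folds to T[C>T]A
        _variant("s1", "C", "T", "AAT"),        # bad context -> skipped
        _variant("s1", "CA", "C", "NNN"),       # indel -> ignored
        _variant("s2", "T", "G", "TTC"),
    ]
    cat = build_catalog(pd.DataFrame(rows))
    assert cat.loc["s1", "A[C>T]A"] == 1
    assert cat.loc["s1", "T[C>T]A"] == 1
    assert cat.loc["s2", "T[T>G]C"] == 1
    assert cat.attrs["n_skipped"] == 1 and cat.attrs["n_non_snv"] == 1
    assert cat.sum().sum() == 3
    empty = build_catalog(pd.DataFrame(rows)[:0].assign(sample=None))
    assert (empty.to_numpy() == 0).all()


def test_folding_conservation(small_cohort):
    v = small_cohort.variants
    som = v[v["true_label"] == "somatic"]
    cat = build_catalog(som)
    snvs = som[(som["ref"].str.len() == 1) & (som["alt"].str.len() == 1)]
    per_sample = snvs.groupby("sample").size()
    assert (cat.sum(axis=1).loc[per_sample.index] == per_sample).all()


def test_rank_selection_noise_free_and_ties():
    H0 = default_signatures()
    rng = np.random.default_rng(0)
    W = rng.dirichlet((4, 2.5, 1.5), 60) * 500
    V = pd.DataFrame(W @ H0.to_numpy(), columns=list(CHANNELS))
    k, rss = select_rank(V, range(2, 7), seed=0)
    assert k == 3
    assert rss[3] < rss[2] and set(rss) == {2, 3, 4, 5, 6}
    with pytest.raises(ValueError):
        select_rank(V, [2, 3], seed=0)


def test_rank_selection_degenerate_flat_curve():
    flat = pd.DataFrame(np.ones((10, 96)), columns=list(CHANNELS))
    with pytest.warns(UserWarning, match="flat"):
        k, _ = select_rank(flat, [2, 3, 4], seed=0)
    assert k == 2


def test_extract_shapes_and_degenerate_single_channel():
    cat, _ = simulate_catalogs(default_signatures(), (4, 2.5, 1.5), 50, 100, seed=3)
    sigs = extract_signatures(cat, 3, restarts=3, seed=0)
    assert sigs.W.shape == (50, 3) and sigs.H.shape == (3, 96)
    assert np.allclose(sigs.H.sum(axis=1), 1.0, atol=1e-9)
    assert (sigs.W.to_numpy() >= 0).all() and (sigs.H.to_numpy() >= 0).all()
    single = pd.DataFrame(0.0, index=["a", "b"], columns=list(CHANNELS))
    single["A[C>T]A"] = [30.0, 50.0]
    s1 = extract_signatures(single, 1, restarts=2, seed=0)
    assert s1.H.loc[s1.H.index[0], "A[C>T]A"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        extract_signatures(single, 5, seed=0)
    with pytest.raises(ValueError):
        extract_signatures(single.iloc[:0], 1, seed=0)


def test_extraction_recovers_planted_factors():
    """Noise-free W0 @ H0 input: assigned cosine >= 0.99 per signature.

    Exact NMF recovery is only well-posed for an identifiable construction:
    signatures with disjoint supports (no shared background mass) and an
    exposure matrix containing near-pure anchor samples.
    """
    H0 = default_signatures()
    H0 = H0.where(H0.gt(1.1 * H0.min(axis=1), axis=0), 0.0)
    H0 = H0.div(H0.sum(axis=1), axis=0)
    assert ((H0.to_numpy() > 0).sum(axis=0) <= 1).all()  # supports disjoint
    rng = np.random.default_rng(1)
    W0 = np.vstack([rng.dirichlet((4, 2.5, 1.5), 80), np.eye(3), np.eye(3)]) * 400
    V = pd.DataFrame(W0 @ H0.to_numpy(), columns=list(CHANNELS))
    sigs = extract_signatures(V, 3, restarts=10, seed=1, max_iter=5000, tol=1e-10)
    C = cosine_similarity_matrix(sigs.H, H0)
    from scipy.optimize import linear_sum_assignment
    ri, ci = linear_sum_assignment(-C.to_numpy())
    assert (C.to_numpy()[ri, ci] >= 0.99).all()


def test_match_signatures_identity_permutation_uncatalogued():
    ref = reference_signatures()
    out = match_signatures(ref, ref)
    assert (out["cosine"] > 0.999).all()
    assert list(out["matched_reference"]) == list(ref.index)
    perm = ref.iloc[[2, 0, 3, 1]]
    out = match_signatures(perm, ref)
    assert list(out["matched_reference"]) == list(perm.index)
    # planted novel signature: flat profile matches nothing above 0.8
    novel = pd.DataFrame([np.ones(96) / 96], index=["novel"], columns=ref.columns)
    H = pd.concat([ref.iloc[:1], novel])
    out = match_signatures(H, ref, threshold=0.8)
    assert bool(out.loc["novel", "uncatalogued"])
    assert not bool(out.loc[ref.index[0], "uncatalogued"])
    with pytest.raises(ValueError):
        match_signatures(ref, ref.iloc[:0])


def test_reference_roundtrip(tmp_path):
    ref = reference_signatures()
    write_reference(ref, tmp_path / "ref.tsv")
    back = read_reference(tmp_path / "ref.tsv")
    pd.testing.assert_frame_equal(back, ref, check_names=False)


def test_associate_exposure_constant_flagged():
    y = np.array([0, 1] * 20)
    out = associate_exposure(pd.Series(np.ones(40)), y)
    assert out.inestimable and np.isnan(out.effect)
    with pytest.raises(ValueError):
        associate_exposure(pd.Series(np.arange(40.0)), np.zeros(40))


def test_associate_exposure_wald_ci_coverage():
    """Planted logistic effect beta=1.5 at n=204: 95% CI coverage ~0.95."""
    rng = np.random.default_rng(7)
    covered = 0
    sims = 200
    for _ in range(sims):
        x = rng.normal(size=204)
        y = rng.random(204) < 1 / (1 + np.exp(-(-0.5 + 1.5 * x)))
        res = associate_exposure(pd.Series(x), y.astype(float), standardize=False)
        covered += res.ci[0] <= 1.5 <= res.ci[1]
    assert 0.89 <= covered / sims <= 0.99


def test_associate_exposure_separation_fallback():
    x = np.r_[np.zeros(20), np.ones(20) * 5]
    y = np.r_[np.zeros(20), np.ones(20)]
    out = associate_exposure(pd.Series(x), y)
    assert out.separation and np.isnan(out.p) and out.effect > 0


def test_exposure_group_test_symmetry_and_null():
    rng = np.random.default_rng(3)
    x = pd.Series(rng.normal(size=40))
    g = np.array([True] * 18 + [False] * 22)
    a = exposure_group_test(x, g)
    b = exposure_group_test(x, ~g)
    assert a.p == pytest.approx(b.p)
    assert a.means == (b.means[1], b.means[0])
    lo, hi = a.cis[0]
    assert lo < a.means[0] < hi
    with pytest.raises(ValueError):
        exposure_group_test(x, np.array([True] + [False] * 39))
    # null: p roughly uniform -> not systematically tiny
    ps = []
    for s in range(60):
        r = np.random.default_rng(s)
        ps.append(exposure_group_test(pd.Series(r.normal(size=30)),
                                      r.random(30) < 0.5).p)
    ps = [p for p in ps if not np.isnan(p)]
    assert 0.3 < np.mean(ps) < 0.7
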