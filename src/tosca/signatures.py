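"""Mutational-signature extraction and exposure association.

Per-sample catalogs of single-base substitutions in trinucleotide context
(96 pyrimidine-centered channels, COSMIC order) are factorized with
non-negative matrix factorization under Frobenius loss. The number of
signatures is chosen at the inflection of the residual-sum-of-squares curve
over candidate ranks, operationalized as the rank maximizing the discrete
second difference RSS(k-1) - 2 RSS(k) + RSS(k+1) (ties break to the smallest
rank). Extracted signatures are matched to a reference catalog one-to-one by
maximum total cosine similarity; signatures below a similarity threshold are
flagged uncatalogued. Signature exposures (attributed mutation counts) are
tested against phenotypes by covariate-adjusted logistic regression and by
Welch two-sample tests between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .channels import CHANNELS, fold


def build_catalog(variants: pd.DataFrame) -> pd.DataFrame:
    """Bin each sample's SNVs into the 96 channels.

    Non-SNV records are ignored; SNVs whose context middle base does not
    match the reference allele are skipped and counted in the returned
    frame's ``attrs['n_skipped']`` (``attrs['n_non_snv']`` holds the indel
    count). Row sums equal each sample's number of valid-context SNVs.
    """
    samples = list(dict.fromkeys(variants["sample"]))
    ref = variants["ref"].astype(str)
    alt = variants["alt"].astype(str)
    is_snv = (ref.str.len() == 1) & (alt.str.len() == 1)
    n_non_snv = int((~is_snv).sum())
    snv = variants[is_snv]
    # fold each distinct (ref, alt, context) once, then map
    triples = pd.MultiIndex.from_arrays(
        [snv["ref"].astype(str), snv["alt"].astype(str),
         snv["context"].astype(str)]
    )
    memo: dict[tuple, str | None] = {}
    for t in triples.unique():
        try:
            memo[t] = fold(*t)
        except ValueError:
            memo[t] = None
    channel = pd.Series(triples.map(memo.get), index=snv.index)
    n_skipped = int(channel.isna().sum())
    kept = snv[channel.notna()]
    mat = (
        pd.crosstab(kept["sample"], channel.dropna())
        .reindex(index=samples, columns=list(CHANNELS), fill_value=0)
        .astype(int)
    )
    mat.index.name = None
    mat.columns.name = None
    mat.attrs["n_non_snv"] = n_non_snv
    mat.attrs["n_skipped"] = n_skipped
    return mat


@dataclass
class SignatureSet:
    """NMF factorization of a catalog: H rows are probability profiles
    (sum 1), W holds attributed counts so that W @ H reconstructs the
    catalog up to ``reconstruction_error`` (Frobenius)."""

    W: pd.DataFrame
    H: pd.DataFrame
    rank: int
    reconstruction_error: float
    rss_by_rank: dict[int, float] = field(default_factory=dict)
    seed: int = 0


def _nmf_best(V: np.ndarray, k: int, seed: int, restarts: int,
              max_iter: int, tol: float):
    """Best-of-restarts NMF (multiplicative updates, Frobenius loss)."""
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for r in range(restarts):
            model = NMF(
                n_components=k, init="random", solver="mu",
                beta_loss="frobenius", max_iter=max_iter, tol=tol,
                random_state=(seed * 1009 + r) % (2**31 - 1),
            )
            W = model.fit_transform(V)
            if best is None or model.reconstruction_err_ < best[0]:
                best = (model.reconstruction_err_, W, model.components_)
    return best


def select_rank(
    catalog: pd.DataFrame,
    candidate_ranks,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> tuple[int, dict[int, float]]:
    """Choose the signature count at the RSS curve's inflection.

    Fits NMF at each candidate rank, records RSS, and returns the interior
    rank maximizing the discrete second difference of RSS (first/most convex
    bend), with ties to the smallest rank. A flat RSS curve degenerates to
    the smallest candidate, with a warning. Returns (k, rss_by_rank).
    """
    ranks = sorted(set(int(k) for k in candidate_ranks))
    if len(ranks) < 3:
        raise ValueError("need at least 3 candidate ranks")
    V = catalog.to_numpy(dtype=float)
    rss = {
        k: _nmf_best(V, k, seed, restarts, max_iter, tol)[0] ** 2 for k in ranks
    }
    values = np.array(list(rss.values()))
    flat_tol = 1e-9 * max(float((V ** 2).sum()), 1.0)
    if values.max() - values.min() <= flat_tol:
        warnings.warn("RSS curve is flat; returning smallest candidate rank")
        return ranks[0], rss
    second = {
        k: rss[lo] - 2 * rss[k] + rss[hi]
        for lo, k, hi in zip(ranks, ranks[1:], ranks[2:])
    }
    best = max(second, key=lambda k: (second[k], -k))
    return best, rss


def extract_signatures(
    catalog: pd.DataFrame,
    k: int,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> SignatureSet:
    """Best-of-restarts NMF factorization at rank ``k``.

    H rows are normalized to sum 1 and W rescaled so W @ H is unchanged.
    Deterministic given ``seed``.
    """
    if catalog.empty:
        raise ValueError("catalog is empty")
    if k < 1 or k > min(catalog.shape):
        raise ValueError(f"rank {k} outside [1, {min(catalog.shape)}]")
    V = catalog.to_numpy(dtype=float)
    err, W, H = _nmf_best(V, k, seed, restarts, max_iter, tol)
    scale = H.sum(axis=1)
    scale[scale == 0] = 1.0
    Hn = H / scale[:, None]
    Wn = W * scale[None, :]
    names = [f"signature_{i+1}" for i in range(k)]
    return SignatureSet(
        W=pd.DataFrame(Wn, index=catalog.index, columns=names),
        H=pd.DataFrame(Hn, index=names, columns=catalog.columns),
        rank=k,
        reconstruction_error=float(err),
        seed=seed,
    )


def cosine_similarity_matrix(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity between rows of A and rows of B."""
    a = A.to_numpy(dtype=float)
    b = B.to_numpy(dtype=float)
    an = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-300)
    bn = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-300)
    return pd.DataFrame(an @ bn.T, index=A.index, columns=B.index)


def match_signatures(
    H: pd.DataFrame,
    reference: pd.DataFrame,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """One-to-one assignment of extracted signatures to reference profiles.

    Maximizes total cosine similarity via optimal bipartite matching.
    Signatures whose best-assigned cosine falls below ``threshold`` are
    flagged ``uncatalogued``. Returns a frame with one row per extracted
    signature: assigned reference, cosine, uncatalogued flag.
    """
    if reference.empty:
        raise ValueError("reference signature matrix is empty")
    C = cosine_similarity_matrix(H, reference)
    ri, ci = linear_sum_assignment(-C.to_numpy())
    assigned = {int(r): int(c) for r, c in zip(ri, ci)}
    rows = []
    for i, name in enumerate(H.index):
        if i in assigned:
            ref_name = reference.index[assigned[i]]
            cos = float(C.iloc[i, assigned[i]])
        else:  # more extracted signatures than references
            ref_name, cos = None, float(C.iloc[i].max())
        rows.append({
            "signature": name,
            "matched_reference": ref_name if cos >= threshold else None,
            "cosine": cos,
            "uncatalogued": cos < threshold,
        })
    return pd.DataFrame(rows).set_index("signature")


def reference_signatures() -> pd.DataFrame:
    """A small synthetic reference catalog for matching tests and demos.

    Contains aging-like and MMR-like profiles (matching the simulator's
    planted truth) plus UV-like and APOBEC-like decoys. Synthetic stand-ins
    for a curated signature catalog — not COSMIC values.
    """
    from .channels import CHANNEL_INDEX
    from .simulate import default_signatures

    H0 = default_signatures()
    uv = np.full(96, 0.15 / 96)
    apobec = np.full(96, 0.2 / 96)
    for f in "CT":
        for t in "ACGT":
            uv[CHANNEL_INDEX[f"{f}[C>T]{t}"]] += 0.85 / 8
    for f in "T":
        for t in "ACGT":
            apobec[CHANNEL_INDEX[f"{f}[C>T]{t}"]] += 0.4 / 4
            apobec[CHANNEL_INDEX[f"{f}[C>G]{t}"]] += 0.4 / 4
    ref = pd.DataFrame(
        [H0.loc["aging-like"], H0.loc["MMR-like"],
         pd.Series(uv / uv.sum(), index=H0.columns),
         pd.Series(apobec / apobec.sum(), index=H0.columns)],
        index=["ref_aging", "ref_MMR", "ref_UV", "ref_APOBEC"],
    )
    return ref


def write_reference(reference: pd.DataFrame, path) -> None:
    """Write a signature catalog as a COSMIC-style 96-row TSV."""
    reference.T.rename_axis("Trinucleotide").to_csv(path, sep="\t")


def read_reference(path) -> pd.DataFrame:
    ref = pd.read_csv(path, sep="\t", index_col=0).T
    ref.columns.name = None
    return ref[list(CHANNELS)]


@dataclass
class ExposureAssociation:
    effect: float                # log-odds per SD (standardized) or per unit
    ci: tuple[float, float]
    p: float
    n: int
    standardized: bool
    separation: bool = False
    inestimable: bool = False


def associate_exposure(
    exposure: pd.Series,
    outcome,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
) -> ExposureAssociation:
    """Logistic regression of a binary outcome on a signature exposure.

    Covariates (age, menopausal status, histology class, ...) are added as
    given; categorical columns are dummy-coded. Returns the Wald effect
    estimate, 95% CI and two-sided p for the exposure term. A constant
    exposure is flagged inestimable; perfect separation falls back to an
    L2-penalized fit, flagged, with no p-value.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if np.std(x) == 0:
        return ExposureAssociation(np.nan, (np.nan, np.nan), np.nan, len(y),
                                   standardize, inestimable=True)
    if standardize:
        x = (x - x.mean()) / x.std()
    X = pd.DataFrame({"exposure": x})
    if covariates is not None:
        cov = pd.get_dummies(covariates.reset_index(drop=True), drop_first=True)
        X = pd.concat([X, cov.astype(float)], axis=1)
    X = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False) or np.isnan(res.bse["exposure"]) \
                or res.bse["exposure"] > 1e3:
            raise np.linalg.LinAlgError("non-converged")
        lo, hi = res.conf_int().loc["exposure"]
        return ExposureAssociation(
            effect=float(res.params["exposure"]), ci=(float(lo), float(hi)),
            p=float(res.pvalues["exposure"]), n=len(y), standardized=standardize,
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError,
            ValueError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        return ExposureAssociation(
            effect=float(res.params["exposure"]), ci=(np.nan, np.nan), p=np.nan,
            n=len(y), standardized=standardize, separation=True,
        )


@dataclass
class GroupTest:
    p: float
    means: tuple[float, float]          # (group True/1, group False/0)
    cis: tuple[tuple[float, float], tuple[float, float]]
    n: tuple[int, int]


def exposure_group_test(exposure: pd.Series, group) -> GroupTest:
    """Welch two-sample test of exposures between two groups.

    Returns the two-sided p, per-group means and 95% t confidence
    intervals. Requires both groups to have at least 2 samples.
    """
    x = np.asarray(exposure, dtype=float)
    g = np.asarray(group).astype(bool)
    a, b = x[g], x[~g]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t = stats.ttest_ind(a, b, equal_var=False)

    def ci(v):
        m, se = v.mean(), stats.sem(v)
        h = se * stats.t.ppf(0.975, len(v) - 1)
        return (float(m - h), float(m + h))

    return GroupTest(
        p=float(t.pvalue),
        means=(float(a.mean()), float(b.mean())),
        cis=(ci(a), ci(b)),
        n=(len(a), len(b)),
    )
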