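"""Case-control and subgroup mutation-enrichment statistics.

Per-gene enrichment fits a logistic regression of group membership on the
sample's mutation indicator and reports the Wald p-value; when the fit is
degenerate (zero cell or separation) an exact Fisher test replaces it.
Hotspot-level analyses group variants by (gene, protein change). Gene rates
can be adjusted by coding length (mutations per sample per kb). P-values are
converted to false-discovery rates with Benjamini-Hochberg.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

NON_SILENT = ("missense", "nonsense", "frameshift", "stop_gain", "splice")

PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z*])$")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _two_group_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, str]:
    """Two-sided p for a difference in mutated fractions.

    Logistic Wald is primary; Fisher exact replaces it on zero cells,
    separation, or non-convergence. Returns (p, method).
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if min(k1, n1 - k1, k2, n2 - k2) == 0:
        return float(fisher_exact(table)[1]), "fisher"
    y = np.r_[np.ones(n1), np.zeros(n2)]
    x = np.zeros(n1 + n2)
    x[:k1] = 1.0
    x[n1:n1 + k2] = 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", False) or res.bse[1] > 1e3:
            raise np.linalg.LinAlgError
        return float(res.pvalues[1]), "logit_wald"
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError,
            ValueError):
        return float(fisher_exact(table)[1]), "fisher"


@dataclass
class GeneTestResult:
    gene: str
    frac_group1: float
    frac_group2: float
    direction: int              # +1 enriched in group 1, -1 in group 2, 0 tie
    p: float
    log10_p: float
    q: float
    method: str
    rate_group1: float | None   # mutations / sample / kb
    rate_group2: float | None


def per_gene_case_control(
    indicators: pd.DataFrame,
    labels,
    gene_lengths_kb: pd.Series | dict | None = None,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene enrichment between two groups of samples.

    ``indicators`` is samples x genes (0/1 mutated); ``labels`` is a boolean
    or 0/1 vector marking group 1 (cases). Genes mutated in no sample are
    excluded. ``counts`` (samples x genes mutation counts, default =
    indicators) feeds the length-adjusted rates when ``gene_lengths_kb`` is
    given; genes with no known length get no adjusted rate. Results are
    sorted by p with BH q-values computed over the tested genes.
    """
    y = np.asarray(labels).astype(bool)
    if counts is None:
        counts = indicators
    lengths = pd.Series(gene_lengths_kb, dtype=float) if gene_lengths_kb is not None else None
    n1, n2 = int(y.sum()), int((~y).sum())
    rows = []
    for gene in indicators.columns:
        col = indicators[gene].to_numpy().astype(bool)
        if not col.any():
            continue
        k1, k2 = int(col[y].sum()), int(col[~y].sum())
        p, method = _two_group_test(k1, n1, k2, n2)
        f1, f2 = k1 / n1 if n1 else np.nan, k2 / n2 if n2 else np.nan
        r1 = r2 = None
        if lengths is not None and gene in lengths.index and lengths[gene] > 0:
            c = counts[gene].to_numpy(dtype=float)
            r1 = float(c[y].mean() / lengths[gene]) if n1 else None
            r2 = float(c[~y].mean() / lengths[gene]) if n2 else None
        rows.append(GeneTestResult(
            gene=gene, frac_group1=f1, frac_group2=f2,
            direction=int(np.sign(f1 - f2)), p=p,
            log10_p=float(np.log10(p)) if p > 0 else -np.inf,
            q=np.nan, method=method, rate_group1=r1, rate_group2=r2,
        ))
    out = pd.DataFrame([vars(r) for r in rows])
    if out.empty:
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def mutation_indicators(
    variants: pd.DataFrame,
    samples,
    level: str = "gene",
    include_silent: bool = False,
    min_vaf: float | None = None,
) -> pd.DataFrame:
    """Samples x units 0/1 indicator matrix at gene or hotspot level.

    Hotspot level groups by (gene, protein change), labeled
    ``GENE:p.CHANGE``. Silent variants are excluded by default; rows cover
    ``samples`` even when unmutated. ``min_vaf`` restricts to variants with
    VAF strictly above the threshold (the "VAF > 25%" secondary analysis).
    """
    v = variants
    if not include_silent:
        v = v[v["variant_class"].isin(NON_SILENT)]
    if min_vaf is not None:
        v = v[v["vaf"] > min_vaf]
    if level == "gene":
        unit = v["gene"].astype(str)
    elif level == "hotspot":
        unit = v["gene"].astype(str) + ":" + v["protein_change"].astype(str)
    else:
        raise ValueError(f"unknown level {level!r}")
    tab = (
        pd.crosstab(v["sample"], unit).clip(upper=1)
        .reindex(list(samples), fill_value=0)
    )
    tab.columns.name = None
    tab.index.name = "sample"
    return tab


def subgroup_enrichment(
    variants: pd.DataFrame,
    subgroup: pd.Series,
    level: str = "gene",
    include_silent: bool = False,
    gene_lengths_kb=None,
    min_vaf: float | None = None,
) -> pd.DataFrame:
    """Enrichment between two histology subgroups (e.g. PDWA vs NP).

    ``subgroup`` is a boolean per-sample series (True = subgroup 1, indexed
    by sample id); both subgroups must be non-empty. Hotspot rows with an
    unparseable protein change are excluded and counted in
    ``attrs['n_unparseable']``.
    """
    g = subgroup.astype(bool)
    if not g.any() or g.all():
        raise ValueError("both subgroups must be non-empty")
    n_unparseable = 0
    v = variants[variants["sample"].isin(g.index)]
    if level == "hotspot":
        parseable = v["protein_change"].astype(str).str.match(
            r"^p\.[A-Z*]\w*\d+", na=False
        )
        n_unparseable = int((~parseable).sum())
        v = v[parseable]
    ind = mutation_indicators(v, g.index, level=level,
                              include_silent=include_silent, min_vaf=min_vaf)
    res = per_gene_case_control(ind, g.loc[ind.index], gene_lengths_kb)
    res.attrs["n_unparseable"] = n_unparseable
    return res


@dataclass
class SerThrAccounting:
    fractions: dict             # loss_S, loss_T, gain_S, gain_T over missense set
    n_missense: int
    p_case_control: float | None


def ser_thr_accounting(
    missense: pd.DataFrame, case_mask=None
) -> SerThrAccounting:
    """Serine/threonine gain-loss accounting over one gene's missense set.

    Protein changes must parse as p.<refAA><pos><altAA>; a p.S100T counts as
    both loss-of-serine and gain-of-threonine. With ``case_mask`` given, a
    Fisher exact test compares the count of Ser/Thr-affecting mutations
    between cases and controls.
    """
    if (~missense["variant_class"].eq("missense")).any():
        raise ValueError("input must contain only missense records")
    parsed = []
    for pc in missense["protein_change"].astype(str):
        m = PROTEIN_CHANGE_RE.match(pc)
        if not m:
            raise ValueError(f"unparseable protein change {pc!r}")
        parsed.append((m.group(1), m.group(3)))
    n = len(parsed)
    frac = {
        "loss_S": sum(r == "S" for r, a in parsed) / n if n else 0.0,
        "loss_T": sum(r == "T" for r, a in parsed) / n if n else 0.0,
        "gain_S": sum(a == "S" for r, a in parsed) / n if n else 0.0,
        "gain_T": sum(a == "T" for r, a in parsed) / n if n else 0.0,
    }
    p = None
    if case_mask is not None and n:
        mask = np.asarray(case_mask).astype(bool)
        affecting = np.array([r in "ST" or a in "ST" for r, a in parsed])
        table = [
            [int(affecting[mask].sum()), int((~affecting)[mask].sum())],
            [int(affecting[~mask].sum()), int((~affecting)[~mask].sum())],
        ]
        p = float(fisher_exact(table)[1])
    return SerThrAccounting(fractions=frac, n_missense=n, p_case_control=p)
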