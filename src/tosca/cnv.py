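"""Gene-level deletion calls from CNV segments and their associations.

A gene is called deleted in a sample when at least a configurable fraction of
its interval (default 0.5) is covered by segments whose log2 copy ratio falls
at or below a threshold (default -0.3). Deletion status is then tested
against signature exposures (Welch test, delegated to
:func:`tosca.signatures.exposure_group_test`) and summarized alongside
deleterious mutations in the mismatch-repair gene set.
"""

from __future__ import annotations

import pandas as pd

from .signatures import GroupTest, exposure_group_test
from .simulate import GENE_CATALOG, MMR_GENES

DELETERIOUS_CLASSES = ("nonsense", "frameshift", "stop_gain", "splice")

DEFAULT_LOG2_THRESHOLD = -0.3
DEFAULT_MIN_OVERLAP = 0.5


def gene_intervals(genes=None) -> pd.DataFrame:
    """(gene, chrom, start, end) intervals from the built-in synthetic catalog."""
    genes = list(genes) if genes is not None else list(GENE_CATALOG)
    rows = [
        {"gene": g, "chrom": GENE_CATALOG[g][0], "start": GENE_CATALOG[g][1],
         "end": GENE_CATALOG[g][2]}
        for g in genes
    ]
    return pd.DataFrame(rows)


def _covered_fraction(seg_starts, seg_ends, start: int, end: int) -> float:
    """Fraction of [start, end] (1-based inclusive) covered by the union of
    the given segments."""
    ivals = sorted(
        (max(s, start), min(e, end))
        for s, e in zip(seg_starts, seg_ends)
        if min(e, end) >= max(s, start)
    )
    covered, cur_s, cur_e = 0, None, None
    for s, e in ivals:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered / (end - start + 1)


def call_gene_deletion(
    segments: pd.DataFrame,
    genes: pd.DataFrame,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-sample x gene deletion indicator matrix.

    ``segments`` has columns sample/chrom/start/end/log2 (1-based inclusive);
    ``genes`` has gene/chrom/start/end. Unknown segment chromosomes (absent
    from the gene table's assembly) are tolerated, but gene chromosomes
    absent from the segment table's chromosome set raise, listing them,
    to surface assembly mismatches.
    """
    seg_chroms = set(segments["chrom"].astype(str))
    missing = sorted(set(genes["chrom"].astype(str)) - seg_chroms) if len(segments) else []
    if missing and len(segments):
        raise ValueError(f"gene chromosomes absent from segments: {missing}")
    samples = list(dict.fromkeys(segments["sample"]))
    dele = segments[segments["log2"] <= log2_threshold]
    out = pd.DataFrame(False, index=samples, columns=list(genes["gene"]))
    for gene_row in genes.itertuples():
        sub = dele[dele["chrom"] == gene_row.chrom]
        for sample, seg in sub.groupby("sample"):
            frac = _covered_fraction(
                seg["start"].to_numpy(), seg["end"].to_numpy(),
                gene_row.start, gene_row.end,
            )
            if frac >= min_overlap:
                out.loc[sample, gene_row.gene] = True
    out.index.name = "sample"
    return out


def deletion_frequencies(deletion_matrix: pd.DataFrame) -> pd.Series:
    """Per-gene "deleted in k of n samples" summary as 'k/n' strings."""
    n = len(deletion_matrix)
    return deletion_matrix.sum(axis=0).map(lambda k: f"{int(k)}/{n}")


def deletion_signature_association(
    deleted: pd.Series, exposure: pd.Series
) -> GroupTest:
    """Welch test of a signature exposure between deleted and intact samples."""
    d = deleted.astype(bool)
    if d.all() or not d.any():
        raise ValueError("deletion status is constant; association undefined")
    exposure = exposure.loc[d.index]
    return exposure_group_test(exposure, d)


def mmr_gene_mutation_summary(
    variants: pd.DataFrame,
    genes=MMR_GENES,
    deleterious_classes=DELETERIOUS_CLASSES,
    damaging_missense_sift: float = 0.05,
) -> tuple[pd.Series, pd.Series]:
    """Deleterious mismatch-repair-gene mutation status per sample.

    A variant is deleterious when its class is in ``deleterious_classes`` or
    it is a missense call with SIFT <= ``damaging_missense_sift``. Returns
    (per-sample boolean indexed by sample, per-gene deleterious counts).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    v = variants[variants["gene"].isin(genes)]
    cls = v["variant_class"].astype(str)
    deleterious = cls.isin(deleterious_classes)
    if "sift" in v.columns:
        deleterious |= cls.eq("missense") & (
            pd.to_numeric(v["sift"], errors="coerce") <= damaging_missense_sift
        )
    hits = v[deleterious]
    all_samples = list(dict.fromkeys(variants["sample"]))
    per_sample = pd.Series(False, index=all_samples, name="mmr_deleterious")
    per_sample[hits["sample"].unique()] = True
    per_gene = hits.groupby("gene").size().reindex(genes, fill_value=0)
    return per_sample, per_gene
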