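"""Variant table I/O, hard filters, and classifier feature assembly.

A *variant table* is a pandas DataFrame with one row per (sample, chrom, pos,
ref, alt) ALT allele, carrying sequencing features (VAF, depths), annotations
(gene, protein change, variant class, trinucleotide context, population AF,
dbSNP-common flag, somatic-catalog count, pathogenicity scores, domain) and an
optional truth label. Coordinates are 1-based, VCF convention.

Two hard filters precede classification: a panel-of-normals (PON) filter that
removes any site observed in at least 2 normal samples, and a total-depth
filter removing records with depth < 20 reads. The 31-column feature schema
for the somatic/germline classifier is assembled here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import KEY, PATHOGENICITY_SCORES

SITE = ["chrom", "pos", "ref", "alt"]

#: variant classes receiving one-hot columns in the feature schema
VARIANT_CLASSES = (
    "missense", "silent", "nonsense", "frameshift", "splice",
    "inframe_indel", "stop_gain", "other",
)
BASE_CHANGES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the default 31-column classifier feature schema
FEATURE_SCHEMA: tuple[str, ...] = (
    "vaf", "alt_depth", "ref_depth", "total_depth",
    "cohort_recurrence", "population_af", "dbsnp_common",
    "cosmic_present", "cosmic_count",
    *PATHOGENICITY_SCORES,
    *(f"class_{c}" for c in VARIANT_CLASSES),
    *(f"change_{c.replace('>', '')}" for c in BASE_CHANGES),
    "context_gc", "homopolymer",
)
assert len(FEATURE_SCHEMA) == 31


def read_variants(vcf_path: str | Path, sidecar_path: str | Path) -> pd.DataFrame:
    """Read one sample's VCF plus its feature sidecar CSV into a variant table.

    Multi-allelic records are split into one row per ALT allele. The sidecar
    is joined on (sample, chrom, pos, ref, alt); sidecar keys with no VCF
    record (or vice versa) raise with the orphan keys listed.
    """
    vcf_path, sidecar_path = Path(vcf_path), Path(sidecar_path)
    rows = []
    for rec in VCF(str(vcf_path)):
        for alt in rec.ALT:
            rows.append({
                "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": alt,
            })
    calls = pd.DataFrame(rows, columns=SITE)
    sidecar = pd.read_csv(sidecar_path)
    missing = [k for k in KEY if k not in sidecar.columns]
    if missing:
        raise ValueError(f"sidecar lacks key columns: {missing}")
    sample = vcf_path.stem
    side = sidecar[sidecar["sample"] == sample]
    merged = calls.merge(side, on=SITE, how="outer", indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        keys = orphans[SITE].head(10).to_dict(orient="records")
        raise ValueError(
            f"{len(orphans)} unmatched keys between VCF and sidecar, e.g. {keys}"
        )
    out = merged.drop(columns="_merge")
    out["sample"] = sample
    return out[[c for c in side.columns]].reset_index(drop=True)


@dataclass(frozen=True)
class PanelOfNormals:
    """Blacklist of sites observed in >= 2 contributing normal samples."""

    sites: frozenset[tuple]
    n_normals: int

    def __contains__(self, site: tuple) -> bool:
        return site in self.sites


def build_pon(normal_call_sets: list) -> PanelOfNormals:
    """Build a panel of normals from per-normal site sets.

    A site (chrom, pos, ref, alt) enters the PON iff it is present in at
    least 2 distinct normals. Order-independent and idempotent; an empty
    list yields an empty PON.
    """
    counts: dict[tuple, int] = {}
    for call_set in normal_call_sets:
        for site in set(map(tuple, call_set)):
            counts[site] = counts.get(site, 0) + 1
    sites = frozenset(s for s, c in counts.items() if c >= 2)
    return PanelOfNormals(sites=sites, n_normals=len(normal_call_sets))


def apply_pon(table: pd.DataFrame, pon: PanelOfNormals) -> pd.DataFrame:
    """Remove records whose (chrom, pos, ref, alt) is in the PON; order kept."""
    if not pon.sites or table.empty:
        return table.copy()
    keys = list(map(tuple, table[SITE].itertuples(index=False, name=None)))
    keep = [k not in pon.sites for k in keys]
    return table[keep].copy()


def filter_depth(table: pd.DataFrame, min_depth: int = 20) -> pd.DataFrame:
    """Remove records with total read depth below ``min_depth`` (boundary kept)."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    return table[table["total_depth"] >= min_depth].copy()


def write_pon(pon: PanelOfNormals, path: str | Path) -> None:
    """Serialize a PON as a sorted TSV of sites."""
    df = pd.DataFrame(sorted(pon.sites), columns=SITE)
    with open(path, "w") as fh:
        fh.write(f"#normals={pon.n_normals}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pon(path: str | Path) -> PanelOfNormals:
    with open(path) as fh:
        header = fh.readline()
        n = int(header.strip().split("=")[1]) if header.startswith("#normals=") else 0
        df = pd.read_csv(fh, sep="\t")
    return PanelOfNormals(
        sites=frozenset(map(tuple, df.itertuples(index=False, name=None))),
        n_normals=n,
    )


def _is_homopolymer(context: str) -> int:
    c = str(context).upper()
    return int(len(c) == 3 and c[0] == c[1] == c[2])


def _base_change(ref: str, alt: str) -> str | None:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if len(str(ref)) != 1 or len(str(alt)) != 1 or ref == alt:
        return None
    if ref not in comp or alt not in comp:
        return None
    if ref in "AG":
        ref, alt = comp[ref], comp[alt]
    return f"{ref}>{alt}"


def assemble_features(
    table: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    schema: tuple[str, ...] = FEATURE_SCHEMA,
) -> pd.DataFrame:
    """Build the numeric classifier feature matrix for ``table``.

    ``cohort`` (default: ``table`` itself) supplies the cohort-recurrence
    count: the number of distinct cohort samples carrying the identical
    (chrom, pos, ref, alt). Categorical annotations are one-hot encoded per
    the schema; missing numeric annotations are imputed with the column
    median (all-missing columns fall back to 0), so the output is total.
    """
    unknown = set(schema) - set(FEATURE_SCHEMA)
    if unknown:
        raise ValueError(f"unknown schema columns: {sorted(unknown)}")
    if cohort is None:
        cohort = table
    rec = (
        cohort.drop_duplicates(KEY)
        .groupby(SITE, sort=False)
        .size()
        .rename("cohort_recurrence")
    )
    out = pd.DataFrame(index=table.index)
    joined = table[SITE].merge(
        rec.reset_index(), on=SITE, how="left"
    )["cohort_recurrence"].to_numpy()
    numeric = {
        "vaf": "vaf", "alt_depth": "alt_depth", "ref_depth": "ref_depth",
        "total_depth": "total_depth", "population_af": "population_af",
        "dbsnp_common": "dbsnp_common", "cosmic_count": "cosmic_count",
        **{s: s for s in PATHOGENICITY_SCORES},
    }
    for feat, col in numeric.items():
        if feat in schema:
            if col in table.columns:
                vals = pd.to_numeric(table[col], errors="coerce")
            else:
                vals = pd.Series(np.nan, index=table.index)
            med = vals.median() if vals.notna().any() else np.nan
            out[feat] = vals.fillna(0.0 if pd.isna(med) else med).to_numpy()
    if "cohort_recurrence" in schema:
        out["cohort_recurrence"] = np.nan_to_num(joined, nan=0.0)
    if "cosmic_present" in schema:
        cc = (pd.to_numeric(table["cosmic_count"], errors="coerce")
              if "cosmic_count" in table.columns
              else pd.Series(0.0, index=table.index))
        out["cosmic_present"] = (cc.fillna(0) > 0).astype(float)
    vclass = table.get("variant_class", pd.Series("other", index=table.index)).astype(str)
    vclass = vclass.where(vclass.isin(VARIANT_CLASSES), "other")
    for c in VARIANT_CLASSES:
        name = f"class_{c}"
        if name in schema:
            out[name] = (vclass == c).astype(float)
    changes = [
        _base_change(r, a) for r, a in zip(table["ref"], table["alt"])
    ]
    for c in BASE_CHANGES:
        name = f"change_{c.replace('>', '')}"
        if name in schema:
            out[name] = np.array([ch == c for ch in changes], dtype=float)
    ctx = table.get("context", pd.Series("", index=table.index)).astype(str)
    if "context_gc" in schema:
        out["context_gc"] = np.array(
            [int(sum(b in "GC" for b in c.upper()) >= 2) for c in ctx], dtype=float
        )
    if "homopolymer" in schema:
        out["homopolymer"] = np.array([_is_homopolymer(c) for c in ctx], dtype=float)
    out = out[list(schema)]
    assert not out.isna().any().any()
    return out
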