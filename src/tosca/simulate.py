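"""Synthetic cohort generator for the tumor-only somatic pipeline.

Emulates a case-control benign-biopsy whole-exome study: per-sample variant
tables with class-dependent feature structure (VAF, depth, population
frequency, cohort recurrence, pathogenicity scores), trinucleotide mutation
catalogs mixed from three planted signatures (aging-like, mismatch-repair-like
and an oxidation-like T>G signature topped by T[T>G]C), genotyping-array
calls, CNV segment tables with planted MLH3/PMS2 deletions, and protein-domain
burden cohorts with planted log-odds effects.

Every generator is a pure function of (config, seed). Gene and domain
coordinates used here are synthetic stand-ins: gene symbols are real, their
intervals are not.

Default scales mirror the study the pipeline is designed for: 135 cases vs 69
controls, ~180 somatic SNVs per sample at mean depth 99 and mean somatic VAF
0.232, three mutational signatures, 1966 protein domains, a 26-sample subset
with copy-number data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, CHANNEL_INDEX, revcomp, unfold

KEY = ["sample", "chrom", "pos", "ref", "alt"]

SIGNATURE_NAMES = ("aging-like", "MMR-like", "O/TN-like")

#: synthetic gene catalog: symbol -> (chrom, start, end, coding kb)
#: intervals are invented; symbols match genes recurrently mutated in benign
#: breast tissue plus the mismatch-repair gene set.
GENE_CATALOG = {
    "PIK3CA": ("chr3", 178_860_000, 178_960_000, 3.2),
    "AKT1": ("chr14", 105_230_000, 105_260_000, 1.4),
    "TP53": ("chr17", 7_570_000, 7_590_000, 1.2),
    "GNAS": ("chr20", 57_410_000, 57_490_000, 2.3),
    "CTNNA2": ("chr2", 79_590_000, 80_740_000, 2.9),
    "BCORL1": ("chrX", 129_140_000, 129_190_000, 5.2),
    "FLG": ("chr1", 152_270_000, 152_300_000, 12.2),
    "FLG2": ("chr1", 152_320_000, 152_330_000, 7.2),
    "MUC17": ("chr7", 100_660_000, 100_700_000, 13.5),
    "OBSCN": ("chr1", 228_390_000, 228_570_000, 23.0),
    "ABCA13": ("chr7", 48_210_000, 48_690_000, 15.2),
    "GLTPD2": ("chr17", 7_000_000, 7_010_000, 0.6),
    "SLC7A4": ("chr22", 21_380_000, 21_390_000, 1.9),
    "PGBD1": ("chr6", 28_240_000, 28_270_000, 2.4),
    "PLA2G3": ("chr22", 31_520_000, 31_540_000, 1.5),
    "ADAM30": ("chr1", 120_430_000, 120_440_000, 2.4),
    "NCOA3": ("chr20", 46_130_000, 46_280_000, 4.3),
    "HYDIN": ("chr16", 70_840_000, 71_260_000, 15.9),
    "DNMT3B": ("chr20", 31_350_000, 31_400_000, 2.6),
    "FAT1": ("chr4", 187_510_000, 187_650_000, 13.7),
    "ATR": ("chr3", 142_170_000, 142_300_000, 7.9),
    "ETAA1": ("chr2", 67_620_000, 67_640_000, 2.8),
    "MLH1": ("chr3", 37_030_000, 37_090_000, 2.3),
    "MLH3": ("chr14", 75_480_000, 75_520_000, 4.4),
    "MSH2": ("chr2", 47_630_000, 47_710_000, 2.8),
    "MSH3": ("chr5", 79_950_000, 80_170_000, 3.4),
    "MSH6": ("chr2", 48_010_000, 48_030_000, 4.1),
    "PMS2": ("chr7", 6_010_000, 6_050_000, 2.6),
    "MUTYH": ("chr1", 45_790_000, 45_810_000, 1.6),
    "SETD2": ("chr3", 47_050_000, 47_200_000, 7.7),
}

MMR_GENES = ("MLH1", "MLH3", "MSH2", "MSH3", "MSH6", "PMS2", "MUTYH", "SETD2")

#: PIK3CA helical-domain hotspot used for subgroup enrichment planting
HOTSPOT = {
    "gene": "PIK3CA",
    "protein_change": "p.H1047R",
    "chrom": "chr3",
    "pos": 178_952_085,
    "ref": "A",
    "alt": "G",
    "context": "CAT",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# channel -> (ref, alt, context) on the pyrimidine strand (row 0) and the
# purine strand (row 1); used to vectorize variant expansion
_unfolded = [unfold(c) for c in CHANNELS]
_CHANNEL_REF = np.array([[r for r, a, c in _unfolded],
                         [revcomp(r) for r, a, c in _unfolded]], dtype=object)
_CHANNEL_ALT = np.array([[a for r, a, c in _unfolded],
                         [revcomp(a) for r, a, c in _unfolded]], dtype=object)
_CHANNEL_CTX = np.array([[c for r, a, c in _unfolded],
                         [revcomp(c) for r, a, c in _unfolded]], dtype=object)

PATHOGENICITY_SCORES = ("sift", "polyphen", "cadd", "phylop", "gerp", "revel")


def default_signatures() -> pd.DataFrame:
    """The three planted signature profiles (rows sum to 1).

    Synthetic stand-ins, not COSMIC reproductions: an aging-like profile
    concentrated on N[C>T]G (5-methylcytosine deamination at CpG), an
    MMR-like profile concentrated on C>T outside CpG with a minor C>A
    component, and an oxidation-like "O/TN" profile carrying 60% of its mass
    on T>G channels with T[T>G]C the single largest channel.
    """
    H = np.zeros((3, 96))
    H += np.array([0.2, 0.2, 0.4])[:, None] / 96.0  # flat backgrounds
    for f in "ACGT":
        H[0, CHANNEL_INDEX[f"{f}[C>T]G"]] += 0.8 / 4
        H[1, CHANNEL_INDEX[f"{f}[C>A]A"]] += 0.1 / 4
        for t in "ACT":
            H[1, CHANNEL_INDEX[f"{f}[C>T]{t}"]] += 0.7 / 12
    H[2, CHANNEL_INDEX["T[T>G]C"]] += 0.25
    for f in "ACGT":
        for t in "ACGT":
            ch = f"{f}[T>G]{t}"
            if ch != "T[T>G]C":
                H[2, CHANNEL_INDEX[ch]] += 0.35 / 15
    H /= H.sum(axis=1, keepdims=True)
    return pd.DataFrame(H, index=list(SIGNATURE_NAMES), columns=list(CHANNELS))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators.

    Counts must be non-negative (zero cohorts yield empty outputs); fractions
    must lie in [0, 1]; the seed fully determines every output.
    """

    n_cases: int = 135
    n_controls: int = 69
    seed: int = 0
    somatic_vaf_mean: float = 0.232
    somatic_vaf_shape: float = 2.3          # Beta alpha; beta derived from the mean
    germline_vaf_modes: tuple[float, float] = (0.5, 0.97)
    mean_depth: float = 99.0
    depth_dispersion: float = 20.0          # negative-binomial size parameter
    snvs_per_sample: int = 180
    germline_per_sample: int = 220
    indel_fraction: float = 0.06
    exposure_concentration: tuple[float, ...] = (4.0, 2.5, 1.5)
    tnbc_fraction: float = 0.15
    tnbc_otn_shift: float = 1.0             # log-odds per SD of O/TN exposure
    pdwa_fraction: float = 76 / 195
    hotspot_pdwa_rate: float = 0.28
    hotspot_np_rate: float = 0.05
    n_domains: int = 1966
    informative_domains: tuple[tuple[str, float], ...] = tuple(
        (f"D{i:04d}", 1.0) for i in range(5)
    )
    cnv_subset_size: int = 26
    deletion_rate: float = 0.3
    deletion_mmr_shift: float = 2.0         # in SDs of the MMR exposure
    array_error_rate: float = 0.15
    true_signatures: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "snvs_per_sample", "germline_per_sample",
                     "n_domains", "cnv_subset_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("somatic_vaf_mean", "tnbc_fraction", "pdwa_fraction",
                     "hotspot_pdwa_rate", "hotspot_np_rate", "deletion_rate",
                     "array_error_rate", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        ids = [d for d, _ in self.informative_domains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate informative domain ids")
        H = self.signatures().to_numpy()
        if (H < 0).any():
            raise ValueError("true signatures must be nonnegative")
        if not np.allclose(H.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each true-signature row must sum to 1")

    def signatures(self) -> pd.DataFrame:
        return self.true_signatures if self.true_signatures is not None else default_signatures()

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class GroundTruth:
    """Generative truth retained for recovery tests."""

    W0: pd.DataFrame            # samples x signatures, attributed mutation counts
    H0: pd.DataFrame            # signatures x 96, rows sum to 1
    labels: pd.Series           # per-variant 'somatic' | 'germline'
    hotspot_carriers: pd.Series  # per-sample bool


@dataclass
class SimulatedCohort:
    variants: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth


def _beta_from_mode(mode: float, concentration: float) -> tuple[float, float]:
    a = mode * (concentration - 2.0) + 1.0
    return a, concentration - a


def _draw_depth(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    r = cfg.depth_dispersion
    depth = rng.negative_binomial(r, r / (r + cfg.mean_depth), n)
    return np.maximum(depth, 1)


def _protein_change(rng: np.random.Generator, variant_class: str) -> str:
    pos = int(rng.integers(1, 1500))
    if variant_class == "silent":
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        return f"p.{aa}{pos}{aa}"
    if variant_class in ("nonsense", "stop_gain"):
        return f"p.{AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]}{pos}*"
    a, b = rng.integers(len(AMINO_ACIDS), size=2)
    if a == b:
        b = (b + 1) % len(AMINO_ACIDS)
    return f"p.{AMINO_ACIDS[a]}{pos}{AMINO_ACIDS[b]}"


def _sample_metadata(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    n = cfg.n_samples
    samples = [f"case_{i:03d}" for i in range(cfg.n_cases)] + [
        f"ctrl_{i:03d}" for i in range(cfg.n_controls)
    ]
    group = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    meta = pd.DataFrame(
        {
            "sample": samples,
            "group": group,
            "age": np.round(rng.normal(49.7, 9.8, n), 1),
            "menopausal": np.where(rng.random(n) < 0.56, "pre", "post"),
        }
    )
    # exact-count planting of the histology split
    n_pdwa = int(round(cfg.pdwa_fraction * n))
    hist = np.array(["NP"] * n, dtype=object)
    hist[rng.permutation(n)[:n_pdwa]] = "PDWA"
    meta["histology"] = hist
    return meta


def plant_carriers(rng: np.random.Generator, mask: np.ndarray, rate: float) -> np.ndarray:
    """Select exactly round(rate * mask.sum()) carriers among ``mask`` samples."""
    idx = np.flatnonzero(mask)
    k = int(round(rate * idx.size))
    carriers = np.zeros(mask.size, dtype=bool)
    if k:
        carriers[rng.choice(idx, size=k, replace=False)] = True
    return carriers


def _germline_pool(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    """Shared population of germline sites; carrier popularity gives cohort
    recurrence, site-level frequencies give the population-AF separation."""
    genes = list(GENE_CATALOG)
    kb = np.array([GENE_CATALOG[g][3] for g in genes])
    n_pool = max(int(round(cfg.germline_per_sample / 0.2)), 1)
    gidx = rng.choice(len(genes), n_pool, p=kb / kb.sum())
    chrom = np.array([GENE_CATALOG[genes[i]][0] for i in gidx])
    start = np.array([GENE_CATALOG[genes[i]][1] for i in gidx])
    end = np.array([GENE_CATALOG[genes[i]][2] for i in gidx])
    pos = rng.integers(start, end + 1)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(4, size=n_pool)]
    alt_off = rng.integers(1, 4, size=n_pool)
    alt = bases[(np.searchsorted(bases, ref) + alt_off) % 4]
    flank5 = bases[rng.integers(4, size=n_pool)]
    flank3 = bases[rng.integers(4, size=n_pool)]
    common = rng.random(n_pool) < 0.85
    pop_af = np.where(common, rng.beta(1.2, 1.2, n_pool), rng.beta(0.5, 20, n_pool))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "context": np.char.add(np.char.add(flank5, ref), flank3),
            "gene": [genes[i] for i in gidx],
            "popularity": rng.beta(0.25, 1.0, n_pool),
            "population_af": pop_af,
            "dbsnp_common": (common & (rng.random(n_pool) < 0.94)).astype(int),
            "hom_bias": rng.beta(2, 4, n_pool),  # per-site homozygosity probability
        }
    )


def _pathogenicity(rng: np.random.Generator, somatic: np.ndarray) -> dict[str, np.ndarray]:
    """Six class-separated pathogenicity/conservation scores."""
    n = somatic.size
    s = somatic
    return {
        "sift": np.where(s, rng.beta(1.2, 3.0, n), rng.beta(3.0, 1.2, n)),
        "polyphen": np.where(s, rng.beta(3.0, 1.5, n), rng.beta(1.2, 3.5, n)),
        "cadd": np.clip(np.where(s, rng.normal(18, 6, n), rng.normal(8, 4, n)), 0, 50),
        "phylop": np.where(s, rng.normal(3.0, 1.5, n), rng.normal(1.0, 1.0, n)),
        "gerp": np.where(s, rng.normal(4.0, 1.0, n), rng.normal(2.0, 1.5, n)),
        "revel": np.where(s, rng.beta(4, 3, n), rng.beta(1.5, 6, n)),
    }


def simulate_exposure_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample metadata plus truth signature exposures, without variant tables.

    Returns (metadata, W0). W0 holds per-sample attributed mutation counts
    (Dirichlet exposure proportions times a Poisson mutation count). The TNBC
    flag is assigned among cases with log-odds linear in the standardized
    O/TN exposure, slope ``tnbc_otn_shift``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    meta = _sample_metadata(rng, config)
    n = config.n_samples
    H0 = config.signatures()
    if n == 0:
        meta["tnbc"] = pd.Series(dtype=bool)
        return meta, pd.DataFrame(columns=list(H0.index))
    alpha = np.asarray(config.exposure_concentration, dtype=float)
    Wp = rng.dirichlet(alpha, n)
    n_som = rng.poisson(config.snvs_per_sample, n)
    W0 = pd.DataFrame(Wp * n_som[:, None], index=meta["sample"],
                      columns=list(H0.index))
    otn = W0.iloc[:, -1].to_numpy()
    z = (otn - otn.mean()) / otn.std() if otn.std() > 0 else np.zeros(n)
    b0 = np.log(config.tnbc_fraction / (1 - config.tnbc_fraction))
    p_tnbc = 1.0 / (1.0 + np.exp(-(b0 + config.tnbc_otn_shift * z)))
    meta["tnbc"] = (rng.random(n) < p_tnbc) & (meta["group"] == "case").to_numpy()
    return meta, W0


def simulate_variant_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the full labeled variant cohort with metadata and truth.

    Germline VAFs follow a two-mode mixture near the configured modes
    (heterozygous/homozygous); somatic VAFs a Beta with the configured mean;
    depths a negative binomial around the configured mean; somatic
    trinucleotide channels are drawn from each sample's signature mixture.
    """
    rng = np.random.default_rng(config.seed)
    meta, W0 = simulate_exposure_cohort(config, rng)
    n = config.n_samples
    H0 = config.signatures()

    if n == 0:
        empty = pd.DataFrame(
            columns=KEY + ["vaf", "ref_depth", "alt_depth", "total_depth", "gene",
                           "protein_change", "variant_class", "context",
                           "population_af", "dbsnp_common", "cosmic_count",
                           *PATHOGENICITY_SCORES, "domain", "true_label"]
        )
        truth = GroundTruth(
            W0=pd.DataFrame(columns=list(SIGNATURE_NAMES)),
            H0=H0,
            labels=pd.Series(dtype=object),
            hotspot_carriers=pd.Series(dtype=bool),
        )
        return SimulatedCohort(empty, meta, truth)

    # per-sample exposure proportions and somatic counts, recovered from W0
    n_som = np.rint(W0.sum(axis=1).to_numpy()).astype(int)
    Wp = W0.to_numpy() / np.maximum(W0.sum(axis=1).to_numpy()[:, None], 1e-300)
    Wp[n_som == 0] = 1.0 / W0.shape[1]

    genes = list(GENE_CATALOG)
    kb = np.array([GENE_CATALOG[g][3] for g in genes])
    gene_p = kb / kb.sum()
    Hnp = H0.to_numpy()
    pool = _germline_pool(rng, config)
    carrier_mat = rng.random((n, len(pool))) < pool["popularity"].to_numpy()

    hotspot_carriers = plant_carriers(
        rng, (meta["histology"] == "PDWA").to_numpy(), config.hotspot_pdwa_rate
    ) | plant_carriers(
        rng, (meta["histology"] == "NP").to_numpy(), config.hotspot_np_rate
    )

    frames = []
    for i, sample in enumerate(meta["sample"]):
        # somatic SNVs from the sample's signature mixture
        probs = Wp[i] @ Hnp
        counts = rng.multinomial(n_som[i], probs)
        ch_idx = np.repeat(np.arange(96), counts)
        m = ch_idx.size
        flip = rng.random(m) < 0.5  # report on the purine strand half the time
        strand = flip.astype(int)
        ref = _CHANNEL_REF[strand, ch_idx]
        alt = _CHANNEL_ALT[strand, ch_idx]
        ctx = _CHANNEL_CTX[strand, ch_idx]
        gsel = rng.choice(len(genes), m, p=gene_p)
        gene = np.array([genes[g] for g in gsel], dtype=object)
        start = np.array([GENE_CATALOG[g][1] for g in gene])
        end = np.array([GENE_CATALOG[g][2] for g in gene])
        chrom = np.array([GENE_CATALOG[g][0] for g in gene], dtype=object)
        pos = rng.integers(start, end + 1)
        vclass = rng.choice(
            ["missense", "silent", "nonsense", "splice"], m, p=[0.58, 0.30, 0.07, 0.05]
        )
        som = pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "context": ctx,
            "gene": gene, "variant_class": vclass, "true_label": "somatic",
        })
        som["protein_change"] = [_protein_change(rng, v) for v in vclass]

        # small indels (frameshift / inframe), outside the 96-channel space
        n_indel = rng.poisson(config.indel_fraction * max(config.snvs_per_sample, 1))
        if n_indel:
            gsel = rng.choice(len(genes), n_indel, p=gene_p)
            igene = np.array([genes[g] for g in gsel], dtype=object)
            istart = np.array([GENE_CATALOG[g][1] for g in igene])
            iend = np.array([GENE_CATALOG[g][2] for g in igene])
            size = rng.integers(1, 7, n_indel)
            ins = rng.random(n_indel) < 0.5
            bases = np.array(list("ACGT"))
            iref, ialt = [], []
            for k in range(n_indel):
                anchor = bases[rng.integers(4)]
                tail = "".join(bases[rng.integers(4, size=size[k])])
                iref.append(anchor if ins[k] else anchor + tail)
                ialt.append(anchor + tail if ins[k] else anchor)
            indels = pd.DataFrame({
                "chrom": [GENE_CATALOG[g][0] for g in igene],
                "pos": rng.integers(istart, iend + 1),
                "ref": iref, "alt": ialt, "context": "NNN",
                "gene": igene,
                "variant_class": np.where(
                    rng.random(n_indel) < 0.8, "frameshift", "inframe_indel"
                ),
                "true_label": "somatic",
            })
            indels["protein_change"] = [
                f"p.{AMINO_ACIDS[rng.integers(20)]}{rng.integers(1, 1500)}fs"
                for _ in range(n_indel)
            ]
            som = pd.concat([som, indels], ignore_index=True)

        if hotspot_carriers[i]:
            som = pd.concat([som, pd.DataFrame([{
                "chrom": HOTSPOT["chrom"], "pos": HOTSPOT["pos"],
                "ref": HOTSPOT["ref"], "alt": HOTSPOT["alt"],
                "context": HOTSPOT["context"], "gene": HOTSPOT["gene"],
                "variant_class": "missense", "true_label": "somatic",
                "protein_change": HOTSPOT["protein_change"],
            }])], ignore_index=True)

        ms = len(som)
        som["population_af"] = np.where(
            rng.random(ms) < 0.92, 0.0, rng.beta(0.5, 60, ms)
        )
        som["dbsnp_common"] = (rng.random(ms) < 0.02).astype(int)
        som["cosmic_count"] = np.where(
            rng.random(ms) < 0.8, 0, rng.geometric(0.3, ms)
        )
        som.loc[som["protein_change"] == HOTSPOT["protein_change"], "cosmic_count"] = 1200
        som["true_vaf"] = rng.beta(
            config.somatic_vaf_shape,
            config.somatic_vaf_shape * (1 - config.somatic_vaf_mean) / config.somatic_vaf_mean,
            ms,
        )

        # germline variants drawn from the shared pool
        sites = pool[carrier_mat[i]]
        mg = len(sites)
        germ = sites[["chrom", "pos", "ref", "alt", "context", "gene",
                      "population_af", "dbsnp_common"]].copy()
        germ["variant_class"] = rng.choice(
            ["missense", "silent", "nonsense", "splice"], mg, p=[0.33, 0.58, 0.04, 0.05]
        )
        germ["protein_change"] = [_protein_change(rng, v) for v in germ["variant_class"]]
        germ["cosmic_count"] = np.where(rng.random(mg) < 0.97, 0, rng.geometric(0.5, mg))
        germ["true_label"] = "germline"
        hom = rng.random(mg) < sites["hom_bias"].to_numpy()
        m_het, m_hom = config.germline_vaf_modes
        a1, b1 = _beta_from_mode(m_het, 120.0)
        a2, b2 = _beta_from_mode(m_hom, 70.0)
        germ["true_vaf"] = np.where(hom, rng.beta(a2, b2, mg), rng.beta(a1, b1, mg))

        tab = pd.concat([som, germ], ignore_index=True)
        m = len(tab)
        depth = _draw_depth(rng, config, m)
        alt_d = rng.binomial(depth, tab["true_vaf"].to_numpy())
        tab.insert(0, "sample", sample)
        tab["total_depth"] = depth
        tab["alt_depth"] = alt_d
        tab["ref_depth"] = depth - alt_d
        tab["vaf"] = alt_d / depth
        for name, col in _pathogenicity(rng, (tab["true_label"] == "somatic").to_numpy()).items():
            tab[name] = col
        gene_dom = {g: f"D{(k * 7) % config.n_domains:04d}" for k, g in enumerate(genes)}
        tab["domain"] = tab["gene"].map(gene_dom).where(rng.random(m) < 0.5)
        frames.append(tab)

    variants = pd.concat(frames, ignore_index=True)
    variants = variants.drop(columns=["true_vaf"])
    cols = KEY + ["vaf", "ref_depth", "alt_depth", "total_depth", "gene",
                  "protein_change", "variant_class", "context", "population_af",
                  "dbsnp_common", "cosmic_count", *PATHOGENICITY_SCORES,
                  "domain", "true_label"]
    variants = variants[cols]
    variants["pos"] = variants["pos"].astype(int)
    truth = GroundTruth(
        W0=W0, H0=H0, labels=variants["true_label"].copy(),
        hotspot_carriers=pd.Series(hotspot_carriers, index=meta["sample"].to_numpy()),
    )
    return SimulatedCohort(variants, meta, truth)


def simulate_catalogs(
    H0: pd.DataFrame | np.ndarray,
    exposure_concentration,
    n_samples: int,
    snvs_per_sample: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial 96-channel catalogs from planted signatures.

    Each sample draws exposure proportions ``w`` from a Dirichlet, a mutation
    count from Poisson(snvs_per_sample), and channel counts from
    Multinomial(count, w @ H0). Returns (catalog, W0) where W0 holds the
    attributed counts ``w * count``.
    """
    H = np.asarray(H0, dtype=float)
    if (H < 0).any():
        raise ValueError("H0 must be nonnegative")
    if not np.allclose(H.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("H0 rows must sum to 1")
    rng = np.random.default_rng(seed)
    k = H.shape[0]
    Wp = rng.dirichlet(np.asarray(exposure_concentration, dtype=float), n_samples)
    counts = (
        rng.poisson(snvs_per_sample, n_samples)
        if snvs_per_sample > 0
        else np.zeros(n_samples, dtype=int)
    )
    V = np.vstack([rng.multinomial(c, w @ H) for c, w in zip(counts, Wp)]) \
        if n_samples else np.zeros((0, 96), dtype=int)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    sig_names = list(H0.index) if isinstance(H0, pd.DataFrame) else [f"sig{j}" for j in range(k)]
    catalog = pd.DataFrame(V, index=samples, columns=list(CHANNELS))
    W0 = pd.DataFrame(Wp * counts[:, None], index=samples, columns=sig_names)
    return catalog, W0


def simulate_array_genotypes(
    variants: pd.DataFrame, error_rate: float, seed: int
) -> pd.DataFrame:
    """Orthogonal genotyping-array calls for the cohort's sites.

    Each variant's array allele frequency is the member of {0, 0.5, 1}
    nearest its sequencing VAF (the underlying allele dosage), flipped to a
    uniformly-chosen wrong state with probability ``error_rate``.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate={error_rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    states = np.array([0.0, 0.5, 1.0])
    vaf = variants["vaf"].to_numpy(dtype=float)
    idx = np.abs(vaf[:, None] - states[None, :]).argmin(axis=1)
    flip = rng.random(len(variants)) < error_rate
    wrong = (idx + rng.integers(1, 3, len(variants))) % 3
    idx = np.where(flip, wrong, idx)
    out = variants[KEY].copy()
    out["array_af"] = states[idx]
    return out.reset_index(drop=True)


@dataclass
class CnvSimulation:
    segments: pd.DataFrame       # sample, chrom, start, end, num_mark, log2
    deletions: pd.DataFrame      # samples x genes truth indicator
    mmr_exposure: pd.Series      # per-sample MMR-signature exposure


def simulate_cnv_segments(config: SimConfig) -> CnvSimulation:
    """CNV segment tables with planted MLH3 (and PMS2) deletions.

    Exactly ``round(deletion_rate * n)`` samples receive a deep-deletion
    segment spanning MLH3; their MMR-signature exposure is shifted upward by
    ``deletion_mmr_shift`` SDs. PMS2 deletions are planted at the same rate
    independently, without an exposure link.
    """
    rng = np.random.default_rng(config.seed + 7)
    n = config.cnv_subset_size
    samples = [f"cnv_{i:02d}" for i in range(n)]
    all_mask = np.ones(n, dtype=bool)
    del_mlh3 = plant_carriers(rng, all_mask, config.deletion_rate)
    del_pms2 = plant_carriers(rng, all_mask, config.deletion_rate)
    rows = []
    for gene in ("MLH3", "PMS2", "MLH1", "MSH2"):
        chrom, start, end, _ = GENE_CATALOG[gene]
        deleted = {"MLH3": del_mlh3, "PMS2": del_pms2}.get(gene, np.zeros(n, bool))
        for i, s in enumerate(samples):
            pad = int(rng.integers(5_000, 50_000, 2).sum() / 2)
            log2 = rng.normal(-1.0, 0.15) if deleted[i] else rng.normal(0.0, 0.05)
            rows.append({
                "sample": s, "chrom": chrom,
                "start": start - pad, "end": end + pad,
                "num_mark": int(rng.integers(20, 200)), "log2": log2,
            })
    segments = pd.DataFrame(rows)
    deletions = pd.DataFrame(
        {"MLH3": del_mlh3, "PMS2": del_pms2}, index=samples
    )
    base_mean, base_sd = 45.0, 12.0
    expo = rng.normal(base_mean, base_sd, n)
    expo[del_mlh3] += config.deletion_mmr_shift * base_sd
    mmr = pd.Series(np.clip(expo, 0, None), index=samples, name="MMR-like")
    return CnvSimulation(segments, deletions, mmr)


def simulate_domain_burden_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Protein-domain burden matrix with planted informative domains.

    Non-informative domains draw Poisson burdens with lognormal per-domain
    rates, identically in both classes. Each informative domain ``(d, beta)``
    has its Poisson rate multiplied by ``exp(beta)`` in cases, so the Bayes
    log-odds of case status is linear in the burden with slope ``beta``.
    """
    rng = np.random.default_rng(config.seed + 13)
    n, d = config.n_samples, config.n_domains
    domains = [f"D{i:04d}" for i in range(d)]
    labels = pd.Series(
        [1] * config.n_cases + [0] * config.n_controls,
        index=[f"case_{i:03d}" for i in range(config.n_cases)]
        + [f"ctrl_{i:03d}" for i in range(config.n_controls)],
        name="case",
    )
    mu = np.clip(rng.lognormal(np.log(0.06), 1.0, d), 0, 2.0)
    X = rng.poisson(mu, (n, d)).astype(float)
    info = dict(config.informative_domains)
    unknown = set(info) - set(domains)
    if unknown:
        raise ValueError(f"informative domains outside vocabulary: {sorted(unknown)}")
    y = labels.to_numpy()
    for dom, beta in info.items():
        j = domains.index(dom)
        base = 0.3
        X[:, j] = np.where(
            y == 1, rng.poisson(base * np.exp(beta), n), rng.poisson(base, n)
        )
    burden = pd.DataFrame(X.astype(int), index=labels.index, columns=domains)
    return burden, labels


# --- writers ------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##source=tosca-simulate
{contigs}
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's variants as a minimal VCF 4.2 text file."""
    chroms = list(dict.fromkeys(variants["chrom"]))
    contigs = "\n".join(f"##contig=<ID={c}>" for c in chroms)
    out = variants.sort_values(["chrom", "pos"], kind="stable")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contigs))
        for row in out.itertuples():
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"DP={row.total_depth};AF={row.vaf:.6g}\n"
            )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as VCFs + feature sidecar CSV + metadata CSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample, tab in cohort.variants.groupby("sample", sort=False):
        write_vcf(tab, vcf_dir / f"{sample}.vcf")
    sidecar = outdir / "features.csv"
    cohort.variants.to_csv(sidecar, index=False)
    meta_path = outdir / "metadata.csv"
    cohort.metadata.to_csv(meta_path, index=False)
    truth_path = outdir / "truth.json"
    truth = {
        "W0": cohort.truth.W0.round(6).to_dict(orient="index"),
        "H0": cohort.truth.H0.round(8).to_dict(orient="index"),
        "hotspot_carriers": {
            k: bool(v) for k, v in cohort.truth.hotspot_carriers.items()
        },
    }
    truth_path.write_text(json.dumps(truth))
    return {"vcf_dir": vcf_dir, "features": sidecar, "metadata": meta_path,
            "truth": truth_path}


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    """Write segments in SEG format (sample, chrom, start, end, num_mark, log2)."""
    segments.to_csv(path, sep="\t", index=False,
                    header=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"])


def read_seg(path: str | Path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    seg.columns = ["sample", "chrom", "start", "end", "num_mark", "log2"]
    return seg
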