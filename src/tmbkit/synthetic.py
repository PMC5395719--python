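"""Synthetic cohorts with the statistical structure the pipeline assumes.

Specimens get a disease label, age, and a true TMB drawn on the log10 scale:
per-disease baseline, a linear age term of log10(age_fold_per_80y)/80 per
year, multiplicative driver effects (MMR, POLE, PMS2 promoter), and a
multiplicative bump for microsatellite-unstable specimens.  Somatic variant
counts are Poisson with mean true_tmb x panel territory; germline
polymorphisms are drawn from a shared site pool with population allele
counts and allele fractions consistent with het/hom zygosity.  MSI read
profiles concentrate at the reference repeat length for stable specimens
and show shifted, variance-inflated lengths at a fraction of loci for
unstable ones.

Everything is driven by one seed through named substreams, so identical
configs give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import msi as msi_mod
from . import tmb as tmb_mod
from .tmb import MMR_GENES, PanelDefinition, default_cgp_panel

DRIVER_CLASSES = ("MMR", "POLE", "PMS2_promoter")

_DEFAULT_DISEASE_MIX = {
    "Skin melanoma": 0.20,
    "Lung adenocarcinoma": 0.25,
    "Colon adenocarcinoma": 0.20,
    "Breast carcinoma (NOS)": 0.20,
    "Skin squamous cell carcinoma (SCC)": 0.15,
}

# per-disease (mean, sd) of log10 true TMB; medians loosely follow the
# published per-disease medians, spreads are free parameters
_DEFAULT_BASELINES = {
    "Skin melanoma": (np.log10(14.4), 0.55),
    "Lung adenocarcinoma": (np.log10(6.3), 0.45),
    "Colon adenocarcinoma": (np.log10(3.6), 0.40),
    "Breast carcinoma (NOS)": (np.log10(2.5), 0.40),
    "Skin squamous cell carcinoma (SCC)": (np.log10(45.2), 0.50),
}


class SyntheticConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Knobs for the cohort generator; defaults give a realistic mixture."""

    n_specimens: int = 500
    disease_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DISEASE_MIX))
    age_range: tuple[float, float] = (10.0, 90.0)  # uniform draw, years
    baseline_log10_tmb: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES))
    driver_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"MMR": 0.01, "POLE": 0.002,
                                 "PMS2_promoter": 0.02})
    driver_fold_effect: Mapping[str, float] = field(
        default_factory=lambda: {"MMR": 5.0, "POLE": 10.0,
                                 "PMS2_promoter": 5.3})
    age_fold_per_80y: float = 2.4
    germline_snp_rate: float = 25.0  # expected germline variants per specimen
    synonymous_fraction: float = 0.25
    msi_high_rate: float = 0.05
    msi_tmb_fold: float = 10.0  # TMB multiplier for unstable specimens
    panel_mb: float = 1.1
    duplicate_patient_rate: float = 0.0
    low_coverage_rate: float = 0.0
    zygosity_mode: str = "oracle"  # or "af_proxy"
    zygosity_miscall_rate: float = 0.03  # oracle mode: ambiguous-call rate
    seed: int = 0

    def validate(self) -> None:
        if self.n_specimens < 1:
            raise SyntheticConfigError("n_specimens: must be a positive count")
        total = sum(self.disease_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"disease_mix: probabilities sum to {total}, expected 1")
        for name, p in self.disease_mix.items():
            if not 0 <= p <= 1:
                raise SyntheticConfigError(f"disease_mix[{name}]: {p} not in [0,1]")
        for name in self.disease_mix:
            if name not in self.baseline_log10_tmb:
                raise SyntheticConfigError(
                    f"baseline_log10_tmb: missing disease {name!r}")
        for cls, p in self.driver_prevalence.items():
            if not 0 <= p <= 1:
                raise SyntheticConfigError(
                    f"driver_prevalence[{cls}]: {p} not in [0,1]")
        for cls, f in self.driver_fold_effect.items():
            if f <= 0:
                raise SyntheticConfigError(
                    f"driver_fold_effect[{cls}]: fold effects must be > 0")
        for name in ("msi_high_rate", "synonymous_fraction",
                     "duplicate_patient_rate", "low_coverage_rate",
                     "zygosity_miscall_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SyntheticConfigError(f"{name}: {v} not in [0,1]")
        if self.age_fold_per_80y <= 0 or self.msi_tmb_fold <= 0:
            raise SyntheticConfigError("fold parameters must be > 0")
        if self.germline_snp_rate < 0:
            raise SyntheticConfigError("germline_snp_rate: must be >= 0")
        if self.panel_mb <= 0:
            raise SyntheticConfigError("panel_mb: must be > 0")
        if self.zygosity_mode not in ("oracle", "af_proxy"):
            raise SyntheticConfigError(
                f"zygosity_mode: unknown mode {self.zygosity_mode!r}")


@dataclass
class GroundTruth:
    """Generator-side truth: per-specimen state and per-variant origin."""

    specimens: pd.DataFrame  # specimen_id, true_tmb, driver flags, msi_truth
    variant_origins: pd.DataFrame  # variant_uid, origin in {somatic, germline}


@dataclass
class CohortData:
    specimens: pd.DataFrame
    variants: pd.DataFrame
    msi_profiles: pd.DataFrame
    truth: GroundTruth


def _streams(seed: int, names: Sequence[str],
             namespace: int = 0) -> dict[str, np.random.Generator]:
    """Named independent substreams; namespaces keep call sites disjoint."""
    children = np.random.SeedSequence((seed, namespace)).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_SOMATIC_EFFECTS = np.array(
    ["missense", "nonsense", "frameshift", "splice", "inframe_indel"])
_SOMATIC_EFFECT_P = np.array([0.70, 0.10, 0.10, 0.05, 0.05])
_BASES = np.array(list("ACGT"))


def _germline_site_pool(rng: np.random.Generator, panel: PanelDefinition,
                        size: int = 300) -> pd.DataFrame:
    """Shared polymorphic sites so cohort-level germline recurrence exists.

    Population allele counts are heavy-tailed with >= 2 counts at
    probability 0.95, exercising the ExAC-style filter both ways.
    """
    genes = sorted(panel.genes)
    regions = {g: r for g, r in zip(sorted(panel.genes), panel.regions)} \
        if len(panel.regions) == len(genes) else {}
    gene_idx = rng.integers(0, len(genes), size)
    gene_arr = np.array(genes)[gene_idx]
    chroms, positions = [], []
    for g in gene_arr:
        if g in regions:
            chrom, start, end = regions[g]
        else:
            chrom, start, end = "chr1", 1, 10_000_000
        chroms.append(chrom)
        positions.append(int(rng.integers(start, end + 1)))
    u = rng.random(size)
    pop = np.where(u < 0.03, 0, np.where(u < 0.05, 1,
                                         2 + rng.zipf(1.6, size)))
    ref = rng.choice(_BASES, size)
    alt_shift = rng.integers(1, 4, size)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "gene": gene_arr,
            "population_count": pop.astype(int),
            "dbsnp": rng.random(size) < 0.9,
            "common": rng.random(size),  # sampling weight shape
        }
    )


def generate_specimens(config: CohortConfig) -> pd.DataFrame:
    """Specimen metadata + ground-truth columns (no variants).

    Returned columns: specimen_id, patient_id, disease, age, sex,
    median_coverage, purity, true_tmb, msi_truth, and one boolean per
    driver class.
    """
    config.validate()
    rngs = _streams(config.seed, ["specimen", "age", "tmb", "driver", "msi"])
    n = config.n_specimens
    diseases = list(config.disease_mix)
    probs = np.array([config.disease_mix[d] for d in diseases])
    disease = rngs["specimen"].choice(diseases, n, p=probs / probs.sum())
    lo, hi = config.age_range
    age = rngs["age"].uniform(lo, hi, n)
    sex = rngs["specimen"].choice(["F", "M"], n)
    coverage = rngs["specimen"].normal(550, 80, n).clip(min=20)
    low_cov = rngs["specimen"].random(n) < config.low_coverage_rate
    coverage[low_cov] = rngs["specimen"].uniform(100, 299, low_cov.sum())
    purity = np.ones(n)

    base_mean = np.array([config.baseline_log10_tmb[d][0] for d in disease])
    base_sd = np.array([config.baseline_log10_tmb[d][1] for d in disease])
    age_center = (lo + hi) / 2.0
    age_slope = np.log10(config.age_fold_per_80y) / 80.0
    log_tmb = base_mean + base_sd * rngs["tmb"].standard_normal(n)
    log_tmb += age_slope * (age - age_center)

    drivers = {}
    for cls in DRIVER_CLASSES:
        prev = config.driver_prevalence.get(cls, 0.0)
        flag = rngs["driver"].random(n) < prev
        fold = config.driver_fold_effect.get(cls, 1.0)
        log_tmb = log_tmb + np.log10(fold) * flag
        drivers[cls] = flag

    msi_truth = rngs["msi"].random(n) < config.msi_high_rate
    log_tmb = log_tmb + np.log10(config.msi_tmb_fold) * msi_truth

    specimen_id = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    patient_id = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    if config.duplicate_patient_rate > 0 and n > 1:
        dup = rngs["specimen"].random(n) < config.duplicate_patient_rate
        dup[0] = False
        idx = np.where(dup)[0]
        patient_id[idx] = patient_id[idx - 1]

    return pd.DataFrame(
        {
            "specimen_id": specimen_id,
            "patient_id": patient_id,
            "disease": disease,
            "age": age,
            "sex": sex,
            "median_coverage": coverage,
            "purity": purity,
            "true_tmb": 10.0 ** log_tmb,
            "msi_truth": np.where(msi_truth, "unstable", "stable"),
            **{f"driver_{c}": drivers[c] for c in DRIVER_CLASSES},
        }
    )


def _somatic_variants(config: CohortConfig, specimens: pd.DataFrame,
                      panel: PanelDefinition,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized somatic draw: Poisson counts, panel genes, flags."""
    counts = rng.poisson(specimens["true_tmb"].to_numpy() * config.panel_mb)
    total = int(counts.sum())
    spec_ids = np.repeat(specimens["specimen_id"].to_numpy(), counts)
    genes_sorted = sorted(panel.genes)
    gene_idx = rng.integers(0, len(genes_sorted), total)
    gene = np.array(genes_sorted)[gene_idx]
    region_by_gene = {g: r for g, r in zip(genes_sorted, panel.regions)} \
        if len(panel.regions) == len(genes_sorted) else {}
    if region_by_gene:
        starts = np.array([region_by_gene[g][1] for g in genes_sorted])
        ends = np.array([region_by_gene[g][2] for g in genes_sorted])
        chrom_arr = np.array([region_by_gene[g][0] for g in genes_sorted])
        pos = starts[gene_idx] + rng.integers(
            0, np.maximum(ends - starts, 1)[gene_idx])
        chrom = chrom_arr[gene_idx]
    else:
        pos = rng.integers(1, 10_000_000, total)
        chrom = np.repeat("chr1", total)

    u = rng.random(total)
    effect = np.where(
        u < config.synonymous_fraction,
        "synonymous",
        rng.choice(_SOMATIC_EFFECTS, total, p=_SOMATIC_EFFECT_P),
    )
    truncating = np.isin(effect, ["nonsense", "frameshift"])
    ts_trunc = truncating & np.isin(gene, list(tmb_mod.TUMOR_SUPPRESSORS))
    hotspot = rng.random(total) < 0.01
    af = rng.uniform(0.05, 0.85, total)
    hp = np.where(rng.random(total) < 0.10,
                  rng.integers(6, 13, total), rng.integers(0, 6, total))
    if config.zygosity_mode == "oracle":
        zyg = np.where(rng.random(total) < config.zygosity_miscall_rate,
                       "ambiguous", "somatic")
    else:
        zyg = np.array([
            tmb_mod.call_zygosity_proxy(a) for a in af])
    ref = rng.choice(_BASES, total)
    alt = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4, total)) % 4]
    pop = np.where(rng.random(total) < 0.01, 1, 0)
    return pd.DataFrame(
        {
            "specimen_id": spec_ids,
            "chrom": chrom,
            "pos": pos.astype(int),
            "ref": ref,
            "alt": alt,
            "gene": gene,
            "effect": effect,
            "coding": True,
            "known_somatic_hotspot": hotspot,
            "ts_truncation": ts_trunc,
            "dbsnp": False,
            "population_count": pop.astype(int),
            "recurrent_germline": False,
            "zygosity_call": zyg,
            "allele_fraction": af,
            "homopolymer_len": hp.astype(int),
            "origin": "somatic",
        }
    )


def _germline_variants(config: CohortConfig, specimens: pd.DataFrame,
                       pool: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    counts = rng.poisson(config.germline_snp_rate, len(specimens))
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame()
    spec_ids = np.repeat(specimens["specimen_id"].to_numpy(), counts)
    site_idx = rng.integers(0, len(pool), total)
    sites = pool.iloc[site_idx].reset_index(drop=True)
    het = rng.random(total) < 0.7
    af = np.where(het, rng.normal(0.5, 0.05, total),
                  rng.normal(1.0, 0.05, total)).clip(0, 1)
    if config.zygosity_mode == "oracle":
        zyg = np.where(rng.random(total) < 0.05, "ambiguous", "germline")
    else:
        zyg = np.array([tmb_mod.call_zygosity_proxy(a) for a in af])
    u = rng.random(total)
    effect = np.where(u < 0.5, "missense",
                      np.where(u < 0.9, "synonymous", "inframe_indel"))
    return pd.DataFrame(
        {
            "specimen_id": spec_ids,
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "ref": sites["ref"].to_numpy(),
            "alt": sites["alt"].to_numpy(),
            "gene": sites["gene"].to_numpy(),
            "effect": effect,
            "coding": True,
            "known_somatic_hotspot": False,
            "ts_truncation": False,
            "dbsnp": sites["dbsnp"].to_numpy(),
            "population_count": sites["population_count"].to_numpy(),
            "recurrent_germline": False,
            "zygosity_call": zyg,
            "allele_fraction": af,
            "homopolymer_len": rng.integers(0, 6, total),
            "origin": "germline",
        }
    )


def _driver_variants(specimens: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """One identifiable variant per flagged driver class per specimen."""
    rows = []
    mmr_list = sorted(MMR_GENES)
    for spec in specimens.itertuples(index=False):
        if spec.driver_MMR:
            g = mmr_list[int(rng.integers(0, len(mmr_list)))]
            rows.append((spec.specimen_id, "chr2", int(rng.integers(47_000_000, 47_100_000)),
                         "C", "T", g, "frameshift", True, False, True))
        if spec.driver_POLE:
            rows.append((spec.specimen_id, "chr12", 133_250_250, "C", "G",
                         "POLE", "missense", True, True, False))
        if spec.driver_PMS2_promoter:
            rows.append((spec.specimen_id, "chr7",
                         int(rng.integers(6_048_723, 6_048_837)), "C", "T",
                         "PMS2", "promoter", False, False, False))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(
        rows, columns=["specimen_id", "chrom", "pos", "ref", "alt", "gene",
                       "effect", "coding", "known_somatic_hotspot",
                       "ts_truncation"])
    n = len(df)
    df["dbsnp"] = False
    df["population_count"] = 0
    df["recurrent_germline"] = False
    df["zygosity_call"] = "somatic"
    df["allele_fraction"] = rng.uniform(0.05, 0.85, n)
    df["homopolymer_len"] = 0
    df["origin"] = "somatic"
    return df


def generate_msi_profile(
    specimen_id: str,
    loci: Sequence[msi_mod.MSILocus],
    msi_truth: str,
    seed: int | np.random.Generator = 0,
    reads_per_locus: int = 30,
    stable_noise_rate: float = 0.02,
    unstable_locus_fraction: float = 0.3,
    unstable_len_sd: float = 2.0,
    unstable_shift: float = -3.0,
) -> pd.DataFrame:
    """Read repeat lengths for one specimen over a locus panel.

    Stable specimens (and unaffected loci of unstable ones) emit the
    reference length, with each read independently slipping by +/-1 bp at
    ``stable_noise_rate``; zero noise gives zero per-locus variance exactly.
    Unstable specimens perturb a ``unstable_locus_fraction`` of loci: reads
    there are shifted by ``unstable_shift`` and jittered by a centered
    integer distribution with variance ``unstable_len_sd**2`` (a symmetric
    binomial, so the target variance is exact).
    """
    if reads_per_locus < 20:
        raise SyntheticConfigError("reads_per_locus: read support must be >= 20")
    for locus in loci:
        if not 10 <= locus.reference_repeat_len <= 20:
            raise SyntheticConfigError(
                f"locus {locus.locus_id}: reference length outside [10, 20]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_loci = len(loci)
    ref = np.array([l.reference_repeat_len for l in loci])
    lengths = np.repeat(ref, reads_per_locus).astype(float).reshape(
        n_loci, reads_per_locus)
    if stable_noise_rate > 0:
        slip = rng.random((n_loci, reads_per_locus)) < stable_noise_rate
        signs = rng.choice([-1.0, 1.0], (n_loci, reads_per_locus))
        lengths += slip * signs
    if msi_truth == "unstable":
        affected = rng.random(n_loci) < unstable_locus_fraction
        n_binom = int(round(4 * unstable_len_sd ** 2))
        jitter = rng.binomial(n_binom, 0.5, (n_loci, reads_per_locus)) - n_binom / 2.0
        lengths = np.where(affected[:, None],
                           ref[:, None] + unstable_shift + jitter, lengths)
    lengths = np.clip(np.rint(lengths), 0, None).astype(int)
    return pd.DataFrame(
        {
            "specimen_id": specimen_id,
            "locus_id": np.repeat([l.locus_id for l in loci], reads_per_locus),
            "read_index": np.tile(np.arange(reads_per_locus), n_loci),
            "repeat_length": lengths.ravel(),
        }
    )


def generate_cohort(
    config: CohortConfig,
    panel: PanelDefinition | None = None,
    loci: Sequence[msi_mod.MSILocus] | None = None,
    include_variants: bool = True,
    include_msi: bool = True,
    reads_per_locus: int = 30,
) -> CohortData:
    """Full synthetic cohort: specimens, variant calls, MSI profiles, truth."""
    config.validate()
    panel = panel if panel is not None else default_cgp_panel()
    loci = list(loci) if loci is not None else msi_mod.default_locus_panel()
    rngs = _streams(config.seed,
                    ["pool", "somatic", "germline", "driver", "msi_reads"],
                    namespace=1)
    specimens = generate_specimens(config)

    if include_variants:
        pool = _germline_site_pool(rngs["pool"], panel)
        parts = [
            _somatic_variants(config, specimens, panel, rngs["somatic"]),
            _germline_variants(config, specimens, pool, rngs["germline"]),
            _driver_variants(specimens, rngs["driver"]),
        ]
        variants = pd.concat([p for p in parts if len(p)], ignore_index=True) \
            if any(len(p) for p in parts) else pd.DataFrame()
        if len(variants):
            variants.insert(0, "variant_uid",
                            [f"V{i:08d}" for i in range(len(variants))])
    else:
        variants = pd.DataFrame()

    if include_msi:
        profiles = [
            generate_msi_profile(
                row.specimen_id, loci, row.msi_truth, rngs["msi_reads"],
                reads_per_locus=reads_per_locus)
            for row in specimens.itertuples(index=False)
        ]
        msi_profiles = pd.concat(profiles, ignore_index=True)
    else:
        msi_profiles = pd.DataFrame()

    truth_cols = ["specimen_id", "true_tmb", "msi_truth"] + \
        [f"driver_{c}" for c in DRIVER_CLASSES]
    origins = variants[["variant_uid", "origin"]].copy() if len(variants) \
        else pd.DataFrame(columns=["variant_uid", "origin"])
    public_variants = variants.drop(columns=["origin"], errors="ignore")
    public_specimens = specimens.drop(
        columns=["true_tmb", "msi_truth"] +
        [f"driver_{c}" for c in DRIVER_CLASSES])
    return CohortData(
        specimens=public_specimens,
        variants=public_variants,
        msi_profiles=msi_profiles,
        truth=GroundTruth(specimens=specimens[truth_cols].copy(),
                          variant_origins=origins),
    )


def generate_exome_variants(
    n_specimens: int,
    panel: PanelDefinition,
    tmb_range: tuple[float, float] = (1.0, 100.0),
    exome_mb: float = tmb_mod.EXOME_MB,
    seed: int = 0,
) -> pd.DataFrame:
    """Exome-wide somatic coding calls with genes placed by territory.

    Panel genes carry panel_mb/exome_mb of the total territory, so
    restricting to the panel is binomial thinning of the exome counts -- the
    regime in which panel TMB tracks exome TMB.
    """
    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log10(tmb_range[0]), np.log10(tmb_range[1])
    true_tmb = 10 ** rng.uniform(log_lo, log_hi, n_specimens)
    counts = rng.poisson(true_tmb * exome_mb)
    total = int(counts.sum())
    spec_ids = np.repeat(
        np.array([f"E{i:05d}" for i in range(1, n_specimens + 1)]), counts)
    panel_genes = sorted(panel.genes)
    p_panel = panel.coding_mb / exome_mb
    in_panel = rng.random(total) < p_panel
    gene = np.where(
        in_panel,
        np.array(panel_genes)[rng.integers(0, len(panel_genes), total)],
        np.array([f"EXG{i:05d}" for i in range(1, 6001)])[
            rng.integers(0, 6000, total)],
    )
    effects = rng.choice(_SOMATIC_EFFECTS, total, p=_SOMATIC_EFFECT_P)
    return pd.DataFrame(
        {
            "specimen_id": spec_ids,
            "chrom": "chr1",
            "pos": rng.integers(1, 200_000_000, total),
            "ref": "C",
            "alt": "T",
            "gene": gene,
            "effect": effects,
            "coding": True,
        }
    )
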