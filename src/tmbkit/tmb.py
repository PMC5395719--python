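"""Tumor mutational burden: the somatic filter cascade and mutations-per-megabase.

A variant is initially counted if it falls in the coding region of a panel
gene (synonymous alterations included), then removed by the first matching
exclusion rule:

1. non-coding alteration
2. known somatic hotspot (COSMIC-style knowledge-base flag)
3. truncation in a tumor suppressor gene
4. predicted germline by the zygosity model
5. recurrently predicted germline across the cohort
6. present in dbSNP
7. population allele count >= 2 (ExAC-style)

The counted *set* is independent of rule order; the order above only fixes
which reason is reported in the audit trail.  TMB is the number of counted
mutations divided by the coding territory in megabases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EXOME_MB = 38.0  # conventional estimate of coding exome size

#: Audit reasons, in the order the cascade assigns them.
FILTER_REASONS = (
    "noncoding",
    "known_somatic",
    "ts_truncation",
    "zygosity_germline",
    "recurrent_germline",
    "dbsnp",
    "population_count",
    "counted",
)

VALID_EFFECTS = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice",
        "noncoding",
        "promoter",
    }
)

#: Boolean/annotation columns the cascade consumes; absent columns are
#: defaulted by :func:`ensure_variant_columns`.
FLAG_DEFAULTS: Mapping[str, object] = {
    "coding": True,
    "known_somatic_hotspot": False,
    "ts_truncation": False,
    "dbsnp": False,
    "population_count": 0,
    "recurrent_germline": False,
    "zygosity_call": "uncalled",
    "homopolymer_len": 0,
}


class TMBError(ValueError):
    """Raised for invalid panel/variant inputs."""


@dataclass(frozen=True)
class PanelDefinition:
    """A gene panel with its coding territory.

    ``regions`` are 1-based inclusive intervals; BED input must be converted
    on read (see :mod:`tmbkit.io`).  An empty ``genes`` set means "no gene
    restriction" (whole-exome territory).
    """

    name: str
    genes: frozenset[str]
    coding_mb: float
    regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.coding_mb <= 0:
            raise TMBError(f"coding_mb must be > 0, got {self.coding_mb}")

    def contains_gene(self, gene: str) -> bool:
        return not self.genes or gene in self.genes


@dataclass(frozen=True)
class FilterDecision:
    """Audit record for one variant: counted or the first exclusion reason."""

    counted: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in FILTER_REASONS:
            raise TMBError(f"unknown filter reason {self.reason!r}")
        if (self.reason == "counted") != self.counted:
            raise TMBError("reason 'counted' must coincide with counted=True")


@dataclass(frozen=True)
class TMBRecord:
    specimen_id: str
    counted_mutations: int
    territory_mb: float
    tmb: float


# Cancer gene symbols used to seed the default panel; the remainder of the
# 315 genes are synthetic fillers.
_CORE_PANEL_GENES = (
    "ABL1", "AKT1", "ALK", "APC", "AR", "ARID1A", "ATM", "ATR", "BRAF",
    "BRCA1", "BRCA2", "CDH1", "CDK4", "CDK6", "CDKN2A", "CTNNB1", "EGFR",
    "ERBB2", "EZH2", "FBXW7", "FGFR1", "FGFR2", "FGFR3", "FLT3", "GNAQ",
    "GNAS", "HRAS", "IDH1", "IDH2", "JAK2", "KDR", "KIT", "KRAS", "MET",
    "MLH1", "MSH2", "MSH6", "MTOR", "MYC", "NF1", "NF2", "NOTCH1", "NRAS",
    "PDGFRA", "PIK3CA", "PMS2", "POLE", "PTCH1", "PTEN", "RB1", "RET",
    "SMAD4", "SMARCB1", "SMO", "STK11", "TP53", "TSC1", "TSC2", "VHL",
)

#: Genes treated as tumor suppressors when flagging truncations.
TUMOR_SUPPRESSORS = frozenset(
    {"APC", "ARID1A", "ATM", "BRCA1", "BRCA2", "CDH1", "CDKN2A", "MLH1",
     "MSH2", "MSH6", "NF1", "NF2", "PMS2", "PTEN", "RB1", "SMAD4",
     "SMARCB1", "STK11", "TP53", "TSC1", "TSC2", "VHL"}
)

MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})


def default_cgp_panel(n_genes: int = 315, coding_mb: float = 1.1) -> PanelDefinition:
    """Default hybrid-capture panel: 315 genes over 1.1 Mb of coding territory.

    Gene regions are synthetic but internally consistent: each gene gets an
    equal share of the territory, laid out across chr1..chr22.
    """
    genes = list(_CORE_PANEL_GENES)
    genes += [f"GEN{i:04d}" for i in range(1, n_genes - len(genes) + 1)]
    genes = sorted(genes[:n_genes])  # regions align with sorted gene order
    bp_per_gene = int(coding_mb * 1e6 / n_genes)
    regions = []
    for i, g in enumerate(genes):
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 + (i // 22) * 100_000
        regions.append((chrom, start, start + bp_per_gene - 1))
    return PanelDefinition(
        name="cgp315",
        genes=frozenset(genes),
        coding_mb=coding_mb,
        regions=tuple(regions),
    )


def panel_gene_order(panel: PanelDefinition) -> list[str]:
    """Deterministic gene order for a panel (region order, else sorted)."""
    if panel.regions and len(panel.regions) == len(panel.genes):
        # regions were built gene-aligned by default_cgp_panel
        return sorted(panel.genes)
    return sorted(panel.genes)


def ensure_variant_columns(variants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with all cascade flags present (missing ones defaulted)."""
    out = variants.copy()
    for col, default in FLAG_DEFAULTS.items():
        if col not in out.columns:
            out[col] = default
    return out


def classify_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Vectorized filter cascade.

    Returns a frame aligned with ``variants`` with boolean ``counted`` and
    the audit ``reason`` (first matching rule).
    """
    v = ensure_variant_columns(variants)
    noncoding = (~v["coding"].astype(bool)) | (v["effect"] == "noncoding") | (
        v["effect"] == "promoter"
    )
    conds = [
        noncoding.to_numpy(),
        v["known_somatic_hotspot"].astype(bool).to_numpy(),
        v["ts_truncation"].astype(bool).to_numpy(),
        (v["zygosity_call"] == "germline").to_numpy(),
        v["recurrent_germline"].astype(bool).to_numpy(),
        v["dbsnp"].astype(bool).to_numpy(),
        (v["population_count"].astype(int) >= 2).to_numpy(),
    ]
    reason = np.select(conds, FILTER_REASONS[:7], default="counted")
    return pd.DataFrame(
        {"counted": reason == "counted", "reason": reason}, index=variants.index
    )


def classify_variant(variant: Mapping[str, object]) -> FilterDecision:
    """Scalar form of the cascade; total over any valid variant record."""
    df = pd.DataFrame([dict(variant)])
    row = classify_variants(df).iloc[0]
    return FilterDecision(counted=bool(row["counted"]), reason=str(row["reason"]))


def compute_tmb(
    variants: pd.DataFrame,
    panel: PanelDefinition,
    territory_mb: float | None = None,
) -> TMBRecord:
    """TMB for one specimen: counted mutations in panel genes per megabase.

    ``territory_mb`` overrides ``panel.coding_mb`` (e.g. exome territory).
    Empty input yields TMB 0.
    """
    mb = panel.coding_mb if territory_mb is None else territory_mb
    if mb <= 0:
        raise TMBError(f"territory_mb must be > 0, got {mb}")
    if len(variants) == 0:
        return TMBRecord("", 0, mb, 0.0)
    specimens = variants["specimen_id"].unique()
    if len(specimens) > 1:
        raise TMBError(
            f"compute_tmb expects a single specimen, got {len(specimens)}"
        )
    in_panel = variants["gene"].map(panel.contains_gene)
    decisions = classify_variants(variants.loc[in_panel])
    counted = int(decisions["counted"].sum())
    return TMBRecord(str(specimens[0]), counted, mb, counted / mb)


def compute_tmb_table(
    variants: pd.DataFrame,
    panel: PanelDefinition,
    territory_mb: float | None = None,
    specimen_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-specimen TMB over a cohort variant table.

    ``specimen_ids`` forces rows (with TMB 0) for specimens absent from the
    variant table.
    """
    mb = panel.coding_mb if territory_mb is None else territory_mb
    if mb <= 0:
        raise TMBError(f"territory_mb must be > 0, got {mb}")
    if len(variants):
        in_panel = variants["gene"].map(panel.contains_gene)
        sub = variants.loc[in_panel]
        decisions = classify_variants(sub)
        counts = (
            decisions["counted"]
            .groupby(sub["specimen_id"].to_numpy())
            .sum()
            .astype(int)
        )
    else:
        counts = pd.Series(dtype=int)
    if specimen_ids is not None:
        counts = counts.reindex(list(specimen_ids), fill_value=0).astype(int)
    out = counts.rename("counted_mutations").rename_axis("specimen_id").reset_index()
    out["territory_mb"] = mb
    out["tmb"] = out["counted_mutations"] / mb
    return out


def call_zygosity_proxy(
    allele_fraction: float,
    local_copy_number: float = 2.0,
    purity: float = 1.0,
    delta: float = 0.10,
) -> str:
    """Simplified somatic/germline call from allele fraction, CN and purity.

    Germline expectations (variant present in the normal compartment):
    heterozygous AF = (p·1 + (1−p)·1) / (p·C + (1−p)·2); homozygous AF = 1.
    A clonal somatic variant on one tumor copy has AF = p / (p·C + (1−p)·2);
    subclonal somatic variants fall below the het germline expectation.

    Returns ``germline`` within ``delta`` of a germline expectation,
    ``somatic`` if below all germline expectations or near the clonal somatic
    expectation, else ``ambiguous``.
    """
    if not 0 < purity <= 1:
        raise TMBError(f"purity must be in (0, 1], got {purity}")
    if local_copy_number < 0:
        raise TMBError(f"copy number must be >= 0, got {local_copy_number}")
    if not 0 <= allele_fraction <= 1:
        raise TMBError(f"allele_fraction must be in [0, 1], got {allele_fraction}")
    denom = purity * local_copy_number + (1 - purity) * 2
    if denom <= 0:
        return "ambiguous"
    het_exp = 1.0 / denom
    hom_exp = 1.0
    som_exp = purity / denom
    af = allele_fraction
    if abs(af - het_exp) <= delta or abs(af - hom_exp) <= delta:
        return "germline"
    if af < het_exp - delta or abs(af - som_exp) <= delta:
        return "somatic"
    return "ambiguous"


def flag_recurrent_germline(
    variants: pd.DataFrame,
    min_specimens: int | None = None,
    cohort_fraction: float = 0.001,
) -> pd.DataFrame:
    """Set ``recurrent_germline`` on sites predicted germline in many specimens.

    A site (chrom, pos, ref, alt) is recurrent when distinct specimens with a
    germline zygosity call at that site reach max(3, cohort_fraction·cohort),
    unless ``min_specimens`` overrides the threshold.
    """
    out = ensure_variant_columns(variants)
    if not len(out):
        return out
    n_specimens = out["specimen_id"].nunique()
    threshold = (
        min_specimens
        if min_specimens is not None
        else max(3, int(np.ceil(cohort_fraction * n_specimens)))
    )
    germ = out[out["zygosity_call"] == "germline"]
    key_cols = ["chrom", "pos", "ref", "alt"]
    counts = germ.groupby(key_cols)["specimen_id"].nunique()
    recurrent = set(counts[counts >= threshold].index)
    if recurrent:
        keys = list(map(tuple, out[key_cols].itertuples(index=False, name=None)))
        mask = np.fromiter((k in recurrent for k in keys), bool, len(keys))
        out.loc[mask, "recurrent_germline"] = True
    return out


def panel_vs_exome(
    exome_variants: pd.DataFrame,
    panel: PanelDefinition,
    exome_mb: float = EXOME_MB,
) -> tuple[pd.DataFrame, float]:
    """Compare panel-restricted TMB against exome-wide TMB per specimen.

    Returns the paired table (columns ``tmb_panel``, ``tmb_exome``) and the
    squared Pearson correlation across specimens.
    """
    specimens = sorted(exome_variants["specimen_id"].unique())
    if len(specimens) < 3:
        raise TMBError(
            f"panel_vs_exome requires >= 3 specimens, got {len(specimens)}"
        )
    exome_panel = PanelDefinition("exome", frozenset(), exome_mb)
    tab_panel = compute_tmb_table(exome_variants, panel, specimen_ids=specimens)
    tab_exome = compute_tmb_table(
        exome_variants, exome_panel, specimen_ids=specimens
    )
    paired = pd.DataFrame(
        {
            "specimen_id": specimens,
            "tmb_panel": tab_panel.set_index("specimen_id").loc[specimens, "tmb"].to_numpy(),
            "tmb_exome": tab_exome.set_index("specimen_id").loc[specimens, "tmb"].to_numpy(),
        }
    )
    x, y = paired["tmb_panel"].to_numpy(), paired["tmb_exome"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        r2 = float("nan")  # degenerate: no between-specimen variation
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return paired, r2
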