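"""Readers and writers for the pipeline's table formats.

MAF-like TSV dialect: UTF-8, tab-delimited, '#' comment lines, one header
row, 1-based positions.  VCF input is v4.2; POS is already 1-based and kept
as-is, and annotation flags are read from INFO keys (see ``VCF_INFO_KEYS``).
BED input is 0-based half-open and converted to 1-based inclusive on read.
Numeric columns are serialized at full precision via ``repr`` round-tripping
(pandas ``to_csv`` default).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .tmb import FLAG_DEFAULTS, PanelDefinition, ensure_variant_columns

log = logging.getLogger("tmbkit")

#: INFO keys carrying variant annotations in VCF input/output.
VCF_INFO_KEYS = {
    "GENE": ("gene", str),
    "EFFECT": ("effect", str),
    "CODING": ("coding", bool),
    "KSH": ("known_somatic_hotspot", bool),
    "TST": ("ts_truncation", bool),
    "DBSNP": ("dbsnp", bool),
    "POPC": ("population_count", int),
    "RECG": ("recurrent_germline", bool),
    "ZYG": ("zygosity_call", str),
    "VAF": ("allele_fraction", float),
    "HPL": ("homopolymer_len", int),
    "SID": ("specimen_id", str),
}

REQUIRED_VARIANT_COLUMNS = ("specimen_id", "chrom", "pos", "ref", "alt",
                            "gene", "effect")


class FormatError(ValueError):
    pass


def read_variants(path: str | Path, format: str = "maf_tsv") -> pd.DataFrame:
    if format == "maf_tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path)
    raise FormatError(f"unknown variant format {format!r}")


def _read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    bad = df.index[df["pos"] < 1]
    if len(bad):
        # +2: header line plus 1-based numbering (comment lines not tracked)
        raise FormatError(f"{path}: pos < 1 at data line {bad[0] + 2}")
    defaulted = [c for c in FLAG_DEFAULTS if c not in df.columns]
    if defaulted:
        log.warning("%s: defaulting %d absent annotation columns: %s",
                    path, len(defaulted), defaulted)
    return ensure_variant_columns(df)


def _read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal VCF v4.2 reader for annotation-bearing single-sample files."""
    rows = []
    defaulted_keys: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: fewer than 8 VCF columns")
            chrom, pos_s, _id, ref, alt, _qual, _filt, info = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer POS {pos_s!r}")
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: POS must be >= 1")
            info_map = {}
            for item in info.split(";"):
                if not item or item == ".":
                    continue
                key, _, value = item.partition("=")
                info_map[key] = value if value else True
            row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
            for key, (col, typ) in VCF_INFO_KEYS.items():
                if key in info_map:
                    raw = info_map[key]
                    if typ is bool:
                        row[col] = True if raw is True else raw not in ("0", "false")
                    else:
                        row[col] = typ(raw)
                else:
                    defaulted_keys.add(key)
            rows.append(row)
    if defaulted_keys:
        log.warning("%s: INFO keys absent on some records (defaulted): %s",
                    path, sorted(defaulted_keys))
    cols = ["specimen_id", "chrom", "pos", "ref", "alt", "gene", "effect"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = "" if c != "pos" else df.get("pos")
    return ensure_variant_columns(df[cols + [c for c in df.columns
                                             if c not in cols]])


def write_variants_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """One-file VCF v4.2 export carrying annotations in INFO."""
    col_by_key = {key: col for key, (col, _t) in VCF_INFO_KEYS.items()}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, (col, typ) in VCF_INFO_KEYS.items():
            vtype = {bool: "Flag", int: "Integer", float: "Float"}.get(typ, "String")
            number = "0" if typ is bool else "1"
            fh.write(f'##INFO=<ID={key},Number={number},Type={vtype},'
                     f'Description="{col}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            d = row._asdict()
            parts = []
            for key, col in col_by_key.items():
                if col not in d:
                    continue
                val = d[col]
                if isinstance(val, (bool, np.bool_)):
                    if val:
                        parts.append(key)
                else:
                    parts.append(f"{key}={val}")
            fh.write(f"{d['chrom']}\t{d['pos']}\t.\t{d['ref']}\t{d['alt']}"
                     f"\t.\t.\t{';'.join(parts)}\n")


def write_table(df: pd.DataFrame, path: str | Path,
                header_comment: str | None = None) -> None:
    """TSV writer with an optional leading '#' metadata line (e.g. seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_panel(bed_path: str | Path, coding_mb: float,
               name: str = "panel") -> PanelDefinition:
    """Panel from a BED file (0-based half-open -> 1-based inclusive).

    The BED name column (4th) carries the gene symbol.
    """
    genes: set[str] = set()
    regions: list[tuple[str, int, int]] = []
    with open(bed_path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{bed_path}:{lineno}: need chrom/start/end/gene")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            regions.append((chrom, start + 1, end))  # to 1-based inclusive
            genes.add(gene)
    return PanelDefinition(name=name, genes=frozenset(genes),
                           coding_mb=coding_mb, regions=tuple(regions))


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> None:
    genes = sorted(panel.genes)
    with open(path, "wt", encoding="utf-8") as fh:
        for gene, (chrom, start, end) in zip(genes, panel.regions):
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\n")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
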