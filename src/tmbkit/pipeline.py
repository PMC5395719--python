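"""End-to-end orchestration: cohort filter -> TMB -> MSI -> summaries -> associations."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import association as assoc_mod
from . import io as io_mod
from . import landscape as land_mod
from . import msi as msi_mod
from . import synthetic as syn_mod
from . import tmb as tmb_mod

log = logging.getLogger("tmbkit")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    variants_path: str | None = None  # None -> simulate a cohort
    specimens_path: str | None = None
    msi_profiles_path: str | None = None
    variant_format: str = "maf_tsv"
    territory_mb: float = 1.1
    high_tmb_threshold: float = 20.0
    min_disease_n: int = 50
    min_coverage: float = 300.0
    n_specimens: int = 500  # simulate mode
    seed: int = 0
    log_level: str = "INFO"
    model_spec: assoc_mod.ModelSpec = field(default_factory=assoc_mod.ModelSpec)

    def validate(self) -> None:
        if self.variants_path is None and self.specimens_path is not None:
            raise PipelineError("specimens_path given without variants_path")
        for p in (self.variants_path, self.specimens_path,
                  self.msi_profiles_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input path does not exist: {p}")
        if self.territory_mb <= 0:
            raise PipelineError("territory_mb must be > 0")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; writes outputs plus a run manifest, returns manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_note = f"seed={config.seed} tmbkit={__version__}"
    inputs: dict[str, str] = {}

    stage = "load"
    try:
        panel = tmb_mod.default_cgp_panel(coding_mb=config.territory_mb)
        if config.variants_path is None:
            cohort = syn_mod.generate_cohort(
                syn_mod.CohortConfig(n_specimens=config.n_specimens,
                                     seed=config.seed))
            specimens, variants = cohort.specimens, cohort.variants
            msi_profiles = cohort.msi_profiles
            truth = cohort.truth
        else:
            variants = io_mod.read_variants(config.variants_path,
                                            config.variant_format)
            inputs[config.variants_path] = _sha256(Path(config.variants_path))
            specimens = io_mod.read_table(config.specimens_path) \
                if config.specimens_path else None
            if config.specimens_path:
                inputs[config.specimens_path] = _sha256(Path(config.specimens_path))
            msi_profiles = (io_mod.read_table(config.msi_profiles_path)
                            if config.msi_profiles_path else pd.DataFrame())
            if config.msi_profiles_path:
                inputs[config.msi_profiles_path] = _sha256(
                    Path(config.msi_profiles_path))
            truth = None
            if specimens is None:
                ids = sorted(variants["specimen_id"].unique())
                specimens = pd.DataFrame(
                    {"specimen_id": ids, "patient_id": ids,
                     "disease": "unknown", "age": float("nan"),
                     "median_coverage": float("inf")})

        stage = "filter_cohort"
        eligible, exclusions = land_mod.filter_cohort(
            specimens, min_coverage=config.min_coverage)
        keep_ids = set(eligible["specimen_id"])
        variants = variants[variants["specimen_id"].isin(keep_ids)].reset_index(
            drop=True) if len(variants) else variants

        stage = "compute_tmb"
        if len(variants):
            variants = tmb_mod.flag_recurrent_germline(variants)
        tmb_table = tmb_mod.compute_tmb_table(
            variants, panel, territory_mb=config.territory_mb,
            specimen_ids=sorted(keep_ids))
        decisions = tmb_mod.classify_variants(variants) if len(variants) \
            else pd.DataFrame(columns=["counted", "reason"])
        audit = pd.concat([variants, decisions], axis=1) if len(variants) \
            else decisions
        eligible = eligible.merge(
            tmb_table[["specimen_id", "tmb"]], on="specimen_id", how="left")

        stage = "msi"
        msi_calls = pd.DataFrame(columns=["specimen_id", "msi_score", "msi_call"])
        if len(msi_profiles):
            loci = msi_mod.default_locus_panel()
            features = msi_mod.featurize_cohort(msi_profiles, loci)
            scores, _evr = msi_mod.msi_score(features)
            cls = msi_mod.classify_msi(scores)
            msi_calls = pd.DataFrame(
                {"specimen_id": features.index, "msi_score": scores.to_numpy(),
                 "msi_call": cls.calls.to_numpy()})
            eligible = eligible.merge(msi_calls[["specimen_id", "msi_call"]],
                                      on="specimen_id", how="left")

        stage = "landscape"
        summary = land_mod.disease_summary(
            eligible, high_threshold=config.high_tmb_threshold,
            min_n=config.min_disease_n)
        trend = None
        if eligible["age"].notna().sum() >= 2 and \
                eligible["age"].nunique() >= 2:
            trend = land_mod.age_trend(eligible.dropna(subset=["age"]))
        crosstab = None
        if "msi_call" in eligible.columns and eligible["msi_call"].notna().any():
            crosstab = land_mod.msi_tmb_crosstab(
                eligible.dropna(subset=["msi_call"]))

        stage = "association"
        assoc_table = pd.DataFrame()
        if len(variants):
            counted = variants.loc[decisions["counted"].to_numpy()]
            carriers = counted[["specimen_id", "gene"]].rename(
                columns={"gene": "term"})
            assoc_table = assoc_mod.gene_association(
                eligible, carriers, spec=config.model_spec)

        stage = "write"
        io_mod.write_table(tmb_table, out / "tmb_records.tsv", seed_note)
        io_mod.write_table(audit, out / "filter_audit.tsv", seed_note)
        io_mod.write_table(eligible, out / "specimens_eligible.tsv", seed_note)
        io_mod.write_table(summary, out / "disease_summary.tsv", seed_note)
        io_mod.write_table(msi_calls, out / "msi_calls.tsv", seed_note)
        io_mod.write_table(assoc_table, out / "associations.tsv", seed_note)
        if crosstab is not None:
            io_mod.write_table(crosstab.by_disease,
                               out / "msi_tmb_by_disease.tsv", seed_note)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    outputs = {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))}
    manifest = {
        "tmbkit_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()
                   if k != "model_spec"},
        "exclusions": exclusions,
        "inputs_sha256": inputs,
        "outputs_sha256": outputs,
        "age_trend_fold_10_90": trend.fold_10_90 if trend else None,
        "n_eligible": int(len(eligible)),
    }
    io_mod.write_json(manifest, out / "manifest.json")
    return manifest
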