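"""Association of genes/mutations with log-TMB, and co-occurrence testing.

The core model is ordinary least squares on

    log10(TMB + pseudo_count) ~ carrier status + disease type

fit independently per term.  The carrier coefficient ("factor loading") is
the change in log10(TMB) attributable to a functional mutation in the term,
holding disease constant; 10**loading is the fold-change.  P-values are
two-sided coefficient tests; multiple testing is controlled per analysis
family with Benjamini-Hochberg.

Mutation-level testing applies three eligibility filters first: carrier
frequency above 1/2000, homopolymer context shorter than 6 bp, and absence
from dbSNP.  Co-occurrence with a binary driver status uses per-gene
logistic regression with TMB as covariate; complete separation is reported
as non-estimable rather than raised.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Thresholds for the association analyses."""

    pseudo_count: float = 1.0  # mutations/Mb added before log10
    min_carriers_gene: int = 6
    mutation_frequency_floor: float = 1.0 / 2000.0
    homopolymer_exclusion_len: int = 6
    fdr_level_gene: float = 0.0001
    fdr_level_mutation: float = 0.05
    loading_cutoff_gene: float = 0.5
    loading_cutoff_mutation: float = 0.15
    drop_zero_tmb: bool = False  # alternative to the pseudo-count

    def __post_init__(self) -> None:
        for name in (
            "pseudo_count", "min_carriers_gene", "mutation_frequency_floor",
            "homopolymer_exclusion_len", "fdr_level_gene",
            "fdr_level_mutation", "loading_cutoff_gene",
            "loading_cutoff_mutation",
        ):
            if getattr(self, name) <= 0:
                raise AssociationError(f"{name} must be positive")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise AssociationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _normalize_carriers(
    carriers: Mapping[str, Sequence[str]] | pd.DataFrame,
    specimen_ids: pd.Index,
) -> dict[str, np.ndarray]:
    """Carrier sets -> {term: boolean vector aligned to specimen_ids}."""
    out: dict[str, np.ndarray] = {}
    if isinstance(carriers, pd.DataFrame):
        term_col = "term" if "term" in carriers.columns else "term_id"
        for term, grp in carriers.groupby(term_col):
            out[str(term)] = specimen_ids.isin(set(grp["specimen_id"])).astype(bool)
    else:
        for term, ids in carriers.items():
            out[str(term)] = specimen_ids.isin(set(ids)).astype(bool)
    return out


def _log_tmb(tmb: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Returns (log10 response, keep-mask) per the pseudo-count policy."""
    if spec.drop_zero_tmb:
        keep = tmb > 0
        return np.log10(tmb[keep]), keep
    keep = np.ones(len(tmb), dtype=bool)
    return np.log10(tmb + spec.pseudo_count), keep


def _disease_design(disease: pd.Series) -> pd.DataFrame:
    """One-hot disease columns with the most frequent level as reference."""
    counts = disease.value_counts()
    reference = counts.index[0]
    levels = [lvl for lvl in counts.index if lvl != reference]
    design = pd.DataFrame(index=disease.index)
    for lvl in levels:
        design[f"disease[{lvl}]"] = (disease == lvl).astype(float)
    return design


def _fit_term(y: np.ndarray, carrier: np.ndarray,
              disease_design: np.ndarray) -> tuple[float, float, bool]:
    """OLS of y on [1, carrier, disease dummies]; returns (loading, p, ok)."""
    X = np.column_stack(
        [np.ones(len(y)), carrier.astype(float), disease_design]
    )
    if carrier.all() or not carrier.any():
        return np.nan, np.nan, False
    model = sm.OLS(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
    except Exception:
        return np.nan, np.nan, False
    # rank-deficient design (e.g. carrier collinear with a disease dummy)
    if res.df_resid <= 0 or np.linalg.matrix_rank(X) < X.shape[1]:
        return np.nan, np.nan, False
    return float(res.params[1]), float(res.pvalues[1]), True


def _association_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["term", "n_carriers", "loading", "fold_change", "p", "q",
            "estimable"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    ok = out["estimable"].to_numpy(dtype=bool)
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    out["fold_change"] = np.power(10.0, out["loading"])
    out = out.sort_values("loading", ascending=False, kind="mergesort")
    return out[cols].reset_index(drop=True)


def gene_association(
    specimens: pd.DataFrame,
    carriers: Mapping[str, Sequence[str]] | pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> pd.DataFrame:
    """Per-gene log-linear TMB association, disease-adjusted.

    ``specimens`` needs columns specimen_id, tmb, disease.  ``carriers`` maps
    gene -> carrier specimen ids (or a long frame with columns specimen_id,
    term).  Genes with fewer than ``spec.min_carriers_gene`` carriers are
    skipped entirely; singular designs are reported with estimable=False.
    """
    if (specimens["tmb"] < 0).any():
        raise AssociationError("tmb must be >= 0 for all specimens")
    ids = pd.Index(specimens["specimen_id"])
    carrier_vecs = _normalize_carriers(carriers, ids)
    tmb = specimens["tmb"].to_numpy(dtype=float)
    y_all, keep = _log_tmb(tmb, spec)
    disease = specimens.loc[keep, "disease"].reset_index(drop=True)
    dis_design = _disease_design(disease).to_numpy()
    rows = []
    for term in sorted(carrier_vecs):
        vec = carrier_vecs[term]
        n_carriers = int(vec.sum())
        if n_carriers < spec.min_carriers_gene:
            continue
        loading, p, ok = _fit_term(y_all, vec[keep], dis_design)
        rows.append(
            {"term": term, "n_carriers": n_carriers, "loading": loading,
             "p": p, "estimable": ok}
        )
    return _association_frame(rows)


def mutation_association(
    specimens: pd.DataFrame,
    carriers: Mapping[str, Sequence[str]] | pd.DataFrame,
    annotations: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> pd.DataFrame:
    """Per-mutation association after the three eligibility filters.

    ``annotations`` indexes mutations by ``term`` with columns
    ``homopolymer_len`` and ``dbsnp``.  The returned frame adds a
    ``selected`` column: q below the mutation FDR level and loading above the
    mutation loading cutoff.
    """
    ids = pd.Index(specimens["specimen_id"])
    carrier_vecs = _normalize_carriers(carriers, ids)
    ann = annotations.set_index("term") if "term" in annotations.columns else annotations
    n = len(ids)
    eligible: dict[str, list[str]] = {}
    for term, vec in carrier_vecs.items():
        freq = vec.sum() / n
        if freq <= spec.mutation_frequency_floor:
            continue
        if term in ann.index:
            if int(ann.loc[term, "homopolymer_len"]) >= spec.homopolymer_exclusion_len:
                continue
            if bool(ann.loc[term, "dbsnp"]):
                continue
        eligible[term] = ids[vec].tolist()
    result = gene_association(
        specimens, eligible, spec=dataclasses.replace(spec, min_carriers_gene=1)
    )
    result["selected"] = (
        (result["q"] < spec.fdr_level_mutation)
        & (result["loading"] > spec.loading_cutoff_mutation)
    ).fillna(False)
    return result


def cooccurrence_test(
    outcome: pd.Series,
    carriers: Mapping[str, Sequence[str]] | pd.DataFrame,
    specimens: pd.DataFrame,
) -> pd.DataFrame:
    """Logistic co-occurrence test per gene, adjusting for TMB.

    ``outcome`` is a boolean per-specimen status (e.g. promoter-mutant),
    indexed like ``specimens['specimen_id']``.  Complete separation or
    non-convergence is flagged estimable=False for the affected gene only.
    Returns columns term, n_carriers, odds_ratio, p, q, estimable.
    """
    ids = pd.Index(specimens["specimen_id"])
    y = np.asarray(outcome.reindex(ids).to_numpy() if isinstance(outcome, pd.Series)
                   else outcome, dtype=float)
    if np.isnan(y).any():
        raise AssociationError("outcome missing for some specimens")
    if y.all() or not y.any():
        raise AssociationError("outcome is degenerate (all 0 or all 1)")
    tmb = specimens["tmb"].to_numpy(dtype=float)
    if not np.isfinite(tmb).all():
        raise AssociationError("tmb must be finite")
    carrier_vecs = _normalize_carriers(carriers, ids)
    rows = []
    for term in sorted(carrier_vecs):
        vec = carrier_vecs[term].astype(float)
        X = np.column_stack([np.ones(len(y)), vec, tmb])
        beta, p, ok = _fit_logit(y, X)
        rows.append(
            {"term": term, "n_carriers": int(vec.sum()),
             "odds_ratio": float(np.exp(beta)) if ok else np.nan,
             "p": p, "estimable": ok}
        )
    out = pd.DataFrame(rows)
    ok_mask = out["estimable"].to_numpy(dtype=bool)
    q = np.full(len(out), np.nan)
    if ok_mask.any():
        q[ok_mask] = bh_fdr(out.loc[ok_mask, "p"].to_numpy())
    out["q"] = q
    return out[["term", "n_carriers", "odds_ratio", "p", "q", "estimable"]]


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[float, float, bool]:
    if X[:, 1].sum() in (0, len(y)):
        return np.nan, np.nan, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", False):
            return np.nan, np.nan, False
        beta = float(res.params[1])
        p = float(res.pvalues[1])
        # huge coefficients betray quasi-separation that slipped past the
        # statsmodels check
        if not np.isfinite(p) or abs(beta) > 15:
            return np.nan, np.nan, False
        return beta, p, True
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return np.nan, np.nan, False
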