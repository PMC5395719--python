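"""Microsatellite-instability scoring from homopolymer read repeat lengths.

For each locus in a fixed panel of intronic homopolymers (reference repeat
length 10-20 bp), the repeat length of every read spanning the locus is
recorded.  Per-locus means and variances form the feature vector (2 features
per locus; 228 for the default 114-locus panel).  Specimens are projected
onto the first principal component of the centered feature matrix, with the
sign oriented so that higher score means greater length variability, and the
score axis is partitioned into MSS / ambiguous / MSI-H ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

DEFAULT_PANEL_SIZE = 114
MIN_REF_REPEAT_LEN = 10
MAX_REF_REPEAT_LEN = 20

CALL_MSI_HIGH = "MSI-H"
CALL_AMBIGUOUS = "ambiguous"
CALL_MSS = "MSS"


class MSIError(ValueError):
    pass


class MissingLocusDataError(MSIError):
    """A panel locus lacks the reads needed to define its variance feature."""


@dataclass(frozen=True)
class MSILocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    reference_repeat_len: int
    intronic: bool = True

    def __post_init__(self) -> None:
        if not MIN_REF_REPEAT_LEN <= self.reference_repeat_len <= MAX_REF_REPEAT_LEN:
            raise MSIError(
                f"locus {self.locus_id}: reference repeat length "
                f"{self.reference_repeat_len} outside "
                f"[{MIN_REF_REPEAT_LEN}, {MAX_REF_REPEAT_LEN}]"
            )
        if not self.intronic:
            raise MSIError(f"locus {self.locus_id}: panel loci must be intronic")


@dataclass
class MSIClassification:
    calls: pd.Series  # specimen-indexed calls
    threshold_low: float  # score <= low -> MSS
    threshold_high: float  # score >= high -> MSI-H
    method: str


def default_locus_panel(n_loci: int = DEFAULT_PANEL_SIZE) -> list[MSILocus]:
    """Deterministic synthetic locus panel mimicking the production one.

    Reference repeat lengths cycle through 10-20 bp; all loci intronic.
    """
    loci = []
    for i in range(n_loci):
        ref_len = MIN_REF_REPEAT_LEN + i % (MAX_REF_REPEAT_LEN - MIN_REF_REPEAT_LEN + 1)
        chrom = f"chr{(i % 22) + 1}"
        start = 5_000_000 + i * 10_000
        loci.append(
            MSILocus(
                locus_id=f"MSI{i + 1:03d}",
                chrom=chrom,
                start=start,
                end=start + ref_len - 1,
                reference_repeat_len=ref_len,
            )
        )
    return loci


def locus_variability(mean_lengths: pd.DataFrame) -> pd.Series:
    """Between-sample variability of per-locus mean repeat length.

    ``mean_lengths``: specimens x loci matrix of per-locus mean lengths.
    Returns the per-locus variance across specimens (ddof=1).
    """
    return mean_lengths.var(axis=0, ddof=1)


def select_loci(candidates: pd.DataFrame, k: int,
                variability_col: str = "variability") -> pd.DataFrame:
    """Keep the k candidate loci with the highest between-sample variability.

    Ties broken lexicographically on ``locus_id`` so selection is
    deterministic.
    """
    if k > len(candidates):
        raise MSIError(f"k={k} exceeds candidate count {len(candidates)}")
    ordered = candidates.sort_values(
        [variability_col, "locus_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(k).reset_index(drop=True)


def feature_names(panel: list[MSILocus]) -> list[str]:
    names = []
    for locus in panel:
        names.append(f"{locus.locus_id}_mean")
        names.append(f"{locus.locus_id}_var")
    return names


def featurize(profile: pd.DataFrame, panel: list[MSILocus],
              ddof: int = 1) -> np.ndarray:
    """Per-locus (mean, variance) features for one specimen.

    ``profile`` is long-format with columns ``locus_id`` and
    ``repeat_length``.  Every panel locus needs >= 2 reads so the sample
    variance is defined.  Feature order is (mean, var) per locus in panel
    order; length 2L.
    """
    grouped = profile.groupby("locus_id")["repeat_length"]
    means = grouped.mean()
    variances = grouped.var(ddof=ddof)
    counts = grouped.size()
    features = np.empty(2 * len(panel))
    for i, locus in enumerate(panel):
        if locus.locus_id not in counts.index or counts[locus.locus_id] < 2:
            raise MissingLocusDataError(
                f"locus {locus.locus_id} has fewer than 2 spanning reads"
            )
        features[2 * i] = means[locus.locus_id]
        features[2 * i + 1] = variances[locus.locus_id]
    return features


def featurize_cohort(profiles: pd.DataFrame, panel: list[MSILocus],
                     ddof: int = 1) -> pd.DataFrame:
    """Feature matrix (specimens x 2L) from a cohort-long profile table."""
    grouped = profiles.groupby(["specimen_id", "locus_id"])["repeat_length"]
    stats = grouped.agg(["mean", "var", "size"])
    if ddof != 1:
        stats["var"] = grouped.var(ddof=ddof)
    if (stats["size"] < 2).any():
        bad = stats.index[stats["size"] < 2][0]
        raise MissingLocusDataError(
            f"locus {bad[1]} has fewer than 2 spanning reads in specimen {bad[0]}"
        )
    mean_wide = stats["mean"].unstack("locus_id")
    var_wide = stats["var"].unstack("locus_id")
    panel_ids = [l.locus_id for l in panel]
    missing = set(panel_ids) - set(mean_wide.columns)
    if missing:
        raise MissingLocusDataError(
            f"loci absent from profiles: {sorted(missing)[:5]}"
        )
    out = pd.DataFrame(index=mean_wide.index, columns=feature_names(panel),
                       dtype=float)
    for lid in panel_ids:
        out[f"{lid}_mean"] = mean_wide[lid]
        out[f"{lid}_var"] = var_wide[lid]
    if out.isna().any().any():
        bad = out.columns[out.isna().any()][0]
        raise MissingLocusDataError(f"missing data in feature {bad}")
    return out


def msi_score(features: pd.DataFrame, scale: bool = False
              ) -> tuple[pd.Series, np.ndarray]:
    """Project specimens onto the first principal component of the features.

    Features are centered per column (optionally standardized when
    ``scale``).  The PC sign is oriented so that higher score correlates
    positively with the mean of the variance features, i.e. score increases
    with instability.  Returns (scores, variance-explained fractions).
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 3:
        raise MSIError(f"msi_score requires >= 3 specimens, got {X.shape[0]}")
    if not np.isfinite(X).all():
        raise MSIError("features must be finite")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if np.allclose(Xc, 0):
        raise MSIError("degenerate PCA: feature matrix is constant")
    n_comp = min(Xc.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    projections = pca.fit_transform(Xc)
    scores = projections[:, 0]
    # orientation: instability shows up as inflated per-locus variances,
    # which live in the odd feature columns
    var_cols = np.arange(1, X.shape[1], 2)
    mean_variance = X[:, var_cols].mean(axis=1)
    if np.std(mean_variance) > 0 and np.corrcoef(scores, mean_variance)[0, 1] < 0:
        scores = -scores
    index = features.index if isinstance(features, pd.DataFrame) else None
    return pd.Series(scores, index=index, name="msi_score"), pca.explained_variance_ratio_


def _labeled_thresholds(scores: np.ndarray, labels: np.ndarray
                        ) -> tuple[float, float]:
    """Score thresholds minimizing training misclassification.

    Ambiguous band = overlap of labeled score ranges (empty band when the
    classes separate perfectly).
    """
    high_scores = scores[labels]
    low_scores = scores[~labels]
    if len(high_scores) == 0 or len(low_scores) == 0:
        raise MSIError("labeled thresholding needs both classes present")
    lo, hi = float(np.min(high_scores)), float(np.max(low_scores))
    if lo > hi:  # perfect separation: single threshold, empty band
        t = (lo + hi) / 2.0
        return t, t
    return lo, hi


def classify_msi(scores: pd.Series, labels: pd.Series | None = None,
                 posterior_band: tuple[float, float] = (0.1, 0.9),
                 random_state: int = 0) -> MSIClassification:
    """Partition the score axis into MSS / ambiguous / MSI-H ranges.

    With training ``labels`` (boolean, True = MSI-H) the thresholds minimize
    training misclassification.  Without labels a two-component 1-D Gaussian
    mixture is fit and the ambiguous band is where the posterior probability
    of the unstable component lies strictly inside ``posterior_band``.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 10:
        raise MSIError(f"classify_msi requires >= 10 specimens, got {len(s)}")
    if np.all(s == s[0]):
        raise MSIError("all scores identical; cannot threshold")

    if labels is not None:
        lab = np.asarray(labels, dtype=bool)
        t_low, t_high = _labeled_thresholds(s, lab)
        method = "labeled"
    else:
        gmm = GaussianMixture(
            n_components=2, covariance_type="full", random_state=random_state,
            n_init=3,
        )
        gmm.fit(s.reshape(-1, 1))
        high_comp = int(np.argmax(gmm.means_.ravel()))
        grid = np.linspace(s.min(), s.max(), 2001)
        post = gmm.predict_proba(grid.reshape(-1, 1))[:, high_comp]
        lo_band, hi_band = posterior_band
        below = grid[post <= lo_band]
        above = grid[post >= hi_band]
        t_low = float(below.max()) if len(below) else float(s.min())
        t_high = float(above.min()) if len(above) else float(s.max())
        if t_low > t_high:  # posterior not monotone on the grid; collapse band
            t_low = t_high = (t_low + t_high) / 2.0
        method = "gmm"

    calls = np.where(
        s > t_high, CALL_MSI_HIGH, np.where(s < t_low, CALL_MSS, CALL_AMBIGUOUS)
    )
    # boundary scores at a collapsed band resolve by side
    if t_low == t_high:
        calls = np.where(s > t_high, CALL_MSI_HIGH, CALL_MSS)
    index = scores.index if isinstance(scores, pd.Series) else None
    return MSIClassification(
        calls=pd.Series(calls, index=index, name="msi_call"),
        threshold_low=t_low,
        threshold_high=t_high,
        method=method,
    )
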