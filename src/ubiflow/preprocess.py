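"""Filtering, normalisation and imputation for intensity matrices.

The processing order mirrors standard label-free MS practice: (1) drop
features with too many missing detections per replicate group, (2)
quantile-normalise the surviving raw intensities and move to log2, (3)
replace remaining missing cells with draws from a per-sample left-shifted
Gaussian — the de facto convention for left-censored (detection-limit)
missingness.  A separate QC filter implements the metabolomics "80% rule"
and the QC-sample RSD cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, SampleDesign

__all__ = [
    "PreprocessParams",
    "filter_by_missingness",
    "quantile_normalize_log2",
    "impute_missing",
    "metabolome_qc_filter",
    "preprocess_matrix",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable preprocessing parameters.

    max_missing_protein / max_missing_peptide: a feature is excluded when
    any replicate group has MORE than this many missing detections
    (defaults 2 and 3 for 4-replicate groups).
    impute_shift / impute_width: location shift and width of the imputation
    distribution, in units of the per-sample SD of observed log2 values.
    metabolome_presence_fraction: "80% rule" presence threshold.
    metabolome_max_rsd: maximum relative SD over QC samples (0.30 = 30%).
    """

    max_missing_protein: int = 2
    max_missing_peptide: int = 3
    impute_shift: float = 1.8
    impute_width: float = 0.3
    seed: int = 0
    metabolome_presence_fraction: float = 0.8
    metabolome_max_rsd: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 <= self.metabolome_presence_fraction <= 1.0):
            raise ValueError("presence fraction must lie in [0, 1]")
        if self.impute_shift <= 0 or self.impute_width <= 0:
            raise ValueError("imputation shift and width must be positive")
        if self.max_missing_protein < 0 or self.max_missing_peptide < 0:
            raise ValueError("max_missing thresholds must be >= 0")


def filter_by_missingness(
    matrix: AbundanceMatrix, design: SampleDesign, max_missing: int
) -> AbundanceMatrix:
    """Keep features with <= ``max_missing`` missing cells in EVERY group.

    Feature order is preserved.  A threshold as large as the group size
    makes the filter vacuous; that is warned about, not an error.
    """
    matrix.check_design(design)
    for g, n in design.replicates_per_group.items():
        if max_missing >= n:
            warnings.warn(
                f"max_missing={max_missing} >= group size {n} for {g!r}; "
                "filter is vacuous for that group",
                stacklevel=2,
            )
    keep = pd.Series(True, index=matrix.feature_ids)
    for g in design.group_order:
        cols = list(design.samples_in(g))
        n_missing = matrix.values[cols].isna().sum(axis=1)
        keep &= n_missing <= max_missing
    return AbundanceMatrix(matrix.values.loc[keep].copy(), matrix.scale)


def quantile_normalize_log2(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Classical quantile normalisation on observed values, then log2.

    Each sample's observed values are mapped, by mid-rank quantile, onto a
    reference distribution: the across-sample mean of sorted observed
    values, interpolated to a common grid of length equal to the largest
    per-sample observed count.  Ties receive the mean of their rank range.
    For complete data this is exactly the classical procedure: every
    sample's sorted vector becomes the cross-sample mean of sorted vectors.
    Missing cells stay missing.
    """
    if matrix.scale != "raw":
        raise ValueError("quantile_normalize_log2 expects a raw-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    counts = (~np.isnan(vals)).sum(axis=0)
    if np.any(counts == 0):
        empty = matrix.sample_ids[counts == 0].tolist()
        raise ValueError(f"samples with zero observed values: {empty}")
    grid_len = int(counts.max())
    grid = np.linspace(0.0, 1.0, grid_len)

    # reference = mean over samples of each sample's observed quantile curve
    ref = np.zeros(grid_len)
    for j in range(n_samp):
        obs = np.sort(vals[~np.isnan(vals[:, j]), j])
        if obs.size == 1:
            ref += obs[0]
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, obs.size), obs)
    ref /= n_samp

    from scipy.stats import rankdata

    out = np.full_like(vals, np.nan)
    for j in range(n_samp):
        mask = ~np.isnan(vals[:, j])
        obs = vals[mask, j]
        if obs.size == 1:
            out[mask, j] = ref.mean()
            continue
        q = (rankdata(obs, method="average") - 1.0) / (obs.size - 1.0)
        out[mask, j] = np.interp(q, grid, ref)

    normed = pd.DataFrame(np.log2(out), index=matrix.feature_ids, columns=matrix.sample_ids)
    return AbundanceMatrix(normed, scale="log2_normalized")


def impute_missing(
    matrix: AbundanceMatrix,
    params: PreprocessParams | None = None,
    rng: np.random.Generator | None = None,
) -> AbundanceMatrix:
    """Replace missing log2 cells with left-shifted Gaussian draws.

    Per sample: mean = observed mean − shift·SD, sd = width·SD, emulating
    intensities below the detection limit ("small values captured in each
    sample").  Observed cells are never altered; a fixed seed gives
    bit-identical output.
    """
    params = params or PreprocessParams()
    if matrix.scale != "log2_normalized":
        raise ValueError("impute_missing expects a log2-normalised matrix")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    vals = matrix.values.to_numpy(dtype=float).copy()
    if not np.isnan(vals).any():
        return matrix.copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            raise ValueError(
                f"sample {matrix.sample_ids[j]!r} has fewer than 2 observed "
                "values; imputation SD undefined"
            )
        mu = obs.mean() - params.impute_shift * obs.std(ddof=1)
        sd = params.impute_width * obs.std(ddof=1)
        miss = np.isnan(col)
        col[miss] = rng.normal(mu, sd, size=int(miss.sum()))
    out = pd.DataFrame(vals, index=matrix.feature_ids, columns=matrix.sample_ids)
    return AbundanceMatrix(out, scale="log2_normalized")


def metabolome_qc_filter(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    qc_samples: Sequence[str] = (),
    params: PreprocessParams | None = None,
) -> AbundanceMatrix:
    """Metabolomics feature QC: the "80% rule" then the QC-RSD cut.

    A feature is kept if observed in >= ``metabolome_presence_fraction`` of
    the samples of at least one group (preserves group-specific
    metabolites); then, when QC injections exist, features whose relative
    SD (SD/mean) over QC samples exceeds ``metabolome_max_rsd`` are dropped.
    """
    params = params or PreprocessParams()
    unknown = set(qc_samples) - set(matrix.sample_ids)
    if unknown:
        raise ValueError(f"QC samples absent from matrix: {sorted(unknown)}")
    keep = pd.Series(False, index=matrix.feature_ids)
    for g in design.group_order:
        cols = [s for s in design.samples_in(g) if s in matrix.sample_ids]
        if not cols:
            continue
        frac = matrix.values[cols].notna().mean(axis=1)
        keep |= frac >= params.metabolome_presence_fraction
    if qc_samples:
        qc = matrix.values[list(qc_samples)]
        rsd = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
        keep &= ~(rsd > params.metabolome_max_rsd).fillna(False)
    return AbundanceMatrix(matrix.values.loc[keep].copy(), matrix.scale)


def preprocess_matrix(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    max_missing: int,
    params: PreprocessParams | None = None,
    rng: np.random.Generator | None = None,
) -> AbundanceMatrix:
    """Filter -> quantile-normalise+log2 -> impute, in that order."""
    params = params or PreprocessParams()
    filtered = filter_by_missingness(matrix, design, max_missing)
    normed = quantile_normalize_log2(filtered)
    return impute_missing(normed, params, rng=rng)
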