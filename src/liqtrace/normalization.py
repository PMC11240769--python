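"""Median-of-ratios count normalization.

Each sample's size factor is the median, over a reference set of features, of
the ratio between that sample's raw count and the feature's pseudo-reference
value (the geometric mean of the feature's counts across all samples).  The
reference set is the features with strictly positive counts in every sample;
a feature with a zero anywhere has an undefined geometric-mean ratio and is
excluded.  Dividing each column by its size factor puts samples of different
sequencing depths on a common scale, on which downstream expression thresholds
(e.g. "at least 10 normalized counts") are interpreted.

Size factors are deliberately not rescaled to geometric mean one: the raw
median ratios are what downstream absolute thresholds consume.

For sparse matrices (small-RNA panels) where almost every feature contains a
zero, an optional positive-subset mode computes each feature's reference over
its positive samples only, and each sample's median over the features positive
in that sample.  It is off by default and always logged when used.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from liqtrace.core_data import CountMatrix

log = logging.getLogger(__name__)

# Below this many all-positive features the plain median is fragile; the error
# message points at the positive-subset fallback.
MIN_USABLE_FEATURES = 1


class NormalizationError(ValueError):
    pass


def _as_frame(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, CountMatrix):
        return matrix.values
    return matrix


def compute_size_factors(
    matrix: CountMatrix | pd.DataFrame, positive_subset: bool = False
) -> pd.Series:
    """Per-sample size factors from the median-of-ratios procedure.

    Parameters
    ----------
    matrix
        Raw counts, features x samples.
    positive_subset
        Use the sparse-matrix fallback: geometric means over positive samples
        only, and per-sample medians over features positive in that sample.

    Returns
    -------
    pandas.Series of positive floats indexed by sample ID.
    """
    counts = _as_frame(matrix).to_numpy(dtype=float)
    sample_ids = list(_as_frame(matrix).columns)
    if counts.shape[1] == 0:
        raise NormalizationError("matrix has no samples")

    if positive_subset:
        log.info("median-of-ratios: positive-subset fallback enabled")
        pos = counts > 0
        if not pos.any():
            raise NormalizationError("matrix has no positive counts")
        with np.errstate(divide="ignore"):
            logc = np.where(pos, np.log(np.where(pos, counts, 1.0)), np.nan)
        n_pos = pos.sum(axis=1)
        usable = n_pos > 0
        log_ref = np.nanmean(logc[usable], axis=1)
        ratios = counts[usable] / np.exp(log_ref)[:, None]
        pos_u = pos[usable]
        sf = np.empty(counts.shape[1])
        for j in range(counts.shape[1]):
            col = ratios[pos_u[:, j], j]
            if col.size == 0:
                raise NormalizationError(
                    f"sample {sample_ids[j]!r} has no positive counts; cannot normalize"
                )
            sf[j] = np.median(col)
    else:
        usable = (counts > 0).all(axis=1)
        n_usable = int(usable.sum())
        if n_usable < MIN_USABLE_FEATURES:
            raise NormalizationError(
                "no feature has strictly positive counts in every sample; "
                "enable the positive-subset fallback (positive_subset=True) "
                "for sparse matrices"
            )
        if n_usable < 20:
            log.warning(
                "median-of-ratios reference has only %d all-positive features; "
                "consider the positive-subset fallback", n_usable,
            )
        sub = counts[usable]
        log_ref = np.log(sub).mean(axis=1)  # log geometric mean per feature
        ratios = sub / np.exp(log_ref)[:, None]
        sf = np.median(ratios, axis=0)

    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise NormalizationError("computed a non-finite or non-positive size factor")
    return pd.Series(sf, index=sample_ids, name="size_factor")


def normalize(matrix: CountMatrix | pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor.

    Zero counts stay zero; ``normalized * size_factor`` reconstructs the raw
    counts exactly.
    """
    df = _as_frame(matrix)
    missing = [s for s in df.columns if s not in size_factors.index]
    if missing:
        raise NormalizationError(f"size factors missing for samples: {missing}")
    sf = size_factors.reindex(df.columns)
    return df.astype(float) / sf


__all__ = ["NormalizationError", "compute_size_factors", "normalize"]
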