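"""Per-sample scale calibration.

Two routes, mirroring how the counts were produced:

* :func:`ercc_calibrate` — when ERCC spike-ins were sequenced, a single
  proportional response line (shared slope) is fit to log2 spike counts
  against log2 nominal mix concentration, with per-sample intercepts;
  iteratively reweighted least squares with Tukey bisquare weights plus a
  MAD-based outlier pruning loop absorbs pipetting/amplification errors.
  The per-sample intercepts become size factors.
* :func:`median_normalize` — without spike-ins, a median-of-ratios
  correction against the per-gene median reference.

Size factors are geometric-mean normalised to 1; dividing a sample's
counts by its factor puts all libraries on a common scale.  One factor
per library applies to both exon and intron counts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from statsmodels.robust.norms import TukeyBiweight
from statsmodels.robust.robust_linear_model import RLM

from .genemodel import MatchedCounts

__all__ = ["ercc_calibrate", "median_normalize", "apply_factors", "read_ercc_mix"]

MIN_USABLE_SPIKES = 8


def read_ercc_mix(path, conc_column: str = "mix1_conc") -> pd.Series:
    """Read an ERCC mix table (TSV: spike_id, mix1_conc[, mix2_conc])."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    conc = df[conc_column].astype(float)
    if (conc <= 0).any():
        bad = conc.index[conc <= 0].tolist()
        raise ValueError(f"non-positive nominal concentration for {bad}")
    if conc.index.has_duplicates:
        raise ValueError("duplicated spike ids in mix table")
    return conc


def _normalize_geometric(factors: pd.Series) -> pd.Series:
    return factors / np.exp(np.log(factors).mean())


def ercc_calibrate(
    spike_counts: pd.DataFrame,
    mix: pd.Series,
    max_iter: int = 20,
    resid_mad_cut: float = 2.0,
) -> pd.Series:
    """Estimate size factors from ERCC spike-in counts.

    Model: log2(count_ij + 0.5) = a_j + b * log2(nominal_i), one intercept
    a_j per sample j and a single shared slope b — the spike response is
    proportional, not an absolute concentration calibration.  The fit is
    IRLS with Tukey bisquare weights; after each fit, observations with
    |residual| > resid_mad_cut * MAD are excluded and the model refit
    until the excluded set stabilises (or ``max_iter``).  Size factors are
    2**(a_j - mean(a)), geometric-mean normalised.
    """
    shared = spike_counts.index.intersection(mix.index)
    counts = spike_counts.loc[shared]
    usable = (counts > 0).all(axis=1)
    counts = counts.loc[usable]
    if counts.shape[0] < MIN_USABLE_SPIKES:
        raise ValueError(
            f"only {counts.shape[0]} spike-ins with nonzero counts in every sample "
            f"(need >= {MIN_USABLE_SPIKES}); fall back to median_normalize"
        )
    nominal = np.log2(mix.loc[counts.index].to_numpy(dtype=float))
    n_spikes, n_samples = counts.shape
    y = np.log2(counts.to_numpy(dtype=float) + 0.5).ravel(order="F")
    # design: per-sample intercept dummies + shared slope column
    X = np.zeros((n_spikes * n_samples, n_samples + 1))
    for j in range(n_samples):
        X[j * n_spikes : (j + 1) * n_spikes, j] = 1.0
        X[j * n_spikes : (j + 1) * n_spikes, n_samples] = nominal

    keep = np.ones(y.size, dtype=bool)
    params = None
    for _ in range(max_iter):
        params = _robust_fit(y[keep], X[keep])
        resid = y - X @ params
        mad = median_abs_deviation(resid[keep], scale="normal")
        if mad <= 0:
            break
        new_keep = np.abs(resid) <= resid_mad_cut * mad
        # never prune a sample's entire spike set
        for j in range(n_samples):
            block = slice(j * n_spikes, (j + 1) * n_spikes)
            if not new_keep[block].any():
                new_keep[block] = keep[block]
        if (new_keep == keep).all():
            break
        keep = new_keep
    intercepts = params[:n_samples]
    factors = pd.Series(
        2.0 ** (intercepts - intercepts.mean()), index=counts.columns, name="size_factor"
    )
    return _normalize_geometric(factors)


def _robust_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ ols
    if np.abs(resid).max() < 1e-10 * max(np.abs(y).max(), 1.0):
        return ols  # noiseless: IRLS scale degenerates
    return np.asarray(RLM(y, X, M=TukeyBiweight()).fit(start_params=ols).params)


def median_normalize(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the per-gene median reference.

    reference_g = median_j(count_gj); s_j = median_g(count_gj / reference_g)
    over genes with a nonzero reference, geometric-mean normalised.
    """
    mat = counts.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    if not (mat > 0).all(axis=1).any():
        raise ValueError("no gene with nonzero counts in every sample")
    ref = np.median(mat, axis=1)
    ok = ref > 0
    ratios = mat[ok] / ref[ok, None]
    factors = pd.Series(
        np.median(ratios, axis=0), index=counts.columns, name="size_factor"
    )
    if (factors <= 0).any():
        raise ValueError("a sample has median ratio 0; matrix too sparse to normalise")
    return _normalize_geometric(factors)


def apply_factors(mc: MatchedCounts, factors: pd.Series) -> MatchedCounts:
    """Divide each sample's exon and intron columns by its size factor."""
    missing = mc.samples.difference(factors.index)
    if len(missing) > 0:
        raise ValueError(f"no size factor for samples: {missing.tolist()}")
    f = factors.loc[mc.samples]
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    exon = mc.exon / f
    intron = mc.intron / f
    exon.attrs["calibrated"] = intron.attrs["calibrated"] = True
    return replace(mc, exon=exon, intron=intron, calibrated=True)
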