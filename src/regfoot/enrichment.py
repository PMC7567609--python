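"""Stable-isotope (SILAC-style) pulldown enrichment statistics.

In a DNA-affinity chromatography experiment, lysate grown on heavy lysine
is incubated with the target promoter sequence and lysate grown on light
lysine with a scrambled control (or vice versa); mass spectrometry then
yields a heavy and a light intensity per protein.  The transcription
factor that binds the target specifically shows up as an *outlier* in the
distribution of log2(heavy/light) ratios over all detected proteins.

This module computes the per-protein log ratios, fits a robust null
(median/MAD Gaussian) to the bulk of the distribution, assigns one-sided
upper-tail p-values, and applies Benjamini–Hochberg multiple-testing
correction; a protein is flagged significant when its adjusted p-value
falls below the threshold (0.01 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_enrichment",
    "detect_outliers",
    "enrichment_table",
]

_MAD_SCALE = 1.4826  # MAD -> sigma for a Gaussian


def compute_enrichment(quant: pd.DataFrame, pseudo_intensity: float = 0.0) -> pd.Series:
    """Per-protein log2((heavy + pseudo) / (light + pseudo)) ratios.

    ``quant`` needs columns ``protein``, ``heavy``, ``light``.  A small
    ``pseudo_intensity`` guards against zero intensities in either channel.
    """
    required = [c for c in ("protein", "heavy", "light") if c not in quant.columns]
    if required:
        raise ValueError(f"quant table missing columns: {required}")
    if len(quant) == 0:
        raise ValueError("empty quantification table")
    if len(quant) < 3:
        raise ValueError("need at least 3 proteins to compute enrichment")
    heavy = quant["heavy"].to_numpy(dtype=float)
    light = quant["light"].to_numpy(dtype=float)
    if (heavy < 0).any() or (light < 0).any():
        raise ValueError("intensities must be non-negative")
    if ((heavy + light) <= 0).any():
        raise ValueError("each protein needs at least one positive intensity")
    with np.errstate(divide="ignore"):
        ratios = np.log2((heavy + pseudo_intensity) / (light + pseudo_intensity))
    if not np.isfinite(ratios).all():
        raise ValueError(
            "non-finite log ratio (zero intensity?); set pseudo_intensity > 0"
        )
    return pd.Series(ratios, index=quant["protein"].to_numpy(), name="log2_ratio")


def detect_outliers(
    log_ratios: pd.Series | np.ndarray,
    alpha: float = 0.01,
    min_proteins: int = 10,
) -> pd.DataFrame:
    """Robust upper-tail outlier detection with BH correction.

    The bulk of the log-ratio distribution estimates the null: center =
    median, scale = 1.4826 x MAD (the Gaussian-consistent median absolute
    deviation).  Each protein gets a one-sided upper-tail normal p-value
    for its robust z-score, then Benjamini–Hochberg adjusted q-values;
    ``significant`` marks q < ``alpha``.

    Returns a DataFrame with columns ``log2_ratio``, ``z``, ``p``, ``q``,
    ``significant``, indexed like the input.
    """
    values = np.asarray(log_ratios, dtype=float)
    index = log_ratios.index if isinstance(log_ratios, pd.Series) else pd.RangeIndex(len(values))
    if values.size < min_proteins:
        raise ValueError(
            f"need >= {min_proteins} proteins for a stable null, got {values.size}"
        )
    center = np.median(values)
    mad = np.median(np.abs(values - center))
    if mad == 0:
        raise ValueError("MAD of log ratios is zero; null scale undefined")
    z = (values - center) / (_MAD_SCALE * mad)
    p = stats.norm.sf(z)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "log2_ratio": values,
            "z": z,
            "p": p,
            "q": q,
            "significant": q < alpha,
        },
        index=index,
    )


def enrichment_table(
    quant: pd.DataFrame, pseudo_intensity: float = 0.0, alpha: float = 0.01
) -> pd.DataFrame:
    """End-to-end enrichment analysis of a protein quantification table."""
    ratios = compute_enrichment(quant, pseudo_intensity=pseudo_intensity)
    result = detect_outliers(ratios, alpha=alpha)
    result.insert(0, "protein", result.index)
    return result.reset_index(drop=True)
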