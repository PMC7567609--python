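"""Per-base mutual-information footprints of promoter-variant libraries.

For each position b of the mutagenized window, reads are cross-classified
by two binary variables: m (0 = the read's variant is mutated at b, 1 =
wild type at b) and mu (0 = the read comes from the DNA library, 1 = from
mRNA).  The footprint value at b is the plug-in mutual information

    I_b = sum_{m, mu} p(m, mu) log2[ p(m, mu) / (p_mut(m) p_expr(mu)) ]

in bits, where the probabilities are read-mass fractions.  Positions where
mutations *raise* the average mRNA/DNA ratio are marked repressor-like,
positions where they lower it activator-like — the polarity that seeds
downstream binding-site calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import encode, encode_many
from .synth import CountTable

__all__ = [
    "ACTIVATING",
    "REPRESSING",
    "MutationProfile",
    "InformationFootprint",
    "compute_mutation_profile",
    "compute_footprint",
    "smooth_footprint",
]

ACTIVATING = 1  # mutations lower expression: position supports activation
REPRESSING = -1  # mutations raise expression: position supports repression

_POLARITY_LABEL = {ACTIVATING: "activating", REPRESSING: "repressing"}


@dataclass
class MutationProfile:
    """Binary wild-type/mutated profile of each variant at each position.

    ``values[v, b]`` is 1 where variant v carries the wild-type base at
    position b and 0 where it is mutated, matching the footprint's m
    variable.  ``variant_ids`` aligns rows to count-table variant ids.
    """

    values: np.ndarray  # (n_variants, L) uint8; 1 = wild type
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mutation profile entries must be 0 or 1")
        if self.values.shape[0] != len(self.variant_ids):
            raise ValueError("variant_ids length does not match profile rows")

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass
class InformationFootprint:
    """Per-position mutual information with polarity and read support."""

    info: np.ndarray  # bits, >= 0
    polarity: np.ndarray  # ACTIVATING / REPRESSING per position
    n_reads: np.ndarray  # total reads informing each position
    low_support: np.ndarray  # True where a mutation class was absent
    tss_offset: int = 0  # display coordinate 0 = window index tss_offset

    def __post_init__(self) -> None:
        if not (self.info >= 0).all():
            raise ValueError("information values must be non-negative")
        if (self.info > 1.0 + 1e-9).any():
            raise ValueError("binary-binary MI cannot exceed 1 bit")

    def __len__(self) -> int:
        return self.info.size

    def polarity_labels(self) -> list[str]:
        return [_POLARITY_LABEL[int(p)] for p in self.polarity]

    def display_positions(self) -> np.ndarray:
        return np.arange(len(self)) - self.tss_offset

    def to_frame(self, window: int = 15) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.display_positions(),
                "info_bits": self.info,
                "smoothed_bits": smooth_footprint(self.info, window),
                "polarity": self.polarity_labels(),
                "n_reads": self.n_reads,
            }
        )


def compute_mutation_profile(
    variants, wildtype: str, variant_ids: list[str] | None = None
) -> MutationProfile:
    """Positionwise wild-type indicator of each variant against the wild type."""
    enc = encode_many(variants)
    wt = encode(wildtype)
    if enc.shape[1] != wt.size:
        raise ValueError(
            f"variant length {enc.shape[1]} does not match wildtype length {wt.size}"
        )
    values = (enc == wt[None, :]).astype(np.uint8)
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(enc.shape[0])]
    return MutationProfile(values=values, variant_ids=list(variant_ids))


def _mi_2x2(joint: np.ndarray) -> np.ndarray:
    """Plug-in MI in bits for stacked 2x2 joints of shape (L, 2, 2)."""
    total = joint.sum(axis=(1, 2), keepdims=True)
    p = np.divide(joint, total, out=np.zeros_like(joint, dtype=float), where=total > 0)
    pm = p.sum(axis=2, keepdims=True)
    pe = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (pm * pe)), 0.0)
    return terms.sum(axis=(1, 2))


def compute_footprint(
    counts: CountTable,
    profile: MutationProfile,
    pseudocount: float = 1.0,
    weighting: str = "reads",
    tss_offset: int = 0,
) -> InformationFootprint:
    """Compute the information footprint from read counts and a mutation profile.

    For each position the 2x2 joint table accumulates, per barcode, DNA
    reads into (m, mu=0) and mRNA reads into (m, mu=1) according to the
    barcode's variant's mutation state m; ``pseudocount`` is added to every
    cell (shrinking toward independence, i.e. toward MI = 0) before
    normalizing.  With ``weighting="reads"`` each read carries unit
    probability mass, as the footprint's probabilities are defined; with
    ``weighting="barcodes"`` each barcode contributes unit mass split
    between DNA and mRNA in proportion to its counts, de-weighting
    abundance skew.

    Positions where every read is wild type (or every read mutated) carry
    no mutational contrast: their information is set to 0 and flagged in
    ``low_support``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if weighting not in ("reads", "barcodes"):
        raise ValueError(f"unknown weighting {weighting!r}")
    df = counts.df
    id_to_row = {vid: i for i, vid in enumerate(profile.variant_ids)}
    unknown = [v for v in df["variant_id"].unique() if v not in id_to_row]
    if unknown:
        raise ValueError(f"count table references unknown variant ids: {unknown[:3]}")
    rows = df["variant_id"].map(id_to_row).to_numpy()

    dna = df["dna_ct"].to_numpy(dtype=float)
    mrna = df["mrna_ct"].to_numpy(dtype=float)
    if weighting == "barcodes":
        tot = dna + mrna
        with np.errstate(invalid="ignore"):
            dna = np.divide(dna, tot, out=np.zeros_like(dna), where=tot > 0)
            mrna = np.divide(mrna, tot, out=np.zeros_like(mrna), where=tot > 0)

    n_variants = len(profile.variant_ids)
    dna_v = np.bincount(rows, weights=dna, minlength=n_variants)
    mrna_v = np.bincount(rows, weights=mrna, minlength=n_variants)

    wt = profile.values.astype(float)  # (n, L); 1 = wild type
    dna_wt = dna_v @ wt
    mrna_wt = mrna_v @ wt
    dna_mut = dna_v.sum() - dna_wt
    mrna_mut = mrna_v.sum() - mrna_wt

    L = profile.length
    joint = np.empty((L, 2, 2))
    joint[:, 0, 0] = dna_mut
    joint[:, 0, 1] = mrna_mut
    joint[:, 1, 0] = dna_wt
    joint[:, 1, 1] = mrna_wt
    n_reads = joint.sum(axis=(1, 2))

    mut_mass = dna_mut + mrna_mut
    wt_mass = dna_wt + mrna_wt
    low_support = (mut_mass <= 0) | (wt_mass <= 0)

    info = _mi_2x2(joint + pseudocount)
    info[low_support] = 0.0
    info = np.clip(info, 0.0, None)

    # polarity: does mutation raise (repressing) or lower (activating) the
    # mRNA/DNA read ratio?
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_mut = np.where(dna_mut > 0, mrna_mut / np.maximum(dna_mut, 1e-300), np.inf)
        ratio_wt = np.where(dna_wt > 0, mrna_wt / np.maximum(dna_wt, 1e-300), np.inf)
    polarity = np.where(ratio_mut > ratio_wt, REPRESSING, ACTIVATING)
    ties = (ratio_mut == ratio_wt) & ~low_support
    if ties.any():
        warnings.warn(
            f"polarity tie at {int(ties.sum())} position(s); assigned activating",
            stacklevel=2,
        )
    polarity[low_support] = ACTIVATING

    return InformationFootprint(
        info=info,
        polarity=polarity.astype(np.int8),
        n_reads=n_reads,
        low_support=low_support,
        tss_offset=tss_offset,
    )


def smooth_footprint(values: np.ndarray, window: int = 15) -> np.ndarray:
    """Centered moving average with shrunken windows at the edges.

    Each output position is the mean of the raw values over a window of
    ``window`` positions centered there; near the edges the mean runs over
    however many positions actually exist.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > values.size:
        raise ValueError(f"window {window} exceeds footprint length {values.size}")
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts
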