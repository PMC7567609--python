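"""Synthetic barcoded promoter-mutagenesis libraries with planted regulation.

This module emulates the experimental design of a barcoded
mutagenized-promoter MPRA so that the whole analysis pipeline is testable
without any sequencing data:

* a 160-bp promoter window (45 bp downstream and 115 bp upstream of the
  assumed transcription start site, which displays as position 0);
* ~2200 variant sequences in which each base mutates independently with
  probability 0.10, the library-average rate held within 9.5–10.5%;
* an average of five distinct 20-nt barcodes per variant;
* DNA and mRNA read counts sampled multinomially, with mRNA weights set by
  a thermodynamic occupancy model over *planted* binding sites (RNAP,
  activators, repressors), each carrying a ground-truth energy matrix.

Every random draw flows through an explicit seed; identical seeds give
byte-identical libraries and count tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .matrix import EnergyMatrix, predict_energies
from .seqs import BASES, decode, encode, encode_many, validate_dna

__all__ = [
    "PlantedSite",
    "PromoterTemplate",
    "VariantLibrary",
    "CountTable",
    "generate_variants",
    "assign_barcodes",
    "simulate_expression",
    "sample_reads",
    "default_template",
    "make_rnap_matrix",
    "DEFAULT_N_VARIANTS",
    "DEFAULT_MUT_RATE",
    "DEFAULT_WINDOW_LENGTH",
    "DEFAULT_TSS_OFFSET",
    "DEFAULT_MEAN_BARCODES",
    "DEFAULT_BARCODE_LEN",
    "DEFAULT_READ_DEPTH",
]

DEFAULT_WINDOW_LENGTH = 160
DEFAULT_TSS_OFFSET = 115  # window spans -115..+44 relative to the TSS
DEFAULT_N_VARIANTS = 2200
DEFAULT_MUT_RATE = 0.10
DEFAULT_MEAN_BARCODES = 5
DEFAULT_BARCODE_LEN = 20
DEFAULT_READ_DEPTH = 50_000


@dataclass
class PlantedSite:
    """A ground-truth binding site planted in a promoter template.

    ``interval`` is half-open ``[start, end)`` in 0-based window
    coordinates.  ``true_matrix`` is the site's energy matrix
    (wildtype-zero gauge relative to the template); the occupancy of the
    site on a variant is a logistic (Boltzmann) function of the matrix
    energy, anchored so the wild type is bound with probability
    ``wt_occupancy``.  ``interaction_strength`` (> 0) couples occupancy to
    expression: a bound repressor multiplies expression by
    ``exp(-strength)`` < 1, a bound activator or RNAP by ``1 + strength``
    >= 1.
    """

    role: str  # "rnap" | "activator" | "repressor"
    interval: tuple[int, int]
    true_matrix: EnergyMatrix
    interaction_strength: float
    wt_occupancy: float = 0.95

    def __post_init__(self) -> None:
        if self.role not in ("rnap", "activator", "repressor"):
            raise ValueError(f"unknown site role {self.role!r}")
        start, end = self.interval
        if end - start != len(self.true_matrix):
            raise ValueError(
                f"interval length {end - start} != matrix length {len(self.true_matrix)}"
            )
        if self.interaction_strength <= 0:
            raise ValueError("interaction_strength must be positive")
        if not 0.0 < self.wt_occupancy < 1.0:
            raise ValueError("wt_occupancy must lie in (0, 1)")


@dataclass
class PromoterTemplate:
    """A wild-type promoter window plus its planted regulatory architecture."""

    name: str
    wildtype_seq: str
    tss_offset: int = DEFAULT_TSS_OFFSET
    planted_sites: list[PlantedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wildtype_seq = validate_dna(self.wildtype_seq, f"template {self.name}")
        L = len(self.wildtype_seq)
        if L == 0:
            raise ValueError("degenerate template: empty wild-type sequence")
        if not 0 <= self.tss_offset < L:
            raise ValueError(f"tss_offset {self.tss_offset} outside window [0, {L})")
        for site in self.planted_sites:
            start, end = site.interval
            if not (0 <= start < end <= L):
                raise ValueError(
                    f"planted site interval [{start}, {end}) outside window [0, {L})"
                )

    def __len__(self) -> int:
        return len(self.wildtype_seq)

    def to_display(self, pos: int) -> int:
        """Window coordinate -> display coordinate (0 = assumed TSS)."""
        return pos - self.tss_offset


@dataclass
class VariantLibrary:
    """Mutagenized variants of one template, with barcodes and ground truth."""

    template: PromoterTemplate
    variants: list[str]
    mutation_indicators: np.ndarray  # (n, L) uint8; 1 = mutated vs wild type
    barcodes: dict[str, int] | None = None  # barcode -> variant index
    true_expression: np.ndarray | None = None  # per-variant mRNA/DNA ratio

    def __post_init__(self) -> None:
        n, L = self.mutation_indicators.shape
        if n != len(self.variants) or L != len(self.template):
            raise ValueError("mutation indicator shape inconsistent with variants")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [f"{self.template.name}_v{i}" for i in range(self.n_variants)]

    @property
    def mean_mutation_rate(self) -> float:
        """Per-base mutation fraction averaged across all variant sequences."""
        return float(self.mutation_indicators.mean())


@dataclass
class CountTable:
    """Per-barcode DNA and mRNA read counts, joined to variant ids.

    Wraps a DataFrame with columns ``barcode``, ``variant_id``, ``dna_ct``,
    ``mrna_ct``.  Barcodes are unique; counts are non-negative integers and
    at least one DNA count is nonzero.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["barcode", "variant_id", "dna_ct", "mrna_ct"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        dup = self.df["barcode"].duplicated()
        if dup.any():
            bad = self.df.loc[dup, "barcode"].iloc[0]
            raise ValueError(f"duplicated barcode {bad!r} in count table")
        for col in ("dna_ct", "mrna_ct"):
            vals = self.df[col]
            if (vals < 0).any():
                raise ValueError(f"negative counts in column {col}")
        if not (self.df["dna_ct"] > 0).any():
            raise ValueError("count table has no nonzero DNA counts")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_dna(self) -> int:
        return int(self.df["dna_ct"].sum())

    @property
    def total_mrna(self) -> int:
        return int(self.df["mrna_ct"].sum())


# ---------------------------------------------------------------------------
# Variant generation


def _mutate(wt_enc: np.ndarray, n: int, mut_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n mutagenized copies of the encoded wild type.

    Each base mutates independently with probability ``mut_rate``; a mutated
    base is replaced uniformly by one of the three non-wild-type bases.
    """
    L = wt_enc.size
    mask = rng.random((n, L)) < mut_rate
    # offset 1..3 from the wild-type index, mod 4, is uniform over the others
    offsets = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
    out = np.broadcast_to(wt_enc, (n, L)).copy()
    out[mask] = (out[mask] + offsets[mask]) % 4
    return out


def generate_variants(
    template: PromoterTemplate,
    n_variants: int = DEFAULT_N_VARIANTS,
    mut_rate: float = DEFAULT_MUT_RATE,
    seed: int | None = None,
    *,
    include_wildtype: bool = True,
    ensure_unique: bool = True,
    rate_band: float | None = 0.005,
    max_attempts: int = 25,
) -> VariantLibrary:
    """Generate a mutagenized variant library for one promoter template.

    Each base mutates with probability ``mut_rate`` (substitutions only,
    uniform over the three alternatives).  Duplicate sequences are
    regenerated until all variants are unique, and the whole library is
    regenerated if its average mutation rate falls outside
    ``mut_rate ± rate_band`` — mirroring the quality gate applied to real
    oligo pools (pass ``rate_band=None`` to skip the gate, e.g. for tiny
    libraries where the average fluctuates widely).  The wild type itself
    is included once (variant 0) when ``include_wildtype`` is set.
    """
    if not 0.0 <= mut_rate < 1.0:
        raise ValueError(f"mut_rate must lie in [0, 1), got {mut_rate}")
    if mut_rate == 0.0 and ensure_unique and n_variants > 1:
        raise ValueError("mut_rate=0 cannot yield unique variants")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    L = len(template)
    wt_enc = encode(template.wildtype_seq)
    rng = np.random.default_rng(seed)

    n_random = n_variants - 1 if include_wildtype else n_variants
    achieved = float("nan")
    for _attempt in range(max_attempts):
        enc = _mutate(wt_enc, n_random, mut_rate, rng)
        if ensure_unique:
            for _retry in range(max_attempts):
                seqs = ["".join(BASES[i] for i in row) for row in enc.tolist()]
                seen: dict[str, int] = {}
                dup_rows = []
                for i, s in enumerate(seqs):
                    if s in seen or (include_wildtype and s == template.wildtype_seq):
                        dup_rows.append(i)
                    else:
                        seen[s] = i
                if not dup_rows:
                    break
                enc[dup_rows] = _mutate(wt_enc, len(dup_rows), mut_rate, rng)
            else:
                raise RuntimeError("could not generate unique variants")
        if include_wildtype:
            enc = np.vstack([wt_enc[None, :], enc])
        indicators = (enc != wt_enc[None, :]).astype(np.uint8)
        achieved = float(indicators.mean())
        if rate_band is None or abs(achieved - mut_rate) <= rate_band:
            break
    else:
        raise RuntimeError(
            f"library mutation rate {achieved:.4f} outside "
            f"[{mut_rate - rate_band:.4f}, {mut_rate + rate_band:.4f}] "
            f"after {max_attempts} attempts"
        )
    variants = [decode(row) for row in enc]
    return VariantLibrary(template=template, variants=variants, mutation_indicators=indicators)


# ---------------------------------------------------------------------------
# Barcodes


def _truncated_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the requested mean.

    Solves mean = lam / (1 - exp(-lam)); the truncated mean is > 1 for any
    lam > 0, so mean must exceed 1 (mean == 1 degenerates to all-ones).
    """
    if mean <= 1.0:
        raise ValueError("truncated-Poisson mean must be > 1")
    return brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, 10 * mean)


def _sample_truncated_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if abs(mean - 1.0) < 1e-12:
        return np.ones(size, dtype=np.int64)
    lam = _truncated_poisson_lambda(mean)
    counts = rng.poisson(lam, size=size)
    zeros = counts == 0
    while zeros.any():
        counts[zeros] = rng.poisson(lam, size=int(zeros.sum()))
        zeros = counts == 0
    return counts


def assign_barcodes(
    library: VariantLibrary,
    mean_barcodes_per_variant: float = DEFAULT_MEAN_BARCODES,
    barcode_len: int = DEFAULT_BARCODE_LEN,
    seed: int | None = None,
) -> VariantLibrary:
    """Attach random barcodes to each variant (in place; returns the library).

    The number of barcodes per variant is drawn from a Poisson truncated at
    >= 1 with the requested mean; barcodes are random ``barcode_len``-mers,
    distinct library-wide.
    """
    if barcode_len < 1:
        raise ValueError("barcode_len must be >= 1")
    if mean_barcodes_per_variant < 1:
        raise ValueError("mean_barcodes_per_variant must be >= 1")
    rng = np.random.default_rng(seed)
    n = library.n_variants
    counts = _sample_truncated_poisson(mean_barcodes_per_variant, n, rng)
    total = int(counts.sum())
    if 4**barcode_len < total:
        raise ValueError(
            f"cannot draw {total} distinct barcodes of length {barcode_len} "
            f"(only {4**barcode_len} exist)"
        )
    barcodes: dict[str, int] = {}
    seen: set[str] = set()
    for v_idx, c in enumerate(counts.tolist()):
        assigned = 0
        while assigned < c:
            bc = decode(rng.integers(0, 4, size=barcode_len, dtype=np.uint8))
            if bc in seen:
                continue
            seen.add(bc)
            barcodes[bc] = v_idx
            assigned += 1
    library.barcodes = barcodes
    return library


# ---------------------------------------------------------------------------
# Expression model


def site_occupancies(library: VariantLibrary, site: PlantedSite) -> np.ndarray:
    """Per-variant Boltzmann occupancy of one planted site.

    The site's energy on each variant is the sum of true-matrix entries at
    the bases present (wildtype-zero gauge, so the wild type scores 0); the
    occupancy is ``expit(e0 - E)`` with ``e0 = logit(wt_occupancy)``.
    """
    start, end = site.interval
    enc = encode_many(library.variants)[:, start:end]
    matrix = site.true_matrix.to_wildtype_zero(
        site.true_matrix.wildtype or library.template.wildtype_seq[start:end]
    )
    energies = predict_energies(enc, matrix.values)
    e0 = np.log(site.wt_occupancy / (1.0 - site.wt_occupancy))
    return expit(e0 - energies)


def simulate_expression(library: VariantLibrary, baseline: float = 1.0) -> np.ndarray:
    """Expected mRNA/DNA ratio per variant under the planted architecture.

    Sites act independently (no cooperativity): expression is the baseline
    times a product of per-site factors, ``1 + strength * p`` for bound
    activators and RNAP and ``(1 - p) + p * exp(-strength)`` for bound
    repressors, where ``p`` is the site's occupancy on that variant.  A
    fully occupied strong repressor thus scales expression by
    ``exp(-strength)``; an unbound site (occupancy 0) leaves the baseline.
    Deterministic given the sequences; with no planted sites, expression is
    constant across variants.
    """
    expr = np.full(library.n_variants, float(baseline))
    for site in library.template.planted_sites:
        p = site_occupancies(library, site)
        if site.role == "repressor":
            expr *= (1.0 - p) + p * np.exp(-site.interaction_strength)
        else:
            expr *= 1.0 + site.interaction_strength * p
    library.true_expression = expr
    return expr


# ---------------------------------------------------------------------------
# Read sampling


def sample_reads(
    library: VariantLibrary,
    n_dna_reads: int = DEFAULT_READ_DEPTH,
    n_mrna_reads: int = DEFAULT_READ_DEPTH,
    seed: int | None = None,
    dna_skew_sigma: float = 0.3,
) -> CountTable:
    """Sample per-barcode DNA and mRNA read counts.

    DNA counts are multinomial over barcodes with near-uniform weights
    perturbed by a log-normal factor (``dna_skew_sigma``), emulating
    library-abundance skew; mRNA counts are multinomial with weights
    proportional to DNA weight times the variant's expected expression.
    Column sums equal the requested totals exactly.
    """
    if library.barcodes is None:
        raise ValueError("library has no barcodes; call assign_barcodes first")
    if n_dna_reads < 1 or n_mrna_reads < 1:
        raise ValueError("read totals must be >= 1")
    expr = library.true_expression
    if expr is None:
        expr = simulate_expression(library)
    rng = np.random.default_rng(seed)
    barcodes = list(library.barcodes.keys())
    v_idx = np.fromiter(library.barcodes.values(), dtype=np.int64, count=len(barcodes))
    w_dna = rng.lognormal(0.0, dna_skew_sigma, size=len(barcodes))
    w_dna /= w_dna.sum()
    w_mrna = w_dna * expr[v_idx]
    w_mrna /= w_mrna.sum()
    dna_ct = rng.multinomial(n_dna_reads, w_dna)
    mrna_ct = rng.multinomial(n_mrna_reads, w_mrna)
    ids = library.variant_ids()
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "variant_id": [ids[i] for i in v_idx.tolist()],
            "dna_ct": dna_ct,
            "mrna_ct": mrna_ct,
        }
    )
    return CountTable(df)


# ---------------------------------------------------------------------------
# Default study design


def make_rnap_matrix(
    wildtype: str, spacer_noise: float = 0.2, seed: int = 20_26
) -> EnergyMatrix:
    """Build a sigma70-like RNAP energy matrix over a 30-bp site.

    SYNTHETIC exemplar: the -35 (TTGACA) and -10 (TATAAT) hexamers carry
    strong penalties for non-wild-type bases (~2.5 A.U.) while the 17-bp
    spacer and flanks are nearly neutral, mimicking the bipartite
    specificity of bacterial RNAP holoenzyme.  Gauge: wildtype-zero
    relative to ``wildtype`` (which should carry the consensus hexamers).
    """
    if len(wildtype) != 30:
        raise ValueError("RNAP exemplar site is 30 bp")
    rng = np.random.default_rng(seed)
    values = np.abs(rng.normal(0.0, spacer_noise, size=(30, 4)))
    hexamers = list(range(0, 6)) + list(range(23, 29))  # -35 and -10 elements
    values[hexamers] = np.abs(rng.normal(2.5, 0.5, size=(len(hexamers), 4)))
    wt_idx = encode(wildtype)
    values[np.arange(30), wt_idx] = 0.0
    return EnergyMatrix(values, gauge="wildtype-zero", wildtype=wildtype)


def default_template(
    name: str = "synthpro",
    seed: int = 20_26,
    architecture: str = "simple-repression",
    repressor_strength: float = 2.5,
    rnap_strength: float = 9.0,
) -> PromoterTemplate:
    """The package's default study design: a simple-repression promoter.

    A random 160-bp window (TSS at display position 0) carries a 30-bp
    sigma70-like RNAP site at display [-35, -5) with consensus -35/-10
    hexamers, and — for the ``"simple-repression"`` architecture, the
    (0, 1) motif — a 15-bp repressor operator at display [+1, +16).
    ``architecture="constitutive"`` plants only the RNAP site;
    ``"empty"`` plants nothing (a null promoter).
    """
    rng = np.random.default_rng(seed)
    L, tss = DEFAULT_WINDOW_LENGTH, DEFAULT_TSS_OFFSET
    wt = rng.integers(0, 4, size=L, dtype=np.uint8)

    rnap_start, rnap_end = tss - 35, tss - 5
    rnap_wt = list("TTGACA") + [BASES[i] for i in wt[rnap_start + 6 : rnap_start + 23]] + list(
        "TATAAT"
    ) + [BASES[wt[rnap_end - 1]]]
    wt[rnap_start:rnap_end] = encode("".join(rnap_wt))
    wildtype = decode(wt)

    sites: list[PlantedSite] = []
    if architecture in ("simple-repression", "constitutive"):
        rnap_matrix = make_rnap_matrix(wildtype[rnap_start:rnap_end], seed=seed)
        sites.append(
            PlantedSite(
                role="rnap",
                interval=(rnap_start, rnap_end),
                true_matrix=rnap_matrix,
                interaction_strength=rnap_strength,
            )
        )
    if architecture == "simple-repression":
        rep_start, rep_end = tss + 1, tss + 16
        rep_values = np.abs(rng.normal(2.0, 0.5, size=(15, 4)))
        rep_wt = wildtype[rep_start:rep_end]
        rep_values[np.arange(15), encode(rep_wt)] = 0.0
        sites.append(
            PlantedSite(
                role="repressor",
                interval=(rep_start, rep_end),
                true_matrix=EnergyMatrix(rep_values, gauge="wildtype-zero", wildtype=rep_wt),
                interaction_strength=repressor_strength,
            )
        )
    elif architecture not in ("constitutive", "empty"):
        raise ValueError(f"unknown architecture {architecture!r}")
    return PromoterTemplate(
        name=name, wildtype_seq=wildtype, tss_offset=tss, planted_sites=sites
    )
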