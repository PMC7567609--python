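"""Energy matrices: the additive (linear) model of protein-DNA binding.

An energy matrix assigns each (position, base) pair within a binding site a
contribution ``eps[i, b]`` (arbitrary units) to the total binding energy of a
site sequence, which is simply the sum of the contributions of the bases
present.  Because only energy *differences* between sequences are
identifiable from expression data, matrices carry an explicit gauge:
``wildtype-zero`` (the wild-type base contributes 0 at every position) or
``mean-centered`` (each position's four values average to 0).

This module provides

* :class:`EnergyMatrix` and :func:`predict_energy` — the linear model itself;
* :func:`infer_matrix` — Metropolis MCMC inference of a matrix from barcoded
  DNA/mRNA read counts, maximizing the mutual information between
  rank-binned predicted energies and the DNA-vs-mRNA read label;
* :func:`estimate_matrix_ols` — a fast weighted-least-squares estimate of
  per-base mutation effects, used to seed the MCMC and to produce
  whole-window matrices for motif scanning;
* :func:`matrix_to_logo` — conversion to sequence-logo letter heights;
* :func:`matrix_pearson` — gauge-insensitive similarity between matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .seqs import BASES, encode, encode_many, one_hot

__all__ = [
    "EnergyMatrix",
    "SequenceLogo",
    "predict_energy",
    "predict_energies",
    "estimate_matrix_ols",
    "infer_matrix",
    "matrix_to_logo",
    "matrix_pearson",
]


@dataclass
class EnergyMatrix:
    """Additive per-base binding-energy model over a site of length L.

    Parameters
    ----------
    values
        Array of shape (L, 4), base order A, C, G, T, arbitrary units.
    gauge
        ``"wildtype-zero"``, ``"mean-centered"`` or ``"none"``.
    wildtype
        Optional wild-type site sequence (length L); required for the
        wildtype-zero gauge.
    start
        Optional offset of the site within a larger coordinate window
        (0-based; the site spans ``[start, start + L)``).
    units
        Energy units; ``"A.U."`` unless externally calibrated.
    """

    values: np.ndarray
    gauge: str = "none"
    wildtype: str | None = None
    start: int | None = None
    units: str = "A.U."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError(f"matrix values must be (L, 4), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains non-finite entries")
        if self.wildtype is not None and len(self.wildtype) != len(self):
            raise ValueError("wildtype length does not match matrix length")
        if self.gauge not in ("wildtype-zero", "mean-centered", "none"):
            raise ValueError(f"unknown gauge {self.gauge!r}")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_wildtype_zero(self, wildtype: str | None = None) -> "EnergyMatrix":
        """Re-gauge so the wild-type base contributes 0 at every position."""
        wt = wildtype if wildtype is not None else self.wildtype
        if wt is None:
            raise ValueError("wildtype-zero gauge requires a wild-type sequence")
        idx = encode(wt)
        shifted = self.values - self.values[np.arange(len(self)), idx][:, None]
        return replace(self, values=shifted, gauge="wildtype-zero", wildtype=wt)

    def to_mean_centered(self) -> "EnergyMatrix":
        """Re-gauge so each position's four values average to zero."""
        centered = self.values - self.values.mean(axis=1, keepdims=True)
        return replace(self, values=centered, gauge="mean-centered")


def predict_energy(seq: str, matrix: EnergyMatrix) -> float:
    """Binding energy of ``seq`` under the additive model: sum of eps[i, seq[i]]."""
    idx = encode(seq)
    if idx.size != len(matrix):
        raise ValueError(
            f"sequence length {idx.size} does not match matrix length {len(matrix)}"
        )
    return float(matrix.values[np.arange(idx.size), idx].sum())


def predict_energies(encoded: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Vectorized energies for an (n, L) encoded sequence array."""
    n, L = encoded.shape
    return values[np.arange(L)[None, :], encoded].sum(axis=1)


def matrix_pearson(a: EnergyMatrix, b: EnergyMatrix) -> float:
    """Pearson correlation between two matrices after mean-centering each.

    Both matrices are flattened after subtracting their own mean, so the
    result is invariant to the additive gauge and to overall scaling —
    only the *pattern* of base preferences is compared.
    """
    va, vb = a.values, b.values
    if va.shape != vb.shape:
        raise ValueError(f"matrix shapes differ: {va.shape} vs {vb.shape}")
    xa = (va - va.mean()).ravel()
    xb = (vb - vb.mean()).ravel()
    sa, sb = np.sqrt((xa**2).sum()), np.sqrt((xb**2).sum())
    if sa == 0.0 or sb == 0.0:
        raise ValueError("matrix has zero variance; Pearson r undefined")
    return float((xa @ xb) / (sa * sb))


# ---------------------------------------------------------------------------
# Sequence logos


@dataclass
class SequenceLogo:
    """Letter heights for a sequence logo derived from an energy matrix.

    ``probs`` holds the per-position base probabilities (rows sum to 1);
    ``heights`` scales them by the position's information content in bits,
    so the total column height equals ``2 - H(p)``.
    """

    probs: np.ndarray  # (L, 4)
    heights: np.ndarray  # (L, 4)

    @property
    def info_bits(self) -> np.ndarray:
        return self.heights.sum(axis=1)


def matrix_to_logo(matrix: EnergyMatrix, scale_factor: float = 1.0) -> SequenceLogo:
    """Convert an energy matrix to sequence-logo letter heights.

    Per position, base probabilities are a Boltzmann weight of the energies,
    ``p(b) ∝ exp(-scale_factor * eps[i, b])`` — lower energy means stronger
    binding and a larger letter.  Heights are probabilities times the
    position's information content ``2 - H(p)`` bits.
    """
    e = -scale_factor * matrix.values
    e = e - e.max(axis=1, keepdims=True)  # overflow-safe softmax
    w = np.exp(e)
    probs = w / w.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return SequenceLogo(probs=probs, heights=probs * info[:, None])


# ---------------------------------------------------------------------------
# Mutual-information objective shared by the MCMC


def _mi_bits_from_joint(joint: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a non-negative joint count table."""
    total = joint.sum()
    if total <= 0:
        return 0.0
    p = joint / total
    pm = p.sum(axis=1, keepdims=True)
    pe = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (pm * pe)), 0.0)
    return float(terms.sum())


def rank_mi_objective(
    energies: np.ndarray,
    dna: np.ndarray,
    mrna: np.ndarray,
    n_bins: int = 10,
    pseudocount: float = 1.0,
) -> float:
    """MI (bits) between quantile-binned energy ranks and the DNA/mRNA label.

    Sequences are ordered by predicted energy and partitioned into
    ``n_bins`` bins of (approximately) equal total read mass; the joint
    table of (energy bin, read origin) then yields a plug-in MI.  Because
    only the rank order of energies enters, the objective is invariant to
    any increasing affine transform of the matrix.
    """
    w = dna + mrna
    order = np.argsort(energies, kind="stable")
    cum = np.cumsum(w[order])
    total = cum[-1]
    if total <= 0:
        raise ValueError("no reads: objective undefined")
    # bin index by cumulative read mass of each sequence's left edge
    left = cum - w[order]
    bins = np.minimum((left * n_bins / total).astype(np.intp), n_bins - 1)
    joint = np.empty((n_bins, 2))
    joint[:, 0] = np.bincount(bins, weights=dna[order], minlength=n_bins)
    joint[:, 1] = np.bincount(bins, weights=mrna[order], minlength=n_bins)
    joint += pseudocount
    return _mi_bits_from_joint(joint)


# ---------------------------------------------------------------------------
# Fast least-squares estimate


def estimate_matrix_ols(
    seqs,
    dna: np.ndarray,
    mrna: np.ndarray,
    wildtype: str,
    pseudocount: float = 0.5,
) -> EnergyMatrix:
    """Weighted-least-squares estimate of per-base mutation effects.

    Regresses each sequence's log2(mRNA/DNA) read ratio on indicators of
    its non-wild-type bases, weighting by total reads.  Coefficients are
    negated so that expression-*lowering* mutations get *positive* energy
    (the activator/polymerase sign convention: weaker binding = higher
    energy = less expression).  Fast and deterministic; used to initialize
    :func:`infer_matrix` and to build whole-window matrices for RNAP
    motif scanning.
    """
    enc = encode_many(seqs)
    dna = np.asarray(dna, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    wt_idx = encode(wildtype)
    n, L = enc.shape
    if L != wt_idx.size:
        raise ValueError("sequence length does not match wildtype length")
    X = one_hot(enc).reshape(n, L * 4)
    # drop wild-type columns (their effect is the gauge zero)
    keep = np.ones(L * 4, dtype=bool)
    keep[np.arange(L) * 4 + wt_idx] = False
    X = X[:, keep]
    y = np.log2((mrna + pseudocount) / (dna + pseudocount))
    y = y - y.mean()
    w = np.sqrt(dna + mrna)
    coef, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    values = np.zeros((L, 4))
    values.ravel()[keep] = -coef
    return EnergyMatrix(values, gauge="wildtype-zero", wildtype=wildtype)


# ---------------------------------------------------------------------------
# MCMC inference


def _gauge_sample(values: np.ndarray, nonwt_mask: np.ndarray | None) -> tuple[np.ndarray, bool]:
    """Mean-center, sign-align and scale-normalize one MCMC sample.

    The MI objective is blind to the matrix's sign and scale, so recorded
    samples are put in a canonical form before averaging: per-position mean
    zero, unit Frobenius norm, and (when the wild type is known) mean
    non-wild-type energy >= 0, i.e. mutations are deleterious on average.
    Returns the canonical values and whether the sign was flipped.
    """
    v = values - values.mean(axis=1, keepdims=True)
    flipped = False
    if nonwt_mask is not None:
        if v[nonwt_mask].mean() < 0:
            v = -v
            flipped = True
    norm = np.sqrt((v**2).sum())
    if norm > 0:
        v = v / norm
    return v, flipped


def infer_matrix(
    seqs,
    dna: np.ndarray,
    mrna: np.ndarray,
    *,
    wildtype: str | None = None,
    n_steps: int = 50_000,
    seed: int | None = None,
    n_bins: int = 10,
    pseudocount: float = 1.0,
    burn_in_frac: float = 0.2,
    beta: float | None = None,
    prior_sigma: float = 1.0,
    init: str = "ols",
    estimate: str = "posterior_mean",
    min_sequences: int = 100,
) -> tuple[EnergyMatrix, dict]:
    """Infer an energy matrix by MCMC maximization of rank mutual information.

    A Metropolis chain perturbs one random matrix cell per step (Gaussian
    proposal, step size adapted during burn-in toward 20–40% acceptance)
    and scores each state by the mutual information between rank-binned
    predicted energies and the DNA-vs-mRNA read label, weighted by read
    counts (see :func:`rank_mi_objective`).  States are accepted with
    probability ``min(1, exp(beta * ΔMI + Δlogprior))``; the independent
    Gaussian prior (scale ``prior_sigma``) matters because the objective
    is flat both along the overall energy scale and in cells with little
    read support — without it those directions random-walk freely instead
    of shrinking to zero.

    Parameters
    ----------
    seqs
        Equal-length site sequences, one per variant (aligned to the region).
    dna, mrna
        Per-variant DNA and mRNA read counts.
    wildtype
        Wild-type site sequence; enables the wildtype-zero gauge and the
        sign convention (mutations deleterious on average).
    beta
        Inverse temperature; defaults to the total read count, so accepted
        MI drops are on the order of the estimator's sampling noise.
    init
        ``"ols"`` (default) starts the chain at the least-squares estimate
        of :func:`estimate_matrix_ols`; with single-cell moves and a sharp
        objective, a cold start (``"zero"``) is prone to trapping in local
        optima of the finite-sample MI landscape.
    estimate
        ``"posterior_mean"`` (default) averages canonicalized post-burn-in
        samples; ``"map"`` returns the best-objective state.

    Returns
    -------
    (EnergyMatrix, dict)
        The point estimate (gauge-fixed) and diagnostics with keys
        ``objective_trace``, ``acceptance_rate``, ``best_objective``,
        ``map_matrix``, ``sign_flipped``.
    """
    enc = encode_many(seqs)
    dna = np.asarray(dna, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    n, L = enc.shape
    if L < 4:
        raise ValueError(f"region too short for matrix inference: {L} bp (need >= 4)")
    n_informative = int(((dna + mrna) > 0).sum())
    if n_informative < min_sequences:
        raise ValueError(
            f"only {n_informative} sequences with nonzero reads "
            f"(need >= {min_sequences})"
        )
    n_burn = int(n_steps * burn_in_frac)
    if n_steps - n_burn < 1:
        raise ValueError("chain shorter than burn-in")

    rng = np.random.default_rng(seed)
    X = one_hot(enc).reshape(n, L * 4).astype(bool)
    nonwt_mask = None
    free_cells = np.arange(L * 4)
    if wildtype is not None:
        wt_idx = encode(wildtype)
        if wt_idx.size != L:
            raise ValueError("wildtype length does not match sequences")
        wt_cells = np.arange(L) * 4 + wt_idx
        free_cells = np.setdiff1d(free_cells, wt_cells)
        nonwt_mask = np.ones((L, 4), dtype=bool)
        nonwt_mask[np.arange(L), wt_idx] = False

    if init == "ols":
        if wildtype is None:
            raise ValueError("init='ols' requires a wildtype sequence")
        theta = estimate_matrix_ols(seqs, dna, mrna, wildtype).values.ravel().copy()
    elif init == "zero":
        theta = np.zeros(L * 4)
    else:
        raise ValueError(f"unknown init {init!r}")

    if beta is None:
        beta = float(dna.sum() + mrna.sum())

    energies = predict_energies(enc, theta.reshape(L, 4))
    current = rank_mi_objective(energies, dna, mrna, n_bins, pseudocount)
    if not np.isfinite(current):
        raise ValueError("non-finite objective at initialization")

    sigma = 0.1
    n_accept = 0
    n_window_accept = 0
    best_obj = current
    best_theta = theta.copy()
    trace: list[float] = []
    mean_acc = np.zeros((L, 4))
    n_samples = 0
    any_flip = False

    for step in range(n_steps):
        j = int(free_cells[rng.integers(free_cells.size)])
        delta = rng.normal(0.0, sigma)
        new_energies = energies + delta * X[:, j]
        proposal = rank_mi_objective(new_energies, dna, mrna, n_bins, pseudocount)
        if not np.isfinite(proposal):
            raise ValueError("non-finite objective during sampling")
        d_logprior = (theta[j] ** 2 - (theta[j] + delta) ** 2) / (2 * prior_sigma**2)
        log_alpha = beta * (proposal - current) + d_logprior
        if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
            theta[j] += delta
            energies = new_energies
            current = proposal
            n_accept += 1
            n_window_accept += 1
            if current > best_obj:
                best_obj = current
                best_theta = theta.copy()
        # adapt step size toward 20-40% acceptance during burn-in
        if step < n_burn and (step + 1) % 200 == 0:
            rate = n_window_accept / 200
            if rate < 0.2:
                sigma *= 0.8
            elif rate > 0.4:
                sigma *= 1.25
            n_window_accept = 0
        if step >= n_burn:
            canon, flipped = _gauge_sample(theta.reshape(L, 4), nonwt_mask)
            mean_acc += canon
            n_samples += 1
            any_flip = any_flip or flipped
        if (step + 1) % 50 == 0:
            trace.append(current)

    if estimate == "posterior_mean":
        values = mean_acc / n_samples
    elif estimate == "map":
        values, _ = _gauge_sample(best_theta.reshape(L, 4), nonwt_mask)
    else:
        raise ValueError(f"unknown estimate {estimate!r}")

    result = EnergyMatrix(values, gauge="mean-centered", wildtype=wildtype)
    if wildtype is not None:
        result = result.to_wildtype_zero()
    map_values, _ = _gauge_sample(best_theta.reshape(L, 4), nonwt_mask)
    diagnostics = {
        "objective_trace": np.asarray(trace),
        "acceptance_rate": n_accept / n_steps,
        "best_objective": best_obj,
        "map_matrix": EnergyMatrix(map_values, gauge="mean-centered", wildtype=wildtype),
        "sign_flipped": any_flip,
        "final_sigma": sigma,
    }
    if any_flip:
        warnings.warn(
            "MI objective is sign-blind; sample signs were aligned so that "
            "mutations away from wild type raise the mean energy",
            stacklevel=2,
        )
    return result, diagnostics
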