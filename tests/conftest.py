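import numpy as np
import pytest

from regfoot.matrix import EnergyMatrix
from regfoot.seqs import decode, encode
from regfoot.synth import (
    PlantedSite,
    PromoterTemplate,
    assign_barcodes,
    generate_variants,
    sample_reads,
    simulate_expression,
)


@pytest.fixture
def toy_template():
    """A 20-bp template with no planted sites, for cheap structural tests."""
    return PromoterTemplate(name="toy", wildtype_seq="ACGTACGTACGTACGTACGT", tss_offset=10)


def make_site_template(
    seed: int,
    site_len: int = 8,
    start: int = 70,
    window: int = 160,
    role: str = "repressor",
    strength: float = 2.5,
    effect_scale: float = 1.5,
):
    """Random template with one planted site of known energy matrix."""
    rng = np.random.default_rng(seed)
    wt = decode(rng.integers(0, 4, window, dtype=np.uint8))
    end = start + site_len
    vals = np.abs(rng.normal(effect_scale, effect_scale / 2, size=(site_len, 4)))
    vals[np.arange(site_len), encode(wt[start:end])] = 0.0
    true_matrix = EnergyMatrix(vals, gauge="wildtype-zero", wildtype=wt[start:end])
    site = PlantedSite(
        role=role, interval=(start, end), true_matrix=true_matrix, interaction_strength=strength
    )
    template = PromoterTemplate(name="planted", wildtype_seq=wt, planted_sites=[site])
    return template, true_matrix


def make_counts(template, seed: int, n_variants: int = 2200, depth: int = 50_000):
    """Generate library + barcodes + expression + sampled reads."""
    library = generate_variants(template, n_variants=n_variants, seed=seed)
    assign_barcodes(library, seed=seed + 1)
    simulate_expression(library)
    counts = sample_reads(library, n_dna_reads=depth, n_mrna_reads=depth, seed=seed + 2)
    return library, counts


def variant_read_totals(library, counts):
    """Aggregate per-barcode counts to per-variant DNA/mRNA totals."""
    idx = {v: i for i, v in enumerate(library.variant_ids())}
    rows = counts.df["variant_id"].map(idx).to_numpy()
    dna = np.bincount(rows, weights=counts.df["dna_ct"].to_numpy(float), minlength=library.n_variants)
    mrna = np.bincount(rows, weights=counts.df["mrna_ct"].to_numpy(float), minlength=library.n_variants)
    return dna, mrna
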