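"""Unit and property tests for the synthetic library generator."""

import numpy as np
import pytest

from regfoot.matrix import EnergyMatrix, predict_energy
from regfoot.seqs import decode, encode
from regfoot.synth import (
    PlantedSite,
    PromoterTemplate,
    _truncated_poisson_lambda,
    assign_barcodes,
    default_template,
    generate_variants,
    sample_reads,
    simulate_expression,
)

from conftest import make_site_template


class TestGenerateVariants:
    def test_default_library_mutation_rate_in_band(self):
        lib = generate_variants(default_template(), n_variants=2200, mut_rate=0.10, seed=1)
        assert 0.095 <= lib.mean_mutation_rate <= 0.105
        assert lib.n_variants == 2200
        assert len(set(lib.variants)) == 2200

    def test_wildtype_included_once(self, toy_template):
        lib = generate_variants(toy_template, n_variants=10, mut_rate=0.2, seed=0, rate_band=None)
        assert lib.variants[0] == toy_template.wildtype_seq
        assert lib.variants.count(toy_template.wildtype_seq) == 1

    def test_zero_rate_identity(self, toy_template):
        lib = generate_variants(
            toy_template, n_variants=5, mut_rate=0.0, seed=0,
            ensure_unique=False, rate_band=None,
        )
        assert all(v == toy_template.wildtype_seq for v in lib.variants)
        assert not lib.mutation_indicators.any()

    def test_indicators_match_string_comparison(self):
        # brute-force oracle: positionwise string inequality with wild type
        template = PromoterTemplate(name="t4", wildtype_seq="ACGT", tss_offset=0)
        lib = generate_variants(
            template, n_variants=16, mut_rate=0.6, seed=3, rate_band=None
        )
        for variant, row in zip(lib.variants, lib.mutation_indicators):
            expected = [int(a != b) for a, b in zip(variant, template.wildtype_seq)]
            assert row.tolist() == expected

    def test_degenerate_template_rejected(self):
        with pytest.raises(ValueError):
            PromoterTemplate(name="empty", wildtype_seq="", tss_offset=0)

    def test_rate_band_exhaustion_names_rate(self, toy_template):
        with pytest.raises(RuntimeError, match="mutation rate"):
            # 20-bp, 3 variants: the library average almost never lands in
            # a +/-0.001 band around 0.5
            generate_variants(
                toy_template, n_variants=3, mut_rate=0.5, seed=0,
                rate_band=0.001, max_attempts=3,
            )

    def test_determinism(self, toy_template):
        a = generate_variants(toy_template, n_variants=20, mut_rate=0.1, seed=7, rate_band=None)
        b = generate_variants(toy_template, n_variants=20, mut_rate=0.1, seed=7, rate_band=None)
        assert a.variants == b.variants


class TestAssignBarcodes:
    def test_defaults_length_and_mean(self, toy_template):
        lib = generate_variants(toy_template, n_variants=1000, mut_rate=0.2, seed=0, rate_band=None)
        assign_barcodes(lib, seed=1)
        assert all(len(bc) == 20 for bc in lib.barcodes)
        per_variant = np.bincount(list(lib.barcodes.values()), minlength=1000)
        assert per_variant.min() >= 1
        # truncated-Poisson mean check: within 3 standard errors of 5
        lam = _truncated_poisson_lambda(5.0)
        var = lam / (1 - np.exp(-lam)) * (1 + lam - lam / (1 - np.exp(-lam)))
        se = np.sqrt(var / 1000)
        assert abs(per_variant.mean() - 5.0) < 3 * se

    def test_mean_one_gives_exactly_one(self, toy_template):
        lib = generate_variants(toy_template, n_variants=50, mut_rate=0.2, seed=0, rate_band=None)
        assign_barcodes(lib, mean_barcodes_per_variant=1, seed=2)
        counts = np.bincount(list(lib.barcodes.values()), minlength=50)
        assert (counts == 1).all()

    def test_barcodes_distinct_library_wide(self, toy_template):
        lib = generate_variants(toy_template, n_variants=200, mut_rate=0.2, seed=0, rate_band=None)
        assign_barcodes(lib, seed=3)
        assert len(lib.barcodes) == len(set(lib.barcodes))

    def test_barcode_space_exhaustion(self, toy_template):
        lib = generate_variants(toy_template, n_variants=50, mut_rate=0.2, seed=0, rate_band=None)
        with pytest.raises(ValueError, match="distinct barcodes"):
            assign_barcodes(lib, mean_barcodes_per_variant=5, barcode_len=2, seed=0)


class TestSimulateExpression:
    def test_no_sites_constant(self, toy_template):
        lib = generate_variants(toy_template, n_variants=30, mut_rate=0.2, seed=0, rate_band=None)
        expr = simulate_expression(lib)
        assert np.allclose(expr, expr[0])

    def test_wildtype_repression_factor(self):
        # strong repressor gauged to 0 at wild type: expression at the wild
        # type equals baseline x (1 - p + p e^-s) at occupancy p
        template, _ = make_site_template(seed=5, role="repressor", strength=2.0)
        lib = generate_variants(template, n_variants=5, mut_rate=0.05, seed=1, rate_band=None)
        expr = simulate_expression(lib, baseline=1.0)
        site = template.planted_sites[0]
        p = site.wt_occupancy
        expected = (1 - p) + p * np.exp(-site.interaction_strength)
        assert expr[0] == pytest.approx(expected)

    def test_ablated_site_returns_to_baseline(self):
        template, true_m = make_site_template(seed=5, role="repressor", strength=2.0)
        start, end = template.planted_sites[0].interval
        worst = "".join(
            "ACGT"[int(np.argmax(row))] for row in true_m.values
        )
        ablated = (
            template.wildtype_seq[:start] + worst + template.wildtype_seq[end:]
        )
        lib = generate_variants(template, n_variants=1, mut_rate=0.0, seed=0,
                                ensure_unique=False, rate_band=None)
        lib.variants[0] = ablated
        lib.mutation_indicators = (
            np.frombuffer(ablated.encode(), dtype=np.uint8)
            != np.frombuffer(template.wildtype_seq.encode(), dtype=np.uint8)
        ).astype(np.uint8)[None, :]
        expr = simulate_expression(lib, baseline=1.0)
        # worst bases ~ +1.5 A.U. each over 8 bp: occupancy collapses
        assert expr[0] > 0.9

    def test_expression_ranking_matches_enumeration(self):
        # 3-bp toy site, all 64 site sequences: expression order must equal
        # the brute-force energy order (repressor: higher energy -> less
        # binding -> more expression)
        rng = np.random.default_rng(0)
        wt = "ACGTACGTAC"
        vals = np.abs(rng.normal(1.0, 0.5, size=(3, 4)))
        vals[np.arange(3), [0, 1, 2]] = 0.0  # wt site "ACG" at 2:5
        m = EnergyMatrix(vals, gauge="wildtype-zero", wildtype="ACG")
        site = PlantedSite(role="repressor", interval=(2, 5), true_matrix=m,
                           interaction_strength=2.0)
        template = PromoterTemplate(
            name="enum", wildtype_seq=wt, tss_offset=0, planted_sites=[site]
        )
        variants = []
        for i in range(64):
            s = decode(np.array([i // 16, (i // 4) % 4, i % 4], dtype=np.uint8))
            variants.append(wt[:2] + s + wt[5:])
        indicators = np.stack([
            np.frombuffer(v.encode(), np.uint8) != np.frombuffer(wt.encode(), np.uint8)
            for v in variants
        ]).astype(np.uint8)
        lib_vars = variants
        from regfoot.synth import VariantLibrary

        lib = VariantLibrary(template=template, variants=lib_vars, mutation_indicators=indicators)
        expr = simulate_expression(lib)
        energies = np.array([predict_energy(v[2:5], m) for v in variants])
        # ties in energy are ties in expression; compare sort orders robustly
        assert np.allclose(np.argsort(expr, kind="stable"), np.argsort(energies, kind="stable"))


class TestSampleReads:
    def test_read_conservation_and_determinism(self, toy_template):
        lib = generate_variants(toy_template, n_variants=100, mut_rate=0.2, seed=0, rate_band=None)
        assign_barcodes(lib, seed=1)
        simulate_expression(lib)
        a = sample_reads(lib, n_dna_reads=5000, n_mrna_reads=4000, seed=9)
        b = sample_reads(lib, n_dna_reads=5000, n_mrna_reads=4000, seed=9)
        assert a.total_dna == 5000 and a.total_mrna == 4000
        assert a.df.equals(b.df)

    def test_expression_ratio_law_of_large_numbers(self):
        # 2 barcodes, expressions 1 and 2: at huge depth the mRNA/DNA ratio
        # of barcode 2 approaches twice that of barcode 1
        template = PromoterTemplate(name="two", wildtype_seq="ACGT", tss_offset=0)
        from regfoot.synth import VariantLibrary

        lib = VariantLibrary(
            template=template,
            variants=["ACGT", "ACGA"],
            mutation_indicators=np.array([[0, 0, 0, 0], [0, 0, 0, 1]], dtype=np.uint8),
            barcodes={"AAAA": 0, "CCCC": 1},
            true_expression=np.array([1.0, 2.0]),
        )
        counts = sample_reads(lib, n_dna_reads=400_000, n_mrna_reads=400_000,
                              seed=4, dna_skew_sigma=0.0)
        df = counts.df.set_index("barcode")
        r0 = df.loc["AAAA", "mrna_ct"] / df.loc["AAAA", "dna_ct"]
        r1 = df.loc["CCCC", "mrna_ct"] / df.loc["CCCC", "dna_ct"]
        assert r1 / r0 == pytest.approx(2.0, rel=0.05)

    def test_equal_expression_equal_expected_ratio(self, toy_template):
        lib = generate_variants(toy_template, n_variants=20, mut_rate=0.2, seed=0, rate_band=None)
        assign_barcodes(lib, seed=1)
        expr = simulate_expression(lib)
        assert np.allclose(expr, expr[0])
        counts = sample_reads(lib, n_dna_reads=200_000, n_mrna_reads=200_000, seed=2)
        df = counts.df
        ratios = (df["mrna_ct"] + 1) / (df["dna_ct"] + 1)
        # no systematic trend with barcode index under constant expression
        assert abs(np.corrcoef(ratios, np.arange(len(df)))[0, 1]) < 0.2


def test_default_template_architectures():
    simple = default_template(architecture="simple-repression")
    roles = sorted(s.role for s in simple.planted_sites)
    assert roles == ["repressor", "rnap"]
    assert len(default_template(architecture="constitutive").planted_sites) == 1
    assert default_template(architecture="empty").planted_sites == []
    assert len(simple) == 160 and simple.tss_offset == 115
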