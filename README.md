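# regfoot

Mutual-information footprinting and binding-site inference for barcoded
promoter-mutagenesis reporter assays (MPRAs).

## The problem

A massively parallel reporter assay for bacterial promoters mutagenizes a
160-bp window around a transcription start site (each base substituted
with ~10% probability), tags every variant with ~5 random 20-nt barcodes,
and sequences both the plasmid DNA pool and the mRNA it produces. The
per-barcode DNA and mRNA read counts then carry a base-pair-resolution
record of which positions matter for expression. `regfoot` turns those
counts into regulatory hypotheses:

1. **Information footprint.** For each position *b*, reads are
   cross-classified by mutation state *m* (0 = mutated, 1 = wild type)
   and origin *μ* (0 = DNA, 1 = mRNA), and scored by the mutual
   information

   *I*<sub>b</sub> = Σ<sub>m,μ</sub> p(m,μ) log₂ [ p(m,μ) / p<sub>mut</sub>(m) p<sub>expr</sub>(μ) ],

   in bits. Positions inside functional binding sites show elevated
   *I*<sub>b</sub>; the sign of the mutational effect on the mRNA/DNA
   ratio marks each position activator-like (mutation lowers expression)
   or repressor-like (mutation raises it).
2. **Site calling.** Footprints are smoothed over 15-bp windows,
   thresholded at 2.5×10⁻⁴ bits, joined across gaps of up to 4 bp
   (per polarity), and trimmed back to raw supra-threshold bases. RNAP
   (polymerase) sites are identified by sliding an exemplar RNAP energy
   matrix along a whole-window inferred matrix and thresholding the
   Pearson correlation at 0.45. The result is an (n_a, n_r) architecture
   label — e.g. (0, 1) is simple repression — or "inactive" when no RNAP
   site is found.
3. **Energy matrices and logos.** For a called site, the additive model
   *E*(s) = Σᵢ ε[i, sᵢ] is fit by Metropolis MCMC that maximizes the
   mutual information between rank-binned energy predictions and the
   DNA/mRNA read label (matrices are gauge-fixed and reported in
   arbitrary units), then rendered as a sequence logo.
4. **Pulldown enrichment.** SILAC-style heavy/light protein
   quantifications from DNA-affinity chromatography are scored by robust
   (median/MAD) upper-tail outlier p-values with Benjamini–Hochberg
   correction, to name the factor that binds a called site.

A first-class synthetic-data generator plants known regulatory
architectures (RNAP sites with consensus −35/−10 hexamers, activator and
repressor operators with ground-truth energy matrices) and samples read
counts through a thermodynamic occupancy model, so every stage of the
pipeline is validated end to end without any sequencing downloads.

## Worked example

Run the one-command demo — simulate a simple-repression promoter
(planted RNAP site at window positions 80–110, repressor operator at
116–131), sample 5×10⁴ DNA and 5×10⁴ mRNA reads, and analyze:

```bash
regfoot demo --outdir demo_out --seed 1
# {"architecture_label": "(0, 1)"}
```

`demo_out/summary.json` then contains (abridged):

```json
{
  "architecture_label": "(0, 1)",
  "mean_mutation_rate": 0.099778,
  "n_variants": 2200,
  "n_barcodes": 10919,
  "called_regions": [
    {"start": 80,  "end": 110, "polarity": "rnap",           "score": 0.973},
    {"start": 116, "end": 131, "polarity": "repressor-like", "mean_info": 0.00257}
  ],
  "planted_sites": [
    {"role": "rnap",      "interval": [80, 110],  "best_jaccard_with_calls": 1.0},
    {"role": "repressor", "interval": [116, 131], "best_jaccard_with_calls": 1.0}
  ]
}
```

Reading this: the library hit its 10% design mutation rate (9.98%
realized); the RNAP scan found the planted polymerase site at exactly the
right offset with Pearson r = 0.97; the threshold caller recovered the
repressor operator at Jaccard overlap 1.0 with the planted interval; and
one RNAP site plus one repressor yields the simple-repression label
(0, 1). The demo directory also holds the variant FASTA, barcode map,
count table, footprint track, inferred matrices, and the repressor-site
logo heights.

Each stage is also exposed as a subcommand over plain TSV/FASTA files —
`simulate`, `footprint`, `callsites`, `fitmatrix`, `logo`, `enrich` —
see `regfoot --help`.

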