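# ncarray

Design and analysis toolkit for custom spotted microarrays profiling small
and medium-sized noncoding RNAs (18–400 nt): snoRNAs, miRNAs, tRNA-derived
fragments, snRNAs and unclassified species. It is aimed at groups who build
their own two-color ncRNA chips from RNA-Seq evidence — no commercial
platform covers these RNA classes — and at anyone analyzing two-color
dye-swap experiments with PM/MM control probes.

The package covers the whole life cycle of such a chip:

1. **Region selection** (`ncarray.region_selection`) — candidate loci come
   in as coverage contigs (BED6 + bedGraph + FASTA). Contigs supported by
   fewer than 5 reads are dropped. Contigs < 70 nt yield one probe region
   of 18–30 nt at the coverage maximum; longer contigs are tiled in 30-nt
   windows and every window with above-average coverage becomes a region.
   Per contig, one low-coverage window (mean below ⅓ of the maximum
   coverage) is kept as a control/precursor region — the coverage signature
   of a processed RNA excised from a longer precursor.
2. **Probe design** (`ncarray.probe_design`) — within each region every
   antisense oligo of length 18–30 (preferred 25) is scored on five
   criteria in [0, 1] — cross-hybridization, ΔTm to the 60 °C DNA:RNA
   target (Sugimoto nearest-neighbor model), folding, position in the
   region, sequence complexity — combined with weights
   24.2/32.3/6.1/11.3/16.1 % (renormalized to 1). Each signal probe gets a
   mismatch (MM) partner: one substitution at position 13 that is a true
   mismatch and never forms a stabilizing G·U / T·G wobble with the target.
   Eight random spike-ins and 40 U2/U6 snRNA probes serve as controls.
3. **Array layout** (`ncarray.array_layout`) — each PM is spotted next to
   its MM (same row, adjacent columns); every probe appears eight times as
   two quadruplicates in disjoint halves of the print-tip blocks, so local
   artifacts cannot erase a probe. Layouts round-trip through a GAL-like
   TSV and can be validated independently.
4. **Hybridization simulator** (`ncarray.hyb_simulator`) — a generative
   model of dye-swap scans (gene-wise dye bias, per-block intensity-
   dependent curvature, MM cross-hybridization, multiplicative noise,
   additive background) with a ground-truth table, so the analysis pipeline
   is testable end to end without any downloaded data.
5. **Expression analysis** (`ncarray.expression_analysis`) — net intensity
   (foreground − local background), PM>MM specificity filter, print-tip
   loess normalization of M on A within arrays, quantile normalization of A
   between arrays, a dye-swap linear model over replicate spots, moderated
   t-statistics with an empirical-Bayes variance prior

   s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),  t̃_g = β̂_g / (s̃_g √v_g),

   and Benjamini–Hochberg adjustment; candidates with adjusted p < 0.05 are
   called differentially expressed.
6. **Workbench** (`ncarray.workbench`, `ncarray.cli`) — reporting
   (biotype up/down counts, overlap tables, chip composition) and the
   `ncarray` command line tying everything together.

## Worked example

Generate a synthetic design input set, design a chip, lay it out, simulate
a dye-swap experiment with 10 % spiked differential expression, and analyze
it:

```bash
python -c "from ncarray.hyb_simulator import simulate_design_inputs; \
           simulate_design_inputs(60, seed=42, out_dir='fixtures')"
ncarray design   --bed fixtures/contigs.bed --bedgraph fixtures/coverage.bedgraph \
                 --fasta fixtures/contigs.fasta --seed 42 --out design
ncarray layout   --design-report design/design_report.tsv \
                 --blocks 4 --rows 40 --cols 40 --seed 42 --out layout
ncarray simulate --layout layout/layout.gal.tsv --seed 42 --out sim
ncarray analyze  --scans sim --sheet sim/experiment_sheet.tsv --out analysis
ncarray report   --de-table demo analysis/de_table.tsv --out report
```

which prints

```
designed 131 probes from 43 contigs -> design
layout: 1520 spots, 131 PM-type probes, 190 spotted oligo species -> layout
simulated 6 scans (3 dye-swap pairs) -> sim
13 DE candidates at adjusted p < 0.05 -> analysis
report for 1 comparison(s) -> report
```

Reading the numbers: 60 simulated contigs reduce to 43 after the 5-read
filter; they yield 131 probes (signal pairs, MM-less control-region probes,
48 spike-in/snRNA controls), spotted as 190 distinct oligo species (each
signal PM plus its MM partner) on 1520 spots. Six scans are three dye-swap
pairs. With ~10 % of candidates spiked at |log2FC| = 1, the pipeline calls
13 differentially expressed candidates at adjusted p < 0.05; the ground
truth is in `sim/truth.tsv`, and `analysis/de_table.tsv` has per-candidate
log2 fold change, moderated t, raw and adjusted p, and the PM>MM filter
flag.

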