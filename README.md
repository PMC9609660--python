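# rumenbatch

Quantitative analysis of **in vitro rumen batch-culture experiments** — the
standard assay in ruminant nutrition where a feed substrate is incubated in
buffered rumen fluid and gas production, methane, fermentation end-products,
microbial populations, and community composition are measured to evaluate
feed additives (here: sodium nitrate as a methane inhibitor and cysteamine
as a growth promoter, alone and combined, in a four-treatment design).

The package is aimed at rumen microbiologists and animal nutritionists who
have the raw bench tables (syringe readings, GC volatile-fatty-acid
concentrations, qPCR plates, OTU count tables) and want the full desk-side
analysis, reproducibly, in one place:

* **Gas kinetics** — blank correction from substrate-free bottles, interval
  cumulation, per-gram-dry-matter totals, and replicate rejection (bottles
  deviating > 10 % from their group mean in 72-h cumulative net gas).
* **Metabolic hydrogen balance** from the VFA profile and methane amount:

  ```
  H2 produced = 2A + P + 4B + 2iV + 2V
  H2 utilized = 4M + 2P + 3B + V
  H2 recovery (%) = utilized / produced x 100
  ```

  with A, P, B, iV, V the net molar amounts of acetate, propionate,
  butyrate, isovalerate, and valerate and M the methane amount (mmol).
* **Fermentation chemistry** — TVFA, acetate:propionate ratio, molar
  proportions, dry-matter digestibility, linear colorimetric standard
  curves, and essential/non-essential amino-acid panel totals.
* **qPCR absolute quantification** — amplicon copy math (660 g/mol/bp),
  standard-curve fitting with efficiency QC, and log10 copies/mL.
* **Community diversity** — Shannon, Simpson (unbiased dominance form),
  Chao1, ACE, Good's coverage; shared/unique OTU Venn partitions;
  Bray–Curtis dissimilarity; seeded permutation PERMANOVA.
* **Group statistics** — one-way ANOVA on per-run bottle averages, pooled
  SEM, Tukey HSD compact significance letters, and Spearman correlation
  screens with the `*`/`**`/`***` star convention.
* **Synthetic experiments** — a generator that emulates the whole study
  (4 treatments x 5 bottles x 2 runs, saturating gas curves, blank drift,
  Dirichlet-multinomial OTU tables) with known ground truth, so every stage
  is testable without wet-lab data.

## Worked example

```python
from rumenbatch import hydrogen as h2, chemistry as chem

# end-point VFA concentrations (mmol/L) of an unsupplemented bottle
vfa = {"acetate": 38.3, "propionate": 21.4, "butyrate": 13.4,
       "isobutyrate": 2.05, "valerate": 2.13, "isovalerate": 4.47}

bal = h2.hydrogen_balance(vfa, ch4_mmol=0.748)   # 60 mL liquid volume
print(f"H2 produced  {bal.h2_produced:.2f} mmol")
print(f"H2 utilized  {bal.h2_utilized:.2f} mmol")
print(f"H2 recovery  {bal.h2_recovery:.1f} %")

s = chem.summarize_vfa(vfa)
print(f"TVFA {s.tvfa:.1f} mmol/L   A/P {s.ap_ratio:.2f}")
```

prints

```
H2 produced  9.89 mmol
H2 utilized  8.10 mmol
H2 recovery  81.9 %
TVFA 81.7 mmol/L   A/P 1.79
```

Reading: this bottle's fermentation released 9.89 mmol of reducing
equivalents through VFA synthesis, of which 8.10 mmol (81.9 %) are accounted
for by methanogenesis and propionate/butyrate synthesis — a typical recovery
for an uninhibited culture. An acetate:propionate ratio of 1.79 marks
propionate-leaning fermentation; nitrate supplementation shifts it upward.

The same analysis runs end to end from files via the CLI:

```bash
rumenbatch simulate --out demo --seed 1          # synthetic bench tables
rumenbatch all --gas demo/gas_readings.csv \
               --chemistry demo/chemistry.csv \
               --amino-acids demo/amino_acids.csv \
               --qpcr demo/qpcr_plate.csv \
               --otu demo/otu_table.tsv \
               --out demo/results --seed 1
```

which writes publication-shaped tables (treatment means with compact
significance letters, pooled SEM, ANOVA p), the Bray–Curtis matrix, the
PERMANOVA summary, the OTU Venn partition, correlation screens, and a JSON
manifest sufficient to reproduce the run.

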