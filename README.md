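# trzmir

Screening pipeline and assay statistics for **treatment-responsive microRNAs
in HER2-positive breast cancer cell lines**.

Trastuzumab, the anti-HER2 antibody, alters the microRNA complement of
HER2-positive breast cancer cells. Identifying which miRNAs respond — and
only in HER2-positive lines — takes a small, replicate-free two-factor
microarray design: four cell lines (SKBR3 and BT474 HER2-positive, MCF7 and
MDA-MB-231 HER2-negative), each profiled with and without trastuzumab
(4 µg/ml, 144 h). This package implements that screen as a tested, reusable
pipeline, together with the downstream assay estimators used to validate
candidate miRNAs, a seed-site matcher for target localization, and a
synthetic-data generator so every stage is testable without the original
array data.

## The screen

Raw linear intensities (median foreground minus local background) are
quantile-normalized across the 8 samples and log2-transformed. Then:

1. **Expression floor** — keep miRNA *i* iff, in every line *ℓ*,
   max(x_{i,ℓ,treated}, x_{i,ℓ,control}) > 6 (log2 units).
2. **Fold changes** — per line, log2 FC_{i,ℓ} = x_{i,ℓ,treated} − x_{i,ℓ,control}.
3. **Negative-line exclusion** — drop miRNA *i* if FC_{i,ℓ} > 1.5 or
   < 1/1.5 (linear) in *any* HER2-negative line ℓ.
4. **Relative fold change (RFC)** — for each HER2-positive line *p*:

       log2 RFC_{i,p} = log2 FC_{i,p} − mean_{ℓ∈neg} log2 FC_{i,ℓ}

   i.e. on the linear scale the positive-line fold change divided by the
   geometric mean of the negative-line fold changes. miRNAs with
   RFC > 1.5 (up) or < 1/1.5 (down) are ranked by |log2 RFC|; the
   cross-line summary is the geometric mean of the per-positive-line RFCs.

Downstream estimators (`trzmir.assays`): ΔΔCq relative quantification with
multi-reference normalization, WST-1 viability inhibition
100·(1 − A450_treated/A450_control), maximum-likelihood G1/S/G2-M fractions
from PI DNA-content histograms (Gaussian G1 at µ, Gaussian G2/M at 2µ,
Gaussian-smoothed-uniform S), Annexin-V positive fractions, dual-luciferase
percent repression 100·(1 − mean(firefly/renilla)_miR / mean(firefly/renilla)_ncRNA),
and the unpaired pooled-variance Student t-test. `trzmir.seeds` scans 3′UTRs
for canonical seed-match site types (6mer, 7mer-A1, 7mer-m8, 8mer; seed =
miRNA nt 2–8, e.g. GUAAACA for the miR-30 family) and builds site-disrupted
reporter mutants.

## Worked example

The numbered scripts under `analysis/` run the whole workflow on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate.py    # 200 miRNAs x 8 samples, 10 planted responders
python analysis/02_screen.py
python analysis/03_assays.py
python analysis/04_seed_sites.py
```

`02_screen.py` prints:

```
140 miRNAs passed the expression filter; 140 survived negative-line exclusion
cross-line up list: 10 miRNAs (sensitivity 1.00, false positives 0)
top of the up list (miRNA, mean RFC):
  miR-sim-0007	2.4818
  miR-sim-0008	2.4364
  ...
```

All ten miRNAs planted with a +1.2 log2 treatment effect in the
HER2-positive lines only (ideal RFC 2^1.2 ≈ 2.30; quantile normalization
compresses it slightly) are recovered with no false positives.
`03_assays.py` recovers the assay ground truths the same way — e.g. WST-1
inhibitions of 55.8% and 24.5% (truths 56%/24%, cross-line mean 40.2%),
a fitted G1-fraction shift of 0.26 for a 0.65→0.91 control/treated pair,
and 24.6% luciferase repression for the wild-type two-site construct
(truth 27%) falling to −2.5% for the double site mutant.

The same workflow is scriptable from a shell via the `trzmir` CLI
(`simulate`, `screen`, `assays`, `seeds`, `report` subcommands), e.g.

```sh
trzmir simulate --seed 17 --out data/
trzmir screen --matrix data/expression.tsv --samples data/samples.csv --out out/
trzmir seeds --mirna-fasta mirs.fa --utr-fasta utrs.fa --out sites.tsv
```

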