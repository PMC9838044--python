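# hdzip

A tested re-implementation of the bespoke computations behind a plant
gene-family characterization study: identification of an HD-Zip
transcription-factor family from domain evidence, genome locus assignment,
Ka/Ks-based duplication dating, expression-breadth analysis against a
random-transcript null, Spearman co-expression networks with a bootstrap
network-formation-tendency test and hub calling, and qPCR-based pH-stress
response analysis. Every stage runs on synthetic data with planted ground
truth, so the whole pipeline is testable without any external downloads.

It is written for computational biologists who want the statistical
machinery of such gene-family surveys as a reusable, inspectable library
rather than a collection of one-off spreadsheets and web tools.

## What it computes

**Family identification** (`hdzip.family`). HD-Zip genes are diagnosed by
domain co-occurrence: a homeodomain (HD) plus either a leucine zipper
(HALZ) or a START domain. Subfamilies follow the classical rules — I:
HD+HALZ; II: HD+HALZ+CPSCE; III: HD+START+MEKHLA; IV: HD+START — with the
motif-bearing subfamilies II/III taking precedence over their plain
supersets. Candidate sets from independent searches are unioned with
per-method provenance; transcripts are placed on chromosomes from BLAST
outfmt-6 tables (filters: aligned length ≥ 180 bp, identity ≥ 99 %,
E ≤ 1e-6) and collapsed into loci by transitive ≥ 1 bp interval overlap.

**Molecular evolution** (`hdzip.molevo`). Nei–Gojobori (1986) counting:
per-codon synonymous site fractions from single-nucleotide mutation fates
under the standard genetic code, averaged between the two sequences;
observed differences partitioned by equal-weight pathway averaging
(pathways through stop codons excluded); Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)·p). Duplication dates follow the synonymous clock
T = Ks/(2λ) with λ = 6.5×10⁻⁹ substitutions per synonymous site per year.

**Expression breadth** (`hdzip.expression`). A gene's breadth is the number
of samples (4 root ages, 14 tissues, or 42 cultivars) where TPM > 0. The
family's breadth is contrasted with 20 random same-size draws from a
background pool using a prediction-interval t-test with a finite-pool
variance correction (see `docs/methods.md`).

**Co-expression networks** (`hdzip.network`). Spearman ρ with tie-corrected
average ranks; two-sided p from t = ρ·√((n−2)/(1−ρ²)) on n−2 df. Networks
retain edges at p ≤ threshold over a decade sweep 5.0E-02 … 1.0E-08;
clusters are connected components; hubs are nodes with degree strictly
above a connectivity cutoff (15 for the cultivar design, 10 for tissues).

**Stress response** (`hdzip.stress`). Livak 2^−ΔΔCt relative expression
against the pH 6.0 calibrator, Welch two-tailed stars (\* p ≤ 5e-2,
\*\* p ≤ 1e-2), and Spearman coupling among hub-gene response profiles.

**Synthetic data** (`hdzip.simulate`). Deterministic generators with
emitted truth for every stage: domain tables (default subfamily sizes
73/13/11/20), candidate sets (114/83/112 → union 117), alignment tables
(64 loci, 5 genotype-specific), divergence-controlled CDS pairs,
latent-factor expression matrices with planted modules/hubs/breadth
classes, and replicate qPCR tables with planted folds.

## Worked example

```python
from hdzip.molevo import kaks_ratio, divergence_time
print(round(kaks_ratio(0.205, 0.364), 3), round(divergence_time(0.364), 2))
print(round(kaks_ratio(0.159, 0.383), 3), round(divergence_time(0.383), 2))
```

prints `0.563 28.0` and `0.415 29.46`: the ω ratios and clock dates (in
million years) of the two most recently duplicated gene pairs, from their
published Ka/Ks values — both pairs under purifying selection (ω < 1),
diverging roughly 28–29 MYA.

The numbered drivers under `analysis/` run each stage end to end on
generated data and write tables under `results/`, e.g.

```sh
python analysis/03_expression_breadth.py --seed 1
```

```
ages design: 95 of 117 family transcripts expressed in >=1 root age (81.2%)
random background: 45.5 of 117 expressed on average; p = 2.64e-07 (significant at 1e-2)
core set expressed in every sample of every design: 19 genes
```

i.e. the family is expressed far more broadly than a random same-size
transcript draw, and 19 members are expressed in every sample of all three
designs.

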