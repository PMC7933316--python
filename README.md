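# cleavedrive

Quantification and simulation tools for ribozyme-switch biosensor screens.

In cleavage-based selections, a library of aptamer-coupled hammerhead
ribozymes is transcribed and each molecule either self-cleaves or not,
depending on its sequence and on whether a ligand is bound. A regeneration
step replaces the 5' end of cleaved molecules with a new prefix, so a single
sequencing run can count cleaved (prefix `Z`) and uncleaved (prefix `W`)
molecules for every sequence in the library, with or without ligand.
`cleavedrive` implements the desk side of that workflow:

- **`seqio`** — merge paired amplicon reads, demultiplex condition barcodes,
  classify the cleavage-state prefix, tabulate read counts, and flag likely
  misassignment artifacts (low-count sequences one edit away from a ≥100×
  more abundant neighbor).
- **`cleaveseq`** — the quantitative core. The cleavage fraction of
  sequence *s* is

  `c_s = (r_Z,s / r_Z,ref) / (r_W,s / r_W,ref + r_Z,s / r_Z,ref)`

  where `r_P,ref` counts spike-in reference reads (15 references at a fixed
  18 pM each) carrying prefix `P`. Ligand response is the fold change of the
  uncleaved fraction, `f_s = k (1 − c_s,+ligand) / (1 − c_s,−ligand)`, with
  `k` set so the run-wide median fold change is 1. Bootstrap percentile
  intervals (1000 resamples, 5th/95th percentiles), replicate concordance
  tests, switching tests on the 2×2 count table, and the hit rule
  (`f_s > 2` and `p < 1/N`) complete the pipeline.
- **`driver_sim`** — a stochastic model of alternating
  cleaved/uncleaved-selection rounds; survival weight `c_minus` on cleaved
  rounds, `1 − c_plus` on uncleaved rounds. Includes estimators for the
  per-round enrichment rate η and back-extrapolated initial fraction f₀,
  the dilution bottleneck ("constriction") used before sequencing, and
  randomized-library combinatorics.
- **`doseresponse`** — four-parameter logistic EC₅₀ fits and
  sensor × molecule selectivity matrices.
- **`kinetics`** — 1:1 Langmuir SPR sensorgram simulation, the three-step
  background-subtraction chain, global kinetic fits
  (`K_D = k_off / k_on`), equilibrium isotherm fits, and the non-measurable
  rule for transitions faster than 2 s.
- **`reporters`** — gel-band quantification (length-normalized,
  background-subtracted fraction cleaved) and two-color flow-cytometry
  normalization (`RFU = 100 × F_sample / F_control`).
- **`mutscan`** — single-mutation effect maps around a parent sensor and
  hierarchical clustering of hits into sequence families.
- **`synthgen`** — ground-truth generators for every input above, so each
  analysis can be validated against planted truth.

## Worked example

Plant three switchers (true fold change ρ = 3) among 197 ligand-insensitive
sequences, simulate a sequencing run of two million reads per condition, and
quantify:

```python
from cleavedrive import cleaveseq as cs
from cleavedrive import synthgen as sg

truth = sg.random_truth(n_sequences=200, n_switchers=3, rho=3.0,
                        depth=2_000_000, seed=42)
table = sg.generate_count_run(truth)
df = cs.quantify_run(table, "minus", "plus", B=1000, seed=7)
print("k =", round(df.attrs["k"], 4), " N =", df.attrs["N"])
print(df[df["is_hit"]][["accession", "c_minus", "c_plus", "f",
                        "f_ci_lo", "f_ci_hi", "p_value"]].round(3))
```

prints

```
k = 0.9989  N = 200
 accession  c_minus  c_plus     f  f_ci_lo  f_ci_hi  p_value
         1    0.744   0.233 2.993    2.895    3.094      0.0
         2    0.833   0.493 3.040    2.917    3.180      0.0
         3    0.857   0.558 3.076    2.933    3.237      0.0
```

The three hits are exactly the planted switchers (accessions 1–3): their
estimated fold changes cluster around the planted ρ = 3 with 90% bootstrap
intervals of a few percent at this depth, the normalization factor `k` is
≈1 because almost all sequences are non-switching, and none of the 197 null
sequences is called (the hit rule requires both `f > 2` and significance at
the Bonferroni-corrected `1/N` level).

The same operations are available from a shell:

```sh
cleavedrive demux --r1 r1.fastq --r2 r2.fastq --scheme scheme.yaml --out table.tsv
cleavedrive quantify --table table.tsv --minus minus --plus plus --out results/
cleavedrive simulate --config sim.yaml --rounds 60 --seed 7 --out traj.tsv
```

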