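# sigensemble

Ensemble assignment of single-base-substitution (SBS96) mutational
signatures to tumor samples.

Reference signature assignment estimates, for each sample, how many of its
somatic mutations were contributed by each of a set of known mutational
processes.  Given a mutational catalog **V** (96 trinucleotide-context
channels × N samples) and a reference signature set **W** (96 × K
column-stochastic profiles, e.g. COSMIC SBS signatures), the task is the
non-negative deconvolution **V ≈ W · H**, where **H** (K × N) holds the
signature activities.  Published assignment tools differ in two ways that
materially change results: the optimizer used for the deconvolution, and
the strategy used to suppress spurious low-activity assignments
(overfitting).  `sigensemble` makes both dimensions explicit and
controllable, and adds consensus models that integrate several assignments
into one.

It is intended for cancer-genomics analysts who want signature activities
with an explicit handle on inter-tool variability, and for method
developers who need a controlled test-bed with simulated ground truth.

## What is implemented

**Engines** (per-sample solvers for v ≈ W h, h ≥ 0):

| engine   | objective | algorithm |
|----------|-----------|-----------|
| `nnls`   | min ‖v − W h‖₂ | Lawson–Hanson active set |
| `fcnnls` | min ‖v − W h‖₂, many samples | fast combinatorial NNLS (shared passive-set factorizations) |
| `qp`     | min ‖p − W h‖₂², Σh = 1, p = v/Σv | primal active-set quadratic program on the simplex |
| `mu`     | min D<sub>KL</sub>(v ‖ W h) | multiplicative updates, monotone in the divergence |

**Strategies** (overfitting control, threshold t = 5% of assigned mass by
default):

* **Regular** — fit the full reference set; every mutation stays assigned.
* **Remove** — zero activities below t; their mass becomes *Unassigned*
  (utilization drops below 1, and the removal distorts the reconstructed
  spectrum).
* **Refit** — keep the signatures at or above t and re-run the engine on
  that subset (optionally iterating); all mutations are redistributed.

**Ensembles** over M ≥ 2 activity matrices (engines here, or external
tools' outputs read from TSV): *Majority* (> M/2 members assign it),
*Unanimous* (all members), and *Mean* (per-cell bootstrap resampling of
means, n = 500, then per-sample standardization to sum 1).

**Metrics**: reconstructed-vs-original cosine similarity (RvO), mutation
utilization, Jaccard agreement of assigned sets, tie-corrected Kendall
tau-b with sample- and signature-level validity rules, Shannon diversity
(profile flatness), pooled RMSE against simulated truth restricted to truly
active entries, PPV/NPV/accuracy for qualitative calls, and
dominant-signature consensus.

**Simulator**: synthetic signature sets (spiky and flat profiles),
ground-truth activities (per-signature prevalence, gamma magnitudes on the
simplex, log-uniform burdens), and multinomial/Poisson catalogs — so the
whole pipeline is testable end to end with a known answer.

**Catalog construction**: SBS96 catalogs from VCF + indexed FASTA with
pyrimidine-strand canonicalization, multi-allelic splitting and a skip log.

## Worked example

```python
from sigensemble import (CohortSpec, EngineSpec, align_members, assign_refit,
                         ensemble_mean, rmse_vs_truth, simulate_cohort)

truth = simulate_cohort(
    CohortSpec(n_samples=30, prevalence=0.5, burden_range=(1000, 20000)),
    k=6, flat_fraction=1/3, seed=7,
)
engines = ["nnls", "fcnnls", "qp", "mu"]
members = []
for name in engines:
    result = assign_refit(truth.catalog, truth.signatures, EngineSpec(name=name))
    members.append(result.activities)
    print(f"{name:7s} RMSE={rmse_vs_truth(result.activities, truth.activities):.4f} "
          f"mean RvO={result.rvo.mean():.4f} "
          f"mean signatures/sample={result.n_assigned_signatures.mean():.2f}")

consensus = ensemble_mean(align_members(members, engines), n_resamples=500, seed=7)
print(f"ensemble-mean RMSE={rmse_vs_truth(consensus, truth.activities):.4f}")
```

prints

```
nnls    RMSE=0.0190 mean RvO=0.9973 mean signatures/sample=3.23
fcnnls  RMSE=0.0190 mean RvO=0.9973 mean signatures/sample=3.23
qp      RMSE=0.0187 mean RvO=0.9973 mean signatures/sample=3.23
mu      RMSE=0.0182 mean RvO=0.9973 mean signatures/sample=3.23
ensemble-mean RMSE=0.0185
```

Reading this: every engine reconstructs the observed spectra almost
perfectly (RvO ≈ 0.997) using about three signatures per sample, and each
engine's activity estimates sit within ~0.02 (RMSE, proportion units) of
the simulated truth.  The across-engine mean lands at or below the middle
of the member errors — on harder cohorts (flatter signatures, lower
burdens) it is typically first or second best, because averaging cancels
the engines' partly independent errors.

The same workflow is available from a shell:

```bash
sigensemble simulate --n-samples 30 --k 6 --seed 7 --out sim/
sigensemble assign --catalog sim/catalog.tsv --signatures sim/signatures.tsv \
    --engines nnls,fcnnls,qp,mu --strategy refit --out fits/
sigensemble ensemble --inputs fits/activities_nnls_refit.tsv \
    --inputs fits/activities_fcnnls_refit.tsv \
    --inputs fits/activities_qp_refit.tsv \
    --inputs fits/activities_mu_refit.tsv --seed 7 --out consensus/
sigensemble benchmark --truth sim/truth_activities.tsv \
    --estimates fits/activities_nnls_refit.tsv \
    --estimates consensus/activities_ensemble_mean.tsv --out bench.tsv
```

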