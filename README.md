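# emodoc

Emotional-oddball EEG analysis for disorders-of-consciousness research:
event-related potential (ERP) permutation statistics, phase-locking-value
(PLV) functional networks, weighted graph metrics, and mixed
repeated-measures group inference — plus a synthetic EEG generator that
makes every stage testable end to end.

## Who this is for

Researchers probing residual emotional processing in patients with
disorders of consciousness — unresponsive wakefulness syndrome (UWS) and
minimally conscious state (MCS) — against healthy controls (HC), using a
passive auditory oddball paradigm (86 neutral standards, 12 happy and 12
angry deviants per 110-stimulus block).  The package takes multichannel
EEG (EDF/EDF+ with annotation events, standard 10-20 montage, 500 Hz) or
simulates it, and produces per-group ERP statistics, per-subject
condition-wise PLV networks, their graph-theoretic properties, and the
group x condition statistical layer.

## The statistics at the core

**Mass-univariate ERP contrast.**  At every (channel, timepoint) cell, a
paired t-test of emotional vs neutral subject-mean amplitudes whose
p-value comes from the sign-flip permutation null (all 2^n flips for
n ≤ 12, else 1000 random flips, p = (b+1)/(m+1)), corrected across all
cells by the Benjamini–Yekutieli step-up, which controls FDR < 5% under
arbitrary dependence.

**Phase-locking value.**  For channels a, b with per-trial instantaneous
phases φ extracted from the analytic signal,

    PLV_ab(t) = | (1/K) Σ_k exp(i(φ_a,k(t) − φ_b,k(t))) |

averaged over 0–1000 ms post-stimulus; 0 = no phase locking, 1 = perfect.
Standard-condition trials are subsampled to the deviant count so the
finite-trial bias (E[PLV] ≈ √π/(2√K) for independent phases) cancels in
condition contrasts.

**Weighted network properties.**  On the dense PLV matrix (diagonal
zeroed): Onnela clustering coefficient C, characteristic path length L
(edge length 1/w), Latora–Marchiori global and local efficiency Ge, Le,
and small-worldness σ = (C/C_rand)/(L/L_rand) against degree-preserving
weight-shuffled nulls.

**Group inference.**  Per property, a mixed ANOVA with group (HC, MCS,
UWS) between subjects and condition (neutral, emotional) within, with
Mauchly's test and Greenhouse–Geisser correction (ε = 1 exactly for the
2-level factor), Bonferroni post hocs and simple effects; per edge,
t-contrasts with uncorrected (p < 0.05) and Bonferroni (p < 0.05/m,
m = 190 edges) masks.

The synthetic generator plants group-specific ERP amplitudes and von
Mises phase coupling whose expected PLV is the Bessel ratio
I1(κ)/I0(κ) — so parameter recovery is checkable against a closed form.

## Worked example

```python
from emodoc import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=1), "results/full")
print(summary["edge_mask_cardinality"]["HC:emotional-neutral"])
print(summary["erp"]["HC"]["n_significant_cells"],
      summary["erp"]["HC"]["significant_time_range_ms"])
```

With the default configuration (15 subjects per group, 110-stimulus
blocks, seed 1) this prints:

```
{'uncorrected': 153, 'bonferroni': 123}
2531 [226.0, 972.0]
```

meaning: in healthy controls the emotional-vs-neutral contrast finds 153
of 190 PLV edges significant uncorrected and 123 after Bonferroni
(patients show fewer: MCS 68, UWS 33 Bonferroni edges — the planted
gradient of emotional network reactivity), and 2531 channel-time cells
survive FDR correction in the ERP contrast, spanning 226–972 ms and
concentrated over central/parieto-occipital channels — the planted late
positive potential.  Condition-wise graph metrics, ANOVA tables, post
hocs and edge lists are written under `results/full/` as TSV/JSON.

The same stages are available from a shell:

```sh
emodoc simulate  --out ws --seed 1      # EDF + montage sidecars
emodoc preprocess --in ws --out ws      # epochs
emodoc erp   --in ws --out ws
emodoc plv   --in ws --out ws
emodoc graph --in ws --out ws
emodoc stats --in ws --out ws
emodoc run-all --out results/full --seed 1
```

See `docs/methods.md` for the model, parameter defaults, numerical
choices and known limitations.

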