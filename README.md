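# herdsync

Behavioural-synchrony analysis of scan-sampled herd data.

Group-living animals often do the same thing at the same time. If that
synchrony spreads through local interactions — animals attending to their
nearest neighbours — then a focal animal should be more synchronised with
its closest neighbour than with its second or third closest, and least with
a randomly chosen herd member. `herdsync` implements the complete analysis
pipeline for testing that prediction from instantaneous scan samples of a
herd of unmarked animals (the design was developed for a managed fallow
deer herd), together with a spatially explicit herd simulator that
generates protocol-shaped synthetic datasets with tunable
proximity-dependent behavioural coupling.

It is aimed at behavioural ecologists who collect focal/nearest-neighbour
scan samples and want a tested, reproducible version of the full
statistical path from raw observation records to publication statistics.

## The design and the statistics

Each 15-minute **session** follows one randomly chosen focal animal. Every
60 s the observer records the instantaneous behaviour (a 14-category
ethogram) of five animals: the focal, its three nearest neighbours
(re-ranked at every scan as animals move) and a **control** drawn uniformly
at random from the remaining visible animals, freshly at every scan.
Behaviours are compared either **strictly** (exact ethogram category) or
**dichotomously** (Active vs Inactive, where Inactive = the three lying
postures).

For each session and comparison role the pipeline counts the scans on which
that animal matched the focal, giving a sessions × 4 synchrony-count
matrix per classification. Inference is rank-based throughout:

- **Friedman test** (tie-corrected,
  `T1 = (k−1) Σⱼ (Rⱼ − n(k+1)/2)² / (A1 − C1)`) across the four comparison
  roles, with sessions as blocks;
- **Conover pairwise comparisons** for the Friedman design
  (t with (n−1)(k−1) df on rank-sum differences, tie-corrected variance),
  Bonferroni-adjusted over the 6 role pairs;
- the **independence expectation**: if every animal is independently active
  with probability *a*, two animals share an activity class with
  probability *a*² + (1−*a*)². With the pooled activity proportion
  *a* = 0.411 this is 0.516;
- a one-sample **Wilcoxon signed-rank test** of the per-session
  focal–control synchrony proportions against that expectation;
- a **focal-identity resampling** robustness check for pseudoreplication:
  focal identities are drawn uniformly from a finite herd (default 70) for
  the 30 sessions, the data are filtered to one session per identity, the
  Friedman test is re-run, and the p-value distribution over many
  replicates (default 100,000) is summarised.

## Worked example

Simulate a strongly coupled, tightly clustered herd, then run the full
analysis:

```python
import herdsync as hs

herd, dynamics, schedule = hs.strong_copy_scenario()
records = hs.simulate_study(herd, dynamics, schedule, seed=2024)

matrix = hs.score_sessions(records, mode="dichotomous")
print(matrix.median_proportions().round(3).to_dict())
print(hs.friedman_test(matrix))
print(hs.conover_posthoc(matrix).table[["treatment_a", "treatment_b",
                                        "adjusted_p"]])
```

Output:

```
{'neighbour1': 0.767, 'neighbour2': 0.7, 'neighbour3': 0.633, 'control': 0.533}
FriedmanResult(statistic=391.51873698820265, df=3, p_value=1.521275448142274e-84,
               tie_corrected=True, n_blocks=300, k_treatments=4, degenerate=False)
  treatment_a treatment_b     adjusted_p
0  neighbour1  neighbour2   8.504695e-24
1  neighbour1  neighbour3   3.090976e-52
2  neighbour1     control  3.394659e-108
3  neighbour2  neighbour3   4.147139e-08
4  neighbour2     control   4.253383e-45
5  neighbour3     control   1.314647e-18
```

Median synchrony declines strictly with neighbour rank (0.767 → 0.700 →
0.633) and the random control sits near the independence expectation
(0.533 vs 0.516); every pairwise contrast survives Bonferroni correction —
the spatial signature of locally propagated synchrony.

The same pipeline runs from the shell:

```bash
herdsync simulate --n-sessions 30 --copy-strength 49 --seed 1 --out records.csv
herdsync report --records records.csv --resample --replicates 10000 \
    --seed 1 --out report.json
```

`report.json` contains, per classification: the Friedman χ², the six
adjusted post-hoc p-values, the median synchrony proportions per role, the
pooled activity proportion, the independence expectation, the signed-rank
test and the resampling summary (maximum p across replicates, quantiles,
retained-session distribution).

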