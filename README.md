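# percolome

Percolation-based targeted-attack analysis of functional brain connectomes.

Functional connectomes — networks whose nodes are brain regions and whose
edge weights are pairwise Pearson correlations of regional resting-state
fMRI signals — degrade in characteristic ways under disease.  This package
implements a complete, tested pipeline for asking *how* a diseased network
differs from a healthy one in percolation terms: which nodes, when removed
from the healthy network, drive its global quantifiers toward the diseased
baseline fastest?

The pipeline covers:

* **Preprocessing** — within-group averaging of raw correlation matrices,
  normalization (clip negatives, rescale to unit maximum), and proportional
  thresholding to a fixed graph density *d* = *E* / [*n*(*n*−1)/2]
  (default 10%; for *n* = 90 regions this keeps exactly 401 of the 4,005
  region pairs, density 0.1001, mean degree 8.911).
* **Quantifiers** — the full weighted battery: characteristic path length
  (CPL), global efficiency, radius/diameter (all computed over finite
  shortest-path distances with edge length 1/*w*), largest cluster size,
  Louvain modularity *Q* and participation coefficient, transitivity,
  assortativity, small-worldness σ, and nodal degree/strength/betweenness/
  eigenvector/clustering/local-efficiency tables.
* **Collective influence** — CI<sub>ℓ</sub>(*i*) = (*k*<sub>*i*</sub>−1)
  Σ<sub>*j*∈∂B(*i*,ℓ)</sub> (*k*<sub>*j*</sub>−1), the optimal-percolation
  node ranking over ball boundaries at hop radius ℓ.
* **Targeted attacks** — basis (rank once), iterative (re-rank after every
  removal) and random-ensemble node-removal percolation, with global
  quantifier snapshots after each of the *n* removals.
* **Progression analysis** — difference curves
  Δ<sub>*t*</sub> = *q*<sub>disease</sub>(baseline) − *q*<sub>control</sub>(after *t* attacks)
  and the (fractional) attack count at which the attacked healthy network
  first reaches the diseased level.
* **Group statistics** — Wilcoxon rank-sum tests (tie/continuity-corrected
  normal approximation, exact enumeration for small samples) and effect
  sizes *r* = |*z*|/√*n*.
* **Synthetic cohorts** — a latent-factor generator producing two-group
  cohorts of genuine correlation matrices with bilateral mirror symmetry,
  modular structure, heavy-tailed hub strengths, and a controllable
  disease effect (attenuated anterior–posterior coupling, boosted
  posterior core), so the whole pipeline is testable without any data
  download.

## Worked example

```python
from percolome.synthetic import CohortConfig, generate_cohort
from percolome.pipeline import preprocess_group, subject_quantifier_tables
from percolome.stats import compare_quantifiers
from percolome.attack import run_targeted_attack
from percolome.progression import progression_result
from percolome.quantifiers import compute_global_quantifiers

cfg = CohortConfig(seed=0)                      # 90 regions, 17 vs 17 subjects
control, disease, atlas = generate_cohort(cfg)

avg_c = preprocess_group(control, 0.10)         # average -> normalize -> threshold
avg_d = preprocess_group(disease, 0.10)
print(avg_c.n_edges, round(avg_c.density, 4))   # 401 0.1001

gc, _ = subject_quantifier_tables(control, 0.10, seed=0, restarts=25)
gd, _ = subject_quantifier_tables(disease, 0.10, seed=0, restarts=25)
print(compare_quantifiers(gc.dropna(axis=1), gd.dropna(axis=1)).head(4))

traj = run_targeted_attack(avg_c, "iterative", "betweenness", seed=0,
                           metrics=("largest_cluster",))
baseline = compute_global_quantifiers(avg_d, seed=0, restarts=25)
res = progression_result(traj, baseline, "largest_cluster")
print(res.crossing_step)
```

prints (abridged):

```
401 0.1001
           metric  mean_a  mean_b       z      p      r
  largest_cluster 71.2941 58.4706  5.0075 0.0000 0.8588
global_efficiency  0.2678  0.3205 -4.9599 0.0000 0.8506
           radius  5.9791  1.9233  4.9599 0.0000 0.8506
           avg_bc 50.1418 27.6595  4.9599 0.0000 0.8506
3.26
```

Reading this: at 10% density the control group-average network holds a
71-node giant cluster against the diseased network's 60; subject-level
rank-sum tests flag the designed group differences (the diseased group is
more fragmented but its surviving core is *more* efficient); and an
iterative betweenness attack on the healthy network drags its largest
cluster down to the diseased baseline within 3–4 node removals — the
percolation signature of a disease that silences a few high-traffic hub
regions.

The same stages are available from the shell:

```bash
percolome simulate --seed 0 --out-dir cohort/
percolome attack cohort/control-00.csv --scheme iterative --quantifier betweenness \
    --seed 0 --out traj.csv
percolome run-all --seed 0 --out-dir full-run/
```

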