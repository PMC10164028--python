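# meddecode

Connectivity-based multivariate decoding of meditation styles from ROI-level
BOLD time series.

Attentional meditation comes in two canonical styles: **focused attention
(FA)**, which narrows attention onto an endogenous object such as the breath,
and **open monitoring (OM)**, which non-reactively monitors ongoing
experience. `meddecode` implements the full analysis chain used to ask
whether large-scale functional connectomes carry a decodable signature of the
style being practiced — and whether meditation expertise sharpens that
signature — in a two-group design (expert monastics, n = 12, vs novice
practitioners, n = 10; 2 conditions × 3 six-minute blocks per subject;
TR = 4.087 s).

The pipeline, per group:

1. **Preprocess** each ROI time-series block: nuisance regression (WM/CSF
   surrogates + motion parameters), linear detrend, zero-phase band-pass
   0.009–0.08 Hz, and scrubbing of volumes with framewise displacement
   FD > 0.5 mm (Power formulation, 50 mm head radius).
2. **Connectivity**: Pearson correlation between all ROI pairs per block,
   Fisher z-transformed; the strict upper triangle of the 90 × 90 matrix
   (4005 edges) is the feature vector. One sample per (subject, condition,
   block): 36 per class for experts, 30 for novices.
3. **Decoding**: 200 random subject-level 75/25 train/test splits. Inside
   each repetition, per-edge one-way ANOVA F scores are computed on training
   rows only, the top k = 200 edges are kept, and a linear soft-margin SVM
   (C = 1, FA encoded +1) is fit; accuracy is scored on held-out subjects.
4. **Inference**: permutation test (labels shuffled within subject, the whole
   fold-wise chain rerun, default add-one Monte-Carlo p), Bonferroni over the
   two groups, Mann-Whitney U on the two fold-accuracy distributions, a
   Bayesian correlated t-test against a chance classifier, bootstrap
   subsampling of the larger group, and an age-regression control.
5. **Relevance**: per-edge selection probability (fraction of repetitions an
   edge survived selection), network-level aggregation, the probability-1
   "stable" edge set, per-fold L2-normalized SVM weights averaged per stable
   edge with FA/OM sign attribution and one-sample t-tests, and intra-left /
   intra-right / inter-hemispheric statistics.

Because no subject recordings are distributable, the package ships a
first-class synthetic study generator: block-wise stationary multivariate
Gaussian BOLD with network-structured baseline covariance and
condition-specific Fisher-z effects planted on known edges at group-dependent
scale, plus motion traces, confound channels and subject ages — so every
downstream claim can be checked against ground truth.

## Worked example

```python
import meddecode as md

parcellation = md.load_parcellation()        # bundled 90-ROI / 14-network fixture
edges = md.build_edge_table(parcellation)    # 4005 edges

config = md.SimulationConfig(seed=1)         # 20 planted edges, dz = 0.5,
study = md.generate_study(parcellation, config)  # novice scale 0.15
md.preprocess_study(study)

expert = md.assemble_dataset(study, "expert")
print(expert.class_counts())                 # {'FA': 36, 'OM': 36}

cv = md.run_cv(expert, md.CVConfig(n_repetitions=200, seed=1))
print(f"{100 * cv.mean_accuracy:.1f}%")      # 100.0%

sp = md.selection_probability(cv, edges)
stable = md.stable_edges(sp)                 # edges selected in all 200 reps
print(sp.per_edge.sum(), stable.size)        # 200.0 24
```

With the default planted-effect strength the expert decoder is essentially
perfect (100.0% mean accuracy) while the novice group, whose effects are
scaled to 0.15, stays near chance (53.1% with the same seed); the 24 stable
edges recover the 20 planted ones (Jaccard 0.83) and every recovered edge is
attributed to the condition it was planted in. The same chain is available
from the shell:

```bash
meddecode run-all --seed 1 --out runs/demo
cat runs/demo/summary.txt
```

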