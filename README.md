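# rinsev

Residue interaction networks and clinical-severity prediction for
coagulation factor IX point mutations.

## The problem

Missense mutations in the F9 gene cause hemophilia B with symptoms
ranging from mild to life-threatening. Which substitutions are dangerous
is largely a question of protein architecture: the activated protease
FIXa (light chain 47–191, heavy chain 227–461 in HGVS mature-protein
numbering; domains Gla, EGF1, EGF2 and the serine protease domain)
tolerates substitutions at exposed, peripheral residues far better than
at buried, highly connected ones. `rinsev` turns a FIXa structure (or
any single-chain PDB model) into quantitative per-residue evidence and a
trained classifier for the severity of point mutations:

1. **Residue interaction network (RIN).** Nodes are residues; an edge
   means at least one heavy-atom contact within 5 Å (sequence
   separation ≥ 2), typed as main-chain/side-chain and flagged as a
   hydrogen bond when donor–acceptor geometry allows (D–A ≤ 3.5 Å,
   antecedent–donor–acceptor angle ≥ 120°). Parallel typed edges are
   simplified to a single undirected edge.
2. **Centrality panel.** Degree, unnormalized shortest-path betweenness
   *C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st*, closeness, PageRank, HITS
   authority, and Burt's constraint
   *c(i) = Σ_{j∈N(i)} (p_ij + Σ_q p_iq p_qj)²* with *p_ij = 1/deg(i)* —
   low constraint marks brokers between residue neighborhoods. Every
   measure gets a percentile twin: the percentage of other residues with
   a strictly smaller value.
3. **Structural measures.** Solvent surface areas (Shrake–Rupley style),
   relative exposure against Gly-X-Gly reference areas, a buried call at
   < 0.25 of the structure maximum, Kyte–Doolittle hydropathy, and
   backbone φ/ψ with a Ramachandran fallback secondary-structure
   assigner.
4. **Critical residues.** HDHB/LDHB/LDLB groups from degree/betweenness
   percentiles, cross-domain link residues, and a "supercritical" Pareto
   front maximizing degree and betweenness while minimizing constraint.
5. **Amino-acid distance index.** The 544-property amino-acid collection
   (obtained at run time from R's seqinr) is standardized, PCA-reduced
   to 99% variance, and pairwise Euclidean distances between the 20
   score vectors quantify how drastic a substitution is.
6. **Severity classifier.** Features per mutation (structure +
   centrality panel + conservation + substitution distance + optional
   external predictor scores) are min-max normalized to [0, 1] and fed
   to a repeated stratified 10-fold protocol with per-fold grid-search
   tuning of six classifier families (decision tree, random forest,
   Gaussian naive Bayes, radial and polynomial SVM, XGBoost). All 2⁶−1
   classifier subsets are scored as median-probability ensembles; the
   winner's per-instance median P(severe) is the **Severity Score**,
   with an optional abstention margin around 0.5 (the "exclusion zone")
   trading coverage for accuracy, and full saturation mutagenesis
   (every position × 19 substitutions).

Every stage is runnable on fully synthetic inputs (toy structures with
ideal geometry, planted-signal mutation tables), so the pipeline is
testable end to end without any external download.

## Worked example

Generate a synthetic study (60-residue toy globule, 400 mutations with a
planted severity signal), train, and inspect:

```bash
rinsev synth --n 400 --seed 3 --out demo/
rinsev rin --pdb demo/structure.pdb --out demo/rin.graphml
rinsev train --features demo/position_features.csv \
             --mutations demo/mutations.csv \
             --aa-dist demo/aa_distance.csv \
             --reps 1 --folds 3 --inner-folds 2 --seed 3 \
             --no-sanitize --out demo/train.json
```

The RIN step prints `RIN: 60 nodes, 136 edges`. Training prints the
per-algorithm cross-validated metrics and the ensemble search result,
e.g.:

```
"mean_metrics": { "accuracy": { "DT": 0.8395, "NB": 0.8971, "RF": 0.837,
                  "SVM_poly": 0.837, "SVM_radial": 0.8971, "XGB": 0.8578 }, ... }
"best_ensemble": ["SVM_radial", "XGB"],
"best_ensemble_metrics": { "accuracy": 0.9184, "kappa": 0.8336,
                           "mcc": 0.8365, "auc": 0.9747 }
```

Read: each single algorithm classifies 84–90% of held-out synthetic
mutations correctly; the best median-probability pair raises that to
~92% with an AUC of 0.97. (`--no-sanitize` is needed because toy
positions 1–60 lie outside the real mature-protein residue ranges that
the clinical sanitation rules enforce.) `rinsev saturate` then scores
all 19 substitutions at every position with the fitted ensemble.

In Python the same objects compose as scikit-learn estimators:

```python
from rinsev import MedianEnsemble
ens = MedianEnsemble(("RF", "XGB"), seed=0).fit(X, y)
scores = ens.severity_score(X_new)            # median P(severe)
calls = ens.predict_with_abstention(X_new, margin=0.1)
```

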