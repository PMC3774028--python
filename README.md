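# netsam

Differential network-based identification of disease-associated genes from
case/control gene-expression data.

Conventional differential-expression screens rank genes one at a time and
struggle to separate drivers from passengers. `netsam` instead infers a
gene regulatory network *per condition*, subtracts the two networks, and
looks for genes whose wiring — not just whose mean expression — changes
between disease and control. The hubs of that differential network, ranked
by GeneRank and by degree, form the candidate gene signature.

## The method

Given a genes × samples log2 expression matrix split into case and control
samples, the pipeline runs five stages:

1. **DE screen.** Keep genes with fold change `2^|Δ log2 mean| > 2` and a
   Student's t-test p-value `< 0.01`.
2. **Per-condition network inference.** For each target gene *i*, fit a
   sparse regression on all other genes by componentwise L2 boosting.
   Candidate coefficient updates are scored by a posterior structure score

   ```
   score = −log(RSS_i + ε) + log(C²)
   ```

   where `RSS_i` is the residual sum of squares of gene *i* and
   `C = r(log π(d), log d)` is the Pearson correlation between log degree
   and log empirical degree-frequency of the current coefficient matrix
   (weighted degrees `d_j = Σ_m |β_mj|`). The prior term rewards coefficient
   matrices whose degree distribution is scale-free, the hallmark topology
   of real regulatory networks. The binary network places an edge *i–j*
   when both directed coefficients `β_ij` and `β_ji` are nonzero.
3. **Network subtraction.** The differential network is the symmetric
   difference of the case and control networks; case-specific edges are
   tagged *positive* (inducible), control-specific edges *negative*
   (suppressive).
4. **Hub detection.** Hubs are differential-network genes with degree ≥ 5
   and DE p-value ≤ 0.01.
5. **Prioritization.** Hubs are ranked by GeneRank
   (`r = (1−d)·e + d·W·r`, damping `d = 0.5`, `e` the normalized
   |log2 fold change|) and independently by differential degree; the
   intersection of the two top-10 lists is the candidate signature.

A synthetic benchmark generator (scale-free topology, linear-Gaussian
expression, planted differential edges and DE genes) and edge-recovery
metrics (ROC/AUC, PPV, FDR, robustness vs. SNR) are included, along with
|t| and lasso gene-ranking baselines.

## Worked example

```sh
netsam simulate --genes 200 --samples 100 --edges 500 --seed 1 --out-dir sim/
netsam de    --expr sim/expression.tsv --labels sim/labels.tsv --out sim/de.tsv
netsam infer --expr sim/expression.tsv --labels sim/labels.tsv --group case    --out sim/case_net.tsv
netsam infer --expr sim/expression.tsv --labels sim/labels.tsv --group control --out sim/control_net.tsv
netsam diff  --case sim/case_net.tsv --control sim/control_net.tsv --de sim/de.tsv \
             --out sim/diff_net.tsv --hubs sim/hubs.tsv
netsam eval  --pred sim/control_net.tsv --truth sim/truth_control_network.tsv --out sim/metrics.json
```

which prints, stage by stage:

```
wrote benchmark (200 genes, 200 samples) to sim
20/200 genes pass fold-change > 2.0, p < 0.01
case network: 938 edges over 200 genes
control network: 921 edges over 200 genes
1235 differential interactions (626 positive, 609 negative); 20 hubs
AUC = 0.8322
```

The simulated truth has ~500 edges; the binary control network alone
recovers them with edge AUC 0.83 (the continuous edge-confidence ranking
used by the benchmark scores higher, ≈ 0.89). The 20 DE genes are exactly
the genes with a planted 1.5 log2-unit shift, and the 20 hubs are genes
that are both differentially expressed and heavily rewired between the two
conditions.

The same analysis is available as a library:

```python
from netsam import SimulationConfig, generate_case_control, combine_case_control, run_netsam

case, control, truth = generate_case_control(SimulationConfig(seed=1))
expr, labels = combine_case_control(case, control)
result = run_netsam(expr, labels, skip_de_filter=True)
print(len(result.hubs), result.signature)
```

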