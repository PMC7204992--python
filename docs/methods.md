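# Methods

## The prioritization model

`rnscore` ranks candidate disease genes by combining two orthogonal lines
of evidence. The first is discriminative relevance: after per-dataset
differential expression (two-sided Welch t-test on log2 intensities,
Benjamini–Hochberg adjustment over all tested genes, DEG call at
adjusted p < 0.01 and linear fold change outside [1/1.5, 1.5]), the DEGs
are ranked by SVM recursive feature elimination and rank $r_i$ among $n$
genes is mapped to $R_s = (1+n-r_i)/n$. The second is interaction
topology on the PPI network induced by the union of the datasets' DEG
sets: degree $K$ and average shortest-path length $L$. The composite
score $RN_s = L \cdot R_s / K$ is largest for genes that the classifier
finds informative but that are *not* hubs — a deliberate inversion of
hub-centric centrality screening, motivated by the observation that drug
targets tend to have unremarkable degree but peripheral placement. The
per-dataset top-20 lists are intersected and genes present in at least
two datasets form the consensus target set.

Assumptions worth keeping in mind: expression matrices are taken as
already normalized on the log2 scale (no normalization is performed);
one row per gene (probe-to-gene collapsing is the caller's
responsibility); tumor/normal groups are treated as independent samples
(no matched-pair modelling); the interaction graph is treated as
unweighted once thresholded — confidences gate edge construction but
never act as path lengths.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `p_thresh` | 0.01 | DEG adjusted-p cutoff |
| `fc_thresh` | 1.5 | linear fold-change cutoff, symmetric (down-regulation at < 1/1.5) |
| `min_confidence` | 0.9 | STRING-style combined-score threshold (strict >) |
| `top_k` | 20 | per-dataset RNs short-list length |
| `min_datasets` | 2 | consensus support requirement |
| SVM `C` | 1.0 | soft-margin penalty, linear kernel |
| RFE step | 10 %/round | switching to 1-by-1 for the final 50 features |
| `sim_threshold` | 0.5 | Wang-similarity edge filter inside modules |
| `min_module_size` | 3 | smallest reported functional module |
| `split_quantile` | 0.5 | survival high/low expression split (ties go low) |
| `survival_p` | 0.01 | prognostic-call threshold (log-rank) |
| `alpha` | 0.05 | enrichment significance on BH-adjusted p |
| `gnm_cutoff` | 7.3 Å | GNM contact distance between Cα nodes |

The SVM-RFE hyperparameters are explicit design choices: the canonical
formulation uses a linear kernel with squared-weight elimination, and
C = 1 with per-round feature standardization keeps weight magnitudes
comparable across genes. Chunked elimination (10 % per round until 50
features remain, then one-by-one) trades negligible ranking resolution in
the tail for tractability on thousands of genes; ties in the elimination
criterion are broken lexicographically by gene id so the ranking is a
pure function of (data, gene set, config) — gene input order never
matters.

## Topology conventions

$L$, closeness and betweenness are computed within each node's connected
component: $L(v)$ averages distances over nodes reachable from $v$
(excluding $v$), closeness is its reciprocal, and betweenness sums the
pass-through fraction over unordered pairs within the component,
unnormalized. This keeps every quantity finite on disconnected graphs
(the global $n-1$ normalization is undefined there) and matches common
practice. Isolated genes are excluded at network construction, so degree
is always ≥ 1 where RNs is defined. One shared network is built from the
union of per-dataset DEG sets; $K$ and $L$ are computed once, $R_s$ per
dataset, so the per-dataset RNs tables differ only through the ranking. A
config switch (`shared_network=False`) computes per-dataset networks
instead.

## Module detection

"Topological" modules come from Girvan–Newman edge-betweenness
clustering: edges of maximal betweenness are removed one at a time (ties
broken by lexicographic endpoint pair), each resulting component
partition is scored by Newman–Girvan modularity on the original graph,
and the first partition attaining the maximal Q is returned. Functional
coherence is enforced afterwards, in that order: inside each module,
edges whose endpoint genes have Wang semantic similarity below
`sim_threshold` are removed and components are re-extracted, dropping
fragments below `min_module_size`. Pairs without annotation evidence are
*kept* — absence of annotation is not evidence of functional
dissimilarity. Wang similarity uses the standard relation weights
(is_a 0.8, part_of 0.6), S-value decay up the term DAG, and best-match
averaging over the two genes' term sets; a Jaccard fallback on raw
annotation sets is available.

## Survival and enrichment

Kaplan–Meier estimation and the unweighted log-rank statistic are
delegated to lifelines; the screening layer owns the median split (ties
to the low group; degenerate splits skip the gene), the prognostic call
(p < 0.01) and the direction call, which compares restricted-mean
survival (area under the KM curve up to the last observed event time)
between arms. Over-representation uses the hypergeometric upper tail
with BH adjustment; the universe defaults to the genes of the network
under study, and because the universe choice changes p-values it is
recorded in every output row.

## Gaussian Network Model

One node per Cα, no mass weighting. The Kirchhoff matrix has −1 for
pairs within the 7.3 Å cutoff and contact degrees on the diagonal; a full
symmetric eigendecomposition is used (dense `scipy.linalg.eigh` —
structures of a few thousand residues are well within reach), with
eigenvector signs fixed so each mode's largest-magnitude component is
positive. Zero modes (|λ| < 1e−8) equal the contact graph's connected
components and are excluded from slow-mode indexing. Hinges are called
on a slow mode's squared shape profile as strict local minima that lie
below the profile mean and are flanked on both sides by values exceeding
them by at least 10 % of the profile range — raw minima alone are
noise-sensitive — plus all residues where the raw mode component crosses
zero (the residue nearer zero of a sign-flipping pair). A flat profile
yields no hinges.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *study design* the pipeline targets:
several independent case/control datasets (default sizes 36/36, 45/45,
14/8 tumor/normal) sharing 40 planted DEGs among 1,000 genes, of which 8
are planted disease genes; a scale-free background interactome
(preferential attachment, m = 3) in which the DEG set forms a denser
perturbed-pathway core and each disease gene attaches to that core with
uniform degree 2–5 and nothing else; exponential survival for 176
patients whose hazard is multiplied by 3 for high expression of each
disease gene, with ~30 % independent censoring; a toy two-branch
ontology annotating disease genes and background DEGs coherently within
their groups; and idealized Cα chains (ideal α-helix geometry of 1.5 Å
rise, 2.3 Å radius, 100°/residue; a dumbbell of two helical lobes
bridged by a single axial linker; seeded 3.8 Å random coils).

Disease genes carry the full 3-SD expression shift while the remaining
DEGs carry 2 SD — both far past the DEG filter, but giving the
classifier a real signal gradient so that disease genes earn top ranks;
this is the regime the score is designed for (strong relevance, modest
connectivity), and planting it is what makes recovery a meaningful
end-to-end test. Every generator is a pure function of (parameters,
seed).

What the generators deliberately do **not** emulate: probe-level
microarray artifacts, batch effects, matched-pair correlation between
tumor and adjacent tissue, correlated co-expression among genes,
annotation incompleteness biases, or non-exponential survival. Passing
the recovery tests therefore shows that the pipeline's machinery is
correct and well-calibrated under its own model — not that the score
would achieve the same recovery on real cohorts, where effect sizes are
smaller and the interactome is noisier.

## Numerical choices and degenerate inputs

Zero-variance genes: equal group means give t = 0, p = 1; unequal means
with zero variance give p = 0 with a log note (the difference is
unambiguous). Constant features entering the SVM are standardized to
all-zero columns and eliminated first. Duplicate edges keep the maximum
confidence; self-loops are dropped. RNs ties in top-k selection and
elimination ties in RFE break lexicographically, and eigenvector signs
are pinned, so every pipeline output is byte-identical across reruns
with a fixed seed. Problem sizes used by the test-suite oracles (graphs
≤ 30 nodes for brute-force topology, ≤ 12 for community enumeration,
100-seed recovery studies) were chosen so the whole suite and the
acceptance script each complete in a couple of minutes on a single CPU.

## Known limitations

The "average path length" of the score is component-restricted; on very
fragmented DEG networks RNs values from different components are not
strictly comparable (a two-node component gives L = 1). SVM-RFE rankings
below the top tier are noisy by construction — only the top-k enters the
consensus, and k is the meaningful resolution. The Wang similarity
implementation expects a DAG supplied as explicit child–parent edges;
full OBO parsing and information-content similarities are out of scope.
The GNM is single-chain and environment-free; hinge calls near chain
termini are suppressed by the flanking-prominence rule.
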