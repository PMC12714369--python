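# Methods

`pdinet` analyzes directed protein–DNA interaction (PDI) networks — graphs
whose edges run from a transcription factor (TF) to a gene promoter, as
produced by enhanced yeast one-hybrid (eY1H) screens — together with
time-course expression data from nutrient deprivation/recovery designs.
This note records the models and statistics implemented, the defaults and
their rationale, the generative model behind the synthetic benchmark, and
the numerical choices a maintainer would want pinned down.

## Network model and degree statistics

A network is a set of unique (tf, promoter) edges over a single gene-id
space. A gene appearing only as a regulator has role `TF`, only as a bound
promoter `promoter`, and on both sides `TF_and_promoter` (a "dual" node;
these are what make feed-forward loops possible). Identifier matching is
exact and case-sensitive after trimming surrounding whitespace, because
deposited gene ids are canonical strings. Duplicate edge-list rows collapse
to one edge with a logged count — PDIs are counted as unique TF–promoter
pairs. Self-binding edges (a TF bound to its own promoter) are retained in
degree counts but can never enter a three-node motif.

Indegree of a gene is the number of distinct TFs binding its promoter;
outdegree the number of distinct promoters its product binds. Hub reports
use strict thresholds (`indegree > t`), matching the "bound by more than
N TFs" convention of connectivity tables.

## TF-family enrichment

For a family with `m` members among `N` TFs in a network of `T` edges the
expected outdegree is `E = m/N · T`. Observed family outdegree `O` is tested
with a two-cell goodness-of-fit statistic (family vs all other TFs):

    chi2 = (O − E)²/E + ((T − O) − (T − E))²/(T − E),   df = 1

The two-cell construction rather than a bare one-cell term is deliberate:
it is the df = 1 test for one category against the rest, and on the maize
network's marginal counts (53 of 301 TFs carrying 447 of 1625 edges) it
reproduces the published p-value's order of magnitude (1.1e-25 computed vs
1.24e-25 printed; the residual gap traces to rounded member counts).
Significance is flagged on the raw p-value at `alpha = 0.05`; a
Benjamini–Hochberg column is emitted alongside for reference but does not
drive the flag, mirroring how such family panels are usually reported.
P-values are kept in full double precision since real panels reach 1e-59.

## DEG overlay, tissue specificity, clustering

Differential-expression status is a pure function of the supplied
(log2FC, adjusted p) pair: `up` iff `padj < 0.05` and `log2FC > 1`,
`down` iff `padj < 0.05` and `log2FC < −1`, else `not_de`. Thresholds are
strict inequalities ("less than" / "greater than"), so boundary values are
`not_de`; down-regulation uses the symmetric negative threshold. DEG tables
are consumed as ground truth — no DESeq2-style statistics are recomputed.

Tissue specificity of a gene is the classical Gini inequality index over
per-tissue mean TPM: `G = ΣᵢΣⱼ|mᵢ − mⱼ| / (2 g² m̄)`; 0 for equal means,
`(g−1)/g` when one tissue carries all expression, 0 by convention when all
means are zero. It is scale-invariant.

Temporal clustering uses k-means (k = 10 by default, Euclidean distance,
10 restarts, fixed seed) on per-gene z-scored profiles after averaging
replicates within each (tissue, time). k-means is the simplest standard
choice for profile grouping and is recorded in the run manifest;
constant-profile genes cannot be z-scored and are excluded and reported.
Replicates are averaged before clustering but *not* before Gini
correlation: clusters describe mean temporal shape, whereas rank
correlations benefit from sample-level n.

## Gini correlation and edge polarity

The Gini correlation coefficient (GCC) between x and y is

    GCC(x; y) = Σᵢ (2i − n − 1) · x_{π_y(i)}  /  Σᵢ (2i − n − 1) · x_{π_x(i)}

with π_y the ascending order of y (ties broken by original sample index —
a deterministic, documented rule) and π_x the ascending order of x. It
equals cov(x, rank(y))/cov(x, rank(x)), is invariant to strictly increasing
transforms of the ranking variable and to positive affine transforms of x,
and is undefined for constant x. Both asymmetric directions are computed
per edge; the polarity-determining value is the direction with the larger
absolute value (ties favor the TF-ranks direction), and both are recorded
so either convention can be audited. All in-context samples — every phase,
time point and replicate of one tissue — enter the correlation.

Polarity: activating iff GCC > 0.5, repressing iff GCC < −0.5, strict
comparisons; otherwise undetermined with a reason code
(`below_threshold`, `missing_gene`, `constant_profile`).

## Feed-forward loops

An FFL is an ordered triple (tf1, tf2, target): tf1 binds tf2's promoter
and both bind the target, all three nodes distinct. Ordered means
(A, B, p) and (B, A, p) are distinct instances when both TF→TF edges exist
("tf1 regulates tf2" is directional); an `ordered=False` option collapses
mirror pairs for comparison with unordered counts. Enumeration is verified
against a brute-force scan over all ordered node triples.

With signs s1 = tf1→tf2, s2 = tf2→target, s3 = tf1→target, a loop is
coherent iff s1·s2 = s3. The eight sign triples map onto the canonical
Mangan–Alon taxonomy, pinned as a single constant table:

| s1 | s2 | s3 | type |   | s1 | s2 | s3 | type |
|----|----|----|------|---|----|----|----|------|
| +  | +  | +  | c1   |   | +  | −  | +  | i1   |
| −  | +  | −  | c2   |   | −  | −  | −  | i2   |
| +  | −  | −  | c3   |   | +  | +  | −  | i3   |
| −  | −  | +  | c4   |   | −  | +  | +  | i4   |

A loop is "significant" in a context only when all three edges have
determined polarity (|GCC| beyond the threshold) — the strictest reading
of filtering loops on co-expression support.

## Cross-species projection and conservation

Projection replaces both endpoints of every edge with their orthologs
(optionally restricted to syntenic pairs, the default for projection),
expanding one-to-many relations as a full Cartesian product with
deduplication; edges with an unmapped endpoint are dropped and counted.
Conservation between two experimentally tested networks counts an A edge
as *tested* when both endpoints have at least one ortholog among B's nodes
(the interaction was assayable in both screens — the only denominator
consistent with published tested-edge counts) and *conserved* when any
ortholog combination is a B edge (orthologous genes validated in both,
without requiring all paralogs). Synteny restriction defaults off for
conservation, since genome-wide ortholog calls rather than syntenic
subsets are the usual comparison substrate.

## Synthetic-data generator

The generator emulates the target study design so every stage has a
parameter-recovery test without downloads:

- **Network**: `n_tfs` TFs, `n_promoters` pure promoters, `n_dual_nodes`
  TFs also targetable. A `hub_fraction` of TFs draws outdegree from a
  Poisson with 5× the mean; the rest get a low-variance draw (floor plus a
  Bernoulli on the fractional part) keeping the overall mean at
  `mean_outdegree`. Families are assigned with a geometric skew.
- **Edge signs**: `iid` mode draws each sign independently (negative with
  probability 0.4 by default, roughly the negative-interaction share seen
  in signed PDI networks); `consistent` mode derives signs from random
  ±1 node potentials, sign(u→v) = pot(u)·pot(v).
- **Expression**: defaults mirror the study design — tissues (leaf, root),
  time points (0, 0.5, 3, 24 h deprivation; 24.5, 48 h recovery), 3
  replicates. Every gene gets a smooth random intrinsic curve (two
  sinusoids plus a linear trend, standardized). A regulated gene's latent
  profile is rebuilt iteratively (4 Jacobi passes, enough for the
  regulatory depth the generator produces) as
  `standardize(Σ_e sign_e · x_regulator/√k + 0.3 · intrinsic)`, which
  propagates regulation through TF→TF chains. Replicates add i.i.d.
  Gaussian noise (sd `noise_sigma = 0.05` in latent units, i.e. 5% of
  profile variance — small relative to biological signal, as expected for
  pooled-seedling replicates). An affine map onto a positive TPM-like
  scale follows; negatives are clipped at zero and the clipped fraction
  recorded, since GCC is affine-invariant but not clip-invariant.
- **DEG tables** draw statuses at requested rates with values constructed
  to satisfy the status thresholds (up: log2FC ~ U(1.1, 4),
  padj ~ U(0, 0.049), etc.).
- **Ortholog pairs** mint one species-B id per A gene (two at the
  one-to-many rate), copy a planted fraction of A edges into B through the
  map, and add B-only noise edges, rejecting any that would back-translate
  to an A edge so the planted conserved fraction stays exact.

Every generator is a pure function of (parameters, seed).

### Identifiability of planted loop types

Under this linear generative model, an incoherent loop's direct and
indirect contributions to the target cancel: writing the target as
`b·s2·tf2 + c·s3·tf1`, the coefficient on tf1 is `c·s3 + b·s2·s1·r` (r the
tf1–tf2 correlation), reinforcing exactly when s1·s2 = s3. For an
incoherent loop with balanced weights the three |correlations| cannot all
exceed 0.5 (a √((1−r)/2) vs r > 0.5 squeeze), so incoherent planted types
are generically unclassifiable from observational co-expression at the
±0.5 threshold — a genuine property of correlation-signed networks, not an
implementation limit. The end-to-end recovery benchmark therefore uses
`consistent` sign mode, under which every planted loop is coherent while
all four coherent types (c1–c4) still arise, and plants loops
(`n_planted_ffls`) on dual nodes and promoters without other incoming
edges so target indegree stays low enough (≤ 2–3) for each edge's
correlation to clear the threshold. Incoherent *labels* remain fully
supported and tested at the classification level; they simply cannot be
planted-and-recovered through the co-expression route.

### What the synthetic data does not emulate

No read counts, library-size effects, or dispersion; no batch effects; no
nonlinear or combinatorial (AND/OR) regulation; replicate noise is
homoscedastic Gaussian rather than count-based. Passing recovery tests
therefore demonstrates correctness of the statistics and bookkeeping under
a favorable monotone-regulation regime, not performance on real RNA-seq,
where hub targets integrate many regulators and most edges are expected to
remain undetermined at the ±0.5 threshold (as the generator itself shows
when run with realistic hub-skewed indegrees).

## Problem sizes and tolerances

Recovery benchmarks use: 100 single-regulator edges for polarity recovery
(≥95% at sigma 0.05); ~1000-edge networks for conservation-fraction
recovery (planted 0.1/0.3/0.5, recovered within ±0.05); a 100-TF network
with 25 planted loops for end-to-end type recovery (≥90%); 200 random
networks of up to 60 nodes for brute-force enumeration equivalence; GCC
oracle agreement at 1e-10 absolute. These sizes give stable results across
seeds while keeping the full suite and the acceptance script in the
seconds-to-minutes range.

## Known limitations

- Family enrichment treats each family marginally (df = 1 per family);
  no joint or hierarchical model.
- The GCC tie rule (original sample index) makes results dependent on
  sample order only in the presence of exact ties; heavy tying (many
  zero-TPM samples) deserves a sensitivity check.
- Conservation's ANY-combination rule can saturate for promiscuous
  one-to-many families; the tested/conserved edge lists are exposed so
  alternative denominators can be reconciled.
- Temporal clustering treats time points as unordered coordinates after
  z-scoring; no smoothness or autocorrelation model.
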