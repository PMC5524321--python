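# Methods

## The problem

A sequence similarity network (SSN) over N protein sequences has one node
per sequence and one undirected link per pair alignment; in a complete
all-vs-all comparison every pair carries a link, so the topology alone is
featureless (every node has degree N−1) and all structure lives in the link
attributes.  The goal is to partition the nodes into communities that
recover the evolutionary families of the sequences, using nothing but the
pair-alignment information — no E-value cutoff, no user-tuned threshold.

## Scaled link attributes

A gapped local alignment between sequences A and B is summarized by its bit
score S, alignment length L_a, identical count N_id, mismatch count N_m and
gap-position count N_g, with L_a = N_id + N_m + N_g (so N_g carries no
extra information).  Each link is rescaled by the pair's natural scales —
the shorter sequence length L_min and the smaller self-alignment score
S_min:

    l_a = L_a / L_min,   f_id = N_id / L_a,   f_m = N_m / L_a,   s_a = S / S_min

A perfect alignment maps to (1, 1, 0, 1); the Euclidean distance d of a
link's vector from that point (range 0 to ≈2) is the composite similarity
variable used throughout.  Components are not clipped: gapped alignments
legitimately push l_a above 1 and composition effects can push s_a slightly
above 1; values beyond loose sanity bounds (l_a > 1.5, s_a > 1.2) are
warned about but kept.  Because the scaling is ratio-based, multiplying all
bit scores by a constant changes nothing downstream.

In this attribute space, empirical superfamily data shows two limiting
regions joined by a continuous transition band: Region 1 (near-global
alignments, l_a ≈ 1, f_id ≳ 0.3, s_a large — homologous pairs) and
Region 2 (short weak alignments with the elevated identities typical of
random matches — unrelated pairs).

## Unsupervised detection pipeline

1. **Attribute clustering.**  The 4-D vectors are mean-centered and rotated
   onto all four principal axes (rotation only; dropping components would
   discard attribute information, and k-means behaves better on the rotated
   frame).  For each candidate cluster count k = 2..10, k-means is run with
   100 random restarts (`kmeans_replicas`) and scored by the
   Calinski–Harabasz (CH) coefficient.  The cluster count q is read at the
   elbow of the CH curve: the interior candidate with the largest knee
   strength 2·CH(k) − CH(k−1) − CH(k+1) among candidates that bend out of a
   rise (CH(k) > CH(k−1)); if no candidate qualifies (flat or decreasing
   curve — single-cluster data) the CH argmax is used, and if the elbow
   lands on 8 or 9 the candidate range is extended to 15 and re-read.  The
   CH coefficient is undefined at k = 1, so candidates start at 2.

2. **Region-1 selection.**  The q cluster-mean vectors are 2-means grouped;
   the group with the larger mean s_a is Region 1.  Because k-means knows
   nothing about the Region-1/transition separatrix, a borderline cluster
   can be dragged into the low group; any cluster whose mean s_a reaches
   the floor of 0.30 (`mean_sa_floor`) is therefore forced into Region 1.
   The floor sits where the transition band ends and the Region-1 trend
   begins in the empirical data.

3. **l_a outlier filtering.**  Links mis-assigned to Region-1 clusters tend
   to betray themselves by their scaled length; the l_a values of the
   selected links are screened with the medcouple-adjusted boxplot fences
   (below) and links outside the fences are excluded.

4. **Partition-density maximization.**  Surviving links are sorted by
   ascending d and added one distinct d value at a time (ties enter as a
   block) to an incremental union-find structure that tracks per-component
   link count m_c and node count n_c.  After each step the partition
   density

       D = (2/N) Σ_c m_c (m_c − (n_c − 1)) / ((n_c − 1)(n_c − 2)),

   restricted to components of more than two nodes and with N the number
   of links currently included, is recorded; a linear chain scores 0 and a
   complete clique 1.  The partition at maximal D is retained, ties broken
   toward the larger link count (keeping more similarity information at no
   density cost; refinement acts downstream).  Untouched nodes remain
   singleton communities.

5. **Refinement.**  Two error modes are corrected by merging, with the
   link distance d as the similarity measure Z (small = similar).  With
   Z_max(i,i) the largest retained intra-community distance and Z_min(i,j)
   the smallest inter-community distance over the *complete* link table:

   * *Type 1* — if Z_min(i,j) ≤ max[Z_max(i,i), Z_max(j,j)] the pair
     violates the consensus definition of a community and is merged,
     adding every link between them up to that bound.  Merges run
     most-similar-pair first, rebuilding the matrices after each, until no
     pair violates the ordering.
   * *Type 2* — a genuinely split family shows up as a *left outlier* of
     the off-diagonal Z_min distribution (its halves are far closer than
     any true community pair).  Starting from Z_m = max_i Z_max(i,i), each
     sweep scales Z_m by s_f > 1, computes the lower adjusted fence Z_L of
     the Z_min values (with fewer than 4 community pairs the fence is
     undefined and the criterion degrades to min{Z_m, Z_0}), and merges
     every pair with Z_min ≤ min{Z_L, Z_m, Z_0}; Z_m is then re-evaluated
     from the merged structure.  Sweeps stop when nothing merged or
     Z_m ≥ Z_0.

   The (s_f, Z_0) plane is scanned on the grid s_f = 1.01..1.10 (step
   0.01) × Z_0 = 1.100..1.110 (step 0.001).  A grid point whose final Z_m
   fails to exceed 1 never reached the inter-community distance scale
   (inter-community d_min sits above 1 in both the empirical and the
   synthetic networks) and is discarded; among admissible points the
   maximal-density partition wins.  When no point is admissible — the
   typical outcome on a clean network with nothing to merge — the
   Type-1-refined partition is returned with a warning.

## Robust outlier fences

The medcouple mc is the median of the kernel
h(x_i, x_j) = ((x_j − q2) − (q2 − x_i))/(x_j − x_i) over all pairs
x_i ≤ q2 ≤ x_j; for k observations tied at the median the kernel over the
k×k tied pairs is the balanced sign multiset enumerated by
sign(i + j − 1 − k).  mc ∈ [−1, 1]; 0 for symmetric samples; an all-tied
sample is defined to have mc = 0.  The implementation is the O(n²)
definition, vectorized; tests pin it to an independent brute-force oracle
and to statsmodels on tie-free samples.

The adjusted fences are centered on the median with 4× quartile arms
asymmetrized by mc:

    [q2 − 4 e^(−1.93 mc)(q2 − q1),  q2 + 4 e^(2.18 mc)(q3 − q2)]

For a normal sample 4 × (q2 − q1) ≈ 2.70 σ per arm, so ≈0.7% of points
fall outside — the same calibration as the classic Tukey fences (also
provided, in their standard [q1 − 1.5 IQR, q3 + 1.5 IQR] form), but stable
under skew.  Quartiles use linear interpolation of the empirical CDF
("type 7", the default of mainstream numeric stacks); the quartile
convention is otherwise unspecified and this choice is pinned for
reproducibility.

## The GridS benchmark

With ground-truth families available, a cutoff vector
(l_a,c, f_id,c, f_m,c, s_a,c) retains links with l_a ≥ l_a,c, f_id ≥ f_id,c,
f_m ≤ f_m,c, s_a ≥ s_a,c; connected components plus singletons are scored by
the F-measure Q.  The search scans the four 3-D subspaces (free dimension
at its no-op cutoff) on a 0.01 grid, shortlists cutoffs with
Q ≥ 0.9·Q_max,3, and 1-D-scans each shortlisted cutoff's free dimension;
reported are Q_max,4, all Q-maximal vectors and their per-component ranges.
Two exact optimizations keep this tractable: along each axis only cutoffs
that change the retained set (grouped by insertion rank within the current
survivor subset) are evaluated, and Q is memoized on the retained-set
bitmask.  Neither changes any reported value.  A coarse desk mode
(step = 0.05) trades resolution for speed.  GridS needs the ground truth,
so it is a best-performance reference, not a predictor.

## Evaluation

For ground-truth family i (size n_i), predicted community j (size m_j) and
overlap O_ij, the per-pair precision/recall convention is P_ij = O_ij/n_i,
R_ij = O_ij/m_j (the source's naming; their harmonic mean is symmetric, so
the familiar swap is immaterial) and

    F = (1/N) Σ_i n_i · max_j 2 O_ij / (n_i + m_j).

F = 1 exactly for identical set partitions; all-singleton predictions
against one family of n nodes give the floor 2/(n + 1).

## Synthetic study networks

The generator emits complete planted-family SSNs in three mutually
consistent forms: the exact scaled-attribute table, an invertible BLAST
tabular file (12-column dialect, self-alignment rows included), and the
family labels.  Default study conditions:

* three families of 20 sequences (tests and the acceptance script vary
  3–10 families of 10–17, sized so the whole pipeline stays within desk
  runtimes);
* intra-family links: l_a ~ U(0.90, 1.00), s_a ~ U(0.40, 0.95), f_id on
  the empirical trend 0.30 + 0.68·s_a with σ = 0.015 noise, f_m a
  U(0.78, 0.92) fraction of the non-identical remainder — distances d up
  to ≈0.86;
* one *anchor* link per family (per half of a split family) planted at
  d ~ U(0.875, 0.885): the most diverged homolog pair.  It pins the
  intra-family distance scale Z_m that the Type-2 sweep scales by
  s_f ≤ 1.10, so the refinement grid's reach (and its final-Z_m > 1
  admissibility bound) does not drift with the seed;
* inter-family links: l_a ~ U(0.05, 0.30), s_a ~ U(0.02, 0.14), f_id ~
  U(0.18, 0.38) (short random matches carry elevated identities), giving
  d ≈ 1.35–1.7;
* 5% of intra-family links drawn from a transition band
  (s_a ~ U(0.16, 0.26), shrinking l_a) between the regions;
* sequence lengths U(150, 400) residues with self scores at ≈2 bits per
  residue, so inverting the score scaling is well conditioned.

A `SplitInjection` severs one family: cross-half pairs become inter-family
links except for 4 suppressed bridges planted at d ~ U(0.92, 0.93) — above
every intra-family distance (so density maximization and Type-1 refinement
leave the halves apart; the bridges' small l_a also makes them l_a
outliers, excluded from Region 1) yet a clear left outlier of the
inter-community d_min distribution, which is exactly the Type-2 signature.

The tabular inversion rounds counts to integers (L_a = round(l_a·L_min),
N_id = round(f_id·L_a), N_m = round(f_m·L_a), percent identity printed to
2 decimals, bit scores to 1), so re-parsing recovers the planted vectors
within 0.5/L_min for l_a, 0.5/L_a per identity fraction and 0.05/S_min for
s_a; infeasible roundings (N_id + N_m > L_a) are resampled internally.
Distributions are uniform / truncated-normal mixtures, not fits to real
superfamilies: what the synthetic networks share with real data is the
*structure* (two regions, a transition band, separable planted families),
and that is all that passing tests certify.  Real alignment data adds
heavy-tailed score distributions, fragment sequences, multi-domain
architectures and family-size imbalance that the generator does not
emulate; performance there is checked only by the benchmark-reproduction
test, which requires the external gold-standard alignment tables.

## Numerical choices and degenerate inputs

* N_id is reconstructed from the stored percent identity with
  round-half-to-even; N_g is positions-in-gaps (L_a − N_id − N_m), not the
  gap-open count; records with N_id + N_m > L_a are rejected.
* Multiple HSPs per ordered pair and reciprocal query/subject rows
  collapse to the single highest-bit-score record before symmetrization;
  absent pairs are absent links, never zero-score links.
* Sequence length defaults to the self-alignment row's L_a, overridable by
  a two-column lengths table; a sequence with neither is an error naming
  the ids.
* D of an empty link set is 0; two-node communities contribute 0 (their
  Eq denominator vanishes); tie-breaks everywhere are deterministic
  (lexicographic pair order, smallest-k elbow, smallest-Z_min merge
  first, first grid point at equal density).
* Degenerate fence samples (q1 == q3) collapse both fences to the median
  and warn; left outliers of fewer than 4 values are undefined and the
  refinement criterion drops the fence term.
* All randomness (k-means restarts) flows from a single `random_state`;
  fits are bit-reproducible for a fixed value.

## Known limitations

* Type-3 errors (two true families merged into one community) are not
  corrected; the refinement can only merge, never split, so community
  counts are non-increasing across refinement.
* The Z_0 grid (1.100–1.110) encodes the empirical observation that
  inter-community d_min concentrates near 1.5 with intra-community
  distances below ≈1; networks violating that geometry need the exposed
  grid bounds adjusted.
* The scaled-attribute design assumes local alignments against the
  shorter sequence's scales; profile or global alignment scores would
  need a different scaling.
* GridS at step 0.01 on dense networks is exhaustive by design; use the
  coarse mode (0.05) for desk-scale exploration.
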