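# Methods

## The model

`abnet` analyses the co-occurrence structure of IgG antibody reactivities
measured by one-dimensional immunoblot. Each serum is scored against a panel
of protein antigen bands (nodes), giving a binary participants × bands matrix
per cohort group. The working hypothesis is that the IgG-producing cell
clones behind the bands form a regulatory network, and that statistically
dependent presence/absence of two bands across a cohort's sera is evidence of
a connection (link) between the corresponding clones.

For each group the pipeline computes all pairwise Pearson correlations among
band columns. On 0/1 data the Pearson coefficient is exactly the phi
coefficient of the 2×2 contingency table; this closed form serves as the
independent oracle in the test suite while the implementation uses the
standard product-moment computation. Significance uses the t test of a
correlation,

    t = r·√(n−2) / √(1−r²),   df = n − 2,

two-tailed at level α (equivalently a one-tailed p compared with α/2 — the
equivalence is unit-tested). The correlation matrix R is binarized to the
adjacency B with b_ij = 1 exactly when pair (i, j) is significant, of either
sign; b_ii = 0. Links are counted as the ones in B, i.e. each undirected edge
twice. At the study's n = 50 and α = 0.05 the significance boundary is
|r| ≈ 0.2787.

No multiple-testing correction is applied by default. Each of the
121·120/2 = 7260 pairs is tested at the raw α, which is what the published
link counts imply; Bonferroni and Benjamini–Hochberg corrections are
available behind a flag for users who want error control rather than
reproduction of this convention.

### Network attributes

* **Density** is unique edges / n(n−1): half the standard undirected density
  (a complete graph scores 0.5). This is the convention that reproduces the
  published per-group densities (0.06 / 0.07 / 0.06), consistent with an
  undirected edge count taken against ordered node pairs; the standard
  undirected density is reported alongside as `density_undirected`.
* **Mean degree** is n_links / n_nodes, which reproduces the published H
  value exactly (1642/121 = 13.57). The published BBP and BC means (15.93,
  13.28) deviate slightly from this identity (1932/121 = 15.97,
  1610/121 = 13.31); the deviation cannot be resolved without the raw data
  and is deliberately not matched. The same applies to the published degree
  SD/variance rows.
* **Diameter** is the longest shortest path over *connected* node pairs;
  disconnected pairs are excluded and the component count is reported, since
  the published diameters are finite without any connectivity claim.
* The **degree histogram** uses the published five classes (2–6, 7–12,
  13–18, 19–24, 25+); nodes with degree < 2 are reported as a remainder so
  the classes need not sum to 100%. The hub cutoff defaults to 19 links and
  is a parameter, because "more than 19 links" and the 19–24 class boundary
  are not mutually consistent readings.

### Connection intensity

Per node: N is the degree in B, M the **signed** mean of the Pearson
coefficients over that node's N significant pairs (M = 0 when N = 0), and
I = N·M; nodes are ranked by descending I with ties broken by ascending band
id. The signed mean is the only reading consistent with the published table,
which contains negative M and near-zero M at large N. Per group: N_k is the
total ones in B, M_k the signed mean of r over all significant entries (each
unordered pair enters twice, which leaves the mean unchanged), I_k = M_k·N_k.
The averaging denominator is the count of significant correlations being
averaged — the source formula leaves its denominator symbol undefined, and
this is the reading adopted.

The published per-node I values were evidently computed from unrounded M:
validation therefore asserts the rounding-bounded identity
|N·round(M, 2) − I| ≤ 0.005·N + 0.005 across all 363 printed rows, rather
than exact products of rounded factors.

### Disconnection ledgers

Comparing group a's adjacency against group b's entrywise: (1,0) → code 2
(lost), (0,1) → code 1 (gained), otherwise 0. Comparisons are ordered —
"H vs BC" means links present in H's network and absent in BC's, the reading
consistent with the published prose. The ledger stores, per node, the sorted
partner lists for losses and gains, ordered by descending loss count with
ties by ascending id; zero-loss nodes are retained with empty lists.

The published tables list each lost unordered pair exactly once, under its
smaller-numbered endpoint (verified systematically during fixture
construction). `DisconnectionLedger.to_frame(style="upper")` reproduces that
layout; the default symmetric view lists each lost pair under both
endpoints. The published headline counts (e.g. node 24 losing 27 links from
H to BC) are counts in the upper-triangle presentation.

### Group comparison

Per-node degree vectors and per-node I vectors are compared across groups
with the Kruskal–Wallis rank test (tie-corrected H, chi-square reference
with g−1 df). Degrees are heavily tied small integers, so the statistic is
implemented from its rank formula and its tie behaviour pinned by tests
(cross-checked against an independent implementation and, for two small
groups, an exact permutation enumeration). When all pooled values are
identical the result is defined as H = 0, p = 1. The published p-values
(0.207 for link counts, 0.001 for intensities) require the raw band
matrices and are not reproduction targets.

## Synthetic cohorts

The raw matrices were never deposited, so the generator emulates the study
shape: 3 groups × 50 participants × 121 bands. Each cohort is sampled from a
Gaussian-copula threshold model: bands are partitioned into blocks (default:
consecutive blocks of ~11 bands, standing in for sets of co-regulated
clones); the latent normal vector has correlation `rho_within` (default
0.35) inside a block and `rho_between` (default 0.05) across blocks; band j
is present when its latent coordinate exceeds the normal quantile matching
its marginal prevalence. Per-band prevalences default to independent draws
from U(0.10, 0.60) — the study reports no prevalence distribution, and this
range keeps bands informative without saturation. All randomness is
seed-derived and bit-reproducible.

The copula was chosen over direct correlated-Bernoulli constructions because
it provides one dependence dial valid at any prevalence. Thresholding
attenuates dependence, so the realized phi between two bands is smaller than
the latent rho; accordingly, tests assert calibrations and orderings, never
rho recovery. The three-group scenario scales `rho_within` by (1.0, 0.7,
0.4) across groups ordered BBP > H > BC from a base of 0.5, which reproduces
the published ordering of link counts and mean intensities in ≥ 90% of
seeded replicates.

What the generator does **not** emulate: real per-band prevalence spectra,
serum-level effects (some sera reacting broadly), cross-reactivity structure
tied to molecular weight, or any disease mechanism. Passing tests
demonstrate that the inference chain is correctly calibrated and recovers
constructed orderings — not that the biological conclusions would replicate
on new cohorts.

## Numerical choices and degenerate inputs

* Zero-variance bands (present in all or no sera) are flagged undefined and
  get no links, rather than raising; their count is logged.
* |r| = 1 maps to an infinite t and p = 0 (declared significant directly),
  avoiding division by zero.
* `np.corrcoef` output is symmetrized ((R + Rᵀ)/2) and clipped to [−1, 1] to
  enforce the exact symmetry contract.
* Argmax ties (top node, ranking) break toward the smallest band id.
* An edgeless graph has an undefined diameter (a dedicated error; the
  summary reports it as null).
* Band matrices with zero participants round-trip as header-only files;
  missing values are rejected, never imputed.

## Validation scale

Property suites run at deliberately small scale chosen to keep the full
suite fast while leaving comfortable statistical margins: type-I calibration
on ~2000 band pairs (3 Monte-Carlo SE ≈ 0.015), ordering recovery over 100
seeded scenario replicates, prevalence recovery at n = 10⁴ within 2%,
oracle cross-checks on random graphs up to 50 nodes.

## Known limitations

* The raw cohort matrices are unavailable, so the published group networks
  themselves cannot be rebuilt; validation rests on in-table identities plus
  synthetic calibration.
* Three rows of the published disconnection table state counts that differ
  from their printed list lengths, and two partner ids are out-of-range
  typos; fixtures mirror the print verbatim and the tests assert the
  discrepancy set explicitly.
* The t reference distribution is used for significance exactly as the
  source formula states; on binary data the test is approximate (concordance
  with the exact permutation test is ~96% at n ≤ 12, asserted ≥ 95%).
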