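# Methods

## Assay model and normalization

The simulated assay is a TR-FRET kinase binding readout on 384-well plates
(16 rows × 24 columns): the ratio-channel signal is high for uninhibited
enzyme and drops toward the fully inhibited level as a compound displaces the
tracer. Columns 1–2 hold the DMSO negative controls, columns 23–24 the
staurosporine positive controls (32 wells each), and columns 3–22 hold
library compounds at a single concentration. The published layout states the
control columns but not which pair carries which control; the assignment here
(low columns negative) is a convention and is configurable.

A sample well's raw value is

    k_raw = μ_neg + (μ_pos − μ_neg) · inhibition/100 + ε,   ε ~ N(0, σ_well)

Per plate, control means and sample standard deviations (ddof = 1 — the
estimator is not dictated by the assay description; n−1 is the standard
choice at n = 32 control wells) give

    Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n|,
    k_norm = 100 · (k_raw − μ_neg)/(μ_pos − μ_neg).

Z′ ≤ 1 always, with equality only for noiseless controls; the QC bound is
Z′ ≥ 0.5. k_norm is deliberately not clipped: real screens show mass below 0%
and above 100%, and threshold sweeps must be able to probe that tail.
Normalization is affine and invertible, and Z′ is invariant under common
affine transforms of all fluorescence values — both properties are tested.

## Synthetic campaign: what it emulates, and what not

Defaults are the campaign's stated conditions where stated, and a realistic
choice where not:

| parameter | default | rationale |
|---|---|---|
| n_compounds | 46,743 | diversity-library scale |
| active_fraction | 0.0076 | ≈ the realized 0.76% primary hit rate |
| plate layout | 384 wells, 32+32 controls, samples in cols 3–22 | stated layout |
| μ_neg, μ_pos | 1000, 200 a.u. | arbitrary units; signal decreases with inhibition |
| σ_well | 25 a.u. | unpublished; chosen so expected Z′ ≈ 0.81, comfortably ≥ 0.5 |
| active inhibition | N(85, 20) truncated to [0, 120] | "strong inhibition" actives; the >100% tail exercises sweeps above 100 |
| dose series | 30, 7.5, 1.875, 0.469, 0.117, 0.029, 0.007, 0.002 µM × 3 replicates | stated 8-point ~4-fold series |
| dose-response noise σ | 2% | the level used in the parameter-recovery criterion |
| score enrichment | hydra_like 0.8, docking_like 0.4, random 0.0 | spans strong/moderate/null methods |

σ_well = 0 is accepted as the documented noiseless limit (it makes the
exactness properties — raw value equals μ_pos at 100% inhibition, Z′ = 1 —
directly testable).

Structures are assembled from 12 fixed drug-like core templates × 45
substituents² × 5 decorations (~121k combinations), canonicalized and
deduplicated, so fingerprint similarity and MCS behave as on a real library;
fully random molecular graphs would make MCS degenerate. Undefined
stereocenter counts span 0–6. Method scores are

    score = e · clip(inhibition, 0, 120)/120 + (1 − e) · U(0, 1)

with enrichment e per method: e = 0 gives exchangeable ranks, e = 1 sorts by
true activity.

One global seed drives independent substreams per stage (library = 1, screen
= 2, dose-response = 3, scores = 4, true curve parameters = 5), so each stage
is bitwise reproducible in isolation.

The generator does **not** emulate: spatial plate artifacts (edge effects,
dispenser striping), compound interference or autofluorescence, docking poses
or any 3D structure, inter-day assay drift, or correlations between chemistry
and activity (actives are sampled independently of structure). A green test
therefore establishes correctness of the *analysis* under the stated noise
model, not robustness to real-plate pathologies.

## Dose-response fitting

The 4PL model f(x) = A + (D − A)/(1 + (x/C)^B) is fitted by nonlinear least
squares (`scipy.optimize.curve_fit`) over all replicate points jointly.
Initialization is analytic — D from the lowest-dose responses, A from the
highest, C at the concentration whose mean response is nearest the half-range
crossing, B = 1 — plus three perturbed restarts (internal fixed RNG: the
restarts are part of the algorithm, not of the experiment's randomness), best
residual kept. B is bounded to [−20, 20] and C to positive values.

Capping: the reported IC50 = C is clipped to the tested concentration range
on both ends — the symmetric reading of capping "within the range of measured
concentrations"; nothing can be reported more potent than the lowest or
weaker than the highest tested dose (pIC50 ≥ 4.52 for the default series).
A fit is flagged *erroneous* when it does not converge, when C lands above
the top dose, or when the Hill slope is negative while the responses clearly
rise with concentration (positive Spearman trend with A < D); erroneous fits
report IC50 = top dose. A flat response vector is reported as an erroneous,
high-capped fit rather than an exception, so batch fitting a real plate of
mostly inactive compounds does not abort.

Activity classes: micromolar pIC50 < 6, high nanomolar 6 ≤ pIC50 < 7,
nanomolar ≥ 7; "sub-micromolar" is the union of the upper two.

## Clustering and diversification

Morgan fingerprints use radius 2 (the ECFP4-equivalent) at 2048 bits; both
are configurable — the bit length is not specified by the source campaign.
Salts are stripped (largest organic fragment) before fingerprinting.
Tanimoto similarity of two all-zero fingerprints is defined as 1.0 (they are
indistinguishable); this convention only matters for featureless degenerate
inputs. The similarity graph connects pairs with TS ≥ 0.4 — the edge
threshold behind the published cluster counts is unstated; 0.4 matches the
lowest novelty-table cut and common practice — and Louvain community
detection (networkx, seeded, single-threaded) yields the clusters. Cluster
ids are ordered by each cluster's lexicographically smallest member, making
the labelling deterministic. Reproducing the published "200 clusters / 160
singletons / 283 diversified" exactly is therefore a calibration experiment,
not a test.

Scaffolds: the RDKit MCS of all cluster members (element + bond-order
matching, rings matching rings, bounded by a configurable timeout with
best-so-far returned); clusters whose MCS falls below 3 heavy atoms get an
empty scaffold but are retained. Singletons use the Bemis–Murcko framework
of their lone member (the MCS of one molecule is the molecule, which is not a
scaffold in any useful sense). Diversification takes the top
min(k, |cluster|) members per cluster by k_norm/MW, ties broken by compound
id.

## Ranking evaluation

Top-k at fraction f is ⌈f·N⌉ (the published "top 1% (470)" of 46,743
suggests rounding up from 467.4; a fixed integer k is also supported). Score
ties are broken by compound id so every curve is deterministic. The default
fraction grid is {0.5, 1, 2, 5, 10, 20, 50, 100}%. Hit discovery curves are
verified against brute-force prefix enumeration for small N; the mean curve
over unenriched score draws converges to the diagonal (checked at 1000
replicates within ±0.02). A scaffold is "discovered" at fraction f if any
member of its cluster ranks in the top ⌈f·N⌉.

## Score aggregation

The pose-ensemble "Boltzmann-like average" is implemented as the
softmax-weighted mean Σ s_i·w_i, w_i ∝ exp(s_i/τ), τ = 1 on the score scale
by default: the exact functional form used upstream is not public, so only
its boundary behavior is treated as normative — bounded by [min, max],
arithmetic mean as τ → ∞, max as τ → 0⁺, shift-invariant (computed with
max-subtraction). The docking ensemble score takes the most favorable (most
negative) pose energy and negates it; the literal alternative reading
("largest" = least favorable) would anti-rank actives and contradicts the
observed docking performance. All methods are normalized to higher-is-better
before ranking.

Stereoisomers: all 2^n enumerated for n ≤ 4 undefined centers (≤ 16), a
seed-deterministic sample of exactly 16 distinct assignments for n > 4, with
a per-compound substream (CRC32 of the compound id mixed into the seed) so
the sample does not depend on enumeration order. Per-compound scores are the
arithmetic mean over stereoisomers, matching the racemic character of the
assay. Isomers are identifiers with assignment bitstrings, not 3D structures
— pose generation is out of scope.

## Pharmacophore subset score

Matching a sub-hypothesis is an injective, type-respecting assignment of
conformer features to hypothesis points admitting one rigid superposition
(Kabsch, via SVD with reflection guard) that places every assigned feature
within its point's tolerance radius (default 1.0 Å). The correspondence
search prunes assignments by pairwise-distance compatibility before aligning.
The continuous combiner

    score = (K + m_K/C(n, K) − 1)/n,  K = deepest matched subset size,
                                      m_K = matched subsets of that size

is this package's own definition — the upstream combination rule is not
published; the normative intent preserved is that compounds rank first by
match depth, refined by breadth, with 1 attained only on a full match and 0
below min_size (default 3). The matcher is verified against exhaustive
assignment enumeration on small instances.

## Replicate confirmation

A primary hit is confirmed if present in every replicate hit set; precision =
confirmed/|primary|, recall = confirmed/|confirmed ∪ new replicate hits|.
Note the published counts (88 confirmed of 94) give 93.6% under this
definition, while the source text prints 93.4%; the denominator behind the
printed figure is not reconstructible, so the set-based definition above is
the implemented contract.

## Known limitations

- Activity is statistically independent of structure in the generator, so
  cluster-level activity labels on synthetic data carry no chemical signal.
- The MCS timeout makes very large clusters' scaffolds best-effort;
  determinism of the scaffold string is guaranteed only when the search
  completes within the timeout.
- Louvain is seeded but its partition on weakly modular graphs can change
  across networkx versions; the tested guarantees are partition validity and
  recovery of clearly separated communities.
- The 4PL erroneous-fit rule is a heuristic; the criterion used for the seven
  manually-rejected fits in the source campaign is not fully specified, so
  the rule here is documented and configurable rather than exact.
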