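# Methods

## Network model

A transfer network is a directed valued graph: nodes are hospital EDs,
an arc (s → r) exists when at least one patient was transferred from s to
r during the period, and its weight is the transfer count. Self-transfers
are invalid and rejected at ingestion. Two node universes are supported:
the default keeps only hospitals incident to at least one arc (what a
registry of *observed* flows defines), and `include_isolates=True` keeps
the full hospital registry, which changes the denominator of density and
centralization — useful as a sensitivity check, and the right choice for
the population regression, where a hospital with zero transfer-in partners
is a data point, not a missing one.

All centrality and cohesion statistics treat the graph as directed and
**unweighted**: weights define which ties exist (and drive skeleton
thresholds) but do not enter geodesics. This matches the classical
standardizations used for these statistics — raw betweenness over
(N−1)(N−2), closeness times (N−1), centralization over (N−1)² — whose
ranges are only meaningful for binary ties.

### Conventions and degenerate inputs

* **Betweenness** is Brandes' algorithm with fractional credit over tied
  geodesics; standardization requires N ≥ 3.
* **Closeness with unreachable targets**: sparse directed flow networks
  are rarely strongly connected, so plain farness is ill-defined. Default
  (`penalize`): a node reaching no other node scores 0; otherwise each
  unreachable target contributes distance N, one more than any possible
  geodesic. Alternative (`reachable_only`): the Wasserman–Faust composite
  (k/(N−1))·(k/farness) over the k reached nodes. Both stay in [0, 1];
  both ship because published summaries rarely say which was used.
  Closeness direction defaults to outgoing distances.
* **Local clustering** uses the union of in- and out-neighbors with
  directed arc counting (k(k−1) possible); nodes with fewer than 2
  neighbors score 0 and are *included* in the network average.
* **In-degree centralization** uses the (N−1)² denominator because it is
  the unique choice making the inward star score exactly 1, the anchor
  that defines the statistic's scale; (N−1)(N−2) fails that anchor.
* **Reciprocity** is dyadic — mutual/(mutual+asymmetric) — not arc-wise;
  it is reported as missing (NaN) when no connected dyads exist.
* **Dyad census** identities (mutual+asym+null = N(N−1)/2 and
  2·mutual+asym = arcs) are enforced by construction and re-checked
  against exhaustive pair enumeration in tests.
* Time-of-day bands assign the boundary hour to the later band's start;
  weekend and season come from the local departure date (arrivals can
  cross midnight or year boundaries, departures cannot be ambiguous).
* Percentages in descriptive tables use each variable's non-missing
  denominator, reported to one decimal.

## Secondary analyses

* **In-degree ∼ population**: ordinary least squares of transfer-in
  partner count on served population in millions (scipy closed form);
  the slope has units of partners per million residents. Requires ≥ 3
  hospitals with known population and non-degenerate population variance.
* **Distributor outcome comparison**: sender hospitals are ranked by net
  connectivity ascending; transfers sent by the bottom 5% (ties at the
  boundary included; the quantile is over hospitals, not transfers) are
  compared with all other transfers on the proportion directly discharged
  at the receiving ED, using a two-sided pooled two-proportion z-test
  without continuity correction (statsmodels). Identical groups give
  p = 1 exactly.

## Synthetic data generator

Real national transfer registries are access-restricted, so the generator
produces datasets with *planted, recorded* structure. What it emulates:

* **Registry**: `n_regions` (default 14) referral regions on an abstract
  10°×10° planar grid (not real geography), 11–17 hospitals each, one
  designated base (hub) ED per region placed near the region centroid.
  Hubs draw served populations from the upper half of `population_range`
  (default 0.1–4.5 M persons), spokes from the lower quarter — hubs serve
  whole regions.
* **In-degree structure**: each hospital's planned transfer-in partner
  count is round(`target_slope` × population-in-millions + N(0,
  `in_degree_noise_sd`)), clipped to [0, N−1]. The population regression
  slope (default 5.5 partners per million) is therefore recovered by
  construction, and because hub populations dominate, in-degree is
  heavy-tailed with hubs in the long tail (planted hub in-degrees land in
  the ~15–25 partner range at defaults).
* **Regionalization**: a receiver's in-partners are sampled with weight
  1 + `region_affinity` for same-region senders, plus
  `hub_attachment_strength` (default 8) when the receiver is a hub —
  yielding the multiple hub-and-spoke, regionalized pattern.
* **Reciprocity**: planted *exactly*. After arc construction the dyad
  census is adjusted to the target — asymmetric dyads gain a weak reverse
  arc (weight 1 + Poisson(2)), or chance mutuals are trimmed — until
  mutual/(mutual+asymmetric) equals round(target·D)/D. A target of 0
  yields exactly 0; a positive target with zero connected dyads is an
  error.
* **Weights**: discretized log-normal (default μ=3.0, σ=1.5 on the log
  scale, median ≈ 20 transfers/3 years), chosen because it naturally
  spans both the < 36 ("incidental") and > 365 ("strong," more than one
  per three days) thresholds.
* **Time**: each arc's weight is split across study years by a
  multinomial with shares ∝ `yearly_growth`^year (default 1.08), so
  volumes grow; tie counts are non-decreasing rather than strictly
  increasing, because established high-weight ties are present every year
  and only marginal weight-1 arcs move in and out.
* **Records**: attributes are sampled from calibrated categorical tables
  (packaged in `_generator_defaults.yaml`); ages are Gaussian (55.7 ±
  23.8, clipped to [0, 111]). Transfers sent by planted distributor
  hospitals (bottom 5% net connectivity among senders) have their direct-
  discharge probability raised from 5.4% by an additive 0.8% boost.

The `GroundTruthLedger` records planned pair counts, per-year volumes,
hub and distributor identities, the planted slope, the realized planted
reciprocity, and the two discharge rates; identical seed and config give
byte-identical output.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: the full tie *volume* of a national system (the
generated network has ~1,000 arcs at defaults, the scale of a robust-tie
skeleton rather than an every-last-transfer census, so thresholding it at
36 thins it much further than a real overall network); co-base hospitals
and multi-hub regions (configurable but defaulted to one hub per region);
real geography, travel times, or hospital capacity constraints;
seasonality and weekday structure beyond uniform dates; and any
correlation between patient attributes and routing. The degree medians of
a real skeleton (≈ 5 out-partners / 2 in-partners) are consequently not a
generator target.

## Problem sizes and tolerances

The shipped tests and the acceptance script run at: ~200-hospital /
~50,000-record synthetic datasets for pipeline and recovery checks (slope
within 2 standard errors of 5.5 at a 50-hospital configuration;
reciprocity within 0.05 of 0.21 at ~200 nodes; hub dominance in ≥ 90% of
regions; outcome-difference sign); 210 random digraphs of 4–12 nodes for
exhaustive-oracle equivalence of betweenness, closeness, clustering and
dyad census (agreement to 1e−9); and exact assertions for the count-only
formulas (density, reciprocity, centralization anchors) evaluated on
networks constructed at published national margins.

## Known limitations

* Path metrics ignore weights entirely; a weighted-geodesic variant
  (e.g., inverse-weight distances) is out of scope.
* The discharge comparison is a crude two-proportion test with no
  case-mix adjustment; it detects the planted difference's direction, not
  a causal effect.
* The cleaning layer validates fields independently; cross-field
  plausibility (e.g., a ward admission with a same-minute arrival) is not
  checked.
* GraphML round-trips preserve structure and node attributes but not
  arbitrary metadata.
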