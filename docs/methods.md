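# Methods

## The delimitation model

The pipeline tests whether an ultrametric single-locus gene tree is
better explained as one coalescing population or as several. A
threshold age T classifies every branching event: events older than T
belong to a generalized pure-birth (Yule) diversification process,
events younger than T to the within-species coalescent of whichever
lineage crosses T (an *entity*). Between successive branching events
(ordered in time, each waiting interval ending in the next event) the
total branching rate is

    rho_i = b1 * n_s,i^p1 + sum_k b2 * (n_k,i (n_k,i - 1))^p2

where `n_s,i` counts lineages on the diversification process — below the
threshold this is the constant number of entities, since species
lineages persist to the present — and `n_k,i` counts gene lineages in
coalescent group k. Waiting times are exponential, so each interval of
duration `x_i` contributes `ln rho_i - rho_i x_i` to the log-likelihood.
The scaling exponents generalize the linear Yule rate and the quadratic
coalescent rate (absorbing, e.g., population growth); one `(b2, p2)`
pair is shared across groups. The null model is a single coalescent
process spanning the whole tree (parameters `b, p`).

Model dimensions: the alternative has five free parameters
(`b1, p1, b2, p2, T`), the null two, so the likelihood-ratio statistic
`LR = 2 (logL_alt - logL_null)` is referred to chi-square with **3
degrees of freedom**. This convention reproduces the published
arithmetic for the beetle data set this pipeline re-implements
(LR = 12.4592 giving p = 0.00596 at df 3; df 2 would give 0.00197), and
`reproduce_paper_numbers()` documents exactly that check. The threshold
parameter is not regular, so the chi-square reference is approximate;
the null calibration test measures the realized size empirically (it
lands near the nominal 5% on 20-tip coalescent trees).

### Fitting

* Candidate thresholds are midpoints between consecutive distinct node
  heights, tips included — so the candidates range from the
  all-singleton pure-Yule configuration to a two-entity split — plus an
  above-root candidate. The above-root configuration reduces exactly to
  the null model (its Yule component idles at one lineage and its
  supremum is at `b1 -> 0`), so it is scored with the null's maximized
  log-likelihood; this makes `logL_alt >= logL_null` an identity rather
  than a numerical accident.
* Per threshold, the likelihood is maximized over
  `(ln b1, p1, ln b2, p2)` by Nelder-Mead from 5 deterministic
  moment-matched starts (`p` pairs (1,1), (0.5,1), (1,0.5), (1.5,1.5),
  (0.2,0.2); rate scales from the event-count/exposure ratio). A
  spot-check against differential evolution on contentious fits found
  the multistart within 0.04 log-units of the global optimum.
  Pure-Yule candidate series use an exact profile: for fixed `p` the ML
  rate scale is `m / sum(n_i^p x_i)`, leaving a 1-D bounded search.
* Bounds: exponents in [0, 3], rate scales in (1e-10, 1e6). Ties in
  log-likelihood (within 1e-9) break toward the solution with fewer
  entities. The confidence set holds every candidate within 2
  log-likelihood units of the maximum.
* Tied node heights (polytomies) are separated by a deterministic
  jitter of 1e-9 x root height before interval construction so no
  waiting interval has zero length.

### Degenerate inputs: identical haplotypes

Zero-length branches are fundamentally incompatible with the
branching-process likelihood: an interval of length ~0 rewards an
arbitrarily large rate, so its ln-rate term grows without bound and the
ML threshold degenerates to whatever placement isolates the tied events.
Barcoding data sets routinely contain identical sequences, and a plain
UPGMA tree puts their coalescences at height 0. The pipeline therefore
builds its UPGMA stand-in with a **minimum height separation** between
internal nodes, defaulting to `1/(8L)` for an alignment of L sites — a
quarter of the height that a single substitution contributes under a
strict clock (a distance quantum of `1/L` maps to a height quantum of
`1/(2L)`). This mimics the strictly positive, spread-out node times a
probabilistic clock tree assigns identical haplotypes, at the resolution
actually supported by the data. Users supplying their own clock tree
(`--tree`) bypass this entirely.

## Distances

K2P with pairwise deletion; a pair's P and Q are computed over sites
where both sequences carry an unambiguous A/C/G/T. All IUPAC ambiguity
codes, N, `-` and `?` count uniformly as missing — the conservative
convention when the original base-call treatment is unknown. A sequence
is retained in the matrix only if it shares at least `min_overlap`
(default 300) comparable sites with every other retained sequence; the
default sits between the 147-site fragment the emulated study excluded
and the 665-site fragment it kept, and is configurable. A saturated pair
(log of a non-positive argument) yields a missing entry rather than an
exception; range summaries skip missing values.

## Parsimony

Unordered states, missing data as wildcards. Tree length by Fitch
counting over condensed site patterns. The heuristic search does random
stepwise addition followed by nearest-neighbor-interchange to a local
optimum, over `reps` independent seeded replicates (NNI is sufficient at
the ~30-tip scale with deep structure this targets; no
branch-swapping beyond it is attempted). Character optimization is
exact: per site, up/down Sankoff tables give, for every branch, the
minimum tree cost subject to "no change on this branch"; a change is
unambiguous iff that constrained cost exceeds the site minimum —
equivalent to intersecting all most-parsimonious reconstructions. The
root's two edges are treated as the single unrooted branch they
represent. A site is homoplasious iff its minimum change count exceeds
distinct-observed-states minus one. Branches carrying no unambiguous
change can be hard-collapsed before counting distinct topologies,
matching common practice for reporting most-parsimonious trees; exact
topology counts are sensitive to that convention and are not treated as
a primary output.

## Synthetic data

The generator mirrors the inference model: a Yule species tree
(exponential waiting times at rate lambda*k, one extra waiting time
after the last split so terminal branches are positive), a neutral
coalescent within each species branch (k lineages merge at rate
k(k-1)/2 per `coalescent_size` time units, unmerged lineages passed up
at species-tree nodes), and K2P sequence evolution using the closed-form
transition probabilities (transitions kappa-fold each transversion,
total rate = expected substitutions/site/time). One integer seed drives
everything; fixed seed means bit-identical output.

The study-like fixture uses a fixed species tree rather than a random
Yule draw, because it emulates a specific published structure: splits at
12 (sanctus-anatolicus), 18 (ovatus), 21 (outgroup) time units with
`coalescent_size` 0.5, substitution rate 0.003/site/time, kappa 4
(typical insect mtDNA), 825 sites, species sizes 19/7/4 plus one
outgroup, and one sanctus tip truncated to its first 147 sites. Expected
K2P distances are then ~0.072 / ~0.108 / ~0.126 between species and
mostly below 0.01 within — reproducing the published table's barcode gap
— and species splits are >20x deeper than within-species coalescence,
so reciprocal monophyly holds in essentially every replicate.

What the generator does **not** emulate: rate heterogeneity across sites
(the study's Bayesian analysis used gamma + invariant sites),
saturation, selection, migration or hybridization, and tree-estimation
error beyond UPGMA's (the real analysis integrated over clock-tree
uncertainty via MCMC). Passing tests therefore demonstrate correctness
of the pipeline's statistics under its own generative assumptions, not
robustness to those real-data complications.

## Problem sizes used in the checks

Recovery and calibration checks run at the scale a desktop reproduces
comfortably: 50 fixture replicates (~30 tips each) for cluster-recovery
and barcode-gap rates, 200 single-population 20-tip coalescent trees for
the size of the LRT, 100 mixed trees for the nesting invariant, and 200
random 4-6-taxon matrices against the brute-force parsimony oracle. The
acceptance script reports the same quantities at 25 fixture replicates
and 100 null trees.

## Known limitations

* Single-threshold GMYC only; no multiple thresholds, no Bayesian
  variant, no integration over tree uncertainty.
* The LRT's chi-square reference is approximate (threshold
  non-regularity); the measured size is close to nominal but mild
  oversplitting of the ML solution occurs in roughly one replicate in
  ten under the fixture conditions — usually an extra singleton or one
  split species, with the true 3-cluster solution inside the 2-unit
  confidence set.
* UPGMA is a stand-in for a proper clock tree. With between-species
  divergence several-fold above within-species divergence the cluster
  structure is insensitive to this, but for shallower systems a real
  clock tree should be supplied.
* The study's published fitted GMYC rate parameters are not available,
  so only likelihoods, cluster counts and the LR arithmetic are
  comparable; fitted `b`/`p` values are reported but uncalibrated
  against external software.
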