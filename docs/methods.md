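# Methods

## Model

A mutagenized diploid population of `N = pools_per_dim ** n_dims`
individuals is arrayed on an `n_dims`-dimensional grid (default 3 × 16,
i.e. 4096 plants) and pooled along each axis, giving
`n_dims * pools_per_dim` pools of `P = pools_per_dim ** (n_dims - 1)`
individuals each; every plant is in exactly one pool per dimension.

A mutation private to one plant contributes an expected mutant-allele
fraction of

    f = c / (2 P),   c = 1 (heterozygous), 2 (homozygous)

to each of its pools (0.00195 and 0.0039 at P = 256).  The observed alt
count at depth `d` is modelled Binomial(d, f + e/3), where `e` is the
per-base sequencing-error rate and errors are split evenly over the
three non-reference bases.  The minimum depth at which `k` mutant reads
are expected is `ceil(k / f)` — 512·k for a het at P = 256 — computed in
exact integer arithmetic.

## Simulator

`simulate_population` plants a Poisson(density × panel bp) number of
SNVs per individual (positions uniform without replacement within an
individual; alt base uniform over the three alternatives, or forced to
the G→A / C→T transition at G/C sites under the optional EMS bias).
Defaults:

* `density_per_bp`: 1/150,000 for the `paper_scale` profile — the dense
  end of the range typical of diploid TILLING populations, chosen so a
  single simulated population carries ~1000 planted sites for
  calibration statistics; the `toy` profile uses 1e-4 so a 64-plant
  miniature still carries ~25 mutations.
* `het_fraction`: 2/3.  Mendelian segregation of an M1 heterozygote
  predicts 2:1 het:hom among M2 carriers.
* `error_rate`: 0.001/base, a typical short-read substitution rate.

`simulate_pool_counts` draws one depth per (pool, amplicon) cell and
holds it constant across positions: fragmented amplicons sequence
evenly along their length, and the analysis operates on per-amplicon
means, so terminal coverage inflation is deliberately not modelled.
Depth is `round(S_pool · LogNormal(log_mean, log_sd))` with `S_pool`
itself log-normal (`per_pool_log_sd`), reproducing the heavy right skew
of real pool-level representation.  The `paper_scale` parameters
(`log_mean = ln 6365`, `log_sd = 0.5`, `per_pool_log_sd = 0.7`) put the
median cell near 6365× with pool means spanning roughly 1500–30000×;
extreme single-pool overloading caused by library-quantification error
is a real phenomenon the model does not force.

What the generator does **not** emulate: read-level artefacts (mapping,
base quality, strand bias), PCR jackpot amplification, the 2–3×
over-dispersion of observed versus expected control allele frequencies
seen in real pools, and shared natural variants.  Passing tests
therefore demonstrate correctness of the arithmetic and the
deconvolution logic under binomial sampling, not robustness to every
failure mode of a wet-lab assay.

## Caller

Per (pool, amplicon, position, alt base), a candidate requires
`alt_count >= min_alt_reads` (default 2) and a one-sided exact binomial
tail `P(X >= alt_count | depth, e/3) < alpha` (default 1e-4).  The
defaults are set so one stray error read at realistic depth is never
called.  This is a deliberately simple stand-in occupying the position
of purpose-built pooled callers; external per-pool VCFs can be supplied
instead.

The common-variant filter keeps `AF < af_max` strictly (a site at
exactly the cutoff is removed).  The reference cutoff is 0.05 at
P = 256, which sits 12.8× above the homozygous expectation; because a
fixed 0.05 would sit *below* the homozygous expectation for pools
smaller than 20, the pipeline scales the cutoff as `0.05 · 256 / P`,
preserving that 12.8× headroom at every pool size.  `filter_common`
itself defaults to the plain 0.05.

## Deconvolution

Variant keys default to (amplicon, position, ref, alt); matching on
position alone is available via `match_alleles=False` (stricter
per-allele matching reduces false merges of coincident mutations).

* **uniqueness** — per dimension, keep keys observed in exactly one
  pool; multi-pool keys are dropped from that dimension and reported.
* **intersection** — keys unique in all dimensions become full calls;
  the coordinate tuple resolves the carrier through the row-major
  sample/coordinate bijection (any bijection works; the simplest
  deterministic one is fixed and documented in `pooling.py`).
* **rescue** — a key unique in exactly `n_dims − 1` dimensions is
  searched for in a *separate, more permissively called* candidate set
  for the missing dimension (pipeline default: same `min_alt_reads`,
  relaxed `alpha` = 1e-2, still AF-filtered).  Exactly one hit
  completes a "rescued" call; zero or several hits leave the key
  unresolved and reported.  The permissive set must be a superset of
  the strict one: a key unique in D−1 dimensions occurs 0 or ≥2 times
  in the missing dimension *within the strict set by construction*, so
  rescue against the strict set itself can never succeed — it exists to
  recover signals that barely missed the strict calling threshold in
  one pool.
* **zygosity** — the mean AF over supporting pools is compared with
  f_het and f_hom on a log scale and assigned the nearer expectation
  (an exact midpoint tie goes to heterozygous, the more common state);
  means above 4·f_hom or below f_het/4 are labelled ambiguous.  The
  ×4 band and log-midpoint are this package's own classifier; the
  underlying expectations are the design arithmetic above.

All ambiguity (collisions, multi-pool keys, failed rescues) is surfaced
in the report, never resolved heuristically.  The output is independent
of candidate input order.

## Coverage QC

Operating on mean coverage per (pool, amplicon) cell:

* **failure**: a cell strictly below `threshold_frac` (default 5%) of
  its amplicon's mean across pools, that mean *including* the candidate
  cell (the plain per-amplicon mean, which makes the statistic
  well-defined without excluding anything); the failure rate is the
  percentage of all cells.
* **sufficiency**: percentage of cells with depth ≥ k · ceil(1/f_het)
  (≥, so a cell exactly at k·512 counts).  A homozygote needs half the
  depth, so its sufficiency at 2k equals the heterozygous value at k.
* **correlations**: Pearson r between per-amplicon mean coverage,
  length and GC%; zero variance in either variable raises rather than
  returning NaN.

GC% counts N toward length but not toward the numerator; the panel
summary's standard deviation is the population form
`sqrt(Σx²/N − (Σx/N)²)`, matching the convention of summarising a
complete panel.

## Numerical and interface choices

* All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`, so pipeline stages are
  independently reproducible and child seeds stay below 2³¹.
* Binomial tails use `scipy.stats.binom.sf` (exact, not normal
  approximation); at `error_rate = 0` any non-zero alt count has tail
  probability 0 and passes any alpha, which is the intended noise-free
  behaviour.
* Counts conserve by construction: the reference count is depth minus
  the drawn alt counts (clipped at 0, relevant only for pathological
  fraction sums).
* Degenerate inputs raise early with the offending name in the message
  (duplicate FASTA IDs, unknown pool IDs, amplicon-name mismatches,
  non-contiguous position runs in a counts TSV).
* Test problem sizes: 20 toy replicates for the soundness and
  completeness properties and one 48 × 32 paper-shaped replicate for
  distribution-level checks — large enough that the binomial bounds in
  the assertions are meaningful, small enough to run comfortably on a
  laptop.

## Known limitations

* The binomial caller is not a Bayesian pooled caller; at paper-scale
  depths (~6000×) heterozygous signals of ~12 expected reads sit close
  to its detection limit, which is faithful to why rescue exists.
* The simulator draws depth per cell, not per base; per-base QC
  (coverage profiles along an amplicon) is out of scope.
* Pool-ploidy genotype models of external callers are consumed, not
  reimplemented.
* Real-experiment deconvolution to named individuals additionally
  requires the laboratory's sample→grid layout, which is external
  metadata; with pool-level inputs only, results are per-pool.
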