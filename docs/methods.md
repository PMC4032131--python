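# Methods

## The question the package addresses

Eurasian genomes match the Neandertal genome more often than African
genomes do. Two demographic histories can produce that asymmetry:
hybridization between Neandertals and the modern humans who left
Africa, or population structure in the common ancestor that kept the
ancestors of Eurasians geographically closer to the Neandertal range.
Two statistics are used to weigh them:

* **Patterson's D.** Over biallelic sites where the Neandertal differs
  from the chimpanzee and exactly one of a chosen African/European
  chromosome pair matches the Neandertal,
  `D = (n_ABBA - n_BABA) / (n_ABBA + n_BABA)`, positive when Europeans
  match the Neandertal more often.
* **The doubly conditioned frequency spectrum (dcfs).** Restrict to
  sites where (i) chimp and Neandertal differ and (ii) the African
  chromosome carries the chimp allele, then tabulate the count
  `i = 1..nE` of the Neandertal allele in a panel of `nE` European
  chromosomes. The shape of this spectrum — in particular the share of
  rare classes (`i` of 1 or 2) — is the discriminating signal.

The package simulates both statistics under three model families and
provides the calibration loop that sweeps parameters, keeps the
combinations whose predicted D matches an observed value
(default 0.0457 ± 0.0020), and ranks them by the fit (R²) of their
predicted dcfs to an observed spectrum.

## Demographic models

All sizes are diploid individuals; parameter times are years before
present and are divided by the generation time (default 25 y) for
simulation. The chimpanzee outgroup diverges 6 My ago; the Neandertal
lineage is sampled 50 ky ago. All three families are compiled to
msprime demographies and simulated with the exact continuous-time
structured coalescent (within-deme pairwise coalescence at `1/(2N)`
per generation; per-lineage migration along active edges).

**Spatial stepping-stone model** (8 free parameters: `k_demes, N_anc,
m0, N_mod, m, t_modern, t_exit, founder_size`). Forward in time: a
linear chain of `k_demes` demes of size `N_anc` with nearest-neighbour
migration `m0`. At the Neandertal split (320 kya, fixed) the chain is
cut between a Neandertal segment (default one deme) and the African
segment, with no parameter change. At `t_modern` the African demes
become modern: size `N_mod`, migration `m`. At `t_exit` modern humans
colonise a Eurasian extension of the chain serially from the African
deme nearest the old Neandertal range (default 4 demes over 5 ky, each
founded by `founder_size` individuals that hold for one colonisation
interval before growing to `N_mod`); Eurasian demes never exchange
migrants with Neandertal demes, and migration stays `m` throughout the
modern range, so the Africa/Eurasia separation is the range expansion
itself. The African chromosome samples the deme farthest from the
boundary; Europeans sample the last-colonised deme. Defaults (chosen
once; the supplementary parameter fits behind the original analysis
are not published in the available text): `k_demes=10, N_anc=1000,
N_mod=5000, m=0.005, m0=0.0015, t_modern=100 ky, t_exit=60 ky,
founder_size=2000`. The chain is linear (end demes have one
neighbour), and migration is symmetric per adjacency.

**Two-population ancient structure** (coarse model). The ancestor is
structured into two populations exchanging migrants at `m_high` from
`t_structure` (550 ky); the Neandertal branches from the subpopulation
whose descendants later colonise Eurasia; at `t_ooa` the exchange
decreases (but does not stop) to `m_low`. Defaults: `N_afr=10000,
N_eur=5000, N_nea=2500, m_high=1e-4, m_low=1e-5`.

**Clean split ± admixture pulse** (9 free parameters: four sizes, the
two split times, the out-of-Africa bottleneck size, and the pulse time
and fraction `f`). Panmictic ancestor; Neandertal splits at 320 kya;
Africans and Europeans separate at `t_ooa` with a Eurasian founder
bottleneck (`N_bottleneck` for 2.5 ky); a fraction `f` of Eurasian
ancestry is drawn from Neandertal at `t_admix` (50 kya). With `f = 0`
this is the null model used as the panmictic baseline.

## Statistics: two routes per quantity

Every statistic is computed by a **site path** (counting qualifying
sites in a genotype table after polarising each site against the chimp
chromosome — what one would run on sequenced genomes) and a **branch
path** (accumulating, over simulated genealogies, the length of every
branch a qualifying mutation could land on — the infinite-sites
expectation, free of the mutation rate). A branch whose descendant set
contains the chimp chromosome contributes through the complement of
that set, exactly mirroring site polarisation. The two routes agree on
the same genealogies within Monte Carlo error; this equivalence is a
standing test.

The null spectrum is not flat. For the panmictic clean-split null the
exchangeable-coalescent calculation gives `p_i ∝ (nE + 1 - i)` for one
conditioning African chromosome (expected branch length subtending
`j` of `n` leaves scales as `1/j`, times the count of qualifying leaf
configurations); simulations reproduce this closed form to within
Monte Carlo error, and the test suite asserts it.

## Low-variance D for calibration

The D filter targets the model's *predicted* (expected) D, but plain
branch sums over full genealogies carry heavy-tailed noise from the
deep ancestral phase (standard error ≈ 0.007 at 50 000 loci — several
times the 0.0020 acceptance window). The package removes that noise
exactly rather than by brute force, using a structural property of
both structure models: the Neandertal segment exchanges no migrants
before the split, so no ABBA/BABA weight can accrue earlier, and the
expected weights are a function of the lineage configuration at the
split time only.

* `chain_pair_coalescence_time` / `chain_abba_weight` solve sparse
  linear systems of the structured coalescent on the homogeneous
  ancestral chain (states = lineage positions; `k³` unknowns) for the
  expected time during which an ancestor of exactly
  {Neandertal, European} (or {Neandertal, African}) is extant.
* `expected_patterson_d_spatial` simulates only the recent epochs with
  msprime, reads the configuration at the split from a census event,
  and averages the exact conditional weights (Rao-Blackwellised
  hybrid).
* `exact_patterson_d_spatial` and `exact_patterson_d_two_pop` go one
  step further and propagate the African/European pair distribution
  through the piecewise-homogeneous recent epochs with matrix
  exponentials, yielding a deterministic D with no sampling at all.
  Two truncations are made, both with exponentially small error at
  these time scales: the chimp lineage cannot enter ingroup
  genealogies before the outgroup merge, and the ancestral phase is
  integrated to an infinite horizon.

The three routes (plain Monte Carlo, hybrid, deterministic) are
cross-validated against each other in the test suite at 3 standard
errors. Sweeps default to Monte Carlo branch sums
(`d_method="branch"`, with the European panel marginalised by
exchangeability: a branch subtending `i` of `nE` Europeans carries
ABBA weight `i/nE`); `d_method="exact"` selects the deterministic
solver for the spatial and two-population families, and is what the
calibration-feasibility analysis uses, since a Monte Carlo estimate
cannot honestly resolve a ±0.0020 window at desk-scale replication.

A corollary used in testing: on a conservative symmetric chain the
*deme-averaged* within-deme pair coalescence time equals the panmictic
`2kN` exactly (individual demes deviate by a few percent on a finite
chain — end demes low, interior demes high); tests therefore average
over the sampling deme.

## Calibration procedure

`run_sweep` evaluates a parameter grid (one independent derived seed
per grid point, so results are independent of evaluation order),
`filter_by_d` keeps combinations with `|D - target| <= tol`
(default 0.0457 ± 0.0020, the tolerance read as absolute),
`rank_by_r2` orders them by the coefficient of determination between
predicted and observed dcfs over frequency classes
(`R² = 1 - SS_res/SS_tot`, reported as a percentage; the squared
Pearson correlation is available behind a flag), and `compare_models`
reports the best fit and rare-allele proportions per family.
`find_d_match` root-finds the value of one parameter at which the
deterministic D equals the target — the package's constructive answer
to whether the subsetting criterion is satisfiable.

## Synthetic data

`generate_pseudo_observed` emulates an empirical dcfs: the generating
model's branch-expectation spectrum plus multinomial sampling noise at
a stated number of doubly conditioned loci (loci are unlinked, so
multinomial noise is the right model). `build_toy_panel` materialises
explicit per-site allele descriptors as a genotype table. What the
synthetic path deliberately does not emulate: sequencing error,
ancient-DNA damage, missing data patterns, linkage between sites, and
transversion-only site filtering. Passing tests therefore demonstrate
the statistical machinery and the demographic mechanism, not
robustness to the error processes of real archaic-genome data. No
empirical spectrum ships with the package (published values would have
to be read off a figure); users supply their own observed-dcfs TSV.

## Numerical and design choices

* Diploid convention throughout: coalescence at `1/(2N)` per pair per
  generation; `nE = 10` chromosomes = five diploid Europeans.
* One African chromosome conditions the dcfs by default
  (`all_africans=True` requires the whole African sample ancestral);
  class `nE` (fixed in Europeans) is retained.
* Sites with missing or more than two alleles are dropped and counted,
  never imputed.
* Event ties at equal times break deterministically (merges before
  parameter changes before expansions, then by deme id).
* Replicate genealogies come from a single derived-seed msprime stream
  per call (the first replicate equals the single-genealogy entry
  point); parallelism is applied across sweep grid points, each with
  its own derived seed.
* Problem sizes in the test suite (e.g. 50 000 loci for site/branch
  equivalence, 100 000 genealogies per condition for the model
  contrast, 3×3 grids for recovery) were chosen so Monte Carlo
  standard errors sit well inside the asserted tolerances.

## Known limitations

* The spatial family is a linear chain; no two-dimensional lattices,
  landscape friction, or the full worldwide calibration of the
  original spatial framework.
* No recombination within loci, no selection, no linked-site (tree
  sequence) simulation; D has no block-jackknife standard errors
  because loci are unlinked by construction.
* The deterministic D solvers assume the sampled Neandertal deme count
  and geometry used by the builders; models edited by hand should fall
  back to the Monte Carlo routes.
* Supplementary parameter tables of the original analysis are not
  available; all default grids and parameter values are this package's
  own documented choices and are fully user-overridable.
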