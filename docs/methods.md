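# Methods

## Evolutionary model

Sequence evolution is modelled as a reversible continuous-time Markov chain
on the 20 amino acids.  A model is assembled from a published symmetric
exchangeability matrix S (WAG, LG or Dayhoff; bundled as plain-text files in
PAML `.dat` layout and checksum-verified at load) and equilibrium
frequencies π — either the published defaults or "+F" frequencies counted
from the alignment's non-gap residues with a pseudocount of 1 per amino acid
(avoiding unreachable states; the choice matters little for realistic
alignments).  The rate matrix is Q = S·diag(π) with the diagonal set so rows
sum to zero, normalized so −Σᵢ πᵢQᵢᵢ = 1: one unit of branch length is one
expected substitution per site.  Transition probabilities P(t) = exp(Qt) are
computed once per branch via the symmetric eigendecomposition
diag(√π)·Q·diag(1/√π); tiny negative entries from round-off are clipped and
rows renormalized (perturbation ≤ 1e-15).

Among-site rate variation uses the discrete-gamma approximation: K
equiprobable categories (default K = 4), each carrying the conditional mean
rate of its quantile bin of Gamma(α, rate α), renormalized to mean exactly 1.
Mean-of-bin (not median) rates are used.  The shape α can be fixed or
estimated by bounded 1-D maximum likelihood over [0.05, 100] (on a log
scale); when the likelihood at the upper bound is within half a log-unit of
the optimum the data are flagged as effectively rate-homogeneous, because
the surface is flat there and the point estimate is arbitrary.

## Likelihood

The alignment likelihood on a rooted tree with branch lengths is computed by
Felsenstein pruning.  Gaps and ambiguity codes (X/B/Z/J) are missing data:
their leaf partials are all-ones, so such sites contribute through
marginalization (the convention of standard ML phylogenetics packages).
Per-node per-site scaling factors are carried in log space, so alignments of
hundreds of sites cannot underflow.  Identical columns are collapsed into
weighted site patterns; the inner reductions use fixed-order `einsum`
contractions, which makes compressed and uncompressed evaluation bit-identical
(this is asserted by a test).

Branch lengths, when re-optimized rather than taken from the input tree, use
coordinate-wise bounded Brent search per branch, clamped to [1e-8, 20], at
least two full sweeps, stopping when a sweep improves the log-likelihood by
less than 1e-6; the recorded history is non-decreasing.  The default is to
*keep* the input branch lengths, since the intended workflow takes an
ML tree (with its lengths) as input; both modes are exposed.

Model comparison ranks candidate models by AIC = 2k − 2 logL, with k
counting only parameters actually estimated in-pipeline (α if estimated,
branch lengths if re-optimized); ties break by model name.

## Marginal ancestral reconstruction

For each internal node and site the per-amino-acid posterior given all tip
data is computed marginally (empirical Bayes), mixing over rate categories:

  P(aₛ = x | data) ∝ Σₖ wₖ · Fₖ(v, x, s) · Gₖ(v, x, s)

where F are the inside (pruning) partials, G the outside partials (the root
carries π), and wₖ = 1/K.  The default implementation is one inside–outside
sweep, O(nodes) total for all ancestors; a re-rooting route (pull the node
to the root, where the posterior is π·F normalized) is kept as an
independent path, and both must agree to 1e-9 — for a reversible model they
are mathematically identical.  Joint reconstruction is out of scope.

The most-probable sequence takes the per-site argmax, with exact ties broken
by alphabetical amino-acid order.  Mean confidence is the arithmetic mean of
per-site maximum posteriors over unmasked sites only.

**Indels.**  Presence/absence is not modelled in the CTMC.  A site is called
ancestrally absent at a node iff fewer than half of the node's descendant
leaves have a residue there (a fraction of exactly 0.5 counts as present);
the threshold is configurable.  This descendant-majority rule is an explicit,
automated approximation to the progeny-based manual indel curation practised
when ancestors are prepared for resurrection; it cannot reproduce curation
decisions that used information beyond the descendant rows.

## Monte-Carlo sampling of alternative ancestors

At each unmasked site, residues with posterior ≥ θ·p_max (relative to the
site's maximum) are eligible under threshold θ, and one is drawn with
probability proportional to its posterior among eligibles.  Sites are
independent.  The requested total n is split evenly across the configured
thresholds (default 0.2 and 0.5, n = 5000, matching the published sampling
design; the first threshold absorbs the remainder), and the pooled draws
form the set.  The most-probable sequence is always a member: if it was not
drawn it replaces the first draw, keeping the set size exactly n.  (An
alternative reading — append it as an n+1-th member — conflicts with a
fixed set size; the replacement convention keeps both properties and changes
frequency statistics by at most 1/n.)  Duplicates are retained so residue
frequencies across the sample are unbiased estimates of the renormalized
posteriors.  One seeded generator per node; uniforms are consumed
samples-outermost, sites in column order, so identical inputs give
byte-identical FASTA output.  With θ = 1 only the argmax is eligible and
every sample equals the most-probable sequence.

## Catalytic typing

The two substrate-oxidation sites are detected at named positions resolved
through a reference sequence: the Mn²⁺-binding triad (default labels 37, 41,
183 requiring Glu, Glu, Asp) and the catalytic tryptophan (default 172,
requiring Trp).  Positions are 1-based on the ungapped reference; alignment
columns are 0-based internally.  Matching is exact — Asp at 37 is acidic but
is *not* the triad residue, consistent with the observation that an
Asp37-containing ancestor lost Mn²⁺ oxidation while the Glu37 form retained
it.  The triad state is: `typical` (3 exact matches), `atypical` (2 matches,
non-basic third residue — weak Mn²⁺ oxidation), `blocked` (2 matches with
Arg or Lys at the mismatch — the basic side chain occludes the cation site;
His is deliberately excluded from the basic set), else `none`.  The type is
a total function of (triad state, tryptophan): typical → VP/MnP (with/without
Trp), atypical → VP-atypical/MnP-atypical, blocked or none → LiP/GP.  A gap
at a named position counts as a mismatch and is flagged.

One numbering caveat: source descriptions of the triad vary between
Glu37/Glu40/Asp183 and Glu37/Glu41/Asp183 in different places; the default
configuration uses 37/41/183 and the positions are configuration, not code,
so either convention can be declared.

## Synthetic data

The simulator evolves a root sequence (drawn from π or given) down a tree
under the chosen model, with one gamma category drawn per site.  Catalytic
motif states are imposed as overrides — forced residues at a node, inherited
by descendants unless re-overridden — treating motif gains/losses as given
history rather than a modelled selective process.  Yule topologies with
fixed or uniform-range branch lengths; all outputs are a pure function of
the seed.  What the generator does *not* emulate: indel evolution (the only
gap source is an optional fixed C-terminal truncation of a clade, present to
exercise the gap-mask logic), site-specific selective constraint beyond
gamma rates, compositional drift, and alignment error.  Passing tests on
these data therefore validate the inference machinery under its own model
assumptions; they do not certify robustness to real-data violations of
those assumptions.

The packaged peroxidase-like fixture is a 10-leaf, 300-site family with the
designed MnP → VP → LiP history (triad at the root, Trp gained at one
internal node, triad degraded distal to the gain) and known types at every
internal node.

Kinetic and stability curves are generated from known parameters: default
designs use 8 concentrations log-spaced from K_m/4 to 8·K_m (12 spanning
both phases for biphasic curves), Gaussian noise with sd 2% of k_cat and 3
replicates for noisy recovery studies, 5 °C steps over 25–85 °C for
inactivation curves, and 1 °C steps over 20–95 °C for CD melting profiles —
the designs a practitioner would use at the bench.

## Kinetics and stability

Units are fixed: K_m in µM, k_cat in s⁻¹, efficiency k_cat/K_m in
s⁻¹·mM⁻¹; the 1000× µM→mM factor is applied in exactly one function.
Efficiencies are reported at 2–3 significant figures matching the precision
of the published constants they derive from.  Michaelis–Menten fits use
nonlinear least squares initialized from the largest observed rate and the
concentration nearest its half; 95% confidence limits come from the
asymptotic covariance (t-quantiles).  Biphasic curves are fitted as the sum
of two independent Michaelis–Menten terms — the standard reading of
two-site ("sigmoid") saturation behaviour for enzymes with a high-efficiency
tryptophan site and a low-efficiency heme-channel site — from several
starts, sites reported with K_m ascending; AIC selects between the single-
and two-site forms.  Fits with < 5-fold K_m separation or a site carrying
< 1% of total turnover are flagged ill-conditioned.  T50 is the linearly
interpolated first downward 50% crossing of a residual-activity curve; Tm is
the midpoint of a 4-parameter two-state sigmoid fitted to the melting
profile (flat profiles are an error, and the midpoint must fall inside the
measured range).  Tm is invariant to uniform rescaling of the CD axis.

**Known data inconsistency.**  Among the published kinetic rows used as
worked-example inputs, the extant-LiP/DMP high-efficiency row (K_m 4.0 µM,
k_cat 6.9 s⁻¹, printed efficiency 600 s⁻¹·mM⁻¹) is internally inconsistent:
1000·6.9/4.0 = 1725.  One of the three printed numbers is presumably a
typographical error; this row is excluded from the reproduced-arithmetic
set.  A few other rows differ from recomputation by about one unit in the
last printed digit (e.g. 617 printed vs 618 recomputed), consistent with
efficiencies having been computed from unrounded fit parameters before
rounding; rows reported by `scripts/acceptance.py` under `efficiency_*`
recompute from the printed K_m/k_cat pairs.

## Problem sizes

The test suite and acceptance script use: 20 random 4-leaf instances of 10
sites for the enumeration-oracle checks (the brute-force oracle enumerates
the full 20³ joint over internal states); 16-leaf, 300-site families with 20
paired replicates for ancestor-recovery comparisons (branch lengths 0.02 vs
0.5, plus a 1e-6 zero-divergence limit); 2000 sites for gamma-shape
recovery; n = 5000 for sampling statistics; 100 seeds for noisy kinetic
recovery.  These sizes give stable statistics while keeping a full run in
seconds on one CPU.

## Limitations

- Marginal (not joint) reconstruction; no indel evolution model; no
  covarion/profile-mixture models; no topology search or bootstrap — the
  tree is an input.
- The gap mask is independent of the residue posteriors; ancestors near
  clade boundaries with heterogeneous gap structure inherit the majority
  call, not a probabilistic one.
- Catalytic typing reads primary sequence only; it does not verify surface
  exposure of the tryptophan or model C-terminal tail classes.
- Two-site kinetic fits assume independent sites; cooperative (Hill-type)
  behaviour is out of scope.
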