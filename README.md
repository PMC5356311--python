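# peroxevo

Ancestral sequence reconstruction and functional typing of fungal class-II
peroxidases, with steady-state kinetics and stability analysis of
resurrected enzymes.

## The problem

White-rot fungi degrade lignin with three families of secreted heme
peroxidases that differ only in their substrate-oxidation sites: manganese
peroxidases (**MnP**) oxidize Mn²⁺ at an acidic triad (Glu37/Glu41/Asp183 in
ancestral numbering), lignin peroxidases (**LiP**) oxidize nonphenolic lignin
through an exposed catalytic tryptophan (Trp172), versatile peroxidases
(**VP**) carry both sites, and generic peroxidases (**GP**) carry neither.
Reconstructing the ancestors of this family — and resurrecting them in the
laboratory — turns the order in which these sites were gained and lost into a
testable history: a MnP-like common ancestor, gain of the tryptophan (first
VP), then loss of the Mn²⁺ site (first LiP).

`peroxevo` implements the computational side of that programme as a tested,
reusable pipeline:

1. **Likelihood machinery** — empirical amino-acid substitution models
   (WAG, LG, Dayhoff) with equilibrium frequencies π, reversible rate matrix
   Q = S·diag(π) normalized to one expected substitution per site per unit
   branch length, discrete-gamma rate heterogeneity (K equiprobable
   categories, shape α), and Felsenstein pruning with per-site scaling.
2. **Marginal ancestral reconstruction** — empirical-Bayes per-site posterior
   probabilities P(aₛ = x | data) at every internal node via a single
   inside–outside sweep, most-probable sequences, descendant-majority gap
   masks, and per-node mean confidence.
3. **Monte-Carlo "near-ancestors"** — alternative sequences sampled
   site-independently from the posteriors under relative probability
   thresholds θ (a residue is eligible when p ≥ θ·p_max at its site),
   pooled across thresholds with the most-probable sequence always included.
4. **Catalytic typing** — configurable detection of the Mn²⁺ triad and the
   catalytic tryptophan; the type is a pure function of (triad state,
   tryptophan): intact triad → MnP/VP, one non-basic substitution →
   atypical MnP/VP, a basic (Arg/Lys) substitution blocks the site → GP/LiP.
5. **Kinetics & stability** — Michaelis–Menten fits v = k_cat[S]/(K_m+[S]),
   biphasic two-site fits (sum of two independent Michaelis–Menten terms),
   catalytic efficiencies k_cat/K_m (s⁻¹·mM⁻¹), fold changes, relative
   efficiency profiles (per-substrate maximum = 100%), residual-activity
   normalization, T50 (linear interpolation of the 50% crossing) and Tm
   (midpoint of a fitted two-state sigmoid).
6. **Synthetic data** — a sequence-evolution simulator with known
   internal-node truths and designed catalytic-motif histories, plus
   known-parameter kinetic and melting curve generators, so every step is
   testable without any external download.

Amino acids are ordered alphabetically by one-letter code
(`ACDEFGHIKLMNPQRSTVWY`) in every vector and matrix.

## Worked example

A 10-leaf synthetic peroxidase family evolves under WAG+Γ with a designed
MnP → VP → LiP history: the root carries the intact triad, node `VP1` gains
Trp172, node `LIP1` degrades the triad (Glu37→Asp, Asp183→Asn).

```python
from peroxevo import (build_model, all_marginal_posteriors,
                      most_probable_sequence, classify_catalytic_profile,
                      sample_ancestors, partition_ancestor_set,
                      make_peroxidase_like_fixture)

fam, rules, sitemap, expected = make_peroxidase_like_fixture(seed=7)
model = build_model("WAG", alpha=1.0, K=4)
posts = all_marginal_posteriors(fam.tree, fam.leaf_alignment(), model,
                                nodes=["ROOT", "VP1", "LIP1"])
for name in ("ROOT", "VP1", "LIP1"):
    mp = most_probable_sequence(posts[name])
    prof = classify_catalytic_profile(mp.sequence, sitemap, rules)
    aset = sample_ancestors(posts[name], 1000, [0.2, 0.5], seed=1)
    part = partition_ancestor_set(aset, sitemap, rules)
    print(name, prof.type_label, prof.residues,
          round(mp.mean_confidence, 3), part.type_fractions)
```

prints

```
ROOT: type=MnP  residues={'37': 'E', '41': 'E', '183': 'D', '172': 'A'}  confidence=0.956  sampled type fractions={'MnP': 1.0}
VP1:  type=VP   residues={'37': 'E', '41': 'E', '183': 'D', '172': 'W'}  confidence=0.987  sampled type fractions={'VP': 1.0}
LIP1: type=LiP  residues={'37': 'D', '41': 'E', '183': 'N', '172': 'W'}  confidence=0.989  sampled type fractions={'LiP': 1.0}
```

i.e. the reconstruction recovers the designed catalytic history: the oldest
node is typed MnP (triad E/E/D, Ala at 172), the tryptophan gain makes `VP1`
a VP, and the degraded triad (D/E/N) with the retained tryptophan makes
`LIP1` a LiP — unanimously across 1000 sampled alternative ancestors, with
mean per-site posterior confidences of 0.95–0.99.

On the kinetics side, the published constants of the resurrected enzymes
reproduce the quoted evolutionary arithmetic: K_m = 62 µM and
k_cat = 106 s⁻¹ for Mn²⁺ oxidation give k_cat/K_m = 1710 s⁻¹·mM⁻¹, an
11-fold K_m drop from the first ancestor (700 µM), and fitting a noiseless
biphasic DMP curve recovers both sites, (K_m 5.3 µM, k_cat 4.5 s⁻¹) and
(32 500 µM, 31 s⁻¹), to better than 1%.

The same analyses are available from the shell:

```sh
peroxevo simulate --fixture peroxidase --seed 7 --out-dir family/
peroxevo asr --alignment family/leaves.fasta --tree family/tree.nwk \
             --alpha 1.0 --out-dir asr/
peroxevo classify --alignment asr/ancestors.fasta --reference ROOT
peroxevo run --config pipeline.yaml     # the full chain, deterministic by seed
```

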