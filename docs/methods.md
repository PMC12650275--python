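# Methods notes

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Synthetic study generator

The generator emulates a 4-diet × 3-replicate amplicon feeding trial
(groups CK, HFD, LSF, HSF; ~1500 ASVs; sequencing depth Poisson around
33,000 reads/sample).

**Count model.** Each ASV *i* has a baseline log abundance
μᵢ ~ N(0, 2²) and an occupancy probability ~ Beta(0.5, 1), so most ASVs
are absent from most samples (the sparsity real tables show). A sample's
latent abundance is exp(μᵢ + effects + εᵢ), ε ~ N(0, noise_sd²) with
noise_sd = 1 by default (lognormal overdispersion); counts are one
multinomial draw per sample at its Poisson depth. Proportions, not
absolute abundances, are observable — all planted effects are therefore
subject to compositional closure, which is deliberate.

**Planted differential ASVs** (per contrast against CK, default 30,
alternating sign, log2FC = 3) get baseline μ ~ N(1, 0.4²) and occupancy 1:
abundant enough to yield stable counts, small enough a share of reads that
the planted shift does not materially move the compositional denominator.
With very abundant planted taxa the log-ratio of group means visibly
attenuates; that regime is reachable by raising the baseline and is
intentionally not the default.

**Planted modules** (default 3 × 8 ASVs) share a latent factor per module:
member log abundance adds `module_strength` · f (strength 1.0) with
member-specific noise sd `module_noise_sd` = 0.35, giving a within-module
log-scale correlation of strength²/(strength² + 0.35²) ≈ 0.89 — above the
0.7 network threshold, near the 0.8 sensitivity threshold. The strength is
kept at 1 so the module's total read share does not swing enough to leak
(via the denominator) into background taxa; the early design with large
strengths produced exactly that artifact. The realized factor is
standardized across samples so the planted correlation is what the config
states rather than a draw-dependent quantity — at n = 12 an unstandardized
factor occasionally realizes with half its nominal variance and silently
weakens every planted association.

**Phenotypes.** Each linked module drives one trait block (3 traits,
alternating sign): trait = r·f + √(1−r²)·ε with r = `module_phenotype_r`
(default 0.9), then affine-rescaled. Unlinked blocks share their own latent
factor plus per-group offsets (so group effects exist without touching the
module factors). Categories alternate "Gut health" / "Gut development".

**Ct tables.** A group-invariant reference gene, per-sample template
shifts (which cancel in ΔΔCt), planted expression fold changes entered as
Ct decreases (one cycle per doubling), noise 0.1 cycles, Ct clipped to
[15, 35], efficiencies Uniform(85, 115)%.

**What passing tests do and do not show.** The generator reproduces
compositionality, sparsity, overdispersion, depth jitter and planted
module/trait structure. It does not emulate phylogenetic correlation,
taxon-specific PCR bias, chimeras, batch effects, or real taxa; recovery
results bound what the pipeline can do under its own assumptions, not
under every failure mode of real data.

## Diversity stage

Rarefaction is without replacement (multivariate hypergeometric), seeded;
samples below the target depth are dropped, never up-sampled; default
depth is the minimum sample total. Shannon uses the natural log (base
configurable). Group "presence" pools counts over the group's samples
(> 0), the convention UpSet summaries of pooled groups imply. PCoA drops
negative eigenvalues from the variance denominator (no Cailliez
correction) and logs how many were dropped — the simplest defensible
default for a semi-metric like Bray–Curtis.

## Group statistics

Shapiro–Wilk per group and Levene across groups (α = 0.05) gate into
one-way ANOVA + Tukey HSD, otherwise Kruskal–Wallis + Dunn with Bonferroni
over the pairwise family (flag for none/Holm). At n = 3 per group the
normality gate has essentially no power; it is applied verbatim because it
is the emulated trial's stated procedure, and the caveat is logged here.
Letters come from the insert-and-absorb compact-letter algorithm, lettered
from the highest group mean. ΔΔCt uses the arithmetic mean ΔCt of the
calibrator group (Livak convention); the 90–110% efficiency gate is
advisory (a warning, not a filter).

## Differential screen

log2(relative abundance + pseudocount) regressed on the group indicator;
the two-group linear model is computed in its closed form (pooled-variance
t), vectorized over ASVs; degenerate (constant) ASVs record p = 1. The
pseudocount is half the smallest nonzero relative abundance (scale-aware).
"Fold change > 1" is read as |log2FC| > 1, i.e. > 2-fold — the
`fc_scale="ratio"` flag gives the literal-ratio reading, under which every
significant ASV with any nonzero change qualifies. Raw p-values by default
(mirroring the stated screen); `correction="bh"` is available. The
"core" differential set is the intersection of significant ASVs across the
supplied contrasts; the union is reported alongside, since both readings
of a multi-contrast core exist in practice.

## Module linking

The linking chain runs on **CLR-transformed** proportions. Plain
log-proportions carry a per-sample offset −log(total latent) that loads as
a shared factor on every taxon and contaminates each module's first
principal component; CLR centering removes exactly that term. (The
differential screen intentionally keeps plain log2 proportions — its
contract is the simple linear-model screen.)

Module detection is greedy modularity maximization on |ρ| weights with a
deterministic ordering (Louvain behind a flag, seeded); modules below
`min_size` (3) pool into an explicit unassigned label. In the linking
chain, detected modules whose eigenvectors correlate at |r| ≥ 0.75 are
merged (the WGCNA merge step): threshold graphs routinely fragment one
correlated block into near-duplicate communities, and without merging a
single planted module can be reported — and linked — twice.

The module eigenvector is PC1 of the column-standardized member submatrix,
unit-norm, oriented so its mean correlation with members is ≥ 0. Note this
orientation is necessarily *equivariant*, not invariant, under flipping
every member's sign: no rule defined on the member submatrix alone can be
sign-invariant.

Phenotype traits cluster by average linkage on 1 − |Spearman ρ|, cut to
`n_blocks`; each block's eigengene is computed the same way and the block
inherits the majority category tag of its traits.

The Mantel test uses Spearman correlation of condensed distances with
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm) (rows/columns of the second
matrix permuted jointly; exact enumeration for n ≤ 7). Eigenvector
distance matrices |sᵢ − sⱼ| are invariant to the eigenvector's sign, so a
negatively linked block still produces a *positive* Mantel r and the
one-sided test covers both link signs; the direct Spearman column carries
the sign. A link is called only when **both** statistics clear r > 0.3,
p < 0.05 — the two report different aspects (distance structure vs
monotone association), and requiring agreement is what keeps the
false-link rate low enough that a single planted association is reported
as a single link. Biomarkers are member ASVs ranked by |correlation with
their own module eigenvector| (module membership, WGCNA-style).

Sensitivity: the network is rebuilt at ρ ≥ 0.8; a module is recovered if
its best Jaccard overlap with the stricter partition is ≥ 0.5 and its
significant links persist for the matched module.

## Ecological networks

Per-group Spearman networks at a fixed similarity threshold St = 0.995 by
default; the optional RMT-style scan walks a candidate grid and returns
the smallest threshold whose thresholded matrix has Poisson-consistent
nearest-neighbour eigenvalue spacings (χ² against the exponential form,
p > 0.05), falling back to the grid maximum with a warning. The fixed
default exists because the scan is a heuristic and reproducibility of the
printed threshold matters more than re-deriving it.

Topology: avgK = 2E/N; avgCC is the unweighted local clustering
coefficient averaged over all nodes (degree < 2 contributes 0); modularity
scores the greedy partition on |weights|; GD averages shortest paths over
connected pairs only (the networks are fragmented; excluded pairs are a
consequence, not an error). The null model is degree-preserving double-edge
swapping (10·E swap attempts per randomization, default 20–100
randomizations), with an Erdős–Rényi same-N-same-E fallback (logged) for
graphs too small or too saturated to rewire. Module preservation across
group networks: one-sided (enrichment) Fisher's exact test on the 2×2
share/exclusive/background table over the union node universe — including
unassigned nodes, so near-total overlaps in a tiny universe are not
spuriously "significant" — with p < 0.05 pairs merged into clusters by
transitive closure and the retained percentage reported to 2 decimals.

## Neutral community model

Detection limit d = 1/N with N the mean sample depth (the standard
Sloan/Burns convention); predicted occurrence is the Beta(Nm·p, Nm(1−p))
upper tail beyond d; Nm is fitted by bounded scalar least squares on the
frequency scale over log Nm ∈ [0, ln 10⁶]; R² = 1 − SSE/SST may be
negative. The 95% band is the Wilson binomial interval of the predicted
frequency at the sample count. The simulator draws a fixed lognormal(0, 2)
metacommunity and per-sample proportions from Dirichlet(Nm·p) — whose
marginals are the Sloan Beta — then multinomial counts. Self-recovery has
a known upward bias of roughly 25% in fitted Nm: the hard threshold d is
only an approximation to multinomial detection. The recovery guarantee is
therefore stated on the median over seeds (within ±30%), with per-seed
R² ≥ 0.6; the neutral-vs-deterministic R² contrast is unaffected.

## Functional projection

Pathway abundance = relative abundance × taxon-to-KO3 weight matrix,
renormalized per sample; only KO3 pathways with KO1 ancestor "Metabolism"
are retained; per-pathway group differences reuse the gated comparison and
are starred at p ≤ 0.05 / 0.01 / 0.001. The reference mapping is a
user-supplied input at whatever rank the table uses; a seeded synthetic
mapping fixture ships for testing. No claim is made about real metabolic
capacity — projections are in-silico inference.

## Problem sizes

The bundled experiments run at deliberately modest sizes — 200–500 ASVs
and 12 samples for recovery and calibration runs, 20–50 seeds per
property, 999 Mantel permutations, 5–100 network randomizations — chosen
so each property is measured with useful precision while the whole
validation surface executes in minutes on one core.

## Known limitations

- The screen is a plain linear model on log proportions: no zero-inflation,
  no negative-binomial dispersion, no compositional bias correction.
- Trait clustering at n = 12 samples is noisy; blocks occasionally
  fragment, and a fragmented linked block yields two honest links to the
  same latent factor.
- The RMT scan is a coarse spacing test, not a full spectral unfolding.
- The NCM fit inherits the d = 1/N approximation (bias noted above).
- Group networks built from 3 replicates can only resolve |ρ| = 1 edges at
  St = 0.995; the per-group topology panel is correspondingly coarse.
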