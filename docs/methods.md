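# Methods

This note documents the models, estimators, numerical choices and open
design decisions behind `desertam`, and what the synthetic-data tests do and
do not demonstrate about real survey data.

## Read processing

Primers are matched **only at the 5′ terminus** of each mate (amplicon
primers are terminal by construction; no internal search). A primer
position with an IUPAC degeneracy code matches every base it covers at no
cost; an uncalled `N` in the read matches nothing and counts as a mismatch,
because an uncalled base is no evidence of primer presence. The default
allowance is 1 mismatch per mate. Default primer sequences are WANDA
(`CAGCCGCGGTAATTCCAGCT`) and AML2 (`GAACCCAAACACTTTGGTTTCC`), the standard
AM-fungal SSU pair from the primer literature; both are configuration
inputs.

Quality filtering keeps a pair iff **both** mates have an arithmetic mean
of their integer Phred scores ≥ `min_mean_q` (default 30, inclusive). The
arithmetic mean is used deliberately (not the error-probability mean): the
criterion is an average quality *score*.

Merging reverse-complements the reverse mate and scans every candidate
overlap length in `[min_overlap, max_overlap]` (defaults 10–300 bp). The
accepted overlap is the **highest-identity** candidate at ≥ `min_identity`
(default 0.75); among equal identities the **longest** overlap wins (the
tie rule of upstream merge tools is undocumented, so we fix one). In the
overlap, the consensus base is the mate with the higher Phred score, ties
going to the forward mate. `N` matches nothing in overlap identity.
Per-site accounting partitions every input pair into exactly one of
{primer fail, quality fail, merge fail, merged}; this conservation is
asserted on every run. Chimera screening is out of scope; an
`exclude_ids` hook drops reads flagged by an external tool.

## Virtual-taxon assignment

The reference catalogue is desk-scale (tens to a few hundred type
sequences), so assignment uses a **native local aligner** rather than an
external search binary: Gotoh dynamic programming with match +1,
mismatch −1, gap open −2, gap extension −1 (numba-compiled; its optimal
scores are cross-checked against an independent implementation in the test
suite). Only the thresholds — not the scoring — are part of the method
definition, so the scoring scheme is a fixed package choice.

Per hit we report identity = matches / aligned columns (gap columns count
in the denominator) and coverage = aligned read span / **read** length.
Whether the 95% "alignment length" threshold refers to query or subject is
genuinely ambiguous in the method's source; we chose read (query) length
and flag it here. Both the read and its reverse complement are scored
(merged-read orientation depends on library layout); each strand's hit is
thresholded independently. Among references passing identity ≥ 0.97 **and**
coverage ≥ 0.95 the highest identity wins (ties: higher coverage, then
smallest vt_id), making assignment independent of reference order.

At pipeline scale an **edit-distance prescreen** (edlib, bit-parallel)
ranks candidate references and strands first, and only the leading
candidates (those within 4 edits of the best, at most `prescreen_top`) are
confirmed with the exact aligner — the same seeding idea BLAST uses. The
final accept/reject decision is always made by the exact aligner;
`assign_vt(…, prescreen=None)` is fully exhaustive and is the behaviour the
unit tests pin down. With references ≥ 6% divergent and reads ≤ ~3% from
their source (the regime of a 97%-identity species proxy), prescreened and
exhaustive assignment agree; a dedicated test asserts this.

Dataset-wide singletons (VT with exactly one read across **all** sites) are
removed after table construction; the operation is idempotent. The cultured
fraction is the share of retained VT flagged as containing sequences of
known morphospecies identity.

## Diversity

Rarefaction uses the exact hypergeometric expectation
E[S_m] = Σᵢ [1 − C(n−nᵢ, m)/C(n, m)], evaluated with log-gamma for
stability. Hill numbers follow the effective-number convention: ⁰D =
richness, ¹D = exp(Shannon entropy), ²D = inverse Simpson. Published
Table-3-style "Shannon diversity" values of ~1.9–6.6 are only consistent
with exponentiated entropy, so the Hill convention is assumed throughout.

Asymptotic estimates extrapolate to full sample coverage: Chao1
(S_obs + f₁²/2f₂; bias-corrected f₁(f₁−1)/(2(f₂+1)) when f₂ = 0) for
richness, and the Chao–Jost rare-frequency estimators for q = 1 (entropy
estimator with the (1−A)^(1−n) singleton correction, A from f₁, f₂) and
q = 2 (the minimum-variance unbiased concentration 1/Σ[nᵢ(nᵢ−1)/n(n−1)];
degenerate all-singleton samples fall back to the observed value). The
uncertainty is a **multinomial bootstrap** (default B = 200, seeded):
resample n reads from the observed proportions, recompute, report the
bootstrap SD and normal 95% limits, flooring the q=0 lower limit at the
observed richness. This is simpler than the coverage-adjusted bootstrap of
dedicated rarefaction/extrapolation software; its intervals are honest at
the sample sizes used here (a coverage simulation in the test suite checks
≥ 90% empirical coverage of nominal 95% intervals).

## Phylogenetic structure

Type sequences arrive **pre-aligned** (the generator evolves them without
indels; real inputs should be aligned upstream — MSA is out of scope).
Distances are Jukes–Cantor, d = −¾ ln(1 − 4p/3), computed over pairwise
ungapped columns; saturated pairs (p ≥ 0.75) are capped at a finite 10.0
substitutions/site rather than infinity so the NJ matrix stays usable.

Neighbor joining is the classical Saitou–Nei algorithm with two
determinism rules: Q-matrix ties are broken toward the pair whose
(smallest, then largest) representative leaf labels sort first, and
children are attached in label order, so the same matrix always yields the
same Newick string. Negative branch-length estimates are clamped to zero
with the deficit moved to the sister branch (standard practice; preserves
the joined pair's summed length). Patristic distances are leaf-to-leaf path
sums on the resulting (unrooted, trifurcating-root) tree.

mpd is the unweighted mean pairwise patristic distance among a sample's
taxa — presence–absence only, per the method definition; a one-taxon
sample has **no** pairs and returns missing, not zero. comdist averages
all cross pairs between two samples. ses.mpd draws `n_reps` (default 999)
uniform same-richness subsets of a pool **without replacement**, and
reports Z = (obs − null mean)/null SD using the sample SD (ddof = 1) of
the 999 null values; the observed community is *not* pooled into the null.
A null SD at floating-point-noise level (every draw numerically identical)
marks the result degenerate instead of producing a meaningless huge Z.

## Habitat affiliation

The aridity index of a VT is the fraction of its database records labelled
"deserts and xeric shrublands" (the label set is configurable); a VT with
zero records has an undefined index and is excluded from community means
and pools. The community aridity is the unweighted mean over scored
members. The null draws size-matched uniform subsets from the pool —
uniform over *taxa*, not record-weighted, because the method is defined as
"randomly selecting n VT". Sample VT absent from a sub-global pool still
count in the observed mean; the pool only shapes the null (this asymmetry
is intentional and tested). Significance is two-sided at |Z| > 1.96
(configurable), while the count of sites with *over-represented*
desert-affiliation uses the directional rule Z > +1.96 with a strict
inequality.

## Ordination

Jaccard dissimilarity is 1 − |A∩B|/|A∪B| on presence sets (two empty
samples are at distance 0 by convention). PCoA double-centres −½D² and
eigendecomposes; scores are eigenvectors × √eigenvalue, all eigenvalues
(including negative ones) are reported uncorrected, and axes whose
eigenvalues sit at numerical-noise level get exact-zero scores so
duplicate samples coincide. NMDS minimizes Kruskal stress-1 with isotonic
regression (delegated to scikit-learn's non-metric MDS), taking the best
of a PCoA start plus seeded random restarts (default 4 starts, 300
iterations, relative convergence 1e-6). envfit regresses each centred
environmental variable on the score axes; r² is the explained-variance
fraction, the arrow is the unit coefficient vector, and the permutation
p-value uses the add-one convention (1 + #{r²_perm ≥ r²_obs})/(n_perm + 1),
floored at 1/(n_perm + 1). Both dissimilarity matrices can feed either
ordination; the pipeline default pairs Jaccard with PCoA and comdist with
NMDS, 2 axes.

## Synthetic data: what it emulates and what it does not

The generator produces a Yule (pure-birth) phylogeny over `n_vt` taxa
(default 50), scales it to a mean root-to-tip depth of 0.15
substitutions/site and floors pendant edges at 0.05 so sister taxa stay
resolvable at the 97% species proxy, then evolves `seq_length` = 500 bp
type sequences under JC69 **without indels** (sequences stay aligned by
construction). Each VT receives 5–40 biome records whose desert fraction
is drawn from the configured range (default U(0, 0.8)), continent/realm
occurrences (each region with probability 0.8), and a cultured flag
(p = 0.42, the survey-scale fraction).

Default site structure mirrors the study design: 6 sites, richness
3–36 VT per site, ~5000 read pairs per site, 2 × 300 bp reads. Community
assembly draws members without replacement with weight
exp(`affiliation_beta` × aridity index); β defaults to 8 — a strong
habitat-filtering regime chosen (by a design-stage power calculation)
so the planted effect is detectable across the whole 3–36 richness range.
`clustering_mode="clade"` instead restricts each site to one lineage of
roughly a third (at most half) of the tree, with richness ≥ 5 capped at
the lineage size — the generator's stated planted clustering effect.
Per-member read counts are log-normal, floored at 2 so no planted member
is lost to the dataset-wide singleton filter by construction. Reads carry
the primers, configured substitution error (default 1%/base), Gaussian
Phred profiles (N(35, 3) good, N(20, 3) planted low-quality), and
mutually exclusive planted defects (2% bad-primer, 5% low-quality, 2%
unmergeable by default), all recorded in a ground-truth sidecar.

Not emulated: quality-dependent Illumina miscall spectra, indels,
chimeras, PCR abundance bias, and real biome/biogeography correlation
structure. Passing recovery tests therefore demonstrates correctness of
the *computational* chain under a faithful error model of the right scale
— not robustness to every artefact of real sequencing.

## Problem sizes and reproducibility

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one global seed by stage-name hashing (CRC32,
< 2³¹), so standalone stage runs are byte-identical to full runs. The
acceptance script sizes its checks as follows (package choices): exact
null enumeration on pools up to C(16, 4); calibration over 1000 β = 0
communities; power over 200 replicates each for affiliation and clade
clustering; 100 NJ round-trip trees (4–12 taxa); 20 rarefaction vectors ×
100,000 subsamples; error-free end-to-end recovery at 600 reads/site
(an identity check — size-independent) and noisy recovery at the full
6 × 5000-read defaults; manifest determinism on a reduced 12-VT, 3-site
configuration (determinism is size-independent).

## Known limitations

- Identity/coverage are properties of *one* optimal local alignment;
  co-optimal alignments with different gap placement could report slightly
  different identity at equal score (ties are broken deterministically by
  the DP traversal order).
- The Chao–Jost q = 1 correction term is numerically delicate for n ≫ 10⁴
  with many singletons; the implementation follows the standard closed
  form without further stabilization.
- NJ is the only tree method offered (by design); no ML/Bayesian trees,
  no abundance-weighted mpd, no MNTD.
- The exhaustive null oracles are for validation only and scale as
  C(|pool|, n); the Monte-Carlo path is the production route.
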