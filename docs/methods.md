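# Methods

`ecometab` implements an integrated ecological + metabolic modelling
workflow for genome-resolved meta-omics of microbial communities
(designed around marine bacterioplankton, applicable to any paired
metagenome/metatranscriptome survey). This note documents the models,
the defaults and the design decisions, and what the synthetic-data
module does and does not emulate.

## Genome catalogue

Genomes are classified by CheckM-style completeness/contamination into
HQ (>=90% / <=5%), MHQ (>=75% / <=10%), MQ (>=50% / <=25%) and LQ;
boundaries are inclusive. LQ genomes are retained in outputs but
excluded from downstream analyses. Species-level dereplication is a
two-step single-linkage scheme on precomputed matrices: connected
components at ANI >= 0.90 with aligned coverage >= 0.60, refined inside
each component at ANI >= 0.95. The cluster representative maximizes
`completeness - 5 x contamination` (the weight is exposed), with ties
broken by genome length and then id; this scoring is a widely used
dereplication default — the underlying tools specify only "most
complete, least contaminated".

Bacterial and archaeal phylogenies are joined under a fresh root with
two branches of 0.061 so that every inter-domain leaf pair gains
exactly 0.122 of patristic distance. Only path lengths matter
downstream, so splitting the bridge symmetrically is inconsequential;
the alternative (a single 0.122 branch on one side) yields identical
leaf-to-leaf distances.

## Meta-omics profiling

Alignment identity is `1 - (NM - XN)/L`: the edit distance NM corrected
for ambiguous reference bases XN, relative to read length L. The raw
quantity `(NM - XN)/L` is a mismatch fraction; stating the filter as
"identity >= 95%" therefore means the mismatch load is at most 5%.
Alignments are kept when MAPQ >= 20 and identity >= 0.95 (both
inclusive). Coverage uses 0-based half-open spans: depth is the summed
aligned bases over genome length (vertical coverage), breadth the
fraction of positions covered at least once (horizontal coverage).

A genome is observed in a sample when its metagenomic breadth is
>= 30%. Abundance is metagenomic depth, optionally normalized per
million mapped sample bases (`sample_million_bases`, the default when
genome lengths are available; `none` otherwise). The normalization
dialect is ambiguous in the field — depth already normalizes by genome
length, so the extra factor here corrects for sequencing effort across
samples; because the CLR transform is invariant to per-sample scaling,
the choice does not affect network inference. Activity is the ratio of
metatranscriptomic over metagenomic depth; zero activity is legitimate
(present but transcriptionally silent), while a present genome with
zero metagenomic depth is rejected as inconsistent. Genomes observed in
fewer than 10 samples are dropped, independently per layer.

The CLR transform operates per sample over observed genomes only.
Zeros receive an adaptive pseudo-count of half the smallest nonzero
observed value of that sample — a reproducible stand-in for the
unexported behaviour of the network-inference tool this emulates.
Masked cells are NaN and never enter any statistic.

## Scaling laws

Per functional category the gene count scales as `y = c x^beta` with
the total gene count x, fitted by OLS on log10-transformed variables;
genomes with zero counts are excluded from that category's fit (log
undefined; no pseudo-count is introduced because none is specified for
this analysis in the literature the workflow follows). Enrichment of a
genome group is read from residuals of the *pooled* fit (both groups
together): this mirrors the "deviation from the general trend" logic;
per-group fits are available as an option. Categories with pooled
R^2 < 0.3 are not tested. Group comparisons use the two-sided
Mann-Whitney U test on residuals with Bonferroni and Benjamini-Hochberg
corrections across tested categories.

A note on the "sole significant category" power experiment: with one
overwhelming true positive among 20 categories, the BH step-up line is
lifted for the remaining null categories, so a second (false) category
crosses BH <= 0.05 in roughly 5-10% of scans. The observed sole-hit
rate of ~0.94 at the default conditions (500 genomes, shift +0.30,
sigma 0.1) is a property of BH itself, not of the fit.

## Co-activity network inference

Direct associations are inferred with a PC-stable-style
conditional-independence procedure on the CLR matrix: all marginally
significant edges (Fisher z-test, `z = atanh(r) sqrt(n - |S| - 3)`,
two-sided normal) are pruned for conditioning-set sizes k = 1..max_k
(default 3), testing subsets drawn from the union of the endpoints'
current neighbourhoods, with neighbourhoods frozen per level. An edge
is removed on the first non-significant test and its removal is
recorded in an audit trail; surviving edges are weighted by the partial
correlation given the largest certifying conditioning set. Partial
correlations are computed by precision-matrix inversion on
pairwise-complete observations; a test needs at least `n_obs_min = 10`
shared observations, and an edge exists only if at least one
significant test certified it. Defaults: alpha = 0.01 (the original
tool does not export its level), max_k = 3, n_obs_min = 10. The
original tool's local-to-global heuristics are not published at
procedure level; the PC-stable variant is a documented simplification
whose behaviour is pinned by an exhaustive-conditioning oracle on small
instances (where neighbourhood-restricted and all-subsets conditioning
provably coincide) and by a one-sided superset guarantee elsewhere.

## Markov clustering

MCL runs on positive-weight edges only (flow interpretation requires
non-negative similarities; absolute weights are available behind a
flag; negative edges stay in the network and in all sign-based
summaries). Self-loops are set to the node's maximal incident weight, a
standard regularization. Expansion 2, inflation 1.5, pruning threshold
1e-5, convergence by max-change < 1e-8; non-convergence raises with
diagnostics. Clusters come from attractor rows with overlapping rows
merged; singletons are reported separately. Closeness centrality is
component-normalized: `(n_c - 1) / sum(shortest paths)` with unit edge
lengths.

## Community metabolic modelling

Models are small stoichiometric networks in a versioned JSON schema
(optional SBML import via cobra); exchange reactions `EX_<met>` touch
exactly one extracellular metabolite, negative flux is uptake, and
inorganic compounds (water, phosphate, ammonium, iron, ...) are freely
available everywhere and excluded from all cross-feeding records.
Growth means biomass flux >= `g_min = 1e-4` (the literature requires
only "non-zero growth"; the threshold is exposed). No gap-filling is
performed anywhere, which avoids manufacturing false-positive
cross-feedings at the cost of missing some true ones.

Minimal media are enumerated exhaustively (ascending cardinality with
superset pruning, valid because growth is monotone in the medium) over
at most 20 organic candidates; `molweight` weighting selects the
minimal medium by total molecular weight instead of cardinality.
The community scores follow the verbal semantics of the published
coupling analysis, pinned by brute-force oracles rather than by the
external tool (whose exact published denominators may differ — anyone
needing bit-compatibility should not assume it):

* MRO = sum over member pairs of |M_i & M_j| / sum of min(|M_i|,|M_j|),
  with M_i the union of species i's minimal media.
* MIP = |smallest community medium with private extracellular pools| -
  |smallest community medium with a shared pool|; non-negative because
  sharing relaxes the private problem.
* SCS(d, r): fraction of the receiver's inclusion-minimal donor sets
  containing d (donors must themselves grow); 0 if r is self-sufficient
  on the medium. MUS(m, r): fraction of r's minimal uptake sets
  containing m. MPS(m, d): 1 iff d can secrete m at nonzero flux while
  growing. smetana = SCS x MUS x MPS per (donor, receiver, metabolite).
* The community sum score is normalized by N(N-1)/2 potential pairs.

Detailed scoring defaults to the community-specific minimal medium
(smallest-cardinality shared-mode medium, lexicographic tie-break) and
is bounded to communities of 6 members for exact enumeration.

Transporters are classified into nine mechanism classes (ABC, proton
symport/antiport, sodium symport, uniport, diffusion, PTS, vectorial
group translocation, other) from annotations or compartment-crossing
stoichiometry; reversible transporters count in both directions. A
transporter is active when at least one gene of its rule is expressed —
meta-omics detection is too sparse at gene level to require complete
complexes.

## Community typing

Random communities are sampled uniformly without replacement from the
network genome pool, with sizes resampled from the observed co-active
size multiset (the size distribution of the reference random
communities is not documented; a uniform size range is available behind
a flag). Null thresholds are the 5th percentile of mean patristic
distance and the 95th percentile of the normalized cross-feeding score
over >= 30 random communities, with linear-interpolation quantiles for
reproducibility. "Smaller than 95% of random communities" is read as
below the 5th percentile. LPD iff mean PD < q05; HCP iff score > q95;
null draws land in HPD-LCP with probability ~0.95^2 by construction.

The functional Gini coefficient uses the bias-corrected denominator
`2 n (n-1) mean(x)` so that the verbal endpoints are exactly attainable
(equal capitals -> 0; a single holder of all community functions -> 1);
the raw `2 n^2 mean(x)` version is available. Functional capital is the
number of community-occurring KOs a member carries. Jaccard distances
operate on KO presence sets, optionally restricted to KOs detected in
at least 10 samples ("expressed" mode). Exchange profiles sum smetana
scores per metabolite category ("uncategorized" for unmapped ids);
per-metabolite group tests are two-sided Mann-Whitney with BH
correction and the conventional star coding (**** p<=1e-4 down to ns).
The NMDS ordination is non-metric MDS on Bray-Curtis distances, seeded.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with planted truth:
power-law gene counts with log10-normal noise (additive in log space,
matching the fitting model; counts rounded half-up, zeros permitted);
random bifurcating trees; paired coverage tables; alignment summaries
with consistent `0 <= XN <= NM <= L` fields and filter labels; toy
stoichiometric models over a shared ~13-metabolite universe; and
ANI/coverage matrices with a planted species partition.

Planted co-active communities drive the *activity* layer through one
shared lognormal latent factor per community scaled by member loadings;
metagenomic depths are only weakly structured, reflecting that
co-abundance and co-activity carry largely distinct signals. Depths are
closed per sample to a fixed total, reproducing compositionality. The
lognormal latent-factor model is a stand-in: the noise structure of
real activity ratios is uncharacterized, so passing recovery tests
demonstrates correctness of the machinery under the stated model, not
performance on ocean survey data.

One identifiability constraint shaped the default world used by the
end-to-end tests: under a single shared factor, the partial correlation
between two equally loaded members given k other members decays as
`r/(1 + k r)`, so fully recovering cliques of four or more members
would need hundreds of support samples at alpha = 0.01 with max_k = 3.
The default world therefore plants three communities of three genomes:
a tightly coupled core pair (loadings ~1.3; the planted donor and
receiver) plus a loosely coupled associate (loading ~0.7). The core
edge's partial correlation given the weak member stays ~0.75 and
survives pruning, while the associate is occasionally and legitimately
pruned to a path or dropped — community recovery stays at Rand >= 0.95
across seeds at 48 samples with 40-sample support, a sample size
matching real euphotic-ocean activity surveys (~71 samples). Toy
worlds use 18 genomes so that closure-induced CLR correlations stay
well below the association signal.

Obligate cross-feeding is planted by making the receiver's biomass
require a metabolite it cannot synthesize while the donor gains a
synthesis + secretion route; prototroph controls grow on glucose plus
inorganics. All models stay under ~20 reactions so that every score has
an exhaustive enumeration oracle.

## Numerical choices and degenerate inputs

LPs are solved with HiGHS via `scipy.optimize.linprog`; solver failure
is reported distinctly from infeasibility. Uptake bound 10, generic
flux bound 1000, secretion detection tolerance 1e-6. Correlations are
clipped to (-1, 1) before the z-transform; singular conditioning sets
make a test undecidable (the edge is not removed by it). Constant
variables yield undefined correlations and are skipped. All iteration
orders (nodes, subsets, media) are sorted, making every procedure
deterministic given its seed.

## Known limitations

* The association procedure is a PC-stable variant, not a
  re-implementation of the original tool's heuristics (its
  "heterogeneous" meta-variable handling is out of scope); agreement is
  guaranteed only against the package's own oracle semantics.
* MRO/MIP/SCS/MUS/MPS follow verbal definitions; numeric
  bit-compatibility with the original MILP-based implementation is not
  claimed.
* Exact enumeration bounds (20 medium candidates, 6 community members)
  are hard limits; larger instances need a different algorithmic
  approach, deliberately out of scope.
* The SBML importer is a thin optional mapping and is not validated
  against the full SBML-FBC feature set.
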