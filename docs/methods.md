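# Methods

## The study design being modelled

The package analyses a treatment × time RNA-seq count matrix from fruit
stored under seven regimes: an at-harvest baseline (PreTreat, a single
timepoint), air storage at three temperatures (A1, A10, A20), air + the
ethylene-perception inhibitor 1-MCP (MCP), controlled-atmosphere
hypoxia (CA, ~2% O₂ at 1 °C), and 1-MCP + CA (MCPCA). CA and MCPCA are
hypoxic; everything else is normoxic. MCP, CA and MCPCA are the
long-term arms, sampled monthly over months 2–9 of storage with three
biological replicates per treatment × timepoint cell. Crossing hypoxia
with ethylene-perception blockade is what lets the set logic separate
an oxygen-sensed ("n-degron") response from an ethylene-dependent one.

## Synthetic data generator

`simulate_counts` draws counts from a negative binomial with
`Var(K) = μ + αμ²` (`α = 0` degenerates to Poisson; default
`α = 0.05`, typical of bulk RNA-seq biological replicates). Per-gene
baseline means are log-uniform on [50, 2000] — the working range of
expressed genes after the usual expression filters; the lower bound was
fixed during the calibration of the default configuration so that the
planted classes are recoverable at three replicates (see below). Five
response archetypes set a log2 induction added to the baseline
log-mean, with default amplitude 2 log2 units (4-fold):

| class | where induced | time profile |
|---|---|---|
| `null` | — | flat |
| `ndegron_sustained` | CA, MCPCA | full amplitude at all long-term months |
| `ndegron_transient` | CA, MCPCA | full at month 2, decaying linearly (in log-mean) to 0 at month 9 |
| `ethylene_late` | CA only | 0 at month 2, rising linearly to full at month 9 |
| `maturation` | A1, A10, A20 | full amplitude (true negatives for the hypoxia logic) |

Linear-in-log-mean ramps are the simplest shapes matching the
fast-then-fading and slow-late archetypes of long-term storage
transcriptomes. Defaults: 2000 genes, 60 TFs, class fractions
0.70/0.08/0.08/0.08/0.06, short-term sampling grid {0.25, 1, 2, 3}
months (a placeholder cadence — the long-term monthly grid is the
scientifically constrained one), giving 102 samples.

Regulatory structure: each TF carries a per-sample standard-normal
latent on its log-mean, and each of its planted targets receives
`edge_strength ×` the same standardized latent (log-linear coupling).
Both are scaled by `edge_strength`, so `edge_strength = 0` yields fully
exchangeable null genes. Targets are drawn from null-class genes only,
keeping the regulatory and treatment ground truths orthogonal. The
default `edge_strength = 0.3` was calibrated once: large latents
(scale ≳ 0.5) make the latent noise itself generate spurious joint
up-calls in 3-vs-3 cell contrasts, while 0.3 still gives essentially
complete recovery of planted edges by the forest (the coupling is
strong relative to NB noise, whose log-scale s.d. is ≈ 0.25 at these
means). Sequences: motif-carrying genes (the two n-degron classes) get
exactly placed HRPE instances with random realizations of the
ambiguity codes; all other upstream windows are HRPE-free by rejection
sampling on both strands; 5 of the TFs carry CDS translating to
N-terminal MCGGAI or MCGGAV, the rest are degron-free by construction.

What the simulator does *not* emulate: library-size confounding beyond
scalar size factors, gene length/GC effects, count outliers, correlated
replicate structure, mean-dependent dispersion trends, or realistic
promoter composition. Passing the recovery suites therefore shows the
pipeline's logic and calibration are correct under its own model, not
that real data would reach the same sensitivities.

## Normalization and differential expression

Size factors are classic median-of-ratios: reference genes are rows
positive in every sample; `s_j` is the median across reference genes of
the count over the gene's geometric mean. No pseudocount is injected —
a matrix with no all-positive gene raises an error. Genes with zero
counts across all samples are dropped before testing.

The per-contrast test is a deliberately simple NB Wald test on group
means of normalized counts: `log2FC = log2((m_A + c)/(m_B + c))` with
pseudocount `c = 0.5`, delta-method standard error from
`Var(mean) = (m + αm²)/n`, two-sided normal p, Bonferroni within the
contrast (family = genes tested in that contrast), and the
up-regulation call `log2FC > 1 ∧ p_adj < 0.05` (both strict). This is
not a DESeq2 reimplementation — no dispersion shrinkage, independent
filtering, outlier handling or LFC shrinkage — because the scientific
content here is the contrast-set logic downstream, not the test
internals.

Dispersion. The single-gene API uses that gene's pooled within-group
moment estimate `α = max(0, (v̂ − m̄)/m̄²)`. For a whole contrast table
this per-gene estimator at n = 3 per group is far too noisy to
calibrate a normal tail (clipping alone pushes the null type-I rate to
~0.12 and produces extreme false calls), so the table-level test pools
one dispersion across genes: the across-genes **median** of the
per-gene moment ratios, rescaled by `d / median(χ²_d)` (d = pooled
within-group degrees of freedom) to make the median Fisher-consistent
for the mean. The median is robust to the minority of genes with
genuine extra variance (regulator-driven expression, or time-varying
classes pooled into one treatment group), and the χ² correction removes
its downward bias: on 2000-gene 3-vs-3 null runs the raw p < 0.05 rate
is ~0.05–0.07 and Bonferroni joint calls are almost always zero, while
the full 4-fold planted effect is detected with sensitivity ≳ 0.96.

Numerical notes: an all-zero gene reports log2FC 0 and p = 1; swapping
the groups negates log2FC and preserves p exactly; multiplying one
sample's counts by a constant rescales the whole normalized matrix by a
common factor (a property of median-of-ratios), under which log2FC is
stable to ~10⁻³ (pseudocount) and p to ~0.1 at n = 3 (the NB variance
model is mean-scale dependent); the discrete up-calls coincide.

## Contrast-set logic

The hypoxia-upregulated set uses the ∃H∀N rule: a gene qualifies iff
there is a hypoxic treatment H ∈ {CA, MCPCA} called up versus **all**
five normoxic treatments. The looser any-single-pair reading is exposed
as `mode="any_pair"` but is not the default, since only ∃H∀N is
consistent with the exclusive-subset constructions. The CA-only
(MCPCA-only) subsets require up-calls versus all six other treatments
and are intersected with the hypoxia set, so the declared invariants
(subset-ness, and disjointness — which follows from the anti-symmetry
of the CA/MCPCA pair) hold on any input. Per long-term timepoint, the
n-degron set is the intersection of the CA-vs-MCP and MCPCA-vs-MCP
up-calls, the ethylene set the intersection of CA-vs-MCP and
CA-vs-MCPCA. Set files are written as sorted gene-ID lists for
deterministic output.

## Network inference

One random-forest regression per target gene on the expression of all
candidate TFs (a TF is excluded from its own predictor set), 1000 trees
and `max_features = "sqrt"`; edge weight = mean impurity-reduction
importance (permutation importance available as an option); per-target
predictability = out-of-bag R² (a constant target records importances 0
and R² 0). Per-target seeds derive from (global seed, target id), so
results are independent of row/column order. Because targets are fit
independently, restricting the target list is an exact shortcut when
only a subgraph is needed — the pipeline exploits this by fitting
forests only for the hypoxia-set and planted-edge targets.

Thresholding keeps the 5 highest-importance TFs per target with a
deterministic (importance desc, tf id asc) tie-break. The hypoxia
subgraph restricts targets to the hypoxia set and drops TFs regulating
fewer than 10 of them; extraction is idempotent. TF roles: with
`x` = standard-hypoxia targets (hypoxia set minus the CA-only/MCPCA-only
union) and `y` = targets in that union, a TF is "ethylene-mediated" iff
`y > (y_max/x_max)·x` strictly (points on the line are standard); the
maxima are taken over the subgraph's TFs after the degree filter. If no
TF has any standard target the slope is degenerate and any TF with
`y > 0` is ethylene-mediated. With `max_features = "sqrt"` an
exact-copy target gives its parent rank 1 with roughly a third of the
total importance (the share approaches 1 only as `max_features → 1.0`).

## Motif annotation

Exact IUPAC consensus matching (uppercased input; an input `N` matches
only a pattern `N`), both strands by default, overlapping hits all
reported, reverse-strand hits mapped to forward coordinates; 0-based
half-open coordinates internally, 1-based only in human-readable
output. This is presence/absence consensus matching rather than PWM
log-odds scanning: for a consensus like GCCVCYGGTTTY the match set *is*
the motif definition, and presence/absence is the quantity consumed
downstream. Translation uses the standard genetic code, stops at the
first stop codon, ignores a trailing partial codon, and maps N-containing
codons to X; the degron call is residues 1–6 ∈ {MCGGAI, MCGGAV}.
Upstream extraction takes the n bases 5′ of the translational start,
strand-aware, truncating (with a warning) at contig edges.

The published PCO/ERF VII sequence files are not redistributable here;
`synthetic_refs.py` generates clearly-labelled synthetic stand-ins that
reproduce only their reported motif structure (5/5 ERF VII degrons;
HRPE in all B-type and no A-type PCO promoters) so the annotation
workflow can be exercised end to end.

## Enrichment

Upper-tail hypergeometric per term, `P(X ≥ overlap)` with the declared
universe as background (term genes outside the universe are ignored for
the margins), Benjamini–Hochberg across tested terms. This is a generic
over-representation test, not a replica of any web service's settings;
the universe should be the post-filter expressed genes.

## Pipeline and determinism

`run_all` chains the stages under one config and writes TSV/JSON
outputs with sorted keys and no timestamps; two runs with the same
config and seed are byte-identical. Any stage failure aborts with the
stage name and cause. All randomness flows from explicit seeds through
per-purpose generator streams.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the default synthetic
study (2000 genes, 102 samples) for DE/set recovery and null
calibration, and measure planted-edge recovery on a seeded 100-target
subset of the 300 planted targets at the full 1000 trees — per-target
forests are independent, so the subset measurement is exact for the
edges it covers. Smaller configurations are used for orchestration and
unit tests.

## Known limitations

- The Wald test's normal tail is only approximately calibrated at two
  to three replicates; Bonferroni keeps family-wise false joint calls
  near zero, but a single false call in a 2000-gene null run remains a
  possible (few-percent) event by construction.
- The genes-pooled dispersion assumes most genes in a contrast share a
  dispersion scale; strong mean–dispersion trends would violate this.
- Consensus motif matching cannot score degenerate near-matches; a PWM
  scanner would be needed for threshold-based discovery.
- The simulator's independence assumptions (above) mean its recovery
  rates are upper bounds on what identical settings would achieve on
  real data.
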