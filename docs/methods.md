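# Methods

## Generative model of the nicking chemistry

A library is simulated molecule by molecule (implemented as vectorized
batches over all molecules of a contig):

1. **Fragmentation.** Per contig of length *L*, the fragment count is
   Poisson with mean `depth · L / frag_len_mean`, so `depth` is the expected
   fold-coverage. Starts are uniform; lengths are Normal(`frag_len_mean`,
   `frag_len_sd`) truncated below at `min_frag_len` and clipped at the
   contig end.
2. **Per-molecule methylation.** The methylome stores population
   methylation levels β per cytosine site. Sites may be registered as
   symmetric dyads (the two strand cytosines of a CpG, or the two internal
   Cs of a Dcm CCWGG motif); a dyad is realized jointly on a molecule —
   both strands methylated with probability β, neither otherwise — while
   lone sites realize independently. A unit participates only when it lies
   entirely inside the fragment.
3. **Excision nicking.** Each realized 5mC unit is nicked with probability
   `p_nick`. For a symmetrically methylated dyad at most one strand of the
   duplex is cleaved per molecule, the strand chosen by a fair coin —
   the single-strand-break behaviour of the glycosylase on symmetric
   substrates. 5hmC units are never nicked. Background (nonspecific) nicks
   arrive per base per strand with probability `p_bg`. The excised
   nucleotide is removed, so the downstream piece's 5′ terminus lies one
   nucleotide 3′ of the nicked C along the nicked strand.
4. **Positive design (DMN+).** Each strand is cut at its nicks; every
   nick-derived piece of length ≥ `min_frag_len` yields one read pair whose
   read 1 starts with the adaptor tag (`prefix_tag`, default `AAA`)
   followed by the piece's 5′ sequence. Molecules without nicks yield
   nothing (their original 5′ ends are dephosphorylated in the protocol and
   cannot ligate the second adaptor). Dense methylation therefore shreds a
   strand into sub-threshold pieces — the same mechanism that drives the
   depletion design.
5. **Negative design (DMN−).** A treated molecule survives iff it carries
   zero realized 5mC on either strand, except it escapes with probability
   `epsilon_escape`; survivors inside the `size_select` window yield read
   pairs spanning the fragment. The untreated input applies size selection
   only.
6. **Bisulfite-style truth.** Per site, total coverage is
   Poisson(`depth`) and unconverted counts Binomial(total, β); the
   methylation ratio is unconverted/total and missing (never 0) at
   uncovered sites.

Randomness uses one root seed with deterministically derived sub-streams
per stage (fragmentation, realization, nicking, background, survival), so a
rerun with the same parameters is byte-identical, including FASTQ output.

## Coordinate and offset conventions

Coordinates are 0-based half-open internally and in BED; every user-facing
table is 1-based. Because the excised nucleotide is removed, a read 5′
start sits at `site + 1` on the plus strand and `site − 1` on the minus
strand; the caller subtracts/adds a strand-aware `offset` (default 1,
configurable 0/1 since the upstream pipeline's convention is not fixed by
the assay) to report the cytosine itself. Cytosine context is classified
from the two bases 3′ of the C along its own strand (CpG / CHG / CHH with
H = A/C/T); bases off the contig end or `N` count as H, so a C without
readable neighbours is CHH — a conservative fallback for boundary sites.
`N` is never methylatable and never part of a motif match. CCWGG scanning
matches CCAGG and CCTGG explicitly; since the motif family is its own
reverse complement, one overlapping plus-strand scan yields every dyad as
(internal C at i+1 on +, i+3 on −).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `depth` | 30 | expected fold-coverage (fragments · mean length / genome) |
| `frag_len_mean`/`sd` | 350 / 70 bp | fragmentase-style insert distribution (150 / 30 in the cfDNA preset) |
| `min_frag_len` | 30 bp | shortest ligatable / mappable piece |
| `p_nick` | 0.5 | per-molecule excision probability at a realized 5mC |
| `p_bg` | 1e−6 /bp/strand | nonspecific nicking incl. residual cleanup failures |
| `epsilon_escape` | 0 | methylated-molecule survival in the depletion design |
| `prefix_tag` | `AAA` | adaptor-derived read-1 prefix; the filter trims exactly k bases |
| `size_select` | (100, 1000) bp | depletion-design size window |
| `min_intensity` | 5 | signal coverage threshold for site calling |
| pseudocount | 1 CPM | in all log2 ratios, to avoid infinities |

Deduplication is off by default for the positive design: identical start
positions are the signal itself, and collapsing them would destroy
quantification; an optional endpoint-level dedup is provided. Replicate
correlation uses a union join with zero imputation by default
(intersection available).

## Synthetic study material

The generators are pure functions of their arguments and seed. The λ-like
preset is a 50 kb, GC-0.5 genome enriched by motif planting to ~600 Dcm
dyads, each dyad at β ~ U(0.05, 0.95) — a partially methylated control with
known per-site truth. The TSS preset methylates CpG dyads at 0.8 in gene
bodies and 0.02 within ±1 kb of each TSS. The cohort generator plants
promoter DMRs (tumor β shifted down in a chosen fraction of regions, up in
the rest, clipped to [0, 1]) with one truncated-Gaussian jitter per sample
and region, and returns the planted truth table.

The cohort generator additionally plants condition-invariant,
constitutively hypomethylated background windows (`n_open`). In a real
library the mapped mass is dominated by genome-wide unmethylated DNA that
does not change between conditions, which is what keeps total-count (CPM)
normalization stable; a desk-scale genome consisting mostly of planted
DMRs would otherwise suffer a compositional artifact in which strong
asymmetric effects shift every null region's CPM. The cohort preset uses a
600 kb genome, 12 promoters of which 6 are planted (half hypo-, half
hypermethylated, β shift 0.5, jitter SD 0.01), 6 paired samples, and 150
invariant open windows.

What the synthetic material does **not** emulate: real chromosome sizes and
repeat content, CpG-island statistics, sequencing errors and quality
scores, PCR duplicates, mappability, or patient-level heterogeneity beyond
the per-sample jitter. Passing tests therefore demonstrate the internal
consistency of chemistry, callers and statistics under the stated model —
not performance on real libraries.

## Analysis choices

* Region counting follows featureCounts-like semantics: `any_overlap`
  counts a fragment once per region it touches; a `midpoint` rule is
  provided (and conserves totals over tiling windows). CPM uses total
  mapped fragments.
* Metagene profiles average per-base fragment coverage in equal bins over
  ±flank around TSS/TES, mirror minus-strand genes, and normalize the
  profile to mean 1; anchors whose window leaves the contig are skipped.
* Sliding-window correlation tiles the genome (step = window unless
  configured — "sliding" is read as non-overlapping tiles by default) and,
  within a window, averages only positions with depth ≥ `min_depth` in
  both samples; windows with no qualifying position are excluded.
* Differential regions: two-sided t-tests on per-region CPM — Welch for
  unpaired contrasts, the paired t for the paired tumor/adjacent design —
  with Benjamini–Hochberg correction across regions; raw p is emitted too,
  since selection rules in this assay family are often stated on raw p
  (e.g. p < 1e−4). A region with zero variance in both groups and equal
  means is reported t = 0, p = 1. log2 fold-changes use the 1-CPM
  pseudocount; `direction` is `hypo` when the condition of interest has the
  higher depletion-design signal. An optional log2-CPM scale for the tests
  is exposed because the upstream convention is not fixed.
* Volcano tables cap −log10 p at 320 and sort by |log2fc| then name;
  hierarchical clustering is average linkage on 1 − Pearson distance with
  SciPy's deterministic lowest-index tie-breaking, and constant-profile
  samples raise an error naming the sample.

## Numerical and degenerate-input conventions

Correlations require ≥ 3 paired observations and non-constant vectors,
otherwise an error is raised (never a silent NaN). Zero mapped fragments is
an error in counting; an empty genome yields an empty motif scan. Site
calling is stable under rerun (sorted by contig, position, strand). The
PFM reverse-complements minus-strand sites before accumulation and skips
(and counts) sites within `flank` of a contig edge.

## Benchmark scenario sizes

The packaged scenarios are sized for a single CPU: the replicate-
concordance run simulates two ~500k-fragment libraries over the 50 kb
control (~3500× coverage, matching the high-depth control setting); the
CpG-specificity run uses a 1 Mb genome at 150× (≈ 20 filtered read starts
per methylated site at the ≥ 5 calling threshold); the cohort and
clustering scenarios use 100× depletion libraries over 600 kb. At these
depths the replicate Pearson r is dominated by the between-site spread of
expected intensities, and the observed ~0.996 sits where the
variance-ratio argument σ²(μ)/(σ²(μ) + E[μ]) predicts.

## Known limitations

The simulator has no indel or quality-score realism, no adapter
read-through, and models incomplete enzymatic cleanup only through `p_bg`.
Whether the real pipeline's read-start offset is 0 or 1 nucleotide is not
fixed by the assay description, hence the configurable `offset`. The
depletion design's strand bookkeeping collapses to "zero realized 5mC on
the molecule"; a stricter template-strand-only variant would change escape
behaviour at heterogeneously methylated loci and is not implemented.
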