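# dmnseq

Simulation and analysis toolkit for glycosylase nick-site methylation
sequencing (DMN-seq).

The assay uses the plant 5-methylcytosine glycosylase DEMETER (DME), which
excises 5mC — and only 5mC, never 5hmC — by β/δ-elimination, cleaving one
strand of a symmetrically methylated duplex and leaving a downstream
5′-phosphate one nucleotide 3′ of the excised cytosine. Two library designs
build on that chemistry:

* **DMN+** (methylation enrichment): only fragments whose 5′ end was created
  by a DME nick are amplified, so the 5′ start positions of filtered read 1
  map 5mC at single-base resolution. The per-site statistic is the
  *enrichment intensity* — the count of read 5′ starts assigned to the site.
* **DMN−** (hypomethylation enrichment): any molecule carrying at least one
  realized 5mC is depleted, so sequencing coverage concentrates on DNA truly
  free of methylation (promoter troughs, hypomethylated tumor regions,
  low-input cfDNA).

The package provides, as importable modules and a thin CLI:

1. a **forward simulator** of both designs with complete per-molecule ground
   truth (`dmnseq.simulate`): fragmentation, per-molecule realization of
   population methylation levels β, dyad-aware single-strand nicking with
   probability `p_nick`, background nicks at `p_bg`, size selection and
   escape (`epsilon_escape`) for the depletion design, plus a bisulfite-style
   per-site counts generator;
2. **synthetic study material** (`dmnseq.synthetic`): random genomes
   optionally enriched to a target Dcm (CCWGG) dyad count, λ-like partially
   methylated Dcm methylomes, CpG methylomes with TSS hypomethylation
   troughs, paired tumor/healthy cohorts with planted DMRs, and spike-in
   oligos with known 5mC/5hmC positions;
3. the **analysis pipeline**: prefix-tag read filtering, start-signal
   extraction with strand-aware offset correction, single-base site calling
   with context annotation and position-frequency matrices
   (`dmnseq.callers`); region counting, CPM, log2 treated/input enrichment,
   strand-oriented metagene profiles, sliding-window correlations and sample
   clustering (`dmnseq.regions`); paired/Welch t-tests with
   Benjamini–Hochberg correction, volcano tables and rank-sum comparisons
   (`dmnseq.dmr`).

In the model, the expected intensity at a site with methylation level β and
molecule coverage *c* is ≈ *c* · β · `p_nick` / 2 (the factor 2 from
single-strand cleavage of the dyad), which is what makes the intensity a
quantitative readout of β; the DMN− survival probability of a fragment with
realized methylated units is 0 (up to `epsilon_escape`), giving the
hypomethylation enrichment log2((treated_cpm + c)/(input_cpm + c)).

## Worked example

```python
import dmnseq as d
from dmnseq import presets

# 50 kb λ-like control: ~600 Dcm dyads, each dyad at beta ~ U(0.05, 0.95)
genome, methylome = presets.lambda_like(7)

# two technical-replicate DMN+ libraries, ~500k fragments each
lib1 = d.build_dmnplus_library(genome, methylome, presets.lambda_params(1))
lib2 = d.build_dmnplus_library(genome, methylome, presets.lambda_params(2))

sig1 = d.extract_start_signals(lib1.truth, offset=1)
sig2 = d.extract_start_signals(lib2.truth, offset=1)
print(round(d.replicate_correlation(sig1, sig2, mode="union"), 4))

called = d.call_sites(sig1, genome, min_intensity=5)
table, r = d.intensity_vs_beta(called, methylome)
print(len(called), round(r, 3))
```

prints

```
0.9955
1200 0.974
```

— the two replicates agree site-by-site with Pearson r = 0.9955 over the
union of detected sites, all 1200 dyad cytosines (600 dyads × 2 strands) are
recovered at signal coverage ≥ 5, and their intensities track the true
methylation levels with r = 0.974.

The same objects drive the CLI:

```bash
dmnseq simulate-plus --genome genome.fasta --methylome methylome.tsv \
    --depth 100 --seed 1 --outdir run/
dmnseq call-sites --genome genome.fasta --placements run/truth.tsv \
    --min-intensity 5 --outdir run/calls/
```

Every run writes a `manifest.json` echoing seeds, thresholds and input/output
checksums, so identical configurations reproduce identical outputs.

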