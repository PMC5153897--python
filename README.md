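# nimap — nuclear-interference maps for a circular target genome

Low-abundance variant calling in mitochondrial DNA (heteroplasmy at minor
allele frequencies of ~1% and below) is vulnerable to a specific artifact:
the nuclear genome contains transposed copies of mitochondrial sequence
(NUMTs) plus many short incidental look-alikes, so sequencing reads that
actually originate from nuclear DNA can map perfectly — or almost
perfectly — to the mitochondrial reference and masquerade as rare variants.
`nimap` quantifies this risk position by position.

## What it computes

Given a background genome (e.g. nuclear chromosomes) and a circular target
genome (e.g. mtDNA), the background is decomposed into all overlapping
windows of length *W* (default 450) on both strands, de-replicated with
multiplicities, and every target start position *s* is searched for

* **LCS(s)** — the longest prefix of the target sequence starting at *s*
  that occurs *exactly* somewhere in the background, and
* **LSS(s)** — the same with at most one mismatch (substitution by
  default; a one-edit Levenshtein mode is available),

wrapping past the origin and capped at *W* (the pipeline re-runs with *W*
doubled if any value hits the cap). A start with length *L(s)* covers
positions *s … s+L(s)−1*; per position the **max** and **average**
covering lengths form four tracks (`lcs_max`, `lcs_avg`, `lss_max`,
`lss_avg`) — the interference map. A placeholder `N` in the target (kept
in the mitochondrial reference only to preserve historical numbering) is
removed before searching and its track values restored from the preceding
position.

From the map, `nimap` derives:

* per-gene maxima and averages of the tracks;
* **safe read-length fractions** — the fraction of positions *p* with
  `lss_max(p) ≤ R`, where a read of length *R* cannot be wholly contained
  in a nuclear look-alike;
* **primer specificity reports** — for a primer bound at a given site:
  the number of background occurrences within one mismatch, the
  one-mismatch extension length from its 3′-growing start, and the count
  and percentage of target positions with a strictly smaller `lss_max`;
* minimum-similarity windows (candidate sites for target-specific
  primers) and the per-position length histogram;
* least-squares fits of the track length densities by mixtures of
  linearly transformed Poisson components
  G(l) = Σᵢ αᵢ βᵢ P(λᵢ, βᵢ l), Σᵢ αᵢ = 1,
  with P the Gamma-extended Poisson pmf — 3k−1 free parameters, smoothed
  first with a 21-tap Gaussian kernel (σ = 3 grid units).

A seeded simulator generates background/target pairs with implanted,
mutated target segments ("age classes") and ground truth, so the whole
pipeline is testable without reference downloads, and every indexed
search is cross-checked against an independent brute-force oracle.

## Worked example

```python
import nimap as nm

target, background, truths = nm.simulate_pair(
    42, target_length=1000, background_length=20000,
    implants=[(2, 150, 250, 0.0), (2, 150, 250, 0.03), (2, 150, 250, 0.10)],
)
imap = nm.run_map(background, target)
print("global max LCS:", int(imap.lcs_max.max()))
print("global max LSS:", int(imap.lss_max.max()))
for R in (36, 76, 150):
    print(f"safe fraction at R={R}: {100*nm.safe_fraction(imap, R):.1f}%")
```

prints

```
global max LCS: 170
global max LSS: 171
safe fraction at R=36: 46.3%
safe fraction at R=76: 53.8%
safe fraction at R=150: 65.7%
```

The three implant classes (0%, 3%, 10% per-base divergence) leave exact
matches up to 170 bases; 46.3% of target positions are already safe with
36-base reads, rising with read length. Per-gene summaries, primer
candidates and a mixture fit of the length density:

```python
genes = [nm.GeneAnnotation("geneA", 1, 500), nm.GeneAnnotation("geneB", 501, 1000)]
print(nm.gene_summary(imap, genes).to_string(index=False))
print(nm.find_min_regions(imap, window_len=25, top_n=1)[0])
l, F = nm.density_from_track(imap.lss_avg)
print(nm.fit_mixture(l, F, k=2, seed=17))
```

```
 name  length  start  end  max_lcs  avg_lcs  max_lss  avg_lss
geneA     500      1  500      168     39.9      170     43.9
geneB     500    501 1000      170     67.0      171     75.7
{'start': 93, 'end': 117, 'max_lss': 11, 'mean_lss': 10.48}
MixtureModel(k=2, alpha=(0.570..., 0.429...), beta=(0.0506..., 0.8796...),
             lam=(5.934..., 9.852...), error=5.93e-04)
```

The 25-base window at positions 93–117, where the longest one-mismatch
shared subsequence is only 11 bases, is the best candidate site for a
target-specific primer.

The same workflow is available from the shell; full-scale references can
be supplied directly:

```sh
nimap simulate --seed 42 --target-len 16000 --background-len 200000 \
      --implants "5:200-400:0.0,5:200-400:0.02,5:200-400:0.10" --out-dir sim/
nimap map --background sim/background.fa --target sim/target.fa --circular \
      --window 450 --out map.tsv --bedgraph-dir tracks/
nimap readlen --map map.tsv --lengths 36,76,150
nimap summarize --map map.tsv --genes genes.tsv --out table.tsv
nimap fit-mixture --map map.tsv --track lss_avg --k 2 --seed 17 --out fit.json
```

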