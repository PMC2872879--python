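# motifrank

Evidence-ranked de novo motif discovery for regulatory genomics.

Given a genome-wide set of putative regulatory regions (promoters, ChIP
peaks, open-chromatin regions, 3' UTRs) and a quantitative evidence score
per region — ChIP-chip binding *P*-values, ChIP-seq peak densities, or
expression fold-changes from regulator perturbations — `motifrank` searches
the space of degenerate IUPAC consensus motifs for the motif whose presence
best concentrates the evidence.  It is aimed at analyses where the region
set is large (thousands to tens of thousands of regions) and no significance
cutoff should be imposed up front: the whole evidence vector drives the
search.

## Method in brief

A motif *m* over the IUPAC alphabet {A,C,G,T,W,S,R,Y,K,M,N} partitions the
region set *S* (|S| = d) into a positive set S⁺(m) — regions with at least
one exact match on either DNA strand (forward strand only in RNA mode) —
and its complement.  Candidate motifs are scored with a gene-set-enrichment
style statistic on the evidence vector E = (e₁,…,e_d):

    J(m) = √n · ( mean(E⁺) − mean(E) ) / sd(E),        n = |S⁺(m)|

subject to a ≤ n ≤ b·d (defaults a = 20, b = 0.15; preset `chip-seq` uses
a = 100, b = 0.30), since tiny or near-global positive sets have unstable
averages.  The search starts from all non-degenerate 5-mers (pooled with
reverse complements: 512 canonical seeds) and greedily evolves each seed by
single-base extension, single-side truncation, and single-position
degeneracy widening until no move improves J.  Matching is served by a
suffix array over the concatenated regions, so each candidate is scored in
near-constant time.  Evidence transforms include a Bayes-factor calibration
of *P*-values, ln B₁₀(p) with B₁₀(p) = 1/(−e·p·ln p), a log-odds transform
of peak densities against the 85th-percentile background, and −log₂
fold-changes.  Redundant predictions are clustered (PSSM similarity ≥ 0.75
plus significant co-occurrence within τ = 50 nt) and each cluster is
summarized by a score-weighted PSSM.  Significance of the top score comes
from a permutation null (evidence shuffled across regions, search re-run)
summarized by a maximum-likelihood Gamma fit for tail P-values.

Orthologous sequences from related species can optionally refine positive
sets: a region counts as a target only if the motif also occurs in every
available ortholog of that region.

## Worked example

Generate a synthetic dataset (500 regions of 200 nt, the 7-mer TGACTCA
planted in 50 of them, evidence = 3·indicator + N(0,1)) and search it:

```sh
motifrank simulate --seed 7 --out-dir data
motifrank search --fasta data/regions.fa --evidence data/evidence.tsv \
    --evidence-type raw --preset chip-chip --top-n 25 --out-dir out
```

which prints

```
wrote 500 regions (50 planted) to data
422 distinct motifs from 500 regions
top motif: TGACTCA  J=12.599  targets=62
```

The top-ranked motif is exactly the planted consensus; its enrichment score
J = 12.60 means the 62 predicted target regions carry evidence about 12.6
null standard errors above a random set of the same size.  `out/motifs.tsv`
holds the full ranking (the runners-up TGAGTCA and TGASTCA are the reverse
complement and a degenerate variant of the same site), `out/clusters.tsv`
groups them into one cluster under TGACTCA, and `out/clusters.meme` holds
cluster PSSMs in MEME minimal format.  Adding `--n-perm 100` attaches
permutation P-values and writes the null dump `out/null.tsv`.

Other subcommands: `motifrank prep` (ChIP-seq peak normalization, ensemble
region definition, evidence assignment), `motifrank null` (stand-alone
permutation null), `motifrank evaluate` / `motifrank rates` (benchmark
bookkeeping against a known consensus).

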