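# mhc2popkit

Population-genetic characterization of MHC class II exon 2 (the β1 /
peptide-binding domain) from clone-based genotyping data, written for
molecular ecologists working on non-model vertebrates — seabirds in
particular — who amplify a short multi-locus fragment (typically 198 bp /
66 codons), clone it, and need every downstream step from allele validation
to demographic inference in one reproducible toolchain.

## What it computes

**Allele validation.** Cloning amplifies polymerase errors along with real
alleles, so haplotypes are classified by the standard count rules: a
haplotype found in ≥ 2 individuals is a *putative true* allele; a
single-individual haplotype needs ≥ 3 identical clones to be a *unique*
allele; both require ≥ 2 independent PCRs; a haplotype whose translation
contains an internal stop codon is a *pseudogene*; everything else is an
*artifact*.

**Diversity.** Segregating sites *S*, mean pairwise differences *K*,
per-site nucleotide diversity π = *K*/*L*, haplotype diversity
*Hd* = n/(n−1)·(1 − Σpᵢ²), and nucleotide / amino-acid p-distances with
codon-bootstrap standard errors — all restrictable to a codon partition
(peptide-binding sites vs. the rest).

**Selection.** Nei–Gojobori dN/dS with equal-weight pathway averaging for
multi-hit codons and the Jukes–Cantor correction
d = −¾ ln(1 − 4p/3); Z-tests of dN = dS with bootstrap variances
(two-tailed, and one-tailed for diversifying dN > dS and purifying
dN < dS); Wu–Kabat variability W = N·k/n per residue with conserved-run
detection.

**Demography.** Tajima's *D*, Fu's *F*ₛ (Ewens sampling formula with
log-space Stirling numbers), and Ramos-Onsins & Rozas *R*₂, each with
p-values from simulated constant-size coalescent nulls; the mismatch
distribution fitted to the sudden-expansion model (τ, θ₀, θ₁) by least
squares, with SSD and raggedness goodness-of-fit and parametric-bootstrap
CIs; expansion time t = τ/(2uL) for a substitution rate u per site.

**Networks.** ε = 0 minimum spanning networks over Hamming distances (all
co-minimal alternative edges retained and flagged) and a two-cluster locus
partition with site-bootstrap support, for fragments co-amplified from
duplicated loci.

**Synthetic data.** A clone-library generator (two divergent loci,
nonsynonymous variation concentrated at designated peptide-binding codons,
stop-codon pseudogenes, per-base PCR error) with an exact truth table, and
a coalescent simulator under the sudden-expansion demography — so every
stage is testable without downloads.

## Worked example

```python
from mhc2popkit import (
    simulate_clone_library, classify_haplotypes, summarize_catalog,
    make_alignment, gull_pbs_partition, ng_dn_ds, diversity_summary,
    expansion_time,
)

clones, truth = simulate_clone_library(n_individuals=68, seed=1)
cat = classify_haplotypes(clones)
print(summarize_catalog(cat)["class_counts"])

aln = make_alignment([(e.haplotype_id, e.seq) for e in cat.coding()])
div = diversity_summary(aln, bootstrap_reps=200, seed=1)
print(f"n={div.n}  S={div.S}  K={div.K:.3f}  pi={div.pi:.3f}")

res = ng_dn_ds(aln, gull_pbs_partition(), bootstrap_reps=1000, seed=1)
print(f"PBS dN={res.dN:.3f}  dS={res.dS:.3f}  omega={res.omega:.2f}  "
      f"p(dN>dS)={res.p_pos:.4f}")

print(expansion_time(19.82, 0.00177, 198).t_rounded, "yr BP")
```

prints

```
{'putative_true': 50, 'unique': 6, 'pseudogene': 2, 'artifact': 27}
n=56  S=116  K=14.686  pi=0.074
PBS dN=0.097  dS=0.021  omega=4.52  p(dN>dS)=0.0005
28 yr BP
```

The 68 simulated gulls carry 58 recoverable alleles (the default per-base
PCR error of 10⁻⁴ additionally produces 27 error haplotypes, all correctly
rejected as artifacts); dN exceeds dS more than four-fold at the
peptide-binding codons, the signature of pathogen-driven balancing
selection the partition is designed to expose; and a fitted expansion
parameter τ = 19.82 over 198 sites at the chicken calibration rate
(0.00177 substitutions/site/Myr) converts to a 28-year-old expansion.

A command-line interface mirrors the library
(`mhc2popkit validate-alleles | diversity | selection | network |
neutrality | mismatch | simulate | run`); `mhc2popkit run --config
config.yaml` executes the whole pipeline with one fanned-out seed and
writes one JSON/TSV per stage.

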