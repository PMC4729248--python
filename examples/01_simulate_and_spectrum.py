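"""Simulate a small transcriptome-SNP dataset and build the folded joint SFS.

The generator draws one coalescent genealogy per contig under the best-fit
three-lineage demography, so sites within a contig are linked, and layers on
annotation classes, site qualities and sporadic missing genotypes.  The
filtering step keeps high-quality, fully genotyped synonymous sites — the
same rules used ahead of the real analysis — and the spectrum tallies them
by per-population minor-allele count.
"""

import demosfs as d

cfg = d.SimConfig(n_contigs=800, seed=11)
variants = d.simulate_variants(cfg)
print(f"simulated {variants.n_sites} SNPs on {variants.n_contigs} contigs")

kept = d.filter_variants(variants, min_quality=20.0)
print(f"retained {kept.n_sites} complete-genotype synonymous SNPs "
      f"(quality >= 20)")

afs = d.build_joint_sfs(kept, ("MOJ", "SIN", "SON"), fold=True)
print(f"folded joint SFS shape {afs.shape}, {afs.sum():.0f} segregating sites")
print("MOJ marginal (minor-allele counts 0..4):")
print(d.marginalize_pair(afs, "MOJ", "SIN").counts.sum(axis=1))
# Entry i of the marginal is the number of sites where the minor allele
# appears i times among the 4 Mojave chromosomes; the masked corners hold
# sites invisible to (or monomorphic in) the sample.
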