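"""Synthetic transcriptome-SNP datasets with the structure the analysis assumes.

The generator emulates the statistical shape of the study data — a few
thousand expressed-sequence contigs carrying on average ~2.6 retained
synonymous SNPs each, genotyped in two diploids per lineage — without any
read-level simulation.  Per contig one coalescent genealogy is drawn under
the configured demography (sites within a contig are fully linked, contigs
are independent), mutations are dropped at an intensity tuned so that the
*retained* synonymous variants hit the target density, and nuisance
structure (nonsynonymous/ambiguous annotations, sub-threshold site
qualities, sporadic missing genotypes) is layered on so the filtering stage
has real work to do.

``sample_sfs_poisson`` is the linkage-free fast path: independent Poisson
draws per spectrum cell, sharing the same cellwise expectations as the
full generator under the same demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine, models
from .spectra import MISSING, JointSFS, VariantTable

#: Best-fit six-parameter demography used as the default simulation truth:
#: sizes in individuals and divergence times in years, with the 25-year
#: generation time, expressed in coalescent-scaled units.
_NA = 336_200.0
_G = 25.0
TRUE_TRIO_PARAMS = {
    "nu_moj": 128_400.0 / _NA,
    "nu_sinson": 149_600.0 / _NA,
    "nu_son": 600_000.0 / _NA,
    "T1": (5.9e6 - 5.65e6) / (2 * _G * _NA),
    "T2": 5.65e6 / (2 * _G * _NA),
}

POPS = ("MOJ", "SIN", "SON")


@dataclass
class SimConfig:
    """Configuration of the synthetic dataset generator."""

    model: str = "trio_6param"
    #: scaled true parameters (free parameters of ``model``, by name)
    params: dict = field(default_factory=lambda: dict(TRUE_TRIO_PARAMS))
    n_contigs: int = 7665
    #: mean *retained synonymous* SNPs per contig after default filtering
    mean_syn_snps_per_contig: float = 20126 / 7665
    diploids_per_pop: int = 2
    frac_nonsynonymous: float = 0.20
    frac_ambiguous: float = 0.05
    prob_low_quality: float = 0.05
    #: per-genotype missing probability (a single missing call drops the
    #: site under complete-genotype filtering)
    missing_rate: float = 0.02
    #: within-contig recombination rate per unit time (fully linked contigs
    #: by default, matching the bootstrap's exchangeable-contig assumption)
    recombination_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 0 or self.diploids_per_pop < 1:
            raise ValueError("counts must be positive")
        if self.mean_syn_snps_per_contig <= 0:
            raise ValueError("mean SNPs per contig must be positive")
        bad = self.frac_nonsynonymous + self.frac_ambiguous
        if not 0 <= bad < 1:
            raise ValueError("annotation fractions must leave synonymous mass")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible datasets")


def _free_param_vector(spec, params: dict) -> np.ndarray:
    missing = [p for p in spec.param_names if p not in params]
    if missing:
        raise ValueError(f"params missing {missing} for model {spec.name}")
    return np.array([params[p] for p in spec.param_names], dtype=float)


def simulate_variants(cfg: SimConfig) -> VariantTable:
    """Simulate a linked-SNP variant table under the configured demography.

    One genealogy per contig; the per-contig mutation intensity is set so
    the expected number of synonymous, high-quality, fully genotyped SNPs
    per contig equals ``cfg.mean_syn_snps_per_contig``.  Deterministic for a
    given seed.
    """
    import msprime

    cfg.validate()
    spec = models.get_model(cfg.model)
    # population labels follow the model's own pop_ids (two-population
    # configurations are allowed for method studies)
    pvec = _free_param_vector(spec, cfg.params)
    demography = models.to_demography(spec, pvec)
    npop = len(spec.pop_ids)
    sizes = (2 * cfg.diploids_per_pop,) * npop

    # expected total branch length per genealogy (in 2*Na generations):
    # twice the sum of the per-unit-theta spectrum over all cells
    exp_sfs = engine.expected_sfs(spec, pvec, sizes, fold=False)
    total_branch = 2.0 * exp_sfs.counts.sum()
    n_genotypes = npop * cfg.diploids_per_pop
    retain = ((1 - cfg.frac_nonsynonymous - cfg.frac_ambiguous)
              * (1 - cfg.prob_low_quality)
              * (1 - cfg.missing_rate) ** n_genotypes)
    mu_contig = cfg.mean_syn_snps_per_contig / (retain * total_branch)

    rng = np.random.default_rng(cfg.seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    samples = {p: cfg.diploids_per_pop for p in spec.pop_ids}
    reps = msprime.sim_ancestry(
        samples=samples, demography=demography, num_replicates=cfg.n_contigs,
        recombination_rate=cfg.recombination_rate, sequence_length=1,
        discrete_genome=False, random_seed=anc_seed)

    width = max(4, len(str(max(cfg.n_contigs, 1))))
    sample_names = [f"{p}_{i}" for p in spec.pop_ids
                    for i in range(cfg.diploids_per_pop)]
    popmap = {f"{p}_{i}": p for p in spec.pop_ids
              for i in range(cfg.diploids_per_pop)}

    mut_rng = np.random.default_rng(mut_seed)
    rows: list[tuple] = []
    dosage_rows: list[np.ndarray] = []
    for c, ts in enumerate(reps):
        ts = msprime.sim_mutations(
            ts, rate=mu_contig, discrete_genome=False,
            model=msprime.BinaryMutationModel(),
            random_seed=int(mut_rng.integers(1, 2**31 - 1)))
        contig = f"c{c + 1:0{width}d}"
        if ts.num_sites == 0:
            continue
        geno = ts.genotype_matrix()  # sites x haploid samples
        # haploid sample columns come grouped per individual
        dosages = geno.reshape(geno.shape[0], -1, 2).sum(axis=2)
        for s in range(geno.shape[0]):
            rows.append((contig, s + 1, "A", "G"))
            dosage_rows.append(dosages[s])

    n_sites = len(rows)
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    # site qualities: mostly comfortably above the Phred-20 cutoff, a
    # configured fraction below it
    low = rng.random(n_sites) < cfg.prob_low_quality
    qual = rng.uniform(20.0, 60.0, size=n_sites)
    qual[low] = rng.uniform(10.0, 20.0, size=int(low.sum()))
    df["qual"] = np.round(qual, 2)
    ann = rng.choice(
        ["synonymous", "nonsynonymous", "ambiguous"], size=n_sites,
        p=[1 - cfg.frac_nonsynonymous - cfg.frac_ambiguous,
           cfg.frac_nonsynonymous, cfg.frac_ambiguous])
    df["annotation"] = ann
    dos = (np.stack(dosage_rows).astype(np.int64) if n_sites
           else np.empty((0, n_genotypes), dtype=np.int64))
    miss = rng.random(dos.shape) < cfg.missing_rate
    dos[miss] = MISSING
    for j, s in enumerate(sample_names):
        df[s] = dos[:, j] if n_sites else np.array([], dtype=np.int64)
    return VariantTable(df, popmap)


def sample_sfs_poisson(expected: JointSFS, theta: float, seed: int) -> JointSFS:
    """Independent Poisson draw per unmasked cell with mean ``theta * m_c``."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(expected.counts)
    keep = ~expected.mask
    counts[keep] = rng.poisson(theta * expected.counts[keep])
    return JointSFS(counts, expected.mask.copy(), expected.folded, expected.pop_ids)


# ---------------------------------------------------------------------------
# plain-text outputs


def write_vcf(vt: VariantTable, path) -> None:
    """Write the variant table as an uncompressed VCF 4.2 file."""
    samples = vt.samples
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in vt.df["contig"].unique():
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dos = vt.dosage_matrix()
        for i, row in enumerate(vt.df.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in dos[i])
            fh.write(f"{row.contig}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:g}\t.\t.\tGT\t{gts}\n")


def write_annotation(vt: VariantTable, path) -> None:
    """Write the 3-column (contig, position, class) annotation TSV."""
    vt.df[["contig", "pos", "annotation"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_popmap(vt: VariantTable, path) -> None:
    with open(path, "w") as fh:
        for s, p in vt.popmap.items():
            fh.write(f"{s}\t{p}\n")
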