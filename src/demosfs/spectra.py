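"""Joint site-frequency-spectrum containers and variant-table handling.

The two central data structures of the package live here:

``VariantTable``
    A thin wrapper around a :class:`pandas.DataFrame` of biallelic SNP
    genotypes (one row per site, one alt-allele-dosage column per sample)
    together with the sample-to-population map.  Dosages are 0/1/2 copies
    of the alternate allele; missing genotypes are coded ``-1``.

``JointSFS``
    A k-dimensional array of site counts indexed by the per-population
    allele count of each site, with an entry mask and a folded flag.  The
    all-reference and all-alternate corner cells are always masked: they
    correspond to sites that are monomorphic in the sample and carry no
    information for frequency-spectrum likelihoods.

Folding converts the spectrum to minor-allele counts, the appropriate
representation when the ancestral allele is unknown.  Cells whose total
allele count exceeds half the total sample size are added into their
complement and masked; cells exactly at half are counted once, with the
lexicographically smaller member of each complementary pair retained.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

ANNOTATION_CLASSES = ("synonymous", "nonsynonymous", "other", "ambiguous")

_META_COLUMNS = ["contig", "pos", "ref", "alt", "qual", "annotation"]


# ---------------------------------------------------------------------------
# VariantTable


@dataclass
class VariantTable:
    """Per-site genotypes plus contig, quality and annotation metadata.

    Parameters
    ----------
    df
        One row per biallelic site with columns ``contig``, ``pos`` (1-based),
        ``ref``, ``alt``, ``qual`` (Phred-scaled site quality), ``annotation``
        (one of ``synonymous``/``nonsynonymous``/``other``/``ambiguous``) and
        one integer dosage column per sample (0, 1, 2 or -1 for missing).
    popmap
        Mapping from sample name to population label.
    """

    df: pd.DataFrame
    popmap: dict[str, str]

    def __post_init__(self) -> None:
        missing_cols = [c for c in _META_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        for s in self.popmap:
            if s not in self.df.columns:
                raise ValueError(f"sample {s!r} from popmap has no dosage column")

    @property
    def samples(self) -> list[str]:
        return list(self.popmap)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.popmap.values():
            seen.setdefault(p)
        return list(seen)

    def samples_for(self, pop: str) -> list[str]:
        return [s for s, p in self.popmap.items() if p == pop]

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def n_contigs(self) -> int:
        return self.df["contig"].nunique()

    def dosage_matrix(self) -> np.ndarray:
        """Sites x samples integer dosage matrix (missing = -1)."""
        return self.df[self.samples].to_numpy(dtype=np.int64)

    def subset(self, row_mask: np.ndarray) -> "VariantTable":
        return VariantTable(self.df.loc[row_mask].reset_index(drop=True), dict(self.popmap))


def filter_variants(
    raw: VariantTable,
    min_quality: float = 20.0,
    require_complete: bool = True,
    synonymous_only: bool = True,
) -> VariantTable:
    """Apply the site filters used ahead of spectrum construction.

    Retains records with site quality at or above ``min_quality``, with a
    called genotype for every sample when ``require_complete`` is set, and
    annotated as unambiguously synonymous when ``synonymous_only`` is set.
    Records with malformed dosages (outside {0, 1, 2, -1}) are rejected with
    a logged reason.  Record order is preserved.
    """
    if not np.isfinite(min_quality):
        raise ValueError("min_quality must be finite")
    dos = raw.dosage_matrix()
    valid = np.all(np.isin(dos, (0, 1, 2, MISSING)), axis=1)
    n_malformed = int((~valid).sum())
    if n_malformed:
        logger.warning("rejected %d records with malformed dosage", n_malformed)
    keep = valid & (raw.df["qual"].to_numpy(dtype=float) >= min_quality)
    if require_complete:
        keep &= np.all(dos != MISSING, axis=1)
    if synonymous_only:
        keep &= (raw.df["annotation"] == "synonymous").to_numpy()
    out = raw.subset(keep)
    logger.info("filter_variants retained %d of %d records", out.n_sites, raw.n_sites)
    if out.n_sites == 0:
        logger.warning("filter_variants produced an empty table")
    return out


# ---------------------------------------------------------------------------
# JointSFS


@dataclass
class JointSFS:
    """k-dimensional (joint) site frequency spectrum.

    ``counts[i1, ..., ik]`` is the number (or expected number) of sites at
    which population j carries ``ij`` copies of the derived (or minor, if
    ``folded``) allele.  ``mask`` is True for cells excluded from
    likelihoods.  The shape is ``(n1+1, ..., nk+1)`` for nj sampled
    chromosomes in population j.
    """

    counts: np.ndarray
    mask: np.ndarray
    folded: bool
    pop_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.counts.shape != self.mask.shape:
            raise ValueError("counts and mask shapes differ")
        if len(self.pop_ids) != self.counts.ndim:
            raise ValueError("pop_ids length must match dimensionality")
        self.pop_ids = tuple(self.pop_ids)

    # -- basic properties ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.shape)

    @property
    def total_samples(self) -> int:
        return sum(self.sample_sizes)

    def sum(self) -> float:
        """Total mass over unmasked cells."""
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.counts.copy(), self.mask.copy(), self.folded, self.pop_ids)

    def scaled(self, factor: float) -> "JointSFS":
        out = self.copy()
        out.counts *= factor
        return out

    # -- construction helpers ----------------------------------------------

    @staticmethod
    def corner_mask(shape: tuple[int, ...]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[(0,) * len(shape)] = True
        mask[tuple(s - 1 for s in shape)] = True
        return mask

    @classmethod
    def zeros(cls, sample_sizes: tuple[int, ...], pop_ids: tuple[str, ...],
              folded: bool = False) -> "JointSFS":
        shape = tuple(n + 1 for n in sample_sizes)
        return cls(np.zeros(shape), cls.corner_mask(shape), folded, pop_ids)

    # -- flat-file I/O ------------------------------------------------------

    def to_file(self, path) -> None:
        """Write the de-facto flat SFS text dialect.

        Line 1: shape integers, ``folded``/``unfolded`` and quoted pop ids;
        line 2: counts in row-major order; line 3: mask bits (1 = masked).
        """
        with open(path, "w") as fh:
            shape = " ".join(str(s) for s in self.shape)
            ids = " ".join(f'"{p}"' for p in self.pop_ids)
            fh.write(f"{shape} {'folded' if self.folded else 'unfolded'} {ids}\n")
            fh.write(" ".join(repr(float(v)) for v in self.counts.ravel()) + "\n")
            fh.write(" ".join("1" if m else "0" for m in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().split()
            shape = []
            i = 0
            while i < len(header) and header[i].isdigit():
                shape.append(int(header[i]))
                i += 1
            if i == len(header) or header[i] not in ("folded", "unfolded"):
                raise ValueError(f"malformed SFS header in {path}")
            folded = header[i] == "folded"
            ids = tuple(t.strip('"') for t in header[i + 1:])
            if len(ids) != len(shape):
                ids = tuple(f"pop{j}" for j in range(len(shape)))
            counts = np.array(fh.readline().split(), dtype=float).reshape(shape)
            mask = np.array(fh.readline().split(), dtype=int).astype(bool).reshape(shape)
        return cls(counts, mask, folded, ids)


def build_joint_sfs(
    variants: VariantTable,
    pop_order: tuple[str, ...] | list[str],
    fold: bool = True,
) -> JointSFS:
    """Tally filtered variants into a joint SFS.

    Cell ``(i1, ..., ik)`` counts the sites whose summed alt-allele dosage in
    population j equals ``ij``.  Sites that are monomorphic within the sample
    land in the (masked) corner cells and are thereby excluded from
    likelihoods, which keeps bootstrap bookkeeping simple.  With ``fold`` the
    minor-allele spectrum is returned.
    """
    pop_order = tuple(pop_order)
    pops_present = set(variants.popmap.values())
    if set(pop_order) != pops_present:
        raise ValueError(f"pop_order {pop_order} does not cover populations {sorted(pops_present)}")
    dos = variants.dosage_matrix()
    if np.any(dos == MISSING):
        raise ValueError("build_joint_sfs requires complete genotypes; run filter_variants first")
    samples = variants.samples
    sizes = []
    per_pop_counts = []
    for pop in pop_order:
        cols = [samples.index(s) for s in variants.samples_for(pop)]
        sizes.append(2 * len(cols))
        per_pop_counts.append(dos[:, cols].sum(axis=1))
    shape = tuple(n + 1 for n in sizes)
    sfs = JointSFS.zeros(tuple(sizes), pop_order)
    if variants.n_sites:
        flat = np.ravel_multi_index(np.stack(per_pop_counts), shape)
        np.add.at(sfs.counts.ravel(), flat, 1.0)
    n_mono = sfs.counts[(0,) * len(shape)] + sfs.counts[tuple(s - 1 for s in shape)]
    if n_mono:
        logger.info("build_joint_sfs: %d monomorphic-in-sample sites routed to masked corners",
                    int(n_mono))
    if fold:
        sfs = fold_sfs(sfs)
    return sfs


@lru_cache(maxsize=None)
def _fold_plan(shape: tuple[int, ...]):
    """Flat-index folding plan: complement index, kept cells, self-complements."""
    n = tuple(s - 1 for s in shape)
    half = sum(n) / 2.0
    size = int(np.prod(shape))
    comp_idx = np.empty(size, dtype=np.int64)
    keep = np.zeros(size, dtype=bool)
    selfc = np.zeros(size, dtype=bool)
    for cell in itertools.product(*(range(s) for s in shape)):
        i = np.ravel_multi_index(cell, shape)
        comp = tuple(nj - c for nj, c in zip(n, cell))
        comp_idx[i] = np.ravel_multi_index(comp, shape)
        t = sum(cell)
        keep[i] = t < half or (t == half and cell <= comp)
        selfc[i] = cell == comp
    return comp_idx, keep, selfc


def fold_sfs(sfs: JointSFS) -> JointSFS:
    """Fold onto minor-allele counts.

    Each cell and its complement are summed into whichever of the two has
    total allele count at most half the total sample size; exact-half pairs
    are counted once in the lexicographically smaller member, and
    self-complementary cells are left untouched.  Total unmasked mass is
    conserved and the mask is propagated (a folded cell is masked if both
    contributors were masked, or if it is a corner).
    """
    if sfs.folded:
        logger.warning("fold_sfs called on an already-folded spectrum; returning a copy")
        return sfs.copy()
    shape = sfs.shape
    comp_idx, keep, selfc = _fold_plan(shape)
    c = sfs.counts.ravel()
    m = sfs.mask.ravel()
    counts = np.where(keep, c + np.where(selfc, 0.0, c[comp_idx]), 0.0)
    mask = ~keep | np.where(selfc, m, m & m[comp_idx])
    counts = counts.reshape(shape)
    mask = mask.reshape(shape) | JointSFS.corner_mask(shape)
    counts[mask] = 0.0
    return JointSFS(counts, mask, True, sfs.pop_ids)


def marginalize_pair(sfs: JointSFS, pop_a: str, pop_b: str) -> JointSFS:
    """Two-dimensional marginal spectrum for a pair of populations.

    Counts are summed over the remaining axes (masked cells contribute
    nothing); a marginal cell is masked only when every contributing cell
    was masked.  Total unmasked mass is conserved.
    """
    for p in (pop_a, pop_b):
        if p not in sfs.pop_ids:
            raise ValueError(f"unknown population {p!r}; have {sfs.pop_ids}")
    axes = (sfs.pop_ids.index(pop_a), sfs.pop_ids.index(pop_b))
    other = tuple(i for i in range(sfs.counts.ndim) if i not in axes)
    contrib = np.where(sfs.mask, 0.0, sfs.counts)
    counts = contrib.sum(axis=other)
    mask = sfs.mask.all(axis=other)
    if axes[0] > axes[1]:  # summing keeps the original axis order
        counts, mask = counts.T, mask.T
    return JointSFS(counts, mask, sfs.folded, (pop_a, pop_b))


def anscombe_residuals(model: JointSFS, data: JointSFS,
                       sign: str = "model_minus_data") -> np.ma.MaskedArray:
    """Variance-stabilised Poisson residuals between model and data spectra.

    Uses the Anscombe transform for Poisson counts,
    ``1.5 * (data**(2/3) - model**(2/3)) / model**(1/6)``, negated when
    ``sign == 'model_minus_data'`` (the convention used for the residual
    panels of pairwise marginal spectra).  Masked cells are undefined.
    """
    if model.shape != data.shape:
        raise ValueError("model and data shapes differ")
    if model.folded != data.folded:
        raise ValueError("model and data folding differ")
    mask = model.mask | data.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.5 * (data.counts ** (2 / 3) - model.counts ** (2 / 3)) / model.counts ** (1 / 6)
    if sign == "model_minus_data":
        r = -r
    elif sign != "data_minus_model":
        raise ValueError("sign must be 'model_minus_data' or 'data_minus_model'")
    return np.ma.masked_array(r, mask=mask)


# ---------------------------------------------------------------------------
# External file formats


def read_popmap(path) -> dict[str, str]:
    """Two-column TSV mapping sample name to population label."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            popmap[sample] = pop
    return popmap


def read_annotation(path) -> pd.DataFrame:
    """Three-column TSV of (contig, position, class) site annotations.

    The class vocabulary follows variant-annotation summaries: anything not
    recognised as synonymous / nonsynonymous / ambiguous is mapped to
    ``other``.
    """
    ann = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["contig", "pos", "annotation"],
                      dtype={"contig": str, "pos": np.int64, "annotation": str})
    cls = ann["annotation"].str.lower()
    ann["annotation"] = np.select(
        [cls.str.startswith("syn"), cls.str.startswith("non"), cls.str.startswith("amb")],
        ["synonymous", "nonsynonymous", "ambiguous"],
        default="other",
    )
    return ann


def read_vcf(vcf_path, popmap: dict[str, str], annotation_path=None) -> VariantTable:
    """Parse a VCF into a :class:`VariantTable`.

    Only biallelic SNPs are kept (multi-allelic and indel records are
    rejected with a logged count — how such records were treated upstream of
    spectrum construction is unspecified, so we take the conservative
    route).  Site quality comes from QUAL and dosages from GT.  If an
    annotation TSV is given, classes are joined on (contig, position);
    unannotated sites become ``other``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_order = list(vcf.samples)
    for s in popmap:
        if s not in sample_order:
            raise ValueError(f"popmap sample {s!r} absent from VCF")
    rows = []
    dosages = []
    n_rejected = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_rejected += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dos = np.choose(v.gt_types, [0, 1, MISSING, 2])
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0],
                     float(v.QUAL) if v.QUAL is not None else np.nan))
        dosages.append(dos)
    if n_rejected:
        logger.warning("read_vcf: rejected %d non-biallelic-SNP records", n_rejected)
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "qual"])
    dos_arr = (np.array(dosages, dtype=np.int64) if dosages
               else np.empty((0, len(sample_order)), dtype=np.int64))
    for s in popmap:
        df[s] = dos_arr[:, sample_order.index(s)] if len(df) else np.array([], dtype=np.int64)
    df["annotation"] = "other"
    if annotation_path is not None:
        ann = read_annotation(annotation_path)
        merged = df[["contig", "pos"]].merge(ann, on=["contig", "pos"], how="left")
        df["annotation"] = merged["annotation"].fillna("other").to_numpy()
    df = df[_META_COLUMNS + list(popmap)]
    return VariantTable(df, dict(popmap))
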