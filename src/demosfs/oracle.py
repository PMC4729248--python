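"""Monte-Carlo coalescent estimate of the expected joint SFS.

This is the independent validation oracle for :func:`demosfs.engine.expected_sfs`:
genealogies are simulated with msprime under the same demography and the
branch-mode allele-frequency spectrum is averaged over replicates.  It shares
nothing with the deterministic engine beyond the demography builder.
"""

from __future__ import annotations

import numpy as np

from . import models
from .spectra import JointSFS, fold_sfs


def mc_expected_sfs(model, params, sample_sizes=None, n_replicates: int = 10_000,
                    seed: int = 1, fold: bool = False):
    """Simulation estimate of the expected SFS at ``theta = 1``.

    Returns ``(sfs, se)``: the mean spectrum over ``n_replicates``
    independent genealogies and the per-cell Monte-Carlo standard error.
    Reproducible given ``seed``.  Sample sizes must be even (simulations run
    with diploid individuals).
    """
    import msprime

    spec = models.get_model(model)
    if sample_sizes is None:
        sample_sizes = (4,) * len(spec.pop_ids)
    if any(n % 2 for n in sample_sizes):
        raise ValueError("sample sizes must be even (diploid simulation)")
    demography = models.to_demography(spec, params)
    reps = msprime.sim_ancestry(
        samples={p: n // 2 for p, n in zip(spec.pop_ids, sample_sizes)},
        demography=demography,
        num_replicates=n_replicates,
        random_seed=seed,
    )
    total = total_sq = None
    for ts in reps:
        sets = [ts.samples(population=i) for i in range(len(sample_sizes))]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=False)
        if total is None:
            total = np.zeros_like(afs)
            total_sq = np.zeros_like(afs)
        total += afs
        total_sq += afs * afs
    mean = total / n_replicates
    var = np.maximum(total_sq / n_replicates - mean ** 2, 0.0)
    # engine scaling: entry = 0.5 * expected branch length
    counts = 0.5 * mean
    se = 0.5 * np.sqrt(var / n_replicates)
    mask = JointSFS.corner_mask(counts.shape)
    counts = counts.copy()
    counts[mask] = 0.0
    sfs = JointSFS(counts, mask, False, spec.pop_ids)
    if fold:
        sfs = fold_sfs(sfs)
        se = np.sqrt(fold_sfs(JointSFS(se ** 2, mask, False, spec.pop_ids)).counts)
    return sfs, se
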