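"""Deterministic expected joint SFS under the registered demographies.

The expected spectrum is computed exactly from the structured coalescent
rather than by diffusion or simulation.  The entry for allele configuration
``c`` is, at ``theta = 1``, half the expected total genealogical branch
length (in units of 2*Na generations) subtending exactly the samples in
``c`` — so a single equilibrium population of sample size n yields the
classical ``1/i`` spectrum, and every entry scales linearly in theta.

Two computational regimes are used:

* **Exchangeable (no migration within an epoch).**  In a panmictic epoch the
  embedded jump chain of the coalescent (which pair of lineages merges next)
  is independent of the holding times and of population size: every pair is
  equally likely.  The chain over "configurations" — multisets of ancestral
  blocks, each block labelled by the number of sampled chromosomes it
  subtends per population — is therefore parameter-free and is tabulated
  once per sample-size signature.  Population sizes and epoch lengths enter
  only through the occupancy times of the pure-death chain on the number of
  surviving lineages, obtained from a (2k x 2k) matrix exponential.  This
  covers all divergence-without-gene-flow models and is fast enough for
  optimisation loops (~1 ms per spectrum at sample sizes 4,4,4).

* **Located CTMC (migration).**  While two populations exchange migrants the
  lineage configuration must carry each block's location.  The full
  continuous-time Markov chain over located configurations (1,431 states for
  4+4 chromosomes) is built once; each evaluation assembles the generator
  from the rates and computes state occupancies and the exit distribution
  with a sparse matrix exponential.

Both regimes are exact up to floating-point and matrix-exponential error;
the Monte-Carlo coalescent oracle in :mod:`demosfs.oracle` provides an
independent check.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .models import ModelSpec, get_model
from .spectra import JointSFS


class EngineError(RuntimeError):
    """Raised when the expected-SFS computation fails its internal checks."""


#: tolerance for the internal sanity check on computed spectra (entries may
#: undershoot zero by at most this much before an error is raised)
NEGATIVE_TOL = 1e-8


# ---------------------------------------------------------------------------
# configuration (block-multiset) spaces and their parameter-free jump chains


def _vector_partitions(total: tuple[int, ...]) -> list[tuple[tuple[int, ...], ...]]:
    """All multisets of nonzero vectors summing to ``total`` (descending order)."""
    vecs = [v for v in itertools.product(*(range(t + 1) for t in total)) if any(v)]
    vecs.sort(reverse=True)
    out: list[tuple[tuple[int, ...], ...]] = []

    def rec(remaining, maxidx, acc):
        if not any(remaining):
            out.append(tuple(acc))
            return
        for i in range(maxidx, len(vecs)):
            v = vecs[i]
            if all(v[d] <= remaining[d] for d in range(len(total))):
                acc.append(v)
                rec(tuple(r - x for r, x in zip(remaining, v)), i, acc)
                acc.pop()

    rec(total, 0, [])
    return out


class _JumpSpace:
    """Parameter-free tables for the coalescent jump chain on one space.

    ``total`` is the per-population chromosome count subtended by the whole
    space (e.g. ``(4, 4)`` for the shared Sinaloan+Sonoran branch).  For
    every configuration x the table ``phi[x][j]`` holds the expected number
    of blocks of each type when the chain started at x has j surviving
    lineages; ``dist[x][j]`` holds the distribution over configurations at
    that level.  Both follow from the uniform-pair-merger recursion and are
    filled bottom-up (configurations with fewer blocks first).
    """

    def __init__(self, total: tuple[int, ...], with_dist: bool):
        self.total = total
        self.shape = tuple(t + 1 for t in total)
        self.ncells = int(np.prod(self.shape))
        self.configs = sorted(_vector_partitions(total), key=len)
        self.index = {c: i for i, c in enumerate(self.configs)}
        self.n = len(self.configs)
        self.kmax = sum(total)

        counts = np.zeros((self.n, self.ncells))
        for i, cfg in enumerate(self.configs):
            for block in cfg:
                counts[i, np.ravel_multi_index(block, self.shape)] += 1.0
        self.counts = counts

        # children of each config under a single (uniform) pair merger
        children: list[list[tuple[int, float]]] = []
        for cfg in self.configs:
            k = len(cfg)
            agg: dict[int, float] = {}
            if k >= 2:
                npairs = k * (k - 1) / 2
                for a in range(k):
                    for b in range(a + 1, k):
                        merged = tuple(x + y for x, y in zip(cfg[a], cfg[b]))
                        child = tuple(sorted(
                            [v for t, v in enumerate(cfg) if t not in (a, b)] + [merged],
                            reverse=True))
                        ci = self.index[child]
                        agg[ci] = agg.get(ci, 0.0) + 1.0 / npairs
            children.append(sorted(agg.items()))
        self.children = children

        # phi[x]: (k_x + 1, ncells); row j = E[block-type counts at level j]
        self.phi: list[np.ndarray] = [None] * self.n  # type: ignore[list-item]
        self.dist: list[dict[int, np.ndarray]] | None = [] if with_dist else None
        for i, cfg in enumerate(self.configs):
            k = len(cfg)
            phi = np.zeros((k + 1, self.ncells))
            phi[k] = counts[i]
            for ci, w in children[i]:
                child_phi = self.phi[ci]
                phi[1:k] += w * child_phi[1:k]
            self.phi[i] = phi
            if with_dist:
                dist = {k: {i: 1.0}}
                for j in range(k - 1, 0, -1):
                    acc: dict[int, float] = {}
                    for ci, w in children[i]:
                        for y, p in self.dist[ci].get(j, {}).items():  # type: ignore[index]
                            acc[y] = acc.get(y, 0.0) + w * p
                    dist[j] = acc
                self.dist.append(dist)  # type: ignore[union-attr]

        # V[x] = sum_j 2/(j(j-1)) * phi[x][j] for j >= 2: expected branch
        # lengths accumulated while coalescing to a common ancestor in a
        # population of unit size and unbounded duration
        V = np.zeros((self.n, self.ncells))
        for i, cfg in enumerate(self.configs):
            k = len(cfg)
            for j in range(2, k + 1):
                V[i] += (2.0 / (j * (j - 1))) * self.phi[i][j]
        self.V = V

        self.klevels = np.array([len(c) for c in self.configs])
        if with_dist:
            # dense stacks for vectorised branch evaluation
            PHI = np.zeros((self.n, self.kmax + 1, self.ncells))
            DIST = np.zeros((self.n, self.kmax + 1, self.n))
            for i in range(self.n):
                k = self.klevels[i]
                PHI[i, :k + 1] = self.phi[i]
                for j, d in self.dist[i].items():  # type: ignore[index]
                    for y, p in d.items():
                        DIST[i, j, y] = p
            self.PHI = PHI
            self.DIST = DIST

    def levels(self, i: int) -> int:
        return len(self.configs[i])


@lru_cache(maxsize=None)
def _space(total: tuple[int, ...], with_dist: bool = False) -> _JumpSpace:
    return _JumpSpace(total, with_dist)


# ---------------------------------------------------------------------------
# pure-death occupancy of the lineage-count chain


@lru_cache(maxsize=4096)
def _death_occupancy(kmax: int, T: float, nu: float):
    """Level-occupancy integrals for the coalescent lineage-count chain.

    Returns ``(P, A)`` with ``P[k, j] = P(j lineages at time T | k at 0)``
    and ``A[k, j] = E[time spent with j lineages during [0, T)]`` in a
    population of relative size ``nu``, via the matrix exponential of the
    augmented bidiagonal generator.
    """
    if nu <= 0:
        raise EngineError(f"population size must be positive, got nu={nu}")
    if T < 0:
        raise EngineError(f"epoch duration must be non-negative, got T={T}")
    m = kmax
    Q = np.zeros((m, m))
    for j in range(2, kmax + 1):
        lam = j * (j - 1) / (2.0 * nu)
        Q[j - 1, j - 1] = -lam
        Q[j - 1, j - 2] = lam
    aug = np.zeros((2 * m, 2 * m))
    aug[:m, :m] = Q
    aug[:m, m:] = np.eye(m)
    E = scipy.linalg.expm(aug * T)
    P = np.zeros((kmax + 1, kmax + 1))
    A = np.zeros((kmax + 1, kmax + 1))
    P[1:, 1:] = E[:m, :m]
    A[1:, 1:] = E[:m, m:]
    return P, A


# ---------------------------------------------------------------------------
# exchangeable branch evaluation


def _branch(space: _JumpSpace, entry: np.ndarray, T: float, nu: float,
            need_top: bool):
    """Contributions of one panmictic branch of finite duration.

    ``entry`` is a dense probability vector over the space's configurations
    at the bottom (recent end) of the branch.  Returns the per-cell expected
    branch lengths accumulated during the branch and, if requested, the
    configuration distribution at its top.
    """
    kmax = int(space.klevels[entry > 0].max())
    P, A = _death_occupancy(kmax, T, nu)
    # pad to the space's own level range for indexing
    if kmax < space.kmax:
        P = np.pad(P, ((0, space.kmax - kmax), (0, space.kmax - kmax)))
        A = np.pad(A, ((0, space.kmax - kmax), (0, space.kmax - kmax)))
    Wa = entry[:, None] * A[space.klevels]        # (nconfig, kmax+1)
    contrib = np.einsum("xj,xjc->c", Wa, space.PHI)
    top = None
    if need_top:
        Wp = entry[:, None] * P[space.klevels]
        top = np.einsum("xj,xjy->y", Wp, space.DIST)
    return contrib, top


def _terminal(space: _JumpSpace, entry: np.ndarray, nu: float) -> np.ndarray:
    """Contributions of the final (unbounded) ancestral population."""
    return nu * (entry @ space.V)


def _singleton_entry(space: _JumpSpace) -> np.ndarray:
    """Dense entry distribution: every sampled chromosome its own block."""
    blocks = []
    for d, t in enumerate(space.total):
        v = tuple(1 if e == d else 0 for e in range(len(space.total)))
        blocks += [v] * t
    cfg = tuple(sorted(blocks, reverse=True))
    entry = np.zeros(space.n)
    entry[space.index[cfg]] = 1.0
    return entry


@lru_cache(maxsize=None)
def _embedding(local_shape: tuple[int, ...], axes: tuple[int, ...],
               global_shape: tuple[int, ...]) -> np.ndarray:
    """Flat-index map embedding local cells into the global spectrum array."""
    idx = np.zeros(int(np.prod(local_shape)), dtype=np.int64)
    for cell in itertools.product(*(range(s) for s in local_shape)):
        g = [0] * len(global_shape)
        for a, c in zip(axes, cell):
            g[a] = c
        idx[np.ravel_multi_index(cell, local_shape)] = np.ravel_multi_index(
            tuple(g), global_shape)
    return idx


@lru_cache(maxsize=None)
def _product_map(total_a: tuple[int, ...], total_b: tuple[int, ...]):
    """Map (config of A, config of B) -> config index in the union space.

    A's populations occupy the leading axes of the union, B's the trailing
    ones.  Used to combine the independent branch tops that enter a common
    ancestral population.
    """
    da, db = len(total_a), len(total_b)
    sp_a, sp_b = _space(total_a), _space(total_b)
    sp_u = _space(total_a + total_b)
    out = np.zeros((sp_a.n, sp_b.n), dtype=np.int64)
    for ia, ca in enumerate(sp_a.configs):
        ba = [v + (0,) * db for v in ca]
        for ib, cb in enumerate(sp_b.configs):
            bb = [(0,) * da + v for v in cb]
            out[ia, ib] = sp_u.index[tuple(sorted(ba + bb, reverse=True))]
    return out


def _combine_tops(total_a, total_b, top_a: np.ndarray,
                  top_b: np.ndarray) -> np.ndarray:
    pmap = _product_map(total_a, total_b)
    sp_u = _space(total_a + total_b)
    out = np.zeros(sp_u.n)
    ia = np.flatnonzero(top_a > 0)
    ib = np.flatnonzero(top_b > 0)
    w = np.outer(top_a[ia], top_b[ib]).ravel()
    np.add.at(out, pmap[np.ix_(ia, ib)].ravel(), w)
    return out


# ---------------------------------------------------------------------------
# located CTMC for epochs with migration between two demes


class _LocatedCTMC:
    """Structured-coalescent CTMC over located block configurations.

    States are multisets of (block vector, deme) pairs for two demes whose
    samples subtend ``total`` chromosomes.  The generator decomposes as
    ``Q = C0/nu0 + C1/nu1 + m01*G01 + m10*G10`` with parameter-free sparse
    components (coalescence within each deme, migration each way), so per
    evaluation only a sparse matrix exponential remains.
    """

    def __init__(self, total: tuple[int, int]):
        self.total = total
        self.shape = tuple(t + 1 for t in total)
        self.ncells = int(np.prod(self.shape))
        self.strip_space = _space(total, True)

        # enumerate located states reachable from the sampled configuration
        init_blocks = []
        for d, t in enumerate(total):
            v = tuple(1 if e == d else 0 for e in range(2))
            init_blocks += [(v, d)] * t
        init = tuple(sorted(init_blocks, reverse=True))
        index: dict[tuple, int] = {init: 0}
        states = [init]
        frontier = [init]
        while frontier:
            new = []
            for st in frontier:
                k = len(st)
                for a in range(k):
                    # migration moves
                    v, loc = st[a]
                    moved = tuple(sorted(
                        [x for t2, x in enumerate(st) if t2 != a] + [(v, 1 - loc)],
                        reverse=True))
                    if moved not in index:
                        index[moved] = len(states)
                        states.append(moved)
                        new.append(moved)
                    # coalescence moves
                    for b in range(a + 1, k):
                        vb, locb = st[b]
                        if locb != loc:
                            continue
                        merged = ((v[0] + vb[0], v[1] + vb[1]), loc)
                        child = tuple(sorted(
                            [x for t2, x in enumerate(st) if t2 not in (a, b)] + [merged],
                            reverse=True))
                        if child not in index:
                            index[child] = len(states)
                            states.append(child)
                            new.append(child)
            frontier = new
        self.states = states
        self.index = index
        self.S = len(states)
        self.initial = 0

        comp = {key: ([], [], []) for key in ("C0", "C1", "G01", "G10")}

        def add(key, i, j, rate):
            rows, cols, vals = comp[key]
            rows += [j, i]
            cols += [i, i]
            vals += [rate, -rate]

        for i, st in enumerate(states):
            k = len(st)
            for a in range(k):
                v, loc = st[a]
                moved = tuple(sorted(
                    [x for t2, x in enumerate(st) if t2 != a] + [(v, 1 - loc)],
                    reverse=True))
                add("G01" if loc == 0 else "G10", i, index[moved], 1.0)
                for b in range(a + 1, k):
                    vb, locb = st[b]
                    if locb != loc:
                        continue
                    merged = ((v[0] + vb[0], v[1] + vb[1]), loc)
                    child = tuple(sorted(
                        [x for t2, x in enumerate(st) if t2 not in (a, b)] + [merged],
                        reverse=True))
                    add("C0" if loc == 0 else "C1", i, index[child], 1.0)

        # column-oriented generators: d/dt p = Q p for column vector p
        self.comp = {key: scipy.sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.S, self.S))
            for key, (rows, cols, vals) in comp.items()}

        cnt = np.zeros((self.S, self.ncells))
        strip = np.zeros(self.S, dtype=np.int64)
        for i, st in enumerate(states):
            for v, _loc in st:
                cnt[i, np.ravel_multi_index(v, self.shape)] += 1.0
            cfg = tuple(sorted((v for v, _loc in st), reverse=True))
            strip[i] = self.strip_space.index[cfg]
        self.cnt = cnt
        self.strip = strip

    def phase(self, p0: np.ndarray, T: float, nu0: float, nu1: float,
              m01: float, m10: float):
        """Occupancy integral and exit distribution over one epoch."""
        if T <= 0:
            return np.zeros(self.S), p0
        Q = (self.comp["C0"] / nu0 + self.comp["C1"] / nu1
             + m01 * self.comp["G01"] + m10 * self.comp["G10"])
        aug = scipy.sparse.bmat(
            [[Q * T, scipy.sparse.csc_matrix((self.S, self.S))],
             [scipy.sparse.identity(self.S) * T,
              scipy.sparse.csc_matrix((self.S, self.S))]], format="csc")
        y0 = np.concatenate([p0, np.zeros(self.S)])
        y = scipy.sparse.linalg.expm_multiply(aug, y0)
        pT, occ = y[:self.S], y[self.S:]
        return occ, pT

    def exit_config_dist(self, pT: np.ndarray) -> np.ndarray:
        """Location-stripped configuration distribution entering the merger."""
        out = np.zeros(self.strip_space.n)
        np.add.at(out, self.strip, pT)
        return out


@lru_cache(maxsize=None)
def _ctmc(total: tuple[int, int]) -> _LocatedCTMC:
    return _LocatedCTMC(total)


# ---------------------------------------------------------------------------
# model-family evaluators (unfolded expected branch lengths, flat cell array)


def _eval_one_pop(sizes, p):
    (n,) = sizes
    shape = (n + 1,)
    sp = _space((n,), True)
    entry = _singleton_entry(sp)
    contrib, top = _branch(sp, entry, p["T"], p["nu"], True)
    contrib = contrib + _terminal(sp, top, 1.0)
    return contrib, shape


def _eval_split2(sizes, p):
    n1, n2 = sizes
    shape = (n1 + 1, n2 + 1)
    flat = np.zeros(int(np.prod(shape)))
    T, tc = p["T"], min(p["Tc"], p["T"])
    migrating = (p["m12"] > 0 or p["m21"] > 0) and tc > 0
    sp_u = _space((n1, n2), True)
    if not migrating:
        sp1, sp2 = _space((n1,), True), _space((n2,), True)
        c1, top1 = _branch(sp1, _singleton_entry(sp1), T, p["nu1"], True)
        c2, top2 = _branch(sp2, _singleton_entry(sp2), T, p["nu2"], True)
        flat[_embedding((n1 + 1,), (0,), shape)] += c1
        flat[_embedding((n2 + 1,), (1,), shape)] += c2
        anc_entry = _combine_tops((n1,), (n2,), top1, top2)
    else:
        ctmc = _ctmc((n1, n2))
        p0 = np.zeros(ctmc.S)
        p0[ctmc.initial] = 1.0
        occ, pmid = ctmc.phase(p0, tc, p["nu1"], p["nu2"], p["m12"], p["m21"])
        flat += occ @ ctmc.cnt
        if T > tc:
            occ2, pmid = ctmc.phase(pmid, T - tc, p["nu1"], p["nu2"], 0.0, 0.0)
            flat += occ2 @ ctmc.cnt
        anc_entry = ctmc.exit_config_dist(pmid)
    flat += _terminal(sp_u, anc_entry, 1.0)
    return flat, shape


def _eval_trio(sizes, p):
    nm, ns, no = sizes
    shape = (nm + 1, ns + 1, no + 1)
    flat = np.zeros(int(np.prod(shape)))
    T1, T2 = p["T1"], p["T2"]

    # Mojave leaf spans both epochs at constant size
    sp_m = _space((nm,), True)
    c_m, top_m = _branch(sp_m, _singleton_entry(sp_m), T1 + T2, p["nu_moj"], True)
    flat[_embedding((nm + 1,), (0,), shape)] += c_m

    sp_ss = _space((ns, no), True)
    emb_ss = _embedding((ns + 1, no + 1), (1, 2), shape)
    if p["m_sinson"] > 0 and T2 > 0:
        ctmc = _ctmc((ns, no))
        p0 = np.zeros(ctmc.S)
        p0[ctmc.initial] = 1.0
        occ, pT = ctmc.phase(p0, T2, p["nu_sinson"], p["nu_son"],
                             p["m_sinson"], p["m_sinson"])
        flat[emb_ss] += occ @ ctmc.cnt
        ss_entry = ctmc.exit_config_dist(pT)
    else:
        sp_s, sp_o = _space((ns,), True), _space((no,), True)
        c_s, top_s = _branch(sp_s, _singleton_entry(sp_s), T2, p["nu_sinson"], True)
        c_o, top_o = _branch(sp_o, _singleton_entry(sp_o), T2, p["nu_son"], True)
        flat[_embedding((ns + 1,), (1,), shape)] += c_s
        flat[_embedding((no + 1,), (2,), shape)] += c_o
        ss_entry = _combine_tops((ns,), (no,), top_s, top_o)

    # shared Sinaloan+Sonoran branch between the splits
    c_ss, top_ss = _branch(sp_ss, ss_entry, T1, p["nu_sinson"], True)
    flat[emb_ss] += c_ss

    # common ancestral population (size 1, unbounded)
    anc_entry = _combine_tops((nm,), (ns, no), top_m, top_ss)
    sp_anc = _space((nm, ns, no))
    flat += _terminal(sp_anc, anc_entry, 1.0)
    return flat, shape


_FAMILY_EVAL = {"one_pop": _eval_one_pop, "split2": _eval_split2, "trio": _eval_trio}


# ---------------------------------------------------------------------------
# public interface


def expected_sfs(model: ModelSpec | str, params, sample_sizes=None,
                 fold: bool = False) -> JointSFS:
    """Expected joint SFS at ``theta = 1`` under a registered model.

    Parameters
    ----------
    model
        A :class:`~demosfs.models.ModelSpec` or registered model name.
    params
        Free-parameter vector in the model's ``param_names`` order (or a
        dict of the family's canonical arguments).
    sample_sizes
        Chromosomes sampled per population, in ``model.pop_ids`` order.
        Defaults to 4 per population (two diploids each).
    fold
        Return the minor-allele spectrum.

    Returns
    -------
    JointSFS
        Real-valued spectrum with the monomorphic corners masked.  Entry
        ``c`` equals half the expected branch length subtending ``c`` in
        units of 2*Na generations; multiply by theta for expected counts.
    """
    model = get_model(model)
    p = model.full_params(params) if not isinstance(params, dict) else dict(params)
    for name, v in p.items():
        if name.startswith("nu") and not v > 0:
            raise EngineError(f"{name} must be positive, got {v}")
        if (name.startswith("T") or name.startswith("m")) and v < 0:
            raise EngineError(f"{name} must be non-negative, got {v}")
    if sample_sizes is None:
        sample_sizes = (4,) * len(model.pop_ids)
    sample_sizes = tuple(int(n) for n in sample_sizes)
    if len(sample_sizes) != len(model.pop_ids):
        raise ValueError("sample_sizes length must match the model's populations")
    if any(n < 2 for n in sample_sizes):
        raise ValueError("need at least 2 sampled chromosomes per population")

    flat, shape = _FAMILY_EVAL[model.family](sample_sizes, p)
    counts = 0.5 * flat.reshape(shape)

    if not np.all(np.isfinite(counts)):
        raise EngineError(
            f"non-finite expected SFS for {model.name} at {p}; "
            "the matrix-exponential evaluation did not converge")
    if counts.min() < -NEGATIVE_TOL:
        raise EngineError(
            f"negative expected SFS entries (min {counts.min():.3e}) for "
            f"{model.name} at {p}")
    counts = np.clip(counts, 0.0, None)

    mask = JointSFS.corner_mask(tuple(s for s in counts.shape))
    counts[mask] = 0.0
    sfs = JointSFS(counts, mask, False, model.pop_ids)
    if fold:
        from .spectra import fold_sfs
        sfs = fold_sfs(sfs)
    return sfs
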