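"""Poisson composite-likelihood fitting of demographic models to a joint SFS.

Sites are treated as independent, so each unmasked spectrum cell contributes
a Poisson term with mean ``theta * m_c``, where ``m_c`` is the expected
per-unit-theta spectrum from the engine.  Because the expectation is linear
in theta, its maximum-likelihood value is available in closed form
(``theta_hat = sum(data) / sum(model)`` over jointly unmasked cells) and is
profiled out of every optimisation: only the shape parameters are searched.

Optimisation is multi-start: each start perturbs the initial vector
log-uniformly within a factor of two, runs a bounded Nelder-Mead simplex and
polishes with L-BFGS-B.  Sizes are searched on a log scale; times and
migration rates linearly.  Ties between starts are broken by the distance of
the end point from the median start, which keeps results deterministic for a
given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from . import engine
from .models import ModelSpec, get_model
from .spectra import JointSFS

logger = logging.getLogger(__name__)

LL_TOL = 1e-6


def optimal_theta(model_sfs: JointSFS, data: JointSFS) -> float:
    """Analytic maximum-likelihood theta: ratio of unmasked totals."""
    if model_sfs.shape != data.shape:
        raise ValueError("model and data shapes differ")
    keep = ~(model_sfs.mask | data.mask)
    denom = float(model_sfs.counts[keep].sum())
    if denom <= 0:
        raise ValueError("model spectrum has zero unmasked mass")
    return float(data.counts[keep].sum()) / denom


def poisson_composite_ll(model_sfs: JointSFS, data: JointSFS, theta: float) -> float:
    """Poisson composite log-likelihood of the data spectrum.

    ``sum_c [k_c * ln(theta*m_c) - theta*m_c - ln(k_c!)]`` over unmasked
    cells.  A model entry of zero with observed data yields ``-inf``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if model_sfs.shape != data.shape:
        raise ValueError("model and data shapes differ")
    keep = ~(model_sfs.mask | data.mask)
    m = theta * model_sfs.counts[keep]
    k = data.counts[keep]
    bad = (m == 0) & (k > 0)
    if np.any(bad):
        logger.warning("model assigns zero mass to %d cells with data; ll = -inf",
                       int(bad.sum()))
        return -np.inf
    pos = m > 0
    return float(np.sum(k[pos] * np.log(m[pos]) - m[pos] - gammaln(k[pos] + 1)))


def profile_ll(model: ModelSpec | str, params, data: JointSFS,
               sample_sizes=None) -> tuple[float, float]:
    """Composite log-likelihood with theta profiled out; returns (ll, theta)."""
    model = get_model(model)
    if sample_sizes is None:
        sample_sizes = data.sample_sizes
    exp = engine.expected_sfs(model, params, sample_sizes, fold=data.folded)
    theta = optimal_theta(exp, data)
    return poisson_composite_ll(exp, data, theta), theta


@dataclass
class StartRecord:
    start: np.ndarray
    end: np.ndarray
    ll: float
    converged: bool
    message: str = ""


@dataclass
class FitResult:
    """Best multi-start composite-likelihood fit of one model."""

    model: str
    params: np.ndarray
    param_names: tuple[str, ...]
    theta: float
    ll: float
    n_starts: int
    starts: list[StartRecord] = field(repr=False, default_factory=list)
    seed: int | None = None

    def params_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.param_names, self.params)}

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params_dict(),
            "theta": self.theta,
            "ll": self.ll,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }


def _transforms(model: ModelSpec):
    logs = model.log_scale()

    def to_z(p):
        z = np.array(p, dtype=float)
        z[logs] = np.log(z[logs])
        return z

    def from_z(z):
        p = np.array(z, dtype=float)
        p[logs] = np.exp(p[logs])
        return p

    zbounds = []
    for (lo, hi), is_log in zip(model.bounds(), logs):
        zbounds.append((np.log(lo), np.log(hi)) if is_log else (lo, hi))
    return to_z, from_z, zbounds


def fit_model(
    data: JointSFS,
    model: ModelSpec | str,
    n_starts: int = 20,
    seed: int | None = None,
    start: np.ndarray | None = None,
    perturb_fold: float = 2.0,
    maxiter: int = 2000,
) -> FitResult:
    """Maximum composite-likelihood fit by multi-start bounded optimisation.

    Each start is drawn by perturbing ``start`` (default: the model's
    canonical starting point) log-uniformly by up to ``perturb_fold`` in
    each coordinate, clipped to the bounds.  Deterministic given ``seed``.
    """
    model = get_model(model)
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    to_z, from_z, zbounds = _transforms(model)
    base = np.asarray(start if start is not None else model.default_start(), dtype=float)
    lo = np.array([b[0] for b in model.bounds()])
    hi = np.array([b[1] for b in model.bounds()])
    base = np.clip(base, lo, hi)

    def negll(z):
        p = from_z(z)
        try:
            ll, _ = profile_ll(model, p, data)
        except engine.EngineError:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    records: list[StartRecord] = []
    starts_z = []
    for s in range(n_starts):
        p0 = base * perturb_fold ** rng.uniform(-1, 1, size=base.size)
        # additive jitter for parameters that may start at zero
        zero = base == 0
        p0[zero] = rng.uniform(0, 0.1, size=int(zero.sum()))
        p0 = np.clip(p0, lo, hi)
        z0 = to_z(p0)
        starts_z.append(z0)
        try:
            res = minimize(negll, z0, method="Nelder-Mead", bounds=zbounds,
                           options={"maxiter": maxiter, "xatol": 1e-6, "fatol": LL_TOL})
            res2 = minimize(negll, res.x, method="L-BFGS-B", bounds=zbounds,
                            options={"maxiter": 500, "ftol": 1e-12})
            if res2.fun <= res.fun:
                res = res2
            records.append(StartRecord(p0, from_z(res.x), -res.fun,
                                       np.isfinite(res.fun), str(res.message)))
        except Exception as exc:  # pragma: no cover - defensive
            records.append(StartRecord(p0, p0, -np.inf, False, repr(exc)))
    ok = [r for r in records if np.isfinite(r.ll)]
    if not ok:
        raise RuntimeError(
            f"all {n_starts} optimisation starts failed for {model.name}; "
            f"messages: {[r.message for r in records]}")
    best_ll = max(r.ll for r in ok)
    contenders = [r for r in ok if r.ll >= best_ll - LL_TOL]
    median_start = np.median(np.stack([to_z(r.start) for r in records]), axis=0)
    best = min(contenders, key=lambda r: float(np.linalg.norm(to_z(r.end) - median_start)))
    ll, theta = profile_ll(model, best.end, data)
    return FitResult(model.name, best.end, model.param_names, theta, ll,
                     n_starts, records, seed)


def compare_models(
    data: JointSFS,
    model_names,
    n_starts: int = 20,
    seed: int | None = None,
    starts: dict | None = None,
) -> pd.DataFrame:
    """Fit several models and tabulate them by composite log-likelihood.

    Returns a DataFrame sorted by ``ll`` (best first) with model df,
    delta-ll from the best, theta and the fitted parameters.  A failed fit
    is reported in its row rather than aborting the table.
    """
    rows = []
    fits = {}
    for i, name in enumerate(model_names):
        spec = get_model(name)
        row = {"model": spec.name, "df": spec.df}
        try:
            fit = fit_model(data, spec, n_starts=n_starts,
                            seed=None if seed is None else seed + i,
                            start=None if not starts else starts.get(spec.name))
            row.update(ll=fit.ll, theta=fit.theta, status="ok",
                       **{f"p_{k}": v for k, v in fit.params_dict().items()})
            fits[spec.name] = fit
        except Exception as exc:
            row.update(ll=np.nan, theta=np.nan, status=f"error: {exc}")
            logger.error("fit of %s failed: %s", spec.name, exc)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("ll", ascending=False, ignore_index=True)
    table.insert(3, "delta_ll", table["ll"].max() - table["ll"])
    table.attrs["fits"] = fits
    return table
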