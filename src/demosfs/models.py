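"""Registry of divergence demographies for the three tortoise lineages.

All models are parameterised in coalescent-scaled units relative to the
ancestral effective size Na:

* ``nu_*`` — population size / Na (dimensionless),
* ``T*``  — epoch durations in units of 2*Na generations, measured backward
  from the present,
* ``m_*`` — scaled migration rates 2*Na*m, where m is the per-generation
  fraction of the recipient population replaced by migrants,
* ``theta = 4*Na*mu*L`` — the mutation scale, never optimised directly: the
  expected spectrum is linear in theta, so its maximum-likelihood value is
  computed analytically during fitting.

The three-population topology is fixed to ((SIN, SON), MOJ): the Mojave
lineage splits from the common ancestor ``T1 + T2`` ago and the Sinaloan and
Sonoran lineages separate ``T2`` ago.  Between the two splits the shared
Sinaloan+Sonoran branch has size ``nu_sinson``, which the contemporary
Sinaloan population inherits.  The ancestral population size is the unit
(nu = 1) throughout.

Two-population models come in three flavours: clean isolation
(``split2_noMig``), isolation-with-migration with continuous gene flow
(``split2_IM``) and secondary contact (``split2_SC``), where migration is
restricted to the most recent ``Tc`` time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_BOUNDS = {"nu": (1e-3, 1e3), "T": (0.0, 10.0), "m": (0.0, 20.0)}

#: canonical argument lists consumed by the engine, per model family
FAMILY_ARGS = {
    "one_pop": ("nu", "T"),
    "split2": ("nu1", "nu2", "T", "Tc", "m12", "m21"),
    "trio": ("nu_moj", "nu_sinson", "nu_son", "T1", "T2", "m_sinson"),
}

FAMILY_POPS = {
    "one_pop": ("pop0",),
    "split2": ("pop1", "pop2"),
    "trio": ("MOJ", "SIN", "SON"),
}


def _kind(pname: str) -> str:
    if pname.startswith("nu"):
        return "nu"
    if pname.startswith("T"):
        return "T"
    return "m"


@dataclass(frozen=True)
class ModelSpec:
    """A named demographic model: free parameters plus fixed constraints."""

    name: str
    family: str
    param_names: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    description: str = ""
    #: whether theta (equivalently the free ancestral size) is counted as a
    #: model parameter; the named three-population models count it, which is
    #: how the "5-parameter" and "6-parameter" labels arise.
    count_theta: bool = False
    bounds_override: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        known = set(FAMILY_ARGS[self.family])
        for p in list(self.param_names) + list(self.fixed):
            if p not in known:
                raise ValueError(f"parameter {p!r} unknown to family {self.family!r}")
        overlap = set(self.param_names) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")

    @property
    def pop_ids(self) -> tuple[str, ...]:
        return FAMILY_POPS[self.family]

    @property
    def df(self) -> int:
        """Number of free model parameters (including theta when counted)."""
        return len(self.param_names) + (1 if self.count_theta else 0)

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for p in self.param_names:
            out.append(self.bounds_override.get(p, DEFAULT_BOUNDS[_kind(p)]))
        return out

    def default_start(self) -> np.ndarray:
        defaults = {"nu": 1.0, "T": 0.3, "m": 0.5}
        start = np.array([defaults[_kind(p)] for p in self.param_names])
        # keep epoch durations distinct so starts are not degenerate
        for i, p in enumerate(self.param_names):
            if p == "T1":
                start[i] = 0.1
        return start

    def log_scale(self) -> np.ndarray:
        """True for parameters optimised on a log scale (sizes)."""
        return np.array([_kind(p) == "nu" for p in self.param_names])

    def full_params(self, params) -> dict[str, float]:
        """Merge a free-parameter vector with the fixed constraints."""
        params = np.asarray(params, dtype=float)
        if params.shape != (len(self.param_names),):
            raise ValueError(
                f"{self.name} expects {len(self.param_names)} parameters "
                f"{self.param_names}, got shape {params.shape}")
        full = {p: float(v) for p, v in zip(self.param_names, params)}
        full.update(self.fixed)
        for arg in FAMILY_ARGS[self.family]:
            full.setdefault(arg, 0.0)
        return full


_INF = float("inf")

MODELS: dict[str, ModelSpec] = {}


def _register(spec: ModelSpec) -> ModelSpec:
    MODELS[spec.name] = spec
    return spec


_register(ModelSpec(
    name="one_pop",
    family="one_pop",
    param_names=("nu", "T"),
    description="Single population of size nu for the last T, ancestral size 1."))

_register(ModelSpec(
    name="split2_noMig",
    family="split2",
    param_names=("nu1", "nu2", "T"),
    fixed={"Tc": _INF, "m12": 0.0, "m21": 0.0},
    description="Clean two-population split T ago (allopatric divergence)."))

_register(ModelSpec(
    name="split2_IM",
    family="split2",
    param_names=("nu1", "nu2", "T", "m12", "m21"),
    fixed={"Tc": _INF},
    description="Two-population split with continuous asymmetric gene flow."))

_register(ModelSpec(
    name="split2_SC",
    family="split2",
    param_names=("nu1", "nu2", "T", "Tc", "m12", "m21"),
    description=("Secondary contact: split T ago, isolation, then gene flow "
                 "during the most recent Tc (Tc >= T recovers split2_IM).")))

_register(ModelSpec(
    name="trio_5param",
    family="trio",
    param_names=("nu_sinson", "nu_son", "T1", "T2"),
    fixed={"nu_moj": 1.0, "m_sinson": 0.0},
    count_theta=True,
    description=("((SIN,SON),MOJ) divergence without gene flow; the "
                 "contemporary Mojave population keeps the ancestral size.")))

_register(ModelSpec(
    name="trio_6param",
    family="trio",
    param_names=("nu_moj", "nu_sinson", "nu_son", "T1", "T2"),
    fixed={"m_sinson": 0.0},
    count_theta=True,
    description=("((SIN,SON),MOJ) divergence without gene flow, with a free "
                 "contemporary Mojave size.")))

_register(ModelSpec(
    name="trio_6param_IM",
    family="trio",
    param_names=("nu_moj", "nu_sinson", "nu_son", "T1", "T2", "m_sinson"),
    count_theta=True,
    description=("trio_6param plus symmetric Sinaloan<->Sonoran gene flow "
                 "since their split (the gene-flow alternative hypothesis).")))


def get_model(name: str) -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: {sorted(MODELS)}") from None


def nested_indices(full: ModelSpec, nested: ModelSpec) -> tuple[list[int], list[float]]:
    """Indices (into ``full``'s parameter vector) constrained by ``nested``.

    ``nested`` must be ``full`` with some free parameters pinned to fixed
    values; the returned constraint values embed a nested-model optimum into
    the full parameterisation.  Self-nesting yields an empty list.
    """
    full, nested = get_model(full), get_model(nested)
    if full.family != nested.family:
        raise ValueError(f"{nested.name} is not nested in {full.name}: different families")
    if not set(nested.param_names) <= set(full.param_names):
        extra = set(nested.param_names) - set(full.param_names)
        raise ValueError(
            f"{nested.name} is not nested in {full.name}: frees {sorted(extra)}")
    for p, v in full.fixed.items():
        if nested.fixed.get(p) != v:
            raise ValueError(
                f"{nested.name} is not nested in {full.name}: "
                f"constraint {p}={v} not preserved")
    indices, values = [], []
    for i, p in enumerate(full.param_names):
        if p not in nested.param_names:
            indices.append(i)
            values.append(nested.fixed[p])
    return indices, values


def to_demography(model, params):
    """Build an msprime demography for a model at given scaled parameters.

    Sizes are ``nu / 2`` so that, at the default ploidy of two, one msprime
    generation equals one scaled time unit (pairs of lineages in a
    population of scaled size nu coalesce at rate 1/nu) and migration-matrix
    entries equal the scaled rates directly.
    """
    import msprime

    model = get_model(model)
    p = model.full_params(params) if not isinstance(params, dict) else dict(params)
    dem = msprime.Demography()
    if model.family == "one_pop":
        dem.add_population(name="pop0", initial_size=p["nu"] / 2)
        dem.add_population_parameters_change(time=p["T"], population="pop0",
                                             initial_size=0.5)
    elif model.family == "split2":
        dem.add_population(name="pop1", initial_size=p["nu1"] / 2)
        dem.add_population(name="pop2", initial_size=p["nu2"] / 2)
        dem.add_population(name="ANC", initial_size=0.5)
        tc = min(p["Tc"], p["T"])
        if p["m12"] > 0 or p["m21"] > 0:
            # backward in time: lineages in pop1 jump to pop2 at the rate at
            # which pop1 receives migrants from pop2 forward in time
            dem.set_migration_rate(source="pop1", dest="pop2", rate=p["m12"])
            dem.set_migration_rate(source="pop2", dest="pop1", rate=p["m21"])
            if tc < p["T"]:
                dem.add_migration_rate_change(time=tc, rate=0.0,
                                              source="pop1", dest="pop2")
                dem.add_migration_rate_change(time=tc, rate=0.0,
                                              source="pop2", dest="pop1")
        dem.add_population_split(time=p["T"], derived=["pop1", "pop2"], ancestral="ANC")
    elif model.family == "trio":
        dem.add_population(name="MOJ", initial_size=p["nu_moj"] / 2)
        dem.add_population(name="SIN", initial_size=p["nu_sinson"] / 2)
        dem.add_population(name="SON", initial_size=p["nu_son"] / 2)
        dem.add_population(name="SINSON", initial_size=p["nu_sinson"] / 2)
        dem.add_population(name="ANC", initial_size=0.5)
        if p["m_sinson"] > 0:
            dem.set_migration_rate(source="SIN", dest="SON", rate=p["m_sinson"])
            dem.set_migration_rate(source="SON", dest="SIN", rate=p["m_sinson"])
        dem.add_population_split(time=p["T2"], derived=["SIN", "SON"],
                                 ancestral="SINSON")
        dem.add_population_split(time=p["T1"] + p["T2"], derived=["SINSON", "MOJ"],
                                 ancestral="ANC")
    else:  # pragma: no cover
        raise ValueError(f"unknown family {model.family!r}")
    dem.sort_events()
    return dem
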