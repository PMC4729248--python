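"""Conversion of coalescent-scaled estimates to individuals and years.

Scaled fits leave one degree of freedom undetermined: the ancestral
effective size Na.  It is anchored by equating the scaled Mojave divergence
time (``T1 + T2``, in units of 2*Na generations) to an external calibration
— the 5.9 Ma vicariant split of the Mojave lineage — under a fixed
generation time:

    Na = anchor_years / (2 * g * (T1 + T2))

With Na in hand, ``mu*L = theta / (4 * Na)`` (the per-generation mutation
rate times effective sequence length), population sizes are ``nu_i * Na``
individuals and times ``T * 2 * Na * g`` years.  By construction the
converted Mojave divergence of the full-data fit equals the anchor exactly.

Bootstrap replicates are converted differently: ``mu*L`` from the full-data
calibration is held fixed and each replicate's Na comes from its own theta
(``Na_b = theta_b / (4 * mu*L)``), so replicate divergence times scatter
around — rather than equal — the anchor, which is what makes the interval
on the anchored time meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

ANCHOR_YEARS = 5.9e6
GENERATION_YEARS = 25.0


@dataclass
class PhysicalParams:
    """Demographic parameters in individuals and years."""

    Na: float
    N: dict[str, float]
    T_years: dict[str, float]
    muL: float
    generation_years: float
    theta: float
    anchor_years: float

    def to_dict(self) -> dict:
        return {
            "Na": self.Na,
            **{f"N_{k}": v for k, v in self.N.items()},
            **{f"T_{k}_years": v for k, v in self.T_years.items()},
            "muL": self.muL,
            "generation_years": self.generation_years,
            "theta": self.theta,
        }


def _trio_scaled(scaled: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    nus = {
        "moj": scaled.get("nu_moj", 1.0),
        "sinson": scaled["nu_sinson"],
        "son": scaled["nu_son"],
    }
    times = {"div1": scaled["T1"] + scaled["T2"], "div2": scaled["T2"]}
    return nus, times


def calibrate_physical(
    scaled: dict[str, float],
    theta: float,
    anchor_years: float = ANCHOR_YEARS,
    generation_years: float = GENERATION_YEARS,
) -> PhysicalParams:
    """Convert a full-data trio fit to physical units via the time anchor.

    ``scaled`` holds the fitted scaled parameters (``nu_*``, ``T1``, ``T2``;
    a missing ``nu_moj`` means it was fixed at 1).  The anchor is the Mojave
    divergence, ``T1 + T2`` scaled.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    nus, times = _trio_scaled(scaled)
    t_anchor = times["div1"]
    if t_anchor <= 0:
        raise ValueError("anchored divergence time is zero; cannot calibrate")
    Na = anchor_years / (2.0 * generation_years * t_anchor)
    muL = theta / (4.0 * Na)
    N = {k: nu * Na for k, nu in nus.items()}
    T_years = {k: t * 2.0 * Na * generation_years for k, t in times.items()}
    return PhysicalParams(Na, N, T_years, muL, generation_years, theta, anchor_years)


def scaled_from_physical(
    phys: PhysicalParams,
) -> tuple[dict[str, float], float]:
    """Inverse conversion (used for round-trip checks and simulation truth)."""
    Na = phys.Na
    scaled = {
        "nu_moj": phys.N["moj"] / Na,
        "nu_sinson": phys.N["sinson"] / Na,
        "nu_son": phys.N["son"] / Na,
        "T2": phys.T_years["div2"] / (2.0 * Na * phys.generation_years),
    }
    scaled["T1"] = (phys.T_years["div1"] / (2.0 * Na * phys.generation_years)
                    - scaled["T2"])
    return scaled, 4.0 * Na * phys.muL


def convert_bootstrap(
    boot_params: pd.DataFrame,
    muL_fixed: float,
    generation_years: float = GENERATION_YEARS,
) -> pd.DataFrame:
    """Convert bootstrap replicate fits using the fixed full-data ``mu*L``.

    ``boot_params`` needs columns ``theta``, ``T1``, ``T2``, ``nu_sinson``,
    ``nu_son`` and optionally ``nu_moj``.  Replicates with non-positive
    theta are dropped (logged).  Returns per-replicate physical parameters
    (sizes in individuals, times in years).
    """
    import logging

    logger = logging.getLogger(__name__)
    if muL_fixed <= 0:
        raise ValueError("muL must be positive")
    ok = boot_params["theta"] > 0
    if (~ok).any():
        logger.warning("convert_bootstrap: dropped %d replicates with theta <= 0",
                       int((~ok).sum()))
    bp = boot_params[ok]
    Na = bp["theta"] / (4.0 * muL_fixed)
    out = pd.DataFrame({
        "Na": Na,
        "N_moj": bp.get("nu_moj", pd.Series(1.0, index=bp.index)) * Na,
        "N_sinson": bp["nu_sinson"] * Na,
        "N_son": bp["nu_son"] * Na,
        "T_div1_years": (bp["T1"] + bp["T2"]) * 2.0 * Na * generation_years,
        "T_div2_years": bp["T2"] * 2.0 * Na * generation_years,
    })
    return out.reset_index(drop=True)
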