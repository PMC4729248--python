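"""End-to-end inference: filter -> spectrum -> fits -> tests -> CIs -> units.

``run_full_inference`` reproduces the full analysis workflow on a VCF +
annotation + population map: two-population fits for every pair (with and
without gene flow, testing the gene-flow hypotheses H-MS_gf and H-SS_gf
against their isolation counterparts H-MS_i and H-SS_i), three-population
fits with fixed ((SIN,SON),MOJ) topology, a Godambe-corrected LRT between
the 5- and 6-parameter variants, contig bootstraps on the winning model and
calibration to physical units.  Every stage's artifact is persisted and the
report is a pure function of (inputs, config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import engine, fit as fit_mod, models, spectra, uncertainty, units

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "min_quality": 20.0,
    "require_complete": True,
    "synonymous_only": True,
    "pop_order": ["MOJ", "SIN", "SON"],
    "pairs": [["MOJ", "SIN"], ["MOJ", "SON"], ["SIN", "SON"]],
    "models_2pop": ["split2_noMig", "split2_IM"],
    "models_3pop": ["trio_5param", "trio_6param"],
    "fit_gene_flow_trio": False,
    "n_starts": 20,
    "n_starts_2pop": 5,
    "bootstrap_B": 100,
    "bootstrap_starts": 3,
    "godambe_step": 1e-2,
    "anchor_years": units.ANCHOR_YEARS,
    "generation_years": units.GENERATION_YEARS,
    "seed": 0,
}


@dataclass
class RunReport:
    """Structured record of a full inference run."""

    config: dict
    filter_counts: dict
    afs_summary: dict
    pair_tables: dict
    compare_table: list
    chosen_model: str
    lrt: dict
    gene_flow: dict
    bootstrap_ci_scaled: dict
    bootstrap_ci_physical: dict
    physical: dict
    seeds: dict
    config_hash: str
    fits: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "fits"}
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self, path=None) -> str:
        lines = [
            "# Demographic inference report", "",
            f"config hash: `{self.config_hash}`", "",
            "## Filtering",
            *(f"- {k}: {v}" for k, v in self.filter_counts.items()), "",
            "## Spectrum",
            *(f"- {k}: {v}" for k, v in self.afs_summary.items()), "",
            "## Three-population model comparison", "",
        ]
        for row in self.compare_table:
            lines.append(f"- {row['model']} (df {row['df']}): ll = {row['ll']:.2f}")
        lines += ["", f"chosen model: **{self.chosen_model}**", ""]
        if self.lrt:
            lines += ["## Godambe-adjusted LRT (6- vs 5-parameter)",
                      f"- D = {self.lrt['D']:.3f}, adjusted D = {self.lrt['D_adj']:.3f}, "
                      f"df = {self.lrt['df']}, p = {self.lrt['p_value']:.4g}", ""]
        if self.gene_flow:
            lines.append("## Gene-flow hypotheses")
            for name, res in self.gene_flow.items():
                lines.append(
                    f"- {name}: Mhat = {res['m_hat']}, delta-ll = {res['delta_ll']:.3f}")
            lines.append("")
        if self.physical:
            lines.append("## Physical units (estimate and 95% bootstrap CI)")
            for k, v in self.physical.items():
                ci = self.bootstrap_ci_physical.get(k)
                tail = f" ({ci['low']:.4g} - {ci['high']:.4g})" if ci else ""
                lines.append(f"- {k}: {v:.6g}{tail}")
            lines.append("")
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=_jsonable).encode()).hexdigest()[:16]


def run_full_inference(vcf_path, annotation_path, popmap_path, config=None,
                       out_dir=None) -> RunReport:
    """Run the complete pipeline; see the module docstring for the stages."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    popmap = spectra.read_popmap(popmap_path)
    raw = spectra.read_vcf(vcf_path, popmap, annotation_path)
    filtered = spectra.filter_variants(
        raw, min_quality=cfg["min_quality"],
        require_complete=cfg["require_complete"],
        synonymous_only=cfg["synonymous_only"])
    filter_counts = {
        "input_sites": raw.n_sites,
        "retained_sites": filtered.n_sites,
        "retained_contigs": filtered.n_contigs,
    }

    pop_order = tuple(cfg["pop_order"])
    afs = spectra.build_joint_sfs(filtered, pop_order, fold=True)
    afs_summary = {
        "shape": list(afs.shape), "folded": afs.folded,
        "segregating_sites": afs.sum(), "pop_ids": list(afs.pop_ids),
    }
    if out is not None:
        afs.to_file(out / "afs_folded.fs")

    # --- two-population stage: topology guidance + gene-flow hypotheses ----
    pair_tables = {}
    gene_flow = {}
    for pair in cfg["pairs"]:
        pa, pb = pair
        marg = spectra.marginalize_pair(afs, pa, pb)
        table = fit_mod.compare_models(
            marg, cfg["models_2pop"], n_starts=cfg["n_starts_2pop"], seed=seed + 101)
        pair_tables[f"{pa}-{pb}"] = table.drop(columns="status").to_dict("records")
        fits = table.attrs["fits"]
        if "split2_IM" in fits and "split2_noMig" in fits:
            im, nm = fits["split2_IM"], fits["split2_noMig"]
            pd_ = im.params_dict()
            hyp = "H-SS" if set(pair) == {"SIN", "SON"} else "H-MS"
            gene_flow[f"{hyp}_gf:{pa}-{pb}"] = {
                "m_hat": [pd_["m12"], pd_["m21"]],
                "delta_ll": im.ll - nm.ll,
            }

    # --- three-population stage -------------------------------------------
    trio_models = list(cfg["models_3pop"])
    if cfg["fit_gene_flow_trio"] and "trio_6param_IM" not in trio_models:
        trio_models.append("trio_6param_IM")
    compare = fit_mod.compare_models(afs, trio_models,
                                     n_starts=cfg["n_starts"], seed=seed + 202)
    fits = compare.attrs["fits"]
    chosen = compare.iloc[0]["model"]
    if out is not None:
        compare.drop(columns="status").to_csv(out / "model_comparison.tsv",
                                              sep="\t", index=False)

    # --- Godambe LRT between the 5- and 6-parameter models -----------------
    boots = uncertainty.bootstrap_by_contig(
        filtered, B=cfg["bootstrap_B"], seed=seed + 303, pop_order=pop_order)
    lrt = {}
    if "trio_5param" in fits and "trio_6param" in fits:
        res = uncertainty.godambe_adjusted_lrt(
            fits["trio_6param"], fits["trio_5param"], afs, boots,
            step=cfg["godambe_step"])
        lrt = res.to_dict()
    if cfg["fit_gene_flow_trio"] and "trio_6param_IM" in fits and "trio_6param" in fits:
        res = uncertainty.godambe_adjusted_lrt(
            fits["trio_6param_IM"], fits["trio_6param"], afs, boots,
            step=cfg["godambe_step"])
        gene_flow["H-SS_gf:trio"] = {
            "m_hat": [fits["trio_6param_IM"].params_dict()["m_sinson"]],
            "delta_ll": fits["trio_6param_IM"].ll - fits["trio_6param"].ll,
            "lrt": res.to_dict(),
        }

    # --- bootstrap CIs on the winning trio model ---------------------------
    win_name = chosen if chosen.startswith("trio") else "trio_6param"
    win = fits[win_name]
    boot_fits = uncertainty.refit_bootstraps(
        boots, win_name, win, n_starts=cfg["bootstrap_starts"], seed=seed + 404)
    ci_scaled = uncertainty.param_ci(boot_fits)

    phys = units.calibrate_physical(
        win.params_dict(), win.theta,
        anchor_years=cfg["anchor_years"], generation_years=cfg["generation_years"])
    boot_phys = units.convert_bootstrap(
        boot_fits, phys.muL, generation_years=cfg["generation_years"])
    ci_phys = uncertainty.param_ci(boot_phys)

    if out is not None:
        boot_fits.to_csv(out / "bootstrap_fits_scaled.tsv", sep="\t", index=False)
        boot_phys.to_csv(out / "bootstrap_fits_physical.tsv", sep="\t", index=False)
        try:
            plot_fit_panels(afs, win, out / "fit_panels.png")
        except Exception as exc:  # plotting must never sink the run
            logger.warning("figure generation failed: %s", exc)

    report = RunReport(
        config={k: v for k, v in cfg.items()},
        filter_counts=filter_counts,
        afs_summary=afs_summary,
        pair_tables=pair_tables,
        compare_table=compare.drop(columns="status").to_dict("records"),
        chosen_model=str(chosen),
        lrt=lrt,
        gene_flow=gene_flow,
        bootstrap_ci_scaled=ci_scaled.to_dict("index"),
        bootstrap_ci_physical=ci_phys.to_dict("index"),
        physical=phys.to_dict(),
        seeds={"base": seed, "pair_fits": seed + 101, "trio_fits": seed + 202,
               "bootstrap": seed + 303, "bootstrap_fits": seed + 404},
        config_hash=_config_hash(cfg),
        fits={name: f for name, f in fits.items()},
    )
    if out is not None:
        report.to_json(out / "report.json")
        report.to_markdown(out / "report.md")
    return report


def recovery_experiment(
    seed: int,
    n_contigs: int = 7665,
    mean_syn_snps_per_contig: float = 20126 / 7665,
    n_starts: int = 20,
    B: int = 100,
    bootstrap_starts: int = 3,
    fit_gene_flow: bool = False,
):
    """Simulate-and-refit study at the best-fit six-parameter demography.

    Generates a synthetic dataset of the study's size (by default ~20k
    retained synonymous SNPs on ~7.7k fully linked contigs, two diploids per
    population) under the six-parameter no-gene-flow truth, rebuilds the
    folded 5x5x5 spectrum through the standard filters, re-fits the model by
    multi-start maximum composite likelihood, bootstraps over contigs and
    converts to physical units with the 5.9 Ma / 25-year calibration.

    Returns a dict with the generating values, the point estimates, the 95%
    bootstrap intervals and (optionally) the gene-flow fit of the
    isolation-with-migration variant to the same data.
    """
    from . import synthetic_data

    rng = np.random.default_rng(seed)
    s_sim, s_fit, s_boot, s_refit, s_gf = (int(x) for x in
                                           rng.integers(1, 2 ** 31 - 1, size=5))
    cfg = synthetic_data.SimConfig(n_contigs=n_contigs,
                                   mean_syn_snps_per_contig=mean_syn_snps_per_contig,
                                   seed=s_sim)
    vt = synthetic_data.simulate_variants(cfg)
    filtered = spectra.filter_variants(vt)
    afs = spectra.build_joint_sfs(filtered, ("MOJ", "SIN", "SON"), fold=True)

    best = fit_mod.fit_model(afs, "trio_6param", n_starts=n_starts, seed=s_fit)
    boots = uncertainty.bootstrap_by_contig(filtered, B=B, seed=s_boot,
                                            pop_order=("MOJ", "SIN", "SON"))
    boot_fits = uncertainty.refit_bootstraps(boots, "trio_6param", best,
                                             n_starts=bootstrap_starts,
                                             seed=s_refit)
    phys = units.calibrate_physical(best.params_dict(), best.theta)
    boot_phys = units.convert_bootstrap(boot_fits, phys.muL)
    ci_phys = uncertainty.param_ci(boot_phys)
    ci_scaled = uncertainty.param_ci(boot_fits)

    truth_scaled = dict(synthetic_data.TRUE_TRIO_PARAMS)
    g = units.GENERATION_YEARS
    na_true = units.ANCHOR_YEARS / (2 * g * (truth_scaled["T1"] + truth_scaled["T2"]))
    truth_phys = {
        "Na": na_true,
        "N_moj": truth_scaled["nu_moj"] * na_true,
        "N_sinson": truth_scaled["nu_sinson"] * na_true,
        "N_son": truth_scaled["nu_son"] * na_true,
        "T_div1_years": units.ANCHOR_YEARS,
        "T_div2_years": truth_scaled["T2"] * 2 * na_true * g,
    }
    out = {
        "n_snps": int(afs.sum()),
        "n_contigs": filtered.n_contigs,
        "truth_scaled": truth_scaled,
        "truth_physical": truth_phys,
        "fit": best,
        "physical": phys,
        "estimates_physical": {
            "Na": phys.Na, "N_moj": phys.N["moj"], "N_sinson": phys.N["sinson"],
            "N_son": phys.N["son"], "T_div1_years": phys.T_years["div1"],
            "T_div2_years": phys.T_years["div2"],
        },
        "ci_physical": ci_phys,
        "ci_scaled": ci_scaled,
        "afs": afs,
    }
    if fit_gene_flow:
        gf = fit_mod.fit_model(
            afs, "trio_6param_IM", n_starts=2, seed=s_gf,
            start=np.concatenate([best.params, [0.2]]))
        out["gene_flow_fit"] = gf
    return out


def plot_fit_panels(data: "spectra.JointSFS", fit_result, path,
                    sample_sizes=None) -> None:
    """Pairwise marginal spectra of data and model with Anscombe residuals.

    One column per population pair; rows are data, model and the
    (model - data) residual panel.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    model = models.get_model(fit_result.model)
    exp = engine.expected_sfs(model, fit_result.params,
                              sample_sizes or data.sample_sizes, fold=data.folded)
    exp = exp.scaled(fit_result.theta)
    pairs = [(a, b) for i, a in enumerate(data.pop_ids)
             for b in data.pop_ids[i + 1:]]
    fig, axes = plt.subplots(3, len(pairs), figsize=(3.2 * len(pairs), 9),
                             squeeze=False)
    for col, (pa, pb) in enumerate(pairs):
        dm = spectra.marginalize_pair(data, pa, pb)
        mm = spectra.marginalize_pair(exp, pa, pb)
        resid = spectra.anscombe_residuals(mm, dm)
        for row, (arr, title, cmap) in enumerate([
                (np.ma.masked_array(dm.counts, dm.mask), "data", "viridis"),
                (np.ma.masked_array(mm.counts, mm.mask), "model", "viridis"),
                (resid, "residuals (model - data)", "RdBu")]):
            ax = axes[row][col]
            if title.startswith("residuals"):
                lim = float(np.abs(arr).max()) if arr.count() else 1.0
                im = ax.imshow(arr.T, origin="lower", cmap=cmap,
                               vmin=-lim, vmax=lim)
            else:
                im = ax.imshow(np.ma.log10(arr.T + 1e-12), origin="lower", cmap=cmap)
            ax.set_xlabel(pa)
            ax.set_ylabel(pb)
            ax.set_title(f"{pa}-{pb} {title}", fontsize=9)
            fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
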