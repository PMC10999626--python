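"""End-to-end orchestration: data -> NCA -> CGNM fit -> identifiability/sensitivity.

The pipeline reproduces the full analysis from either a user-supplied
long-format PK dataset or the synthetic study generator, writing each
stage's tables (CSV/JSON) and figures under one output directory together
with a manifest recording the seed, configuration hash and package
versions, so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cgnm_fit import CGNMConfig, FitProblem, cgnm_run, summarize_accepted
from .core_model import (
    MDTCS,
    MDTCS_FC,
    FixedPhysiology,
    rank1_params,
    simulate,
)
from .nca import nca_params, pool_naive
from .post_analysis import DEFAULT_AUC_WINDOW, apl, local_sensitivity
from .synthetic_study import ErrorModel, StudyDesign, generate_pk_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("fcrnpk")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Stage toggles allow partial runs (e.g. NCA only); every stochastic
    stage derives its stream from ``seed``.
    """

    out_dir: Path = Path("fcrnpk_out")
    dataset_csv: Path | None = None  # None -> generate synthetic data
    seed: int = 0
    cv: float = 0.20
    proteins: tuple[str, ...] = (MDTCS, MDTCS_FC)
    run_generate: bool = True
    run_nca: bool = True
    run_fit: bool = True
    run_apl: bool = True
    run_sensitivity: bool = True
    run_plots: bool = True
    cgnm: CGNMConfig = field(default_factory=lambda: CGNMConfig(
        n_iterates=200, n_iterations=30))
    design: StudyDesign = field(default_factory=StudyDesign)
    fixed: FixedPhysiology = field(default_factory=FixedPhysiology)

    def config_hash(self) -> str:
        payload = json.dumps({
            "seed": self.seed, "cv": self.cv, "proteins": list(self.proteins),
            "cgnm": [self.cgnm.n_iterates, self.cgnm.n_iterations,
                     self.cgnm.grubbs_alpha, self.cgnm.seed],
            "design": self.design.to_dict(),
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_generate(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.dataset_csv is not None:
        log.info("loading dataset from %s", cfg.dataset_csv)
        return pd.read_csv(cfg.dataset_csv)
    log.info("generating synthetic study (seed=%d, cv=%.2f)", cfg.seed, cfg.cv)
    return generate_pk_dataset(design=cfg.design, fixed=cfg.fixed,
                               error_model=ErrorModel(cv=cfg.cv), seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages; returns a manifest of written artifacts.

    Raises on stage failure after persisting whatever earlier stages
    produced, so partial outputs remain inspectable.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": {},
    }

    def save_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index)
        manifest["outputs"][name] = str(path)

    dataset = _load_or_generate(cfg)
    if cfg.run_generate:
        save_df(dataset, "pk_dataset.csv")
    pooled = pool_naive(dataset)
    save_df(pooled, "pooled_profiles.csv")

    if cfg.run_nca:
        rows = []
        for (protein, dose), grp in pooled.groupby(["protein", "dose_nmol_per_kg"]):
            res = nca_params(grp, dose)
            rows.append({"protein": protein, "dose_nmol_per_kg": dose,
                         "t_half_terminal_h": res.t_half,
                         "auc_last_nM_h": res.auc_last,
                         "auc_inf_nM_h": res.auc_inf,
                         "cl_L_per_kg_h": res.cl, "mrt_h": res.mrt,
                         "vss_L_per_kg": res.vss,
                         "n_terminal_points": res.n_terminal_points})
        save_df(pd.DataFrame(rows), "nca_table.csv")

    clouds = {}
    if cfg.run_fit:
        for protein in cfg.proteins:
            sub = pooled[pooled["protein"] == protein]
            problem = FitProblem(protein_id=protein, pooled=sub, fixed=cfg.fixed,
                                 body_weight=cfg.design.body_weight)
            ccfg = CGNMConfig(n_iterates=cfg.cgnm.n_iterates,
                              n_iterations=cfg.cgnm.n_iterations,
                              grubbs_alpha=cfg.cgnm.grubbs_alpha,
                              seed=(cfg.seed + zlib.crc32(protein.encode())) % 2**31)
            log.info("CGNM fit for %s (%d x %d)", protein,
                     ccfg.n_iterates, ccfg.n_iterations)
            cloud = cgnm_run(problem, ccfg)
            clouds[protein] = (problem, cloud)
            summary = summarize_accepted(cloud, cfg.fixed)
            tag = protein.lower().replace("-", "_")
            save_df(summary.table, f"accepted_summary_{tag}.csv", index=True)
            acc = pd.DataFrame(cloud.accepted_params(), columns=cloud.param_names)
            acc["ssr"] = cloud.final_ssr[cloud.accepted]
            save_df(acc.sort_values("ssr"), f"accepted_sets_{tag}.csv")
            hist = pd.DataFrame(np.column_stack(cloud.history_ssr),
                                columns=[f"iter_{k}" for k in
                                         range(len(cloud.history_ssr))])
            save_df(hist, f"ssr_history_{tag}.csv")

    if cfg.run_apl and clouds:
        rows = []
        for protein, (problem, cloud) in clouds.items():
            for name in cloud.param_names:
                prof = apl(cloud, name)
                for g, s in zip(prof.grid, prof.min_ssr):
                    rows.append({"protein": protein, "parameter": name,
                                 "grid_transformed": g, "min_ssr": s,
                                 "cutoff": prof.cutoff, "bounded": prof.bounded})
        save_df(pd.DataFrame(rows), "apl_profiles.csv")

    if cfg.run_sensitivity:
        rows = []
        scans = {MDTCS: ("k_up", "k_pi", "FR"),
                 MDTCS_FC: ("k_on", "k_off", "k_up", "k_pi", "FR")}
        for protein in cfg.proteins:
            params = rank1_params(protein)
            for par in scans[protein]:
                for r in local_sensitivity(protein, params, cfg.fixed, par):
                    rows.append({"protein": protein, "parameter": par,
                                 "fold_change": r.fold_change,
                                 "auc_window_h": r.auc_window[1],
                                 "percent_change": r.percent_change})
        save_df(pd.DataFrame(rows), "sensitivity.csv")

    if cfg.run_plots:
        _write_plots(cfg, pooled, clouds, out, manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_plots(cfg: PipelineConfig, pooled: pd.DataFrame, clouds: dict,
                 out: Path, manifest: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # overlay: accepted-set curves vs pooled data, per protein
    for protein, (problem, cloud) in clouds.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        t_end = DEFAULT_AUC_WINDOW[protein][1]
        grid = np.geomspace(0.05, t_end, 120)
        P = cloud.accepted_params()
        # at most 50 accepted curves keeps the figure light; they overlap anyway
        for row in P[:50]:
            params = problem.make_params(row)
            for dose in sorted(pooled.loc[pooled.protein == protein,
                                          "dose_nmol_per_kg"].unique()):
                tr = simulate(protein, params, cfg.fixed,
                              dose * cfg.design.body_weight, grid,
                              rtol=1e-8)
                ax.plot(grid, tr.C_plasma, color="0.6", lw=0.5, alpha=0.4)
        sub = pooled[pooled.protein == protein]
        for dose, g in sub.groupby("dose_nmol_per_kg"):
            ax.plot(g.time_h, g.conc_nM, "o", ms=4, label=f"{dose} nmol/kg")
        ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("plasma conc (nM)")
        ax.set_title(f"{protein}: accepted fits vs pooled data")
        ax.legend()
        name = f"overlay_{protein.lower().replace('-', '_')}.png"
        fig.savefig(out / name, dpi=100)
        plt.close(fig)
        manifest["outputs"][name] = str(out / name)

    sens_path = out / "sensitivity.csv"
    if sens_path.exists():
        sens = pd.read_csv(sens_path)
        fc = sens[(sens.protein == MDTCS_FC) & sens.parameter.isin(["k_on", "k_off"])]
        if not fc.empty:
            fig, ax = plt.subplots(figsize=(5, 4))
            labels = [f"{p} x{f:g}" for p, f in zip(fc.parameter, fc.fold_change)]
            ax.bar(labels, fc.percent_change)
            ax.set_ylabel("% change AUC(0-96h)")
            ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            fig.savefig(out / "sensitivity_bars.png", dpi=100)
            plt.close(fig)
            manifest["outputs"]["sensitivity_bars.png"] = str(out / "sensitivity_bars.png")
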