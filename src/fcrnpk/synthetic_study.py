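"""Synthetic mouse PK study, BLI sensorgram and ELISA standard generators.

The animal study that motivates this package used destructive sampling:
each mouse contributes a single terminal plasma sample, with three to four
mice per sampling time, two dose levels per protein, and ELISA quantitation
whose lowest standard (times the minimum dilution) sets the limit of
quantitation.  Its raw per-animal data are not public, so this module
regenerates datasets with the same design and statistical structure --
model-simulated true concentrations, independent multiplicative lognormal
replicate error, and BLQ censoring to missing -- allowing every analysis
stage to run end-to-end from a single seed.

Defaults reproduce the study conditions: sampling times 0.083-168 h, doses
0.39/0.78 nmol/kg (MDTCS) and 0.0394/0.0788 nmol/kg (MDTCS-Fc), LLOQs of
9.77 pM and 0.888 pM expressed in nM, and a 20% replicate coefficient of
variation, a typical magnitude for ligand-binding-assay PK data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bli_binding import BindingParams, Sensorgram, predict_sensorgram
from .core_model import (
    MDTCS,
    MDTCS_FC,
    DEFAULT_BODY_WEIGHT_KG,
    FixedPhysiology,
    ProteinParams,
    rank1_params,
    simulate,
)

__all__ = ["StudyDesign", "ErrorModel", "study_design_default",
           "generate_pk_dataset", "generate_sensorgrams",
           "generate_elisa_standards", "default_binding_truth"]

#: Sampling schedule (h): 5 min through 7 days.
SAMPLING_TIMES = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0,
                  48.0, 72.0, 96.0, 168.0)

#: Assay LLOQ per protein (pM): lowest standard x minimum 10-fold dilution.
LLOQ_PM = {MDTCS: 9.77, MDTCS_FC: 0.888}


@dataclass(frozen=True)
class StudyDesign:
    """Design of the two-dose destructive-sampling PK study."""

    doses_nmol_per_kg: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {MDTCS: (0.39, 0.78), MDTCS_FC: (0.0394, 0.0788)})
    times_h: tuple[float, ...] = SAMPLING_TIMES
    n_replicates: int = 4
    body_weight: float = DEFAULT_BODY_WEIGHT_KG
    lloq_nM: dict[str, float] = field(
        default_factory=lambda: {p: v * 1e-3 for p, v in LLOQ_PM.items()})

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be positive and increasing")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per time")

    def to_dict(self) -> dict:
        return {
            "doses_nmol_per_kg": {k: list(v) for k, v in self.doses_nmol_per_kg.items()},
            "times_h": list(self.times_h),
            "n_replicates": self.n_replicates,
            "body_weight": self.body_weight,
            "lloq_nM": dict(self.lloq_nM),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            doses_nmol_per_kg={k: tuple(v) for k, v in d["doses_nmol_per_kg"].items()},
            times_h=tuple(d["times_h"]),
            n_replicates=int(d["n_replicates"]),
            body_weight=float(d["body_weight"]),
            lloq_nM={k: float(v) for k, v in d["lloq_nM"].items()},
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ErrorModel:
    """Multiplicative lognormal replicate error.

    A concentration ``c`` is observed as ``c * exp(sigma*z - sigma^2/2)``
    with ``sigma^2 = ln(1 + cv^2)``, so the replicate mean is unbiased and
    the coefficient of variation equals ``cv``.  Lognormal error keeps
    observations strictly positive, matching the log10 least-squares
    objective used downstream.
    """

    cv: float = 0.20

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    def draw(self, true_conc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(true_conc, float).copy()
        sigma = np.sqrt(np.log1p(self.cv**2))
        z = rng.standard_normal(np.shape(true_conc))
        return np.asarray(true_conc) * np.exp(sigma * z - sigma**2 / 2.0)


def study_design_default() -> StudyDesign:
    """The study design with all defaults (doses, times, LLOQs, 0.025 kg)."""
    return StudyDesign()


def generate_pk_dataset(truth: dict[str, ProteinParams] | None = None,
                        fixed: FixedPhysiology | None = None,
                        design: StudyDesign | None = None,
                        error_model: ErrorModel = ErrorModel(),
                        seed: int = 0) -> pd.DataFrame:
    """Simulate the full two-protein, two-dose study as a long-format table.

    For every protein and dose the disposition model is integrated over the
    sampling schedule; at each time ``n_replicates`` independent lognormal
    observations are drawn and censored against the protein's LLOQ.
    Censored records keep their row with ``blq_flag=True`` and a missing
    concentration, mirroring assay practice of treating BLQ as missing.

    Returns columns: protein, dose_nmol_per_kg, time_h, replicate, conc_nM,
    blq_flag.
    """
    if truth is None:
        truth = {MDTCS: rank1_params(MDTCS), MDTCS_FC: rank1_params(MDTCS_FC)}
    if fixed is None:
        fixed = FixedPhysiology()
    if design is None:
        design = study_design_default()
    rng = np.random.default_rng(seed)
    times = np.asarray(design.times_h)
    rows = []
    for protein in sorted(truth):
        params = truth[protein]
        lloq = design.lloq_nM[protein]
        for dose in design.doses_nmol_per_kg[protein]:
            trace = simulate(protein, params, fixed, dose * design.body_weight,
                             times)
            for t, c_true in zip(times, trace.C_plasma):
                obs = error_model.draw(np.full(design.n_replicates, c_true), rng)
                for rep, c in enumerate(obs, start=1):
                    blq = bool(c < lloq)
                    rows.append((protein, dose, t, rep,
                                 np.nan if blq else float(c), blq))
    return pd.DataFrame(rows, columns=["protein", "dose_nmol_per_kg", "time_h",
                                       "replicate", "conc_nM", "blq_flag"])


def default_binding_truth() -> BindingParams:
    """The measured FcRn binding kinetics used as generator truth."""
    return BindingParams(k_on=0.0487, k_off=0.00704, R_max=0.8)


def generate_sensorgrams(truth: BindingParams | None = None,
                         concs_nM: tuple[float, ...] = (0.625, 1.25, 2.5, 5.0, 10.0, 20.0),
                         noise_sd: float = 0.0,
                         t_assoc_end: float = 300.0,
                         t_total: float = 600.0,
                         dt: float = 2.0,
                         drift_per_s: float = 0.0,
                         seed: int = 0) -> list[Sensorgram]:
    """Synthetic BLI concentration series: 5 min association, 5 min dissociation.

    ``noise_sd`` adds i.i.d. Gaussian noise (nm); ``drift_per_s`` adds a
    linear baseline drift emulating a reference-channel artifact, which
    :func:`~fcrnpk.bli_binding.subtract_reference` should remove.
    """
    if truth is None:
        truth = default_binding_truth()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_total + dt / 2, dt)
    out = []
    for conc in concs_nM:
        r = predict_sensorgram(truth, conc, times, t_assoc_end)
        r = r + drift_per_s * times
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=times.shape)
        out.append(Sensorgram(analyte_conc=conc, times=times, response=r,
                              t_assoc_end=t_assoc_end))
    return out


def generate_elisa_standards(a: float = 0.05, d: float = 3.2, c: float = 1.5,
                             b: float = 1.2,
                             conc_range_pM: tuple[float, float] = (0.0888, 5.68),
                             n_levels: int = 7, noise_sd: float = 0.0,
                             seed: int = 0) -> np.ndarray:
    """Synthetic 4PL standard-curve data: (conc pM, OD) pairs.

    Concentrations are geometric (two-fold-style serial dilution) across
    ``conc_range_pM``; optional Gaussian OD noise emulates plate reads.
    """
    rng = np.random.default_rng(seed)
    conc = np.geomspace(conc_range_pM[0], conc_range_pM[1], n_levels)
    od = d + (a - d) / (1.0 + (conc / c) ** b)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=conc.shape)
    return np.column_stack([conc, od])
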