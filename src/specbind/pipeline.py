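"""Configuration and orchestration: chain the analysis stages into one run.

A run is described by an :class:`AnalysisConfig` (usually loaded from YAML):
physical constants with their conventional defaults (fluorophore lifetime
tau0 = 1e-8 s, diffusion-limit threshold 2.0e10 L/mol/s, R = 8.314
J/mol/K), a seed, an output directory, and a ``stages`` mapping from stage
name to its input files.  :func:`run_pipeline` executes the requested
stages, writes a single self-describing JSON report (every number carries
its units in its key) plus per-stage plots, and is byte-reproducible: the
same config and seed produce an identical report body.

:func:`simulate_bundle` writes a complete synthetic input set — three
quenching titrations on a shared van't Hoff ground truth, an ITC experiment
with its buffer control, free and complexed amide-I spectra, free and
protein-protected degradation series, and two EEM surfaces — together with
a ``ground_truth.json`` sidecar and a ready-to-run ``config.yaml``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .fluorescence import (
    DEFAULT_TAU0,
    DIFFUSION_LIMIT_KQ,
    classify_mechanism,
    double_log_fit,
    eem_peak_extract,
    stern_volmer_fit,
)
from .ftir import assign_structures, baseline_correct, deconvolve_amide1, structure_delta
from .itc import fit_one_site, integrate_injections, subtract_control
from .stability import first_order_rate, percent_remaining, protection_effect
from .synthetic import (
    AmideBandSpec,
    EEMPeak,
    ITCGroundTruth,
    QuenchModel,
    default_quench_concentrations,
    gen_amide_spectrum,
    gen_degradation_series,
    gen_eem_surface,
    gen_itc_experiment,
    gen_quench_titration,
)
from .thermodynamics import GAS_CONSTANT, ka_from_thermo, vant_hoff_fit

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """Everything a run needs: constants, seed, paths and requested stages.

    Defaults are the conventional constants of the field; every value is
    overridable from YAML.  ``stages`` maps a stage name (``quench``,
    ``binding``, ``vanthoff``, ``itc``, ``ftir``, ``stability``, ``eem``)
    to a dict of that stage's input paths.
    """

    tau0: float = DEFAULT_TAU0
    kq_threshold: float = DIFFUSION_LIMIT_KQ
    gas_constant: float = GAS_CONSTANT
    amide_max_bands: int = 8
    seed: int = 0
    output_dir: str = "results"
    make_plots: bool = True
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg._resolve_paths(path.parent)
        return cfg

    def _resolve_paths(self, base: Path) -> None:
        def resolve(value):
            if isinstance(value, str) and not Path(value).is_absolute():
                return str((base / value).resolve())
            return value

        for stage, inputs in self.stages.items():
            self.stages[stage] = {
                key: (resolve(v) if key != "windows" else v) for key, v in inputs.items()
            }
        if not Path(self.output_dir).is_absolute():
            self.output_dir = str((base / self.output_dir).resolve())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ------------------------------------------------------------ simulation

#: Shared van't Hoff ground truth for the synthetic titrations: exothermic
#: binding with negative entropy (van der Waals / hydrogen-bond signature)
#: tuned so K_a(298 K) = 2e4 L/mol.
BUNDLE_DH = -30.0  # kJ/mol
BUNDLE_DS = -18.33  # J/(mol K)
BUNDLE_TEMPERATURES = (288.0, 298.0, 308.0)

BUNDLE_ITC = ITCGroundTruth(
    n_sites=1.0, ka=1.0e5, dh=-20.0, dilution_heat=-0.3, noise_sd=0.1
)

BUNDLE_FTIR_FREE = AmideBandSpec(area_fractions=(0.42, 0.14, 0.24, 0.20))
BUNDLE_FTIR_COMPLEX = AmideBandSpec(area_fractions=(0.458, 0.144, 0.1939, 0.2041))

BUNDLE_K_FREE = 0.01494  # h^-1: 58.4% left after 36 h of visible light
BUNDLE_K_PROTECTED = 0.000817  # h^-1: ~2.9% lost at 36 h with protein

EEM_WINDOWS = {
    "peak_a": [260.0, 300.0, 310.0, 360.0],  # aromatic residues
    "peak_b": [215.0, 245.0, 310.0, 360.0],  # polypeptide backbone
}


def simulate_bundle(out_dir, seed: int = 0, titration_noise: float = 0.0002,
                    ftir_noise: float = 0.0005, stability_noise: float = 0.05) -> dict:
    """Write a full synthetic input bundle plus ground truth and config.

    Returns the ground-truth dict.  Noise levels are deliberately modest so
    a single end-to-end run recovers every parameter; the titration noise in
    particular must be small because the van't Hoff slope over a 20 K window
    amplifies relative intensity noise into ΔH by three to four orders of
    magnitude.  Set all three to 0 for exact round trips.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)

    # fluorescence titrations at three temperatures, one shared truth
    conc = default_quench_concentrations()
    titration_files = []
    ka_truth = {}
    for i, temp in enumerate(BUNDLE_TEMPERATURES):
        ka = ka_from_thermo(BUNDLE_DH, BUNDLE_DS, temp)
        ka_truth[temp] = ka
        model = QuenchModel(
            f0=1000.0, mode="binding", ka=ka, n_sites=1.0,
            noise_sd=titration_noise, temperature=temp,
        )
        series = gen_quench_titration(model, conc, seed=rng_seed + i)
        fname = f"titration_{int(temp)}K.csv"
        sio.write_titration(series, out / fname)
        titration_files.append(fname)

    # ITC: sample plus buffer-titration control carrying only dilution heat
    sample = gen_itc_experiment(BUNDLE_ITC, seed=rng_seed + 10)
    control_truth = dataclasses.replace(BUNDLE_ITC, dh=0.0, noise_sd=0.02)
    control = gen_itc_experiment(control_truth, seed=rng_seed + 11)
    sio.write_thermogram(sample, out / "itc_sample.csv", out / "itc_schedule.csv",
                         out / "itc_geometry.json")
    sio.write_thermogram(control, out / "itc_control.csv", out / "itc_control_schedule.csv",
                         out / "itc_geometry.json")

    # FTIR: free protein and 1:1 complex
    free = gen_amide_spectrum(
        dataclasses.replace(BUNDLE_FTIR_FREE, noise_sd=ftir_noise), seed=rng_seed + 20
    )
    complexed = gen_amide_spectrum(
        dataclasses.replace(BUNDLE_FTIR_COMPLEX, noise_sd=ftir_noise), seed=rng_seed + 21
    )
    sio.write_spectrum(free, out / "ftir_free.csv")
    sio.write_spectrum(complexed, out / "ftir_complex.csv")

    # photostability: free ligand vs protein-protected, 0-36 h
    base_condition = {"light": "visible", "ligand": "FA"}
    free_series = gen_degradation_series(
        17.5, BUNDLE_K_FREE, noise_sd=stability_noise, seed=rng_seed + 30,
        condition={**base_condition, "with_protein": "no"},
    )
    protected_series = gen_degradation_series(
        17.5, BUNDLE_K_PROTECTED, noise_sd=stability_noise, seed=rng_seed + 31,
        condition={**base_condition, "with_protein": "yes"},
    )
    sio.write_degradation(free_series, out / "stability_free.csv")
    sio.write_degradation(protected_series, out / "stability_protein.csv")

    # EEM: peaks a (aromatic residues) and b (backbone); complex attenuated
    free_peaks = (EEMPeak(280.0, 334.0, 500.0), EEMPeak(230.0, 334.0, 350.0))
    complex_peaks = (EEMPeak(280.0, 334.0, 400.0), EEMPeak(230.0, 334.0, 280.0))
    sio.write_eem(gen_eem_surface(free_peaks, noise_sd=2.0, seed=rng_seed + 40),
                  out / "eem_free.csv")
    sio.write_eem(gen_eem_surface(complex_peaks, noise_sd=2.0, seed=rng_seed + 41),
                  out / "eem_complex.csv")

    truth = {
        "vant_hoff": {
            "dh_kJ_per_mol": BUNDLE_DH,
            "ds_J_per_mol_K": BUNDLE_DS,
            "ka_L_per_mol_by_T": {str(t): ka_truth[t] for t in BUNDLE_TEMPERATURES},
            "force_class": "vdw_hbond",
        },
        "quench": {"n_sites": 1.0, "f0": 1000.0, "mechanism": "static"},
        "itc": {
            "n_sites": BUNDLE_ITC.n_sites,
            "ka_L_per_mol": BUNDLE_ITC.ka,
            "dh_kJ_per_mol": BUNDLE_ITC.dh,
            "dilution_heat_uJ": BUNDLE_ITC.dilution_heat,
        },
        "ftir": {
            "free_fractions_percent": _spec_fractions(BUNDLE_FTIR_FREE),
            "complex_fractions_percent": _spec_fractions(BUNDLE_FTIR_COMPLEX),
        },
        "stability": {
            "c0_ug_mL": 17.5,
            "k_free_per_h": BUNDLE_K_FREE,
            "k_protected_per_h": BUNDLE_K_PROTECTED,
        },
        "eem": {
            "free_peak_a_intensity": 500.0,
            "free_peak_b_intensity": 350.0,
            "complex_peak_a_intensity": 400.0,
            "complex_peak_b_intensity": 280.0,
        },
        "seed": rng_seed,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    config = {
        "seed": rng_seed,
        "output_dir": "results",
        "stages": {
            "quench": {"titrations": titration_files},
            "binding": {"titrations": titration_files},
            "vanthoff": {},
            "itc": {
                "thermogram": "itc_sample.csv",
                "schedule": "itc_schedule.csv",
                "geometry": "itc_geometry.json",
                "control_thermogram": "itc_control.csv",
                "control_schedule": "itc_control_schedule.csv",
            },
            "ftir": {"free": "ftir_free.csv", "complex": "ftir_complex.csv"},
            "stability": {
                "with_protein": "stability_protein.csv",
                "without_protein": "stability_free.csv",
            },
            "eem": {
                "sample": "eem_complex.csv",
                "reference": "eem_free.csv",
                "windows": EEM_WINDOWS,
            },
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth


def _spec_fractions(spec: AmideBandSpec) -> dict:
    keys = ("beta_sheet", "random_coil", "alpha_helix", "beta_turn")
    return {k: 100.0 * f for k, f in zip(keys, spec.area_fractions)}


# -------------------------------------------------------------- stages

def _stage_titrations(config, inputs):
    paths = inputs["titrations"]
    if isinstance(paths, str):
        paths = [paths]
    base = Path(config.output_dir).parent
    series = []
    for p in paths:
        p = Path(p)
        series.append(sio.read_titration(p if p.is_absolute() else base / p))
    return sorted(series, key=lambda s: s.temperature)


def _run_quench(config, inputs):
    series = _stage_titrations(config, inputs)
    results = [stern_volmer_fit(s, tau0=config.tau0) for s in series]
    call = classify_mechanism(results, kq_threshold=config.kq_threshold)
    return {
        "per_temperature": [
            {
                "temperature_K": r.temperature,
                "ksv_L_per_mol": r.ksv,
                "kq_L_per_mol_s": r.kq,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
            }
            for r in results
        ],
        "mechanism": {"label": call.label, "evidence": [list(e) for e in call.evidence]},
    }


def _run_binding(config, inputs):
    series = _stage_titrations(config, inputs)
    out = []
    for s in series:
        fit = double_log_fit(s)
        out.append(
            {
                "temperature_K": s.temperature,
                "ka_L_per_mol": fit.ka,
                "n_sites": fit.n_sites,
                "log10_ka": fit.log10_ka,
                "r_squared": fit.r_squared,
            }
        )
    return {"per_temperature": out}


def _run_vanthoff(config, inputs, binding_report):
    if "ka_csv" in inputs:
        import pandas as pd

        df = pd.read_csv(inputs["ka_csv"])
        ka_by_t = dict(zip(df["temperature_K"].astype(float), df["ka"].astype(float)))
    elif binding_report is not None:
        ka_by_t = {
            row["temperature_K"]: row["ka_L_per_mol"]
            for row in binding_report["per_temperature"]
        }
    else:
        raise StageError("vanthoff: no ka_csv given and no binding stage ran first")
    params = vant_hoff_fit(ka_by_t, gas_constant=config.gas_constant)
    return {
        "dh_kJ_per_mol": params.dh,
        "ds_J_per_mol_K": params.ds,
        "dg_kJ_per_mol_by_T": {str(t): v for t, v in sorted(params.dg_at.items())},
        "r_squared": params.r_squared,
        "force_class": params.force_class,
    }


def _run_itc(config, inputs):
    thermogram = sio.read_thermogram(inputs["thermogram"], inputs["schedule"], inputs["geometry"])
    heats = integrate_injections(thermogram)
    if "control_thermogram" in inputs:
        control_sched = inputs.get("control_schedule", inputs["schedule"])
        control = sio.read_thermogram(inputs["control_thermogram"], control_sched,
                                      inputs["geometry"])
        heats = subtract_control(heats, integrate_injections(control))
    fit = fit_one_site(
        heats,
        thermogram.cell_volume,
        thermogram.cell_conc,
        thermogram.syringe_conc,
        temperature=thermogram.temperature,
    )
    return {
        "n_sites": fit.n_sites,
        "ka_L_per_mol": fit.ka,
        "dh_kJ_per_mol": fit.dh,
        "dilution_heat_uJ": fit.dilution_heat,
        "dg_kJ_per_mol": fit.dg,
        "ds_J_per_mol_K": fit.ds,
        "final_molar_ratio": float(heats.molar_ratio[-1]),
        "residual_norm_uJ": fit.residual_norm,
        "warnings": list(fit.warnings),
    }, heats


def _run_ftir_one(config, path):
    spectrum = baseline_correct(sio.read_spectrum(path))
    components = deconvolve_amide1(spectrum, max_bands=config.amide_max_bands)
    structure = assign_structures(components)
    return components, structure


def _run_ftir(config, inputs):
    _, free = _run_ftir_one(config, inputs["free"])
    _, complexed = _run_ftir_one(config, inputs["complex"])
    delta = structure_delta(free, complexed)
    return {
        "free_fractions_percent": dict(free.fractions),
        "complex_fractions_percent": dict(complexed.fractions),
        "delta_percentage_points": delta,
    }


def _run_stability(config, inputs):
    with_p = sio.read_degradation(inputs["with_protein"])
    without_p = sio.read_degradation(inputs["without_protein"])
    k_with, r2_with = first_order_rate(with_p)
    k_without, r2_without = first_order_rate(without_p)
    t_end = float(min(with_p.time[-1], without_p.time[-1]))
    effect = dict(protection_effect(with_p, without_p))
    if effect["rate_ratio_infinite"]:
        effect["rate_ratio"] = None  # JSON-safe representation of the flagged infinity
    return {
        "with_protein": {
            "k_per_h": k_with,
            "r_squared": r2_with,
            "percent_remaining_at_end": percent_remaining(with_p, t_end),
        },
        "without_protein": {
            "k_per_h": k_without,
            "r_squared": r2_without,
            "percent_remaining_at_end": percent_remaining(without_p, t_end),
        },
        "protection": effect,
    }


def _run_eem(config, inputs):
    surface = sio.read_eem(inputs["sample"])
    reference = sio.read_eem(inputs["reference"]) if "reference" in inputs else None
    windows = {name: tuple(rect) for name, rect in inputs["windows"].items()}
    peaks = eem_peak_extract(surface, windows, reference=reference)
    return {"peaks": peaks}


# --------------------------------------------------------------- plots

def _write_plots(out_dir: Path, report: dict, itc_heats) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = report["stages"]
    if "quench" in stages:
        fig, ax = plt.subplots()
        for row in stages["quench"]["per_temperature"]:
            ax.scatter([row["temperature_K"]], [row["ksv_L_per_mol"]])
        ax.set_xlabel("T (K)")
        ax.set_ylabel("K_SV (L/mol)")
        ax.set_title("Stern-Volmer constants")
        fig.savefig(out_dir / "quench.png", dpi=100)
        plt.close(fig)
    if "itc" in stages and itc_heats is not None:
        fig, ax = plt.subplots()
        ax.plot(itc_heats.molar_ratio, itc_heats.enthalpy_kJ_per_mol_injectant, "o-")
        ax.set_xlabel("molar ratio (ligand/protein)")
        ax.set_ylabel("kJ/mol of injectant")
        ax.set_title("ITC binding isotherm")
        fig.savefig(out_dir / "itc.png", dpi=100)
        plt.close(fig)
    if "stability" in stages:
        fig, ax = plt.subplots()
        rows = stages["stability"]
        ax.bar(["with protein", "without"], [
            rows["with_protein"]["percent_remaining_at_end"],
            rows["without_protein"]["percent_remaining_at_end"],
        ])
        ax.set_ylabel("% remaining at endpoint")
        fig.savefig(out_dir / "stability.png", dpi=100)
        plt.close(fig)


# ------------------------------------------------------------ pipeline

STAGE_ORDER = ("quench", "binding", "vanthoff", "itc", "ftir", "stability", "eem")


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every requested stage and write ``report.json`` to the output dir.

    Stage failures propagate as :class:`StageError` naming the stage.  An
    empty ``stages`` mapping produces a report with an explicit
    "no stages requested" notice rather than an error.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "specbind",
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "constants": {
            "tau0_s": config.tau0,
            "kq_threshold_L_per_mol_s": config.kq_threshold,
            "gas_constant_J_per_mol_K": config.gas_constant,
        },
        "stages": {},
    }
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise StageError(f"unknown stages requested: {sorted(unknown)}")
    if not config.stages:
        report["notice"] = "no stages requested"

    binding_report = None
    itc_heats = None
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        inputs = config.stages[stage]
        try:
            if stage == "quench":
                report["stages"]["quench"] = _run_quench(config, inputs)
            elif stage == "binding":
                binding_report = _run_binding(config, inputs)
                report["stages"]["binding"] = binding_report
            elif stage == "vanthoff":
                report["stages"]["vanthoff"] = _run_vanthoff(config, inputs, binding_report)
            elif stage == "itc":
                report["stages"]["itc"], itc_heats = _run_itc(config, inputs)
            elif stage == "ftir":
                report["stages"]["ftir"] = _run_ftir(config, inputs)
            elif stage == "stability":
                report["stages"]["stability"] = _run_stability(config, inputs)
            elif stage == "eem":
                report["stages"]["eem"] = _run_eem(config, inputs)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    body = json.dumps(report, indent=2, sort_keys=True, allow_nan=False)
    (out_dir / "report.json").write_text(body + "\n")
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"specbind {__version__}\n")
        fh.write(f"numpy {np.__version__}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(f"config_hash {config.content_hash()}\n")
        fh.write(f"stages {sorted(config.stages)}\n")
    if config.make_plots:
        _write_plots(out_dir, report, itc_heats)
    return report
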