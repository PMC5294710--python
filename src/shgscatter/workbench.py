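"""Pipeline orchestration: configuration, logging, CLI, reporting.

Ties the stages together end to end: image stacks -> depth responses ->
Monte Carlo inversion of F_SHG/B_SHG and conversion efficiency;
transmission measurements -> scattering spectra -> shape-factor fits;
assembly of the per-sample feature table; canonical-discriminant
classification and group statistics.  Every numeric output carries the
seed and a configuration hash so a run can be reproduced exactly;
identical config + seed gives byte-identical metric files regardless of
the worker count.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import classification as cls
from . import depth_profiles as dp
from . import shg_extraction as ext
from . import synthetic_data as synth
from . import tissue_optics as optics
from .photon_transport import DetectionGeometry, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report", "cli"]


def _setup_logging(log_path: Path | None = None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_path is not None:
        handlers.append(logging.FileHandler(log_path))
    logging.basicConfig(
        level=logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis exactly."""

    sample_dirs: list
    output_dir: str
    seed: int = 0
    n_photons: int = 4000
    fb_grid_min: float = 0.25
    fb_grid_max: float = 16.0
    fb_grid_size: int = 33
    refine: bool = False
    cv: str = "resubstitution"
    n_workers: int = 1
    m_fit_wavelength_max: float = 535.0

    def fb_grid(self) -> np.ndarray:
        return np.geomspace(self.fb_grid_min, self.fb_grid_max, self.fb_grid_size)

    def config_hash(self) -> str:
        payload = {
            "sample_dirs": [str(s) for s in self.sample_dirs],
            "seed": self.seed,
            "n_photons": self.n_photons,
            "fb_grid": [self.fb_grid_min, self.fb_grid_max, self.fb_grid_size],
            "refine": self.refine,
            "cv": self.cv,
            "m_fit_wavelength_max": self.m_fit_wavelength_max,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and sample names."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


def _analyze_sample(sample_dir: Path, config: PipelineConfig) -> dict:
    """Run one sample through profiles, scattering fits, and extraction."""
    sample_dir = Path(sample_dir)
    manifest = yaml.safe_load((sample_dir / "manifest.yaml").read_text())
    sample_id = manifest["sample_id"]
    label = manifest.get("tissue_label", "unknown")

    # --- scattering spectroscopy ------------------------------------------
    try:
        trans = optics.read_scattering_csv(sample_dir / manifest["transmission_csv"])
        spectrum = optics.spectrum_from_measurements(trans)
        fit_mask = spectrum.wavelengths <= config.m_fit_wavelength_max
        fit_spectrum = optics.ScatteringSpectrum(
            spectrum.wavelengths[fit_mask],
            spectrum.mu_s_prime_values[fit_mask],
            None if spectrum.standard_errors is None
            else spectrum.standard_errors[fit_mask],
        )
        power_fit = optics.fit_power_law(fit_spectrum)
        g = float(trans["g"].iloc[0])
        n = float(trans["n"].iloc[0])
        props = {
            float(wl): optics.OpticalProperties(
                wavelength=float(wl), n=n, mu_s=msp / (1.0 - g), g=g
            )
            for wl, msp in zip(spectrum.wavelengths, spectrum.mu_s_prime_values)
        }
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise StageError("tissue_optics", sample_id, exc) from exc

    # --- depth profiles ----------------------------------------------------
    responses = {}
    try:
        for entry in manifest["stacks"]:
            wl = float(entry["excitation_wavelength_nm"])
            pair = dp.read_stack_pair(
                sample_dir / entry["forward"],
                sample_dir / entry["backward"],
                z_step=float(entry["z_step_um"]),
                excitation_wavelength=wl,
                detector_calibration=float(entry.get("detector_calibration", 1.0)),
            )
            resp = dp.compute_depth_response([pair])
            responses[wl] = dp.normalize_attenuation(resp)
    except FileNotFoundError as exc:
        raise StageError("depth_profiles", sample_id, exc) from exc
    except Exception as exc:  # noqa: BLE001
        raise StageError("depth_profiles", sample_id, exc) from exc

    # --- Monte Carlo inversion ---------------------------------------------
    try:
        thickness_cm = max(r.depths.max() for r in responses.values()) * 1e-4
        sim_config = SimulationConfig(
            depth_grid=next(iter(responses.values())).depths * 1e-4,
            n_photons=config.n_photons,
            rng_seed=config.seed,
        )
        sweep = ext.wavelength_sweep(
            responses,
            props,
            thickness_cm,
            DetectionGeometry(),
            sim_config,
            fb_grid=config.fb_grid(),
            refine=config.refine,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("shg_extraction", sample_id, exc) from exc

    row = {"sample_id": sample_id, "tissue_label": label, "m_shape": power_fit.m}
    for wl in (390.0, 445.0, 494.0, 535.0):
        row[f"mus_prime_{int(wl)}"] = power_fit.predict([wl])[0]
    for wl, res in sorted(sweep.items()):
        row[f"fb_{int(wl)}"] = res.intrinsic_fb
        row[f"fb_err_{int(wl)}"] = res.fb_uncertainty
        row[f"eff_{int(wl)}"] = res.relative_efficiency
        row[f"chi2_{int(wl)}"] = res.chi_square
        row[f"accepted_{int(wl)}"] = res.accepted
    return row


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis over a cohort of sample directories.

    Returns the results bundle: per-sample metrics table, pairwise
    accuracy matrix and group comparisons when at least two labeled
    classes are present, plus seed and config hash.  Partial per-sample
    outputs are written before classification, so a late-stage failure
    preserves finished work.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    chash = config.config_hash()
    logger.info("pipeline start: %d samples, seed=%d, config=%s",
                len(config.sample_dirs), config.seed, chash)

    if config.n_workers > 1:
        with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
            rows = list(pool.map(lambda d: _analyze_sample(d, config),
                                 config.sample_dirs))
    else:
        rows = [_analyze_sample(d, config) for d in config.sample_dirs]

    metrics = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    metrics.insert(0, "config_hash", chash)
    metrics.insert(1, "seed", config.seed)
    metrics.to_csv(out / "metrics.csv", index=False)

    bundle: dict = {
        "metrics": metrics,
        "seed": config.seed,
        "config_hash": chash,
        "output_dir": str(out),
    }

    labels = metrics["tissue_label"]
    counts = labels.value_counts()
    feature_cols = [
        c for c in metrics.columns
        if c.split("_")[0] in ("fb", "eff", "mus", "m")
        and not c.startswith(("fb_err", "chi2", "accepted"))
    ]
    if (counts >= 2).sum() >= 2:
        ok_labels = counts[counts >= 2].index
        table = cls.FeatureTable(
            metrics[labels.isin(ok_labels)][
                ["sample_id", "tissue_label"] + feature_cols
            ].reset_index(drop=True)
        )
        accuracy = cls.pairwise_classify(table, cv=config.cv)
        accuracy.to_json(out / "pairwise_accuracy.json")
        bundle["pairwise_accuracy"] = accuracy
        comparisons = {}
        for colname in feature_cols:
            groups = {
                lab: metrics.loc[labels == lab, colname].to_numpy()
                for lab in ok_labels
            }
            try:
                comparisons[colname] = cls.group_comparison(groups)
            except ValueError:
                continue
        bundle["group_comparisons"] = comparisons

    run_info = {
        "seed": config.seed,
        "config_hash": chash,
        "n_samples": len(config.sample_dirs),
        "n_photons": config.n_photons,
    }
    (out / "run.json").write_text(json.dumps(run_info, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return bundle


def report(bundle: Mapping, output_dir=None, plots: bool = True) -> str:
    """Human-readable summary of a results bundle.

    Writes ``report.txt`` (and metric spectra plots when matplotlib
    output is requested) into the bundle's output directory;
    regeneration is idempotent.  Returns the report text.
    """
    lines = []
    metrics = bundle.get("metrics")
    if metrics is None or len(metrics) == 0:
        text = "Empty results bundle: no samples were analyzed.\n"
        if output_dir:
            Path(output_dir).mkdir(parents=True, exist_ok=True)
            (Path(output_dir) / "report.txt").write_text(text)
        return text
    out = Path(output_dir or bundle.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    lines.append(f"Samples analyzed: {len(metrics)}")
    lines.append(f"Seed: {bundle.get('seed')}   config: {bundle.get('config_hash')}")
    lines.append("")
    lines.append("Per-sample metrics:")
    lines.append(metrics.to_string(index=False))
    if "pairwise_accuracy" in bundle:
        lines.append("")
        lines.append("Pairwise classification accuracy:")
        lines.append(bundle["pairwise_accuracy"].frame.to_string())
    if "group_comparisons" in bundle:
        lines.append("")
        lines.append("Group comparisons (ANOVA p):")
        for metric, res in sorted(bundle["group_comparisons"].items()):
            lines.append(f"  {metric}: p = {res['anova_p']:.3g}")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        for _, row in metrics.iterrows():
            wls = [int(c.split("_")[-1]) for c in metrics.columns
                   if c.startswith("mus_prime_")]
            axes[0].plot(wls, [row[f"mus_prime_{w}"] for w in wls],
                         marker="o", label=row["sample_id"])
            fb_wls = sorted(int(c.split("_")[1]) for c in metrics.columns
                            if c.startswith("fb_") and c.split("_")[1].isdigit())
            if fb_wls:
                axes[1].plot(fb_wls, [row[f"fb_{w}"] for w in fb_wls], marker="s")
                axes[2].plot(fb_wls, [row[f"eff_{w}"] for w in fb_wls], marker="^")
        axes[0].set_xlabel("wavelength (nm)")
        axes[0].set_ylabel(r"$\mu_s'$ (cm$^{-1}$)")
        axes[1].set_xlabel("excitation (nm)")
        axes[1].set_ylabel(r"$F_{SHG}/B_{SHG}$")
        axes[2].set_xlabel("excitation (nm)")
        axes[2].set_ylabel("relative efficiency")
        axes[0].legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "metric_spectra.png", dpi=120)
        plt.close(fig)
    return text


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli():
    """SHG directionality + optical scattering tissue analysis."""


@cli.command("synth")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--preset", "preset_names", multiple=True,
              default=tuple(synth.builtin_presets()))
@click.option("--seed", default=0, show_default=True)
@click.option("--wavelength", "wavelengths", multiple=True, type=float,
              default=(988.0,))
def synth_cmd(out_dir, preset_names, seed, wavelengths):
    """Generate synthetic sample directories for the chosen presets."""
    presets = synth.builtin_presets()
    for i, name in enumerate(preset_names):
        sample_dir = Path(out_dir) / name
        synth.write_sample(presets[name], sample_dir, seed=seed + i,
                           excitation_wavelengths=wavelengths)
        click.echo(f"wrote {sample_dir}")


@cli.command("profiles")
@click.argument("sample_dir", type=click.Path(exists=True))
@click.option("--out", "out_csv", required=True, type=click.Path())
def profiles_cmd(sample_dir, out_csv):
    """Integrate a sample's stacks into depth-response CSV curves."""
    manifest = yaml.safe_load((Path(sample_dir) / "manifest.yaml").read_text())
    frames = []
    for entry in manifest["stacks"]:
        pair = dp.read_stack_pair(
            Path(sample_dir) / entry["forward"],
            Path(sample_dir) / entry["backward"],
            z_step=float(entry["z_step_um"]),
            excitation_wavelength=float(entry["excitation_wavelength_nm"]),
            detector_calibration=float(entry.get("detector_calibration", 1.0)),
        )
        resp = dp.normalize_attenuation(dp.compute_depth_response([pair]))
        frame = resp.to_frame()
        frame.insert(0, "excitation_wavelength_nm", entry["excitation_wavelength_nm"])
        frames.append(frame)
    pd.concat(frames).to_csv(out_csv, index=False)
    click.echo(f"wrote {out_csv}")


@cli.command("scatterfit")
@click.argument("transmission_csv", type=click.Path(exists=True))
@click.option("--out", "out_json", required=True, type=click.Path())
@click.option("--wavelength-max", default=535.0, show_default=True)
def scatterfit_cmd(transmission_csv, out_json, wavelength_max):
    """Fit the reduced-scattering power law from a transmission CSV."""
    trans = optics.read_scattering_csv(transmission_csv)
    spectrum = optics.spectrum_from_measurements(trans)
    mask = spectrum.wavelengths <= wavelength_max
    fit = optics.fit_power_law(
        optics.ScatteringSpectrum(
            spectrum.wavelengths[mask], spectrum.mu_s_prime_values[mask]
        )
    )
    fit.to_json(out_json)
    click.echo(f"m = {fit.m:.3f}  -> {out_json}")


@cli.command("extract")
@click.argument("sample_dir", type=click.Path(exists=True))
@click.option("--out", "out_csv", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True)
@click.option("--n-photons", default=4000, show_default=True)
def extract_cmd(sample_dir, out_csv, seed, n_photons):
    """Invert one sample's depth curves into F/B and efficiency."""
    config = PipelineConfig(
        sample_dirs=[sample_dir], output_dir=str(Path(out_csv).parent),
        seed=seed, n_photons=n_photons,
    )
    row = _analyze_sample(Path(sample_dir), config)
    pd.DataFrame([row]).to_csv(out_csv, index=False)
    click.echo(f"wrote {out_csv}")


@cli.command("classify")
@click.argument("features_csv", type=click.Path(exists=True))
@click.option("--out", "out_json", required=True, type=click.Path())
@click.option("--cv", default="loo", show_default=True)
def classify_cmd(features_csv, out_json, cv):
    """Pairwise canonical-discriminant classification of a feature CSV."""
    table = cls.FeatureTable.from_csv(features_csv)
    cls.pairwise_classify(table, cv=cv).to_json(out_json)
    click.echo(f"wrote {out_json}")


@cli.command("run")
@click.argument("config_yaml", type=click.Path(exists=True))
def run_cmd(config_yaml):
    """Run the full pipeline from a YAML configuration."""
    bundle = run_pipeline(PipelineConfig.from_yaml(config_yaml))
    click.echo(f"pipeline complete: {bundle['output_dir']}")


@cli.command("report")
@click.argument("output_dir", type=click.Path(exists=True))
def report_cmd(output_dir):
    """Regenerate the report from a completed run directory."""
    out = Path(output_dir)
    metrics_path = out / "metrics.csv"
    if not metrics_path.exists():
        click.echo("Empty results bundle: no metrics found.")
        return
    run_info = json.loads((out / "run.json").read_text())
    bundle = {
        "metrics": pd.read_csv(metrics_path),
        "seed": run_info["seed"],
        "config_hash": run_info["config_hash"],
        "output_dir": str(out),
    }
    click.echo(report(bundle, out))


if __name__ == "__main__":
    cli()
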