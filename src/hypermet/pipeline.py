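"""Stage orchestration: reduce -> fit -> correct -> quantify -> report.

Every run is regenerable from config + seed; the JSON report embeds the
config hash and package version, all floats at full precision.  A failed
stage halts the run and leaves a MANIFEST marking the outputs incomplete.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .exometabolome import QuantReference, assemble_timecourse, quantify_panel
from .io import PipelineConfig, read_supernatant_csv, write_dynamic_csv
from .kinetics import AcquisitionParams, DynamicSeries, correct_t1_apparent
from .model import FitConfig, fit_two_pool
from .spectra import DEFAULT_C13_PEAKS, SpectrumSeries, series_to_dynamic

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("hypermet")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _setup_logging(verbosity: int) -> None:
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    logging.basicConfig(stream=sys.stderr, level=level, format="%(name)s %(levelname)s %(message)s")


def run_pipeline(
    config: PipelineConfig,
    dynamic: DynamicSeries | None = None,
    spectra: SpectrumSeries | None = None,
    supernatant_csv: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the requested stages and write a machine-readable report.

    Stages run in order on whatever inputs are present: spectrum reduction
    (``spectra``), kinetic fitting + T1 correction (``dynamic`` or the
    reduced series), and exometabolome quantification (``supernatant_csv``).
    Returns the report dict; files go under ``out_dir``.
    """
    _setup_logging(config.verbosity)
    if dynamic is None and spectra is None and supernatant_csv is None:
        raise PipelineError("inputs", "no inputs given (need dynamic, spectra or supernatant)")

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "MANIFEST"
    manifest.write_text("INCOMPLETE\n")

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": [],
    }
    acq = AcquisitionParams(
        config.flip_angle_effective_deg, config.repetition_time_s, config.n_scans
    )

    try:
        if spectra is not None:
            log.info("reduce: integrating %d scans", spectra.n_scans)
            try:
                sub = DEFAULT_C13_PEAKS[config.substrate_peak]
                prod = DEFAULT_C13_PEAKS[config.product_peak]
            except KeyError as exc:
                raise PipelineError("reduce", f"unknown peak {exc.args[0]!r}") from None
            reduced = series_to_dynamic(spectra, sub, prod)
            write_dynamic_csv(reduced, out / "reduced_dynamic.csv")
            report["stages"].append({"stage": "reduce", "n_scans": spectra.n_scans})
            if dynamic is None:
                dynamic = reduced

        if dynamic is not None:
            log.info("fit: %d points", len(dynamic))
            try:
                results = fit_two_pool(dynamic, FitConfig(**config.fit))
            except Exception as exc:
                raise PipelineError("fit", str(exc)) from exc
            fit_report = results.to_dict()
            try:
                t1s_true, t1p_true = results.corrected_t1(acq)
                fit_report["T1_substrate_true_s"] = t1s_true
                fit_report["T1_product_true_s"] = t1p_true
            except ValueError as exc:  # apparent decay slower than pulsing loss
                fit_report["t1_correction_error"] = str(exc)
            report["stages"].append({"stage": "fit", **fit_report})
            fitted = results.fittedvalues
            write_dynamic_csv(fitted, out / "fitted_curves.csv")

        if supernatant_csv is not None:
            log.info("quantify: %s", supernatant_csv)
            try:
                panel = read_supernatant_csv(supernatant_csv)
                ref = QuantReference(
                    dss_buffer_conc_mM=config.dss_buffer_conc_mM,
                    sample_volume_uL=config.sample_volume_uL,
                    buffer_volume_uL=config.buffer_volume_uL,
                )
                conc = quantify_panel(panel, ref)
                tc = assemble_timecourse(conc)
            except Exception as exc:
                raise PipelineError("quantify", str(exc)) from exc
            profile_frame = tc.to_frame()
            profile_frame.to_csv(out / "consumption_profiles.csv", index=False, float_format="%.17g")
            report["stages"].append(
                {
                    "stage": "quantify",
                    "n_metabolites": len(tc.profiles),
                    "n_orphan_spent": int(len(tc.orphans)),
                }
            )
    except PipelineError as exc:
        manifest.write_text(f"INCOMPLETE: failed at stage {exc.stage}\n{exc}\n")
        raise

    report_path = out / "report.json"
    report_path.write_text(json.dumps(_jsonify(report), indent=1))
    manifest.write_text("COMPLETE\n" + "\n".join(
        p.name for p in sorted(out.iterdir()) if p.name != "MANIFEST"
    ) + "\n")
    log.info("report written to %s", report_path)
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonify(asdict(obj))
    return repr(obj)
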