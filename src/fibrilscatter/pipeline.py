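"""End-to-end per-sample analysis: volume fraction, form-factor fit,
Guinier/IFT cross-checks, effective structure factors, DLS reduction with
Broersma length inversion, and solubility — with per-stage error isolation
and a deterministic, auditable report.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .dls import BroersmaInputs, broersma_length, cumulant_fit, \
    siegert_normalize
from .exceptions import FibrilScatterError
from .saxs_ift import cross_section_ift, rcs_from_pddf
from .saxs_models import FibrilModel, elliptical_cylinder_pq, \
    fit_form_factor, guinier_rod_fit, sheet_count, width_from_rcs
from .scatter_io import SampleSpec, load_sample_spec, read_correlation, \
    read_curve, read_dilution_series
from .solution_props import estimate_solubility, volume_fraction
from .structure_factor import correlation_length, \
    effective_structure_factor, extrapolate_seff0, locate_peak

__all__ = ["run_pipeline", "AnalysisReport", "DEFAULT_OPTIONS"]

DEFAULT_OPTIONS = {
    "freeze_length": True,
    "dmax": 8.0,                # nm, IFT support: a little above the
                                # ~6 nm cross-section diameter
    "ift_q_min": 0.3,           # nm^-1, cross-section regime
    "ift_q_max": 3.0,
    "peak_search_q_max": 0.635,  # nm^-1; above this, concentration curves
                                 # superimpose and no correlation peak lives
    "dls_diameter": 6.0,        # nm, from the SAXS cross-section fits
    "dls_order": 2,
}


@dataclass
class AnalysisReport:
    """Structured result of :func:`run_pipeline`; serializes losslessly."""

    samples: dict
    options: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"samples": self.samples, "options": self.options,
             "provenance": self.provenance},
            indent=2, sort_keys=True, default=_jsonify)

    def to_markdown(self) -> str:
        lines = ["# Fibril analysis report", ""]
        for name, rep in sorted(self.samples.items()):
            lines.append(f"## {name}")
            for stage, payload in rep.items():
                status = payload.get("status", "ok") \
                    if isinstance(payload, dict) else "ok"
                lines.append(f"- **{stage}** [{status}]")
                if isinstance(payload, dict):
                    for key, val in sorted(payload.items()):
                        if key == "status":
                            continue
                        lines.append(f"    - {key}: {_fmt(val)}")
            lines.append("")
        lines.append(f"_fibrilscatter {self.provenance['version']}_")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _fmt(val):
    if isinstance(val, float):
        return f"{val:.6g}"
    return str(val)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(report: dict, name: str, func, *, requires=()):
    """Run one stage, recording errors instead of propagating them.

    Returns the stage payload, or None when the stage failed or a required
    upstream stage did not complete.
    """
    for dep in requires:
        dep_payload = report.get(dep)
        if not (isinstance(dep_payload, dict)
                and dep_payload.get("status") == "ok"):
            report[name] = {"status": "skipped",
                            "reason": f"requires stage {dep!r}"}
            return None
    try:
        payload = func()
    except (FibrilScatterError, ValueError, OSError) as exc:
        report[name] = {"status": "error",
                        "error": f"{type(exc).__name__}: {exc}"}
        return None
    payload["status"] = "ok"
    report[name] = payload
    return payload


def run_pipeline(config, base_dir=None) -> AnalysisReport:
    """Run the full analysis chain described by a study config.

    ``config`` is a mapping (or path to a YAML file) with a ``samples``
    list and an optional ``options`` mapping; see the shipped example.
    Every stage failure is recorded in the report and only its dependents
    are skipped.
    """
    if isinstance(config, (str, Path)):
        base_dir = base_dir or Path(config).parent
        with open(config) as fh:
            config = yaml.safe_load(fh)
    base_dir = Path(base_dir) if base_dir else Path(".")
    options = {**DEFAULT_OPTIONS, **(config.get("options") or {})}

    input_hashes = {}
    samples = {}
    for sample_cfg in config.get("samples", []):
        name = sample_cfg.get("name", f"sample-{len(samples)}")
        samples[name] = _analyze_sample(sample_cfg, options, base_dir,
                                        input_hashes)

    provenance = {
        "version": __version__,
        "input_sha256": input_hashes,
        "options": options,
    }
    return AnalysisReport(samples=samples, options=options,
                          provenance=provenance)


def _resolve(base_dir: Path, path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else base_dir / p


def _analyze_sample(cfg: dict, options: dict, base_dir: Path,
                    input_hashes: dict) -> dict:
    report: dict = {}

    spec_holder = {}

    def stage_spec():
        if "preset" in cfg:
            from .synthetic_data import get_preset
            spec = get_preset(cfg["preset"]).sample
        else:
            spec = load_sample_spec(cfg["sample_spec"])
        if "concentration_wt_percent" in cfg:
            spec = spec.with_concentration(cfg["concentration_wt_percent"])
        spec_holder["spec"] = spec
        phi = volume_fraction(spec)
        spec_holder["phi"] = phi
        return {"peptide": spec.peptide_name, "solvent": spec.solvent_name,
                "concentration_wt_percent": spec.concentration_wt_percent,
                "volume_fraction": phi}

    _stage(report, "sample", stage_spec)

    curve_holder = {}

    def stage_fit():
        entry = cfg["saxs_dilute"]
        path = _resolve(base_dir, entry["path"])
        input_hashes[str(path)] = _sha256(path)
        curve = read_curve(path)
        curve_holder["curve"] = curve
        curve_holder["concentration"] = entry.get(
            "concentration_wt_percent",
            spec_holder["spec"].concentration_wt_percent)
        spec = spec_holder["spec"]
        a0 = spec.extended_length / 2.0
        b0 = 1.5 * a0
        length = (2.0 * math.pi / curve.q[0] if options["freeze_length"]
                  else 10.0 * b0)
        init = FibrilModel(a=a0, b=b0, length=length,
                           volume_fraction=spec_holder["phi"])
        pq = elliptical_cylinder_pq(curve.q, a0, b0, length, check=False)
        ratio = curve.intensity / (init.volume * pq + 1e-300)
        scale0 = float(np.median(ratio[(curve.q > 0.05) & (curve.q < 0.5)]))
        init = replace(init, contrast=math.sqrt(
            max(scale0, 1e-12) / init.volume_fraction))
        frozen = ("length",) if options["freeze_length"] else ()
        fit = fit_form_factor(curve, init, frozen=frozen)
        return {
            "a_nm": fit.model.a, "b_nm": fit.model.b,
            "length_nm": fit.model.length,
            "length_frozen": options["freeze_length"],
            "scale": fit.model.scale,
            "background": fit.model.background,
            "stderr": fit.stderr, "redchi": fit.redchi,
            "at_bound": fit.at_bound,
            "rcs_model_nm": fit.model.rcs,
        }

    fit_payload = _stage(report, "form_factor", stage_fit,
                         requires=("sample",))

    def _subtracted():
        """Dilute curve with the fitted flat background removed, so the
        cross-section analyses see only the particle scattering."""
        from .scatter_io import ScatteringCurve
        curve = curve_holder["curve"]
        bkg = (fit_payload or {}).get("background", 0.0)
        return ScatteringCurve(curve.q, curve.intensity - bkg, curve.sigma,
                               label=curve.label, kind=curve.kind)

    def stage_guinier():
        fit = guinier_rod_fit(_subtracted())
        return {"rcs_nm": fit.rcs, "q_window": list(fit.q_window),
                "r2": fit.r2, "n_points": fit.n_points}

    guinier_payload = _stage(report, "guinier", stage_guinier,
                             requires=("form_factor",))

    def stage_ift():
        pddf = cross_section_ift(
            _subtracted(), dmax=options["dmax"],
            q_min=options["ift_q_min"], q_max=options["ift_q_max"])
        return {"rcs_nm": rcs_from_pddf(pddf),
                "dmax_nm": pddf.dmax, "lambda_reg": pddf.lambda_reg,
                "chi2_red": pddf.chi2_red}

    ift_payload = _stage(report, "ift", stage_ift, requires=("form_factor",))

    def stage_geometry():
        spec = spec_holder["spec"]
        rcs_values = {"model": fit_payload["rcs_model_nm"]}
        if guinier_payload:
            rcs_values["guinier"] = guinier_payload["rcs_nm"]
        if ift_payload:
            rcs_values["ift"] = ift_payload["rcs_nm"]
        rcs = float(np.mean(list(rcs_values.values())))
        width = width_from_rcs(rcs, spec.extended_length)
        return {"rcs_nm": rcs_values, "rcs_mean_nm": rcs,
                "thickness_2a_nm": spec.extended_length,
                "width_2b_nm": width,
                "n_sheets": sheet_count(width)}

    _stage(report, "geometry", stage_geometry, requires=("form_factor",))

    def stage_structure():
        spec = spec_holder["spec"]
        dilute = curve_holder["curve"]
        c_dil = curve_holder["concentration"]
        phi_dil = volume_fraction(spec.with_concentration(c_dil))
        bkg = (fit_payload or {}).get("background", 0.0)
        entries = []
        for entry in cfg.get("saxs_concentrated", []):
            path = _resolve(base_dir, entry["path"])
            input_hashes[str(path)] = _sha256(path)
            conc = read_curve(path)
            c_conc = entry["concentration_wt_percent"]
            phi_conc = volume_fraction(spec.with_concentration(c_conc))
            sf = effective_structure_factor(
                conc, dilute, conc_ratio=phi_conc / phi_dil,
                background_concentrated=bkg, background_dilute=bkg)
            q_peak = locate_peak(sf, q_max=options["peak_search_q_max"])
            sf.q_peak = q_peak
            item = {"concentration_wt_percent": c_conc,
                    "volume_fraction": phi_conc,
                    "q_peak_nm_inv": q_peak}
            if q_peak is not None:
                item["xi_nm"] = correlation_length(q_peak)
            try:
                s0, s0_err = extrapolate_seff0(sf)
                item["s_eff_0"] = s0
                item["s_eff_0_err"] = s0_err
            except FibrilScatterError as exc:
                item["s_eff_0_error"] = str(exc)
            entries.append(item)
        if not entries:
            raise FibrilScatterError("no concentrated curves configured")
        return {"series": entries}

    if cfg.get("saxs_concentrated"):
        _stage(report, "structure_factor", stage_structure,
               requires=("form_factor",))
    else:
        report["structure_factor"] = {"status": "skipped",
                                      "reason": "no concentrated curves"}

    def stage_dls():
        entry = cfg["dls"]
        path = _resolve(base_dir, entry["path"])
        input_hashes[str(path)] = _sha256(path)
        spec = spec_holder["spec"]
        trace = read_correlation(
            path, beta=entry.get("beta", 1.0),
            wavelength=entry.get("wavelength", 632.8),
            angle=entry.get("angle", 90.0),
            refractive_index=entry.get("refractive_index",
                                       spec.refractive_index))
        c = siegert_normalize(trace)
        cum = cumulant_fit(trace.tau, c, q=trace.q,
                           order=options["dls_order"])
        inputs = BroersmaInputs(eta=spec.solvent_viscosity,
                                temperature=spec.temperature,
                                diameter=options["dls_diameter"],
                                d_trans=cum.d_mean)
        inv = broersma_length(inputs)
        return {"gamma_mean_s_inv": cum.gamma_mean, "pdi": cum.pdi,
                "d_mean_m2_s": cum.d_mean,
                "length_nm": inv.length, "delta": inv.delta,
                "broersma_valid": inv.valid, "variant": inv.variant,
                "diameter_nm": options["dls_diameter"]}

    if "dls" in cfg:
        _stage(report, "dls", stage_dls, requires=("sample",))
    else:
        report["dls"] = {"status": "skipped", "reason": "no DLS trace"}

    def stage_solubility():
        entry = cfg["dilution"]
        path = _resolve(base_dir, entry["path"])
        input_hashes[str(path)] = _sha256(path)
        spec = spec_holder["spec"]
        series = read_dilution_series(path, entry["baseline"])
        est = estimate_solubility(series, spec.molecular_weight,
                                  spec.solvent_density)
        return {"c_s_wt_percent": est.c_s_wt_percent,
                "c_s_molar": est.c_s_molar,
                "uncertainty_wt_percent": est.uncertainty_wt_percent,
                "estimate_status": est.status, "method": est.method}

    if "dilution" in cfg:
        _stage(report, "solubility", stage_solubility, requires=("sample",))
    else:
        report["solubility"] = {"status": "skipped",
                                "reason": "no dilution series"}

    return report
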