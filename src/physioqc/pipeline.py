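"""Config-driven end-to-end quality pipeline.

``run_pipeline`` executes, per input signal, the full quality-assessment
chain: cardiac signals get the SQI pipeline (kurtosis + spectral power
ratio), beat detection, AOD cleaning, and — when a reference beat series is
given — beat-pairing validation, HRV indicators and Bland-Altman agreement;
EDA signals get the three EDA metrics.  One JSON report is written per run.

Config (dict or YAML file)::

    inputs:
      - path: ecg.csv
        kind: ecg            # ecg | bvp | eda
        fs: 256              # optional; inferred from the time column
        units: mV
        reference: beats.csv # optional, single-column beat times
    output: report.json
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io
from .beats import abd_detect, derivative_bvp_detect
from .cardiac import cardiac_sqi
from .eda import eda_sqi
from .errors import PhysioQCError
from .ibi import aod_filter, bland_altman_percent, compare_ibi, hrv_indicators, ibi_from_beats


def _analyze_cardiac(signal, kind, reference_beats=None):
    out = {"sqi": cardiac_sqi(signal, kind=kind)}
    detect = abd_detect if kind == "ecg" else derivative_bvp_detect
    beats = detect(signal)
    out["n_beats_detected"] = len(beats)
    if len(beats) >= 2:
        ibi = aod_filter(ibi_from_beats(beats))
        out["n_beats_valid"] = int(np.count_nonzero(ibi.valid))
        try:
            out["hrv"] = hrv_indicators(ibi)
        except PhysioQCError as exc:
            out["hrv_error"] = str(exc)
        if reference_beats is not None:
            out["comparison"] = compare_ibi(beats, reference_beats)
            try:
                ref_hrv = hrv_indicators(aod_filter(ibi_from_beats(reference_beats)))
                if "hrv" in out:
                    test = out["hrv"]
                    pairs_t = [test.mean_ibi, test.rmssd]
                    pairs_r = [ref_hrv.mean_ibi, ref_hrv.rmssd]
                    out["bland_altman_time_domain"] = bland_altman_percent(pairs_t, pairs_r)
                    out["reference_hrv"] = ref_hrv
            except PhysioQCError as exc:
                out["reference_hrv_error"] = str(exc)
    return out


def run_pipeline(config) -> dict:
    """Run the full procedure described by ``config``; return the report.

    Stage errors are recorded with context in the report's ``errors`` list
    and a partial report is still produced (and written, when ``output`` is
    configured).
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    results, errors, warnings_list = {}, [], []
    for entry in config.get("inputs", []):
        name = entry.get("name") or Path(entry["path"]).stem
        try:
            sig = io.read_signal_csv(entry["path"], fs=entry.get("fs"),
                                     units=entry.get("units", "a.u."),
                                     kind=entry.get("kind", "other"))
            warnings_list.extend(sig.meta.get("warnings", []))
            kind = entry.get("kind", sig.kind)
            if kind in ("ecg", "bvp"):
                ref = (io.read_beats_csv(entry["reference"])
                       if entry.get("reference") else None)
                results[name] = _analyze_cardiac(sig, kind, ref)
            elif kind == "eda":
                results[name] = {"sqi": eda_sqi(sig)}
            else:
                raise PhysioQCError(f"no pipeline for kind {kind!r}")
        except PhysioQCError as exc:
            errors.append({"input": name, "error": str(exc)})
    report = io.build_report(
        input_descriptor={"inputs": config.get("inputs", [])},
        parameters=_default_parameters(),
        results=results, warnings_list=warnings_list)
    report["errors"] = errors
    if config.get("output"):
        io.write_report(config["output"], report)
    return report


def _default_parameters() -> dict:
    """Materialize every default threshold/constant into the echoed block."""
    from . import beats, cardiac, eda, ibi

    return {
        "cardiac": {"fs": cardiac.PIPELINE_FS, "band": cardiac.PIPELINE_BAND,
                    "window_s": cardiac.WINDOW_S, "bands": cardiac.DEFAULT_BANDS,
                    "k_threshold_ecg": cardiac.K_THRESHOLD_ECG,
                    "k_threshold_bvp": cardiac.K_THRESHOLD_BVP,
                    "psi_range": cardiac.PSI_RANGE},
        "beats": {"refractory_s": beats.REFRACTORY_S,
                  "abd_range_fraction": beats.ABD_RANGE_FRACTION,
                  "abd_lookahead_s": beats.ABD_LOOKAHEAD_S},
        "ibi": {"aod_cache_size": ibi.AOD_CACHE_SIZE,
                "aod_sensitivity": ibi.AOD_SENSITIVITY,
                "pairing_tol_s": ibi.PAIRING_TOL_S,
                "hf_band": ibi.HF_BAND, "total_band": ibi.TOTAL_BAND,
                "tachogram_fs": ibi.TACHOGRAM_FS},
        "eda": {"fs": eda.EDA_FS, "lowpass_hz": eda.EDA_LOWPASS_HZ,
                "trend_cutoff_hz": eda.TREND_CUTOFF_HZ,
                "window_s": eda.WINDOW_S,
                "roor_range_uS": (eda.ROOR_LO_US, eda.ROOR_HI_US),
                "roor_good_max": eda.ROOR_GOOD_MAX,
                "jump_threshold": eda.JUMP_DN_THRESHOLD,
                "nj_good_max": eda.NJ_GOOD_MAX,
                "alpha_good_min_uS": eda.ALPHA_GOOD_MIN_US},
    }
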