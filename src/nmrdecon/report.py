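"""Machine-readable reports for a deconvolution run (CSV and JSON).

Each candidate model contributes one row per peak with its fractional
area (share of the model total), center (ppm), width (ppm and Hz when the
spectrometer frequency is known), phase, and the model-level rss / BIC /
delta-BIC.  Peaks are listed by descending fractional area.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .lineshape import fractional_areas, ppm_to_hz
from .model_selection import ModelEnsemble

CSV_COLUMNS = ["model_id", "n_peaks", "bic", "delta_bic", "peak_index",
               "frac_area", "center_ppm", "fwhm_ppm", "fwhm_hz", "phase_rad"]


def _model_id(result, index: int) -> str:
    return result.stage if result.stage else f"candidate_{index}"


def _peak_entries(result, freq_mhz):
    fracs = fractional_areas(result.model)
    order = np.argsort(fracs)[::-1]
    entries = []
    for rank, j in enumerate(order):
        pk = result.model.peaks[j]
        entries.append({
            "peak_index": int(rank),
            "frac_area": float(fracs[j]),
            "center_ppm": float(pk.center_ppm),
            "fwhm_ppm": float(pk.fwhm_ppm),
            "fwhm_hz": float(ppm_to_hz(pk.fwhm_ppm, freq_mhz))
            if freq_mhz else None,
            "phase_rad": float(pk.phase_rad),
        })
    return entries


def candidate_records(ensemble: ModelEnsemble,
                      reported_only: bool = True) -> list[dict]:
    """Flat per-peak rows for the (reported) candidates."""
    freq = ensemble.spectrum.spectrometer_freq_mhz
    best_bic = ensemble.best.bic
    results = ensemble.reported if reported_only else ensemble.candidates
    rows = []
    for i, res in enumerate(results):
        base = {
            "model_id": _model_id(res, i),
            "n_peaks": res.n_peaks,
            "bic": float(res.bic),
            "delta_bic": float(res.bic - best_bic),
        }
        peaks = _peak_entries(res, freq)
        if not peaks:
            rows.append({**base, "peak_index": None, "frac_area": None,
                         "center_ppm": None, "fwhm_ppm": None,
                         "fwhm_hz": None, "phase_rad": None})
        for entry in peaks:
            rows.append({**base, **entry})
    return rows


def ensemble_report(ensemble: ModelEnsemble) -> dict:
    """JSON-serialisable summary of a deconvolution run."""
    freq = ensemble.spectrum.spectrometer_freq_mhz
    best_bic = ensemble.best.bic

    def serialise(res, i):
        return {
            "model_id": _model_id(res, i),
            "stage": res.stage,
            "n_peaks": res.n_peaks,
            "rss": float(res.rss),
            "bic": float(res.bic),
            "delta_bic": float(res.bic - best_bic),
            "converged": bool(res.converged),
            "peaks": _peak_entries(res, freq),
        }

    opts = asdict(ensemble.options)
    return {
        "config": opts,
        "seed": ensemble.seed,
        "snr": float(ensemble.best.snr) if ensemble.best.snr is not None else None,
        "plimit": ensemble.plimit,
        "n_candidates": len(ensemble.candidates),
        "best_model_id": _model_id(ensemble.best, ensemble.best_index),
        "best_n_peaks": ensemble.best.n_peaks,
        "best_bic": float(best_bic),
        "models": [serialise(r, i) for i, r in enumerate(ensemble.reported)],
        "monte_carlo": [serialise(r, i) for i, r in
                        enumerate(ensemble.mc_results)],
        "monte_carlo_new_best": [_model_id(r, i) for i, r in
                                 enumerate(ensemble.mc_new_best)],
    }


def write_report_csv(ensemble: ModelEnsemble, path) -> None:
    df = pd.DataFrame(candidate_records(ensemble), columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def write_report_json(ensemble: ModelEnsemble, path) -> None:
    Path(path).write_text(json.dumps(ensemble_report(ensemble), indent=2)
                          + "\n")
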