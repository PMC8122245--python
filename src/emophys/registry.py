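"""Canonical feature registry.

Thirty-six physiological indexes are computed from a single-channel EEG
band-power stream and a PPG-derived inter-beat-interval (IBI) stream:

* 22 EEG indexes — the 8 sensor bands (delta, theta, low/high alpha,
  low/high beta, low/mid gamma), 3 composite bands (alpha, beta, gamma),
  and the 15-sample moving average of each of those 11;
* 14 HRV indexes — 11 time-domain (IBI, HR, CVNN, SDNN, RMSSD,
  SDNN/RMSSD, pNN10..pNN50 over a 30-beat sliding window) and 3
  frequency-domain (LF, HF, LF/HF over a trailing 200-s window).

The registry order below is the canonical column order of the extracted
feature table and the deterministic tie-break order used by the
feature-selection ensemble.
"""

from __future__ import annotations

# 8 raw sensor bands, in stream-column order
RAW_BANDS: tuple[str, ...] = (
    "delta",
    "theta",
    "low_alpha",
    "high_alpha",
    "low_beta",
    "high_beta",
    "low_gamma",
    "mid_gamma",
)

# composite wide bands derived from the raw ones
COMPOSITE_BANDS: tuple[str, ...] = ("alpha", "beta", "gamma")

# the 11 instantaneous EEG indexes, canonical order
EEG_BASE: tuple[str, ...] = (
    "theta",
    "delta",
    "low_alpha",
    "high_alpha",
    "low_beta",
    "high_beta",
    "low_gamma",
    "mid_gamma",
    "alpha",
    "beta",
    "gamma",
)

EEG_MA15: tuple[str, ...] = tuple(f"ma15_{name}" for name in EEG_BASE)

EEG_FEATURES: tuple[str, ...] = EEG_BASE + EEG_MA15  # 22

HRV_TIME: tuple[str, ...] = (
    "ibi",
    "hr",
    "cvnn",
    "sdnn",
    "rmssd",
    "sdnn_rmssd",
    "pnn10",
    "pnn20",
    "pnn30",
    "pnn40",
    "pnn50",
)

HRV_FREQ: tuple[str, ...] = ("lf", "hf", "lf_hf")

HRV_FEATURES: tuple[str, ...] = HRV_TIME + HRV_FREQ  # 14

ALL_FEATURES: tuple[str, ...] = EEG_FEATURES + HRV_FEATURES  # 36

# human-readable display names, for reports
DISPLAY_NAMES: dict[str, str] = {
    "theta": "θ",
    "delta": "δ",
    "low_alpha": "Low α",
    "high_alpha": "High α",
    "low_beta": "Low β",
    "high_beta": "High β",
    "low_gamma": "Low γ",
    "mid_gamma": "Mid γ",
    "alpha": "α",
    "beta": "β",
    "gamma": "γ",
    "ibi": "IBI",
    "hr": "HR",
    "cvnn": "CVNN",
    "sdnn": "SDNN",
    "rmssd": "RMSSD",
    "sdnn_rmssd": "SDNN/RMSSD",
    "pnn10": "pNN10",
    "pnn20": "pNN20",
    "pnn30": "pNN30",
    "pnn40": "pNN40",
    "pnn50": "pNN50",
    "lf": "LF",
    "hf": "HF",
    "lf_hf": "LF/HF",
}
DISPLAY_NAMES.update({f"ma15_{k}": f"MA15 {v}" for k, v in list(DISPLAY_NAMES.items()) if k in EEG_BASE})


def registry_index(name: str) -> int:
    """Position of ``name`` in the canonical order (tie-break key)."""
    try:
        return ALL_FEATURES.index(name)
    except ValueError:
        raise KeyError(f"unknown feature name: {name!r}") from None
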