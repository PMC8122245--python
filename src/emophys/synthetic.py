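"""Synthetic physiological study generator.

Emulates the data-collection design the pipeline targets: 25
participants each hear 8 one-minute musical stimuli (two per
Arousal–Valence quadrant), wearing a single-channel EEG band-power
sensor (~1 Hz output of 8 relative band powers) and a PPG pulse sensor
emitting inter-beat intervals (IBIs, ms).  After each trial the
participant reports a SAM (arousal, valence) rating on the 1..9 grid,
drawn here so that it labels back to the trial's target quadrant.

Class-conditional structure is planted per quadrant:

* the IBI mean (``ibi_base``) shifts per class — slower hearts for
  low-arousal quadrants;
* sinusoidal IBI modulation at 0.1 Hz and 0.3 Hz with per-class
  amplitudes plants LF-band (0.04–0.15 Hz) and HF-band (0.15–0.40 Hz)
  spectral power;
* selected EEG bands are multiplied by a per-class shift; all other
  bands are class-independent log-normal noise.

Because the frequency-domain HRV indexes need a trailing 200-s window,
each trial stream carries a lead-in segment (default 240 s, mimicking
the continuous recording through the pre-stimulus rest) with the same
class-conditional dynamics; the labelled stimulus window is the final
``trial_duration`` seconds.

Reproducibility: one global seed feeds a `numpy` SeedSequence spawned
hierarchically per participant and per trial, so output is
byte-identical for a fixed config regardless of generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import QUADRANTS, SAMRating, quadrant_label
from .registry import RAW_BANDS

__all__ = [
    "SimConfig",
    "SimulatedTrial",
    "SimulatedStudy",
    "simulate_study",
    "simulate_sam",
    "write_study",
]


def _per_class(value) -> dict[str, float]:
    """Broadcast a scalar to a per-quadrant map; pass dicts through."""
    if isinstance(value, dict):
        missing = set(QUADRANTS) - set(value)
        if missing:
            raise ValueError(f"per-class map missing quadrants: {sorted(missing)}")
        return {q: float(value[q]) for q in QUADRANTS}
    return {q: float(value) for q in QUADRANTS}


# default per-quadrant IBI means (ms): high arousal -> faster heart,
# all four classes well separated within a physiological 600-1100 ms range
_DEFAULT_IBI_BASE = {"HAHV": 600.0, "HALV": 750.0, "LAHV": 900.0, "LALV": 1050.0}
# LF (sympathetic-like, 0.1 Hz) modulation amplitude, ms
_DEFAULT_LF_AMP = {"HAHV": 40.0, "HALV": 30.0, "LAHV": 20.0, "LALV": 10.0}
# HF (parasympathetic-like, 0.3 Hz) modulation amplitude, ms
_DEFAULT_HF_AMP = {"HAHV": 10.0, "HALV": 15.0, "LAHV": 25.0, "LALV": 40.0}
# multiplicative per-class shifts on selected EEG bands
_DEFAULT_BAND_SHIFT = {
    "mid_gamma": {"HAHV": 1.6, "HALV": 1.2, "LAHV": 1.0, "LALV": 0.8},
    "delta": {"HAHV": 0.8, "HALV": 1.0, "LAHV": 1.1, "LALV": 1.3},
}
# typical relative-power scale per band (unitless, right-skewed)
_BAND_SCALE = {
    "delta": 500.0,
    "theta": 300.0,
    "low_alpha": 200.0,
    "high_alpha": 180.0,
    "low_beta": 120.0,
    "high_beta": 100.0,
    "low_gamma": 60.0,
    "mid_gamma": 40.0,
}


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Per-class parameters may be given as a scalar (same for every
    quadrant) or as a ``{quadrant: value}`` map.
    """

    n_participants: int = 25
    trials_per_participant: int = 8
    trial_duration: float = 60.0  # s of labelled stimulus per trial
    lead_in: float = 240.0  # s of pre-stimulus recording kept per trial
    eeg_rate: float = 1.0  # Hz
    ibi_base: dict | float = field(default_factory=lambda: dict(_DEFAULT_IBI_BASE))
    ibi_sd: float = 20.0  # ms, Gaussian beat-to-beat noise
    lf_mod_amp: dict | float = field(default_factory=lambda: dict(_DEFAULT_LF_AMP))
    hf_mod_amp: dict | float = field(default_factory=lambda: dict(_DEFAULT_HF_AMP))
    lf_mod_freq: float = 0.1  # Hz, inside the LF band
    hf_mod_freq: float = 0.3  # Hz, inside the HF band
    band_shift: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_BAND_SHIFT.items()})
    eeg_log_sd: float = 0.5  # sd of log band power
    ibi_floor: float = 300.0  # ms, physiological truncation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.trials_per_participant <= 0:
            raise ValueError("participant and trial counts must be positive")
        if self.trial_duration <= 0 or self.eeg_rate <= 0:
            raise ValueError("trial_duration and eeg_rate must be positive")
        if self.lead_in < 0:
            raise ValueError("lead_in must be non-negative")
        self.ibi_base = _per_class(self.ibi_base)
        if min(self.ibi_base.values()) <= 0:
            raise ValueError("ibi_base must be positive")
        if self.ibi_sd < 0:
            raise ValueError("ibi_sd must be non-negative")
        self.lf_mod_amp = _per_class(self.lf_mod_amp)
        self.hf_mod_amp = _per_class(self.hf_mod_amp)
        for band, shifts in self.band_shift.items():
            if band not in RAW_BANDS:
                raise ValueError(f"band_shift references unknown band {band!r}")
            self.band_shift[band] = _per_class(shifts)

    @property
    def informative_channels(self) -> frozenset[str]:
        """EEG bands planted as class-dependent."""
        return frozenset(
            band
            for band, shifts in self.band_shift.items()
            if len(set(shifts.values())) > 1
        )

    @property
    def total_duration(self) -> float:
        return self.lead_in + self.trial_duration

    @property
    def span(self) -> tuple[float, float]:
        """(start, stop) of the labelled stimulus window within a trial stream."""
        return (self.lead_in, self.lead_in + self.trial_duration)


@dataclass
class SimulatedTrial:
    pid: int
    trial: int
    quadrant: str
    eeg: pd.DataFrame  # time_s + 8 raw band columns
    ibi: pd.DataFrame  # time_s, ibi_ms
    sam: SAMRating


@dataclass
class SimulatedStudy:
    config: SimConfig
    trials: list[SimulatedTrial]

    @property
    def sam_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pid": [t.pid for t in self.trials],
                "trial": [t.trial for t in self.trials],
                "arousal": [t.sam.arousal for t in self.trials],
                "valence": [t.sam.valence for t in self.trials],
            }
        )

    @property
    def ground_truth(self) -> dict:
        return {
            "informative_channels": sorted(self.config.informative_channels),
            "quadrants": {
                f"{t.pid}_{t.trial}": t.quadrant for t in self.trials
            },
            "span": list(self.config.span),
        }


def simulate_sam(quadrant: str, rng: np.random.Generator, convention: str = "threshold") -> SAMRating:
    """Draw a SAM rating uniformly from the grid cells of a quadrant.

    The returned (arousal, valence) pair satisfies
    ``quadrant_label(rating, convention) == quadrant`` by construction.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}; expected one of {QUADRANTS}")
    cells = [
        (a, v)
        for a in range(1, 10)
        for v in range(1, 10)
        if quadrant_label((a, v), convention) == quadrant
    ]
    a, v = cells[rng.integers(len(cells))]
    return SAMRating(a, v)


def _simulate_ibi(config: SimConfig, quadrant: str, rng: np.random.Generator) -> pd.DataFrame:
    base = config.ibi_base[quadrant]
    lf_amp = config.lf_mod_amp[quadrant]
    hf_amp = config.hf_mod_amp[quadrant]
    times, ibis = [], []
    t = 0.0
    total = config.total_duration
    while True:
        mean = (
            base
            + lf_amp * np.sin(2 * np.pi * config.lf_mod_freq * t)
            + hf_amp * np.sin(2 * np.pi * config.hf_mod_freq * t)
        )
        ibi = max(mean + rng.normal(0.0, config.ibi_sd), config.ibi_floor)
        t += ibi / 1000.0
        if t > total:
            break
        times.append(t)
        ibis.append(ibi)
    return pd.DataFrame({"time_s": times, "ibi_ms": ibis})


def _simulate_eeg(config: SimConfig, quadrant: str, rng: np.random.Generator) -> pd.DataFrame:
    n = int(np.floor(config.total_duration * config.eeg_rate))
    times = np.arange(n) / config.eeg_rate
    data = {"time_s": times}
    for band in RAW_BANDS:
        # log-normal relative power; class shift multiplies informative bands
        values = np.exp(rng.normal(np.log(_BAND_SCALE[band]), config.eeg_log_sd, size=n))
        shift = config.band_shift.get(band)
        if shift is not None:
            values = values * shift[quadrant]
        data[band] = values
    return pd.DataFrame(data)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate the full study: streams, ratings and ground truth.

    Each participant hears ``trials_per_participant`` stimuli with target
    quadrants balanced across the four classes (two each at the default
    eight trials) in a per-participant shuffled order.
    """
    root = np.random.SeedSequence(config.seed)
    participant_seeds = root.spawn(config.n_participants)
    n_trials = config.trials_per_participant
    # balanced quadrant assignment, padded cyclically if not divisible by 4
    base_quadrants = [QUADRANTS[i % 4] for i in range(n_trials)]

    trials: list[SimulatedTrial] = []
    for pid, pseed in enumerate(participant_seeds):
        trial_seeds = pseed.spawn(n_trials)
        order_rng = np.random.default_rng(pseed.spawn(1)[0])
        quadrants = list(base_quadrants)
        order_rng.shuffle(quadrants)
        for trial, tseed in enumerate(trial_seeds):
            rng = np.random.default_rng(tseed)
            quadrant = quadrants[trial]
            eeg = _simulate_eeg(config, quadrant, rng)
            ibi = _simulate_ibi(config, quadrant, rng)
            sam = simulate_sam(quadrant, rng)
            trials.append(SimulatedTrial(pid, trial, quadrant, eeg, ibi, sam))
    return SimulatedStudy(config=config, trials=trials)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write a study as plain CSV streams plus ratings and ground truth.

    Layout: ``eeg_<pid>_<trial>.csv`` (time_s + 8 band columns),
    ``ibi_<pid>_<trial>.csv`` (time_s, ibi_ms), ``sam.csv``
    (pid, trial, arousal, valence), ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in study.trials:
        t.eeg.to_csv(outdir / f"eeg_{t.pid}_{t.trial}.csv", index=False)
        t.ibi.to_csv(outdir / f"ibi_{t.pid}_{t.trial}.csv", index=False)
    study.sam_table.to_csv(outdir / "sam.csv", index=False)
    truth = dict(study.ground_truth)
    truth["config"] = {
        k: (sorted(v) if isinstance(v, frozenset) else v)
        for k, v in dataclasses.asdict(study.config).items()
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
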