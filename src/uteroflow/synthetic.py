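"""Synthetic cine cohorts with a known outcome-generating mechanism.

No public cine-MRI dataset of uterine peristalsis exists, so this module
fabricates one with controllable signal.  Each case is a 30-frame 256x256
grayscale stack holding a static uterus phantom — an ellipse with a darker
junctional-zone band — inside an annotation rectangle.  A sinusoidal
traveling wave displaces the band vertically; its amplitude is drawn from
a class-conditional range, the outcome-generating mechanism.  Excessive
peristalsis during the implantation window is the adverse condition, so
the failure class gets the larger amplitudes by default.  Clinical tables
are drawn to match the cohort prevalences and means of the study
population (55.3% pregnancy rate, leiomyoma 38.3%, age 36.8 +/- 4.1, ...),
with per-variable missingness mirroring how often each test was actually
run (CD138 182/188, microbiome 42/188, Mycoplasma/Ureaplasma 155/188).
An optional logit shift ties the risk indicators to the outcome so that
clinical-only models also have recoverable (weaker) signal.

The phantom is deliberately not anatomically realistic MRI: downstream
stages only require motion structure inside an ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .encoding import FrameSequence, write_array_archive, write_png_sequence
from .fusion import (
    BINARY_VARS,
    ClinicalRecord,
    write_clinical_csv,
)
from .roi import AnnotationRect, write_annotations

#: Cohort prevalence of each binary indicator (fraction positive among tested).
DEFAULT_PREVALENCES = {
    "leiomyoma": 0.383,
    "adenomyosis": 0.176,
    "ovarian_endometrioma": 0.202,
    "endometrial_polyp": 0.016,
    "uterine_anomaly": 0.053,
    "oviductal_anomaly": 0.021,
    "hysteroscopy_abnormal": 0.505,
    "cd138_positive": 0.429,
    "non_lactobacillus": 0.595,
    "mycoplasma_positive": 0.200,
}

#: Fraction of cases in which each test result is unavailable
#: (182/188 CD138, 42/188 microbiome, 155/188 Mycoplasma tested).
DEFAULT_MISSING_FRACTIONS = {
    "cd138_positive": 1.0 - 182 / 188,
    "non_lactobacillus": 1.0 - 42 / 188,
    "mycoplasma_positive": 1.0 - 155 / 188,
}

#: (mean, sd) of the continuous indices.
DEFAULT_CONTINUOUS = {
    "age": (36.8, 4.1),
    "gravidity": (0.6, 1.0),
    "parity": (0.2, 0.4),
    "transfers_before": (3.7, 2.3),
    "transfers_after": (1.6, 0.9),
}


@dataclass
class SimulationConfig:
    n_cases: int = 40
    frames_per_case: int = 30
    frame_interval_s: float = 6.0
    image_size: tuple[int, int] = (256, 256)
    #: peak band displacement in pixels, per outcome class
    wave_amplitude_range_by_class: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.5, 2.0), 0: (4.0, 8.0)}
    )
    wave_frequency: float = 3.0  # cycles over the whole sequence
    wave_length_px: float = 60.0  # spatial wavelength of the traveling wave
    noise_sd: float = 2.0  # grayscale units
    pregnancy_rate: float = 0.553
    prevalence_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    missing_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_FRACTIONS)
    )
    #: logit shift applied to risk-indicator prevalences for failure cases,
    #: giving clinical-only models a weaker but recoverable signal
    clinical_signal_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames_per_case < 4:
            raise ValueError("frames_per_case must be >= 4")
        if not (0.0 < self.pregnancy_rate < 1.0):
            raise ValueError("pregnancy_rate must lie in (0, 1)")
        for name, p in self.prevalence_map.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {name!r} outside [0, 1]: {p}")
        for cls in (0, 1):
            lo, hi = self.wave_amplitude_range_by_class[cls]
            if lo < 0 or hi < lo:
                raise ValueError(f"bad amplitude range for class {cls}: ({lo}, {hi})")


@dataclass
class SyntheticCase:
    case_id: str
    sequence: FrameSequence
    annotation: AnnotationRect
    clinical: ClinicalRecord
    truth: int
    latent_amplitude: float


def _case_rng(config: SimulationConfig, case_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 7919, case_index])


def _phantom_stack(
    config: SimulationConfig,
    rng: np.random.Generator,
    amplitude: float,
) -> tuple[np.ndarray, AnnotationRect]:
    """Render the ellipse-plus-band phantom and its annotation rectangle."""
    h, w = config.image_size
    cy = h / 2.0 + rng.uniform(-h * 0.05, h * 0.05)
    cx = w / 2.0 + rng.uniform(-w * 0.05, w * 0.05)
    semi_x = w * rng.uniform(0.22, 0.28)
    semi_y = h * rng.uniform(0.15, 0.20)
    band_half = max(3.0, h * 0.02)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    ellipse = ((xx - cx) / semi_x) ** 2 + ((yy - cy) / semi_y) ** 2 <= 1.0

    frames = np.empty((config.frames_per_case, h, w), dtype=np.float64)
    t_denom = max(config.frames_per_case - 1, 1)
    for t in range(config.frames_per_case):
        # traveling wave: band center line oscillates along x and in time
        delta = amplitude * np.sin(
            2.0 * np.pi * (xx / config.wave_length_px
                           - config.wave_frequency * t / t_denom)
            + phase
        )
        band = np.abs(yy - (cy + delta)) <= band_half
        img = np.full((h, w), 40.0)
        img[ellipse] = 160.0
        img[band & ellipse] = 90.0
        frames[t] = img
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)
    np.clip(frames, 0.0, 255.0, out=frames)

    margin = 6.0
    rect = AnnotationRect(
        case_id="",
        x0=max(0, int(np.floor(cx - semi_x - margin))),
        y0=max(0, int(np.floor(cy - semi_y - amplitude - margin))),
        x1=min(w, int(np.ceil(cx + semi_x + margin))),
        y1=min(h, int(np.ceil(cy + semi_y + amplitude + margin))),
    )
    return frames, rect


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_clinical(
    config: SimulationConfig,
    rng: np.random.Generator,
    case_id: str,
    truth: int,
) -> ClinicalRecord:
    kwargs: dict = {"case_id": case_id, "truth": truth}
    mean, sd = DEFAULT_CONTINUOUS["age"]
    # failure cases skew slightly older — part of the clinical signal
    age_shift = config.clinical_signal_weight * (1 - truth)
    kwargs["age"] = float(np.clip(rng.normal(mean + age_shift, sd), 25.0, 47.0))
    kwargs["gravidity"] = int(rng.poisson(DEFAULT_CONTINUOUS["gravidity"][0]))
    kwargs["parity"] = int(min(rng.poisson(DEFAULT_CONTINUOUS["parity"][0]),
                               kwargs["gravidity"]))
    mean, sd = DEFAULT_CONTINUOUS["transfers_before"]
    kwargs["transfers_before"] = int(max(2, round(rng.normal(mean, sd))))
    mean, sd = DEFAULT_CONTINUOUS["transfers_after"]
    kwargs["transfers_after"] = int(max(1, round(rng.normal(mean, sd))))
    for name in BINARY_VARS:
        p0 = config.prevalence_map.get(name, 0.0)
        if 0.0 < p0 < 1.0:
            logit = np.log(p0 / (1.0 - p0))
            p = _sigmoid(logit + config.clinical_signal_weight * (1 - 2 * truth))
        else:
            p = p0
        value: int | None = int(rng.random() < p)
        if rng.random() < config.missing_fractions.get(name, 0.0):
            value = None
        kwargs[name] = value
    return ClinicalRecord(**kwargs)


def generate_case(
    config: SimulationConfig, case_index: int, truth: int
) -> SyntheticCase:
    """Generate one case; identical (config, case_index, truth) is
    bit-identical."""
    if case_index < 0:
        raise ValueError("case_index must be >= 0")
    if truth not in (0, 1):
        raise ValueError("truth must be 0 or 1")
    rng = _case_rng(config, case_index)
    lo, hi = config.wave_amplitude_range_by_class[truth]
    amplitude = float(rng.uniform(lo, hi))
    frames, rect = _phantom_stack(config, rng, amplitude)
    case_id = f"case_{case_index:04d}"
    rect.case_id = case_id
    clinical = _draw_clinical(config, rng, case_id, truth)
    return SyntheticCase(
        case_id=case_id,
        sequence=FrameSequence(
            case_id=case_id,
            frames=frames,
            frame_interval_s=config.frame_interval_s,
        ),
        annotation=rect,
        clinical=clinical,
        truth=truth,
        latent_amplitude=amplitude,
    )


def generate_cohort(config: SimulationConfig) -> list[SyntheticCase]:
    """Generate the full cohort; exactly round(n x rate) positive cases."""
    if config.n_cases < 2:
        raise ValueError("need n_cases >= 2 to form a cohort")
    n_pos = int(round(config.n_cases * config.pregnancy_rate))
    truths = np.zeros(config.n_cases, dtype=int)
    truths[:n_pos] = 1
    np.random.default_rng([config.seed, 104729]).shuffle(truths)
    return [
        generate_case(config, i, int(truths[i])) for i in range(config.n_cases)
    ]


def motion_energy(seq: FrameSequence, rect: AnnotationRect) -> float:
    """Mean per-pixel absolute inter-frame difference inside the rectangle.

    A CNN-free oracle for the class signal: higher wave amplitude produces
    higher motion energy.
    """
    sub = seq.frames[:, rect.y0 : rect.y1, rect.x0 : rect.x1]
    return float(np.abs(np.diff(sub, axis=0)).mean())


def write_cohort(cases: Iterable[SyntheticCase], out_dir: str | Path) -> dict:
    """Write PNG frame sequences, an array archive, annotations and the
    clinical CSV under ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = list(cases)
    frame_dirs = {}
    for case in cases:
        frame_dir = out_dir / "frames" / case.case_id
        write_png_sequence(case.sequence, frame_dir)
        frame_dirs[case.case_id] = frame_dir
    archive = write_array_archive(
        (c.sequence for c in cases), out_dir / "cohort.npz"
    )
    annotations = write_annotations(
        {c.case_id: c.annotation for c in cases}, out_dir / "annotations.csv"
    )
    clinical_path = out_dir / "clinical.csv"
    write_clinical_csv((c.clinical for c in cases), clinical_path)
    return {
        "frames": frame_dirs,
        "archive": archive,
        "annotations": annotations,
        "clinical": clinical_path,
    }
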