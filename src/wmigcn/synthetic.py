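"""Synthetic 12-lead ECG-like records with cluster-structured lead coupling.

The generator produces abstract band-limited signals, not morphologically
faithful PQRST complexes: the downstream pipeline consumes only the
statistical structure between leads, so each record is a mixture of

* one global quasi-periodic source ``g(t)`` — a harmonic stack at the class
  beat rate with per-record phase jitter (every lead sees it; the analogue of
  the shared cardiac drive),
* three cluster sources — independent low-pass-filtered noise processes, one
  per pole cluster (bipolar limb, unipolar limb, precordial), shared by the
  leads of that cluster only, and
* per-lead private noise, band-limited with the same low-pass filter as the
  cluster sources so that single-lead marginal spectra are (up to the beat
  line) identical across classes — the classes differ in inter-lead
  structure, which is what the pipeline is meant to detect.

Lead i of a record from class ``c`` is

    lead_i(t) = gain_i * [ beta*g(t) + alpha*s_{cluster(i)}(t)
                           + (1 - alpha - beta)*eps_i(t) ]

with all sources scaled to unit variance, so ``alpha`` (within-cluster
coupling) and ``beta`` (global coupling) are interpretable mixing weights.
Classes differ by beat rate and coupling strength, mirroring a rate-defined
rhythm taxonomy (bradycardia-like / normal-rate / tachycardia-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io import DatasetManifest, ECGRecord, LEAD_ORDER, N_LEADS, write_record, write_manifest
from .structure import Cluster, DEFAULT_CLUSTER_MAP

#: Fixed per-lead amplitude gains (mV-ish scale differences between leads).
LEAD_GAINS = np.array(
    [1.0, 1.2, 0.8, 0.7, 0.6, 0.9, 0.8, 1.1, 1.3, 1.4, 1.2, 1.0]
)

_HARMONIC_AMPLITUDES = np.array([1.0, 0.5, 0.25])


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters for one rhythm class."""

    name: str
    beat_rate_hz: float
    within_cluster_coupling: float  # alpha, in [0, 1]
    global_coupling: float = 0.3  # beta, in [0, 1]
    noise_sd: float = 1.0
    waveform_jitter: float = math.pi  # phase jitter sd (radians) per harmonic

    def __post_init__(self) -> None:
        a, b = self.within_cluster_coupling, self.global_coupling
        if not (0 <= a <= 1 and 0 <= b <= 1 and a + b <= 1):
            raise ValueError("need alpha, beta in [0,1] with alpha + beta <= 1")
        if not (0.5 < self.beat_rate_hz < 5.0):
            raise ValueError("beat rate must lie in (0.5, 5) Hz (30-300 bpm)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic dataset description."""

    classes: tuple[ClassSpec, ...]
    n_records_per_class: int = 50
    n_samples: int = 2500
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        pairs = {
            (c.beat_rate_hz, c.within_cluster_coupling) for c in self.classes
        }
        if len(pairs) != len(self.classes):
            raise ValueError("classes must have distinct (rate, alpha) pairs")
        if self.n_records_per_class < 1 or self.n_samples < 2:
            raise ValueError("need at least 1 record and 2 samples")


def default_spec(
    n_records_per_class: int = 50, seed: int = 0, n_samples: int = 2500
) -> SyntheticSpec:
    """The shipped three-class spec: SB-like, SR-like and ST-like rhythms."""
    return SyntheticSpec(
        classes=(
            ClassSpec("SB", beat_rate_hz=1.0, within_cluster_coupling=0.5),
            ClassSpec("SR", beat_rate_hz=1.3, within_cluster_coupling=0.5),
            ClassSpec("ST", beat_rate_hz=2.0, within_cluster_coupling=0.6),
        ),
        n_records_per_class=n_records_per_class,
        n_samples=n_samples,
        fs=250.0,
        seed=seed,
    )


def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x if sd == 0 else x / sd


def _global_source(
    cls: ClassSpec, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    g = np.zeros_like(t)
    for h, amp in enumerate(_HARMONIC_AMPLITUDES, start=1):
        phase = cls.waveform_jitter * rng.standard_normal()
        g += amp * np.sin(2 * np.pi * h * cls.beat_rate_hz * t + phase)
    return _unit_sd(g)


def _cluster_source(
    n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    # low-pass filtered white noise, passband ~0-8 Hz
    b, a = sps.butter(4, 8.0 / (fs / 2), btype="low")
    return _unit_sd(sps.filtfilt(b, a, rng.standard_normal(n)))


def generate_record(
    cls: ClassSpec,
    rng: np.random.Generator,
    record_id: str = "synthetic",
    n_samples: int = 2500,
    fs: float = 250.0,
) -> ECGRecord:
    """Draw one record from a class spec using the supplied random stream."""
    t = np.arange(n_samples) / fs
    alpha, beta = cls.within_cluster_coupling, cls.global_coupling
    g = _global_source(cls, t, rng)
    cluster_sources = {
        c: _cluster_source(n_samples, fs, rng)
        for c in (Cluster.BIPOLAR_LIMB, Cluster.UNIPOLAR_LIMB, Cluster.PRECORDIAL)
    }
    sig = np.empty((N_LEADS, n_samples))
    for i, name in enumerate(LEAD_ORDER):
        eps = cls.noise_sd * _cluster_source(n_samples, fs, rng)
        mix = (
            beta * g
            + alpha * cluster_sources[DEFAULT_CLUSTER_MAP[name]]
            + (1.0 - alpha - beta) * eps
        )
        sig[i] = LEAD_GAINS[i] * mix
    return ECGRecord(
        record_id=record_id,
        signal=sig,
        leads=LEAD_ORDER,
        sampling_rate_hz=fs,
        label=cls.name,
    )


def _record_rng(master_seed: int, class_index: int, record_index: int) -> np.random.Generator:
    # one named stream per record id: reproducible under partial regeneration
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(class_index, record_index)
    )
    return np.random.default_rng(ss)


def generate_dataset(
    spec: SyntheticSpec,
    rare_class: Optional[ClassSpec] = None,
    rare_fraction: float = 0.01,
) -> tuple[list[ECGRecord], DatasetManifest]:
    """Generate ``n_records_per_class`` records per class, reproducibly.

    ``rare_class`` optionally injects a minority class at ``rare_fraction`` of
    the main total (at least one record), to exercise class-frequency
    filtering downstream.
    """
    records: list[ECGRecord] = []
    for ci, cls in enumerate(spec.classes):
        for ri in range(spec.n_records_per_class):
            rng = _record_rng(spec.seed, ci, ri)
            rid = f"{cls.name}_{ri:04d}"
            records.append(
                generate_record(cls, rng, rid, spec.n_samples, spec.fs)
            )
    if rare_class is not None:
        n_rare = max(1, int(round(rare_fraction * len(records))))
        for ri in range(n_rare):
            rng = _record_rng(spec.seed, len(spec.classes), ri)
            rid = f"{rare_class.name}_{ri:04d}"
            records.append(
                generate_record(rare_class, rng, rid, spec.n_samples, spec.fs)
            )
    manifest = DatasetManifest(
        records=[(r.record_id, None, r.label) for r in records]
    )
    return records, manifest


def write_dataset(
    records: list[ECGRecord],
    manifest: DatasetManifest,
    directory: str | Path,
) -> None:
    """Write records in the per-record CSV dialect plus a label table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_record(rec, directory / f"{rec.record_id}.csv")
    rows = [
        (rid, str(directory / f"{rid}.csv"), label)
        for rid, _, label in manifest.records
    ]
    write_manifest(DatasetManifest(records=rows), directory / "labels.csv")


def dominant_frequency(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.5, 5.0)
) -> float:
    """Peak of the periodogram of ``x`` restricted to a physiological band."""
    freqs, psd = sps.periodogram(x, fs=fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[mask][np.argmax(psd[mask])])
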