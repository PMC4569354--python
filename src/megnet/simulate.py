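"""Synthetic resting-state MEG cohorts with planted lagged coupling.

Source dynamics are narrow-band filtered Gaussian noise.  A coupled node
pair shares a common band-limited signal, one member receiving a
Hilbert-phase-shifted copy mixed with independent noise so that the
source-level coherence magnitude equals the coupling strength and the
coherency phase equals the imposed lag.  "Patient" subjects get every
coupling strength multiplied by a planted group effect; with the
multiplier at 1 the two groups are statistically exchangeable, which is
the null construction used by the type-I-error suites.

Sensor data are the lead-field projection of all source signals plus
white Gaussian channel noise.  One master seed deterministically derives
per-subject seeds (master + subject ordinal), so cohorts are reproducible
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .forward import LeadField
from .geometry import SensorArray, SourceGrid
from .preprocessing import EpochedRecording
from .spectral import CANONICAL_BANDS, FrequencyBand, get_band

__all__ = [
    "ActiveSource",
    "CoupledPair",
    "SimulationConfig",
    "simulate_subject",
    "make_cohort",
    "narrowband_noise",
    "phase_shift",
]


@dataclass(frozen=True)
class ActiveSource:
    """Independent band-limited source at one grid node."""

    node: int
    orientation: tuple[float, float, float]
    band: str
    amplitude: float = 1.0  # relative to SimulationConfig.dipole_moment


@dataclass(frozen=True)
class CoupledPair:
    """Two nodes sharing a band-limited signal at a fixed phase lag.

    Pairs carrying the same ``signal_id`` reuse one base signal, so a set
    of pairs can plant a coherent clump whose every cross-clump edge is
    elevated (a dense-subgraph effect); with the default ``None`` each
    pair draws independent signals.  A node should appear in at most one
    pair of a signal group — repeated nodes superpose their dipoles.
    """

    node_a: int
    node_b: int
    band: str
    phase_lag: float
    coupling_strength: float
    amplitude: float = 1.0
    signal_id: str | None = None

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("cannot couple a node with itself")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if np.isclose(self.phase_lag % np.pi, 0.0):
            raise ValueError(
                "phase lag of 0 or pi yields purely real coherency and is "
                "invisible to imaginary coherence; choose a lag strictly "
                "between"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the study conditions: 13 patients vs 19 controls,
    30 epochs of 10 s per subject at 409.6 Hz.
    """

    n_subjects_per_group: tuple[int, int] = (13, 19)  # (patients, controls)
    n_epochs: int = 30
    epoch_length_s: float = 10.0
    fs: float = 409.6
    active_nodes: tuple[ActiveSource, ...] = ()
    coupled_pairs: tuple[CoupledPair, ...] = ()
    planted_group_effect: float = 1.0
    sensor_noise_sd: float = 5e-14  # tesla
    dipole_moment: float = 1e-8  # A·m, typical cortical patch strength
    seed: int = 0
    group_labels: tuple[str, str] = ("patient", "control")

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.planted_group_effect < 0:
            raise ValueError("planted_group_effect must be non-negative")

    @property
    def n_samples_per_epoch(self) -> int:
        return int(round(self.epoch_length_s * self.fs))


def narrowband_noise(
    rng: np.random.Generator, band: FrequencyBand, n_samples: int, fs: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal(n_samples)
    # steep edges keep planted effects out of neighbouring analysis bands
    if band.low <= 0:
        sos = sps.butter(6, band.high, btype="lowpass", fs=fs, output="sos")
    else:
        sos = sps.butter(6, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def phase_shift(x: np.ndarray, lag_radians: float) -> np.ndarray:
    """Rotate the analytic phase of a narrow-band signal by ``lag_radians``.

    For a narrow-band signal this delays every in-band component by the
    same phase angle, the construction that plants a controllable lag for
    imaginary-coherence recovery.
    """
    analytic = sps.hilbert(x)
    return np.real(analytic * np.exp(-1j * lag_radians))


def _tangential_orientation(position: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Deterministic unit vector tangential to the radial direction."""
    radial = position - center
    nrm = np.linalg.norm(radial)
    if nrm < 1e-12:
        return np.array([1.0, 0.0, 0.0])
    radial = radial / nrm
    ref = np.array([0.0, 0.0, 1.0])
    if abs(radial @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    tang = np.cross(radial, ref)
    return tang / np.linalg.norm(tang)


def _gain_column(lf: LeadField, node: int, orientation: np.ndarray) -> np.ndarray:
    return lf.node_gain(node) @ np.asarray(orientation, dtype=float)


def exchangeable_strength_maps(
    rng: np.random.Generator,
    n_a: int,
    n_b: int,
    positions: np.ndarray,
    smoothness_m: float = 0.03,
    subject_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Null cohorts of spatially smooth per-node maps, iid across subjects.

    Every subject's map is one shared smooth base field plus an
    independent smooth subject field (Gaussian-kernel-correlated over the
    node positions), so group labels carry no information — the
    construction behind the type-I-error suites.  Returns
    ``(maps_a, maps_b)`` of shapes (n_a, n_nodes) and (n_b, n_nodes).
    """
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    K = np.exp(-0.5 * (d / smoothness_m) ** 2)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(len(positions)))
    base = L @ rng.standard_normal(len(positions))
    maps = base[None, :] + subject_sd * (rng.standard_normal((n_a + n_b, len(positions))) @ L.T)
    return maps[:n_a], maps[n_a:]


def exchangeable_networks(
    rng: np.random.Generator,
    n_a: int,
    n_b: int,
    n_nodes: int,
    base_weight: float = 0.15,
    subject_sd: float = 0.04,
) -> tuple[np.ndarray, np.ndarray]:
    """Null cohorts of weighted networks, iid across subjects.

    Each subject's adjacency is a shared random base matrix plus
    independent symmetric noise, clipped to [0, 1] — exchangeable between
    groups by construction.
    """
    iu = np.triu_indices(n_nodes, k=1)
    base = rng.uniform(0.5 * base_weight, 1.5 * base_weight, size=len(iu[0]))
    nets = []
    for _ in range(n_a + n_b):
        w = np.clip(base + subject_sd * rng.standard_normal(len(iu[0])), 0.0, 1.0)
        A = np.zeros((n_nodes, n_nodes))
        A[iu] = w
        nets.append(A + A.T)
    nets = np.array(nets)
    return nets[:n_a], nets[n_a:]


def planted_clump_config(
    grid: SourceGrid,
    band: str = "beta2",
    clump_centers: tuple = ((0.03, 0.03, 0.03), (-0.03, -0.03, 0.03)),
    clump_size: int = 5,
    base_coupling: float = 0.28,
    planted_group_effect: float = 1.5,
    phase_lag: float = np.pi / 2,
    n_subjects_per_group: tuple[int, int] = (13, 19),
    n_epochs: int = 30,
    epoch_length_s: float = 2.0,
    fs: float = 256.0,
    sensor_noise_sd: float = 1.5e-14,
    seed: int = 0,
) -> tuple[SimulationConfig, dict]:
    """Study-condition cohort config: two coherent clumps with lagged coupling.

    Two clumps of ``clump_size`` grid nodes nearest the given centres share
    one band-limited signal per clump side, the second clump lagged by
    ``phase_lag``; every cross-clump edge is elevated.  With the defaults
    the planted coupling increase yields an effect of about d = 2 on the
    clump-to-clump regional edge weight between groups of 13 and 19
    subjects.  Returns the config plus the ground-truth node sets.
    """
    clumps = []
    for center in clump_centers:
        dist = np.linalg.norm(grid.positions - np.asarray(center), axis=1)
        clumps.append([int(i) for i in np.argsort(dist)[:clump_size]])
    pairs = tuple(
        CoupledPair(a, b, band, phase_lag, base_coupling, signal_id="clump")
        for a, b in zip(*clumps)
    )
    cfg = SimulationConfig(
        n_subjects_per_group=n_subjects_per_group,
        n_epochs=n_epochs,
        epoch_length_s=epoch_length_s,
        fs=fs,
        coupled_pairs=pairs,
        planted_group_effect=planted_group_effect,
        sensor_noise_sd=sensor_noise_sd,
        seed=seed,
    )
    truth = {"clump_a": clumps[0], "clump_b": clumps[1],
             "planted_nodes": sorted(clumps[0] + clumps[1]), "band": band}
    return cfg, truth


def simulate_subject(
    config: SimulationConfig,
    grid: SourceGrid,
    lf: LeadField,
    sensors: SensorArray,
    group: str,
) -> tuple[EpochedRecording, dict]:
    """One subject's epoched sensor recording plus a ground-truth record.

    Coupled pairs get tangential dipole orientations derived
    deterministically from the node position; group membership in
    ``config.group_labels[0]`` multiplies every coupling strength by
    ``config.planted_group_effect`` (clipped nowhere — strengths above 1
    raise).  Returns the recording and a dict with the realized SNR and
    per-source bookkeeping.
    """
    if group not in config.group_labels:
        raise ValueError(f"unknown group {group!r}")
    for src in config.active_nodes:
        if not 0 <= src.node < grid.n_nodes:
            raise ValueError(f"active node {src.node} outside grid")
    for pair in config.coupled_pairs:
        for nd in (pair.node_a, pair.node_b):
            if not 0 <= nd < grid.n_nodes:
                raise ValueError(f"coupled node {nd} outside grid")

    rng = np.random.default_rng(config.seed)
    n_total = config.n_epochs * config.n_samples_per_epoch
    n_chan = sensors.count
    center = grid.positions.mean(axis=0)

    signal_part = np.zeros((n_chan, n_total))

    effect = config.planted_group_effect if group == config.group_labels[0] else 1.0

    for src in config.active_nodes:
        band = get_band(src.band)
        s = narrowband_noise(rng, band, n_total, config.fs)
        col = _gain_column(lf, src.node, src.orientation)
        signal_part += np.outer(col, s) * (src.amplitude * config.dipole_moment)

    signal_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pair in config.coupled_pairs:
        band = get_band(pair.band)
        c = pair.coupling_strength * effect
        if c > 1.0 + 1e-12:
            raise ValueError(
                f"planted effect {effect} pushes coupling {pair.coupling_strength} "
                f"above 1"
            )
        c = min(c, 1.0)
        if pair.signal_id is not None and pair.signal_id in signal_cache:
            common, indep = signal_cache[pair.signal_id]
        else:
            common = narrowband_noise(rng, band, n_total, config.fs)
            indep = narrowband_noise(rng, band, n_total, config.fs)
            if pair.signal_id is not None:
                signal_cache[pair.signal_id] = (common, indep)
        s_a = common
        s_b = c * phase_shift(common, pair.phase_lag) + np.sqrt(1 - c**2) * indep
        for node, s in ((pair.node_a, s_a), (pair.node_b, s_b)):
            ori = _tangential_orientation(grid.positions[node], center)
            col = _gain_column(lf, node, ori)
            signal_part += np.outer(col, s) * (pair.amplitude * config.dipole_moment)

    noise = rng.standard_normal((n_chan, n_total)) * config.sensor_noise_sd
    x = signal_part + noise

    rms_sig = float(np.sqrt(np.mean(signal_part**2)))
    rms_noise = float(np.sqrt(np.mean(noise**2)))
    snr = rms_sig / rms_noise if rms_noise > 0 else np.inf

    data = x.reshape(n_chan, config.n_epochs, config.n_samples_per_epoch)
    data = np.transpose(data, (1, 0, 2))
    rec = EpochedRecording(
        data=data, fs=config.fs, sensors=sensors, epoch_length_s=config.epoch_length_s
    )
    info = {"group": group, "seed": int(config.seed), "snr": snr,
            "coupling_effect": effect}
    return rec, info


def make_cohort(
    config: SimulationConfig,
    grid: SourceGrid,
    lf: LeadField,
    sensors: SensorArray,
) -> tuple[list[tuple[str, str, EpochedRecording]], dict]:
    """Simulate both groups and assemble the ground-truth manifest.

    Returns ``(subjects, manifest)`` where ``subjects`` is a list of
    ``(subject_id, group, recording)`` and the manifest records every
    planted pair, the affected node set, per-subject seeds and SNRs.
    """
    n_pat, n_ctl = config.n_subjects_per_group
    if min(n_pat, n_ctl) < 2:
        raise ValueError("need at least 2 subjects per group")
    subjects: list[tuple[str, str, EpochedRecording]] = []
    manifest: dict = {
        "master_seed": int(config.seed),
        "groups": {config.group_labels[0]: n_pat, config.group_labels[1]: n_ctl},
        "planted_pairs": [
            {
                "node_a": p.node_a,
                "node_b": p.node_b,
                "band": p.band,
                "phase_lag": p.phase_lag,
                "coupling_strength": p.coupling_strength,
            }
            for p in config.coupled_pairs
        ],
        "planted_group_effect": config.planted_group_effect,
        "planted_nodes": sorted(
            {p.node_a for p in config.coupled_pairs}
            | {p.node_b for p in config.coupled_pairs}
        ),
        "subjects": [],
    }
    ordinal = 0
    for group, n_group in zip(config.group_labels, (n_pat, n_ctl)):
        for k in range(n_group):
            subj_seed = config.seed + ordinal
            subj_cfg = replace(config, seed=subj_seed)
            sid = f"{group}{k:02d}"
            rec, info = simulate_subject(subj_cfg, grid, lf, sensors, group)
            subjects.append((sid, group, rec))
            manifest["subjects"].append(
                {"id": sid, "group": group, "seed": int(subj_seed), "snr": info["snr"]}
            )
            ordinal += 1
    return subjects, manifest
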