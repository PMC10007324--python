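"""Seeded synthetic stress-profile recordings with known ground truth.

The generator models what the RSI actually measures — the geometry of
per-stage cluster means — rather than biophysically detailed waveforms.
Each channel holds a stage-dependent level:

* baseline stages sit at the configured resting level;
* stressor stages are displaced by the per-channel reactivity (skin
  conductance and respiration rise under sympathetic arousal, blood
  volume pulse falls);
* recovery stages relieve a fraction of the preceding stressor's
  excursion;
* the final stage's level is placed on the straight segment from the
  penultimate stage's level back to baseline, at position ρ (the
  *final-recovery* parameter): ρ = 1 is complete return to baseline,
  ρ = 0 no recovery at all.

On top of the stage levels the generator superposes cardiac-band and
respiratory-band oscillations, white noise, a slowly drifting AR(1)
component on skin conductance, and Poisson-timed impulse artifacts —
the features the median filter and standard scaler are there to handle.
By construction the ground-truth RSI of a noise-free subject equals ρ,
which makes the full pipeline testable end to end without any recorded
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import CHANNELS, ProtocolDefinition, Recording

__all__ = [
    "SubjectSimConfig",
    "CohortSimConfig",
    "stage_levels",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SubjectSimConfig:
    """Ground-truth parameters for one simulated subject-session.

    Channel order everywhere is (blood_volume_pulse [%], respiration [%],
    skin_conductance [uS]).  Default levels and excursions follow typical
    resting biofeedback readings: BVP around 36%, abdominal respiration
    around 33%, skin conductance a few micro-Siemens, with stress raising
    conductance and respiration and lowering BVP.
    """

    baseline_means: tuple[float, float, float] = (36.0, 33.0, 4.4)
    reactivity: tuple[float, float, float] = (-2.0, 2.5, 1.5)
    recovery_fraction: float = 0.6
    final_recovery: float = 0.5  # rho
    osc_amplitude: tuple[float, float, float] = (1.5, 1.2, 0.0)
    osc_freq_hz: tuple[float, float, float] = (1.2, 0.25, 0.0)
    noise_sd: tuple[float, float, float] = (0.5, 0.4, 0.05)
    ar_phi: float = 0.98  # first-order autocorrelation of the SC drift
    ar_sd: float = 0.02  # innovation SD of the SC drift
    artifact_rate_per_min: float = 1.0
    artifact_amplitude: float = 30.0
    artifact_duration_samples: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.final_recovery <= 1.0:
            raise ValueError("final_recovery must lie in [0, 1]")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must lie in [0, 1]")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ValueError("ar_phi must lie in [0, 1)")
        if self.artifact_rate_per_min < 0 or self.artifact_amplitude < 0:
            raise ValueError("artifact parameters must be >= 0")


def stage_levels(config: SubjectSimConfig, protocol: ProtocolDefinition) -> np.ndarray:
    """Ground-truth per-stage channel levels, shape (n_stages, 3).

    Stressors add the full reactivity; each recovery stage retains
    (1 - recovery_fraction) of the preceding stressor's excursion; the
    final stage is interpolated by ρ from the penultimate stage's level
    back to baseline.
    """
    base = np.asarray(config.baseline_means, dtype=float)
    react = np.asarray(config.reactivity, dtype=float)
    levels = np.empty((protocol.n_stages, base.size))
    last_excursion = np.zeros_like(base)
    for i, stage in enumerate(protocol.stages):
        if stage.role == "baseline":
            levels[i] = base
        elif stage.role == "stressor":
            last_excursion = react
            levels[i] = base + react
        else:  # recovery
            levels[i] = base + (1.0 - config.recovery_fraction) * last_excursion
    # Final stage: position rho on the segment from the penultimate stage
    # level back to baseline.  Convex-combination form so the endpoints are
    # exact: rho = 1 is bit-identical to baseline, rho = 0 to the
    # penultimate level.
    rho = config.final_recovery
    levels[-1] = (1.0 - rho) * levels[-2] + rho * base
    return levels


def simulate_subject(
    config: SubjectSimConfig,
    protocol: ProtocolDefinition,
    *,
    subject_id: str = "sim",
    session: str = "other",
) -> Recording:
    """Generate one protocol-conformant multichannel recording.

    Deterministic given ``config.seed``: the same configuration always
    produces a bit-identical recording.
    """
    rng = np.random.default_rng(config.seed)
    fs = protocol.sampling_rate
    counts = protocol.stage_samples()
    n = sum(counts)
    t = np.arange(n) / fs
    levels = stage_levels(config, protocol)

    # Piecewise-constant stage levels.
    X = np.repeat(levels, counts, axis=0).astype(float)

    # Band-limited oscillations with random phase per channel.
    for j in range(3):
        amp, freq = config.osc_amplitude[j], config.osc_freq_hz[j]
        if amp > 0 and freq > 0:
            phase = rng.uniform(0, 2 * np.pi)
            X[:, j] += amp * np.sin(2 * np.pi * freq * t + phase)

    # White measurement noise.
    for j in range(3):
        if config.noise_sd[j] > 0:
            X[:, j] += rng.normal(0.0, config.noise_sd[j], size=n)

    # Slow AR(1) drift on skin conductance (tonic electrodermal level).
    if config.ar_sd > 0:
        from scipy.signal import lfilter

        eps = rng.normal(0.0, config.ar_sd, size=n)
        drift = lfilter([1.0], [1.0, -config.ar_phi], eps)
        X[:, 2] += drift

    # Poisson-timed impulse artifacts (electrode pops, motion transients),
    # independent per channel, short rectangular bursts of random sign.
    if config.artifact_rate_per_min > 0 and config.artifact_amplitude > 0:
        minutes = n / fs / 60.0
        dur = max(1, int(config.artifact_duration_samples))
        for j in range(3):
            n_art = rng.poisson(config.artifact_rate_per_min * minutes)
            starts = rng.integers(0, max(1, n - dur), size=n_art)
            signs = rng.choice([-1.0, 1.0], size=n_art)
            for s, sign in zip(starts, signs):
                X[s : s + dur, j] += sign * config.artifact_amplitude

    return Recording(
        subject_id=subject_id,
        session=session,
        channels=CHANNELS,
        samples=X,
        sampling_rate=fs,
    )


@dataclass(frozen=True)
class CohortSimConfig:
    """A pre/post cohort: per-subject final-recovery values ρ are drawn
    from Gaussians (clipped to [0, 1]) whose means differ by the
    intervention effect; all other subject parameters come from the
    shared template."""

    n_subjects: int = 20
    rho_pre_mean: float = 0.3
    rho_pre_sd: float = 0.15
    rho_post_mean: float = 0.6
    rho_post_sd: float = 0.15
    template: SubjectSimConfig = field(default_factory=SubjectSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")


def simulate_cohort(
    config: CohortSimConfig, protocol: ProtocolDefinition
) -> tuple[list[tuple[Recording, Recording]], pd.DataFrame]:
    """Generate paired pre/post recordings and the ground-truth ρ table.

    Per-subject seeds are spawned reproducibly from the master seed; the
    returned frame has columns subject, rho_pre, rho_post.
    """
    master = np.random.SeedSequence(config.seed)
    rho_rng = np.random.default_rng(master.spawn(1)[0])
    seeds = master.spawn(2 * config.n_subjects)

    rho_pre = np.clip(
        rho_rng.normal(config.rho_pre_mean, config.rho_pre_sd, config.n_subjects), 0.0, 1.0
    )
    rho_post = np.clip(
        rho_rng.normal(config.rho_post_mean, config.rho_post_sd, config.n_subjects), 0.0, 1.0
    )

    recordings: list[tuple[Recording, Recording]] = []
    for i in range(config.n_subjects):
        sid = f"sim{i + 1:03d}"
        pre_cfg = replace(
            config.template, final_recovery=float(rho_pre[i]), seed=_seed_int(seeds[2 * i])
        )
        post_cfg = replace(
            config.template, final_recovery=float(rho_post[i]), seed=_seed_int(seeds[2 * i + 1])
        )
        pre = simulate_subject(pre_cfg, protocol, subject_id=sid, session="pre")
        post = simulate_subject(post_cfg, protocol, subject_id=sid, session="post")
        recordings.append((pre, post))

    truth = pd.DataFrame(
        {
            "subject": [f"sim{i + 1:03d}" for i in range(config.n_subjects)],
            "rho_pre": rho_pre,
            "rho_post": rho_post,
        }
    )
    return recordings, truth


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))
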