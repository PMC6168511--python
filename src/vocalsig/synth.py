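"""Synthetic vocal repertoires with controllable individual signatures.

Generates annotated call datasets (waveform + vocalizer ID + call type) whose
statistical structure can be dialled between two regimes of individual identity
coding:

* a *voice* regime, in which each individual carries one additive offset vector
  shared by every call type it produces (identity cues generalize across types),
* a *signature* regime, in which each (individual, call type) cell gets an
  independent offset (identity cues must be learned per call type).

An individual's offset for call type ``t`` is

    offset[i, t] = sqrt(rho_voice) * v[i] + sqrt(1 - rho_voice) * s[i, t]

with ``v`` and ``s`` i.i.d. zero-mean Gaussian vectors scaled by
``sigma_between``.  The square-root mixing keeps the total between-individual
variance constant as ``rho_voice`` varies, so classification performance across
regimes is not confounded by overall signature strength.

Offsets perturb log fundamental frequency, log formant (resonance) centers,
log duration, and the amplitude-envelope shape, so the sigma parameters are
unit-free.  Rendition-to-rendition jitter uses the same components at scale
``sigma_within``.

The module also simulates operant trial logs (go/no-go interruption task) with
specified per-role interruption probabilities.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: components of an offset vector, in order
OFFSET_FIELDS = ("log_f0", "log_f1", "log_f2", "log_f3", "log_duration", "env_shape")
N_OFFSET = len(OFFSET_FIELDS)

# Per-component spread of a unit-sigma offset.  Frequencies and duration are
# perturbed on a log scale (a value of 0.06 ~ 6% multiplicative change); the
# envelope-shape component is additive on the shape parameter.
_OFFSET_SCALE = np.array([0.06, 0.04, 0.04, 0.04, 0.08, 0.30])

PEAK_LEVEL = 10.0 ** (-3.0 / 20.0)  # -3 dBFS peak normalization
BAND = (250.0, 12000.0)  # analysis band of interest, Hz

DEFAULT_LABELS = ("DC", "LT", "Te", "Tu", "Th", "Ws", "Ne", "Wh", "Song", "Be")


@dataclass(frozen=True)
class CallTypeTemplate:
    """Acoustic recipe for one call type.

    ``base_f0 = 0`` marks an unvoiced (noisy) type such as the aggressive Wsst
    call; such types carry no fundamental and receive formant / duration /
    envelope offsets only.
    """

    label: str
    base_f0: float  # Hz; 0 for unvoiced types
    f0_contour: tuple[str, float] = ("flat", 0.0)  # (kind, octave extent)
    formant_centers: tuple[float, ...] = (2500.0, 4200.0, 6500.0)
    duration_mean: float = 0.15  # s
    duration_cv: float = 0.05
    harmonicity: float = 0.9  # weight of harmonic stack vs. shaped noise
    envelope_shape: float = 0.0  # skew of the unimodal envelope; 0 = symmetric

    def __post_init__(self) -> None:
        if self.duration_mean <= 0:
            raise ValueError(f"duration_mean must be > 0, got {self.duration_mean}")
        if not 0.0 <= self.harmonicity <= 1.0:
            raise ValueError(f"harmonicity must be in [0, 1], got {self.harmonicity}")
        if any(f <= 0 for f in self.formant_centers):
            raise ValueError("formant_centers must be positive")
        if self.f0_contour[0] not in ("flat", "down", "up"):
            raise ValueError(f"unknown f0 contour kind {self.f0_contour[0]!r}")


def default_templates(labels: tuple[str, ...] = DEFAULT_LABELS) -> list[CallTypeTemplate]:
    """A plausible repertoire spanning tonal, harmonic, noisy and long types."""
    recipes = {
        "DC": CallTypeTemplate("DC", 680.0, ("down", 0.4), (2800.0, 4600.0, 6800.0), 0.18, 0.06, 0.92, 0.3),
        "LT": CallTypeTemplate("LT", 550.0, ("flat", 0.0), (2400.0, 4000.0, 6200.0), 0.30, 0.08, 0.90, -0.2),
        "Te": CallTypeTemplate("Te", 600.0, ("flat", 0.0), (3000.0, 5000.0, 7200.0), 0.08, 0.08, 0.95, 0.0),
        "Tu": CallTypeTemplate("Tu", 480.0, ("up", 0.5), (2600.0, 4400.0, 6400.0), 0.12, 0.06, 0.92, 0.0),
        "Th": CallTypeTemplate("Th", 520.0, ("down", 0.2), (2200.0, 3800.0, 5800.0), 0.10, 0.07, 0.85, 0.2),
        "Ws": CallTypeTemplate("Ws", 0.0, ("flat", 0.0), (3200.0, 5400.0, 7600.0), 0.12, 0.10, 0.0, 0.0),
        "Ne": CallTypeTemplate("Ne", 440.0, ("flat", 0.0), (2000.0, 3600.0, 5600.0), 0.09, 0.08, 0.75, 0.1),
        "Wh": CallTypeTemplate("Wh", 620.0, ("up", 0.3), (2700.0, 4500.0, 6600.0), 0.11, 0.06, 0.88, -0.1),
        "Song": CallTypeTemplate("Song", 700.0, ("down", 0.6), (3100.0, 5200.0, 7400.0), 0.40, 0.05, 0.90, 0.1),
        "Be": CallTypeTemplate("Be", 0.0, ("flat", 0.0), (2900.0, 4800.0, 7000.0), 0.06, 0.12, 0.0, -0.3),
    }
    return [recipes[lb] for lb in labels]


@dataclass(frozen=True)
class IndividualProfile:
    """Latent identity of one vocalizer: per-call-type offset vectors."""

    vocalizer_id: str
    offsets: dict[str, np.ndarray]  # label -> length-N_OFFSET vector


@dataclass(frozen=True)
class SignatureConfig:
    n_individuals: int = 10
    renditions_per_type: int = 30
    sigma_between: float = 4.0
    sigma_within: float = 1.0
    rho_voice: float = 0.0
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_between) or not np.isfinite(self.sigma_within):
            raise ValueError("sigma parameters must be finite")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("sigma parameters must be >= 0")
        if not 0.0 <= self.rho_voice <= 1.0:
            raise ValueError(f"rho_voice must be in [0, 1], got {self.rho_voice}")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.renditions_per_type < 1:
            raise ValueError("renditions_per_type must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class CallRecord:
    """One rendition: waveform plus annotation."""

    vocalizer_id: str
    call_type: str
    rendition_id: str
    waveform: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        if self.waveform.size == 0 or not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be non-empty and finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.waveform.size / self.sample_rate


def make_population(
    config: SignatureConfig, templates: list[CallTypeTemplate]
) -> list[IndividualProfile]:
    """Draw latent identity offsets for each individual.

    Deterministic given ``config.seed``.  The shared ("voice") and per-type
    ("signature") components are mixed with square-root weights so the marginal
    spread of each offset component is ``sigma_between`` times the component's
    base scale regardless of ``rho_voice``.
    """
    if not templates:
        raise ValueError("at least one template is required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    scale = config.sigma_between * _OFFSET_SCALE
    w_voice = np.sqrt(config.rho_voice)
    w_sig = np.sqrt(1.0 - config.rho_voice)
    profiles = []
    for i in range(config.n_individuals):
        voice = rng.standard_normal(N_OFFSET) * scale
        offsets = {}
        for tpl in templates:
            specific = rng.standard_normal(N_OFFSET) * scale
            offsets[tpl.label] = w_voice * voice + w_sig * specific
        profiles.append(IndividualProfile(f"v{i:02d}", offsets))
    return profiles


def _envelope(n: int, shape: float) -> np.ndarray:
    """Smooth unimodal amplitude envelope; ``shape`` skews the peak position."""
    x = np.linspace(0.0, 1.0, n)
    a = 1.5 * np.exp(np.clip(shape, -2.0, 2.0))
    b = 1.5 * np.exp(-np.clip(shape, -2.0, 2.0))
    env = x**a * (1.0 - x) ** b
    peak = env.max()
    return env / peak if peak > 0 else env


def _formant_gain(freqs: np.ndarray, centers: np.ndarray, bandwidth: float = 900.0) -> np.ndarray:
    """Spectral shaping: Gaussian resonance peaks plus a small broadband floor."""
    gain = np.full_like(freqs, 0.03, dtype=float)
    for c in centers:
        gain += np.exp(-0.5 * ((freqs - c) / bandwidth) ** 2)
    return gain


def _clamp_band(value: float, low: float, high: float, what: str) -> float:
    if value < low or value > high:
        logger.warning("%s = %.1f Hz outside (%.1f, %.1f); clamped", what, value, low, high)
        return float(np.clip(value, low, high))
    return value


def render_call(
    profile: IndividualProfile,
    template: CallTypeTemplate,
    sigma_within: float,
    rng: np.random.Generator,
    sample_rate: int = 44100,
    rendition_id: str = "r000",
) -> CallRecord:
    """Synthesize one rendition.

    The waveform is an amplitude envelope times a mix of (a) a harmonic stack
    following the offset-shifted f0 contour, spectrally shaped by resonance
    peaks at the offset-shifted formant centers, and (b) noise shaped by the
    same resonances, weighted ``harmonicity : 1 - harmonicity``.  The noise
    component is seeded from the synthesis parameters themselves, so two
    renditions with identical parameters (e.g. ``sigma_within = 0``) are
    bit-identical regardless of the rng state passed in.
    """
    if template.label not in profile.offsets:
        raise KeyError(f"profile {profile.vocalizer_id} has no offsets for {template.label!r}")
    nyquist = sample_rate / 2.0

    jitter = sigma_within * _OFFSET_SCALE * rng.standard_normal(N_OFFSET)
    dur_jitter = sigma_within * template.duration_cv * rng.standard_normal()
    off = profile.offsets[template.label] + jitter

    duration = template.duration_mean * np.exp(off[4] + dur_jitter)
    n = max(int(round(duration * sample_rate)), 64)
    t = np.arange(n) / sample_rate

    centers = []
    for k, c in enumerate(np.asarray(template.formant_centers, dtype=float)[:3]):
        shifted = c * np.exp(off[1 + k])
        centers.append(_clamp_band(shifted, BAND[0], min(BAND[1], 0.95 * nyquist), f"formant {k + 1}"))
    centers = np.asarray(centers)

    voiced = template.base_f0 > 0 and template.harmonicity > 0
    harm = np.zeros(n)
    if voiced:
        f0_c = template.base_f0 * np.exp(off[0])
        f0_c = _clamp_band(f0_c, 80.0, 0.45 * nyquist, "f0")
        kind, extent = template.f0_contour
        if kind == "flat":
            f0_t = np.full(n, f0_c)
        elif kind == "down":
            f0_t = f0_c * 2.0 ** (extent * (0.5 - t / t[-1]))
        else:  # up
            f0_t = f0_c * 2.0 ** (extent * (t / t[-1] - 0.5))
        phase = 2.0 * np.pi * np.cumsum(f0_t) / sample_rate
        n_harm = int(min(BAND[1], 0.95 * nyquist) / f0_t.max())
        for h in range(1, max(n_harm, 1) + 1):
            amp = _formant_gain(h * f0_t, centers) * h**-0.3
            harm += amp * np.sin(h * phase)

    # deterministic noise: seeded from the synthesis parameters, not the rng
    param_bytes = np.round(
        np.concatenate([[duration, template.harmonicity], centers, off]), 9
    ).tobytes() + template.label.encode()
    noise_rng = np.random.default_rng(zlib.crc32(param_bytes))
    noise = noise_rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    shaping = _formant_gain(freqs, centers)
    shaping[(freqs < BAND[0]) | (freqs > min(BAND[1], 0.95 * nyquist))] = 0.0
    noise = np.fft.irfft(spec * shaping, n)

    def _rms_norm(x: np.ndarray) -> np.ndarray:
        r = np.sqrt(np.mean(x**2))
        return x / r if r > 0 else x

    h_weight = template.harmonicity if voiced else 0.0
    mix = np.zeros(n)
    if h_weight > 0:
        mix += h_weight * _rms_norm(harm)
    if h_weight < 1:
        mix += (1.0 - h_weight) * _rms_norm(noise)

    env_shape = template.envelope_shape + off[5]
    wave = mix * _envelope(n, env_shape)
    peak = np.abs(wave).max()
    if peak > 0:
        wave = wave * (PEAK_LEVEL / peak)
    return CallRecord(profile.vocalizer_id, template.label, rendition_id, wave, sample_rate)


def generate_calls(
    config: SignatureConfig, templates: list[CallTypeTemplate]
) -> list[CallRecord]:
    """Render the full dataset in memory, deterministic given ``config.seed``."""
    profiles = make_population(config, templates)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    calls = []
    for profile in profiles:
        for tpl in templates:
            for r in range(config.renditions_per_type):
                calls.append(
                    render_call(
                        profile, tpl, config.sigma_within, rng,
                        sample_rate=config.sample_rate, rendition_id=f"r{r:03d}",
                    )
                )
    return calls


def generate_dataset(
    config: SignatureConfig, templates: list[CallTypeTemplate], out_dir: str | Path
) -> pd.DataFrame:
    """Write one 16-bit PCM WAV per rendition plus a CSV manifest.

    Returns the manifest (columns ``file, vocalizer_id, call_type,
    rendition_id``); row count = n_individuals x n_templates x renditions.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for call in generate_calls(config, templates):
        fname = f"{call.vocalizer_id}_{call.call_type}_{call.rendition_id}.wav"
        pcm = np.round(call.waveform * 32767.0).astype(np.int16)
        try:
            wavfile.write(out_dir / fname, call.sample_rate, pcm)
        except OSError as exc:
            raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
        rows.append((fname, call.vocalizer_id, call.call_type, call.rendition_id))
    manifest = pd.DataFrame(rows, columns=["file", "vocalizer_id", "call_type", "rendition_id"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[CallRecord]:
    """Read a manifest CSV and its WAV files back into CallRecords."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    calls = []
    for row in manifest.itertuples(index=False):
        rate, pcm = wavfile.read(base / row.file)
        wave = pcm.astype(np.float64) / 32767.0 if pcm.dtype == np.int16 else pcm.astype(np.float64)
        calls.append(CallRecord(str(row.vocalizer_id), str(row.call_type), str(row.rendition_id), wave, rate))
    return calls


def simulate_trials(
    n_trials: int,
    p_interrupt_re: float,
    p_interrupt_nore: float,
    frac_re: float = 0.2,
    n_renditions_per_role: int = 20,
    seed: int = 0,
    call_type: str = "DC",
    mean_trial_interval_s: float = 10.0,
    start_time_s: float = 0.0,
) -> pd.DataFrame:
    """Simulate an operant interruption log.

    Each trial plays the rewarded (Re) vocalizer with probability ``frac_re``
    (default 20%, the schedule used in the go/no-go task) and the nonrewarded
    (NoRe) vocalizer otherwise; the subject interrupts with the role-specific
    probability.  Rendition IDs are drawn uniformly from disjoint per-role
    pools.  Returns the trial-log table with columns
    ``trial_index, time_s, role, call_type, rendition_id, interrupted``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for name, p in (("p_interrupt_re", p_interrupt_re), ("p_interrupt_nore", p_interrupt_nore), ("frac_re", frac_re)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    is_re = rng.random(n_trials) < frac_re
    p_int = np.where(is_re, p_interrupt_re, p_interrupt_nore)
    interrupted = (rng.random(n_trials) < p_int).astype(int)
    rend_idx = rng.integers(0, n_renditions_per_role, n_trials)
    times = start_time_s + np.cumsum(rng.uniform(0.5, 1.5, n_trials) * mean_trial_interval_s)
    roles = np.where(is_re, "Re", "NoRe")
    return pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "time_s": times,
            "role": roles,
            "call_type": call_type,
            "rendition_id": [f"{r}_r{i:02d}" for r, i in zip(roles, rend_idx)],
            "interrupted": interrupted,
        }
    )
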