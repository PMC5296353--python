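"""Synthetic stimulus and rating generation.

Real studies of instrument timbre and emotion rate short recorded tones
(here emulated: 500-ms monophonic clips at 44.1 kHz, pitch class D# across
octaves 1-7, four instrument-family archetypes) on 9-point scales.  Because
commercial sample libraries and raw participant ratings are not
redistributable, this module synthesises both sides of the dataset:

* additive tones whose controllable parameters (partial rolloff, attack
  time, decay, noisiness, AM "flutter", FM "vibrato") span wide ranges of
  the spectral/temporal descriptors downstream code measures, and
* simulated participant ratings driven by a planted, known mapping from
  stimulus features to a latent emotion value, with participant random
  intercepts and rating noise.

The family archetypes are deliberately *not* imitations of real
instruments; they only need to produce acoustic diversity.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

SAMPLE_RATE = 44_100
DURATION_S = 0.5
FADE_S = 0.05

#: Rating scales collected per stimulus (9-point, 1..9).
SCALES = ("valence", "pleasure", "tension", "energy", "preference", "familiarity")

FAMILIES = ("brass", "woodwind", "string", "percussion")


class SynthesisError(ValueError):
    """Invalid tone or generator specification."""


# ---------------------------------------------------------------------------
# Pitch
# ---------------------------------------------------------------------------

_A4_HZ = 440.0
# D# sits six semitones below A within the same octave number.
_DSHARP_SEMITONES_BELOW_A = 6


def pitch_to_frequency(octave: int) -> float:
    """Equal-temperament fundamental of D# in ``octave`` (A4 = 440 Hz).

    D#4 evaluates to ~311.13 Hz; each octave doubles the frequency.
    """
    if not (1 <= int(octave) <= 7) or int(octave) != octave:
        raise SynthesisError(f"octave must be an integer in 1..7, got {octave!r}")
    dsharp4 = _A4_HZ * 2.0 ** (-_DSHARP_SEMITONES_BELOW_A / 12.0)
    return dsharp4 * 2.0 ** (int(octave) - 4)


# ---------------------------------------------------------------------------
# Tone specification and synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToneSpec:
    """Parameters of one additive-synthesis stimulus.

    ``slope_param`` is the exponent of the ``k**-slope_param`` partial
    amplitude rolloff; ``noise_level`` is the RMS ratio of the white-noise
    floor to the harmonic part; ``fm_depth`` is in cents, ``am_depth`` a
    unitless modulation index in [0, 1).
    """

    pitch_octave: int
    family: str
    n_partials: int = 20
    slope_param: float = 1.0
    attack_time: float = 0.05
    decay_param: float = 0.5
    noise_level: float = 0.0
    am_rate: float = 0.0
    am_depth: float = 0.0
    fm_rate: float = 0.0
    fm_depth: float = 0.0
    peak_level: float = 0.9

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SynthesisError(f"unknown family {self.family!r}")
        if self.n_partials < 1:
            raise SynthesisError("n_partials must be >= 1")
        if not (0.0 < self.attack_time < DURATION_S):
            raise SynthesisError("attack_time must lie in (0, clip duration)")
        if not (0.0 <= self.noise_level <= 1.0):
            raise SynthesisError("noise_level must lie in [0, 1]")
        if not (0.0 < self.peak_level <= 1.0):
            raise SynthesisError("peak_level must lie in (0, 1]")
        # guard against a fundamental at or above Nyquist (octave 7 D# is
        # ~2489 Hz, so this only triggers for hand-built pathological specs)
        if pitch_to_frequency(self.pitch_octave) >= SAMPLE_RATE / 2:
            raise SynthesisError("fundamental at or above Nyquist")


@dataclass
class AudioClip:
    """Fixed-rate mono waveform plus the metadata it was built from."""

    samples: np.ndarray
    sample_rate: int = SAMPLE_RATE
    stimulus_id: str = ""
    spec: ToneSpec | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def to_wav_bytes(self) -> bytes:
        """16-bit PCM RIFF encoding of the clip."""
        buf = io.BytesIO()
        pcm = np.clip(np.round(self.samples * 32767.0), -32768, 32767).astype(np.int16)
        wavfile.write(buf, self.sample_rate, pcm)
        return buf.getvalue()

    def write_wav(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_wav_bytes())


def read_wav(path, stimulus_id: str = "") -> AudioClip:
    """Load a mono 16-bit PCM WAV file into float samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples=samples, sample_rate=int(rate), stimulus_id=stimulus_id)


def synthesize_tone(spec: ToneSpec, seed: int) -> AudioClip:
    """Render one 500-ms additive tone; deterministic for a given seed.

    Partial k has amplitude ``k**-slope_param`` (partials at or above
    Nyquist are dropped), the envelope is a linear attack ramp followed by
    exponential decay (impulsive for percussion), a white-noise floor is
    mixed at ``noise_level`` relative RMS, AM/FM are applied, the result is
    peak-normalised to ``peak_level`` and faded out with a raised-cosine
    ramp over the final 50 ms (last sample exactly zero).
    """
    rng = np.random.default_rng(seed)
    sr = SAMPLE_RATE
    n = round(DURATION_S * sr)
    t = np.arange(n) / sr
    f0 = pitch_to_frequency(spec.pitch_octave)

    # FM: instantaneous fundamental in Hz, integrated to phase so every
    # partial stays exactly harmonic.
    if spec.fm_rate > 0 and spec.fm_depth != 0:
        inst_f0 = f0 * 2.0 ** ((spec.fm_depth / 1200.0) * np.sin(2 * np.pi * spec.fm_rate * t))
    else:
        inst_f0 = np.full(n, f0)
    phase = 2 * np.pi * np.cumsum(inst_f0) / sr

    tone = np.zeros(n)
    nyquist = sr / 2.0
    for k in range(1, spec.n_partials + 1):
        if k * f0 >= nyquist:
            break
        amp = float(k) ** (-spec.slope_param)
        tone += amp * np.sin(k * phase + rng.uniform(0, 2 * np.pi))

    if spec.am_rate > 0 and spec.am_depth != 0:
        tone *= 1.0 + spec.am_depth * np.sin(2 * np.pi * spec.am_rate * t)

    if spec.noise_level > 0:
        noise = rng.standard_normal(n)
        tone_rms = np.sqrt(np.mean(tone**2))
        noise *= spec.noise_level * tone_rms / np.sqrt(np.mean(noise**2))
        tone = tone + noise

    # Envelope: linear attack to 1, then exponential decay.  Percussion is
    # impulsive: its decay rate is boosted so the tail dies within the clip.
    env = np.minimum(t / spec.attack_time, 1.0)
    rate = spec.decay_param * (12.0 if spec.family == "percussion" else 1.0)
    post = t > spec.attack_time
    env[post] *= np.exp(-rate * (t[post] - spec.attack_time))
    tone *= env

    peak = np.max(np.abs(tone))
    if peak > 0:
        tone *= spec.peak_level / peak

    # raised-cosine fade over the final 50 ms; endpoint lands exactly on 0
    n_fade = round(FADE_S * sr)
    fade = 0.5 * (1.0 + np.cos(np.pi * np.arange(n_fade) / (n_fade - 1)))
    tone[-n_fade:] *= fade
    return AudioClip(samples=tone, sample_rate=sr, spec=spec)


# ---------------------------------------------------------------------------
# Stimulus-set generation
# ---------------------------------------------------------------------------

#: Default stimulus roster: family archetypes x instruments x octaves x
#: variants, totalling 137 clips.  Counts per family/octave only need to be
#: plausible for an orchestral set, not to match any real sample library.
DEFAULT_STIMULUS_CONFIG: dict = {
    "series": [
        # brass: three instruments over octaves 1-5, attack strength varies
        {"family": "brass", "instrument": "brass_a", "octaves": [1, 2, 3, 4, 5],
         "variants": ["weak", "normal", "strong"]},
        {"family": "brass", "instrument": "brass_b", "octaves": [2, 3, 4, 5],
         "variants": ["normal", "strong", "flutter"]},
        {"family": "brass", "instrument": "brass_c", "octaves": [2, 3, 4, 5],
         "variants": ["normal", "flutter"]},
        # woodwinds: octaves 2-7, normal vs flutter-tongued
        {"family": "woodwind", "instrument": "wood_a", "octaves": [2, 3, 4, 5, 6, 7],
         "variants": ["normal", "flutter"]},
        {"family": "woodwind", "instrument": "wood_b", "octaves": [2, 3, 4, 5, 6],
         "variants": ["normal", "flutter"]},
        {"family": "woodwind", "instrument": "wood_c", "octaves": [4, 5, 6, 7],
         "variants": ["normal"]},
        # strings: octaves 1-7, normal / vibrato / pizzicato
        {"family": "string", "instrument": "string_a", "octaves": [1, 2, 3, 4, 5, 6, 7],
         "variants": ["normal", "vibrato", "pizzicato"]},
        {"family": "string", "instrument": "string_b", "octaves": [2, 3, 4, 5, 6],
         "variants": ["normal", "vibrato", "pizzicato"]},
        {"family": "string", "instrument": "string_c", "octaves": [3, 4, 5, 6, 7],
         "variants": ["normal", "vibrato"]},
        # pitched percussion: mallet material varies
        {"family": "percussion", "instrument": "perc_a", "octaves": [2, 3, 4, 5, 6],
         "variants": ["felt", "wood", "metal"]},
        {"family": "percussion", "instrument": "perc_b", "octaves": [5, 6, 7],
         "variants": ["felt", "wood", "metal"]},
        {"family": "percussion", "instrument": "perc_c", "octaves": [5, 6, 7],
         "variants": ["wood", "metal"]},
    ]
}

# Per-family archetype base parameters.
_FAMILY_BASE = {
    "brass": dict(n_partials=30, slope_param=0.7, attack_time=0.05,
                  decay_param=0.4, noise_level=0.02),
    "woodwind": dict(n_partials=14, slope_param=1.3, attack_time=0.07,
                     decay_param=0.3, noise_level=0.05),
    "string": dict(n_partials=25, slope_param=1.0, attack_time=0.09,
                   decay_param=0.5, noise_level=0.03),
    "percussion": dict(n_partials=7, slope_param=1.6, attack_time=0.004,
                       decay_param=0.6, noise_level=0.02),
}

# Variant (technique / attack / mallet) modifiers on top of the base.
_VARIANT_MODS = {
    "weak": dict(attack_time=0.14),
    "normal": dict(),
    "strong": dict(attack_time=0.012),
    "flutter": dict(am_rate=22.0, am_depth=0.5),
    "vibrato": dict(fm_rate=5.5, fm_depth=35.0),
    "pizzicato": dict(attack_time=0.004, decay_param=9.0, family_decay_boost=1.0),
    "felt": dict(slope_param=2.2, noise_level=0.05),
    "wood": dict(slope_param=1.4),
    "metal": dict(slope_param=0.8, n_partials=12),
}

_ATTACK_LABELS = {"weak": "weak", "normal": "normal", "strong": "strong"}


def _spec_for(family: str, instrument: str, octave: int, variant: str,
              rng: np.random.Generator) -> ToneSpec:
    params = dict(_FAMILY_BASE[family])
    mods = dict(_VARIANT_MODS.get(variant, {}))
    mods.pop("family_decay_boost", None)
    params.update(mods)
    # small per-instrument / per-stimulus jitter so no two stimuli are
    # exact copies and descriptor columns are not degenerate
    params["slope_param"] = max(0.2, params["slope_param"] * rng.uniform(0.85, 1.15))
    params["attack_time"] = float(np.clip(params["attack_time"] * rng.uniform(0.8, 1.25),
                                          0.002, 0.3))
    params["decay_param"] = max(0.05, params["decay_param"] * rng.uniform(0.8, 1.25))
    params["noise_level"] = float(np.clip(params["noise_level"] * rng.uniform(0.7, 1.4),
                                          0.0, 0.5))
    return ToneSpec(pitch_octave=octave, family=family, **params)


def generate_stimulus_set(config: dict | None = None, seed: int = 0
                          ) -> tuple[list[AudioClip], pd.DataFrame]:
    """Synthesise the full stimulus roster and its metadata table.

    Returns the clips plus a DataFrame with one row per stimulus
    (stimulus_id, family, instrument, octave, technique, attack and the
    realised ToneSpec parameters).  The default configuration yields 137
    clips; output is byte-deterministic for a fixed seed.
    """
    config = DEFAULT_STIMULUS_CONFIG if config is None else config
    series = config.get("series", [])
    if not series:
        raise SynthesisError("stimulus config lists no series")
    rng = np.random.default_rng(seed)
    clips: list[AudioClip] = []
    rows = []
    idx = 0
    for entry in series:
        family = entry["family"]
        if family not in FAMILIES:
            raise SynthesisError(f"unknown family {family!r} in config")
        for octave in entry["octaves"]:
            for variant in entry["variants"]:
                spec = _spec_for(family, entry["instrument"], octave, variant, rng)
                clip = synthesize_tone(spec, seed=int(rng.integers(0, 2**31 - 1)))
                sid = f"s{idx:03d}_{family}_{entry['instrument']}_o{octave}_{variant}"
                clip.stimulus_id = sid
                clip.metadata = {
                    "stimulus_id": sid, "family": family,
                    "instrument": entry["instrument"], "octave": octave,
                    "technique": variant,
                    "attack": _ATTACK_LABELS.get(variant, "normal"),
                }
                clips.append(clip)
                rows.append({**clip.metadata, **dataclasses.asdict(spec)})
                idx += 1
    meta = pd.DataFrame(rows).set_index("stimulus_id")
    return clips, meta


# ---------------------------------------------------------------------------
# Simulated ratings
# ---------------------------------------------------------------------------


@dataclass
class PlantedEffectSpec:
    """Known ground-truth mapping from stimulus features to latent emotion.

    ``effects`` maps each rating scale to ``{feature_name: weight}``;
    features are range-normalised to [0, 1] before the weighted sum, which
    is added to ``intercept`` and clamped to [0, 1].  With
    ``nonlinear=True`` a logistic squashing is applied to the latent mean
    before clamping.  Ratings are then discretised onto 1..9.

    ``noise_sd`` is per-rating noise (averages out across participants);
    ``stimulus_sd`` is a stimulus-level random effect shared by all
    participants, i.e. noise on the unit-scale mean response that no model
    of the descriptors can explain.
    """

    effects: dict[str, dict[str, float]]
    intercepts: dict[str, float] = field(default_factory=dict)
    nonlinear: bool = False
    noise_sd: float = 0.05
    participant_sd: float = 0.05
    stimulus_sd: float = 0.0

    def scales(self) -> tuple[str, ...]:
        return tuple(self.effects)


#: Default planted mapping on ToneSpec parameters / metadata, loosely shaped
#: like the study conditions: energy rises with register and brightness,
#: tension with register and modulation, valence peaks mid-register with
#: sharp attacks and strong partial emergence.
DEFAULT_EFFECTS = PlantedEffectSpec(
    effects={
        "valence": {"slope_param": -0.25, "attack_time": -0.20, "octave_peak": 0.30},
        "pleasure": {"slope_param": -0.25, "attack_time": -0.18, "octave_peak": 0.30},
        "tension": {"octave": 0.30, "am_depth": 0.15, "noise_level": 0.15,
                    "attack_time": 0.15},
        "energy": {"octave": 0.45, "slope_param": -0.25, "attack_time": -0.10},
        "preference": {"slope_param": -0.20, "octave_peak": 0.25, "noise_level": -0.15},
        "familiarity": {"octave_peak": 0.20, "noise_level": -0.10},
    },
    intercepts={s: 0.45 for s in SCALES},
    noise_sd=0.08,
    participant_sd=0.08,
)


def _feature_table(meta: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Feature columns usable in planted effects, range-normalised to [0,1].

    Returns the table plus the names of constant columns, which carry no
    between-stimulus information and are dropped (a planted weight on one
    contributes nothing).
    """
    feats = meta.select_dtypes(include=[np.number]).astype(float).copy()
    if "octave" in feats:
        oc = feats["octave"]
        # concave register profile peaking mid-range
        feats["octave_peak"] = 1.0 - ((oc - 4.5) / 3.5) ** 2
    span = feats.max() - feats.min()
    keep = span > 0
    dropped = set(feats.columns[~keep])
    return (feats.loc[:, keep] - feats.min()[keep]) / span[keep], dropped


def latent_means(meta_or_features: pd.DataFrame, effect: PlantedEffectSpec) -> pd.DataFrame:
    """Per-stimulus latent emotion means in [0, 1], one column per scale."""
    feats, dropped = _feature_table(meta_or_features)
    out = {}
    for scale, weights in effect.effects.items():
        latent = np.full(len(feats), effect.intercepts.get(scale, 0.5))
        for name, w in weights.items():
            if name in dropped:
                continue
            if name not in feats:
                raise SynthesisError(f"planted-effect feature {name!r} not available")
            latent = latent + w * (feats[name].to_numpy() - 0.5)
        if effect.nonlinear:
            latent = 1.0 / (1.0 + np.exp(-4.0 * (latent - 0.5)))
        out[scale] = np.clip(latent, 0.0, 1.0)
    return pd.DataFrame(out, index=feats.index)


def generate_ratings(meta: pd.DataFrame, effect: PlantedEffectSpec,
                     n_participants: int, seed: int = 0) -> pd.DataFrame:
    """Simulate the full participant x stimulus x scale rating table.

    Each rating is ``clamp(round(1 + 8 * (latent + participant intercept +
    noise)), 1, 9)``.  Returns a long-format DataFrame with columns
    participant_id, group, stimulus_id, scale, rating.
    """
    if n_participants < 2:
        raise SynthesisError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    latents = latent_means(meta, effect)
    if effect.stimulus_sd > 0:
        latents = latents + rng.normal(0.0, effect.stimulus_sd, size=latents.shape)
    scales = latents.columns
    rows = []
    for p in range(n_participants):
        group = "musician" if p < n_participants // 2 else "nonmusician"
        intercept = rng.normal(0.0, effect.participant_sd)
        noise = rng.normal(0.0, effect.noise_sd, size=latents.shape)
        latent_p = latents.to_numpy() + intercept + noise
        ratings = np.clip(np.rint(1.0 + 8.0 * latent_p), 1, 9).astype(int)
        for j, scale in enumerate(scales):
            rows.append(pd.DataFrame({
                "participant_id": f"p{p:02d}", "group": group,
                "stimulus_id": latents.index, "scale": scale,
                "rating": ratings[:, j],
            }))
    return pd.concat(rows, ignore_index=True)
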