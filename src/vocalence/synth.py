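"""Synthetic pig-call generator.

Real pig vocalizations fall into two broad types: low-frequency calls (LF;
grunts, dominant energy below ~1 kHz) and high-frequency calls (HF; screams
and squeals, dominant energy at 2-4 kHz).  This module generates labelled
synthetic calls whose *extracted* acoustic features carry the valence
structure reported for real pigs:

* calls are shorter in positive contexts (both types),
* calls have fewer amplitude modulations in positive contexts (both types),
* the spectral center of gravity (Q50) is higher in positive contexts for
  LF calls and lower for HF calls,
* Wiener entropy is lower (more tonal) in positive contexts for LF calls
  and higher (noisier) for HF calls.

The waveform model is deliberately simple and controllable rather than
physiologically realistic: a harmonic stack (fundamental plus partials,
amplitude-weighted by a Gaussian around a target spectral center) mixed
with band-shaped Gaussian noise at a prescribed tonal-to-noise energy
ratio, then shaped by an attack/decay envelope and a sinusoidal amplitude
modulation envelope.  Every randomized quantity used to build a call is
recorded in ``CallRecording.true_synth_params`` so recovery tests can
compare extracted features against ground truth.

Individual pigs carry random multiplicative offsets on duration and
spectral center (nested within recording team), which gives the
permutation-based discriminant analysis a genuine control factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "CallParams",
    "ContextDef",
    "SynthSpec",
    "CallRecording",
    "Pig",
    "default_spec",
    "build_pigs",
    "synthesize_call",
    "synthesize_dataset",
    "write_dataset",
    "load_dataset",
]

#: age classes and the day ranges they cover (inclusive)
AGE_CLASS_DAYS = {1: (1, 25), 2: (32, 43), 3: (85, 180)}

_MAX_REDRAWS = 50


@dataclass
class CallParams:
    """Distribution of the synthesis parameters for one (call type, valence) cell.

    Durations and AM rates are drawn from truncated normals (redrawn while
    non-positive); the AM extent is the intended peak-to-trough depth of the
    intensity contour in dB; ``tonal_ratio`` is the fraction of waveform
    energy contributed by the harmonic stack (the rest is band noise).
    """

    duration_mean: float  # s
    duration_sd: float  # s
    am_rate_mean: float  # Hz
    am_rate_sd: float  # Hz
    am_extent_db: float  # dB peak-to-trough
    am_extent_sd: float  # dB
    center_hz: float  # target spectral center of gravity, Hz
    center_sd: float  # Hz
    tonal_ratio: float  # in (0, 1)
    tonal_sd: float = 0.03
    bandwidth_hz: float = 250.0  # spectral band half-width, fixed per call type so
    # Wiener entropy tracks tonality rather than band occupancy
    noise_bw_factor: float = 2.0  # noise band is broader than the harmonic stack


@dataclass
class ContextDef:
    """One recording context: label, the valence attributed to it, and a
    sampling weight controlling how many calls it contributes (contexts are
    deliberately imbalanced, mirroring field datasets where e.g. isolation
    recordings dominate and startle events are rare)."""

    label: str
    valence: str  # "negative" | "positive"
    weight: float


@dataclass
class Pig:
    pig_id: str
    team_id: str
    age_days: int
    age_class: int
    logdur_offset: float
    logcenter_offset: float


@dataclass
class SynthSpec:
    """Full description of a synthetic dataset.

    Invariants (checked by :meth:`validate`): age-class probabilities sum
    to 1, all spreads are non-negative, each context maps to exactly one
    valence, and the sample rate satisfies Nyquist for the highest
    synthesized partial.
    """

    n_pigs: int = 24
    teams: tuple[str, ...] = ("teamA", "teamB", "teamC", "teamD")
    age_class_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    contexts: tuple[ContextDef, ...] = ()
    params: dict = field(default_factory=dict)  # (call_type, valence) -> CallParams
    hf_prob: dict = field(default_factory=lambda: {"negative": 0.33, "positive": 0.10})
    pig_logdur_sd: float = 0.12
    pig_logcenter_sd: float = 0.06
    team_logdur_sd: float = 0.05
    team_logcenter_sd: float = 0.03
    noise_floor_db: float = -60.0  # broadband floor relative to call RMS, as any microphone has
    min_duration_s: float = 0.08  # shortest croppable call; shorter draws are redrawn
    age_center_factor: dict = field(default_factory=lambda: {1: 1.1, 2: 1.0, 3: 0.9})
    sample_rate: int = 44100
    n_calls: int = 1000
    rng_seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if abs(sum(self.age_class_probs) - 1.0) > 1e-9:
            raise ValueError("age_class_probs must sum to 1")
        if self.n_pigs < 1 or not self.teams:
            raise ValueError("need at least one pig and one team")
        seen = {}
        for c in self.contexts:
            if c.valence not in ("negative", "positive"):
                raise ValueError(f"unknown valence {c.valence!r}")
            if c.label in seen and seen[c.label] != c.valence:
                raise ValueError(f"context {c.label!r} mapped to two valences")
            seen[c.label] = c.valence
            if c.weight < 0:
                raise ValueError("context weights must be >= 0")
        for key, p in self.params.items():
            for name in ("duration_sd", "am_rate_sd", "am_extent_sd", "center_sd"):
                if getattr(p, name) < 0:
                    raise ValueError(f"{key}: {name} must be >= 0")
            if not 0 < p.tonal_ratio < 1:
                raise ValueError(f"{key}: tonal_ratio must be in (0,1)")
            # highest partial reaches ~center + 2 bandwidths; demand Nyquist above it
            if self.sample_rate < 2 * (p.center_hz + p.center_sd) * 1.4:
                raise ValueError(f"{key}: sample_rate too low for center {p.center_hz} Hz")

    @property
    def context_map(self) -> dict:
        return {c.label: c.valence for c in self.contexts}

    # -- JSON round trip -------------------------------------------------
    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["contexts"] = [asdict(c) if not isinstance(c, dict) else c for c in self.contexts]
        d["params"] = {f"{k[0]}|{k[1]}": asdict(v) for k, v in self.params.items()}
        d["age_center_factor"] = {str(k): v for k, v in self.age_center_factor.items()}
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "SynthSpec":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists() else source
        d = json.loads(text)
        d["contexts"] = tuple(ContextDef(**c) for c in d["contexts"])
        d["params"] = {tuple(k.split("|")): CallParams(**v) for k, v in d["params"].items()}
        d["age_center_factor"] = {int(k): v for k, v in d["age_center_factor"].items()}
        d["teams"] = tuple(d["teams"])
        d["age_class_probs"] = tuple(d["age_class_probs"])
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class CallRecording:
    """One cropped synthetic call with its metadata and ground truth."""

    call_id: str
    waveform: np.ndarray
    sample_rate: int
    pig_id: str
    team_id: str
    age_days: int
    age_class: int
    context: str
    valence: str
    true_synth_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.waveform.size == 0 or not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be finite and non-empty")
        lo, hi = AGE_CLASS_DAYS[self.age_class]
        if self.age_class == 3:
            if self.age_days < lo:
                raise ValueError("age_days inconsistent with age_class 3")
        elif not lo <= self.age_days <= hi:
            raise ValueError("age_days inconsistent with age_class")

    @property
    def duration(self) -> float:
        return self.waveform.size / self.sample_rate


# ---------------------------------------------------------------------------
# defaults

_DEFAULT_CONTEXTS = (
    # negative contexts
    ContextDef("Isolation", "negative", 25.0),
    ContextDef("Castration", "negative", 6.0),
    ContextDef("Slaughterhouse", "negative", 5.0),
    ContextDef("Fight", "negative", 5.0),
    ContextDef("Restraint", "negative", 4.0),
    ContextDef("Weaning", "negative", 5.0),
    ContextDef("Crushing", "negative", 2.0),
    ContextDef("MissedNursing", "negative", 3.0),
    ContextDef("NegativeConditioning", "negative", 3.0),
    ContextDef("Handling", "negative", 4.0),
    ContextDef("Surprise", "negative", 0.3),
    # positive contexts
    ContextDef("Reunion", "positive", 10.0),
    ContextDef("Huddling", "positive", 6.0),
    ContextDef("Nursing", "positive", 8.0),
    ContextDef("Suckling", "positive", 5.0),
    ContextDef("PositiveConditioning", "positive", 3.0),
    ContextDef("Enrichment", "positive", 4.0),
    ContextDef("Play", "positive", 3.0),
    ContextDef("FoodAnticipation", "positive", 4.0),
)

_DEFAULT_PARAMS = {
    # durations shorter and AM rates lower in positive contexts for both types;
    # Q50 higher in positive for LF, lower in positive for HF;
    # tonal ratio higher (lower Wiener entropy) in positive for LF, lower for HF
    ("LF", "negative"): CallParams(0.50, 0.12, 12.0, 2.0, 10.0, 0.5, 450.0, 60.0, 0.70,
                                   bandwidth_hz=220.0),
    ("LF", "positive"): CallParams(0.35, 0.12, 7.0, 2.0, 10.0, 0.5, 620.0, 60.0, 0.94,
                                   bandwidth_hz=220.0),
    ("HF", "negative"): CallParams(0.80, 0.16, 12.0, 2.0, 10.0, 0.5, 3300.0, 200.0, 0.94,
                                   bandwidth_hz=900.0),
    ("HF", "positive"): CallParams(0.55, 0.16, 7.0, 2.0, 10.0, 0.5, 2700.0, 180.0, 0.60,
                                   bandwidth_hz=900.0),
}


def default_spec(**overrides) -> SynthSpec:
    """The default study conditions: 19 imbalanced contexts, pigs nested in
    four teams, three age classes, and per-cell parameter distributions that
    encode the four valence sign patterns."""
    spec = SynthSpec(contexts=_DEFAULT_CONTEXTS, params=dict(_DEFAULT_PARAMS), **overrides)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# pigs

def build_pigs(spec: SynthSpec, rng: np.random.Generator | None = None) -> dict[str, Pig]:
    """Deterministically allocate pigs to teams and draw their ages and
    individual offsets.  Pigs are assigned to teams round-robin so every
    team is populated; ages are drawn once per pig (a pig keeps its age
    class across its calls)."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    team_off = {
        t: (rng.normal(0.0, spec.team_logdur_sd), rng.normal(0.0, spec.team_logcenter_sd))
        for t in spec.teams
    }
    pigs = {}
    for i in range(spec.n_pigs):
        pid = f"pig{i:03d}"
        team = spec.teams[i % len(spec.teams)]
        age_class = int(rng.choice([1, 2, 3], p=spec.age_class_probs))
        lo, hi = AGE_CLASS_DAYS[age_class]
        age_days = int(rng.integers(lo, hi + 1))
        pigs[pid] = Pig(
            pig_id=pid,
            team_id=team,
            age_days=age_days,
            age_class=age_class,
            logdur_offset=float(team_off[team][0] + rng.normal(0.0, spec.pig_logdur_sd)),
            logcenter_offset=float(team_off[team][1] + rng.normal(0.0, spec.pig_logcenter_sd)),
        )
    return pigs


# ---------------------------------------------------------------------------
# waveform synthesis

def _draw_positive(rng, mean, sd, what, floor=0.0):
    """Truncated-normal draw: redraw while <= floor, bounded retries."""
    if sd == 0:
        if mean <= floor:
            raise ValueError(f"{what}: value {mean} at or below floor {floor} with sd=0")
        return float(mean)
    for _ in range(_MAX_REDRAWS):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    raise ValueError(f"{what}: could not draw above {floor} from N({mean}, {sd})")


def _harmonic_stack(rng, n, sr, f0, center, bandwidth):
    """Sum of partials k*f0 with Gaussian amplitude weights around ``center``."""
    t = np.arange(n) / sr
    nyq = 0.45 * sr
    k_max = max(1, int(min(nyq, center + 2.5 * bandwidth) // f0))
    wave = np.zeros(n)
    for k in range(1, k_max + 1):
        f = k * f0
        amp = np.exp(-0.5 * ((f - center) / bandwidth) ** 2)
        if amp < 1e-4:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        wave += amp * np.sin(2 * np.pi * f * t + phase)
    if not wave.any():  # degenerate weights: keep the partial nearest the center
        k = int(np.clip(round(center / f0), 1, k_max))
        wave = np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
    return wave


def _band_noise(rng, n, sr, center, bandwidth):
    """Gaussian noise spectrally shaped to a Gaussian band around ``center``."""
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1 / sr)
    spec *= np.exp(-0.5 * ((freqs - center) / bandwidth) ** 2)
    return np.fft.irfft(spec, n)


def synthesize_call(
    spec: SynthSpec,
    call_type: str,
    valence: str,
    pig_id: str,
    rng: np.random.Generator,
    pigs: dict | None = None,
    context: str | None = None,
    call_id: str = "call",
) -> CallRecording:
    """Synthesize one call for a registered pig.

    The waveform is ``sqrt(q) * harmonics + sqrt(1-q) * band noise`` (each
    normalized to unit RMS, ``q`` the tonal energy ratio), multiplied by a
    15 ms raised-cosine attack/decay envelope and the AM envelope
    ``(1 + m sin(2 pi f_am t - pi/2)) / (1 + m)`` where ``m`` is set so
    the intensity contour swings by the drawn dB extent peak-to-trough.
    """
    if call_type not in ("LF", "HF"):
        raise ValueError(f"invalid call_type {call_type!r}")
    if valence not in ("negative", "positive"):
        raise ValueError(f"invalid valence {valence!r}")
    if pigs is None:
        pigs = build_pigs(spec)
    if pig_id not in pigs:
        raise KeyError(f"pig {pig_id!r} not registered in spec")
    pig = pigs[pig_id]
    p: CallParams = spec.params[(call_type, valence)]
    sr = spec.sample_rate

    dur = _draw_positive(rng, p.duration_mean, p.duration_sd, "duration",
                         floor=spec.min_duration_s if p.duration_sd > 0 else 0.0)
    dur *= np.exp(pig.logdur_offset)
    am_rate = _draw_positive(rng, p.am_rate_mean, p.am_rate_sd, "am_rate")
    am_extent = max(0.5, rng.normal(p.am_extent_db, p.am_extent_sd)) if p.am_extent_sd else p.am_extent_db
    center = _draw_positive(rng, p.center_hz, p.center_sd, "center")
    center *= np.exp(pig.logcenter_offset) * spec.age_center_factor[pig.age_class]
    tonal = float(np.clip(rng.normal(p.tonal_ratio, p.tonal_sd), 0.02, 0.98))

    n = max(2, int(round(dur * sr)))
    bandwidth = p.bandwidth_hz
    f0 = _draw_positive(rng, 140.0, 25.0, "f0") if call_type == "LF" else _draw_positive(rng, 0.33 * center, 40.0, "f0")

    harm = _harmonic_stack(rng, n, sr, f0, center, bandwidth)
    noise = _band_noise(rng, n, sr, center, bandwidth * p.noise_bw_factor)
    harm /= np.sqrt(np.mean(harm**2)) + 1e-12
    noise /= np.sqrt(np.mean(noise**2)) + 1e-12
    wave = np.sqrt(tonal) * harm + np.sqrt(1.0 - tonal) * noise

    t = np.arange(n) / sr
    # AM depth from the dB extent: extent = 20 log10((1+m)/(1-m))
    r = 10 ** (am_extent / 20.0)
    m = (r - 1.0) / (r + 1.0)
    wave *= (1.0 + m * np.sin(2 * np.pi * am_rate * t - np.pi / 2)) / (1.0 + m)
    # attack / decay
    fade = min(int(0.015 * sr), n // 4)
    if fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))
        wave[:fade] *= ramp
        wave[-fade:] *= ramp[::-1]
    # broadband recording floor so spectra are finite everywhere
    rms = np.sqrt(np.mean(wave**2))
    wave += rng.standard_normal(n) * rms * 10 ** (spec.noise_floor_db / 20.0)
    wave *= 0.9 / (np.max(np.abs(wave)) + 1e-12)

    return CallRecording(
        call_id=call_id,
        waveform=wave,
        sample_rate=sr,
        pig_id=pig.pig_id,
        team_id=pig.team_id,
        age_days=pig.age_days,
        age_class=pig.age_class,
        context=context or ("Isolation" if valence == "negative" else "Reunion"),
        valence=valence,
        true_synth_params={
            "call_type": call_type,
            "duration": dur,
            "am_rate": am_rate,
            "am_extent_db": am_extent,
            "center_hz": center,
            "tonal_ratio": tonal,
            "f0": f0,
        },
    )


def synthesize_dataset(
    spec: SynthSpec,
    n_calls: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[CallRecording], pd.DataFrame]:
    """Generate a full labelled dataset.

    Contexts are sampled by weight (imbalanced), each call's valence follows
    its context's mapping, call type is drawn per valence (HF calls are much
    rarer in positive contexts), and pigs are drawn uniformly from the
    registry.  Returns the calls plus a metadata table.
    """
    spec.validate()
    n_calls = spec.n_calls if n_calls is None else n_calls
    if n_calls <= 0:
        raise ValueError("zero total calls requested")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    pigs = build_pigs(spec, rng)
    labels = [c.label for c in spec.contexts]
    weights = np.array([c.weight for c in spec.contexts], float)
    probs = weights / weights.sum()
    vmap = spec.context_map

    calls, rows = [], []
    pig_ids = sorted(pigs)
    for i in range(n_calls):
        ctx = labels[rng.choice(len(labels), p=probs)]
        val = vmap[ctx]
        ctype = "HF" if rng.random() < spec.hf_prob[val] else "LF"
        pid = pig_ids[rng.integers(len(pig_ids))]
        call = synthesize_call(
            spec, ctype, val, pid, rng, pigs=pigs, context=ctx, call_id=f"call{i:05d}"
        )
        calls.append(call)
        rows.append(
            {
                "call_id": call.call_id,
                "pig_id": call.pig_id,
                "team_id": call.team_id,
                "age_days": call.age_days,
                "age_class": call.age_class,
                "context": call.context,
                "valence": call.valence,
                "synth_call_type": ctype,
            }
        )
    return calls, pd.DataFrame(rows)


def synthesize_cells(spec: SynthSpec, n_per_cell: int,
                     rng: np.random.Generator | None = None,
                     call_types=("LF", "HF"), valences=("negative", "positive")):
    """Balanced design: ``n_per_cell`` calls for every (call type, valence)
    cell, pigs cycled through the registry.  Convenient for direction and
    recovery analyses where the imbalanced default dataset would leave the
    rare cells (positive HF) underpowered."""
    if n_per_cell <= 0:
        raise ValueError("zero total calls requested")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    pigs = build_pigs(spec, rng)
    pig_ids = sorted(pigs)
    calls, rows = [], []
    i = 0
    for ctype in call_types:
        for val in valences:
            ctx = "Isolation" if val == "negative" else "Reunion"
            for _ in range(n_per_cell):
                pid = pig_ids[i % len(pig_ids)]
                call = synthesize_call(spec, ctype, val, pid, rng, pigs=pigs,
                                       context=ctx, call_id=f"call{i:05d}")
                calls.append(call)
                rows.append({
                    "call_id": call.call_id, "pig_id": pid,
                    "team_id": call.team_id, "age_days": call.age_days,
                    "age_class": call.age_class, "context": ctx,
                    "valence": val, "synth_call_type": ctype,
                })
                i += 1
    return calls, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk round trip (WAV PCM16 + metadata CSV)

def write_dataset(calls: list[CallRecording], meta: pd.DataFrame, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for call in calls:
        path = outdir / f"{call.call_id}.wav"
        pcm = np.clip(call.waveform, -1, 1)
        wavfile.write(path, call.sample_rate, (pcm * 32767).astype(np.int16))
        paths.append(path.name)
    meta = meta.copy()
    meta["wav_path"] = paths
    cols = ["call_id", "wav_path", "pig_id", "team_id", "age_days", "age_class", "context", "valence"]
    extra = [c for c in meta.columns if c not in cols]
    meta_path = outdir / "meta.csv"
    meta[cols + extra].to_csv(meta_path, index=False)
    return meta_path


def load_dataset(meta_csv) -> tuple[list[CallRecording], pd.DataFrame]:
    """Read back a WAV+CSV dataset into CallRecording objects."""
    meta_csv = Path(meta_csv)
    meta = pd.read_csv(meta_csv)
    calls = []
    for _, row in meta.iterrows():
        sr, pcm = wavfile.read(meta_csv.parent / row["wav_path"])
        wave = pcm.astype(np.float64) / 32767.0
        calls.append(
            CallRecording(
                call_id=row["call_id"],
                waveform=wave,
                sample_rate=int(sr),
                pig_id=row["pig_id"],
                team_id=row["team_id"],
                age_days=int(row["age_days"]),
                age_class=int(row["age_class"]),
                context=row["context"],
                valence=row["valence"],
            )
        )
    return calls, meta
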