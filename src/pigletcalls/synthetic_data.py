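"""Synthetic piglet-call generator with known ground truth.

The generator emulates the structure of the study data — eleven recording
situations in three gross categories, five latent call types with distinct
pitch/duration/tonality/modulation profiles, situation-specific call-type
mixtures, per-piglet and per-litter random effects, and unbalanced call
counts — so every downstream stage (clustering, classification, valence
modelling) can be tested against known truth.

Two generation paths exist. The primary path draws calls directly in the
8-feature space as a Gaussian mixture (one component per latent call type)
with additive individual effects; this is the representation all the
statistics operate on. The secondary path synthesizes waveforms (harmonic
stack with a linearly swept fundamental mixed with band-limited noise) so
the acoustic feature-extraction stage can be exercised end to end.

Default call-type prototypes follow the qualitative profiles of the five
repertoire clusters: the two high-frequency (HF) types are higher-pitched
and longer than the low-frequency (LF) types, HFm rises steeply in pitch,
LFt is the most tonal (lowest entropy) LF type, and LFs is the lowest and
least modulated. Default situation mixtures concentrate HF types in
life-threatening situations, LFt around nursing, and LFs/LFm in the other
social situations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import FEATURE_NAMES, META_NAMES, write_wav
from .study import GROSS_CATEGORY, load_study_fixture

# ---------------------------------------------------------------------------
# prototypes


@dataclass(frozen=True)
class CallTypePrototype:
    """One latent call type: feature-space distribution + synthesis recipe.

    ``mean_features`` / ``feature_sd`` are in natural units and ordered as
    :data:`pigletcalls.acoustics.FEATURE_NAMES`. ``f_start``/``f_end`` give
    the fundamental sweep (Hz) and ``tonal_fraction`` the proportion of
    harmonic versus noise energy used for waveform synthesis.
    """

    label: str
    mean_features: np.ndarray
    feature_sd: np.ndarray
    f_start: float
    f_end: float
    tonal_fraction: float
    dur_mean: float

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_features, dtype=np.float64)
        sd = np.asarray(self.feature_sd, dtype=np.float64)
        object.__setattr__(self, "mean_features", mean)
        object.__setattr__(self, "feature_sd", sd)
        if mean.shape != (len(FEATURE_NAMES),) or sd.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"prototype {self.label}: feature vectors must have length 8")
        if np.any(sd < 0):
            raise ValueError(f"prototype {self.label}: feature_sd must be non-negative")
        if not 0.0 <= self.tonal_fraction <= 1.0:
            raise ValueError(f"prototype {self.label}: tonal_fraction must be in [0, 1]")
        if self.dur_mean <= 0:
            raise ValueError(f"prototype {self.label}: dur_mean must be positive")


CALL_TYPES = ["LFs", "LFm", "LFt", "HFs", "HFm"]

# mean features per type, order: pf, q50, ent, q50start, q50end, q50min, dur, q50maxloc
_PROTO_MEANS = {
    "LFs": [300, 500, 0.75, 520, 520, 450, 0.12, 5],
    "LFm": [500, 900, 0.65, 700, 1350, 650, 0.16, 8],
    "LFt": [900, 1400, 0.30, 1350, 1450, 1250, 0.20, 5],
    "HFs": [3600, 3800, 0.25, 3700, 3800, 3500, 0.90, 5],
    "HFm": [2400, 3000, 0.40, 2000, 4300, 1900, 0.50, 9],
}
_PROTO_SDS = {
    "LFs": [150, 180, 0.12, 200, 200, 180, 0.05, 2.0],
    "LFm": [200, 250, 0.12, 250, 350, 250, 0.06, 1.5],
    "LFt": [300, 350, 0.10, 350, 350, 330, 0.08, 2.0],
    "HFs": [700, 700, 0.10, 700, 700, 700, 0.30, 2.0],
    "HFm": [600, 700, 0.12, 600, 800, 600, 0.20, 1.5],
}
_PROTO_SYNTH = {  # f_start, f_end, tonal_fraction, dur_mean
    "LFs": (250, 260, 0.20, 0.12),
    "LFm": (300, 600, 0.30, 0.16),
    "LFt": (700, 750, 0.85, 0.20),
    "HFs": (1800, 1900, 0.90, 0.90),
    "HFm": (1000, 2200, 0.80, 0.50),
}


def default_prototypes(sd_scale: float = 1.0) -> list[CallTypePrototype]:
    """The five default call-type prototypes.

    ``sd_scale`` multiplies every within-type SD; values well below 1 give
    sharply separated types (useful for recovery experiments), 1 gives the
    blurred, overlapping repertoire the defaults emulate.
    """
    protos = []
    for label in CALL_TYPES:
        f_start, f_end, tonal, dur = _PROTO_SYNTH[label]
        protos.append(
            CallTypePrototype(
                label=label,
                mean_features=np.array(_PROTO_MEANS[label], dtype=float),
                feature_sd=sd_scale * np.array(_PROTO_SDS[label], dtype=float),
                f_start=f_start,
                f_end=f_end,
                tonal_fraction=tonal,
                dur_mean=dur,
            )
        )
    return protos


# ---------------------------------------------------------------------------
# study design


@dataclass(frozen=True)
class SituationSpec:
    code: str
    gross_category: str
    n_calls: int
    n_piglets: int
    n_litters: int


# per-situation mixture over (LFs, LFm, LFt, HFs, HFm); HF types concentrate
# in life-threatening situations, LFt around nursing, LFs/LFm elsewhere
DEFAULT_MIXTURES: dict[str, tuple[float, ...]] = {
    "CA": (0.05, 0.05, 0.10, 0.45, 0.35),
    "CR": (0.10, 0.10, 0.15, 0.25, 0.40),
    "AR": (0.10, 0.10, 0.10, 0.25, 0.45),
    "FI": (0.10, 0.15, 0.15, 0.20, 0.40),
    "BN": (0.15, 0.15, 0.55, 0.05, 0.10),
    "AN": (0.10, 0.15, 0.60, 0.05, 0.10),
    "MN": (0.25, 0.25, 0.35, 0.05, 0.10),
    "HU": (0.45, 0.30, 0.15, 0.05, 0.05),
    "IS": (0.55, 0.25, 0.10, 0.05, 0.05),
    "RE": (0.30, 0.35, 0.25, 0.05, 0.05),
    "SU": (0.40, 0.35, 0.15, 0.05, 0.05),
}

# situation-diagnostic mixture variant for method-validation (recovery)
# experiments: each gross category owns a disjoint dominant-type set
# (life-threat: HFs/HFm, nursing: LFt, other: LFs/LFm) and situations within
# a category differ mainly in how they share that set, so situations remain
# identifiable from pooled calls while categories stay coherent
CONTRAST_MIXTURES: dict[str, tuple[float, ...]] = {
    "CA": (0.02, 0.03, 0.05, 0.80, 0.10),
    "CR": (0.04, 0.04, 0.07, 0.55, 0.30),
    "AR": (0.03, 0.04, 0.03, 0.10, 0.80),
    "FI": (0.06, 0.06, 0.08, 0.30, 0.50),
    "BN": (0.10, 0.18, 0.66, 0.02, 0.04),
    "AN": (0.04, 0.06, 0.86, 0.01, 0.03),
    "MN": (0.28, 0.06, 0.60, 0.02, 0.04),
    "HU": (0.48, 0.40, 0.07, 0.02, 0.03),
    "IS": (0.80, 0.10, 0.06, 0.02, 0.02),
    "RE": (0.12, 0.72, 0.12, 0.02, 0.02),
    "SU": (0.40, 0.40, 0.14, 0.03, 0.03),
}

#: situations ordered from most negative (rank 1) to most positive (rank 11)
DEFAULT_VALENCE_ORDER = ["CA", "CR", "IS", "AR", "MN", "FI", "SU", "BN", "HU", "RE", "AN"]


@dataclass
class StudyDesign:
    """Sampling design: situations, type mixtures and random-effect scales.

    ``piglet_effect_sd`` / ``litter_effect_sd`` are expressed as fractions
    of the per-feature pooled within-type SD, so 0.3 means an individual
    shifts each of its calls' features by ~30 % of a within-type SD.
    """

    situations: list[SituationSpec]
    type_mixture: dict[str, np.ndarray]
    piglet_effect_sd: float = 0.3
    litter_effect_sd: float = 0.15
    valence_true_order: list[str] = field(default_factory=lambda: list(DEFAULT_VALENCE_ORDER))

    def __post_init__(self) -> None:
        for spec in self.situations:
            if spec.n_calls < 1:
                raise ValueError(f"situation {spec.code}: n_calls must be >= 1")
            mixture = np.asarray(self.type_mixture[spec.code], dtype=np.float64)
            if mixture.size == 0:
                raise ValueError(f"situation {spec.code}: empty mixture")
            if abs(mixture.sum() - 1.0) > 1e-9:
                raise ValueError(f"situation {spec.code}: mixture sums to {mixture.sum()}")
            self.type_mixture[spec.code] = mixture
        if self.piglet_effect_sd < 0 or self.litter_effect_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")


def default_design(
    piglet_effect_sd: float = 0.3, litter_effect_sd: float = 0.15
) -> StudyDesign:
    """Study design transcribed from the recording-design table: 11
    situations, 1513 calls, 3 gross categories, default type mixtures."""
    fixture = load_study_fixture()
    situations = [
        SituationSpec(r.situation, r.gross_category, r.n_calls, r.n_piglets, r.n_litters)
        for r in fixture.itertuples(index=False)
    ]
    return StudyDesign(
        situations=situations,
        type_mixture={k: np.array(v) for k, v in DEFAULT_MIXTURES.items()},
        piglet_effect_sd=piglet_effect_sd,
        litter_effect_sd=litter_effect_sd,
    )


def recovery_design(
    piglet_effect_sd: float = 0.3, litter_effect_sd: float = 0.15
) -> StudyDesign:
    """Study design for recovery experiments: the same situations and
    counts as :func:`default_design` but with the situation-diagnostic
    :data:`CONTRAST_MIXTURES`, so that methods which should succeed when
    signal is present can be validated against known truth."""
    design = default_design(piglet_effect_sd, litter_effect_sd)
    design.type_mixture = {k: np.array(v) for k, v in CONTRAST_MIXTURES.items()}
    return design


# ---------------------------------------------------------------------------
# feature-space generation (primary path)


def generate_feature_dataset(
    design: StudyDesign, prototypes: list[CallTypePrototype], seed: int
) -> pd.DataFrame:
    """Draw a call-level feature table with metadata and true latent types.

    Each call's features are its prototype mean plus a per-piglet offset,
    a per-litter offset and residual within-type noise (all Gaussian).
    Columns: the metadata, ``true_type``, then the eight features.
    Per-situation call counts match the design exactly.
    """
    rng = np.random.default_rng(seed)
    labels = [p.label for p in prototypes]
    means = np.stack([p.mean_features for p in prototypes])
    sds = np.stack([p.feature_sd for p in prototypes])
    pooled_sd = sds.mean(axis=0)  # natural-unit scale for the random effects

    rows = []
    for spec in design.situations:
        mixture = design.type_mixture[spec.code]
        if mixture.size != len(prototypes):
            raise ValueError(
                f"situation {spec.code}: mixture has {mixture.size} entries for "
                f"{len(prototypes)} prototypes"
            )
        piglets = [f"{spec.code}_p{i + 1}" for i in range(spec.n_piglets)]
        litter_of = {
            pig: f"{spec.code}_l{(i % spec.n_litters) + 1}" for i, pig in enumerate(piglets)
        }
        piglet_offset = {
            pig: rng.normal(0.0, design.piglet_effect_sd * pooled_sd) for pig in piglets
        }
        litter_ids = sorted(set(litter_of.values()))
        litter_offset = {
            lit: rng.normal(0.0, design.litter_effect_sd * pooled_sd) for lit in litter_ids
        }
        type_idx = rng.choice(len(prototypes), size=spec.n_calls, p=mixture)
        pig_idx = rng.integers(0, spec.n_piglets, size=spec.n_calls)
        for k in range(spec.n_calls):
            t = int(type_idx[k])
            pig = piglets[int(pig_idx[k])]
            lit = litter_of[pig]
            x = (
                means[t]
                + piglet_offset[pig]
                + litter_offset[lit]
                + rng.normal(0.0, sds[t])
            )
            x = _coerce_feature_vector(x)
            rows.append(
                {
                    "call_id": f"{spec.code}_{k + 1:04d}",
                    "situation": spec.code,
                    "piglet": pig,
                    "litter": lit,
                    "true_type": labels[t],
                    **dict(zip(FEATURE_NAMES, x)),
                }
            )
    return pd.DataFrame(rows, columns=META_NAMES + ["true_type"] + FEATURE_NAMES)


def _coerce_feature_vector(x: np.ndarray) -> np.ndarray:
    """Push a sampled vector back into the feasible feature region."""
    x = x.copy()
    for j, name in enumerate(FEATURE_NAMES):
        if name in ("pf", "q50", "q50start", "q50end", "q50min"):
            x[j] = max(x[j], 43.0)  # one frequency bin
    ent = FEATURE_NAMES.index("ent")
    x[ent] = float(np.clip(x[ent], 0.0, 1.0))
    dur = FEATURE_NAMES.index("dur")
    x[dur] = max(x[dur], 0.034)
    loc = FEATURE_NAMES.index("q50maxloc")
    x[loc] = float(np.clip(round(x[loc]), 1, 9))
    # q50min may not exceed the endpoint q50 values
    q50min = FEATURE_NAMES.index("q50min")
    x[q50min] = min(x[q50min], x[FEATURE_NAMES.index("q50start")], x[FEATURE_NAMES.index("q50end")])
    return x


# ---------------------------------------------------------------------------
# waveform synthesis (secondary path)


def generate_waveform(
    prototype: CallTypePrototype,
    sample_rate: float = 44100.0,
    seed: int = 0,
    dur: float | None = None,
    pad_s: float = 0.05,
    n_harmonics: int = 8,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Synthesize one call and return (waveform, (start_s, end_s)).

    The call is a ``tonal_fraction``-weighted harmonic stack whose
    fundamental sweeps linearly from ``f_start`` to ``f_end``, mixed with
    ``(1 - tonal_fraction)``-weighted band-limited Gaussian noise,
    amplitude-tapered at the edges and embedded in ``pad_s`` seconds of
    silence on each side. Deterministic given the seed.
    """
    dur = prototype.dur_mean if dur is None else dur
    if dur <= 0:
        raise ValueError(f"duration must be positive, got {dur}")
    nyquist = sample_rate / 2.0
    f_max = max(prototype.f_start, prototype.f_end)
    if f_max >= nyquist:
        raise ValueError(
            f"synthesis frequency {f_max} Hz is not below the Nyquist limit {nyquist} Hz"
        )
    rng = np.random.default_rng(seed)
    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    f0 = prototype.f_start + (prototype.f_end - prototype.f_start) * t / dur
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate

    tone = np.zeros(n)
    used = 0
    for h in range(1, n_harmonics + 1):
        if h * f_max >= 0.95 * nyquist:
            break
        tone += np.sin(h * phase) / h
        used += 1
    if used:
        tone /= np.max(np.abs(tone))

    noise = rng.standard_normal(n)
    from scipy.signal import butter, sosfiltfilt

    lo = max(0.5 * min(prototype.f_start, prototype.f_end), 20.0)
    hi = min(4.0 * f_max, 0.9 * nyquist)
    sos = butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    noise = sosfiltfilt(sos, noise)
    noise /= np.max(np.abs(noise))

    call = prototype.tonal_fraction * tone + (1.0 - prototype.tonal_fraction) * noise
    from scipy.signal.windows import tukey

    call *= tukey(n, alpha=min(0.2, 2 * 0.005 * sample_rate / max(n, 1)))
    call = 0.9 * call / np.max(np.abs(call))

    pad = np.zeros(int(round(pad_s * sample_rate)))
    waveform = np.concatenate([pad, call, pad])
    start = pad.size / sample_rate
    return waveform, (start, start + n / sample_rate)


def write_waveform_dataset(
    out_dir,
    prototypes: list[CallTypePrototype] | None = None,
    n_per_type: int = 3,
    sample_rate: float = 44100.0,
    seed: int = 0,
    situation: str = "IS",
) -> pd.DataFrame:
    """Write one WAV file per synthetic call plus an annotation table.

    Returns the annotation table (also saved as ``annotations.csv``);
    columns follow the annotation schema used by the acoustics stage.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prototypes = prototypes or default_prototypes()
    rows = []
    counter = 0
    for proto in prototypes:
        for k in range(n_per_type):
            counter += 1
            waveform, (start, end) = generate_waveform(
                proto, sample_rate=sample_rate, seed=seed * 10_000 + counter
            )
            fname = f"call_{proto.label}_{k + 1}.wav"
            write_wav(out_dir / fname, waveform, sample_rate)
            rows.append(
                {
                    "call_id": f"{proto.label}_{k + 1}",
                    "file": fname,
                    "start_s": round(start, 6),
                    "end_s": round(end, 6),
                    "situation": situation,
                    "piglet": f"syn_p{counter}",
                    "litter": "syn_l1",
                    "true_type": proto.label,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "annotations.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# expert valence ranks


def generate_expert_ranks(
    true_order: list[str], n_experts: int, swap_noise: float, seed: int
) -> pd.DataFrame:
    """Simulate the expert negativity-ranking questionnaire.

    ``true_order`` lists situations from most negative (rank 1) to most
    positive. Each expert's ranking is the true order perturbed by random
    adjacent transpositions: every adjacent pair is swapped independently
    with probability ``swap_noise`` in one left-to-right pass. Returns a
    table of ranks (experts x situations); every row is a permutation of
    1..S.
    """
    if n_experts < 1:
        raise ValueError("n_experts must be >= 1")
    if not 0.0 <= swap_noise <= 1.0:
        raise ValueError(f"swap_noise must be in [0, 1], got {swap_noise}")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_experts):
        order = list(true_order)
        for i in range(len(order) - 1):
            if rng.random() < swap_noise:
                order[i], order[i + 1] = order[i + 1], order[i]
        ranks = {code: rank for rank, code in enumerate(order, start=1)}
        rows.append([ranks[code] for code in true_order])
    return pd.DataFrame(
        rows, columns=list(true_order), index=[f"expert_{i + 1}" for i in range(n_experts)]
    )


def gross_category_of(code: str) -> str:
    return GROSS_CATEGORY[code]
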