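"""Synthetic dyadic-session generator with per-nod ground truth.

Emulates what the analysis pipeline consumes: 50 fps keypoint streams with
per-frame Gaussian jitter, occasional dropped and low-confidence frames, and
person-scale variation, together with matching annotation tiers (nod
form/function/turn, gloss, mouth) and a truth table of scripted kinematics.

A nod is modeled as a windowed sinusoid: amplitude is the scripted
peak-to-trough excursion in npix, frequency the nod cycle rate in Hz, and
duration follows as n_cycles / frequency.  Sinusoids keep closed-form truths
available (peak-to-trough = amplitude; mean |velocity| = 2 * amplitude *
frequency), which is what makes end-to-end parameter-recovery tests possible.

Defaults place synthetic corpora in the observed operating range of natural
DGS conversation: small-nod amplitudes around 0.023 npix and large around
0.087 npix, a function mix of 64% feedback / 13% affirmation / 23% other,
affirmative nods larger and faster than feedback nods, 87% vs 35% manual
co-occurrence, and turn-initialization rates of 86.7% (affirmation) vs 27.8%
(feedback).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from nodphon.pose_io import (
    N_BODY,
    N_FACE,
    BODY_MIDHIP,
    BODY_NECK,
    FACE_NOSE_TIP,
    AnnotationDocument,
    AnnotationSpan,
    PoseFrame,
    PoseSequence,
)

#: amplitude (npix) at or above which a scripted nod counts as "large"
LARGE_AMPLITUDE_NPIX = 0.05

LEXICAL_GLOSSES = ["JA1", "STIMMT1", "GUT1", "OKAY1", "INDEX1", "AUCH1"]
GESTURE_GLOSSES = ["$GEST-OFF^", "$GEST-NM^", "$GEST^"]
MOUTHINGS = ["ja", "stimmt", "klar", "gut"]
MOUTH_GESTURE = "[MG]"


@dataclass(frozen=True)
class NodScript:
    """One scripted nod: where it is, how it moves, what it means."""

    start_ms: float
    n_cycles: int
    amplitude: float
    frequency: float
    function: str
    turn: str = "unset"
    signer: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.5 < self.frequency < 5.0:
            raise ValueError("frequency must lie in (0.5, 5) Hz")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_cycles / self.frequency

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms

    @property
    def form(self) -> str:
        size = "l" if self.amplitude >= LARGE_AMPLITUDE_NPIX else "s"
        return f"{size}n" if self.n_cycles == 1 else f"{size[0]}nn" if size == "l" else "hnn"


@dataclass
class SessionConfig:
    """Study conditions for one synthetic corpus.  ``seed`` is mandatory."""

    seed: int
    n_signers: int = 24
    nods_per_signer: int = 27
    fps: float = 50.0
    jitter_sd: float = 0.003          # npix, per frame per keypoint
    dropped_frame_rate: float = 0.01
    low_confidence_rate: float = 0.005
    function_mix: dict[str, float] = field(
        default_factory=lambda: {"feedback": 0.64, "affirmation": 0.13, "other": 0.23}
    )
    # kinematic population: lognormal amplitude/frequency; affirmation offsets
    median_amplitude_npix: float = 0.025
    log_amplitude_sd: float = 0.6
    median_frequency_hz: float = 1.4
    log_frequency_sd: float = 0.25
    affirmation_log_amplitude_offset: float = 0.8
    affirmation_log_velocity_offset: float = 0.8
    ti_log_frequency_offset: float = 0.35
    affirmation_extra_cycles: float = 0.7
    single_nod_prob: float = 0.3
    signer_intercept_sd: float = 0.8  # log-odds heterogeneity across signers
    p_manual: dict[str, float] = field(
        default_factory=lambda: {"feedback": 0.35, "affirmation": 0.87, "other": 0.30}
    )
    p_gesture_given_manual: float = 0.28
    p_mouth: dict[str, float] = field(
        default_factory=lambda: {"feedback": 0.60, "affirmation": 0.80, "other": 0.50}
    )
    p_mouth_gesture_given_mouth: float = 0.2
    p_turn_initialization: dict[str, float] = field(
        default_factory=lambda: {"feedback": 0.278, "affirmation": 0.867}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.function_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"function_mix must sum to 1, got {total}")
        for p in (self.dropped_frame_rate, self.low_confidence_rate, *self.p_manual.values(),
                  *self.p_mouth.values(), *self.p_turn_initialization.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SessionResult:
    """Everything one synthetic corpus run produces."""

    sequences: dict[str, PoseSequence]
    documents: dict[str, AnnotationDocument]
    truth: pd.DataFrame
    config: SessionConfig


def nod_waveform(script: NodScript, fps: float) -> np.ndarray:
    """Noise-free vertical nose displacement of one nod, in npix, up-positive.

    A sine at the scripted frequency, tapered with a Tukey window whose flat
    interior covers every interior peak, so the head leaves and returns to
    rest smoothly while the core peak-to-trough excursion equals the scripted
    amplitude within 2%.
    """
    n = int(round(script.duration_ms / 1000.0 * fps))
    if n < 2:
        raise ValueError(f"nod of {script.duration_ms:.0f} ms spans fewer than 2 frames at {fps} fps")
    t = np.arange(n) / fps
    core = (script.amplitude / 2.0) * np.sin(2 * np.pi * script.frequency * t)
    return core * tukey(n, alpha=0.2)


def _signer_function_probs(config: SessionConfig, intercept: float) -> np.ndarray:
    """Shift a signer's affirmation share on the log-odds scale.

    The random intercept moves the affirmation-vs-rest log-odds; feedback and
    'other' absorb the complement in their original ratio.  This is the
    heterogeneity the mixed model's random signer intercept is meant to soak
    up, so fitted sigma_u estimates ``signer_intercept_sd``.
    """
    functions = list(config.function_mix)
    base = np.array([config.function_mix[f] for f in functions])
    i_aff = functions.index("affirmation") if "affirmation" in functions else None
    if i_aff is None or base[i_aff] in (0.0, 1.0):
        return base
    logit = math.log(base[i_aff] / (1 - base[i_aff])) + intercept
    p_aff = 1.0 / (1.0 + math.exp(-logit))
    probs = base * (1 - p_aff) / (1 - base[i_aff])
    probs[i_aff] = p_aff
    return probs


def _sample_scripts(config: SessionConfig, signer: str, rng: np.random.Generator) -> list[NodScript]:
    """Script one signer's nods sequentially, leaving >= 400 ms between them."""
    functions = list(config.function_mix)
    intercept = rng.normal(0, config.signer_intercept_sd)
    probs = _signer_function_probs(config, intercept)
    scripts: list[NodScript] = []
    cursor = 1000.0
    for _ in range(config.nods_per_signer):
        fn = functions[rng.choice(len(functions), p=probs)]
        turn = "unset"
        if fn in config.p_turn_initialization:
            turn = "TI" if rng.random() < config.p_turn_initialization[fn] else "PR"
        log_a = math.log(config.median_amplitude_npix) + rng.normal(0, config.log_amplitude_sd)
        log_f = math.log(config.median_frequency_hz) + rng.normal(0, config.log_frequency_sd)
        cycles_mean = 1.0
        if fn == "affirmation":
            log_a += config.affirmation_log_amplitude_offset
            log_f += config.affirmation_log_velocity_offset - config.affirmation_log_amplitude_offset
            # affirmative nodding spreads over the articulated response, which
            # roughly offsets the faster turn-initiation cycle rate below
            cycles_mean += config.affirmation_extra_cycles
        if turn == "TI":
            log_f += config.ti_log_frequency_offset
        amplitude = math.exp(log_a)
        frequency = float(np.clip(math.exp(log_f), 0.6, 4.5))
        n_cycles = 1 if rng.random() < config.single_nod_prob else 2 + rng.poisson(cycles_mean)
        scripts.append(
            NodScript(
                start_ms=cursor, n_cycles=int(n_cycles), amplitude=amplitude,
                frequency=frequency, function=fn, turn=turn, signer=signer,
            )
        )
        gloss_tail = 1900.0 if turn == "TI" else 0.0  # room for turn glosses
        cursor = scripts[-1].end_ms + gloss_tail + rng.uniform(600.0, 2500.0)
    return scripts


def _annotation_tiers(
    scripts: list[NodScript], config: SessionConfig, rng: np.random.Generator
) -> dict[str, list[AnnotationSpan]]:
    form, function, turn, gloss, mouth = [], [], [], [], []
    for s in scripts:
        form.append(AnnotationSpan(s.start_ms, s.end_ms, s.form))
        function.append(AnnotationSpan(s.start_ms, s.end_ms, s.function))
        if s.turn != "unset":
            turn.append(AnnotationSpan(s.start_ms, s.end_ms, s.turn))
        # co-occurring manual item: inside the nod, ending clear of the
        # turn-transition window so it cannot read as taking the floor
        if s.duration_ms > 500 and rng.random() < config.p_manual[s.function]:
            is_gesture = rng.random() < config.p_gesture_given_manual
            label = GESTURE_GLOSSES[rng.integers(len(GESTURE_GLOSSES))] if is_gesture \
                else LEXICAL_GLOSSES[rng.integers(len(LEXICAL_GLOSSES))]
            g_start = s.start_ms + 50
            g_end = min(s.end_ms - 350, g_start + rng.uniform(200, 500))
            if g_end > g_start:
                gloss.append(AnnotationSpan(g_start, g_end, label))
        if s.turn == "TI":
            g1_start = s.end_ms + rng.uniform(50, 250)
            g1_end = g1_start + rng.uniform(300, 700)
            g2_start = g1_end + rng.uniform(50, 150)
            g2_end = g2_start + rng.uniform(200, 600)
            gloss.append(AnnotationSpan(g1_start, g1_end, LEXICAL_GLOSSES[rng.integers(len(LEXICAL_GLOSSES))]))
            gloss.append(AnnotationSpan(g2_start, g2_end, LEXICAL_GLOSSES[rng.integers(len(LEXICAL_GLOSSES))]))
        if rng.random() < config.p_mouth[s.function]:
            is_mg = rng.random() < config.p_mouth_gesture_given_mouth
            label = MOUTH_GESTURE if is_mg else MOUTHINGS[rng.integers(len(MOUTHINGS))]
            m_start = s.start_ms + 30
            m_end = min(s.end_ms, m_start + rng.uniform(150, 600))
            if m_end > m_start:
                mouth.append(AnnotationSpan(m_start, m_end, label))
    return {
        "nod_form": form, "nod_function": function, "nod_turn": turn,
        "gloss": sorted(gloss, key=lambda s: s.start), "mouth": sorted(mouth, key=lambda s: s.start),
    }


# unit skeleton: keypoint offsets from the collarbone in hip-collarbone units
_BODY_OFFSETS = np.zeros((N_BODY, 2))
_BODY_OFFSETS[0] = (0.0, -0.35)            # nose (body model)
_BODY_OFFSETS[BODY_NECK] = (0.0, 0.0)      # collarbone / neck
_BODY_OFFSETS[BODY_MIDHIP] = (0.0, 1.0)    # mid-hip
_BODY_OFFSETS[2] = (-0.25, 0.02); _BODY_OFFSETS[5] = (0.25, 0.02)    # shoulders
_BODY_OFFSETS[3] = (-0.32, 0.40); _BODY_OFFSETS[6] = (0.32, 0.40)    # elbows
_BODY_OFFSETS[4] = (-0.30, 0.75); _BODY_OFFSETS[7] = (0.30, 0.75)    # wrists
_BODY_OFFSETS[9] = (-0.15, 1.0); _BODY_OFFSETS[12] = (0.15, 1.0)     # hips
_FACE_OFFSETS = np.zeros((N_FACE, 2))
_FACE_OFFSETS[:, 0] = np.linspace(-0.12, 0.12, N_FACE)
_FACE_OFFSETS[:, 1] = -0.40
_FACE_OFFSETS[FACE_NOSE_TIP] = (0.0, -0.42)


def _render_pose(
    scripts: list[NodScript],
    config: SessionConfig,
    rng: np.random.Generator,
    signer: str,
) -> tuple[PoseSequence, np.ndarray]:
    """Pixel-space keypoint stream plus the clean npix nose trajectory."""
    fps = config.fps
    t_end_ms = scripts[-1].end_ms + 1000.0 if scripts else 2000.0
    n_frames = int(math.ceil(t_end_ms / 1000.0 * fps)) + 1

    scale_px = float(np.clip(rng.normal(550.0, 60.0), 350.0, 800.0))
    collar = np.array([640.0 + rng.normal(0, 40), 380.0 + rng.normal(0, 25)])

    clean = np.zeros(n_frames)  # npix nose displacement, up-positive
    for s in scripts:
        seg = nod_waveform(s, fps)
        i0 = int(round(s.start_ms / 1000.0 * fps))
        seg = seg[: max(0, n_frames - i0)]
        clean[i0 : i0 + len(seg)] += seg

    body_base = collar[None, :] + _BODY_OFFSETS * scale_px
    face_base = collar[None, :] + _FACE_OFFSETS * scale_px

    keep = rng.random(n_frames) >= config.dropped_frame_rate
    keep[0] = keep[-1] = True
    low_conf = rng.random(n_frames) < config.low_confidence_rate

    frames: list[PoseFrame] = []
    jitter_px = config.jitter_sd * scale_px
    for i in np.flatnonzero(keep):
        body = np.ones((N_BODY, 3))
        face = np.ones((N_FACE, 3))
        body[:, :2] = body_base + rng.normal(0, jitter_px, (N_BODY, 2))
        head_dy = -clean[i] * scale_px  # up-positive npix -> smaller pixel y
        face[:, :2] = face_base + np.array([0.0, head_dy]) + rng.normal(0, jitter_px, (N_FACE, 2))
        body[0, 1] += head_dy  # body-model nose rides with the head
        if low_conf[i]:
            face[FACE_NOSE_TIP] = 0.0
        frames.append(PoseFrame(int(i), body, face))
    return PoseSequence(frames=frames, fps=fps, participant_id=signer), clean


def _truth_rows(
    scripts: list[NodScript], clean: np.ndarray, config: SessionConfig
) -> list[dict]:
    rows = []
    fps = config.fps
    for k, s in enumerate(scripts):
        # same frame-inclusion convention as the measurement stage: frames
        # whose timestamp falls inside [start, end]
        i0 = int(math.ceil(s.start_ms / 1000.0 * fps - 1e-9))
        i1 = int(math.floor(s.end_ms / 1000.0 * fps + 1e-9))
        seg = clean[i0 : i1 + 1]
        rows.append(
            {
                "signer": s.signer,
                "nod_id": f"{s.signer}_{k:03d}",
                "start_ms": s.start_ms,
                "end_ms": s.end_ms,
                "form": s.form,
                "function": s.function,
                "turn": s.turn,
                "n_cycles": s.n_cycles,
                "scripted_amplitude_npix": s.amplitude,
                "scripted_frequency_hz": s.frequency,
                "true_duration_s": s.duration_ms / 1000.0,
                "true_amplitude_npix": float(seg.max() - seg.min()) if len(seg) else 0.0,
                "true_velocity_npix_s": float(fps * np.mean(np.abs(np.diff(seg)))) if len(seg) > 1 else 0.0,
            }
        )
    return rows


def simulate_session(config: SessionConfig) -> SessionResult:
    """Generate a full synthetic corpus: pose, annotations, and ground truth.

    Deterministic for a fixed config (same seed twice gives bit-identical
    output).  Signer-level heterogeneity enters through person scale,
    geometry, and each signer's random draw sequence.
    """
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, PoseSequence] = {}
    documents: dict[str, AnnotationDocument] = {}
    rows: list[dict] = []
    for s in range(config.n_signers):
        signer = f"S{s:02d}"
        scripts = _sample_scripts(config, signer, rng)
        tiers = _annotation_tiers(scripts, config, rng)
        seq, clean = _render_pose(scripts, config, rng, signer)
        sequences[signer] = seq
        documents[signer] = AnnotationDocument(tiers=tiers, participant_id=signer)
        rows.extend(_truth_rows(scripts, clean, config))
    truth = pd.DataFrame(rows)
    return SessionResult(sequences=sequences, documents=documents, truth=truth, config=config)


def perturb_annotator(
    form_spans: list[AnnotationSpan],
    seed: int,
    time_sd_ms: float = 80.0,
    miss_rate: float = 0.15,
    tag_confusion: float = 0.15,
    tags: tuple[str, ...] = ("sn", "ln", "hnn", "lnn", "mn"),
) -> list[AnnotationSpan]:
    """Simulate a second independent annotator of the same recording.

    Boundaries are shifted by Gaussian noise, a fraction of spans is missed
    entirely, and a fraction of tags is confused with a random other tag —
    the ingredients that temporal-overlap reliability statistics respond to.
    """
    rng = np.random.default_rng(seed)
    out: list[AnnotationSpan] = []
    prev_end = 0.0
    for span in form_spans:
        if rng.random() < miss_rate:
            continue
        start = max(prev_end + 1.0, span.start + rng.normal(0, time_sd_ms))
        end = max(start + 40.0, span.end + rng.normal(0, time_sd_ms))
        value = span.value
        if rng.random() < tag_confusion:
            others = [t for t in tags if t != value]
            value = others[rng.integers(len(others))]
        out.append(AnnotationSpan(start, end, value))
        prev_end = end
    return out


def simulate_binary_mixed(
    n_groups: int,
    n_per_group: int,
    beta: np.ndarray,
    sigma_u: float,
    seed: int,
    predictor_names: list[str] | None = None,
) -> pd.DataFrame:
    """Draw from a random-intercept logistic model with known parameters.

    ``beta`` is (intercept, slopes...); predictors are iid standard normal.
    Used for calibration and parameter-recovery checks of the mixed-model
    fitter.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = len(beta) - 1
    names = predictor_names or [f"x{i + 1}" for i in range(p)]
    n = n_groups * n_per_group
    X = rng.normal(size=(n, p))
    groups = np.repeat([f"S{g:02d}" for g in range(n_groups)], n_per_group)
    u = rng.normal(0, sigma_u, size=n_groups)
    eta = beta[0] + X @ beta[1:] + np.repeat(u, n_per_group)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    df = pd.DataFrame(X, columns=names)
    df["signer"] = groups
    df["is_affirmation"] = y
    return df


def config_to_dict(config: SessionConfig) -> dict:
    """Plain-dict snapshot of a config, for manifests and metadata headers."""
    return asdict(config)
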