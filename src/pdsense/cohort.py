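"""Synthetic labeled cohort of inertial-sensor examinations.

The clinical dataset this analysis was designed for (motor examinations of
Parkinson's disease patients, rated 0-4 per symptom by a clinician and
-4..+4 on a treatment-response scale) is not publicly deposited, so this
module generates a synthetic stand-in with the statistical structure the
downstream pipeline assumes:

* 30 s tri-axial recordings at 50 Hz from two devices (smartphone in hand,
  armband on forearm), each with accelerometer and gyroscope, per hand,
  for three exercises (1 = rest, 2 = postural hold, 3 = pronation-
  supination);
* tremor as a 4-6 Hz sinusoid whose amplitude grows with the tremor label,
  strongest at rest;
* bradykinesia as a slowed, damped voluntary pronation-supination
  oscillation in exercise 3;
* dyskinesia as an irregular smooth 1-3 Hz random process scaled by its
  label;
* stiffness as a multiplicative shrinkage of all motion variance;
* imbalanced severity-class weights, with severe dyskinesia nearly absent;
* repeated examinations per patient with within-patient label correlation.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as _sig

DEVICES = ("phone", "myo")
SENSORS = ("accelerometer", "gyroscope")
HANDS = ("left", "right")
EXERCISES = (1, 2, 3)
SYMPTOMS = ("tremor", "bradykinesia", "stiffness", "dyskinesia")

AFFECTED_SIDES = ("left", "right", "both")
HANDEDNESS_VOCAB = ("left", "right")
GROUP_VOCAB = ("oral_medication", "duodopa", "dbs")

FS = 50.0
N_SAMPLES = 1500  # 30 s at 50 Hz
GRAVITY = 9.81

# Severity-class weights per symptom (classes 0..4). Shapes mirror an
# imbalanced clinical sample: tremor is the most balanced symptom, level 1
# is modal for bradykinesia and stiffness, and severe dyskinesia is rare.
DEFAULT_SEVERITY_WEIGHTS = {
    "tremor": (0.30, 0.28, 0.22, 0.17, 0.03),
    "bradykinesia": (0.18, 0.35, 0.27, 0.15, 0.05),
    "stiffness": (0.15, 0.40, 0.26, 0.14, 0.05),
    "dyskinesia": (0.55, 0.25, 0.12, 0.075, 0.005),
}

# Effect sizes of the signal model (per unit of severity label).
TREMOR_GAIN = 0.12          # m/s^2 per label unit, accelerometer
TREMOR_EXERCISE_FACTOR = {1: 1.0, 2: 0.7, 3: 0.4}
PRONATION_BASE_FREQ = 1.5   # Hz at bradykinesia 0
PRONATION_FREQ_SLOPE = 0.18  # Hz lost per bradykinesia unit
PRONATION_BASE_AMP = 1.2    # rad/s gyroscope amplitude at bradykinesia 0
PRONATION_AMP_SLOPE = 0.15  # fractional loss per bradykinesia unit
DYSKINESIA_GAIN = 0.05      # m/s^2 RMS per label unit, 1-3 Hz band
STIFFNESS_SHRINK = 0.12     # fractional motion-variance shrink per unit
SWAY_AMP = {1: 0.0, 2: 0.06, 3: 0.05}  # postural sway, absent at rest
GYRO_SCALE = 0.5            # gyroscope amplitude relative to accelerometer
UNAFFECTED_SIDE_FACTOR = 0.6
MAX_AXIS_ROTATION_DEG = 15.0


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``seed`` fully determines the generated dataset. ``exams_mean`` /
    ``exams_sd`` parametrize a shifted negative-binomial for the number of
    examinations per patient. ``severity_weights`` maps each symptom to
    five nonnegative class weights summing to one.
    """

    n_patients: int = 200
    exams_mean: float = 3.07
    exams_sd: float = 2.77
    severity_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_WEIGHTS)
    )
    tremor_band: tuple = (4.0, 6.0)
    noise_sd: float = 0.05
    missing_block_probability: float = 0.05
    label_jitter_sd: float = 0.7
    trs_noise_sd: float = 0.5
    devices: tuple = DEVICES
    sensors: tuple = SENSORS
    hands: tuple = HANDS
    exercises: tuple = EXERCISES
    seed: int = 0

    def validate(self) -> None:
        for sym in SYMPTOMS:
            if sym not in self.severity_weights:
                raise ConfigurationError(f"missing severity weights for {sym!r}")
            w = np.asarray(self.severity_weights[sym], dtype=float)
            if w.shape != (5,) or (w < 0).any():
                raise ConfigurationError(
                    f"severity weights for {sym!r} must be 5 nonnegative values"
                )
            if abs(w.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"severity weights for {sym!r} sum to {w.sum()}, not 1"
                )
        if not 0.0 <= self.missing_block_probability <= 1.0:
            raise ConfigurationError("missing_block_probability outside [0, 1]")
        if not self.tremor_band[0] < self.tremor_band[1]:
            raise ConfigurationError("tremor_band must be an increasing interval")


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    affected_side: str
    handedness: str
    group: str
    age_at_baseline: float
    years_since_diagnosis: float
    trait_severities: dict  # symptom -> latent mean severity in [0, 4]


@dataclass(frozen=True)
class SeverityLabels:
    """Clinician symptom ratings (integers 0-4) and overall-state TRS values.

    TRS sign convention: negative = parkinsonian symptoms, positive =
    dyskinesia, 0 = optimal, on a 0.5-step grid in [-4, 4].
    """

    tremor: int
    bradykinesia: int
    stiffness: int
    dyskinesia: int
    trs_clinician: float
    trs_patient: float

    def symptom(self, name: str) -> int:
        return int(getattr(self, name))


@dataclass
class SensorRecording:
    device: str
    sensor: str
    hand: str
    exercise: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float = FS

    @property
    def block_key(self) -> tuple:
        return (self.device, self.sensor, self.hand, self.exercise)


@dataclass
class Examination:
    exam_id: str
    patient_id: str
    exam_index: int
    age_at_exam: float
    labels: SeverityLabels
    recordings: dict  # block_key -> SensorRecording


@dataclass
class Cohort:
    config: SyntheticConfig
    patients: list
    examinations: list

    def patient(self, patient_id: str) -> PatientProfile:
        return next(p for p in self.patients if p.patient_id == patient_id)


def _rng(*keys: int) -> np.random.Generator:
    # Composite integer key -> independent, order-insensitive stream.
    return np.random.default_rng(np.array(keys, dtype=np.uint64))


def generate_patient(config: SyntheticConfig, index: int) -> PatientProfile:
    """Draw one patient profile, deterministic given ``(config.seed, index)``."""
    config.validate()
    if index >= config.n_patients:
        raise ValueError(f"index {index} >= n_patients {config.n_patients}")
    rng = _rng(config.seed, 11, index)
    affected = rng.choice(AFFECTED_SIDES, p=(0.40, 0.45, 0.15))
    handed = rng.choice(HANDEDNESS_VOCAB, p=(0.10, 0.90))
    group = rng.choice(GROUP_VOCAB, p=(0.60, 0.25, 0.15))
    age = float(np.clip(rng.normal(62.0, 11.1), 35.0, 90.0))
    years = float(np.clip(rng.normal(10.5, 6.1), 0.0, age - 25.0))
    traits = {
        sym: float(rng.choice(5, p=config.severity_weights[sym]))
        for sym in SYMPTOMS
    }
    return PatientProfile(
        patient_id=f"P{index:04d}",
        affected_side=str(affected),
        handedness=str(handed),
        group=str(group),
        age_at_baseline=age,
        years_since_diagnosis=years,
        trait_severities=traits,
    )


def _round_to_half(v: float) -> float:
    return float(np.round(v * 2.0) / 2.0)


def derive_trs_label(
    symptoms: dict, noise_sd: float, rng: np.random.Generator
) -> tuple:
    """Map symptom severities to (clinician, patient) TRS values.

    The latent state is the dyskinesia severity minus the equally weighted
    mean of the three parkinsonian symptoms (tremor, bradykinesia,
    stiffness); each observer adds independent Gaussian noise, then the
    value is clipped to [-4, 4] and rounded to the 0.5 grid.
    """
    parkinsonian = (
        symptoms["tremor"] + symptoms["bradykinesia"] + symptoms["stiffness"]
    ) / 3.0
    latent = symptoms["dyskinesia"] - parkinsonian
    out = []
    for _ in range(2):
        v = latent + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        out.append(_round_to_half(float(np.clip(v, -4.0, 4.0))))
    return out[0], out[1]


def _sample_labels(
    profile: PatientProfile, config: SyntheticConfig, rng: np.random.Generator
) -> SeverityLabels:
    sev = {}
    for sym in SYMPTOMS:
        v = profile.trait_severities[sym] + rng.normal(0.0, config.label_jitter_sd)
        sev[sym] = int(np.clip(np.round(v), 0, 4))
    trs_c, trs_p = derive_trs_label(sev, config.trs_noise_sd, rng)
    return SeverityLabels(trs_clinician=trs_c, trs_patient=trs_p, **sev)


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _small_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    """Rotation matrix about a random axis by an angle <= max_deg."""
    axis = _unit_vector(rng)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _smooth_band_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS irregular smooth process band-limited to [lo, hi] Hz."""
    white = rng.normal(size=n + 200)
    sos = _sig.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    band = _sig.sosfiltfilt(sos, white)[100:-100]
    rms = np.sqrt(np.mean(band**2))
    return band / rms if rms > 0 else band


def simulate_exercise_signal(
    profile: PatientProfile,
    labels: SeverityLabels,
    device: str,
    sensor: str,
    hand: str,
    exercise: int,
    rng: np.random.Generator,
    config: SyntheticConfig | None = None,
    exam_state: dict | None = None,
) -> SensorRecording:
    """Simulate one 30 s tri-axial recording for a (device, sensor, hand,
    exercise) block.

    The signal is a sum of directed components in a body frame — tremor
    sinusoid (4-6 Hz, amplitude growing with the tremor label, strongest at
    rest), voluntary pronation-supination (exercise 3; slower and smaller
    with bradykinesia), an irregular 1-3 Hz dyskinetic process, and postural
    sway — shrunk multiplicatively by the stiffness label, rotated by a
    small random device-orientation offset, with gravity added on the
    accelerometer and white sensor noise on top.
    """
    config = config or SyntheticConfig()
    if exercise not in (1, 2, 3):
        raise ValueError(f"exercise must be 1, 2 or 3, got {exercise!r}")
    for sym in SYMPTOMS:
        if not 0 <= labels.symptom(sym) <= 4:
            raise ValueError(f"label {sym} out of range")

    n = N_SAMPLES
    t = np.arange(n) / FS
    side_factor = (
        1.0
        if profile.affected_side == "both" or profile.affected_side == hand
        else UNAFFECTED_SIDE_FACTOR
    )
    motion = np.zeros((3, n))

    # Tremor: per-recording frequency uniform in the physiological band.
    if labels.tremor > 0:
        f_t = rng.uniform(*config.tremor_band)
        amp = TREMOR_GAIN * labels.tremor * TREMOR_EXERCISE_FACTOR[exercise]
        amp *= side_factor
        wave = np.sin(2 * np.pi * f_t * t + rng.uniform(0, 2 * np.pi))
        if exercise == 3:
            # kinetic tremor rides on the voluntary movement: modulate
            wave = wave * (1.0 + 0.3 * np.sin(2 * np.pi * 0.2 * t))
        motion += amp * np.outer(_unit_vector(rng), wave)
    else:
        rng.uniform(*config.tremor_band)  # keep stream aligned across labels
        rng.uniform(0, 2 * np.pi)
        _unit_vector(rng)

    # Voluntary pronation-supination, slowed and damped by bradykinesia.
    if exercise == 3:
        f_v = PRONATION_BASE_FREQ - PRONATION_FREQ_SLOPE * labels.bradykinesia
        amp_v = PRONATION_BASE_AMP * (1.0 - PRONATION_AMP_SLOPE * labels.bradykinesia)
        amp_v *= 1.0 if sensor == "gyroscope" else 0.3
        wave = np.sin(2 * np.pi * f_v * t + rng.uniform(0, 2 * np.pi))
        direction = _unit_vector(rng)
        motion += amp_v * np.outer(direction, wave)

    # Dyskinesia: irregular smooth involuntary movement, 1-3 Hz. Its
    # expression is episodic and medication-state dependent: the intensity
    # fluctuates between examinations (a factor shared by all recordings
    # of an exam, via exam_state) and within a recording (burst envelope),
    # which is what makes this symptom hard to rate from a 30 s snippet.
    if labels.dyskinesia > 0:
        amp_d = DYSKINESIA_GAIN * labels.dyskinesia * side_factor
        if exam_state is not None and "dyskinesia_expression" in exam_state:
            amp_d *= exam_state["dyskinesia_expression"]
        else:
            amp_d *= rng.lognormal(mean=-0.32, sigma=0.8)
        amp_d *= rng.lognormal(mean=-0.045, sigma=0.3)
        envelope = np.clip(
            1.0 + 0.8 * _smooth_band_noise(n, FS, 0.05, 0.4, rng), 0.0, None
        )
        proc = np.vstack(
            [_smooth_band_noise(n, FS, 1.0, 3.0, rng) for _ in range(3)]
        )
        motion += amp_d * envelope * proc

    # Postural sway (absent at rest so a fully asymptomatic, noise-free
    # rest recording is constant).
    if SWAY_AMP[exercise] > 0:
        sway = _smooth_band_noise(n, FS, 0.1, 0.8, rng)
        motion += SWAY_AMP[exercise] * np.outer(_unit_vector(rng), sway)

    # Stiffness shrinks overall motion variance.
    motion *= 1.0 - STIFFNESS_SHRINK * labels.stiffness

    if sensor == "gyroscope" and exercise != 3:
        # rad/s scale for involuntary components; the voluntary pronation
        # amplitude in exercise 3 is already expressed in rad/s.
        motion *= GYRO_SCALE

    R = _small_rotation(rng, MAX_AXIS_ROTATION_DEG)
    frame = R @ motion
    if sensor == "accelerometer":
        frame = frame + GRAVITY * (R @ np.array([0.0, 0.0, 1.0]))[:, None]
    noise_scale = config.noise_sd * (GYRO_SCALE if sensor == "gyroscope" else 1.0)
    if noise_scale > 0:
        frame = frame + rng.normal(0.0, noise_scale, size=frame.shape)

    return SensorRecording(
        device=device,
        sensor=sensor,
        hand=hand,
        exercise=exercise,
        x=frame[0],
        y=frame[1],
        z=frame[2],
    )


def _n_exams(config: SyntheticConfig, rng: np.random.Generator) -> int:
    mean = config.exams_mean - 1.0
    var = config.exams_sd**2
    if var > mean > 0:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        return 1 + int(rng.negative_binomial(r, p))
    return 1 + int(rng.poisson(max(mean, 0.0)))


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate the full labeled cohort, reproducible from ``config.seed``."""
    config.validate()
    patients = [generate_patient(config, i) for i in range(config.n_patients)]
    exams = []
    for i, profile in enumerate(patients):
        rng_p = _rng(config.seed, 13, i)
        for e in range(_n_exams(config, rng_p)):
            rng_e = _rng(config.seed, 17, i, e)
            labels = _sample_labels(profile, config, rng_e)
            exam_state = {
                "dyskinesia_expression": rng_e.lognormal(mean=-0.32, sigma=0.8)
            }
            age = profile.age_at_baseline + 0.5 * e
            recordings = {}
            for di, device in enumerate(config.devices):
                for si, sensor in enumerate(config.sensors):
                    for hi, hand in enumerate(config.hands):
                        for ex in config.exercises:
                            rng_b = _rng(config.seed, 19, i, e, di, si, hi, ex)
                            if rng_b.random() < config.missing_block_probability:
                                continue
                            rec = simulate_exercise_signal(
                                profile, labels, device, sensor, hand, ex,
                                rng_b, config, exam_state,
                            )
                            recordings[rec.block_key] = rec
            exams.append(
                Examination(
                    exam_id=f"{profile.patient_id}-E{e:02d}",
                    patient_id=profile.patient_id,
                    exam_index=e,
                    age_at_exam=age,
                    labels=labels,
                    recordings=recordings,
                )
            )
    return Cohort(config=config, patients=patients, examinations=exams)


# ---------------------------------------------------------------------------
# serialization: CSV per recording, JSON manifest, YAML config


def _block_name(key: tuple) -> str:
    device, sensor, hand, exercise = key
    return f"{device}_{sensor}_{hand}_{exercise}"


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as patient/exam/device_sensor_hand_exercise.csv plus
    a JSON manifest (profiles, labels) and the YAML config."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    cfg = asdict(cohort.config)
    cfg["severity_weights"] = {
        k: list(v) for k, v in cfg["severity_weights"].items()
    }
    for key in ("tremor_band", "devices", "sensors", "hands", "exercises"):
        cfg[key] = list(cfg[key])
    (root / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    manifest = {"patients": [], "examinations": []}
    for p in cohort.patients:
        manifest["patients"].append(asdict(p))
    for exam in cohort.examinations:
        exam_dir = root / exam.patient_id / exam.exam_id
        exam_dir.mkdir(parents=True, exist_ok=True)
        for key in sorted(exam.recordings):
            rec = exam.recordings[key]
            tcol = np.arange(rec.x.size) / rec.sampling_rate
            lines = ["t,x,y,z"]
            for ti, xi, yi, zi in zip(tcol, rec.x, rec.y, rec.z):
                lines.append(f"{ti:.2f},{xi:.6f},{yi:.6f},{zi:.6f}")
            (exam_dir / f"{_block_name(key)}.csv").write_text(
                "\n".join(lines) + "\n"
            )
        manifest["examinations"].append(
            {
                "exam_id": exam.exam_id,
                "patient_id": exam.patient_id,
                "exam_index": exam.exam_index,
                "age_at_exam": exam.age_at_exam,
                "labels": asdict(exam.labels),
                "blocks": [_block_name(k) for k in sorted(exam.recordings)],
            }
        )
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )


def load_cohort(path: str | Path) -> Cohort:
    root = Path(path)
    cfg = yaml.safe_load((root / "config.yaml").read_text())
    cfg["severity_weights"] = {
        k: tuple(v) for k, v in cfg["severity_weights"].items()
    }
    for key in ("tremor_band", "devices", "sensors", "hands"):
        cfg[key] = tuple(cfg[key])
    cfg["exercises"] = tuple(int(v) for v in cfg["exercises"])
    config = SyntheticConfig(**cfg)
    manifest = json.loads((root / "manifest.json").read_text())
    patients = [PatientProfile(**p) for p in manifest["patients"]]
    exams = []
    for entry in manifest["examinations"]:
        recordings = {}
        exam_dir = root / entry["patient_id"] / entry["exam_id"]
        for block in entry["blocks"]:
            device, sensor, hand, exercise = block.rsplit("_", 3)
            data = np.loadtxt(
                exam_dir / f"{block}.csv", delimiter=",", skiprows=1
            )
            recordings[(device, sensor, hand, int(exercise))] = SensorRecording(
                device=device,
                sensor=sensor,
                hand=hand,
                exercise=int(exercise),
                x=data[:, 1],
                y=data[:, 2],
                z=data[:, 3],
            )
        exams.append(
            Examination(
                exam_id=entry["exam_id"],
                patient_id=entry["patient_id"],
                exam_index=entry["exam_index"],
                age_at_exam=entry["age_at_exam"],
                labels=SeverityLabels(**entry["labels"]),
                recordings=recordings,
            )
        )
    return Cohort(config=config, patients=patients, examinations=exams)
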