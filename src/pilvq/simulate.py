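"""Synthetic two-class cohort generator (cognitive scores + ROI time series).

The generator emulates a small clinical cohort of MCI patients and healthy
controls in which

* every subject has four cognitive scores — working memory (``n_dots``,
  dots), inhibition (``t_delay``, ms), divided attention (``t_disp_d``, ms)
  and selective attention (``t_disp_s``, ms) — drawn from class-conditional
  multivariate Gaussians with a shared within-class covariance,
* a subset of subjects additionally has block-design BOLD time series for
  three ROIs in two sessions (pre/post behavioural training), with
  class/session-dependent activation offsets (driving PSC differences) and
  planted cluster-level connectivity structure (driving graph-feature
  differences).

Default effect structure mirrors the qualitative findings the package is
designed to detect: divided attention is the most discriminative cognitive
score (patients slower), patients show a post-training activation increase
in the frontal ROI, and frontal inter-cluster connectivity differs between
groups before training and less so afterwards.

All randomness flows from a single integer seed through named substreams,
so cohorts are bit-reproducible and subjects can be generated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import ROITimeSeries

__all__ = [
    "ROISpec",
    "PlantedEdge",
    "SimulationConfig",
    "CognitiveProfile",
    "SyntheticCohort",
    "simulate_cognitive",
    "simulate_roi_session",
    "simulate_cohort",
    "default_config",
    "null_config",
    "COGNITIVE_FEATURES",
    "PATIENT",
    "CONTROL",
    "SESSIONS",
]

COGNITIVE_FEATURES = ("n_dots", "t_delay", "t_disp_d", "t_disp_s")
PATIENT = "patient"
CONTROL = "control"
SESSIONS = ("pre", "post")


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ROISpec:
    name: str
    n_voxels: int
    n_kernels: int


@dataclass(frozen=True)
class PlantedEdge:
    """Latent correlation between two voxel clusters of one ROI.

    ``strength`` maps (class, session) to a correlation in (-1, 1);
    missing keys mean zero.
    """

    roi: str
    cluster_a: int
    cluster_b: int
    strength: Mapping[tuple[str, str], float]


@dataclass
class SimulationConfig:
    n_patients: int = 13
    n_controls: int = 47
    n_with_imaging: int = 34
    # imaging patients fixed at 9 by default (13/47/34 cohort); None = proportional
    n_imaging_patients: int | None = 9
    # class means differ primarily along divided attention (t_disp_d, +1.5
    # within-class SD for patients); the secondary shifts keep the clinical
    # sign structure (patients: fewer dots held, shorter tolerated stop
    # delay, slightly longer selective-attention display time)
    cognitive_class_means: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            CONTROL: (6.0, 260.0, 90.0, 85.0),
            PATIENT: (5.6, 250.0, 138.0, 90.0),
        }
    )
    cognitive_covariance: np.ndarray | None = None
    roi_specs: Sequence[ROISpec] = field(
        default_factory=lambda: (
            ROISpec("cerebellar", 82, 4),
            ROISpec("frontal", 126, 8),
            ROISpec("subcortical", 32, 3),
        )
    )
    n_volumes_structured: int = 30
    n_volumes_random: int = 30
    # raw activation offset added to structured volumes, per (class, session, roi)
    psc_effect: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: {
            (PATIENT, "post", "frontal"): 6.0,
            (PATIENT, "post", "cerebellar"): 3.0,
        }
    )
    planted_edges: Sequence[PlantedEdge] = field(
        default_factory=lambda: (
            PlantedEdge(
                "frontal",
                0,
                1,
                {
                    (PATIENT, "pre"): 0.7,
                    (CONTROL, "pre"): 0.1,
                    (PATIENT, "post"): 0.45,
                    (CONTROL, "post"): 0.35,
                },
            ),
        )
    )
    baseline: float = 100.0
    cluster_signal_sd: float = 1.0
    noise_sd: float = 1.0
    blob_scatter_mm: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cognitive_covariance is None:
            sd = np.array([1.2, 35.0, 32.0, 30.0])
            R = np.eye(4)
            R[0, 1] = R[1, 0] = 0.3  # memory ~ inhibition
            R[2, 3] = R[3, 2] = 0.2  # the two attention measures
            self.cognitive_covariance = (sd[:, None] * R) * sd[None, :]
        self.cognitive_covariance = np.asarray(self.cognitive_covariance, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise InvalidConfigError("negative class counts")
        if self.n_with_imaging > self.n_patients + self.n_controls:
            raise InvalidConfigError(
                "n_with_imaging exceeds cohort size "
                f"({self.n_with_imaging} > {self.n_patients + self.n_controls})"
            )
        C = self.cognitive_covariance
        if C.shape != (4, 4) or not np.allclose(C, C.T):
            raise InvalidConfigError("cognitive_covariance must be symmetric 4x4")
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise InvalidConfigError("cognitive_covariance is not SPD") from exc
        for spec in self.roi_specs:
            if spec.n_kernels >= spec.n_voxels:
                raise InvalidConfigError(
                    f"ROI {spec.name}: K={spec.n_kernels} must be < V={spec.n_voxels}"
                )
        roi_names = {s.name for s in self.roi_specs}
        for e in self.planted_edges:
            if e.roi not in roi_names:
                raise InvalidConfigError(f"planted edge on unknown ROI {e.roi!r}")
            for rho in e.strength.values():
                if not -1.0 < rho < 1.0:
                    raise InvalidConfigError(
                        f"planted correlation {rho} outside (-1, 1)"
                    )
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")

    def roi_spec(self, name: str) -> ROISpec:
        for spec in self.roi_specs:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown ROI {name!r}")


@dataclass
class CognitiveProfile:
    subject_id: str
    group: str  # "patient" / "control"
    scores: np.ndarray  # (n_dots, t_delay, t_disp_d, t_disp_s)
    has_imaging: bool = False


@dataclass
class SyntheticCohort:
    profiles: list[CognitiveProfile]
    # subject_id -> (roi, session) -> ROITimeSeries
    imaging: dict[str, dict[tuple[str, str], ROITimeSeries]]
    truth: dict

    def cognitive_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": p.subject_id,
                "group": p.group,
                **dict(zip(COGNITIVE_FEATURES, p.scores)),
                "has_imaging": p.has_imaging,
            }
            for p in self.profiles
        ]
        return pd.DataFrame(rows).set_index("subject_id")

    def cognitive_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([p.scores for p in self.profiles])
        y = np.array([p.group for p in self.profiles])
        return X, y


# ---------------------------------------------------------------------------
# substream helpers: one master seed, named derived streams
# ---------------------------------------------------------------------------

_STREAM_CODES = {"cognitive": 1, "coords": 2, "series": 3, "assign": 4}


def _rng(config_seed: int, stream: str, *keys: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(config_seed), _STREAM_CODES[stream], *[int(k) for k in keys]]
    )


def _roi_code(config: SimulationConfig, roi_name: str) -> int:
    for i, spec in enumerate(config.roi_specs):
        if spec.name == roi_name:
            return i
    raise KeyError(f"unknown ROI {roi_name!r}")


# ---------------------------------------------------------------------------
# cognitive scores
# ---------------------------------------------------------------------------

def simulate_cognitive(config: SimulationConfig) -> list[CognitiveProfile]:
    """Draw class-conditional Gaussian cognitive profiles.

    Patients first (ids p01..), then controls (c01..); deterministic for a
    given config seed.
    """
    config.validate()
    rng = _rng(config.seed, "cognitive")
    chol = np.linalg.cholesky(config.cognitive_covariance)
    profiles: list[CognitiveProfile] = []
    for group, n, prefix in (
        (PATIENT, config.n_patients, "p"),
        (CONTROL, config.n_controls, "c"),
    ):
        mean = np.asarray(config.cognitive_class_means[group], dtype=float)
        z = rng.standard_normal((n, 4))
        scores = mean + z @ chol.T
        for i in range(n):
            profiles.append(
                CognitiveProfile(f"{prefix}{i + 1:02d}", group, scores[i])
            )
    return profiles


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def _roi_coords(config: SimulationConfig, roi_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Voxel positions as K Gaussian blobs; fixed per (config.seed, ROI).

    Returns (coords, blob_labels). For an 8-kernel ROI the blob centres are
    split across the two hemispheres (sign of x).
    """
    spec = config.roi_spec(roi_name)
    rng = _rng(config.seed, "coords", _roi_code(config, roi_name))
    K, V = spec.n_kernels, spec.n_voxels
    if K % 2 == 0 and K >= 8:
        # bilateral ROI: half the blobs per hemisphere
        half = K // 2
        centres = []
        for sign in (-1.0, 1.0):
            for j in range(half):
                centres.append(
                    [sign * (15.0 + 8.0 * (j % 2)), 10.0 * (j // 2), 8.0 * (j % 3)]
                )
        centres = np.array(centres)
    else:
        grid = []
        for j in range(K):
            grid.append([12.0 * (j % 2), 12.0 * ((j // 2) % 2), 12.0 * (j // 4)])
        centres = np.array(grid)
    sizes = np.full(K, V // K)
    sizes[: V % K] += 1
    labels = np.repeat(np.arange(K), sizes)
    coords = centres[labels] + rng.normal(0.0, config.blob_scatter_mm, (V, 3))
    return coords, labels


def _cluster_cov(config: SimulationConfig, roi_name: str, subject_class: str,
                 session: str, K: int) -> np.ndarray:
    C = np.eye(K)
    for e in config.planted_edges:
        if e.roi != roi_name:
            continue
        rho = e.strength.get((subject_class, session), 0.0)
        C[e.cluster_a, e.cluster_b] = rho
        C[e.cluster_b, e.cluster_a] = rho
    return C


def _volume_labels(n_s: int, n_r: int, block: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Interleave structured/random volumes in alternating blocks."""
    labels = []
    remaining = {"s": n_s, "r": n_r}
    turn = "s"
    while remaining["s"] or remaining["r"]:
        take = min(block, remaining[turn])
        labels.extend([turn] * take)
        remaining[turn] -= take
        turn = "r" if turn == "s" else "s"
    labels = np.array(labels)
    return np.flatnonzero(labels == "s"), np.flatnonzero(labels == "r")


def simulate_roi_session(
    config: SimulationConfig,
    subject_class: str,
    roi_name: str,
    session: str,
    seed: int,
    subject_id: str = "",
) -> ROITimeSeries:
    """One subject's BOLD matrix for one ROI and session.

    The series is baseline + condition-dependent activation offset (the
    configured PSC effect, applied to structured volumes) + latent cluster
    signals with the planted inter-cluster correlations + white noise.
    """
    if subject_class not in (PATIENT, CONTROL):
        raise ValueError(f"unknown class {subject_class!r}")
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}; expected one of {SESSIONS}")
    spec = config.roi_spec(roi_name)
    coords, blob = _roi_coords(config, roi_name)
    n_s, n_r = config.n_volumes_structured, config.n_volumes_random
    T = n_s + n_r
    s_idx, r_idx = _volume_labels(n_s, n_r)

    rng = _rng(config.seed, "series", seed, _roi_code(config, roi_name),
               SESSIONS.index(session))
    C = _cluster_cov(config, roi_name, subject_class, session, spec.n_kernels)
    # latent cluster signals with the planted correlation structure
    jitter = 1e-9 * np.eye(spec.n_kernels)
    L = np.linalg.cholesky(C + jitter)
    z = rng.standard_normal((spec.n_kernels, T))
    latents = config.cluster_signal_sd * (L @ z)

    offset = config.psc_effect.get((subject_class, session, roi_name), 0.0)
    Y = np.full((spec.n_voxels, T), config.baseline)
    Y[:, s_idx] += offset
    Y += latents[blob]
    Y += rng.normal(0.0, config.noise_sd, (spec.n_voxels, T))
    return ROITimeSeries(
        Y=Y,
        coords=coords,
        structured_idx=s_idx,
        random_idx=r_idx,
        roi_name=roi_name,
        session=session,
        subject_id=subject_id,
    )


def _imaging_assignment(config: SimulationConfig) -> tuple[int, int]:
    """Number of (patients, controls) receiving imaging."""
    n_img = config.n_with_imaging
    if config.n_imaging_patients is not None:
        n_p = min(config.n_imaging_patients, config.n_patients, n_img)
    else:
        total = config.n_patients + config.n_controls
        n_p = int(round(n_img * config.n_patients / total)) if total else 0
        n_p = min(n_p, config.n_patients)
    n_c = min(n_img - n_p, config.n_controls)
    if n_p + n_c != n_img:
        raise InvalidConfigError(
            f"cannot place {n_img} imaging subjects with classes "
            f"{config.n_patients}/{config.n_controls}"
        )
    return n_p, n_c


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: cognitive profiles plus imaging for a subset.

    Imaging is assigned to the first ``n_imaging_patients`` patients and
    enough leading controls to reach ``n_with_imaging`` (the generator
    orders subjects randomly within class, so this is a random subset).
    The ``truth`` record stores every planted effect for recovery scoring.
    """
    profiles = simulate_cognitive(config)
    n_img_p, n_img_c = _imaging_assignment(config)
    patients = [p for p in profiles if p.group == PATIENT]
    controls = [p for p in profiles if p.group == CONTROL]
    for p in patients[:n_img_p]:
        p.has_imaging = True
    for p in controls[:n_img_c]:
        p.has_imaging = True

    imaging: dict[str, dict[tuple[str, str], ROITimeSeries]] = {}
    for subj_i, p in enumerate(profiles):
        if not p.has_imaging:
            continue
        entry: dict[tuple[str, str], ROITimeSeries] = {}
        for spec in config.roi_specs:
            for session in SESSIONS:
                entry[(spec.name, session)] = simulate_roi_session(
                    config, p.group, spec.name, session, seed=subj_i,
                    subject_id=p.subject_id,
                )
        imaging[p.subject_id] = entry

    means = {g: np.asarray(m, float) for g, m in config.cognitive_class_means.items()}
    diff = np.abs(means[PATIENT] - means[CONTROL])
    sds = np.sqrt(np.diag(config.cognitive_covariance))
    standardized = np.divide(diff, sds, out=np.zeros_like(diff), where=sds > 0)
    truth = {
        "informative_cognitive_feature": (
            COGNITIVE_FEATURES[int(np.argmax(standardized))]
            if standardized.max() > 0
            else None
        ),
        "cognitive_standardized_separation": dict(
            zip(COGNITIVE_FEATURES, standardized)
        ),
        "psc_effect": dict(config.psc_effect),
        "planted_edges": list(config.planted_edges),
        "blob_labels": {
            spec.name: _roi_coords(config, spec.name)[1]
            for spec in config.roi_specs
        },
    }
    return SyntheticCohort(profiles=profiles, imaging=imaging, truth=truth)


def default_config(**overrides) -> SimulationConfig:
    """The standard study-sized cohort (13 patients / 47 controls / 34 imaged)."""
    return SimulationConfig(**overrides)


def null_config(**overrides) -> SimulationConfig:
    """A cohort with no class signal anywhere (calibration / type-I checks)."""
    base = dict(
        cognitive_class_means={
            CONTROL: (6.0, 260.0, 90.0, 85.0),
            PATIENT: (6.0, 260.0, 90.0, 85.0),
        },
        psc_effect={},
        planted_edges=(),
    )
    base.update(overrides)
    return SimulationConfig(**base)
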