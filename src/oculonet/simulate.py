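"""Synthetic cohort generator.

Stands in for the unavailable raw recordings of the study design this
package analyses: two groups (93 patients, 41 controls), an 80-trial
anti-saccade task (40 left / 40 right at 15 degrees eccentricity), an
80-trial Go/NoGo task (40 Go + 40 NoGo over 8 diamond locations, 10 each),
trial latencies from shifted-lognormal distributions, and a 12-measure
subject profile (6 cognitive sub-tests + 6 oculomotor summaries) whose
correlation structure is calibrated to the published patient tables.

The measure-level generator is a Gaussian copula (NORTA): each measure has
a marginal distribution (normal for scores and latency medians,
logit-normal for proportions) and the latent normal correlation of every
pair is solved numerically so that the *output* Pearson correlation hits
its target — the standard Pearson-matching NORTA construction.  Gaze
traces embed saccades as raised-cosine displacements obeying a
main-sequence duration law, plus white fixation noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import datasets
from .events import GazeRecording
from .measures import ALL_MEASURES

__all__ = [
    "TrialSpec",
    "TrialOutcome",
    "LatencyParams",
    "NormalMargin",
    "LogitNormalMargin",
    "SimulationConfig",
    "SimulatedCohort",
    "GNG_LOCATIONS",
    "GROUP_DEFAULTS",
    "nearest_correlation",
    "generate_task_design",
    "generate_cognitive_scores",
    "generate_trial_outcomes",
    "generate_gaze_trace",
    "default_margins",
    "matched_latent_correlation",
    "simulate_measures",
    "simulate_cohort",
    "saccade_duration_ms",
]

AS_ECCENTRICITY_DEG = 15.0
#: 8 stimulus positions in a diamond formation: 4 vertices at 15 degrees on
#: the axes plus the 4 edge midpoints.
GNG_LOCATIONS: tuple[tuple[float, float], ...] = (
    (15.0, 0.0),
    (7.5, 7.5),
    (0.0, 15.0),
    (-7.5, 7.5),
    (-15.0, 0.0),
    (-7.5, -7.5),
    (0.0, -15.0),
    (7.5, -7.5),
)

_Q75 = 0.6744897501960817  # standard normal upper quartile


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialSpec:
    """Design of one trial: task, cue condition, stimulus position, timing.

    The trial clock starts at fixation onset; the peripheral stimulus (PS)
    appears at ``ps_onset_ms`` (the end of the fixation interval).
    """

    task: Literal["AS", "GnG"]
    condition: Literal["none", "Go", "NoGo"]
    ps_x_deg: float
    ps_y_deg: float
    fp_duration_ms: float
    intertrial_ms: float
    location_index: int | None = None

    def __post_init__(self) -> None:
        if self.task not in ("AS", "GnG"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "AS":
            if self.condition != "none":
                raise ValueError("AS trials carry no cue condition")
            if not math.isclose(abs(self.ps_x_deg), AS_ECCENTRICITY_DEG):
                raise ValueError("AS eccentricity must be 15 degrees")
        else:
            if self.condition not in ("Go", "NoGo"):
                raise ValueError("GnG trials need a Go or NoGo condition")
            if self.location_index is None or not 0 <= self.location_index <= 7:
                raise ValueError("GnG location index must be in 0..7")
        if not 2000.0 <= self.fp_duration_ms <= 4000.0:
            raise ValueError("fp_duration_ms must lie in [2000, 4000]")
        if not 2000.0 <= self.intertrial_ms <= 3000.0:
            raise ValueError("intertrial_ms must lie in [2000, 3000]")

    @property
    def ps_onset_ms(self) -> float:
        return self.fp_duration_ms

    @property
    def ps_amplitude_deg(self) -> float:
        return math.hypot(self.ps_x_deg, self.ps_y_deg)


def generate_task_design(task: str, seed) -> list[TrialSpec]:
    """Pseudorandom 80-trial design for one task.

    AS: each horizontal side (±15 degrees) used 40 times.  GnG: 40 Go and
    40 NoGo cues, each of the 8 diamond locations used 10 times (5 per
    cue colour).  Fixation intervals are uniform on [2000, 4000] ms and
    intertrial gaps uniform on [2000, 3000] ms.
    """
    rng = _rng(seed)
    if task == "AS":
        cells = [(side, "none") for side in (-1.0, 1.0) for _ in range(40)]
    elif task == "GnG":
        cells = [
            (loc, cond)
            for loc in range(8)
            for cond in ("Go", "NoGo")
            for _ in range(5)
        ]
    else:
        raise ValueError(f"unknown task {task!r}")
    order = rng.permutation(len(cells))
    fp = rng.uniform(2000.0, 4000.0, size=len(cells))
    iti = rng.uniform(2000.0, 3000.0, size=len(cells))
    trials = []
    for k, idx in enumerate(order):
        cell, cond = cells[idx]
        if task == "AS":
            x, y, loc = cell * AS_ECCENTRICITY_DEG, 0.0, None
        else:
            x, y = GNG_LOCATIONS[int(cell)]
            loc = int(cell)
        trials.append(
            TrialSpec(
                task=task,  # type: ignore[arg-type]
                condition=cond,  # type: ignore[arg-type]
                ps_x_deg=x,
                ps_y_deg=y,
                fp_duration_ms=float(fp[k]),
                intertrial_ms=float(iti[k]),
                location_index=loc,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# latency and outcome models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatencyParams:
    """Shifted lognormal latency distribution given by its mean and SD (ms).

    ``shift_ms`` is the physiological floor; mean and SD refer to the whole
    shifted distribution.
    """

    mean_ms: float
    sd_ms: float
    shift_ms: float = 80.0

    def __post_init__(self) -> None:
        if self.sd_ms < 0:
            raise ValueError("sd_ms must be non-negative")
        if self.mean_ms <= self.shift_ms:
            raise ValueError("mean_ms must exceed shift_ms")

    def _mu_sigma(self) -> tuple[float, float]:
        m = self.mean_ms - self.shift_ms
        if self.sd_ms == 0:
            return math.log(m), 0.0
        cv2 = (self.sd_ms / m) ** 2
        sigma2 = math.log1p(cv2)
        return math.log(m) - sigma2 / 2, math.sqrt(sigma2)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        mu, sigma = self._mu_sigma()
        return self.shift_ms + rng.lognormal(mu, sigma, size=n)


@dataclass(frozen=True)
class TrialOutcome:
    """Ground-truth outcome of one trial."""

    label: Literal["correct", "error", "miss"]
    latency_ms: float | None

    def __post_init__(self) -> None:
        if self.label not in ("correct", "error", "miss"):
            raise ValueError(f"unknown outcome label {self.label!r}")


def generate_trial_outcomes(
    design: Sequence[TrialSpec],
    subject_accuracy: float,
    latency_params: LatencyParams,
    seed,
    error_latency_params: LatencyParams | None = None,
    miss_prob: float = 0.02,
) -> list[TrialOutcome]:
    """Per-trial outcome labels and latencies for one subject.

    Each trial is correct with probability ``subject_accuracy`` and
    otherwise an error; trials whose correct response is a saccade (AS and
    Go) can additionally be missed with probability ``miss_prob``.  Correct
    saccades draw latency from ``latency_params``; erroneous saccades from
    ``error_latency_params``, which defaults to the same distribution with
    the mean scaled by 0.7 (reflexive errors are faster than instructed
    responses).  Outcomes without a saccade (misses, correct NoGo
    withholds, Go errors) carry no latency.
    """
    if not 0.0 <= subject_accuracy <= 1.0:
        raise ValueError("subject_accuracy must lie in [0, 1]")
    if not 0.0 <= miss_prob <= 1.0:
        raise ValueError("miss_prob must lie in [0, 1]")
    rng = _rng(seed)
    if error_latency_params is None:
        err_mean = max(
            0.7 * latency_params.mean_ms, latency_params.shift_ms + 20.0
        )
        error_latency_params = replace(latency_params, mean_ms=err_mean)
    out: list[TrialOutcome] = []
    for trial in design:
        saccade_expected = trial.condition != "NoGo"
        if saccade_expected and rng.uniform() < miss_prob:
            out.append(TrialOutcome("miss", None))
            continue
        correct = rng.uniform() < subject_accuracy
        if correct:
            lat = float(latency_params.sample(rng)[0]) if saccade_expected else None
            out.append(TrialOutcome("correct", lat))
        else:
            # error saccade: reflexive prosaccade (AS) or NoGo break; a Go
            # error is a failure to move and carries no latency
            has_saccade = trial.condition != "Go"
            lat = float(error_latency_params.sample(rng)[0]) if has_saccade else None
            out.append(TrialOutcome("error", lat))
    return out


# ---------------------------------------------------------------------------
# gaze trace synthesis
# ---------------------------------------------------------------------------


def expected_classification(
    trial: TrialSpec,
    outcome: TrialOutcome,
    latency_window_ms: tuple[float, float] = (80.0, 900.0),
) -> str:
    """Classification a correct scorer should assign to an embedded outcome.

    A Go-condition error is a failure to move, which a scorer observing the
    gaze can only report as a miss (it still counts against accuracy); a
    saccade whose embedded latency falls outside the filter window must be
    discarded regardless of its direction.
    """
    if outcome.label == "miss":
        return "miss"
    if trial.condition == "Go" and outcome.label == "error":
        return "miss"
    if outcome.latency_ms is not None:
        lo, hi = latency_window_ms
        if not lo <= outcome.latency_ms <= hi:
            return "discarded"
    return outcome.label


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence duration approximation: 2.2 ms/deg + 21 ms intercept."""
    return 2.2 * amplitude_deg + 21.0


def _saccade_target(trial: TrialSpec, outcome: TrialOutcome) -> tuple[float, float] | None:
    """End position of the outcome's saccade, or None for maintained fixation."""
    if outcome.label == "miss":
        return None
    if trial.task == "AS":
        if outcome.label == "correct":
            return (-trial.ps_x_deg, -trial.ps_y_deg)  # mirror position
        return (trial.ps_x_deg, trial.ps_y_deg)  # reflexive error
    if trial.condition == "Go":
        return (trial.ps_x_deg, trial.ps_y_deg) if outcome.label == "correct" else None
    # NoGo: correct = hold fixation, error = reflexive saccade to the PS
    return None if outcome.label == "correct" else (trial.ps_x_deg, trial.ps_y_deg)


def generate_gaze_trace(
    trial: TrialSpec,
    outcome: TrialOutcome,
    seed,
    sampling_rate: float = 250.0,
    noise_sd: float = 0.15,
    subject_id: str = "s0",
    trial_id: str = "t0",
    hold_ms: float = 600.0,
) -> GazeRecording:
    """Synthesize a gaze-sample stream embedding the given outcome.

    The eye rests at the fixation point (screen centre) with isotropic
    white positional noise of SD ``noise_sd`` degrees.  If the outcome
    includes a saccade, the displacement follows a raised-cosine profile of
    the commanded amplitude starting at ``ps_onset + latency`` with the
    main-sequence duration; the trace then holds the endpoint for
    ``hold_ms``.  No-saccade outcomes hold fixation for a 1000 ms response
    window after PS onset.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed)
    target = _saccade_target(trial, outcome)
    if target is not None and outcome.latency_ms is None:
        raise ValueError("outcome implies a saccade but carries no latency")
    dt = 1000.0 / sampling_rate
    if target is None:
        total = trial.ps_onset_ms + 1000.0
    else:
        amp = math.hypot(*target)
        total = trial.ps_onset_ms + outcome.latency_ms + saccade_duration_ms(amp) + hold_ms
    t = np.arange(0.0, total, dt)
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    if target is not None:
        onset = trial.ps_onset_ms + outcome.latency_ms
        dur = saccade_duration_ms(math.hypot(*target))
        u = np.clip((t - onset) / dur, 0.0, 1.0)
        profile = 0.5 * (1.0 - np.cos(math.pi * u))  # raised-cosine smooth step
        x = target[0] * profile
        y = target[1] * profile
    x = x + rng.normal(0.0, noise_sd, size=t.size)
    y = y + rng.normal(0.0, noise_sd, size=t.size)
    return GazeRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        sampling_rate=sampling_rate,
        t_ms=t,
        x_deg=x,
        y_deg=y,
    )


# ---------------------------------------------------------------------------
# measure-level cohort model (Gaussian copula with Pearson matching)
# ---------------------------------------------------------------------------


def nearest_correlation(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``floor`` and the result renormalized to a
    unit diagonal — the deterministic nearest-correlation practice for
    mildly indefinite target matrices.
    """
    c = np.asarray(corr, dtype=float)
    if not np.allclose(c, c.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh(c)
    if w.min() >= floor:
        return c
    w = np.clip(w, floor, None)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    return c2 / np.outer(d, d)


def generate_cognitive_scores(
    n: int,
    means: Sequence[float],
    sds: Sequence[float],
    corr: np.ndarray,
    seed,
) -> np.ndarray:
    """Draw ``n`` six-test cognitive profiles from a multivariate normal.

    ``corr`` is repaired to the nearest correlation matrix if needed;
    impossible negative scores are clipped at 0.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != (6,) or sds.shape != (6,):
        raise ValueError("means and sds must be 6-vectors")
    if np.any(sds < 0):
        raise ValueError("sds must be non-negative")
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (6, 6):
        raise ValueError("corr must be 6x6")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("corr must have a unit diagonal")
    rng = _rng(seed)
    repaired = nearest_correlation(corr)
    chol = np.linalg.cholesky(repaired)
    z = rng.standard_normal((n, 6))
    scores = means + sds * (z @ chol.T)
    return np.clip(scores, 0.0, None)


@dataclass(frozen=True)
class NormalMargin:
    """Normal marginal; optional clipping applied after the draw.

    Treated as linear for copula Pearson matching (clip bounds, where set,
    are several SDs from the mean and perturb correlations negligibly).
    """

    mean: float
    sd: float
    clip_min: float | None = None
    clip_max: float | None = None

    def transform(self, z: np.ndarray) -> np.ndarray:
        x = self.mean + self.sd * np.asarray(z, dtype=float)
        return np.clip(
            x,
            -np.inf if self.clip_min is None else self.clip_min,
            np.inf if self.clip_max is None else self.clip_max,
        )

    @property
    def linear(self) -> bool:
        return True


@dataclass(frozen=True)
class LogitNormalMargin:
    """Logit-normal marginal for proportions, fit to median and quartiles."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not 0 < self.q1 <= self.median <= self.q3 < 1:
            raise ValueError("need 0 < q1 <= median <= q3 < 1")

    @property
    def mu(self) -> float:
        return float(logit(self.median))

    @property
    def sigma(self) -> float:
        return float(logit(self.q3) - logit(self.q1)) / (2 * _Q75)

    def transform(self, z: np.ndarray) -> np.ndarray:
        return expit(self.mu + self.sigma * np.asarray(z, dtype=float))

    @property
    def linear(self) -> bool:
        return False


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(64)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@lru_cache(maxsize=256)
def _margin_moments(margin) -> tuple[float, float]:
    g = margin.transform(_GH_NODES)
    mu = float(_GH_WEIGHTS @ g)
    var = float(_GH_WEIGHTS @ (g - mu) ** 2)
    return mu, math.sqrt(var)


def _copula_pearson(m1, m2, rho: float) -> float:
    """Output Pearson correlation of (g1(Z1), g2(Z2)) with latent corr rho."""
    mu1, sd1 = _margin_moments(m1)
    mu2, sd2 = _margin_moments(m2)
    z1 = _GH_NODES[:, None]
    z2 = _GH_NODES[None, :]
    g1 = m1.transform(z1)
    g2 = m2.transform(rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * z2)
    w = _GH_WEIGHTS[:, None] * _GH_WEIGHTS[None, :]
    exy = float(np.sum(w * g1 * g2))
    return (exy - mu1 * mu2) / (sd1 * sd2)


def matched_latent_correlation(margins: Sequence, target: np.ndarray) -> np.ndarray:
    """Solve the latent normal correlation matrix of a NORTA generator.

    For every measure pair the latent correlation is chosen so the output
    Pearson correlation equals the target (pairs of linear margins need no
    adjustment).  The assembled matrix is repaired to the nearest valid
    correlation matrix if the pairwise solutions leave it indefinite.
    """
    target = np.asarray(target, dtype=float)
    k = len(margins)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = target[i, j]
            if r == 0 or (margins[i].linear and margins[j].linear):
                latent[i, j] = latent[j, i] = r
                continue
            f = lambda rho: _copula_pearson(margins[i], margins[j], rho) - r
            latent[i, j] = latent[j, i] = brentq(f, -0.9999, 0.9999, xtol=1e-10)
    return nearest_correlation(latent)


# ---------------------------------------------------------------------------
# cohort configuration and top-level simulation
# ---------------------------------------------------------------------------

#: Calibration defaults per group: cognitive sub-test means/SDs, trial-level
#: latency mean/SD per response type (ms), and accuracy quartiles
#: (median, q1, q3) per task measure.  The control Go accuracy quartiles are
#: pulled just inside (0, 1) so a logit fit exists at ceiling performance.
GROUP_DEFAULTS: Mapping[str, Mapping] = {
    "patient": {
        "cognitive_means": (43.5, 18.9, 63.7, 51.4, 49.1, 16.9),
        "cognitive_sds": (11.2, 3.8, 14.4, 13.4, 13.5, 3.8),
        "latency": {
            "AS": (361.0, 139.0),
            "ASE": (241.0, 114.0),
            "Go": (409.0, 156.0),
            "NoGoE": (355.0, 154.0),
        },
        "accuracy": {
            "AS_PA": (0.738, 0.619, 0.888),
            "Go_PA": (0.900, 0.800, 0.975),
            "NoGo_PA": (0.600, 0.475, 0.713),
            "ASE_prop": (0.100, 0.050, 0.263),
        },
    },
    "control": {
        "cognitive_means": (51.1, 22.4, 75.3, 60.2, 64.3, 19.6),
        "cognitive_sds": (6.9, 2.8, 12.0, 12.6, 9.5, 2.4),
        "latency": {
            "AS": (276.0, 87.0),
            "ASE": (228.0, 67.0),
            "Go": (379.0, 136.0),
            "NoGoE": (297.0, 81.0),
        },
        "accuracy": {
            "AS_PA": (0.963, 0.913, 0.988),
            "Go_PA": (0.995, 0.975, 0.999),
            "NoGo_PA": (0.800, 0.725, 0.850),
            "ASE_prop": (0.038, 0.013, 0.075),
        },
    },
}


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    ``between_variance_fraction`` splits each trial-level latency variance
    into a between-subject part (variance of per-subject medians) and a
    within-subject part; the default halves it.  ``target_correlation``
    defaults to the 12x12 matrix assembled from the published tables and
    applies to both groups.
    """

    n_patients: int = 93
    n_controls: int = 41
    seed: int = 0
    sampling_rate: float = 250.0
    noise_sd: float = 0.15
    miss_prob: float = 0.02
    between_variance_fraction: float = 0.5
    group_params: Mapping[str, Mapping] = field(
        default_factory=lambda: GROUP_DEFAULTS
    )
    target_correlation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be at least 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.between_variance_fraction < 1:
            raise ValueError("between_variance_fraction must lie in (0, 1)")
        if self.target_correlation is None:
            self.target_correlation = datasets.target_correlation_matrix()
        tc = self.target_correlation
        if list(tc.index) != list(ALL_MEASURES) or list(tc.columns) != list(
            ALL_MEASURES
        ):
            raise ValueError("target_correlation must be indexed by the 12 measures")
        vals = tc.to_numpy()
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("target_correlation must be symmetric")
        if not np.allclose(np.diag(vals), 1.0):
            raise ValueError("target_correlation must have a unit diagonal")
        if np.any(np.abs(vals) > 1):
            raise ValueError("target_correlation entries must lie in [-1, 1]")

    def between_sd(self, trial_sd: float) -> float:
        return trial_sd * math.sqrt(self.between_variance_fraction)

    def within_sd(self, trial_sd: float) -> float:
        return trial_sd * math.sqrt(1.0 - self.between_variance_fraction)


def default_margins(config: SimulationConfig, group: str) -> list:
    """Marginal distributions of the 12 measures for one group."""
    gp = config.group_params[group]
    lat = gp["latency"]
    acc = gp["accuracy"]
    cognitive = [
        NormalMargin(mean, sd, clip_min=0.0)
        for mean, sd in zip(gp["cognitive_means"], gp["cognitive_sds"])
    ]
    mAS = NormalMargin(lat["AS"][0], config.between_sd(lat["AS"][1]), clip_min=1.0)
    mASE = NormalMargin(lat["ASE"][0], config.between_sd(lat["ASE"][1]), clip_min=1.0)
    mGo = NormalMargin(lat["Go"][0], config.between_sd(lat["Go"][1]), clip_min=1.0)
    mNoGoE = NormalMargin(
        lat["NoGoE"][0], config.between_sd(lat["NoGoE"][1]), clip_min=1.0
    )
    ase = LogitNormalMargin(*acc["ASE_prop"])
    med, q1, q3 = acc["NoGo_PA"]
    gnge = LogitNormalMargin(1 - med, 1 - q3, 1 - q1)
    # measure order: VM DS TMT VF SC TL ASLs ASELs ASEs GnGLs GnGELs GnGEs
    return cognitive + [mAS, mASE, ase, mGo, mNoGoE, gnge]


def simulate_measures(
    n: int, config: SimulationConfig, group: str, seed
) -> pd.DataFrame:
    """Draw ``n`` subject profiles over the 12 network measures.

    Gaussian-copula draw with Pearson-matched latent correlations; columns
    follow the canonical measure order.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = _rng(seed)
    margins = default_margins(config, group)
    latent = matched_latent_correlation(
        margins, config.target_correlation.to_numpy()
    )
    chol = np.linalg.cholesky(latent)
    z = rng.standard_normal((n, len(margins))) @ chol.T
    cols = {
        name: margins[i].transform(z[:, i]) for i, name in enumerate(ALL_MEASURES)
    }
    return pd.DataFrame(cols)


@dataclass
class SimulatedCohort:
    """Measure table plus optional trial-level ground truth."""

    measures: pd.DataFrame  # subject_id, group, 12 measure columns
    designs: dict[str, dict[str, list[TrialSpec]]] | None = None
    outcomes: dict[str, dict[str, list[TrialOutcome]]] | None = None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.measures["subject_id"])


def _subject_trials(
    config: SimulationConfig,
    row: pd.Series,
    go_accuracy: float,
    rng: np.random.Generator,
) -> tuple[dict[str, list[TrialSpec]], dict[str, list[TrialOutcome]]]:
    group = row["group"]
    lat = config.group_params[group]["latency"]

    def lp(mean: float, trial_sd: float) -> LatencyParams:
        mean = max(float(mean), 80.0 + 20.0)
        return LatencyParams(mean_ms=mean, sd_ms=config.within_sd(trial_sd))

    designs: dict[str, list[TrialSpec]] = {}
    outcomes: dict[str, list[TrialOutcome]] = {}

    as_design = generate_task_design("AS", rng)
    as_acc = float(np.clip(1.0 - row["ASEs"], 0.0, 1.0))
    outcomes["AS"] = generate_trial_outcomes(
        as_design,
        as_acc,
        lp(row["ASLs"], lat["AS"][1]),
        rng,
        error_latency_params=lp(row["ASELs"], lat["ASE"][1]),
        miss_prob=config.miss_prob,
    )
    designs["AS"] = as_design

    gng_design = generate_task_design("GnG", rng)
    go_trials = [tr for tr in gng_design if tr.condition == "Go"]
    nogo_trials = [tr for tr in gng_design if tr.condition == "NoGo"]
    go_out = generate_trial_outcomes(
        go_trials,
        float(np.clip(go_accuracy, 0.0, 1.0)),
        lp(row["GnGLs"], lat["Go"][1]),
        rng,
        miss_prob=config.miss_prob,
    )
    nogo_out = generate_trial_outcomes(
        nogo_trials,
        float(np.clip(1.0 - row["GnGEs"], 0.0, 1.0)),
        lp(row["GnGLs"], lat["Go"][1]),
        rng,
        error_latency_params=lp(row["GnGELs"], lat["NoGoE"][1]),
        miss_prob=0.0,
    )
    gi = iter(go_out)
    ni = iter(nogo_out)
    outcomes["GnG"] = [
        next(gi) if tr.condition == "Go" else next(ni) for tr in gng_design
    ]
    designs["GnG"] = gng_design
    return designs, outcomes


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    include_trials: bool = True,
) -> SimulatedCohort:
    """Simulate the full two-group cohort.

    Measures come from the calibrated copula model; when
    ``include_trials`` is set, each subject additionally receives both
    80-trial task designs with ground-truth outcomes parameterized by that
    subject's drawn measures (error rates, median latencies).  Gaze traces
    are produced lazily by :func:`generate_gaze_trace` on demand.
    """
    config = config or SimulationConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    measure_seed, trial_seed = root.spawn(2)
    frames = []
    for group, n in (("patient", config.n_patients), ("control", config.n_controls)):
        sub_rng = np.random.default_rng(measure_seed.spawn(1)[0])
        df = simulate_measures(n, config, group, sub_rng)
        df.insert(0, "group", group)
        frames.append(df)
    measures = pd.concat(frames, ignore_index=True)
    measures.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(measures))])

    if not include_trials:
        return SimulatedCohort(measures=measures)

    designs: dict[str, dict[str, list[TrialSpec]]] = {}
    outcomes: dict[str, dict[str, list[TrialOutcome]]] = {}
    child_seeds = trial_seed.spawn(len(measures))
    for (idx, row), child in zip(measures.iterrows(), child_seeds):
        rng = np.random.default_rng(child)
        acc = config.group_params[row["group"]]["accuracy"]
        go_margin = LogitNormalMargin(*acc["Go_PA"])
        go_acc = float(go_margin.transform(rng.standard_normal()))
        d, o = _subject_trials(config, row, go_acc, rng)
        designs[row["subject_id"]] = d
        outcomes[row["subject_id"]] = o
    return SimulatedCohort(measures=measures, designs=designs, outcomes=outcomes)
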