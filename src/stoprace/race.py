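"""Race-model primitives for the stop-signal task.

Four generating mechanisms for stop-trial behaviour are implemented, all
built from the same accumulator architecture:

* ``independent_race`` — go and stop processes race independently; the go
  process is identical on go and stop trials (context independence).
* ``slowed_go`` — the go drift rate is attenuated at short SSDs, because
  the go stimulus is only displayed for the SSD on stop trials.
* ``guessing`` — the go process on stop trials is a mixture of fast
  guesses (all guesses at SSD 0) and stimulus-driven responses.
* ``confusion`` — both go and stop drift rates are attenuated at short
  SSDs.

Each accumulator is a single-boundary Wiener diffusion: drift ``mu``
(evidence/ms), threshold (evidence units), diffusion coefficient ``sigma``
(evidence/sqrt(ms)).  Its first-passage time is inverse-Gaussian with mean
``threshold/mu`` and shape ``(threshold/sigma)**2``; at zero drift the
first-passage time is the Levy closed form ``(threshold/(sigma*Z))**2``.
Choice errors arise from a competing error accumulator with drift
``error_ratio * mu``; the observed response is the faster of the two plus
a nondecision time.  ``sigma`` is the one free parameter and is calibrated
to a target baseline go accuracy (90% by default).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "DRIFT_SCALE_KNEE_MS",
    "RaceParams",
    "ExGaussParams",
    "GuessMixture",
    "ModelKind",
    "GeneratingModel",
    "drift_from_latency",
    "ssd_drift_scale",
    "fit_exgauss",
    "sample_guess_rt",
    "guess_probability_by_ssd",
    "first_passage_time",
    "race_go_trials",
    "race_stop_trials",
    "simulate_go_trial",
    "simulate_stop_trial",
    "calibrate_noise",
]

#: SSD (ms) above which the drift-attenuation ramp saturates at 1.
DRIFT_SCALE_KNEE_MS = 550.0


@dataclass(frozen=True)
class RaceParams:
    """Accumulator parameters shared by the four generating models.

    ``mu_go``/``mu_stop`` are drifts in evidence units per ms;
    ``error_ratio`` is the drift of the competing error accumulator as a
    fraction of ``mu_go``; responses slower than ``max_rt`` are omissions.
    """

    mu_go: float
    mu_stop: float
    threshold: float = 100.0
    ndt: float = 50.0
    sigma: float = 1.0
    error_ratio: float = 0.5
    max_rt: float = 3000.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.ndt < 0:
            raise ValueError("nondecision time must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.mu_go < 0 or self.mu_stop < 0:
            raise ValueError("drift rates must be >= 0")
        if not 0 <= self.error_ratio < 1:
            raise ValueError("error_ratio must be in [0, 1)")


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian RT distribution parameters (ms): Normal(mu, sigma) + Exp(tau)."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be > 0")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


def _default_p_guess() -> dict[int, float]:
    # Linear ramp: all guesses at SSD 0, none once the go stimulus is shown
    # for >= DRIFT_SCALE_KNEE_MS; mirrors the empirical pattern that choice
    # accuracy on stop failures recovers gradually with SSD.
    return {
        ssd: max(1.0 - ssd / DRIFT_SCALE_KNEE_MS, 0.0) for ssd in range(0, 901, 50)
    }


@dataclass(frozen=True)
class GuessMixture:
    """Guess-mixture specification for the guessing model.

    ``p_guess`` maps SSD (ms) to the probability that a stop-trial go
    finishing time is a guess; intermediate SSDs are linearly
    interpolated.  ``acc_go``/``acc_ssd0`` record the accuracies that the
    mixture was solved from (baseline go accuracy and accuracy at SSD 0).
    """

    acc_go: float = 0.9
    acc_ssd0: float = 0.5
    p_guess: Mapping[int, float] = field(default_factory=_default_p_guess)
    guess_dist: ExGaussParams = ExGaussParams(300.0, 50.0, 150.0)

    def __post_init__(self) -> None:
        if not 0 <= self.acc_go <= 1 or not 0 <= self.acc_ssd0 <= 1:
            raise ValueError("accuracies must be proportions")
        if abs(self.p_guess_at(0.0) - 1.0) > 1e-9:
            raise ValueError("p_guess(0) must be 1 (all guesses at SSD 0)")

    def p_guess_at(self, ssd) -> np.ndarray | float:
        grid = np.array(sorted(self.p_guess), dtype=float)
        vals = np.array([self.p_guess[int(s)] for s in grid], dtype=float)
        return np.clip(np.interp(ssd, grid, vals), 0.0, 1.0)

    @classmethod
    def from_accuracy_curve(
        cls,
        acc_by_ssd: Mapping[int, float],
        acc_go: float,
        guess_dist: ExGaussParams,
    ) -> "GuessMixture":
        """Solve the mixture equation per SSD from an observed accuracy curve."""
        if 0 not in acc_by_ssd:
            raise ValueError("accuracy curve must include SSD 0")
        acc_ssd0 = acc_by_ssd[0]
        p = {
            int(ssd): float(guess_probability_by_ssd(acc, acc_go, acc_ssd0))
            for ssd, acc in acc_by_ssd.items()
        }
        p[0] = 1.0
        return cls(acc_go=acc_go, acc_ssd0=acc_ssd0, p_guess=p, guess_dist=guess_dist)


class ModelKind(str, enum.Enum):
    INDEPENDENT_RACE = "independent_race"
    SLOWED_GO = "slowed_go"
    GUESSING = "guessing"
    CONFUSION = "confusion"


@dataclass(frozen=True)
class GeneratingModel:
    """A generating mechanism: model kind + race parameters (+ mixture)."""

    kind: ModelKind
    race: RaceParams
    mixture: GuessMixture | None = None

    def __post_init__(self) -> None:
        if self.kind is ModelKind.GUESSING and self.mixture is None:
            object.__setattr__(self, "mixture", GuessMixture())


def drift_from_latency(latency_ms, threshold: float = 100.0, ndt_ms: float = 50.0):
    """Convert a mean latency to a drift rate: threshold / (latency - ndt)."""
    latency_ms = np.asarray(latency_ms, dtype=float)
    if np.any(latency_ms <= ndt_ms):
        raise ValueError(f"latency must exceed the nondecision time ({ndt_ms} ms)")
    out = threshold / (latency_ms - ndt_ms)
    return float(out) if out.ndim == 0 else out


def ssd_drift_scale(ssd_ms):
    """Drift attenuation at short SSDs: max(ln(SSD/550)/4 + 1, 0); 1 above 550.

    Zero at SSD 0 (no go stimulus at all) and first positive just above
    10 ms of go-stimulus presentation.
    """
    ssd = np.asarray(ssd_ms, dtype=float)
    if np.any(ssd < 0):
        raise ValueError("ssd must be >= 0")
    with np.errstate(divide="ignore"):
        ramp = np.log(np.where(ssd > 0, ssd, 1.0) / DRIFT_SCALE_KNEE_MS) / 4.0 + 1.0
    scale = np.where(ssd > 0, np.clip(ramp, 0.0, 1.0), 0.0)
    return float(scale) if scale.ndim == 0 else scale


def fit_exgauss(rts) -> ExGaussParams:
    """Maximum-likelihood ex-Gaussian fit with moment-based initialization."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 10:
        raise ValueError("need at least 10 RTs to fit an ex-Gaussian")
    if np.std(rts) == 0:
        raise ValueError("degenerate sample: zero variance")
    m, s = float(np.mean(rts)), float(np.std(rts))
    m3 = float(np.mean((rts - m) ** 3))
    tau0 = max((m3 / 2.0) ** (1.0 / 3.0) if m3 > 0 else s / 2.0, 1e-3)
    sigma0 = math.sqrt(max(s**2 - tau0**2, (0.1 * s) ** 2))
    mu0 = m - tau0
    k0 = tau0 / sigma0
    k, loc, scale = stats.exponnorm.fit(rts, k0, loc=mu0, scale=sigma0)
    if scale <= 0 or k <= 0:
        raise RuntimeError("ex-Gaussian fit failed to converge")
    return ExGaussParams(mu=float(loc), sigma=float(scale), tau=float(k * scale))


def sample_guess_rt(params: ExGaussParams, rng: np.random.Generator, size=None):
    """Ex-Gaussian draws, rejection-resampled until strictly positive."""
    shape = () if size is None else (size if isinstance(size, tuple) else (size,))
    out = params.mu + params.sigma * rng.standard_normal(shape) + rng.exponential(
        params.tau, shape
    )
    out = np.atleast_1d(np.asarray(out, dtype=float))
    bad = out <= 0
    while np.any(bad):
        n = int(bad.sum())
        out[bad] = (
            params.mu
            + params.sigma * rng.standard_normal(n)
            + rng.exponential(params.tau, n)
        )
        bad = out <= 0
    return float(out[0]) if size is None else out.reshape(shape)


def guess_probability_by_ssd(acc_ssd, acc_go: float, acc_ssd0: float):
    """Solve the accuracy mixture equation for P(guess | SSD).

    ``acc_ssd = p*acc_ssd0 + (1-p)*acc_go`` gives
    ``p = (acc_go - acc_ssd) / (acc_go - acc_ssd0)``, clipped to [0, 1].
    """
    if acc_go == acc_ssd0:
        raise ValueError("unidentifiable mixture: acc_go == acc_ssd0")
    p = (acc_go - np.asarray(acc_ssd, dtype=float)) / (acc_go - acc_ssd0)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def first_passage_time(mu, threshold: float, sigma: float, rng: np.random.Generator, size):
    """Single-boundary diffusion first-passage times (ms).

    Inverse-Gaussian for positive drift; the Levy closed form
    ``(threshold/(sigma*Z))**2`` for zero drift.
    """
    shape = size if isinstance(size, tuple) else (size,)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), shape)
    lam = (threshold / sigma) ** 2
    out = np.empty(shape, dtype=float)
    pos = mu > 0
    if np.any(pos):
        out[pos] = rng.wald(threshold / mu[pos], lam)
    if np.any(~pos):
        z = rng.standard_normal(int((~pos).sum()))
        # guard the measure-zero event Z == 0
        z = np.where(z == 0, np.finfo(float).tiny, z)
        out[~pos] = lam / z**2
    return out


def race_go_trials(params: RaceParams, rng: np.random.Generator, size, mu_go=None):
    """Vectorized go trials.

    Returns ``(rt, correct, omission)`` arrays; ``rt`` is the finishing
    time of the faster accumulator plus nondecision time (reported even
    when it exceeds ``max_rt``; ``omission`` marks those trials).
    ``mu_go`` may be an array for per-trial/per-subject drifts.
    """
    shape = size if isinstance(size, tuple) else (size,)
    mu = np.broadcast_to(
        np.asarray(params.mu_go if mu_go is None else mu_go, dtype=float), shape
    )
    t_correct = first_passage_time(mu, params.threshold, params.sigma, rng, shape)
    t_error = first_passage_time(
        params.error_ratio * mu, params.threshold, params.sigma, rng, shape
    )
    rt = params.ndt + np.minimum(t_correct, t_error)
    correct = t_correct <= t_error
    omission = rt > params.max_rt
    return rt, correct, omission


def race_stop_trials(
    kind: ModelKind,
    ssd,
    params: RaceParams,
    rng: np.random.Generator,
    mixture: GuessMixture | None = None,
    mu_go=None,
    mu_stop=None,
    size=None,
):
    """Vectorized stop trials for any generating model.

    ``ssd`` (and optionally the drifts) broadcast to ``size``.  Returns
    ``(responded, rt, correct)``; ``rt`` and ``correct`` are NaN / False
    where the stop process won.  A response occurs iff the go finishing
    time beats both the stop finishing time (``ssd + ndt + stop first
    passage``) and the ``max_rt`` response window.
    """
    ssd = np.asarray(ssd, dtype=float)
    if np.any(ssd < 0):
        raise ValueError("ssd must be >= 0")
    shape = (
        ssd.shape if size is None else (size if isinstance(size, tuple) else (size,))
    )
    ssd = np.broadcast_to(ssd, shape)
    mu_go_arr = np.broadcast_to(
        np.asarray(params.mu_go if mu_go is None else mu_go, dtype=float), shape
    )
    mu_stop_arr = np.broadcast_to(
        np.asarray(params.mu_stop if mu_stop is None else mu_stop, dtype=float), shape
    )

    scale = ssd_drift_scale(ssd)
    if kind in (ModelKind.SLOWED_GO, ModelKind.CONFUSION):
        go_drift = mu_go_arr * scale
    else:
        go_drift = mu_go_arr
    if kind is ModelKind.CONFUSION:
        stop_drift = mu_stop_arr * scale
    else:
        stop_drift = mu_stop_arr

    t_correct = first_passage_time(go_drift, params.threshold, params.sigma, rng, shape)
    t_error = first_passage_time(
        params.error_ratio * go_drift, params.threshold, params.sigma, rng, shape
    )
    go_finish = params.ndt + np.minimum(t_correct, t_error)
    correct = t_correct <= t_error

    if kind is ModelKind.GUESSING:
        if mixture is None:
            raise ValueError("guessing model requires a GuessMixture")
        guess = rng.random(shape) < mixture.p_guess_at(ssd)
        if np.any(guess):
            n = int(guess.sum())
            go_finish = go_finish.copy()
            correct = correct.copy()
            go_finish[guess] = sample_guess_rt(mixture.guess_dist, rng, n)
            correct[guess] = rng.random(n) < 0.5

    stop_finish = ssd + params.ndt + first_passage_time(
        stop_drift, params.threshold, params.sigma, rng, shape
    )
    responded = (go_finish < stop_finish) & (go_finish <= params.max_rt)
    rt = np.where(responded, go_finish, np.nan)
    correct = np.where(responded, correct, False)
    return responded, rt, correct


def simulate_go_trial(model: GeneratingModel | RaceParams, rng: np.random.Generator):
    """One go trial: ``(rt | None, choice_correct)``; ``rt None`` = omission."""
    params = model.race if isinstance(model, GeneratingModel) else model
    rt, correct, omission = race_go_trials(params, rng, 1)
    return (None if omission[0] else float(rt[0])), bool(correct[0])


def simulate_stop_trial(model: GeneratingModel, ssd: float, rng: np.random.Generator):
    """One stop trial: ``(responded, rt | None, choice_correct | None)``."""
    responded, rt, correct = race_stop_trials(
        model.kind, ssd, model.race, rng, mixture=model.mixture, size=1
    )
    if responded[0]:
        return True, float(rt[0]), bool(correct[0])
    return False, None, None


def calibrate_noise(
    mu_go: float,
    error_ratio: float = 0.5,
    target_accuracy: float = 0.90,
    rng: np.random.Generator | None = None,
    n_trials: int = 100_000,
    tol: float = 0.005,
    threshold: float = 100.0,
    ndt: float = 50.0,
    max_rt: float = 3000.0,
    max_iter: int = 40,
) -> float:
    """Bisect the diffusion coefficient to a target overt go accuracy.

    Accuracy is P(correct | overt response), decreasing in ``sigma`` (from
    1 at ``sigma -> 0`` toward chance); targets outside (0.5, 1) are
    unreachable with ``error_ratio < 1``.
    """
    if not 0.5 < target_accuracy < 1.0:
        raise ValueError("target accuracy must be in (0.5, 1)")
    rng = np.random.default_rng(0) if rng is None else rng

    def acc(sigma: float) -> float:
        p = RaceParams(
            mu_go=mu_go, mu_stop=mu_go, threshold=threshold, ndt=ndt,
            sigma=sigma, error_ratio=error_ratio, max_rt=max_rt,
        )
        rt, correct, omission = race_go_trials(p, rng, n_trials)
        overt = ~omission
        if not np.any(overt):
            return 0.5
        return float(np.mean(correct[overt]))

    lo, hi = 1e-2, 1e-2
    if acc(lo) < target_accuracy:
        raise RuntimeError("target accuracy unattainable even at minimal noise")
    while acc(hi) > target_accuracy:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("failed to bracket the target accuracy")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        a = acc(mid)
        if abs(a - target_accuracy) <= tol:
            return mid
        if a > target_accuracy:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)
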