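"""Synthetic cohorts from a three-state donor-availability process.

Each patient starts in state 0 (searching, on chemotherapy).  A fraction
``donor_prob`` has a donor available; for them a latent waiting time
``W <= tau`` to identification (state 1) is drawn from the waiting-time
law.  Event times before identification follow a mixture-cure law
``S(t) = pi + (1 - pi) S_u(t)`` (a cured fraction ``pi`` gives the
survival curve its plateau); times are drawn by inversion.  A patient
who is identified at ``W`` (still event-free there) continues with a
post-identification residual time, either

* ``ContinuationPost`` — the residual is drawn from the conditional
  pre-identification law given survival past ``W`` (a genuine no-effect
  model: the marginal event-time law is unchanged), or
* ``FreshClockPost`` — a fresh mixture-cure draw on the
  time-since-identification clock, optionally with the cure fraction
  rescaled so the long-term plateau matches the no-donor plateau
  (short-term-difference-only shapes).

Uniform censoring on ``(0, c_max)`` is superimposed, and the observables
are assembled exactly as a real cohort would be recorded: identification
requires the patient to be event-free and uncensored at ``W``; otherwise
the search ends by completion at ``tau``, by the (search-ceasing) event,
or by censoring — whichever comes first.

``true_values`` computes the generative truth

    S1(t*) = E_W[ S_pre(W) * S_post(t* - W | W) ],   S0(t*) = S_pre(t*),

with the expectation a finite sum for discrete waiting laws and an
adaptive quadrature for continuous ones, and the cumulative hazard ratio
``cHR = log S1(t*) / log S0(t*)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import integrate

from .survdata import SearchEndReason, StudyConfig, SubjectRecord

__all__ = [
    "MixtureCureLaw",
    "DiscreteWaitingLaw",
    "ExponentialWaitingLaw",
    "ContinuationPost",
    "FreshClockPost",
    "ScenarioSpec",
    "LatentRecord",
    "draw_event_time",
    "simulate_cohort",
    "observed_cohort",
    "true_values",
    "scenario_library",
    "load_scenario",
    "save_scenario",
]


# ---------------------------------------------------------------------------
# event-time laws


@dataclass(frozen=True)
class MixtureCureLaw:
    """Mixture-cure survival ``S(t) = cure + (1 - cure) * S_u(t)``.

    The uncured component ``S_u`` is Weibull with ``S_u(t) =
    exp(-(t / scale) ** shape)``; ``shape = 1`` gives the exponential
    with rate ``1 / scale``.
    """

    cure_frac: float
    shape: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.cure_frac <= 1.0):
            raise ValueError(f"cure_frac must be in [0,1], got {self.cure_frac}")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be > 0")

    @classmethod
    def exponential(cls, rate: float, cure_frac: float = 0.0) -> "MixtureCureLaw":
        return cls(cure_frac=cure_frac, shape=1.0, scale=1.0 / rate)

    def uncured_survival(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(np.isinf(t), 0.0, np.exp(-((np.clip(t, 0, None) / self.scale) ** self.shape)))
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        out = self.cure_frac + (1.0 - self.cure_frac) * np.asarray(
            self.uncured_survival(t)
        )
        return float(out) if np.ndim(out) == 0 else out

    def _uncured_inverse(self, v):
        """Solve ``S_u(t) = v`` for ``t`` (v in (0,1]; v=0 gives +inf)."""
        v = np.asarray(v, dtype=float)
        with np.errstate(divide="ignore"):
            out = self.scale * (-np.log(v)) ** (1.0 / self.shape)
        return out

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Inversion sampling; cured patients get ``+inf``."""
        u = rng.uniform(size=size)
        times = np.full(size, np.inf)
        uncured = u >= self.cure_frac
        if self.cure_frac < 1.0 and uncured.any():
            v = (u[uncured] - self.cure_frac) / (1.0 - self.cure_frac)
            times[uncured] = self._uncured_inverse(v)
        return times

    def draw_conditional(self, w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Residual times beyond ``w`` under this law given survival past ``w``.

        Draws ``T - w | T > w`` by inverting ``S(t) = U * S(w)``.
        """
        w = np.asarray(w, dtype=float)
        u = rng.uniform(size=w.size)
        target = u * np.asarray(self.survival(w))
        resid = np.full(w.size, np.inf)
        uncured = target > self.cure_frac
        if uncured.any():
            v = (target[uncured] - self.cure_frac) / (1.0 - self.cure_frac)
            resid[uncured] = self._uncured_inverse(v) - w[uncured]
        return resid


def draw_event_time(
    law: MixtureCureLaw, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw mixture-cure event times by closed-form inversion.

    Cured patients (probability ``law.cure_frac``) receive ``+inf``;
    observables downstream are always finite through censoring.
    """
    return law.draw(rng, size)


# ---------------------------------------------------------------------------
# waiting-time laws (law of W given a donor is available; support in [0, tau])


@dataclass(frozen=True)
class DiscreteWaitingLaw:
    """Point masses ``P(W = times[k]) = probs[k]``; masses must sum to 1."""

    times: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.times) != len(self.probs):
            raise ValueError("times and probs must have equal length")
        if not math.isclose(sum(self.probs), 1.0, rel_tol=1e-9):
            raise ValueError("probs must sum to 1")
        if any(p < 0 for p in self.probs):
            raise ValueError("probs must be non-negative")

    def draw(self, rng, size, tau):
        if max(self.times) > tau:
            raise ValueError("waiting-time masses must lie within [0, tau]")
        return rng.choice(np.asarray(self.times), size=size, p=np.asarray(self.probs))

    def mean(self, tau):
        return float(np.dot(self.times, self.probs))


@dataclass(frozen=True)
class ExponentialWaitingLaw:
    """Exponential waiting times truncated at ``tau``.

    The draw is conditioned on ``W <= tau``: in the donor-available
    population every patient leaves the search state by ``tau``.
    """

    mean: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("mean must be > 0")

    def draw(self, rng, size, tau):
        u = rng.uniform(size=size)
        return -self.mean * np.log1p(-u * (1.0 - math.exp(-tau / self.mean)))

    def pdf(self, w, tau):
        w = np.asarray(w, dtype=float)
        norm = 1.0 - math.exp(-tau / self.mean)
        return np.where(
            (w >= 0) & (w <= tau), np.exp(-w / self.mean) / (self.mean * norm), 0.0
        )

    def mean_waiting(self, tau):
        # mean of the truncated distribution
        a = tau / self.mean
        return self.mean * (1.0 - (1.0 + a) * math.exp(-a)) / (1.0 - math.exp(-a))


WaitingLaw = Union[DiscreteWaitingLaw, ExponentialWaitingLaw]


# ---------------------------------------------------------------------------
# post-identification laws


@dataclass(frozen=True)
class ContinuationPost:
    """No-effect post law: continue the pre-identification process."""


@dataclass(frozen=True)
class FreshClockPost:
    """Mixture-cure law on the time-since-identification clock.

    With ``plateau_match=True`` the cure fraction is rescaled per waiting
    time, ``cure(w) = min(1, cure_frac / S_pre(w))``, so the donor
    group's long-term plateau coincides with the no-donor plateau and
    only short-term survival differs.
    """

    law: MixtureCureLaw
    plateau_match: bool = False

    def cure_at(self, w, pre: MixtureCureLaw):
        if not self.plateau_match:
            return np.full_like(np.asarray(w, dtype=float), self.law.cure_frac)
        return np.minimum(1.0, self.law.cure_frac / np.asarray(pre.survival(w)))

    def residual_survival(self, u, w, pre: MixtureCureLaw):
        """S_post(u | w): survival of the residual time at lag ``u``."""
        cure = self.cure_at(w, pre)
        return cure + (1.0 - cure) * np.asarray(self.law.uncured_survival(u))

    def draw_residual(self, w: np.ndarray, rng, pre: MixtureCureLaw) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        cure = np.asarray(self.cure_at(w, pre))
        u = rng.uniform(size=w.size)
        resid = np.full(w.size, np.inf)
        uncured = u >= cure
        if uncured.any():
            v = (u[uncured] - cure[uncured]) / (1.0 - cure[uncured])
            resid[uncured] = self.law._uncured_inverse(v)
        return resid


PostLaw = Union[ContinuationPost, FreshClockPost]


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative truth for one simulation scenario."""

    label: str
    donor_prob: float
    waiting_law: WaitingLaw
    pre_law: MixtureCureLaw
    post_law: PostLaw
    censor_max: float
    n: int = 400

    def __post_init__(self):
        if not (0.0 <= self.donor_prob <= 1.0):
            raise ValueError("donor_prob must be in [0,1]")
        if self.censor_max <= 0:
            raise ValueError("censor_max must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class LatentRecord:
    """Observable record plus the generating latent truth.

    The latent fields exist only for bias/coverage evaluation; estimators
    never see them.
    """

    record: SubjectRecord
    has_donor: bool
    latent_w: float  #: waiting time (nan if no donor)
    latent_event_time: float  #: event time before censoring (inf if cured)


def observed_cohort(latents: list[LatentRecord]) -> list[SubjectRecord]:
    """Project latent records onto their observable part."""
    return [lr.record for lr in latents]


def simulate_cohort(
    spec: ScenarioSpec, config: StudyConfig, seed
) -> list[LatentRecord]:
    """Generate one cohort; ``(spec, config, seed)`` fully determine it.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = spec.n
    tau = config.tau

    has_donor = rng.uniform(size=n) < spec.donor_prob
    W = np.full(n, np.nan)
    n_d = int(has_donor.sum())
    if n_d:
        W[has_donor] = spec.waiting_law.draw(rng, n_d, tau)

    T0 = spec.pre_law.draw(rng, n)

    # identified in the latent process: donor available and event-free at W
    transitioned = has_donor & (T0 > W)
    T = T0.copy()
    if transitioned.any():
        w_t = W[transitioned]
        if isinstance(spec.post_law, ContinuationPost):
            resid = spec.pre_law.draw_conditional(w_t, rng)
        else:
            resid = spec.post_law.draw_residual(w_t, rng, spec.pre_law)
        T[transitioned] = w_t + resid

    C = rng.uniform(0.0, spec.censor_max, size=n)

    outcome_time = np.minimum(T, C)
    outcome_event = (T <= C).astype(int)
    identified = transitioned & (W <= C) & (W <= tau)

    out: list[LatentRecord] = []
    for i in range(n):
        if identified[i]:
            reason = SearchEndReason.IDENTIFIED
            end = float(W[i])
            ident: float | None = float(W[i])
        elif tau <= outcome_time[i]:
            reason = SearchEndReason.COMPLETED
            end = float(tau)
            ident = None
        elif T[i] <= C[i]:
            reason = SearchEndReason.CEASED
            end = float(T[i])
            ident = None
        else:
            reason = SearchEndReason.CENSORED
            end = float(C[i])
            ident = None
        rec = SubjectRecord(
            subject_id=f"p{i:06d}",
            outcome_time=float(outcome_time[i]),
            outcome_event=int(outcome_event[i]),
            ident_time=ident,
            search_end_time=end,
            search_end_reason=reason,
        )
        out.append(
            LatentRecord(
                record=rec,
                has_donor=bool(has_donor[i]),
                latent_w=float(W[i]),
                latent_event_time=float(T[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# truth


def _s1_given_w(w: float, t_star: float, spec: ScenarioSpec) -> float:
    """P(T > t* | donor, W = w): survive state 0 to w, then the post law."""
    pre = spec.pre_law
    if w > t_star:
        return float(pre.survival(t_star))
    if isinstance(spec.post_law, ContinuationPost):
        return float(pre.survival(t_star))
    return float(pre.survival(w)) * float(
        spec.post_law.residual_survival(t_star - w, w, pre)
    )


def true_values(
    spec: ScenarioSpec, config: StudyConfig
) -> tuple[float, float, float]:
    """Exact ``(S0(t*), S1(t*), cHR)`` for a scenario.

    ``S0`` is the pre-identification mixture-cure survival; ``S1``
    averages the conditional survival over the waiting-time law (a sum
    for point masses, adaptive quadrature otherwise); ``cHR =
    log S1 / log S0``.
    """
    t_star = config.t_star
    s0 = float(spec.pre_law.survival(t_star))

    law = spec.waiting_law
    if isinstance(spec.post_law, ContinuationPost):
        s1 = s0
    elif isinstance(law, DiscreteWaitingLaw):
        s1 = sum(
            p * _s1_given_w(w, t_star, spec) for w, p in zip(law.times, law.probs)
        )
    else:
        upper = min(config.tau, t_star)
        val, _err = integrate.quad(
            lambda w: law.pdf(w, config.tau) * _s1_given_w(w, t_star, spec),
            0.0,
            upper,
            epsabs=1e-10,
            epsrel=1e-10,
            limit=200,
        )
        s1 = val
        if config.tau > t_star:
            # waiting times beyond t*: patient still in state 0 at t*
            tail = integrate.quad(
                lambda w: law.pdf(w, config.tau), t_star, config.tau
            )[0]
            s1 += tail * float(spec.pre_law.survival(t_star))

    for name, s in (("S0", s0), ("S1", s1)):
        if not (0.0 < s < 1.0):
            raise ValueError(
                f"{name}(t*) = {s}: cumulative hazard ratio undefined"
            )
    chr_true = math.log(s1) / math.log(s0)
    return s0, s1, chr_true


# ---------------------------------------------------------------------------
# scenario library


def scenario_library() -> dict[str, tuple[ScenarioSpec, StudyConfig]]:
    """Named default scenarios with their study configurations.

    ``study1`` is the discrete-waiting-time design: 25% of patients in
    each of four latent groups (no donor; donor at 0.5, 1 or 3 years),
    tau = 3, uniform censoring on (0, 6), outcome at t* = 5.  Scenarios
    ``A``–``G`` use tau = t* = 5, uniform censoring on (0, 11) and
    exponential waiting times (mean 0.4 years, except the long-waiting
    scenario G with mean 3), covering: a long-term-only difference (A),
    crossing survival curves (B, C), a short-term-only difference with
    matched plateaus (D), proportional hazards without cure (E), no
    effect (F), and unrealistically long waiting times (G).  Exact
    parameter values are this package's own calibrations; they are
    documented in docs/methods.md.
    """
    study2 = StudyConfig(t_star=5.0, tau=5.0)
    base_pre = MixtureCureLaw.exponential(rate=0.8, cure_frac=0.30)
    wait = ExponentialWaitingLaw(mean=0.4)
    lib: dict[str, tuple[ScenarioSpec, StudyConfig]] = {}

    lib["study1"] = (
        ScenarioSpec(
            label="study1",
            donor_prob=0.75,
            waiting_law=DiscreteWaitingLaw(
                times=(0.5, 1.0, 3.0), probs=(1 / 3, 1 / 3, 1 / 3)
            ),
            pre_law=MixtureCureLaw.exponential(rate=0.12),
            post_law=ContinuationPost(),
            censor_max=6.0,
            n=400,
        ),
        StudyConfig(t_star=5.0, tau=3.0),
    )
    lib["A"] = (
        ScenarioSpec(
            label="A",
            donor_prob=0.25,
            waiting_law=wait,
            pre_law=base_pre,
            post_law=FreshClockPost(MixtureCureLaw.exponential(rate=0.8, cure_frac=0.45)),
            censor_max=11.0,
        ),
        study2,
    )
    lib["B"] = (
        ScenarioSpec(
            label="B",
            donor_prob=0.40,
            waiting_law=wait,
            pre_law=base_pre,
            post_law=FreshClockPost(MixtureCureLaw.exponential(rate=1.6, cure_frac=0.45)),
            censor_max=11.0,
        ),
        study2,
    )
    lib["C"] = (
        ScenarioSpec(
            label="C",
            donor_prob=0.40,
            waiting_law=wait,
            pre_law=base_pre,
            post_law=FreshClockPost(MixtureCureLaw.exponential(rate=2.5, cure_frac=0.50)),
            censor_max=11.0,
        ),
        study2,
    )
    lib["D"] = (
        ScenarioSpec(
            label="D",
            donor_prob=0.40,
            waiting_law=wait,
            pre_law=base_pre,
            post_law=FreshClockPost(
                MixtureCureLaw.exponential(rate=1.6, cure_frac=0.30),
                plateau_match=True,
            ),
            censor_max=11.0,
        ),
        study2,
    )
    lib["E"] = (
        ScenarioSpec(
            label="E",
            donor_prob=0.40,
            waiting_law=wait,
            pre_law=MixtureCureLaw.exponential(rate=0.2),
            post_law=FreshClockPost(MixtureCureLaw.exponential(rate=0.12)),
            censor_max=11.0,
        ),
        study2,
    )
    lib["F"] = (
        ScenarioSpec(
            label="F",
            donor_prob=0.40,
            waiting_law=wait,
            pre_law=base_pre,
            post_law=ContinuationPost(),
            censor_max=11.0,
        ),
        study2,
    )
    lib["G"] = (
        ScenarioSpec(
            label="G",
            donor_prob=0.45,
            waiting_law=ExponentialWaitingLaw(mean=3.0),
            pre_law=base_pre,
            post_law=FreshClockPost(MixtureCureLaw.exponential(rate=0.8, cure_frac=0.45)),
            censor_max=11.0,
        ),
        study2,
    )
    return lib


# ---------------------------------------------------------------------------
# scenario (de)serialisation


def _law_to_dict(obj):
    if isinstance(obj, MixtureCureLaw):
        return {
            "kind": "mixture_cure",
            "cure_frac": obj.cure_frac,
            "shape": obj.shape,
            "scale": obj.scale,
        }
    if isinstance(obj, DiscreteWaitingLaw):
        return {
            "kind": "discrete",
            "times": list(obj.times),
            "probs": list(obj.probs),
        }
    if isinstance(obj, ExponentialWaitingLaw):
        return {"kind": "exponential", "mean": obj.mean}
    if isinstance(obj, ContinuationPost):
        return {"kind": "continuation"}
    if isinstance(obj, FreshClockPost):
        return {
            "kind": "fresh_clock",
            "law": _law_to_dict(obj.law),
            "plateau_match": obj.plateau_match,
        }
    raise TypeError(f"cannot serialise {type(obj).__name__}")


def _law_from_dict(d):
    kind = d["kind"]
    if kind == "mixture_cure":
        return MixtureCureLaw(
            cure_frac=float(d["cure_frac"]),
            shape=float(d.get("shape", 1.0)),
            scale=float(d.get("scale", 1.0)),
        )
    if kind == "discrete":
        return DiscreteWaitingLaw(
            times=tuple(float(t) for t in d["times"]),
            probs=tuple(float(p) for p in d["probs"]),
        )
    if kind == "exponential":
        return ExponentialWaitingLaw(mean=float(d["mean"]))
    if kind == "continuation":
        return ContinuationPost()
    if kind == "fresh_clock":
        return FreshClockPost(
            law=_law_from_dict(d["law"]),
            plateau_match=bool(d.get("plateau_match", False)),
        )
    raise ValueError(f"unknown law kind {kind!r}")


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "label": spec.label,
        "donor_prob": spec.donor_prob,
        "waiting_law": _law_to_dict(spec.waiting_law),
        "pre_law": _law_to_dict(spec.pre_law),
        "post_law": _law_to_dict(spec.post_law),
        "censor_max": spec.censor_max,
        "n": spec.n,
    }


def scenario_from_dict(d: dict) -> ScenarioSpec:
    return ScenarioSpec(
        label=str(d["label"]),
        donor_prob=float(d["donor_prob"]),
        waiting_law=_law_from_dict(d["waiting_law"]),
        pre_law=_law_from_dict(d["pre_law"]),
        post_law=_law_from_dict(d["post_law"]),
        censor_max=float(d["censor_max"]),
        n=int(d.get("n", 400)),
    )


def save_scenario(spec: ScenarioSpec, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(spec), fh)


def load_scenario(path) -> ScenarioSpec:
    import yaml

    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
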