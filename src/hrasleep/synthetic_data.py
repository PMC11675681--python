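"""Synthetic polysomnography-like cohorts with known ground-truth effects.

A cohort is a set of subjects, each with a hypnogram (first-order Markov
chain over 30-s epochs, merged into bouts) and a beat-by-beat RR series
whose mean level, variability, oscillatory content, smoothness and run
asymmetry all depend on the concurrent stage:

    RR_i = mean_rr(stage) + colored/white noise + LF tone (0.10 Hz)
           + HF tone (0.25 Hz) + asymmetric event process

The event process injects, at rate ``asym_skew`` per beat, one abrupt RR
lengthening followed by a gradual multi-beat shortening ramp, producing the
longer and more numerous acceleration runs seen in real heart rhythms.
Subject-level random perturbations of the dynamics create the exchangeable
within-subject correlation that the GEE layer is meant to absorb.

The chain's transition matrix is built to be reversible with a prescribed
stationary stage occupancy, so long recordings hit the configured occupancy
targets by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .rr_io import Hypnogram, RRSeries, STAGES

#: stage time-occupancy targets; Table-style cohort composition with
#: transition-segment time shared between the endpoint stages
DEFAULT_OCCUPANCY: dict[str, float] = {
    "W": 0.28,
    "N1": 0.16,
    "N2": 0.29,
    "N3": 0.14,
    "R": 0.13,
}

#: symmetric adjacency weights: which stage changes are common in hypnograms
DEFAULT_ADJACENCY: dict[frozenset, float] = {
    frozenset(("W", "N1")): 3.0,
    frozenset(("W", "N2")): 0.5,
    frozenset(("W", "N3")): 0.1,
    frozenset(("W", "R")): 0.4,
    frozenset(("N1", "N2")): 3.0,
    frozenset(("N1", "N3")): 0.1,
    frozenset(("N1", "R")): 0.5,
    frozenset(("N2", "N3")): 2.0,
    frozenset(("N2", "R")): 1.5,
    frozenset(("N3", "R")): 0.2,
}


@dataclass
class StageDynamics:
    """Beat-generation parameters for one sleep stage.

    mean_rr, sd_scale, lf_amp, hf_amp are in ms; ar1_rho in [0, 1) sets the
    noise smoothness; asym_skew is the per-beat probability of an asymmetric
    deceleration event; complexity_noise in [0, 1] is the white-noise share
    of the stochastic part (higher -> higher sample entropy).
    """

    mean_rr: float
    sd_scale: float
    lf_amp: float
    hf_amp: float
    ar1_rho: float
    asym_skew: float
    complexity_noise: float

    def __post_init__(self) -> None:
        if not (600.0 <= self.mean_rr <= 1400.0):
            raise ConfigError(f"mean_rr {self.mean_rr} outside [600, 1400] ms")
        if min(self.sd_scale, self.lf_amp, self.hf_amp) < 0:
            raise ConfigError("amplitudes must be non-negative")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ConfigError("ar1_rho must be in [0, 1)")
        if not (0.0 <= self.asym_skew <= 1.0):
            raise ConfigError("asym_skew must be in [0, 1]")
        if not (0.0 <= self.complexity_noise <= 1.0):
            raise ConfigError("complexity_noise must be in [0, 1]")


#: ground-truth stage physiology of the default cohort: N2 carries the
#: largest LF/HF tone ratio, N3 is HF-dominated, N1 is the most regular
#: (lowest white-noise share), wake is fast, noisy and irregular.
DEFAULT_DYNAMICS: dict[str, StageDynamics] = {
    "W": StageDynamics(850.0, 45.0, 25.0, 15.0, 0.85, 0.020, 1.00),
    "N1": StageDynamics(900.0, 35.0, 15.0, 18.0, 0.85, 0.030, 0.20),
    "N2": StageDynamics(950.0, 30.0, 40.0, 8.0, 0.80, 0.050, 0.70),
    "N3": StageDynamics(1000.0, 20.0, 8.0, 22.0, 0.70, 0.040, 0.55),
    "R": StageDynamics(880.0, 40.0, 22.0, 12.0, 0.90, 0.060, 0.90),
}


@dataclass
class CohortConfig:
    n_subjects: int = 31
    recording_hours: float = 8.0
    epoch_s: float = 30.0
    occupancy: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OCCUPANCY))
    leave_rate: float = 0.12  # per-epoch probability scale of leaving a stage
    subject_mean_rr_sd: float = 30.0  # ms, between-subject random intercept
    subject_scale_sd: float = 0.12  # lognormal sigma on amplitudes

    def __post_init__(self) -> None:
        if set(self.occupancy) != set(STAGES):
            raise ConfigError("occupancy must cover exactly the five stages")
        if abs(sum(self.occupancy.values()) - 1.0) > 1e-9:
            raise ConfigError("occupancy targets must sum to 1")
        if not (0 < self.leave_rate < 1):
            raise ConfigError("leave_rate must be in (0, 1)")


def build_transition_matrix(
    occupancy: dict[str, float] | None = None,
    adjacency: dict[frozenset, float] | None = None,
    leave_rate: float = 0.12,
) -> np.ndarray:
    """Reversible per-epoch transition matrix with the given stationary law.

    Off-diagonal entries are P[i, j] = c * pi_j * A[i, j] with symmetric
    adjacency weights A, which satisfies detailed balance, so the stationary
    distribution equals the occupancy targets exactly; c is set so the
    largest per-epoch leave probability equals ``leave_rate``.
    """
    occupancy = occupancy or DEFAULT_OCCUPANCY
    adjacency = adjacency or DEFAULT_ADJACENCY
    pi = np.array([occupancy[s] for s in STAGES])
    A = np.zeros((len(STAGES), len(STAGES)))
    for i, si in enumerate(STAGES):
        for j, sj in enumerate(STAGES):
            if i != j:
                A[i, j] = adjacency.get(frozenset((si, sj)), 0.0)
    raw_leave = (A * pi[None, :]).sum(axis=1)
    if raw_leave.min() <= 0:
        raise ConfigError("adjacency leaves some stage unreachable")
    c = leave_rate / raw_leave.max()
    P = c * A * pi[None, :]
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    if (np.diag(P) < 0).any():
        raise ConfigError("leave_rate too high for the adjacency weights")
    return P


def generate_hypnogram(
    cfg: CohortConfig,
    seed: int | np.random.Generator,
    subject_id: str = "S01",
    matrix: np.ndarray | None = None,
) -> Hypnogram:
    """Markov-chain hypnogram over 30-s epochs, merged into bouts.

    ``matrix`` overrides the occupancy-derived transition matrix (rows must
    sum to 1 over the stage order W, N1, N2, N3, R).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if matrix is None:
        P = build_transition_matrix(cfg.occupancy, leave_rate=cfg.leave_rate)
    else:
        P = np.asarray(matrix, dtype=float)
        if P.shape != (len(STAGES), len(STAGES)) or not np.allclose(P.sum(axis=1), 1.0):
            raise ConfigError("transition matrix rows must sum to 1")
    n_epochs = int(round(cfg.recording_hours * 3600.0 / cfg.epoch_s))
    states = np.empty(n_epochs, dtype=int)
    states[0] = STAGES.index("W")
    for k in range(1, n_epochs):
        states[k] = rng.choice(len(STAGES), p=P[states[k - 1]])
    bouts: list[tuple[str, float, float]] = []
    start = 0
    for k in range(1, n_epochs + 1):
        if k == n_epochs or states[k] != states[start]:
            bouts.append((STAGES[states[start]], start * cfg.epoch_s, k * cfg.epoch_s))
            start = k
    return Hypnogram(subject_id, bouts)


def generate_rr(
    hyp: Hypnogram,
    dynamics: dict[str, StageDynamics] | None = None,
    seed: int | np.random.Generator = 0,
) -> RRSeries:
    """Beat-by-beat RR simulation following a hypnogram."""
    dynamics = dynamics or DEFAULT_DYNAMICS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total_s = hyp.end_s
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)

    bout_starts = np.array([a for _, a, _ in hyp.bouts])
    bout_stage = [s for s, _, _ in hyp.bouts]

    intervals: list[float] = []
    t = 0.0
    ar_state = 0.0
    pending: list[float] = []  # event offsets for upcoming beats
    while t < total_s:
        k = int(np.searchsorted(bout_starts, t, side="right")) - 1
        dyn = dynamics[bout_stage[max(k, 0)]]
        colored = dyn.ar1_rho * ar_state + np.sqrt(1 - dyn.ar1_rho**2) * rng.standard_normal()
        ar_state = colored
        white = rng.standard_normal()
        w = dyn.complexity_noise
        norm = np.sqrt((1 - w) ** 2 + w**2)
        noise = dyn.sd_scale * ((1 - w) * colored + w * white) / norm

        if pending:
            # slow-recovery ramp: noise is damped so the multi-beat gradual
            # shortening stays quasi-monotone (a long acceleration run)
            event = pending.pop(0)
            noise *= 0.2
        else:
            event = 0.0
            if rng.random() < dyn.asym_skew:
                jump = rng.uniform(60.0, 120.0)
                ramp_len = int(rng.integers(4, 8))
                event = jump
                pending = [jump * (1 - (i + 1) / ramp_len) for i in range(ramp_len)]

        rr = (
            dyn.mean_rr
            + noise
            + dyn.lf_amp * np.sin(2 * np.pi * 0.10 * t + phase_lf)
            + dyn.hf_amp * np.sin(2 * np.pi * 0.25 * t + phase_hf)
            + event
        )
        rr = float(np.clip(rr, 250.0, 2900.0))
        intervals.append(rr)
        t += rr / 1000.0
    return RRSeries(hyp.subject_id, np.array(intervals))


def jittered_dynamics(
    dynamics: dict[str, StageDynamics],
    rng: np.random.Generator,
    mean_rr_sd: float,
    scale_sd: float,
) -> dict[str, StageDynamics]:
    """Subject-level random effects: shared RR-level shift and amplitude scales."""
    shift = rng.normal(0.0, mean_rr_sd)
    sd_f, lf_f, hf_f = np.exp(rng.normal(0.0, scale_sd, size=3))
    out = {}
    for stage, dyn in dynamics.items():
        out[stage] = replace(
            dyn,
            mean_rr=float(np.clip(dyn.mean_rr + shift, 600.0, 1400.0)),
            sd_scale=dyn.sd_scale * sd_f,
            lf_amp=dyn.lf_amp * lf_f,
            hf_amp=dyn.hf_amp * hf_f,
        )
    return out


def generate_cohort(
    cfg: CohortConfig | None = None,
    dynamics: dict[str, StageDynamics] | None = None,
    seed: int = 0,
) -> list[tuple[RRSeries, Hypnogram]]:
    """Independent subjects with per-subject jitter of the stage dynamics."""
    cfg = cfg or CohortConfig()
    dynamics = dynamics or DEFAULT_DYNAMICS
    seqs = np.random.SeedSequence(seed).spawn(cfg.n_subjects)
    cohort = []
    for i, sseq in enumerate(seqs):
        rng = np.random.default_rng(sseq)
        sid = f"S{i + 1:02d}"
        subj_dyn = jittered_dynamics(
            dynamics, rng, cfg.subject_mean_rr_sd, cfg.subject_scale_sd
        )
        hyp = generate_hypnogram(cfg, rng, subject_id=sid)
        rr = generate_rr(hyp, subj_dyn, rng)
        cohort.append((rr, hyp))
    return cohort


def ground_truth(cfg: CohortConfig, dynamics: dict[str, StageDynamics]) -> dict:
    """JSON-serializable record of the configured effects."""
    return {
        "config": {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, dict)
        }
        | {"occupancy": cfg.occupancy},
        "dynamics": {s: asdict(d) for s, d in dynamics.items()},
    }


def write_cohort(
    cohort: list[tuple[RRSeries, Hypnogram]],
    out_dir: str | Path,
    cfg: CohortConfig | None = None,
    dynamics: dict[str, StageDynamics] | None = None,
) -> None:
    """Write RR and hypnogram files plus the ground-truth JSON."""
    from .rr_io import write_hypnogram, write_rr

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rr, hyp in cohort:
        write_rr(rr, out / f"{rr.subject_id}_rr.csv")
        write_hypnogram(hyp, out / f"{hyp.subject_id}_hyp.csv")
    truth = ground_truth(cfg or CohortConfig(), dynamics or DEFAULT_DYNAMICS)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
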