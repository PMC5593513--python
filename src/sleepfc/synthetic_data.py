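"""Ground-truth-known synthetic experiments.

This module emulates the study design the analysis pipeline is built for: a
two-night within-subject crossover in which each subject practices either an
explicit five-item finger sequence (MSL) or a rate-matched simultaneous-press
control task (CTL), with resting-state runs before and after practice (RS1-RS3),
task runs (S1 evening training, S2 morning retest), and an EEG-scored sleep run
in between.

The signal model is additive::

    Y(v, t) = baseline + sum_p a_p(t) * X_p(v) + nuisance(v, t) + noise(v, t)

where each ``X_p`` is a spatial pattern ("learning" / "consolidated" network)
and ``a_p(t)`` its co-activation amplitude.  In stochastic mode the amplitude
is a smooth unit-variance latent process scaled by a deterministic envelope,
so the variance of the pattern's co-activation — exactly what the connectivity
index measures — is controlled by the envelope.  Nuisance structure comprises
a global signal, low-frequency drift, motion-coupled signal (a linear mixture
of the emitted motion traces), and WM/CSF compartment signals, so that the
seed-connectivity nuisance regression has something real to remove.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import BoldRun, SpatialPattern, default_affine

__all__ = [
    "SLEEP_STAGES",
    "SimSpec",
    "CohortSpec",
    "KeypressParams",
    "CouplingSchedule",
    "NuisanceSpec",
    "Hypnogram",
    "CohortDataset",
    "default_brain_mask",
    "default_tissue_masks",
    "make_pattern_pair",
    "simulate_run",
    "simulate_hypnogram",
    "simulate_keypresses",
    "simulate_cohort",
    "draw_coupling_gains",
    "simulate_localization_cohort",
    "simulate_dynamics_pair",
]

SLEEP_STAGES = ("wake", "N1", "N2", "SWS", "REM", "artifact")


# ---------------------------------------------------------------------------
# masks and patterns


def default_brain_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal 'brain' inscribed in the grid (radii 0.45 of each axis)."""
    grids = np.meshgrid(
        *[np.arange(n) - (n - 1) / 2 for n in grid_shape], indexing="ij"
    )
    radii = [0.45 * n for n in grid_shape]
    d2 = sum((g / r) ** 2 for g, r in zip(grids, radii))
    return d2 <= 1.0


def default_tissue_masks(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Toy (WM, CSF) compartments: concentric shells inside the brain mask."""
    shape = mask.shape
    grids = np.meshgrid(*[np.arange(n) - (n - 1) / 2 for n in shape], indexing="ij")
    radii = [0.45 * n for n in shape]
    d2 = sum((g / r) ** 2 for g, r in zip(grids, radii))
    csf = (d2 <= 0.05) & mask
    wm = (d2 > 0.05) & (d2 <= 0.20) & mask
    return wm, csf


def make_pattern_pair(
    grid_shape: tuple[int, int, int],
    overlap_fraction: float,
    seed: int,
    support_size: int | None = None,
    mask: np.ndarray | None = None,
) -> tuple[SpatialPattern, SpatialPattern]:
    """Two weight maps whose supports share ``overlap_fraction`` of voxels.

    Emulates a "learning" and a "consolidated" network that comprise similar
    core regions but are not identical.  The second support contains exactly
    ``round(overlap_fraction * support_size)`` voxels of the first plus fresh
    voxels disjoint from it, so the containment fraction equals the request up
    to rounding.  Weights are positive on support, zero elsewhere.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if mask is None:
        mask = default_brain_mask(grid_shape)
    candidates = np.flatnonzero(mask.ravel())
    if support_size is None:
        support_size = max(20, int(0.04 * candidates.size))
    n_shared = int(round(overlap_fraction * support_size))
    n_total = 2 * support_size - n_shared
    if n_total > candidates.size:
        raise ValueError(
            f"grid too small: need {n_total} in-mask voxels for two supports "
            f"of {support_size}, mask has {candidates.size}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_total, replace=False)
    sup_a = chosen[:support_size]
    # second support: the first n_shared voxels of A plus fresh ones
    sup_b = np.concatenate([sup_a[:n_shared], chosen[support_size:]])

    def _weights(sup: np.ndarray) -> np.ndarray:
        w = np.zeros(int(np.prod(grid_shape)))
        w[sup] = rng.uniform(0.5, 1.5, size=sup.size)
        return w.reshape(grid_shape)

    pat_a = SpatialPattern(_weights(sup_a), pattern_id="learning")
    pat_b = SpatialPattern(_weights(sup_b), pattern_id="consolidated")
    return pat_a, pat_b


# ---------------------------------------------------------------------------
# run simulation


@dataclass
class CouplingSchedule:
    """Amplitude schedule for one pattern.

    If ``stochastic`` the per-volume amplitude is ``envelope[t] * z[t]`` with
    ``z`` a unit-marginal-variance AR(1) latent (lag-1 correlation ``ar``);
    the envelope is then the SD of the pattern's co-activation, which is what
    the connectivity index tracks.  If not stochastic the envelope is used
    verbatim as the amplitude (useful for exact-reconstruction oracles).
    """

    pattern_id: str
    envelope: np.ndarray
    stochastic: bool = True
    ar: float = 0.5

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        if not np.all(np.isfinite(self.envelope)):
            raise ValueError(f"non-finite amplitude schedule for {self.pattern_id}")


@dataclass
class NuisanceSpec:
    """Amplitudes of the structured nuisance components (in noise-SD units)."""

    global_amp: float = 0.5
    drift_amp: float = 0.3
    motion_amp: float = 0.3
    wm_amp: float = 0.5
    csf_amp: float = 0.5

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"nuisance amplitude {name}={v} must be finite, >= 0")


@dataclass
class SimSpec:
    """Full specification of one simulated run.

    Defaults mirror the analysis scale of the study design: a 20 cubed grid,
    600 volumes and TR 2.16 s (so a 100-volume window lasts 216 s).
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_volumes: int = 600
    tr: float = 2.16
    patterns: list[SpatialPattern] = field(default_factory=list)
    coupling: list[CouplingSchedule] = field(default_factory=list)
    noise_sd: float = 1.0
    nuisance: NuisanceSpec = field(default_factory=NuisanceSpec)
    baseline: float = 100.0
    voxel_size: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.nuisance.validate()
        ids = {p.pattern_id for p in self.patterns}
        for c in self.coupling:
            if c.pattern_id not in ids:
                raise ValueError(f"coupling references unknown pattern {c.pattern_id}")
            if len(c.envelope) != self.n_volumes:
                raise ValueError(
                    f"schedule for {c.pattern_id} has length {len(c.envelope)}, "
                    f"expected {self.n_volumes}"
                )
        mask = default_brain_mask(self.grid_shape)
        for p in self.patterns:
            if np.any(p.support & ~mask):
                raise ValueError(f"pattern {p.pattern_id} leaves the brain mask")

    def to_json(self) -> str:
        d = {
            "grid_shape": list(self.grid_shape),
            "n_volumes": self.n_volumes,
            "tr": self.tr,
            "noise_sd": self.noise_sd,
            "baseline": self.baseline,
            "voxel_size": self.voxel_size,
            "seed": self.seed,
            "nuisance": asdict(self.nuisance),
            "patterns": [p.pattern_id for p in self.patterns],
            "coupling": [
                {
                    "pattern_id": c.pattern_id,
                    "stochastic": c.stochastic,
                    "ar": c.ar,
                    "envelope_mean": float(np.mean(c.envelope)) if len(c.envelope) else 0.0,
                }
                for c in self.coupling
            ],
        }
        return json.dumps(d, indent=2)


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) series."""
    e = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = e[0]
    c = np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + c * e[t]
    return z


def simulate_run(spec: SimSpec, labels: dict | None = None) -> BoldRun:
    """Simulate one 4D run from ``spec`` (deterministic under ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    T = spec.n_volumes
    mask = default_brain_mask(spec.grid_shape)
    wm, csf = default_tissue_masks(mask)
    n_vox = int(mask.sum())

    data = np.zeros((n_vox, T), dtype=np.float64)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=(n_vox, T))
    data += spec.baseline

    # pattern co-activation
    truth_amp: dict[str, np.ndarray] = {}
    pat_by_id = {p.pattern_id: p for p in spec.patterns}
    for sched in spec.coupling:
        amp = sched.envelope.copy()
        if sched.stochastic:
            amp = amp * _ar1(rng, T, sched.ar)
        truth_amp[sched.pattern_id] = amp
        x = pat_by_id[sched.pattern_id].data[mask]
        data += np.outer(x, amp)

    # structured nuisance
    nu = spec.nuisance
    scale = spec.noise_sd if spec.noise_sd > 0 else 1.0
    truth_nuis: dict[str, np.ndarray] = {}
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(T, 6)), axis=0)
    if nu.global_amp > 0:
        g = _ar1(rng, T, 0.8) * nu.global_amp * scale
        data += g[None, :]
        truth_nuis["global"] = g
    if nu.drift_amp > 0:
        ramp = np.linspace(-1.0, 1.0, T)
        w = rng.normal(1.0, 0.3, size=n_vox)
        data += nu.drift_amp * scale * np.outer(w, ramp)
        truth_nuis["drift"] = ramp
    if nu.motion_amp > 0:
        mix = rng.normal(size=6)
        mix /= np.linalg.norm(mix)
        m = (motion - motion.mean(axis=0)) @ mix
        msd = m.std()
        if msd > 0:
            m = m / msd
        profile = rng.uniform(0.5, 1.5, size=n_vox)
        data += nu.motion_amp * scale * np.outer(profile, m)
        truth_nuis["motion_coupled"] = m
    wm_in = wm[mask]
    csf_in = csf[mask]
    if nu.wm_amp > 0 and wm_in.any():
        s = _ar1(rng, T, 0.8) * nu.wm_amp * scale
        data[wm_in] += s[None, :]
        truth_nuis["wm"] = s
    if nu.csf_amp > 0 and csf_in.any():
        s = _ar1(rng, T, 0.8) * nu.csf_amp * scale
        data[csf_in] += s[None, :]
        truth_nuis["csf"] = s

    vol = np.zeros(spec.grid_shape + (T,), dtype=np.float64)
    vol[mask] = data
    labels = labels or {}
    return BoldRun(
        data=vol,
        tr=spec.tr,
        mask=mask,
        motion=motion,
        affine=default_affine(spec.voxel_size),
        wm_mask=wm,
        csf_mask=csf,
        ground_truth={"amplitudes": truth_amp, "nuisance": truth_nuis},
        **labels,
    )


# ---------------------------------------------------------------------------
# hypnogram


@dataclass
class Hypnogram:
    """Per-volume sleep-stage labels aligned to the fMRI time axis."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"volume_index": np.arange(len(self)), "stage": self.labels}
        )


def simulate_hypnogram(
    n_volumes: int,
    stage_plan: list[tuple[str, int]],
    seed: int,
    jitter: float = 0.1,
) -> Hypnogram:
    """Contiguous stage bouts with lengths randomized around ``stage_plan``.

    ``stage_plan`` is a list of ``(stage, n_volumes)`` bouts whose total must
    not exceed ``n_volumes``; each bout length is jittered by a Gaussian factor
    of relative SD ``jitter`` (``jitter=0`` reproduces the plan exactly).  Any
    remaining tail is labeled ``wake`` and the result is truncated so every
    volume carries exactly one label.
    """
    if not stage_plan:
        raise ValueError("stage_plan is empty")
    for stage, dur in stage_plan:
        if stage not in SLEEP_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if dur < 1:
            raise ValueError("bout durations must be >= 1 volume")
    if sum(d for _, d in stage_plan) > n_volumes:
        raise ValueError("stage plan exceeds the run length")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for stage, dur in stage_plan:
        if jitter > 0:
            dur = max(1, int(round(dur * (1.0 + jitter * rng.standard_normal()))))
        labels.extend([stage] * dur)
    if len(labels) < n_volumes:
        labels.extend(["wake"] * (n_volumes - len(labels)))
    return Hypnogram(np.array(labels[:n_volumes], dtype=object))


# ---------------------------------------------------------------------------
# key presses


@dataclass
class KeypressParams:
    """Behavioral generator parameters.

    The MSL mean inter-key interval follows an exponentially decaying learning
    curve over blocks, ``plateau + span * exp(-(block-1)/tau)``; the retest
    session starts at the end-of-training level minus ``overnight_gain``
    (seconds; positive = faster after sleep).  The CTL task is a flat ~1/3 s
    rhythm of simultaneous 4-key chords.
    """

    n_blocks: int = 14
    presses_per_block: int = 60
    sequence: tuple[int, ...] = (4, 1, 3, 2, 4)
    error_prob: float = 0.02
    plateau: float = 0.30
    span: float = 0.20
    tau: float = 3.0
    overnight_gain: float = 0.03
    interval_jitter_sd: float = 0.02
    ctl_interval: float = 1.0 / 3.0
    rest_s: float = 15.0
    chord_spread_sd: float = 0.005

    def validate(self) -> None:
        for name in ("plateau", "span", "ctl_interval", "interval_jitter_sd",
                     "chord_spread_sd", "rest_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError("error_prob must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def _msl_block_interval(params: KeypressParams, session: str, block: int) -> float:
    if session == "S1":
        return params.plateau + params.span * np.exp(-(block - 1) / params.tau)
    # S2: flat at the mean of the last three S1 block levels minus the gain
    last3 = [
        params.plateau + params.span * np.exp(-(b - 1) / params.tau)
        for b in range(params.n_blocks - 2, params.n_blocks + 1)
    ]
    return float(np.mean(last3)) - params.overnight_gain


def simulate_keypresses(
    condition: str,
    params: KeypressParams | None = None,
    seed: int = 0,
    subject: str | None = None,
) -> pd.DataFrame:
    """Simulate the full S1+S2 key-press log for one subject and condition.

    Returns a tidy frame with columns ``time`` (s, continuous within session),
    ``key`` (1-4), ``block`` (1-based), ``session`` (S1/S2), ``condition`` and
    ``chord`` (chord index for CTL, -1 for MSL).
    """
    if condition not in ("MSL", "CTL"):
        raise ValueError("condition must be MSL or CTL")
    params = params or KeypressParams()
    params.validate()
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    seq = params.sequence
    for session in ("S1", "S2"):
        t = 0.0
        for block in range(1, params.n_blocks + 1):
            if condition == "MSL":
                mean_iv = _msl_block_interval(params, session, block)
                for i in range(params.presses_per_block):
                    if i > 0:
                        iv = mean_iv + params.interval_jitter_sd * rng.standard_normal()
                        t += max(iv, 0.05)
                    key = seq[i % len(seq)]
                    if params.error_prob > 0 and rng.random() < params.error_prob:
                        key = int(rng.choice([k for k in (1, 2, 3, 4) if k != key]))
                    rows.append((t, key, block, session, condition, -1))
            else:
                mean_iv = params.ctl_interval - (
                    params.overnight_gain if session == "S2" else 0.0
                )
                for i in range(params.presses_per_block):
                    if i > 0:
                        iv = mean_iv + params.interval_jitter_sd * rng.standard_normal()
                        t += max(iv, 0.05)
                    onset = t
                    spread = np.abs(
                        rng.normal(0.0, params.chord_spread_sd, size=4)
                    )
                    spread[int(rng.integers(4))] = 0.0  # one finger lands first
                    for key in (1, 2, 3, 4):
                        rows.append(
                            (onset + spread[key - 1], key, block, session, condition, i)
                        )
            t += params.rest_s  # rest period between blocks
        # sessions are separate scans; time restarts
    log = pd.DataFrame(
        rows, columns=["time", "key", "block", "session", "condition", "chord"]
    )
    if subject is not None:
        log.insert(0, "subject", subject)
    return log


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """A multi-subject two-condition crossover.

    ``brain_behavior_rho`` is the target correlation between each subject's
    consolidated-pattern sleep coupling gain ``g_i`` (growth of the pattern's
    co-activation SD over the sleep run, MSL night) and the overnight
    behavioral gain ``b_i`` planted in the MSL key-press log.  The pair is
    drawn from a bivariate Gaussian so the population correlation is exact.
    """

    n_subjects: int = 13
    sessions: tuple[str, ...] = ("RS1", "RS2", "RS3", "sleep")
    conditions: tuple[str, ...] = ("MSL", "CTL")
    brain_behavior_rho: float = 0.72
    coupling_gain_mean: float = 0.6
    coupling_gain_sd: float = 0.15
    behavior_gain_mean: float = 0.03
    behavior_gain_sd: float = 0.012
    rest_volumes: int = 150
    sleep_volumes: int = 600
    base_envelope: float = 0.4
    # per (pattern_id, condition, session) envelope scale; "ramp" entries grow
    # linearly from base to base+gain over the run (subject gain for the
    # consolidated pattern on the MSL sleep night)
    effects: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 <= self.brain_behavior_rho <= 1.0:
            raise ValueError("brain_behavior_rho must lie in [-1, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def draw_coupling_gains(
    n: int,
    rho: float,
    seed: int,
    coupling_mean: float = 0.6,
    coupling_sd: float = 0.15,
    gain_mean: float = 0.03,
    gain_sd: float = 0.012,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``(g_i, b_i)`` pairs with population correlation ``rho``.

    This is the scalar core of the cohort generator, exposed separately so
    that recovery of the brain-behavior correlation can be checked at large n
    without simulating images.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    zb = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    g = coupling_mean + coupling_sd * z1
    b = gain_mean + gain_sd * zb
    return g, b


@dataclass
class CohortDataset:
    """Everything one synthetic experiment produced, keyed for the pipeline."""

    runs: dict
    hypnograms: dict
    keypresses: dict
    patterns: dict
    subjects: pd.DataFrame
    spec: CohortSpec


def _default_effects(base: float) -> dict:
    """Envelope scales emulating the study's qualitative findings.

    Learning network: co-activation up right after training (RS2, MSL only),
    back to baseline by morning; decays over the sleep run.  Consolidated
    network: unchanged before sleep, elevated post-sleep (RS3, MSL only);
    ramps up over the MSL sleep run with subject-specific gain.
    """
    hi = 2.0 * base
    eff = {}
    for cond in ("MSL", "CTL"):
        for ses in ("RS1", "RS2", "RS3", "sleep"):
            eff[("learning", cond, ses)] = base
            eff[("consolidated", cond, ses)] = base
    eff[("learning", "MSL", "RS2")] = hi
    eff[("learning", "MSL", "sleep")] = "ramp_down"
    eff[("consolidated", "MSL", "RS3")] = hi
    eff[("consolidated", "MSL", "sleep")] = "ramp_up"
    return eff


DEFAULT_SLEEP_PLAN_FRACTION = (
    # loosely mirrors in-scanner sleep architecture: long wake at lights-off,
    # N2-dominated NREM with interspersed wake and some SWS
    ("wake", 0.15),
    ("N1", 0.05),
    ("N2", 0.25),
    ("wake", 0.10),
    ("N2", 0.20),
    ("SWS", 0.10),
    ("wake", 0.05),
    ("N2", 0.10),
)


def default_sleep_plan(n_volumes: int) -> list[tuple[str, int]]:
    plan = [(s, max(1, int(f * n_volumes))) for s, f in DEFAULT_SLEEP_PLAN_FRACTION]
    total = sum(d for _, d in plan)
    if total > n_volumes:  # rounding guard
        stage, d = plan[-1]
        plan[-1] = (stage, max(1, d - (total - n_volumes)))
    return plan


def simulate_cohort(
    cohort: CohortSpec, run_spec: SimSpec | None = None
) -> CohortDataset:
    """Generate the full synthetic experiment for every subject x condition.

    ``run_spec`` acts as a template for grid size, TR, noise and nuisance; run
    lengths come from the cohort spec (``rest_volumes`` per resting run,
    ``sleep_volumes`` for the sleep run).
    """
    cohort.validate()
    template = run_spec or SimSpec()
    rng = np.random.default_rng(cohort.seed)
    pat_learn, pat_cons = make_pattern_pair(
        template.grid_shape, overlap_fraction=0.5, seed=cohort.seed
    )
    patterns = {"learning": pat_learn, "consolidated": pat_cons}
    effects = cohort.effects or _default_effects(cohort.base_envelope)
    g, b = draw_coupling_gains(
        cohort.n_subjects,
        cohort.brain_behavior_rho,
        seed=int(rng.integers(2**31)),
        coupling_mean=cohort.coupling_gain_mean,
        coupling_sd=cohort.coupling_gain_sd,
        gain_mean=cohort.behavior_gain_mean,
        gain_sd=cohort.behavior_gain_sd,
    )
    runs: dict = {}
    hypnograms: dict = {}
    keypresses: dict = {}
    subjects = []
    for i in range(cohort.n_subjects):
        sid = f"sub{i + 1:02d}"
        subjects.append({"subject": sid, "coupling_gain": g[i], "behavior_gain": b[i]})
        for cond in cohort.conditions:
            for ses in cohort.sessions:
                T = (
                    cohort.sleep_volumes
                    if ses == "sleep"
                    else cohort.rest_volumes
                )
                coupling = []
                for pid in patterns:
                    scale = effects.get((pid, cond, ses), cohort.base_envelope)
                    if scale == "ramp_up":
                        env = np.linspace(
                            cohort.base_envelope, cohort.base_envelope + g[i], T
                        )
                    elif scale == "ramp_down":
                        env = np.linspace(
                            cohort.base_envelope + g[i], cohort.base_envelope, T
                        )
                    else:
                        env = np.full(T, float(scale))
                    coupling.append(CouplingSchedule(pid, env))
                spec_i = SimSpec(
                    grid_shape=template.grid_shape,
                    n_volumes=T,
                    tr=template.tr,
                    patterns=list(patterns.values()),
                    coupling=coupling,
                    noise_sd=template.noise_sd,
                    nuisance=template.nuisance,
                    baseline=template.baseline,
                    voxel_size=template.voxel_size,
                    seed=int(rng.integers(2**31)),
                )
                runs[(sid, cond, ses)] = simulate_run(
                    spec_i,
                    labels={"subject": sid, "condition": cond, "session": ses},
                )
                if ses == "sleep":
                    hypnograms[(sid, cond)] = simulate_hypnogram(
                        T,
                        default_sleep_plan(T),
                        seed=int(rng.integers(2**31)),
                    )
            params = KeypressParams(
                overnight_gain=float(b[i]) if cond == "MSL" else 0.0
            )
            keypresses[(sid, cond)] = simulate_keypresses(
                cond, params, seed=int(rng.integers(2**31)), subject=sid
            )
    return CohortDataset(
        runs=runs,
        hypnograms=hypnograms,
        keypresses=keypresses,
        patterns=patterns,
        subjects=pd.DataFrame(subjects),
        spec=cohort,
    )


# ---------------------------------------------------------------------------
# canned experiments: the study conditions the recovery analyses assume


def _box_pattern(
    grid_shape: tuple[int, int, int], lo: int, hi: int, mask: np.ndarray,
    rng: np.random.Generator, pattern_id: str,
) -> SpatialPattern:
    sup = np.zeros(grid_shape, dtype=bool)
    sup[lo:hi, lo:hi, lo:hi] = True
    sup &= mask
    w = np.zeros(grid_shape)
    w[sup] = rng.uniform(0.5, 1.5, size=int(sup.sum()))
    return SpatialPattern(w, pattern_id=pattern_id)


def simulate_localization_cohort(
    n_subjects: int = 12,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_volumes: int = 150,
    delta: float = 0.8,
    envelope: float = 0.8,
    seed: int = 0,
):
    """Paired runs whose condition difference is confined to a subregion.

    The group pattern is a contiguous box-shaped network; in the MSL condition
    the voxels of a central subregion R couple with the pattern's time course
    more strongly (weights raised by ``delta``), while the CTL condition uses
    the unmodified pattern.  Dual regression against the group pattern should
    localize the difference to R.

    Returns ``(runs_msl, runs_ctl, group_pattern, region_mask, brain_mask)``.
    """
    rng = np.random.default_rng(seed)
    mask = default_brain_mask(grid_shape)
    c = grid_shape[0] // 2
    pattern = _box_pattern(grid_shape, c - 3, c + 3, mask, rng, "consolidated")
    region = np.zeros(grid_shape, dtype=bool)
    region[c - 1 : c + 2, c - 1 : c + 2, c - 1 : c + 2] = True
    region &= pattern.support
    modulated = SpatialPattern(
        pattern.data + delta * np.where(region, pattern.data, 0.0),
        pattern_id="consolidated",
    )
    runs_msl, runs_ctl = [], []
    for i in range(n_subjects):
        for cond, pat, bucket in (
            ("MSL", modulated, runs_msl),
            ("CTL", pattern, runs_ctl),
        ):
            spec = SimSpec(
                grid_shape=grid_shape,
                n_volumes=n_volumes,
                patterns=[pat],
                coupling=[
                    CouplingSchedule("consolidated", np.full(n_volumes, envelope))
                ],
                seed=int(rng.integers(2**31)),
            )
            bucket.append(
                simulate_run(spec, labels={"subject": f"sub{i:02d}",
                                           "condition": cond})
            )
    return runs_msl, runs_ctl, pattern, region, mask


def simulate_dynamics_pair(
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    n_volumes: int = 600,
    ramp: tuple[float, float] = (0.3, 1.2),
    ctl_level: float = 0.75,
    pattern_seed: int | None = None,
):
    """One MSL / CTL sleep-series pair for the sliding-window analyses.

    The consolidated pattern's co-activation envelope ramps up linearly over
    the MSL series (the gradual strengthening the dynamics analysis is meant
    to detect) and stays flat at ``ctl_level`` (the ramp midpoint) in CTL.

    Returns ``(runs_by_condition, consolidated_pattern)``.
    """
    rng = np.random.default_rng(seed)
    la, co = make_pattern_pair(
        grid_shape, overlap_fraction=0.5,
        seed=seed if pattern_seed is None else pattern_seed,
    )
    envs = {
        "MSL": np.linspace(ramp[0], ramp[1], n_volumes),
        "CTL": np.full(n_volumes, ctl_level),
    }
    runs = {}
    for cond, env in envs.items():
        spec = SimSpec(
            grid_shape=grid_shape,
            n_volumes=n_volumes,
            patterns=[la, co],
            coupling=[CouplingSchedule("consolidated", env)],
            seed=int(rng.integers(2**31)),
        )
        runs[cond] = simulate_run(spec, labels={"condition": cond})
    return runs, co
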