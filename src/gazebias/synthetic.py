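"""Synthetic two-AOI free-viewing gaze studies with known ground truth.

The generator emulates a paired emotional-image free-viewing experiment:
each trial shows a positive and a negative image side by side for 3000 ms
while gaze is sampled at 150 Hz.  Latent per-trial quantities (total dwell,
dwell split between the two areas of interest, first-look side, first-look
latency, blinks, track loss) are drawn from an explicit probabilistic model
so that every downstream preprocessing and inference stage can be tested
against exact bookkeeping.

Latent model per trial for subject i in group g:

* dwell bias   b = clamp(mu_nbi[g] + u_i + eps, -1, 1),  u_i ~ N(0, sigma_u^2),
  eps ~ N(0, sigma_trial^2); total in-AOI time T ~ N(dwell_total_mean,
  dwell_total_sd) truncated to the available window.  Dwell on the positive
  image is T(1+b)/2, on the negative image T(1-b)/2.
* first look   Bernoulli(logit^-1(eta_firstlook[g] + v_i)) for the positive
  side, v_i ~ N(0, sigma_v^2); latency ~ N(ttff_mean, ttff_sd) truncated
  positive.
* blinks       Poisson(blink_rate) per trial, durations uniform in
  blink_dur_range, embedded inside in-AOI fixation runs and annotated the
  way video-oculography exports annotate them (blink id + duration).
* track loss   with probability trackloss_prob[cohort] the whole trial is
  recorded as invalid samples, yielding zero dwell in both AOIs.

All durations are snapped to the 150 Hz sample grid, so the generator's
per-trial truth record matches what sample-level accumulation can recover
to machine precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError

SAMPLING_RATE_HZ = 150.0
SAMPLE_INTERVAL_MS = 1000.0 / SAMPLING_RATE_HZ
WINDOW_MS = 3000.0
N_SAMPLES_PER_TRIAL = int(round(WINDOW_MS / SAMPLE_INTERVAL_MS))  # 450

#: samples of saccade gap (recorded as signal loss) between the two AOI visits
GAP_SAMPLES = 3

COHORTS = ("child", "adolescent")
CONDITIONS = ("aggressive", "non_aggressive")
CELLS = tuple((g, c) for g in COHORTS for c in CONDITIONS)

SAMPLE_COLUMNS = [
    "participant_id",
    "trial_index",
    "time_ms",
    "x_px",
    "y_px",
    "valid",
    "fixation_id",
    "blink_id",
    "blink_duration_ms",
]


@dataclass(frozen=True)
class Participant:
    """One study participant with cohort and behavioral-condition labels."""

    id: str
    cohort: str
    condition: str

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ConfigurationError(f"unknown cohort {self.cohort!r}")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with half-open bounds [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ConfigurationError("degenerate rectangle")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass(frozen=True)
class TrialGeometry:
    """Screen layout of one trial: two lateral AOIs and the positive side."""

    screen_w: float = 1920.0
    screen_h: float = 1080.0
    left_rect: Rect = Rect(260.0, 290.0, 860.0, 790.0)
    right_rect: Rect = Rect(1060.0, 290.0, 1660.0, 790.0)
    positive_side: str = "left"

    def __post_init__(self) -> None:
        if self.positive_side not in ("left", "right"):
            raise ConfigurationError("positive_side must be 'left' or 'right'")
        if self.left_rect.overlaps(self.right_rect):
            raise ConfigurationError("AOI rectangles overlap")
        for r in (self.left_rect, self.right_rect):
            if not (0 <= r.x0 and r.x1 <= self.screen_w and 0 <= r.y0 and r.y1 <= self.screen_h):
                raise ConfigurationError("AOI rectangle outside the screen")

    def rect_for(self, valence: str) -> Rect:
        if valence == "positive":
            return self.left_rect if self.positive_side == "left" else self.right_rect
        return self.right_rect if self.positive_side == "left" else self.left_rect


@dataclass
class TrialRecording:
    """One trial's gaze-sample stream plus geometry and (optionally) truth."""

    participant_id: str
    trial_index: int
    geometry: TrialGeometry
    samples: pd.DataFrame
    truth: dict | None = None


def _cell_dict(values: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    missing = [c for c in CELLS if c not in values]
    if missing:
        raise ConfigurationError(f"missing cohort/condition cells: {missing}")
    return dict(values)


@dataclass
class GeneratingParameters:
    """Complete configuration of the synthetic study generator.

    ``mu_nbi`` and ``eta_firstlook`` are per-cell latent means keyed by
    (cohort, condition); ``trackloss_prob`` is keyed by cohort; counts in
    ``n_participants`` are keyed by (cohort, condition).
    """

    mu_nbi: dict[tuple[str, str], float]
    eta_firstlook: dict[tuple[str, str], float]
    sigma_u: float
    sigma_v: float
    sigma_trial: float
    dwell_total_mean: float
    dwell_total_sd: float
    ttff_mean: float  # seconds
    ttff_sd: float  # seconds
    blink_rate: float
    blink_dur_range: tuple[float, float]  # ms
    trackloss_prob: dict[str, float]
    n_participants: dict[tuple[str, str], int]
    n_trials: int
    seed: int
    geometry: TrialGeometry = field(default_factory=TrialGeometry)

    def __post_init__(self) -> None:
        self.mu_nbi = _cell_dict(self.mu_nbi)
        self.eta_firstlook = _cell_dict(self.eta_firstlook)
        self.n_participants = _cell_dict(self.n_participants)  # type: ignore[arg-type]
        self.validate()

    def validate(self) -> None:
        for cell, mu in self.mu_nbi.items():
            if not -1.0 < mu < 1.0:
                raise ConfigurationError(f"mu_nbi{cell} must lie in (-1, 1)")
        for sd_name in ("sigma_u", "sigma_v", "sigma_trial", "dwell_total_sd", "ttff_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigurationError(f"{sd_name} must be nonnegative")
        for g in COHORTS:
            p = self.trackloss_prob.get(g)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"trackloss_prob[{g}] must be in [0, 1]")
        for cell, n in self.n_participants.items():
            if n < 0:
                raise ConfigurationError(f"negative participant count in cell {cell}")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.blink_rate < 0:
            raise ConfigurationError("blink_rate must be nonnegative")
        lo, hi = self.blink_dur_range
        if not 0 < lo <= hi:
            raise ConfigurationError("blink_dur_range must satisfy 0 < lo <= hi")
        if self.dwell_total_mean <= 0:
            raise ConfigurationError("dwell_total_mean must be positive")

    def replace(self, **kwargs) -> "GeneratingParameters":
        return dataclasses.replace(self, **kwargs)

    # -- flat serialization (YAML/JSON friendly) ---------------------------

    def to_dict(self) -> dict:
        def nest(d):
            out: dict = {}
            for (g, c), v in d.items():
                out.setdefault(g, {})[c] = v
            return out

        return {
            "mu_nbi": nest(self.mu_nbi),
            "eta_firstlook": nest(self.eta_firstlook),
            "sigma_u": self.sigma_u,
            "sigma_v": self.sigma_v,
            "sigma_trial": self.sigma_trial,
            "dwell_total_mean": self.dwell_total_mean,
            "dwell_total_sd": self.dwell_total_sd,
            "ttff_mean": self.ttff_mean,
            "ttff_sd": self.ttff_sd,
            "blink_rate": self.blink_rate,
            "blink_dur_range": list(self.blink_dur_range),
            "trackloss_prob": dict(self.trackloss_prob),
            "n_participants": nest(self.n_participants),
            "n_trials": self.n_trials,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingParameters":
        def unnest(d2, cast=float):
            return {(g, c): cast(v) for g, sub in d2.items() for c, v in sub.items()}

        if "seed" not in d:
            raise ConfigurationError("seed is mandatory in generator configuration")
        return cls(
            mu_nbi=unnest(d["mu_nbi"]),
            eta_firstlook=unnest(d["eta_firstlook"]),
            sigma_u=float(d["sigma_u"]),
            sigma_v=float(d["sigma_v"]),
            sigma_trial=float(d["sigma_trial"]),
            dwell_total_mean=float(d["dwell_total_mean"]),
            dwell_total_sd=float(d["dwell_total_sd"]),
            ttff_mean=float(d["ttff_mean"]),
            ttff_sd=float(d["ttff_sd"]),
            blink_rate=float(d["blink_rate"]),
            blink_dur_range=tuple(float(x) for x in d["blink_dur_range"]),  # type: ignore[arg-type]
            trackloss_prob={g: float(v) for g, v in d["trackloss_prob"].items()},
            n_participants=unnest(d["n_participants"], cast=int),
            n_trials=int(d["n_trials"]),
            seed=int(d["seed"]),
        )


@dataclass
class GazeDataset:
    """A full synthetic study: roster, long sample table, and ground truth.

    ``samples`` is one long device-export-style frame (columns
    :data:`SAMPLE_COLUMNS`); ``geometry`` has one row per trial with the
    randomized positive side; ``trial_truth`` records the latent per-trial
    quantities actually realized on the sample grid.
    """

    roster: list[Participant]
    samples: pd.DataFrame
    geometry: pd.DataFrame
    truth: GeneratingParameters
    trial_truth: pd.DataFrame

    @property
    def n_recordings(self) -> int:
        return len(self.trial_truth)

    def roster_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.id for p in self.roster],
                "cohort": [p.cohort for p in self.roster],
                "condition": [p.condition for p in self.roster],
            }
        )

    def recordings(self) -> Iterator[TrialRecording]:
        """Yield per-trial views (small studies / inspection; not the fast path)."""
        truth_idx = self.trial_truth.set_index(["participant_id", "trial_index"])
        base = self.truth.geometry
        for (pid, trial), grp in self.samples.groupby(
            ["participant_id", "trial_index"], sort=False
        ):
            row = truth_idx.loc[(pid, trial)]
            geom = dataclasses.replace(base, positive_side=row["positive_side"])
            yield TrialRecording(
                participant_id=pid,
                trial_index=int(trial),
                geometry=geom,
                samples=grp.drop(columns=["participant_id", "trial_index"]).reset_index(
                    drop=True
                ),
                truth=row.to_dict(),
            )


def calibrated_params(seed: int = 0) -> GeneratingParameters:
    """Default configuration calibrated to the motivating study design.

    119 participants (60 children: 30 aggressive / 30 non-aggressive;
    59 adolescents: 29 aggressive / 30 non-aggressive), 16 trials each.
    Cell means of the latent dwell bias and of the logit-scale first-look
    propensity follow the reported fixed-effect structure (reference cell:
    aggressive adolescents); first-look latency averages 0.79 s, total
    in-AOI dwell averages about 2064 ms, and track loss concentrates in the
    child cohort (3.75% of trials vs 0.1% in adolescents).
    """
    mu = {
        ("adolescent", "aggressive"): -0.17,
        ("adolescent", "non_aggressive"): -0.17 + 0.16,
        ("child", "aggressive"): -0.17 + 0.05,
        ("child", "non_aggressive"): -0.17 + 0.16 + 0.05 - 0.03,
    }
    eta = {
        ("adolescent", "aggressive"): -0.37,
        ("adolescent", "non_aggressive"): -0.37 + 0.29,
        ("child", "aggressive"): -0.37 + 0.22,
        ("child", "non_aggressive"): -0.37 + 0.29 + 0.22 - 0.41,
    }
    return GeneratingParameters(
        mu_nbi=mu,
        eta_firstlook=eta,
        sigma_u=0.11,
        sigma_v=0.10,
        sigma_trial=0.36,
        dwell_total_mean=2064.0,
        dwell_total_sd=350.0,
        ttff_mean=0.79,
        ttff_sd=0.30,
        blink_rate=0.5,
        blink_dur_range=(100.0, 400.0),
        trackloss_prob={"child": 0.0375, "adolescent": 0.001},
        n_participants={
            ("child", "aggressive"): 30,
            ("child", "non_aggressive"): 30,
            ("adolescent", "aggressive"): 29,
            ("adolescent", "non_aggressive"): 30,
        },
        n_trials=16,
        seed=seed,
    )


def make_roster(params: GeneratingParameters) -> list[Participant]:
    """Build the participant roster with the configured cell counts."""
    roster: list[Participant] = []
    k = 0
    for cohort, condition in CELLS:
        n = params.n_participants[(cohort, condition)]
        if n < 0:
            raise ConfigurationError("negative cell count")
        for _ in range(n):
            k += 1
            roster.append(Participant(id=f"P{k:03d}", cohort=cohort, condition=condition))
    return roster


def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                           low: float = 0.0) -> float:
    # rejection sampling; the calibrated settings truncate far in the tail
    if sd == 0:
        return max(mean, np.nextafter(low, np.inf))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    return np.nextafter(low, np.inf)


def _embed_blinks(n_active: int, blink_samples: list[int], rng: np.random.Generator):
    """Interleave blink blocks into a fixation run of ``n_active`` samples.

    Each blink starts after at least one active sample so its onset can be
    attributed to the AOI.  Returns (is_blink, blink_local, onset) arrays of
    length n_active + sum(blink_samples).
    """
    if not blink_samples:
        z = np.zeros(n_active, dtype=bool)
        return z, np.full(n_active, -1), z
    positions = sorted(
        (int(rng.integers(1, n_active)), j) for j, _ in enumerate(blink_samples)
    )
    is_blink: list[bool] = []
    blink_local: list[int] = []
    onset: list[bool] = []
    pi = 0
    for a in range(n_active):
        is_blink.append(False)
        blink_local.append(-1)
        onset.append(False)
        while pi < len(positions) and positions[pi][0] == a + 1:
            j = positions[pi][1]
            nb = blink_samples[j]
            is_blink.extend([True] * nb)
            blink_local.extend([j] * nb)
            onset.extend([True] + [False] * (nb - 1))
            pi += 1
    return (
        np.asarray(is_blink, dtype=bool),
        np.asarray(blink_local),
        np.asarray(onset, dtype=bool),
    )


def _trial_arrays(
    participant: Participant,
    trial_index: int,
    params: GeneratingParameters,
    rng: np.random.Generator,
    u: float,
    v: float,
    blink_id_start: int = 1,
):
    """Simulate one trial; returns (sample column dict, truth dict).

    The sample dict holds length-450 arrays for every gaze column; the truth
    dict records the grid-snapped latent quantities.
    """
    cell = (participant.cohort, participant.condition)
    if cell not in params.mu_nbi:
        raise ConfigurationError(f"no generating parameters for cell {cell}")

    n = N_SAMPLES_PER_TRIAL
    dt = SAMPLE_INTERVAL_MS
    t = np.arange(n) * dt
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    fixation_id = np.full(n, np.nan)
    blink_id = np.full(n, np.nan)
    blink_dur = np.full(n, np.nan)

    positive_side = "left" if rng.random() < 0.5 else "right"
    geom = dataclasses.replace(params.geometry, positive_side=positive_side)

    truth = {
        "participant_id": participant.id,
        "trial_index": trial_index,
        "cohort": participant.cohort,
        "condition": participant.condition,
        "positive_side": positive_side,
        "trackloss": False,
        "b": np.nan,
        "first_look_drawn": np.nan,
        "first_look": np.nan,
        "dwell_pos_ms": 0.0,
        "dwell_neg_ms": 0.0,
        "ttff_pos_ms": np.nan,
        "ttff_neg_ms": np.nan,
        "blink_ms_pos": 0.0,
        "blink_ms_neg": 0.0,
        "n_blinks": 0,
    }

    if rng.random() < params.trackloss_prob[participant.cohort]:
        # whole-trial track loss: nothing but invalid samples
        truth["trackloss"] = True
        cols = {
            "time_ms": t, "x_px": x, "y_px": y, "valid": valid,
            "fixation_id": fixation_id, "blink_id": blink_id,
            "blink_duration_ms": blink_dur,
        }
        return cols, truth, geom

    first_pos = rng.random() < expit(params.eta_firstlook[cell] + v)
    ttff = _draw_truncated_normal(rng, params.ttff_mean * 1000.0, params.ttff_sd * 1000.0)
    b = float(np.clip(params.mu_nbi[cell] + u + rng.normal(0.0, params.sigma_trial), -1.0, 1.0))
    total = _draw_truncated_normal(rng, params.dwell_total_mean, params.dwell_total_sd)

    n_blinks = int(rng.poisson(params.blink_rate))
    lo, hi = params.blink_dur_range
    blink_samples = [
        max(1, int(round(rng.uniform(lo, hi) / dt))) for _ in range(n_blinks)
    ]

    k_first = int(np.clip(round(ttff / dt), 1, n - GAP_SAMPLES - 2))
    cap = n - k_first - GAP_SAMPLES - sum(blink_samples)
    if cap < 2:
        blink_samples = []
        cap = n - k_first - GAP_SAMPLES
    n_total = int(np.clip(round(min(total, cap * dt) / dt), 1, cap))
    n_pos = int(round(n_total * (1.0 + b) / 2.0))
    n_pos = min(max(n_pos, 0), n_total)
    n_neg = n_total - n_pos

    first_valence = "positive" if first_pos else "negative"
    second_valence = "negative" if first_pos else "positive"
    n_first = n_pos if first_pos else n_neg
    n_second = n_total - n_first
    if n_first == 0:
        # the drawn side received no dwell; the first actual fixation is on
        # the other side
        first_valence, second_valence = second_valence, first_valence
        n_first, n_second = n_second, n_first

    # blinks go into fixation runs, chosen with probability proportional to
    # run length; runs shorter than 2 samples cannot host a blink
    run_lens = [n_first, n_second]
    run_blinks: list[list[int]] = [[], []]
    hosts = [i for i, m in enumerate(run_lens) if m >= 2]
    for nb in blink_samples:
        if not hosts:
            break
        w = np.asarray([run_lens[i] for i in hosts], dtype=float)
        choice = hosts[int(rng.choice(len(hosts), p=w / w.sum()))]
        run_blinks[choice].append(nb)

    truth.update(
        b=b,
        first_look_drawn=float(first_pos),
        first_look=1.0 if first_valence == "positive" else 0.0,
        dwell_pos_ms=n_pos * dt,
        dwell_neg_ms=n_neg * dt,
        n_blinks=sum(len(r) for r in run_blinks),
    )

    def fill_center(idx0: int, idx1: int, fid: float) -> None:
        m = idx1 - idx0
        if m <= 0:
            return
        cx, cy = geom.screen_w / 2.0, geom.screen_h / 2.0
        x[idx0:idx1] = cx + rng.normal(0.0, 15.0, m)
        y[idx0:idx1] = cy + rng.normal(0.0, 15.0, m)
        valid[idx0:idx1] = True
        fixation_id[idx0:idx1] = fid

    def fill_run(idx0: int, valence: str, n_act: int, blinks: list[int],
                 fid0: float, bid0: int) -> tuple[int, float]:
        """Fill one AOI visit (active + embedded blink samples).

        The visit is split into several consecutive fixations (ids counting
        up from ``fid0``) of roughly 300 ms each, the way real viewers
        refixate within an image, so fixation counts grow with dwell time.
        Returns (next sample index, next fixation id).
        """
        if n_act == 0:
            return idx0, fid0
        is_b, local, onset = _embed_blinks(n_act, blinks, rng)
        m = len(is_b)
        rect = geom.rect_for(valence)
        cx, cy = rect.center
        xs = np.clip(cx + rng.normal(0.0, 30.0, m), rect.x0 + 1.0, rect.x1 - 1.0)
        ys = np.clip(cy + rng.normal(0.0, 30.0, m), rect.y0 + 1.0, rect.y1 - 1.0)
        sl = slice(idx0, idx0 + m)
        x[sl] = xs
        y[sl] = ys
        valid[sl] = True
        # consecutive ~300 ms fixation segments; a blink never splits one
        fid = fid0
        seg_start = 0
        while seg_start < m:
            seg_len = max(8, int(round(rng.normal(45.0, 15.0))))
            fixation_id[idx0 + seg_start: idx0 + min(seg_start + seg_len, m)] = fid
            seg_start += seg_len
            fid += 1.0
        if blinks:
            blink_id[sl] = np.where(is_b, bid0 + local, np.nan)
            dur = np.full(m, np.nan)
            dur[onset] = np.asarray(blinks, dtype=float) * dt
            blink_dur[sl] = dur
            key = "blink_ms_pos" if valence == "positive" else "blink_ms_neg"
            truth[key] = float(sum(blinks)) * dt
        return idx0 + m, fid

    fill_center(0, k_first, 0.0)
    truth["ttff_%s" % ("pos_ms" if first_valence == "positive" else "neg_ms")] = k_first * dt
    pos, fid = fill_run(k_first, first_valence, n_first, run_blinks[0], 1.0,
                        blink_id_start)
    if n_second > 0:
        pos += GAP_SAMPLES  # saccade modeled as signal loss
        truth["ttff_%s" % ("pos_ms" if second_valence == "positive" else "neg_ms")] = pos * dt
        pos, fid = fill_run(pos, second_valence, n_second, run_blinks[1], fid,
                            blink_id_start + len(run_blinks[0]))
    fill_center(pos, n, fid)

    cols = {
        "time_ms": t, "x_px": x, "y_px": y, "valid": valid,
        "fixation_id": fixation_id, "blink_id": blink_id,
        "blink_duration_ms": blink_dur,
    }
    return cols, truth, geom


def simulate_trial(
    participant: Participant,
    trial_index: int,
    params: GeneratingParameters,
    rng: np.random.Generator,
    u: float | None = None,
    v: float | None = None,
) -> TrialRecording:
    """Simulate a single trial recording.

    ``u`` and ``v`` are the participant's latent random intercepts on the
    dwell-bias and first-look scales; when omitted they are drawn fresh,
    which is appropriate only for one-off trials.
    """
    if u is None:
        u = float(rng.normal(0.0, params.sigma_u))
    if v is None:
        v = float(rng.normal(0.0, params.sigma_v))
    cols, truth, geom = _trial_arrays(participant, trial_index, params, rng, u, v)
    return TrialRecording(
        participant_id=participant.id,
        trial_index=trial_index,
        geometry=geom,
        samples=pd.DataFrame(cols),
        truth=truth,
    )


def simulate_study(params: GeneratingParameters) -> GazeDataset:
    """Simulate a complete study; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    roster = make_roster(params)
    u = rng.normal(0.0, params.sigma_u, len(roster))
    v = rng.normal(0.0, params.sigma_v, len(roster))

    chunks: list[dict] = []
    truths: list[dict] = []
    pid_col: list[str] = []
    trial_col: list[int] = []
    for i, p in enumerate(roster):
        for trial in range(1, params.n_trials + 1):
            cols, truth, _geom = _trial_arrays(p, trial, params, rng, u[i], v[i])
            chunks.append(cols)
            truths.append(truth)
            pid_col.append(p.id)
            trial_col.append(trial)

    n = N_SAMPLES_PER_TRIAL
    data = {
        "participant_id": np.repeat(np.asarray(pid_col, dtype=object), n),
        "trial_index": np.repeat(np.asarray(trial_col), n),
    }
    for key in ("time_ms", "x_px", "y_px", "valid", "fixation_id", "blink_id",
                "blink_duration_ms"):
        data[key] = np.concatenate([c[key] for c in chunks])
    samples = pd.DataFrame(data)

    trial_truth = pd.DataFrame(truths)
    geometry = _geometry_frame(params, trial_truth)
    return GazeDataset(
        roster=roster,
        samples=samples,
        geometry=geometry,
        truth=params,
        trial_truth=trial_truth,
    )


def _geometry_frame(params: GeneratingParameters, trial_truth: pd.DataFrame) -> pd.DataFrame:
    g = params.geometry
    out = trial_truth[["participant_id", "trial_index", "positive_side"]].copy()
    out["screen_w"] = g.screen_w
    out["screen_h"] = g.screen_h
    for name, r in (("left", g.left_rect), ("right", g.right_rect)):
        out[f"{name}_x0"] = r.x0
        out[f"{name}_y0"] = r.y0
        out[f"{name}_x1"] = r.x1
        out[f"{name}_y1"] = r.y1
    return out
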