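"""Synthetic lickometer experiments with known ground truth.

The generator emulates the structure of a handling-method sucrose study: a
two-group (tail vs tunnel handling) x two-concentration (4% vs 16% w/w)
counterbalanced crossover, five daily 15-minute sessions per phase, sixteen
mice per group housed two per cage, with consumption proportional to lick
count.

Licking is modelled as an alternating renewal process.  A drinking session
is a sequence of *clusters*: a cluster size K is drawn from a shifted
negative binomial (1 + NB, so every cluster has at least one lick — the
empirical cluster-size distributions of rodent licking are long-tailed,
which the NB reproduces), K licks are emitted at the ~8 Hz rodent lick
rhythm (inter-lick intervals ~ N(0.125 s, 0.02 s), truncated to stay below
the interbout threshold), then a pause drawn from shift + Exponential with
shift >= the threshold.  The construction therefore *inverts* interbout
segmentation by design: every generated pause splits, no within-cluster gap
ever does, so segmentation at the configured threshold recovers the
generator's clusters exactly.  All inter-event increments are quantized to
the 0.01 s lickometer resolution *before* cumulative summation so that grid
rounding can never flip a gap across the threshold.

Condition differences enter through two maps: the mean cluster size per
(handling, concentration) — the palatability/hedonic readout — and the
fraction of the session the animal spends drinking, which drives total lick
count and hence consumed mass.  Mice are individuals: lognormal per-subject
multipliers (mean 1) perturb both, with a separate subject-by-concentration
multiplier so the within-subject error stratum of the mixed ANOVA is
non-degenerate.

A single master seed expands into per-subject substreams
(`numpy.random.SeedSequence.spawn`), so enlarging the experiment never
perturbs existing subjects' data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io_medpc import ConsumptionRecord, LickTrain, SubjectRecord

Condition = tuple[str, float]  # (handling, concentration)

_CONDITIONS: tuple[Condition, ...] = (
    ("tail", 4.0), ("tunnel", 4.0), ("tail", 16.0), ("tunnel", 16.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic experiment generator.

    Defaults reproduce the study conditions of the assay this package
    analyses: 16 mice per handling group, two phases of five daily 900 s
    sessions, 0.01 s lickometer resolution, 250 ms interbout threshold.
    Per-lick volume (1.5 mg of solution per lick) and engagement fractions
    are documented placeholders — the real quantities are not published —
    chosen so session totals land in the realistic range of one to a few
    grams per 15-minute session.
    """

    n_per_group: int = 16
    sessions_per_phase: int = 5
    session_duration: float = 900.0
    interbout_interval: float = 0.25

    # within-cluster licking rhythm (~8 Hz)
    ili_mean: float = 0.125
    ili_sd: float = 0.02
    ili_min: float = 0.05

    # pauses between clusters: shift + exponential
    pause_shift: float = 0.25
    pause_mean: float = 2.0

    # condition structure
    cluster_size_mean: Mapping[Condition, float] = field(
        default_factory=lambda: {c: 18.0 for c in _CONDITIONS}
    )
    cluster_size_dispersion: float = 2.0
    drinking_fraction: Mapping[Condition, float] = field(
        default_factory=lambda: {c: 0.45 for c in _CONDITIONS}
    )

    # consumption model
    volume_per_lick: float = 0.0015   # grams of solution per lick
    consumption_noise_sd: float = 0.05  # grams, measurement noise

    # biological variability (sd of mean-one lognormal multipliers, log scale)
    subject_sd: float = 0.08          # stable appetite/palatability differences
    subject_conc_sd: float = 0.08     # subject x concentration idiosyncrasy
    engagement_subject_sd: float = 0.08
    session_sd: float = 0.10          # day-to-day engagement fluctuation

    body_weight_mean: float = 24.6    # grams, young adult C57BL/6J
    body_weight_sd: float = 2.0

    phase1_first_day: int = 22
    phase2_first_day: int = 29
    concentrations: tuple[float, float] = (4.0, 16.0)

    def validate(self) -> None:
        if self.pause_shift < self.interbout_interval:
            raise ValidationError(
                "pause_shift must be >= interbout_interval so every generated "
                "pause splits clusters"
            )
        if self.ili_mean >= self.interbout_interval:
            raise ValidationError(
                "mean inter-lick interval must be below the interbout threshold"
            )
        if self._ili_max() <= self.ili_min:
            raise ValidationError("inter-lick interval truncation window is empty")
        for cond in _CONDITIONS:
            if self.cluster_size_mean[cond] < 1:
                raise ValidationError(f"cluster size mean < 1 for {cond}")
            if not (0 < self.drinking_fraction[cond] <= 0.95):
                raise ValidationError(f"drinking fraction out of (0, 0.95] for {cond}")
        if self.n_per_group % 2:
            raise ValidationError("n_per_group must be even for counterbalancing")

    def _ili_max(self) -> float:
        # two ticks below the threshold: after 0.01 s quantization a
        # within-cluster gap can then never reach the threshold
        return self.interbout_interval - 0.02

    def equalized(self) -> "SimConfig":
        """Null variant: all condition means equalized (no group differences).

        Used for type-I-error calibration of the analysis battery.
        """
        mean_k = float(np.mean(list(self.cluster_size_mean.values())))
        mean_f = float(np.mean(list(self.drinking_fraction.values())))
        return dataclasses.replace(
            self,
            cluster_size_mean={c: mean_k for c in _CONDITIONS},
            drinking_fraction={c: mean_f for c in _CONDITIONS},
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cluster_size_mean"] = {f"{h}|{c:g}": v for (h, c), v in self.cluster_size_mean.items()}
        d["drinking_fraction"] = {f"{h}|{c:g}": v for (h, c), v in self.drinking_fraction.items()}
        return json.dumps(d, indent=2, sort_keys=True)


def handling_effect_preset() -> SimConfig:
    """Preset mirroring the qualitative effect pattern of the tail- vs
    tunnel-handling sucrose assay.

    * consumption higher at 16% than 4% in both groups;
    * tunnel-handled mice drink more at both concentrations, with parallel
      group differences (no handling x concentration interaction on
      consumption) and a ~27% deficit of tail- relative to tunnel-handled
      consumption at 4%;
    * lick cluster sizes larger at 16%;
    * a handling gap in cluster size at 4% only — cluster size saturates at
      the high concentration (ceiling), so the handling x concentration
      interaction is carried entirely by the 4% cells.

    Effect sizes were calibrated once against those qualitative constraints;
    see the methods note for the arithmetic.
    """
    return SimConfig(
        cluster_size_mean={
            ("tail", 4.0): 14.0,
            ("tunnel", 4.0): 20.0,
            ("tail", 16.0): 26.0,
            ("tunnel", 16.0): 27.0,
        },
        drinking_fraction={
            ("tail", 4.0): 0.35,
            ("tunnel", 4.0): 0.40,
            ("tail", 16.0): 0.50,
            ("tunnel", 16.0): 0.59,
        },
    )


@dataclass
class SyntheticExperiment:
    """A complete simulated experiment plus its ground truth."""

    subjects: list[SubjectRecord]
    trains: list[LickTrain]
    consumption: list[ConsumptionRecord]
    config: SimConfig
    ground_truth: dict


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_cluster_sizes(
    rng: np.random.Generator, mean: float, dispersion: float, n: int
) -> np.ndarray:
    """K = 1 + NB(r, p) with E[K] = mean, shape r = dispersion.

    ``dispersion = inf`` degenerates to a deterministic size round(mean)
    (the NB variance (mean-1)^2 / r vanishes), handy for exactness tests.
    """
    nb_mean = mean - 1.0
    if nb_mean <= 0:
        return np.ones(n, dtype=np.int64)
    if np.isinf(dispersion):
        return np.full(n, int(round(mean)), dtype=np.int64)
    p = dispersion / (dispersion + nb_mean)
    return 1 + rng.negative_binomial(dispersion, p, size=n)


def simulate_lick_train(
    config: SimConfig,
    condition: Condition,
    seed,
    subject_id: str = "sim",
    session_day: int = 0,
    cluster_mean: float | None = None,
    fraction: float | None = None,
) -> LickTrain:
    """Simulate one session's lick train for the given condition.

    ``cluster_mean`` and ``fraction`` override the condition maps (the
    experiment-level generator passes subject- and day-perturbed values).
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    config.validate()
    rng = _rng_from(seed)
    handling, conc = condition
    m = config.cluster_size_mean[(handling, float(conc))] if cluster_mean is None else cluster_mean
    m = max(m, 1.0)
    f = config.drinking_fraction[(handling, float(conc))] if fraction is None else fraction
    budget = min(f, 0.95) * config.session_duration

    cycle = m * config.ili_mean + config.pause_shift + config.pause_mean
    sizes = np.empty(0, dtype=np.int64)
    n_est = int(budget / cycle * 1.5) + 16
    # draw clusters in batches until the engaged-time budget is covered
    while True:
        sizes = np.concatenate(
            [sizes, _draw_cluster_sizes(rng, m, config.cluster_size_dispersion, n_est)]
        )
        total = int(sizes.sum())
        ili = rng.normal(config.ili_mean, config.ili_sd, total)
        ili = np.round(np.clip(ili, config.ili_min, config._ili_max()), 2)
        pauses = np.round(
            config.pause_shift + rng.exponential(config.pause_mean, sizes.size), 2
        )
        starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        incr = ili
        incr[starts] = pauses  # gap before each cluster's first lick
        ts = np.cumsum(incr)
        ends_t = ts[starts + sizes - 1]
        if ends_t[-1] > budget or budget <= 0:
            break
        n_est *= 2  # rare: budget not yet covered, redraw larger
        sizes = np.empty(0, dtype=np.int64)

    keep = np.searchsorted(ends_t, budget, side="right")
    if keep == 0:
        timestamps: tuple[float, ...] = ()
    else:
        last = starts[keep - 1] + sizes[keep - 1]
        timestamps = tuple(np.round(ts[:last], 2).tolist())
    return LickTrain(
        subject_id=subject_id,
        session_day=session_day,
        concentration=float(conc),
        timestamps=timestamps,
        session_duration=config.session_duration,
    )


def _mean_one_lognormal(rng: np.random.Generator, sd: float, size=None):
    """Lognormal multiplier with mean exactly 1 (mu = -sd^2/2)."""
    if sd == 0:
        return np.ones(size) if size else 1.0
    return rng.lognormal(-0.5 * sd * sd, sd, size)


def simulate_experiment(config: SimConfig, seed: int) -> SyntheticExperiment:
    """Simulate the full counterbalanced crossover experiment.

    2 handling groups x ``n_per_group`` mice x 2 concentrations x
    ``sessions_per_phase`` days.  Half of each handling group receives the
    low concentration in phase 1 and the high in phase 2, half the reverse.
    Consumed mass = total licks x ``volume_per_lick`` + Gaussian measurement
    noise, truncated at zero.  Every drawn subject-level parameter is logged
    in ``ground_truth``.
    """
    config.validate()
    low, high = config.concentrations

    subjects: list[SubjectRecord] = []
    trains: list[LickTrain] = []
    consumption: list[ConsumptionRecord] = []
    subject_log: dict[str, dict] = {}

    idx = 0
    for gi, handling in enumerate(("tail", "tunnel")):
        for j in range(config.n_per_group):
            sid = f"M{idx + 1:02d}"
            cage = f"C{idx // 2 + 1:02d}"  # two consecutive mice share a cage
            # substream keyed by (group, position): enlarging the experiment
            # never perturbs existing subjects' draws
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(gi, j))
            )
            weight = float(rng.normal(config.body_weight_mean, config.body_weight_sd))
            mult_k = float(_mean_one_lognormal(rng, config.subject_sd))
            mult_k_conc = {
                low: float(_mean_one_lognormal(rng, config.subject_conc_sd)),
                high: float(_mean_one_lognormal(rng, config.subject_conc_sd)),
            }
            mult_f = float(_mean_one_lognormal(rng, config.engagement_subject_sd))
            low_first = j % 2 == 0  # counterbalanced within handling group
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    cage_id=cage,
                    handling=handling,
                    body_weight=round(weight, 1),
                    testing_group=(idx // 2) % 4 + 1,
                )
            )
            subject_log[sid] = {
                "handling": handling,
                "low_first": low_first,
                "body_weight": round(weight, 1),
                "cluster_multiplier": mult_k,
                "cluster_multiplier_by_conc": {f"{k:g}": v for k, v in mult_k_conc.items()},
                "engagement_multiplier": mult_f,
            }

            for phase, first_day in (
                (1, config.phase1_first_day), (2, config.phase2_first_day),
            ):
                conc = (low if low_first else high) if phase == 1 else (high if low_first else low)
                base_m = config.cluster_size_mean[(handling, conc)]
                base_f = config.drinking_fraction[(handling, conc)]
                m_subj = 1.0 + (base_m - 1.0) * mult_k * mult_k_conc[conc]
                for s in range(config.sessions_per_phase):
                    day = first_day + s
                    f_day = base_f * mult_f * float(
                        _mean_one_lognormal(rng, config.session_sd)
                    )
                    train = simulate_lick_train(
                        config, (handling, conc), rng,
                        subject_id=sid, session_day=day,
                        cluster_mean=m_subj, fraction=min(f_day, 0.95),
                    )
                    trains.append(train)
                    mass = train.n_licks * config.volume_per_lick + rng.normal(
                        0.0, config.consumption_noise_sd
                    )
                    consumption.append(
                        ConsumptionRecord(
                            subject_id=sid,
                            session_day=day,
                            concentration=conc,
                            mass_consumed=max(0.0, float(mass)),
                        )
                    )
            idx += 1

    ground_truth = {
        "seed": seed,
        "config": json.loads(config.to_json()),
        "subjects": subject_log,
    }
    return SyntheticExperiment(
        subjects=subjects,
        trains=trains,
        consumption=consumption,
        config=config,
        ground_truth=ground_truth,
    )
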