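"""Per-animal sucrose consumption summaries.

Consumption (grams of solution drunk in a 15-min session) is the classic
anhedonia readout: a less hedonic animal drinks less.  The per-animal
summary is the unweighted mean of the daily consumed masses across the test
days at each concentration.  "Controlling for body weight" is offered two
ways: per-gram normalization (mass divided by body weight, the default) and
ANCOVA with weight as a covariate (via the stats engine); dividing by a
constant rescales the response, which leaves ANOVA F statistics unchanged
when all weights are equal — a property the tests exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_medpc import ConsumptionRecord, SubjectRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsumptionSummary:
    """Mean consumed mass per (subject, concentration), optionally per gram
    of body weight."""

    subject_id: str
    concentration: float
    mean_mass: float                      # grams
    n_sessions: int
    mean_mass_per_gram_bw: float | None = None  # grams per gram body weight

    def __post_init__(self):
        if self.mean_mass < 0:
            raise ValidationError(
                f"subject {self.subject_id}: mean mass must be >= 0"
            )


def mean_consumption(records: Iterable[ConsumptionRecord]) -> list[ConsumptionSummary]:
    """Unweighted mean of the daily consumed masses per (subject, concentration).

    A subject missing a day simply contributes a mean over the remaining days
    (with a log entry if fewer sessions than the modal count are present).
    A subject whose every mass is zero is flagged as a non-drinker in the log
    but still summarized: zero consumption is an observation.
    """
    rows = [
        {"subject_id": r.subject_id, "concentration": r.concentration,
         "mass": r.mass_consumed}
        for r in records
    ]
    if not rows:
        return []
    df = pd.DataFrame(rows)
    grouped = df.groupby(["subject_id", "concentration"])["mass"]
    agg = grouped.agg(["mean", "size"]).reset_index()
    modal_n = int(agg["size"].mode().max())  # largest modal count on ties
    out = []
    for row in agg.itertuples():
        if row.size < modal_n:
            logger.warning(
                "subject %s at %s%%: only %d of %d sessions present; mean over those",
                row.subject_id, row.concentration, row.size, modal_n,
            )
        if row.mean == 0:
            logger.warning("subject %s at %s%%: non-drinker (all masses zero)",
                           row.subject_id, row.concentration)
        out.append(
            ConsumptionSummary(
                subject_id=str(row.subject_id),
                concentration=float(row.concentration),
                mean_mass=float(row.mean),
                n_sessions=int(row.size),
            )
        )
    return out


def weight_adjusted(
    summaries: Sequence[ConsumptionSummary],
    subjects: Sequence[SubjectRecord],
) -> list[ConsumptionSummary]:
    """Divide each subject's mean mass by its body weight (g solution / g mouse).

    Subjects with missing or non-positive weight are excluded with a warning;
    the number excluded is logged so downstream group sizes are explicit.
    """
    weights = {s.subject_id: s.body_weight for s in subjects}
    out, excluded = [], 0
    for s in summaries:
        w = weights.get(s.subject_id)
        if w is None or w <= 0:
            excluded += 1
            logger.warning(
                "subject %s: body weight missing or non-positive; excluded from "
                "weight-adjusted consumption", s.subject_id,
            )
            continue
        out.append(
            ConsumptionSummary(
                subject_id=s.subject_id,
                concentration=s.concentration,
                mean_mass=s.mean_mass,
                n_sessions=s.n_sessions,
                mean_mass_per_gram_bw=s.mean_mass / w,
            )
        )
    if excluded:
        logger.warning("weight adjustment excluded %d summaries; n reported", excluded)
    return out


def weight_ancova_adjusted(
    summaries: Sequence[ConsumptionSummary],
    subjects: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Covariate-adjusted consumption: residualize mean mass on body weight.

    The alternative to per-gram normalization: within each concentration,
    mean mass is regressed on body weight (simple least squares) and the
    adjusted response is residual + concentration mean — i.e. consumption at
    the average body weight.  The mixed ANOVA can then run on
    ``adjusted_mass`` exactly as on the raw masses.  If weights carry no
    variance the regression is degenerate and the raw values are returned
    unchanged (a constant covariate adjusts nothing).
    """
    weights = {s.subject_id: s.body_weight for s in subjects}
    rows = []
    for s in summaries:
        w = weights.get(s.subject_id)
        if w is None or w <= 0:
            logger.warning("subject %s: no usable weight; excluded from ANCOVA",
                           s.subject_id)
            continue
        rows.append({"subject_id": s.subject_id, "concentration": s.concentration,
                     "mean_mass": s.mean_mass, "body_weight": w})
    df = pd.DataFrame(rows)
    out = []
    for _, sub in df.groupby("concentration"):
        x = sub["body_weight"].to_numpy(dtype=float)
        y = sub["mean_mass"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            adj = y
        else:
            slope, intercept = np.polyfit(x, y, 1)
            adj = y - (intercept + slope * x) + y.mean()
        out.append(sub.assign(adjusted_mass=adj))
    return pd.concat(out, ignore_index=True)


def consumption_frame(summaries: Iterable[ConsumptionSummary]) -> pd.DataFrame:
    """Tabulate summaries for the ANOVA path (long format)."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "concentration": s.concentration,
                "mean_mass": s.mean_mass,
                "mean_mass_per_gram_bw": s.mean_mass_per_gram_bw,
                "n_sessions": s.n_sessions,
            }
            for s in summaries
        ]
    )
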