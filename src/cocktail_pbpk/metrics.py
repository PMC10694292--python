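"""Summary PK metrics and predicted-vs-observed bookkeeping.

Covers the study's descriptive quantities: 0-2 h plasma AUC by linear
trapezoid, fractions of dose recovered in urine and bile, the two-fold
goodness-of-fit coverage, and group ratio-of-means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import DomainError
from .ode import TimeCourseSet

OBS_COLUMNS = ["subject_id", "group", "species", "kind", "time_min", "value", "below_loq"]
OBS_KINDS = ("plasma_conc", "urine_cumulative", "bile_cumulative")


class MetricError(ValueError):
    """A metric precondition (enough points, positivity) is violated."""


class PairingError(ValueError):
    """Observations could not be matched to simulated values."""


class ObservationSet:
    """Per-subject measured plasma / urine / bile values with group labels.

    Thin wrapper around a tidy DataFrame with columns
    ``subject_id, group, species, kind, time_min, value, below_loq``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(OBS_COLUMNS) - set(frame.columns)
        if missing:
            raise DomainError(f"observation table missing columns {sorted(missing)}")
        bad = set(frame["kind"].unique()) - set(OBS_KINDS)
        if bad:
            raise DomainError(f"unknown observation kinds {sorted(bad)}")
        if (frame["value"] < 0).any():
            raise DomainError("observation values must be >= 0")
        self.frame = frame.reset_index(drop=True)[OBS_COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, **criteria) -> "ObservationSet":
        f = self.frame
        for col, val in criteria.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            f = f[f[col].isin(vals)]
        return ObservationSet(f.reset_index(drop=True))

    def concat(self, other: "ObservationSet") -> "ObservationSet":
        return ObservationSet(pd.concat([self.frame, other.frame], ignore_index=True))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ObservationSet":
        return cls(pd.read_csv(path, sep="\t"))


def auc_trapezoid(times, conc, window: tuple[float, float] = (0.0, 120.0)) -> float:
    """Linear-trapezoid AUC over the points inside ``window``.

    No extrapolation beyond the first/last point inside the window;
    requires at least two points there.  Units: nmol*min/L.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise MetricError("times and conc must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise MetricError("times must be strictly increasing")
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise MetricError(f"need >= 2 points inside window {window}, got {int(mask.sum())}")
    return float(np.trapezoid(c[mask], t[mask]))


def fraction_dose_excreted(cumulative_amount: float, dose: float) -> tuple[float, bool]:
    """Fraction of the molar dose recovered in an excretion sink.

    Returns ``(fraction, violation_flag)``; fractions above 1 are
    reported but flagged as a molar-bookkeeping violation.
    """
    if dose <= 0:
        raise DomainError("dose must be > 0")
    if cumulative_amount < 0:
        raise DomainError("cumulative amount must be >= 0")
    frac = cumulative_amount / dose
    return frac, frac > 1.0


def twofold_fraction(pairs) -> float:
    """Percentage of (predicted, observed) pairs within the two-fold range.

    A pair counts as inside when predicted/2 <= observed <= 2*predicted;
    the boundary counts as inside.  Symmetric under swapping the roles of
    predicted and observed.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise MetricError("empty pair list")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise MetricError("pairs must be (predicted, observed) tuples")
    pred, obs = arr[:, 0], arr[:, 1]
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise DomainError("predicted and observed values must be > 0")
    inside = (obs >= pred / 2.0) & (obs <= 2.0 * pred)
    return 100.0 * float(inside.sum()) / len(arr)


def pair_pred_obs(tc: TimeCourseSet, obs: ObservationSet, time_tol: float = 1e-9) -> pd.DataFrame:
    """Match each observation to the simulated value of the same quantity.

    Plasma observations pair with the plasma concentration of the species
    at the same time; urine/bile observations pair with the cumulative
    sink amount.  Any unmatched observation is a pairing error.
    """
    misses = []
    rows = []
    species_known = set(tc.system.species)
    for rec in obs.frame.itertuples(index=False):
        if rec.species not in species_known:
            misses.append(f"{rec.species}@{rec.time_min} (unknown species)")
            continue
        ix = np.flatnonzero(np.abs(tc.times - rec.time_min) <= time_tol)
        if len(ix) == 0:
            misses.append(f"{rec.species}@{rec.time_min} (time not simulated)")
            continue
        i = int(ix[0])
        if rec.kind == "plasma_conc":
            pred = tc.concentration("plasma", rec.species)[i]
        elif rec.kind == "urine_cumulative":
            pred = tc.amount("urine", rec.species)[i]
        elif rec.kind == "bile_cumulative":
            pred = tc.amount("bile", rec.species)[i]
        else:  # pragma: no cover - kinds validated on construction
            misses.append(f"{rec.species}@{rec.time_min} (kind {rec.kind})")
            continue
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "species": rec.species,
                "kind": rec.kind,
                "time_min": rec.time_min,
                "predicted": float(pred),
                "observed": float(rec.value),
                "below_loq": bool(rec.below_loq),
            }
        )
    if misses:
        raise PairingError("unmatched observations: " + "; ".join(misses))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "species",
            "kind",
            "time_min",
            "predicted",
            "observed",
            "below_loq",
        ],
    )


def ratio_of_means(group_a, group_b) -> float:
    """mean(a) / mean(b); by convention a = cirrhosis, b = control."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    mb = float(b.mean())
    if mb == 0:
        raise DomainError("denominator group has zero mean")
    return float(a.mean()) / mb
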