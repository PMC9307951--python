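"""FRET flow-cytometry gating and the integrated FRET density seeding statistic.

Biosensor cells co-express the tau repeat domain fused to CFP and YFP;
aggregation seeded by exogenous tau brings the fluorophores close enough for
energy transfer, so seeding activity is read out per well as

    IFD = (percentage of FRET-positive cells) x (median FRET intensity of the
          FRET-positive cells)

i.e. ``100 * p * m``. The FRET-positive gate is anchored on an unseeded
control: the threshold is an upper order statistic of the control's FRET
channel (default 99.5th percentile), optionally combined with a CFP-positive
sub-gate. The median uses standard midpoint interpolation for even counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_GATE_QUANTILE = 0.995
DEFAULT_EVENTS_PER_REPLICATE = 20_000

_CHANNELS = ("cfp", "fret", "yfp")


@dataclass
class FlowEventTable:
    """Per-event channel intensities for one well.

    cfp: 405 nm ex / 405/50 em; fret: 405 nm ex / 525/50 em;
    yfp: 488 nm ex / 525/50 em. Arbitrary (post-compensation) units, >= 0.
    """

    events: pd.DataFrame
    well_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _CHANNELS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing channels: {missing}")
        if (self.events[list(_CHANNELS)].to_numpy() < 0).any():
            raise ValueError("channel intensities must be >= 0")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def fret(self) -> np.ndarray:
        return self.events["fret"].to_numpy(dtype=float)

    @property
    def cfp(self) -> np.ndarray:
        return self.events["cfp"].to_numpy(dtype=float)


@dataclass(frozen=True)
class GateSpec:
    """FRET-positivity gate: event is positive iff fret > fret_threshold
    (and cfp > cfp_threshold when a CFP sub-gate is set)."""

    fret_threshold: float
    quantile: float
    cfp_threshold: Optional[float] = None

    def positive_mask(self, table: FlowEventTable) -> np.ndarray:
        mask = table.fret > self.fret_threshold
        if self.cfp_threshold is not None:
            mask &= table.cfp > self.cfp_threshold
        return mask


@dataclass
class SeedingResult:
    """Per-well seeding readout."""

    well_id: str
    condition: str
    n_events: int
    fret_positive_fraction: float
    median_fret_positive: float
    ifd: float


def fit_gate(
    negative_control: FlowEventTable,
    quantile: float = DEFAULT_GATE_QUANTILE,
    cfp_quantile: Optional[float] = None,
) -> GateSpec:
    """Fit the FRET threshold as an order statistic of an unseeded control.

    The threshold is the ceil(quantile * n)-th order statistic (1-based,
    "lower" convention, no interpolation) of the control FRET channel, so at
    most ceil((1 - quantile) * n) control events lie strictly above it.
    ``cfp_quantile``, when given, sets an additional CFP-positive sub-gate the
    same way on the CFP channel (as a lower bound).
    """
    n = negative_control.n_events
    if n == 0:
        raise ValueError("empty negative control")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if n < 1000:
        import warnings

        warnings.warn(
            f"negative control has only {n} events (< 1000); gate may be unstable",
            stacklevel=2,
        )
    order = np.sort(negative_control.fret)
    threshold = float(order[math.ceil(quantile * n) - 1])
    cfp_threshold = None
    if cfp_quantile is not None:
        cfp_order = np.sort(negative_control.cfp)
        cfp_threshold = float(cfp_order[math.ceil(cfp_quantile * n) - 1])
    return GateSpec(fret_threshold=threshold, quantile=quantile, cfp_threshold=cfp_threshold)


def ifd(events: FlowEventTable, gate: GateSpec) -> SeedingResult:
    """Integrated FRET density for one well.

    p = positive fraction, m = median FRET intensity among positives
    (midpoint interpolation), IFD = 100 * p * m. With no positive events
    m is reported as 0 and IFD is exactly 0.
    """
    n = events.n_events
    if n == 0:
        raise ValueError(f"well {events.well_id!r} has zero events")
    mask = gate.positive_mask(events)
    n_pos = int(mask.sum())
    p = n_pos / n
    m = float(np.median(events.fret[mask])) if n_pos else 0.0
    return SeedingResult(
        well_id=events.well_id,
        condition=events.condition,
        n_events=n,
        fret_positive_fraction=p,
        median_fret_positive=m,
        ifd=100.0 * p * m,
    )


def aggregate_replicates(
    results: Sequence[SeedingResult],
    grouping: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Summarise technical replicates per group.

    ``grouping`` maps well_id -> group label; by default wells group by their
    condition label. Returns per-group mean, sample SD (ddof=1; 0 for a single
    replicate), n, and the member well ids.
    """
    if not results:
        raise ValueError("no results to aggregate")
    rows = []
    for res in results:
        group = grouping[res.well_id] if grouping is not None else res.condition
        rows.append({"group": group, "well_id": res.well_id, "ifd": res.ifd})
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby("group", sort=True)
        .agg(
            n=("ifd", "size"),
            mean_ifd=("ifd", "mean"),
            sd_ifd=("ifd", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
            wells=("well_id", lambda w: ";".join(sorted(w))),
        )
        .reset_index()
    )
    return out


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample two-tailed t test on per-replicate IFD values.

    Degenerate case: when both groups have zero variance the standard error is
    floored at 1e-12 x max(1, |mean|) so perfectly separated constant groups
    (e.g. (0,0,0) vs (10,10,10)) yield p ~ 0 instead of NaN, and identical
    constant groups yield t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if ma == mb:
            return 0.0, 1.0
        floor = 1e-12 * max(1.0, abs(ma), abs(mb))
        se2 = floor**2
        df = na + nb - 2  # Welch df is 0/0 here; fall back to pooled df
    else:
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (ma - mb) / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), min(p, 1.0)


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_event_table(
    path,
    well_id: str = "",
    condition: str = "",
    channel_map: Optional[Mapping[str, str]] = None,
) -> FlowEventTable:
    """Read one-row-per-event CSV; ``channel_map`` renames file columns to the
    cfp/fret/yfp roles (identity by default). ``#`` lines are comments."""
    frame = pd.read_csv(path, comment="#")
    if channel_map:
        frame = frame.rename(columns=dict(channel_map))
    return FlowEventTable(events=frame, well_id=well_id, condition=condition)


def results_to_frame(results: Sequence[SeedingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "condition": r.condition,
                "n_events": r.n_events,
                "fret_positive_fraction": r.fret_positive_fraction,
                "median_fret_positive": r.median_fret_positive,
                "ifd": r.ifd,
            }
            for r in results
        ]
    )
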