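"""Size-exclusion chromatography calibration and oligomer-order assignment.

SEC resolution is approximately log-linear in elution volume over a column's
resolving range, so molecular-weight standards are fit as

    log10(MW) = a + b * Ve        (b < 0: larger species elute earlier)

and a fraction's apparent MW follows by inversion. The oligomer order (n-mer)
is the nearest of the reported assembly bins {1, 2, 3, ~10, ~20} to
apparent_MW / monomer_MW in log space. Tau is intrinsically disordered and
elutes anomalously versus globular standards, so the monomer reference MW is a
configuration value (apparent, not formula, weight may be appropriate) and a
declarative fraction-letter lookup (B5/B7/B8/A7/A4 -> 1/2/3/~10/~20) is
provided to bypass calibration where fraction identities were validated
upstream.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: oligomer-order bins and their display labels
NMER_BINS: tuple[int, ...] = (1, 2, 3, 10, 20)
NMER_LABELS: dict[int, str] = {1: "1", 2: "2", 3: "3", 10: "~10", 20: "~20"}

#: validated fraction-letter identities (monomer .. ~20-mer)
FRACTION_NMER: dict[str, int] = {"B5": 1, "B7": 2, "B8": 3, "A7": 10, "A4": 20}

#: 2N4R tau formula weight, kDa (config default for the monomer reference)
DEFAULT_MONOMER_MW_KDA = 45.9


@dataclass(frozen=True)
class SECStandard:
    name: str
    molecular_weight_kda: float
    elution_volume_ml: float

    def __post_init__(self) -> None:
        if self.molecular_weight_kda <= 0:
            raise ValueError(f"standard {self.name!r}: MW must be > 0")


@dataclass
class SECCalibration:
    """log10(MW[kDa]) = intercept + slope * Ve[mL], least squares."""

    intercept: float
    slope: float
    residuals: np.ndarray
    volume_range: tuple[float, float]
    standards: list[SECStandard] = field(default_factory=list)

    def predict_mw(self, elution_volume_ml: float) -> float:
        return float(10.0 ** (self.intercept + self.slope * elution_volume_ml))

    def predict_volume(self, mw_kda: float) -> float:
        if mw_kda <= 0:
            raise ValueError("MW must be > 0")
        return float((math.log10(mw_kda) - self.intercept) / self.slope)

    def to_json(self, path=None, extra: Optional[dict] = None) -> str:
        payload = {
            "model": "log10(MW_kDa) = a + b * Ve_mL",
            "a": self.intercept,
            "b": self.slope,
            "residuals_log10": list(map(float, self.residuals)),
            "volume_range_ml": list(self.volume_range),
            "standards": [
                {
                    "name": s.name,
                    "molecular_weight_kda": s.molecular_weight_kda,
                    "elution_volume_ml": s.elution_volume_ml,
                }
                for s in self.standards
            ],
        }
        if extra:
            payload.update(extra)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class FractionAssignment:
    fraction_label: str
    elution_volume_ml: float
    estimated_mw_kda: float
    monomer_ratio: float
    n_mer: int
    n_mer_label: str
    extrapolated: bool


def fit_calibration(standards: Sequence[SECStandard]) -> SECCalibration:
    """Least-squares linear fit of log10(MW) on elution volume.

    Requires >= 3 standards. Standards whose MW does not decrease with
    increasing elution volume trigger a warning (fit proceeds); duplicate
    volumes with distinct MW simply show up as large residuals.
    """
    if len(standards) < 3:
        raise ValueError(f"need >= 3 standards, got {len(standards)}")
    ve = np.array([s.elution_volume_ml for s in standards], dtype=float)
    logmw = np.log10([s.molecular_weight_kda for s in standards])
    order = np.argsort(ve)
    if np.any(np.diff(logmw[order]) > 0):
        warnings.warn(
            "standards are not monotone (MW does not strictly decrease with "
            "elution volume); fitting anyway",
            stacklevel=2,
        )
    slope, intercept = np.polyfit(ve, logmw, 1)
    residuals = logmw - (intercept + slope * ve)
    return SECCalibration(
        intercept=float(intercept),
        slope=float(slope),
        residuals=residuals,
        volume_range=(float(ve.min()), float(ve.max())),
        standards=list(standards),
    )


def assign_nmer(
    cal: SECCalibration,
    elution_volume_ml: float,
    monomer_mw_kda: float = DEFAULT_MONOMER_MW_KDA,
    fraction_label: str = "",
    bins: Sequence[int] = NMER_BINS,
) -> FractionAssignment:
    """Assign an oligomer-order bin to one elution volume.

    The apparent MW comes from the calibration; the bin is the nearest of
    ``bins`` to apparent_MW / monomer_MW by |log| distance. Volumes outside
    the standards' range are flagged ``extrapolated``.
    """
    if monomer_mw_kda <= 0:
        raise ValueError("monomer_mw_kda must be > 0")
    mw = cal.predict_mw(elution_volume_ml)
    ratio = mw / monomer_mw_kda
    n_mer = min(bins, key=lambda k: abs(math.log(ratio / k)))
    lo, hi = cal.volume_range
    return FractionAssignment(
        fraction_label=fraction_label,
        elution_volume_ml=elution_volume_ml,
        estimated_mw_kda=mw,
        monomer_ratio=ratio,
        n_mer=int(n_mer),
        n_mer_label=NMER_LABELS.get(int(n_mer), str(n_mer)),
        extrapolated=not lo <= elution_volume_ml <= hi,
    )


def lookup_fraction_nmer(fraction_label: str) -> tuple[int, str]:
    """Validated fraction-letter identity, bypassing calibration."""
    try:
        n = FRACTION_NMER[fraction_label]
    except KeyError:
        raise KeyError(
            f"fraction {fraction_label!r} has no validated identity; known: "
            f"{sorted(FRACTION_NMER)}"
        ) from None
    return n, NMER_LABELS[n]


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_standards(path) -> list[SECStandard]:
    """CSV with columns name, molecular_weight_kda, elution_volume_ml."""
    frame = pd.read_csv(path, comment="#")
    return [
        SECStandard(
            name=str(row.name_),
            molecular_weight_kda=float(row.molecular_weight_kda),
            elution_volume_ml=float(row.elution_volume_ml),
        )
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def assignments_to_frame(assignments: Sequence[FractionAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fraction_label": a.fraction_label,
                "elution_volume_ml": a.elution_volume_ml,
                "estimated_mw_kda": a.estimated_mw_kda,
                "monomer_ratio": a.monomer_ratio,
                "n_mer": a.n_mer,
                "n_mer_label": a.n_mer_label,
                "extrapolated": a.extrapolated,
            }
            for a in assignments
        ]
    )
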