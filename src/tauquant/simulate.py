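"""Ground-truth-known synthetic data for every pipeline stage.

Three generators emulate the tabular evidence the analysis consumes — nothing
upstream of it (no spectra, no chromatograms, no cells):

* flow-cytometry event tables with a controllable FRET-positive fraction and
  log-normal channel intensities (20,000 events x 3 technical replicates by
  default, matching typical acquisition);
* peptide abundance tables drawn from the tryptic digest of a tau isoform
  with a known per-residue modification-frequency map, log-normal abundances,
  and decoy identifications whose q-values sit above the FDR cutoff;
* noisy log-linear SEC calibration standards plus fraction volumes placed at
  chosen monomer-MW multiples.

Every generator is a pure function of (params, seed): same inputs, identical
tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import sec as sec_mod
from .fret import FlowEventTable
from .isoforms import Isoform, IsoformRegistry, digest, load_default_registry
from .ptm import MOD_TYPES, VALID_TARGET_RESIDUES, PeptideRecord

# ---------------------------------------------------------------------------
# FRET biosensor events
# ---------------------------------------------------------------------------


@dataclass
class FlowSimParams:
    """Mixture of FRET-negative and FRET-positive event populations.

    Intensities are log-normal: the FRET channel of negatives has median
    ``neg_median`` (geometric) with log-sd ``neg_sigma``; positives have
    median ``pos_median``. CFP/YFP are drawn from the negative-like law for
    all events (they carry no class signal here). Defaults follow the
    acquisition convention of 20,000 events per replicate in technical
    triplicate.
    """

    true_positive_fraction: float
    n_events: int = 20_000
    replicates: int = 3
    neg_median: float = 50.0
    neg_sigma: float = 0.5
    pos_median: float = 500.0
    pos_sigma: float = 0.5
    condition: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_positive_fraction <= 1.0:
            raise ValueError("true_positive_fraction must be in [0, 1]")
        if self.n_events < 1 or self.replicates < 1:
            raise ValueError("n_events and replicates must be >= 1")
        # identifiability: positive median should clear the negatives' bulk
        neg_q995 = self.neg_median * math.exp(3.29 * self.neg_sigma)
        if 0 < self.true_positive_fraction and self.pos_median <= neg_q995:
            warnings.warn(
                "positive median does not exceed the negatives' 99.95% quantile; "
                "populations may be indistinguishable under a control-anchored gate",
                stacklevel=2,
            )


def simulate_flow(params: FlowSimParams) -> tuple[list[FlowEventTable], dict]:
    """Generate one event table per technical replicate plus the truth record."""
    rng = np.random.default_rng(params.seed)
    tables = []
    for rep in range(1, params.replicates + 1):
        n = params.n_events
        is_pos = rng.random(n) < params.true_positive_fraction
        fret = np.where(
            is_pos,
            rng.lognormal(math.log(params.pos_median), params.pos_sigma, n),
            rng.lognormal(math.log(params.neg_median), params.neg_sigma, n),
        )
        cfp = rng.lognormal(math.log(params.neg_median * 4), params.neg_sigma, n)
        yfp = rng.lognormal(math.log(params.neg_median * 4), params.neg_sigma, n)
        well = f"{params.condition or 'well'}_r{rep}"
        tables.append(
            FlowEventTable(
                events=pd.DataFrame({"cfp": cfp, "fret": fret, "yfp": yfp}),
                well_id=well,
                condition=params.condition,
            )
        )
    truth = {
        "true_positive_fraction": params.true_positive_fraction,
        "true_positive_median": params.pos_median,
        "true_negative_median": params.neg_median,
        "expected_ifd": 100.0 * params.true_positive_fraction * params.pos_median,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# Peptide abundance tables
# ---------------------------------------------------------------------------


@dataclass
class PTMSimParams:
    """Ground-truth PTM world for one sample.

    ``truth`` maps canonical position -> modification frequency in [0, 1] for
    ``mod_type``; sites must sit on chemically valid residues of the isoform.
    ``draws_per_site`` targeted covering draws are sampled per true site and
    ``background_depth`` draws per tryptic peptide give whole-sequence
    coverage. Every draw covering a true site is modified there with
    probability f*(r), so background coverage never biases the frequency.
    Abundances are log-normal (mu=10, sigma=1 on the natural-log scale, MS-like
    heavy tail). Decoys are real peptide sequences with q ~ U(0.05, 1);
    targets have q ~ U(0, 0.01).
    """

    mod_type: str = "phospho"
    truth: Mapping[int, float] = field(default_factory=dict)
    isoform_name: str = "2N4R"
    sample_id: str = "sample"
    draws_per_site: int = 500
    background_depth: int = 3
    abundance_mu: float = 10.0
    abundance_sigma: float = 1.0
    decoy_fraction: float = 0.1
    max_missed: int = 1
    min_len: int = 6
    max_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"unknown mod_type {self.mod_type!r}")
        for pos, f in self.truth.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"truth frequency at {pos} outside [0, 1]")


def _unique_location_peptides(iso: Isoform, peptides) -> list:
    """Drop peptides whose sequence occurs more than once in the isoform (the
    quantifier excludes them, so simulating them would distort coverage)."""
    return sorted(
        (p for p in peptides if iso.sequence.count(p.sequence) == 1),
        key=lambda p: (p.local_start, p.local_end),
    )


def simulate_peptides(
    params: PTMSimParams, registry: Optional[IsoformRegistry] = None
) -> tuple[list[PeptideRecord], dict]:
    """Generate a peptide abundance table plus its ground-truth record."""
    registry = registry or load_default_registry()
    iso = registry[params.isoform_name]
    valid = VALID_TARGET_RESIDUES[params.mod_type]

    local_truth: dict[int, float] = {}
    for canonical_pos, f in params.truth.items():
        local = iso.from_canonical(canonical_pos)
        if local is None:
            raise ValueError(
                f"canonical position {canonical_pos} is absent from isoform "
                f"{params.isoform_name}"
            )
        if iso.sequence[local - 1] not in valid:
            raise ValueError(
                f"truth site {canonical_pos} ({iso.sequence[local - 1]}) is not a "
                f"valid {params.mod_type} residue ({valid})"
            )
        local_truth[local] = f

    peptides = _unique_location_peptides(
        iso, digest(iso, params.max_missed, params.min_len, params.max_len)
    )
    rng = np.random.default_rng(params.seed)

    draws: list = []
    for site in sorted(local_truth):
        covering = [p for p in peptides if p.local_start <= site <= p.local_end]
        if not covering:
            raise ValueError(f"no unique tryptic peptide covers local site {site}")
        idx = rng.integers(0, len(covering), params.draws_per_site)
        draws.extend(covering[i] for i in idx)
    for pep in peptides:
        draws.extend([pep] * params.background_depth)

    records: list[PeptideRecord] = []
    for i, pep in enumerate(draws):
        mods = []
        for local_site, f in local_truth.items():
            if pep.local_start <= local_site <= pep.local_end and rng.random() < f:
                mods.append((local_site - pep.local_start + 1, params.mod_type))
        records.append(
            PeptideRecord(
                peptide_sequence=pep.sequence,
                isoform_name=params.isoform_name,
                local_start=pep.local_start,
                modifications=tuple(mods),
                abundance=float(
                    rng.lognormal(params.abundance_mu, params.abundance_sigma)
                ),
                q_value=float(rng.uniform(0.0, 0.01)),
                sample_id=params.sample_id,
            )
        )

    n_decoys = int(round(params.decoy_fraction * len(records)))
    if n_decoys and peptides:
        idx = rng.integers(0, len(peptides), n_decoys)
        for i in idx:
            pep = peptides[i]
            records.append(
                PeptideRecord(
                    peptide_sequence=pep.sequence,
                    isoform_name=params.isoform_name,
                    local_start=pep.local_start,
                    modifications=(),
                    abundance=float(
                        rng.lognormal(params.abundance_mu, params.abundance_sigma)
                    ),
                    q_value=float(rng.uniform(0.05, 1.0)),
                    sample_id=params.sample_id,
                )
            )

    truth = {
        "mod_type": params.mod_type,
        "isoform": params.isoform_name,
        "canonical_truth": dict(params.truth),
        "n_target_records": len(records) - n_decoys,
        "n_decoy_records": n_decoys,
    }
    return records, truth


# ---------------------------------------------------------------------------
# SEC standards and fractions
# ---------------------------------------------------------------------------

#: Bio-Rad gel-filtration standard mix (names, kDa)
DEFAULT_STANDARDS: tuple[tuple[str, float], ...] = (
    ("thyroglobulin", 670.0),
    ("gamma-globulin", 158.0),
    ("ovalbumin", 44.0),
    ("myoglobin", 17.0),
    ("vitamin-B12", 1.35),
)


@dataclass
class SECSimParams:
    """True calibration line log10(MW kDa) = a + b*Ve plus noisy standards.

    Defaults mimic a Superdex-200 10/300-class column. Fraction volumes are
    placed exactly at the line's volumes for ``multiples`` x ``monomer_mw_kda``
    and labelled with the validated fraction letters.
    """

    a: float = 4.85
    b: float = -0.225
    sigma_log10: float = 0.02
    standards: tuple[tuple[str, float], ...] = DEFAULT_STANDARDS
    monomer_mw_kda: float = sec_mod.DEFAULT_MONOMER_MW_KDA
    multiples: tuple[float, ...] = (1, 2, 3, 10, 20)
    fraction_labels: tuple[str, ...] = ("B5", "B7", "B8", "A7", "A4")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b >= 0:
            raise ValueError("slope b must be negative (larger species elute earlier)")
        if self.sigma_log10 < 0:
            raise ValueError("sigma_log10 must be >= 0")
        if len(self.multiples) != len(self.fraction_labels):
            raise ValueError("multiples and fraction_labels must align")


def simulate_sec(
    params: SECSimParams,
) -> tuple[list[sec_mod.SECStandard], pd.DataFrame, dict]:
    """Noisy standards on the true line, fraction volumes at MW multiples."""
    rng = np.random.default_rng(params.seed)
    standards = []
    for name, mw in params.standards:
        ve = (math.log10(mw) - params.a) / params.b
        noisy_logmw = math.log10(mw) + rng.normal(0.0, params.sigma_log10)
        standards.append(
            sec_mod.SECStandard(
                name=name,
                molecular_weight_kda=float(10.0 ** noisy_logmw),
                elution_volume_ml=float(ve),
            )
        )
    fractions = pd.DataFrame(
        {
            "fraction_label": params.fraction_labels,
            "elution_volume_ml": [
                (math.log10(k * params.monomer_mw_kda) - params.a) / params.b
                for k in params.multiples
            ],
            "true_multiple": params.multiples,
        }
    )
    truth = {
        "a": params.a,
        "b": params.b,
        "monomer_mw_kda": params.monomer_mw_kda,
        "multiples": list(params.multiples),
    }
    return standards, fractions, truth
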