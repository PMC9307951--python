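"""Per-residue posttranslational-modification frequency maps from peptide tables.

The statistic is the abundance-weighted site occupancy used in bottom-up
proteomics: for a canonical residue r and one modification type,

    f(r) = (sum of abundances of peptides carrying the modification at r)
         / (sum of abundances of ALL peptides whose span contains r)

The denominator deliberately includes peptides modified elsewhere — a peptide
contributes coverage at every residue it spans regardless of its modification
status at other sites. Positions with zero coverage are reported as missing
(NaN), never as 0: an unobserved residue and an observed-but-unmodified
residue are different findings.

Each modification type (phospho / acetyl / ubiquitin) is quantified in an
independent pass; their abundances never share a denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .isoforms import CANONICAL_LENGTH, IsoformRegistry

logger = logging.getLogger(__name__)

MOD_TYPES = ("phospho", "acetyl", "ubiquitin")

#: residues on which each modification type is chemically plausible
VALID_TARGET_RESIDUES: Mapping[str, str] = {
    "phospho": "STY",
    "acetyl": "K",
    "ubiquitin": "K",
}

DEFAULT_FDR_CUTOFF = 0.01


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide observation from an abundance table.

    ``modifications`` holds (peptide-local 1-based index, mod_type) pairs.
    """

    peptide_sequence: str
    isoform_name: str
    abundance: float
    q_value: float
    sample_id: str
    local_start: Optional[int] = None
    modifications: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError(f"abundance must be positive ({self!r})")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must be in [0, 1] ({self!r})")
        for idx, mod in self.modifications:
            if not 1 <= idx <= len(self.peptide_sequence):
                raise ValueError(
                    f"modification index {idx} outside peptide "
                    f"{self.peptide_sequence!r}"
                )
            if mod not in VALID_TARGET_RESIDUES:
                raise ValueError(f"unknown modification type {mod!r}")

    def validate_chemistry(self) -> None:
        """Raise if any modification sits on a chemically impossible residue."""
        for idx, mod in self.modifications:
            residue = self.peptide_sequence[idx - 1]
            if residue not in VALID_TARGET_RESIDUES[mod]:
                raise ValueError(
                    f"{mod} on {residue}{idx} of peptide "
                    f"{self.peptide_sequence!r} (sample {self.sample_id!r}) is "
                    f"chemically invalid; allowed residues: "
                    f"{VALID_TARGET_RESIDUES[mod]}"
                )


@dataclass
class ModFrequencyMap:
    """Per-canonical-position modification frequencies for one mod type.

    Arrays are indexed 0..length-1 for canonical positions 1..length.
    ``coverage`` and ``modified_abundance`` are abundance sums;
    ``mappable[r]`` is False where every contributing isoform lacks the
    canonical residue (spliced-out insert), distinguishing "absent" from
    "covered by no peptide".
    """

    mod_type: str
    length: int = CANONICAL_LENGTH
    coverage: np.ndarray = None  # type: ignore[assignment]
    modified_abundance: np.ndarray = None  # type: ignore[assignment]
    mappable: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.coverage is None:
            self.coverage = np.zeros(self.length)
        if self.modified_abundance is None:
            self.modified_abundance = np.zeros(self.length)
        if self.mappable is None:
            self.mappable = np.ones(self.length, dtype=bool)

    @property
    def frequency(self) -> np.ndarray:
        """f(r) where covered; NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.coverage > 0, self.modified_abundance / self.coverage, np.nan)
        return f

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0

    def frequency_at(self, canonical_pos: int) -> float:
        return float(self.frequency[canonical_pos - 1])

    def to_frame(self, canonical_sequence: Optional[str] = None) -> pd.DataFrame:
        """Long-format table over all canonical positions."""
        status = np.where(
            ~self.mappable, "absent", np.where(self.covered, "covered", "no_coverage")
        )
        data = {
            "canonical_position": np.arange(1, self.length + 1),
            "mod_type": self.mod_type,
            "frequency": self.frequency,
            "coverage_abundance": self.coverage,
            "modified_abundance": self.modified_abundance,
            "status": status,
        }
        frame = pd.DataFrame(data)
        if canonical_sequence is not None:
            frame.insert(1, "residue_letter", list(canonical_sequence[: self.length]))
        return frame


def fdr_filter(
    records: Sequence[PeptideRecord], cutoff: float = DEFAULT_FDR_CUTOFF
) -> list[PeptideRecord]:
    """Keep records with q_value <= cutoff, preserving order."""
    if not 0 < cutoff <= 1:
        raise ValueError("FDR cutoff must be in (0, 1]")
    return [rec for rec in records if rec.q_value <= cutoff]


def _locate(record: PeptideRecord, registry: IsoformRegistry) -> Optional[int]:
    """Resolve the record's local start; None when the peptide is ambiguous."""
    iso = registry[record.isoform_name]
    if record.local_start is not None:
        start = record.local_start
        end = start + len(record.peptide_sequence) - 1
        if iso.sequence[start - 1 : end] != record.peptide_sequence:
            raise ValueError(
                f"peptide {record.peptide_sequence!r} does not match isoform "
                f"{record.isoform_name} at position {start}"
            )
        return start
    hits = []
    pos = iso.sequence.find(record.peptide_sequence)
    while pos != -1:
        hits.append(pos + 1)
        pos = iso.sequence.find(record.peptide_sequence, pos + 1)
    if not hits:
        raise ValueError(
            f"peptide {record.peptide_sequence!r} not found in isoform "
            f"{record.isoform_name}"
        )
    if len(hits) > 1:
        logger.warning(
            "peptide %s maps to %d locations in %s; excluded from frequency computation",
            record.peptide_sequence, len(hits), record.isoform_name,
        )
        return None
    return hits[0]


def _aggregate_duplicates(records: Iterable[PeptideRecord]) -> list[PeptideRecord]:
    """Sum abundances of duplicate rows (same sequence, position, modification
    set, sample) — e.g. charge states reported separately."""
    merged: dict[tuple, PeptideRecord] = {}
    for rec in records:
        key = (
            rec.peptide_sequence,
            rec.isoform_name,
            rec.local_start,
            frozenset(rec.modifications),
            rec.sample_id,
        )
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                abundance=prev.abundance + rec.abundance,
                q_value=min(prev.q_value, rec.q_value),
            )
        else:
            merged[key] = rec
    return list(merged.values())


def site_frequencies(
    records: Sequence[PeptideRecord],
    mod_type: str,
    registry: IsoformRegistry,
) -> ModFrequencyMap:
    """Compute the per-canonical-residue frequency map for one modification type.

    Records are expected to be FDR-filtered already. Peptides whose sequence
    occurs at more than one location in their isoform are excluded (logged).
    Duplicate rows (charge states) are summed first. Records from shorter
    isoforms contribute nothing at canonical positions they do not encode;
    those positions are marked unmappable when no contributing isoform
    encodes them.
    """
    if mod_type not in MOD_TYPES:
        raise ValueError(f"unknown mod_type {mod_type!r}")
    fmap = ModFrequencyMap(mod_type=mod_type)

    isoform_names = {rec.isoform_name for rec in records}
    if isoform_names:
        mappable = np.zeros(fmap.length, dtype=bool)
        for name in isoform_names:
            for c in registry[name].mapped_canonical_positions():
                mappable[c - 1] = True
        fmap.mappable = mappable

    for rec in _aggregate_duplicates(records):
        rec.validate_chemistry()
        start = _locate(rec, registry)
        if start is None:
            continue
        iso = registry[rec.isoform_name]
        mod_offsets = {idx for idx, mod in rec.modifications if mod == mod_type}
        for offset in range(len(rec.peptide_sequence)):
            canonical = iso.to_canonical(start + offset)
            if canonical is None:
                continue
            fmap.coverage[canonical - 1] += rec.abundance
            if (offset + 1) in mod_offsets:
                fmap.modified_abundance[canonical - 1] += rec.abundance
    return fmap


def per_sample_maps(
    records: Sequence[PeptideRecord],
    mod_type: str,
    registry: IsoformRegistry,
) -> dict[str, ModFrequencyMap]:
    """One independent frequency map per sample_id."""
    samples = sorted({rec.sample_id for rec in records})
    if not samples:
        raise ValueError("no records / no sample ids")
    return {
        sample: site_frequencies(
            [rec for rec in records if rec.sample_id == sample], mod_type, registry
        )
        for sample in samples
    }


def compare_maps(map_a: ModFrequencyMap, map_b: ModFrequencyMap) -> pd.DataFrame:
    """Per-position frequency differences (b minus a) with coverage flags.

    Positions covered in only one map are flagged and get no delta.
    """
    if map_a.mod_type != map_b.mod_type:
        raise ValueError(
            f"cannot compare maps of different mod types "
            f"({map_a.mod_type!r} vs {map_b.mod_type!r})"
        )
    fa, fb = map_a.frequency, map_b.frequency
    both = map_a.covered & map_b.covered
    flag = np.select(
        [both, map_a.covered & ~map_b.covered, ~map_a.covered & map_b.covered],
        ["both", "a_only", "b_only"],
        default="neither",
    )
    delta = np.where(both, fb - fa, np.nan)
    return pd.DataFrame(
        {
            "canonical_position": np.arange(1, map_a.length + 1),
            "frequency_a": fa,
            "frequency_b": fb,
            "delta": delta,
            "flag": flag,
        }
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def parse_modification_string(text: str, peptide: str) -> tuple[tuple[int, str], ...]:
    """Parse the compact modification column, e.g. ``"S7:phospho;K12:ubiquitin"``.

    Indices are peptide-local and 1-based; the leading residue letter is
    checked against the peptide sequence.
    """
    text = (text or "").strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        token = token.strip()
        site, mod = token.split(":")
        letter, idx = site[0], int(site[1:])
        if not 1 <= idx <= len(peptide) or peptide[idx - 1] != letter:
            raise ValueError(
                f"modification token {token!r} inconsistent with peptide {peptide!r}"
            )
        mods.append((idx, mod))
    return tuple(mods)


def format_modification_string(
    modifications: Iterable[tuple[int, str]], peptide: str
) -> str:
    return ";".join(f"{peptide[idx - 1]}{idx}:{mod}" for idx, mod in sorted(modifications))


def read_peptide_table(path) -> list[PeptideRecord]:
    """Read a peptide abundance table (CSV/TSV; ``#`` lines are comments).

    Required columns: peptide_sequence, isoform, modifications, abundance,
    q_value, sample_id. Optional: local_start (inferred by exact match when
    absent).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, comment="#", dtype={"modifications": str})
    records = []
    for row in frame.itertuples(index=False):
        seq = row.peptide_sequence
        local_start = getattr(row, "local_start", None)
        if local_start is not None and pd.isna(local_start):
            local_start = None
        records.append(
            PeptideRecord(
                peptide_sequence=seq,
                isoform_name=row.isoform,
                local_start=None if local_start is None else int(local_start),
                modifications=parse_modification_string(
                    "" if pd.isna(row.modifications) else row.modifications, seq
                ),
                abundance=float(row.abundance),
                q_value=float(row.q_value),
                sample_id=str(row.sample_id),
            )
        )
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path, header: str = "") -> None:
    rows = [
        {
            "peptide_sequence": rec.peptide_sequence,
            "isoform": rec.isoform_name,
            "local_start": rec.local_start,
            "modifications": format_modification_string(
                rec.modifications, rec.peptide_sequence
            ),
            "abundance": rec.abundance,
            "q_value": rec.q_value,
            "sample_id": rec.sample_id,
        }
        for rec in records
    ]
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        pd.DataFrame(rows).to_csv(fh, index=False)


def maps_to_long_frame(
    maps: Mapping[str, ModFrequencyMap], canonical_sequence: str
) -> pd.DataFrame:
    """Stack per-sample maps into one long table (missing coverage stays NaN)."""
    parts = []
    for sample, fmap in maps.items():
        frame = fmap.to_frame(canonical_sequence)
        frame.insert(0, "sample_id", sample)
        parts.append(frame)
    return pd.concat(parts, ignore_index=True)


def maps_to_wide_frame(maps: Mapping[str, ModFrequencyMap]) -> pd.DataFrame:
    """Positions x samples frequency matrix; NaN marks no coverage / absent."""
    data = {sample: fmap.frequency for sample, fmap in maps.items()}
    index = pd.Index(
        np.arange(1, next(iter(maps.values())).length + 1), name="canonical_position"
    )
    return pd.DataFrame(data, index=index)
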