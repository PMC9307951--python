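"""Per-residue modification-frequency computation and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauquant.isoforms import CANONICAL_LENGTH, digest
from tauquant.ptm import (
    ModFrequencyMap,
    PeptideRecord,
    compare_maps,
    fdr_filter,
    format_modification_string,
    parse_modification_string,
    per_sample_maps,
    read_peptide_table,
    site_frequencies,
    write_peptide_table,
)
from tauquant.simulate import PTMSimParams, simulate_peptides


def make_record(seq="VAVVR", start=226, mods=(), abundance=100.0, q=0.001,
                sample="s1", isoform="2N4R"):
    return PeptideRecord(
        peptide_sequence=seq,
        isoform_name=isoform,
        local_start=start,
        modifications=tuple(mods),
        abundance=abundance,
        q_value=q,
        sample_id=sample,
    )


def brute_force_frequencies(records, mod_type, registry):
    """Independent per-residue loop: for every canonical residue, scan every
    record and ask whether its mapped span contains the residue."""
    coverage = np.zeros(CANONICAL_LENGTH)
    modified = np.zeros(CANONICAL_LENGTH)
    for rec in records:
        iso = registry[rec.isoform_name]
        start = rec.local_start
        end = start + len(rec.peptide_sequence) - 1
        for canonical in range(1, CANONICAL_LENGTH + 1):
            local = iso.from_canonical(canonical)
            if local is None or not start <= local <= end:
                continue
            coverage[canonical - 1] += rec.abundance
            if (local - start + 1, mod_type) in rec.modifications:
                modified[canonical - 1] += rec.abundance
    with np.errstate(invalid="ignore"):
        return coverage, modified, np.where(coverage > 0, modified / coverage, np.nan)


def random_table(rng, registry, n_records, mod_type="phospho"):
    """Random valid peptide table over unambiguous tryptic peptides."""
    valid = {"phospho": "STY", "acetyl": "K", "ubiquitin": "K"}[mod_type]
    records = []
    for _ in range(n_records):
        name = ["2N4R", "1N4R", "1N4R-P301S"][rng.integers(0, 3)]
        iso = registry[name]
        peps = sorted(
            (p for p in digest(iso, 1, 6, 30) if iso.sequence.count(p.sequence) == 1),
            key=lambda p: (p.local_start, p.local_end),
        )
        pep = peps[rng.integers(0, len(peps))]
        sites = [i + 1 for i, ch in enumerate(pep.sequence) if ch in valid]
        mods = tuple(
            (int(s), mod_type) for s in sites if sites and rng.random() < 0.4
        )
        records.append(
            make_record(
                seq=pep.sequence,
                start=pep.local_start,
                mods=mods,
                abundance=float(rng.lognormal(10, 1)),
                isoform=name,
            )
        )
    return records


class TestFdrFilter:
    def test_threshold_is_inclusive(self):
        records = [make_record(q=q) for q in (0.001, 0.009, 0.02)]
        kept = fdr_filter(records, 0.01)
        assert kept == records[:2]

    def test_empty_and_all_zero(self):
        assert fdr_filter([], 0.01) == []
        records = [make_record(q=0.0) for _ in range(3)]
        assert fdr_filter(records, 0.01) == records

    def test_order_preserved(self):
        records = [make_record(q=0.001, abundance=float(i + 1)) for i in range(5)]
        assert fdr_filter(records, 0.01) == records

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            fdr_filter([], 0.0)
        with pytest.raises(ValueError):
            fdr_filter([], 1.5)


class TestSiteFrequencies:
    def test_ratio_of_modified_to_total(self, registry):
        # 70 units unmodified + 30 units phosphorylated at T231 -> f = 0.30
        seq = "TPPKSPSSAK"  # canonical 231-240 in 2N4R
        unmod = make_record(seq=seq, start=231, abundance=70.0)
        mod = make_record(seq=seq, start=231, mods=[(1, "phospho")], abundance=30.0)
        fmap = site_frequencies([unmod, mod], "phospho", registry)
        assert fmap.frequency_at(231) == pytest.approx(0.30)
        # unmodified-only residues in the same peptides read 0, not missing
        assert fmap.frequency_at(235) == 0.0

    def test_uncovered_positions_are_missing_not_zero(self, registry):
        fmap = site_frequencies([make_record()], "phospho", registry)
        assert np.isnan(fmap.frequency_at(1))
        assert not fmap.covered[0]

    def test_single_fully_modified_peptide_reads_one(self, registry):
        # lone peptide carrying an acetyl mark: occupancy 1.0 at its site
        seq = "TPPKSPSSAK"
        rec = make_record(seq=seq, start=231, mods=[(4, "acetyl")], abundance=5.0)
        fmap = site_frequencies([rec], "acetyl", registry)
        assert fmap.frequency_at(234) == 1.0

    def test_modified_peptide_still_covers_other_sites(self, registry):
        """A peptide modified at site a joins the denominator at site b."""
        seq = "TPPKSPSSAK"  # canonical 231..240; T231 and S235 both inside
        mod_at_231 = make_record(seq=seq, start=231, mods=[(1, "phospho")], abundance=40.0)
        mod_at_235 = make_record(seq=seq, start=231, mods=[(5, "phospho")], abundance=60.0)
        fmap = site_frequencies([mod_at_231, mod_at_235], "phospho", registry)
        assert fmap.coverage[230] == pytest.approx(100.0)
        assert fmap.coverage[234] == pytest.approx(100.0)
        assert fmap.frequency_at(231) == pytest.approx(0.40)
        assert fmap.frequency_at(235) == pytest.approx(0.60)

    def test_chemically_invalid_modification_rejected(self, registry):
        rec = make_record(mods=[(1, "phospho")])
        with pytest.raises(ValueError, match="VAVVR"):
            site_frequencies([rec], "phospho", registry)

    def test_mismatched_local_start_rejected(self, registry):
        with pytest.raises(ValueError, match="does not match"):
            site_frequencies([make_record(seq="VAVVR", start=10)], "phospho", registry)

    def test_ambiguous_peptides_excluded(self, registry):
        # tau's repeat region contains recurring motifs; a peptide whose
        # sequence occurs at >1 location (no stated start) must be dropped
        seq2 = registry["2N4R"].sequence
        repeated = next(
            seq2[i : i + 6]
            for i in range(len(seq2) - 6)
            if seq2.count(seq2[i : i + 6]) > 1
        )
        amb = PeptideRecord(
            peptide_sequence=repeated,
            isoform_name="2N4R",
            local_start=None,
            modifications=(),
            abundance=10.0,
            q_value=0.001,
            sample_id="s1",
        )
        fmap = site_frequencies([amb], "phospho", registry)
        assert not fmap.covered.any()

    def test_duplicate_charge_state_rows_summed(self, registry):
        seq = "TPPKSPSSAK"
        a = make_record(seq=seq, start=231, mods=[(1, "phospho")], abundance=10.0)
        b = make_record(seq=seq, start=231, mods=[(1, "phospho")], abundance=20.0)
        c = make_record(seq=seq, start=231, abundance=70.0)
        fmap = site_frequencies([a, b, c], "phospho", registry)
        assert fmap.frequency_at(231) == pytest.approx(0.30)

    def test_shorter_isoform_contributes_nothing_in_its_gap(self, registry):
        iso = registry["1N4R"]
        gap = [c for c in range(1, 442) if iso.from_canonical(c) is None]
        # peptide spanning the splice junction of 1N4R
        junction = 73
        seq = iso.sequence[junction - 4 : junction + 4]
        rec = make_record(seq=seq, start=junction - 3, isoform="1N4R")
        fmap = site_frequencies([rec], "phospho", registry)
        assert all(fmap.coverage[c - 1] == 0 for c in gap)
        assert not fmap.mappable[gap[0] - 1]

    def test_matches_brute_force_oracle_on_random_tables(self, registry, rng):
        for _ in range(25):
            records = random_table(rng, registry, int(rng.integers(1, 21)))
            fmap = site_frequencies(records, "phospho", registry)
            cov, mod, freq = brute_force_frequencies(records, "phospho", registry)
            np.testing.assert_allclose(fmap.coverage, cov)
            np.testing.assert_allclose(fmap.modified_abundance, mod)
            np.testing.assert_allclose(fmap.frequency, freq, equal_nan=True)

    def test_abundance_scale_invariance(self, registry, rng):
        records = random_table(rng, registry, 15)
        scaled = [
            PeptideRecord(
                peptide_sequence=r.peptide_sequence,
                isoform_name=r.isoform_name,
                local_start=r.local_start,
                modifications=r.modifications,
                abundance=r.abundance * 37.5,
                q_value=r.q_value,
                sample_id=r.sample_id,
            )
            for r in records
        ]
        f1 = site_frequencies(records, "phospho", registry).frequency
        f2 = site_frequencies(scaled, "phospho", registry).frequency
        np.testing.assert_allclose(f1, f2, equal_nan=True)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(data=st.data())
    def test_frequencies_bounded(self, registry, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        records = random_table(rng, registry, int(rng.integers(1, 15)))
        f = site_frequencies(records, "phospho", registry).frequency
        covered = ~np.isnan(f)
        assert ((f[covered] >= 0) & (f[covered] <= 1)).all()


class TestPerSampleMaps:
    def test_disjoint_samples_independent(self, registry):
        seq = "TPPKSPSSAK"
        a = make_record(seq=seq, start=231, mods=[(1, "phospho")], sample="a")
        b = make_record(seq=seq, start=231, sample="b")
        maps = per_sample_maps([a, b], "phospho", registry)
        assert maps["a"].frequency_at(231) == 1.0
        assert maps["b"].frequency_at(231) == 0.0

    def test_lone_modified_peptide_reads_hundred_percent(self, registry):
        # one sample, one peptide, fully acetylated at its K — occupancy 1.0
        # (the single-observation caveat: coverage is one peptide species)
        seq = "IPAKTPPAPK"  # canonical 171-180
        rec = make_record(seq=seq, start=171, mods=[(4, "acetyl")], sample="w6")
        maps = per_sample_maps([rec], "acetyl", registry)
        assert maps["w6"].frequency_at(174) == 1.0
        assert maps["w6"].coverage[173] == rec.abundance

    def test_record_order_irrelevant(self, registry, rng):
        records = random_table(rng, registry, 12)
        maps1 = per_sample_maps(records, "phospho", registry)
        maps2 = per_sample_maps(records[::-1], "phospho", registry)
        for k in maps1:
            np.testing.assert_allclose(
                maps1[k].frequency, maps2[k].frequency, equal_nan=True
            )

    def test_empty_input_rejected(self, registry):
        with pytest.raises(ValueError):
            per_sample_maps([], "phospho", registry)


class TestCompareMaps:
    def test_identical_maps_give_zero_delta(self, registry, rng):
        records = random_table(rng, registry, 10)
        fmap = site_frequencies(records, "phospho", registry)
        diff = compare_maps(fmap, fmap)
        both = diff["flag"] == "both"
        assert both.any()
        assert (diff.loc[both, "delta"] == 0).all()

    def test_gain_of_modification_detected(self, registry):
        seq = "CGSKDNIK"  # canonical 291-298? ensure S262 region instead
        seq = "IGSTENLK"  # canonical 260-267 in 2N4R: S262 at offset 3
        a = make_record(seq=seq, start=260, abundance=100.0)
        b_un = make_record(seq=seq, start=260, abundance=80.0)
        b_mod = make_record(seq=seq, start=260, mods=[(3, "phospho")], abundance=20.0)
        map_a = site_frequencies([a], "phospho", registry)
        map_b = site_frequencies([b_un, b_mod], "phospho", registry)
        diff = compare_maps(map_a, map_b)
        row = diff[diff["canonical_position"] == 262].iloc[0]
        assert row["delta"] == pytest.approx(0.20)
        assert row["flag"] == "both"

    def test_one_sided_coverage_flagged(self, registry):
        a = make_record(seq="IGSTENLK", start=260)
        b = make_record(seq="TPPKSPSSAK", start=231)
        diff = compare_maps(
            site_frequencies([a], "phospho", registry),
            site_frequencies([b], "phospho", registry),
        )
        row = diff[diff["canonical_position"] == 262].iloc[0]
        assert row["flag"] == "a_only"
        assert np.isnan(row["delta"])

    def test_mod_type_mismatch_rejected(self, registry):
        a = site_frequencies([], "phospho", registry)
        b = site_frequencies([], "acetyl", registry)
        with pytest.raises(ValueError, match="mod type"):
            compare_maps(a, b)


class TestParameterRecovery:
    def test_recovery_from_synthetic_tables(self, registry):
        """MAE of the frequency estimate over seeded synthetic datasets < 0.05."""
        truth = {202: 0.3, 231: 0.65, 262: 0.2}
        errors = {pos: [] for pos in truth}
        for seed in range(1, 11):
            params = PTMSimParams(
                truth=truth, isoform_name="2N4R", draws_per_site=500,
                background_depth=0, seed=seed,
            )
            records, _ = simulate_peptides(params, registry)
            kept = fdr_filter(records, 0.01)
            fmap = site_frequencies(kept, "phospho", registry)
            for pos, f_true in truth.items():
                errors[pos].append(abs(fmap.frequency_at(pos) - f_true))
        for pos, errs in errors.items():
            assert np.mean(errs) < 0.05

    def test_moderate_sample_recovery(self, registry):
        """f* = 0.65 with 200 draws recovered within 3 weighted-binomial SE.

        Abundance weights are log-normal(sigma=1), so the estimator's SE is
        the binomial SE inflated by the design effect sqrt(sum w^2)*... the
        per-dataset band uses the realised weights.
        """
        params = PTMSimParams(
            truth={231: 0.65}, isoform_name="2N4R", draws_per_site=200,
            background_depth=0, seed=42,
        )
        records, _ = simulate_peptides(params, registry)
        fmap = site_frequencies(fdr_filter(records, 0.01), "phospho", registry)
        f_hat = fmap.frequency_at(231)
        # effective sample size from realised weights of covering records
        w = np.array(
            [r.abundance for r in fdr_filter(records, 0.01)
             if r.local_start <= 231 <= r.local_start + len(r.peptide_sequence) - 1]
        )
        n_eff = w.sum() ** 2 / (w**2).sum()
        se = np.sqrt(0.65 * 0.35 / n_eff)
        assert abs(f_hat - 0.65) < 3 * se


class TestCsvRoundTrip:
    def test_modification_string_round_trip(self):
        pep = "TPPKSPSSAK"
        mods = ((1, "phospho"), (4, "acetyl"))
        text = format_modification_string(mods, pep)
        assert text == "T1:phospho;K4:acetyl"
        assert parse_modification_string(text, pep) == mods
        assert parse_modification_string("", pep) == ()

    def test_inconsistent_token_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            parse_modification_string("S1:phospho", "TPPK")

    def test_table_round_trip(self, tmp_path, registry, rng):
        records = random_table(rng, registry, 8)
        path = tmp_path / "peptides.csv"
        write_peptide_table(records, path, header="# provenance line\n")
        back = read_peptide_table(path)
        assert len(back) == len(records)
        for got, want in zip(back, records):
            assert got.peptide_sequence == want.peptide_sequence
            assert got.isoform_name == want.isoform_name
            assert got.local_start == want.local_start
            assert got.modifications == want.modifications
            assert got.sample_id == want.sample_id
            assert got.abundance == pytest.approx(want.abundance)
            assert got.q_value == pytest.approx(want.q_value)
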