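"""IS curve fitting and the reads -> mass -> copies conversion."""
import numpy as np
import pytest

import spikequant as sq
from spikequant.errors import FitError, QuantError, ValidationError


def _is_counts(default_panel, level_reads, extra=()):
    """Count table with the given reads per gradient level (split evenly
    over the level's molecules) plus optional extra rows."""
    rows = []
    for m in default_panel.molecules:
        rows.append((m.id, "is", level_reads[m.gradient_level - 1] / 3))
    rows.extend(extra)
    return sq.ReadCountTable.from_rows(rows)


def test_dnac_constant_value():
    # 650 g/mol/bp over Avogadro's number, expressed in ng
    assert sq.NG_PER_BP_DSDNA == pytest.approx(1.0794e-12, rel=1e-4)


# ---------------------------------------------------------------------------
# IS observations
# ---------------------------------------------------------------------------

def test_cis_ladder_at_default_volume(default_panel):
    counts = _is_counts(default_panel, [3000, 300, 30, 3, 1])
    obs = sq.is_observations(counts, default_panel, spike_volume_ul=2.0)
    assert [o.cis_ng for o in obs] == pytest.approx([1.2, 0.12, 0.012, 1.2e-3, 1.2e-4])
    assert [o.ris for o in obs] == pytest.approx([3000, 300, 30, 3, 1])


def test_doubling_volume_doubles_cis_only(default_panel):
    counts = _is_counts(default_panel, [3000, 300, 30, 3, 1])
    obs2 = sq.is_observations(counts, default_panel, spike_volume_ul=2.0)
    obs4 = sq.is_observations(counts, default_panel, spike_volume_ul=4.0)
    for a, b in zip(obs2, obs4):
        assert b.cis_ng == pytest.approx(2 * a.cis_ng)
        assert b.ris == a.ris


def test_pool_convention_divides_cis_by_molecule_count(default_panel):
    counts = _is_counts(default_panel, [3000, 300, 30, 3, 1])
    per = sq.is_observations(counts, default_panel, convention="per_molecule")
    pool = sq.is_observations(counts, default_panel, convention="pool")
    for a, b in zip(per, pool):
        assert a.cis_ng == pytest.approx(3 * b.cis_ng)


def test_missing_molecule_rows_error(default_panel):
    counts = sq.ReadCountTable.from_rows([("IS_01", "is", 10.0)])
    with pytest.raises(ValidationError, match="IS_02"):
        sq.is_observations(counts, default_panel)


def test_zero_read_observations_allowed_but_unfittable(default_panel):
    counts = _is_counts(default_panel, [0, 0, 0, 0, 0])
    obs = sq.is_observations(counts, default_panel)
    assert all(o.ris == 0 for o in obs)
    with pytest.raises(FitError):
        sq.fit_is_curve(obs)


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

def test_proportional_reads_fit_slope_one(default_panel):
    # R_is exactly proportional to C_is over the 5 levels
    counts = _is_counts(default_panel, [120000, 12000, 1200, 120, 12])
    obs = sq.is_observations(counts, default_panel)
    fit = sq.fit_is_curve(obs)
    assert fit.slope == pytest.approx(1.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.n_points_used == 5 and fit.dropped_levels == ()


def test_constant_reads_are_degenerate(default_panel):
    counts = _is_counts(default_panel, [300, 300, 300, 300, 300])
    obs = sq.is_observations(counts, default_panel)
    with pytest.raises(FitError, match="degenerate"):
        sq.fit_is_curve(obs)


def test_zero_read_levels_dropped_with_record(default_panel):
    counts = _is_counts(default_panel, [120000, 12000, 1200, 0, 0])
    fit = sq.fit_is_curve(sq.is_observations(counts, default_panel))
    assert fit.n_points_used == 3
    assert set(fit.dropped_levels) == {4, 5}
    assert fit.slope == pytest.approx(1.0, abs=1e-12)


def test_single_usable_level_fails(default_panel):
    counts = _is_counts(default_panel, [120000, 0, 0, 0, 0])
    with pytest.raises(FitError, match=">= 2"):
        sq.fit_is_curve(sq.is_observations(counts, default_panel))


# ---------------------------------------------------------------------------
# Mass and copies
# ---------------------------------------------------------------------------

def test_mass_inversion_identity_on_gradient_point(default_panel):
    counts = _is_counts(default_panel, [120000, 12000, 1200, 120, 12])
    obs = sq.is_observations(counts, default_panel)
    fit = sq.fit_is_curve(obs)
    for o in obs:
        assert sq.mass_from_reads(o.ris, fit=fit) == pytest.approx(o.cis_ng, rel=1e-9)
        # curve and ratio mode coincide under a perfect slope-1 fit
        assert sq.mass_from_reads(o.ris, mode="ratio", observations=obs) == pytest.approx(
            o.cis_ng, rel=1e-9
        )


def test_zero_reads_zero_mass():
    assert sq.mass_from_reads(0.0, fit=None, mode="curve") == 0.0


def test_nonpositive_slope_rejected():
    bad = sq.RegressionFit(slope=-0.5, intercept=1.0, r_squared=0.9,
                           fit_space="log10", n_points_used=5)
    with pytest.raises(QuantError):
        sq.mass_from_reads(10.0, fit=bad)


def test_copies_from_mass_unit_factor():
    # 5.397e-6 ng over a 5 Mbp genome is almost exactly one genome copy
    assert sq.copies_from_mass(5.397e-6, 5e6) == pytest.approx(1.0, rel=1e-3)
    assert sq.copies_from_mass(0.0, 5e6) == 0.0
    assert sq.copies_from_mass(1.0, 2e6) == pytest.approx(2 * sq.copies_from_mass(1.0, 4e6))
    with pytest.raises(ValidationError):
        sq.copies_from_mass(1.0, 0.0)


# ---------------------------------------------------------------------------
# Sample-level quantification
# ---------------------------------------------------------------------------

def test_noiseless_round_trip_recovers_truth(default_panel, mock10):
    counts = sq.simulate_counts(mock10, sq.SequencingRun(20_000_000, seed=0), mode="expected")
    result = sq.quantify_sample(counts, default_panel, mock10.genome_lengths())
    true = mock10.true_copies()
    for q in result.quants:
        assert q.copies == pytest.approx(true[q.taxon_id], rel=1e-9)


def test_round_trip_is_depth_invariant(default_panel, mock10):
    lengths = mock10.genome_lengths()
    by_depth = []
    for depth in (1_000_000, 50_000_000):
        counts = sq.simulate_counts(mock10, sq.SequencingRun(depth, seed=0), mode="expected")
        result = sq.quantify_sample(counts, default_panel, lengths)
        by_depth.append(result.copies_by_taxon())
    for taxon in by_depth[0]:
        assert by_depth[0][taxon] == pytest.approx(by_depth[1][taxon], rel=1e-9)


def test_is_recovery_loss_inflates_copies_by_its_inverse(default_panel):
    """IS recovered at efficiency e while microbes recover fully makes every
    microbial estimate exactly 1/e too high."""
    taxa = [sq.TaxonProfile.from_copies("t1", 5e6, 1e4)]
    base = sq.SampleComposition(panel=default_panel, host_mass_ng=5.0, taxa=taxa)
    lossy = sq.SampleComposition(panel=default_panel, host_mass_ng=5.0, taxa=taxa,
                                 recovery_efficiency={"is": 0.5})
    run = sq.SequencingRun(5_000_000, seed=0)
    lengths = {"t1": 5e6}
    ref = sq.quantify_sample(sq.simulate_counts(base, run, "expected"),
                             default_panel, lengths).copies_by_taxon()["t1"]
    est = sq.quantify_sample(sq.simulate_counts(lossy, run, "expected"),
                             default_panel, lengths).copies_by_taxon()["t1"]
    assert est == pytest.approx(ref / 0.5, rel=1e-9)


def test_pool_convention_shifts_estimates_by_molecule_count(default_panel, mock10):
    counts = sq.simulate_counts(mock10, sq.SequencingRun(20_000_000, seed=0), mode="expected")
    lengths = mock10.genome_lengths()
    per = sq.quantify_sample(counts, default_panel, lengths, convention="per_molecule")
    pool = sq.quantify_sample(counts, default_panel, lengths, convention="pool")
    true = mock10.true_copies()
    for q in pool.quants:
        assert q.copies == pytest.approx(true[q.taxon_id] / 3, rel=1e-9)
    for q in per.quants:
        assert q.copies == pytest.approx(true[q.taxon_id], rel=1e-9)


def test_low_evidence_flag_and_missing_length(default_panel):
    rows = [(m.id, "is", [12000, 1200, 120, 12, 1.2][m.gradient_level - 1] / 3)
            for m in default_panel.molecules]
    rows += [("rare", "taxon", 2.0), ("common", "taxon", 5000.0)]
    counts = sq.ReadCountTable.from_rows(rows)
    result = sq.quantify_sample(counts, default_panel, {"rare": 1e6})
    by_id = {q.taxon_id: q for q in result.quants}
    assert "low_evidence" in by_id["rare"].flags
    assert "low_evidence" not in by_id["common"].flags
    assert "missing_genome_length" in by_id["common"].flags
    assert np.isnan(by_id["common"].copies)
    assert result.errors == {"common": "missing genome length"}
    # the valid taxon is still quantified
    assert by_id["rare"].copies > 0


def test_no_microbial_rows_yields_empty_quants(default_panel):
    counts = _is_counts(default_panel, [12000, 1200, 120, 12, 3],
                        extra=[("host", "host", 50000.0)])
    result = sq.quantify_sample(counts, default_panel, {})
    assert result.quants == []
    assert result.fit.n_points_used == 5


def test_quant_report_roundtrip(tmp_path, default_panel, mock10):
    counts = sq.simulate_counts(mock10, sq.SequencingRun(1_000_000, seed=0), mode="expected")
    result = sq.quantify_sample(counts, default_panel, mock10.genome_lengths())
    report = tmp_path / "report.tsv"
    fit_json = tmp_path / "fit.json"
    result.write(report, fit_json)
    assert report.exists() and fit_json.exists()
    frame = result.to_frame()
    assert list(frame.columns) == ["taxon_id", "reads", "mass_ng", "genome_length_bp",
                                   "copies", "flags"]
    assert len(frame) == 10
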