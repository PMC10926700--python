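"""Simulator: mass fractions, count sampling, read generation, presets."""
import numpy as np
import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator

import spikequant as sq
from spikequant.errors import ValidationError
from spikequant.panel import random_dna
from spikequant.simulate import largest_remainder_round

DNAC = sq.NG_PER_BP_DSDNA


def _taxon(name, length_bp, mass_ng):
    return sq.TaxonProfile.from_mass(name, length_bp, mass_ng)


# ---------------------------------------------------------------------------
# Mass fractions
# ---------------------------------------------------------------------------

def test_mass_fractions_direct_ratio():
    comp = sq.SampleComposition(panel=None, host_mass_ng=9.0, taxa=[_taxon("t1", 5e6, 1.0)])
    fractions = sq.expected_mass_fractions(comp)
    assert fractions == pytest.approx({"host": 0.9, "t1": 0.1})


def test_is_molecule_masses_at_2ul(default_panel):
    comp = sq.SampleComposition(panel=default_panel, is_spike_volume_ul=2.0)
    table = comp.mass_table()
    per_level = {
        level: sorted(
            table.loc[table["category"] == m.id, "mass_ng"].iloc[0]
            for m in default_panel.level_molecules(level)
        )
        for level in range(1, 6)
    }
    expected = [0.4, 0.04, 0.004, 4e-4, 4e-5]
    for level, mass in enumerate(expected, start=1):
        assert per_level[level] == pytest.approx([mass] * 3)


def test_recovery_efficiency_renormalizes_like_brute_force(default_panel):
    comp = sq.SampleComposition(
        panel=default_panel,
        host_mass_ng=5.0,
        taxa=[_taxon("t1", 5e6, 1.0)],
        recovery_efficiency={"is": 0.5},
    )
    fractions = sq.expected_mass_fractions(comp)
    # brute-force renormalization oracle
    masses = {"host": 5.0, "t1": 1.0}
    for m in default_panel.molecules:
        masses[m.id] = 0.5 * m.concentration * 2.0
    total = sum(masses.values())
    for category, expected in masses.items():
        assert fractions[category] == pytest.approx(expected / total)
    # IS fractions drop, everything else rises, vs the e=1 composition
    full = sq.expected_mass_fractions(
        sq.SampleComposition(panel=default_panel, host_mass_ng=5.0, taxa=[_taxon("t1", 5e6, 1.0)])
    )
    assert fractions["host"] > full["host"]
    assert all(fractions[m.id] < full[m.id] for m in default_panel.molecules)


def test_all_zero_mass_errors():
    comp = sq.SampleComposition(panel=None, host_mass_ng=0.0)
    with pytest.raises(ValidationError):
        sq.expected_mass_fractions(comp)


def test_fraction_scale_invariance(default_panel):
    base = sq.SampleComposition(
        panel=default_panel, host_mass_ng=2.0, taxa=[_taxon("t1", 5e6, 0.5)],
        is_spike_volume_ul=2.0,
    )
    scaled = sq.SampleComposition(
        panel=default_panel, host_mass_ng=6.0, taxa=[_taxon("t1", 5e6, 1.5)],
        is_spike_volume_ul=6.0,
    )
    a, b = sq.expected_mass_fractions(base), sq.expected_mass_fractions(scaled)
    assert a.keys() == b.keys()
    for key in a:
        assert a[key] == pytest.approx(b[key])


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------

def test_expected_mode_is_exact(mock10):
    run = sq.SequencingRun(total_reads=1_000_000, seed=0)
    counts = sq.simulate_counts(mock10, run, mode="expected")
    fractions = sq.expected_mass_fractions(mock10)
    for category, fraction in fractions.items():
        assert counts.reads_for(category) == pytest.approx(1_000_000 * fraction, rel=1e-12)
    assert counts.total_reads == pytest.approx(1_000_000)


def test_expected_rounded_mode_conserves_total(mock10):
    run = sq.SequencingRun(total_reads=999_983, seed=0)
    counts = sq.simulate_counts(mock10, run, mode="expected_rounded")
    assert counts.total_reads == 999_983
    fractions = sq.expected_mass_fractions(mock10)
    for category, fraction in fractions.items():
        assert abs(counts.reads_for(category) - 999_983 * fraction) < 1.0


def test_largest_remainder_rounding_properties(rng):
    for _ in range(20):
        weights = rng.random(8)
        total = int(rng.integers(1, 10_000))
        values = weights / weights.sum() * total
        rounded = largest_remainder_round(values, total)
        assert rounded.sum() == total
        assert np.all(np.abs(rounded - values) < 1.0)


def test_multinomial_mode_conserves_and_is_seeded(mock10):
    run = sq.SequencingRun(total_reads=2_000_000, seed=42)
    a = sq.simulate_counts(mock10, run)
    b = sq.simulate_counts(mock10, run)
    assert a.frame.equals(b.frame)
    assert a.total_reads == 2_000_000


def test_multinomial_mean_matches_expectation():
    comp = sq.SampleComposition(
        panel=None, host_mass_ng=1.0, taxa=[_taxon("t1", 5e6, 1.0)]
    )
    n, depth, reps = 0.5, 100_000, 60
    draws = [
        sq.simulate_counts(comp, sq.SequencingRun(depth, seed=s)).reads_for("t1")
        for s in range(reps)
    ]
    expected = depth * n
    sigma = np.sqrt(depth * n * (1 - n))
    assert abs(np.mean(draws) - expected) < 5 * sigma / np.sqrt(reps)


def test_zero_mass_taxon_gets_zero_reads(default_panel):
    comp = sq.SampleComposition(
        panel=default_panel, host_mass_ng=1.0,
        taxa=[sq.TaxonProfile.from_copies("ghost", 5e6, 0.0)],
    )
    for mode in ("expected", "expected_rounded", "multinomial", "poisson"):
        counts = sq.simulate_counts(comp, sq.SequencingRun(100_000, seed=1), mode=mode)
        assert counts.reads_for("ghost") == 0


# ---------------------------------------------------------------------------
# Fixture genomes and read-level simulation
# ---------------------------------------------------------------------------

def test_fixture_genome_deterministic_and_screened(default_panel):
    index = sq.panel_kmer_index(default_panel)
    a = sq.make_fixture_genome("g1", 5000, seed=9, exclusion_index=index)
    b = sq.make_fixture_genome("g1", 5000, seed=9, exclusion_index=index)
    assert a == b and len(a) == 5000
    assert sq.homology_screen(a, index, 50) == 0
    with pytest.raises(ValidationError):
        sq.make_fixture_genome("g1", 500, seed=9)


def test_simulate_reads_error_free_substrings(tmp_path, default_panel, rng):
    genome = random_dna(rng, 4000)
    comp = sq.SampleComposition(panel=default_panel, taxa=[_taxon("t1", 5e6, 0.5)])
    run = sq.SequencingRun(total_reads=400, read_length=75, error_rate=0.0, seed=5)
    fastq = tmp_path / "reads.fastq"
    counts = sq.simulate_reads(comp, run, {"t1": genome}, fastq, mode="expected_rounded")
    sources = {"t1": genome}
    for m in default_panel.molecules:
        sources[m.id] = m.insert_seq
    n_reads = 0
    with open(fastq) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            n_reads += 1
            category = title.split("cat=")[1]
            source = sources[category]
            assert seq in source or seq in sq.reverse_complement(source)
            assert len(seq) == 75 and len(qual) == 75
    assert n_reads == counts.total_reads == 400


def test_simulate_reads_matches_counts_only_path(tmp_path, default_panel, rng):
    comp = sq.SampleComposition(panel=default_panel, taxa=[_taxon("t1", 5e6, 0.5)])
    run = sq.SequencingRun(total_reads=300, seed=8)
    expected = sq.simulate_counts(comp, run)
    realised = sq.simulate_reads(comp, run, {"t1": random_dna(rng, 2000)},
                                 tmp_path / "r.fastq")
    assert realised.frame.equals(expected.frame)


def test_simulate_reads_error_rate_mean_mismatches(tmp_path, default_panel, rng):
    genome = random_dna(rng, 4000)
    comp = sq.SampleComposition(panel=None or default_panel, taxa=[_taxon("t1", 5e6, 100.0)])
    run = sq.SequencingRun(total_reads=2000, read_length=75, error_rate=0.01, seed=5)
    fastq = tmp_path / "reads.fastq"
    sq.simulate_reads(comp, run, {"t1": genome}, fastq, mode="expected_rounded")
    rc = sq.reverse_complement(genome)
    mismatches = []
    with open(fastq) as handle:
        for title, seq, _ in FastqGeneralIterator(handle):
            if title.split("cat=")[1] != "t1":
                continue
            best = min(
                min(sum(a != b for a, b in zip(seq, ref[i:i + 75]))
                    for i in range(len(ref) - 74))
                for ref in (genome, rc)
            )
            mismatches.append(best)
    mean = np.mean(mismatches)
    # binomial mean 0.75 substitutions per 75-nt read
    assert 0.5 < mean < 1.0


def test_simulate_reads_missing_sequence_errors(tmp_path, default_panel):
    comp = sq.SampleComposition(panel=default_panel, taxa=[_taxon("t1", 5e6, 0.5)])
    run = sq.SequencingRun(total_reads=100, seed=1)
    with pytest.raises(ValidationError, match="t1"):
        sq.simulate_reads(comp, run, {}, tmp_path / "r.fastq")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def test_taxon_profile_consistency_enforced():
    with pytest.raises(ValidationError):
        sq.TaxonProfile("t", 5e6, true_copies=10.0, mass_ng=1.0)
    t = sq.TaxonProfile.from_copies("t", 5e6, 10.0)
    assert t.mass_ng == pytest.approx(10.0 * 5e6 * DNAC)


def test_preset_masses(default_panel):
    low = sq.preset("low_host", default_panel)
    assert low.host_mass_ng == 5.5
    assert sum(t.mass_ng for t in low.taxa) == pytest.approx(1.1)
    high = sq.preset("high_host", default_panel)
    assert high.host_mass_ng == 5.0
    assert sum(t.mass_ng for t in high.taxa) == pytest.approx(0.01)
    mock = sq.preset("mock10", default_panel)
    copies = sorted(t.true_copies for t in mock.taxa)
    assert copies[0] == pytest.approx(10.0) and copies[-1] == pytest.approx(1e6)
    assert len(mock.taxa) == 10 and mock.host_mass_ng == 0.0


def test_clinical_preset_host_dominates(default_panel):
    comp = sq.preset("clinical_like", default_panel)
    specimen = comp.host_mass_ng + sum(t.mass_ng for t in comp.taxa)
    assert comp.host_mass_ng / specimen >= 0.95


def test_low_host_read_fraction_tracks_masses(default_panel):
    comp = sq.preset("low_host", default_panel)
    counts = sq.simulate_counts(comp, sq.SequencingRun(1_000_000, seed=2))
    is_mass = sum(m.concentration * 2.0 for m in default_panel.molecules)
    expected = 5.5 / (5.5 + 1.1 + is_mass)
    assert counts.reads_for("host") / counts.total_reads == pytest.approx(expected, rel=0.01)


def test_unknown_preset_errors(default_panel):
    with pytest.raises(ValidationError):
        sq.preset("mock99", default_panel)


def test_random_composition_spans_clinical_range(default_panel, rng):
    comps = [sq.random_composition(rng, default_panel) for _ in range(30)]
    sizes = {len(c.taxa) for c in comps}
    assert sizes <= {2, 3, 4} and 2 in sizes
    copies = [t.true_copies for c in comps for t in c.taxa]
    assert min(copies) >= 10 and max(copies) <= 1e6
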