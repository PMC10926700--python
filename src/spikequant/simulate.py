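"""Simulation of spike-in mNGS experiments.

The simulator is the ground-truth generator for the whole package: it
builds sample compositions (host DNA + microbial taxa + the IS spike),
draws read counts proportional to each component's mass fraction (shotgun
sequencing samples nucleotides, so reads track mass, not copies), and can
optionally emit read-level FASTQ with substitution errors for the k-mer
counter. Experimental presets encode the standard bench conditions:
a ten-organism mock community, low- and high-host-background mixtures
(5.5 ng host + 1.1 ng microbial, 5.0 ng host + 0.01 ng microbial), and a
CSF-like specimen dominated by human DNA.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import ReadCountTable
from .errors import DesignError, ValidationError
from .panel import DesignSpec, ISPanel, design_panel, homology_screen, random_dna, reverse_complement
from .quant import NG_PER_BP_DSDNA

logger = logging.getLogger(__name__)

#: Seed used when a preset has to design its own default panel.
DEFAULT_PANEL_SEED = 101

PRESET_NAMES = ("mock10", "low_host", "high_host", "clinical_like")

#: Fixture taxa standing in for a commercial ten-organism mock community
#: (genome lengths are typical Gram+/Gram- bacterial genome sizes in bp;
#: per-species reference copy numbers of the commercial material are not
#: public, so mock copies are configurable stand-ins).
MOCK_TAXA: tuple[tuple[str, float], ...] = (
    ("mock_ecoli_like", 5.0e6),
    ("mock_saureus_like", 2.8e6),
    ("mock_nmeningitidis_like", 2.2e6),
    ("mock_spyogenes_like", 1.9e6),
    ("mock_abaumannii_like", 4.0e6),
    ("mock_kpneumoniae_like", 5.5e6),
    ("mock_paeruginosa_like", 6.3e6),
    ("mock_spneumoniae_like", 2.1e6),
    ("mock_efaecalis_like", 3.3e6),
    ("mock_lmonocytogenes_like", 3.0e6),
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonProfile:
    """One microbial component of a sample, with mass and copies locked
    together through mass = copies * genome_length * DNA_c."""

    taxon_id: str
    genome_length: float
    true_copies: float
    mass_ng: float

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValidationError("genome_length must be positive")
        if self.true_copies < 0 or self.mass_ng < 0:
            raise ValidationError("copies and mass must be non-negative")
        expected = self.true_copies * self.genome_length * NG_PER_BP_DSDNA
        if not np.isclose(self.mass_ng, expected, rtol=1e-6, atol=1e-30):
            raise ValidationError(
                f"mass {self.mass_ng:g} ng inconsistent with copies x length x DNAc "
                f"({expected:g} ng) for {self.taxon_id}"
            )

    @classmethod
    def from_copies(cls, taxon_id: str, genome_length: float, copies: float) -> "TaxonProfile":
        return cls(taxon_id, genome_length, copies, copies * genome_length * NG_PER_BP_DSDNA)

    @classmethod
    def from_mass(cls, taxon_id: str, genome_length: float, mass_ng: float) -> "TaxonProfile":
        return cls(taxon_id, genome_length, mass_ng / (genome_length * NG_PER_BP_DSDNA), mass_ng)


@dataclass
class SampleComposition:
    """Ground-truth composition of one spiked specimen.

    ``recovery_efficiency`` maps a category id or a category type
    (host / is / taxon / contaminant) to a recovery fraction in (0, 1];
    anything absent recovers fully. A depressed IS recovery reproduces the
    known failure mode of adding the spike before nucleic-acid extraction.
    """

    panel: ISPanel | None
    host_mass_ng: float = 0.0
    taxa: list[TaxonProfile] = field(default_factory=list)
    is_spike_volume_ul: float = 2.0
    recovery_efficiency: dict[str, float] = field(default_factory=dict)
    contamination: list[TaxonProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.host_mass_ng < 0:
            raise ValidationError("host mass must be non-negative")
        if self.is_spike_volume_ul <= 0:
            raise ValidationError("spike volume must be positive")
        for eff in self.recovery_efficiency.values():
            if not (0 < eff <= 1):
                raise ValidationError("recovery efficiencies must lie in (0, 1]")
        ids = [t.taxon_id for t in self.taxa] + [t.taxon_id for t in self.contamination]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate taxon ids in composition")

    def _efficiency(self, category: str, category_type: str) -> float:
        if category in self.recovery_efficiency:
            return self.recovery_efficiency[category]
        return self.recovery_efficiency.get(category_type, 1.0)

    def mass_table(self) -> pd.DataFrame:
        """Per-category mass (ng), recovery efficiency and effective mass."""
        rows: list[tuple[str, str, float]] = []
        if self.host_mass_ng > 0:
            rows.append(("host", "host", self.host_mass_ng))
        for t in self.taxa:
            rows.append((t.taxon_id, "taxon", t.mass_ng))
        if self.panel is not None:
            for m in self.panel.molecules:
                rows.append((m.id, "is", m.concentration * self.is_spike_volume_ul))
        for t in self.contamination:
            rows.append((t.taxon_id, "contaminant", t.mass_ng))
        frame = pd.DataFrame(rows, columns=["category", "category_type", "mass_ng"])
        frame["efficiency"] = [
            self._efficiency(c, ct) for c, ct in zip(frame["category"], frame["category_type"])
        ]
        frame["effective_mass"] = frame["mass_ng"] * frame["efficiency"]
        return frame

    def genome_lengths(self) -> dict[str, float]:
        return {t.taxon_id: t.genome_length for t in self.taxa + self.contamination}

    def true_copies(self) -> dict[str, float]:
        return {t.taxon_id: t.true_copies for t in self.taxa + self.contamination}

    def write_truth(self, path: str | Path) -> Path:
        payload = {
            t.taxon_id: {
                "genome_length_bp": t.genome_length,
                "true_copies": t.true_copies,
                "mass_ng": t.mass_ng,
            }
            for t in self.taxa + self.contamination
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


@dataclass(frozen=True)
class SequencingRun:
    """Sequencing parameters: depth, single-end read length, substitution
    error rate and the run's random seed."""

    total_reads: int
    read_length: int = 75
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValidationError("total_reads must be positive")
        if not (0 <= self.error_rate < 0.1):
            raise ValidationError("error_rate must lie in [0, 0.1)")
        if self.read_length <= 0:
            raise ValidationError("read_length must be positive")


# ---------------------------------------------------------------------------
# Fixture sequences
# ---------------------------------------------------------------------------

def make_fixture_genome(
    taxon_id: str,
    length: int,
    seed: int,
    exclusion_index: set[str] | frozenset[str] = frozenset(),
    k: int = 50,
    max_attempts: int = 20,
) -> str:
    """Random fixture genome sharing no k-mer with ``exclusion_index``
    (typically the IS panel's 50-mers); deterministic per seed."""
    if length < 1000:
        raise ValidationError("fixture genomes must be at least 1000 bp")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        seq = random_dna(rng, length)
        if not exclusion_index or homology_screen(seq, set(exclusion_index), k) == 0:
            return seq
    raise DesignError(
        f"could not draw a fixture genome for {taxon_id} avoiding the exclusion "
        f"index within {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Count-level simulation
# ---------------------------------------------------------------------------

def expected_mass_fractions(comp: SampleComposition) -> dict[str, float]:
    """Expected read fraction per category: recovery-weighted mass over the
    recovery-weighted total. Fractions sum to one."""
    table = comp.mass_table()
    total = table["effective_mass"].sum()
    if total <= 0:
        raise ValidationError("sample has no recoverable mass")
    return dict(zip(table["category"], table["effective_mass"] / total))


def largest_remainder_round(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative ``values`` (summing to ``total``) to integers that
    still sum to ``total``, assigning leftovers by largest fractional part."""
    floors = np.floor(values).astype(np.int64)
    short = int(total - floors.sum())
    if short > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:short]] += 1
    return floors

COUNT_MODES = ("multinomial", "poisson", "expected", "expected_rounded")


def simulate_counts(
    comp: SampleComposition,
    run: SequencingRun,
    mode: str = "multinomial",
) -> ReadCountTable:
    """Draw a read-count table for one sequencing run.

    Modes: ``multinomial`` (default; fixed total depth), ``poisson``
    (independent per-category counts with the same means), ``expected``
    (noise off: exact real-valued expectations) and ``expected_rounded``
    (expectations rounded by largest remainder, conserving the total).
    """
    if mode not in COUNT_MODES:
        raise ValidationError(f"unknown count mode: {mode}")
    table = comp.mass_table()
    total = table["effective_mass"].sum()
    if total <= 0:
        raise ValidationError("sample has no recoverable mass")
    fractions = (table["effective_mass"] / total).to_numpy()
    expected = fractions * run.total_reads
    if mode == "expected":
        reads = expected
    elif mode == "expected_rounded":
        reads = largest_remainder_round(expected, run.total_reads)
    else:
        rng = np.random.default_rng(run.seed)
        if mode == "multinomial":
            reads = rng.multinomial(run.total_reads, fractions)
        else:
            reads = rng.poisson(expected)
    out = table.loc[:, ["category", "category_type"]].copy()
    out["reads"] = np.asarray(reads, dtype=float)
    return ReadCountTable(out)


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    comp: SampleComposition,
    run: SequencingRun,
    sequences: Mapping[str, str],
    out_fastq: str | Path,
    counts: ReadCountTable | None = None,
    mode: str = "multinomial",
) -> ReadCountTable:
    """Write a single-end FASTQ realising a count table.

    Reads are uniform-start substrings drawn from either strand of the
    category's sequence, with i.i.d. substitution errors at
    ``run.error_rate``. Every header carries ``cat=<category>`` so the true
    origin stays available as a classification oracle. Returns the count
    table actually realised (computed with :func:`simulate_counts` from the
    same seed when not supplied), so the counts-only and read-level paths
    see identical tables.
    """
    if counts is None:
        counts = simulate_counts(comp, run, mode=mode)
    seqs = dict(sequences)
    if comp.panel is not None:
        for m in comp.panel.molecules:
            seqs.setdefault(m.id, m.insert_seq)
    table = counts.frame
    rng = np.random.default_rng(np.random.SeedSequence([run.seed, 7]))
    bases = np.array(list("ACGT"))
    out_fastq = Path(out_fastq)
    n_written = 0
    with open(out_fastq, "w") as handle:
        for _, row in table.iterrows():
            category = row["category"]
            n = int(round(row["reads"]))
            if n == 0:
                continue
            seq = seqs.get(category)
            if seq is None:
                raise ValidationError(f"no sequence provided for category {category}")
            if len(seq) < run.read_length:
                raise ValidationError(
                    f"sequence for {category} shorter than read length {run.read_length}"
                )
            starts = rng.integers(0, len(seq) - run.read_length + 1, size=n)
            strands = rng.integers(0, 2, size=n)
            qual = "I" * run.read_length
            for start, strand in zip(starts, strands):
                read = seq[start : start + run.read_length]
                if strand:
                    read = reverse_complement(read)
                if run.error_rate > 0:
                    errs = np.flatnonzero(rng.random(run.read_length) < run.error_rate)
                    if errs.size:
                        arr = np.array(list(read))
                        shift = rng.integers(1, 4, size=errs.size)
                        codes = np.frombuffer(read.encode(), dtype=np.uint8)
                        lut = {65: 0, 67: 1, 71: 2, 84: 3}
                        old = np.array([lut[c] for c in codes[errs]])
                        arr[errs] = bases[(old + shift) % 4]
                        read = "".join(arr)
                n_written += 1
                handle.write(f"@r{n_written} cat={category}\n{read}\n+\n{qual}\n")
    logger.info("wrote %d reads to %s", n_written, out_fastq)
    return counts


# ---------------------------------------------------------------------------
# Presets and composition helpers
# ---------------------------------------------------------------------------

def _mock_profiles() -> list[TaxonProfile]:
    copies = np.logspace(1, 6, len(MOCK_TAXA))
    return [
        TaxonProfile.from_copies(taxon_id, length, c)
        for (taxon_id, length), c in zip(MOCK_TAXA, copies)
    ]


def scale_taxa_to_total(taxa: Sequence[TaxonProfile], total_mass_ng: float) -> list[TaxonProfile]:
    """Rescale a microbial profile so its masses sum to ``total_mass_ng``,
    preserving relative abundances (copies rescale with mass)."""
    current = sum(t.mass_ng for t in taxa)
    if current <= 0:
        raise ValidationError("cannot rescale an all-zero profile")
    factor = total_mass_ng / current
    return [
        TaxonProfile.from_mass(t.taxon_id, t.genome_length, t.mass_ng * factor) for t in taxa
    ]


def preset(
    name: str,
    panel: ISPanel | None = None,
    is_spike_volume_ul: float = 2.0,
) -> SampleComposition:
    """Standard experimental compositions.

    ``mock10``: the ten-organism mock community alone, true copies spanning
    10..1e6. ``low_host``: 5.5 ng host + 1.1 ng microbial DNA.
    ``high_host``: 5.0 ng host + 0.01 ng microbial DNA. ``clinical_like``:
    CSF-like specimen, host >= 95 % of specimen (non-IS) DNA.
    """
    if name not in PRESET_NAMES:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if panel is None:
        panel = design_panel(DesignSpec(rng_seed=DEFAULT_PANEL_SEED))
    mock = _mock_profiles()
    if name == "mock10":
        return SampleComposition(panel=panel, host_mass_ng=0.0, taxa=mock,
                                 is_spike_volume_ul=is_spike_volume_ul)
    if name == "low_host":
        return SampleComposition(panel=panel, host_mass_ng=5.5,
                                 taxa=scale_taxa_to_total(mock, 1.1),
                                 is_spike_volume_ul=is_spike_volume_ul)
    if name == "high_host":
        return SampleComposition(panel=panel, host_mass_ng=5.0,
                                 taxa=scale_taxa_to_total(mock, 0.01),
                                 is_spike_volume_ul=is_spike_volume_ul)
    # clinical_like: a few pathogens at modest load under a heavy host background
    pathogens = [
        TaxonProfile.from_copies("path_kpneumoniae_like", 5.5e6, 2e4),
        TaxonProfile.from_copies("path_spneumoniae_like", 2.1e6, 5e3),
        TaxonProfile.from_copies("path_ecoli_like", 5.0e6, 5e2),
        TaxonProfile.from_copies("path_saureus_like", 2.8e6, 5e1),
    ]
    return SampleComposition(panel=panel, host_mass_ng=10.0, taxa=pathogens,
                             is_spike_volume_ul=is_spike_volume_ul)


def random_composition(
    rng: np.random.Generator,
    panel: ISPanel,
    host_mass_ng: float = 5.0,
    n_taxa_choices: Sequence[int] = (2, 3, 4),
    n_taxa_probs: Sequence[float] = (0.75, 0.20, 0.05),
    log10_copies_range: tuple[float, float] = (1.0, 6.0),
    is_spike_volume_ul: float = 2.0,
) -> SampleComposition:
    """A random clinical-style sample: a handful of taxa whose true copy
    numbers are log-uniform over the clinically relevant 10..1e6 range."""
    n_taxa = int(rng.choice(n_taxa_choices, p=n_taxa_probs))
    picks = rng.choice(len(MOCK_TAXA), size=n_taxa, replace=False)
    taxa = []
    for j, pick in enumerate(picks):
        name, length = MOCK_TAXA[pick]
        copies = 10.0 ** rng.uniform(*log10_copies_range)
        taxa.append(TaxonProfile.from_copies(f"s{j}_{name}", length, copies))
    return SampleComposition(panel=panel, host_mass_ng=host_mass_ng, taxa=taxa,
                             is_spike_volume_ul=is_spike_volume_ul)
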