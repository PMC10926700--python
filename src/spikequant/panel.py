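"""Design and validation of synthetic internal-standard (IS) spike-in panels.

An IS panel is a set of artificial dsDNA molecules that are spiked into a
metagenomic library at known mass so that their recovered read counts
calibrate the read-to-mass conversion for everything else in the sample.
The molecules must be sequencing-friendly (bounded GC, no long
homopolymers) and, critically, must share no subsequence with anything
that could plausibly be in a specimen, so that no read is ever
mis-assigned between an IS molecule and a real genome.

The designer draws random candidate inserts, enforces composition
constraints, screens every overlapping k-mer (default 50-mer, both
strands) against user-supplied reference sequences and against all
previously accepted molecules, and assigns accepted molecules round-robin
to a ladder of concentration gradient levels (default 5 levels x 3
molecules, 2e-1 ... 2e-5 ng/uL).
"""
from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DesignError, ValidationError

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValidationError(f"empty {what}")
    if not set(seq) <= set(_BASES):
        bad = sorted(set(seq) - set(_BASES))
        raise ValidationError(f"{what} contains non-ACGT symbols: {bad}")


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in ``seq``.

    Raises :class:`ValidationError` for an empty sequence or any symbol
    outside {A, C, G, T}.
    """
    _check_dna(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of identical consecutive bases."""
    if not seq:
        raise ValidationError("empty sequence")
    best = run = 1
    prev = seq[0]
    for ch in seq[1:]:
        if ch == prev:
            run += 1
            if run > best:
                best = run
        else:
            run = 1
            prev = ch
    return best


# ---------------------------------------------------------------------------
# k-mer screening
# ---------------------------------------------------------------------------

def iter_kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def add_sequence_kmers(index: set[str], seq: str, k: int) -> None:
    """Add every k-mer of ``seq`` (both strands) to ``index``.

    k-mers containing non-ACGT symbols (e.g. N in reference assemblies)
    are skipped.
    """
    acgt = set(_BASES)
    rc = reverse_complement(seq) if set(seq) <= acgt else None
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= acgt:
            index.add(kmer)
            index.add(reverse_complement(kmer) if rc is None else rc[len(seq) - k - i : len(seq) - i])


def build_screen_index(references: Sequence[str | Path], k: int) -> set[str]:
    """k-mer set (both strands) over all records of the given FASTA files."""
    index: set[str] = set()
    for path in references:
        for record in SeqIO.parse(str(path), "fasta"):
            add_sequence_kmers(index, str(record.seq).upper(), k)
    return index


def homology_screen(candidate: str, reference_kmer_index: set[str], k: int) -> int:
    """Number of candidate positions whose k-mer (either strand) hits the index.

    Counts over overlapping windows at stride 1; a position is counted once
    even if both its forward k-mer and its reverse complement are indexed.
    Panel acceptance requires this to be 0.
    """
    _check_dna(candidate, "candidate")
    if len(candidate) < k:
        raise ValidationError(f"candidate shorter than k ({len(candidate)} < {k})")
    hits = 0
    for kmer in iter_kmers(candidate, k):
        if kmer in reference_kmer_index or reverse_complement(kmer) in reference_kmer_index:
            hits += 1
    return hits


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the IS panel design.

    Defaults encode the standard panel: 1000-bp synthesised inserts whose
    PCR-amplifiable core (insert minus one primer flank on each side) is
    970 bp, GC within [35 %, 70 %], homopolymer runs shorter than four
    bases, and 5 concentration levels x 3 molecules spanning
    2e-1 ... 2e-5 ng/uL.
    """

    insert_length: int = 1000
    amplicon_flank: int = 15
    gc_min: float = 0.35
    gc_max: float = 0.70
    max_run: int = 3
    n_gradients: int = 5
    molecules_per_gradient: int = 3
    gradient_concentrations: tuple[float, ...] = (2e-1, 2e-2, 2e-3, 2e-4, 2e-5)
    screen_k: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValidationError("need 0 <= gc_min <= gc_max <= 1")
        if self.insert_length <= 2 * self.amplicon_flank:
            raise ValidationError("insert_length must exceed twice the amplicon flank")
        if self.max_run < 1:
            raise ValidationError("max_run must be >= 1")
        if len(self.gradient_concentrations) != self.n_gradients:
            raise ValidationError("one concentration per gradient level required")
        diffs = np.diff(self.gradient_concentrations)
        if not np.all(diffs < 0):
            raise ValidationError("gradient_concentrations must be strictly decreasing")
        if min(self.gradient_concentrations) <= 0:
            raise ValidationError("concentrations must be positive")
        if self.screen_k > self.insert_length:
            raise ValidationError("screen_k cannot exceed insert_length")

    @property
    def amplicon_length(self) -> int:
        return self.insert_length - 2 * self.amplicon_flank

    @property
    def panel_size(self) -> int:
        return self.n_gradients * self.molecules_per_gradient


@dataclass(frozen=True)
class ISMolecule:
    """One synthetic internal-standard molecule."""

    id: str
    insert_seq: str
    gradient_level: int
    concentration: float  # ng/uL in the spike mix

    def amplicon(self, flank: int) -> str:
        """PCR-amplifiable core: insert minus one primer flank on each side."""
        return self.insert_seq[flank : len(self.insert_seq) - flank]


@dataclass
class ISPanel:
    """A complete IS panel: molecules plus the spec they satisfy."""

    molecules: list[ISMolecule]
    spec: DesignSpec

    def __post_init__(self) -> None:
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate molecule ids in panel")
        if len(self.molecules) != self.spec.panel_size:
            raise ValidationError(
                f"panel has {len(self.molecules)} molecules, spec requires {self.spec.panel_size}"
            )
        per_level = Counter(m.gradient_level for m in self.molecules)
        for level in range(1, self.spec.n_gradients + 1):
            if per_level.get(level, 0) != self.spec.molecules_per_gradient:
                raise ValidationError(f"gradient level {level} does not have "
                                      f"{self.spec.molecules_per_gradient} molecules")

    @property
    def molecule_ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def level_molecules(self, level: int) -> list[ISMolecule]:
        return [m for m in self.molecules if m.gradient_level == level]

    def level_concentration(self, level: int) -> float:
        return self.spec.gradient_concentrations[level - 1]

    def amplicon(self, molecule: ISMolecule) -> str:
        return molecule.amplicon(self.spec.amplicon_flank)

    # -- serialization ------------------------------------------------------

    def manifest(self) -> dict:
        flank = self.spec.amplicon_flank
        return {
            "spec": {
                "insert_length": self.spec.insert_length,
                "amplicon_flank": flank,
                "gc_min": self.spec.gc_min,
                "gc_max": self.spec.gc_max,
                "max_run": self.spec.max_run,
                "n_gradients": self.spec.n_gradients,
                "molecules_per_gradient": self.spec.molecules_per_gradient,
                "gradient_concentrations": list(self.spec.gradient_concentrations),
                "screen_k": self.spec.screen_k,
                "rng_seed": self.spec.rng_seed,
            },
            "molecules": [
                {
                    "id": m.id,
                    "gradient_level": m.gradient_level,
                    "concentration_ng_per_ul": m.concentration,
                    "insert_length": len(m.insert_seq),
                    "amplicon_length": len(m.amplicon(flank)),
                    "insert_sha256": hashlib.sha256(m.insert_seq.encode()).hexdigest(),
                    "amplicon_sha256": hashlib.sha256(m.amplicon(flank).encode()).hexdigest(),
                }
                for m in self.molecules
            ],
        }

    def write_fasta(self, path: str | Path, which: str = "insert") -> Path:
        if which not in ("insert", "amplicon"):
            raise ValidationError("which must be 'insert' or 'amplicon'")
        flank = self.spec.amplicon_flank
        records = [
            SeqRecord(
                Seq(m.insert_seq if which == "insert" else m.amplicon(flank)),
                id=m.id,
                description=f"gradient_level={m.gradient_level} "
                            f"concentration_ng_per_ul={m.concentration:g}",
            )
            for m in self.molecules
        ]
        path = Path(path)
        SeqIO.write(records, str(path), "fasta")
        return path

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "inserts": self.write_fasta(outdir / "is_inserts.fasta", "insert"),
            "amplicons": self.write_fasta(outdir / "is_amplicons.fasta", "amplicon"),
            "manifest": outdir / "panel_manifest.json",
        }
        paths["manifest"].write_text(json.dumps(self.manifest(), indent=2) + "\n")
        return paths

    @classmethod
    def load(cls, manifest_path: str | Path, inserts_fasta: str | Path) -> "ISPanel":
        """Rebuild a panel from its manifest and insert FASTA, verifying digests."""
        data = json.loads(Path(manifest_path).read_text())
        spec = DesignSpec(
            insert_length=data["spec"]["insert_length"],
            amplicon_flank=data["spec"]["amplicon_flank"],
            gc_min=data["spec"]["gc_min"],
            gc_max=data["spec"]["gc_max"],
            max_run=data["spec"]["max_run"],
            n_gradients=data["spec"]["n_gradients"],
            molecules_per_gradient=data["spec"]["molecules_per_gradient"],
            gradient_concentrations=tuple(data["spec"]["gradient_concentrations"]),
            screen_k=data["spec"]["screen_k"],
            rng_seed=data["spec"]["rng_seed"],
        )
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(inserts_fasta), "fasta")}
        molecules = []
        for entry in data["molecules"]:
            mol_id = entry["id"]
            if mol_id not in seqs:
                raise ValidationError(f"insert FASTA is missing molecule {mol_id}")
            seq = seqs[mol_id]
            digest = hashlib.sha256(seq.encode()).hexdigest()
            if digest != entry["insert_sha256"]:
                raise ValidationError(f"sha256 mismatch for molecule {mol_id}")
            molecules.append(
                ISMolecule(
                    id=mol_id,
                    insert_seq=seq,
                    gradient_level=entry["gradient_level"],
                    concentration=entry["concentration_ng_per_ul"],
                )
            )
        return cls(molecules=molecules, spec=spec)


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def _run_lengths(codes: np.ndarray) -> np.ndarray:
    """Run length ending at each position of a code array."""
    n = codes.size
    idx = np.arange(n)
    is_reset = np.empty(n, dtype=bool)
    is_reset[0] = True
    is_reset[1:] = codes[1:] != codes[:-1]
    last_reset = np.maximum.accumulate(np.where(is_reset, idx, 0))
    return idx - last_reset + 1


def random_dna_codes(rng: np.random.Generator, length: int, max_run: int | None = None) -> np.ndarray:
    """i.i.d. uniform base codes; optionally resample positions that extend a
    homopolymer run beyond ``max_run`` until none remain.

    Resampled positions are redrawn uniformly from the three other bases, so
    the marginal composition stays uniform.
    """
    codes = rng.integers(0, 4, size=length, dtype=np.int64)
    if max_run is not None:
        while True:
            viol = np.flatnonzero(_run_lengths(codes) > max_run)
            if viol.size == 0:
                break
            codes[viol] = (codes[viol] + rng.integers(1, 4, size=viol.size)) % 4
    return codes


def codes_to_str(codes: np.ndarray) -> str:
    return _BASE_CODES[codes].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, length: int, max_run: int | None = None) -> str:
    return codes_to_str(random_dna_codes(rng, length, max_run))


# ---------------------------------------------------------------------------
# Panel design
# ---------------------------------------------------------------------------

def design_panel(
    spec: DesignSpec,
    references: Sequence[str | Path] = (),
    seed: int | None = None,
    max_attempts: int | None = None,
) -> ISPanel:
    """Design a full IS panel by constrained rejection sampling.

    Candidates of ``insert_length`` are drawn at random (uniform bases, runs
    capped at ``max_run`` during generation), then rejected unless both the
    insert and its amplicon satisfy the GC window and no k-mer of the insert
    (either strand, stride 1) occurs in the screening references or in any
    previously accepted molecule. Accepted molecules are assigned to
    gradient levels round-robin in acceptance order. Deterministic for a
    fixed seed.

    Raises :class:`DesignError`, naming the binding constraint, if the panel
    is not complete within the attempt budget.
    """
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    k = spec.screen_k
    index = build_screen_index(references, k)
    budget = max_attempts if max_attempts is not None else 200 * spec.panel_size
    accepted: list[str] = []
    rejections: Counter[str] = Counter()
    attempts = 0
    while len(accepted) < spec.panel_size:
        if attempts >= budget:
            binding = rejections.most_common(1)[0][0] if rejections else "none"
            raise DesignError(
                f"panel design incomplete after {attempts} candidates "
                f"({len(accepted)}/{spec.panel_size} accepted); "
                f"binding constraint: {binding}; rejections: {dict(rejections)}"
            )
        attempts += 1
        insert = random_dna(rng, spec.insert_length, spec.max_run)
        amplicon = insert[spec.amplicon_flank : spec.insert_length - spec.amplicon_flank]
        if not (spec.gc_min <= gc_content(insert) <= spec.gc_max) or not (
            spec.gc_min <= gc_content(amplicon) <= spec.gc_max
        ):
            rejections["gc_content"] += 1
            continue
        if max_homopolymer_run(insert) > spec.max_run:  # guaranteed by generator
            rejections["homopolymer_run"] += 1
            continue
        if homology_screen(insert, index, k) > 0:
            rejections["homology"] += 1
            continue
        accepted.append(insert)
        add_sequence_kmers(index, insert, k)
    logger.info("panel designed: %d candidates drawn, rejections %s", attempts, dict(rejections))
    molecules = [
        ISMolecule(
            id=f"IS_{i + 1:02d}",
            insert_seq=seq,
            gradient_level=(i % spec.n_gradients) + 1,
            concentration=spec.gradient_concentrations[i % spec.n_gradients],
        )
        for i, seq in enumerate(accepted)
    ]
    return ISPanel(molecules=molecules, spec=spec)


def panel_kmer_index(panel: ISPanel, k: int | None = None) -> set[str]:
    """Both-strand k-mer set over all panel inserts (default k = screen_k)."""
    k = panel.spec.screen_k if k is None else k
    index: set[str] = set()
    for m in panel.molecules:
        add_sequence_kmers(index, m.insert_seq, k)
    return index
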