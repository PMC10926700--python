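"""Read-count to copy-number conversion via the internal-standard curve.

Model
-----
Shotgun sequencing samples nucleotides at random, so for any dsDNA species
in the library the detected reads R are proportional to its input mass C
with a single sample-wide constant:

    C_is / R_is = C_mic / R_mic                                   (mass law)

The IS panel provides (C_is, R_is) pairs over five concentration levels
spanning four orders of magnitude. An ordinary least-squares line is
fitted in log10-log10 space (log-space keeps the low gradients from being
swamped by the top one); inverting the fitted line converts microbial
reads R_mic into mass C_mic, and mass into genome copies via

    COPY_mic = C_mic / (L_mic * DNA_c)

where L_mic is the genome length in bp and DNA_c the mass of one bp of
dsDNA (650 g/mol/bp divided by Avogadro's number, about 1.0794e-12 ng/bp).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import ReadCountTable
from .errors import FitError, QuantError, ValidationError
from .panel import ISPanel

logger = logging.getLogger(__name__)

#: Mass of one base pair of double-stranded DNA, in ng:
#: 650 g/mol/bp divided by Avogadro's number, times 1e9 ng/g.
NG_PER_BP_DSDNA = 650.0 / 6.02214076e23 * 1e9

IS_MASS_CONVENTIONS = ("per_molecule", "pool")


@dataclass(frozen=True)
class Constants:
    """Physical constants of the mass-to-copies conversion."""

    dnac_ng_per_bp: float = NG_PER_BP_DSDNA

    def __post_init__(self) -> None:
        if self.dnac_ng_per_bp <= 0:
            raise ValidationError("dnac_ng_per_bp must be positive")


@dataclass(frozen=True)
class ISObservation:
    """One gradient level of the IS ladder: total input mass C_is (ng) in the
    spiked volume versus total detected reads R_is, with the per-molecule
    read breakdown retained."""

    gradient_level: int
    cis_ng: float
    ris: float
    molecule_reads: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cis_ng <= 0:
            raise ValidationError("C_is must be positive")
        if self.ris < 0:
            raise ValidationError("R_is must be non-negative")


@dataclass(frozen=True)
class RegressionFit:
    """IS standard curve: log10(R_is) (or R_is) regressed on log10(C_is)."""

    slope: float
    intercept: float
    r_squared: float
    fit_space: str
    n_points_used: int
    dropped_levels: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "fit_space": self.fit_space,
            "n_points_used": self.n_points_used,
            "dropped_levels": list(self.dropped_levels),
        }


@dataclass(frozen=True)
class MicrobeQuant:
    """Per-taxon quantification output."""

    taxon_id: str
    reads: float
    mass_ng: float
    genome_length: float | None
    copies: float
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def is_observations(
    counts: ReadCountTable,
    panel: ISPanel,
    spike_volume_ul: float = 2.0,
    convention: str = "per_molecule",
) -> list[ISObservation]:
    """Aggregate the count table into one (C_is, R_is) observation per
    gradient level.

    ``convention`` resolves how the printed gradient concentrations map to
    mass: ``per_molecule`` treats each of the level's molecules as present
    at that concentration (C_is = molecules_per_gradient * conc * volume,
    the default); ``pool`` treats the concentration as that of the level's
    pooled molecules (C_is = conc * volume). The two differ by a constant
    factor equal to molecules_per_gradient and propagate directly into
    every inferred mass.
    """
    if convention not in IS_MASS_CONVENTIONS:
        raise ValidationError(f"unknown IS mass convention: {convention}")
    if spike_volume_ul <= 0:
        raise ValidationError("spike volume must be positive")
    missing = [m for m in panel.molecule_ids if not counts.has_category(m)]
    if missing:
        raise ValidationError(f"count table is missing IS molecules: {missing}")
    observations = []
    for level in range(1, panel.spec.n_gradients + 1):
        mols = panel.level_molecules(level)
        molecule_reads = {m.id: counts.reads_for(m.id) for m in mols}
        conc = panel.level_concentration(level)
        multiplier = len(mols) if convention == "per_molecule" else 1
        observations.append(
            ISObservation(
                gradient_level=level,
                cis_ng=multiplier * conc * spike_volume_ul,
                ris=float(sum(molecule_reads.values())),
                molecule_reads=molecule_reads,
            )
        )
    return observations


def fit_is_curve(
    observations: Sequence[ISObservation],
    fit_space: str = "log10",
) -> RegressionFit:
    """Ordinary least squares of detected IS reads on IS input mass.

    Zero-read levels are dropped with a warning (a pseudo-count would bias
    the intercept). Requires at least two usable levels and non-degenerate
    reads; ``r_squared`` is the squared Pearson correlation of the fitted
    variables.
    """
    if fit_space not in ("log10", "linear"):
        raise ValidationError("fit_space must be 'log10' or 'linear'")
    usable = [o for o in observations if o.ris > 0]
    dropped = tuple(o.gradient_level for o in observations if o.ris <= 0)
    if dropped:
        logger.warning("dropping zero-read IS gradient levels: %s", list(dropped))
    if len(usable) < 2:
        raise FitError(
            f"IS curve needs >= 2 gradient levels with reads; got {len(usable)} "
            f"(dropped levels: {list(dropped)})"
        )
    cis = np.array([o.cis_ng for o in usable], dtype=float)
    ris = np.array([o.ris for o in usable], dtype=float)
    if fit_space == "log10":
        x, y = np.log10(cis), np.log10(ris)
    else:
        x, y = cis, ris
    if np.ptp(y) == 0:
        raise FitError("degenerate IS curve: detected reads constant across gradients")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_space=fit_space,
        n_points_used=len(usable),
        dropped_levels=dropped,
    )


def mass_from_reads(
    rmic: float,
    fit: RegressionFit | None = None,
    mode: str = "curve",
    observations: Sequence[ISObservation] | None = None,
) -> float:
    """Invert microbial reads to input mass C_mic (ng).

    ``curve`` mode inverts the fitted line: C = 10**((log10 R - b) / a)
    (linear-space fits invert the line algebraically). ``ratio`` mode uses
    the mass law directly with the pooled IS ratio: C = R * sum(C_is)/sum(R_is).
    Zero reads always map to zero mass.
    """
    if rmic < 0:
        raise ValidationError("reads must be non-negative")
    if rmic == 0:
        return 0.0
    if mode == "curve":
        if fit is None:
            raise ValidationError("curve mode requires a RegressionFit")
        if fit.slope <= 0:
            raise QuantError(f"cannot invert IS curve with slope {fit.slope:g} <= 0")
        if fit.fit_space == "log10":
            return float(10.0 ** ((math.log10(rmic) - fit.intercept) / fit.slope))
        return float((rmic - fit.intercept) / fit.slope)
    if mode == "ratio":
        if not observations:
            raise ValidationError("ratio mode requires IS observations")
        total_ris = sum(o.ris for o in observations)
        if total_ris <= 0:
            raise QuantError("ratio mode undefined: no IS reads detected")
        total_cis = sum(o.cis_ng for o in observations)
        return float(rmic * total_cis / total_ris)
    raise ValidationError(f"unknown mode: {mode}")


def copies_from_mass(
    cmic_ng: float,
    lmic_bp: float,
    constants: Constants | None = None,
) -> float:
    """Genome copies from mass: COPY = C / (L * DNA_c)."""
    if lmic_bp is None or lmic_bp <= 0:
        raise ValidationError("genome length must be positive")
    if cmic_ng < 0:
        raise ValidationError("mass must be non-negative")
    constants = constants or Constants()
    return cmic_ng / (lmic_bp * constants.dnac_ng_per_bp)


# ---------------------------------------------------------------------------
# Sample-level driver
# ---------------------------------------------------------------------------

def load_genome_lengths(path: str | Path) -> dict[str, float]:
    """Genome-length TSV (columns: taxon_id, length_bp) to a mapping."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"taxon_id", "length_bp"} - set(frame.columns)
    if missing:
        raise ValidationError(f"genome length table missing columns: {sorted(missing)}")
    lengths = dict(zip(frame["taxon_id"], frame["length_bp"].astype(float)))
    if any(v <= 0 for v in lengths.values()):
        raise ValidationError("genome lengths must be positive")
    return lengths


@dataclass
class QuantResult:
    """Quantification of one sample: per-taxon results plus the IS fit."""

    quants: list[MicrobeQuant]
    fit: RegressionFit
    observations: list[ISObservation]
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon_id": q.taxon_id,
                    "reads": q.reads,
                    "mass_ng": q.mass_ng,
                    "genome_length_bp": q.genome_length,
                    "copies": q.copies,
                    "flags": ";".join(q.flags),
                }
                for q in self.quants
            ],
            columns=["taxon_id", "reads", "mass_ng", "genome_length_bp", "copies", "flags"],
        )

    def copies_by_taxon(self) -> dict[str, float]:
        return {q.taxon_id: q.copies for q in self.quants}

    def write(self, report_tsv: str | Path, fit_json: str | Path | None = None) -> None:
        self.to_frame().to_csv(report_tsv, sep="\t", index=False)
        if fit_json is not None:
            payload = {"fit": self.fit.to_dict(), "per_taxon_errors": self.errors}
            Path(fit_json).write_text(json.dumps(payload, indent=2) + "\n")


def quantify_sample(
    counts: ReadCountTable,
    panel: ISPanel,
    genome_lengths: Mapping[str, float],
    spike_volume_ul: float = 2.0,
    convention: str = "per_molecule",
    fit_space: str = "log10",
    mode: str = "curve",
    min_reads: float = 3,
    constants: Constants | None = None,
) -> QuantResult:
    """Quantify every microbial category of a count table.

    Rows of type ``taxon`` and ``contaminant`` are converted reads -> mass
    -> copies. Taxa below ``min_reads`` are still reported but flagged
    ``low_evidence``; a missing genome length yields a per-taxon error entry
    (copies NaN) rather than a global abort.
    """
    constants = constants or Constants()
    observations = is_observations(counts, panel, spike_volume_ul, convention)
    fit = fit_is_curve(observations, fit_space)
    microbial = counts.frame[counts.frame["category_type"].isin(["taxon", "contaminant"])]
    quants: list[MicrobeQuant] = []
    errors: dict[str, str] = {}
    for _, row in microbial.iterrows():
        taxon = str(row["category"])
        reads = float(row["reads"])
        mass = mass_from_reads(reads, fit=fit, mode=mode, observations=observations)
        flags: list[str] = []
        if reads < min_reads:
            flags.append("low_evidence")
        if row["category_type"] == "contaminant":
            flags.append("contaminant")
        length = genome_lengths.get(taxon)
        if length is None:
            errors[taxon] = "missing genome length"
            flags.append("missing_genome_length")
            copies = float("nan")
        else:
            copies = copies_from_mass(mass, length, constants)
        quants.append(
            MicrobeQuant(
                taxon_id=taxon,
                reads=reads,
                mass_ng=mass,
                genome_length=length,
                copies=copies,
                flags=tuple(flags),
            )
        )
    return QuantResult(quants=quants, fit=fit, observations=observations, errors=errors)
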