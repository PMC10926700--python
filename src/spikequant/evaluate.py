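"""Evaluation procedures: depth subsampling, gradient-ratio CV%, and
comparison of estimated copy numbers against a reference.

Depth stability is assessed the way a sequencing lab would: draw reads
without replacement (hypergeometric, mirroring `seqkit sample` on real
read sets) from one deep run at a ladder of target depths, many replicates
per depth, and summarise each adjacent IS gradient pair by the coefficient
of variation of its read ratio R_is(n)/R_is(n-1) across replicates.
Reference comparison pools Pearson correlation of log10 copies and runs a
per-taxon one-sample t-test of replicate estimates against the reference
value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import ReadCountTable
from .errors import ValidationError
from .panel import ISPanel

logger = logging.getLogger(__name__)

#: Depth ladder used for the standard sweep (reads).
DEFAULT_DEPTHS: tuple[int, ...] = (1_000_000, 5_000_000, 20_000_000, 35_000_000, 50_000_000)
DEFAULT_N_REPS = 20


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def subsample_counts(
    table: ReadCountTable,
    depth: int,
    n_reps: int,
    seed: int | np.random.SeedSequence = 0,
) -> list[ReadCountTable]:
    """Without-replacement subsamples of a count table.

    Each replicate is a multivariate-hypergeometric draw of ``depth`` reads
    from the table's integer counts; totals equal ``depth`` exactly and no
    category ever exceeds its source count.
    """
    counts = table.integer_counts()
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(f"requested depth {depth} exceeds table total {total}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    template = table.frame.loc[:, ["category", "category_type"]]
    replicates = []
    for _ in range(n_reps):
        draw = rng.multivariate_hypergeometric(counts, int(depth))
        frame = template.copy()
        frame["reads"] = draw.astype(float)
        replicates.append(ReadCountTable(frame))
    return replicates


# ---------------------------------------------------------------------------
# Gradient-ratio CV%
# ---------------------------------------------------------------------------

def _level_reads(table: ReadCountTable, panel: ISPanel) -> dict[int, float]:
    return {
        level: sum(table.reads_for(m.id) for m in panel.level_molecules(level))
        for level in range(1, panel.spec.n_gradients + 1)
    }


def gradient_ratio_cv(
    replicates: Sequence[ReadCountTable],
    panel: ISPanel,
) -> pd.DataFrame:
    """CV% of each adjacent-gradient IS read ratio across replicates.

    For level pairs (n, n-1) the statistic is 100 * sd / mean (sample sd,
    ddof=1) of R_is(n)/R_is(n-1) over replicates. A pair is flagged
    undefined when any replicate has a zero denominator or the mean ratio
    is zero.
    """
    if len(replicates) < 2:
        raise ValidationError("need at least two replicates for a CV")
    per_rep = [_level_reads(rep, panel) for rep in replicates]
    rows = []
    for level in range(2, panel.spec.n_gradients + 1):
        num = np.array([r[level] for r in per_rep], dtype=float)
        den = np.array([r[level - 1] for r in per_rep], dtype=float)
        if (den == 0).any():
            rows.append((f"L{level}/L{level - 1}", np.nan, np.nan, len(replicates), False))
            continue
        ratios = num / den
        mean = ratios.mean()
        if mean == 0:
            rows.append((f"L{level}/L{level - 1}", 0.0, np.nan, len(replicates), False))
            continue
        cv = 100.0 * ratios.std(ddof=1) / mean
        rows.append((f"L{level}/L{level - 1}", mean, cv, len(replicates), True))
    return pd.DataFrame(
        rows, columns=["level_pair", "mean_ratio", "cv_percent", "n_reps", "defined"]
    )


@dataclass
class SubsampleReport:
    """Tidy results of a depth sweep: per-replicate level reads and
    per-depth CV% of adjacent-gradient ratios."""

    ris: pd.DataFrame  # depth, replicate, gradient_level, ris
    cv: pd.DataFrame  # depth, level_pair, mean_ratio, cv_percent, n_reps, defined

    def write(self, ris_tsv: str | Path, cv_tsv: str | Path) -> None:
        self.ris.to_csv(ris_tsv, sep="\t", index=False)
        self.cv.to_csv(cv_tsv, sep="\t", index=False)


def depth_sweep(
    table: ReadCountTable,
    panel: ISPanel,
    depths: Sequence[int] = DEFAULT_DEPTHS,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> SubsampleReport:
    """Subsample at each depth of the ladder and summarise gradient-ratio
    CV% per depth. Each depth gets an independent child seed so single-depth
    reruns reproduce."""
    if max(depths) > table.total_reads:
        raise ValidationError("max depth exceeds the source table's total reads")
    ris_rows = []
    cv_frames = []
    for i, depth in enumerate(depths):
        reps = subsample_counts(table, int(depth), n_reps, np.random.SeedSequence([seed, i]))
        for r, rep in enumerate(reps, start=1):
            for level, reads in _level_reads(rep, panel).items():
                ris_rows.append((int(depth), r, level, reads))
        cv = gradient_ratio_cv(reps, panel)
        cv.insert(0, "depth", int(depth))
        cv_frames.append(cv)
    return SubsampleReport(
        ris=pd.DataFrame(ris_rows, columns=["depth", "replicate", "gradient_level", "ris"]),
        cv=pd.concat(cv_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Comparison against reference copies
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Pooled correlation plus per-taxon tests against reference copies."""

    pearson_r: float
    n_pairs: int
    per_taxon: pd.DataFrame  # taxon_id, n_reps, mean_log10_copies, ref_log10_copies, t_stat, p_value, flag
    excluded: list[str]

    def write(self, path: str | Path) -> None:
        self.per_taxon.to_csv(path, sep="\t", index=False)


def quants_to_frame(quant_sets: Sequence[Sequence]) -> pd.DataFrame:
    """Stack replicate lists of :class:`~spikequant.quant.MicrobeQuant` into
    a tidy (taxon_id, replicate, copies) frame."""
    rows = []
    for rep, quants in enumerate(quant_sets, start=1):
        for q in quants:
            rows.append((q.taxon_id, rep, q.copies))
    return pd.DataFrame(rows, columns=["taxon_id", "replicate", "copies"])


def compare_to_reference(
    quants: pd.DataFrame | Sequence[Sequence],
    ref_copies: Mapping[str, float],
) -> ComparisonReport:
    """Compare estimated copy numbers with reference values.

    ``quants`` is a tidy frame (taxon_id, replicate, copies) or a sequence
    of per-replicate MicrobeQuant lists. Non-positive or missing-reference
    entries are excluded from the log-scale analysis with a warning. The
    pooled statistic is Pearson r of log10 copies over all
    (taxon, replicate) pairs; per taxon, a two-sided one-sample t-test of
    replicate log10 copies against the log10 reference (an exact match at
    zero variance short-circuits to p = 1).
    """
    frame = quants if isinstance(quants, pd.DataFrame) else quants_to_frame(quants)
    missing = {"taxon_id", "replicate", "copies"} - set(frame.columns)
    if missing:
        raise ValidationError(f"quant frame missing columns: {sorted(missing)}")
    excluded = []
    keep = []
    for _, row in frame.iterrows():
        taxon = row["taxon_id"]
        ref = ref_copies.get(taxon)
        if ref is None or not np.isfinite(row["copies"]) or row["copies"] <= 0 or ref <= 0:
            excluded.append(str(taxon))
            continue
        keep.append((taxon, int(row["replicate"]), float(row["copies"]), float(ref)))
    if excluded:
        logger.warning("excluded %d entries from log-scale comparison: %s",
                       len(excluded), sorted(set(excluded)))
    if not keep:
        raise ValidationError("no usable (estimate, reference) pairs")
    tidy = pd.DataFrame(keep, columns=["taxon_id", "replicate", "copies", "ref"])
    if tidy["taxon_id"].nunique() < 2:
        raise ValidationError("pooled correlation needs at least two distinct taxa")
    est_log = np.log10(tidy["copies"].to_numpy())
    ref_log = np.log10(tidy["ref"].to_numpy())
    if np.allclose(est_log, ref_log):
        pearson_r = 1.0
    elif np.ptp(est_log) == 0 or np.ptp(ref_log) == 0:
        pearson_r = float("nan")  # correlation undefined for a constant margin
    else:
        pearson_r = float(stats.pearsonr(est_log, ref_log).statistic)
    rows = []
    for taxon, group in tidy.groupby("taxon_id", sort=False):
        vals = np.log10(group["copies"].to_numpy())
        ref_val = float(np.log10(group["ref"].iloc[0]))
        n = len(vals)
        if n < 2:
            t_stat, p_value = np.nan, np.nan
        elif np.ptp(vals) == 0:
            t_stat = np.nan
            p_value = 1.0 if np.isclose(vals[0], ref_val) else 0.0
        else:
            res = stats.ttest_1samp(vals, ref_val)
            t_stat, p_value = float(res.statistic), float(res.pvalue)
        flag = "**" if p_value < 0.01 else ("*" if p_value < 0.05 else "")
        rows.append((taxon, n, float(vals.mean()), ref_val, t_stat, p_value, flag))
    per_taxon = pd.DataFrame(
        rows,
        columns=["taxon_id", "n_reps", "mean_log10_copies", "ref_log10_copies",
                 "t_stat", "p_value", "flag"],
    )
    return ComparisonReport(
        pearson_r=pearson_r,
        n_pairs=len(tidy),
        per_taxon=per_taxon,
        excluded=sorted(set(excluded)),
    )
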