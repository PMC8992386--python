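"""Weighted donor-segment calling and library characterization.

The estimator is the classic rule-based graphical-genotype one used for SSR
introgression libraries: the interval between two markers homozygous for the
donor genotype (a DD interval) is counted as fully introgressed (weight 1.0);
an interval flanked by one donor-type and one recurrent-type marker (DR) is
counted at half weight (0.5), reflecting that the true breakpoint is unknown
within it; an RR interval contributes nothing. Chromosome-end intervals
adjacent to a terminal donor marker are treated like DR (weight 0.5), the end
acting as an unknown-genotype pseudo-marker. Donor genome proportion is
sum(weight x span) / genome size and background recovery is its complement.

Heterozygous calls physically carry a donor segment; by default they are
treated as donor-carrying for segment calling (``het="donor"``); ``het="ignore"``
treats them as missing. Missing markers are removed before the rules are
applied, so intervals are defined by nearest informative neighbours.

Coordinates: marker positions are 1-based bp; a chromosome is treated as the
span [0, L] so that segment length is always ``end - start`` and an end flank
up to the first marker at position p has span p.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io_core import GenomeSpec, GenotypeMatrix, MarkerMap

log = logging.getLogger(__name__)

MB = 1_000_000  # 1 Mb = 1,000,000 bp exactly

DONOR_WEIGHT = 1.0
FLANK_WEIGHT = 0.5


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for all reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SegmentSet:
    """Weighted donor intervals for one IL.

    ``pieces`` holds the elementary weighted intervals (cores at weight 1.0,
    flanks at 0.5); ``merged`` holds one interval per contiguous donor run
    with its flanks folded in, which is the unit reported as "a segment".
    """

    il_id: str
    pieces: pd.DataFrame  # chromosome, start, end, weight
    merged: pd.DataFrame  # chromosome, start, end

    def weighted_length(self) -> float:
        if self.pieces.empty:
            return 0.0
        p = self.pieces
        return float(((p["end"] - p["start"]) * p["weight"]).sum())

    @property
    def n_segments(self) -> int:
        return len(self.merged)


@dataclass
class ILProfile:
    il_id: str
    donor: str
    segments: SegmentSet
    donor_proportion: float
    background_recovery: float = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.donor_proportion <= 1.0:
            raise ValueError(f"donor proportion {self.donor_proportion} outside [0, 1]")
        self.background_recovery = 1.0 - self.donor_proportion


def _informative(calls: np.ndarray, positions: np.ndarray, het: str):
    """Reduce one chromosome's calls to informative (donor/recurrent) markers.

    Returns positions and a boolean donor-state array, with NA (and H when
    ``het='ignore'``) removed.
    """
    calls = np.asarray(calls, dtype=object)
    if het == "donor":
        state = np.where(calls == "R", 0, np.where((calls == "D") | (calls == "H"), 1, -1))
    elif het == "ignore":
        state = np.where(calls == "R", 0, np.where(calls == "D", 1, -1))
    else:
        raise ValueError(f"unknown het policy {het!r}")
    keep = state >= 0
    return positions[keep], state[keep].astype(bool)


def call_segments(
    calls: pd.Series | dict,
    marker_map: MarkerMap,
    genome: GenomeSpec,
    il_id: str = "",
    het: str = "donor",
) -> SegmentSet:
    """Call weighted donor segments for one IL from its marker calls.

    ``calls`` maps marker_id -> internal code, aligned with ``marker_map``.
    For each maximal run of donor-carrying informative markers the span
    between the outermost run markers is a weight-1.0 piece, and the interval
    to the adjacent informative recurrent marker (or to the chromosome end)
    on each side is a weight-0.5 flank.
    """
    calls = pd.Series(calls)
    pieces: list[tuple] = []
    merged: list[tuple] = []
    for chrom in genome.chromosomes:
        cm = marker_map.chromosome_markers(chrom)
        if cm.empty:
            continue
        chrom_calls = calls.reindex(cm["marker_id"]).fillna("NA").to_numpy()
        pos, donor = _informative(chrom_calls, cm["position_bp"].to_numpy(), het)
        if len(pos) == 0:
            log.warning("IL %s: chromosome %s has no informative calls", il_id, chrom)
            continue
        L = genome.lengths[chrom]
        # maximal runs of donor-carrying markers
        i = 0
        while i < len(pos):
            if not donor[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(pos) and donor[j + 1]:
                j += 1
            run_start, run_end = float(pos[i]), float(pos[j])
            if run_end > run_start:
                pieces.append((chrom, run_start, run_end, DONOR_WEIGHT))
            left = 0.0 if i == 0 else float(pos[i - 1])
            right = float(L) if j == len(pos) - 1 else float(pos[j + 1])
            if run_start > left:
                pieces.append((chrom, left, run_start, FLANK_WEIGHT))
            if right > run_end:
                pieces.append((chrom, run_end, right, FLANK_WEIGHT))
            merged.append((chrom, left, right))
            i = j + 1
    return SegmentSet(
        il_id,
        pd.DataFrame(pieces, columns=["chromosome", "start", "end", "weight"]),
        pd.DataFrame(merged, columns=["chromosome", "start", "end"]),
    )


def donor_proportion(segments: SegmentSet, genome: GenomeSpec) -> float:
    """Weighted donor length over total genome size (DD + half DR)."""
    return segments.weighted_length() / genome.total_size


def profile_library(
    genotypes: GenotypeMatrix, marker_map: MarkerMap, genome: GenomeSpec, het: str = "donor"
) -> list[ILProfile]:
    """Call segments and donor proportions for every IL in a genotype matrix."""
    profiles = []
    for il_id, row in genotypes.calls.iterrows():
        segs = call_segments(row, marker_map, genome, il_id=str(il_id), het=het)
        profiles.append(
            ILProfile(
                il_id=str(il_id),
                donor=genotypes.donor_of_il.get(il_id, ""),
                segments=segs,
                donor_proportion=donor_proportion(segs, genome),
            )
        )
    return profiles


def _union_length(intervals: np.ndarray) -> float:
    """Total length of the union of [start, end) spans (n x 2 array)."""
    if len(intervals) == 0:
        return 0.0
    iv = intervals[np.argsort(intervals[:, 0])]
    total, cur_s, cur_e = 0.0, iv[0, 0], iv[0, 1]
    for s, e in iv[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return float(total + (cur_e - cur_s))


def library_coverage(profiles: list[ILProfile], genome: GenomeSpec) -> pd.DataFrame:
    """Per-chromosome (and genome-wide) percent of the genome covered by donor
    segments of any weight in at least one IL."""
    if not profiles:
        raise ValueError("library_coverage requires at least one profile")
    rows = []
    covered_total = 0.0
    for chrom in genome.chromosomes:
        spans = []
        for p in profiles:
            pc = p.segments.pieces
            if pc.empty:
                continue
            sub = pc[pc["chromosome"] == chrom]
            spans.extend(zip(sub["start"], sub["end"]))
        length = _union_length(np.array(spans, dtype=float).reshape(-1, 2))
        covered_total += length
        rows.append((chrom, 100.0 * length / genome.lengths[chrom]))
    df = pd.DataFrame(rows, columns=["chromosome", "coverage_pct"])
    df.loc[len(df)] = ("genome", 100.0 * covered_total / genome.total_size)
    return df


def segment_stats(profiles: list[ILProfile], genome: GenomeSpec) -> dict:
    """Library summary: segment counts, merged-segment length range/mean (Mb),
    and mean background recovery (%), as reported for IL libraries."""
    lengths_mb = []
    n_per_il = {}
    n_per_chrom = {c: 0 for c in genome.chromosomes}
    for p in profiles:
        n_per_il[p.il_id] = p.segments.n_segments
        for row in p.segments.merged.itertuples(index=False):
            lengths_mb.append((row.end - row.start) / MB)
            n_per_chrom[row.chromosome] += 1
    if not lengths_mb:
        return {
            "empty": True,
            "n_ils": len(profiles),
            "n_segments": 0,
            "segments_per_chromosome": float("nan"),
            "length_min_mb": float("nan"),
            "length_max_mb": float("nan"),
            "length_mean_mb": float("nan"),
            "mean_background_recovery_pct": 100.0 if profiles else float("nan"),
            "n_per_il": n_per_il,
            "n_per_chrom": n_per_chrom,
        }
    lengths_mb = np.asarray(lengths_mb)
    return {
        "empty": False,
        "n_ils": len(profiles),
        "n_segments": int(lengths_mb.size),
        "segments_per_chromosome": lengths_mb.size / len(genome.chromosomes),
        "length_min_mb": float(lengths_mb.min()),
        "length_max_mb": float(lengths_mb.max()),
        "length_mean_mb": float(lengths_mb.mean()),
        "mean_background_recovery_pct": 100.0 * float(np.mean([p.background_recovery for p in profiles])),
        "n_per_il": n_per_il,
        "n_per_chrom": n_per_chrom,
    }


def polymorphism_summary(marker_map: MarkerMap, donor: str, mode: str = "weighted") -> pd.DataFrame:
    """Per-chromosome marker polymorphism rates (%) for one donor plus a mean row.

    ``weighted`` mean = total polymorphic / total markers; ``simple`` mean =
    arithmetic mean of the per-chromosome rates. Percentages are rounded
    half-up to 2 decimals at this reporting layer.
    """
    if donor not in marker_map.polymorphic:
        raise KeyError(f"no polymorphism flags for donor {donor!r}")
    flags = marker_map.polymorphic[donor]
    t = marker_map.table
    rows = []
    rates = []
    n_poly_total = 0
    for chrom in marker_map.genome.chromosomes:
        idx = (t["chromosome"] == chrom).to_numpy()
        n = int(idx.sum())
        if n == 0:
            continue
        k = int(flags[idx].sum())
        n_poly_total += k
        rate = 100.0 * k / n
        rates.append(rate)
        rows.append((chrom, n, k, round_half_up(rate)))
    if mode == "weighted":
        mean = 100.0 * n_poly_total / len(t)
    elif mode == "simple":
        mean = float(np.mean(rates))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.DataFrame(rows, columns=["chromosome", "n_markers", "n_polymorphic", "rate_pct"])
    df.loc[len(df)] = ("mean", len(t), n_poly_total, round_half_up(mean))
    return df


def marker_density(marker_map: MarkerMap) -> pd.DataFrame:
    """Mean inter-marker interval (Mb) per chromosome and its overall mean.

    Per chromosome the density is the chromosome's mean marker spacing; the
    summary value is the arithmetic mean of the per-chromosome densities.
    """
    rows = []
    for chrom in marker_map.genome.chromosomes:
        pos = marker_map.chromosome_markers(chrom)["position_bp"].to_numpy()
        if len(pos) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 markers, density undefined")
            continue
        rows.append((chrom, len(pos), float(np.diff(pos).mean()) / MB))
    df = pd.DataFrame(rows, columns=["chromosome", "n_markers", "density_mb"])
    df.loc[len(df)] = ("mean", df["n_markers"].sum(), round_half_up(df["density_mb"].mean()))
    return df


def segments_table(profiles: list[ILProfile]) -> pd.DataFrame:
    """Flat per-IL weighted-piece table (il_id, chromosome, start, end, weight)."""
    frames = []
    for p in profiles:
        if p.segments.pieces.empty:
            continue
        t = p.segments.pieces.copy()
        t.insert(0, "il_id", p.il_id)
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["il_id", "chromosome", "start", "end", "weight"])
    return pd.concat(frames, ignore_index=True)
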