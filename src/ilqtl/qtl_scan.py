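"""Binomial donor-allele enrichment scan for trait-linked loci.

Given the set of ILs whose trait differs significantly from the recurrent
parent, each marker is tested for enrichment of the donor genotype among
those ILs: with n informative significant ILs of which k carry the donor
allele, the score is the one-sided binomial tail P(X >= k), X ~ Bin(n, p0).
A locus whose donor rate among trait-selected lines significantly exceeds
its expected rate p0 is declared linked.

p0 can be the per-locus donor-carrier frequency across the whole genotyped
library of that donor (default; trait-based line selection distorts
genome-wide expectations, so the locus's own library frequency is the
appropriate null), the genome-wide mean frequency, or the pedigree
expectation 2^-(b+1) after b backcrosses.

Scans run separately on increase- and decrease-direction significant sets;
loci are then consolidated across donor species, classified by direction,
and annotated as known or novel against a set of published loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GenotypeMatrix, KnownLociSet, MarkerMap

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1e-3
DEFAULT_NOVELTY_WINDOW = 2_500_000  # bp, about one marker interval

#: calls counted as donor-carrying, consistent with the segments module
DONOR_CARRYING = ("D", "H")


def theoretical_p0(n_backcrosses: int) -> float:
    """Expected donor-genotype rate after b backcrosses: 2^-(b+1)."""
    if n_backcrosses < 1:
        raise ValueError("need at least one backcross")
    return 2.0 ** -(n_backcrosses + 1)


def expected_p0(
    mode: str,
    genotypes: GenotypeMatrix | None = None,
    n_backcrosses: int | None = None,
) -> pd.Series | float:
    """Null donor-carrier rate per locus.

    ``empirical_locus`` -> Series over markers (donor-carrier frequency among
    all genotyped ILs of the donor); ``empirical_genome`` -> single rate over
    all calls; ``theoretical`` -> 2^-(b+1). Empirical rates of exactly 0 or 1
    are clamped to [1/(2N), 1 - 1/(2N)].
    """
    if mode == "theoretical":
        if n_backcrosses is None:
            raise ValueError("theoretical mode requires n_backcrosses")
        return theoretical_p0(n_backcrosses)
    if genotypes is None:
        raise ValueError(f"{mode} mode requires the genotyped library")
    calls = genotypes.calls
    informative = calls != "NA"
    donor = calls.isin(DONOR_CARRYING)
    n_lines = len(calls)
    lo, hi = 1.0 / (2 * n_lines), 1.0 - 1.0 / (2 * n_lines)
    if mode == "empirical_locus":
        with np.errstate(invalid="ignore"):
            freq = donor.sum(axis=0) / informative.sum(axis=0)
        clamped = (freq < lo) | (freq > hi)
        for m in freq.index[clamped.fillna(False)]:
            log.warning("marker %s: empirical donor rate %.4g clamped", m, freq[m])
        return freq.clip(lo, hi)
    if mode == "empirical_genome":
        rate = float(donor.to_numpy().sum()) / float(informative.to_numpy().sum())
        return min(max(rate, lo), hi)
    raise ValueError(f"unknown p0 mode {mode!r}")


def binomial_tail(k: int, n: int, p0: float) -> float:
    """One-sided upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass
class ScanResult:
    marker_id: str
    trait: str
    donor: str
    direction: str
    n_sig: int
    k_donor: int
    p0: float
    p_value: float
    linked: bool


def binomial_scan(
    sig_ils: list[str],
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    p0: pd.Series | float,
    threshold: float = DEFAULT_THRESHOLD,
    trait: str = "",
    donor: str = "",
    direction: str = "",
    bh_column: bool = True,
) -> pd.DataFrame:
    """Score every marker for donor enrichment among the significant ILs.

    Returns one row per marker with k_donor, n_sig, p0, the raw one-sided
    binomial p-value, an optional Benjamini-Hochberg column, and the linkage
    flag at ``threshold`` (applied to the raw p-value, as no across-locus
    correction is part of the scoring rule).
    """
    if not sig_ils:
        raise ValueError("significant-IL set is empty")
    missing = [i for i in sig_ils if i not in set(genotypes.il_ids)]
    if missing:
        raise KeyError(f"significant IL {missing[0]!r} has no genotype row")
    sub = genotypes.calls.loc[sig_ils]
    rows = []
    for marker in sub.columns:
        col = sub[marker]
        informative = col != "NA"
        n = int(informative.sum())
        if n == 0:
            log.warning("marker %s: all calls missing in significant set; skipped", marker)
            continue
        k = int(col.isin(DONOR_CARRYING).sum())
        p0_m = float(p0[marker]) if isinstance(p0, pd.Series) else float(p0)
        rows.append((marker, trait, donor, direction, n, k, p0_m, binomial_tail(k, n, p0_m)))
    df = pd.DataFrame(
        rows, columns=["marker_id", "trait", "donor", "direction", "n_sig", "k_donor", "p0", "p_value"]
    )
    pos = marker_map.table.set_index("marker_id")
    df["chromosome"] = df["marker_id"].map(pos["chromosome"])
    df["position_bp"] = df["marker_id"].map(pos["position_bp"])
    if bh_column:
        df["p_bh"] = _benjamini_hochberg(df["p_value"].to_numpy())
    df["linked"] = df["p_value"] < threshold
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def classify_direction(scans: pd.DataFrame) -> pd.DataFrame:
    """Direction class per linked (marker, trait, donor) group.

    ``increase-only`` if linked only in increase-direction scans,
    ``decrease-only`` for the converse, ``both`` when linked in both.
    Loci linked nowhere are excluded.
    """
    linked = scans[scans["linked"]]
    rows = []
    for (marker, trait), grp in linked.groupby(["marker_id", "trait"]):
        dirs = set(grp["direction"])
        cls = "both" if dirs == {"increase", "decrease"} else f"{next(iter(dirs))}-only"
        rows.append((marker, trait, cls))
    return pd.DataFrame(rows, columns=["marker_id", "trait", "direction_class"])


def consolidate_across_donors(scans: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    """Group linked scan hits by (marker, trait) across donors.

    Returns one row per consolidated locus with the set of donors, the number
    of distinct donor species, and the direction class; the multiplicity
    histogram (loci hit in exactly m donors) is obtainable with
    :func:`multiplicity_histogram`.
    """
    linked = scans[scans["linked"]]
    direction = classify_direction(scans).set_index(["marker_id", "trait"])["direction_class"]
    rows = []
    for (marker, trait), grp in linked.groupby(["marker_id", "trait"]):
        donors = sorted(set(grp["donor"]))
        rows.append(
            (
                marker,
                trait,
                ",".join(donors),
                len(donors),
                direction.loc[(marker, trait)],
                float(grp["p_value"].min()),
            )
        )
    df = pd.DataFrame(
        rows, columns=["marker_id", "trait", "donors", "n_donor_species", "direction_class", "min_p"]
    )
    pos = marker_map.table.set_index("marker_id")
    df["chromosome"] = df["marker_id"].map(pos["chromosome"])
    df["position_bp"] = df["marker_id"].map(pos["position_bp"])
    return df.sort_values(["trait", "chromosome", "position_bp"]).reset_index(drop=True)


def multiplicity_histogram(consolidated: pd.DataFrame, trait: str | None = None) -> dict[int, int]:
    """How many consolidated loci were detected in exactly m donor species."""
    sub = consolidated if trait is None else consolidated[consolidated["trait"] == trait]
    counts = sub["n_donor_species"].value_counts().sort_index()
    return {int(m): int(c) for m, c in counts.items()}


def annotate_novelty(
    consolidated: pd.DataFrame,
    known: KnownLociSet,
    window: int = DEFAULT_NOVELTY_WINDOW,
) -> pd.DataFrame:
    """Flag each consolidated locus as known or novel.

    A locus is "known" when it lies inside a known-locus interval on the same
    chromosome, or strictly closer than ``window`` bp to one, with matching
    trait tags (an untagged known locus matches any trait). A marker exactly
    ``window`` bp beyond an interval end is therefore novel. The nearest
    known locus and its distance are always reported.
    """
    out = consolidated.copy()
    novelty, nearest, distance = [], [], []
    entries = known.entries
    for row in out.itertuples(index=False):
        cand = entries[entries["chromosome"] == row.chromosome] if len(entries) else entries
        best_name, best_dist, is_known = "", np.inf, False
        for e in cand.itertuples(index=False):
            tags = [t for t in str(e.traits).split(",") if t]
            if tags and row.trait not in tags:
                continue
            if e.start > row.position_bp:
                d = e.start - row.position_bp
            elif e.end < row.position_bp:
                d = row.position_bp - e.end
            else:
                d = 0
            if d < best_dist:
                best_dist, best_name = d, e.name
            if d == 0 or d < window:
                is_known = True
        novelty.append("known" if is_known else "novel")
        nearest.append(best_name)
        distance.append(best_dist if np.isfinite(best_dist) else np.nan)
    out["novelty"] = novelty
    out["nearest_known"] = nearest
    out["distance_bp"] = distance
    return out


def merge_adjacent_linked(scan: pd.DataFrame, marker_map: MarkerMap) -> pd.DataFrame:
    """Optionally fuse linked markers that are adjacent on the map into one
    reported locus (anchored at the member with the smallest p-value)."""
    linked = scan[scan["linked"]].copy()
    if linked.empty:
        return linked.assign(n_markers=pd.Series(dtype=int))
    order = {m: i for i, m in enumerate(marker_map.marker_ids)}
    linked["_idx"] = linked["marker_id"].map(order)
    linked = linked.sort_values("_idx")
    groups, cur = [], [linked.iloc[0]]
    for _, row in linked.iloc[1:].iterrows():
        prev = cur[-1]
        if row["chromosome"] == prev["chromosome"] and row["_idx"] == prev["_idx"] + 1:
            cur.append(row)
        else:
            groups.append(cur)
            cur = [row]
    groups.append(cur)
    rows = []
    for g in groups:
        best = min(g, key=lambda r: r["p_value"])
        rows.append({**best.drop("_idx").to_dict(), "n_markers": len(g)})
    return pd.DataFrame(rows).reset_index(drop=True)
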