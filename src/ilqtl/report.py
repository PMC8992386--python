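"""Pipeline orchestration, library summary reports, and the run manifest.

Also hosts the published-table helpers: the printed marker/library
description tables bundled with the package can be re-expanded into marker
maps with polymorphism flags, so the reporting arithmetic (weighted vs
simple polymorphism means, marker densities, structural sums) is reproduced
by the same operations that serve simulated or user data.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import shutil
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io_core, qtl_scan, segments, simulate, trait_tests
from .config import RunConfig
from .io_core import GenomeSpec, MarkerMap
from .segments import MB, round_half_up

log = logging.getLogger(__name__)

DONOR_LABELS = [
    "O_barthii",
    "O_glumaepatula",
    "O_meridionalis",
    "O_nivara",
    "O_rufipogon",
    "O_glaberrima",
    "upland_rice",
]


# ---------------------------------------------------------------------------
# published printed tables
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("ilqtl") / "data" / name)


def published_marker_table() -> pd.DataFrame:
    """The printed per-chromosome marker panel description (counts, density,
    per-donor polymorphism rates in %)."""
    return pd.read_csv(_data_path("published_marker_table.tsv"), sep="\t", comment="#")


def published_library_table() -> pd.DataFrame:
    """The printed per-donor library characterization table."""
    return pd.read_csv(_data_path("published_library_table.tsv"), sep="\t", comment="#")


def marker_map_from_printed(
    table: pd.DataFrame | None = None, equal_denominator: int | None = None
) -> MarkerMap:
    """Expand the printed marker table into a MarkerMap with polymorphism flags.

    Positions are placeholders (1 Mb grid). By default each chromosome keeps
    its printed marker count and the per-donor polymorphic counts are
    reconstructed as round(rate x n / 100) — exact whenever the printed rate
    came from an integer count, which holds for the wild-species donors and
    is what the weighted mean needs. With ``equal_denominator`` every
    chromosome instead carries that many markers with exactly
    rate x denominator / 100 of them flagged, which realizes each printed
    percentage exactly (some printed rates, e.g. 83.34% of 10 markers, do not
    correspond to an integer count at the printed panel size) and is the
    right input for the simple (per-chromosome-average) mean. The result
    feeds :func:`ilqtl.segments.polymorphism_summary` unchanged.
    """
    if table is None:
        table = published_marker_table()
    rows = []
    flags: dict[str, list[bool]] = {d: [] for d in table.columns if d in DONOR_LABELS}
    lengths = {}
    for r in table.itertuples(index=False):
        n = equal_denominator if equal_denominator is not None else int(r.n_markers)
        lengths[str(r.chromosome)] = n * MB
        for donor in flags:
            k = int(round_half_up(getattr(r, donor) * n / 100.0, 0))
            flags[donor].extend([True] * k + [False] * (n - k))
        for j in range(n):
            rows.append((f"P{r.chromosome}_{j + 1}", str(r.chromosome), (j + 1) * MB))
    mm = MarkerMap(
        pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]),
        GenomeSpec(lengths),
        {d: np.asarray(f) for d, f in flags.items()},
    )
    return mm


def printed_density_mean(table: pd.DataFrame | None = None) -> float:
    """Mean inter-marker interval (Mb) as the mean of the printed
    per-chromosome densities, half-up rounded to 2 decimals."""
    if table is None:
        table = published_marker_table()
    return round_half_up(float(table["density_mb"].mean()))


# ---------------------------------------------------------------------------
# library summaries
# ---------------------------------------------------------------------------

def summarize_library(
    marker_map: MarkerMap,
    genotypes: io_core.GenotypeMatrix,
    profiles: list[segments.ILProfile],
) -> dict[str, pd.DataFrame]:
    """Marker-panel and per-donor library summary tables.

    ``markers``: per-chromosome marker count, density (Mb) and polymorphism
    rates (both weighted and simple means). ``library``: per-donor IL count,
    segment count, segments per chromosome, merged-segment length range/mean
    (Mb) and mean background recovery (%). ``coverage``: per-donor
    per-chromosome coverage (%).
    """
    genome = marker_map.genome
    density = segments.marker_density(marker_map)
    marker_rows = density.rename(columns={"density_mb": "density_mb"})
    for donor in marker_map.polymorphic:
        w = segments.polymorphism_summary(marker_map, donor, mode="weighted")
        s = segments.polymorphism_summary(marker_map, donor, mode="simple")
        col = w.set_index("chromosome")["rate_pct"]
        marker_rows[f"poly_{donor}_pct"] = marker_rows["chromosome"].map(col)
        # the mean row differs between modes; report both
        marker_rows.loc[marker_rows["chromosome"] == "mean", f"poly_{donor}_pct"] = float(
            w["rate_pct"].iloc[-1]
        )
        marker_rows[f"poly_{donor}_simple_mean"] = float(s["rate_pct"].iloc[-1])

    donors = sorted({d for d in genotypes.donor_of_il.values()}) or [""]
    lib_rows, cov_frames = [], []
    by_donor = {d: [p for p in profiles if p.donor == d] for d in donors}
    for donor, prof in by_donor.items():
        if not prof:
            lib_rows.append((donor, 0, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        st = segments.segment_stats(prof, genome)
        lib_rows.append(
            (
                donor,
                st["n_ils"],
                st["n_segments"],
                round_half_up(st["segments_per_chromosome"]) if not st["empty"] else np.nan,
                st["length_min_mb"],
                st["length_max_mb"],
                st["length_mean_mb"],
                round_half_up(st["mean_background_recovery_pct"]),
            )
        )
        cov = segments.library_coverage(prof, genome)
        cov.insert(0, "donor", donor)
        cov["coverage_pct"] = cov["coverage_pct"].map(round_half_up)
        cov_frames.append(cov)
    library = pd.DataFrame(
        lib_rows,
        columns=[
            "donor",
            "n_ils",
            "n_segments",
            "segments_per_chromosome",
            "length_min_mb",
            "length_max_mb",
            "length_mean_mb",
            "background_recovery_pct",
        ],
    )
    coverage = pd.concat(cov_frames, ignore_index=True) if cov_frames else pd.DataFrame(
        columns=["donor", "chromosome", "coverage_pct"]
    )
    return {"markers": marker_rows, "library": library, "coverage": coverage}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, quiet: bool = False) -> dict:
    """Run io -> segments -> trait screen -> scan end to end; write all
    artifacts plus a JSON manifest under ``config.output_dir``."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
        "inputs": {},
    }
    try:
        # ---- stage: inputs -------------------------------------------------
        if config.simulate:
            sim = config.sim_config()
            marker_map = simulate.build_marker_map(sim)
            ils = simulate.run_breeding_scheme(sim, marker_map)
            genotypes, phenotypes, truth = simulate.library_tables(ils, sim, marker_map)
            genome = sim.genome
            io_core.write_genome(genome, out / "genome.tsv")
            io_core.write_marker_map(marker_map, out / "marker_map.tsv")
            io_core.write_genotypes(genotypes, out / "genotypes.tsv")
            io_core.write_phenotypes(phenotypes, out / "phenotypes.tsv")
            io_core.write_table(truth, out / "truth_donor_proportion.tsv")
            io_core.write_table(simulate.true_segments_table(ils), out / "truth_segments.tsv")
            known = io_core.KnownLociSet(
                pd.DataFrame(columns=["name", "chromosome", "start", "end", "traits"])
            )
        else:
            for key, path in config.inputs.items():
                p = Path(path)
                if not p.exists():
                    raise FileNotFoundError(f"input {key!r}: no such file {path}")
                manifest["inputs"][key] = _digest(p)
            genome = io_core.read_genome(config.inputs["genome"])
            marker_map = io_core.read_marker_map(config.inputs["marker_map"], genome)
            genotypes = io_core.read_genotypes(config.inputs["genotypes"], marker_map)
            phenotypes = io_core.read_phenotypes(config.inputs["phenotypes"], config.control_id)
            known = (
                io_core.read_known_loci(config.inputs["known_loci"])
                if "known_loci" in config.inputs
                else io_core.KnownLociSet(
                    pd.DataFrame(columns=["name", "chromosome", "start", "end", "traits"])
                )
            )
        manifest["stages"]["io"] = {"n_ils": len(genotypes.il_ids), "n_markers": len(marker_map.table)}

        # ---- stage: segments ----------------------------------------------
        profiles = segments.profile_library(genotypes, marker_map, genome, het=config.het)
        seg_table = segments.segments_table(profiles)
        io_core.write_table(seg_table, out / "segments.tsv")
        summary = summarize_library(marker_map, genotypes, profiles)
        io_core.write_table(summary["markers"], out / "report_markers.tsv")
        io_core.write_table(summary["library"], out / "report_library.tsv")
        io_core.write_table(summary["coverage"], out / "report_coverage.tsv")
        manifest["stages"]["segments"] = {"n_rows": len(seg_table)}

        # ---- stage: trait screen -------------------------------------------
        screen = trait_tests.screen_traits(
            phenotypes, alpha=config.alpha, variance_model=config.variance_model
        )
        io_core.write_table(screen, out / "trait_tests.tsv")
        manifest["stages"]["trait_tests"] = {
            "n_rows": len(screen),
            "alpha": config.alpha,
            "variance_model": config.variance_model,
            "per_environment": True,
            "n_significant": int(screen["significant"].sum()),
        }

        # ---- stage: scan ----------------------------------------------------
        sig_sets = trait_tests.significant_sets(screen)
        donors = sorted(set(genotypes.donor_of_il.values())) or [""]
        scan_frames = []
        for (trait, direction), ils_sig in sig_sets.items():
            for donor in donors:
                sub = genotypes.for_donor(donor) if donor else genotypes
                ids = [i for i in ils_sig if i in set(sub.il_ids)]
                if not ids:
                    continue
                p0 = qtl_scan.expected_p0(
                    config.p0_mode,
                    genotypes=sub,
                    n_backcrosses=config.n_backcrosses,
                )
                scan_frames.append(
                    qtl_scan.binomial_scan(
                        ids, sub, marker_map, p0, threshold=config.scan_threshold,
                        trait=trait, donor=donor, direction=direction,
                    )
                )
        if scan_frames:
            scan = pd.concat(scan_frames, ignore_index=True)
            consolidated = qtl_scan.consolidate_across_donors(scan, marker_map)
            consolidated = qtl_scan.annotate_novelty(consolidated, known, config.novelty_window_bp)
            if config.merge_adjacent:
                io_core.write_table(
                    qtl_scan.merge_adjacent_linked(scan, marker_map), out / "scan_merged.tsv"
                )
        else:
            scan = pd.DataFrame(
                columns=["marker_id", "trait", "donor", "direction", "n_sig", "k_donor",
                         "p0", "p_value", "chromosome", "position_bp", "p_bh", "linked"]
            )
            consolidated = pd.DataFrame(
                columns=["marker_id", "trait", "donors", "n_donor_species", "direction_class",
                         "min_p", "chromosome", "position_bp", "novelty", "nearest_known",
                         "distance_bp"]
            )
        io_core.write_table(scan, out / "scan.tsv")
        io_core.write_table(consolidated, out / "consolidated_loci.tsv")
        manifest["stages"]["qtl_scan"] = {
            "n_rows": len(scan),
            "p0_mode": config.p0_mode,
            "threshold": config.scan_threshold,
            "n_linked": int(scan["linked"].sum()) if len(scan) else 0,
            "n_consolidated": len(consolidated),
            "multiplicity_histogram": qtl_scan.multiplicity_histogram(consolidated)
            if len(consolidated)
            else {},
        }
        manifest["runtime_s"] = round(time.time() - t0, 3)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    except Exception:
        # no partial artifact sets: remove what this run wrote
        if not quiet:
            log.exception("pipeline failed; removing partial outputs in %s", out)
        shutil.rmtree(out, ignore_errors=True)
        raise
    if not quiet:
        log.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return manifest


def plot_graphical_genotype(profile: segments.ILProfile, genome: GenomeSpec, path) -> None:
    """Chromosome bars with donor segments for one IL (graphical genotype)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = genome.chromosomes
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(chroms) + 1))
    for y, chrom in enumerate(chroms):
        ax.barh(y, genome.lengths[chrom] / MB, color="0.9", edgecolor="0.4", height=0.6)
        pc = profile.segments.pieces
        for row in pc[pc["chromosome"] == chrom].itertuples(index=False):
            color = "tab:red" if row.weight == 1.0 else "tab:orange"
            ax.barh(y, (row.end - row.start) / MB, left=row.start / MB, color=color, height=0.6)
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (Mb)")
    ax.set_title(f"{profile.il_id} (donor {profile.donor}, "
                 f"introgression {100 * profile.donor_proportion:.2f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
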