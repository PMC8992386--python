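"""Tabular input/output with validated schemas and explicit coordinate conventions.

Conventions used throughout the package:

* Marker positions are 1-based physical coordinates in base pairs.
* Intervals stored internally (known loci, donor segments) are closed on both
  ends; BED input (0-based, half-open) is converted on ingest.
* Genotype calls use the four-symbol internal alphabet ``R`` (homozygous
  recurrent), ``D`` (homozygous donor), ``H`` (heterozygous), ``NA`` (missing).
* Every table writer emits a ``#ilqtl-v1`` format header as its first line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FORMAT_HEADER = "#ilqtl-v1"

#: internal genotype alphabet
CODES = ("R", "D", "H", "NA")

#: default on-disk symbol dialect (file symbol -> internal code)
DEFAULT_DIALECT = {"R": "R", "D": "D", "H": "H", "-": "NA"}

#: reserved phenotype-table id for the recurrent parent (control) rows
CONTROL_ID = "__CONTROL__"


class SchemaError(ValueError):
    """Raised when an input file violates its schema or an invariant."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths in base pairs."""

    lengths: dict[str, int]

    def __post_init__(self):
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise SchemaError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def total_size(self) -> int:
        return int(sum(self.lengths.values()))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass
class MarkerMap:
    """Ordered SSR marker positions, optionally with per-donor polymorphism flags.

    ``table`` has columns ``marker_id``, ``chromosome``, ``position_bp`` and is
    sorted by (chromosome, position). ``polymorphic`` maps a donor label to a
    boolean array aligned with ``table`` rows.
    """

    table: pd.DataFrame
    genome: GenomeSpec
    polymorphic: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        t = self.table
        required = {"marker_id", "chromosome", "position_bp"}
        if not required.issubset(t.columns):
            raise SchemaError(f"marker map missing columns {sorted(required - set(t.columns))}")
        dup = t["marker_id"][t["marker_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate marker id {dup.iloc[0]!r}")
        for i, row in enumerate(t.itertuples(index=False)):
            if row.chromosome not in self.genome:
                raise SchemaError(
                    f"line {i + 1}: unknown chromosome {row.chromosome!r} for marker {row.marker_id!r}"
                )
            if not 1 <= row.position_bp <= self.genome.lengths[row.chromosome]:
                raise SchemaError(
                    f"line {i + 1}: marker {row.marker_id!r} position {row.position_bp} "
                    f"outside chromosome {row.chromosome!r} (length "
                    f"{self.genome.lengths[row.chromosome]})"
                )
        for donor, flags in self.polymorphic.items():
            if len(flags) != len(t):
                raise SchemaError(f"polymorphism flags for donor {donor!r} misaligned with map")
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise SchemaError(f"positions not strictly increasing on chromosome {chrom!r}")

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    def chromosome_markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    def position_of(self, marker_id: str) -> tuple[str, int]:
        row = self.table[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(marker_id)
        r = row.iloc[0]
        return str(r["chromosome"]), int(r["position_bp"])


@dataclass
class GenotypeMatrix:
    """IL x marker call matrix over the internal {R, D, H, NA} alphabet."""

    calls: pd.DataFrame  # index il_id, columns marker_id
    donor_of_il: dict[str, str] = field(default_factory=dict)
    generation_of_il: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(np.unique(self.calls.to_numpy().astype(str))) - set(CODES)
        if bad:
            raise SchemaError(f"invalid genotype codes {sorted(bad)}")
        if self.calls.index.duplicated().any():
            raise SchemaError("duplicate il_id rows in genotype matrix")

    @property
    def il_ids(self) -> list[str]:
        return self.calls.index.tolist()

    def for_donor(self, donor: str) -> "GenotypeMatrix":
        keep = [i for i in self.il_ids if self.donor_of_il.get(i) == donor]
        return GenotypeMatrix(
            self.calls.loc[keep],
            {i: donor for i in keep},
            {i: g for i, g in self.generation_of_il.items() if i in keep},
        )


@dataclass
class PhenotypeTable:
    """Long-format phenotype records; control rows carry the reserved id."""

    records: pd.DataFrame  # il_id, trait, environment, replicate, value
    control_id: str = CONTROL_ID

    def __post_init__(self):
        req = {"il_id", "trait", "environment", "replicate", "value"}
        if not req.issubset(self.records.columns):
            raise SchemaError(f"phenotype table missing columns {sorted(req - set(self.records.columns))}")
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SchemaError("non-finite phenotype values")
        for (trait, env), grp in self.records.groupby(["trait", "environment"]):
            is_ctrl = grp["il_id"] == self.control_id
            if (~is_ctrl).any() and is_ctrl.sum() < 2:
                raise SchemaError(
                    f"stratum (trait={trait!r}, environment={env!r}) has ILs but "
                    f"fewer than 2 control replicates"
                )

    def stratum(self, trait: str, environment: str) -> pd.DataFrame:
        r = self.records
        return r[(r["trait"] == trait) & (r["environment"] == environment)]

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["environment"].unique())


@dataclass
class KnownLociSet:
    """Known (published) loci as 1-based closed intervals with trait tags."""

    entries: pd.DataFrame  # name, chromosome, start, end, traits (comma-joined tags)

    def __post_init__(self):
        if len(self.entries):
            bad = self.entries[self.entries["start"] > self.entries["end"]]
            if len(bad):
                raise SchemaError(f"known locus {bad.iloc[0]['name']!r} has start > end")

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path, **kw) -> pd.DataFrame:
    """Read a TSV, skipping any leading '#' comment/format lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_genome(path) -> GenomeSpec:
    """Read a chromosome-length table (columns: chromosome, length_bp)."""
    t = _read_table(path, dtype={"chromosome": str})
    return GenomeSpec(dict(zip(t["chromosome"], t["length_bp"].astype(int))))


def read_marker_map(path, genome: GenomeSpec) -> MarkerMap:
    """Read and validate a marker map.

    Expected columns: ``marker_id``, ``chromosome``, ``position_bp``; any
    additional ``poly_<donor>`` columns (0/1) become polymorphism flags.
    The returned map is sorted by (chromosome, position); chromosome order
    follows the genome spec.
    """
    t = _read_table(path, dtype={"marker_id": str, "chromosome": str})
    for col in ("marker_id", "chromosome", "position_bp"):
        if col not in t.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    t["position_bp"] = t["position_bp"].astype(int)
    dup = t["marker_id"][t["marker_id"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2  # header line + 1-based
        raise SchemaError(f"{path}, line {line}: duplicate marker id {dup.iloc[0]!r}")
    chrom_order = {c: i for i, c in enumerate(genome.chromosomes)}
    unknown = set(t["chromosome"]) - set(chrom_order)
    if unknown:
        bad = t[t["chromosome"].isin(unknown)].index[0]
        raise SchemaError(f"{path}, line {int(bad) + 2}: unknown chromosome {t.loc[bad, 'chromosome']!r}")
    t = t.sort_values(
        ["chromosome", "position_bp"], key=lambda s: s.map(chrom_order) if s.name == "chromosome" else s
    ).reset_index(drop=True)
    poly = {
        c.removeprefix("poly_"): t[c].astype(int).to_numpy().astype(bool)
        for c in t.columns
        if c.startswith("poly_")
    }
    core = t[["marker_id", "chromosome", "position_bp"]].copy()
    return MarkerMap(core, genome, poly)


def read_genotypes(path, marker_map: MarkerMap, dialect: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read an IL x marker genotype matrix.

    First column is ``il_id`` (optional ``donor``, ``n_backcrosses``,
    ``n_selfs`` metadata columns follow); remaining columns are marker ids
    that must all be present in the map. ``dialect`` maps file symbols to the
    internal alphabet (default ``R/D/H/-``).
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    t = _read_table(path, dtype=str)
    if "il_id" not in t.columns:
        raise SchemaError(f"{path}: first column must be 'il_id'")
    meta_cols = [c for c in ("donor", "n_backcrosses", "n_selfs") if c in t.columns]
    marker_cols = [c for c in t.columns if c != "il_id" and c not in meta_cols]
    if not marker_cols or t.empty:
        raise SchemaError(f"{path}: empty genotype matrix")
    missing = [m for m in marker_cols if m not in set(marker_map.marker_ids)]
    if missing:
        raise SchemaError(f"{path}: marker {missing[0]!r} absent from marker map")
    calls = t.set_index("il_id")[marker_cols]
    arr = calls.to_numpy()
    for sym in map(str, np.unique(arr.astype(str))):
        if sym not in dialect:
            r, c = np.argwhere(arr == sym)[0]
            raise SchemaError(
                f"{path}: unknown symbol {sym!r} at row {calls.index[r]!r}, column {marker_cols[c]!r}"
            )
    calls = calls.replace(dialect)
    # align column order to the map
    order = [m for m in marker_map.marker_ids if m in marker_cols]
    calls = calls[order]
    donor_of = dict(zip(t["il_id"], t["donor"])) if "donor" in meta_cols else {}
    gen_of = (
        {
            i: (int(b), int(s))
            for i, b, s in zip(t["il_id"], t["n_backcrosses"], t["n_selfs"])
        }
        if {"n_backcrosses", "n_selfs"}.issubset(meta_cols)
        else {}
    )
    return GenotypeMatrix(calls, donor_of, gen_of)


def read_phenotypes(path, control_id: str = CONTROL_ID) -> PhenotypeTable:
    """Read a long-format phenotype table (il_id, trait, environment, replicate, value)."""
    t = _read_table(path, dtype={"il_id": str, "trait": str, "environment": str})
    try:
        t["value"] = pd.to_numeric(t["value"], errors="raise")
    except (ValueError, TypeError) as e:
        raise SchemaError(f"{path}: non-numeric phenotype value ({e})") from None
    t["replicate"] = t["replicate"].astype(int)
    return PhenotypeTable(t, control_id=control_id)


def read_known_loci(path) -> KnownLociSet:
    """Read a BED3+ file of known loci, converting to 1-based closed intervals.

    BED is 0-based half-open; the internal convention is 1-based closed, so
    ``start`` gains 1 and ``end`` is kept. Column 4 (if present) is the locus
    name; column 5 a comma-separated list of trait tags.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise SchemaError(f"{path}, line {lineno}: malformed BED line")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise SchemaError(f"{path}, line {lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else f"locus{lineno}"
            traits = parts[4] if len(parts) > 4 else ""
            rows.append((name, chrom, start + 1, end, traits))
    df = pd.DataFrame(rows, columns=["name", "chromosome", "start", "end", "traits"])
    return KnownLociSet(df)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, float_format: str = "%.12g") -> None:
    """Write a TSV with the v1 format header; reals at 12 significant digits."""
    with open(path, "w") as fh:
        fh.write(FORMAT_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def write_genome(genome: GenomeSpec, path) -> None:
    write_table(
        pd.DataFrame(
            {"chromosome": genome.chromosomes, "length_bp": [genome.lengths[c] for c in genome.chromosomes]}
        ),
        path,
    )


def write_marker_map(m: MarkerMap, path) -> None:
    t = m.table.copy()
    for donor, flags in m.polymorphic.items():
        t[f"poly_{donor}"] = flags.astype(int)
    write_table(t, path)


def write_genotypes(g: GenotypeMatrix, path, dialect: dict[str, str] | None = None) -> None:
    """Write a genotype matrix using ``dialect`` (internal code -> file symbol)."""
    inv = {v: k for k, v in (DEFAULT_DIALECT if dialect is None else dialect).items()}
    t = g.calls.replace(inv).rename_axis("il_id").reset_index()
    if g.donor_of_il:
        t.insert(1, "donor", [g.donor_of_il.get(i, "") for i in g.calls.index])
    if g.generation_of_il:
        t.insert(2, "n_backcrosses", [g.generation_of_il.get(i, (0, 0))[0] for i in g.calls.index])
        t.insert(3, "n_selfs", [g.generation_of_il.get(i, (0, 0))[1] for i in g.calls.index])
    write_table(t, path)


def write_phenotypes(p: PhenotypeTable, path) -> None:
    write_table(p.records, path)


def to_tsv_string(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    buf.write(FORMAT_HEADER + "\n")
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
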