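"""Core data model and readers/writers for every external format the pipeline touches.

The canonical interchange format is a tab-delimited variant-allele-frequency
matrix (sample sets x rsIDs) as supplied by allele-frequency databases such as
ALFRED. Diploid genotype input (VCF) is an optional second mode for cohorts
distributed as genotypes, e.g. 1000 Genomes panels. UVB input is a long-format
CSV of daily noontime 305 nm surface irradiance on a half-degree grid.

All tables are UTF-8, tab-delimited, '.' decimal separator; ``NA`` is the only
missing-value token. Frequencies are validated to [0, 1] at the boundary so
every value surfaced downstream has passed range validation exactly once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed processing order of the geographic ancestry groups.
GROUPS = ("EUR", "EAS", "AFR")
#: Pairwise comparisons in fixed order.
GROUP_PAIRS = (("EUR", "EAS"), ("EUR", "AFR"), ("EAS", "AFR"))

VALID_GROUPS = frozenset(GROUPS) | {"OTHER"}
VALID_SOURCES = frozenset({"ALFRED", "KG1000", "SYNTHETIC"})
VALID_FUNCTION_CLASSES = frozenset(
    {"Intron", "Missense", "5' UTR", "nearGene-5", "2KB upstream", "Unknown"}
)

#: Half-degree raster cell size (degrees).
CELL_SIZE = 0.5

MISSING = float("nan")


class DataValidationError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass(frozen=True)
class SampleSet:
    """One population cohort: the unit of analysis, weighted by subject count.

    Latitude may be a point (``lat_min == lat_max``) or a range; southern
    latitudes are negative. Coordinates may be absent entirely (``None``),
    in which case the set is excluded from UVB aggregation only.
    """

    id: str
    name: str
    group: str
    n: int
    lat_min: float | None
    lat_max: float | None
    lon: float | None
    source: str
    dup_key: str | None = None
    most_recent: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataValidationError(f"sample set {self.id!r}: n must be >= 1, got {self.n}")
        if self.group not in VALID_GROUPS:
            raise DataValidationError(f"sample set {self.id!r}: unknown group {self.group!r}")
        if self.source not in VALID_SOURCES:
            raise DataValidationError(f"sample set {self.id!r}: unknown source {self.source!r}")
        if (self.lat_min is None) != (self.lat_max is None):
            raise DataValidationError(
                f"sample set {self.id!r}: lat_min and lat_max must both be present or both absent"
            )
        if self.lat_min is not None:
            if not (-90.0 <= self.lat_min <= self.lat_max <= 90.0):
                raise DataValidationError(
                    f"sample set {self.id!r}: invalid latitude range "
                    f"[{self.lat_min}, {self.lat_max}]"
                )
        if self.lon is not None and not (-180.0 <= self.lon <= 180.0):
            raise DataValidationError(f"sample set {self.id!r}: invalid longitude {self.lon}")

    @property
    def has_coordinates(self) -> bool:
        return self.lat_min is not None and self.lon is not None

    @property
    def lat_mid(self) -> float | None:
        if self.lat_min is None:
            return None
        return 0.5 * (self.lat_min + self.lat_max)


@dataclass(frozen=True)
class VariantAnnotation:
    """One panel variant: rsID, locus, variant allele, MAF, fixation index, class.

    ``fst`` is the ALFRED-style fixation index used for differentiation
    ranking; when absent it is computed from the frequency matrix upstream of
    selection.
    """

    rsid: str
    locus: str
    variant_allele: str
    minor_allele_frequency: float | None = None
    fst: float | None = None
    function_class: str = "Unknown"

    def __post_init__(self) -> None:
        if self.minor_allele_frequency is not None and not (
            0.0 <= self.minor_allele_frequency <= 1.0
        ):
            raise DataValidationError(
                f"{self.rsid}: minor allele frequency {self.minor_allele_frequency} not in [0,1]"
            )
        if self.fst is not None and not (0.0 <= self.fst <= 1.0):
            raise DataValidationError(f"{self.rsid}: fst {self.fst} not in [0,1]")
        if self.function_class not in VALID_FUNCTION_CLASSES:
            raise DataValidationError(
                f"{self.rsid}: unknown function class {self.function_class!r}"
            )


class FrequencyMatrix:
    """Sample-set x variant table of variant-allele frequencies with missingness.

    Backed by a float DataFrame (index: sample-set ids, columns: rsIDs,
    NaN = missing). Construction validates every present value to [0, 1].
    """

    def __init__(self, freq: pd.DataFrame):
        freq = freq.astype(float)
        if freq.index.has_duplicates:
            dups = freq.index[freq.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample-set ids: {dups}")
        if freq.columns.has_duplicates:
            dups = freq.columns[freq.columns.duplicated()].tolist()
            raise DataValidationError(f"duplicate rsids: {dups}")
        bad = (freq < 0.0) | (freq > 1.0)
        if bad.any().any():
            rows, cols = np.where(bad.to_numpy())
            r, c = rows[0], cols[0]
            raise DataValidationError(
                f"frequency {freq.iat[r, c]} out of [0,1] at "
                f"(sample set {freq.index[r]!r}, variant {freq.columns[c]!r})"
            )
        self.freq = freq

    @property
    def sample_set_ids(self) -> list[str]:
        return list(self.freq.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.freq.columns)

    def column(self, rsid: str) -> pd.Series:
        if rsid not in self.freq.columns:
            raise KeyError(f"variant {rsid!r} not in frequency matrix")
        return self.freq[rsid]

    def subset_sets(self, ids: Sequence[str]) -> "FrequencyMatrix":
        return FrequencyMatrix(self.freq.loc[list(ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyMatrix):
            return NotImplemented
        return self.freq.equals(other.freq)


@dataclass
class GenotypeCounts:
    """Diploid genotype counts per (sample set, variant): hom-ref / het / hom-alt."""

    counts: pd.DataFrame  # columns: set_id, rsid, hom_ref, het, hom_alt

    REQUIRED = ("set_id", "rsid", "hom_ref", "het", "hom_alt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.counts.columns]
        if missing:
            raise DataValidationError(f"genotype counts missing columns {missing}")
        num = self.counts[["hom_ref", "het", "hom_alt"]]
        if (num < 0).any().any():
            raise DataValidationError("genotype counts must be non-negative")

    def cell(self, set_id: str, rsid: str) -> tuple[int, int, int]:
        row = self.counts[
            (self.counts.set_id == set_id) & (self.counts.rsid == rsid)
        ]
        if row.empty:
            raise KeyError(f"no counts for ({set_id}, {rsid})")
        r = row.iloc[0]
        return int(r.hom_ref), int(r.het), int(r.hom_alt)

    def rsids(self) -> list[str]:
        return sorted(self.counts.rsid.unique())

    def to_frequency_matrix(self) -> FrequencyMatrix:
        """Collapse genotype counts to a variant-allele frequency matrix."""
        from .popgen import allele_frequency  # local import avoids a cycle

        recs = {}
        for (set_id, rsid), grp in self.counts.groupby(["set_id", "rsid"]):
            r = grp.iloc[0]
            recs[(set_id, rsid)] = allele_frequency(
                int(r.hom_ref), int(r.het), int(r.hom_alt)
            )
        df = pd.Series(recs).unstack()
        df.index.name = None
        return FrequencyMatrix(df)


def _on_half_degree_grid(center: float) -> bool:
    # centers sit at k*0.5 + 0.25, i.e. 2*c - 0.5 is an integer
    return abs((2.0 * center - 0.5) - round(2.0 * center - 0.5)) < 1e-6


class UVBRaster:
    """Half-degree gridded daily noontime 305 nm irradiance series.

    Cells are addressed by their centers (…, -0.25, 0.25, 0.75, …). Each cell
    carries a date-ordered sequence of daily irradiance values in Mw/m^2/nm.
    """

    def __init__(self, table: pd.DataFrame):
        req = ["lat_cell", "lon_cell", "date", "irradiance"]
        missing = [c for c in req if c not in table.columns]
        if missing:
            raise DataValidationError(f"raster table missing columns {missing}")
        table = table.copy()
        table["irradiance"] = table["irradiance"].astype(float)
        if (table["irradiance"] < 0).any():
            bad = table[table["irradiance"] < 0].iloc[0]
            raise DataValidationError(
                f"negative irradiance {bad.irradiance} at cell "
                f"({bad.lat_cell}, {bad.lon_cell})"
            )
        for col in ("lat_cell", "lon_cell"):
            offgrid = ~table[col].map(_on_half_degree_grid)
            if offgrid.any():
                bad = table[offgrid].iloc[0]
                raise DataValidationError(
                    f"off-grid cell center ({bad.lat_cell}, {bad.lon_cell}); "
                    f"centers must lie on the half-degree grid"
                )
        dup = table.duplicated(subset=["lat_cell", "lon_cell", "date"])
        if dup.any():
            bad = table[dup].iloc[0]
            raise DataValidationError(
                f"duplicate (cell, date) entry for cell ({bad.lat_cell}, {bad.lon_cell}) "
                f"on {bad.date}"
            )
        table = table.sort_values(["lat_cell", "lon_cell", "date"], kind="mergesort")
        self.table = table.reset_index(drop=True)
        self._by_cell: dict[tuple[float, float], np.ndarray] = {
            (lat, lon): grp["irradiance"].to_numpy()
            for (lat, lon), grp in self.table.groupby(["lat_cell", "lon_cell"], sort=True)
        }

    def cells(self) -> set[tuple[float, float]]:
        return set(self._by_cell)

    def has_cell(self, lat: float, lon: float) -> bool:
        return (round(lat, 6), round(lon, 6)) in {
            (round(a, 6), round(b, 6)) for a, b in self._by_cell
        }

    def values(self, lat: float, lon: float) -> np.ndarray:
        for (a, b), v in self._by_cell.items():
            if abs(a - lat) < 1e-6 and abs(b - lon) < 1e-6:
                return v
        return np.empty(0)


@dataclass
class VariantComparisonResult:
    """One report row: per-group means/CIs, association stats, pairwise p's,
    compact-letter assignments, distribution-pattern and UVB-cline labels."""

    rsid: str
    locus: str
    n_sets: int
    n_subjects: int
    means: dict[str, float]
    ci_lo: dict[str, float]
    ci_hi: dict[str, float]
    p_assoc: float
    adj_r2: float
    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]
    pattern: str
    uvb_cline: str

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g in self.means and g in self.ci_lo:
                lo, hi, m = self.ci_lo[g], self.ci_hi[g], self.means[g]
                if not (lo - 1e-9 <= m <= hi + 1e-9):
                    raise DataValidationError(
                        f"{self.rsid}: CI ({lo}, {hi}) does not bracket mean {m} for {g}"
                    )
        for pair, p in self.pairwise_p.items():
            if not (0.0 <= p <= 1.0):
                raise DataValidationError(f"{self.rsid}: pairwise p {p} for {pair} not in [0,1]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SAMPLE_SET_COLUMNS = ["id", "name", "group", "n", "lat_min", "lat_max", "lon", "source"]


def _parse_optional_float(token: str, what: str, line_no: int) -> float | None:
    if token == "NA" or token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise DataValidationError(f"line {line_no}: cannot parse {what} value {token!r}")


def read_sample_sets(path) -> list[SampleSet]:
    """Read sample-set metadata from a TSV file.

    Required header: ``id name group n lat_min lat_max lon source``
    (tab-separated). Optional extra columns ``dup_key`` and ``most_recent``
    support the duplicate-cohort policy. Latitudes are signed decimal degrees
    (south negative); ``NA`` marks absent coordinates.
    """
    if hasattr(path, "read"):
        lines = [ln.rstrip("\n") for ln in path if ln.strip()]
    else:
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise DataValidationError(f"{path}: empty file, expected a header line")
    header = lines[0].split("\t")
    missing = [c for c in _SAMPLE_SET_COLUMNS if c not in header]
    if missing:
        raise DataValidationError(f"{path}: header missing columns {missing}")
    idx = {c: header.index(c) for c in header}
    out: list[SampleSet] = []
    seen: set[str] = set()
    for line_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataValidationError(
                f"{path} line {line_no}: expected {len(header)} fields, got {len(parts)}"
            )
        get = lambda c: parts[idx[c]].strip()
        sid = get("id")
        if sid in seen:
            raise DataValidationError(f"{path} line {line_no}: duplicate sample-set id {sid!r}")
        seen.add(sid)
        try:
            n = int(get("n"))
        except ValueError:
            raise DataValidationError(f"{path} line {line_no}: cannot parse n {get('n')!r}")
        dup_key = get("dup_key") if "dup_key" in idx else ""
        most_recent = True
        if "most_recent" in idx:
            tok = get("most_recent").lower()
            most_recent = tok in ("1", "true", "yes", "")
        try:
            out.append(
                SampleSet(
                    id=sid,
                    name=get("name"),
                    group=get("group"),
                    n=n,
                    lat_min=_parse_optional_float(get("lat_min"), "lat_min", line_no),
                    lat_max=_parse_optional_float(get("lat_max"), "lat_max", line_no),
                    lon=_parse_optional_float(get("lon"), "lon", line_no),
                    source=get("source"),
                    dup_key=dup_key or None,
                    most_recent=most_recent,
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path} line {line_no}: {exc}") from exc
    return out


def write_sample_sets(sets: Sequence[SampleSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SAMPLE_SET_COLUMNS) + "\n")
        for s in sets:
            fmt = lambda v: "NA" if v is None else f"{v:g}"
            fh.write(
                "\t".join(
                    [s.id, s.name, s.group, str(s.n), fmt(s.lat_min), fmt(s.lat_max),
                     fmt(s.lon), s.source]
                )
                + "\n"
            )


def read_frequency_matrix(path) -> FrequencyMatrix:
    """Read a sample-set x variant frequency TSV (first column: set id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    try:
        return FrequencyMatrix(df)
    except (DataValidationError, ValueError) as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def write_frequency_matrix(matrix: FrequencyMatrix, path) -> None:
    matrix.freq.to_csv(path, sep="\t", na_rep="NA", index_label="id")


def read_variant_annotations(path) -> list[VariantAnnotation]:
    """Read a variant annotation TSV (columns rsid, locus, variant_allele,
    maf, fst, function_class); ``NA`` marks an absent fst or maf."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    req = ["rsid", "locus", "variant_allele", "maf", "fst", "function_class"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: annotation header missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                VariantAnnotation(
                    rsid=str(row.rsid),
                    locus=str(row.locus),
                    variant_allele=str(row.variant_allele),
                    minor_allele_frequency=None if pd.isna(row.maf) else float(row.maf),
                    fst=None if pd.isna(row.fst) else float(row.fst),
                    function_class=str(row.function_class),
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path} line {i + 2}: {exc}") from exc
    return out


def write_variant_annotations(annotations: Sequence[VariantAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rsid\tlocus\tvariant_allele\tmaf\tfst\tfunction_class\n")
        for a in annotations:
            maf = "NA" if a.minor_allele_frequency is None else f"{a.minor_allele_frequency:g}"
            fst = "NA" if a.fst is None else f"{a.fst:g}"
            fh.write(f"{a.rsid}\t{a.locus}\t{a.variant_allele}\t{maf}\t{fst}\t{a.function_class}\n")


def read_genotypes_vcf(path, sample_to_set: Mapping[str, str]) -> GenotypeCounts:
    """Aggregate diploid GT fields of a VCF into per-(set, variant) counts.

    Only biallelic records are consumed; multiallelic records are skipped with
    a logged warning. Samples with missing genotypes (``./.``) are excluded
    from that variant's counts. Every VCF sample name must be mapped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in sample_to_set]
    if unmapped:
        raise DataValidationError(f"unmapped VCF sample names: {unmapped}")
    set_of = [sample_to_set[s] for s in samples]
    rows: list[dict] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s at %s:%s",
                variant.ID, variant.CHROM, variant.POS,
            )
            continue
        rsid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        tallies: dict[str, list[int]] = {}
        for sample_idx, gt in enumerate(variant.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                continue  # missing call
            k = a0 + a1  # 0 hom-ref, 1 het, 2 hom-alt
            t = tallies.setdefault(set_of[sample_idx], [0, 0, 0])
            t[k] += 1
        for set_id, (hr, het, ha) in tallies.items():
            rows.append(
                {"set_id": set_id, "rsid": rsid, "hom_ref": hr, "het": het, "hom_alt": ha}
            )
    return GenotypeCounts(pd.DataFrame(rows, columns=list(GenotypeCounts.REQUIRED)))


def read_uvb_raster(path) -> UVBRaster:
    """Read a long-format raster CSV (columns lat_cell, lon_cell, date, irradiance)."""
    df = pd.read_csv(path)
    try:
        return UVBRaster(df)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def write_uvb_raster(raster: UVBRaster, path) -> None:
    raster.table.to_csv(path, index=False)


REPORT_COLUMNS = ["rsid", "locus", "n_sets", "n_subjects"]
for _g in GROUPS:
    REPORT_COLUMNS += [f"mean_{_g}", f"ci_{_g}_lo", f"ci_{_g}_hi"]
REPORT_COLUMNS += ["p_assoc", "adj_r2"]
REPORT_COLUMNS += [f"p_{a}_{b}" for a, b in GROUP_PAIRS]
REPORT_COLUMNS += [f"letters_{_g}" for _g in GROUPS]
REPORT_COLUMNS += ["pattern", "uvb_cline"]


def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    return f"{p:.2e}"


def _fmt2(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.2f}"


def write_report(results: Sequence[VariantComparisonResult], path) -> None:
    """Write the final per-variant comparison report as TSV.

    Means and CI bounds are rendered with two decimals (the precision allele-
    frequency tables in this literature print); p values use scientific
    notation with three significant digits.
    """
    if not results:
        raise DataValidationError("cannot write an empty report")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in results:
            row = [r.rsid, r.locus, str(r.n_sets), str(r.n_subjects)]
            for g in GROUPS:
                row += [
                    _fmt2(r.means.get(g, MISSING)),
                    _fmt2(r.ci_lo.get(g, MISSING)),
                    _fmt2(r.ci_hi.get(g, MISSING)),
                ]
            row += [_fmt_p(r.p_assoc), _fmt2(r.adj_r2)]
            for pair in GROUP_PAIRS:
                row.append(_fmt_p(r.pairwise_p.get(pair, MISSING)))
            for g in GROUPS:
                row.append(r.letters.get(g, ""))
            row += [r.pattern, r.uvb_cline]
            fh.write("\t".join(row) + "\n")


def read_report(path) -> pd.DataFrame:
    """Read a report TSV back into a DataFrame (rendered precision)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def deduplicate_sample_sets(sets: Sequence[SampleSet]) -> list[SampleSet]:
    """Apply the duplicate-cohort policy: among sets sharing a ``dup_key``,
    keep only those flagged most recent; sets without a key always pass."""
    kept = []
    for s in sets:
        if s.dup_key is None or s.most_recent:
            kept.append(s)
        else:
            logger.info("dropping duplicate sample set %s (dup_key=%s)", s.id, s.dup_key)
    return kept
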