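"""Genotype, site and environmental-layer containers plus file formats.

The canonical interchange formats are deliberately plain text:

* genotypes — a 0/1/2 dosage TSV (rows = individuals, columns = loci,
  blank/NA = missing) or a minimal diploid VCF (GT field only);
* site table — CSV with individual_id, site_id, longitude, latitude, zone;
* environmental grids — ESRI ASCII rasters, one file per variable/period.

Loci are filtered the way a ddRAD SNP panel is typically cleaned for
population-genomic analysis: a minor-allele-frequency floor and a single
SNP per contig (RAD loci on the same contig are in near-complete linkage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

__all__ = [
    "GenotypeMatrix",
    "SiteFrame",
    "EnvLayerSet",
    "read_genotypes",
    "write_genotypes",
    "filter_loci",
    "read_raster",
    "write_raster",
    "read_sites",
    "write_sites",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as alternate-allele dosage.

    Parameters
    ----------
    values
        ``(n_individuals, n_loci)`` float array with entries in {0, 1, 2}
        and ``nan`` for missing calls.
    locus_meta
        One row per locus with columns ``id, contig, position, ref, alt``.
    individual_ids
        Sample identifiers, one per row of ``values``.
    """

    values: np.ndarray
    locus_meta: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        n, L = self.values.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.locus_meta) != L:
            raise ValueError(f"{len(self.locus_meta)} locus rows for {L} columns")
        if self.locus_meta["id"].duplicated().any():
            raise ValueError("locus ids are not unique")
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus."""
        return 1.0 - np.isnan(self.values).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per locus."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[:, index],
            self.locus_meta.iloc[index].reset_index(drop=True),
            list(self.individual_ids),
        )


@dataclass
class SiteFrame:
    """Individual -> sampling-site mapping with coordinates and zone labels.

    ``data`` has one row per individual: ``individual_id, site_id,
    longitude, latitude, zone`` (WGS84 decimal degrees).
    """

    data: pd.DataFrame

    REQUIRED = ("individual_id", "site_id", "longitude", "latitude", "zone")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"site table lacks columns {missing}")
        if self.data["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in site table")
        if (self.data["latitude"].abs() > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        self.data = self.data.reset_index(drop=True)

    def check_matches(self, g: GenotypeMatrix) -> None:
        """Every genotyped individual must appear exactly once."""
        have = set(self.data["individual_id"])
        absent = [i for i in g.individual_ids if i not in have]
        if absent:
            raise ValueError(f"{len(absent)} individuals missing from site table")

    def ordered_for(self, individual_ids: list[str]) -> pd.DataFrame:
        idx = self.data.set_index("individual_id")
        return idx.loc[list(individual_ids)].reset_index()

    def site_coords(self) -> pd.DataFrame:
        """Per-site mean longitude/latitude (sites are points, so identical)."""
        return (
            self.data.groupby("site_id")[["longitude", "latitude"]]
            .mean()
            .sort_index()
        )

    def zone_coords(self) -> pd.DataFrame:
        """Mean coordinates of the sites within each zone."""
        per_site = self.data.drop_duplicates("site_id")
        return per_site.groupby("zone")[["longitude", "latitude"]].mean().sort_index()


@dataclass
class EnvLayerSet:
    """Named environmental variables as grids plus per-site values.

    Grids share one geometry: row 0 is the northernmost row, cell-center
    registration, WGS84 lon/lat. ``grids[var][period]`` is a 2-D array with
    ``nan`` for NODATA. ``site_values[period]`` is a DataFrame indexed by
    site_id with one column per variable. ``standardization`` holds the
    per-variable mean/SD of the *present-period site values*; these are the
    calibration statistics used everywhere a standardized value b_i appears.
    """

    variables: list[str]
    grids: dict[str, dict[str, np.ndarray]]
    xllcorner: float
    yllcorner: float
    cellsize: float
    site_values: dict[str, pd.DataFrame]
    standardization: pd.DataFrame  # index variable, columns mean, sd

    PERIODS = ("present", "future")

    def __post_init__(self) -> None:
        shapes = {
            self.grids[v][p].shape
            for v in self.variables
            for p in self.grids[v]
        }
        if len(shapes) != 1:
            raise ValueError(f"inconsistent grid shapes: {shapes}")
        if (self.standardization["sd"] <= 0).any():
            bad = self.standardization.index[self.standardization["sd"] <= 0]
            raise ValueError(f"zero/negative SD for variables {list(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        v = self.variables[0]
        return next(iter(self.grids[v].values())).shape

    def lon_centers(self) -> np.ndarray:
        ncols = self.shape[1]
        return self.xllcorner + (np.arange(ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitude per row, row 0 northernmost."""
        nrows = self.shape[0]
        top = self.yllcorner + nrows * self.cellsize
        return top - (np.arange(nrows) + 0.5) * self.cellsize

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Containing cell (row, col); half-open cell intervals."""
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        nrows = self.shape[0]
        top = self.yllcorner + nrows * self.cellsize
        row = int(np.floor((top - lat) / self.cellsize))
        if not (0 <= row < nrows and 0 <= col < self.shape[1]):
            raise ValueError(f"({lon}, {lat}) outside the grid")
        return row, col

    def standardized_grid(self, var: str, period: str) -> np.ndarray:
        """Grid of b_i = (value - mean_i) / SD_i with calibration statistics."""
        if var not in self.grids:
            raise KeyError(f"variable {var!r} missing from layer set")
        m = self.standardization.loc[var, "mean"]
        s = self.standardization.loc[var, "sd"]
        return (self.grids[var][period] - m) / s


# ---------------------------------------------------------------------------
# genotype IO
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "tsv012") -> GenotypeMatrix:
    """Read genotypes from a 0/1/2 TSV or a minimal diploid VCF.

    VCF: only the GT subfield is used; ``./.`` becomes missing; records with
    more than one ALT allele are rejected (count logged); non-diploid GT is
    an error.
    """
    if format == "tsv012":
        return _read_tsv012(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tsv012(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    ids = [str(i) for i in df.index]
    meta = pd.DataFrame(
        {
            "id": df.columns,
            "contig": [f"contig_{i}" for i in range(df.shape[1])],
            "position": np.zeros(df.shape[1], dtype=int),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(vals, meta, ids)


def _validate_vcf_header(path) -> None:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise ValueError(f"{path}: line 1: missing ##fileformat header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise ValueError(f"{path}: line {lineno}: malformed #CHROM line")
                return
            raise ValueError(f"{path}: line {lineno}: unexpected content before #CHROM")
    raise ValueError(f"{path}: no #CHROM header line")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    _validate_vcf_header(path)
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, meta_rows = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        dosages = np.full(len(ids), np.nan)
        for j, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype for sample {ids[j]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            if -1 in alleles:
                continue
            dosages[j] = float(sum(alleles))
        rows.append(dosages)
        meta_rows.append(
            {
                "id": rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}",
                "contig": rec.CHROM,
                "position": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    if n_multi:
        logger.info("rejected %d multiallelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    values = np.column_stack(rows) if rows else np.empty((len(ids), 0))
    return GenotypeMatrix(values, pd.DataFrame(meta_rows), ids)


def write_genotypes(g: GenotypeMatrix, path, format: str = "tsv012") -> None:
    """Write genotypes as 0/1/2 TSV (canonical) or minimal VCF."""
    if format == "tsv012":
        df = pd.DataFrame(
            g.values, index=g.individual_ids, columns=g.locus_meta["id"]
        )
        out = df.map(lambda x: "" if np.isnan(x) else str(int(x)))
        out.to_csv(path, sep="\t", index_label="individual_id")
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for l in range(g.n_loci):
            m = g.locus_meta.iloc[l]
            gts = "\t".join(
                "./." if np.isnan(x) else _GT_CODE[x] for x in g.values[:, l]
            )
            fh.write(
                f"{m['contig']}\t{int(m['position'])}\t{m['id']}\t{m['ref']}\t"
                f"{m['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# locus filtering
# ---------------------------------------------------------------------------


def filter_loci(
    g: GenotypeMatrix, maf_min: float = 0.05, one_per_contig: bool = True
) -> GenotypeMatrix:
    """Apply the panel-cleaning filters: MAF floor and one SNP per contig.

    MAF is computed over non-missing allele calls only. Within a contig the
    locus with the highest call rate is kept; ties break to the lowest
    position. Idempotent.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    n0 = g.n_loci
    keep = g.maf() >= maf_min
    n_maf = int((~keep).sum())
    idx = np.flatnonzero(keep)
    if one_per_contig and idx.size:
        sub = g.locus_meta.iloc[idx].copy()
        sub["call_rate"] = g.call_rate()[idx]
        sub["_orig"] = idx
        best = (
            sub.sort_values(
                ["contig", "call_rate", "position"],
                ascending=[True, False, True],
            )
            .groupby("contig", sort=False)
            .head(1)
        )
        idx = np.sort(best["_orig"].to_numpy())
    n_contig = n0 - n_maf - idx.size
    logger.info(
        "filter_loci: %d loci in, %d removed by MAF < %.3g, %d removed by "
        "one-per-contig, %d retained",
        n0, n_maf, maf_min, n_contig, idx.size,
    )
    if idx.size == 0:
        logger.warning("filter_loci: no loci retained")
    return g.take_loci(idx)


# ---------------------------------------------------------------------------
# raster and site-table IO
# ---------------------------------------------------------------------------


def write_raster(path, grid: np.ndarray, xllcorner: float, yllcorner: float,
                 cellsize: float, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid; nan cells become the NODATA value."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("raster grid must be 2-D")
    nrows, ncols = grid.shape
    body = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in body:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid -> (grid with nan NODATA, header dict)."""
    header: dict[str, float] = {}
    expected = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "NODATA_value"]
    with open(path) as fh:
        for key in expected:
            parts = fh.readline().split()
            if len(parts) != 2 or parts[0].lower() != key.lower():
                raise ValueError(f"{path}: malformed header, expected {key}")
            header[key] = float(parts[1])
        body = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    body = np.atleast_2d(body)
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: body shape {body.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    grid = np.where(body == header["NODATA_value"], np.nan, body)
    return grid, header


def write_surface(surface, outdir, xllcorner: float, yllcorner: float,
                  cellsize: float, prefix: str = "offset") -> list:
    """Write an offset surface as rasters plus a reference-distribution CSV.

    ``surface`` needs ``raw``, ``z``, ``mask`` grids and a ``reference``
    with sorted values (duck-typed to avoid a dependency on the offset
    module). Returns the written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in (("raw", surface.raw), ("zprime", surface.z),
                       ("mask", surface.mask.astype(float))):
        p = outdir / f"{prefix}_{name}.asc"
        write_raster(p, grid, xllcorner, yllcorner, cellsize)
        paths.append(p)
    ref = surface.reference.values
    csv = outdir / f"{prefix}_reference.csv"
    pd.DataFrame(
        {
            "quantile": [0.0, 0.25, 0.5, 0.6827, 0.75, 0.9, 0.9545, 1.0],
            "offset": np.quantile(ref, [0.0, 0.25, 0.5, 0.6827, 0.75, 0.9,
                                        0.9545, 1.0]),
        }
    ).to_csv(csv, index=False)
    paths.append(csv)
    return paths


def write_sites(sites: SiteFrame, path) -> None:
    sites.data.to_csv(path, index=False)


def read_sites(path) -> SiteFrame:
    return SiteFrame(pd.read_csv(path))
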