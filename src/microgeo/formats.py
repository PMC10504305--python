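"""Core data types and readers/writers for every file the pipeline touches.

Canonical table dialect: tab-separated, '.' decimal, UTF-8, no quoting.
Longitude is stored in [-180, 180); raster columns are indexed eastward
from the 180°W edge, raster rows southward from the 90°N edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUTRIENT_GROUPS = ("P", "N", "Fe", "none")
DNA_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed object violates a type invariant; the message names the cell."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneInfo:
    gene_id: str
    is_sccg: bool = False
    nutrient_group: str = "none"
    cog_category: str = "unknown"

    def __post_init__(self):
        if self.nutrient_group not in NUTRIENT_GROUPS:
            raise ValidationError(
                f"gene {self.gene_id!r}: nutrient_group {self.nutrient_group!r} "
                f"not in {NUTRIENT_GROUPS}"
            )
        if self.is_sccg and self.nutrient_group != "none":
            raise ValidationError(
                f"gene {self.gene_id!r}: a single-copy core gene cannot carry a "
                f"nutrient_group ({self.nutrient_group!r})"
            )


@dataclass
class CoverageTable:
    """Samples x genes abundance matrix plus per-gene metadata.

    ``values`` is a DataFrame indexed by sample_id with gene_id columns.
    ``gene_meta`` is a DataFrame indexed by gene_id with columns
    ``is_sccg`` (bool), ``nutrient_group``, ``cog_category``.
    ``normalized`` distinguishes raw read coverage from SCCG-normalized
    per-genome copy estimates.
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        missing = [g for g in v.columns if g not in self.gene_meta.index]
        if missing:
            logger.warning(
                "%d gene(s) missing from metadata, using defaults: %s",
                len(missing), ", ".join(map(str, missing[:5])),
            )
            defaults = pd.DataFrame(
                {"is_sccg": False, "nutrient_group": "none", "cog_category": "unknown"},
                index=pd.Index(missing, name="gene_id"),
            )
            self.gene_meta = pd.concat([self.gene_meta, defaults])
        self.gene_meta = self.gene_meta.loc[list(v.columns)]
        bad_group = ~self.gene_meta["nutrient_group"].isin(NUTRIENT_GROUPS)
        if bad_group.any():
            g = self.gene_meta.index[bad_group][0]
            raise ValidationError(
                f"gene {g!r}: invalid nutrient_group "
                f"{self.gene_meta.loc[g, 'nutrient_group']!r}"
            )
        conflict = self.gene_meta["is_sccg"] & (self.gene_meta["nutrient_group"] != "none")
        if conflict.any():
            g = self.gene_meta.index[conflict][0]
            raise ValidationError(f"gene {g!r}: SCCG gene carries a nutrient_group")
        if not self.normalized:
            arr = v.to_numpy(dtype=float)
            if np.any(arr < 0):
                i, j = np.argwhere(arr < 0)[0]
                raise ValidationError(
                    f"negative coverage at sample {v.index[i]!r}, gene {v.columns[j]!r}"
                )
            if not self.gene_meta["is_sccg"].any():
                raise ValidationError("raw coverage table contains no SCCG gene")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sccg_genes(self) -> list[str]:
        return list(self.gene_meta.index[self.gene_meta["is_sccg"]])


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise dissimilarities over labelled ids."""

    ids: list[str]
    d: np.ndarray
    metric_name: str = "unknown"

    def __post_init__(self):
        self.ids = list(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.d.shape} does not match {n} ids"
            )
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix has a nonzero diagonal")
        finite = np.isfinite(self.d)
        if not np.array_equal(self.d, self.d.T) and not np.allclose(
            self.d[finite & finite.T], self.d.T[finite & finite.T], atol=1e-12
        ):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(self.d[finite] < 0):
            raise ValidationError("distance matrix has a negative entry")

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids, self.d[np.ix_(idx, idx)], self.metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

SAMPLE_META_COLUMNS = ["sample_id", "latitude", "longitude", "sst", "transect_id"]


def validate_sample_meta(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table (indexed or keyed by sample_id)."""
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    for col in ("latitude", "longitude"):
        if col not in df.columns:
            raise ValidationError(f"sample metadata missing column {col!r}")
    lat = df["latitude"].to_numpy(dtype=float)
    lon = df["longitude"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        s = df.index[(lat < -90) | (lat > 90)][0]
        raise ValidationError(f"sample {s!r}: latitude out of [-90, 90]")
    if np.any((lon < -180) | (lon >= 180)):
        s = df.index[(lon < -180) | (lon >= 180)][0]
        raise ValidationError(f"sample {s!r}: longitude out of [-180, 180)")
    return df


def read_sample_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_sample_meta(df)


def write_sample_meta(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample_id",
              float_format="%.10g")


# ---------------------------------------------------------------------------
# coverage tables
# ---------------------------------------------------------------------------

def read_gene_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "is_sccg", "nutrient_group", "cog_category"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"gene metadata {path}: missing columns {sorted(missing)}")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in metadata")
    df["is_sccg"] = df["is_sccg"].astype(bool)
    return df


def write_gene_meta(gene_meta: pd.DataFrame, path) -> None:
    gene_meta.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_coverage_table(path, gene_meta_path, normalized: bool = False) -> CoverageTable:
    """Read a samples x genes TSV (header = gene ids, first column = sample ids)."""
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed coverage TSV {path}: {exc}") from None
    non_numeric = values.select_dtypes(exclude="number").columns
    if len(non_numeric):
        col = non_numeric[0]
        bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
        raise ParseError(
            f"coverage TSV {path}: non-numeric value {bad.iloc[0]!r} for gene "
            f"{col!r}, sample {bad.index[0]!r}"
        )
    gene_meta = read_gene_meta(gene_meta_path)
    return CoverageTable(values=values.astype(float), gene_meta=gene_meta,
                         normalized=normalized)


def write_coverage_table(t: CoverageTable, path, gene_meta_path=None) -> None:
    t.values.to_csv(path, sep="\t", index=True, index_label="sample_id",
                    float_format="%.10g")
    if gene_meta_path is not None:
        write_gene_meta(t.gene_meta, gene_meta_path)


# ---------------------------------------------------------------------------
# consensus FASTA
# ---------------------------------------------------------------------------

def write_consensus_fasta(consensus_set: dict[str, str], path) -> None:
    """Write sample -> consensus sequence as FASTA; all sequences equal length."""
    lengths = {len(s) for s in consensus_set.values()}
    if len(lengths) > 1:
        raise ValidationError(
            f"consensus sequences have unequal lengths {sorted(lengths)}; "
            "consensus sequences are columnar by construction"
        )
    records = []
    for sid, seq in consensus_set.items():
        bad = set(seq.upper()) - DNA_ALPHABET
        if bad:
            raise ValidationError(f"sample {sid!r}: invalid bases {sorted(bad)}")
        records.append(SeqRecord(Seq(seq.upper()), id=str(sid), description=""))
    SeqIO.write(records, path, "fasta")


def read_consensus_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:
        raise ValidationError("consensus FASTA has unequal sequence lengths")
    return out


# ---------------------------------------------------------------------------
# land mask
# ---------------------------------------------------------------------------

def read_landmask(path) -> np.ndarray:
    """Read a land mask (1 = land, 0 = ocean) from ESRI ASCII grid or 0/1 TSV.

    Row 0 is the northernmost band, column 0 the 180°W edge.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.strip().lower().startswith(("ncols", "nrows")):
        return _read_esri_ascii(path)
    try:
        arr = np.loadtxt(path, dtype=float)
    except ValueError as exc:
        raise ParseError(f"land mask {path}: {exc}") from None
    return _check_binary(arr, path)


def _read_esri_ascii(path) -> np.ndarray:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    raise ParseError(f"land mask {path} line {lineno}: "
                                     f"non-numeric cell") from None
    arr = np.array(rows, dtype=float)
    if "nrows" in header and arr.shape[0] != int(header["nrows"]):
        raise ParseError(f"land mask {path}: row count {arr.shape[0]} != "
                         f"declared nrows {int(header['nrows'])}")
    if "ncols" in header and arr.shape[1] != int(header["ncols"]):
        raise ParseError(f"land mask {path}: col count {arr.shape[1]} != "
                         f"declared ncols {int(header['ncols'])}")
    return _check_binary(arr, path)


def _check_binary(arr: np.ndarray, path) -> np.ndarray:
    bad = ~np.isin(arr, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"land mask {path}: non-binary cell value {arr[r, c]} at "
            f"row {r}, col {c}"
        )
    return arr.astype(bool)


def write_landmask(mask: np.ndarray, path) -> None:
    np.savetxt(path, mask.astype(int), fmt="%d", delimiter="\t")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def read_distance_matrix(path, metric_name: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"distance TSV {path}: row and column labels differ")
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float),
                          metric_name)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index=True, index_label="id",
                         float_format="%.10g")
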