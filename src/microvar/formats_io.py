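"""Readers/writers for feature tables, metadata and distance matrices.

Conventions
-----------
* Feature table: QIIME-classic-style TSV — taxa as rows, samples as
  columns, a ``#TaxonID`` leading header cell (``#OTU ID`` in the
  ``biom_tsv`` dialect, which may also carry ``#``-prefixed comment
  lines), and an optional trailing ``taxonomy`` column. The taxonomy
  value is either a bare genus label or a semicolon-delimited rank
  string whose 6th rank is the genus; empty/missing genus maps to
  ``"unclassified"``.
* Sample metadata TSV columns: sample_id, patient_id, site, day, order.
* Patient metadata TSV columns: patient_id, age, days_all_abx,
  days_treatment_abx, n_antibiotics, pip_tazo_gt72h, cefepime_gt72h,
  carbapenem_gt72h, chemo_category, infection_during_ic,
  infection_90d_post, remission. Clinical fields may be blank; they are
  recorded as absent (None) and downstream consumers that need them
  fail loudly rather than impute.
* Distance matrix: square labeled TSV; values written with 17
  significant digits so a write/read round trip agrees within 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ReferentialError

__all__ = [
    "FeatureTable",
    "SampleInfo",
    "PatientInfo",
    "CohortMetadata",
    "DistanceMatrix",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
]

SITES = ("oral", "stool")
CHEMO_CATEGORIES = ("fludarabine", "non_fludarabine_high_intensity", "hypomethylator", "other")
INFECTION_LEVELS = ("MDI", "clinical", "none")

SAMPLE_COLUMNS = ["sample_id", "patient_id", "site", "day", "order"]
PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "days_all_abx",
    "days_treatment_abx",
    "n_antibiotics",
    "pip_tazo_gt72h",
    "cefepime_gt72h",
    "carbapenem_gt72h",
    "chemo_category",
    "infection_during_ic",
    "infection_90d_post",
    "remission",
]


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Non-negative taxon × sample count matrix with a taxon→genus map."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_taxa, n_samples) integer
    taxonomy: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(self.taxon_ids) == 0 or len(self.sample_ids) == 0:
            raise FormatError("feature table is empty")
        dup = _first_duplicate(self.taxon_ids)
        if dup is not None:
            raise FormatError(f"duplicate taxon id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.taxon_ids)}, {len(self.sample_ids)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise FormatError(
                    f"non-integer count at row {self.taxon_ids[bad[0]]!r}, "
                    f"column {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at row {self.taxon_ids[bad[0]]!r}, "
                f"column {self.sample_ids[bad[1]]!r}"
            )
        missing = [t for t in self.taxon_ids if t not in self.taxonomy]
        if missing:
            raise FormatError(f"taxa missing taxonomy entries: {missing[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ReferentialError(f"unknown sample ids: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return FeatureTable(
            list(self.taxon_ids), list(sample_ids), self.counts[:, cols], dict(self.taxonomy)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and self.taxonomy == other.taxonomy
        )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def _genus_from_taxonomy(value: str) -> str:
    """Genus = 6th semicolon rank (stripping a QIIME 'g__' prefix) or the
    whole string when unranked; blank maps to 'unclassified'."""
    value = value.strip()
    if not value:
        return "unclassified"
    if ";" in value:
        ranks = [r.strip() for r in value.split(";")]
        if len(ranks) >= 6:
            genus = ranks[5]
        else:
            genus = ranks[-1]
    else:
        genus = value
    if genus.startswith("g__"):
        genus = genus[3:]
    return genus or "unclassified"


def read_feature_table(
    path: str | Path,
    dialect: str = "tsv",
    taxonomy: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Read a taxon × sample count TSV.

    ``dialect='tsv'`` expects a ``#TaxonID`` header cell; ``'biom_tsv'``
    accepts leading ``#``-comment lines and an ``#OTU ID`` header. A
    trailing ``taxonomy`` column (case-insensitive) supplies the genus
    map; alternatively pass a sidecar ``taxonomy`` mapping.
    """
    if dialect not in ("tsv", "biom_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "biom_tsv":
        header_tag = "#OTU ID"
        while lines and lines[0].startswith("#") and not lines[0].startswith(header_tag):
            lines.pop(0)
    else:
        header_tag = "#TaxonID"
    if not lines:
        raise FormatError(f"{path}: empty feature table")
    header = lines[0].split("\t")
    if header[0] != header_tag:
        raise FormatError(
            f"{path}: expected leading header cell {header_tag!r}, got {header[0]!r}"
        )
    columns = header[1:]
    has_tax_col = bool(columns) and columns[-1].lower() == "taxonomy"
    sample_ids = columns[:-1] if has_tax_col else columns
    if not sample_ids or len(lines) < 2:
        raise FormatError(f"{path}: empty feature table")

    taxon_ids: list[str] = []
    rows: list[list[int]] = []
    tax_map: dict[str, str] = dict(taxonomy) if taxonomy is not None else {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        taxon = cells[0]
        values = cells[1 : 1 + len(sample_ids)]
        row: list[int] = []
        for sample, cell in zip(sample_ids, values):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {cell!r} in column {sample!r}"
                ) from None
            if not value.is_integer():
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {cell!r} at row {taxon!r}, "
                    f"column {sample!r}"
                )
            if value < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative count {cell!r} at row {taxon!r}, "
                    f"column {sample!r}"
                )
            row.append(int(value))
        taxon_ids.append(taxon)
        rows.append(row)
        if has_tax_col:
            tax_map[taxon] = _genus_from_taxonomy(cells[-1])
    for taxon in taxon_ids:
        tax_map.setdefault(taxon, "unclassified")
    counts = np.asarray(rows, dtype=np.int64)
    return FeatureTable(taxon_ids, sample_ids, counts, tax_map)


def write_feature_table(table: FeatureTable, path: str | Path, dialect: str = "tsv") -> None:
    if dialect not in ("tsv", "biom_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    header_tag = "#OTU ID" if dialect == "biom_tsv" else "#TaxonID"
    with path.open("w") as fh:
        if dialect == "biom_tsv":
            fh.write("# Feature table exported by microvar\n")
        fh.write("\t".join([header_tag, *table.sample_ids, "taxonomy"]) + "\n")
        for i, taxon in enumerate(table.taxon_ids):
            row = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{taxon}\t{row}\t{table.taxonomy[taxon]}\n")


# ---------------------------------------------------------------------------
# CohortMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleInfo:
    patient_id: str
    site: str
    day: int
    order: int


@dataclass
class PatientInfo:
    age: float | None = None
    days_all_abx: float | None = None
    days_treatment_abx: float | None = None
    n_antibiotics: int | None = None
    pip_tazo_gt72h: bool | None = None
    cefepime_gt72h: bool | None = None
    carbapenem_gt72h: bool | None = None
    chemo_category: str | None = None
    infection_during_ic: str | None = None
    infection_90d_post: bool | None = None
    remission: bool | None = None


@dataclass
class CohortMetadata:
    """sample_id → (patient, site, day, order) plus patient clinical data."""

    samples: dict[str, SampleInfo]
    patients: dict[str, PatientInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        keys: set[tuple[str, str, int]] = set()
        for sid, info in self.samples.items():
            if info.patient_id not in self.patients:
                raise ReferentialError(
                    f"sample {sid!r} references unknown patient {info.patient_id!r}"
                )
            if info.site not in SITES:
                raise FormatError(f"sample {sid!r}: invalid site {info.site!r}")
            if not math.isfinite(info.day):
                raise FormatError(f"sample {sid!r}: non-finite day")
            if info.order < 1:
                raise FormatError(f"sample {sid!r}: order must be a positive integer")
            key = (info.patient_id, info.site, info.order)
            if key in keys:
                raise FormatError(
                    f"duplicate (patient, site, order) = {key} at sample {sid!r}"
                )
            keys.add(key)
        for pid, info in self.patients.items():
            if info.chemo_category is not None and info.chemo_category not in CHEMO_CATEGORIES:
                raise FormatError(f"patient {pid!r}: invalid chemo_category {info.chemo_category!r}")
            if (
                info.infection_during_ic is not None
                and info.infection_during_ic not in INFECTION_LEVELS
            ):
                raise FormatError(
                    f"patient {pid!r}: invalid infection_during_ic {info.infection_during_ic!r}"
                )

    def samples_for(self, patient_id: str, site: str, ordered: bool = True) -> list[str]:
        """Sample ids of one patient at one site, by collection order."""
        hits = [
            (info.order, sid)
            for sid, info in self.samples.items()
            if info.patient_id == patient_id and info.site == site
        ]
        if ordered:
            hits.sort()
        return [sid for _, sid in hits]

    def patient_ids(self) -> list[str]:
        return list(self.patients)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        sample_df = pd.DataFrame(
            [
                {
                    "sample_id": sid,
                    "patient_id": s.patient_id,
                    "site": s.site,
                    "day": s.day,
                    "order": s.order,
                }
                for sid, s in self.samples.items()
            ],
            columns=SAMPLE_COLUMNS,
        )
        patient_df = pd.DataFrame(
            [
                {"patient_id": pid, **{k: getattr(p, k) for k in PATIENT_COLUMNS[1:]}}
                for pid, p in self.patients.items()
            ],
            columns=PATIENT_COLUMNS,
        )
        return sample_df, patient_df


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_optional_bool(value: object, context: str) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("", "na", "nan", "none"):
        return None
    if text in _BOOL_MAP:
        return _BOOL_MAP[text]
    raise FormatError(f"{context}: cannot interpret {value!r} as a boolean")


def _parse_optional_float(value: object, context: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text.lower() in ("", "na", "nan", "none"):
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"{context}: cannot interpret {value!r} as a number") from None


def read_metadata(sample_path: str | Path, patient_path: str | Path) -> CohortMetadata:
    """Read and cross-validate the sample and patient metadata TSVs."""
    sdf = pd.read_csv(sample_path, sep="\t", dtype=str)
    pdf = pd.read_csv(patient_path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in sdf.columns]
    if missing:
        raise FormatError(f"{sample_path}: missing columns {missing}")
    missing = [c for c in PATIENT_COLUMNS if c not in pdf.columns]
    if missing:
        raise FormatError(f"{patient_path}: missing columns {missing}")

    patients: dict[str, PatientInfo] = {}
    for _, row in pdf.iterrows():
        pid = str(row["patient_id"])
        if pid in patients:
            raise FormatError(f"{patient_path}: duplicate patient id {pid!r}")
        ctx = f"patient {pid!r}"
        chemo = row["chemo_category"]
        infection = row["infection_during_ic"]
        n_abx = _parse_optional_float(row["n_antibiotics"], ctx)
        patients[pid] = PatientInfo(
            age=_parse_optional_float(row["age"], ctx),
            days_all_abx=_parse_optional_float(row["days_all_abx"], ctx),
            days_treatment_abx=_parse_optional_float(row["days_treatment_abx"], ctx),
            n_antibiotics=int(n_abx) if n_abx is not None else None,
            pip_tazo_gt72h=_parse_optional_bool(row["pip_tazo_gt72h"], ctx),
            cefepime_gt72h=_parse_optional_bool(row["cefepime_gt72h"], ctx),
            carbapenem_gt72h=_parse_optional_bool(row["carbapenem_gt72h"], ctx),
            chemo_category=None if pd.isna(chemo) or str(chemo) == "" else str(chemo),
            infection_during_ic=None if pd.isna(infection) or str(infection) == "" else str(infection),
            infection_90d_post=_parse_optional_bool(row["infection_90d_post"], ctx),
            remission=_parse_optional_bool(row["remission"], ctx),
        )

    samples: dict[str, SampleInfo] = {}
    for _, row in sdf.iterrows():
        sid = str(row["sample_id"])
        if sid in samples:
            raise FormatError(f"{sample_path}: duplicate sample id {sid!r}")
        pid = str(row["patient_id"])
        if pid not in patients:
            raise ReferentialError(
                f"{sample_path}: sample {sid!r} references unknown patient {pid!r}"
            )
        try:
            day = int(float(row["day"]))
            order = int(float(row["order"]))
        except (TypeError, ValueError):
            raise FormatError(f"{sample_path}: sample {sid!r} has non-numeric day/order") from None
        samples[sid] = SampleInfo(patient_id=pid, site=str(row["site"]), day=day, order=order)

    return CohortMetadata(samples=samples, patients=patients)


def write_metadata(meta: CohortMetadata, sample_path: str | Path, patient_path: str | Path) -> None:
    sample_df, patient_df = meta.to_frames()
    sample_df.to_csv(sample_path, sep="\t", index=False)
    patient_df.to_csv(patient_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal labeled distance matrix."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        dup = _first_duplicate(self.ids)
        if dup is not None:
            raise FormatError(f"duplicate sample id {dup!r} in distance matrix")
        if self.values.shape != (n, n):
            raise FormatError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        if np.any(self.values < 0):
            raise FormatError("distance matrix contains negative values")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0.0):
            raise FormatError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise FormatError("distance matrix diagonal is not zero")

    def submatrix(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ReferentialError(f"unknown sample ids in distance matrix: {missing[:5]}")
        sel = [idx[s] for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(sel, sel)])

    def pair(self, a: str, b: str) -> float:
        i = self.ids.index(a)
        j = self.ids.index(b)
        return float(self.values[i, j])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(["", *dm.ids]) + "\n")
        for i, sid in enumerate(dm.ids):
            row = "\t".join(f"{v:.17g}" for v in dm.values[i])
            fh.write(f"{sid}\t{row}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(s) for s in df.columns]
    if [str(s) for s in df.index] != ids:
        raise FormatError(f"{path}: row and column labels disagree")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        raise FormatError(f"{path}: non-numeric distance value") from None
    return DistanceMatrix(ids, values)
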