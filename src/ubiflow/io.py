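"""Domain types and tabular readers/writers.

Every table the pipeline consumes or produces is UTF-8, tab-separated,
with a header row.  In-memory containers are thin wrappers around pandas
objects so that downstream modules can use vectorised operations while
invariants (unique ids, positive raw intensities, two-group design) are
validated once, at construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "AbundanceMatrix",
    "SiteAnnotation",
    "EsiLibrary",
    "ClinicalCohort",
    "LINKAGE_POSITIONS",
    "read_abundance_table",
    "read_design",
    "read_annotations",
    "read_esi_library",
    "read_clinical",
    "write_results",
    "read_results_table",
]

# Ubiquitin lysines through which poly-Ub chains extend; M1 (linear) chains
# leave no diGly remnant and are invisible to the enrichment.
LINKAGE_POSITIONS: tuple[int, ...] = (6, 11, 27, 29, 33, 48, 63)

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A"}


@dataclass(frozen=True)
class SampleDesign:
    """Two-group experimental design (e.g. Ctrl vs HLU, 4 replicates each).

    ``group_order`` fixes fold-change orientation: log2fc is always
    group_order[1] relative to group_order[0] (treatment over control).
    """

    sample_ids: tuple[str, ...]
    group_of: Mapping[str, str]
    group_order: tuple[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in design")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        groups = {self.group_of[s] for s in self.sample_ids}
        if groups != set(self.group_order):
            raise ValueError(
                f"design groups {sorted(groups)} do not match declared "
                f"group order {self.group_order}"
            )
        if len(self.group_order) != 2:
            raise ValueError("exactly two groups required")
        for g in self.group_order:
            if not self.samples_in(g):
                raise ValueError(f"group {g!r} has no samples")

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, group_order: Sequence[str] | None = None
    ) -> "SampleDesign":
        """Build from a (sample, group) table; first-seen order of groups
        defines orientation unless ``group_order`` is given."""
        samples = tuple(table["sample"].astype(str))
        groups = dict(zip(samples, table["group"].astype(str)))
        if group_order is None:
            seen: list[str] = []
            for s in samples:
                if groups[s] not in seen:
                    seen.append(groups[s])
            group_order = seen
        return cls(samples, groups, tuple(group_order))  # type: ignore[arg-type]

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.group_of[s] == group)

    @property
    def replicates_per_group(self) -> dict[str, int]:
        return {g: len(self.samples_in(g)) for g in self.group_order}

    def swapped(self) -> "SampleDesign":
        """Design with group orientation reversed (for symmetry checks)."""
        return SampleDesign(
            self.sample_ids, self.group_of, (self.group_order[1], self.group_order[0])
        )


@dataclass
class AbundanceMatrix:
    """Features x samples quantitative table; NaN marks a missing detection.

    ``scale`` is either ``"raw"`` (strictly positive intensities) or
    ``"log2_normalized"`` (after quantile normalisation + log2).
    """

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2_normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.scale == "raw":
            obs = self.values.to_numpy(dtype=float)
            if np.any(obs[~np.isnan(obs)] <= 0):
                raise ValueError("raw-scale matrix contains non-positive observed values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def check_design(self, design: SampleDesign) -> None:
        extra = set(self.sample_ids) - set(design.sample_ids)
        absent = set(design.sample_ids) - set(self.sample_ids)
        if extra or absent:
            raise ValueError(
                "sample mismatch between matrix and design: "
                f"not in design={sorted(extra)}, not in matrix={sorted(absent)}"
            )

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.scale)


@dataclass(frozen=True)
class SiteAnnotation:
    """One diGly site: 'PROTEIN_Kpos' id, parent protein, lysine position."""

    site_id: str
    protein_id: str
    position: int
    is_ubiquitin_site: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


def annotations_frame(annotations: Iterable[SiteAnnotation]) -> pd.DataFrame:
    df = pd.DataFrame(
        [dataclasses.asdict(a) for a in annotations],
        columns=["site_id", "protein_id", "position", "is_ubiquitin_site"],
    )
    if df["site_id"].duplicated().any():
        raise ValueError("duplicate site ids in annotation")
    return df.set_index("site_id")


@dataclass
class EsiLibrary:
    """Confidence-scored enzyme-substrate interaction library (E3 + DUB).

    Consumed as an input (e.g. a UbiBrowser export); never computed here.
    """

    records: pd.DataFrame  # columns enzyme_id, enzyme_class, substrate_id, confidence

    def __post_init__(self) -> None:
        req = ["enzyme_id", "enzyme_class", "substrate_id", "confidence"]
        if list(self.records.columns[:4]) != req:
            self.records = self.records[req]
        bad_class = set(self.records["enzyme_class"]) - {"E3", "DUB"}
        if bad_class:
            raise ValueError(f"unknown enzyme classes: {sorted(bad_class)}")
        conf = self.records["confidence"].to_numpy(dtype=float)
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidence scores must lie in [0, 1]")
        if self.records.duplicated(["enzyme_id", "enzyme_class", "substrate_id"]).any():
            raise ValueError("duplicate (enzyme, class, substrate) records in library")


@dataclass
class ClinicalCohort:
    """Subject-level clinical table: group label plus named real variables."""

    subjects: pd.DataFrame  # index subject_id; columns 'group' + variables
    group_order: tuple[str, str] = ("normal", "OP")

    def __post_init__(self) -> None:
        if self.subjects.index.has_duplicates:
            raise ValueError("duplicate subject ids")
        counts = self.subjects["group"].value_counts()
        for g in self.group_order:
            if counts.get(g, 0) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 subjects")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.subjects.columns if c != "group"]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    dialect: str = "wide",
    scale: str = "raw",
    zero_is_missing: bool = False,
) -> AbundanceMatrix:
    """Read an abundance table.

    wide dialect: first column = feature id, remaining columns = samples.
    long dialect: columns (feature, sample, value), one row per cell.
    Empty cells, "NA" and "NaN" are missing; literal 0 in raw scale is
    treated as missing only when ``zero_is_missing`` is set (DIA exports
    differ on this convention).
    """
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(
            path, sep="\t", dtype={0: str}, na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
        feat_col = df.columns[0]
        if df[feat_col].duplicated().any():
            dups = df[feat_col][df[feat_col].duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids in {path}: {dups}")
        values = df.set_index(feat_col).astype(float)
        values.index.name = "feature_id"
    elif dialect == "long":
        df = pd.read_csv(
            path, sep="\t", na_values=list(MISSING_TOKENS), keep_default_na=False,
            dtype={"feature": str, "sample": str},
        )
        if df.duplicated(["feature", "sample"]).any():
            raise ValueError(f"duplicate (feature, sample) cells in {path}")
        values = (
            df.pivot(index="feature", columns="sample", values="value").astype(float)
        )
        # preserve first-appearance order of features and samples
        values = values.reindex(
            index=df["feature"].drop_duplicates(),
            columns=df["sample"].drop_duplicates(),
        )
        values.index.name = "feature_id"
        values.columns.name = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if scale == "raw" and zero_is_missing:
        values = values.mask(values == 0)
    return AbundanceMatrix(values, scale=scale)


def read_design(path: str | Path, group_order: Sequence[str] | None = None) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign.from_table(table, group_order)


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "protein_id": str})
    anns = [
        SiteAnnotation(
            site_id=str(r.site_id),
            protein_id=str(r.protein_id),
            position=int(r.position),
            is_ubiquitin_site=bool(r.is_ubiquitin_site),
        )
        for r in df.itertuples()
    ]
    if len({a.site_id for a in anns}) != len(anns):
        raise ValueError("duplicate site ids in annotation table")
    return anns


def read_esi_library(path: str | Path) -> EsiLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"enzyme_id": str, "substrate_id": str})
    return EsiLibrary(df)


def read_clinical(
    path: str | Path, group_order: Sequence[str] = ("normal", "OP")
) -> ClinicalCohort:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "group": str})
    df = df.set_index("subject_id")
    return ClinicalCohort(df, tuple(group_order))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping | None = None,
) -> dict[str, Path]:
    """Write result tables as TSV plus a machine-readable JSON run summary.

    Re-reading a written table with :func:`read_results_table` yields
    identical content.  Returns the mapping name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False, na_rep="NA")
        written[name] = p
    if summary is not None:
        p = out_dir / "run_summary.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["run_summary"] = p
    return written


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
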