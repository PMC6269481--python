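"""Readers and writers for the pipeline's on-disk artifacts.

All tabular artifacts are UTF-8, tab-separated text with "." as the decimal
point.  Every reader validates its input against the corresponding container
invariants and raises :class:`FormatError` on violation — downstream modules
can therefore assume clean, finite, duplicate-free inputs.  Missing expression
values are rejected outright rather than imputed: the per-sample rank
transform that drives signature scoring is undefined on missing data.

Containers
----------
ExpressionMatrix
    features x samples matrix of log-scale expression values.
DirectionalSignature
    named "up"/"down" feature-id sets (the two columns of a published
    stem-cell signature table).
ClinicalTable
    per-sample survival time, event indicator and risk covariates
    (MYCN amplification, stage 4, age at diagnosis >= 1 year).
GeneSetCollection
    named gene sets as read from a GMT file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "DirectionalSignature",
    "ClinicalTable",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_signature",
    "write_signature",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "write_clinical_table",
    "load_packaged_signature",
]

CLINICAL_COLUMNS = (
    "sample_id",
    "os_time",
    "os_event",
    "mycn_amplified",
    "stage4",
    "age_ge_1y",
)
_COVARIATE_COLUMNS = ("mycn_amplified", "stage4", "age_ge_1y")


class FormatError(ValueError):
    """An on-disk artifact violates the format contract or a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features-by-samples matrix of finite, log-scale expression values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise FormatError(
                f"expression matrix needs >=2 features and >=1 sample, got {df.shape}"
            )
        _check_unique(df.index, "feature id")
        _check_unique(df.columns, "sample id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(df.to_numpy(dtype=float, na_value=np.nan)))
            i, j = bad[0]
            raise FormatError(
                f"non-finite expression value at feature {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class DirectionalSignature:
    """Disjoint up- and down-regulated feature-id sets under one name."""

    name: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        both = self.up & self.down
        if both:
            raise FormatError(
                f"signature {self.name!r} lists features in both directions: "
                f"{sorted(both)}"
            )
        if not (self.up | self.down):
            raise FormatError(f"signature {self.name!r} is empty")

    @property
    def members(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample overall-survival outcome and binary risk covariates.

    ``os_time`` is in years; ``os_event`` is 1 for death of disease, 0 for
    censoring.  The three covariates are nullable 0/1 integers (pandas
    ``Int64``): an empty field on disk means unknown.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns {missing}")
        _check_unique(df["sample_id"], "sample id")
        t = df["os_time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or (t < 0).any():
            raise FormatError("os_time must be finite and >= 0")
        ev = df["os_event"].to_numpy(dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise FormatError("os_event must be 0 or 1")
        for c in _COVARIATE_COLUMNS:
            col = df[c]
            bad = col.dropna()[~col.dropna().isin((0, 1))]
            if len(bad):
                raise FormatError(f"{c} must be 0, 1 or missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; names unique, every set nonempty."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            members = frozenset(members)
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            clean[name] = members
        object.__setattr__(self, "sets", clean)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Load a TSV expression matrix (features in rows, samples in columns).

    The first column holds feature ids, the first row sample ids, and the body
    must be fully numeric — a blank or non-numeric cell is an error reported
    with its (feature, sample) coordinates.  ``transpose=True`` accepts the
    samples-in-rows dialect.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    _check_unique(raw.index, "feature id")
    _check_unique(raw.columns, "sample id")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float)))
    if len(bad):
        i, j = bad[0]
        raise FormatError(
            f"non-numeric or missing value {raw.iat[i, j]!r} at "
            f"feature {raw.index[i]!r}, sample {raw.columns[j]!r} in {path}"
        )
    if transpose:
        numeric = numeric.T
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    df = mat.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.12g", encoding="utf-8")


# ---------------------------------------------------------------------------
# directional signatures
# ---------------------------------------------------------------------------

def read_signature(path: str | Path, name: str | None = None) -> DirectionalSignature:
    """Load a two-column TSV signature: ``feature_id <TAB> direction``.

    ``direction`` must be ``up`` or ``down`` (case-insensitive).  An optional
    literal ``feature_id<TAB>direction`` header line is skipped.
    """
    up: set[str] = set()
    down: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if lineno == 1 and [f.lower() for f in fields[:2]] == ["feature_id", "direction"]:
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            feature, direction = fields[0], fields[1].lower()
            if direction == "up":
                target, other = up, down
            elif direction == "down":
                target, other = down, up
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown direction {fields[1]!r} (expected up/down)"
                )
            if feature in other:
                raise FormatError(
                    f"{path}:{lineno}: feature {feature!r} listed in both directions"
                )
            target.add(feature)
    return DirectionalSignature(name=name or Path(path).stem, up=up, down=down)


def write_signature(sig: DirectionalSignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for feature in sorted(sig.up):
            fh.write(f"{feature}\tup\n")
        for feature in sorted(sig.down):
            fh.write(f"{feature}\tdown\n")


def load_packaged_signature() -> DirectionalSignature:
    """The packaged 60-member embryonic-stem-cell miRNA signature (33 up / 27 down)."""
    ref = importlib.resources.files("stemscore.data") / "esc_mirna_signature.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_signature(path, name="esc_mirna_signature")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Load gene sets from GMT: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 fields (name, description, members)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Load the six-column clinical TSV; empty covariate cells become missing."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table {path} missing columns {missing}")
    out = pd.DataFrame({"sample_id": df["sample_id"].str.strip()})
    for col in ("os_time", "os_event"):
        vals = pd.to_numeric(df[col].str.strip(), errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise FormatError(f"{path}: non-numeric {col} in row {row + 2}")
        out[col] = vals.astype(float)
    out["os_event"] = out["os_event"].astype(int)
    for col in _COVARIATE_COLUMNS:
        vals = pd.to_numeric(df[col].str.strip().replace("", None), errors="coerce")
        out[col] = vals.astype("Int64")
    return ClinicalTable(out)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    for col in _COVARIATE_COLUMNS:
        df[col] = df[col].astype(object).where(df[col].notna(), "")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", encoding="utf-8")
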