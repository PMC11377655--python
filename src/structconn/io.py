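"""Reading, validation and writing of connectome inputs.

The on-disk formats are deliberately plain: connectivity matrices are
delimited numeric text (comma or tab, optional header row of region
labels), the parcellation is a four-column CSV and the cohort manifest a
one-row-per-subject CSV.  Everything is validated on load; the in-memory
containers below are the contracts the rest of the package works with.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9

HEMISPHERES = ("left", "right", "midline")
SUBSYSTEMS = ("MTL", "DMN", "none")
GROUPS = ("patient", "control")

#: regional volumes carried in the manifest (mm^3)
VOLUME_REGIONS = (
    "left_hippocampus",
    "right_hippocampus",
    "posterior_cingulate",
    "cerebral_white_matter",
)

#: clinical / cognitive scores carried in the manifest
SCORE_NAMES = (
    "mrs_acute",
    "onset_treatment_days",
    "ravlt_delayed",
    "rocf_delayed",
    "gonogo",
)


class ConnectomeIOError(ValueError):
    """Raised for any validation failure while reading inputs."""


@dataclass(frozen=True)
class ParcellationTable:
    """Node index -> (label, hemisphere, subsystem) mapping.

    ``node_index`` must be the contiguous sequence 0..n-1; labels are
    unique.  The subsystem tag marks the a-priori modules: MTL
    (hippocampus, parahippocampal gyrus, entorhinal cortex per
    hemisphere) and DMN (seven regions per hemisphere).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"node_index", "label", "hemisphere", "subsystem"}
        missing = required - set(df.columns)
        if missing:
            raise ConnectomeIOError(f"parcellation missing columns: {sorted(missing)}")
        idx = df["node_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(df))):
            raise ConnectomeIOError(
                "parcellation node_index must be the contiguous sequence 0..n-1; "
                f"got {idx.tolist()[:10]}..."
            )
        if df["label"].duplicated().any():
            dupes = df.loc[df["label"].duplicated(), "label"].tolist()
            raise ConnectomeIOError(f"duplicate parcellation labels: {dupes}")
        bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ConnectomeIOError(f"unknown hemisphere values: {sorted(bad_hemi)}")
        bad_sub = set(df["subsystem"]) - set(SUBSYSTEMS)
        if bad_sub:
            raise ConnectomeIOError(f"unknown subsystem values: {sorted(bad_sub)}")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    def nodes_in(self, subsystem: str, hemisphere: str | None = None) -> np.ndarray:
        """0-based node indices tagged with ``subsystem`` (optionally one hemisphere)."""
        df = self.table
        mask = df["subsystem"] == subsystem
        if hemisphere is not None:
            mask &= df["hemisphere"] == hemisphere
        return df.loc[mask, "node_index"].to_numpy()

    def index_of(self, label: str) -> int:
        hits = self.table.loc[self.table["label"] == label, "node_index"]
        if hits.empty:
            raise KeyError(f"label {label!r} not in parcellation")
        return int(hits.iloc[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParcellationTable):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative weighted graph over parcellation nodes.

    Weights are streamline counts (or any nonnegative real); the
    diagonal is zero.  Construction validates these invariants.
    """

    weights: np.ndarray
    parcellation: ParcellationTable

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = self.parcellation.n
        if w.shape != (n, n):
            raise ConnectomeIOError(
                f"matrix shape {w.shape} does not match parcellation of {n} nodes"
            )
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise ConnectomeIOError(f"non-finite entry at cell ({i}, {j})")
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ConnectomeIOError(f"negative entry {w[i, j]} at cell ({i}, {j})")
        asym = np.abs(w - w.T)
        if asym.max() > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ConnectomeIOError(
                f"asymmetry {asym[i, j]:.3g} at cell pair ({i}, {j}) exceeds "
                f"tolerance {SYMMETRY_TOL}"
            )
        if np.any(np.diag(w) != 0):
            raise ConnectomeIOError("diagonal must be zero")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    matrix: ConnectivityMatrix
    age: float
    education: float
    icv: float
    regional_volumes: Mapping[str, float] = field(default_factory=dict)
    scores: Mapping[str, float] = field(default_factory=dict)  # NaN = missing

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConnectomeIOError(
                f"subject {self.subject_id}: unknown group {self.group!r}"
            )
        if not self.age > 0:
            raise ConnectomeIOError(f"subject {self.subject_id}: age must be > 0")
        if not self.icv > 0:
            raise ConnectomeIOError(f"subject {self.subject_id}: icv must be > 0")
        for region, v in self.regional_volumes.items():
            if np.isfinite(v) and v < 0:
                raise ConnectomeIOError(
                    f"subject {self.subject_id}: negative volume for {region}"
                )


@dataclass
class Cohort:
    subjects: list[SubjectRecord]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ConnectomeIOError("cohort is empty")
        p0 = self.subjects[0].matrix.parcellation
        for s in self.subjects[1:]:
            if s.matrix.parcellation != p0:
                raise ConnectomeIOError(
                    f"subject {s.subject_id} uses a different parcellation"
                )

    @property
    def parcellation(self) -> ParcellationTable:
        return self.subjects[0].matrix.parcellation

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


# ---------------------------------------------------------------------------
# loaders


def _sniff(path: Path) -> tuple[str, bool]:
    """Return (delimiter, has_header) for a delimited matrix file."""
    first = path.open().readline()
    sep = "\t" if "\t" in first else ","
    fields = first.rstrip("\n").split(sep)
    has_header = False
    for tok in fields:
        tok = tok.strip()
        if tok == "":
            continue
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    return sep, has_header


def load_matrix(path: str | Path, parcellation: ParcellationTable) -> ConnectivityMatrix:
    """Read an n x n delimited matrix and validate it against ``parcellation``.

    Asymmetries within the 1e-9 tolerance are symmetrized by averaging;
    larger ones are fatal.  A nonzero diagonal is forced to zero with a
    logged warning.
    """
    path = Path(path)
    sep, has_header = _sniff(path)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, float_precision="round_trip")
    if has_header:
        got = [str(c) for c in df.columns]
        if got != parcellation.labels:
            raise ConnectomeIOError(
                f"{path}: header labels do not match parcellation "
                f"(first mismatch at column "
                f"{next(i for i, (a, b) in enumerate(zip(got, parcellation.labels)) if a != b)})"
            )
    try:
        w = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ConnectomeIOError(f"{path}: non-numeric matrix entry ({exc})") from exc
    n = parcellation.n
    if w.shape != (n, n):
        raise ConnectomeIOError(
            f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, parcellation has {n} nodes"
        )
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ConnectomeIOError(f"{path}: NaN/inf entry at cell ({i}, {j})")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise ConnectomeIOError(f"{path}: negative entry {w[i, j]} at cell ({i}, {j})")
    asym = np.abs(w - w.T)
    if asym.max() > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ConnectomeIOError(
            f"{path}: asymmetry {asym[i, j]:.3g} at cell pair ({i}, {j}) "
            f"exceeds tolerance {SYMMETRY_TOL}"
        )
    w = (w + w.T) / 2.0
    if np.any(np.diag(w) != 0):
        log.warning("%s: nonzero diagonal forced to zero", path)
        np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, parcellation)


def write_matrix(m: ConnectivityMatrix, path: str | Path, header: bool = True) -> None:
    """Write a matrix as CSV with 17 significant digits (lossless round-trip)."""
    path = Path(path)
    with path.open("w") as f:
        if header:
            f.write(",".join(m.parcellation.labels) + "\n")
        for row in m.weights:
            f.write(",".join(f"{v:.17g}" for v in row) + "\n")


def load_parcellation(path: str | Path) -> ParcellationTable:
    df = pd.read_csv(path)
    return ParcellationTable(df)


def write_parcellation(p: ParcellationTable, path: str | Path) -> None:
    p.table.to_csv(path, index=False)


def default_parcellation() -> ParcellationTable:
    """The bundled 84-region Desikan-Killiany + subcortical table.

    34 cortical regions and 8 subcortical structures per hemisphere,
    left block first, with MTL and DMN subsystem tags prefilled.
    """
    with resources.files("structconn.data").joinpath("parcellation_dk84.csv").open() as f:
        return ParcellationTable(pd.read_csv(f))


def load_freesurfer_lookup(
    path: str | Path,
    subsystem_map: Mapping[str, str] | None = None,
) -> ParcellationTable:
    """Convenience importer for a FreeSurfer-style label-per-line lookup file.

    Each non-comment line is ``<index> <label> [...]``; indices must form a
    contiguous 0-based sequence after sorting.  Hemisphere is inferred from
    the ``lh.``/``rh.``/``Left-``/``Right-`` label prefix; subsystem tags
    come from ``subsystem_map`` (label -> tag), defaulting to "none".
    """
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        entries.append((int(parts[0]), parts[1]))
    entries.sort()
    rows = []
    for idx, label in entries:
        if label.startswith(("lh.", "Left-")):
            hemi = "left"
        elif label.startswith(("rh.", "Right-")):
            hemi = "right"
        else:
            hemi = "midline"
        sub = (subsystem_map or {}).get(label, "none")
        rows.append((idx, label, hemi, sub))
    df = pd.DataFrame(rows, columns=["node_index", "label", "hemisphere", "subsystem"])
    return ParcellationTable(df)


def _parse_optional(value) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    if isinstance(value, str) and value.strip().upper() in ("", "NA", "NAN"):
        return math.nan
    return float(value)


def load_cohort(
    manifest: str | Path,
    parcellation: ParcellationTable,
    base_dir: str | Path | None = None,
) -> Cohort:
    """Assemble a cohort from a manifest CSV.

    Matrix paths resolve relative to ``base_dir`` (default: the manifest's
    directory).  Group labels are normalized case-insensitively.  Missing
    clinical scores (empty or "NA") are recorded as NaN and counted in a
    log message.
    """
    manifest = Path(manifest)
    base = Path(base_dir) if base_dir is not None else manifest.parent
    df = pd.read_csv(manifest, dtype={"subject_id": str}, float_precision="round_trip")
    required = {"subject_id", "group", "matrix_path", "age", "education", "icv"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeIOError(f"manifest missing columns: {sorted(missing)}")
    subjects = []
    n_missing_scores = 0
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        group = str(row["group"]).strip().lower()
        if group not in GROUPS:
            raise ConnectomeIOError(f"subject {sid}: unknown group label {row['group']!r}")
        mpath = base / str(row["matrix_path"])
        try:
            matrix = load_matrix(mpath, parcellation)
        except (OSError, ConnectomeIOError) as exc:
            raise ConnectomeIOError(f"subject {sid}: cannot read matrix ({exc})") from exc
        volumes = {
            r: _parse_optional(row.get(f"vol_{r}")) for r in VOLUME_REGIONS if f"vol_{r}" in df.columns
        }
        scores = {s: _parse_optional(row.get(s)) for s in SCORE_NAMES if s in df.columns}
        n_missing_scores += sum(1 for v in scores.values() if math.isnan(v))
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                matrix=matrix,
                age=float(row["age"]),
                education=float(row["education"]),
                icv=float(row["icv"]),
                regional_volumes=volumes,
                scores=scores,
            )
        )
    if n_missing_scores:
        log.info("manifest %s: %d missing score values recorded as NaN", manifest, n_missing_scores)
    return Cohort(subjects)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write matrices, parcellation and manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    write_parcellation(cohort.parcellation, out / "parcellation.csv")
    rows = []
    for s in cohort.subjects:
        rel = f"matrices/{s.subject_id}.csv"
        write_matrix(s.matrix, out / rel)
        row: dict[str, object] = {
            "subject_id": s.subject_id,
            "group": s.group,
            "matrix_path": rel,
            "age": s.age,
            "education": s.education,
            "icv": s.icv,
        }
        for r in VOLUME_REGIONS:
            row[f"vol_{r}"] = s.regional_volumes.get(r, math.nan)
        for sc in SCORE_NAMES:
            row[sc] = s.scores.get(sc, math.nan)
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.17g")
    return manifest
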