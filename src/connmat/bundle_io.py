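"""Read, validate, and write connectivity-matrix bundles.

A bundle is the four-file exchange unit used by connectivity-matrix sharing
repositories: a tab-delimited square connection-weight matrix (optionally
several matrices stacked vertically for batch transfer), plus three sidecar
text files — full region names, region abbreviations, and region (x, y, z)
center coordinates in mm — with line i of every sidecar describing node i.
A structured metadata record (study name, network name, modality,
demographics, preprocessing flags) travels alongside as CSV or JSON.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "RegionSet",
    "NetworkMetadata",
    "ConnectivityMatrix",
    "BundleFormatError",
    "read_region_files",
    "read_matrix",
    "read_bundle",
    "write_bundle",
    "export_study_metadata",
]

#: relative symmetry tolerance: max |w_ij - w_ji| <= SYMMETRY_RTOL * max(1, max|w|)
SYMMETRY_RTOL = 1e-8

# Metadata schema: required fields first, then the optional upload-page fields.
METADATA_FIELDS = (
    "study_name",
    "network_name",
    "modality",
    "sharing",
    "atlas",
    "scanner",
    "scan_parameters",
    "age_min",
    "age_max",
    "gender",
    "subject_pool",
    "group_size",
    "preprocessing_notes",
    "funding",
)


class BundleFormatError(ValueError):
    """A bundle file violates the format contract (shape, symmetry, parse)."""


@dataclass(frozen=True)
class RegionSet:
    """Ordered node definition: names, abbreviations and mm coordinates.

    The three sequences are index-aligned: entry ``i`` of each describes
    node ``i`` of the network. Coordinates are conventionally MNI152 mm
    but units are carried as-is.
    """

    names: tuple[str, ...]
    abbreviations: tuple[str, ...]
    coords: np.ndarray  # shape (n, 3), float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.names)
        if n < 2:
            raise BundleFormatError(f"a region set needs at least 2 regions, got {n}")
        if len(self.abbreviations) != n or coords.shape != (n, 3):
            raise BundleFormatError(
                "region set misaligned: "
                f"{n} names, {len(self.abbreviations)} abbreviations, "
                f"coords shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise BundleFormatError("non-finite region coordinate")
        if any(not name.strip() for name in self.names):
            raise BundleFormatError("empty region name")
        if len(set(self.names)) != n:
            warnings.warn("duplicate region names in region set", stacklevel=3)

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return (
            self.names == other.names
            and self.abbreviations == other.abbreviations
            and np.array_equal(self.coords, other.coords)
        )


@dataclass
class NetworkMetadata:
    """Upload-page style metadata for one network.

    Required: study and network names. Everything else is optional and kept
    as explicit ``None`` when absent. Modality-specific boolean/numeric
    preprocessing flags (GSR, eddy correction, tractography type, ...) go in
    ``preprocessing_flags``.
    """

    study_name: str
    network_name: str
    modality: str = "other"  # fMRI, dwMRI/DTI, other
    sharing: str = "public"  # public or private
    atlas: str | None = None
    scanner: str | None = None
    scan_parameters: str | None = None
    age_min: float | None = None
    age_max: float | None = None
    gender: str | None = None
    subject_pool: str | None = None
    group_size: int | None = None
    preprocessing_notes: str | None = None
    funding: str | None = None
    preprocessing_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study_name.strip() or not self.network_name.strip():
            raise BundleFormatError("study_name and network_name must be non-empty")
        if self.sharing not in ("public", "private"):
            raise BundleFormatError(f"sharing must be public or private, got {self.sharing!r}")
        if self.age_min is not None and self.age_max is not None and self.age_min > self.age_max:
            raise BundleFormatError(f"age_min {self.age_min} exceeds age_max {self.age_max}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkMetadata":
        return cls(**d)


@dataclass
class ConnectivityMatrix:
    """A raw symmetric weighted adjacency matrix with node and study context.

    Validation enforces squareness, symmetry within a relative tolerance
    (after which the matrix is symmetrized by averaging so downstream math is
    exact), finiteness, and a zero diagonal: self-connections are undefined
    in the analysis, so nonzero diagonals are zeroed with a warning.
    """

    weights: np.ndarray
    regions: RegionSet
    metadata: NetworkMetadata

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise BundleFormatError(f"connectivity matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n != len(self.regions):
            raise BundleFormatError(
                f"matrix dimension {n} does not match region set length {len(self.regions)}"
            )
        if not np.all(np.isfinite(w)):
            raise BundleFormatError("non-finite matrix entry")
        asym = np.abs(w - w.T)
        tol = SYMMETRY_RTOL * max(1.0, float(np.max(np.abs(w))) if w.size else 1.0)
        worst = float(asym.max()) if asym.size else 0.0
        if worst > tol:
            i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
            raise BundleFormatError(
                f"matrix asymmetric beyond tolerance: |w[{i},{j}] - w[{j},{i}]| = {worst:g}"
            )
        w = (w + w.T) / 2.0
        if np.any(np.diag(w) != 0):
            warnings.warn("nonzero diagonal entries set to 0 (self-connections ignored)",
                          stacklevel=3)
            np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln.rstrip("\r") for ln in text.split("\n")]
    while lines and lines[-1] == "":
        lines.pop()
    return lines


def read_region_files(
    names_path: str | Path, abbrev_path: str | Path, xyz_path: str | Path
) -> RegionSet:
    """Read the three sidecar files into an aligned :class:`RegionSet`.

    Each file lists one entry per line; line i of every file describes node
    i. The coordinate file carries three whitespace- or tab-separated numeric
    columns per line.
    """
    names = _read_lines(names_path)
    abbrevs = _read_lines(abbrev_path)
    xyz_lines = _read_lines(xyz_path)
    lengths = {len(names), len(abbrevs), len(xyz_lines)}
    if len(lengths) != 1:
        raise BundleFormatError(
            "region file length mismatch: "
            f"{len(names)} names, {len(abbrevs)} abbreviations, {len(xyz_lines)} coordinates"
        )
    coords = np.empty((len(xyz_lines), 3), dtype=float)
    for i, line in enumerate(xyz_lines):
        parts = line.split()
        if len(parts) != 3:
            raise BundleFormatError(
                f"coordinate line {i + 1}: expected 3 columns, got {len(parts)}"
            )
        try:
            coords[i] = [float(p) for p in parts]
        except ValueError as exc:
            raise BundleFormatError(f"coordinate line {i + 1}: non-numeric value ({exc})") from exc
    return RegionSet(tuple(n.strip() for n in names), tuple(a.strip() for a in abbrevs), coords)


def read_matrix(
    path: str | Path,
    region_set: RegionSet,
    metadata: NetworkMetadata | None = None,
) -> list[ConnectivityMatrix]:
    """Read a (possibly batch-stacked) tab-delimited matrix file.

    The file holds one or more n x n matrices stacked vertically, n being the
    region-set length; a file of 600 rows by 100 columns with n = 100 yields
    6 matrices, split in stacking order. Each block is validated as a
    :class:`ConnectivityMatrix`.
    """
    n = len(region_set)
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise BundleFormatError(f"could not parse matrix file {path}: {exc}") from exc
    rows, cols = data.shape
    if cols != n:
        raise BundleFormatError(f"matrix has {cols} columns but region set has {n} regions")
    if rows % n != 0:
        raise BundleFormatError(
            f"batch format error: {rows} rows is not a multiple of network size {n}"
        )
    if metadata is None:
        metadata = NetworkMetadata(study_name="unnamed", network_name=Path(path).stem)
    return [
        ConnectivityMatrix(data[k * n : (k + 1) * n], region_set, metadata)
        for k in range(rows // n)
    ]


def read_bundle(bundle_dir: str | Path) -> list[ConnectivityMatrix]:
    """Read a bundle directory written by :func:`write_bundle`."""
    d = Path(bundle_dir)
    regions = read_region_files(
        d / "region_names.txt", d / "region_abbreviations.txt", d / "region_xyz_centers.txt"
    )
    metadata = None
    meta_path = d / "metadata.json"
    if meta_path.exists():
        metadata = NetworkMetadata.from_dict(json.loads(meta_path.read_text(encoding="utf-8")))
    return read_matrix(d / "connectivity_matrix.txt", regions, metadata)


def write_bundle(
    matrices: list[ConnectivityMatrix] | ConnectivityMatrix,
    region_set: RegionSet,
    metadata: NetworkMetadata,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write matrices + region files + metadata as a bundle directory.

    Matrices are stacked vertically in the connectivity-matrix file; the
    region lists are written once (readers repeat them per network as
    needed). Numeric output uses repr precision so a read-back round-trips
    bit-for-bit.
    """
    if isinstance(matrices, ConnectivityMatrix):
        matrices = [matrices]
    if not matrices:
        raise BundleFormatError("no matrices to write")
    n = len(region_set)
    for m in matrices:
        if m.n != n:
            raise BundleFormatError(
                f"matrix dimension {m.n} does not match region set length {n}"
            )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "names": out / "region_names.txt",
        "abbreviations": out / "region_abbreviations.txt",
        "xyz": out / "region_xyz_centers.txt",
        "matrix": out / "connectivity_matrix.txt",
        "metadata": out / "metadata.json",
    }
    paths["names"].write_text("\n".join(region_set.names) + "\n", encoding="utf-8")
    paths["abbreviations"].write_text(
        "\n".join(region_set.abbreviations) + "\n", encoding="utf-8"
    )
    paths["xyz"].write_text(
        "\n".join("\t".join(repr(float(v)) for v in row) for row in region_set.coords) + "\n",
        encoding="utf-8",
    )
    with paths["matrix"].open("w", encoding="utf-8") as fh:
        for m in matrices:
            for row in m.weights:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    paths["metadata"].write_text(
        json.dumps(metadata.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    return paths


def export_study_metadata(records: list[NetworkMetadata], format: str) -> str:
    """Serialize one metadata record per network as CSV or JSON text."""
    if format == "json":
        return json.dumps([r.to_dict() for r in records], indent=2)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(METADATA_FIELDS) + ["preprocessing_flags"])
        writer.writeheader()
        for r in records:
            d = r.to_dict()
            d["preprocessing_flags"] = json.dumps(d["preprocessing_flags"], sort_keys=True)
            writer.writerow(d)
        return buf.getvalue()
    raise ValueError(f"unknown metadata format {format!r}; use 'csv' or 'json'")
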