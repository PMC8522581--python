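"""Reading and writing of point-pattern samples and cohort manifests.

A *point pattern* is the standard representation of a segmented multiplexed
immunofluorescence (mIF) image: one row per cell, carrying the planar
coordinates of the nucleus centre and a symbolic phenotype label.  Disease
class labels live in a separate cohort manifest, not in the per-sample file.

File dialects are deliberately plain: comma-separated UTF-8 text with a
mandatory header.  Coordinates are kept in whatever planar units the
upstream segmentation produced; the downstream k-NN graph only ever uses
relative Euclidean distances, so no rescaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Default phenotype dictionary: pancytokeratin+ epithelium, CD3+CD8+
#: cytotoxic T lymphocytes, FoxP3+ regulatory T cells.
DEFAULT_CELL_TYPES: tuple[str, ...] = ("Epithelial", "CTL", "Treg")

#: Default six-way pancreatic disease class set.
DEFAULT_DISEASE_CLASSES: tuple[str, ...] = (
    "CP",
    "IPMN",
    "MCN",
    "PanIN",
    "PDAC",
    "IPMN-associated PDAC",
)


class PointPatternError(ValueError):
    """Raised when a point pattern violates its invariants."""


@dataclass
class PointPattern:
    """One sample: cell coordinates, phenotype labels and optional class.

    Parameters
    ----------
    sample_id
        Identifier of the sample (file stem by convention).
    coords
        ``(N, 2)`` float array of planar cell positions, arbitrary units.
    labels
        Length-``N`` sequence of phenotype symbols, each a member of
        ``label_dictionary``.
    label_dictionary
        Ordered collection of admissible phenotype symbols (size >= 2).
    disease_class
        Optional disease-class symbol; carried by the manifest, never by
        the per-sample file.
    """

    sample_id: str
    coords: np.ndarray
    labels: tuple[str, ...]
    label_dictionary: tuple[str, ...] = DEFAULT_CELL_TYPES
    disease_class: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = tuple(str(x) for x in self.labels)
        self.label_dictionary = tuple(self.label_dictionary)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise PointPatternError(
                f"coords must be (N, 2); got shape {self.coords.shape}"
            )
        if self.n_cells < 1:
            raise PointPatternError("a point pattern needs at least one cell")
        if not np.isfinite(self.coords).all():
            raise PointPatternError("coordinates must be finite")
        if len(self.labels) != self.n_cells:
            raise PointPatternError(
                f"{len(self.labels)} labels for {self.n_cells} coordinate rows"
            )
        if len(self.label_dictionary) < 2:
            raise PointPatternError("label dictionary needs at least 2 symbols")
        if len(set(self.label_dictionary)) != len(self.label_dictionary):
            raise PointPatternError("label dictionary has duplicate symbols")
        allowed = set(self.label_dictionary)
        for row, lab in enumerate(self.labels):
            if lab not in allowed:
                raise PointPatternError(
                    f"row {row}: label {lab!r} not in dictionary "
                    f"{self.label_dictionary}"
                )

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def label_indices(self) -> np.ndarray:
        """Labels encoded as integer indices into the dictionary."""
        lut = {lab: i for i, lab in enumerate(self.label_dictionary)}
        return np.array([lut[lab] for lab in self.labels], dtype=np.int64)

    def subset(self, indices: Sequence[int], sample_id: str | None = None) -> "PointPattern":
        """New pattern restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=np.int64)
        return PointPattern(
            sample_id=sample_id or self.sample_id,
            coords=self.coords[idx],
            labels=tuple(self.labels[i] for i in idx),
            label_dictionary=self.label_dictionary,
            disease_class=self.disease_class,
        )


@dataclass
class CohortManifest:
    """Maps per-sample files to disease classes."""

    entries: list[tuple[str, str]]
    class_set: tuple[str, ...] = DEFAULT_DISEASE_CLASSES

    def __post_init__(self) -> None:
        self.class_set = tuple(self.class_set)
        paths = [p for p, _ in self.entries]
        if len(set(paths)) != len(paths):
            raise PointPatternError("manifest paths must be unique")
        allowed = set(self.class_set)
        for path, cls in self.entries:
            if cls not in allowed:
                raise PointPatternError(
                    f"manifest entry {path!r}: class {cls!r} not in {self.class_set}"
                )

    def __len__(self) -> int:
        return len(self.entries)


def read_point_pattern(
    path: str | Path,
    label_dictionary: Sequence[str] = DEFAULT_CELL_TYPES,
    sample_id: str | None = None,
) -> PointPattern:
    """Read one sample CSV (columns ``x, y, cell_type``) into a PointPattern.

    Row order is preserved.  Any label outside ``label_dictionary`` raises a
    :class:`PointPatternError` naming the offending row; labels are never
    silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"cell_type": str})
    missing = {"x", "y", "cell_type"} - set(df.columns)
    if missing:
        raise PointPatternError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    if len(df) == 0:
        raise PointPatternError(f"{path}: empty point pattern")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    return PointPattern(
        sample_id=sample_id or path.stem,
        coords=coords,
        labels=tuple(df["cell_type"]),
        label_dictionary=tuple(label_dictionary),
    )


def write_point_pattern(pattern: PointPattern, path: str | Path) -> Path:
    """Write a sample as CSV with header ``x,y,cell_type``, full precision.

    The disease class is deliberately not serialized here; it belongs to the
    cohort manifest.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "x": pattern.coords[:, 0],
            "y": pattern.coords[:, 1],
            "cell_type": list(pattern.labels),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_manifest(
    path: str | Path, class_set: Sequence[str] = DEFAULT_DISEASE_CLASSES
) -> CohortManifest:
    """Read a cohort manifest CSV with columns ``path, disease_class``."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = {"path", "disease_class"} - set(df.columns)
    if missing:
        raise PointPatternError(f"{path}: missing column(s) {sorted(missing)}")
    entries = list(zip(df["path"], df["disease_class"]))
    return CohortManifest(entries=entries, class_set=tuple(class_set))


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(manifest.entries, columns=["path", "disease_class"])
    df.to_csv(path, index=False)
    return path


def load_cohort(
    manifest: CohortManifest,
    root: str | Path = ".",
    label_dictionary: Sequence[str] = DEFAULT_CELL_TYPES,
) -> list[PointPattern]:
    """Load every sample referenced by a manifest, attaching its class."""
    root = Path(root)
    cohort = []
    for rel, cls in manifest.entries:
        p = Path(rel)
        if not p.is_absolute():
            p = root / p
        pat = read_point_pattern(p, label_dictionary=label_dictionary)
        pat.disease_class = cls
        cohort.append(pat)
    return cohort
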