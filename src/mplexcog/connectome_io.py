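"""Readers, writers and weight transforms for connectivity data.

File dialects are deliberately minimal and text-only:

* matrix: N x N tab-separated floats, optional first row of region labels,
  ``#`` comment lines ignored;
* parcellation: TSV with columns ``label`` and ``network``;
* cohort manifest: TSV with one row per subject.

Two modality-specific weight transforms are provided:

* functional: Pearson correlations are Fisher z-transformed (``atanh``)
  and absolutized, in that order;
* structural: positive streamline-weight sums ``w`` become
  ``log10(1 + w)``.  The ``1 +`` keeps transformed weights nonnegative
  (bare ``log10`` maps weights below 1 to negative values); because the
  map is strictly increasing it leaves every maximum spanning tree
  unchanged, so downstream topology is unaffected by the choice.
  Zero entries are preserved as zeros and treated as absent links.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError

#: The seven canonical resting-state networks plus subcortex.
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "limbic",
    "dorsal_attention",
    "ventral_attention",
    "default_mode",
    "frontoparietal",
    "subcortical",
)

#: Maximum tolerated absolute asymmetry when reading a matrix from disk.
SYMMETRY_TOL = 1e-8

#: Correlations are clipped to +/- (1 - R_CLIP) before atanh.
R_CLIP = 1e-7

MANIFEST_COLUMNS = ("subject_id", "site", "age", "gender", "sdmt_z")
MANIFEST_OPTIONAL = ("edss", "mean_fd")


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Parcellation:
    """An ordered region list with one resting-state-network label each."""

    name: str
    labels: tuple[str, ...]
    networks: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.networks):
            raise FormatError("labels and networks differ in length")
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if list(self.labels).count(l) > 1}
            raise FormatError(f"duplicate region labels: {sorted(dupes)[:5]}")
        bad = sorted(set(self.networks) - set(NETWORK_NAMES))
        if bad:
            raise FormatError(
                f"unknown network name(s) {bad}; allowed: {list(NETWORK_NAMES)}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def members(self, network: str) -> np.ndarray:
        """Indices of the regions assigned to ``network``."""
        if network not in NETWORK_NAMES:
            raise FormatError(
                f"unknown network name {network!r}; allowed: {list(NETWORK_NAMES)}"
            )
        return np.flatnonzero(np.asarray(self.networks) == network)


def read_parcellation(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("label", "network"):
        if col not in df.columns:
            raise FormatError(f"parcellation file missing column {col!r}")
    return Parcellation(
        name=Path(path).stem,
        labels=tuple(df["label"]),
        networks=tuple(df["network"]),
    )


def write_parcellation(path, parcellation: Parcellation) -> None:
    pd.DataFrame(
        {"label": parcellation.labels, "network": parcellation.networks}
    ).to_csv(path, sep="\t", index=False)


def packaged_parcellation(name: str) -> Parcellation:
    """Load one of the parcellation tables shipped with the package.

    ``schaefer114`` is the primary 100-cortical + 14-subcortical table;
    ``bna224`` is the alternative 210-cortical + 14-subcortical table.
    """
    from importlib.resources import files

    resource = files("mplexcog.data").joinpath(f"parcellation_{name}.tsv")
    if not resource.is_file():
        raise FormatError(f"no packaged parcellation named {name!r}")
    with resource.open("r") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    return Parcellation(
        name=name, labels=tuple(df["label"]), networks=tuple(df["network"])
    )


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConnectivityMatrix:
    """One subject x one modality square symmetric weight matrix."""

    subject_id: str
    modality: str  # "structural" | "functional"
    weights: np.ndarray
    transform_state: str = "raw"  # "raw" | "transformed"

    def __post_init__(self):
        if self.modality not in ("structural", "functional"):
            raise FormatError(f"unknown modality {self.modality!r}")
        if self.transform_state not in ("raw", "transformed"):
            raise FormatError(f"unknown transform_state {self.transform_state!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"matrix must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise FormatError(f"non-finite entry at ({i}, {j})")
        asym = np.abs(w - w.T)
        if asym.max(initial=0.0) > 1e-10:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise FormatError(f"matrix asymmetric at ({i}, {j})")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise FormatError("diagonal must be zero")
        if self.modality == "structural" and w.min(initial=0.0) < 0:
            i, j = np.argwhere(w < 0)[0]
            raise FormatError(f"negative structural weight at ({i}, {j})")
        if (
            self.modality == "functional"
            and self.transform_state == "transformed"
            and w.min(initial=0.0) < 0
        ):
            raise FormatError("transformed functional weights must be nonnegative")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _load_matrix_rows(path):
    """Parse a matrix TSV into (labels-or-None, float array)."""
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    labels = None
    try:
        float(rows[0][0])
    except ValueError:
        labels = tuple(rows[0])
        rows = rows[1:]
    try:
        data = np.array([[float(x) for x in row] for row in rows], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from None
    return labels, data


def read_matrix(
    path,
    subject_id: str,
    modality: str,
    parcellation: Parcellation | None = None,
) -> ConnectivityMatrix:
    """Read and validate a matrix TSV.

    Asymmetries up to :data:`SYMMETRY_TOL` are repaired by averaging the
    matrix with its transpose; anything larger is a format error naming
    the offending entry.  The diagonal is forced to zero.
    """
    labels, w = _load_matrix_rows(path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError(f"{path}: non-square matrix with shape {w.shape}")
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise FormatError(f"{path}: non-finite entry at ({i}, {j})")
    asym = np.abs(w - w.T)
    if asym.max(initial=0.0) > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise FormatError(
            f"{path}: asymmetry {asym[i, j]:.3g} at ({min(i, j)}, {max(i, j)}) "
            f"exceeds {SYMMETRY_TOL}"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if parcellation is not None:
        if w.shape[0] != parcellation.n_regions:
            raise FormatError(
                f"{path}: {w.shape[0]} regions but parcellation has "
                f"{parcellation.n_regions}"
            )
        if labels is not None and tuple(labels) != parcellation.labels:
            raise FormatError(f"{path}: header labels disagree with parcellation")
    return ConnectivityMatrix(subject_id, modality, w, "raw")


def write_matrix(
    path, matrix: ConnectivityMatrix, labels: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        if labels is not None:
            fh.write("\t".join(labels) + "\n")
        for row in matrix.weights:
            fh.write("\t".join(format(x, ".17g") for x in row) + "\n")


# ---------------------------------------------------------------------------
# Weight transforms
# ---------------------------------------------------------------------------

def timeseries_to_correlation(panel: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of a region x time panel."""
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2:
        raise FormatError(f"panel must be 2-D, got shape {panel.shape}")
    sd = panel.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise FormatError(f"zero-variance time series for region(s) {dead.tolist()}")
    r = np.corrcoef(panel)
    np.fill_diagonal(r, 1.0)
    return r


def preprocess_functional(
    data, subject_id: str = "", *, is_panel: bool | None = None
) -> ConnectivityMatrix:
    """Fisher z-transform and absolutize functional connectivity.

    ``data`` may be a raw-correlation :class:`ConnectivityMatrix`, a square
    symmetric correlation array, or a region x time panel (anything
    non-square, or forced with ``is_panel=True``).  Correlations are
    clipped to ``+/-(1 - 1e-7)`` before ``atanh``.
    """
    if isinstance(data, ConnectivityMatrix):
        subject_id = subject_id or data.subject_id
        r = data.weights
    else:
        arr = np.asarray(data, dtype=float)
        if is_panel is None:
            is_panel = not (
                arr.ndim == 2
                and arr.shape[0] == arr.shape[1]
                and np.allclose(arr, arr.T, atol=SYMMETRY_TOL)
            )
        r = timeseries_to_correlation(arr) if is_panel else arr.copy()
    r = np.clip(np.asarray(r, dtype=float), -1 + R_CLIP, 1 - R_CLIP)
    w = np.abs(np.arctanh(r))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(subject_id, "functional", w, "transformed")


def preprocess_structural(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Apply ``w -> log10(1 + w)`` to positive structural weights."""
    if matrix.modality != "structural":
        raise FormatError("preprocess_structural expects a structural matrix")
    w = matrix.weights
    if w.min(initial=0.0) < 0:
        i, j = np.argwhere(w < 0)[0]
        raise FormatError(f"negative structural weight at ({i}, {j})")
    out = np.where(w > 0, np.log10(1.0 + w), 0.0)
    return ConnectivityMatrix(matrix.subject_id, "structural", out, "transformed")


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing column(s) {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"duplicate subject_id(s): {dupes[:5]}")
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"subject_id": str, "site": str})
    return validate_manifest(df)


def write_manifest(path, df: pd.DataFrame) -> None:
    validate_manifest(df).to_csv(path, sep="\t", index=False)


def filter_subjects(df: pd.DataFrame, predicate: Callable) -> pd.DataFrame:
    """Keep rows for which ``predicate(row)`` is true, preserving order.

    The predicate receives each manifest row as a namedtuple with the
    column names as attributes (e.g. ``row.mean_fd <= 0.2``).
    """
    keep = [bool(predicate(row)) for row in df.itertuples(index=False)]
    return df.loc[keep].reset_index(drop=True)
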