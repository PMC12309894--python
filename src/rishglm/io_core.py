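"""Reading, writing and validation of per-subject diffusion MRI data.

The tool consumes 4D NIfTI diffusion volumes with FSL-dialect ``bval`` /
``bvec`` text files and a covariate CSV, and produces the same formats.
All per-voxel processing downstream is affine-agnostic: volumes are assumed
co-registered on a common grid, and the affine is only carried through for
writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GradientTable",
    "DwiVolume",
    "ShellData",
    "CovariateTable",
    "read_dwi",
    "write_dwi",
    "select_shell",
    "read_covariates",
]

#: b-values at or below this (s/mm^2) count as b=0; robust to vendor rounding.
DEFAULT_B0_THRESHOLD = 50.0
#: Half-width (s/mm^2) of a shell when selecting volumes by nominal b-value.
DEFAULT_SHELL_TOL = 100.0


class FormatError(ValueError):
    """An input file violates the expected on-disk contract."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion weightings and unit gradient directions of an acquisition.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weightings in s/mm^2, non-negative.
    bvecs : (N, 3) array
        Gradient directions in the image frame. Unit norm wherever
        ``bval > b0_threshold``; zero vectors are permitted for b=0 volumes.
    b0_threshold : float
        b-values at or below this count as b=0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise FormatError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} bvals"
            )
        if np.any(bvals < 0):
            raise FormatError("negative b-values are not allowed")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > self.b0_threshold
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-4):
            raise FormatError(
                "non-unit gradient direction at b > "
                f"{self.b0_threshold}: max |norm-1| = "
                f"{np.abs(norms[dwi] - 1.0).max():.2e}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    def shell_mask(self, target_b: float, tol: float = DEFAULT_SHELL_TOL) -> np.ndarray:
        return (np.abs(self.bvals - target_b) <= tol) & ~self.b0_mask

    @property
    def unique_shells(self) -> np.ndarray:
        """Rounded b-values of the non-b0 volumes (for diagnostics)."""
        return np.unique(np.round(self.bvals[~self.b0_mask]))


@dataclass
class DwiVolume:
    """A 4D diffusion-weighted volume plus its gradient table and affine."""

    data: np.ndarray
    affine: np.ndarray
    gradients: GradientTable

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"DWI data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] != len(self.gradients):
            raise FormatError(
                f"{self.data.shape[3]} volumes but {len(self.gradients)} "
                "b-values/b-vectors"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ShellData:
    """All volumes of one b-shell plus the averaged b=0 image."""

    dwi_signals: np.ndarray  # X x Y x Z x M
    directions: np.ndarray  # M x 3, unit norm
    bvalue: float
    b0_mean: np.ndarray  # X x Y x Z

    @property
    def grid_shape(self):
        return self.dwi_signals.shape[:3]


@dataclass
class CovariateTable:
    """Per-subject site labels and covariates, validated.

    ``frame`` is indexed by subject id; ``covariate_columns`` lists the
    numeric columns entering design matrices (categoricals already expanded
    to indicator columns).
    """

    frame: pd.DataFrame
    site_column: str = "site"
    covariate_columns: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.covariate_columns = tuple(self.covariate_columns)
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise FormatError(f"duplicate subject ids: {dupes}")
        missing = [c for c in (self.site_column, *self.covariate_columns)
                   if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        bad = self.frame[list(self.covariate_columns)].isna()
        if bad.to_numpy().any():
            rows = self.frame.index[bad.any(axis=1)].tolist()
            raise FormatError(f"missing covariate values in rows: {rows}")
        counts = self.frame[self.site_column].value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise FormatError(
                f"sites with fewer than 2 subjects: {small.index.tolist()}"
            )

    @property
    def sites(self) -> list:
        return sorted(self.frame[self.site_column].unique())

    @property
    def subjects(self) -> list:
        return self.frame.index.tolist()

    def site_of(self, subject_id) -> str:
        return self.frame.loc[subject_id, self.site_column]

    def __len__(self) -> int:
        return len(self.frame)


def _read_bvals_bvecs(bval_path, bvec_path):
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2:
        raise FormatError(f"{bvec_path}: expected a 2D table of vectors")
    # FSL writes 3 rows x N columns; N rows x 3 columns also accepted.
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise FormatError(f"{bvec_path}: shape {bvecs.shape} is not 3xN or Nx3")
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"{bvec_path}: {bvecs.shape[0]} vectors but {bvals.size} b-values"
        )
    return bvals, bvecs


def read_dwi(image_path, bval_path, bvec_path,
             b0_threshold: float = DEFAULT_B0_THRESHOLD) -> DwiVolume:
    """Load a 4D NIfTI volume with its FSL-dialect bval/bvec files.

    Directions with ``bval > b0_threshold`` are renormalized to unit length;
    zero vectors are only accepted for b=0 volumes.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    bvals, bvecs = _read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[3] != bvals.size:
        raise FormatError(
            f"{image_path}: {data.shape[3]} volumes but {bvals.size} b-values"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dwi = bvals > b0_threshold
    if np.any(norms[dwi] == 0):
        raise FormatError(
            f"{bvec_path}: zero gradient vector at b > {b0_threshold}"
        )
    bvecs = bvecs.copy()
    bvecs[dwi] /= norms[dwi, None]
    grad = GradientTable(bvals, bvecs, b0_threshold=b0_threshold)
    return DwiVolume(data, img.affine, grad)


def write_dwi(dwi: DwiVolume, image_path, bval_path, bvec_path) -> None:
    """Write a DwiVolume as float32 NIfTI plus 3-row bval/bvec text files."""
    try:
        img = nib.Nifti1Image(np.asarray(dwi.data, dtype=np.float32), dwi.affine)
        nib.save(img, str(image_path))
        np.savetxt(bval_path, dwi.gradients.bvals[None, :], fmt="%.6g")
        np.savetxt(bvec_path, dwi.gradients.bvecs.T, fmt="%.8f")
    except OSError as exc:
        raise OSError(
            f"failed writing DWI to {image_path} / {bval_path} / {bvec_path}: {exc}"
        ) from exc


def select_shell(dwi: DwiVolume, target_b: float,
                 tol: float = DEFAULT_SHELL_TOL) -> ShellData:
    """Extract one b-shell and the averaged b=0 image from a 4D volume."""
    grad = dwi.gradients
    in_shell = grad.shell_mask(target_b, tol)
    if not in_shell.any():
        raise FormatError(
            f"no volumes within {tol} of b={target_b}; available shells: "
            f"{grad.unique_shells.tolist()}"
        )
    b0 = grad.b0_mask
    if not b0.any():
        raise FormatError("no b=0 volume found (required for the b0 reference)")
    return ShellData(
        dwi_signals=dwi.data[..., in_shell],
        directions=grad.bvecs[in_shell],
        bvalue=float(np.mean(grad.bvals[in_shell])),
        b0_mean=dwi.data[..., b0].mean(axis=3),
    )


def read_covariates(csv_path, covariate_columns, site_column: str = "site",
                    id_column: str = "subject_id") -> CovariateTable:
    """Read and validate a covariate CSV.

    Categorical covariates with k levels become k-1 indicator columns named
    ``<col>_<level>`` (reference level = lexicographically first). Extra
    columns (e.g. per-subject file paths used by the CLI) are carried along
    untouched.
    """
    df = pd.read_csv(csv_path)
    needed = [id_column, site_column, *covariate_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing columns {missing}")
    bad = df[list(covariate_columns)].isna()
    if bad.to_numpy().any():
        rows = (df.loc[bad.any(axis=1), id_column].tolist()
                if id_column in df else bad.index[bad.any(axis=1)].tolist())
        raise FormatError(f"{csv_path}: missing covariate values for {rows}")
    df = df.set_index(id_column)

    expanded = []
    for col in covariate_columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            expanded.append(col)
            continue
        levels = sorted(df[col].astype(str).unique())
        for level in levels[1:]:
            name = f"{col}_{level}"
            df[name] = (df[col].astype(str) == level).astype(float)
            expanded.append(name)
    return CovariateTable(df, site_column=site_column,
                          covariate_columns=tuple(expanded))
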