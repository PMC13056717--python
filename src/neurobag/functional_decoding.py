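"""Meta-analytic behavioural decoding of a binary ROI mask.

Each focus in a labelled coordinate database is assigned to the ROI if its
nearest voxel (world -> voxel through the inverse affine, rounded) lies in
the mask.  For every behavioural sub-domain with database base rate
p0 = K/N, the in-ROI count k out of n total ROI foci is compared to the
binomial null with

    Z = (k - n * p0) / sqrt(n * p0 * (1 - p0)),

the normal approximation to the binomial; the exact two-sided binomial p is
co-reported so the approximation is auditable.  The decision rule Z > 3.0
corresponds to a Bonferroni-corrected P < 0.05 across the 59 sub-domains and
is applied as given, independently of the co-reported p-values.

The mask and the database must share a stereotaxic space, asserted through a
space tag carried by both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = ["FociDatabase", "DecodingResult", "load_foci_db", "decode_roi",
           "VALID_DOMAINS"]

VALID_DOMAINS = frozenset(
    {"action", "cognition", "emotion", "interoception", "perception"})

_REQUIRED = ("x_mm", "y_mm", "z_mm", "domain", "subdomain")


@dataclass
class FociDatabase:
    foci: pd.DataFrame
    space: str

    def __post_init__(self):
        if len(self.foci) == 0:
            raise ValueError("foci database is empty")
        for col in _REQUIRED:
            if col not in self.foci.columns:
                raise ValueError(f"missing required column {col!r}")
        bad = ~self.foci["domain"].isin(VALID_DOMAINS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown domain {self.foci['domain'].iloc[row]!r} at row {row}")
        xyz = self.foci[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite focus coordinates")
        if self.foci["subdomain"].nunique() > 59:
            raise ValueError("more than 59 sub-domains")

    def __len__(self) -> int:
        return len(self.foci)

    @property
    def coordinates(self) -> np.ndarray:
        return self.foci[["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    def save(self, path) -> None:
        df = self.foci.copy()
        df["space"] = self.space
        df.to_csv(path, sep="\t", index=False)


@dataclass
class DecodingResult:
    table: pd.DataFrame     # one row per sub-domain
    n_roi_total: int
    n_database: int
    z_threshold: float
    no_foci: bool = False

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def load_foci_db(path) -> FociDatabase:
    """Load and validate a TSV foci database."""
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError(f"empty foci database: {path}")
    if "space" in df.columns:
        spaces = df["space"].unique()
        if len(spaces) > 1:
            raise ValueError(f"mixed coordinate spaces in database: {spaces}")
        space = str(spaces[0])
    else:
        space = "unspecified"
    return FociDatabase(df.drop(columns=["space"], errors="ignore"), space)


def _foci_in_mask(mask: np.ndarray, affine: np.ndarray,
                  coords_mm: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    hom = np.column_stack([coords_mm, np.ones(len(coords_mm))])
    vox = np.rint((hom @ inv.T)[:, :3]).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(mask.shape)), axis=1)
    hit = np.zeros(len(coords_mm), bool)
    idx = vox[inside]
    hit[inside] = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    return hit


def decode_roi(mask, db: FociDatabase, affine=None, space: str | None = None,
               z_threshold: float = 3.0, dilation_mm: float = 0.0) -> DecodingResult:
    """Decode a binary ROI mask against the foci database.

    ``mask`` may be a nibabel image (space read from the header description
    unless given) or a boolean array with an explicit ``affine``.
    """
    if hasattr(mask, "get_fdata"):
        arr = np.asanyarray(mask.dataobj).astype(bool)
        affine = mask.affine
        if space is None:
            raw = np.asarray(mask.header.get("descrip", b"")).item() or b""
            descrip = raw.decode() if isinstance(raw, bytes) else str(raw)
            space = descrip.replace("space=", "").strip() or "unspecified"
    else:
        arr = np.asarray(mask, bool)
        affine = np.eye(4) if affine is None else np.asarray(affine)
    if not arr.any():
        raise ValueError("ROI mask is empty")
    if (space not in (None, "unspecified")
            and db.space not in ("unspecified", space)):
        raise ValueError(f"space mismatch: mask {space!r} vs database {db.space!r}")

    if dilation_mm > 0:
        voxel_size = float(np.abs(np.linalg.det(affine[:3, :3])) ** (1 / 3))
        it = max(1, int(np.ceil(dilation_mm / voxel_size)))
        arr = ndimage.binary_dilation(arr, iterations=it)

    hit = _foci_in_mask(arr, affine, db.coordinates)
    n_total = int(hit.sum())
    n_db = len(db)

    sub = db.foci["subdomain"]
    rows = []
    for sd in sorted(sub.unique()):
        in_sd = (sub == sd).to_numpy()
        bigk = int(in_sd.sum())
        p0 = bigk / n_db
        k = int((in_sd & hit).sum())
        dom = db.foci.loc[in_sd, "domain"].iloc[0]
        if p0 == 0.0 or p0 == 1.0:
            rows.append({"subdomain": sd, "domain": dom, "n_in_roi": k,
                         "n_roi_total": n_total, "base_rate": p0,
                         "z": np.nan, "p_exact": np.nan,
                         "significant": False, "note": "degenerate base rate"})
            continue
        if n_total == 0:
            z = np.nan
            p_exact = np.nan
        else:
            z = (k - n_total * p0) / math.sqrt(n_total * p0 * (1.0 - p0))
            p_exact = stats.binomtest(k, n_total, p0).pvalue
        rows.append({"subdomain": sd, "domain": dom, "n_in_roi": k,
                     "n_roi_total": n_total, "base_rate": p0,
                     "z": z, "p_exact": p_exact,
                     "significant": bool(np.isfinite(z) and z > z_threshold),
                     "note": ""})
    table = pd.DataFrame(rows).set_index("subdomain")
    return DecodingResult(table, n_total, n_db, z_threshold,
                          no_foci=(n_total == 0))
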