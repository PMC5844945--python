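"""Radiomic and dosiomic feature extraction for parotid glands.

Implements the full candidate feature set used for xerostomia NTCP
modeling: demographic covariates, parotid shape descriptors, dose-volume
histogram (DVH) statistics, subvolume mean doses, spatial dose gradients,
and scale-normalized central moments of the 3D dose distribution (spread,
correlation, skewness, coskewness), plus the Kendall-tau redundancy filter
that prunes highly correlated feature pairs.

Conventions
-----------
* Coordinates are physical mm in LPS axis order; features computed from
  coordinates are therefore invariant under translation of the volume.
* A "base" feature name (e.g. ``volume``) expands to per-gland columns
  ``volume_ipsi`` and ``volume_contra`` in a :class:`FeatureTable`;
  demographic features are patient-level and keep their bare name.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import DoseGrid, GridError, LateralizationResult, OrganMask

__all__ = [
    "MOMENT_ORDERS",
    "FEATURE_GROUPS",
    "DEFAULT_PRIORITY",
    "ShapeFeatures",
    "DVHFeatures",
    "MomentSet",
    "FeatureTable",
    "shape_features",
    "dvh_features",
    "subvolume_mean_doses",
    "dose_gradients",
    "dose_moments",
    "morphological_features",
    "kendall_tau",
    "concordance_probability",
    "redundancy_filter",
    "extract_patient_features",
]

#: Moment orders (p, q, r) reported by :func:`dose_moments`.
MOMENT_ORDERS: tuple[tuple[int, int, int], ...] = (
    (2, 0, 0), (0, 2, 0), (0, 0, 2),          # spread
    (1, 1, 0), (1, 0, 1), (0, 1, 1),          # correlation
    (3, 0, 0), (0, 3, 0), (0, 0, 3),          # skewness
    (0, 1, 2), (0, 2, 1), (1, 2, 0),          # coskewness
    (1, 0, 2), (2, 1, 0), (2, 0, 1),
    (1, 1, 1),
)

_DX_LEVELS = (2, 98, 10, 20, 30, 40, 50, 60, 70, 80, 90)
_VX_LEVELS = (10, 15, 20, 25, 30, 35, 40, 45)


def _eta_name(pqr: tuple[int, int, int]) -> str:
    return "eta%d%d%d" % pqr


def _moment_group(pqr: tuple[int, int, int]) -> str:
    p, q, r = pqr
    if (p + q + r) == 2:
        return "spatial dose spread" if max(pqr) == 2 else "spatial dose correlation"
    return "spatial dose skewness" if max(pqr) == 3 else "spatial dose coskewness"


#: Base feature name -> feature group.
FEATURE_GROUPS: dict[str, str] = {
    "age": "demographics",
    "sex": "demographics",
    "volume": "parotid shape",
    "area": "parotid shape",
    "sphericity": "parotid shape",
    "eccentricity": "parotid shape",
    "compactness": "parotid shape",
    "lambda1": "parotid shape",
    "lambda2": "parotid shape",
    "lambda3": "parotid shape",
    "mean": "DVH",
    "mean_both": "DVH",  # volume-weighted mean over both glands (patient-level)
    "spread": "DVH",
    "skewness": "DVH",
    **{f"d{x}": "DVH" for x in _DX_LEVELS},
    **{f"v{x}": "DVH" for x in _VX_LEVELS},
    "entropy": "DVH",
    "uniformity": "DVH",
    **{f"s{ax}{k}": "subvolume mean dose" for ax in "xyz" for k in (1, 2, 3)},
    "gradient_x": "spatial dose gradient",
    "gradient_y": "spatial dose gradient",
    "gradient_z": "spatial dose gradient",
    **{_eta_name(o): _moment_group(o) for o in MOMENT_ORDERS},
}

#: All nine feature groups in canonical order.
ALL_GROUPS: tuple[str, ...] = (
    "demographics",
    "parotid shape",
    "DVH",
    "subvolume mean dose",
    "spatial dose gradient",
    "spatial dose spread",
    "spatial dose correlation",
    "spatial dose skewness",
    "spatial dose coskewness",
)

#: Simplicity ranking used by the redundancy filter: when two features are
#: highly correlated in both glands, the one appearing EARLIER here is kept.
#: Encodes "mean dose over Dx" and "volume over compactness".
DEFAULT_PRIORITY: tuple[str, ...] = (
    "age",
    "sex",
    "mean",
    "mean_both",
    "volume",
    "spread",
    "skewness",
    "gradient_x",
    "gradient_y",
    "gradient_z",
    *[_eta_name(o) for o in MOMENT_ORDERS],
    "sphericity",
    "eccentricity",
    "area",
    "compactness",
    "lambda1",
    "lambda2",
    "lambda3",
    *[f"d{x}" for x in _DX_LEVELS],
    *[f"v{x}" for x in _VX_LEVELS],
    "entropy",
    "uniformity",
    *[f"s{ax}{k}" for ax in "xyz" for k in (1, 2, 3)],
)


@dataclass
class ShapeFeatures:
    """Geometric descriptors of a parotid mask.

    ``lambda1 >= lambda2 >= lambda3`` are eigenvalues (mm^2) of the
    covariance of the mask voxel-center coordinates.
    """

    volume: float          # mm^3
    area: float            # mm^2
    sphericity: float      # pi^(1/3) (6V)^(2/3) / A, 1 for a ball
    eccentricity: float    # sqrt(1 - lambda3/lambda1)
    compactness: float     # V / (sqrt(pi) A^(3/2))
    lambda1: float
    lambda2: float
    lambda3: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


@dataclass
class DVHFeatures:
    """Dose-volume histogram statistics of the dose within a gland."""

    mean: float        # Gy
    spread: float      # SD of the dose, Gy
    skewness: float    # third standardized moment
    dx: dict[int, float]   # D2, D98, D10..D90 (Gy)
    vx: dict[int, float]   # V10..V45 (volume fraction, 0-1)
    entropy: float     # bits, over 1-Gy histogram bins
    uniformity: float  # sum p^2 over the same bins

    def as_dict(self) -> dict[str, float]:
        out = {"mean": self.mean, "spread": self.spread, "skewness": self.skewness}
        out.update({f"d{x}": v for x, v in self.dx.items()})
        out.update({f"v{x}": v for x, v in self.vx.items()})
        out.update({"entropy": self.entropy, "uniformity": self.uniformity})
        return out


class MomentSet(dict):
    """Scale-normalized central dose moments eta_pqr keyed by (p, q, r)."""

    def eta(self, p: int, q: int, r: int) -> float:
        return self[(p, q, r)]

    def as_dict(self) -> dict[str, float]:
        return {_eta_name(o): self[o] for o in MOMENT_ORDERS}


# ---------------------------------------------------------------------------
# per-gland extractors


def shape_features(mask: OrganMask) -> ShapeFeatures:
    """Compute shape descriptors of a binary organ mask.

    Volume is voxel count x voxel volume; area comes from a marching-cubes
    surface mesh of the mask; the principal-axis variances are eigenvalues
    of the voxel-coordinate covariance matrix in mm^2.
    """
    from scipy.ndimage import gaussian_filter
    from skimage import measure

    mask.require_nonempty()
    if mask.voxel_count < 2:
        raise GridError("shape features undefined for a single-voxel mask")
    volume = mask.volume
    # mild smoothing removes the voxel staircase that would otherwise
    # overestimate the surface area of the 0.5 level set
    padded = gaussian_filter(np.pad(mask.values.astype(float), 2), sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    compactness = float(volume / (np.sqrt(np.pi) * area ** 1.5))
    coords = mask.voxel_centers()
    cov = np.cov(coords, rowvar=False, ddof=0)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 0:
        raise GridError("degenerate mask: zero principal variance")
    eccentricity = float(np.sqrt(1.0 - lam[2] / lam[0]))
    return ShapeFeatures(
        volume=float(volume),
        area=area,
        sphericity=sphericity,
        eccentricity=eccentricity,
        compactness=compactness,
        lambda1=float(lam[0]),
        lambda2=float(lam[1]),
        lambda3=float(lam[2]),
    )


def dvh_features(dose: DoseGrid, mask: OrganMask, bin_width: float = 1.0) -> DVHFeatures:
    """DVH statistics of the dose within a mask.

    Dx is the smallest dose received by at least x% of the gland volume
    (linear interpolation between order statistics); Vx the volume fraction
    receiving at least x Gy.  Entropy (bits) and uniformity are computed on
    a fixed-width histogram (``bin_width`` Gy, from 0 to the maximum dose).
    """
    mask.require_nonempty()
    d = np.sort(dose.values[mask.values].astype(float))
    if d.size < 2:
        raise GridError("DVH features require at least 2 voxels in the mask")
    mean = float(d.mean())
    spread = float(d.std(ddof=0))
    skewness = float(stats.skew(d, bias=True)) if spread > 0 else 0.0
    # Dx: dose to the hottest x% of the volume = (100 - x)th percentile
    dx = {x: float(np.percentile(d, 100 - x)) for x in _DX_LEVELS}
    vx = {x: float(np.mean(d >= x)) for x in _VX_LEVELS}
    edges = np.arange(0.0, d[-1] + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    p = np.histogram(d, bins=edges)[0] / d.size
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    return DVHFeatures(mean, spread, skewness, dx, vx, entropy, uniformity)


def _bounding_slices(mask: OrganMask) -> list[slice]:
    idx = np.argwhere(mask.values)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    return [slice(a, b + 1) for a, b in zip(lo, hi)]


def subvolume_mean_doses(dose: DoseGrid, mask: OrganMask) -> dict[str, float]:
    """Mean dose in the three equal-width slabs of the mask bounding box.

    For each axis the bounding box is cut into thirds along that axis (the
    remainder voxels of a non-divisible extent join the last slab) and the
    mean dose over mask voxels in each slab is reported, ordered along the
    positive axis direction: sx1..sx3, sy1..sy3, sz1..sz3 (Gy).
    """
    mask.require_nonempty()
    sl = _bounding_slices(mask)
    out: dict[str, float] = {}
    for axis, ax_name in enumerate("xyz"):
        n = sl[axis].stop - sl[axis].start
        if n < 3:
            raise GridError(
                f"mask bounding box spans only {n} voxels along axis {ax_name!r}; "
                "need >= 3 for subvolume doses"
            )
        w = n // 3
        bounds = [sl[axis].start, sl[axis].start + w, sl[axis].start + 2 * w, sl[axis].stop]
        for k in range(3):
            slab = list(sl)
            slab[axis] = slice(bounds[k], bounds[k + 1])
            sub_mask = mask.values[tuple(slab)]
            sub_dose = dose.values[tuple(slab)]
            if not sub_mask.any():
                out[f"s{ax_name}{k + 1}"] = np.nan
            else:
                out[f"s{ax_name}{k + 1}"] = float(sub_dose[sub_mask].mean())
    return out


def dose_gradients(dose: DoseGrid, mask: OrganMask) -> tuple[float, float, float]:
    """Least-squares affine dose gradient over the mask (Gy/mm).

    Fits D ~ a + gx*x + gy*y + gz*z over the mask voxel centers and returns
    (gx, gy, gz).  A planar mask (rank-deficient coordinates) is an error.
    """
    mask.require_nonempty()
    coords = mask.voxel_centers()
    for axis in range(3):
        if np.ptp(coords[:, axis]) == 0:
            raise GridError(
                f"mask is degenerate along axis {'xyz'[axis]!r}; gradient undefined"
            )
    X = np.column_stack([np.ones(len(coords)), coords - coords.mean(axis=0)])
    if np.linalg.matrix_rank(X) < 4:
        raise GridError("rank-deficient coordinate matrix; gradient undefined")
    y = dose.values[mask.values].astype(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1]), float(beta[2]), float(beta[3])


def dose_moments(dose: DoseGrid, mask: OrganMask) -> MomentSet:
    """Scale-normalized central moments of the dose distribution in a mask.

    With the dose-weighted centroid (x̄, ȳ, z̄) over mask voxels,

        mu_pqr = sum_v D(v) (x-x̄)^p (y-ȳ)^q (z-z̄)^r        [Gy mm^(p+q+r)]
        eta_pqr = mu_pqr / mu_000^(1 + (p+q+r)/3)

    which makes eta invariant under translation and under uniform scaling of
    both dose and geometry.  Coordinates are in mm.
    """
    mask.require_nonempty()
    w = dose.values[mask.values].astype(float)
    mu000 = w.sum()
    if mu000 <= 0:
        raise GridError("total dose in mask is zero; moments undefined")
    coords = mask.voxel_centers()
    centroid = (coords * w[:, None]).sum(axis=0) / mu000
    dxyz = coords - centroid
    out = MomentSet()
    for p, q, r in MOMENT_ORDERS:
        mu = float((w * dxyz[:, 0] ** p * dxyz[:, 1] ** q * dxyz[:, 2] ** r).sum())
        out[(p, q, r)] = mu / mu000 ** (1.0 + (p + q + r) / 3.0)
    return out


def morphological_features(
    dose: DoseGrid, ipsi: OrganMask, contra: OrganMask
) -> dict[str, float]:
    """Covariates of the morphological dose-moment reference model.

    Returns eta111 of the ipsilateral gland, eta002 and eta300 of the
    contralateral gland, and the product eta110(ipsi) * eta110(contra).
    """
    mi = dose_moments(dose, ipsi)
    mc = dose_moments(dose, contra)
    return {
        "eta111_ipsi": mi.eta(1, 1, 1),
        "eta002_contra": mc.eta(0, 0, 2),
        "eta300_contra": mc.eta(3, 0, 0),
        "eta110_product": mi.eta(1, 1, 0) * mc.eta(1, 1, 0),
    }


# ---------------------------------------------------------------------------
# redundancy analysis


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("kendall_tau needs two equal-length 1D arrays of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Kendall tau is undefined for a constant input")
    return float(stats.kendalltau(x, y).statistic)


def concordance_probability(tau: float) -> float:
    """Probability that two features rank a random observation pair the same way.

    Kendall's tau is the difference between the concordance and discordance
    probabilities, so P(concordant) = (1 + tau) / 2.
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [-1, 1], got {tau}")
    return (1.0 + tau) / 2.0


class FeatureTable:
    """Wide per-patient feature matrix with group/side annotations.

    ``data`` is a DataFrame indexed by patient id whose columns are either
    patient-level base names (``age``) or per-gland names
    (``volume_ipsi``/``volume_contra``).  Annotation metadata (base name,
    Table-2 feature group, gland side) is derived from the column names.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data.copy()
        self.data.index.name = "patient_id"

    @staticmethod
    def parse_column(column: str) -> tuple[str, str]:
        """Split a column name into (base feature, side)."""
        for suffix, side in (("_ipsi", "ipsi"), ("_contra", "contra")):
            if column.endswith(suffix):
                return column[: -len(suffix)], side
        return column, "patient-level"

    @property
    def metadata(self) -> pd.DataFrame:
        rows = []
        for col in self.data.columns:
            base, side = self.parse_column(col)
            rows.append(
                {
                    "feature": col,
                    "base": base,
                    "group": FEATURE_GROUPS.get(base, "other"),
                    "side": side,
                }
            )
        return pd.DataFrame(rows)

    def columns_in_groups(self, groups: Iterable[str]) -> list[str]:
        groups = set(groups)
        meta = self.metadata
        return meta.loc[meta["group"].isin(groups), "feature"].tolist()

    def to_long(self) -> pd.DataFrame:
        """Long export: patient_id, side, group, feature, value."""
        meta = self.metadata.set_index("feature")
        long = self.data.reset_index().melt(
            id_vars="patient_id", var_name="feature", value_name="value"
        )
        long["side"] = meta.loc[long["feature"], "side"].to_numpy()
        long["group"] = meta.loc[long["feature"], "group"].to_numpy()
        return long[["patient_id", "side", "group", "feature", "value"]]

    def write_csv(self, path, long: bool = False) -> None:
        if long:
            self.to_long().to_csv(path, index=False)
        else:
            self.data.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col="patient_id"))

    def __len__(self) -> int:
        return len(self.data)


def redundancy_filter(
    table: FeatureTable,
    threshold: float = 0.5,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop one member of every feature pair highly correlated in both glands.

    For every pair of base features, Kendall's tau is evaluated separately on
    the ipsilateral and the contralateral columns; when ``|tau| > threshold``
    on BOTH sides the pair is declared redundant and the feature ranked lower
    in ``priority`` (conceptually/computationally more complex) is removed
    from the table.  Patient-level feature pairs use their single tau.

    Returns the reduced table and a drop log with one row per redundant pair
    (kept feature, dropped feature, per-side taus).
    """
    meta = table.metadata
    bases = meta["base"].unique().tolist()
    rank = {name: i for i, name in enumerate(priority)}
    sides_of = {
        b: set(meta.loc[meta["base"] == b, "side"]) for b in bases
    }
    dropped: set[str] = set()
    log_rows = []
    for fa, fb in itertools.combinations(bases, 2):
        if fa in dropped or fb in dropped:
            continue
        bilateral = {"ipsi", "contra"} <= (sides_of[fa] & sides_of[fb])
        taus = {}
        try:
            if bilateral:
                for side in ("ipsi", "contra"):
                    taus[side] = kendall_tau(
                        table.data[f"{fa}_{side}"], table.data[f"{fb}_{side}"]
                    )
                redundant = all(abs(t) > threshold for t in taus.values())
            else:
                ca = fa if "patient-level" in sides_of[fa] else f"{fa}_ipsi"
                cb = fb if "patient-level" in sides_of[fb] else f"{fb}_ipsi"
                taus["pooled"] = kendall_tau(table.data[ca], table.data[cb])
                redundant = abs(taus["pooled"]) > threshold
        except ValueError:
            continue  # constant column: no redundancy decision possible
        if not redundant:
            continue
        for f in (fa, fb):
            if f not in rank:
                raise KeyError(
                    f"feature {f!r} involved in a redundant pair is missing from "
                    "the priority ranking"
                )
        loser = fa if rank[fa] > rank[fb] else fb
        winner = fb if loser is fa else fa
        dropped.add(loser)
        log_rows.append(
            {
                "kept": winner,
                "dropped": loser,
                **{f"tau_{k}": v for k, v in taus.items()},
            }
        )
    drop_cols = [
        c for c in table.data.columns if FeatureTable.parse_column(c)[0] in dropped
    ]
    reduced = FeatureTable(table.data.drop(columns=drop_cols))
    return reduced, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# whole-patient extraction


def extract_patient_features(
    lat: LateralizationResult, age: float, sex: str | int
) -> dict[str, float]:
    """Extract the full candidate feature vector for one lateralized patient.

    ``sex`` may be 'female'/'male' or already-encoded 1/0 (female = 1).
    Returns a flat name -> value mapping with per-gland features suffixed
    ``_ipsi`` / ``_contra``.
    """
    if isinstance(sex, str):
        sex_code = {"female": 1.0, "f": 1.0, "male": 0.0, "m": 0.0}[sex.lower()]
    else:
        sex_code = float(sex)
    out: dict[str, float] = {"age": float(age), "sex": sex_code}
    for side, mask in (("ipsi", lat.ipsi_mask), ("contra", lat.contra_mask)):
        vals: dict[str, float] = {}
        vals.update(shape_features(mask).as_dict())
        vals.update(dvh_features(lat.dose, mask).as_dict())
        vals.update(subvolume_mean_doses(lat.dose, mask))
        gx, gy, gz = dose_gradients(lat.dose, mask)
        vals.update({"gradient_x": gx, "gradient_y": gy, "gradient_z": gz})
        vals.update(dose_moments(lat.dose, mask).as_dict())
        out.update({f"{k}_{side}": v for k, v in vals.items()})
    return out
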