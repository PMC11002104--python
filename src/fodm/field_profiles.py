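"""Per-residue hydrophobicity distributions T, O, R and M.

An analysis unit (a set of effective atoms with intrinsic hydrophobicities)
is first centered on its centroid and rotated onto its principal axes; the
3D Gaussian spanning the molecular body is parameterized by one sigma per
axis using the three-sigma extent rule.  Four unit-sum distributions over
the residues are then defined:

T  theoretical micelle-like distribution — the Gaussian evaluated at each
   effective-atom position, normalized;
O  observed distribution — pairwise inter-residue hydrophobic interactions
   weighted by the Levitt distance polynomial within a cutoff, normalized;
R  uniform reference, 1/N per residue (no hydrophobic core);
M  external-field distribution T + K * complement(T), normalized, modelling
   an environment that departs from bulk water by degree K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateGeometryError, DegenerateProfileError

Role = Literal["T", "O", "R", "M", "C"]

#: default Levitt interaction cutoff, Angstrom
DEFAULT_CUTOFF = 9.0
#: floor for per-axis sigma, Angstrom (guards flat units)
DEFAULT_SIGMA_FLOOR = 1.0
#: default sigma convention; the variance rule is the Gaussian MLE for the
#: point cloud and is the only bundled rule under which idealized micelle /
#: inverted reference units fall on the expected sides of RD = 0.5
DEFAULT_SIGMA_RULE = "std"


@dataclass(frozen=True)
class HydroProfile:
    """A nonnegative per-residue distribution summing to one."""

    role: Role
    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("profile must be a non-empty 1D vector")
        if np.any(v < -1e-12):
            raise ValueError(f"{self.role}-profile has negative entries")
        s = v.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"{self.role}-profile sums to {s!r}, expected 1")
        if self.labels and len(self.labels) != v.size:
            raise ValueError("labels length does not match profile length")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class OrientedUnit:
    """Centered, principal-axes-aligned point cloud with hydrophobicities."""

    points: np.ndarray          # (n, 3), centroid at origin
    h: np.ndarray               # (n,) intrinsic hydrophobicities in [0, 1]
    labels: tuple[str, ...]
    sigmas: tuple[float, float, float]

    @property
    def n(self) -> int:
        return self.points.shape[0]


def estimate_sigmas(
    oriented_points: np.ndarray,
    rule: Literal["extent3", "extent6", "std"] = DEFAULT_SIGMA_RULE,
    floor: float = DEFAULT_SIGMA_FLOOR,
) -> tuple[float, float, float]:
    """Per-axis Gaussian sigmas for centered, axis-aligned points.

    The default ``std`` rule uses the coordinate standard deviation per
    axis (the maximum-likelihood sigma for a Gaussian cloud).  ``extent3``
    sets sigma to max|coordinate|/3 — the three-sigma coverage convention —
    and ``extent6`` divides by six; all are floored at ``floor`` Angstrom
    to avoid collapse for planar or linear units.
    """
    pts = np.asarray(oriented_points, dtype=float)
    if rule == "extent3":
        raw = np.max(np.abs(pts), axis=0) / 3.0
    elif rule == "extent6":
        raw = np.max(np.abs(pts), axis=0) / 6.0
    elif rule == "std":
        raw = pts.std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown sigma rule {rule!r}")
    sx, sy, sz = np.maximum(raw, floor)
    return float(sx), float(sy), float(sz)


def orient_unit(
    points: np.ndarray,
    h: Sequence[float] | np.ndarray,
    labels: Sequence[str] | None = None,
    sigma_rule: Literal["extent3", "extent6", "std"] = DEFAULT_SIGMA_RULE,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
) -> OrientedUnit:
    """Center a point cloud and rotate it onto its principal axes.

    Axes are ordered by descending variance (x, y, z).  The axis-sign
    ambiguity of principal components is left unresolved; every downstream
    quantity (T, O, RD, K) is invariant under axis flips.
    """
    pts = np.asarray(points, dtype=float)
    hv = np.asarray(h, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if pts.shape[0] != hv.size:
        raise ValueError("points and hydrophobicities differ in length")
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 points to orient a unit")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-9):
        raise DegenerateGeometryError("all points coincide")
    cov = centered.T @ centered / centered.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)       # ascending
    rot = eigvecs[:, ::-1]                       # descending variance -> x, y, z
    aligned = centered @ rot
    sigmas = estimate_sigmas(aligned, rule=sigma_rule, floor=sigma_floor)
    lbl = tuple(labels) if labels is not None else tuple(str(i) for i in range(pts.shape[0]))
    return OrientedUnit(points=aligned, h=hv, labels=lbl, sigmas=sigmas)


def t_profile(unit: OrientedUnit) -> HydroProfile:
    """Theoretical micelle-like distribution: the 3D Gaussian at each residue."""
    sx, sy, sz = unit.sigmas
    x, y, z = unit.points.T
    # work in log space: the unnormalized Gaussian underflows for far points
    log_t = -(x**2 / (2 * sx**2) + y**2 / (2 * sy**2) + z**2 / (2 * sz**2))
    log_t -= log_t.max()
    t = np.exp(log_t)
    return HydroProfile(role="T", values=t / t.sum(), labels=unit.labels)


def levitt_weight(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Levitt distance polynomial: 1 at contact, 0 at the cutoff and beyond."""
    t2 = (np.asarray(r, dtype=float) / cutoff) ** 2
    w = 1.0 - 0.5 * (7 * t2 - 9 * t2**2 + 5 * t2**3 - t2**4)
    return np.where(r <= cutoff, w, 0.0)


def o_profile(
    unit: OrientedUnit,
    cutoff_c: float = DEFAULT_CUTOFF,
    include_self: bool = False,
) -> HydroProfile:
    """Observed distribution from pairwise hydrophobic interactions.

    O_j sums (H_i + H_j) * levitt_weight(r_ij) over partners i within the
    cutoff; the self-term i = j is excluded by default (interactions are
    inter-residue).  Residues with no neighbour inside the cutoff contribute
    zero before normalization.
    """
    if cutoff_c <= 0:
        raise ValueError("cutoff must be positive")
    pts = unit.points
    hv = unit.h
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    w = levitt_weight(r, cutoff_c)
    if not include_self:
        np.fill_diagonal(w, 0.0)
    pair = (hv[:, None] + hv[None, :]) * w
    o = np.maximum(pair.sum(axis=0), 0.0)
    total = o.sum()
    if total <= 1e-300:
        raise DegenerateProfileError(
            f"no hydrophobic interactions within {cutoff_c} A; O is identically zero"
        )
    return HydroProfile(role="O", values=o / total, labels=unit.labels)


def r_profile(n: int, labels: Sequence[str] | None = None) -> HydroProfile:
    """Uniform reference distribution, 1/N per residue."""
    if n < 1:
        raise ValueError("empty unit: R-profile needs at least one residue")
    lbl = tuple(labels) if labels is not None else ()
    return HydroProfile(role="R", values=np.full(n, 1.0 / n), labels=lbl)


def complement_profile(t: HydroProfile) -> HydroProfile | None:
    """Normalized complement (T_MAX - T_i); None when T is uniform."""
    c = t.values.max() - t.values
    s = c.sum()
    if s <= 1e-15:
        return None
    return HydroProfile(role="C", values=c / s, labels=t.labels)


def m_profile(t: HydroProfile, k: float) -> HydroProfile:
    """External-field distribution M = (T + K * complement_norm), normalized.

    The complement T_MAX - T is normalized to unit sum before mixing, and
    the mixture is normalized again (it sums to 1 + K).  K = 0 recovers T;
    K -> infinity approaches the pure complement.  For uniform T the
    complement vanishes and M = T for every K.
    """
    if k < 0:
        raise ValueError("field-modification parameter K must be nonnegative")
    c = complement_profile(t)
    if c is None:
        return HydroProfile(role="M", values=t.values.copy(), labels=t.labels)
    m_raw = t.values + k * c.values
    return HydroProfile(role="M", values=m_raw / m_raw.sum(), labels=t.labels)
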