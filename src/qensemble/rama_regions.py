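"""Ramachandran-region assignment and population statistics.

Each defined (phi, psi) pair is assigned to one of four regions of the
Ramachandran torus — alphaR (right-handed helical), alphaL (left-handed
helical), PPII (polyproline II) and beta (extended) — either by hard
rectangular boundaries or by per-residue wrapped k-means clustering that
tolerates population overlap at the region borders.  The four regions
partition the torus: points outside every rectangle take the region of
the nearest canonical center under wrapped Euclidean distance.

The alpha-tilde (alternating alphaR/alphaL) repeat mask marks residues
that alternate between the two helical regions with a sequence
neighbor — the building block of an alpha-sheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import ConformationEnsemble, wrap_angle

logger = logging.getLogger(__name__)

REGION_NAMES = ("alphaR", "alphaL", "PPII", "beta")
ALPHA_R, ALPHA_L, PPII, BETA = 0, 1, 2, 3
MISSING_LABEL = -1

#: canonical (phi, psi) centers, degrees
CANONICAL_CENTERS = {
    "alphaR": (-63.0, -43.0),
    "alphaL": (57.0, 47.0),
    "PPII": (-75.0, 150.0),
    "beta": (-140.0, 150.0),
}

# default axis-aligned rectangles on the torus; half-open [lo, hi),
# psi intervals may wrap across +/-180
_DEFAULT_RECTANGLES = {
    "alphaR": [((-180.0, 0.0), (-120.0, 50.0))],
    "alphaL": [((0.0, 180.0), (-50.0, 120.0))],
    "PPII": [((-110.0, 0.0), (50.0, 180.0)), ((-110.0, 0.0), (-180.0, -120.0))],
    "beta": [((-180.0, -110.0), (50.0, 180.0)), ((-180.0, -110.0), (-180.0, -120.0))],
}


@dataclass
class RegionBoundarySet:
    """Rectangular region boundaries plus canonical centers.

    rectangles: region name -> list of ((phi_lo, phi_hi), (psi_lo, psi_hi)),
    half-open intervals in degrees; an interval with lo > hi wraps across
    the +/-180 seam.
    """

    rectangles: dict = field(default_factory=lambda: {k: list(v) for k, v in _DEFAULT_RECTANGLES.items()})
    centers: dict = field(default_factory=lambda: dict(CANONICAL_CENTERS))

    def center_array(self) -> np.ndarray:
        return np.array([self.centers[name] for name in REGION_NAMES])


def _in_interval(x, lo, hi):
    """Half-open interval membership on the circle (degrees)."""
    if lo <= hi:
        return (x >= lo) & (x < hi)
    return (x >= lo) | (x < hi)


def wrapped_sq_distance(phi, psi, center):
    """Squared wrapped Euclidean distance on the torus (degrees^2)."""
    dphi = np.abs(phi - center[0]) % 360.0
    dphi = np.minimum(dphi, 360.0 - dphi)
    dpsi = np.abs(psi - center[1]) % 360.0
    dpsi = np.minimum(dpsi, 360.0 - dpsi)
    return dphi**2 + dpsi**2


def classify_points(phi, psi, bounds: RegionBoundarySet) -> np.ndarray:
    """Hard-boundary region codes for arrays of defined angles."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    labels = np.full(phi.shape, MISSING_LABEL, dtype=np.int8)
    for code, name in enumerate(REGION_NAMES):
        for (plo, phi_hi), (slo, shi) in bounds.rectangles[name]:
            inside = _in_interval(phi, plo, phi_hi) & _in_interval(psi, slo, shi)
            labels[inside & (labels == MISSING_LABEL)] = code
    leftover = labels == MISSING_LABEL
    if np.any(leftover):
        centers = bounds.center_array()
        d = np.stack(
            [wrapped_sq_distance(phi[leftover], psi[leftover], c) for c in centers]
        )
        labels[leftover] = np.argmin(d, axis=0).astype(np.int8)
    return labels


@dataclass
class RegionLabelMatrix:
    """Categorical region assignment per (conformation, residue)."""

    labels: np.ndarray  # int8 (n_conf, n_res), MISSING_LABEL where undefined
    method: str  # "hard" or "cluster"
    residue_names: list[str] = field(default_factory=list)

    @property
    def n_conformations(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]


def assign_regions_hard(ens: ConformationEnsemble,
                        bounds: RegionBoundarySet | None = None) -> RegionLabelMatrix:
    """Assign every defined (phi, psi) pair by the hard region boundaries."""
    bounds = bounds or RegionBoundarySet()
    defined = ~(np.isnan(ens.phi) | np.isnan(ens.psi))
    labels = np.full(ens.phi.shape, MISSING_LABEL, dtype=np.int8)
    labels[defined] = classify_points(ens.phi[defined], ens.psi[defined], bounds)
    return RegionLabelMatrix(labels, "hard", list(ens.residue_names))


def _wrapped_kmeans(phi, psi, weights, centers, max_iter=100):
    """Weighted k-means on the torus with fixed initial centers.

    Returns (assignments, final_centers).  Deterministic given inputs;
    empty clusters keep their previous center.
    """
    centers = centers.copy().astype(float)
    k = centers.shape[0]
    assign = np.full(phi.shape, -1, dtype=int)
    for _ in range(max_iter):
        d = np.stack([wrapped_sq_distance(phi, psi, c) for c in centers])
        new_assign = np.argmin(d, axis=0)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            sel = assign == j
            if not np.any(sel):
                continue
            w = weights[sel]
            # weighted circular mean per coordinate
            for coord, arr in enumerate((phi, psi)):
                rad = np.radians(arr[sel])
                mean = np.degrees(
                    np.arctan2(np.sum(w * np.sin(rad)), np.sum(w * np.cos(rad)))
                )
                centers[j, coord] = wrap_angle(mean)
    return assign, centers


def assign_regions_cluster(ens: ConformationEnsemble,
                           bounds: RegionBoundarySet | None = None,
                           grid_deg: float = 5.0) -> RegionLabelMatrix:
    """Per-residue clustering assignment tolerant of border overlap.

    Each residue's defined (phi, psi) points are histogrammed on a
    ``grid_deg`` torus grid and clustered by wrapped k-means (k=4) seeded
    at the canonical centers.  Final clusters are re-identified by their
    nearest canonical center; if two clusters collapse onto the same
    center, that residue falls back to hard assignment (logged).
    Ensembles with fewer than 100 defined pairs overall fall back to hard
    assignment entirely.
    """
    bounds = bounds or RegionBoundarySet()
    if 360.0 % grid_deg != 0:
        raise ValueError(f"grid_deg={grid_deg} does not divide 360")
    defined = ~(np.isnan(ens.phi) | np.isnan(ens.psi))
    if defined.sum() < 100:
        logger.warning("fewer than 100 defined (phi,psi) pairs; using hard assignment")
        hard = assign_regions_hard(ens, bounds)
        return RegionLabelMatrix(hard.labels, "cluster", list(ens.residue_names))

    n_bins = int(round(360.0 / grid_deg))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    canonical = bounds.center_array()
    labels = np.full(ens.phi.shape, MISSING_LABEL, dtype=np.int8)
    for r in range(ens.n_residues):
        sel = defined[:, r]
        if not np.any(sel):
            continue
        phi_r = ens.phi[sel, r]
        psi_r = ens.psi[sel, r]
        # histogram: shift +180 so (-180,180] maps into [0, 360)
        hist, _, _ = np.histogram2d(phi_r, psi_r, bins=[edges, edges])
        occ = np.nonzero(hist)
        bin_phi = (edges[occ[0]] + edges[occ[0] + 1]) / 2.0
        bin_psi = (edges[occ[1]] + edges[occ[1] + 1]) / 2.0
        weights = hist[occ]
        assign, centers = _wrapped_kmeans(bin_phi, bin_psi, weights, canonical)
        # re-identify clusters by nearest canonical center
        ident = np.array(
            [
                np.argmin([wrapped_sq_distance(c[0], c[1], cc) for cc in canonical])
                for c in centers
            ],
            dtype=np.int8,
        )
        if len(set(ident.tolist())) < len(ident):
            logger.warning(
                "residue %d: clusters collapsed onto one canonical center; "
                "hard assignment used", r + 1
            )
            labels[sel, r] = classify_points(phi_r, psi_r, bounds)
            continue
        # map every point to the nearest final cluster center
        d = np.stack([wrapped_sq_distance(phi_r, psi_r, c) for c in centers])
        labels[sel, r] = ident[np.argmin(d, axis=0)]
    return RegionLabelMatrix(labels, "cluster", list(ens.residue_names))


def region_population_profile(labels: RegionLabelMatrix,
                              residue_filter=frozenset({"GLN"})) -> dict:
    """Per-residue region percentages over defined labels.

    Only residues whose name is in ``residue_filter`` (default glutamine;
    prolines are thereby excluded from the statistics) are reported.
    Returns {"residue": 1-based indices, <region>: percentage arrays}.
    """
    if not labels.residue_names:
        keep = list(range(labels.n_residues))
    else:
        keep = [i for i, n in enumerate(labels.residue_names) if n in residue_filter]
    if not keep:
        raise ValueError(f"no residues match filter {sorted(residue_filter)}")
    out = {"residue": np.array([i + 1 for i in keep])}
    mat = labels.labels[:, keep]
    defined_counts = (mat != MISSING_LABEL).sum(axis=0).astype(float)
    for code, name in enumerate(REGION_NAMES):
        counts = (mat == code).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(defined_counts > 0, 100.0 * counts / defined_counts, np.nan)
    return out


def alpha_tilde_mask(labels: RegionLabelMatrix) -> np.ndarray:
    """Binary mask of residues in an alternating alphaR/alphaL repeat.

    A cell is 1 iff its label is alphaR and an adjacent residue is
    alphaL, or vice versa (either order).  Terminal residues use their
    single neighbor; MISSING neighbors never match.
    """
    mat = labels.labels
    n_conf, n_res = mat.shape
    mask = np.zeros((n_conf, n_res), dtype=np.int8)
    is_r = mat == ALPHA_R
    is_l = mat == ALPHA_L
    left_r = np.zeros_like(is_r)
    left_l = np.zeros_like(is_l)
    left_r[:, 1:] = is_r[:, :-1]
    left_l[:, 1:] = is_l[:, :-1]
    right_r = np.zeros_like(is_r)
    right_l = np.zeros_like(is_l)
    right_r[:, :-1] = is_r[:, 1:]
    right_l[:, :-1] = is_l[:, 1:]
    mask[(is_r & (left_l | right_l)) | (is_l & (left_r | right_r))] = 1
    return mask


def mean_region_populations(labels: RegionLabelMatrix,
                            residue_filter=frozenset({"GLN"})) -> dict:
    """Ensemble-average region percentages plus the alpha-tilde percentage.

    Region percentages are the average of the per-residue profile over
    the filtered residues (they sum to 100 up to rounding); the
    alpha-tilde value is the percentage of defined (conformation,
    residue) cells participating in an alternating alphaR/alphaL repeat.
    """
    profile = region_population_profile(labels, residue_filter)
    out = {name: float(np.nanmean(profile[name])) for name in REGION_NAMES}
    if not labels.residue_names:
        keep = list(range(labels.n_residues))
    else:
        keep = [i for i, n in enumerate(labels.residue_names) if n in residue_filter]
    mask = alpha_tilde_mask(labels)[:, keep]
    defined = labels.labels[:, keep] != MISSING_LABEL
    out["alpha_tilde"] = float(100.0 * mask[defined].mean()) if defined.any() else 0.0
    return out
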