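"""Synthetic conformational ensembles with controlled statistical structure.

Ensembles of polyQ / polyQ-polyP peptides are emulated with a latent
Gaussian copula: a stationary Gaussian process over residue index with a
damped-cosine covariance k(d) = a*exp(-d/lambda)*cos(2*pi*d/P) +
(1-a)*[d=0] is mapped through the standard-normal CDF and per-residue
categorical marginals to Ramachandran-region labels.  The kernel gives
direct, independent control of the correlation decay length and the
oscillation period — the two properties the correlation statistics must
recover.  Within-region (phi, psi) scatter is wrapped-Gaussian around
the canonical region centers, and prolyl peptide bonds are drawn
cis/trans with a tunable trans probability.

Backbones are reconstructed from dihedrals by sequential
natural-extension (NeRF) placement with fixed ideal geometry; this is
adequate for hydrogen-bond pattern tests on engineered fixtures but is
not an energy-minimized, physical chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .ensemble_io import (ConformationEnsemble, dihedrals_from_coords,
                          ensemble_from_coords, wrap_angle)
from .rama_regions import (ALPHA_L, ALPHA_R, BETA, CANONICAL_CENTERS, PPII,
                           REGION_NAMES, RegionLabelMatrix)

#: ideal backbone geometry (angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7

#: cumulative mapping order of the copula (least to most helical)
_CUM_ORDER = (BETA, PPII, ALPHA_L, ALPHA_R)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic ensemble.

    region_marginals may be a length-4 vector (applied to every
    glutamine residue) or an (n_residues, 4) matrix, in REGION_NAMES
    order (alphaR, alphaL, PPII, beta); rows must sum to 1.  Proline
    rows are forced to PPII.  kernel = (amplitude a in [0,1), decay
    length lambda in residues, period P in residues);
    ``kernel_baseline`` mixes a non-oscillatory positive component into
    the damped envelope so that a slowly decaying kernel produces an
    association profile oscillating around a *positive* level — the
    signature of genuine long-range correlation — rather than around
    zero.
    """

    n_conformations: int
    n_residues: int
    residue_names: list[str] | None = None
    region_marginals: np.ndarray = field(
        default_factory=lambda: np.array([0.80, 0.05, 0.07, 0.08])
    )
    kernel: tuple[float, float, float] = (0.0, 3.0, 7.0)
    kernel_baseline: float = 0.5
    within_region_sd: float = 15.0
    region_centers: dict = field(default_factory=lambda: dict(CANONICAL_CENTERS))
    omega_trans_prob: float = 1.0
    omega_jitter_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.residue_names is None:
            self.residue_names = ["GLN"] * self.n_residues
        if len(self.residue_names) != self.n_residues:
            raise ValueError("residue_names length != n_residues")
        m = np.atleast_2d(np.asarray(self.region_marginals, dtype=float))
        if m.shape[0] == 1:
            m = np.repeat(m, self.n_residues, axis=0)
        if m.shape != (self.n_residues, 4):
            raise ValueError(f"region_marginals shape {m.shape} invalid")
        for j, name in enumerate(self.residue_names):
            if name == "PRO":
                m[j] = [0.0, 0.0, 1.0, 0.0]
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("region marginals must sum to 1")
        self.region_marginals = m
        a, lam, period = self.kernel
        if not (0.0 <= a < 1.0):
            raise ValueError("kernel amplitude must be in [0, 1)")
        if lam <= 0 or period < 2:
            raise ValueError("kernel decay must be > 0 and period >= 2")


def damped_cosine_covariance(n: int, a: float, lam: float, period: float,
                             baseline: float = 0.5) -> np.ndarray:
    """Damped-cosine latent covariance with a positive baseline component.

    k(d) = a*exp(-d/lam)*((1-c)*cos(2*pi*d/P) + c) + (1-a)*[d == 0]
    with c = ``baseline``.  Each summand is a valid stationary kernel
    (Bochner), so k is positive semidefinite by construction.  The
    baseline makes a long decay length show up as a persistently
    *positive* association level at large distance, on top of the
    period-P oscillation.
    """
    if not (0.0 <= baseline <= 1.0):
        raise ValueError("kernel baseline must be in [0, 1]")
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    cov = a * np.exp(-d / lam) * (
        (1.0 - baseline) * np.cos(2.0 * np.pi * d / period) + baseline
    )
    cov[np.diag_indices(n)] = 1.0
    return cov


def sample_regions(spec: SyntheticSpec, rng=None) -> RegionLabelMatrix:
    """Draw correlated region labels through the latent Gaussian copula."""
    rng = rng or np.random.default_rng(spec.seed)
    n, m = spec.n_conformations, spec.n_residues
    a, lam, period = spec.kernel
    cov = damped_cosine_covariance(m, a, lam, period, spec.kernel_baseline)
    try:
        L = np.linalg.cholesky(cov + 1e-8 * np.eye(m))
    except np.linalg.LinAlgError as exc:
        raise ValueError("kernel covariance is not positive semidefinite") from exc
    z = rng.standard_normal((n, m)) @ L.T
    u = norm.cdf(z)
    # per-residue cumulative thresholds in _CUM_ORDER
    cum = np.cumsum(spec.region_marginals[:, list(_CUM_ORDER)], axis=1)
    labels = np.empty((n, m), dtype=np.int8)
    order = np.array(_CUM_ORDER, dtype=np.int8)
    for j in range(m):
        idx = np.searchsorted(cum[j], u[:, j], side="right")
        labels[:, j] = order[np.minimum(idx, 3)]
    return RegionLabelMatrix(labels, "generator", list(spec.residue_names))


def sample_dihedrals(labels: RegionLabelMatrix, spec: SyntheticSpec,
                     rng=None) -> ConformationEnsemble:
    """Wrapped-Gaussian (phi, psi) scatter around the labelled region centers.

    omega is 180 deg for non-prolyl bonds; prolyl bonds are trans with
    probability ``omega_trans_prob`` (else cis, 0 deg) plus
    wrapped-Gaussian jitter.  Terminal undefined angles are NaN.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n, m = labels.labels.shape
    centers = np.array([spec.region_centers[name] for name in REGION_NAMES])
    lab = labels.labels
    phi = np.where(lab >= 0, centers[np.maximum(lab, 0), 0], 0.0)
    psi = np.where(lab >= 0, centers[np.maximum(lab, 0), 1], 0.0)
    if spec.within_region_sd > 0:
        phi = phi + rng.normal(0.0, spec.within_region_sd, size=(n, m))
        psi = psi + rng.normal(0.0, spec.within_region_sd, size=(n, m))
    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    omega = np.full((n, m), 180.0)
    for j, name in enumerate(spec.residue_names):
        if name == "PRO" and j >= 1:
            trans = rng.random(n) < spec.omega_trans_prob
            base = np.where(trans, 180.0, 0.0)
            omega[:, j - 1] = wrap_angle(
                base + rng.normal(0.0, spec.omega_jitter_sd, size=n)
            )
    phi[:, 0] = np.nan
    psi[:, -1] = np.nan
    omega[:, -1] = np.nan
    name = f"synthetic-{spec.n_residues}mer"
    return ConformationEnsemble(name, list(spec.residue_names), phi, psi, omega)


# ---------------------------------------------------------------------------
# backbone reconstruction (NeRF)


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors, bond length, angle, torsion.

    Vectorized over leading axes.  The torsion convention matches
    :func:`qensemble.ensemble_io.compute_dihedral`.
    """
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(angle) * np.ones(np.shape(torsion)),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ],
        axis=-1,
    )
    return c + (
        d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def build_backbone(ens: ConformationEnsemble) -> ConformationEnsemble:
    """Reconstruct N, CA, C, O coordinates from dihedrals by NeRF chaining.

    Terminal undefined angles are replaced by 180 deg for placement
    only; recomputing dihedrals from the built coordinates reproduces
    the stored angles within 1e-4 degrees.
    """
    n_conf, n_res = ens.phi.shape
    phi = np.where(np.isnan(ens.phi), 180.0, ens.phi)
    psi = np.where(np.isnan(ens.psi), 180.0, ens.psi)
    omega = np.where(np.isnan(ens.omega), 180.0, ens.omega)
    coords = np.zeros((n_conf, n_res, 4, 3))
    # first residue in the xy-plane
    coords[:, 0, 0] = [0.0, 0.0, 0.0]
    coords[:, 0, 1] = [BOND_N_CA, 0.0, 0.0]
    alpha = np.radians(180.0 - ANGLE_N_CA_C)
    coords[:, 0, 2] = coords[:, 0, 1] + BOND_CA_C * np.array(
        [np.cos(alpha), np.sin(alpha), 0.0]
    )
    for i in range(n_res - 1):
        N_i, CA_i, C_i = coords[:, i, 0], coords[:, i, 1], coords[:, i, 2]
        N_next = _place_atom(N_i, CA_i, C_i, BOND_C_N, ANGLE_CA_C_N, psi[:, i])
        CA_next = _place_atom(CA_i, C_i, N_next, BOND_N_CA, ANGLE_C_N_CA, omega[:, i])
        C_next = _place_atom(C_i, N_next, CA_next, BOND_CA_C, ANGLE_N_CA_C,
                             phi[:, i + 1])
        coords[:, i + 1, 0] = N_next
        coords[:, i + 1, 1] = CA_next
        coords[:, i + 1, 2] = C_next
    # carbonyl oxygens: in the CA-C-N(i+1) plane, opposite the bisector
    for i in range(n_res):
        CA_i, C_i = coords[:, i, 1], coords[:, i, 2]
        if i + 1 < n_res:
            N_next = coords[:, i + 1, 0]
        else:
            N_next = _place_atom(coords[:, i, 0], CA_i, C_i, BOND_C_N,
                                 ANGLE_CA_C_N, psi[:, i])
        u1 = N_next - C_i
        u1 = u1 / np.linalg.norm(u1, axis=-1, keepdims=True)
        u2 = CA_i - C_i
        u2 = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
        b = u1 + u2
        b = b / np.linalg.norm(b, axis=-1, keepdims=True)
        coords[:, i, 3] = C_i - BOND_C_O * b
    return ConformationEnsemble(
        ens.peptide_name, list(ens.residue_names),
        ens.phi.copy(), ens.psi.copy(), ens.omega.copy(), coords,
    )


def generate_ensemble(spec: SyntheticSpec, build_coords: bool = False):
    """Full generator: labels -> dihedrals -> (optionally) coordinates.

    Returns (labels, ensemble).  Bit-identical for identical seeds.
    """
    rng = np.random.default_rng(spec.seed)
    labels = sample_regions(spec, rng)
    ens = sample_dihedrals(labels, spec, rng)
    if build_coords:
        ens = build_backbone(ens)
    return labels, ens


# ---------------------------------------------------------------------------
# deterministic fixtures


def _from_phi_psi(name, residue_names, phi_psi_list, omega=None):
    """Single-conformation ensemble from a per-residue (phi, psi) list."""
    n = len(phi_psi_list)
    phi = np.full((1, n), np.nan)
    psi = np.full((1, n), np.nan)
    omg = np.full((1, n), np.nan)
    for i, (p, s) in enumerate(phi_psi_list):
        phi[0, i] = p
        psi[0, i] = s
    phi[0, 0] = np.nan
    psi[0, -1] = np.nan
    omg[0, :-1] = 180.0 if omega is None else omega
    ens = ConformationEnsemble(name, list(residue_names), phi, psi, omg)
    return build_backbone(ens)


def ideal_helix(n: int = 12) -> ConformationEnsemble:
    """Right-handed alpha-helix: phi = -57, psi = -47."""
    return _from_phi_psi("ideal_helix", ["GLN"] * n, [(-57.0, -47.0)] * n)


def extended_beta(n: int = 10) -> ConformationEnsemble:
    """Fully extended chain in the beta region: phi = -140, psi = 150."""
    return _from_phi_psi("extended_beta", ["GLN"] * n, [(-140.0, 150.0)] * n)


def ppii_helix(n: int = 8) -> ConformationEnsemble:
    """Polyproline-II helix: phi = -75, psi = 150."""
    return _from_phi_psi("ppii_helix", ["GLN"] * n, [(-75.0, 150.0)] * n)


def alpha_tilde_strand(n: int = 6) -> ConformationEnsemble:
    """Alternating alphaR/alphaL strand (alpha-sheet building block)."""
    angles = [(-63.0, -43.0) if i % 2 == 0 else (57.0, 47.0) for i in range(n)]
    return _from_phi_psi("alpha_tilde_strand", ["GLN"] * n, angles)


def beta_hairpin() -> ConformationEnsemble:
    """Antiparallel beta-hairpin: two 4-residue beta strands, 3-residue
    turn engineered so that cross-strand backbone H-bonds form."""
    strand = (-140.0, 135.0)
    # type-I'-like loop geometry tuned so the NeRF chain closes the hairpin
    loop = [(55.0, 45.0), (80.0, 0.0), (-90.0, 120.0)]
    angles = [strand] * 4 + loop + [strand] * 4
    return _from_phi_psi("beta_hairpin", ["GLN"] * len(angles), angles)


def type_i_beta_turn() -> ConformationEnsemble:
    """Type-I beta-turn: middle residues at (-60, -30) and (-90, 0) with
    an i -> i+3 hydrogen bond."""
    angles = [(-140.0, 135.0), (-60.0, -30.0), (-90.0, 0.0), (-140.0, 135.0)]
    angles = [(-120.0, 120.0)] + angles + [(-120.0, 120.0)]
    return _from_phi_psi("type_i_beta_turn", ["GLN"] * len(angles), angles)


def q40_like(n_conformations: int = 1000, seed: int = 0,
             kernel=(0.0, 3.0, 7.0)) -> SyntheticSpec:
    """Q40 emulation: 40 glutamines with dominant-alphaR marginals."""
    return SyntheticSpec(
        n_conformations=n_conformations,
        n_residues=40,
        region_marginals=np.array([0.80, 0.05, 0.07, 0.08]),
        kernel=kernel,
        seed=seed,
    )


def q40p6_like(n_conformations: int = 1000, seed: int = 0,
               kernel=(0.0, 3.0, 7.0),
               omega_trans_prob: float = 0.85) -> SyntheticSpec:
    """Q40-P6 emulation: 40 glutamines plus a C-terminal hexaproline."""
    return SyntheticSpec(
        n_conformations=n_conformations,
        n_residues=46,
        residue_names=["GLN"] * 40 + ["PRO"] * 6,
        region_marginals=np.array([0.80, 0.05, 0.07, 0.08]),
        kernel=kernel,
        omega_trans_prob=omega_trans_prob,
        seed=seed,
    )


def fixtures() -> dict:
    """Named deterministic fixtures used throughout the test suite."""
    return {
        "ideal_helix": ideal_helix(),
        "extended_beta": extended_beta(),
        "ppii_helix": ppii_helix(),
        "alpha_tilde_strand": alpha_tilde_strand(),
        "beta_hairpin": beta_hairpin(),
        "type_i_beta_turn": type_i_beta_turn(),
    }
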