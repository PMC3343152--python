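"""Conformational-ensemble container and I/O.

An ensemble is a set of conformations of one peptide chain, stored as
per-residue backbone dihedral angles (phi, psi, omega, degrees) with
optional backbone coordinates (N, CA, C, O; angstrom).  Undefined angles
(phi of residue 1; psi and omega of the last residue) are NaN and are
excluded from every downstream denominator.

Residue indices are 1-based in all files and reports; arrays are 0-based
internally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for undefined angles.  Use :func:`is_missing` to test.
MISSING = np.nan

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def is_missing(angle) -> np.ndarray:
    """True where an angle value is undefined."""
    return np.isnan(angle)


def wrap_angle(angle):
    """Wrap angle(s) in degrees into the half-open interval (-180, +180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = ((a + 180.0) % 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle):
        return float(wrapped)
    return wrapped


class EnsembleError(ValueError):
    """Raised for malformed ensemble inputs."""


def angular_difference(a, b):
    """Smallest signed difference a - b on the circle, degrees in [-180, 180)."""
    return ((np.asarray(a) - np.asarray(b) + 180.0) % 360.0) - 180.0


@dataclass
class ConformationEnsemble:
    """Backbone dihedrals (and optionally coordinates) of one peptide.

    Parameters
    ----------
    peptide_name : str
        Free-form identifier, e.g. ``"Q40"`` or ``"Q40P6"``.
    residue_names : list of str
        Three-letter residue codes, length ``n_residues``.
    phi, psi, omega : ndarray, shape (n_conformations, n_residues)
        Backbone dihedrals in degrees within (-180, +180]; NaN where
        undefined.  ``omega[i, j]`` is the peptide-bond torsion
        CA(j)-C(j)-N(j+1)-CA(j+1), i.e. the bond *following* residue j;
        the bond preceding a proline at position j+1 is ``omega[:, j]``.
    coords : ndarray or None, shape (n_conformations, n_residues, 4, 3)
        Backbone coordinates in N, CA, C, O order (angstrom); NaN rows
        for absent O atoms.
    """

    peptide_name: str
    residue_names: list[str]
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n_conf, n_res = self.phi.shape
        if len(self.residue_names) != n_res:
            raise EnsembleError(
                f"residue_names has {len(self.residue_names)} entries "
                f"but angle matrices have {n_res} columns"
            )
        for name, mat in (("psi", self.psi), ("omega", self.omega)):
            if mat.shape != (n_conf, n_res):
                raise EnsembleError(f"{name} shape {mat.shape} != {(n_conf, n_res)}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n_conf, n_res, 4, 3):
                raise EnsembleError(
                    f"coords shape {self.coords.shape} != {(n_conf, n_res, 4, 3)}"
                )

    @property
    def n_conformations(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]

    def gln_mask(self) -> np.ndarray:
        return np.array([r == "GLN" for r in self.residue_names])

    def residue_mask(self, names) -> np.ndarray:
        names = set(names)
        return np.array([r in names for r in self.residue_names])

    def subset(self, conformation_indices) -> "ConformationEnsemble":
        """New ensemble restricted to the given conformations."""
        idx = np.asarray(conformation_indices)
        return ConformationEnsemble(
            peptide_name=self.peptide_name,
            residue_names=list(self.residue_names),
            phi=self.phi[idx].copy(),
            psi=self.psi[idx].copy(),
            omega=self.omega[idx].copy(),
            coords=None if self.coords is None else self.coords[idx].copy(),
        )


# ---------------------------------------------------------------------------
# dihedral geometry


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, degrees in (-180, +180].

    IUPAC sign convention: looking down the p2->p3 axis, a positive angle
    is a clockwise rotation of p4 relative to p1.  An ideal right-handed
    alpha-helix backbone yields phi close to -57 degrees.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 == 0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise EnsembleError("degenerate geometry: torsion undefined (collinear points)")
    m1 = np.cross(n1, b2 / norm_b2)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return wrap_angle(np.degrees(np.arctan2(-y, x)))


def _dihedral_vec(p1, p2, p3, p4):
    """Vectorized torsion over leading axes; NaN where degenerate."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.cross(n1, b2 / norm_b2)
        x = np.einsum("...i,...i->...", n1, n2)
        y = np.einsum("...i,...i->...", m1, n2)
        ang = np.degrees(np.arctan2(-y, x))
    return wrap_angle(ang)


def dihedrals_from_coords(coords, residue_names=None):
    """Compute (phi, psi, omega) matrices from backbone coordinates.

    coords : ndarray (n_conf, n_res, 4, 3), N CA C O order.
    Returns matrices with NaN at the chain-terminal undefined positions.
    """
    coords = np.asarray(coords, dtype=float)
    n_conf, n_res = coords.shape[:2]
    N = coords[:, :, 0]
    CA = coords[:, :, 1]
    C = coords[:, :, 2]
    phi = np.full((n_conf, n_res), np.nan)
    psi = np.full((n_conf, n_res), np.nan)
    omega = np.full((n_conf, n_res), np.nan)
    if n_res >= 2:
        # phi(i) = C(i-1)-N(i)-CA(i)-C(i)
        phi[:, 1:] = _dihedral_vec(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
        # psi(i) = N(i)-CA(i)-C(i)-N(i+1)
        psi[:, :-1] = _dihedral_vec(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
        # omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1)
        omega[:, :-1] = _dihedral_vec(CA[:, :-1], C[:, :-1], N[:, 1:], CA[:, 1:])
    return phi, psi, omega


def ensemble_from_coords(peptide_name, residue_names, coords) -> ConformationEnsemble:
    phi, psi, omega = dihedrals_from_coords(coords)
    return ConformationEnsemble(peptide_name, list(residue_names), phi, psi, omega, coords)


# ---------------------------------------------------------------------------
# PDB I/O (multi-model, single chain)


def read_multimodel_pdb(path, peptide_name=None) -> ConformationEnsemble:
    """Read a multi-model PDB file into an ensemble.

    Models missing any of N, CA, C for some residue are skipped with a
    warning.  O atoms are kept when present (NaN otherwise).  Multiple
    chains are an error.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    reference_names = None
    kept = []
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        chains = sorted(set(atoms.chain_id))
        if len(chains) > 1:
            raise EnsembleError(f"expected a single chain, found: {', '.join(chains)}")
        res_ids = atoms.res_id
        unique_ids = sorted(set(res_ids.tolist()))
        res_names = []
        model_coords = np.full((len(unique_ids), 4, 3), np.nan)
        ok = True
        for ri, rid in enumerate(unique_ids):
            sel = res_ids == rid
            res_names.append(atoms.res_name[sel][0])
            atom_names = atoms.atom_name[sel]
            for ai, aname in enumerate(BACKBONE_ATOMS):
                hit = np.flatnonzero(atom_names == aname)
                if hit.size:
                    model_coords[ri, ai] = atoms.coord[sel][hit[0]]
                elif aname != "O":
                    ok = False
        if not ok:
            logger.warning("model %d skipped: missing backbone atoms", m)
            continue
        if reference_names is None:
            reference_names = res_names
        elif res_names != reference_names:
            logger.warning("model %d skipped: residue mismatch", m)
            continue
        kept.append(model_coords)
    if not kept:
        raise EnsembleError(f"no usable models in {path}")
    coords = np.stack(kept)
    name = peptide_name or str(path)
    return ensemble_from_coords(name, reference_names, coords)


def write_multimodel_pdb(ens: ConformationEnsemble, path) -> None:
    """Write an ensemble with coordinates as a multi-model PDB fixture."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if ens.coords is None:
        raise EnsembleError("ensemble has no coordinates")
    n_res = ens.n_residues
    atoms_per_res = [
        [a for a in BACKBONE_ATOMS if not np.isnan(ens.coords[0, r, BACKBONE_ATOMS.index(a)]).any()]
        for r in range(n_res)
    ]
    n_atoms = sum(len(a) for a in atoms_per_res)
    template = struc.AtomArray(n_atoms)
    coord_index = []
    k = 0
    for r in range(n_res):
        for aname in atoms_per_res[r]:
            template.chain_id[k] = "A"
            template.res_id[k] = r + 1
            template.res_name[k] = ens.residue_names[r]
            template.atom_name[k] = aname
            template.element[k] = aname[0]
            coord_index.append((r, BACKBONE_ATOMS.index(aname)))
            k += 1
    stack = struc.stack([template] * ens.n_conformations)
    for m in range(ens.n_conformations):
        for k, (r, ai) in enumerate(coord_index):
            stack.coord[m, k] = ens.coords[m, r, ai]
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# dihedral-table (TSV) I/O

_TABLE_COLUMNS = ("conformation", "residue_index", "residue_name", "phi", "psi", "omega")


def _parse_angle(token: str, line_no: int):
    token = token.strip()
    if token == "NA":
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise EnsembleError(f"unparseable angle {token!r} at line {line_no}") from None


def read_dihedral_table(path, peptide_name=None) -> ConformationEnsemble:
    """Read a TSV dihedral table (no coordinates).

    Columns: conformation, residue_index (1-based, contiguous),
    residue_name, phi, psi, omega.  "NA" marks undefined angles; angles
    outside (-180, +180] are wrapped into range.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TABLE_COLUMNS:
            raise EnsembleError(
                f"expected header {list(_TABLE_COLUMNS)}, got {header}"
            )
        rows = []
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise EnsembleError(f"expected 6 columns at line {line_no}")
            conf = int(parts[0])
            ridx = int(parts[1])
            rows.append(
                (conf, ridx, parts[2].strip(),
                 _parse_angle(parts[3], line_no),
                 _parse_angle(parts[4], line_no),
                 _parse_angle(parts[5], line_no))
            )
    if not rows:
        raise EnsembleError(f"empty dihedral table: {path}")
    conf_ids = sorted({r[0] for r in rows})
    conf_pos = {c: i for i, c in enumerate(conf_ids)}
    n_res = max(r[1] for r in rows)
    n_conf = len(conf_ids)
    phi = np.full((n_conf, n_res), np.nan)
    psi = np.full((n_conf, n_res), np.nan)
    omega = np.full((n_conf, n_res), np.nan)
    residue_names = [None] * n_res
    seen = {}
    for conf, ridx, rname, a_phi, a_psi, a_omega in rows:
        if ridx < 1:
            raise EnsembleError("residue_index must be 1-based")
        i, j = conf_pos[conf], ridx - 1
        phi[i, j] = a_phi
        psi[i, j] = a_psi
        omega[i, j] = a_omega
        if residue_names[j] is None:
            residue_names[j] = rname
        seen.setdefault(conf, set()).add(ridx)
    for conf, idxs in seen.items():
        if idxs != set(range(1, max(idxs) + 1)):
            raise EnsembleError(f"non-contiguous residue indices in conformation {conf}")
        if max(idxs) != n_res:
            raise EnsembleError(f"conformation {conf} has {max(idxs)} residues, expected {n_res}")
    defined = ~np.isnan(phi)
    phi[defined] = wrap_angle(phi[defined])
    defined = ~np.isnan(psi)
    psi[defined] = wrap_angle(psi[defined])
    defined = ~np.isnan(omega)
    omega[defined] = wrap_angle(omega[defined])
    name = peptide_name or str(path)
    return ConformationEnsemble(name, residue_names, phi, psi, omega)


def _fmt_angle(a) -> str:
    return "NA" if np.isnan(a) else f"{a:.4f}"


def write_dihedral_table(ens: ConformationEnsemble, path) -> None:
    """Write the dihedral table as deterministic TSV (byte-stable)."""
    lines = ["\t".join(_TABLE_COLUMNS)]
    for c in range(ens.n_conformations):
        for r in range(ens.n_residues):
            lines.append(
                f"{c + 1}\t{r + 1}\t{ens.residue_names[r]}\t"
                f"{_fmt_angle(ens.phi[c, r])}\t{_fmt_angle(ens.psi[c, r])}\t"
                f"{_fmt_angle(ens.omega[c, r])}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# analysis-product writers


def write_labels(labels, path) -> None:
    """Write a RegionLabelMatrix as TSV (conformation, residue, region)."""
    from .rama_regions import REGION_NAMES, MISSING_LABEL

    lines = ["conformation\tresidue\tregion"]
    mat = labels.labels
    for c in range(mat.shape[0]):
        for r in range(mat.shape[1]):
            code = mat[c, r]
            name = "NA" if code == MISSING_LABEL else REGION_NAMES[code]
            lines.append(f"{c + 1}\t{r + 1}\t{name}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_motifs(motifs, path) -> None:
    """Write MotifInstance records as TSV (header even when empty)."""
    lines = ["conformation\ttype\tstart\tend\tlength\tisolated\tmin_len"]
    for m in motifs:
        iso = "NA" if m.isolated is None else str(int(m.isolated))
        lines.append(
            f"{m.conformation + 1}\t{m.type}\t{m.start + 1}\t{m.end + 1}\t"
            f"{m.length}\t{iso}\t{m.min_len_variant}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_profile(profile, path) -> None:
    """Write a CorrelationProfile as TSV (r, value, se, n_pairs)."""
    lines = ["r\tvalue\tse\tn_pairs"]
    for i, r in enumerate(profile.r):
        val = "NA" if np.isnan(profile.value[i]) else f"{profile.value[i]:.6f}"
        se = "NA" if profile.se is None or np.isnan(profile.se[i]) else f"{profile.se[i]:.6f}"
        lines.append(f"{r}\t{val}\t{se}\t{profile.n_pairs[i]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, fixed float repr)."""

    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def write_annotations(ens: ConformationEnsemble, out_dir, labels=None,
                      motifs=None, profiles=None) -> None:
    """Write ensemble + analysis products into a directory of fixed filenames.

    Products must match the ensemble dimensions; output files are
    byte-identical across runs for identical inputs.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_dihedral_table(ens, os.path.join(out_dir, "dihedrals.tsv"))
    if labels is not None:
        if labels.labels.shape != ens.phi.shape:
            raise EnsembleError(
                f"label shape {labels.labels.shape} != ensemble shape {ens.phi.shape}"
            )
        write_labels(labels, os.path.join(out_dir, "regions.tsv"))
    if motifs is not None:
        for m in motifs:
            if m.conformation >= ens.n_conformations or m.end >= ens.n_residues:
                raise EnsembleError("motif instance outside ensemble dimensions")
        write_motifs(motifs, os.path.join(out_dir, "motifs.tsv"))
    if profiles is not None:
        for key, prof in sorted(profiles.items()):
            write_profile(prof, os.path.join(out_dir, f"profile_{key}.tsv"))
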