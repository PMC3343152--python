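"""Hydrogen-bond detection, DSSP-subset secondary structure, and motif finding.

The DSSP subset implemented here covers n-turns (3-, 4-, 5-turns giving
G/H/I helix codes by the two-consecutive-turn rule), hydrogen-bonded
turns (T), geometrical bends (S), beta bridges and ladders (B/E), and
coil (C).  Backbone amide hydrogens are placed geometrically and
hydrogen bonds assigned by the Kabsch-Sander electrostatic energy with
the conventional -0.5 kcal/mol cutoff.

On top of the DSSP codes, bespoke motifs used to characterize
polyglutamine ensembles are detected: isolated beta / alpha-tilde
(alternating alphaR-alphaL) / PPII strands, beta and alpha-tilde
hairpins, helix segments and typed turns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ensemble_io import ConformationEnsemble
from .rama_regions import (ALPHA_L, ALPHA_R, BETA, MISSING_LABEL, PPII,
                           RegionLabelMatrix)

logger = logging.getLogger(__name__)

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_FACTOR = 0.084 * 332.0  # kcal/mol * angstrom
_MIN_DIST = 0.5  # angstrom; singular-distance cap

HELIX_CODES = frozenset("HGI")


@dataclass(frozen=True)
class HBond:
    """Backbone hydrogen bond: N-H of ``donor`` to C=O of ``acceptor``."""

    donor: int
    acceptor: int
    energy: float


@dataclass(frozen=True)
class MotifInstance:
    """A detected secondary-structure element (residue indices 0-based)."""

    type: str
    conformation: int
    start: int
    end: int
    isolated: bool | None = None
    min_len_variant: int = 3

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# geometry


def place_backbone_hydrogen(coords, residue_names) -> np.ndarray:
    """Amide H positions for one conformation, (n_res, 3); NaN where absent.

    DSSP convention: H sits 1.0 A from N along the unit vector opposite
    the preceding C=O bond.  The first residue and prolines carry no
    amide hydrogen.
    """
    coords = np.asarray(coords, dtype=float)
    n_res = coords.shape[0]
    H = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        if residue_names[i] == "PRO":
            continue
        C_prev = coords[i - 1, 2]
        O_prev = coords[i - 1, 3]
        if np.isnan(O_prev).any() or np.isnan(C_prev).any():
            continue
        d = C_prev - O_prev
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        H[i] = coords[i, 0] + d / norm
    return H


def kabsch_sander_energy(n_pos, h_pos, c_pos, o_pos) -> tuple[float, bool]:
    """Kabsch-Sander electrostatic H-bond energy, kcal/mol.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN).  Distances
    below 0.5 A are capped (the pair is flagged and never counts as a
    bond).  Returns (energy, capped).
    """
    r_on = np.linalg.norm(o_pos - n_pos)
    r_ch = np.linalg.norm(c_pos - h_pos)
    r_oh = np.linalg.norm(o_pos - h_pos)
    r_cn = np.linalg.norm(c_pos - n_pos)
    capped = min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST
    r_on, r_ch, r_oh, r_cn = (max(r, _MIN_DIST) for r in (r_on, r_ch, r_oh, r_cn))
    e = _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(e), bool(capped)


def reconstruct_oxygens(coords) -> np.ndarray:
    """Fill missing carbonyl O atoms with ideal in-plane geometry.

    O is placed 1.231 A from C, opposite the CA/N(i+1) bisector in the
    CA-C-N plane; the C-terminal residue uses the chain direction in
    place of the absent next N.
    """
    coords = np.asarray(coords, dtype=float).copy()
    n_res = coords.shape[0]
    for i in range(n_res):
        if not np.isnan(coords[i, 3]).any():
            continue
        CA, C = coords[i, 1], coords[i, 2]
        if i + 1 < n_res:
            N_next = coords[i + 1, 0]
        else:
            N_next = C + (C - CA)  # extend along the last CA->C direction
        u1 = (N_next - C) / np.linalg.norm(N_next - C)
        u2 = (CA - C) / np.linalg.norm(CA - C)
        b = u1 + u2
        coords[i, 3] = C - 1.231 * b / np.linalg.norm(b)
    return coords


# ---------------------------------------------------------------------------
# H-bond detection and DSSP-subset assignment


def find_hbonds(coords, residue_names) -> list[HBond]:
    """All backbone H-bonds (energy < cutoff, |donor - acceptor| >= 2)."""
    coords = np.asarray(coords, dtype=float)
    if np.isnan(coords[:, 3]).any():
        logger.debug("reconstructing missing O atoms with ideal geometry")
        coords = reconstruct_oxygens(coords)
    H = place_backbone_hydrogen(coords, residue_names)
    n_res = coords.shape[0]
    bonds = []
    for donor in range(n_res):
        if np.isnan(H[donor]).any():
            continue
        for acceptor in range(n_res):
            if abs(donor - acceptor) < 2:
                continue
            e, capped = kabsch_sander_energy(
                coords[donor, 0], H[donor], coords[acceptor, 2], coords[acceptor, 3]
            )
            if not capped and e < HB_ENERGY_CUTOFF:
                bonds.append(HBond(donor=donor, acceptor=acceptor, energy=e))
    return bonds


def _hbond_set(bonds) -> set[tuple[int, int]]:
    """(acceptor, donor) pairs: CO of i accepts NH of j -> (i, j)."""
    return {(b.acceptor, b.donor) for b in bonds}


def assign_ss_single(coords, residue_names) -> tuple[str, list[HBond]]:
    """DSSP-subset codes for one conformation.

    Codes: H (alpha helix), G (3-10 helix), I (pi helix), E (ladder),
    B (isolated bridge), T (H-bonded turn), S (bend), C (coil).
    Priority where candidates overlap: H > E > I > G > B > T > S > C.
    """
    coords = np.asarray(coords, dtype=float)
    n_res = coords.shape[0]
    bonds = find_hbonds(coords, residue_names)
    hb = _hbond_set(bonds)

    # n-turns: CO(i) -- HN(i+n)
    turns = {n: {i for i in range(n_res) if (i, i + n) in hb} for n in (3, 4, 5)}

    helix = {"G": set(), "H": set(), "I": set()}
    for code, n in (("G", 3), ("H", 4), ("I", 5)):
        for i in range(1, n_res):
            if (i in turns[n]) and (i - 1 in turns[n]):
                helix[code].update(range(i, i + n))

    # bridges (Kabsch-Sander patterns); require |i-j| >= 3
    parallel = set()
    antiparallel = set()
    for i in range(n_res):
        for j in range(n_res):
            if abs(i - j) < 3:
                continue
            if ((i - 1, j) in hb and (j, i + 1) in hb) or (
                (j - 1, i) in hb and (i, j + 1) in hb
            ):
                parallel.add((min(i, j), max(i, j)))
            if ((i, j) in hb and (j, i) in hb) or (
                (i - 1, j + 1) in hb and (j - 1, i + 1) in hb
            ):
                antiparallel.add((min(i, j), max(i, j)))
    bridges = parallel | antiparallel
    # ladders: bridges (i,j) and (i+1, j +/- 1) of the same type connect
    ladder_residues = set()
    bridge_residues = set()
    for (i, j) in bridges:
        extended = False
        for bset in (parallel, antiparallel):
            if (i, j) not in bset:
                continue
            for di, dj in ((1, 1), (1, -1), (-1, -1), (-1, 1)):
                pair = (min(i + di, j + dj), max(i + di, j + dj))
                if pair != (i, j) and pair in bset:
                    extended = True
        (ladder_residues if extended else bridge_residues).update((i, j))

    # turn residues: i+1 .. i+n-1 of each n-turn
    turn_residues = set()
    for n, starts in turns.items():
        for i in starts:
            turn_residues.update(range(i + 1, min(i + n, n_res)))

    # bends: CA direction change over i-2, i, i+2 exceeding 70 degrees
    bend_residues = set()
    CA = coords[:, 1]
    for i in range(2, n_res - 2):
        v1 = CA[i] - CA[i - 2]
        v2 = CA[i + 2] - CA[i]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        ang = np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)))
        if ang > 70.0:
            bend_residues.add(i)

    codes = []
    for i in range(n_res):
        if i in helix["H"]:
            codes.append("H")
        elif i in ladder_residues:
            codes.append("E")
        elif i in helix["I"]:
            codes.append("I")
        elif i in helix["G"]:
            codes.append("G")
        elif i in bridge_residues:
            codes.append("B")
        elif i in turn_residues:
            codes.append("T")
        elif i in bend_residues:
            codes.append("S")
        else:
            codes.append("C")
    # priority overwrites can truncate a G/I stretch below its minimum
    # length; demote those remnants to turn so run-length invariants hold
    for code, min_len in (("G", 3), ("I", 5)):
        for st, en in _runs([c == code for c in codes]):
            if en - st + 1 < min_len:
                for i in range(st, en + 1):
                    codes[i] = "T" if i in turn_residues else (
                        "S" if i in bend_residues else "C")
    return "".join(codes), bonds


def assign_ss(ens: ConformationEnsemble) -> tuple[list[str], list[list[HBond]]]:
    """DSSP-subset strings and H-bond lists for every conformation."""
    if ens.coords is None:
        raise ValueError("secondary-structure assignment requires coordinates")
    ss, hbonds = [], []
    for c in range(ens.n_conformations):
        s, b = assign_ss_single(ens.coords[c], ens.residue_names)
        ss.append(s)
        hbonds.append(b)
    return ss, hbonds


# ---------------------------------------------------------------------------
# helix segments and turns


def _runs(flags):
    """Maximal runs of True as (start, end) inclusive."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def helix_segment_stats(ss_strings, residue_names,
                        long_lengths=(7, 9)) -> dict:
    """Helical content and segment statistics over an SS ensemble.

    Content percentages are over glutamine residues; a helical segment
    is a maximal run of helix codes (H/G/I).  Reports the distribution
    of per-conformation segment counts and the percentage of
    conformations owning a segment of at least L residues for each L in
    ``long_lengths``.
    """
    gln = np.array([r == "GLN" for r in residue_names])
    n_gln = int(gln.sum())
    n_conf = len(ss_strings)
    alpha = three_ten = 0
    seg_counts = []
    seg_lengths = []
    long_hits = {L: 0 for L in long_lengths}
    for s in ss_strings:
        arr = np.array(list(s))
        alpha += int(((arr == "H") & gln).sum())
        three_ten += int(((arr == "G") & gln).sum())
        runs = _runs([c in HELIX_CODES for c in s])
        seg_counts.append(len(runs))
        seg_lengths.extend(e - st + 1 for st, e in runs)
        for L in long_lengths:
            if any(e - st + 1 >= L for st, e in runs):
                long_hits[L] += 1
    total = n_conf * n_gln
    count_dist = {}
    for c in seg_counts:
        count_dist[c] = count_dist.get(c, 0) + 1
    return {
        "alpha_content": 100.0 * alpha / total if total else 0.0,
        "three_ten_content": 100.0 * three_ten / total if total else 0.0,
        "segment_count_distribution": {
            k: 100.0 * v / n_conf for k, v in sorted(count_dist.items())
        },
        "segment_lengths": seg_lengths,
        "long_segment_percent": {
            L: 100.0 * h / n_conf for L, h in long_hits.items()
        },
    }


def classify_turns(ss_strings, hbond_lists, labels: RegionLabelMatrix) -> dict:
    """Turn typing from H-bonds plus Ramachandran labels.

    An i -> i+3 hydrogen bond defines a beta-turn whose middle residues
    are i+1 and i+2; both middle residues in alphaR makes it type I-beta,
    anything else counts as "other beta".  An i -> i+2 bond is a
    gamma-turn.  S-coded residues without a turn H-bond are bends.
    Percentages are over glutamine residues and conformations.
    """
    gln = np.array([r == "GLN" for r in labels.residue_names]) \
        if labels.residue_names else np.ones(labels.n_residues, dtype=bool)
    n_conf = len(ss_strings)
    n_gln = int(gln.sum())
    total = n_conf * n_gln
    i_beta = other_beta = gamma = 0
    hbonded_turn_res = 0
    bend_res = 0
    turns = []
    for c, (s, bonds) in enumerate(zip(ss_strings, hbond_lists)):
        hb = _hbond_set(bonds)
        in_turn = set()
        for (acc, don) in hb:
            if don - acc == 3:
                mids = (acc + 1, acc + 2)
                mid_labels = labels.labels[c, list(mids)]
                kind = "I-beta" if np.all(mid_labels == ALPHA_R) else "other-beta"
                if kind == "I-beta":
                    i_beta += 1
                else:
                    other_beta += 1
                turns.append({"conformation": c, "start": acc, "kind": kind})
                in_turn.update(range(acc, don + 1))
            elif don - acc == 2:
                gamma += 1
                turns.append({"conformation": c, "start": acc, "kind": "gamma"})
                in_turn.update(range(acc, don + 1))
        for i, code in enumerate(s):
            if not gln[i]:
                continue
            if code == "T" or (i in in_turn and code in "TS"):
                hbonded_turn_res += 1
            elif code == "S":
                bend_res += 1
    return {
        "turns": turns,
        "i_beta_percent": 100.0 * i_beta / n_conf if n_conf else 0.0,
        "other_beta_percent": 100.0 * other_beta / n_conf if n_conf else 0.0,
        "gamma_percent": 100.0 * gamma / n_conf if n_conf else 0.0,
        "hbonded_turn_content": 100.0 * hbonded_turn_res / total if total else 0.0,
        "bend_content": 100.0 * bend_res / total if total else 0.0,
    }


# ---------------------------------------------------------------------------
# strand / hairpin motifs

_STRAND_KIND = {
    "beta": ("beta_strand", frozenset({BETA})),
    "alpha_tilde": ("alpha_tilde_strand", frozenset({ALPHA_R, ALPHA_L})),
    "ppii": ("ppii_run", frozenset({PPII})),
}


def _strand_runs(row, kind):
    """Maximal runs satisfying the strand pattern in one label row."""
    n = len(row)
    runs = []
    if kind in ("beta", "ppii"):
        target = BETA if kind == "beta" else PPII
        runs = _runs([lab == target for lab in row])
    else:  # alpha_tilde: strict alternation of alphaR/alphaL, either phase
        i = 0
        while i < n:
            if row[i] not in (ALPHA_R, ALPHA_L):
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and row[j + 1] in (ALPHA_R, ALPHA_L)
                and row[j + 1] != row[j]
            ):
                j += 1
            if j > i:
                runs.append((i, j))
            i = j + 1
    return runs


def detect_strands(labels: RegionLabelMatrix, hbond_lists=None,
                   kind: str = "beta", min_len: int = 3) -> list[MotifInstance]:
    """Maximal strand runs of the given kind with length >= min_len.

    ``isolated`` is True iff no residue of the run takes part in any
    backbone H-bond; None when H-bonds are unavailable.
    """
    if kind not in _STRAND_KIND:
        raise ValueError(f"unknown strand kind {kind!r}")
    motif_type, _ = _STRAND_KIND[kind]
    out = []
    for c in range(labels.n_conformations):
        row = labels.labels[c]
        bonded = None
        if hbond_lists is not None:
            bonded = set()
            for b in hbond_lists[c]:
                bonded.add(b.donor)
                bonded.add(b.acceptor)
        for (st, en) in _strand_runs(row, kind):
            if en - st + 1 < min_len:
                continue
            isolated = None
            if bonded is not None:
                isolated = all(i not in bonded for i in range(st, en + 1))
            out.append(
                MotifInstance(motif_type, c, st, en, isolated, min_len)
            )
    return out


def detect_hairpins(labels: RegionLabelMatrix, ss_strings, hbond_lists,
                    kind: str = "beta", min_len: int = 3,
                    max_loop: int = 8) -> list[MotifInstance]:
    """Hairpins: two adjacent strands joined by a turn-shaped connector.

    Two strand runs of the given kind (each >= min_len residues),
    separated only by a connector of 1..max_loop residues containing at
    least one turn/bend-coded residue (T or S), with at least one H-bond
    linking a region-labeled residue of one strand to a region-labeled
    residue of the other.
    """
    if kind not in ("beta", "alpha_tilde"):
        raise ValueError(f"unknown hairpin kind {kind!r}")
    motif_type = "beta_hairpin" if kind == "beta" else "alpha_tilde_hairpin"
    _, region_set = _STRAND_KIND[kind]
    out = []
    for c in range(labels.n_conformations):
        row = labels.labels[c]
        runs = [r for r in _strand_runs(row, kind) if r[1] - r[0] + 1 >= min_len]
        hb_pairs = {(b.donor, b.acceptor) for b in hbond_lists[c]}
        hb_pairs |= {(b, a) for a, b in hb_pairs}
        s = ss_strings[c]
        for (a_start, a_end), (b_start, b_end) in zip(runs, runs[1:]):
            loop = range(a_end + 1, b_start)
            if not (1 <= len(loop) <= max_loop):
                continue
            if not any(s[i] in "TS" for i in loop):
                continue
            strand_a = [i for i in range(a_start, a_end + 1) if row[i] in region_set]
            strand_b = [i for i in range(b_start, b_end + 1) if row[i] in region_set]
            if any((i, j) in hb_pairs for i in strand_a for j in strand_b):
                out.append(MotifInstance(motif_type, c, a_start, b_end, False, min_len))
    return out


def motif_prevalence(instances, ens: ConformationEnsemble) -> dict:
    """Percentage of conformations with >= 1 instance, per type and variant.

    Only instances whose span lies entirely within the glutamine portion
    of the chain are counted (proline-segment residues excluded).
    """
    gln = ens.gln_mask()
    hits = {}
    for m in instances:
        if not gln[m.start:m.end + 1].all():
            continue
        key = (m.type, m.min_len_variant)
        hits.setdefault(key, set()).add(m.conformation)
    return {
        key: 100.0 * len(confs) / ens.n_conformations
        for key, confs in sorted(hits.items())
    }
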