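"""Odds-ratio correlation statistics over binary residue properties.

For two binary residue properties X, Y observed over an ensemble, the
odds ratio OR = (p00*p11)/(p01*p10) measures their association; mapping
through free-energy language, score = k_B*T*ln(OR) is a
difference-of-differences of free energies (kcal/mol), with asymptotic
standard error k_B*T*sqrt(1/n00 + 1/n01 + 1/n10 + 1/n11).  Profiles of
the score against sequence distance r — over region membership or
alpha-tilde-repeat membership, with end residues trimmed to suppress
end effects — characterize the correlation range, its oscillation
period, and whether a long-range component persists.

A linear Pearson correlation profile of (shifted, wrapped) psi angles
provides an independent cross-check of the odds-ratio profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .ensemble_io import ConformationEnsemble, wrap_angle
from .rama_regions import MISSING_LABEL, REGION_NAMES, RegionLabelMatrix

logger = logging.getLogger(__name__)

KB = 0.0019872  # kcal/mol/K
DEFAULT_TEMPERATURE = 300.0  # K

#: mask code for cells excluded from contingency counts
EXCLUDED = -1


class ZeroCellError(ValueError):
    """A contingency cell is zero and no continuity correction was requested."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for a pair of binary properties."""

    n00: float
    n01: float
    n10: float
    n11: float

    @property
    def total(self) -> float:
        return self.n00 + self.n01 + self.n10 + self.n11

    def cells(self):
        return (self.n00, self.n01, self.n10, self.n11)

    def corrected(self) -> "ContingencyTable":
        """Haldane-Anscombe continuity correction: +0.5 to every cell."""
        return ContingencyTable(*(c + 0.5 for c in self.cells()))

    def has_zero(self) -> bool:
        return any(c == 0 for c in self.cells())


def odds_ratio(table: ContingencyTable, correction: bool = False):
    """OR = (n00*n11)/(n01*n10); returns (value, corrected_flag).

    With ``correction`` and any zero cell, the Haldane-Anscombe +0.5 is
    applied to all cells.  Without correction a zero denominator yields
    inf, a zero numerator 0.0.
    """
    if table.total < 1:
        raise ValueError("empty contingency table")
    corrected = False
    if correction and table.has_zero():
        table = table.corrected()
        corrected = True
    num = table.n00 * table.n11
    den = table.n01 * table.n10
    if den == 0:
        return (np.inf if num > 0 else np.nan), corrected
    return num / den, corrected


def delta_delta_g(table: ContingencyTable,
                  temperature: float = DEFAULT_TEMPERATURE,
                  correction: bool = True) -> tuple[float, float, bool]:
    """Free-energy association score and its asymptotic standard error.

    score = k_B*T*ln(OR) (positive = positive association);
    se = k_B*T*sqrt(sum of reciprocal cell counts).  Zero cells require
    the continuity correction; otherwise an error names the cell.
    Returns (score, se, corrected_flag).
    """
    corrected = False
    if table.has_zero():
        if not correction:
            names = ("n00", "n01", "n10", "n11")
            zero = [n for n, c in zip(names, table.cells()) if c == 0]
            raise ZeroCellError(f"zero contingency cell(s) {zero}; enable correction")
        table = table.corrected()
        corrected = True
    kbt = KB * temperature
    or_value, _ = odds_ratio(table, correction=False)
    score = kbt * np.log(or_value)
    se = kbt * np.sqrt(sum(1.0 / c for c in table.cells()))
    return float(score), float(se), corrected


@dataclass
class CorrelationProfile:
    """Association score (or Pearson r) against sequence distance."""

    r: np.ndarray                 # distances, strictly increasing, >= 1
    value: np.ndarray             # kcal/mol (odds-ratio kinds) or Pearson r
    se: np.ndarray | None         # kcal/mol; None for Pearson profiles
    n_pairs: np.ndarray           # contributing (pair, conformation) counts
    statistic_kind: str           # or_region | or_alpha_tilde | pearson_psi
    region: str | None = None
    trim: int = 0
    corrected: np.ndarray | None = None  # continuity correction applied at r


def default_trim(n_residues: int) -> int:
    """End-residue trimming: 5 per end for chains >= 30 residues, else 2."""
    return 5 if n_residues >= 30 else 2


def region_mask(labels: RegionLabelMatrix, region: str) -> np.ndarray:
    """Binary membership mask for one region; EXCLUDED where undefined."""
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region {region!r}; expected one of {REGION_NAMES}")
    code = REGION_NAMES.index(region)
    mat = labels.labels
    mask = np.where(mat == code, 1, 0).astype(np.int8)
    mask[mat == MISSING_LABEL] = EXCLUDED
    return mask


def _pooled_table(x, y) -> ContingencyTable:
    """Counts over paired binary columns, EXCLUDED cells dropped."""
    ok = (x != EXCLUDED) & (y != EXCLUDED)
    x, y = x[ok], y[ok]
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return ContingencyTable(n00, n01, n10, n11)


def or_profile(mask: np.ndarray, r_max: int | None = None,
               trim: int | None = None, pooling: str = "pooled",
               temperature: float = DEFAULT_TEMPERATURE,
               correction: bool = True, residue_columns=None,
               statistic_kind: str = "or_region",
               region: str | None = None) -> CorrelationProfile:
    """Odds-ratio score profile against sequence distance.

    mask : (n_conformations, n_residues) int array of 0/1 with EXCLUDED
        (-1) for cells to skip.
    residue_columns : optional boolean array restricting eligible columns
        (e.g. glutamine residues only).
    pooling : "pooled" sums one 2x2 table over all pairs (i, i+r) and
        conformations; "per_pair" inverse-variance-averages per-pair
        scores.
    Pairs must have both residues inside [trim, n_residues - trim - 1].
    """
    mask = np.asarray(mask)
    n_conf, n_res = mask.shape
    if trim is None:
        trim = default_trim(n_res)
    if trim >= n_res / 2:
        raise ValueError(f"trim={trim} leaves no residues on a {n_res}-residue chain")
    if pooling not in ("pooled", "per_pair"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    eligible = np.zeros(n_res, dtype=bool)
    eligible[trim:n_res - trim] = True
    if residue_columns is not None:
        eligible &= np.asarray(residue_columns, dtype=bool)
    if r_max is None:
        r_max = n_res - 2 * trim - 1
    rs, values, ses, n_pairs_list, corrected_flags = [], [], [], [], []
    for r in range(1, r_max + 1):
        cols = [i for i in range(n_res - r) if eligible[i] and eligible[i + r]]
        if not cols:
            logger.debug("profile truncated at r=%d (no eligible pairs)", r)
            break
        if pooling == "pooled":
            x = mask[:, cols].ravel()
            y = mask[:, [i + r for i in cols]].ravel()
            table = _pooled_table(x, y)
            if table.total == 0:
                break
            score, se, corr_flag = delta_delta_g(table, temperature, correction)
        else:
            scores, weights = [], []
            corr_flag = False
            for i in cols:
                t = _pooled_table(mask[:, i], mask[:, i + r])
                if t.total == 0:
                    continue
                s, e, cf = delta_delta_g(t, temperature, correction)
                corr_flag = corr_flag or cf
                if e > 0 and np.isfinite(s):
                    scores.append(s)
                    weights.append(1.0 / e**2)
            if not scores:
                break
            w = np.array(weights)
            score = float(np.sum(w * np.array(scores)) / w.sum())
            se = float(np.sqrt(1.0 / w.sum()))
            table = None
        rs.append(r)
        values.append(score)
        ses.append(se)
        n_pairs_list.append(len(cols) * n_conf)
        corrected_flags.append(corr_flag)
    return CorrelationProfile(
        r=np.array(rs), value=np.array(values), se=np.array(ses),
        n_pairs=np.array(n_pairs_list), statistic_kind=statistic_kind,
        region=region, trim=trim, corrected=np.array(corrected_flags),
    )


def pearson_psi_profile(ens: ConformationEnsemble, shift_deg: float = 100.0,
                        r_max: int | None = None, trim: int | None = None,
                        residue_columns=None) -> CorrelationProfile:
    """Pearson correlation of shifted psi angles against sequence distance.

    psi' = wrap(psi + shift_deg); the default +100 deg shift moves the
    wrap seam into the sparsely populated psi band between the alphaL
    and PPII basins so that the linear statistic is meaningful on
    circular data.
    """
    psi = ens.psi
    n_conf, n_res = psi.shape
    if trim is None:
        trim = default_trim(n_res)
    eligible = np.zeros(n_res, dtype=bool)
    eligible[trim:n_res - trim] = True
    if residue_columns is not None:
        eligible &= np.asarray(residue_columns, dtype=bool)
    else:
        eligible &= ens.gln_mask()
    if r_max is None:
        r_max = n_res - 2 * trim - 1
    shifted = np.where(np.isnan(psi), np.nan, wrap_angle(psi + shift_deg))
    rs, values, n_pairs_list = [], [], []
    for r in range(1, r_max + 1):
        cols = [i for i in range(n_res - r) if eligible[i] and eligible[i + r]]
        if not cols:
            break
        x = shifted[:, cols].ravel()
        y = shifted[:, [i + r for i in cols]].ravel()
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(x, y)[0, 1])
        rs.append(r)
        values.append(corr)
        n_pairs_list.append(int(x.size))
    return CorrelationProfile(
        r=np.array(rs), value=np.array(values), se=None,
        n_pairs=np.array(n_pairs_list), statistic_kind="pearson_psi",
        trim=trim,
    )


def profile_similarity(p1: CorrelationProfile, p2: CorrelationProfile) -> float:
    """Pearson correlation of two profiles over their shared r grid."""
    shared = np.intersect1d(p1.r, p2.r)
    v1 = p1.value[np.isin(p1.r, shared)]
    v2 = p2.value[np.isin(p2.r, shared)]
    ok = ~(np.isnan(v1) | np.isnan(v2))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared finite points between profiles")
    return float(np.corrcoef(v1[ok], v2[ok])[0, 1])


def dominant_period(profile: CorrelationProfile, r_min: int = 1,
                    oversample: int = 4) -> tuple[float, float]:
    """Dominant oscillation period of a profile, in residues.

    The profile value over r >= r_min is linearly detrended, then a
    zero-padded (``oversample``-fold) periodogram is taken; returns the
    argmax period within [3, r_span/2] and its fraction of total power.
    """
    sel = profile.r >= r_min
    r = profile.r[sel]
    v = profile.value[sel]
    ok = np.isfinite(v)
    r, v = r[ok], v[ok]
    if r.size < 2 * max(r_min, 2):
        raise ValueError("profile too short for period estimation")
    slope, intercept = np.polyfit(r, v, 1)
    resid = v - (slope * r + intercept)
    n = resid.size
    n_fft = oversample * n
    power = np.abs(np.fft.rfft(resid, n=n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0)
    total = power[1:].sum()
    if total <= 1e-18 * max(float(np.sum(v**2)), 1.0):
        return float(r.max()), 0.0  # residuals are numerically zero
    span = r.max() - r.min() + 1
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    in_band = (periods >= 3.0) & (periods <= span / 2.0)
    if not in_band.any():
        return float(span), 0.0
    band_power = np.where(in_band, power, 0.0)
    best = int(np.argmax(band_power))
    # main lobe: one fundamental-resolution width (= oversample bins each
    # side) around the peak, so leakage from the zero-padding is included
    lo = max(best - oversample, 1)
    hi = min(best + oversample + 1, power.size)
    fraction = float(power[lo:hi].sum() / total)
    return float(periods[best]), min(fraction, 1.0)


def long_range_flag(profile: CorrelationProfile,
                    r_tail: int = 10) -> tuple[bool, float, float]:
    """Diagnose a persistent positive tail in an association profile.

    Returns (flag, tail_mean, threshold) where the tail is r >= r_tail
    and the threshold is twice the mean standard error over the tail;
    the flag is True iff tail_mean exceeds the threshold.
    """
    sel = profile.r >= r_tail
    if not sel.any():
        raise ValueError(f"profile does not extend beyond r_tail={r_tail}")
    tail = profile.value[sel]
    ok = np.isfinite(tail)
    tail_mean = float(np.mean(tail[ok]))
    if profile.se is not None:
        se_tail = profile.se[sel][ok]
        threshold = float(2.0 * np.mean(se_tail))
    else:
        threshold = float(2.0 * np.std(tail[ok]) / max(np.sqrt(ok.sum()), 1.0))
    return tail_mean > threshold, tail_mean, threshold
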